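"""Passive membrane properties from -5 mV voltage-clamp test pulses.

The cell is modelled as a series (access) resistance Rs into a parallel
Rm-Cm membrane.  For a voltage step dV from holding, the clamp current jumps
instantaneously by dV/Rs, then relaxes exponentially with

    tau = Cm * Rs * Rm / (Rs + Rm)

to the steady state dV/(Rs + Rm).  The estimator therefore reads

    Rs      = dV / dI_peak
    R_input = dV / dI_ss
    Rm      = R_input - Rs
    Cm      = tau * (Rs + Rm) / (Rs * Rm)

with dI_peak the baseline-subtracted peak located within 1 ms of pulse
onset, dI_ss the mean over the final 25% of the pulse, and tau from a
single-exponential least-squares fit of the decay from peak to pulse end.

Unit note: with mV and pA, resistances come out in GOhm; they are converted
to the package's MOhm at the interface.  MOhm * pF = microseconds, so the
time-constant identity carries a factor 1e-3 when R is in MOhm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .recordings import DetectionConfig, Sweep
from .spikes import detect_spikes

__all__ = [
    "PassiveProperties",
    "StabilityReport",
    "FitFailureError",
    "fit_test_pulse",
    "measure_resting_potential",
    "average_checkpoints",
    "check_stability",
]


class FitFailureError(RuntimeError):
    """Exponential fit of the test-pulse transient failed to converge."""


class OpenCircuitError(RuntimeError):
    """Steady-state current indistinguishable from zero: no resistive path."""


class ContaminatedBaselineError(ValueError):
    """Spikes detected inside a segment that must be spike-free."""


@dataclass
class PassiveProperties:
    series_resistance: float = np.nan  # MOhm
    input_resistance: float = np.nan  # MOhm (= Rs + Rm)
    membrane_resistance: float = np.nan  # MOhm
    capacitance: float = np.nan  # pF
    resting_potential: float = np.nan  # mV
    timepoint_index: int = 0

    _NUMERIC = (
        "series_resistance",
        "input_resistance",
        "membrane_resistance",
        "capacitance",
        "resting_potential",
    )


@dataclass
class StabilityReport:
    series_resistance_cv: float
    resting_potential_range: float
    passed: bool
    tolerance_used: tuple[float, float]  # (Rs CV fraction, resting range mV)


def fit_test_pulse(
    sweep: Sweep,
    peak_search_ms: float = 1.0,
    steady_fraction: float = 0.25,
    timepoint_index: int = 0,
) -> PassiveProperties:
    """Estimate (Rs, R_input, Rm, Cm) from a small voltage test pulse.

    The sweep must be a voltage-clamp current trace whose epoch is the test
    pulse (amplitude in mV relative to holding, canonically -5 mV), with at
    least 5 ms of pre-pulse baseline.  Resting potential is left unset.
    """
    if sweep.mode != "voltage_clamp":
        raise ValueError("test-pulse fitting requires a voltage-clamp sweep")
    dv = sweep.epoch.amplitude
    if dv == 0:
        raise ValueError("test pulse amplitude must be nonzero")
    dt = sweep.dt
    on_i = int(round(sweep.epoch.onset_time / dt))
    off_i = int(round(sweep.epoch.offset_time / dt))
    if on_i * dt < 5.0:
        raise ValueError("need >= 5 ms of pre-pulse baseline")
    i_trace = sweep.samples

    baseline = float(np.mean(i_trace[:on_i]))
    rel = i_trace - baseline

    # steady state: final 25% of the pulse
    ss_start = off_i - max(int(round(steady_fraction * (off_i - on_i))), 1)
    d_iss = float(np.mean(rel[ss_start:off_i]))
    if abs(d_iss) < 1e-9:
        raise OpenCircuitError("steady-state current ~ 0; no resistive pathway to fit")

    # peak within 1 ms of pulse onset, polarity matching the step
    pk_end = min(on_i + max(int(round(peak_search_ms / dt)), 1) + 1, off_i)
    seg = rel[on_i:pk_end]
    pk_off = int(np.argmin(seg)) if dv < 0 else int(np.argmax(seg))
    pk_i = on_i + pk_off
    d_ipk = float(rel[pk_i])

    r_series_g = dv / d_ipk  # GOhm (mV / pA)
    r_input_g = dv / d_iss
    if not (r_input_g > 0 and r_series_g > 0):
        raise FitFailureError("non-physical resistance signs; check trace polarity")
    r_mem_g = r_input_g - r_series_g

    if r_mem_g <= 0:
        # purely resistive cell: no transient, Rs at the fit floor
        return PassiveProperties(
            series_resistance=r_series_g * 1e3,
            input_resistance=r_input_g * 1e3,
            membrane_resistance=max(r_mem_g, 0.0) * 1e3,
            capacitance=0.0,
            timepoint_index=timepoint_index,
        )

    # single-exponential fit of the decay, steady level pinned to d_iss
    t_fit = (np.arange(pk_i, off_i) - pk_i) * dt
    y_fit = rel[pk_i:off_i]
    a0 = d_ipk - d_iss
    tau0 = max((r_series_g * r_mem_g / (r_input_g)) * 100.0, 5 * dt)  # rough Cm≈100 pF guess

    def decay(t, a, tau):
        return d_iss + a * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(
            decay, t_fit, y_fit, p0=(a0, tau0), maxfev=10000,
            bounds=([-np.inf, dt / 10.0], [np.inf, np.inf]),
        )
    except (RuntimeError, ValueError) as exc:
        resid = float(np.linalg.norm(y_fit - decay(t_fit, a0, tau0)))
        raise FitFailureError(f"transient fit did not converge (residual norm {resid:.3g})") from exc
    tau = float(popt[1])  # ms

    # Cm from tau = Cm * (Rs*Rm)/(Rs+Rm); with R in GOhm, GOhm*pF = ms
    c_m = tau * r_input_g / (r_series_g * r_mem_g)

    return PassiveProperties(
        series_resistance=r_series_g * 1e3,
        input_resistance=r_input_g * 1e3,
        membrane_resistance=r_mem_g * 1e3,
        capacitance=c_m,
        timepoint_index=timepoint_index,
    )


def measure_resting_potential(
    sweep: Sweep,
    baseline_window_ms: float = 200.0,
    cfg: DetectionConfig = DetectionConfig(),
) -> float:
    """Mean voltage over the pre-stimulus baseline at zero injected current.

    Raises when the available zero-current baseline is shorter than 100 ms or
    when the baseline contains detected spikes (spontaneous activity would
    bias the mean).
    """
    if sweep.mode != "current_clamp":
        raise ValueError("resting potential is a current-clamp measurement")
    dt = sweep.dt
    pre_ms = sweep.epoch.onset_time if sweep.epoch.amplitude != 0 else sweep.n_samples * dt
    if pre_ms < 100.0:
        raise ValueError(f"need >= 100 ms of zero-current baseline, have {pre_ms} ms")
    win_ms = min(baseline_window_ms, pre_ms)
    n = int(round(win_ms / dt))
    spikes = detect_spikes(sweep, cfg)
    if any(s.upcross_time < win_ms for s in spikes):
        raise ContaminatedBaselineError("spike detected inside the resting-potential baseline")
    return float(np.mean(sweep.samples[:n]))


def average_checkpoints(props: list[PassiveProperties]) -> PassiveProperties:
    """Field-wise arithmetic mean of passive-property checkpoints.

    Mirrors averaging each cell's metrics across the session time points
    (initial plus after each protocol).  Permutation-invariant; the mean of
    identical checkpoints is the checkpoint itself.
    """
    if not props:
        raise ValueError("cannot average an empty checkpoint list")
    out = PassiveProperties(timepoint_index=-1)
    for name in PassiveProperties._NUMERIC:
        vals = np.array([getattr(p, name) for p in props], dtype=float)
        setattr(out, name, float(np.mean(vals)))
    return out


def check_stability(
    props: list[PassiveProperties],
    rs_cv_tolerance: float = 0.20,
    resting_range_tolerance_mv: float = 5.0,
) -> StabilityReport:
    """Session-stability QC: consistent series resistance and resting potential.

    Passes iff the coefficient of variation of Rs across checkpoints is at
    most ``rs_cv_tolerance`` and the resting-potential range is at most
    ``resting_range_tolerance_mv``.
    """
    if len(props) < 2:
        raise ValueError("stability assessment needs >= 2 checkpoints")
    rs = np.array([p.series_resistance for p in props], dtype=float)
    vr = np.array([p.resting_potential for p in props], dtype=float)
    cv = float(np.std(rs, ddof=0) / np.mean(rs)) if np.mean(rs) != 0 else np.inf
    vr = vr[np.isfinite(vr)]
    vrange = float(np.ptp(vr)) if vr.size else 0.0
    passed = (cv <= rs_cv_tolerance) and (vrange <= resting_range_tolerance_mv)
    return StabilityReport(
        series_resistance_cv=cv,
        resting_potential_range=vrange,
        passed=passed,
        tolerance_used=(rs_cv_tolerance, resting_range_tolerance_mv),
    )
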