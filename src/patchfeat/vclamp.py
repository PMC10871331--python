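"""Voltage-clamp leak subtraction and current extraction.

The smallest negative step (-10 mV relative to holding) is taken as the best
measure of passive current through leak channels and pipette/membrane
capacitance.  Because a passive cell is linear, that trace scales ohmically
with the commanded voltage: the correction for a step of amplitude dV is

    corrected(t) = raw(t) - (dV / leak_amplitude) * leak(t)

applied sample-wise, after which the trace is zeroed on the pre-step
baseline current.  Early maximum inward/outward currents are read from the
first 10 ms after step onset; steady-state current is the mean over the last
third of the step.  Sign convention: inward current negative, outward
positive.  No space-clamp correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recordings import Recording, Sweep

__all__ = [
    "IVCurve",
    "MissingLeakSweepError",
    "leak_subtract",
    "zero_baseline",
    "early_peak_currents",
    "steady_state_current",
    "build_iv",
]


class MissingLeakSweepError(ValueError):
    """The sweep set contains no sweep at the leak-step amplitude."""


@dataclass
class IVCurve:
    cell_id: str
    step_amplitudes: np.ndarray  # mV relative to the -60 mV holding, ascending
    max_inward: np.ndarray  # pA, signed (negative)
    max_outward: np.ndarray  # pA, signed (positive)
    steady_state: np.ndarray  # pA


def leak_subtract(sweeps: list[Sweep], leak_amplitude: float = -10.0) -> list[Sweep]:
    """Ohmic leak subtraction of a voltage-clamp sweep set.

    Requires exactly one sweep at ``leak_amplitude`` and identical timing
    (dt, epoch onset, length) across sweeps.  The leak sweep itself corrects
    to zero.
    """
    leak_candidates = [s for s in sweeps if s.epoch.amplitude == leak_amplitude]
    if len(leak_candidates) == 0:
        raise MissingLeakSweepError(f"no sweep at the {leak_amplitude} mV leak step")
    if len(leak_candidates) > 1:
        raise ValueError(f"multiple sweeps at the {leak_amplitude} mV leak step")
    leak = leak_candidates[0]
    out = []
    for sw in sweeps:
        if sw.mode != "voltage_clamp":
            raise ValueError("leak subtraction applies to voltage-clamp sweeps")
        if sw.n_samples != leak.n_samples or sw.dt != leak.dt:
            raise ValueError("sweeps must share dt and length for sample-wise subtraction")
        if sw.epoch.onset_time != leak.epoch.onset_time:
            raise ValueError("sweeps must be time-aligned on epoch onset")
        scale = sw.epoch.amplitude / leak_amplitude
        out.append(sw.copy_with(samples=sw.samples - scale * leak.samples))
    return out


def zero_baseline(sweep: Sweep, baseline_window_ms: float | None = None) -> Sweep:
    """Zero a sweep on its pre-step baseline current.

    Subtracts the mean over the window ending at epoch onset (default: the
    whole pre-step segment).  Idempotent: re-zeroing a zeroed trace is a
    no-op up to floating-point round-off.
    """
    dt = sweep.dt
    on_i = int(round(sweep.epoch.onset_time / dt))
    if on_i < 1:
        raise ValueError("no pre-step segment to use as baseline")
    if baseline_window_ms is None:
        lo_i = 0
    else:
        n = int(round(baseline_window_ms / dt))
        if n < 1 or n > on_i:
            raise ValueError("baseline window must lie within the pre-step segment")
        lo_i = on_i - n
    mean = float(np.mean(sweep.samples[lo_i:on_i]))
    return sweep.copy_with(samples=sweep.samples - mean)


def early_peak_currents(sweep: Sweep, window_ms: float = 10.0) -> tuple[float, float]:
    """(max inward, max outward) current in the first 10 ms after step onset.

    The sweep is expected to be leak-subtracted and baseline-zeroed.  Inward
    is the signed minimum clipped at 0 from above (so a purely outward trace
    reports 0 inward) and outward the signed maximum clipped at 0 from below.
    """
    dt = sweep.dt
    on_i = int(round(sweep.epoch.onset_time / dt))
    end_ms = min(window_ms, sweep.epoch.duration)  # clipped-window behaviour
    end_i = on_i + int(round(end_ms / dt))
    seg = sweep.samples[on_i:end_i]
    if seg.size == 0:
        return 0.0, 0.0
    return float(min(seg.min(), 0.0)), float(max(seg.max(), 0.0))


def steady_state_current(sweep: Sweep) -> float:
    """Mean current over the last third of the voltage application."""
    dt = sweep.dt
    on_i = int(round(sweep.epoch.onset_time / dt))
    off_i = int(round(sweep.epoch.offset_time / dt))
    lo_i = on_i + int(round(2.0 / 3.0 * (off_i - on_i)))
    return float(np.mean(sweep.samples[lo_i:off_i]))


def build_iv(
    recording: Recording,
    leak_amplitude: float = -10.0,
    early_window_ms: float = 10.0,
) -> IVCurve:
    """Full voltage-clamp pipeline for one recording.

    leak_subtract -> zero_baseline -> early/steady extraction, per step,
    amplitudes ascending.  The leak step itself is reported too (its
    corrected trace is identically zero).
    """
    if recording.mode != "voltage_clamp":
        raise ValueError("I-V extraction requires a voltage-clamp recording")
    corrected = leak_subtract(recording.sweeps, leak_amplitude=leak_amplitude)
    corrected = [zero_baseline(sw) for sw in corrected]
    corrected.sort(key=lambda s: s.epoch.amplitude)
    amps, inward, outward, steady = [], [], [], []
    for sw in corrected:
        mi, mo = early_peak_currents(sw, window_ms=early_window_ms)
        amps.append(sw.epoch.amplitude)
        inward.append(mi)
        outward.append(mo)
        steady.append(steady_state_current(sw))
    return IVCurve(
        cell_id=recording.cell_id,
        step_amplitudes=np.asarray(amps),
        max_inward=np.asarray(inward),
        max_outward=np.asarray(outward),
        steady_state=np.asarray(steady),
    )
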