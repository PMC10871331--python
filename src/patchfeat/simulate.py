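"""Synthetic patch-clamp cohorts with exact ground truth.

The generator emulates the recording protocols the analysis pipeline
expects — current-clamp 20 pA steps from -100 to 480 pA repeated 5 times
(run from rest and from a -60 mV holding), voltage-clamp 10 mV steps from a
-60 mV holding, and -5 mV membrane test pulses — for four phenotype presets
(WT, Tau, WT_AR, Tau_AR) whose parameter shifts follow the qualitative
tauopathy phenotype: Tau cells have elevated membrane resistance, reduced
capacitance, a depolarized resting potential, reduced voltage-gated inward
and outward currents and a tendency to fire only a single spike; the
AR-treated Tau preset restores WT-like values.

Design: the spiking model is a leaky integrate-and-fire membrane with a
spike-triggered adaptation current; at each threshold crossing the exact
event time is recorded and an analytic piecewise-linear spike waveform is
pasted into the trace.  The waveform satisfies the slope/peak detection
criteria by construction and has closed-form amplitude and width, so
simulated recordings double as oracles: every ground-truth quantity
(membrane parameters, spike times, template peak currents) is known exactly
rather than itself estimated.

Voltage-gated currents in voltage clamp are phenomenological templates with
documented closed forms:

* passive: I = dV/(Rs+Rm) steady + (dV/Rs - dV/(Rs+Rm)) exp(-t/tau) capacitive
  transient, tau = Cm Rs Rm/(Rs+Rm) — linear in dV, so ohmic leak
  subtraction removes it exactly;
* inward (Na-like): -g_in * A_in * bell(V) * alpha((t-d_in)/tau_in), with
  alpha(x) = x e^(1-x) (unit peak at x=1) and bell(V) a Gaussian in absolute
  voltage centred near -20 mV;
* outward (K-like): g_out * sig(V) * [A_out_t * alpha((t-d_out)/tau_out)
  + A_out_s * (1 - e^(-t/tau_s))], sig a Boltzmann activation.

Determinism: a master seed is expanded into independent per-cell seeds with
``numpy.random.SeedSequence.spawn``, so cohorts are bit-reproducible across
platforms for a given (presets, n, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .recordings import (
    Protocol,
    Recording,
    StimulusEpoch,
    Sweep,
    build_protocol,
    canonical_current_clamp_protocol,
    canonical_voltage_clamp_protocol,
)

__all__ = [
    "CellParams",
    "PhenotypePreset",
    "SimGroundTruth",
    "CellSession",
    "load_presets",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "simulate_test_pulse",
    "make_cohort",
    "DEFAULT_GROUP_SIZES",
]

DT_MS = 0.1  # 10 kHz sampling
HOLDING_MV = -60.0

# group sizes of the default cohort design (intrinsic-excitability arm)
DEFAULT_GROUP_SIZES = {"WT": 63, "WT_AR": 13, "Tau": 37, "Tau_AR": 31}


@dataclass(frozen=True)
class CellParams:
    """True biophysical parameters of one simulated cell."""

    e_leak: float = -65.0  # mV; leak reversal = resting potential at zero current
    r_mem: float = 150.0  # MOhm
    r_series: float = 10.0  # MOhm
    c_mem: float = 100.0  # pF
    v_threshold: float = -45.0  # mV
    v_reset: float = -55.0  # mV
    spike_peak: float = 30.0  # mV
    spike_rise_slope: float = 150.0  # mV/ms
    spike_fall_slope: float = -50.0  # mV/ms
    adapt_increment: float = 20.0  # pA added per spike
    adapt_tau: float = 120.0  # ms
    g_in_scale: float = 1.0  # scaling of the inward-current template
    g_out_scale: float = 1.0  # scaling of the outward-current template
    noise_sd: float = 10.0  # pA, white current noise

    def __post_init__(self) -> None:
        if self.r_mem <= 0 or self.c_mem <= 0 or self.r_series <= 0:
            raise ValueError("R_m, C_m and R_s must be positive")
        if self.v_threshold <= self.e_leak:
            raise ValueError("V_threshold must exceed E_L")
        if self.g_in_scale < 0 or self.g_out_scale < 0:
            raise ValueError("conductance scales must be >= 0")
        if self.spike_rise_slope <= 0 or self.spike_fall_slope >= 0:
            raise ValueError("spike rise slope must be > 0 and fall slope < 0")

    @property
    def tau_m(self) -> float:
        """Membrane time constant, ms (MOhm * pF = microseconds)."""
        return self.r_mem * self.c_mem * 1e-3

    def analytic_rheobase(self, rest_mv: float | None = None) -> float:
        """LIF-limit rheobase, pA: (V_th - rest)/R_m with R in GOhm."""
        rest = self.e_leak if rest_mv is None else rest_mv
        return (self.v_threshold - rest) * 1000.0 / self.r_mem


@dataclass(frozen=True)
class PhenotypePreset:
    """Population means plus per-cell jitter for one genotype/treatment group.

    ``lognorm_sigma`` is the log-space SD applied to strictly positive
    parameters; ``voltage_sd`` the additive SD (mV) applied to e_leak,
    v_threshold and v_reset.
    """

    label: str
    means: CellParams
    lognorm_sigma: float = 0.15
    voltage_sd: float = 1.5

    _POSITIVE = ("r_mem", "r_series", "c_mem", "adapt_increment", "adapt_tau",
                 "g_in_scale", "g_out_scale")
    _VOLTAGE = ("e_leak", "v_threshold", "v_reset")

    def draw(self, rng: np.random.Generator) -> CellParams:
        changes = {}
        for name in self._POSITIVE:
            mu = getattr(self.means, name)
            if mu > 0 and self.lognorm_sigma > 0:
                changes[name] = float(mu * np.exp(rng.normal(0.0, self.lognorm_sigma)))
        for name in self._VOLTAGE:
            if self.voltage_sd > 0:
                changes[name] = float(getattr(self.means, name) + rng.normal(0.0, self.voltage_sd))
        # keep threshold strictly above the jittered rest
        if changes.get("v_threshold", self.means.v_threshold) <= changes.get(
            "e_leak", self.means.e_leak
        ):
            changes["v_threshold"] = changes.get("e_leak", self.means.e_leak) + 5.0
        return replace(self.means, **changes)


def load_presets() -> dict[str, PhenotypePreset]:
    """Load the versioned phenotype preset table shipped with the package."""
    raw = json.loads(resources.files("patchfeat").joinpath("presets.json").read_text())
    out = {}
    for label, entry in raw["presets"].items():
        out[label] = PhenotypePreset(
            label=label,
            means=CellParams(**entry["means"]),
            lognorm_sigma=entry.get("lognorm_sigma", 0.15),
            voltage_sd=entry.get("voltage_sd", 1.5),
        )
    return out


@dataclass
class SimGroundTruth:
    """Exact simulator state used as a test oracle."""

    params: CellParams
    spike_times: dict = field(default_factory=dict)  # sweep_id -> ndarray of ms
    peak_currents: dict = field(default_factory=dict)  # step mV -> (inward, outward, steady) pA
    spike_amplitude: float = np.nan  # mV, closed form: peak - threshold
    spike_width: float = np.nan  # ms, closed form FWHM of the triangular waveform


@dataclass
class CellSession:
    """All simulated recordings for one cell."""

    cell_id: str
    preset_label: str
    params: CellParams
    recordings: dict  # name -> Recording
    ground_truth: dict  # name -> SimGroundTruth


# ----------------------------------------------------------------- waveforms

def spike_template(params: CellParams, dt: float = DT_MS) -> np.ndarray:
    """Piecewise-linear spike waveform sampled at dt.

    Rises from V_threshold to spike_peak at spike_rise_slope, falls to
    v_reset at spike_fall_slope.  Closed forms: amplitude = peak - threshold;
    FWHM = (amplitude/2) * (1/rise + 1/|fall|).
    """
    t_rise = (params.spike_peak - params.v_threshold) / params.spike_rise_slope
    t_fall = (params.v_reset - params.spike_peak) / params.spike_fall_slope
    t_total = t_rise + t_fall
    t = np.arange(0.0, t_total + dt / 2, dt)
    v = np.where(
        t <= t_rise,
        params.v_threshold + params.spike_rise_slope * t,
        params.spike_peak + params.spike_fall_slope * (t - t_rise),
    )
    return np.clip(v, params.v_reset, params.spike_peak)


def spike_closed_forms(params: CellParams) -> tuple[float, float]:
    """(amplitude mV, FWHM ms) of the analytic spike waveform."""
    amp = params.spike_peak - params.v_threshold
    width = (amp / 2.0) * (1.0 / params.spike_rise_slope + 1.0 / abs(params.spike_fall_slope))
    return amp, width


# ------------------------------------------------------- current clamp (LIF)

def _integrate_lif(
    i_tot: np.ndarray,
    v0: float,
    params: CellParams,
    template: np.ndarray,
    r_g: float,
    decay_m: float,
    decay_w: float,
) -> tuple[np.ndarray, list[int]]:
    """Exact per-step integration of one sweep, propagated segment-wise.

    Between spikes the membrane recursion V[k] = Vss[k] + (V[k-1] - Vss[k]) a
    (a = exp(-dt/tau_m)) is a first-order linear filter and the adaptation
    current decays in closed form, so each inter-spike segment is computed in
    one vectorized pass; at a threshold crossing the spike waveform is pasted
    and the adaptation increment applied.
    """
    from scipy.signal import lfilter

    n = len(i_tot)
    n_template = len(template)
    v = np.empty(n)
    v[0] = v0
    spikes: list[int] = []
    t0 = 1
    v_prev = v0
    w_prev = 0.0
    while t0 < n:
        ks = np.arange(t0, n)
        w_seg = w_prev * decay_w ** (ks - t0 + 1) if w_prev != 0.0 else 0.0
        v_ss = params.e_leak + r_g * (i_tot[t0:] - w_seg)
        seg, _ = lfilter([1.0 - decay_m], [1.0, -decay_m], v_ss,
                         zi=np.array([decay_m * v_prev]))
        crossed = np.nonzero(seg >= params.v_threshold)[0]
        if crossed.size == 0:
            v[t0:] = seg
            break
        c = int(crossed[0])
        v[t0 : t0 + c] = seg[:c]
        k_spike = t0 + c
        spikes.append(k_spike)
        end = min(k_spike + n_template, n)
        v[k_spike:end] = template[: end - k_spike]
        w_at_spike = (w_prev * decay_w ** (c + 1)) + params.adapt_increment
        w_prev = w_at_spike * decay_w ** (end - 1 - k_spike)
        v_prev = v[end - 1]
        t0 = end
    return v, spikes


def simulate_current_clamp(
    params: CellParams,
    protocol: Protocol | None = None,
    holding: str = "rest",
    seed: int | np.random.SeedSequence = 0,
    cell_id: str = "sim",
    genotype: str = "synthetic",
    treatment: str = "vehicle",
) -> tuple[Recording, SimGroundTruth]:
    """Integrate a leaky integrate-and-fire membrane over a step protocol.

    Exact per-step exponential updates (the membrane ODE is solved in closed
    form for piecewise-constant input), spike-triggered adaptation, and the
    analytic spike waveform pasted at each threshold crossing.  With
    ``holding='minus60'`` a bias current (-60 - E_L)/R_m clamps the
    pre-stimulus potential near -60 mV.  Ground-truth spike times are the
    sample times of the threshold crossings.
    """
    if protocol is None:
        protocol = canonical_current_clamp_protocol()
    dt = DT_MS
    tau_m = params.tau_m
    if tau_m < 4 * dt:
        raise ValueError(f"membrane time constant {tau_m} ms too short for dt={dt} ms")
    pairs = protocol.enumerate_sweeps()
    levels = np.array([lvl for lvl, _ in pairs])
    template = spike_template(params, dt)
    n_template = len(template)

    epoch = protocol.epoch_template
    total_ms = epoch.offset_time + 150.0
    n_samples = int(round(total_ms / dt))
    on_i = int(round(epoch.onset_time / dt))
    off_i = int(round(epoch.offset_time / dt))

    if holding == "minus60":
        i_hold = (HOLDING_MV - params.e_leak) * 1000.0 / params.r_mem
        v0 = HOLDING_MV
    elif holding == "rest":
        i_hold = 0.0
        v0 = params.e_leak
    else:
        raise ValueError(f"unknown holding {holding!r}")

    rng = np.random.default_rng(seed)
    n_sweeps = len(pairs)

    decay_m = np.exp(-dt / tau_m)
    decay_w = np.exp(-dt / params.adapt_tau)
    r_g = params.r_mem * 1e-3  # GOhm so that pA * GOhm = mV

    out = np.empty((n_sweeps, n_samples))
    spike_idx: list[list[int]] = []
    step_mask = np.zeros(n_samples)
    step_mask[on_i:off_i] = 1.0
    for j, lvl in enumerate(levels):
        noise = (
            rng.normal(0.0, params.noise_sd, n_samples)
            if params.noise_sd > 0
            else np.zeros(n_samples)
        )
        i_tot = i_hold + lvl * step_mask + noise
        out[j], idx = _integrate_lif(
            i_tot, float(v0), params, template, r_g, decay_m, decay_w
        )
        spike_idx.append(idx)

    sweeps = []
    truth = SimGroundTruth(params=params)
    amp, width = spike_closed_forms(params)
    truth.spike_amplitude, truth.spike_width = amp, width
    for j, (lvl, rep) in enumerate(pairs):
        sid = f"{cell_id}_{holding}_L{lvl:g}_r{rep}"
        sweeps.append(
            Sweep(
                samples=out[j],
                dt=dt,
                mode="current_clamp",
                epoch=protocol.epoch_for(lvl),
                repeat_index=rep,
                sweep_id=sid,
            )
        )
        truth.spike_times[sid] = np.array(spike_idx[j], dtype=float) * dt

    rec = Recording(
        cell_id=cell_id,
        sweeps=sweeps,
        genotype=genotype,
        treatment=treatment,
        holding=holding,
        protocol=protocol,
    )
    return rec, truth


# ------------------------------------------------------------- voltage clamp

# template constants (pA and mV); scaled per cell by g_in_scale / g_out_scale
INWARD_AMP = 1500.0
INWARD_BELL_CENTER = -20.0  # absolute mV of peak inward activation
INWARD_BELL_SIGMA = 12.0
INWARD_DELAY = 0.2  # ms after step onset
INWARD_TAU = 1.0  # ms; alpha-function peak at delay + tau
OUTWARD_AMP_TRANSIENT = 1200.0
OUTWARD_AMP_SUSTAINED = 800.0
OUTWARD_VHALF = -10.0
OUTWARD_SLOPE = 8.0
OUTWARD_DELAY = 1.0
OUTWARD_TAU = 3.0
OUTWARD_TAU_SUSTAINED = 5.0


def _alpha(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x * np.exp(1.0 - x), 0.0)


def _bell(v_abs: float) -> float:
    return float(np.exp(-((v_abs - INWARD_BELL_CENTER) ** 2) / (2 * INWARD_BELL_SIGMA**2)))


def _sig(v_abs: float) -> float:
    return float(1.0 / (1.0 + np.exp(-(v_abs - OUTWARD_VHALF) / OUTWARD_SLOPE)))


def _vc_template_currents(
    params: CellParams, dv: float, t_rel: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(inward, outward) template currents during a step of dv mV rel. holding."""
    v_abs = HOLDING_MV + dv
    inward = -params.g_in_scale * INWARD_AMP * _bell(v_abs) * _alpha(
        (t_rel - INWARD_DELAY) / INWARD_TAU
    )
    outward = params.g_out_scale * _sig(v_abs) * (
        OUTWARD_AMP_TRANSIENT * _alpha((t_rel - OUTWARD_DELAY) / OUTWARD_TAU)
        + OUTWARD_AMP_SUSTAINED * (1.0 - np.exp(-t_rel / OUTWARD_TAU_SUSTAINED))
    )
    return inward, outward


def simulate_voltage_clamp(
    params: CellParams,
    protocol: Protocol | None = None,
    seed: int | np.random.SeedSequence = 0,
    cell_id: str = "sim",
    holding_current: float = -30.0,
    genotype: str = "synthetic",
    treatment: str = "vehicle",
) -> tuple[Recording, SimGroundTruth]:
    """Closed-form voltage-clamp current responses over a step protocol.

    Each sweep is passive leak + capacitive transient (both exactly linear in
    the step amplitude) plus the scaled inward/outward templates, plus a
    constant holding current and seeded white noise.  Ground-truth peak and
    steady-state currents are the extrema of the noise-free templates on the
    sample grid (exact for what the traces contain).
    """
    if protocol is None:
        protocol = canonical_voltage_clamp_protocol()
    dt = DT_MS
    epoch = protocol.epoch_template
    total_ms = epoch.offset_time + 50.0
    n_samples = int(round(total_ms / dt))
    t = np.arange(n_samples) * dt
    on, off = epoch.onset_time, epoch.offset_time
    in_step = (t >= on) & (t < off)
    t_rel = t - on

    r_in_g = (params.r_series + params.r_mem) * 1e-3  # GOhm
    r_s_g = params.r_series * 1e-3
    tau = params.c_mem * (params.r_series * params.r_mem / (params.r_series + params.r_mem)) * 1e-3

    rng = np.random.default_rng(seed)
    sweeps = []
    truth = SimGroundTruth(params=params)
    early_n = int(round(10.0 / dt))
    on_i = int(round(on / dt))
    off_i = int(round(off / dt))
    ss_lo = on_i + int(round(2.0 / 3.0 * (off_i - on_i)))

    for lvl, rep in protocol.enumerate_sweeps():
        dv = lvl
        i_ss = dv / r_in_g
        i_pk = dv / r_s_g
        passive = np.zeros_like(t)
        passive[in_step] = i_ss + (i_pk - i_ss) * np.exp(-t_rel[in_step] / tau)
        tail = np.zeros_like(t)
        post = t >= off
        tail[post] = -(i_pk - i_ss) * np.exp(-(t[post] - off) / tau)
        inward, outward = _vc_template_currents(params, dv, t_rel)
        gated = np.where(in_step, inward + outward, 0.0)
        clean = holding_current + passive + tail + gated
        noisy = clean + (
            rng.normal(0.0, params.noise_sd, n_samples) if params.noise_sd > 0 else 0.0
        )
        sid = f"{cell_id}_vc_{dv:g}_r{rep}"
        sweeps.append(
            Sweep(
                samples=noisy,
                dt=dt,
                mode="voltage_clamp",
                epoch=protocol.epoch_for(dv),
                repeat_index=rep,
                sweep_id=sid,
            )
        )
        early = gated[on_i : on_i + early_n]
        truth.peak_currents[dv] = (
            float(min(early.min(), 0.0)),
            float(max(early.max(), 0.0)),
            float(np.mean(gated[ss_lo:off_i])),
        )

    rec = Recording(
        cell_id=cell_id,
        sweeps=sweeps,
        genotype=genotype,
        treatment=treatment,
        holding="minus60",
        protocol=protocol,
    )
    return rec, truth


def simulate_test_pulse(
    params: CellParams,
    seed: int | np.random.SeedSequence = 0,
    amplitude: float = -5.0,
    pre_ms: float = 50.0,
    pulse_ms: float = 100.0,
    post_ms: float = 50.0,
    holding_current: float = -30.0,
    cell_id: str = "sim",
) -> Sweep:
    """Analytic RC current response to a small voltage test pulse.

    Steady-state current during the pulse is dV/(Rs+Rm) exactly; the
    transient decays with tau = Cm Rs Rm/(Rs+Rm).
    """
    dt = DT_MS
    n = int(round((pre_ms + pulse_ms + post_ms) / dt))
    t = np.arange(n) * dt
    on, off = pre_ms, pre_ms + pulse_ms
    r_in_g = (params.r_series + params.r_mem) * 1e-3
    r_s_g = params.r_series * 1e-3
    tau = params.c_mem * (params.r_series * params.r_mem / (params.r_series + params.r_mem)) * 1e-3
    i_ss = amplitude / r_in_g
    i_pk = amplitude / r_s_g
    resp = np.zeros(n)
    in_pulse = (t >= on) & (t < off)
    resp[in_pulse] = i_ss + (i_pk - i_ss) * np.exp(-(t[in_pulse] - on) / tau)
    post = t >= off
    resp[post] = -(i_pk - i_ss) * np.exp(-(t[post] - off) / tau)
    rng = np.random.default_rng(seed)
    samples = holding_current + resp + (
        rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else 0.0
    )
    return Sweep(
        samples=samples,
        dt=dt,
        mode="voltage_clamp",
        epoch=StimulusEpoch(on, pulse_ms, amplitude, kind="test_pulse"),
        sweep_id=f"{cell_id}_tp",
    )


# ------------------------------------------------------------------- cohorts

SESSION_NAMES = ("cc_rest", "cc_minus60", "vclamp", "test_pulse")


def make_cohort(
    presets: Sequence[PhenotypePreset],
    n_per_group: int | dict | None = None,
    seed: int = 0,
    sessions: Iterable[str] = SESSION_NAMES,
    cc_protocol: Protocol | None = None,
    vc_protocol: Protocol | None = None,
) -> list[CellSession]:
    """Simulate a cohort of cells across phenotype groups.

    ``n_per_group`` may be an integer (same size for every group), a mapping
    from preset label to size, or None to use the default cohort design
    sizes.  Per-cell seeds derive from the master seed via
    ``SeedSequence.spawn``, so the cohort is bit-reproducible.
    """
    sessions = tuple(sessions)
    for s in sessions:
        if s not in SESSION_NAMES:
            raise ValueError(f"unknown session {s!r}")
    sizes = {}
    for preset in presets:
        if n_per_group is None:
            sizes[preset.label] = DEFAULT_GROUP_SIZES.get(preset.label, 30)
        elif isinstance(n_per_group, dict):
            sizes[preset.label] = int(n_per_group[preset.label])
        else:
            sizes[preset.label] = int(n_per_group)
        if sizes[preset.label] < 1:
            raise ValueError("n_per_group must be >= 1")

    master = np.random.SeedSequence(seed)
    cells: list[CellSession] = []
    cell_seeds = master.spawn(sum(sizes.values()))
    pos = 0
    for preset in presets:
        genotype = "Tau" if preset.label.startswith("Tau") else "WT"
        treatment = "AR" if preset.label.endswith("_AR") else "vehicle"
        for i in range(sizes[preset.label]):
            ss = cell_seeds[pos]
            pos += 1
            sub = ss.spawn(5)  # draw, cc_rest, cc_minus60, vclamp, test_pulse
            params = preset.draw(np.random.default_rng(sub[0]))
            cid = f"{preset.label}_{i:03d}"
            recs: dict[str, Recording] = {}
            truths: dict[str, SimGroundTruth] = {}
            if "cc_rest" in sessions:
                rec, tr = simulate_current_clamp(
                    params, cc_protocol, holding="rest", seed=sub[1], cell_id=cid,
                    genotype=genotype, treatment=treatment,
                )
                recs["cc_rest"], truths["cc_rest"] = rec, tr
            if "cc_minus60" in sessions:
                rec, tr = simulate_current_clamp(
                    params, cc_protocol, holding="minus60", seed=sub[2], cell_id=cid,
                    genotype=genotype, treatment=treatment,
                )
                recs["cc_minus60"], truths["cc_minus60"] = rec, tr
            if "vclamp" in sessions:
                rec, tr = simulate_voltage_clamp(
                    params, vc_protocol, seed=sub[3], cell_id=cid,
                    genotype=genotype, treatment=treatment,
                )
                recs["vclamp"], truths["vclamp"] = rec, tr
            if "test_pulse" in sessions:
                recs["test_pulse"] = Recording(
                    cell_id=cid,
                    sweeps=[simulate_test_pulse(params, seed=sub[4], cell_id=cid)],
                    genotype=genotype,
                    treatment=treatment,
                    holding="minus60",
                )
                truths["test_pulse"] = SimGroundTruth(params=params)
            cells.append(
                CellSession(
                    cell_id=cid,
                    preset_label=preset.label,
                    params=params,
                    recordings=recs,
                    ground_truth=truths,
                )
            )
    return cells
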