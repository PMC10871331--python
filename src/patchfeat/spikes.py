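"""Action-potential detection by dV/dt slope criteria and F-I summaries.

A spike is an upward crossing of the first derivative through +30 mV/ms that
is followed within 10 ms by a downward crossing through -15 mV/ms, with the
voltage between the two crossings required to exceed 0 mV.  Crossing
semantics are fixed as: an upward crossing occurs between derivative samples
i and i+1 when ``d[i] < theta <= d[i+1]`` (downward: ``d[i] > theta >=
d[i+1]``), and the event is stamped at sample i+1.  After a spike is
accepted the scan resumes at the first sample after its downward crossing,
so one action potential is never counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recordings import DetectionConfig, Recording, StimulusEpoch, Sweep

__all__ = [
    "SpikeEvent",
    "FICurve",
    "differentiate",
    "detect_spikes",
    "filter_evoked",
    "fi_curve",
    "firing_proportions",
]


@dataclass(frozen=True)
class SpikeEvent:
    """One detected action potential."""

    upcross_time: float  # ms; dV/dt crossed the up-slope threshold
    downcross_time: float  # ms; dV/dt crossed the down-slope threshold
    peak_time: float  # ms; voltage maximum between the crossings
    peak_voltage: float  # mV
    sweep_ref: str = ""


@dataclass
class FICurve:
    """Per-cell spike counts across the current-step grid.

    ``mean_counts`` averages evoked spike counts over the repeats at each
    level.  ``any_spike`` marks levels where at least one repeat fired;
    ``exactly_one`` marks levels whose rounded mean count is a single spike
    (mean in (0, 1.5) with any_spike true).
    """

    cell_id: str
    holding: str
    levels: np.ndarray  # pA, ascending
    mean_counts: np.ndarray
    any_spike: np.ndarray  # bool per level
    exactly_one: np.ndarray  # bool per level
    counts_per_repeat: list  # list of per-repeat count arrays, one per level
    missing_levels: np.ndarray | None = None  # declared-protocol levels absent from data


def differentiate(samples: np.ndarray, dt: float, order: int = 1) -> np.ndarray:
    """Finite-difference derivative of a sampled trace.

    order=1: forward difference, ``d[i] = (v[i+1] - v[i]) / dt`` (length n-1;
    d[i] is stamped at sample i).
    order=2: central second difference, ``d2[i] = (v[i+1] - 2 v[i] + v[i-1]) /
    dt**2`` for i = 1..n-2 (length n-2; d2[j] corresponds to sample j+1).
    """
    v = np.asarray(samples, dtype=float)
    if v.size < 3:
        raise ValueError("differentiate requires at least 3 samples")
    if order == 1:
        return np.diff(v) / dt
    if order == 2:
        return (v[2:] - 2.0 * v[1:-1] + v[:-2]) / dt**2
    raise ValueError("order must be 1 or 2")


def _boxcar(v: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(v, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(v)]
    return out


def detect_spikes(sweep: Sweep, cfg: DetectionConfig = DetectionConfig()) -> list[SpikeEvent]:
    """Detect action potentials in a current-clamp sweep by slope criteria.

    Returns events in time order; an empty list when nothing crosses the
    slope thresholds.  No pre-smoothing is applied by default (hardware
    filtering at 5 kHz is assumed); set ``cfg.smoothing_boxcar`` to enable an
    optional boxcar.
    """
    if sweep.mode != "current_clamp":
        raise ValueError("spike detection applies to current-clamp sweeps")
    v = sweep.samples
    if cfg.smoothing_boxcar > 1:
        v = _boxcar(v, cfg.smoothing_boxcar)
    if v.size < 3:
        return []
    dt = sweep.dt
    d = np.diff(v) / dt  # d[i] stamped at sample i

    up = cfg.up_slope_threshold
    down = cfg.down_slope_threshold
    pair_samples = int(np.floor(cfg.pairing_window / dt))

    # crossings between derivative samples i and i+1; event index = i + 1
    up_idx = np.nonzero((d[:-1] < up) & (d[1:] >= up))[0] + 1
    down_idx = np.nonzero((d[:-1] > down) & (d[1:] <= down))[0] + 1

    events: list[SpikeEvent] = []
    resume = 0  # first derivative sample eligible as an up-cross
    dpos = 0
    for ui in up_idx:
        if ui < resume:
            continue
        # first down-cross strictly after the up-cross, within the pairing window
        while dpos < len(down_idx) and down_idx[dpos] <= ui:
            dpos += 1
        if dpos >= len(down_idx):
            continue
        di = down_idx[dpos]
        if di - ui > pair_samples:
            continue
        seg = v[ui : di + 1]
        peak_off = int(np.argmax(seg))
        peak_v = float(seg[peak_off])
        if peak_v <= cfg.min_peak_voltage:
            continue
        events.append(
            SpikeEvent(
                upcross_time=ui * dt,
                downcross_time=di * dt,
                peak_time=(ui + peak_off) * dt,
                peak_voltage=peak_v,
                sweep_ref=sweep.sweep_id,
            )
        )
        resume = di + 1
    return events


def filter_evoked(spikes: list[SpikeEvent], epoch: StimulusEpoch) -> list[SpikeEvent]:
    """Keep only spikes evoked by a depolarizing current step.

    Spontaneous and rebound spikes — any spike whose up-cross falls outside
    the depolarizing current window — are dropped.  Membership uses the
    up-cross time and the half-open window [onset, onset + duration), so
    rebound spikes after step offset are excluded.
    """
    if epoch.kind != "current_step":
        raise ValueError("evoked-spike filtering applies to current-step epochs")
    if epoch.amplitude <= 0:
        return []
    return [s for s in spikes if epoch.contains(s.upcross_time)]


def fi_curve(recording: Recording, cfg: DetectionConfig = DetectionConfig()) -> FICurve:
    """Evoked spike counts per current level, averaged over repeats."""
    if recording.mode != "current_clamp":
        raise ValueError("F-I curves require a current-clamp recording")
    levels = recording.levels()
    mean_counts = np.empty(len(levels))
    per_repeat: list[np.ndarray] = []
    for j, lvl in enumerate(levels):
        counts = []
        for sw in recording.sweeps_at(lvl):
            evoked = filter_evoked(detect_spikes(sw, cfg), sw.epoch)
            counts.append(len(evoked))
        counts = np.asarray(counts, dtype=float)
        per_repeat.append(counts)
        mean_counts[j] = counts.mean()
    any_spike = mean_counts > 0
    exactly_one = any_spike & (mean_counts < 1.5)
    missing = None
    if recording.protocol is not None:
        declared = recording.protocol.levels
        absent = np.array([lv for lv in declared if lv not in set(levels)])
        if absent.size:
            missing = absent
    return FICurve(
        cell_id=recording.cell_id,
        holding=recording.holding,
        levels=np.asarray(levels, dtype=float),
        mean_counts=mean_counts,
        any_spike=any_spike,
        exactly_one=exactly_one,
        counts_per_repeat=per_repeat,
        missing_levels=missing,
    )


def firing_proportions(cohort: list[FICurve], mode: str = "at_least_one") -> np.ndarray:
    """Percentage of cells per level satisfying a firing criterion.

    ``mode='at_least_one'`` counts cells whose mean count at the level is
    positive; ``mode='exactly_one'`` counts cells flagged as single-spikers
    at the level.  All curves must share the level grid.  Returns percentages
    (0-100) aligned with the shared grid.
    """
    if not cohort:
        raise ValueError("empty cohort")
    grid = cohort[0].levels
    for fc in cohort[1:]:
        if len(fc.levels) != len(grid) or not np.allclose(fc.levels, grid):
            raise ValueError("all F-I curves must share the same level grid")
    if mode == "at_least_one":
        flags = np.stack([fc.any_spike for fc in cohort])
    elif mode == "exactly_one":
        flags = np.stack([fc.exactly_one for fc in cohort])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 100.0 * flags.mean(axis=0)
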