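"""Rheobase identification and first-spike feature extraction.

Rheobase is the minimum current application that elicits at least one evoked
spike.  Features of the first spike fired at rheobase:

* threshold — voltage at the maximum of the second derivative within the
  window from 3 ms before the 30 mV/ms up-cross to the up-cross itself (the
  point of greatest curvature, marking spike initiation);
* latency — time from current-step onset to the threshold point;
* amplitude — voltage from threshold to the spike peak;
* width — full width at half amplitude, with the half-level crossings
  located by linear interpolation between bracketing samples;
* the spike ends when the voltage crosses back under its threshold; a spike
  that never re-crosses is flagged ``excluded_no_recross`` and its width is
  left unset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recordings import DetectionConfig, Recording, StimulusEpoch, Sweep
from .spikes import SpikeEvent, detect_spikes, differentiate, filter_evoked, fi_curve, FICurve

__all__ = [
    "SpikeFeatures",
    "NoRheobaseError",
    "find_rheobase",
    "rheobase_sweep",
    "spike_threshold",
    "rheobase_spike_features",
    "extract_rheobase_features",
]


class NoRheobaseError(ValueError):
    """No level elicited an evoked spike; the cell has no measurable rheobase."""


@dataclass
class SpikeFeatures:
    rheobase: float  # pA
    threshold_time: float  # ms
    threshold_voltage: float  # mV
    latency: float  # ms from step onset to threshold
    amplitude: float  # mV, threshold to peak
    width: float | None  # ms, FWHM; None when excluded
    excluded_no_recross: bool = False
    peak_time: float = np.nan
    peak_voltage: float = np.nan
    truncated_window: bool = False  # threshold window clipped at sweep start


def find_rheobase(fi: FICurve) -> float:
    """Smallest current level at which any repeat fired an evoked spike."""
    if len(fi.levels) == 0:
        raise ValueError("F-I curve has no levels")
    for lvl, counts in zip(fi.levels, fi.counts_per_repeat):
        if np.any(np.asarray(counts) > 0):
            return float(lvl)
    raise NoRheobaseError(f"cell {fi.cell_id}: no evoked spikes at any level")


def rheobase_sweep(
    recording: Recording, cfg: DetectionConfig = DetectionConfig()
) -> tuple[float, Sweep, SpikeEvent]:
    """Locate the rheobase level and the sweep/spike used for features.

    Returns (rheobase, sweep, first evoked spike) where the sweep is the
    first repeat at the rheobase level that contains an evoked spike.
    """
    fi = fi_curve(recording, cfg)
    rheo = find_rheobase(fi)
    for sw in recording.sweeps_at(rheo):
        evoked = filter_evoked(detect_spikes(sw, cfg), sw.epoch)
        if evoked:
            return rheo, sw, evoked[0]
    raise NoRheobaseError(f"cell {recording.cell_id}: rheobase sweep vanished on re-scan")


def spike_threshold(
    sweep: Sweep, spike: SpikeEvent, cfg: DetectionConfig = DetectionConfig()
) -> tuple[float, float, bool]:
    """Threshold time/voltage from the second-derivative maximum.

    Searches [upcross_time - pre_threshold_window, upcross_time] for the
    maximum of the central second difference; ties break to the earliest
    sample.  The threshold voltage is the raw trace value at that sample.
    Returns (threshold_time, threshold_voltage, truncated) where ``truncated``
    flags a search window clipped at the start of the sweep.
    """
    dt = sweep.dt
    up_i = int(round(spike.upcross_time / dt))
    lo_i = up_i - int(round(cfg.pre_threshold_window / dt))
    truncated = lo_i < 1  # second difference is undefined at sample 0
    lo_i = max(lo_i, 1)
    hi_i = min(up_i, sweep.n_samples - 2)
    d2 = differentiate(sweep.samples, dt, order=2)  # d2[j] is at sample j+1
    window = d2[lo_i - 1 : hi_i]  # d2[j] sits at sample j+1 -> samples lo_i..hi_i
    idx = lo_i + int(np.argmax(window))  # argmax returns first max -> earliest tie
    return idx * dt, float(sweep.samples[idx]), truncated


def rheobase_spike_features(
    sweep: Sweep,
    spike: SpikeEvent,
    epoch: StimulusEpoch,
    cfg: DetectionConfig = DetectionConfig(),
    rheobase: float = np.nan,
) -> SpikeFeatures:
    """Features of the first spike fired at rheobase."""
    dt = sweep.dt
    v = sweep.samples
    th_time, th_volt, truncated = spike_threshold(sweep, spike, cfg)
    th_i = int(round(th_time / dt))

    # peak search window: [threshold, downcross]; fall back to the pairing
    # window so a peak exists even for spikes that never re-cross threshold
    end_i = int(round(spike.downcross_time / dt)) if np.isfinite(spike.downcross_time) else None
    if end_i is None or end_i <= th_i:
        end_i = min(th_i + int(round(cfg.pairing_window / dt)), sweep.n_samples - 1)
    seg = v[th_i : end_i + 1]
    peak_off = int(np.argmax(seg))
    peak_i = th_i + peak_off
    peak_v = float(v[peak_i])

    amplitude = peak_v - th_volt
    half = th_volt + amplitude / 2.0

    # end of spike: first sample after the peak at which V drops back under threshold
    after = v[peak_i:]
    below = np.nonzero(after < th_volt)[0]
    if below.size == 0:
        return SpikeFeatures(
            rheobase=rheobase,
            threshold_time=th_time,
            threshold_voltage=th_volt,
            latency=th_time - epoch.onset_time,
            amplitude=amplitude,
            width=None,
            excluded_no_recross=True,
            peak_time=peak_i * dt,
            peak_voltage=peak_v,
            truncated_window=truncated,
        )
    end_spike_i = peak_i + int(below[0])

    def _interp_cross(i0: int, i1: int, rising: bool) -> float:
        """Linear-interpolated time of the half-level crossing in [i0, i1]."""
        seg = v[i0 : i1 + 1]
        if rising:
            k = np.nonzero((seg[:-1] < half) & (seg[1:] >= half))[0]
            k = k[-1] if k.size else None  # last rising crossing before the peak
        else:
            k = np.nonzero((seg[:-1] >= half) & (seg[1:] < half))[0]
            k = k[0] if k.size else None  # first falling crossing after the peak
        if k is None:
            return np.nan
        a, b = seg[k], seg[k + 1]
        frac = (half - a) / (b - a) if b != a else 0.0
        return (i0 + k + frac) * dt

    t_rise = _interp_cross(th_i, peak_i, rising=True)
    t_fall = _interp_cross(peak_i, end_spike_i, rising=False)
    width = t_fall - t_rise if np.isfinite(t_rise) and np.isfinite(t_fall) else None

    return SpikeFeatures(
        rheobase=rheobase,
        threshold_time=th_time,
        threshold_voltage=th_volt,
        latency=th_time - epoch.onset_time,
        amplitude=amplitude,
        width=width,
        excluded_no_recross=False,
        peak_time=peak_i * dt,
        peak_voltage=peak_v,
        truncated_window=truncated,
    )


def extract_rheobase_features(
    recording: Recording, cfg: DetectionConfig = DetectionConfig()
) -> SpikeFeatures:
    """Full rheobase workflow for one current-clamp recording.

    Raises :class:`NoRheobaseError` when no level evoked a spike (such cells
    are omitted from rheobase statistics).  Features are computed per holding
    condition: run this separately on the from-rest and from--60 mV blocks.
    """
    rheo, sweep, spike = rheobase_sweep(recording, cfg)
    return rheobase_spike_features(sweep, spike, sweep.epoch, cfg, rheobase=rheo)
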