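import numpy as np
import pytest
from hypothesis import settings

from patchfeat.recordings import DetectionConfig, StimulusEpoch, Sweep

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

DT = 0.1  # ms, 10 kHz


@pytest.fixture
def cfg():
    return DetectionConfig()


def make_cc_sweep(samples, epoch=None, dt=DT, sweep_id="sw0", repeat=0):
    samples = np.asarray(samples, dtype=float)
    if epoch is None:
        epoch = StimulusEpoch(0.0, len(samples) * dt, 100.0, kind="current_step")
    return Sweep(samples=samples, dt=dt, mode="current_clamp", epoch=epoch,
                 repeat_index=repeat, sweep_id=sweep_id)


def triangular_spike_trace(
    baseline=-60.0,
    threshold=-45.0,
    peak=20.0,
    rise_slope=100.0,
    fall_slope=-50.0,
    after=-60.0,
    dt=DT,
    pre_ms=20.0,
    post_ms=20.0,
):
    """Baseline, linear rise to the peak, linear fall to `after`, baseline.

    Slopes in mV/ms.  Returns (trace, onset_of_rise_ms).
    """
    pre = np.full(int(round(pre_ms / dt)), baseline)
    n_rise = int(round((peak - baseline) / (rise_slope * dt)))
    rise = baseline + rise_slope * dt * np.arange(1, n_rise + 1)
    n_fall = int(round((after - peak) / (fall_slope * dt)))
    fall = peak + fall_slope * dt * np.arange(1, n_fall + 1)
    post = np.full(int(round(post_ms / dt)), after)
    trace = np.concatenate([pre, rise, fall, post])
    return trace, pre_ms
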