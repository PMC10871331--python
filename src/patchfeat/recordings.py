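"""Data model for patch-clamp sweeps, recordings and stimulus protocols.

Units are fixed package-wide: voltage in mV, current in pA, time in ms,
resistance in MOhm, capacitance in pF.  Converters belong at I/O boundaries
only, so the slope thresholds used for spike detection (mV/ms) are
unambiguous everywhere inside the package.

Time is 0-based within a sweep and stimulus-epoch windows are half-open,
``[onset, onset + duration)``, so membership of boundary samples is never
ambiguous.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusEpoch",
    "Sweep",
    "Recording",
    "Protocol",
    "DetectionConfig",
    "build_protocol",
    "read_recording",
    "write_recording",
    "GridMismatchError",
    "RecordingIntegrityError",
]

EpochKind = Literal["current_step", "voltage_step", "test_pulse", "none"]


class GridMismatchError(ValueError):
    """Protocol grid (start, stop, increment) does not tile evenly."""


class RecordingIntegrityError(ValueError):
    """Stored sweep data is internally inconsistent (dt, lengths, metadata)."""


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulus window within a sweep.

    ``amplitude`` is in pA for current-clamp epochs and in mV *relative to the
    holding potential* for voltage-clamp epochs (so under a -60 mV holding a
    "+40 mV step" commands -20 mV absolute).
    """

    onset_time: float  # ms from sweep start
    duration: float  # ms
    amplitude: float  # pA (current clamp) or mV relative to holding (voltage clamp)
    kind: EpochKind = "current_step"

    def __post_init__(self) -> None:
        if self.onset_time < 0:
            raise ValueError(f"epoch onset_time must be >= 0, got {self.onset_time}")
        if self.duration <= 0:
            raise ValueError(f"epoch duration must be > 0, got {self.duration}")

    @property
    def offset_time(self) -> float:
        return self.onset_time + self.duration

    def contains(self, t_ms: float) -> bool:
        """Half-open membership test: onset <= t < onset + duration."""
        return self.onset_time <= t_ms < self.offset_time


@dataclass
class Sweep:
    """One digitized trace (voltage or current) with its primary stimulus epoch."""

    samples: np.ndarray  # mV (current clamp) or pA (voltage clamp)
    dt: float  # ms per sample; 10 kHz sampling -> 0.1
    mode: Literal["current_clamp", "voltage_clamp"]
    epoch: StimulusEpoch
    repeat_index: int = 0
    sweep_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D series")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("all samples must be finite")
        if len(self.samples) * self.dt < self.epoch.offset_time:
            raise ValueError(
                "sweep too short for its epoch: "
                f"{len(self.samples)} samples at dt={self.dt} ms "
                f"end before epoch offset {self.epoch.offset_time} ms"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def copy_with(self, **changes) -> "Sweep":
        out = replace(self, **changes)
        return out


@dataclass
class Recording:
    """An ordered set of sweeps from one cell under one protocol block."""

    cell_id: str
    sweeps: list[Sweep]
    genotype: str = "synthetic"  # WT | Tau | APP_PS1 | synthetic
    treatment: str = "vehicle"  # vehicle | AR
    holding: str = "rest"  # rest | minus60
    sampling_rate_khz: float = 10.0
    filter_cutoff_khz: float = 5.0
    protocol: "Protocol | None" = None
    checkpoints: list = field(default_factory=list)  # PassiveProperties snapshots

    def __post_init__(self) -> None:
        if self.sweeps:
            dt0 = self.sweeps[0].dt
            mode0 = self.sweeps[0].mode
            for sw in self.sweeps:
                if not math.isclose(sw.dt, dt0, rel_tol=1e-12):
                    raise RecordingIntegrityError(
                        f"mixed dt across sweeps in {self.cell_id}: {sw.dt} vs {dt0}"
                    )
                if sw.mode != mode0:
                    raise RecordingIntegrityError(
                        f"mixed clamp modes within one protocol block in {self.cell_id}"
                    )

    @property
    def dt(self) -> float:
        if not self.sweeps:
            return 1.0 / self.sampling_rate_khz
        return self.sweeps[0].dt

    @property
    def mode(self) -> str:
        if not self.sweeps:
            return "current_clamp"
        return self.sweeps[0].mode

    def levels(self) -> list[float]:
        """Distinct stimulus amplitudes in ascending order."""
        return sorted({sw.epoch.amplitude for sw in self.sweeps})

    def sweeps_at(self, level: float) -> list[Sweep]:
        out = [sw for sw in self.sweeps if sw.epoch.amplitude == level]
        return sorted(out, key=lambda s: s.repeat_index)


@dataclass(frozen=True)
class Protocol:
    """A family of step stimuli on a regular amplitude grid."""

    start_amplitude: float
    stop_amplitude: float
    increment: float
    n_repeats: int
    epoch_template: StimulusEpoch

    @property
    def n_levels(self) -> int:
        return int(round((self.stop_amplitude - self.start_amplitude) / self.increment)) + 1

    @property
    def levels(self) -> np.ndarray:
        return self.start_amplitude + self.increment * np.arange(self.n_levels)

    @property
    def n_sweeps(self) -> int:
        return self.n_levels * self.n_repeats

    def enumerate_sweeps(self) -> list[tuple[float, int]]:
        """(level, repeat) pairs in ascending-amplitude order, repeats grouped."""
        return [(lvl, rep) for lvl in self.levels for rep in range(self.n_repeats)]

    def epoch_for(self, level: float) -> StimulusEpoch:
        return replace(self.epoch_template, amplitude=level)


@dataclass(frozen=True)
class DetectionConfig:
    """Slope-based action-potential detection criteria.

    Defaults implement detection of an upward dV/dt crossing of 30 mV/ms
    followed within 10 ms by a downward crossing of -15 mV/ms, with the spike
    required to pass above 0 mV; the threshold search looks back 3 ms from the
    upstroke crossing.
    """

    up_slope_threshold: float = 30.0  # mV/ms
    down_slope_threshold: float = -15.0  # mV/ms
    pairing_window: float = 10.0  # ms
    min_peak_voltage: float = 0.0  # mV
    pre_threshold_window: float = 3.0  # ms
    smoothing_boxcar: int = 0  # samples; 0 disables pre-smoothing

    def __post_init__(self) -> None:
        if self.up_slope_threshold <= 0:
            raise ValueError("up_slope_threshold must be > 0")
        if self.down_slope_threshold >= 0:
            raise ValueError("down_slope_threshold must be < 0")
        if self.pairing_window <= 0 or self.pre_threshold_window <= 0:
            raise ValueError("pairing_window and pre_threshold_window must be > 0")


def build_protocol(
    start: float,
    stop: float,
    increment: float,
    n_repeats: int,
    epoch_template: StimulusEpoch,
) -> Protocol:
    """Build a regular step protocol enumerating levels start..stop.

    Levels run from least to most depolarizing (ascending amplitude), each
    repeated ``n_repeats`` times.  The canonical current-clamp session is
    ``build_protocol(-100, 480, 20, 5, ...)``: 30 levels x 5 repeats.
    """
    if increment <= 0:
        raise GridMismatchError(f"increment must be > 0, got {increment}")
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")
    span = stop - start
    if span < 0:
        raise GridMismatchError("stop must be >= start")
    n_steps = span / increment
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise GridMismatchError(
            f"(stop - start) = {span} is not an integer multiple of increment {increment}"
        )
    return Protocol(start, stop, increment, n_repeats, epoch_template)


# canonical protocol builders -------------------------------------------------

def canonical_current_clamp_protocol(
    onset_ms: float = 100.0, duration_ms: float = 500.0, n_repeats: int = 5
) -> Protocol:
    """20 pA current steps from -100 to 480 pA, 5 repeats per level."""
    epoch = StimulusEpoch(onset_ms, duration_ms, 0.0, kind="current_step")
    return build_protocol(-100.0, 480.0, 20.0, n_repeats, epoch)


def canonical_voltage_clamp_protocol(
    onset_ms: float = 50.0, duration_ms: float = 100.0
) -> Protocol:
    """10 mV voltage steps relative to the -60 mV holding.

    Runs -10 to +100 mV so the series contains the -10 mV leak step used for
    ohmic leak subtraction.
    """
    epoch = StimulusEpoch(onset_ms, duration_ms, 0.0, kind="voltage_step")
    return build_protocol(-10.0, 100.0, 10.0, 1, epoch)


# I/O: native sweep-table dialect ---------------------------------------------
#
# One CSV with columns {cell_id, sweep_id, mode, level, repeat, t_ms, value}
# (long format, one row per sample) plus a JSON sidecar `<stem>.meta.json`
# holding metadata and the protocol. Text-based so diffs and fixtures stay
# human-readable.

_REQUIRED_COLUMNS = ["cell_id", "sweep_id", "mode", "level", "repeat", "t_ms", "value"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" else (
        path.with_name(path.stem + ".meta.json")
    )


def _protocol_to_dict(p: Protocol | None) -> dict | None:
    if p is None:
        return None
    return {
        "start_amplitude": p.start_amplitude,
        "stop_amplitude": p.stop_amplitude,
        "increment": p.increment,
        "n_repeats": p.n_repeats,
        "epoch_template": {
            "onset_time": p.epoch_template.onset_time,
            "duration": p.epoch_template.duration,
            "amplitude": p.epoch_template.amplitude,
            "kind": p.epoch_template.kind,
        },
    }


def _protocol_from_dict(d: dict | None) -> Protocol | None:
    if d is None:
        return None
    et = d["epoch_template"]
    return Protocol(
        d["start_amplitude"],
        d["stop_amplitude"],
        d["increment"],
        d["n_repeats"],
        StimulusEpoch(et["onset_time"], et["duration"], et["amplitude"], et["kind"]),
    )


def write_recording(recording: Recording, path: str | Path, dialect: str = "sweep_table") -> Path:
    """Write a Recording to disk; lossless for sample values (17 sig. digits)."""
    if dialect == "nwb":
        raise NotImplementedError(
            "the NWB dialect requires pynwb, which this build does not depend on; "
            "use dialect='sweep_table'"
        )
    if dialect != "sweep_table":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    frames = []
    epochs = {}
    for sw in recording.sweeps:
        n = sw.n_samples
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": recording.cell_id,
                    "sweep_id": sw.sweep_id,
                    "mode": sw.mode,
                    "level": sw.epoch.amplitude,
                    "repeat": sw.repeat_index,
                    "t_ms": np.arange(n) * sw.dt,
                    "value": sw.samples,
                }
            )
        )
        epochs[sw.sweep_id] = {
            "onset_time": sw.epoch.onset_time,
            "duration": sw.epoch.duration,
            "amplitude": sw.epoch.amplitude,
            "kind": sw.epoch.kind,
        }
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=_REQUIRED_COLUMNS)
    table.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "cell_id": recording.cell_id,
        "genotype": recording.genotype,
        "treatment": recording.treatment,
        "holding": recording.holding,
        "dt_ms": recording.dt,
        "filter_kHz": recording.filter_cutoff_khz,
        "sampling_kHz": recording.sampling_rate_khz,
        "protocol": _protocol_to_dict(recording.protocol),
        "epochs": epochs,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path: str | Path, dialect: str = "sweep_table") -> Recording:
    """Read a Recording; write-then-read is the identity on valid recordings."""
    if dialect == "nwb":
        raise NotImplementedError(
            "the NWB dialect requires pynwb, which this build does not depend on; "
            "use dialect='sweep_table'"
        )
    if dialect != "sweep_table":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise RecordingIntegrityError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("cell_id", "dt_ms", "epochs"):
        if key not in meta:
            raise RecordingIntegrityError(f"sidecar missing required field {key!r}")
    table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise RecordingIntegrityError(f"sweep table missing required columns {missing}")
    dt = float(meta["dt_ms"])
    sweeps: list[Sweep] = []
    if len(table):
        for sweep_id, grp in table.groupby("sweep_id", sort=False):
            ep = meta["epochs"].get(str(sweep_id))
            if ep is None:
                raise RecordingIntegrityError(f"no epoch metadata for sweep {sweep_id!r}")
            values = grp["value"].to_numpy(dtype=float)
            t = grp["t_ms"].to_numpy(dtype=float)
            if len(t) > 1 and not np.allclose(np.diff(t), dt, atol=1e-9):
                raise RecordingIntegrityError(
                    f"sweep {sweep_id!r}: t_ms spacing disagrees with dt={dt} ms"
                )
            sweeps.append(
                Sweep(
                    samples=values,
                    dt=dt,
                    mode=str(grp["mode"].iloc[0]),
                    epoch=StimulusEpoch(
                        ep["onset_time"], ep["duration"], ep["amplitude"], ep["kind"]
                    ),
                    repeat_index=int(grp["repeat"].iloc[0]),
                    sweep_id=str(sweep_id),
                )
            )
    return Recording(
        cell_id=str(meta["cell_id"]),
        sweeps=sweeps,
        genotype=meta.get("genotype", "synthetic"),
        treatment=meta.get("treatment", "vehicle"),
        holding=meta.get("holding", "rest"),
        sampling_rate_khz=float(meta.get("sampling_kHz", 1.0 / dt)),
        filter_cutoff_khz=float(meta.get("filter_kHz", 5.0)),
        protocol=_protocol_from_dict(meta.get("protocol")),
    )
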