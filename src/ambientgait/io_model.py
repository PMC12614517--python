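"""Data containers and file I/O shared by the gait pipeline.

The package analyses two contactless modalities of a hallway walking trial:

* a skeleton stream -- 3-D positions of 32 body joints sampled at roughly
  30 frames per second by a depth camera, with tracking dropouts encoded
  as missing values;
* a floor-vibration record -- vertical floor acceleration sampled at
  several kHz by an array of floor-mounted single-axis accelerometers
  whose hallway positions are known.

All internal units are meters and seconds.  Readers convert millimeter
inputs when told so (``units="mm"``); this is the single conversion point.
Dropouts are encoded as NaN triplets, never zeros, because zero is a legal
coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "AZURE_KINECT_JOINTS",
    "JointStream",
    "VibrationRecord",
    "TrialConfig",
    "GaitMetrics",
    "SubjectRecord",
    "read_joint_stream",
    "write_joint_stream",
    "read_vibration",
    "write_vibration",
    "read_subjects",
]


class FormatError(ValueError):
    """An input file or container violates a declared invariant."""


#: Canonical 32-joint skeleton naming (depth-camera body-tracking order).
AZURE_KINECT_JOINTS: tuple[str, ...] = (
    "pelvis", "spine_navel", "spine_chest", "neck",
    "clavicle_left", "shoulder_left", "elbow_left", "wrist_left",
    "hand_left", "handtip_left", "thumb_left",
    "clavicle_right", "shoulder_right", "elbow_right", "wrist_right",
    "hand_right", "handtip_right", "thumb_right",
    "hip_left", "knee_left", "ankle_left", "foot_left",
    "hip_right", "knee_right", "ankle_right", "foot_right",
    "head", "nose", "eye_left", "ear_left", "eye_right", "ear_right",
)

_AXES = ("x", "y", "z")


@dataclass
class JointStream:
    """Time-stamped 3-D joint-position series with dropout sentinels.

    Parameters
    ----------
    timestamps : (n,) array, seconds, strictly increasing.
    positions : (n, J, 3) array, meters.  A dropout is a joint whose
        three coordinates are all NaN in a frame; mixed NaN triplets are
        rejected.
    joint_names : names for the J joints, in ``positions`` order.
    """

    timestamps: np.ndarray
    positions: np.ndarray
    joint_names: tuple[str, ...] = AZURE_KINECT_JOINTS

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size < 2:
            raise FormatError("need >= 2 frames of timestamps")
        if np.any(~np.isfinite(self.timestamps)):
            raise FormatError("timestamps must be finite")
        if np.any(np.diff(self.timestamps) <= 0):
            raise FormatError("timestamps must be strictly increasing")
        n = self.timestamps.size
        if self.positions.shape != (n, len(self.joint_names), 3):
            raise FormatError(
                f"positions shape {self.positions.shape} does not match "
                f"{n} frames x {len(self.joint_names)} joints x 3 axes"
            )
        nan = np.isnan(self.positions)
        mixed = np.any(nan, axis=2) & ~np.all(nan, axis=2)
        if np.any(mixed):
            raise FormatError(
                "a joint's coordinates must be jointly present or jointly missing"
            )

    @property
    def n_frames(self) -> int:
        return self.timestamps.size

    def joint_index(self, name: str) -> int:
        try:
            return self.joint_names.index(name)
        except ValueError:
            raise KeyError(f"joint {name!r} not in stream") from None

    def joint(self, name: str) -> np.ndarray:
        """Return the (n, 3) position series of one joint."""
        return self.positions[:, self.joint_index(name), :]

    def valid_mask(self, name: str) -> np.ndarray:
        """Per-frame bool mask: joint tracked (not a dropout)."""
        return ~np.isnan(self.joint(name)[:, 0])


@dataclass
class VibrationRecord:
    """Uniformly sampled multi-channel floor acceleration with layout.

    ``data`` is (channels, samples) in the sensors' (dimensionless linear)
    units.  ``layout`` holds each sensor's hallway coordinates (u along the
    hallway, v across it) in meters.  ``daq_group`` tags each channel with
    the acquisition unit it is wired to ("left" / "right"); the two groups
    run on independent clocks.  ``sync_pair`` names the two physically
    co-located channels used for clock synchronization: the first is the
    redundant duplicate (dropped after synchronization), the second its
    partner on the other acquisition unit.
    """

    sample_rate: float
    data: np.ndarray
    layout: np.ndarray
    daq_group: tuple[str, ...]
    sync_pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.layout = np.asarray(self.layout, dtype=float)
        self.daq_group = tuple(self.daq_group)
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be positive")
        if self.data.ndim != 2:
            raise FormatError("data must be 2-D (channels, samples)")
        c = self.data.shape[0]
        if self.layout.shape != (c, 2):
            raise FormatError("layout must be (channels, 2)")
        if len(self.daq_group) != c:
            raise FormatError("daq_group length must match channel count")
        if self.sync_pair is not None:
            i, j = self.sync_pair
            if not (0 <= i < c and 0 <= j < c) or i == j:
                raise FormatError("sync_pair indices out of range")
            if self.daq_group[i] == self.daq_group[j]:
                raise FormatError("sync_pair sensors must be on different DAQ groups")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class TrialConfig:
    """Hallway geometry and trial labelling.

    The walkway is ``hallway_length`` meters between marked lines; the
    first and last ``accel_zone`` meters serve as acceleration and
    deceleration regions, and the middle ``monitored_zone`` meters give
    the steady-state walking estimate.
    """

    hallway_length: float = 14.0
    accel_zone: float = 3.5
    monitored_zone: float = 7.0
    walk_pace_label: str = "regular"

    def __post_init__(self) -> None:
        if 2 * self.accel_zone + self.monitored_zone > self.hallway_length + 1e-9:
            raise FormatError("acceleration zones plus monitored zone exceed hallway")
        if self.walk_pace_label not in ("regular", "fast"):
            raise FormatError("walk_pace_label must be 'regular' or 'fast'")

    @property
    def monitored_start(self) -> float:
        return self.accel_zone

    @property
    def monitored_end(self) -> float:
        return self.accel_zone + self.monitored_zone


@dataclass
class GaitMetrics:
    """Per-trial gait summary with provenance and fit diagnostics."""

    speed: float = np.nan
    cadence: float = np.nan
    speed_r2: float = np.nan
    trimmed_fraction: float = np.nan
    n_steps_detected: int = 0
    source: dict = field(default_factory=dict)  # e.g. {"speed": "kinect"}
    quality_flag: str = "ok"  # ok | trim_failed | too_few_steps

    def __post_init__(self) -> None:
        if np.isfinite(self.speed) and self.speed < 0:
            raise FormatError("speed must be >= 0")
        if np.isfinite(self.cadence) and self.cadence < 0:
            raise FormatError("cadence must be >= 0")
        if np.isfinite(self.speed_r2) and not 0 <= self.speed_r2 <= 1 + 1e-12:
            raise FormatError("speed_r2 must lie in [0, 1]")

    def to_row(self) -> dict:
        row = {
            "speed_mps": self.speed,
            "cadence_spm": self.cadence,
            "speed_r2": self.speed_r2,
            "trimmed_fraction": self.trimmed_fraction,
            "n_steps_detected": self.n_steps_detected,
            "quality_flag": self.quality_flag,
        }
        for k, v in self.source.items():
            row[f"source_{k}"] = v
        return row


@dataclass
class SubjectRecord:
    """One study participant's covariates."""

    id: str
    age: float
    sex: str
    fried_score: int
    qor15: int
    stopwatch_speeds: dict = field(default_factory=dict)  # trial label -> m/s
    smwt_distance: float | None = None
    activity_level: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise FormatError("sex must be 'F' or 'M'")
        if not 0 <= self.fried_score <= 5:
            raise FormatError("fried_score must lie in [0, 5]")
        if not 0 <= self.qor15 <= 150:
            raise FormatError("qor15 must lie in [0, 150]")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _joint_columns(joint_names: Sequence[str]) -> list[str]:
    return [f"{j}_{a}" for j in joint_names for a in _AXES]


def read_joint_stream(path: str | Path, units: str = "m") -> JointStream:
    """Read a skeleton stream from a wide CSV.

    The file must have a ``time_s`` column followed by ``<joint>_<axis>``
    columns; NaN (empty cells) mark dropouts.  ``units`` may be ``"m"``
    (default) or ``"mm"``; millimeter inputs are converted on read.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise FormatError("joint stream CSV must have a time_s column")
    names: list[str] = []
    for col in df.columns:
        if col == "time_s":
            continue
        if col.endswith("_x"):
            names.append(col[:-2])
    for j in names:
        for a in _AXES:
            if f"{j}_{a}" not in df.columns:
                raise FormatError(f"missing column {j}_{a}")
    if "pelvis" not in names:
        raise FormatError("joint stream must include pelvis columns")
    t = df["time_s"].to_numpy(dtype=float)
    pos = np.empty((len(df), len(names), 3))
    for ji, j in enumerate(names):
        for ai, a in enumerate(_AXES):
            pos[:, ji, ai] = df[f"{j}_{a}"].to_numpy(dtype=float)
    if units == "mm":
        pos = pos / 1000.0
    elif units != "m":
        raise FormatError(f"unknown units {units!r}")
    return JointStream(t, pos, tuple(names))


def write_joint_stream(stream: JointStream, path: str | Path) -> None:
    """Write a skeleton stream as a wide CSV (inverse of read_joint_stream)."""
    cols = {"time_s": stream.timestamps}
    for ji, j in enumerate(stream.joint_names):
        for ai, a in enumerate(_AXES):
            cols[f"{j}_{a}"] = stream.positions[:, ji, ai]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_vibration(path: str | Path, sidecar: str | Path) -> VibrationRecord:
    """Read a floor-vibration record from a channel CSV plus a JSON sidecar.

    The CSV holds columns ``ch1..chN`` and no time column: uniform sampling
    is asserted through the sidecar's ``sample_rate`` (this avoids bloating
    multi-kHz files with redundant timestamps).  The sidecar also carries
    ``layout`` (per-sensor [u, v] meters), ``daq_group`` and ``sync_pair``.
    """
    with open(sidecar) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path, float_precision="round_trip")
    n_chan = len(df.columns)
    expected = [f"ch{i + 1}" for i in range(n_chan)]
    if list(df.columns) != expected:
        raise FormatError("vibration CSV columns must be ch1..chN in order")
    if len(meta["layout"]) != n_chan or len(meta["daq_group"]) != n_chan:
        raise FormatError(
            f"sidecar declares {len(meta['layout'])} channels, CSV has {n_chan}"
        )
    data = df.to_numpy(dtype=float).T
    if np.any(~np.isfinite(data)):
        raise FormatError("vibration channels must be finite (ragged channels?)")
    sync = meta.get("sync_pair")
    return VibrationRecord(
        sample_rate=float(meta["sample_rate"]),
        data=data,
        layout=np.asarray(meta["layout"], dtype=float),
        daq_group=tuple(meta["daq_group"]),
        sync_pair=tuple(sync) if sync is not None else None,
    )


def write_vibration(
    record: VibrationRecord, path: str | Path, sidecar: str | Path
) -> None:
    """Write a vibration record as channel CSV + JSON sidecar."""
    cols = {f"ch{i + 1}": record.data[i] for i in range(record.n_channels)}
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "sample_rate": record.sample_rate,
        "layout": record.layout.tolist(),
        "daq_group": list(record.daq_group),
        "sync_pair": list(record.sync_pair) if record.sync_pair else None,
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


_SUBJECT_COLS = ("id", "age", "sex", "fried_score", "qor15")


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject covariates table."""
    df = pd.read_csv(path)
    for col in _SUBJECT_COLS:
        if col not in df.columns:
            raise FormatError(f"subjects table missing column {col!r}")
    if not df["sex"].isin(("F", "M")).all():
        raise FormatError("sex must be 'F' or 'M'")
    if not df["fried_score"].between(0, 5).all():
        raise FormatError("fried_score must lie in [0, 5]")
    if not df["qor15"].between(0, 150).all():
        raise FormatError("qor15 must lie in [0, 150]")
    return df
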