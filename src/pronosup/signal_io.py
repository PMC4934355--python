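"""Reading, writing and validation of raw MARG recordings and rating tables.

The on-disk dialect is plain CSV (comma separator, dot decimal, mandatory
header, UTF-8), one file per sensor.  A raw trace file carries the ten
columns ``t,ax,ay,az,gx,gy,gz,mx,my,mz``: time in seconds, acceleration in
g, angular rate in °/s, magnetic field in µT.  Physical validity is checked
against the sensor's measuring ranges (±4 g, ±2000 °/s, ±1200 µT).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError, ValidationError

__all__ = [
    "Placement",
    "ImuTrace",
    "Recording",
    "RatingTable",
    "PipelineConfig",
    "ACCEL_RANGE_G",
    "GYRO_RANGE_DPS",
    "MAG_RANGE_UT",
    "read_imu_csv",
    "write_imu_csv",
    "read_ratings",
    "write_ratings",
    "load_config",
]

#: Sensor measuring ranges used as validation bounds.
ACCEL_RANGE_G = 4.0
GYRO_RANGE_DPS = 2000.0
MAG_RANGE_UT = 1200.0

RAW_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]


class Placement(str, Enum):
    """Sensor placement: body segment x side."""

    WRIST_LEFT = "wrist_left"
    WRIST_RIGHT = "wrist_right"
    UPPER_ARM_LEFT = "upper_arm_left"
    UPPER_ARM_RIGHT = "upper_arm_right"

    @property
    def side(self) -> str:
        return "left" if self.value.endswith("left") else "right"

    @property
    def segment(self) -> str:
        return "wrist" if self.value.startswith("wrist") else "upper_arm"


@dataclass
class ImuTrace:
    """One sensor's timestamped 9-axis raw stream.

    Channels are (n, 3) float arrays: ``accel`` in g, ``gyro`` in °/s,
    ``mag`` in µT.  ``t`` is strictly increasing, in seconds.
    """

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    placement: Placement
    sample_rate_nominal: float = 100.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        self.placement = Placement(self.placement)
        self.validate()

    def __len__(self) -> int:
        return self.t.size

    def validate(self) -> None:
        n = self.t.size
        for name, arr in (("accel", self.accel), ("gyro", self.gyro), ("mag", self.mag)):
            if arr.shape != (n, 3):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected ({n}, 3)")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise ValidationError(
                    f"timestamps not strictly increasing at row {row}")
            med = float(np.median(dt))
            nominal = 1.0 / self.sample_rate_nominal
            if not (0.8 * nominal <= med <= 1.2 * nominal):
                raise ValidationError(
                    f"median sample interval {med:.4f}s outside 20% of "
                    f"nominal {nominal:.4f}s")
        _check_range("accel", self.accel, ACCEL_RANGE_G)
        _check_range("gyro", self.gyro, GYRO_RANGE_DPS)
        _check_range("mag", self.mag, MAG_RANGE_UT)


def _check_range(name: str, arr: np.ndarray, bound: float) -> None:
    bad = np.abs(arr) > bound
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise RangeError(
            f"{name} value {arr[bad][0]:g} at row {row} exceeds ±{bound:g}")


@dataclass
class Recording:
    """A set of sensor traces for one task execution of one subject."""

    traces: dict[Placement, ImuTrace]
    subject_id: str = ""
    side_performed: str = "unknown"  # left | right | unknown

    def __post_init__(self):
        self.traces = {Placement(k): v for k, v in self.traces.items()}
        if not self.traces:
            raise ValidationError("recording has no traces")
        if self.side_performed not in ("left", "right", "unknown"):
            raise ValidationError(f"bad side_performed {self.side_performed!r}")
        spans = [(tr.t[0], tr.t[-1]) for tr in self.traces.values() if len(tr) > 0]
        lo = max(s for s, _ in spans)
        hi = min(e for _, e in spans)
        if hi <= lo:
            raise ValidationError("traces do not cover a common time span")

    def wrist_trace(self, side: str | None = None) -> ImuTrace:
        """The wrist trace of the performing side (required for features)."""
        side = side or self.side_performed
        for pl, tr in self.traces.items():
            if pl.segment == "wrist" and (side == "unknown" or pl.side == side):
                return tr
        raise ValidationError(f"no wrist trace for side {side!r}")

    def upper_arm_trace(self, side: str | None = None) -> ImuTrace | None:
        side = side or self.side_performed
        for pl, tr in self.traces.items():
            if pl.segment == "upper_arm" and (side == "unknown" or pl.side == side):
                return tr
        return None


@dataclass
class RatingTable:
    """Items x raters matrix of integer scores 0-4; NaN marks missing cells."""

    items: list[str]
    raters: list[str]
    scores: np.ndarray  # float matrix, NaN = missing

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.items), len(self.raters)):
            raise ValidationError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.items)} items x {len(self.raters)} raters")
        present = self.scores[~np.isnan(self.scores)]
        if present.size and (
                np.any(present != np.round(present))
                or np.any(present < 0) or np.any(present > 4)):
            raise ValidationError("scores must be integers in {0..4} or missing")

    def column(self, rater: str) -> np.ndarray:
        return self.scores[:, self.raters.index(rater)]


def read_imu_csv(path: str | Path, placement: Placement | str,
                 sample_rate_nominal: float = 100.0) -> ImuTrace:
    """Parse one raw sensor CSV into a validated :class:`ImuTrace`."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in RAW_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing column {col!r}")
    t = df["t"].to_numpy(dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValidationError(
            f"{path.name}: non-monotone timestamp at row {row}")
    return ImuTrace(
        t=t,
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        mag=df[["mx", "my", "mz"]].to_numpy(dtype=float),
        placement=Placement(placement),
        sample_rate_nominal=sample_rate_nominal,
    )


def write_imu_csv(trace: ImuTrace, path: str | Path) -> None:
    """Write a trace in the raw CSV dialect (6 decimal places)."""
    data = np.column_stack([trace.t, trace.accel, trace.gyro, trace.mag])
    df = pd.DataFrame(data, columns=RAW_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_ratings(path: str | Path) -> RatingTable:
    """Read a rating-table CSV: first column item id, one column per rater."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError("rating table needs an item column and >= 1 rater column")
    items = df.iloc[:, 0].astype(str).tolist()
    raters = [str(c) for c in df.columns[1:]]
    scores = df.iloc[:, 1:].to_numpy(dtype=float)
    return RatingTable(items=items, raters=raters, scores=scores)


def write_ratings(table: RatingTable, path: str | Path) -> None:
    df = pd.DataFrame(table.scores, columns=table.raters)
    df.insert(0, "item_id", table.items)
    # keep integers readable; NaN cells stay empty
    df.to_csv(path, index=False, float_format="%g")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (JSON-serializable).

    Defaults follow the processing chain: 10 Hz zero-phase low-pass,
    Madgwick gain β = 0.041, threshold state-machine segmentation.
    """

    lowpass_cutoff: float = 10.0
    lowpass_order: int = 2
    beta: float = 0.041
    seg_pitch_rise_deg: float = 20.0
    seg_envelope_dps: float = 30.0
    seg_hysteresis_s: float = 0.25
    tree_min_leaf: int = 2
    tree_confidence: float = 0.25
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_json(path)
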