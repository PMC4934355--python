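"""Movement-side detection and export of the 60 Hz avatar animation stream.

A renderer (out of scope here) consumes a JSON stream of per-frame lower-
and upper-arm quaternions.  Because the skeleton's forearm bone inherits
the upper-arm bone's motion, the lower-arm orientation is re-expressed
relative to the upper arm: ``q_rel = q_upper⁻¹ ⊗ q_lower``.

The side of movement is inferred from the rotation angle (integral of the
forearm-axis angular rate) during PS: supination from the horizontal
reaches a typically much larger angle (~120°) than pronation (~30°), so
the sign of the dominant excursion identifies which arm (and hence sensor
axis orientation) produced the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputError
from .features import rotation_angle
from .orientation import (OrientationTrace, quat_conjugate, quat_multiply,
                          resample_spline)
from .segmentation import PhaseSegmentation

__all__ = ["AnimationStream", "SideDetection", "detect_side", "compose_stream"]


@dataclass
class SideDetection:
    side: str                  # left | right | undetermined
    peak_supination_deg: float
    peak_pronation_deg: float

    @property
    def determined(self) -> bool:
        return self.side in ("left", "right")


@dataclass
class AnimationStream:
    """Uniform-rate frames of (t, lower-arm q, upper-arm q) plus metadata."""

    frame_rate: float
    t: np.ndarray
    q_lower: np.ndarray
    q_upper: np.ndarray
    side: str
    camera_hint: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.q_lower = np.asarray(self.q_lower, float)
        self.q_upper = np.asarray(self.q_upper, float)
        n = self.t.size
        if self.q_lower.shape != (n, 4) or self.q_upper.shape != (n, 4):
            raise InputError("frame arrays must be (n, 4) quaternions")
        if not self.camera_hint:
            self.camera_hint = f"camera_{self.side}" if self.side in (
                "left", "right") else "camera_front"

    def __len__(self) -> int:
        return self.t.size

    def to_json(self, path: str | Path) -> None:
        payload = {
            "frame_rate": self.frame_rate,
            "side": self.side,
            "camera_hint": self.camera_hint,
            "frames": [
                {"t": round(float(t), 6),
                 "q_lower": [round(float(v), 9) for v in ql],
                 "q_upper": [round(float(v), 9) for v in qu]}
                for t, ql, qu in zip(self.t, self.q_lower, self.q_upper)
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnimationStream":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        frames = payload["frames"]
        ql = np.array([f["q_lower"] for f in frames], float)
        qu = np.array([f["q_upper"] for f in frames], float)
        ql /= np.linalg.norm(ql, axis=1, keepdims=True)
        qu /= np.linalg.norm(qu, axis=1, keepdims=True)
        return cls(frame_rate=payload["frame_rate"],
                   t=np.array([f["t"] for f in frames], float),
                   q_lower=ql, q_upper=qu, side=payload["side"],
                   camera_hint=payload.get("camera_hint", ""))


def detect_side(gyro_x: np.ndarray, t: np.ndarray, seg: PhaseSegmentation,
                symmetric_margin_deg: float = 10.0) -> SideDetection:
    """Infer the performing side from the PS rotation-angle excursions.

    Integrates gyro_x over the PS phase; the excursion in the supination
    direction is far larger than in the pronation direction, so the sign of
    the dominant excursion maps to the side.  Right-arm convention: sensor
    x distal along the forearm, supination = positive rotation.  Excursions
    symmetric within ``symmetric_margin_deg`` yield ``undetermined``.
    """
    s, e = seg["PS"]
    g = np.asarray(gyro_x, float)[s:e]
    tt = np.asarray(t, float)[s:e]
    if g.size < 2:
        raise InputError("PS phase is empty")
    ang = rotation_angle(g, tt)
    ang -= ang[0]
    peak_pos = float(np.max(ang))
    peak_neg = float(-np.min(ang))
    if abs(peak_pos - peak_neg) < symmetric_margin_deg:
        return SideDetection(side="undetermined",
                             peak_supination_deg=max(peak_pos, peak_neg),
                             peak_pronation_deg=min(peak_pos, peak_neg))
    if peak_pos >= peak_neg:
        return SideDetection(side="right", peak_supination_deg=peak_pos,
                             peak_pronation_deg=peak_neg)
    return SideDetection(side="left", peak_supination_deg=peak_neg,
                         peak_pronation_deg=peak_pos)


def compose_stream(lower: OrientationTrace, upper: OrientationTrace,
                   side: str, frame_rate: float = 60.0) -> AnimationStream:
    """Build the animation stream: both traces at ``frame_rate`` on their
    common time span, with the lower arm re-expressed relative to the upper
    arm (``q_upper⁻¹ ⊗ q_lower``)."""
    t0 = max(lower.t[0], upper.t[0])
    t1 = min(lower.t[-1], upper.t[-1])
    if t1 <= t0:
        raise InputError("orientation traces do not overlap in time")

    def crop(tr: OrientationTrace) -> OrientationTrace:
        keep = (tr.t >= t0 - 1e-9) & (tr.t <= t1 + 1e-9)
        return OrientationTrace(t=tr.t[keep], q=tr.q[keep],
                                source_placement=tr.source_placement)

    lo = resample_spline(crop(lower), frame_rate)
    up = resample_spline(crop(upper), frame_rate)
    n = min(len(lo), len(up))
    q_rel = np.array([
        quat_multiply(quat_conjugate(up.q[i]), lo.q[i]) for i in range(n)])
    q_rel /= np.linalg.norm(q_rel, axis=1, keepdims=True)
    return AnimationStream(frame_rate=frame_rate, t=lo.t[:n],
                           q_lower=q_rel, q_upper=up.q[:n], side=side)
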