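"""Seven-phase segmentation of a pronation-supination recording.

The task has a fixed structure: rest on the thigh (RE1), lift the arm to
roughly 45° (LI), hold (HO1), at least ten alternating hand turns (PS),
hold (HO2), lower the arm (LO), rest (RE2).  A deterministic threshold
state machine recovers the seven intervals from two derived signals:

* the forearm pitch angle (elevation of the sensor x-axis) and its rate,
  which delimit the lift and lower ramps, and
* a moving-RMS envelope of the forearm-axis angular rate ``gyro_x``, which
  delimits the oscillatory PS phase.  Sub-threshold gaps inside the
  oscillatory region (rhythm interruptions) are bridged up to a
  configurable gap length.

Detected threshold crossings are refined to the actual motion onset/offset
(where the smoothed pitch rate leaves its noise band, or where |gyro_x|
first rises from the floor), so boundaries land at the start of movement
rather than mid-ramp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import InputError, SegmentationError
from .orientation import OrientationTrace, pitch_series

__all__ = [
    "PHASES",
    "SegmentationConfig",
    "PhaseSegmentation",
    "segment_phases",
    "extract_phase",
    "count_sign_alternations",
]

PHASES = ("RE1", "LI", "HO1", "PS", "HO2", "LO", "RE2")


@dataclass
class SegmentationConfig:
    """Thresholds of the phase state machine (all config-exposed)."""

    pitch_rise_deg: float = 20.0     # pitch crossing that anchors the lift
    envelope_dps: float = 30.0       # gyro_x RMS envelope for PS activity
    hysteresis_s: float = 0.25       # envelope / smoothing window
    merge_gap_s: float = 3.0         # bridge sub-threshold gaps inside PS
    pitch_rate_eps_dps: float = 5.0  # pitch-rate noise band for ramp edges
    onset_dps: float = 10.0          # |gyro_x| floor that counts as activity
    edge_dps: float = 2.5            # smoothed-|gyro_x| level for PS edges


@dataclass
class PhaseSegmentation:
    """Ordered, contiguous, half-open intervals labeled RE1..RE2.

    ``intervals`` maps each of the seven labels to (start, end) sample
    indices; intervals tile [0, n) in the fixed phase order.
    """

    intervals: dict[str, tuple[int, int]]
    n_samples: int

    def __post_init__(self):
        if tuple(self.intervals.keys()) != PHASES:
            raise InputError(
                f"labels must be exactly {PHASES} in order, "
                f"got {tuple(self.intervals)}")
        prev_end = 0
        for label, (s, e) in self.intervals.items():
            if s != prev_end:
                raise InputError(
                    f"{label} starts at {s}, expected {prev_end} (gap/overlap)")
            if e < s:
                raise InputError(f"{label} has negative length")
            prev_end = e
        if prev_end != self.n_samples:
            raise InputError(
                f"intervals cover [0, {prev_end}), trace has {self.n_samples}")

    def __getitem__(self, label: str) -> tuple[int, int]:
        if label not in self.intervals:
            raise KeyError(f"unknown phase label {label!r}")
        return self.intervals[label]

    def to_json(self, path: str | Path, t: np.ndarray | None = None) -> None:
        rows = []
        for label, (s, e) in self.intervals.items():
            row = {"label": label, "start_idx": int(s), "end_idx": int(e)}
            if t is not None:
                row["start_s"] = float(t[s]) if s < len(t) else float(t[-1])
                row["end_s"] = float(t[e - 1]) if e > s else row["start_s"]
            rows.append(row)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "PhaseSegmentation":
        with open(path, "r", encoding="utf-8") as fh:
            rows = json.load(fh)
        intervals = {r["label"]: (r["start_idx"], r["end_idx"]) for r in rows}
        return cls(intervals=intervals, n_samples=rows[-1]["end_idx"])


def moving_rms(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving RMS with edge replication."""
    window = max(1, int(window))
    ms = uniform_filter1d(np.asarray(x, float) ** 2, size=window, mode="nearest")
    return np.sqrt(np.clip(ms, 0.0, None))


def count_sign_alternations(x: np.ndarray, threshold: float) -> int:
    """Number of alternating-sign excursions (Schmitt-trigger pulse count).

    An excursion is a maximal run during which the signal exceeds
    ``+threshold`` (or ``-threshold``) before next reaching the opposite
    band; sub-threshold wiggle does not count.
    """
    x = np.asarray(x, float)
    state = 0
    pulses = 0
    for v in x:
        if v > threshold and state != 1:
            state = 1
            pulses += 1
        elif v < -threshold and state != -1:
            state = -1
            pulses += 1
    return pulses


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as half-open index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[0::2], idx[1::2]))


def segment_phases(otrace: OrientationTrace, gyro_x: np.ndarray,
                   cfg: SegmentationConfig | None = None) -> PhaseSegmentation:
    """Partition a recording into the seven task phases.

    ``gyro_x`` is the forearm-axis angular rate in °/s on the same time base
    as ``otrace``.  Raises :class:`SegmentationError` (carrying the envelope
    for diagnosis) when no oscillatory PS-like region exists.
    """
    cfg = cfg or SegmentationConfig()
    t = otrace.t
    g = np.asarray(gyro_x, float)
    if g.size != t.size:
        raise InputError("gyro_x and orientation trace are not aligned")
    n = t.size
    if n < 20:
        raise InputError("recording too short to segment")
    fs = 1.0 / float(np.median(np.diff(t)))
    win = max(3, int(round(cfg.hysteresis_s * fs)))

    # --- PS phase from the gyro_x envelope -------------------------------
    env = moving_rms(g, win)
    if float(np.max(env)) <= cfg.envelope_dps:
        raise SegmentationError(
            "no oscillatory region above the envelope threshold",
            envelope=env, threshold=cfg.envelope_dps)
    # adaptive working threshold: a fading performance (amplitude decrement)
    # can drop the envelope of late turns below the configured level while
    # still being task activity, so track a fraction of the observed peak —
    # never below 10 °/s, never above the configured threshold
    thr = max(10.0, min(cfg.envelope_dps, 0.1 * float(np.max(env))))
    active = env > thr
    runs = _runs(active)
    # bridge interruption gaps, then take the longest merged run
    merged = [list(runs[0])]
    max_gap = int(round(cfg.merge_gap_s * fs))
    for s, e in runs[1:]:
        if s - merged[-1][1] <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    ps_s, ps_e = max(merged, key=lambda r: r[1] - r[0])

    # refine edges to where motion actually leaves the noise floor: the
    # smoothed |gyro_x| has a sub-degree/s noise floor, so a low edge level
    # catches the slow tail of the final turn; search out to the
    # bridgeable-gap span so a weak final turn is not clipped
    g_abs = uniform_filter1d(np.abs(g), size=max(3, int(round(0.2 * fs))),
                             mode="nearest")
    # the configured edge level assumes the default noise floor; track the
    # actual floor (median smoothed |rate| over the sub-threshold samples —
    # rests, holds and pauses) so extra sensor noise cannot masquerade as
    # activity
    quiet = g_abs[env <= thr]
    floor = float(np.median(quiet)) if quiet.size else 0.0
    edge = max(cfg.edge_dps, 3.5 * floor)
    lo = max(0, ps_s - max_gap)
    seg = np.flatnonzero(g_abs[lo:ps_s + win] > edge)
    if seg.size:
        ps_s = lo + int(seg[0])
    hi = min(n, ps_e + max_gap)
    seg = np.flatnonzero(g_abs[max(0, ps_e - win):hi] > edge)
    if seg.size:
        ps_e = max(0, ps_e - win) + int(seg[-1]) + 1

    n_alt = count_sign_alternations(g[ps_s:ps_e], thr)
    if n_alt < 3:
        raise SegmentationError(
            f"oscillatory region has only {n_alt} sign alternations",
            envelope=env, threshold=thr)

    # --- lift / lower ramps from the pitch angle -------------------------
    pitch = pitch_series(otrace)
    pitch_s = uniform_filter1d(pitch, size=win, mode="nearest")
    rate = np.gradient(pitch_s, t)
    eps = cfg.pitch_rate_eps_dps

    rest_pitch = float(np.median(pitch_s[:max(3, int(0.5 * fs))]))
    thr = rest_pitch + cfg.pitch_rise_deg

    li_s, li_e = _ramp_before(pitch_s, rate, thr, eps, ps_s)
    lo_s, lo_e = _ramp_after(pitch_s, rate, thr, eps, ps_e, n)

    bounds = _tidy_bounds([0, li_s, li_e, ps_s, ps_e, lo_s, lo_e, n], n)
    intervals = {label: (bounds[i], bounds[i + 1])
                 for i, label in enumerate(PHASES)}
    return PhaseSegmentation(intervals=intervals, n_samples=n)


def _ramp_before(pitch_s, rate, thr, eps, limit):
    """Locate the lift ramp (rising pitch) ending before sample ``limit``."""
    above = pitch_s[:limit] >= thr
    cross = np.flatnonzero(above)
    if cross.size == 0:
        # no clear lift: fall back to the fastest pitch rise before PS
        c = int(np.argmax(rate[:limit])) if limit > 0 else 0
    else:
        c = int(cross[0])
    lo = np.flatnonzero(rate[:c] < eps)
    li_s = int(lo[-1]) + 1 if lo.size else 0
    hi = np.flatnonzero(rate[c:limit] < eps)
    li_e = c + int(hi[0]) if hi.size else limit
    return li_s, li_e


def _ramp_after(pitch_s, rate, thr, eps, start, n):
    """Locate the lowering ramp (falling pitch) after sample ``start``."""
    below = pitch_s[start:] <= thr
    cross = np.flatnonzero(below)
    if cross.size == 0:
        c = start + int(np.argmin(rate[start:])) if start < n else n - 1
    else:
        c = start + int(cross[0])
    lo = np.flatnonzero(rate[start:c] > -eps)
    lo_s = start + int(lo[-1]) + 1 if lo.size else start
    hi = np.flatnonzero(rate[c:] > -eps)
    lo_e = c + int(hi[0]) if hi.size else n
    return lo_s, lo_e


def _tidy_bounds(bounds: list[int], n: int) -> list[int]:
    """Force boundaries into a strictly increasing tiling of [0, n].

    Phases squeezed to nothing (e.g. a hold shorter than one window) are
    emitted as minimal one-sample intervals to preserve the seven-label
    contract.
    """
    b = [int(max(0, min(n, v))) for v in bounds]
    b[0], b[-1] = 0, n
    for i in range(1, 7):
        if b[i] <= b[i - 1]:
            b[i] = b[i - 1] + 1
    for i in range(6, 0, -1):
        if b[i] >= b[i + 1]:
            b[i] = b[i + 1] - 1
    if b[0] != 0 or any(b[i] >= b[i + 1] for i in range(7)):
        raise SegmentationError("recording too short for seven phases")
    return b


def extract_phase(seq, seg: PhaseSegmentation, label: str):
    """Half-open slice of any per-sample sequence for one phase label."""
    s, e = seg[label]
    return np.asarray(seq)[s:e]
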