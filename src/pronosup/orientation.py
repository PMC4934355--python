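"""Orientation estimation: low-pass filtering, Madgwick MARG fusion, Euler
angles and spline resampling.

The Madgwick filter is the original gradient-descent complementary filter:
gyroscope quaternion integration corrected, at rate β, by the normalized
gradient of an objective aligning predicted gravity and magnetic field with
the accelerometer/magnetometer measurements.  Quaternions are scalar-first
(w, x, y, z) and represent the sensor-to-earth rotation: ``v_earth =
q ⊗ v_sensor ⊗ q*``.  The earth frame is right-handed with z up and x along
the horizontal projection of magnetic north.

Euler convention: intrinsic yaw-pitch-roll (z, then y', then x''), with
*pitch* reported as the elevation of the sensor x-axis above horizontal —
the "lift by approx. 45°" angle the phase segmentation keys on.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from math import asin, atan2, degrees, radians, sqrt
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .errors import InputError, ParameterError
from .signal_io import ImuTrace, Placement

__all__ = [
    "FusionConfig",
    "OrientationTrace",
    "lowpass",
    "madgwick_step",
    "estimate_orientation",
    "orientation_from_accel_mag",
    "to_euler",
    "from_euler",
    "quat_multiply",
    "quat_conjugate",
    "quat_rotate",
    "quat_angle_deg",
    "resample_spline",
]

log = logging.getLogger(__name__)


@dataclass
class FusionConfig:
    """Filter parameters: Madgwick gain β and the pre-fusion low-pass."""

    beta: float = 0.041
    lowpass_cutoff: float = 10.0
    lowpass_order: int = 2

    def __post_init__(self):
        if self.beta < 0:
            raise ParameterError("beta must be >= 0")
        if self.lowpass_cutoff <= 0:
            raise ParameterError("lowpass_cutoff must be > 0")


@dataclass
class OrientationTrace:
    """Unit-quaternion time series aligned to timestamps.

    ``q`` is (n, 4) scalar-first; every row is unit-norm within 1e-6.
    """

    t: np.ndarray
    q: np.ndarray
    source_placement: Placement | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (self.t.size, 4):
            raise InputError(
                f"q shape {self.q.shape} does not match {self.t.size} timestamps")
        norms = np.linalg.norm(self.q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InputError("quaternions must be unit-norm within 1e-6")

    def __len__(self) -> int:
        return self.t.size

    def euler_deg(self) -> np.ndarray:
        """(n, 3) array of (roll, pitch, yaw) in degrees."""
        return np.array([to_euler(qi)[0] for qi in self.q])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "t": self.t.tolist(),
            "q": np.round(self.q, 9).tolist(),
            "placement": self.source_placement.value if self.source_placement else None,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "OrientationTrace":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        q = np.asarray(payload["q"], dtype=float)
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        placement = Placement(payload["placement"]) if payload.get("placement") else None
        return cls(t=np.asarray(payload["t"], dtype=float), q=q,
                   source_placement=placement)


# ---------------------------------------------------------------------------
# quaternion algebra
# ---------------------------------------------------------------------------

def quat_multiply(a, b) -> np.ndarray:
    """Hamilton product a ⊗ b, scalar-first."""
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def quat_conjugate(q) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_rotate(q, v) -> np.ndarray:
    """Rotate 3-vector v by q: returns q ⊗ (0,v) ⊗ q*."""
    qv = np.array([0.0, v[0], v[1], v[2]])
    return quat_multiply(quat_multiply(q, qv), quat_conjugate(q))[1:]


def quat_angle_deg(qa, qb) -> float:
    """Geodesic rotation angle between two unit quaternions, degrees."""
    d = min(abs(float(np.dot(qa, qb))), 1.0)
    return degrees(2.0 * np.arccos(d))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def lowpass(trace: ImuTrace, cfg: FusionConfig) -> ImuTrace:
    """Zero-phase Butterworth low-pass of every channel.

    Forward-backward filtering (``filtfilt``) gives zero net phase shift, so
    zero-crossing and phase-boundary times are not displaced.
    """
    fs = trace.sample_rate_nominal
    nyq = fs / 2.0
    if cfg.lowpass_cutoff >= nyq:
        raise ParameterError(
            f"cutoff {cfg.lowpass_cutoff} Hz >= Nyquist {nyq} Hz")
    b, a = butter(cfg.lowpass_order, cfg.lowpass_cutoff / nyq)
    out = {}
    for name in ("accel", "gyro", "mag"):
        arr = getattr(trace, name)
        out[name] = filtfilt(b, a, arr, axis=0)
        # filtering can only shave peaks, never push a valid signal out of
        # range; clip defensively against edge ringing
    return ImuTrace(t=trace.t.copy(), placement=trace.placement,
                    sample_rate_nominal=trace.sample_rate_nominal, **out)


def lowpass_signal(x: np.ndarray, fs: float, cutoff: float = 10.0,
                   order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a bare 1-D signal."""
    nyq = fs / 2.0
    if cutoff >= nyq:
        raise ParameterError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    b, a = butter(order, cutoff / nyq)
    return filtfilt(b, a, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Madgwick MARG update
# ---------------------------------------------------------------------------

def madgwick_step(q, gyro_rad, accel, mag, beta: float, dt: float):
    """One MARG fusion step.

    Parameters: current unit quaternion (scalar-first), angular rate in
    rad/s, acceleration (any scale; only direction used), magnetic field
    (any scale), gain β, and the step dt in seconds.  With β = 0 this is
    pure gyroscope quaternion integration.  A zero-norm accelerometer or
    magnetometer sample degrades to a gyro-only step (logged), never an
    exception.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    q0, q1, q2, q3 = float(q[0]), float(q[1]), float(q[2]), float(q[3])
    gx, gy, gz = float(gyro_rad[0]), float(gyro_rad[1]), float(gyro_rad[2])
    ax, ay, az = float(accel[0]), float(accel[1]), float(accel[2])
    mx, my, mz = float(mag[0]), float(mag[1]), float(mag[2])

    qDot0 = 0.5 * (-q1 * gx - q2 * gy - q3 * gz)
    qDot1 = 0.5 * (q0 * gx + q2 * gz - q3 * gy)
    qDot2 = 0.5 * (q0 * gy - q1 * gz + q3 * gx)
    qDot3 = 0.5 * (q0 * gz + q1 * gy - q2 * gx)

    anorm = sqrt(ax * ax + ay * ay + az * az)
    mnorm = sqrt(mx * mx + my * my + mz * mz)
    if beta > 0.0 and anorm > 0.0 and mnorm > 0.0:
        ax, ay, az = ax / anorm, ay / anorm, az / anorm
        mx, my, mz = mx / mnorm, my / mnorm, mz / mnorm

        q0q0, q1q1, q2q2, q3q3 = q0 * q0, q1 * q1, q2 * q2, q3 * q3
        # earth-frame field reference from the current estimate: the measured
        # field rotated to earth, with its horizontal component collapsed
        # onto x (magnetic-distortion compensation)
        hx = (mx * (q0q0 + q1q1 - q2q2 - q3q3)
              + 2.0 * my * (q1 * q2 - q0 * q3)
              + 2.0 * mz * (q0 * q2 + q1 * q3))
        hy = (2.0 * mx * (q1 * q2 + q0 * q3)
              + my * (q0q0 - q1q1 + q2q2 - q3q3)
              + 2.0 * mz * (q2 * q3 - q0 * q1))
        _2bx = 2.0 * sqrt(hx * hx + hy * hy)
        _2bz = 2.0 * (2.0 * mx * (q1 * q3 - q0 * q2)
                      + 2.0 * my * (q0 * q1 + q2 * q3)
                      + mz * (q0q0 - q1q1 - q2q2 + q3q3))
        _4bx, _4bz = 2.0 * _2bx, 2.0 * _2bz

        f1 = 2.0 * (q1 * q3 - q0 * q2) - ax
        f2 = 2.0 * (q0 * q1 + q2 * q3) - ay
        f3 = 1.0 - 2.0 * (q1q1 + q2q2) - az
        f4 = _2bx * (0.5 - q2q2 - q3q3) + _2bz * (q1 * q3 - q0 * q2) - mx
        f5 = _2bx * (q1 * q2 - q0 * q3) + _2bz * (q0 * q1 + q2 * q3) - my
        f6 = _2bx * (q0 * q2 + q1 * q3) + _2bz * (0.5 - q1q1 - q2q2) - mz

        s0 = (-2.0 * q2 * f1 + 2.0 * q1 * f2
              - _2bz * q2 * f4
              + (-_2bx * q3 + _2bz * q1) * f5
              + _2bx * q2 * f6)
        s1 = (2.0 * q3 * f1 + 2.0 * q0 * f2 - 4.0 * q1 * f3
              + _2bz * q3 * f4
              + (_2bx * q2 + _2bz * q0) * f5
              + (_2bx * q3 - _4bz * q1) * f6)
        s2 = (-2.0 * q0 * f1 + 2.0 * q3 * f2 - 4.0 * q2 * f3
              + (-_4bx * q2 - _2bz * q0) * f4
              + (_2bx * q1 + _2bz * q3) * f5
              + (_2bx * q0 - _4bz * q2) * f6)
        s3 = (2.0 * q1 * f1 + 2.0 * q2 * f2
              + (-_4bx * q3 + _2bz * q1) * f4
              + (-_2bx * q0 + _2bz * q2) * f5
              + _2bx * q1 * f6)
        snorm = sqrt(s0 * s0 + s1 * s1 + s2 * s2 + s3 * s3)
        if snorm > 0.0:
            qDot0 -= beta * s0 / snorm
            qDot1 -= beta * s1 / snorm
            qDot2 -= beta * s2 / snorm
            qDot3 -= beta * s3 / snorm
    elif beta > 0.0:
        log.warning("zero-norm accel or mag sample; gyro-only step")

    q0 += qDot0 * dt
    q1 += qDot1 * dt
    q2 += qDot2 * dt
    q3 += qDot3 * dt
    norm = sqrt(q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3)
    return np.array([q0 / norm, q1 / norm, q2 / norm, q3 / norm])


def orientation_from_accel_mag(accel, mag) -> np.ndarray:
    """Initial sensor-to-earth quaternion from one static accel/mag sample.

    TRIAD-style alignment: the accelerometer fixes "up", the magnetometer's
    horizontal component fixes north.
    """
    up = np.asarray(accel, dtype=float)
    nu = np.linalg.norm(up)
    if nu == 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    up /= nu
    m = np.asarray(mag, dtype=float)
    north = m - np.dot(m, up) * up
    nn = np.linalg.norm(north)
    if nn < 1e-12:
        # field parallel to gravity: heading undefined, pick tilt-only
        north = np.array([1.0, 0.0, 0.0]) - up[0] * up
        north /= np.linalg.norm(north)
    else:
        north /= nn
    west = np.cross(up, north)
    # rows = earth axes (x north, y west, z up) expressed in sensor frame,
    # i.e. the sensor->earth rotation matrix
    R = np.vstack([north, west, up])
    return _quat_from_matrix(R)


def _quat_from_matrix(R: np.ndarray) -> np.ndarray:
    """Scalar-first unit quaternion from a proper rotation matrix."""
    tr = R[0, 0] + R[1, 1] + R[2, 2]
    if tr > 0:
        s = sqrt(tr + 1.0) * 2.0
        w = 0.25 * s
        x = (R[2, 1] - R[1, 2]) / s
        y = (R[0, 2] - R[2, 0]) / s
        z = (R[1, 0] - R[0, 1]) / s
    elif R[0, 0] > R[1, 1] and R[0, 0] > R[2, 2]:
        s = sqrt(1.0 + R[0, 0] - R[1, 1] - R[2, 2]) * 2.0
        w = (R[2, 1] - R[1, 2]) / s
        x = 0.25 * s
        y = (R[0, 1] + R[1, 0]) / s
        z = (R[0, 2] + R[2, 0]) / s
    elif R[1, 1] > R[2, 2]:
        s = sqrt(1.0 + R[1, 1] - R[0, 0] - R[2, 2]) * 2.0
        w = (R[0, 2] - R[2, 0]) / s
        x = (R[0, 1] + R[1, 0]) / s
        y = 0.25 * s
        z = (R[1, 2] + R[2, 1]) / s
    else:
        s = sqrt(1.0 + R[2, 2] - R[0, 0] - R[1, 1]) * 2.0
        w = (R[1, 0] - R[0, 1]) / s
        x = (R[0, 2] + R[2, 0]) / s
        y = (R[1, 2] + R[2, 1]) / s
        z = 0.25 * s
    q = np.array([w, x, y, z])
    return q / np.linalg.norm(q)


def estimate_orientation(trace: ImuTrace, cfg: FusionConfig | None = None,
                         prefilter: bool = True) -> OrientationTrace:
    """Run the Madgwick filter over a raw trace, one quaternion per sample.

    The first quaternion is initialized from accelerometer/magnetometer
    alignment (the protocol starts at rest, so the first sample is static).
    Gyro is converted °/s → rad/s internally.
    """
    cfg = cfg or FusionConfig()
    if len(trace) < 10:
        raise InputError(f"trace of {len(trace)} samples is too short (< 10)")
    if prefilter:
        trace = lowpass(trace, cfg)
    t = trace.t
    gyro = np.radians(trace.gyro)
    accel = trace.accel
    mag = trace.mag
    # the task starts at rest, so average the first ~0.5 s for a noise-robust
    # accelerometer/magnetometer alignment (one magnetometer sample alone can
    # be tens of degrees off in heading)
    n0 = max(1, min(50, t.size // 4))
    q = orientation_from_accel_mag(accel[:n0].mean(axis=0), mag[:n0].mean(axis=0))
    n = t.size
    out = np.empty((n, 4))
    out[0] = q
    for i in range(1, n):
        dt = t[i] - t[i - 1]
        q = madgwick_step(q, gyro[i], accel[i], mag[i], cfg.beta, dt)
        out[i] = q
    # keep the quaternion stream sign-continuous for downstream splining
    for i in range(1, n):
        if np.dot(out[i], out[i - 1]) < 0:
            out[i] = -out[i]
    return OrientationTrace(t=t.copy(), q=out, source_placement=trace.placement)


# ---------------------------------------------------------------------------
# Euler conversions
# ---------------------------------------------------------------------------

def from_euler(roll_deg: float, pitch_deg: float, yaw_deg: float) -> np.ndarray:
    """Quaternion from intrinsic yaw-pitch-roll; pitch = x-axis elevation."""
    cy, sy = np.cos(radians(yaw_deg) / 2), np.sin(radians(yaw_deg) / 2)
    # pitch is elevation: +45° lift = rotation of -45° about +y with z up
    cp, sp = np.cos(radians(-pitch_deg) / 2), np.sin(radians(-pitch_deg) / 2)
    cr, sr = np.cos(radians(roll_deg) / 2), np.sin(radians(roll_deg) / 2)
    qz = np.array([cy, 0.0, 0.0, sy])
    qy = np.array([cp, 0.0, sp, 0.0])
    qx = np.array([cr, sr, 0.0, 0.0])
    return quat_multiply(quat_multiply(qz, qy), qx)


def to_euler(q) -> tuple[tuple[float, float, float], bool]:
    """(roll, pitch, yaw) in degrees, plus a gimbal-proximity flag.

    Pitch is the elevation of the sensor x-axis above horizontal; the flag is
    set when |pitch| > 89.9° (roll/yaw become ill-conditioned there but are
    still returned).
    """
    w, x, y, z = q
    # elevation of the body x-axis = earth-z component of R @ e_x = 2(xz - wy)
    elev = asin(min(1.0, max(-1.0, 2.0 * (x * z - w * y))))
    pitch = degrees(elev)
    gimbal = abs(pitch) > 89.9
    # roll about body x, yaw about earth z (ZYX factorization with theta=-elev)
    roll = degrees(atan2(2.0 * (y * z + w * x), 1.0 - 2.0 * (x * x + y * y)))
    yaw = degrees(atan2(2.0 * (x * y + w * z), 1.0 - 2.0 * (y * y + z * z)))
    return (roll, pitch, yaw), gimbal


def pitch_series(otrace: OrientationTrace) -> np.ndarray:
    """Vectorized x-axis elevation in degrees for every sample."""
    w, x, y, z = otrace.q[:, 0], otrace.q[:, 1], otrace.q[:, 2], otrace.q[:, 3]
    s = np.clip(2.0 * (x * z - w * y), -1.0, 1.0)
    return np.degrees(np.arcsin(s))


def roll_series(otrace: OrientationTrace) -> np.ndarray:
    """Vectorized roll angle (rotation about the forearm x-axis), degrees."""
    w, x, y, z = otrace.q[:, 0], otrace.q[:, 1], otrace.q[:, 2], otrace.q[:, 3]
    return np.degrees(np.arctan2(2.0 * (y * z + w * x),
                                 1.0 - 2.0 * (x * x + y * y)))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_spline(otrace: OrientationTrace, target_hz: float) -> OrientationTrace:
    """Resample to a uniform grid by component-wise cubic spline.

    Quaternion components are splined independently and renormalized to unit
    norm; for the slow rotations of this task the deviation from slerp is
    far below a degree.
    """
    if target_hz <= 0:
        raise ParameterError("target_hz must be > 0")
    if len(otrace) < 4:
        raise InputError("need >= 4 samples for cubic spline resampling")
    q = otrace.q.copy()
    for i in range(1, q.shape[0]):
        if np.dot(q[i], q[i - 1]) < 0:
            q[i] = -q[i]
    span = otrace.t[-1] - otrace.t[0]
    n_out = int(np.floor(span * target_hz + 1e-9)) + 1
    t_new = otrace.t[0] + np.arange(n_out) / target_hz
    spl = CubicSpline(otrace.t, q, axis=0)
    q_new = spl(t_new)
    norms = np.linalg.norm(q_new, axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        q_new = q_new / norms
    return OrientationTrace(t=t_new, q=q_new,
                            source_placement=otrace.source_placement)
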