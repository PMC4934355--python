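"""Oscillation features of the pronation-supination (PS) phase.

The forearm-axis angular rate is split at its zero crossings into single
oscillations (one hand turn each) and then into *pair segments* of two
adjacent oscillations — roughly one full pronation-supination cycle — so
that every interior oscillation belongs to exactly two segments.  Per
segment, three kinds of quantities are computed:

* speed: the maximum absolute angular rate;
* amplitude: the rotation angle (trapezoidal integral of the rate);
* rhythm: the coefficient of determination R² of sum-of-sines fits
  ``y = Σ aᵢ sin(bᵢ x + cᵢ)`` with one and with three terms.

Eight scalar features summarize the per-segment values (mean, median, SD,
quartiles, first-third/last-third ratios).  Additional per-recording
features can be registered via :func:`register_feature`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .errors import FeatureError, InputError, OscillationError

__all__ = [
    "PairSegment",
    "SumOfSinesFit",
    "FeatureVector",
    "FEATURE_NAMES",
    "zero_crossings",
    "build_pair_segments",
    "fit_sum_of_sines",
    "rotation_angle",
    "compute_features",
    "register_feature",
    "write_feature_table",
    "read_feature_table",
]

FEATURE_NAMES = (
    "mean_angRate",
    "median_rotAngle",
    "upQuart_rotAngle",
    "ratioQ13_angRate",
    "ratioQ13_rotAngle",
    "std_rsquare_1n",
    "mean_rsquare_3n",
    "std_rsquare_3n",
)


@dataclass
class PairSegment:
    """Two adjacent oscillations, bounded by zero-crossing times.

    ``start``/``end`` are half-open sample indices into the PS-phase
    sequence; ``osc_indices`` names the pair (k, k+1) of oscillations.
    """

    start: int
    end: int
    osc_indices: tuple[int, int]
    t_start: float = 0.0
    t_end: float = 0.0


@dataclass
class SumOfSinesFit:
    """Result of a sum-of-sines least-squares fit.

    Amplitudes are non-negative and sorted descending (sign folded into the
    phase) for identifiability; phases are wrapped to [-π, π).
    """

    n: int
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    r_squared: float
    converged: bool = True
    ss_res: float = 0.0

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return sum(ai * np.sin(bi * x + ci)
                   for ai, bi, ci in zip(self.a, self.b, self.c))


@dataclass
class FeatureVector:
    """The eight oscillation features of one recording."""

    mean_angRate: float          # °/s
    median_rotAngle: float       # °
    upQuart_rotAngle: float      # °
    ratioQ13_angRate: float      # dimensionless, >1 = slowing over the test
    ratioQ13_rotAngle: float     # dimensionless, >1 = amplitude decrement
    std_rsquare_1n: float
    mean_rsquare_3n: float
    std_rsquare_3n: float
    extras: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in FEATURE_NAMES}
        d.update(self.extras)
        return d

    def as_array(self, names=FEATURE_NAMES) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[n] for n in names], dtype=float)


#: registry of user-defined per-recording features: name -> fn(stats) -> float
_EXTRA_FEATURES: dict[str, Callable] = {}


def register_feature(name: str, fn: Callable) -> None:
    """Register an extra feature; ``fn`` receives the per-segment stats dict
    (keys ``max_rate``, ``ptp_angle``, ``q75_angle``, ``r2_1n``, ``r2_3n``,
    each an array over segments) and returns a scalar."""
    _EXTRA_FEATURES[name] = fn


# ---------------------------------------------------------------------------
# zero crossings and pair segments
# ---------------------------------------------------------------------------

def zero_crossings(signal: np.ndarray, t: np.ndarray,
                   hysteresis_level: float | None = None) -> np.ndarray:
    """Sub-sample zero-crossing times of an oscillatory signal.

    A Schmitt trigger suppresses noise-driven chatter: a crossing is only
    registered once the signal has left the ±h band on the opposite side,
    with h defaulting to 10% of the robust (95th-percentile) peak.  The
    crossing instant itself comes from linear interpolation of the first
    sign change after the band exit.
    """
    y = np.asarray(signal, float)
    t = np.asarray(t, float)
    if y.size != t.size:
        raise InputError("signal and t must have equal length")
    if hysteresis_level is None:
        h = 0.1 * float(np.percentile(np.abs(y), 95))
    else:
        h = float(hysteresis_level)
    h = max(h, 1e-12)

    crossings: list[float] = []
    state = 0
    band_idx = 0
    for i in range(y.size):
        s = 1 if y[i] > h else (-1 if y[i] < -h else 0)
        if s == 0:
            continue
        if state == 0:
            state = s
            band_idx = i
            continue
        if s == state:
            band_idx = i
            continue
        # opposite band reached: locate the sign change in between
        for j in range(band_idx, i):
            if (y[j] >= 0.0) != (y[j + 1] >= 0.0):
                denom = y[j + 1] - y[j]
                frac = -y[j] / denom if denom != 0 else 0.5
                crossings.append(float(t[j] + frac * (t[j + 1] - t[j])))
                break
        else:
            crossings.append(float(0.5 * (t[band_idx] + t[i])))
        state = s
        band_idx = i

    out = np.asarray(crossings)
    if out.size >= 3:
        # merge pathologically close crossings (< quarter median period)
        gaps = np.diff(out)
        min_gap = float(np.median(gaps)) / 4.0
        keep = np.concatenate([[True], gaps >= min_gap])
        out = out[keep]
    if out.size < 3:
        raise OscillationError(
            f"only {out.size} zero crossings; cannot form a pair segment")
    return out


def build_pair_segments(crossings: np.ndarray, t: np.ndarray) -> list[PairSegment]:
    """Pair segments from crossing times: n oscillations ⇒ n − 1 segments.

    Oscillation k spans [c_k, c_{k+1}); segment k spans oscillations
    (k, k+1), so consecutive segments share one oscillation.
    """
    c = np.asarray(crossings, float)
    t = np.asarray(t, float)
    if c.size < 3:
        raise OscillationError(
            f"{c.size} crossings give {max(c.size - 1, 0)} oscillations; "
            "need at least 2")
    segments = []
    for k in range(c.size - 2):
        start = int(np.searchsorted(t, c[k], side="left"))
        end = int(np.searchsorted(t, c[k + 2], side="right"))
        segments.append(PairSegment(start=start, end=end,
                                    osc_indices=(k, k + 1),
                                    t_start=float(c[k]), t_end=float(c[k + 2])))
    return segments


# ---------------------------------------------------------------------------
# sum-of-sines fitting
# ---------------------------------------------------------------------------

def _pack(a, b, c):
    return np.concatenate([a, b, c])


def _unpack(p, n):
    return p[:n], p[n:2 * n], p[2 * n:]


def _residuals(p, x, y, n):
    a, b, c = _unpack(p, n)
    model = np.zeros_like(x)
    for i in range(n):
        model += a[i] * np.sin(b[i] * x + c[i])
    return model - y


def _jacobian(p, x, y, n):
    a, b, c = _unpack(p, n)
    J = np.empty((x.size, 3 * n))
    for i in range(n):
        phase = b[i] * x + c[i]
        cos_ph = np.cos(phase)
        J[:, i] = np.sin(phase)
        J[:, n + i] = a[i] * x * cos_ph
        J[:, 2 * n + i] = a[i] * cos_ph
    return J


def _base_freq(y: np.ndarray, x: np.ndarray) -> float:
    """Angular frequency from the median crossing-to-crossing half-period."""
    try:
        c = zero_crossings(y, x)
        half = float(np.median(np.diff(c)))
        if half > 0:
            return np.pi / half
    except OscillationError:
        pass
    span = x[-1] - x[0]
    return np.pi / max(span, 1e-9)  # assume one half-cycle across the window


def fit_sum_of_sines(y: np.ndarray, t: np.ndarray, n: int = 1,
                     max_iter: int = 200) -> SumOfSinesFit:
    """Damped nonlinear least-squares fit of ``Σ aᵢ sin(bᵢx + cᵢ)``.

    Initialization is deterministic: the base angular frequency from the
    median crossing-to-crossing period, amplitude RMS·√2, phase 0; for
    n = 3 the remaining terms start at 2× and 3× the base frequency with a
    tenth of the amplitude.  For n = 3 a second deterministic start seeded
    from the converged n = 1 solution is also tried and the lower-residual
    optimum kept, which guarantees the nested-model property
    R²(3) ≥ R²(1).  Non-convergence is flagged, never raised.
    """
    if n not in (1, 3):
        raise InputError("n must be 1 or 3")
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    if y.size < 3 * (3 * n):
        raise InputError(
            f"segment of {y.size} samples cannot identify {3 * n} parameters")
    x = t - t[0]
    b0 = _base_freq(y, x)
    a0 = float(np.sqrt(np.mean(y ** 2)) * np.sqrt(2.0))
    a0 = max(a0, 1e-9)

    starts = []
    if n == 1:
        starts.append(_pack([a0], [b0], [0.0]))
    else:
        starts.append(_pack([a0, a0 / 10, a0 / 10],
                            [b0, 2 * b0, 3 * b0], [0.0, 0.0, 0.0]))
        base = fit_sum_of_sines(y, t, 1, max_iter=max_iter)
        starts.append(_pack([base.a[0], base.a[0] / 10, base.a[0] / 10],
                            [base.b[0], 2 * base.b[0], 3 * base.b[0]],
                            [base.c[0], 0.0, 0.0]))

    best = None
    converged = True
    for p0 in starts:
        res = least_squares(_residuals, p0, jac=_jacobian, args=(x, y, n),
                            method="lm", xtol=1e-10, ftol=1e-10,
                            max_nfev=max_iter)
        ssr = float(np.sum(res.fun ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, res)
    ss_res, res = best
    converged = res.status > 0

    a, b, c = _unpack(res.x, n)
    a, b, c = a.copy(), b.copy(), c.copy()
    # canonical form: a >= 0, b >= 0, c in [-pi, pi), sorted by amplitude
    for i in range(n):
        if b[i] < 0:
            b[i], c[i] = -b[i], -c[i] + np.pi  # sin(-bx+c) = sin(bx + pi - c)
        if a[i] < 0:
            a[i], c[i] = -a[i], c[i] + np.pi
        c[i] = (c[i] + np.pi) % (2 * np.pi) - np.pi
    order = np.argsort(-a, kind="stable")
    a, b, c = a[order], b[order], c[order]

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    return SumOfSinesFit(n=n, a=a, b=b, c=c, r_squared=float(r2),
                         converged=bool(converged), ss_res=ss_res)


# ---------------------------------------------------------------------------
# rotation angle and feature aggregation
# ---------------------------------------------------------------------------

def rotation_angle(gyro_x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cumulative rotation angle in degrees: trapezoidal integral of the
    angular rate, starting at 0."""
    g = np.asarray(gyro_x, float)
    t = np.asarray(t, float)
    return cumulative_trapezoid(g, t, initial=0.0)


def segment_stats(ps_gyro_x: np.ndarray, ps_t: np.ndarray,
                  segments: list[PairSegment]) -> dict[str, np.ndarray]:
    """Per-segment speed, amplitude and rhythm quantities."""
    max_rate, ptp_angle, q75_angle, r2_1, r2_3 = [], [], [], [], []
    for seg in segments:
        y = ps_gyro_x[seg.start:seg.end]
        tt = ps_t[seg.start:seg.end]
        if y.size < 9:
            raise FeatureError(
                f"pair segment {seg.osc_indices} has only {y.size} samples")
        ang = rotation_angle(y, tt)
        max_rate.append(float(np.max(np.abs(y))))
        ptp_angle.append(float(np.max(ang) - np.min(ang)))
        q75_angle.append(float(np.percentile(ang, 75)))
        r2_1.append(fit_sum_of_sines(y, tt, 1).r_squared)
        r2_3.append(fit_sum_of_sines(y, tt, 3).r_squared)
    return {
        "max_rate": np.array(max_rate),
        "ptp_angle": np.array(ptp_angle),
        "q75_angle": np.array(q75_angle),
        "r2_1n": np.array(r2_1),
        "r2_3n": np.array(r2_3),
    }


def compute_features(ps_gyro_x: np.ndarray, ps_t: np.ndarray,
                     segments: list[PairSegment] | None = None) -> FeatureVector:
    """The eight oscillation features from the PS-phase angular rate.

    Thirds for the decrement ratios: with m segments, the first and last
    ⌊m/3⌋ segments form the outer thirds (remainder goes to the excluded
    middle), so a slowing/shrinking performance gives ratios above one.
    """
    ps_gyro_x = np.asarray(ps_gyro_x, float)
    ps_t = np.asarray(ps_t, float)
    if segments is None:
        crossings = zero_crossings(ps_gyro_x, ps_t)
        segments = build_pair_segments(crossings, ps_t)
    m = len(segments)
    if m < 4:
        raise FeatureError(
            f"only {m} pair segments; need >= 4 for thirds-based ratios")
    stats = segment_stats(ps_gyro_x, ps_t, segments)
    k = m // 3
    first, last = slice(0, k), slice(m - k, m)

    def ratio(v):
        denom = float(np.mean(v[last]))
        return float(np.mean(v[first])) / denom if denom != 0 else np.inf

    fv = FeatureVector(
        mean_angRate=float(np.mean(stats["max_rate"])),
        median_rotAngle=float(np.median(stats["ptp_angle"])),
        upQuart_rotAngle=float(np.mean(stats["q75_angle"])),
        ratioQ13_angRate=ratio(stats["max_rate"]),
        ratioQ13_rotAngle=ratio(stats["ptp_angle"]),
        std_rsquare_1n=float(np.std(stats["r2_1n"], ddof=1)),
        mean_rsquare_3n=float(np.mean(stats["r2_3n"])),
        std_rsquare_3n=float(np.std(stats["r2_3n"], ddof=1)),
    )
    for name, fn in _EXTRA_FEATURES.items():
        fv.extras[name] = float(fn(stats))
    return fv


# ---------------------------------------------------------------------------
# feature table I/O
# ---------------------------------------------------------------------------

def write_feature_table(rows: list[tuple[str, FeatureVector, int | None]],
                        path) -> None:
    """One row per recording: id, the eight features, optional label."""
    records = []
    for rec_id, fv, label in rows:
        rec = {"recording_id": rec_id}
        rec.update({k: fv.as_dict()[k] for k in FEATURE_NAMES})
        if label is not None:
            rec["label"] = int(label)
        records.append(rec)
    pd.DataFrame(records).to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise InputError(f"feature table missing columns: {missing}")
    return df
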