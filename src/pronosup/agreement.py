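"""Rater-agreement statistics: confusion matrices, support-weighted rates
and weighted Cohen's kappa on the five-point UPDRS scale.

Weighted kappa uses disagreement weights w_ij = |i−j|/4 (linear, default)
or ((i−j)/4)² (quadratic):  κ_w = 1 − Σ w·o / Σ w·e, with observed cell
proportions o and chance proportions e from the two raters' marginals.
Missing ratings are deleted pairwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .signal_io import RatingTable

__all__ = [
    "ConfusionMatrix",
    "KappaConfig",
    "confusion",
    "weighted_rates",
    "weighted_kappa",
    "kappa_matrix",
]

N_CLASSES = 5


@dataclass
class ConfusionMatrix:
    """5x5 counts; rows = reference class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise InputError(f"confusion matrix must be 5x5, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        if self.total == 0:
            raise InputError("empty confusion matrix")
        return float(np.trace(self.counts) / self.total)


@dataclass
class KappaConfig:
    weighting: str = "linear"  # linear | quadratic

    def __post_init__(self):
        if self.weighting not in ("linear", "quadratic"):
            raise InputError(f"unknown weighting {self.weighting!r}")


def _pairwise(r1, r2):
    a = np.asarray(r1, dtype=float)
    b = np.asarray(r2, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"length mismatch: {a.size} vs {b.size}")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep].astype(int), b[keep].astype(int)
    if a.size and (a.min() < 0 or a.max() > 4 or b.min() < 0 or b.max() > 4):
        raise InputError("scores must be in 0..4")
    return a, b


def confusion(reference, predicted) -> ConfusionMatrix:
    """Tally a 5x5 confusion matrix; missing pairs are dropped pairwise."""
    a, b = _pairwise(reference, predicted)
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(counts, (a, b), 1)
    return ConfusionMatrix(counts=counts)


def weighted_rates(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Support-weighted (TP rate, FP rate, precision) over the five classes.

    Per class i: TP rate = recall; FP rate = false positives over all
    non-class-i reference items; precision = TP / predicted-as-i (0 when the
    class is never predicted).  Each is averaged with the reference-row
    support as weight — the convention WEKA prints in its evaluation block.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise InputError("empty confusion matrix")
    support = c.sum(axis=1)
    predicted = c.sum(axis=0)
    tp = np.diag(c)
    fp = predicted - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, tp / support, 0.0)
        fp_rate = np.where(total - support > 0, fp / (total - support), 0.0)
        precision = np.where(predicted > 0, tp / predicted, 0.0)
    w = support / total
    return (float(np.sum(w * recall)),
            float(np.sum(w * fp_rate)),
            float(np.sum(w * precision)))


def _weights(weighting: str) -> np.ndarray:
    i, j = np.meshgrid(np.arange(N_CLASSES), np.arange(N_CLASSES), indexing="ij")
    d = np.abs(i - j) / (N_CLASSES - 1)
    return d if weighting == "linear" else d ** 2


def weighted_kappa(r1, r2, cfg: KappaConfig | None = None) -> float:
    """Weighted Cohen's kappa between two score vectors.

    Degenerate marginals (both raters constant) are returned as the defined
    limit with a warning: 1.0 if the constants agree, else the
    zero-expected-disagreement limit −∞ is avoided by returning 0.0.
    """
    cfg = cfg or KappaConfig()
    a, b = _pairwise(r1, r2)
    if a.size < 2:
        raise InputError("need >= 2 paired items after pairwise deletion")
    w = _weights(cfg.weighting)
    o = np.zeros((N_CLASSES, N_CLASSES))
    np.add.at(o, (a, b), 1.0)
    o /= a.size
    p = o.sum(axis=1)
    q = o.sum(axis=0)
    e = np.outer(p, q)
    exp_dis = float(np.sum(w * e))
    obs_dis = float(np.sum(w * o))
    if np.count_nonzero(p) == 1 and np.count_nonzero(q) == 1 and exp_dis > 0:
        warnings.warn("both raters constant; kappa is a degenerate limit")
    if exp_dis == 0.0:
        if obs_dis == 0.0:
            warnings.warn("both raters constant and equal; kappa degenerate, "
                          "returning 1.0")
            return 1.0
        warnings.warn("zero expected disagreement with nonzero observed "
                      "disagreement; returning 0.0")
        return 0.0
    return 1.0 - obs_dis / exp_dis


def kappa_matrix(table: RatingTable,
                 cfg: KappaConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs weighted-kappa matrix over the raters of a rating table.

    Returns (kappa, n) DataFrames; n holds the pairwise-complete item count
    each kappa was computed from.
    """
    cfg = cfg or KappaConfig()
    r = table.raters
    kap = pd.DataFrame(np.eye(len(r)), index=r, columns=r)
    npairs = pd.DataFrame(0, index=r, columns=r, dtype=int)
    for i, ri in enumerate(r):
        si = table.scores[:, i]
        npairs.loc[ri, ri] = int(np.sum(~np.isnan(si)))
        for j in range(i + 1, len(r)):
            rj = r[j]
            sj = table.scores[:, j]
            keep = ~(np.isnan(si) | np.isnan(sj))
            npairs.loc[ri, rj] = npairs.loc[rj, ri] = int(keep.sum())
            k = weighted_kappa(si[keep], sj[keep], cfg)
            kap.loc[ri, rj] = kap.loc[rj, ri] = k
    return kap, npairs
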