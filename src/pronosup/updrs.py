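"""UPDRS scoring: correlation-based feature selection and a C4.5-style
pruned decision tree.

The tree uses binary threshold splits on numeric features, chosen by
information gain ratio, with error-based (pessimistic) post-pruning at a
configurable confidence factor — the classic C4.5/J48 recipe.  Everything
is deterministic: ties are broken by feature name, then by lower threshold,
so identical data and hyperparameters yield byte-identical serialized
models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ModelIOError, PredictionError, SelectionError, ValidationError
from .features import FEATURE_NAMES, FeatureVector

__all__ = [
    "LabeledFeatures",
    "TreeHyperparams",
    "TreeModel",
    "select_features_bestfirst",
    "cfs_merit",
    "train_tree",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1
N_CLASSES = 5


@dataclass
class LabeledFeatures:
    """Feature matrix with UPDRS class labels 0-4 and recording ids."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    ids: tuple[str, ...]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.feature_names = tuple(self.feature_names)
        self.ids = tuple(str(i) for i in self.ids)
        n, d = self.X.shape
        if self.y.shape != (n,) or len(self.ids) != n or len(self.feature_names) != d:
            raise ValidationError("inconsistent shapes in labeled features")
        if np.any(self.y < 0) or np.any(self.y > 4):
            raise ValidationError("labels must be UPDRS classes 0..4")
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate recording ids")

    @classmethod
    def from_frame(cls, df, feature_names=FEATURE_NAMES,
                   label_col="label", id_col="recording_id") -> "LabeledFeatures":
        return cls(X=df[list(feature_names)].to_numpy(dtype=float),
                   y=df[label_col].to_numpy(dtype=int),
                   feature_names=tuple(feature_names),
                   ids=tuple(df[id_col].astype(str)))

    def subset(self, names) -> "LabeledFeatures":
        idx = [self.feature_names.index(n) for n in names]
        return LabeledFeatures(X=self.X[:, idx], y=self.y,
                               feature_names=tuple(names), ids=self.ids)


# ---------------------------------------------------------------------------
# correlation-based best-first subset selection
# ---------------------------------------------------------------------------

def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def cfs_merit(data: LabeledFeatures, subset: tuple[str, ...]) -> float:
    """Correlation-based subset merit: k·r̄_cf / √(k + k(k−1)·r̄_ff).

    r̄_cf is the mean absolute feature-class correlation, r̄_ff the mean
    absolute feature-feature correlation; the merit rewards relevance and
    penalizes redundancy.
    """
    k = len(subset)
    if k == 0:
        return 0.0
    y = data.y.astype(float)
    cols = [data.X[:, data.feature_names.index(f)] for f in subset]
    r_cf = np.mean([_abs_corr(c, y) for c in cols])
    if k == 1:
        return float(r_cf)
    r_ff = np.mean([_abs_corr(cols[i], cols[j])
                    for i in range(k) for j in range(i + 1, k)])
    return float(k * r_cf / math.sqrt(k + k * (k - 1) * r_ff))


def select_features_bestfirst(data: LabeledFeatures,
                              candidates: list[str] | None = None,
                              evaluator=cfs_merit,
                              stale: int = 5) -> list[str]:
    """Greedy forward hill-climbing over feature subsets with backtracking.

    Expands the best unexpanded subset on an OPEN list; terminates after
    ``stale`` consecutive expansions that fail to improve the best merit
    seen.  Deterministic given the data.
    """
    candidates = list(candidates if candidates is not None else data.feature_names)
    if not candidates:
        raise SelectionError("no candidate features")
    if np.unique(data.y).size < 2:
        raise SelectionError("need at least two classes for feature selection")

    start: tuple[str, ...] = ()
    open_list: list[tuple[float, tuple[str, ...]]] = [(evaluator(data, start), start)]
    visited = {start}
    best_subset, best_merit = start, open_list[0][0]
    no_improve = 0
    while open_list and no_improve < stale:
        # pop the best state (highest merit; ties by lexicographic subset)
        open_list.sort(key=lambda sm: (-sm[0], sm[1]))
        merit, subset = open_list.pop(0)
        improved = False
        for f in sorted(set(candidates) - set(subset)):
            child = tuple(sorted(subset + (f,)))
            if child in visited:
                continue
            visited.add(child)
            m = evaluator(data, child)
            open_list.append((m, child))
            if m > best_merit + 1e-12:
                best_merit, best_subset = m, child
                improved = True
        no_improve = 0 if improved else no_improve + 1
    return sorted(best_subset)


# ---------------------------------------------------------------------------
# C4.5-style decision tree
# ---------------------------------------------------------------------------

@dataclass
class TreeHyperparams:
    min_leaf: int = 2
    confidence: float = 0.25
    class_weights: tuple[float, ...] | None = None  # optional hook, off by default


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log2(p)))


def _class_counts(y: np.ndarray) -> np.ndarray:
    return np.bincount(y, minlength=N_CLASSES)


def _added_errors(n: float, e: float, cf: float) -> float:
    """WEKA-style pessimistic error increment for e errors on n cases."""
    from scipy.stats import norm
    if n <= 0:
        return 0.0
    if e < 1:
        base = n * (1.0 - cf ** (1.0 / n))
        if e == 0:
            return base
        return base + e * (_added_errors(n, 1.0, cf) - base)
    if e + 0.5 >= n:
        return max(n - e, 0.0)
    z = float(norm.ppf(1.0 - cf))
    f = (e + 0.5) / n
    r = (f + z * z / (2 * n)
         + z * math.sqrt(f / n - f * f / n + z * z / (4 * n * n))) / (1 + z * z / n)
    return r * n - e


def _best_split(X, y, names, min_leaf):
    """Best (feature, threshold) by gain ratio; None if no useful split."""
    n = y.size
    parent_entropy = _entropy(_class_counts(y))
    best = None  # (gain_ratio, gain, name, threshold, feature_idx)
    for j in np.argsort(names):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        # candidate thresholds: midpoints between distinct consecutive values
        distinct = np.flatnonzero(np.diff(xs) > 0)
        left_counts = np.zeros(N_CLASSES)
        feat_best = None
        prev = 0
        for i in distinct:
            left_counts += _class_counts(ys[prev:i + 1])
            prev = i + 1
            nl = i + 1
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            right_counts = _class_counts(y) - left_counts
            child_e = (nl * _entropy(left_counts) + nr * _entropy(right_counts)) / n
            gain = parent_entropy - child_e
            if gain <= 1e-12:
                continue
            split_info = _entropy(np.array([nl, nr]))
            gr = gain / split_info if split_info > 0 else 0.0
            thr = 0.5 * (xs[i] + xs[i + 1])
            cand = (gr, gain, thr)
            if feat_best is None or cand[0] > feat_best[0] + 1e-15 or (
                    abs(cand[0] - feat_best[0]) <= 1e-15 and thr < feat_best[2]):
                feat_best = cand
        if feat_best is not None:
            gr, gain, thr = feat_best
            cand = (gr, gain, names[j], thr, j)
            if best is None or gr > best[0] + 1e-15:
                best = cand
            # equal gain ratio: keep earlier (lower) feature name
    return best


def _grow(X, y, names, hp: TreeHyperparams):
    counts = _class_counts(y)
    majority = int(np.argmax(counts))
    leaf = {"kind": "leaf", "cls": majority, "counts": counts.tolist()}
    if np.unique(y).size == 1 or y.size < 2 * hp.min_leaf:
        return leaf
    split = _best_split(X, y, names, hp.min_leaf)
    if split is None:
        return leaf
    _, _, fname, thr, j = split
    mask = X[:, j] <= thr
    node = {
        "kind": "split",
        "feature": fname,
        "threshold": float(thr),
        "counts": counts.tolist(),
        "left": _grow(X[mask], y[mask], names, hp),
        "right": _grow(X[~mask], y[~mask], names, hp),
    }
    return node


def _subtree_errors(node, cf) -> float:
    """Pessimistic error estimate summed over the leaves of a subtree."""
    if node["kind"] == "leaf":
        counts = np.asarray(node["counts"], float)
        n = counts.sum()
        e = n - counts.max()
        return e + _added_errors(n, e, cf)
    return _subtree_errors(node["left"], cf) + _subtree_errors(node["right"], cf)


def _prune(node, cf):
    """Error-based post-pruning by subtree replacement."""
    if node["kind"] == "leaf":
        return node
    node["left"] = _prune(node["left"], cf)
    node["right"] = _prune(node["right"], cf)
    counts = np.asarray(node["counts"], float)
    n = counts.sum()
    e_leaf = n - counts.max()
    leaf_est = e_leaf + _added_errors(n, e_leaf, cf)
    tree_est = _subtree_errors(node, cf)
    if leaf_est <= tree_est + 0.1:
        return {"kind": "leaf", "cls": int(np.argmax(counts)),
                "counts": node["counts"]}
    return node


@dataclass
class TreeModel:
    """A trained, pruned decision tree mapping feature vectors to UPDRS 0-4."""

    root: dict
    feature_names: tuple[str, ...]
    hyperparams: TreeHyperparams = field(default_factory=TreeHyperparams)

    def predict_one(self, fv: FeatureVector | dict) -> int:
        d = fv.as_dict() if isinstance(fv, FeatureVector) else dict(fv)
        node = self.root
        while node["kind"] == "split":
            f = node["feature"]
            if f not in d:
                raise PredictionError(f"feature {f!r} missing from input vector")
            node = node["left"] if d[f] <= node["threshold"] else node["right"]
        return int(node["cls"])

    def predict(self, rows) -> np.ndarray:
        return np.array([self.predict_one(r) for r in rows], dtype=int)

    def n_leaves(self) -> int:
        def count(node):
            if node["kind"] == "leaf":
                return 1
            return count(node["left"]) + count(node["right"])
        return count(self.root)

    def used_features(self) -> set[str]:
        out = set()

        def walk(node):
            if node["kind"] == "split":
                out.add(node["feature"])
                walk(node["left"])
                walk(node["right"])
        walk(self.root)
        return out


def train_tree(data: LabeledFeatures,
               hp: TreeHyperparams | None = None,
               prune: bool = True) -> TreeModel:
    """Grow and prune a C4.5-style tree on labeled features."""
    hp = hp or TreeHyperparams()
    if data.y.size < 2 * hp.min_leaf:
        raise ValidationError(
            f"{data.y.size} rows are too few for min_leaf={hp.min_leaf}")
    root = _grow(data.X, data.y, list(data.feature_names), hp)
    if prune:
        root = _prune(root, hp.confidence)
    return TreeModel(root=root, feature_names=data.feature_names, hyperparams=hp)


def predict(model: TreeModel, fv: FeatureVector | dict) -> int:
    return model.predict_one(fv)


def save_model(model: TreeModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_names": list(model.feature_names),
        "hyperparams": {"min_leaf": model.hyperparams.min_leaf,
                        "confidence": model.hyperparams.confidence},
        "root": model.root,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_model(path: str | Path) -> TreeModel:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelIOError(f"cannot load model from {path}: {exc}") from exc
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"model format version {payload.get('format_version')!r} "
            f"!= {MODEL_FORMAT_VERSION}")
    hp = TreeHyperparams(**payload["hyperparams"])
    return TreeModel(root=payload["root"],
                     feature_names=tuple(payload["feature_names"]),
                     hyperparams=hp)
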