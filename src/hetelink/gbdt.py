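"""Gradient-boosted regression trees with logistic loss, written natively.

The classifier is the field-standard stage-wise additive model. Labels are
held externally in {0, 1}; internally the signed form y~ = 2y - 1 is used
so the loss reads log(1 + exp(-y~ * score)). Each round fits a depth-limited
squared-error regression tree to the pseudo-residuals (the negative loss
gradient, r = y~ / (1 + exp(y~ * score))) and replaces every leaf's mean by
the one-step Newton estimate sum(r) / sum(|r| (2 - |r|)). The initial score
is half the log-odds of the positive class, so the probability map is the
logistic of twice the score.

Splits are exact greedy: every midpoint between consecutive distinct
feature values is scanned and the variance-reduction optimum taken, ties
broken toward the lowest feature index then the lowest threshold — the fit
is fully deterministic and invariant to training-row order.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .core_io import PipelineConfig
from .model import BoostedModel, TreeNode, load_model, save_model

__all__ = ["fit", "predict_score", "predict_proba", "training_loss",
           "BoostedModel", "save_model", "load_model"]

_MIN_LEAF = 1
_MIN_SPLIT = 2


def _best_split(X: np.ndarray, residuals: np.ndarray) -> tuple[int, float] | None:
    """Exact greedy variance-reduction split over all features.

    Returns (feature, threshold) with threshold the midpoint of the two
    straddling values, or None when no split reduces the squared error.
    Ties go to the lowest feature index, then the lowest threshold.
    """
    n = X.shape[0]
    if n < _MIN_SPLIT:
        return None
    best: tuple[float, int, float] | None = None  # (-gain proxy, feature, thr)
    total = residuals.sum()
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        rs = residuals[order]
        csum = np.cumsum(rs)[:-1]
        counts = np.arange(1, n)
        # split after position k is valid only where the value changes
        valid = xs[:-1] < xs[1:]
        if not valid.any():
            continue
        left_sum = csum[valid]
        nL = counts[valid]
        nR = n - nL
        right_sum = total - left_sum
        # maximising sum_L^2/n_L + sum_R^2/n_R minimises the split SSE
        gain = left_sum**2 / nL + right_sum**2 / nR
        k = int(np.argmax(gain))
        pos = np.flatnonzero(valid)[k]
        thr = 0.5 * (xs[pos] + xs[pos + 1])
        score = float(gain[k])
        if best is None or score > best[0] + 1e-15:
            best = (score, f, float(thr))
    if best is None:
        return None
    return best[1], best[2]


def _leaf_value(residuals: np.ndarray) -> float:
    """One-step Newton leaf estimate for the logistic loss."""
    denom = (np.abs(residuals) * (2.0 - np.abs(residuals))).sum()
    if denom <= 0.0:
        return 0.0
    return float(residuals.sum() / denom)


def _grow_tree(
    X: np.ndarray, residuals: np.ndarray, idx: np.ndarray, depth: int
) -> TreeNode:
    r = residuals[idx]
    if depth <= 0 or idx.shape[0] < _MIN_SPLIT or np.ptp(r) == 0.0:
        return TreeNode(value=_leaf_value(r))
    split = _best_split(X[idx], r)
    if split is None:
        return TreeNode(value=_leaf_value(r))
    f, thr = split
    go_left = X[idx, f] <= thr
    left_idx, right_idx = idx[go_left], idx[~go_left]
    if left_idx.size < _MIN_LEAF or right_idx.size < _MIN_LEAF:
        return TreeNode(value=_leaf_value(r))
    return TreeNode(
        feature=f,
        threshold=thr,
        left=_grow_tree(X, residuals, left_idx, depth - 1),
        right=_grow_tree(X, residuals, right_idx, depth - 1),
    )


def fit(
    features: np.ndarray, labels: np.ndarray, config: PipelineConfig | None = None
) -> BoostedModel:
    """Fit the boosted ensemble to binary labels in {0, 1}.

    Raises on single-class labels (the initial log-odds is undefined) and
    on non-finite features. With all-identical feature rows no split is
    possible and the model degenerates to its initial score (warned).
    """
    config = config or PipelineConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    n_pos = y.sum()
    n_neg = y.shape[0] - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes")

    theta0 = 0.5 * math.log(n_pos / n_neg)
    y_signed = 2.0 * y - 1.0
    scores = np.full(y.shape[0], theta0)
    trees: list[TreeNode] = []
    all_idx = np.arange(y.shape[0])
    for _ in range(config.boost_rounds_M):
        residuals = y_signed / (1.0 + np.exp(y_signed * scores))
        tree = _grow_tree(X, residuals, all_idx, config.tree_max_depth)
        trees.append(tree)
        scores = scores + config.learning_rate * tree.predict(X)

    if all(t.is_leaf and t.value == 0.0 for t in trees):
        warnings.warn(
            "no informative split found; model reduces to its initial score",
            stacklevel=2,
        )
    return BoostedModel(
        theta0=theta0,
        trees=tuple(trees),
        learning_rate=config.learning_rate,
        n_features=X.shape[1],
    )


def predict_score(model: BoostedModel, features: np.ndarray) -> np.ndarray:
    """Additive raw score theta0 + lr * sum of tree outputs (half log-odds)."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got shape {X.shape}"
        )
    scores = np.full(X.shape[0], model.theta0)
    for tree in model.trees:
        scores += model.learning_rate * tree.predict(X)
    return scores


def predict_proba(model: BoostedModel, features: np.ndarray) -> np.ndarray:
    """Positive-class probability: logistic of twice the half-log-odds score."""
    return 1.0 / (1.0 + np.exp(-2.0 * predict_score(model, features)))


def training_loss(
    model: BoostedModel, features: np.ndarray, labels: np.ndarray, n_trees: int | None = None
) -> float:
    """Mean logistic loss using the first ``n_trees`` rounds (all by default)."""
    X = np.asarray(features, dtype=float)
    y_signed = 2.0 * np.asarray(labels, dtype=float).ravel() - 1.0
    use = model.trees if n_trees is None else model.trees[:n_trees]
    scores = np.full(X.shape[0], model.theta0)
    for tree in use:
        scores += model.learning_rate * tree.predict(X)
    return float(np.mean(np.log1p(np.exp(-y_signed * scores))))
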