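"""Boosted-tree model container and its documented JSON persistence layout.

The ensemble is an additive model: a constant initial score (half the
log-odds of the positive class) plus ``learning_rate`` times the sum of
regression-tree outputs. Trees are stored as nested split/leaf records so
the format can be re-read from any language.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["TreeNode", "BoostedModel", "save_model", "load_model"]

FORMAT_NAME = "hetelink-gbdt"
FORMAT_VERSION = 1


@dataclass(frozen=True)
class TreeNode:
    """A node of a binary regression tree.

    A leaf holds ``value``; an internal node routes ``x[feature] <= threshold``
    to ``left`` and the rest to ``right``.
    """

    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    value: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.value is not None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Vectorised evaluation over the rows of X."""
        out = np.empty(X.shape[0])
        self._predict_into(X, np.arange(X.shape[0]), out)
        return out

    def _predict_into(self, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
        if self.is_leaf:
            out[idx] = self.value
            return
        go_left = X[idx, self.feature] <= self.threshold
        self.left._predict_into(X, idx[go_left], out)
        self.right._predict_into(X, idx[~go_left], out)

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": float(self.value)}
        return {
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TreeNode":
        if "leaf" in data:
            value = float(data["leaf"])
            if not np.isfinite(value):
                raise ValueError("leaf value is not finite")
            return cls(value=value)
        for key in ("feature", "threshold", "left", "right"):
            if key not in data:
                raise ValueError(f"tree node missing field {key!r}")
        return cls(
            feature=int(data["feature"]),
            threshold=float(data["threshold"]),
            left=cls.from_dict(data["left"]),
            right=cls.from_dict(data["right"]),
        )


@dataclass(frozen=True)
class BoostedModel:
    """Additive ensemble: score(x) = theta0 + learning_rate * sum_m tree_m(x)."""

    theta0: float
    trees: tuple[TreeNode, ...]
    learning_rate: float
    n_features: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta0):
            raise ValueError("initial score must be finite")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        object.__setattr__(self, "trees", tuple(self.trees))


def save_model(model: BoostedModel, path: str | Path) -> None:
    """Serialise a fitted model to the documented JSON layout."""
    payload = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "theta0": float(model.theta0),
        "learning_rate": float(model.learning_rate),
        "n_features": int(model.n_features),
        "trees": [tree.to_dict() for tree in model.trees],
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | Path) -> BoostedModel:
    """Load a model saved by :func:`save_model`; round-trips predictions exactly."""
    try:
        with Path(path).open("r", encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt model file: {exc}") from exc
    if payload.get("format") != FORMAT_NAME:
        raise ValueError("not a hetelink model file")
    trees = payload.get("trees")
    if not trees:
        raise ValueError("model file contains no trees")
    return BoostedModel(
        theta0=float(payload["theta0"]),
        trees=tuple(TreeNode.from_dict(t) for t in trees),
        learning_rate=float(payload["learning_rate"]),
        n_features=int(payload["n_features"]),
    )
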