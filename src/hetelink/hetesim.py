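"""HeteSim meta-path relevance between lncRNAs and environmental factors.

A meta-path is a sequence of node types (L = lncRNA, E = environmental
factor) constraining walks through the heterogeneous network. HeteSim
scores a (source, target) pair along one meta-path as the cosine of two
reachable-probability vectors meeting at the path midpoint: the source's
forward vector along the left half and the target's vector along the
reversed right half. For non-negative transition matrices the score lies
in [0, 1]. For odd-length paths there is no single middle node; both
flanking midpoints are evaluated and the two scores averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iter_product

import numpy as np

from .core_io import AssociationMatrix, SimilarityMatrix

__all__ = [
    "MetaPath",
    "MetaPathTransitions",
    "HeteSimFeatures",
    "enumerate_metapaths",
    "build_transitions",
    "reachable_matrix",
    "hetesim_score",
    "hetesim_features",
]


@dataclass(frozen=True)
class MetaPath:
    """Type sequence from L to E; ``m`` edges connect ``m + 1`` typed nodes."""

    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.types) < 3:
            raise ValueError("a meta-path needs at least 2 edges")
        if self.types[0] != "L" or self.types[-1] != "E":
            raise ValueError("meta-paths must start at L and end at E")
        if any(t not in ("L", "E") for t in self.types):
            raise ValueError("node types must be 'L' or 'E'")
        object.__setattr__(self, "types", tuple(self.types))

    @property
    def m(self) -> int:
        return len(self.types) - 1

    @property
    def name(self) -> str:
        return "".join(self.types)


@dataclass(frozen=True)
class MetaPathTransitions:
    """Row-stochastic one-step transition matrices per typed edge.

    M_LL from the lncRNA similarity block, M_LE from the association
    matrix, M_EL from its transpose (freshly row-normalised, not the
    transpose of M_LE), M_EE from the EF similarity block. Zero rows
    (isolated nodes) stay zero.
    """

    M_LL: np.ndarray
    M_LE: np.ndarray
    M_EL: np.ndarray
    M_EE: np.ndarray

    def step(self, src: str, dst: str) -> np.ndarray:
        try:
            return {"LL": self.M_LL, "LE": self.M_LE,
                    "EL": self.M_EL, "EE": self.M_EE}[src + dst]
        except KeyError:
            raise ValueError(f"invalid type pair {src}{dst}") from None

    @property
    def nl(self) -> int:
        return self.M_LL.shape[0]

    @property
    def ne(self) -> int:
        return self.M_EE.shape[0]


@dataclass(frozen=True)
class HeteSimFeatures:
    """Per-pair relevance scores stacked over meta-paths (nl x ne x K)."""

    scores: np.ndarray
    path_order: tuple[MetaPath, ...]

    @property
    def K(self) -> int:
        return self.scores.shape[2]


def enumerate_metapaths(max_edges: int = 4) -> list[MetaPath]:
    """All type sequences from L to E with 2..max_edges edges.

    Ordered by length ascending, then lexicographically with L < E over
    the interior nodes; the count is sum over m of 2^(m-1) (14 when
    max_edges is 4).
    """
    if max_edges < 2:
        raise ValueError("max_edges must be at least 2")
    paths: list[MetaPath] = []
    for m in range(2, max_edges + 1):
        for interior in iter_product("LE", repeat=m - 1):
            paths.append(MetaPath(("L", *interior, "E")))
    return paths


def _row_normalize(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=1, keepdims=True)
    return np.divide(M, sums, out=np.zeros_like(M, dtype=float), where=sums > 0)


def build_transitions(
    SL: SimilarityMatrix, A: AssociationMatrix, SE: SimilarityMatrix
) -> MetaPathTransitions:
    """Row-normalise the three network blocks into the four step matrices."""
    if SL.n != A.nl or SE.n != A.ne:
        raise ValueError("block dimensions do not conform to the association matrix")
    return MetaPathTransitions(
        M_LL=_row_normalize(SL.values),
        M_LE=_row_normalize(A.values),
        M_EL=_row_normalize(A.values.T),
        M_EE=_row_normalize(SE.values),
    )


def reachable_matrix(trans: MetaPathTransitions, types: tuple[str, ...]) -> np.ndarray:
    """Ordered product of step matrices along a type sequence.

    Entry (i, j) is the probability that a walk started at node i of type
    ``types[0]`` and constrained to the sequence ends at node j of type
    ``types[-1]``.
    """
    if len(types) < 2:
        raise ValueError("a reachability product needs at least one step")
    R = trans.step(types[0], types[1])
    for src, dst in zip(types[1:-1], types[2:]):
        R = R @ trans.step(src, dst)
    return R


def _cosine_pairs(L: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Cosine of every row of L with every row of R; zero-norm rows score 0."""
    num = L @ R.T
    ln = np.linalg.norm(L, axis=1)
    rn = np.linalg.norm(R, axis=1)
    denom = ln[:, None] * rn[None, :]
    out = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    return np.clip(out, 0.0, 1.0)


def _score_at_mid(trans: MetaPathTransitions, types: tuple[str, ...], mid: int) -> np.ndarray:
    """HeteSim at one midpoint split (``mid`` is a 1-based node position).

    The two halves share the middle node: the left half runs h1..h_mid
    forward, the right half h_mid..h_{m+1} is reversed and walked from the
    target back to the middle using the opposite-direction step matrices.
    """
    left = types[:mid]
    right_rev = types[mid - 1:][::-1]
    R_L = reachable_matrix(trans, left) if len(left) >= 2 else np.eye(trans.nl)
    R_R = reachable_matrix(trans, right_rev) if len(right_rev) >= 2 else np.eye(trans.ne)
    return _cosine_pairs(R_L, R_R)


def hetesim_score(trans: MetaPathTransitions, path: MetaPath) -> np.ndarray:
    """nl x ne relevance matrix for one meta-path.

    Even edge count: single split at mid = m/2 + 1. Odd edge count: the
    mean of the scores at mid = (m+1)/2 and mid = (m+3)/2.
    """
    m = path.m
    if m % 2 == 0:
        return _score_at_mid(trans, path.types, m // 2 + 1)
    s1 = _score_at_mid(trans, path.types, (m + 1) // 2)
    s2 = _score_at_mid(trans, path.types, (m + 3) // 2)
    return 0.5 * (s1 + s2)


def hetesim_features(
    trans: MetaPathTransitions, paths: list[MetaPath] | None = None
) -> HeteSimFeatures:
    """Stack per-path scores into the (nl x ne x K) feature array."""
    if paths is None:
        paths = enumerate_metapaths(4)
    if not paths:
        raise ValueError("paths must be non-empty")
    scores = np.stack([hetesim_score(trans, p) for p in paths], axis=2)
    return HeteSimFeatures(scores=scores, path_order=tuple(paths))
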