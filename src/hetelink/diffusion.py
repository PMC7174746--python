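"""Global heterogeneous network, random walk with restart, diffusion embedding.

The two similarity blocks and the association block are stacked into one
adjacency matrix

    G = [[SL, A ],
         [A', SE]]

whose columns are normalised into a transition matrix T. A random walk
with restart run from every node gives each node a diffusion state (the
stationary visiting distribution of a walker that teleports home with
probability r); a truncated SVD of the stacked diffusion states yields the
low-dimensional node features X and context features W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AssociationMatrix, SimilarityMatrix

__all__ = ["HeteroNetwork", "DiffusionEmbedding", "build_network", "rwr", "svd_embed"]


class ConvergenceError(RuntimeError):
    """Raised when the power iteration fails to reach tolerance."""


@dataclass(frozen=True)
class HeteroNetwork:
    """Adjacency G and column-stochastic transition matrix T of the global network."""

    G: np.ndarray
    T: np.ndarray
    node_ids: tuple[str, ...]
    node_types: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.G.shape[0]


@dataclass(frozen=True)
class DiffusionEmbedding:
    """Truncated-SVD factorisation of the diffusion-state matrix P ~ X @ W.

    X (n x d) holds per-node diffusion features (rows); W (d x n) holds the
    context features; singular values are non-increasing.
    """

    X: np.ndarray
    W: np.ndarray
    singular_values: np.ndarray

    @property
    def d(self) -> int:
        return self.X.shape[1]


def build_network(
    SL: SimilarityMatrix, A: AssociationMatrix, SE: SimilarityMatrix
) -> HeteroNetwork:
    """Assemble the block adjacency matrix and its column-normalised transitions.

    Columns of G that sum to zero (fully isolated nodes) are left as zero
    columns of T rather than renormalised.
    """
    nl, ne = A.nl, A.ne
    if SL.n != nl:
        raise ValueError(f"SL dimension {SL.n} != number of lncRNAs {nl}")
    if SE.n != ne:
        raise ValueError(f"SE dimension {SE.n} != number of EFs {ne}")
    if SL.ids != A.lnc_ids or SE.ids != A.ef_ids:
        raise ValueError("similarity block ids do not match association ids")

    G = np.block([[SL.values, A.values], [A.values.T, SE.values]])
    col_sums = G.sum(axis=0)
    T = np.divide(G, col_sums[None, :], out=np.zeros_like(G), where=col_sums > 0)
    node_ids = A.lnc_ids + A.ef_ids
    node_types = ("L",) * nl + ("E",) * ne
    return HeteroNetwork(G=G, T=T, node_ids=node_ids, node_types=node_types)


def rwr(
    net: HeteroNetwork,
    r: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    restart_mode: str = "onehot",
) -> np.ndarray:
    """Random walk with restart from every node simultaneously.

    Column i of the returned matrix P is the fixed point of
    ``p <- (1 - r) T p + r p0_i``. With ``restart_mode="onehot"`` the
    restart distribution p0_i is the indicator of node i, giving each node
    a distinct diffusion state; ``"uniform"`` restarts every walk at the
    uniform distribution (all columns then coincide). Iteration stops when
    the total L1 change over the matrix drops below ``tol``.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError("restart probability must lie in (0, 1]")
    n = net.n
    if restart_mode == "onehot":
        P0 = np.eye(n)
    elif restart_mode == "uniform":
        P0 = np.full((n, n), 1.0 / n)
    else:
        raise ValueError(f"unknown restart_mode: {restart_mode!r}")

    P = P0.copy()
    rP0 = r * P0
    decay = 1.0 - r
    for _ in range(max_iter):
        P_next = decay * (net.T @ P) + rP0
        residual = np.abs(P_next - P).sum()
        P = P_next
        if residual < tol:
            return P
    raise ConvergenceError(
        f"random walk did not converge in {max_iter} iterations "
        f"(last L1 residual {residual:.3e})"
    )


def svd_embed(P: np.ndarray, d: int = 50) -> DiffusionEmbedding:
    """Reduce the n x n diffusion matrix to rank d: X = U sqrt(S), W = sqrt(S) V'.

    The sign of each singular pair is fixed so the largest-magnitude entry
    of the U column is positive, making the embedding reproducible across
    runs and platforms. When d exceeds n it is truncated to n; columns
    beyond the numerical rank are kept as (near-)zero so the downstream
    feature dimensionality stays stable.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise ValueError("P must be a 2-D matrix")
    if not np.isfinite(P).all():
        raise ValueError("P contains non-finite entries")
    if d < 1:
        raise ValueError("embedding dimension must be positive")

    U, s, Vt = np.linalg.svd(P, full_matrices=False)
    d_eff = min(d, s.shape[0])
    U, s, Vt = U[:, :d_eff], s[:d_eff], Vt[:d_eff, :]

    # deterministic sign: largest-|.| entry of each U column made positive
    anchor = np.abs(U).argmax(axis=0)
    signs = np.sign(U[anchor, np.arange(d_eff)])
    signs[signs == 0] = 1.0
    U = U * signs[None, :]
    Vt = Vt * signs[:, None]

    root = np.sqrt(s)
    X = U * root[None, :]
    W = root[:, None] * Vt
    return DiffusionEmbedding(X=X, W=W, singular_values=s)
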