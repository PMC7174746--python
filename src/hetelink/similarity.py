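"""Similarity layers of the heterogeneous network.

Three steps turn the binary association matrix and an externally computed
chemical-structure similarity into the two node-similarity blocks of the
network:

* a Gaussian interaction-profile (GIP) kernel over association profiles,
  with the bandwidth normalised by the mean squared profile norm;
* a logistic transform of the lncRNA kernel that spreads the heavily
  zero-inflated kernel values over (0, 1);
* a weighted fusion of EF chemical similarity with the EF kernel, falling
  back to the kernel wherever no chemical score is available (exact zeros).
"""

from __future__ import annotations

import numpy as np

from .core_io import AssociationMatrix, SimilarityMatrix, ValidationError

__all__ = ["gip_kernel", "logistic_transform", "fuse_ef_similarity"]


def gip_kernel(
    A: AssociationMatrix, axis: str, gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over rows (lncRNAs) or columns (EFs).

    The bandwidth is gamma_prime divided by the mean squared Euclidean norm
    of the profiles, so the kernel adapts to the density of the association
    matrix. Entry (i, j) is exp(-gamma * ||profile_i - profile_j||^2).
    """
    if axis == "lnc":
        profiles = A.values
        ids, kind = A.lnc_ids, "gip_lnc"
    elif axis == "ef":
        profiles = A.values.T
        ids, kind = A.ef_ids, "gip_ef"
    else:
        raise ValueError(f"axis must be 'lnc' or 'ef', got {axis!r}")
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")

    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0.0:
        raise ValidationError("degenerate association matrix: all profiles are zero")
    gamma = gamma_prime / mean_sq

    # ||p_i - p_j||^2 = ||p_i||^2 + ||p_j||^2 - 2 <p_i, p_j>
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(sq_dist, 0.0, out=sq_dist)
    values = np.exp(-gamma * sq_dist)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, ids, kind)


def logistic_transform(
    KL: SimilarityMatrix, c: float = -15.0, v: float = float(np.log(9999.0))
) -> SimilarityMatrix:
    """Elementwise logistic map 1 / (1 + exp(c*K + v)) of the lncRNA kernel.

    With the default (c, v) the map sends kernel value 0 to 1e-4 and 1 to
    ~0.997, stretching the mass of near-zero kernel entries. Monotone
    increasing in the kernel for c < 0.
    """
    if not (np.isfinite(c) and np.isfinite(v)):
        raise ValueError("c and v must be finite")
    values = 1.0 / (1.0 + np.exp(c * KL.values + v))
    return SimilarityMatrix(values, KL.ids, "fused_lnc")


def fuse_ef_similarity(
    E: SimilarityMatrix | None, KE: SimilarityMatrix, ew: float = 0.7
) -> SimilarityMatrix:
    """Blend chemical similarity with the EF kernel.

    Wherever a chemical score exists (entry != 0) the result is
    ``ew * E + (1 - ew) * KE``; elsewhere it falls back to the kernel.
    EF ids present in the kernel but missing from the chemical matrix are
    treated as all-zero chemical rows, so they take the fallback branch.
    The diagonal is forced to 1.
    """
    if not 0.0 <= ew <= 1.0:
        raise ValueError("ew must lie in [0, 1]")
    if E is None:
        aligned = np.zeros_like(KE.values)
    else:
        missing = [i for i in E.ids if i not in set(KE.ids)]
        if missing:
            raise ValidationError(
                f"chemical matrix has ids unknown to the kernel: {missing[:5]}"
            )
        pos = {ef_id: k for k, ef_id in enumerate(KE.ids)}
        aligned = np.zeros_like(KE.values)
        idx = np.array([pos[i] for i in E.ids], dtype=int)
        aligned[np.ix_(idx, idx)] = E.values
    values = np.where(
        aligned != 0.0, ew * aligned + (1.0 - ew) * KE.values, KE.values
    )
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, KE.ids, "fused_ef")
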