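"""Synthetic bipartite association data with planted block structure.

The generator emulates the shape of curated lncRNA-EF association data: a
sparse binary incidence matrix in which latent groups of lncRNAs and EFs
(shared regulatory context, chemical families) associate preferentially,
plus a chemical-similarity surrogate that is elevated within EF blocks,
noisy, and exactly zero for a fraction of pairs — mimicking compounds with
no database entry, which exercises the kernel-fallback branch of the EF
similarity fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AssociationMatrix, SimilarityMatrix

__all__ = ["SyntheticData", "generate", "default_fixture", "write_fixture"]

CHEM_BASE = 0.2
CHEM_BLOCK_BONUS = 0.5


@dataclass(frozen=True)
class SyntheticData:
    associations: AssociationMatrix
    chemical: SimilarityMatrix
    lnc_blocks: np.ndarray
    ef_blocks: np.ndarray


def generate(
    nl: int = 60,
    ne: int = 20,
    n_blocks: int = 3,
    p_in: float = 0.3,
    p_out: float = 0.02,
    chem_noise_sd: float = 0.1,
    chem_zero_frac: float = 0.2,
    seed: int = 0,
) -> SyntheticData:
    """Sample a planted-block bipartite network and a correlated chemical matrix.

    Each lncRNA and EF is assigned one of ``n_blocks`` blocks uniformly;
    an association appears with probability ``p_in`` within a block and
    ``p_out`` across blocks. Chemical similarity between two EFs is
    ``clip(0.2 + 0.5 * [same block] + N(0, chem_noise_sd), 0, 1)`` with a
    fraction ``chem_zero_frac`` of off-diagonal pairs zeroed exactly.
    Fully determined by ``seed``.
    """
    if not 0.0 <= p_out < p_in <= 1.0:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    if n_blocks < 1 or n_blocks > min(nl, ne):
        raise ValueError("n_blocks must lie in [1, min(nl, ne)]")
    if not 0.0 <= chem_zero_frac < 1.0:
        raise ValueError("chem_zero_frac must lie in [0, 1)")
    if chem_noise_sd < 0.0:
        raise ValueError("chem_noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    lnc_blocks = rng.integers(0, n_blocks, size=nl)
    ef_blocks = rng.integers(0, n_blocks, size=ne)

    same = lnc_blocks[:, None] == ef_blocks[None, :]
    probs = np.where(same, p_in, p_out)
    values = (rng.random((nl, ne)) < probs).astype(float)

    ef_same = ef_blocks[:, None] == ef_blocks[None, :]
    chem = CHEM_BASE + CHEM_BLOCK_BONUS * ef_same + rng.normal(
        0.0, chem_noise_sd, size=(ne, ne)
    )
    chem = np.clip((chem + chem.T) / 2.0, 0.0, 1.0)
    # knock a fraction of off-diagonal pairs to exact zero (no chemical entry)
    upper_i, upper_j = np.triu_indices(ne, k=1)
    zero_mask = rng.random(upper_i.shape[0]) < chem_zero_frac
    chem[upper_i[zero_mask], upper_j[zero_mask]] = 0.0
    chem[upper_j[zero_mask], upper_i[zero_mask]] = 0.0
    np.fill_diagonal(chem, 1.0)

    lnc_ids = tuple(f"L{i:03d}" for i in range(nl))
    ef_ids = tuple(f"E{j:03d}" for j in range(ne))
    return SyntheticData(
        associations=AssociationMatrix(values, lnc_ids, ef_ids),
        chemical=SimilarityMatrix(chem, ef_ids, "chemical"),
        lnc_blocks=lnc_blocks,
        ef_blocks=ef_blocks,
    )


def default_fixture(seed: int = 0) -> SyntheticData:
    """The small named instance used throughout the test and example suite.

    60 lncRNAs x 20 EFs in 3 blocks, within-block association probability
    0.3 against 0.02 across blocks — dense enough that diffusion and
    meta-path features carry block signal, small enough that the full
    pipeline runs in seconds.
    """
    return generate(
        nl=60, ne=20, n_blocks=3, p_in=0.3, p_out=0.02,
        chem_noise_sd=0.1, chem_zero_frac=0.2, seed=seed,
    )


def write_fixture(data: SyntheticData, directory) -> dict[str, str]:
    """Write the edge-list TSV, chemical TSV and block-label TSV; return paths."""
    from pathlib import Path

    from .core_io import save_similarity

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    edges = directory / "associations.tsv"
    with edges.open("w", encoding="utf-8") as fh:
        A = data.associations
        for i, j in zip(*np.nonzero(A.values)):
            fh.write(f"{A.lnc_ids[i]}\t{A.ef_ids[j]}\n")
    chem = directory / "chemical.tsv"
    save_similarity(data.chemical, chem)
    blocks = directory / "blocks.tsv"
    with blocks.open("w", encoding="utf-8") as fh:
        for name, b in zip(data.associations.lnc_ids, data.lnc_blocks):
            fh.write(f"{name}\tL\t{b}\n")
        for name, b in zip(data.associations.ef_ids, data.ef_blocks):
            fh.write(f"{name}\tE\t{b}\n")
    return {"associations": str(edges), "chemical": str(chem), "blocks": str(blocks)}
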