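"""Domain containers, TSV readers/writers, configuration and model persistence.

The package works with two node types: lncRNAs (L) and environmental
factors (E). Known associations arrive as a two-column edge list; EF
chemical-structure similarity arrives as a labelled square matrix computed
externally (e.g. by a compound-comparison service). Everything downstream
consumes the validated containers defined here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "PipelineConfig",
    "load_associations",
    "load_similarity",
    "save_similarity",
    "load_config",
    "save_config",
]

SIMILARITY_KINDS = {"gip_lnc", "gip_ef", "chemical", "fused_lnc", "fused_ef"}


class ParseError(ValueError):
    """Raised when an input file is malformed."""


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary lncRNA x EF incidence matrix with id indices.

    ``values[i, j] == 1`` iff lncRNA ``lnc_ids[i]`` is associated with
    EF ``ef_ids[j]``. Row i is the interaction profile of lncRNA i;
    column j is the interaction profile of EF j.
    """

    values: np.ndarray
    lnc_ids: tuple[str, ...]
    ef_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("association matrix must be 2-D")
        nl, ne = values.shape
        if nl == 0 or ne == 0:
            raise ValidationError("association matrix must be non-empty")
        if nl != len(self.lnc_ids) or ne != len(self.ef_ids):
            raise ValidationError("id lists do not match matrix shape")
        if len(set(self.lnc_ids)) != nl or len(set(self.ef_ids)) != ne:
            raise ValidationError("duplicate identifiers")
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValidationError("association entries must be 0 or 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "lnc_ids", tuple(self.lnc_ids))
        object.__setattr__(self, "ef_ids", tuple(self.ef_ids))

    @property
    def nl(self) -> int:
        return self.values.shape[0]

    @property
    def ne(self) -> int:
        return self.values.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def lnc_index(self, lnc_id: str) -> int:
        try:
            return self.lnc_ids.index(lnc_id)
        except ValueError:
            raise KeyError(f"unknown lncRNA id: {lnc_id!r}") from None

    def ef_index(self, ef_id: str) -> int:
        try:
            return self.ef_ids.index(ef_id)
        except ValueError:
            raise KeyError(f"unknown EF id: {ef_id!r}") from None

    def mask_ef(self, ef_id: str) -> "AssociationMatrix":
        """Return a copy with every association of ``ef_id`` removed."""
        j = self.ef_index(ef_id)
        values = self.values.copy()
        values[:, j] = 0.0
        return AssociationMatrix(values, self.lnc_ids, self.ef_ids)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square, symmetric similarity block with labels and a provenance tag."""

    values: np.ndarray
    ids: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError("similarity matrix must be square")
        if values.shape[0] != len(self.ids):
            raise ValidationError("id list does not match matrix dimension")
        if self.kind not in SIMILARITY_KINDS:
            raise ValidationError(f"unknown similarity kind: {self.kind!r}")
        if not np.isfinite(values).all():
            raise ValidationError("similarity entries must be finite")
        if np.abs(values - values.T).max(initial=0.0) > 1e-8:
            raise ValidationError("similarity matrix is not symmetric")
        if values.min(initial=0.0) < -1e-12 or values.max(initial=0.0) > 1 + 1e-12:
            raise ValidationError("similarity entries must lie in [0, 1]")
        # exact symmetry and range after the tolerance checks
        values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with the published defaults.

    gamma_prime_l / gamma_prime_e
        bandwidth scale of the Gaussian interaction-profile kernels.
    c, v
        coefficients of the logistic transform applied to the lncRNA
        GIP kernel; the defaults map kernel value 0 to 1e-4 and 1 to ~0.997.
    ew
        weight of chemical similarity when fusing EF similarities.
    restart_r
        restart probability of the random walk.
    embed_dim_d
        number of singular pairs kept for the diffusion embedding.
    max_path_edges
        meta-path length limit (edges); 4 enumerates the canonical 14 paths.
    boost_rounds_M, learning_rate, tree_max_depth
        gradient-boosting hyperparameters.
    """

    gamma_prime_l: float = 1.0
    gamma_prime_e: float = 1.0
    c: float = -15.0
    v: float = math.log(9999.0)
    ew: float = 0.7
    restart_r: float = 0.5
    embed_dim_d: int = 50
    max_path_edges: int = 4
    boost_rounds_M: int = 10
    learning_rate: float = 0.1
    tree_max_depth: int = 3
    restart_mode: str = "onehot"
    rwr_tol: float = 1e-10
    rwr_max_iter: int = 10_000
    pair_mode: str = "hadamard_xx"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_prime_l <= 0 or self.gamma_prime_e <= 0:
            raise ValidationError("bandwidth scales must be positive")
        if not 0.0 <= self.ew <= 1.0:
            raise ValidationError("ew must lie in [0, 1]")
        if not 0.0 < self.restart_r <= 1.0:
            raise ValidationError("restart probability must lie in (0, 1]")
        if self.embed_dim_d < 1:
            raise ValidationError("embedding dimension must be positive")
        if self.max_path_edges < 2:
            raise ValidationError("meta-path edge limit must be at least 2")
        if self.boost_rounds_M < 1 or self.learning_rate <= 0:
            raise ValidationError("boosting parameters must be positive")
        if self.tree_max_depth < 0:
            raise ValidationError("tree depth must be non-negative")
        if self.restart_mode not in {"onehot", "uniform"}:
            raise ValidationError("restart_mode must be 'onehot' or 'uniform'")
        if self.pair_mode not in {"hadamard_xx", "hadamard_xw"}:
            raise ValidationError("pair_mode must be 'hadamard_xx' or 'hadamard_xw'")


def load_associations(path: str | Path) -> AssociationMatrix:
    """Read a two-column tab-separated edge list into an association matrix.

    Duplicate (lncRNA, EF) lines collapse to a single association. Ids are
    ordered by first appearance and matched exactly after stripping
    surrounding whitespace (case-sensitive).
    """
    path = Path(path)
    lnc_order: dict[str, int] = {}
    ef_order: dict[str, int] = {}
    pairs: set[tuple[str, str]] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            tokens = line.split("\t")
            if len(tokens) != 2:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(tokens)}"
                )
            lnc, ef = tokens[0].strip(), tokens[1].strip()
            if not lnc or not ef:
                raise ParseError(f"{path.name}:{lineno}: empty identifier")
            lnc_order.setdefault(lnc, len(lnc_order))
            ef_order.setdefault(ef, len(ef_order))
            pairs.add((lnc, ef))
    if not pairs:
        raise ParseError(f"{path.name}: no associations found")
    values = np.zeros((len(lnc_order), len(ef_order)))
    for lnc, ef in pairs:
        values[lnc_order[lnc], ef_order[ef]] = 1.0
    return AssociationMatrix(values, tuple(lnc_order), tuple(ef_order))


def load_similarity(path: str | Path, kind: str = "chemical") -> SimilarityMatrix:
    """Read a labelled square similarity matrix from TSV.

    The header row and first column carry the ids; the body must be
    numeric, symmetric (within 1e-8) and within [0, 1].
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path.name}: could not parse similarity TSV: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"{path.name}: matrix is not square: {df.shape}")
    row_ids = [str(i).strip() for i in df.index]
    col_ids = [str(c).strip() for c in df.columns]
    if row_ids != col_ids:
        raise ValidationError(f"{path.name}: row and column ids differ")
    values = df.to_numpy(dtype=float)
    return SimilarityMatrix(values, tuple(row_ids), kind)


def save_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as a labelled TSV (inverse of load_similarity)."""
    df = pd.DataFrame(sim.values, index=list(sim.ids), columns=list(sim.ids))
    df.to_csv(path, sep="\t", float_format="%.10g")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config whose keys mirror the PipelineConfig fields."""
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError("config file must contain a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
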