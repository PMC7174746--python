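"""Pair-feature assembly, sampling, cross-validation, ranking, orchestration.

This module wires the stages together: similarity layers -> global network
-> diffusion embedding -> meta-path relevance -> per-pair feature vectors
-> boosted-tree classifier -> evaluation. A pair (l, e) is described by the
elementwise product of the two nodes' diffusion features concatenated with
the meta-path relevance scores of the pair (50 + 14 = 64 columns at the
default configuration on a full-rank network).

Unlabelled pairs are not verified non-associations; negatives are sampled
uniformly from the zero cells, the standard practice for this task.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import gbdt
from .core_io import AssociationMatrix, PipelineConfig, SimilarityMatrix
from .diffusion import DiffusionEmbedding, HeteroNetwork, build_network, rwr, svd_embed
from .hetesim import (
    HeteSimFeatures,
    build_transitions,
    enumerate_metapaths,
    hetesim_features,
)
from .model import BoostedModel
from .similarity import fuse_ef_similarity, gip_kernel, logistic_transform

__all__ = [
    "FeatureStack",
    "PairDataset",
    "Metrics",
    "EvalReport",
    "build_feature_stack",
    "build_pair_features",
    "sample_negatives",
    "build_dataset",
    "metrics",
    "auc",
    "roc_points",
    "cross_validate",
    "independent_test",
    "rank_ef",
    "run_algorithm1",
]

logger = logging.getLogger("hetelink")


@dataclass(frozen=True)
class FeatureStack:
    """Everything derived from one association matrix: similarities, network,
    diffusion embedding and meta-path relevance scores."""

    A: AssociationMatrix
    SL: SimilarityMatrix
    SE: SimilarityMatrix
    network: HeteroNetwork
    embedding: DiffusionEmbedding
    hetesim: HeteSimFeatures

    @property
    def n_pair_features(self) -> int:
        return self.embedding.d + self.hetesim.K


@dataclass(frozen=True)
class PairDataset:
    """Feature rows, one per (lncRNA, EF) pair, with binary labels."""

    pairs: tuple[tuple[int, int], ...]
    features: np.ndarray
    labels: np.ndarray
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (
            len(self.pairs) == self.features.shape[0] == self.labels.shape[0]
            == len(self.provenance)
        ):
            raise ValueError("pairs, features, labels and provenance must align")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def with_labels(self, labels: np.ndarray) -> "PairDataset":
        return PairDataset(self.pairs, self.features, np.asarray(labels, float),
                           self.provenance)


@dataclass(frozen=True)
class Metrics:
    """Confusion-matrix summary statistics."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    recall: float
    f1: float
    mcc: float


@dataclass(frozen=True)
class EvalReport:
    """Mean metrics with the per-fold breakdown and pooled confusion counts."""

    acc: float
    recall: float
    f1: float
    mcc: float
    auc: float
    fold_metrics: tuple[Metrics, ...]
    fold_auc: tuple[float, ...]
    tp: int
    tn: int
    fp: int
    fn: int


def build_feature_stack(
    A: AssociationMatrix,
    chemical: SimilarityMatrix | None,
    config: PipelineConfig | None = None,
) -> FeatureStack:
    """Run the feature chain: GIP kernels -> SL/SE -> network -> RWR -> SVD -> HeteSim."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    KL = gip_kernel(A, "lnc", config.gamma_prime_l)
    KE = gip_kernel(A, "ef", config.gamma_prime_e)
    SL = logistic_transform(KL, config.c, config.v)
    SL = SimilarityMatrix(SL.values, A.lnc_ids, "fused_lnc")
    SE = fuse_ef_similarity(chemical, KE, config.ew)
    net = build_network(SL, A, SE)
    logger.info("network: %d nodes (%d lncRNAs + %d EFs)", net.n, A.nl, A.ne)
    P = rwr(net, config.restart_r, config.rwr_tol, config.rwr_max_iter,
            config.restart_mode)
    emb = svd_embed(P, config.embed_dim_d)
    trans = build_transitions(SL, A, SE)
    hs = hetesim_features(trans, enumerate_metapaths(config.max_path_edges))
    logger.info(
        "features: %d diffusion + %d meta-path dims in %.2fs",
        emb.d, hs.K, time.perf_counter() - t0,
    )
    return FeatureStack(A=A, SL=SL, SE=SE, network=net, embedding=emb, hetesim=hs)


def build_pair_features(
    pairs: list[tuple[int, int]],
    emb: DiffusionEmbedding,
    hs: HeteSimFeatures,
    mode: str = "hadamard_xx",
    nl: int | None = None,
) -> np.ndarray:
    """Per-pair feature rows: node-feature Hadamard product + meta-path scores.

    ``hadamard_xx`` multiplies the lncRNA's and the EF's diffusion feature
    vectors elementwise; ``hadamard_xw`` multiplies the lncRNA's feature
    vector with the EF's context column instead.
    """
    if nl is None:
        nl = hs.scores.shape[0]
    idx = np.asarray(pairs, dtype=int)
    if idx.ndim != 2 or idx.shape[1] != 2:
        raise ValueError("pairs must be (lnc index, ef index) tuples")
    li, ej = idx[:, 0], idx[:, 1]
    if mode == "hadamard_xx":
        diff = emb.X[li] * emb.X[nl + ej]
    elif mode == "hadamard_xw":
        diff = emb.X[li] * emb.W[:, nl + ej].T
    else:
        raise ValueError(f"unknown pair-feature mode: {mode!r}")
    hete = hs.scores[li, ej, :]
    return np.hstack([diff, hete])


def sample_negatives(
    A: AssociationMatrix,
    n_neg: int,
    seed: int,
    exclude: set[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Uniform sample without replacement from the zero cells of A.

    Cells in ``exclude`` are never drawn. Deterministic for a given seed.
    """
    exclude = exclude or set()
    zeros = np.argwhere(A.values == 0)
    candidates = [(int(i), int(j)) for i, j in zeros if (int(i), int(j)) not in exclude]
    if n_neg > len(candidates):
        raise ValueError(
            f"requested {n_neg} negatives but only {len(candidates)} zero cells exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_neg, replace=False)
    return [candidates[k] for k in sorted(chosen)]


def build_dataset(
    stack: FeatureStack,
    seed: int,
    n_pos: int | None = None,
    n_neg: int | None = None,
    mode: str = "hadamard_xx",
    exclude: set[tuple[int, int]] | None = None,
) -> PairDataset:
    """Assemble a balanced labelled dataset of positive and sampled-negative pairs.

    By default all known associations are positives and an equal number of
    negatives is drawn from the zero cells.
    """
    A = stack.A
    positives = [(int(i), int(j)) for i, j in np.argwhere(A.values == 1)
                 if (int(i), int(j)) not in (exclude or set())]
    rng = np.random.default_rng(seed)
    if n_pos is not None and n_pos < len(positives):
        keep = rng.choice(len(positives), size=n_pos, replace=False)
        positives = [positives[k] for k in sorted(keep)]
    if n_neg is None:
        n_neg = len(positives)
    neg_seed = int(rng.integers(0, 2**31 - 1))
    negatives = sample_negatives(A, n_neg, neg_seed, exclude=exclude)
    pairs = positives + negatives
    labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    features = build_pair_features(pairs, stack.embedding, stack.hetesim, mode, A.nl)
    provenance = ("positive",) * len(positives) + ("sampled_negative",) * len(negatives)
    return PairDataset(tuple(pairs), features, labels, provenance)


def metrics(tp: int, tn: int, fp: int, fn: int) -> Metrics:
    """Accuracy, recall, F1 and Matthews correlation from confusion counts.

    An all-zero denominator in the MCC (a degenerate confusion matrix)
    yields MCC = 0 by convention; an empty positive class yields recall
    and F1 of 0.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("confusion counts are all zero")
    acc = (tp + tn) / total
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    return Metrics(tp=tp, tn=tn, fp=fp, fn=fn, acc=acc, recall=recall, f1=f1, mcc=mcc)


def _confusion(proba: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> Metrics:
    pred = proba >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    return metrics(tp, tn, fp, fn)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2.

    Equals the trapezoidal area under the full ROC curve swept over all
    score cutoffs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float).ravel()
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) pairs swept from the greatest cutoff to the smallest."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float).ravel()
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # collapse ties: keep the last point of each distinct score
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps[distinct] / max(fps[-1], 1)]
    return np.column_stack([fpr, tpr])


def _stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment preserving class balance; deterministic in the seed."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.shape[0], dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(idx.shape[0]) % k
    return assignment


def cross_validate(
    dataset: PairDataset,
    k: int = 10,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation of the boosted classifier.

    Each fold is held out once; metrics are computed at probability
    threshold 0.5 and averaged over folds, with the AUC computed per fold
    and averaged as well.
    """
    config = config or PipelineConfig()
    if dataset.n < k:
        raise ValueError("fewer samples than folds")
    folds = _stratified_folds(dataset.labels, k, seed)
    fold_ms: list[Metrics] = []
    fold_auc: list[float] = []
    for f in range(k):
        test = folds == f
        train = ~test
        y_train = dataset.labels[train]
        if y_train.min() == y_train.max():
            raise ValueError(
                f"fold {f}: training split lacks a class; re-seed or reduce k"
            )
        model = gbdt.fit(dataset.features[train], y_train, config)
        proba = gbdt.predict_proba(model, dataset.features[test])
        fold_ms.append(_confusion(proba, dataset.labels[test]))
        fold_auc.append(auc(proba, dataset.labels[test]))
    return EvalReport(
        acc=float(np.mean([m.acc for m in fold_ms])),
        recall=float(np.mean([m.recall for m in fold_ms])),
        f1=float(np.mean([m.f1 for m in fold_ms])),
        mcc=float(np.mean([m.mcc for m in fold_ms])),
        auc=float(np.mean(fold_auc)),
        fold_metrics=tuple(fold_ms),
        fold_auc=tuple(fold_auc),
        tp=sum(m.tp for m in fold_ms),
        tn=sum(m.tn for m in fold_ms),
        fp=sum(m.fp for m in fold_ms),
        fn=sum(m.fn for m in fold_ms),
    )


def independent_test(
    A: AssociationMatrix,
    chemical: SimilarityMatrix | None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    n_test_pos: int | None = None,
    mask_test_edges: bool = False,
) -> tuple[BoostedModel, Metrics, float]:
    """Held-out evaluation on positives and negatives disjoint from training.

    Test pairs are drawn first and excluded from training sampling (both
    classes). With ``mask_test_edges`` the test positives are also removed
    from the association matrix before feature building, closing the
    information leak through the network itself.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    positives = [(int(i), int(j)) for i, j in np.argwhere(A.values == 1)]
    if n_test_pos is None:
        n_test_pos = len(positives) // 4
    if not 0 < n_test_pos < len(positives):
        raise ValueError("n_test_pos must leave positives for training")
    take = rng.choice(len(positives), size=n_test_pos, replace=False)
    test_pos = [positives[t] for t in sorted(take)]
    test_neg = sample_negatives(A, n_test_pos, int(rng.integers(0, 2**31 - 1)))
    test_pairs = test_pos + test_neg
    test_labels = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])

    A_feat = A
    if mask_test_edges:
        values = A.values.copy()
        for i, j in test_pos:
            values[i, j] = 0.0
        A_feat = AssociationMatrix(values, A.lnc_ids, A.ef_ids)
    stack = build_feature_stack(A_feat, chemical, config)
    train = build_dataset(
        stack, seed=int(rng.integers(0, 2**31 - 1)), exclude=set(test_pairs)
    )
    model = gbdt.fit(train.features, train.labels, config)
    test_X = build_pair_features(
        test_pairs, stack.embedding, stack.hetesim, config.pair_mode, A.nl
    )
    proba = gbdt.predict_proba(model, test_X)
    return model, _confusion(proba, test_labels), auc(proba, test_labels)


def rank_ef(
    ef_id: str,
    A: AssociationMatrix,
    chemical: SimilarityMatrix | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    mask_features: bool = False,
) -> list[tuple[str, float]]:
    """Leave-one-EF-out ranking: the in-silico screen for one EF.

    Every known association of ``ef_id`` is removed from the labelled
    training sample (its whole column is excluded from both positive and
    negative sampling); the classifier is trained on the remaining
    positives plus an equal number of sampled negatives and every lncRNA
    is scored against the EF. Returns (lncRNA id, score) sorted by score
    descending, ties broken by id.

    By default the feature network keeps the EF's edges — the case-study
    protocol, in which the screen asks "which unlabelled pairs look
    associated" and network evidence about the EF is admissible. With
    ``mask_features=True`` the EF's column is zeroed before any feature is
    computed (the mask propagates through the kernels, the network, the
    diffusion and the meta-path scores), giving the strict leakage-free
    variant; note that on cleanly separable training data the boosted
    trees then assign every candidate the same score and the ranking is
    uninformative.
    """
    config = config or PipelineConfig()
    j = A.ef_index(ef_id)
    A_feat = A.mask_ef(ef_id) if mask_features else A
    stack = build_feature_stack(A_feat, chemical, config)
    exclude = {(i, j) for i in range(A.nl)}
    dataset = build_dataset(stack, seed=seed, mode=config.pair_mode, exclude=exclude)
    model = gbdt.fit(dataset.features, dataset.labels, config)
    query = [(i, j) for i in range(A.nl)]
    X = build_pair_features(query, stack.embedding, stack.hetesim,
                            config.pair_mode, A.nl)
    scores = gbdt.predict_score(model, X)
    ranked = sorted(
        zip(A.lnc_ids, scores.tolist()), key=lambda t: (-t[1], t[0])
    )
    return ranked


def run_algorithm1(
    assoc_path,
    chem_path=None,
    config: PipelineConfig | None = None,
) -> tuple[BoostedModel, EvalReport, FeatureStack]:
    """The full chain from input files to a trained, cross-validated model.

    load -> GIP kernels -> SL/SE -> network -> RWR -> SVD -> HeteSim ->
    pair features -> balanced sampling -> 10-fold CV -> final fit on the
    whole dataset.
    """
    from .core_io import load_associations, load_similarity

    config = config or PipelineConfig()
    A = load_associations(assoc_path)
    chemical = load_similarity(chem_path) if chem_path is not None else None
    stack = build_feature_stack(A, chemical, config)
    dataset = build_dataset(stack, seed=config.seed, mode=config.pair_mode)
    logger.info("dataset: %d pairs x %d features", dataset.n, dataset.features.shape[1])
    report = cross_validate(dataset, 10, config, seed=config.seed)
    model = gbdt.fit(dataset.features, dataset.labels, config)
    return model, report, stack
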