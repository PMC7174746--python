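# Methods

## Model and assumptions

The package treats lncRNA–EF association prediction as supervised link
prediction on a two-type heterogeneous network. Its core assumptions:

* **Guilt by association.** lncRNAs with similar association profiles, and
  EFs with similar profiles or similar chemical structure, tend to share
  partners. Similarity is carried by the Gaussian interaction-profile
  (GIP) kernel, whose bandwidth is normalised by the mean squared profile
  norm so it adapts to data density.
* **Network topology is informative at two scales.** Diffusion states
  (random-walk-with-restart fixed points) summarise a node's global
  position; meta-path relevance (HeteSim) captures typed local semantics —
  an L–E–E path (shared chemical neighbourhood) means something different
  from L–L–E (similar lncRNA's partner), and the 14 paths with at most 4
  edges are scored separately.
* **Unlabelled ≠ negative, but sampled negatives suffice.** Negative
  training pairs are drawn uniformly from unobserved cells; some are
  undiscovered true associations, which bounds attainable precision but is
  the standard protocol for this task.

## Parameters

| name | default | meaning |
|---|---|---|
| `gamma_prime_l`, `gamma_prime_e` | 1 | GIP bandwidth scale (dimensionless); 1 makes the bandwidth the reciprocal mean squared profile norm |
| `c`, `v` | −15, log 9999 | logistic spread of the lncRNA kernel; maps kernel 0 → 1e-4 and 1 → ≈0.997 |
| `ew` | 0.7 | weight of chemical similarity in the EF fusion; kernel-only where chemistry is absent (entry exactly 0) |
| `restart_r` | 0.5 | restart probability of the walk; higher = more local diffusion states |
| `embed_dim_d` | 50 | singular pairs kept; on networks with fewer than 50 nodes the effective dimension is the node count |
| `max_path_edges` | 4 | meta-path edge limit; 4 enumerates the canonical 14 paths (2 + 4 + 8 per length) |
| `boost_rounds_M` | 10 | boosting rounds |
| `learning_rate` | 0.1 | shrinkage per round; the published parameterisation names the rate in its update rule without valuing it, and 0.1 is the conventional default |
| `tree_max_depth` | 3 | split depth of each regression tree |
| `rwr_tol`, `rwr_max_iter` | 1e-10, 10 000 | walk convergence: total L1 change of the diffusion matrix |
| `seed` | 0 | single source for all randomness (negative sampling, folds, synthetic data) |

## Numerical and design choices

* **Restart vector.** Each start node restarts at its own indicator
  vector, giving distinct per-node diffusion states. A uniform restart
  (`restart_mode="uniform"`) is kept for completeness; it makes all
  columns of the diffusion matrix identical and the embedding rank-1, so
  it is never the default.
* **Convergence norm** for the walk is the total L1 change over the full
  diffusion matrix, with a 10 000-iteration cap that raises (with the last
  residual) rather than returning silently.
* **SVD sign convention.** Each singular pair is flipped so the
  largest-magnitude entry of its left vector is positive; embeddings are
  then identical across runs and platforms. Requested dimensions beyond
  the matrix rank are kept as (near-)zero columns so downstream feature
  width is stable.
* **Dangling nodes.** Columns of `G` that sum to zero stay zero in `T`
  (no renormalisation); row-normalised meta-path transition matrices keep
  zero rows, and zero-norm reachability vectors score 0 relevance rather
  than NaN. Isolated nodes therefore flow through the whole pipeline.
* **HeteSim normalisation** is the per-row cosine (each pair's score is
  the cosine of two non-negative vectors, hence in [0, 1]); reverse-path
  steps use the freshly row-normalised opposite-direction matrices (e.g.
  the reverse of an L→E step is the row-normalised transpose of the
  association matrix, not the transpose of the forward transition matrix).
  For odd edge counts the two midpoint splits are evaluated and averaged;
  the two halves share the middle node.
* **Meta-path order** is length ascending, then lexicographic with L < E
  over interior nodes. Single-edge paths (bare LE) are excluded; the walk
  must pass through at least one intermediate node.
* **Boosting internals.** Labels live in {0, 1} externally and are mapped
  to ±1 internally, so the initial score is half the log-odds of the
  positive class and probabilities are the logistic of twice the raw
  score. Pseudo-residuals are the exact negative gradient of the logistic
  loss, `r = ỹ/(1 + exp(ỹ·Θ))`; leaf values use the one-step Newton
  estimate `Σr / Σ|r|(2−|r|)` guarded to 0 on empty curvature. Splits are
  exact greedy variance reduction at midpoints of consecutive distinct
  values, ties broken toward the lowest feature index then the lowest
  threshold — training is deterministic and row-order invariant (up to
  floating-point summation order).
* **Evaluation.** Folds are stratified by class (plain random folds can
  go degenerate at a few hundred samples); threshold 0.5 on the
  probability for ACC/REC/F1/MCC; AUC is the Mann–Whitney statistic with
  ties counting one half, which equals the trapezoidal ROC area. A
  degenerate MCC denominator yields 0 by convention.
* **Independent testing.** Test positives and negatives are drawn first
  and excluded from training sampling on both sides. By default the test
  positives remain visible to the feature-building network (the
  transductive protocol); `mask_test_edges=True` removes them from the
  association matrix before any feature is computed, for
  leakage-controlled experiments.

## The leave-one-EF-out screen

`rank_ef` removes every association of one EF from the labelled sample
(its whole column is excluded from positive and negative sampling),
retrains, and ranks all lncRNAs against that EF. Two protocols exist:

* **Default (`mask_features=False`).** The feature network keeps the EF's
  edges. This is the screen's intended use — network evidence about the
  EF is admissible when asking which unlabelled pairs look associated —
  and mirrors how such case studies are conducted; rankings are sharp
  because true partners retain their topological signature. It is,
  deliberately, not a leakage-free generalisation estimate.
* **Strict (`mask_features=True`).** The EF's column is zeroed before any
  similarity, diffusion or meta-path computation. On cleanly separable
  training data this variant degenerates: the first boosting round
  separates the classes on network-proximity features, later trees add
  nothing, all unlinked candidates fall into the same leaf and receive
  identical scores, and the ranking collapses to the id tie-break. The
  same collapse occurs in an independent gradient-boosting implementation
  at these hyperparameters, so it is a property of step-function ensembles
  on separable data, not of this implementation. Use it for leakage
  audits, not for screening.

The bundled evaluation masks the highest-degree EF of the synthetic
fixture — the analogue of screening a well-characterised chemical, which
is the realistic use of such a case study.

## Synthetic data: what it does and does not emulate

`generate` plants `n_blocks` latent groups over lncRNAs and EFs;
associations appear with probability `p_in` within a group and `p_out`
across, and the chemical surrogate is `clip(0.2 + 0.5·[same block] +
N(0, sd), 0, 1)` with a fraction of off-diagonal entries set exactly to 0
to exercise the kernel-fallback branch of the EF fusion (base 0.2 and
bonus 0.5 are fixed, documented constants). The default fixture is 60×20
with 3 blocks, `p_in = 0.3`, `p_out = 0.02`, noise sd 0.1 and zero
fraction 0.2 — dense enough for block signal, small enough that the whole
pipeline runs in seconds on one core; these sizes also keep the test
suite and the bundled evaluation fast.

The generator reproduces the *shape* of curated association data (sparse
bipartite incidence, partially observed chemistry, isolated nodes) but
not its realism: no degree heterogeneity beyond block membership, no
correlated curation bias, no sequence- or structure-level signal.
Passing recovery tests therefore demonstrates that the pipeline extracts
planted topological structure end to end, not that it attains any
particular accuracy on real association databases. On this small, clean
fixture the cross-validated metrics saturate near 1; real data are noisier
in ways the fixture does not model.

## Known limitations

* Dense linear algebra throughout: intended for networks of a few
  thousand nodes at most.
* Chemical similarity is consumed, never computed; pairs of EFs without
  chemical entries fall back to profile-kernel similarity only.
* Negative sampling treats unobserved pairs as negatives during both
  training and evaluation; reported metrics are relative to that
  convention.
* The transductive default (features built on the full association
  matrix) means cross-validated metrics include network-level information
  about held-out pairs; the `mask_test_edges` / `mask_features` flags
  provide the stricter variants where that is the question being asked.
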