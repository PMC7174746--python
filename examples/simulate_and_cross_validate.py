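"""Generate a synthetic association network and cross-validate the classifier.

Samples a 60x20 bipartite lncRNA-EF network with three planted blocks,
builds the full feature stack (diffusion + meta-path relevance), trains
the boosted-tree classifier on all known associations plus an equal number
of sampled negatives, and reports 10-fold cross-validated metrics.
"""

import hetelink as hl

data = hl.default_fixture(seed=1)
A = data.associations
print(f"associations: {A.nl} lncRNAs x {A.ne} EFs, {A.n_associations} known pairs")

cfg = hl.PipelineConfig(seed=1)
stack = hl.build_feature_stack(A, data.chemical, cfg)
print(f"network: {stack.network.n} nodes; pair features: {stack.n_pair_features} "
      f"({stack.embedding.d} diffusion + {stack.hetesim.K} meta-path)")

dataset = hl.build_dataset(stack, seed=1)
report = hl.cross_validate(dataset, k=10, config=cfg, seed=1)
print(f"10-fold CV on {dataset.n} balanced pairs:")
print(f"  ACC={report.acc:.3f}  REC={report.recall:.3f}  F1={report.f1:.3f}  "
      f"MCC={report.mcc:.3f}  AUC={report.auc:.3f}")
print("High AUC here reflects planted block structure that the diffusion and")
print("meta-path features recover; fold metrics use a 0.5 probability cutoff.")
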