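"""Meta-path relevance scores between lncRNAs and environmental factors.

Enumerates the 14 type paths from L to E with at most 4 edges and scores
one associated and one unassociated pair along each, illustrating how
path-constrained relevance separates linked from unlinked pairs.
"""

import numpy as np

import hetelink as hl
from hetelink.hetesim import build_transitions

data = hl.default_fixture(seed=0)
A = data.associations
cfg = hl.PipelineConfig(seed=0)
stack = hl.build_feature_stack(A, data.chemical, cfg)

paths = hl.enumerate_metapaths(cfg.max_path_edges)
print(f"{len(paths)} meta-paths at edge limit {cfg.max_path_edges}:",
      ", ".join(p.name for p in paths))

i, j = map(int, np.argwhere(A.values == 1)[0])
i0, j0 = map(int, np.argwhere(A.values == 0)[0])
print(f"\npath scores for associated pair ({A.lnc_ids[i]}, {A.ef_ids[j]}) vs "
      f"unassociated ({A.lnc_ids[i0]}, {A.ef_ids[j0]}):")
for k, path in enumerate(stack.hetesim.path_order):
    s_pos = stack.hetesim.scores[i, j, k]
    s_neg = stack.hetesim.scores[i0, j0, k]
    print(f"  {path.name:6s}  linked={s_pos:.4f}  unlinked={s_neg:.4f}")
print("Scores are cosines of reachable-probability vectors meeting at the")
print("path midpoint, hence in [0, 1]; linked pairs score systematically higher.")
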