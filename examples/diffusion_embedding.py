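"""Diffusion states of a heterogeneous network and their SVD embedding.

Builds the block adjacency [[SL, A], [A', SE]], runs a random walk with
restart from every node, and factorises the resulting diffusion-state
matrix into 50-dimensional node features.
"""

import numpy as np

import hetelink as hl

data = hl.default_fixture(seed=0)
cfg = hl.PipelineConfig(seed=0)
stack = hl.build_feature_stack(data.associations, data.chemical, cfg)

net = stack.network
emb = stack.embedding
print(f"adjacency G: {net.G.shape}, transition T column sums ~1 "
      f"(min {net.T.sum(axis=0).min():.3f}, max {net.T.sum(axis=0).max():.3f})")
print(f"embedding: X {emb.X.shape}, context W {emb.W.shape}")
print("top 5 singular values:", np.round(emb.singular_values[:5], 4))

# nodes in the same planted block diffuse to similar neighbourhoods, so
# their feature vectors are closer than cross-block pairs
X_lnc = emb.X[: data.associations.nl]
blocks = data.lnc_blocks
same = blocks[:, None] == blocks[None, :]
d = np.linalg.norm(X_lnc[:, None] - X_lnc[None, :], axis=2)
mask = ~np.eye(len(blocks), dtype=bool)
print(f"mean lncRNA feature distance within blocks: {d[same & mask].mean():.4f}")
print(f"mean lncRNA feature distance across blocks: {d[~same].mean():.4f}")
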