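"""Leave-one-EF-out screen: recover a factor's partners from the rest.

Removes every known association of the best-characterised EF from the
training sample, retrains the classifier, ranks all lncRNAs against that
EF and checks how many true partners surface near the top — the in-silico
screen used to validate the method on a well-studied chemical.
"""

import numpy as np

import hetelink as hl

data = hl.default_fixture(seed=2)
A = data.associations
degree = A.values.sum(axis=0)
j = int(np.argmax(degree))
ef = A.ef_ids[j]
partners = {A.lnc_ids[i] for i in np.flatnonzero(A.values[:, j])}
print(f"masking EF {ef} ({int(degree[j])} known lncRNA partners)")

ranked = hl.rank_ef(ef, A, data.chemical, hl.PipelineConfig(seed=2), seed=2)
top_n = 10
print(f"top {top_n} predicted lncRNAs:")
hits = 0
for rank, (lnc, score) in enumerate(ranked[:top_n], start=1):
    mark = "*" if lnc in partners else " "
    hits += lnc in partners
    print(f"  {rank:2d}. {lnc}  score={score:+.4f}  {mark}")
print(f"{hits}/{top_n} of the top predictions are true partners (*).")
top20pct = {l for l, _ in ranked[: int(np.ceil(0.2 * A.nl))]}
frac = len(partners & top20pct) / len(partners)
print(f"{frac:.0%} of all true partners fall in the top 20% of the ranking.")
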