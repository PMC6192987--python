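"""Meta-clustering of samples measured on two platforms.

Two simulated platforms profile the same 8 samples (two planted groups)
with independent noise. Per-platform Pearson correlations are Fisher-z
transformed, combined with a DerSimonian-Laird random-effects summary, and
clustered by average linkage in similarity space. Dendrogram heights are
correlations (inverse Fisher transform of the linkage scores).
"""

import numpy as np
import pandas as pd

from drugseq.metaclust import (
    combine_similarities,
    meta_average_linkage,
    similarity_from_data,
)

rng = np.random.default_rng(5)
samples = [f"s{i}" for i in range(8)]
truth = np.array([0, 0, 0, 0, 1, 1, 1, 1])
signal = np.outer(rng.normal(0, 1.0, 300), np.where(truth == 0, 1.0, -1.0))

platforms = []
for name in ("platformA", "platformB"):
    data = signal + rng.normal(0, 1.2, (300, 8))
    platforms.append(similarity_from_data(pd.DataFrame(data, columns=samples)))

combined = combine_similarities(platforms)
dend = meta_average_linkage(combined)

print("merge sequence (height = correlation at the join):")
for m in dend.merges:
    print(f"  {'+'.join(m.left):>11} | {'+'.join(m.right):<11} r = {m.height_r:+.3f}")
print()
print(f"2-group cut: {dend.cut(2)}")
print(f"newick: {dend.to_newick()}")
print()
print(
    "Within-group joins happen at high correlation; the final join of the\n"
    "two planted groups sits at strongly negative correlation, so the cut\n"
    "recovers the ground-truth structure."
)
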