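"""Cluster compounds by mechanism of action from DE signatures.

Builds differential-expression tables for 12 compounds in 3 mechanism
groups (each group shares dysregulated target genes), filters potent
compounds (> 50 significant genes at padj < 0.05, |log2FC| > 1), assembles
the quantile-normalized log2FC feature matrix over the candidate-gene
union, and clusters compounds on Euclidean distance.
"""

import numpy as np
import pandas as pd

from drugseq.profiling import (
    DETable,
    build_feature_matrix,
    hierarchical_cluster,
    select_potent,
)

rng = np.random.default_rng(11)
genes = [f"g{i:03d}" for i in range(500)]
group_targets = [rng.choice(500, 70, replace=False) for _ in range(3)]

tables = {}
for g, targets in enumerate(group_targets):
    for m in range(4):
        lfc = rng.normal(0, 0.2, 500)
        padj = rng.uniform(0.2, 1.0, 500)
        signs = np.where(np.arange(70) % 2 == 0, 1.0, -1.0)
        lfc[targets] = signs * (2.0 + rng.normal(0, 0.3, 70))
        padj[targets] = 0.001
        name = f"moa{g}_cmp{m}"
        tables[name] = DETable(
            pd.DataFrame({"log2fc": lfc, "padj": padj, "base_mean": 100.0},
                         index=pd.Index(genes, name="gene")),
            treatment=name, dose_um=10.0,
        )

potent = select_potent(tables, min_genes=50)
fm = build_feature_matrix({c: tables[c] for c in potent}, max_genes=200)
dend = hierarchical_cluster(fm, linkage="complete")

print(f"potent compounds:   {len(potent)} of {len(tables)}")
print(f"feature genes:      {len(fm.gene_union)} (union of candidate lists)")
print(f"3-cluster cut:      {dend.cut(3)}")
print()
print(
    "Compounds sharing target genes land in the same cluster: the cut\n"
    "recovers the three planted mechanism groups from expression alone."
)
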