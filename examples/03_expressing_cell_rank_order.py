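"""Expressing-cell proportions, the >5% filter, and library rank ordering.

Simulates a sparse single-nuclei matrix for 8 genes across 4 cell clusters
and the three libraries (0HPA, Cont6HPA, Rom6HPA), filters genes expressed
in more than 5% of cells in at least one stratum, and classifies each
retained (gene, cluster) by the descending order of expressing-cell
proportions across libraries.
"""

import numpy as np
import pandas as pd

from titracurve import (
    apply_gene_filter,
    ordering_summary,
    proportion_expressing,
    rank_order_classify,
)
from titracurve.synthetic import LIBRARIES, generate_cell_matrix

rng = np.random.default_rng(0)
genes = [f"g{i}" for i in range(8)]
clusters = [1, 2, 3, 4]

# drug-up genes: highest proportion in Rom6HPA; drug-down: highest in Cont6HPA;
# two genes planted below the 5% floor
cols = {}
for cl in clusters:
    for lib in LIBRARIES:
        p = rng.uniform(0.1, 0.3, len(genes))
        if lib == "Rom6HPA":
            p[:3] *= 2.0   # up-regulated by the drug
            p[3:6] *= 0.4  # down-regulated
        cols[(cl, lib)] = np.minimum(p, 0.9)
props = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
props.iloc[6:] = 0.02  # below the detection floor everywhere

cells = generate_cell_matrix(props, 500, seed=1)
table = proportion_expressing(cells)
retained = apply_gene_filter(table, min_prop=0.05)
print(f"retained {len(retained)} of {len(genes)} genes after the >5% filter\n")

results = [
    rank_order_classify(table, g, cl) for g in retained for cl in clusters
]
summary = ordering_summary(results)
print("ordering-category counts per gene (columns are library orderings):")
print(summary.to_string())
print()
print(
    "Drug-up genes repeat Rom6HPA-first orderings across clusters and\n"
    "drug-down genes Cont6HPA-first: the drug shifts the same genes in the\n"
    "same direction across many cell types, not in a single cell type."
)
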