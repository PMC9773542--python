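"""Single-cell QC filtering of a toy 10x-style count matrix.

Programs 100 cells of which 10 fall below the 2000-feature floor and 5 carry
excess mitochondrial reads, writes/reads the MatrixMarket triplet, applies
the stated filters and prints the retention report.
"""

import numpy as np

from ccopheno import make_count_matrix, qc_filter

feats = np.full(100, 3000)
feats[:10] = 1500                 # too few detected features
mito = np.zeros(100)
mito[10:15] = 0.15                # above the 10 % mitochondrial cap

matrix, truth = make_count_matrix(100, 4000, features_per_cell=feats,
                                  mito_fraction=mito, seed=0)
filtered, report = qc_filter(matrix)

print(f"input cells            : {matrix.n_cells}")
print(f"retained cells         : {filtered.n_cells} "
      f"(programmed compliant: {100 - 10 - 5})")
print(f"retained genes         : {filtered.n_genes} / {matrix.n_genes} "
      f"(expressed in >= {report.thresholds.min_cells_per_gene} retained cells)")
print(f"feature band           : [{report.thresholds.min_features}, "
      f"{report.thresholds.max_features}] inclusive")
print(f"mito cap               : < {report.thresholds.max_mito:.0%}")
# Cells are filtered before genes, so the per-gene expressing-cell counts are
# taken over the retained cells only.
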