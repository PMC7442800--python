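"""Cell-level QC and normalization on a small constructed count matrix.

Cells are kept when they have enough transcripts, enough detected genes and
an acceptable ERCC spike-in read fraction; surviving endogenous counts are
scaled to the median library size and log-transformed.
"""

import numpy as np

import treefates as tf
from treefates.io import CountMatrix, QCParams

rng = np.random.default_rng(0)
n_genes = 50
vals = rng.integers(5, 40, size=(n_genes, 8))
vals[:, 6] = 1          # cell 6: far too few transcripts
spike = np.full(8, 20)
spike[7] = 2000         # cell 7: spike-in dominated
matrix = CountMatrix(np.vstack([vals, spike]),
                     [f"gene{i}" for i in range(n_genes)] + ["ERCC-00001"],
                     [f"cell{i}" for i in range(8)])

params = QCParams(min_transcripts=500, min_genes=30, max_spikein_fraction=0.25)
kept, report = tf.qc_filter_cells(matrix, params)
print(f"kept {report.n_kept}/{report.n_input} cells")
print(report.table[["total_transcripts", "spikein_fraction", "reason"]])

expr = tf.normalize_counts(kept)
print(f"\nnormalized matrix: {expr.n_genes} genes x {expr.n_cells} cells "
      f"(spike-ins dropped), size factors: {np.round(expr.size_factors, 2)}")
# Values are ln(1 + count * median_depth / cell_depth); a size factor of 1
# means the cell already sits at the median library size.
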