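"""Simulate a branching differentiation dataset with known ground truth.

The default configuration is a progenitor trunk that bifurcates twice:
trunk -> (branchA, branchB) and branchA -> (branchA1, branchA2), with
competing early modules at the first fork, branch-exclusive late modules,
ubiquitous root-activated identity genes, flat noise genes and ERCC
spike-ins. Counts are negative-binomial with depth variation and dropout.
"""

import numpy as np

import treefates as tf

config = tf.default_config(seed=1)
dataset = tf.simulate_dataset(config)

counts = dataset.counts
print(f"genes x cells: {counts.n_genes} x {counts.n_cells} "
      f"({int(counts.is_spikein.sum())} ERCC spike-in rows)")
print(f"pseudotime range: {dataset.truth.true_pseudotime.min():.2f} "
      f"- {dataset.truth.true_pseudotime.max():.2f}")
modules = sorted(set(dataset.truth.module_membership.values()))
print(f"modules: {modules}")
print(f"identity genes: {len(dataset.truth.identity_gene_ids)}, "
      f"mean spike-in fraction: "
      f"{(counts.dense()[counts.is_spikein].sum(0) / counts.dense().sum(0)).mean():.3f}")
# Each module's genes follow a sigmoid program on its committed path;
# the spike-in fraction per cell is jittered around the configured 5%.
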