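"""Sliding-window module correlation dynamics at a fate decision.

For the two competing early modules at the first fork, gene-gene Pearson
correlations are computed inside rank-based sliding windows of cells along
pseudotime: intra-module coordination rises as cells approach the
bifurcation while the cross-module correlation turns negative -- the
repulsion statistic |mean(intra) - inter| peaks near the fork.
"""

import numpy as np

import treefates as tf

dataset = tf.simulate_dataset(tf.default_config(seed=11))
expr = tf.normalize_counts(dataset.counts)
pt = dataset.truth.true_pseudotime
path = np.flatnonzero(np.isin(dataset.truth.true_segment,
                              ["trunk", "branchA", "branchA1"]))
windows = tf.build_windows(pt, path, w=40, s=10)

members = dataset.truth.module_membership
module_a = [g for g, m in members.items() if m == "earlyA"]
module_b = [g for g, m in members.items() if m == "earlyB"]
track = tf.module_correlation_track(expr.values, expr.gene_ids, windows,
                                    module_a, module_b)

cols = ["center", "intra_A", "intra_B", "inter", "repulsion"]
print(track.table[cols].round(3).to_string(index=False))
fork_row = (track.table["center"] - 6.0).abs().idxmin()
print(f"\nrepulsion at root window: {track.table['repulsion'].iloc[0]:.3f}; "
      f"near the fork (t=6): {track.table.loc[fork_row, 'repulsion']:.3f}")
# The growing gap between intra- and inter-module correlation before the
# fork is the signature of competing fate programs being resolved.
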