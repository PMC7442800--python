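# treefates

Tree-based pseudotime analysis of branching differentiation in single-cell
RNA-seq, built around the kind of data produced by deep full-length
(Smart-seq2 style) sequencing of a developing lineage such as the sensory
neuron progeny of the neural crest. The package reconstructs a branching
trajectory from raw counts and provides the statistics that dissect binary
fate decisions along it, together with a seeded synthetic generator so
every stage can be validated against known ground truth.

## What it computes

**Trajectory backbone.** Cells are embedded with a diffusion map (adaptive
Gaussian kNN kernel, eigenvectors of the Markov matrix scaled by their
eigenvalues) and an elastic principal tree is fitted by minimizing

```
E = MSE + λ Σ_edges ‖v_i − v_j‖² + μ Σ_stars ‖v_k − mean(neighbors)‖²
```

where MSE is the mean squared distance from each cell to its nearest tree
node, λ penalizes stretching and μ bending. Trees are grown by grammar
moves (bisect an edge / add a node to a node), or stitched semi-supervised
from per-cluster principal curves — the protocol of choice for real data
where branches meet in narrow regions of the embedding. A cell's
**pseudotime** is its along-tree distance from a chosen root; trees may
carry two roots with segments partitioned between them.

**Gene statistics.** Genes associated with the tree are detected by an
F-test of a cubic B-spline fit of log expression on pseudotime against the
constant model (pooled over root→leaf paths, BH-corrected, with an
amplitude gate); profiles are smoothed with cubic smoothing splines
(penalty γ·∫f″², γ = 5 by default) and clustered into patterns
(Ward/Euclidean). At a **bifurcation**, genes upregulated after the fork
are found by a rank-sum test between the post-fork branches plus an
upregulation gate, assigned to the branch with the higher fitted post-fork
expression, timed by the first crossing of baseline + 0.3·(optimum −
baseline), and split into **early** (activated before the fork) and
**late** modules. Sliding-window module tracks quantify fate competition
via the **repulsion** statistic |mean(intra_A, intra_B) − inter| of local
Pearson correlations. Bootstrap accumulation curves (sample cells with
replacement, union of per-cell top-100 genes) measure population
heterogeneity, and **identity genes** — the program a progenitor pool
hands to all its progeny — are traced as genes activated before a
pseudotime cutoff and present in >98% of later cells on every trajectory.
Endpoint markers follow the rule log2FC > 1 and expressed in >90% of the
cluster.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
import treefates as tf

dataset = tf.simulate_dataset(tf.default_config(seed=1))
result = tf.reconstruct_trajectory(
    dataset.counts,
    cluster_labels=dataset.cells.table["cluster_label"].to_numpy(),
    early_mask=dataset.truth.true_pseudotime < 1.0,
)
print(result.tree.n_nodes, len(result.tree.leaves()), len(result.tree.branch_nodes()))
for traj in (["trunk","branchA","branchA1"], ["trunk","branchA","branchA2"], ["trunk","branchB"]):
    m = np.isin(dataset.truth.true_segment, traj)
    print(traj[-1], spearmanr(result.pseudotime[m], dataset.truth.true_pseudotime[m]).statistic)
```

prints

```
139 5 3
branchA1 0.989
branchA2 0.985
branchB  0.965
```

— a 139-node tree with 5 leaves and 3 bifurcations, and cells ordered
along each root→leaf trajectory in near-perfect agreement (Spearman ρ ≥
0.96) with the pseudotime at which the generator placed them. The
`examples/` directory holds one short script per capability (simulation,
QC and normalization, trajectory reconstruction, fork analysis, module
repulsion, identity tracing and bootstrap curves, branch comparison and TF
activity), each printing the numbers it computes and a line on what they
mean.

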