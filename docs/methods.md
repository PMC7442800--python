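# Methods

## The model and its assumptions

The package treats differentiation as movement along a rooted tree
embedded in expression space. Cells are noisy observations scattered
around the tree; a cell's developmental progress is its **pseudotime**,
the along-tree distance from a root to the cell's projection. Binary fate
decisions are fork nodes; the transcriptional programs that distinguish
the daughters are gene modules whose activation can precede ("early",
fate-biasing) or follow ("late", fate-executing) the fork. These
assumptions — a tree (no convergence or cycles), smooth program
activation, and pseudotime as a proxy for real time — are shared with the
elastic-principal-graph school of trajectory inference and inherit its
limitations (no oscillatory programs, no cell-cell interaction effects).

## Synthetic data generator

`simulate.default_config` defines the study conditions used throughout
the tests: a trunk of 6 pseudotime units (the progenitor pool) forking
into two branches of 6 units, the first branch forking again into two
4-unit sub-branches; 100 cells per segment placed uniformly at random;
20-gene competing early modules at the first fork (activation t_on = 4,
rate k = 1.5, optimum o = 3, baseline b = −2 on the natural-log scale),
20-gene late modules (t_on = 8), 15-gene early/late module pairs at the
second fork (t_on = 10 and 13), 40 ubiquitous identity genes (t_on ∈
[0.5, 2], o = 6 — counts of a few hundred, the regime of strongly
expressed housekeeping-like genes in deep full-length libraries), 200
flat noise genes (log-level ∈ [0.5, 1.5]) and 20 ERCC pseudo-genes at a
5% mean spike-in fraction. Counts are Gamma–Poisson (negative binomial)
with size 2 around depth-scaled exp(log-mean); per-cell depth factors are
log-normal with CV 0.3.

Four generator choices deserve explanation:

- **Gradual activation within modules.** Each gene's activation time is
  jittered uniformly ±1 unit around its module's t_on. Modules whose
  genes all switch at the same instant produce expression that changes in
  discrete episodes, collapsing intermediate cells into clumps no
  ordering method can resolve — and make per-gene activation times
  degenerate. Real co-regulated programs activate over a window.
- **Continuity across forks.** On the branch opposing a competing
  module's commitment, expression decays exponentially (rate k) from its
  fork-level value toward baseline rather than dropping instantaneously.
  An instantaneous collapse tears the expression manifold at the fork, an
  artifact real differentiation does not exhibit.
- **Pre-fork fate bias.** Each pre-fork cell carries a latent fate for
  every competing module pair; its expression of the favored module is
  multiplied by (1 + a·r) and of the disfavored by (1 − a·r), with
  amplitude a = 0.25 and a ramp r growing linearly from module activation
  to the fork. This produces the signature the module-correlation tracks
  are designed to detect — rising intra-module coordination and
  increasingly negative cross-module correlation before the split — while
  both modules still rise on average. At a = 0.25 the biased lobes remain
  a connected tube in the embedding; much larger amplitudes split the
  pre-fork population into geometrically separate lobes.
- **Expression-dependent dropout.** Zero-inflation is Bernoulli after NB
  sampling with probability dropout_rate·exp(−μ) (dropout_rate = 0.1), so
  only lowly expressed genes are affected. With expression-independent
  dropout no gene can be robustly present in >98% of cells, which
  contradicts the deep-coverage data the generator emulates (where
  ubiquitous identity genes are essentially always detected) and would
  make the identity-tracing rule unsatisfiable by construction.

What the generator does **not** emulate: batch effects, doublets,
cell-cycle structure, spliced/unspliced kinetics, amplification-length
biases, or a heterogeneity gradient along the tree. Tests passing on this
generator show the statistics recover the constructs they target under
NB noise and realistic sparsity; they do not certify behavior under batch
confounding or protocol-specific artifacts.

## Pipeline stages and defaults

- **QC** (`qc_filter_cells`): keep cells with ≥ 5×10⁴ transcripts, ≥ 2500
  detected genes (count > 0) and ≤ 25% spike-in fraction; cells exactly at
  a threshold are kept (only strict violations are removed). Spike-in
  rows survive QC (they feed the fraction metric) and are dropped at
  normalization.
- **Normalization** (`normalize_counts`): per-cell scaling to the median
  post-QC endogenous library size, then ln(1 + x). The log base and
  pseudocount are this package's documented choice.
- **Gene selection** (`select_overdispersed_genes`): residual log-variance
  above a quantile-binned median trend of log-variance vs log-mean; the
  binned median is robust to single high-leverage genes. Default 150
  genes in the desk-scale pipeline.
- **Embedding** (`compute_diffusion_map`): 20 PCs, then an adaptive
  Gaussian kernel with per-cell bandwidth equal to the distance to the
  30th neighbor, symmetrized and row-normalized; coordinates are
  eigenvectors 2..6 of the Markov matrix scaled by their eigenvalues
  (five components; the count is configurable but must be ≥ 5 for tree
  fitting). A disconnected kernel graph is an error naming component
  sizes.
- **Tree fitting** (`fit_elastic_tree`): elastic energy with λ = 0.01,
  μ = 0.1; growth from a 2-node seed (two most distant points of a
  random subsample, seeded) by the energy-minimizing grammar move
  {bisect edge, add node to node}; alternating nearest-node assignment
  and a closed-form quadratic solve for all positions. Energy is asserted
  non-increasing at every iteration. After growth, a spanning-tree
  rewiring pass adds short candidate edges between nearby nodes and
  removes the worst edge of the induced cycle when that strictly lowers
  the energy — an escape hatch from topological local optima of greedy
  growth. Path-constrained curves reject moves creating degree-3 nodes
  and skip rewiring.
- **Semi-supervised stitching** (`fit_tree_semisupervised`): one elastic
  principal curve per cluster (14 nodes by default), merged greedily by
  linking the closest node pair between each unattached curve and the
  growing tree. This is the default reconstruction route when cluster
  labels are available, for the same reason the multi-step protocol is
  used on real data: a single unsupervised fit of a multi-fork dataset
  mis-threads the fork region in roughly a third of simulation seeds
  (branch corridors meet in narrow, near-degenerate regions of the
  five-component embedding, where the energy difference between correct
  and reversed threading is tiny), while per-cluster curves cannot thread
  a branch backwards.
- **Subdivision and refit** (`subdivide_edges`, `refine_tree`): every
  edge is split at its midpoint (n + e nodes, 2e edges, geometry
  unchanged), then positions are re-optimized on the data.
- **Projection and pseudotime** (`project_cells`, `compute_pseudotime`):
  continuous projection onto the union of edge segments, clamped to
  [0, 1], ties broken by the canonical (lexicographic) edge order;
  pseudotime is the graph distance from the segment's assigned root.
  With two roots the user (or driver) partitions branch segments between
  them; cells inherit their segment's root.

## Statistical choices

- **Association test**: cubic B-spline basis (6 degrees of freedom,
  interior knots at pseudotime quantiles) vs the per-path constant model,
  pooled RSS over root→leaf paths, F reference distribution, BH
  adjustment, amplitude gate A_min = 0.5 natural-log units. On pure-noise
  genes the fraction called at α = 0.05 stays below 7%.
- **Profile smoothing**: cubic smoothing splines with penalty
  γ·∫f″² (γ = 5), evaluated on a ≥100-point uniform grid; duplicate
  pseudotimes are averaged before fitting; paths with < 4 cells are
  marked unavailable rather than extrapolated. The infinite-γ limit is
  the least-squares line (the penalty's null space), not a constant.
- **Fork statistics**: two-sided Wilcoxon rank-sum between post-fork
  branches (robust to the log-scale zero inflation the generator
  produces), BH adjustment, upregulation gate up_min = 0.5 and branch
  assignment gate effect_min = 0.5 log units, activation fraction
  f = 0.3. When a branch forks again downstream, activation timing is
  read from the linear root→leaf path on which the gene's fitted
  post-fork expression is highest, not from sub-branches pooled.
  Early/late split: strictly before the threshold (default: the fork
  pseudotime) is early; at or after is late.
- **Module tracks**: rank-based sliding windows (w = 40 cells, step 10;
  a trailing partial window is kept if it has ≥ 10 cells) replace the
  by-hand window choices used on real data, for reproducibility.
  Zero-variance genes are excluded from pair means (not scored 0) and
  exclusion counts are reported. Repulsion = |mean(intra_A, intra_B) −
  inter|, symmetric in the two modules.
- **Bootstrap curves**: per-cell top-k sets (ties broken by gene order
  for determinism) are precomputed; each repetition samples cells with
  replacement and tracks the running union size, which is non-decreasing
  within every repetition.
- **Identity tracing**: activation before t₀ = 6 on every trajectory
  where the profile is informative, and raw-count presence strictly above
  98% among cells past t₀ on every root→leaf trajectory. "Present" means
  count > 0 (configurable to a normalized floor). Raising the presence
  threshold or lowering t₀ can only shrink the set.
- **Endpoint markers**: log2((mean_in + ε)/(mean_out + ε)) on de-logged
  normalized expression with ε = 0.1 (bounded fold changes with zero
  means); both thresholds (log2FC > 1, fraction > 0.9) are strict.
  Rank-sum p/q values are reported alongside but are not part of the rule.
- **TF activity**: per grid point, min_a ‖y − M a‖² + α‖a‖₁ solved by
  coordinate descent (scikit-learn's lasso with its objective rescaled
  accordingly); α = 0 falls back to least squares. Gene profiles are
  centered over the grid first. The target matrix is an input; motif
  scanning is out of scope.

## Problem sizes

The test-suite and acceptance runs use 400–500 cell simulations, 20
replicates for calibration/repulsion rates, 500 genes for null
calibration, 5 replicates for fork power, 3 for pseudotime/activation
recovery, and 10⁴-sample-per-edge oracles for projection — sizes at which
every statistic is stable while a full run stays in the minutes range.

## Known limitations

- Unsupervised single-fit tree growth can mis-thread fork corridors (see
  above); the semi-supervised route requires cluster labels.
- Pseudotime inside terminal plateaus (after every program has saturated)
  is unidentifiable in principle; recovery there reflects noise.
- The association F-test treats the spline degrees of freedom as fixed;
  with strongly non-uniform cell densities its null calibration is
  approximate (empirically ≤ 7% at α = 0.05).
- Two-root handling relies on a user-supplied segment partition; nothing
  reconciles pseudotime where the rooted subtrajectories share nodes.
- The generator's ERCC model is depth-independent Poisson with log-normal
  per-cell fraction jitter; it does not model spike-in length bias.
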