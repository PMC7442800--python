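"""End-to-end trajectory reconstruction: counts to pseudotime.

Chains the standard stages -- median-depth log normalization,
overdispersed-gene selection, PCA, diffusion-map embedding, semi-supervised
elastic-tree stitching from cluster labels (or a single unsupervised fit
when labels are absent), edge subdivision with refit, cell projection and
root-anchored pseudotime -- with the defaults used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .embedding import DiffusionEmbedding, compute_diffusion_map
from .io import CountMatrix, ExpressionMatrix, normalize_counts, select_overdispersed_genes
from .tree import (
    CellProjection,
    PrincipalTree,
    compute_pseudotime,
    fit_elastic_tree,
    fit_tree_semisupervised,
    project_cells,
    propose_root,
    refine_tree,
    subdivide_edges,
)

__all__ = ["TrajectoryResult", "reconstruct_trajectory"]


@dataclass
class TrajectoryResult:
    expr: ExpressionMatrix
    embedding: DiffusionEmbedding
    tree: PrincipalTree
    projections: list[CellProjection]

    @property
    def pseudotime(self) -> np.ndarray:
        return np.array([p.pseudotime for p in self.projections])

    @property
    def segments(self) -> np.ndarray:
        return np.array([p.segment for p in self.projections])


def reconstruct_trajectory(
    counts: CountMatrix,
    cluster_labels: np.ndarray | None = None,
    early_mask: np.ndarray | None = None,
    n_top_genes: int = 150,
    n_pcs: int = 20,
    n_components: int = 5,
    n_neighbors: int = 30,
    n_nodes: int = 45,
    n_nodes_per_cluster: int = 14,
    seed: int = 0,
) -> TrajectoryResult:
    """Reconstruct the branching trajectory and pseudotime from raw counts.

    Parameters
    ----------
    cluster_labels
    	Per-cell cluster labels; when given, the tree is stitched from
    	per-cluster principal curves (the semi-supervised protocol), else a
    	single elastic tree of ``n_nodes`` is grown unsupervised.
    early_mask
    	Boolean mask of cells from the earliest timepoint, used to propose
    	the root node; defaults to all cells (root = densest end).
    """
    expr = normalize_counts(counts)
    genes = select_overdispersed_genes(expr, n_top_genes)
    sel = np.isin(expr.gene_ids, genes)
    x = PCA(n_components=min(n_pcs, int(sel.sum()), expr.n_cells - 1), random_state=seed).fit_transform(
        expr.values[sel].T
    )
    emb = compute_diffusion_map(x, n_components=n_components, n_neighbors=n_neighbors)

    if cluster_labels is not None:
        tree = fit_tree_semisupervised(
            emb.coordinates, cluster_labels, n_nodes_per_cluster=n_nodes_per_cluster, seed=seed
        )
    else:
        tree = fit_elastic_tree(emb.coordinates, n_nodes=n_nodes, seed=seed)
    tree = refine_tree(subdivide_edges(tree), emb.coordinates, rewire=cluster_labels is None)

    projections = project_cells(tree, emb.coordinates, counts.cell_ids)
    if early_mask is None:
        early_mask = np.ones(counts.n_cells, dtype=bool)
    root = propose_root(tree, projections, early_mask)
    tree.roots = [root]
    projections = compute_pseudotime(tree, projections, root)
    return TrajectoryResult(expr=expr, embedding=emb, tree=tree, projections=projections)
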