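"""Fork (bifurcation) gene statistics.

At a binary fork, genes differentially upregulated after the branching
point are detected by a rank-sum test between the two post-fork branch
cell sets with BH adjustment, gated on an actual post-fork increase of the
fitted profile. Detected genes are assigned to the branch with the higher
fitted post-fork expression, their activation timing is read off the
fitted profile along the root-to-branch-end path, and an early/late module
split is made at a pseudotime threshold at (or before) the fork.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tree import CellProjection, PrincipalTree
from .trajstats import FittedProfiles, bh_adjust, fit_gene_profiles

__all__ = [
    "ForkDefinition",
    "define_fork",
    "test_fork_genes",
    "assign_branch_specific",
    "estimate_activation",
    "split_early_late",
    "fork_gene_table",
]


@dataclass
class ForkDefinition:
    """A binary fork: upstream root path and the two downstream branches.

    Segments are the indices produced by the tree's branch decomposition;
    ``fork_pseudotime`` is the pseudotime of the fork node itself.
    """

    fork_node: int
    branch1: list[int]  # segment ids downstream, first branch
    branch2: list[int]
    root_path: list[int]  # segment ids upstream of the fork
    fork_pseudotime: float

    def __post_init__(self) -> None:
        if set(self.branch1) & set(self.branch2):
            raise ValueError("branch segment sets must be disjoint")


def define_fork(tree: PrincipalTree, fork_node: int, root: int) -> ForkDefinition:
    """Build a ForkDefinition from the tree topology.

    The two downstream branches are the segment sets reached from the fork
    node away from the root, one per downstream neighbor (the fork must be
    binary once the root side is excluded).
    """
    import networkx as nx

    g = tree.graph()
    segs = tree.segments()
    dist = nx.single_source_dijkstra_path_length(g, root, weight="length")
    toward_root = min(g.neighbors(fork_node), key=lambda n: dist[n])
    downstream = [n for n in g.neighbors(fork_node) if n != toward_root]
    if len(downstream) != 2:
        raise ValueError(f"node {fork_node} is not a binary fork relative to root {root}")

    def segments_via(first: int) -> list[int]:
        h = g.copy()
        h.remove_node(fork_node)
        comp = nx.node_connected_component(h, first)
        out = []
        for si, path in enumerate(segs):
            nodes = set(path)
            if nodes & comp and root not in nodes - {fork_node}:
                if all(n in comp or n == fork_node for n in path):
                    out.append(si)
        return out

    b1, b2 = segments_via(downstream[0]), segments_via(downstream[1])
    upstream = [si for si in range(len(segs)) if si not in b1 and si not in b2]
    return ForkDefinition(
        fork_node=int(fork_node),
        branch1=b1,
        branch2=b2,
        root_path=upstream,
        fork_pseudotime=float(dist[fork_node]),
    )


def _branch_cells(projections: list[CellProjection], segs: list[int]) -> np.ndarray:
    return np.array([i for i, p in enumerate(projections) if p.segment in segs])


def test_fork_genes(
    expr_values: np.ndarray,
    gene_ids: np.ndarray,
    projections: list[CellProjection],
    fork: ForkDefinition,
    alpha: float = 0.05,
    up_min: float = 0.5,
    gamma: float = 5.0,
) -> pd.DataFrame:
    """Detect genes differentially upregulated after the fork.

    Per gene, a two-sided Wilcoxon rank-sum test between the two post-fork
    branch cell sets, BH-adjusted across genes; a gene additionally passes
    an upregulation gate: its fitted profile along the root-to-winning-
    branch-end path must rise by at least ``up_min`` log units between the
    fork and the branch end. Returns one row per gene with ``p_branch``,
    ``q_branch``, ``effect`` (branch1 - branch2 mean, log units),
    ``winning_branch`` and ``is_fork_gene``.
    """
    expr_values = np.asarray(expr_values, dtype=float)
    idx1 = _branch_cells(projections, fork.branch1)
    idx2 = _branch_cells(projections, fork.branch2)
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValueError("empty post-fork branch")
    if len(idx1) < 20 or len(idx2) < 20:
        warnings.warn("fewer than 20 cells on a post-fork branch", stacklevel=2)

    y1, y2 = expr_values[:, idx1], expr_values[:, idx2]
    p = np.ones(expr_values.shape[0])
    for g in range(expr_values.shape[0]):
        if np.ptp(np.r_[y1[g], y2[g]]) == 0:
            continue  # exchangeable constant gene: no evidence
        p[g] = stats.mannwhitneyu(y1[g], y2[g], alternative="two-sided").pvalue
    q = bh_adjust(p)
    effect = y1.mean(axis=1) - y2.mean(axis=1)
    winning = np.where(effect >= 0, 1, 2)

    pt = np.array([pr.pseudotime for pr in projections])
    up_ok = np.zeros(expr_values.shape[0], dtype=bool)
    sig = q < alpha
    if sig.any():
        for br, w in ((fork.branch1, 1), (fork.branch2, 2)):
            gsel = np.flatnonzero(sig & (winning == w))
            if gsel.size == 0:
                continue
            path_idx = np.r_[_branch_cells(projections, fork.root_path), _branch_cells(projections, br)]
            prof = fit_gene_profiles(
                expr_values[gsel][:, path_idx],
                gene_ids[gsel],
                pt[path_idx],
                gamma=gamma,
            ).single()
            at_fork = np.interp(fork.fork_pseudotime, prof.grid, np.arange(prof.grid.size))
            vals_fork = prof.values[:, int(round(np.clip(at_fork, 0, prof.grid.size - 1)))]
            post = prof.grid >= fork.fork_pseudotime
            vals_end = prof.values[:, post].max(axis=1) if post.any() else prof.values[:, -1]
            up_ok[gsel] = (vals_end - vals_fork) >= up_min

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "p_branch": p,
            "q_branch": q,
            "effect": effect,
            "winning_branch": winning,
            "upregulated": up_ok,
            "is_fork_gene": sig & up_ok,
        }
    )


def assign_branch_specific(
    fork_table: pd.DataFrame,
    profiles_branch1: FittedProfiles,
    profiles_branch2: FittedProfiles,
    fork_pseudotime: float,
    effect_min: float = 0.5,
) -> pd.DataFrame:
    """Assign each fork gene to the branch with higher mean fitted
    post-fork expression; genes whose inter-branch fitted difference is
    below ``effect_min`` are dropped as ambiguous (reported with
    ``assigned_branch = 0``)."""
    genes = fork_table.loc[fork_table["is_fork_gene"], "gene_id"].to_numpy()
    pg1, pg2 = profiles_branch1.single(), profiles_branch2.single()
    post1, post2 = pg1.grid >= fork_pseudotime, pg2.grid >= fork_pseudotime
    rows = []
    for g in genes:
        i1 = int(np.flatnonzero(profiles_branch1.gene_ids == g)[0])
        i2 = int(np.flatnonzero(profiles_branch2.gene_ids == g)[0])
        m1 = float(pg1.values[i1, post1].mean())
        m2 = float(pg2.values[i2, post2].mean())
        diff = m1 - m2
        branch = 0 if abs(diff) < effect_min else (1 if diff > 0 else 2)
        rows.append({"gene_id": g, "fitted_mean_b1": m1, "fitted_mean_b2": m2, "assigned_branch": branch})
    out = pd.DataFrame(rows, columns=["gene_id", "fitted_mean_b1", "fitted_mean_b2", "assigned_branch"])
    n_drop = int((out["assigned_branch"] == 0).sum()) if len(out) else 0
    if n_drop:
        warnings.warn(f"{n_drop} fork genes ambiguous (|diff| < {effect_min}); dropped", stacklevel=2)
    return out


def estimate_activation(
    grid: np.ndarray, profile: np.ndarray, fraction: float = 0.3
) -> tuple[float, float] | None:
    """Optimum expression and activation time from a fitted profile.

    Optimum is the profile maximum on the path; baseline the minimum before
    (and including) the optimum; activation time the earliest grid
    pseudotime where the profile reaches baseline + fraction * (optimum -
    baseline), linearly interpolated between grid points. Returns None for
    a flat profile (activation undefined).
    """
    grid = np.asarray(grid, dtype=float)
    profile = np.asarray(profile, dtype=float)
    i_opt = int(np.argmax(profile))
    optimum = float(profile[i_opt])
    baseline = float(profile[: i_opt + 1].min())
    if optimum - baseline < 1e-9:
        return None
    thresh = baseline + fraction * (optimum - baseline)
    above = np.flatnonzero(profile[: i_opt + 1] >= thresh)
    i = int(above[0])
    if i == 0:
        return optimum, float(grid[0])
    # interpolate the crossing between grid[i-1] and grid[i]
    f = (thresh - profile[i - 1]) / (profile[i] - profile[i - 1])
    return optimum, float(grid[i - 1] + f * (grid[i] - grid[i - 1]))


def split_early_late(
    activation_times: pd.Series, early_threshold: float, path_range: tuple[float, float] | None = None
) -> pd.Series:
    """Label genes early (activation strictly before the threshold) or late.

    The threshold defaults to the fork pseudotime upstream; genes whose
    activation falls exactly at the threshold are late.
    """
    if path_range is not None and not (path_range[0] <= early_threshold <= path_range[1]):
        raise ValueError("early_threshold outside the path's pseudotime range")
    return pd.Series(
        np.where(activation_times < early_threshold, "early", "late"),
        index=activation_times.index,
        name="module",
    )


def fork_gene_table(
    expr_values: np.ndarray,
    gene_ids: np.ndarray,
    projections: list[CellProjection],
    fork: ForkDefinition,
    alpha: float = 0.05,
    up_min: float = 0.5,
    effect_min: float = 0.5,
    fraction: float = 0.3,
    early_threshold: float | None = None,
    gamma: float = 5.0,
    leaf_paths: dict[int, list[list[int]]] | None = None,
) -> pd.DataFrame:
    """End-to-end fork analysis: detection, branch assignment, activation
    timing and the early/late module split, one row per assigned fork gene.

    ``leaf_paths`` optionally lists, per branch (1 or 2), the linear
    root-to-leaf segment paths inside that branch; activation timing is
    then read from the leaf path on which the gene's fitted post-fork
    expression is highest, instead of pooling sub-branches of a branch
    that forks again downstream.
    """
    expr_values = np.asarray(expr_values, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    scored = test_fork_genes(expr_values, gene_ids, projections, fork, alpha, up_min, gamma)
    pt = np.array([p.pseudotime for p in projections])
    if leaf_paths is None:
        leaf_paths = {1: [fork.branch1], 2: [fork.branch2]}

    profs = {}
    for name, br in (("b1", fork.branch1), ("b2", fork.branch2)):
        path_idx = np.r_[_branch_cells(projections, fork.root_path), _branch_cells(projections, br)]
        profs[name] = fit_gene_profiles(expr_values[:, path_idx], gene_ids, pt[path_idx], gamma=gamma)
    assigned = assign_branch_specific(scored, profs["b1"], profs["b2"], fork.fork_pseudotime, effect_min)

    leaf_profs: dict[tuple[int, int], FittedProfiles] = {}
    for b, paths in leaf_paths.items():
        for k, segs in enumerate(paths):
            path_idx = np.r_[_branch_cells(projections, fork.root_path), _branch_cells(projections, segs)]
            leaf_profs[(b, k)] = fit_gene_profiles(expr_values[:, path_idx], gene_ids, pt[path_idx], gamma=gamma)

    thresh = fork.fork_pseudotime if early_threshold is None else early_threshold
    rows = []
    for _, row in assigned[assigned["assigned_branch"] > 0].iterrows():
        g = row["gene_id"]
        b = int(row["assigned_branch"])
        # pick the leaf path where the gene's fitted post-fork mean is highest
        best = None
        for k in range(len(leaf_paths[b])):
            grid_k, vals_k = leaf_profs[(b, k)].profile(g)
            post = grid_k >= fork.fork_pseudotime
            score = vals_k[post].mean() if post.any() else vals_k.mean()
            if best is None or score > best[0]:
                best = (score, grid_k, vals_k)
        _, grid, vals = best
        act = estimate_activation(grid, vals, fraction)
        srow = scored.loc[scored["gene_id"] == g].iloc[0]
        rows.append(
            {
                "gene_id": g,
                "p_branch": srow["p_branch"],
                "q_branch": srow["q_branch"],
                "assigned_branch": int(row["assigned_branch"]),
                "effect": srow["effect"],
                "optimum": np.nan if act is None else act[0],
                "activation_time": np.nan if act is None else act[1],
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "p_branch", "q_branch", "assigned_branch", "effect", "optimum", "activation_time"],
    )
    if len(out):
        out["module"] = split_early_late(out["activation_time"], thresh)
    else:
        out["module"] = pd.Series(dtype=object)
    return out
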