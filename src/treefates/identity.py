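"""Heterogeneity curves, identity-gene back-tracing and endpoint markers.

Transcriptional heterogeneity of a cell population is summarized by a
bootstrap accumulation curve: cells are sampled one after the other with
replacement, each contributing its top-k most expressed genes, and the
cumulative number of unique genes is tracked; homogeneous populations
plateau early. Identity genes -- the program a progenitor pool hands to
all its neuronal progeny -- are genes activated inside the early pool
(activation time before a pseudotime cutoff) and present in nearly every
cell beyond the cutoff on every root-to-leaf trajectory. Endpoint markers
are genes strongly and pervasively enriched in one terminal cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bifurcation import estimate_activation
from .trajstats import bh_adjust, fit_gene_profiles

__all__ = [
    "BootstrapCurve",
    "IdentityGeneSet",
    "bootstrap_gene_accumulation",
    "trace_identity_genes",
    "endpoint_markers",
]


@dataclass
class BootstrapCurve:
    """Mean/SD of cumulative unique top-k genes over bootstrap repetitions."""

    mean_unique: np.ndarray  # per draw
    sd_unique: np.ndarray
    n_draws: int
    n_reps: int
    top_k: int
    per_rep: np.ndarray  # (n_reps, n_draws), each row non-decreasing


def bootstrap_gene_accumulation(
    counts: np.ndarray,
    cell_indices: np.ndarray | None = None,
    n_draws: int = 100,
    top_k: int = 100,
    n_reps: int = 100,
    seed: int = 0,
) -> BootstrapCurve:
    """Cumulative-unique-gene bootstrap curve for one cell population.

    Per repetition, ``n_draws`` cells are sampled one after the other with
    replacement; each sampled cell contributes its ``top_k`` most expressed
    genes by raw count (ties broken by gene order) and the running union
    size is recorded after every draw.
    """
    counts = np.asarray(counts)
    n_genes, n_cells_all = counts.shape
    if cell_indices is None:
        cell_indices = np.arange(n_cells_all)
    cell_indices = np.asarray(cell_indices)
    if cell_indices.size == 0:
        raise ValueError("no cells at this timepoint")
    k = min(top_k, n_genes)

    # per-cell top sets, computed once; stable sort on -count breaks ties
    # by canonical (ascending) gene order
    top_sets = []
    for c in cell_indices:
        order = np.argsort(-counts[:, c], kind="stable")
        top_sets.append(order[:k])

    rng = np.random.default_rng(seed)
    per_rep = np.empty((n_reps, n_draws), dtype=int)
    for r in range(n_reps):
        seen = np.zeros(n_genes, dtype=bool)
        picks = rng.integers(0, len(top_sets), size=n_draws)
        total = 0
        for d, p in enumerate(picks):
            t = top_sets[p]
            new = np.count_nonzero(~seen[t])
            seen[t] = True
            total += new
            per_rep[r, d] = total
    return BootstrapCurve(
        mean_unique=per_rep.mean(axis=0),
        sd_unique=per_rep.std(axis=0),
        n_draws=n_draws,
        n_reps=n_reps,
        top_k=k,
        per_rep=per_rep,
    )


@dataclass
class IdentityGeneSet:
    """Genes activated in the early pool and present on every trajectory."""

    gene_ids: list[str]
    t0: float
    presence: float
    presence_fractions: pd.DataFrame  # gene x trajectory
    activation_times: pd.Series  # NaN where undefined


def trace_identity_genes(
    counts: np.ndarray,
    expr_values: np.ndarray,
    gene_ids: np.ndarray,
    pseudotime: np.ndarray,
    trajectories: dict[str, np.ndarray],
    t0: float = 6.0,
    presence: float = 0.98,
    gamma: float = 5.0,
    fraction: float = 0.3,
) -> IdentityGeneSet:
    """Back-trace genes defining a shared neuronal identity.

    A gene qualifies iff (i) its activation time, estimated from a
    smoothing-spline profile along each root-to-leaf trajectory, is before
    ``t0`` on every trajectory where it is defined (and defined on at
    least one), and (ii) on every trajectory, the fraction of cells with
    raw count > 0 among cells at pseudotime > ``t0`` strictly exceeds
    ``presence``.

    ``trajectories`` maps trajectory name -> cell index array of one full
    root-to-leaf path.
    """
    counts = np.asarray(counts)
    expr_values = np.asarray(expr_values, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    pseudotime = np.asarray(pseudotime, dtype=float)

    frac_tab = {}
    act_per_traj = []
    for name, idx in trajectories.items():
        idx = np.asarray(idx)
        late = idx[pseudotime[idx] > t0]
        if late.size == 0:
            raise ValueError(f"trajectory {name!r} has no cells beyond t0={t0}")
        frac_tab[name] = (counts[:, late] > 0).mean(axis=1)
        profs = fit_gene_profiles(expr_values[:, idx], gene_ids, pseudotime[idx], gamma=gamma).single()
        acts = np.full(len(gene_ids), np.nan)
        for g in range(len(gene_ids)):
            est = estimate_activation(profs.grid, profs.values[g], fraction)
            if est is not None:
                acts[g] = est[1]
        act_per_traj.append(acts)
    frac_df = pd.DataFrame(frac_tab, index=pd.Index(gene_ids, name="gene_id"))
    act_mat = np.array(act_per_traj)  # (n_traj, n_genes)

    defined = ~np.isnan(act_mat)
    early_everywhere = defined.any(axis=0) & np.all(np.where(defined, act_mat < t0, True), axis=0)
    present_everywhere = (frac_df.to_numpy() > presence).all(axis=1)
    member = early_everywhere & present_everywhere

    act_series = pd.Series(
        np.where(defined.any(axis=0), np.nanmin(np.where(defined, act_mat, np.inf), axis=0), np.nan),
        index=frac_df.index,
        name="activation_time",
    )
    return IdentityGeneSet(
        gene_ids=list(gene_ids[member]),
        t0=t0,
        presence=presence,
        presence_fractions=frac_df,
        activation_times=act_series,
    )


def endpoint_markers(
    expr_values: np.ndarray,
    gene_ids: np.ndarray,
    cluster_labels: np.ndarray,
    counts: np.ndarray | None = None,
    log2fc_min: float = 1.0,
    fraction_min: float = 0.9,
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """Markers of terminal clusters: strong, pervasive enrichment.

    Per cluster and gene, ``log2fc = log2((mean_in + eps) / (mean_out +
    eps))`` on de-logged normalized expression and the fraction of cluster
    cells expressing the gene (count > 0; falls back to expression > 0
    when counts are not given). Markers pass both strict thresholds
    (log2fc > ``log2fc_min`` and fraction > ``fraction_min``); a rank-sum
    p and BH q are reported alongside but are not part of the rule.
    """
    expr_values = np.asarray(expr_values, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    cluster_labels = np.asarray(cluster_labels)
    clusters = sorted(pd.unique(cluster_labels))
    if len(clusters) < 2:
        raise ValueError("need at least 2 endpoint clusters")
    detect = (counts if counts is not None else expr_values) > 0
    delog = np.expm1(expr_values)

    frames = []
    for cl in clusters:
        inside = cluster_labels == cl
        if inside.sum() == 1:
            warnings.warn(f"cluster {cl!r} is a singleton", stacklevel=2)
        mean_in = delog[:, inside].mean(axis=1)
        mean_out = delog[:, ~inside].mean(axis=1)
        log2fc = np.log2((mean_in + epsilon) / (mean_out + epsilon))
        frac = detect[:, inside].mean(axis=1)
        p = np.ones(len(gene_ids))
        for g in range(len(gene_ids)):
            a, b = expr_values[g, inside], expr_values[g, ~inside]
            if np.ptp(np.r_[a, b]) > 0:
                p[g] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        frames.append(
            pd.DataFrame(
                {
                    "cluster": cl,
                    "gene_id": gene_ids,
                    "log2fc": log2fc,
                    "fraction_expressed": frac,
                    "p_value": p,
                    "q_value": bh_adjust(p),
                    "is_marker": (log2fc > log2fc_min) & (frac > fraction_min),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
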