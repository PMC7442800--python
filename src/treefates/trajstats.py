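"""Gene statistics along the principal tree.

Tree-associated genes are detected per root-to-leaf path by an F-test of a
cubic B-spline regression of log expression on pseudotime against the
constant model, pooled over paths, with Benjamini-Hochberg adjustment
across genes and a minimum fitted-amplitude gate. Associated genes are
smoothed with a cubic smoothing spline (penalty ``gamma`` on the integrated
squared second derivative) on a uniform pseudotime grid, clustered into
major patterns with Ward/Euclidean hierarchical clustering, compared
between two branches from their inferred closest common point, and used to
score transcription-factor activity by L1-penalized regression on a binary
TF-target matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from scipy.interpolate import BSpline, make_smoothing_spline
from sklearn.linear_model import Lasso
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneAssociation",
    "FittedProfiles",
    "ProfileClustering",
    "BranchComparison",
    "TFActivity",
    "test_associated_genes",
    "fit_gene_profiles",
    "cluster_profiles",
    "compare_branches",
    "infer_tf_activity",
    "synthetic_target_matrix",
    "bh_adjust",
]

DEFAULT_GAMMA = 5.0
DEFAULT_GRID_SIZE = 100


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def _spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline design matrix with interior knots at quantiles of x."""
    k = 3
    n_interior = max(df - (k + 1), 0)
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        hi = lo + 1e-12
    if n_interior > 0:
        qs = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
        qs = np.clip(qs, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
    else:
        qs = np.array([])
    t = np.r_[[lo] * (k + 1), np.sort(qs), [hi] * (k + 1)]
    return BSpline.design_matrix(np.clip(x, lo, hi), t, k).toarray()


@dataclass
class GeneAssociation:
    """Per-gene association of expression with pseudotime."""

    table: pd.DataFrame  # gene_id, f_statistic, p_value, q_value, amplitude, associated
    alpha: float
    a_min: float

    @property
    def associated_genes(self) -> list[str]:
        return list(self.table.loc[self.table["associated"], "gene_id"])


def test_associated_genes(
    expr_values: np.ndarray,
    gene_ids: np.ndarray,
    pseudotime: np.ndarray,
    paths: list[np.ndarray] | None = None,
    alpha: float = 0.05,
    a_min: float = 0.5,
    df: int = 6,
) -> GeneAssociation:
    """F-test of a cubic-spline pseudotime fit against the constant model.

    Parameters
    ----------
    expr_values
    	``(n_genes, n_cells)`` log expression.
    paths
    	Cell index arrays, one per root-to-leaf path; residual sums of
    	squares are pooled over paths. Default: all cells as one path.
    a_min
    	Minimum fitted amplitude (max - min over the pooled fits, log
    	units) for a gene to be called associated.
    """
    expr_values = np.asarray(expr_values, dtype=float)
    pseudotime = np.asarray(pseudotime, dtype=float)
    if paths is None:
        paths = [np.arange(expr_values.shape[1])]
    n_total = sum(len(p) for p in paths)
    if n_total < 20:
        raise ValueError("need at least 20 cells on the tested subtree")

    rss1 = np.zeros(expr_values.shape[0])
    rss0 = np.zeros(expr_values.shape[0])
    df1_total, df0_total = 0, 0
    amp_lo = np.full(expr_values.shape[0], np.inf)
    amp_hi = np.full(expr_values.shape[0], -np.inf)
    for idx in paths:
        x, y = pseudotime[idx], expr_values[:, idx]
        if len(idx) <= df + 1:
            raise ValueError("fewer cells than spline degrees of freedom on a path")
        basis = _spline_basis(x, df)
        coef, *_ = np.linalg.lstsq(basis, y.T, rcond=None)
        fitted = basis @ coef  # (n_cells, n_genes)
        rss1 += ((y.T - fitted) ** 2).sum(axis=0)
        rss0 += ((y.T - y.mean(axis=1)) ** 2).sum(axis=0)
        df1_total += basis.shape[1]
        df0_total += 1
        amp_lo = np.minimum(amp_lo, fitted.min(axis=0))
        amp_hi = np.maximum(amp_hi, fitted.max(axis=0))

    num_df = df1_total - df0_total
    den_df = n_total - df1_total
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((rss0 - rss1) / num_df) / np.maximum(rss1 / den_df, 1e-300)
    f_stat = np.where(rss0 <= 1e-300, 0.0, f_stat)  # constant genes: no signal
    p = stats.f.sf(f_stat, num_df, den_df)
    q = bh_adjust(p)
    amplitude = amp_hi - amp_lo
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "f_statistic": f_stat,
            "p_value": p,
            "q_value": q,
            "amplitude": amplitude,
            "associated": (q < alpha) & (amplitude >= a_min),
        }
    )
    return GeneAssociation(table=table, alpha=alpha, a_min=a_min)


@dataclass
class ProfileGrid:
    """Smoothed profiles of all genes along one path."""

    grid: np.ndarray  # strictly increasing pseudotime values
    values: np.ndarray  # (n_genes, n_grid); NaN rows where unavailable

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


@dataclass
class FittedProfiles:
    """Smoothing-spline profiles per root-to-leaf path."""

    gene_ids: np.ndarray
    by_path: dict[str, ProfileGrid]
    gamma: float = DEFAULT_GAMMA

    def single(self) -> ProfileGrid:
        if len(self.by_path) != 1:
            raise ValueError("multiple paths; pick one explicitly")
        return next(iter(self.by_path.values()))

    def profile(self, gene_id: str, path: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        pg = self.by_path[path] if path is not None else self.single()
        idx = int(np.flatnonzero(self.gene_ids == gene_id)[0])
        return pg.grid, pg.values[idx]


def _smooth_one_path(
    x: np.ndarray, y: np.ndarray, gamma: float, grid: np.ndarray
) -> np.ndarray:
    """Smoothing-spline fit of each gene (rows of y) evaluated on grid."""
    order = np.argsort(x)
    xs, ys = x[order], y[:, order]
    ux, inv = np.unique(np.round(xs, 9), return_inverse=True)
    out = np.empty((y.shape[0], grid.size))
    counts = np.bincount(inv).astype(float)
    for g in range(y.shape[0]):
        ym = np.bincount(inv, weights=ys[g]) / counts  # average duplicate x
        spl = make_smoothing_spline(ux, ym, lam=gamma)
        out[g] = spl(grid)
    return out


def fit_gene_profiles(
    expr_values: np.ndarray,
    gene_ids: np.ndarray,
    pseudotime: np.ndarray,
    paths: dict[str, np.ndarray] | None = None,
    gamma: float = DEFAULT_GAMMA,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> FittedProfiles:
    """Cubic smoothing-spline profiles on a uniform pseudotime grid.

    ``gamma`` scales the integrated squared second-derivative penalty;
    large values shrink the fit toward the least-squares line. Paths with
    fewer than 4 cells are marked unavailable (NaN), not extrapolated.
    """
    expr_values = np.asarray(expr_values, dtype=float)
    pseudotime = np.asarray(pseudotime, dtype=float)
    if paths is None:
        paths = {"path": np.arange(expr_values.shape[1])}
    by_path = {}
    for name, idx in paths.items():
        x = pseudotime[idx]
        grid = np.linspace(x.min(), x.max(), max(grid_size, 100))
        if len(idx) < 4 or np.unique(np.round(x, 9)).size < 4:
            warnings.warn(f"path {name!r}: fewer than 4 cells; profiles unavailable", stacklevel=2)
            vals = np.full((expr_values.shape[0], grid.size), np.nan)
        else:
            vals = _smooth_one_path(x, expr_values[:, idx], gamma, grid)
        by_path[name] = ProfileGrid(grid=grid, values=vals)
    return FittedProfiles(gene_ids=np.asarray(gene_ids, dtype=object), by_path=by_path, gamma=gamma)


@dataclass
class ProfileClustering:
    """Gene -> pattern id from Ward/Euclidean hierarchical clustering."""

    labels: pd.Series  # indexed by gene_id
    n_patterns: int
    linkage: str = "ward"
    metric: str = "euclidean"


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    return (values - mu) / np.where(sd < 1e-12, 1.0, sd)


def cluster_profiles(profiles: FittedProfiles, n_patterns: int = 30) -> ProfileClustering:
    """Cut a Ward/Euclidean dendrogram of z-scored profiles at ``n_patterns``.

    Profiles are concatenated across paths (z-scored per gene over the
    concatenation) so a pattern reflects the gene's shape on the whole tree.
    """
    mats = [pg.values for pg in profiles.by_path.values()]
    stacked = np.hstack(mats)
    ok = ~np.isnan(stacked).any(axis=1)
    genes = profiles.gene_ids[ok]
    if n_patterns > ok.sum():
        raise ValueError("n_patterns exceeds number of genes with profiles")
    z = _zscore_rows(stacked[ok])
    link = sch.linkage(z, method="ward", metric="euclidean")
    labels = sch.fcluster(link, t=n_patterns, criterion="maxclust")
    return ProfileClustering(
        labels=pd.Series(labels, index=pd.Index(genes, name="gene_id"), name="pattern"),
        n_patterns=n_patterns,
    )


@dataclass
class BranchComparison:
    """Two branches compared from their closest common point."""

    common_point_a: tuple[float, np.ndarray]  # (pseudotime along A, coordinates)
    common_point_b: tuple[float, np.ndarray]
    common_genes: set[str]
    branch_specific: dict[str, str]  # gene -> "A" | "B"
    early_late: dict[str, str]  # gene -> "early" | "late"


def _sample_skeleton(points: np.ndarray, pt: np.ndarray, n_samples: int):
    """Densely resample a branch skeleton polyline, carrying pseudotime."""
    t = np.linspace(pt.min(), pt.max(), n_samples)
    coords = np.column_stack([np.interp(t, pt, points[:, d]) for d in range(points.shape[1])])
    return t, coords


def compare_branches(
    assoc_a: set[str],
    assoc_b: set[str],
    profiles_a: FittedProfiles,
    profiles_b: FittedProfiles,
    skeleton_a: tuple[np.ndarray, np.ndarray],
    skeleton_b: tuple[np.ndarray, np.ndarray],
    n_samples: int = 200,
) -> BranchComparison:
    """Compare two branches from the point where they are closest in
    embedding space.

    ``skeleton_*`` is ``(points, pseudotime)``: polyline vertices of the
    branch in embedding space with their pseudotime. The common point is
    the argmin of Euclidean distance over a dense sampling of both
    skeletons. Genes associated on both branches are common; the symmetric
    difference is branch-specific. Each gene is labeled early or late by a
    2-cluster Ward split of its z-scored profile re-parameterized from the
    common point, the cluster that rises earlier being "early".
    """
    if not assoc_a or not assoc_b:
        raise ValueError("empty association set on a branch")
    ta, ca = _sample_skeleton(skeleton_a[0], skeleton_a[1], n_samples)
    tb, cb = _sample_skeleton(skeleton_b[0], skeleton_b[1], n_samples)
    d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1)
    ia, ib = np.unravel_index(np.argmin(d2), d2.shape)

    common = assoc_a & assoc_b
    specific = {g: "A" for g in assoc_a - assoc_b}
    specific.update({g: "B" for g in assoc_b - assoc_a})

    rows, genes = [], []
    grid_n = 50
    for g in sorted(assoc_a | assoc_b):
        prof = profiles_a if g in assoc_a else profiles_b
        t0 = ta[ia] if g in assoc_a else tb[ib]
        pg = prof.single()
        mask = pg.grid >= t0
        if mask.sum() < 4:
            mask = np.ones_like(pg.grid, dtype=bool)
        idx = int(np.flatnonzero(prof.gene_ids == g)[0])
        tt = np.linspace(pg.grid[mask].min(), pg.grid[mask].max(), grid_n)
        rows.append(np.interp(tt, pg.grid[mask], pg.values[idx][mask]))
        genes.append(g)
    z = _zscore_rows(np.array(rows))
    if len(genes) >= 2:
        link = sch.linkage(z, method="ward")
        lab = sch.fcluster(link, t=2, criterion="maxclust")
        # the cluster whose mean z-profile crosses its midpoint earlier is "early"
        rise = []
        for c in (1, 2):
            m = z[lab == c].mean(axis=0)
            half = (m.min() + m.max()) / 2
            above = np.flatnonzero(m >= half)
            rise.append(above[0] if above.size else grid_n)
        early_cluster = 1 if rise[0] <= rise[1] else 2
        early_late = {g: ("early" if l == early_cluster else "late") for g, l in zip(genes, lab)}
    else:
        early_late = {g: "early" for g in genes}

    return BranchComparison(
        common_point_a=(float(ta[ia]), ca[ia]),
        common_point_b=(float(tb[ib]), cb[ib]),
        common_genes=common,
        branch_specific=specific,
        early_late=early_late,
    )


def synthetic_target_matrix(
    gene_ids,
    tf_targets: dict[str, list[str]],
    n_decoy_tfs: int = 0,
    decoy_size: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Binary gene x TF target matrix for testing activity inference.

    ``tf_targets`` maps TF name -> target gene ids; decoy TFs draw random
    target sets of ``decoy_size`` genes. Returns the matrix and the TF id
    list (real TFs first).
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    pos = {g: i for i, g in enumerate(gene_ids)}
    rng = np.random.default_rng(seed)
    tf_ids = list(tf_targets) + [f"decoy_{i}" for i in range(n_decoy_tfs)]
    m = np.zeros((len(gene_ids), len(tf_ids)))
    for j, (tf_name, targets) in enumerate(tf_targets.items()):
        for g in targets:
            m[pos[g], j] = 1.0
    for j in range(n_decoy_tfs):
        idx = rng.choice(len(gene_ids), size=min(decoy_size, len(gene_ids)), replace=False)
        m[idx, len(tf_targets) + j] = 1.0
    return m, tf_ids


@dataclass
class TFActivity:
    """Per-TF activity over the pseudotime grid from L1 regression."""

    tf_ids: np.ndarray
    grid: np.ndarray
    activities: np.ndarray  # (n_tf, n_grid)
    alpha: float


def infer_tf_activity(
    profiles: FittedProfiles,
    target_matrix: np.ndarray,
    tf_ids,
    alpha: float = 1.0,
    path: str | None = None,
) -> TFActivity:
    """Infer TF activities by lasso regression of profiles on targets.

    At each grid point t the gene profile vector y(t) is regressed on the
    binary gene x TF target matrix M, minimizing
    ``||y - M a||^2 + alpha * ||a||_1`` by coordinate descent; with
    ``alpha = 0`` the plain least-squares solution is returned.
    """
    target_matrix = np.asarray(target_matrix, dtype=float)
    if target_matrix.sum() == 0:
        raise ValueError("all-zero target matrix")
    pg = profiles.by_path[path] if path is not None else profiles.single()
    if target_matrix.shape[0] != pg.values.shape[0]:
        raise ValueError("target matrix rows must align with profile genes")
    y = pg.values - pg.values.mean(axis=1, keepdims=True)  # center each gene over the grid
    n_genes = target_matrix.shape[0]
    acts = np.empty((target_matrix.shape[1], pg.grid.size))
    if alpha == 0:
        coef, *_ = np.linalg.lstsq(target_matrix, y, rcond=None)
        acts = coef
    else:
        model = Lasso(alpha=alpha / (2 * n_genes), fit_intercept=False, max_iter=10000)
        for j in range(pg.grid.size):
            acts[:, j] = model.fit(target_matrix, y[:, j]).coef_
    return TFActivity(tf_ids=np.asarray(tf_ids, dtype=object), grid=pg.grid, activities=acts, alpha=alpha)
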