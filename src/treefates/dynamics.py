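"""Sliding-window module correlation dynamics ("repulsion").

The coordination of gene programs around a pseudotime t is measured inside
a sliding window of cells: local gene-gene Pearson correlations are
averaged over all pairs within a module (intra) or across two modules
(inter), and the repulsion statistic |mean(intra_A, intra_B) - inter|
quantifies how antagonistic the two programs are. Competing fate-biasing
modules show rising intra-module coordination and falling (increasingly
negative) inter-module correlation as cells approach their bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import CellProjection

__all__ = [
    "WindowSet",
    "ModuleTrack",
    "build_windows",
    "local_gene_correlation",
    "module_correlation_track",
]


@dataclass
class WindowSet:
    """Ordered rank-based sliding windows of cells along pseudotime."""

    windows: list[np.ndarray]  # cell index arrays
    centers: np.ndarray  # mean pseudotime per window
    size: int
    step: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.centers) < 0):
            raise ValueError("windows must be ordered by center")

    def __len__(self) -> int:
        return len(self.windows)


def build_windows(
    pseudotime: np.ndarray,
    cell_indices: np.ndarray | None = None,
    w: int = 40,
    s: int = 10,
    min_cells: int = 10,
) -> WindowSet:
    """Rank-based sliding windows: window i covers pseudotime ranks
    [i*s, i*s + w). A trailing partial window is kept if it has at least
    ``min_cells`` cells."""
    if w < min_cells:
        raise ValueError("window size below min_cells")
    pseudotime = np.asarray(pseudotime, dtype=float)
    if cell_indices is None:
        cell_indices = np.arange(pseudotime.size)
    cell_indices = np.asarray(cell_indices)
    n = cell_indices.size
    if n < w:
        raise ValueError("fewer cells than the window size")
    order = cell_indices[np.argsort(pseudotime[cell_indices], kind="stable")]

    windows, centers = [], []
    n_full = (n - w) // s + 1
    for i in range(n_full):
        idx = order[i * s : i * s + w]
        windows.append(idx)
        centers.append(pseudotime[idx].mean())
    last_end = (n_full - 1) * s + w
    tail_start = n_full * s
    if last_end < n and (n - tail_start) >= min_cells:
        idx = order[tail_start:]
        windows.append(idx)
        centers.append(pseudotime[idx].mean())
    return WindowSet(windows=windows, centers=np.array(centers), size=w, step=s)


def local_gene_correlation(
    expr_values: np.ndarray,
    window: np.ndarray,
    gene_index: int,
    module_indices: np.ndarray,
) -> float | None:
    """Mean local Pearson correlation of one gene with a module.

    Correlation of the gene with every other module member over the
    window's cells; pairs where either gene has zero variance in the
    window are excluded. Returns None when every pair is excluded.
    """
    if len(window) < 3:
        raise ValueError("window must have at least 3 cells")
    g = expr_values[gene_index, window]
    cors = []
    for m in module_indices:
        if m == gene_index:
            continue
        h = expr_values[m, window]
        if g.std() < 1e-12 or h.std() < 1e-12:
            continue
        cors.append(np.corrcoef(g, h)[0, 1])
    return float(np.mean(cors)) if cors else None


@dataclass
class ModuleTrack:
    """Per-window intra/inter-module mean correlations and repulsion."""

    table: pd.DataFrame  # center, intra_A, intra_B, inter, repulsion, pair counts
    module_a: list[str]
    module_b: list[str]

    def last_prefork_windows(self, fork_pseudotime: float, k: int = 3) -> pd.DataFrame:
        pre = self.table[self.table["center"] < fork_pseudotime]
        return pre.tail(k)


def _pair_means(c: np.ndarray, rows: np.ndarray, cols: np.ndarray, within: bool) -> tuple[float, int]:
    """Mean of correlation entries over the requested pairs, NaN-excluded."""
    if within:
        iu = np.triu_indices(len(rows), k=1)
        vals = c[np.ix_(rows, rows)][iu]
    else:
        vals = c[np.ix_(rows, cols)].ravel()
    ok = ~np.isnan(vals)
    return (float(vals[ok].mean()) if ok.any() else np.nan), int(ok.sum())


def module_correlation_track(
    expr_values: np.ndarray,
    gene_ids: np.ndarray,
    windows: WindowSet,
    module_a: list[str],
    module_b: list[str],
) -> ModuleTrack:
    """Intra- and inter-module mean local correlations per window.

    intra_A averages the C(|A|, 2) within-A pairs, intra_B likewise, inter
    the |A| x |B| cross pairs; pairs involving a zero-variance gene in the
    window are excluded and the surviving pair counts reported. The
    repulsion statistic is |mean(intra_A, intra_B) - inter|.
    """
    if len(module_a) < 2 or len(module_b) < 2:
        raise ValueError("modules must have at least 2 genes")
    if set(module_a) & set(module_b):
        raise ValueError("modules overlap")
    gene_ids = np.asarray(gene_ids, dtype=object)
    pos = {g: i for i, g in enumerate(gene_ids)}
    ia = np.array([pos[g] for g in module_a])
    ib = np.array([pos[g] for g in module_b])
    sel = np.r_[ia, ib]
    ra = np.arange(len(ia))
    rb = np.arange(len(ia), len(ia) + len(ib))

    rows = []
    for win, center in zip(windows.windows, windows.centers):
        x = expr_values[np.ix_(sel, win)]
        sd = x.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(x)
        c[sd < 1e-12, :] = np.nan
        c[:, sd < 1e-12] = np.nan
        intra_a, n_a = _pair_means(c, ra, ra, within=True)
        intra_b, n_b = _pair_means(c, rb, rb, within=True)
        inter, n_i = _pair_means(c, ra, rb, within=False)
        rep = abs((intra_a + intra_b) / 2 - inter)
        rows.append(
            {
                "center": center,
                "intra_A": intra_a,
                "intra_B": intra_b,
                "inter": inter,
                "repulsion": rep,
                "n_pairs_A": n_a,
                "n_pairs_B": n_b,
                "n_pairs_inter": n_i,
                "n_cells": len(win),
            }
        )
    return ModuleTrack(table=pd.DataFrame(rows), module_a=list(module_a), module_b=list(module_b))
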