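"""Count-matrix containers, standard-format I/O, QC filtering and normalization.

The entry point of the pipeline is a gene x cell matrix of raw (non-UMI)
transcript counts with ERCC spike-in rows flagged, as produced by a
Smart-seq2 style quantification. Cells are filtered on three per-cell
metrics -- total transcripts, detected genes and spike-in read fraction --
then endogenous counts are depth-normalized to the median post-QC library
size and log-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "CellAnnotation",
    "QCParams",
    "QCReport",
    "ExpressionMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "qc_filter_cells",
    "normalize_counts",
    "select_overdispersed_genes",
]

ERCC_PREFIX = "ERCC-"


@dataclass
class CountMatrix:
    """Raw integer gene x cell counts with spike-in flags.

    Parameters
    ----------
    values
    	``(n_genes, n_cells)`` nonnegative integer matrix; dense ndarray or
    	scipy sparse.
    gene_ids, cell_ids
    	Unique string identifiers for rows and columns.
    is_spikein
    	Per-gene boolean; ERCC spike-in rows. Derived from the ``ERCC-`` id
    	prefix when not given.
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    is_spikein: np.ndarray = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.is_spikein is None:
            self.is_spikein = np.array(
                [str(g).startswith(ERCC_PREFIX) for g in self.gene_ids], dtype=bool
            )
        else:
            self.is_spikein = np.asarray(self.is_spikein, dtype=bool)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        dense = self.dense()
        if np.any(dense < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(dense, np.round(dense)):
            raise ValueError("counts must be integral")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        vals = self.values.tocsc()[:, mask] if sp.issparse(self.values) else self.values[:, mask]
        return CountMatrix(vals, self.gene_ids, self.cell_ids[mask], self.is_spikein)

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        vals = self.values.tocsr()[mask, :] if sp.issparse(self.values) else self.values[mask, :]
        return CountMatrix(vals, self.gene_ids[mask], self.cell_ids, self.is_spikein[mask])


@dataclass
class CellAnnotation:
    """Per-cell metadata: timepoint, lineage-tracing line, optional cluster."""

    table: pd.DataFrame  # indexed by cell_id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate cell ids in annotation")

    @classmethod
    def from_arrays(cls, cell_ids, timepoint=None, tracing_line=None, cluster_label=None):
        df = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
        df["timepoint"] = timepoint if timepoint is not None else "NA"
        df["tracing_line"] = tracing_line if tracing_line is not None else "NA"
        if cluster_label is not None:
            df["cluster_label"] = cluster_label
        return cls(df)


@dataclass
class QCParams:
    """Cell-level QC thresholds.

    A cell is kept when total transcripts >= ``min_transcripts``, detected
    genes (count > 0) >= ``min_genes`` and spike-in read fraction
    <= ``max_spikein_fraction``; only strict violations are removed.
    """

    min_transcripts: int = 50_000
    min_genes: int = 2_500
    max_spikein_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.min_transcripts <= 0 or self.min_genes <= 0:
            raise ValueError("count thresholds must be positive")
        if not 0 < self.max_spikein_fraction <= 1:
            raise ValueError("max_spikein_fraction must be in (0, 1]")


@dataclass
class QCReport:
    """Per-cell QC metrics with pass/fail reasons."""

    table: pd.DataFrame
    n_input: int
    n_kept: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


@dataclass
class ExpressionMatrix:
    """Log-scale gene x cell expression with the normalization record."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    normalization: str = "none"
    size_factors: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.size_factors is not None and np.any(np.asarray(self.size_factors) <= 0):
            raise ValueError("size factors must be positive")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene(self, gene_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if idx.size == 0:
            raise KeyError(gene_id)
        return self.values[idx[0]]


def read_count_matrix(path: str | Path, format: str = "sparse-exchange") -> CountMatrix:
    """Read a gene x cell count matrix.

    ``sparse-exchange``: ``path`` is a directory with ``matrix.mtx`` (genes
    as rows), ``genes.tsv`` and ``cells.tsv``. ``delimited``: ``path`` is a
    TSV with gene ids as the index and cell ids as columns.
    Genes whose id starts with ``ERCC-`` are flagged as spike-ins.
    """
    path = Path(path)
    if format == "sparse-exchange":
        values = sp.csr_matrix(mmread(path / "matrix.mtx"))
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].to_numpy()
        cells = pd.read_csv(path / "cells.tsv", sep="\t", header=None)[0].to_numpy()
        if values.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(genes)} genes x {len(cells)} cells"
            )
    elif format == "delimited":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy()
        genes, cells = df.index.to_numpy(), df.columns.to_numpy()
    else:
        raise ValueError(f"unknown format {format!r}")
    dense = np.asarray(values.todense()) if sp.issparse(values) else values
    if not np.allclose(dense, np.round(dense)):
        raise ValueError("non-integer entries in count matrix")
    return CountMatrix(values, genes, cells)


def write_count_matrix(counts: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as MTX triplets plus gene/cell id tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    vals = counts.values if sp.issparse(counts.values) else sp.coo_matrix(counts.values)
    mmwrite(str(path / "matrix.mtx"), vals)
    pd.Series(counts.gene_ids).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.cell_ids).to_csv(path / "cells.tsv", sep="\t", header=False, index=False)


def qc_filter_cells(counts: CountMatrix, params: QCParams | None = None) -> tuple[CountMatrix, QCReport]:
    """Filter cells on depth, gene detection and spike-in fraction.

    Cells are removed when they have strictly fewer transcripts than
    ``min_transcripts``, strictly fewer detected genes than ``min_genes``,
    or a spike-in fraction strictly above ``max_spikein_fraction``; cells
    sitting exactly on a threshold are kept.
    """
    params = params or QCParams()
    dense = counts.dense()
    total = dense.sum(axis=0)
    n_detected = (dense > 0).sum(axis=0)
    spike_total = dense[counts.is_spikein].sum(axis=0) if counts.is_spikein.any() else np.zeros(counts.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        spike_frac = np.where(total > 0, spike_total / np.maximum(total, 1), 1.0)

    pass_depth = total >= params.min_transcripts
    pass_genes = n_detected >= params.min_genes
    pass_spike = spike_frac <= params.max_spikein_fraction
    keep = pass_depth & pass_genes & pass_spike

    reasons = []
    for d, g, s in zip(pass_depth, pass_genes, pass_spike):
        r = []
        if not d:
            r.append("low_transcripts")
        if not g:
            r.append("few_genes")
        if not s:
            r.append("high_spikein")
        reasons.append(";".join(r) if r else "pass")
    report = QCReport(
        table=pd.DataFrame(
            {
                "total_transcripts": total,
                "n_detected_genes": n_detected,
                "spikein_fraction": spike_frac,
                "kept": keep,
                "reason": reasons,
            },
            index=pd.Index(counts.cell_ids, name="cell_id"),
        ),
        n_input=counts.n_cells,
        n_kept=int(keep.sum()),
    )
    if report.n_kept == 0:
        warnings.warn("QC removed every cell; returning an empty matrix", stacklevel=2)
    return counts.subset_cells(keep), report


def normalize_counts(counts: CountMatrix) -> ExpressionMatrix:
    """Depth-normalize to the median library size, then log(1 + x).

    Spike-in rows are excluded both from the size-factor computation and
    from the output. Size factors are per-cell endogenous totals divided by
    their median, so values are ln(1 + count * median_depth / cell_depth).
    """
    endo = counts.subset_genes(~counts.is_spikein)
    dense = endo.dense().astype(float)
    depth = dense.sum(axis=0)
    if np.any(depth == 0):
        raise ValueError("zero-depth cell encountered; run QC first")
    size_factors = depth / np.median(depth)
    return ExpressionMatrix(
        np.log1p(dense / size_factors),
        endo.gene_ids,
        endo.cell_ids,
        normalization="median-depth log1p",
        size_factors=size_factors,
    )


def select_overdispersed_genes(expr: ExpressionMatrix, n_top: int) -> list[str]:
    """Rank genes by positive residual variance above a mean-variance trend.

    The trend is the median log variance within quantile bins of the log
    mean (a robust stand-in for the local regression used by
    variance-adjustment methods); genes are ranked by their residual from
    it and the top ``n_top`` returned. Zero-variance genes are never
    selected.
    """
    if expr.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if n_top == 0:
        return []
    mean = expr.values.mean(axis=1)
    var = expr.values.var(axis=1, ddof=1)
    ok = var > 0
    if n_top > int(ok.sum()):
        warnings.warn("n_top exceeds number of variable genes; clipping", stacklevel=2)
        n_top = int(ok.sum())
    lm, lv = np.log(mean[ok] + 1e-8), np.log(var[ok])
    n_bins = int(np.clip(ok.sum() // 10, 1, 20))
    edges = np.quantile(lm, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, lm, side="right") - 1, 0, n_bins - 1)
    trend = np.array([np.median(lv[bins == b]) if np.any(bins == b) else 0.0 for b in range(n_bins)])
    resid = lv - trend[bins]
    order = np.argsort(-resid, kind="stable")
    return list(expr.gene_ids[ok][order[:n_top]])
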