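"""Loading, filtering, normalization and informative-gene selection.

Expression matrices are genes x cells.  Supported on-disk formats are
dense CSV/TSV (first column = gene ids, header = cell ids) and Matrix
Market triplets with companion ``genes.tsv`` / ``barcodes.tsv`` files
(10x-style layout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "GeneSelection",
    "load_matrix",
    "save_matrix",
    "filter_matrix",
    "normalize",
    "fano_hvg",
    "gini_hvg",
    "gini_index",
]


@dataclass
class ExpressionMatrix:
    """A non-negative genes x cells matrix with axis identifiers."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        m, n = self.values.shape
        if m != len(self.gene_ids):
            raise ValueError(
                f"{m} rows but {len(self.gene_ids)} gene ids"
            )
        if n != len(self.cell_ids):
            raise ValueError(
                f"{n} columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ln(1 + scale_factor * x / colsum)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    scale_factor: float = 10_000.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GeneSelection:
    """Result of highly-variable-gene selection."""

    selected_indices: np.ndarray
    mean_expression: np.ndarray
    normalized_fano: np.ndarray
    gini: np.ndarray | None = None
    method: str = "fano"


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------

def _read_ids(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"companion {what} file not found: {path}")
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    return ids


def load_matrix(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Load a genes x cells expression matrix.

    ``mtx`` inputs expect ``genes.tsv`` and ``barcodes.tsv`` alongside the
    matrix file.  CSV/TSV inputs are dense with gene rows, cell columns,
    a header of cell ids and the first column holding gene ids.
    """
    path = Path(path)
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(
            path.suffix.lower(), "csv"
        )
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # noqa: BLE001 - rewrap with filename
            raise ValueError(f"malformed Matrix Market file {path}: {exc}") from exc
        values = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
        genes = _read_ids(path.parent / "genes.tsv", "gene")
        cells = _read_ids(path.parent / "barcodes.tsv", "barcode")
        return ExpressionMatrix(values, genes, cells)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"malformed {format} file {path}: {exc}") from exc
        return ExpressionMatrix(
            df.to_numpy(dtype=float), df.index.tolist(), df.columns.tolist()
        )
    raise ValueError(f"unknown format {format!r}; expected mtx, csv or tsv")


def save_matrix(M: ExpressionMatrix | NormalizedMatrix, path: str | Path,
                format: str | None = None) -> None:
    """Write a matrix in the same layouts ``load_matrix`` reads."""
    path = Path(path)
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv"}.get(
            path.suffix.lower(), "csv"
        )
    if format == "mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(M.values))
        pd.Series(M.gene_ids).to_csv(path.parent / "genes.tsv", sep="\t",
                                     header=False, index=False)
        pd.Series(M.cell_ids).to_csv(path.parent / "barcodes.tsv", sep="\t",
                                     header=False, index=False)
        return
    sep = "," if format == "csv" else "\t"
    pd.DataFrame(M.values, index=M.gene_ids, columns=M.cell_ids).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_matrix(M: ExpressionMatrix, min_cells_per_gene: int = 3,
                  min_genes_per_cell: int = 200) -> ExpressionMatrix:
    """Remove lowly detected genes, then sparsely covered cells.

    A gene must be non-zero in at least ``min_cells_per_gene`` cells
    (computed on the input); a cell must express at least
    ``min_genes_per_cell`` of the retained genes.  A single pass, no
    iteration to a fixpoint.
    """
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValueError("filter thresholds must be >= 0")
    nz = M.values > 0
    gene_keep = nz.sum(axis=1) >= min_cells_per_gene
    if not gene_keep.any():
        raise ValueError(
            f"all {M.n_genes} genes removed by min_cells_per_gene={min_cells_per_gene}"
        )
    sub = M.values[gene_keep]
    cell_keep = (sub > 0).sum(axis=0) >= min_genes_per_cell
    if not cell_keep.any():
        raise ValueError(
            f"all {M.n_cells} cells removed by min_genes_per_cell={min_genes_per_cell}"
        )
    return ExpressionMatrix(
        sub[:, cell_keep],
        [g for g, k in zip(M.gene_ids, gene_keep) if k],
        [c for c, k in zip(M.cell_ids, cell_keep) if k],
    )


def normalize(M: ExpressionMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Global normalization: per-cell total scaling then log1p.

    out[i, j] = ln(1 + scale_factor * M[i, j] / sum_i M[i, j]).
    Zeros map exactly to zeros.
    """
    colsum = M.values.sum(axis=0)
    if np.any(colsum <= 0):
        bad = [M.cell_ids[j] for j in np.flatnonzero(colsum <= 0)[:5]]
        raise ValueError(
            f"cells with zero total expression (e.g. {bad}); run filter_matrix first"
        )
    vals = np.log1p(scale_factor * M.values / colsum)
    return NormalizedMatrix(vals, list(M.gene_ids), list(M.cell_ids), scale_factor)


# ---------------------------------------------------------------------------
# highly variable genes
# ---------------------------------------------------------------------------

def _fano_factors(values: np.ndarray, ddof: int = 0) -> tuple[np.ndarray, np.ndarray]:
    mu = values.mean(axis=1)
    var = values.var(axis=1, ddof=ddof)
    fano = np.zeros_like(mu)
    pos = mu > 0
    fano[pos] = var[pos] / mu[pos]
    return mu, fano


def fano_hvg(N: NormalizedMatrix, n_bins: int = 20, fano_threshold: float = 0.05,
             mean_range: tuple[float, float] = (0.01, 3.5),
             ddof: int = 0) -> GeneSelection:
    """Select highly variable genes via bin-normalized Fano factors.

    Genes are ranked by mean expression and split into ``n_bins``
    equal-frequency bins (stable order for ties).  Within each bin the
    Fano factor (variance / mean; 0 for silent genes) is z-scored, and a
    gene is selected when its z-score exceeds ``fano_threshold`` and its
    mean lies inside ``mean_range``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = mean_range
    if not lo < hi:
        raise ValueError("mean_range must be increasing")
    mu, fano = _fano_factors(N.values, ddof=ddof)
    m = mu.size
    if m < n_bins:
        warnings.warn(
            f"only {m} genes for {n_bins} bins; reducing bin count", stacklevel=2
        )
        n_bins = max(1, m)
    order = np.argsort(mu, kind="stable")
    zfano = np.zeros(m)
    for chunk in np.array_split(order, n_bins):
        f = fano[chunk]
        sd = f.std()
        zfano[chunk] = 0.0 if sd == 0 else (f - f.mean()) / sd
    selected = np.flatnonzero((zfano > fano_threshold) & (mu >= lo) & (mu <= hi))
    return GeneSelection(selected, mu, zfano, method="fano")


def gini_index(x: Sequence[float] | np.ndarray) -> float:
    """Gini coefficient of a non-negative vector (0 = perfect equality).

    G = sum_i (2i - n - 1) x_(i) / (n * sum x) with 1-based rank i over
    the ascending sort; an all-zero vector gives 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if np.any(x < 0):
        raise ValueError("gini_index requires non-negative entries")
    total = x.sum()
    if total == 0:
        return 0.0
    xs = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))


def gini_hvg(N: NormalizedMatrix, gini_threshold: float = 0.8,
             mean_range: tuple[float, float] = (0.01, 3.5)) -> GeneSelection:
    """Alternative selection by Gini index, useful for rare sub-populations."""
    mu, fano = _fano_factors(N.values)
    gini = np.array([gini_index(row) for row in N.values])
    lo, hi = mean_range
    selected = np.flatnonzero((gini > gini_threshold) & (mu >= lo) & (mu <= hi))
    return GeneSelection(selected, mu, fano, gini=gini, method="gini")
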