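"""End-to-end imputation: preprocess, cluster, split, bound, solve, merge.

The pipeline filters and log-normalizes the counts, selects highly
variable genes, detects cell sub-populations, cuts the matrix into one
block per sub-population (HVG rows) plus one remainder block (all other
genes, all cells), estimates per-gene dropout bounds within each block,
solves the bounded nuclear-norm completion per block, and reassembles
the imputed matrix.  Observed entries are preserved exactly; only zeros
change, and every imputed zero respects its gene's bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .boundary import BoundaryVector, estimate_boundary
from .io_preprocess import (
    ExpressionMatrix,
    GeneSelection,
    NormalizedMatrix,
    fano_hvg,
    filter_matrix,
    gini_hvg,
    normalize,
)
from .solver import ADMMParams, MaskedSubmatrix, admm_solve
from .subpopulation import ClusterAssignment, cluster_cells, split_submatrices

__all__ = ["PBLRConfig", "ImputationResult", "merge_submatrices", "pblr_impute"]


@dataclass
class PBLRConfig:
    """All tunable knobs of the pipeline with their defaults."""

    # preprocessing
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    scale_factor: float = 10_000.0
    # gene selection
    hvg_method: str = "fano"  # {fano, gini}
    n_bins: int = 20
    fano_threshold: float = 0.05
    mean_range: tuple[float, float] = (0.01, 3.5)
    # clustering
    strategy: str = "auto"  # {nmf, snn, auto}
    cluster_count: int | str = "auto"
    rank_range: tuple[int, int] = (2, 6)
    k_neighbors: int = 20
    resolutions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    # boundary
    boundary_method: str = "sophisticated"
    radius: float = 0.05
    confidence: float = 0.95
    # solver
    beta: float | None = None
    gamma: float = 1.6
    tol: float = 1e-6
    max_iter: int = 500
    svd_backend: str = "partial"
    seed: int = 0


@dataclass
class ImputationResult:
    X: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: ClusterAssignment
    selection: GeneSelection
    boundaries: list[BoundaryVector]
    normalized: NormalizedMatrix
    solver_log: list = field(default_factory=list)
    config: PBLRConfig | None = None


def merge_submatrices(blocks: list[tuple[MaskedSubmatrix, np.ndarray]]) -> np.ndarray:
    """Scatter imputed blocks back into a full matrix via their index maps.

    The blocks must tile the full matrix exactly once; any gap or
    overlap raises.
    """
    if not blocks:
        raise ValueError("no blocks to merge")
    m = 1 + max(int(sub.row_index_map.max()) for sub, _ in blocks)
    n = 1 + max(int(sub.col_index_map.max()) for sub, _ in blocks)
    X = np.zeros((m, n))
    seen = np.zeros((m, n), dtype=bool)
    for sub, imputed in blocks:
        if imputed.shape != sub.shape:
            raise ValueError("imputed block shape does not match its submatrix")
        ix = np.ix_(sub.row_index_map, sub.col_index_map)
        if seen[ix].any():
            raise ValueError("overlapping block index maps")
        X[ix] = imputed
        seen[ix] = True
    if not seen.all():
        raise ValueError("block index maps do not cover the full matrix")
    return X


def _select_genes(N: NormalizedMatrix, config: PBLRConfig) -> GeneSelection:
    if config.hvg_method == "fano":
        sel = fano_hvg(N, config.n_bins, config.fano_threshold, config.mean_range)
    elif config.hvg_method == "gini":
        sel = gini_hvg(N, mean_range=config.mean_range)
    else:
        raise ValueError("hvg_method must be 'fano' or 'gini'")
    if sel.selected_indices.size == 0:
        raise ValueError(
            "gene selection returned no genes; lower fano_threshold or widen mean_range"
        )
    return sel


def pblr_impute(M: ExpressionMatrix, config: PBLRConfig | None = None,
                skip_filter: bool = False) -> ImputationResult:
    """Run the full imputation pipeline on a raw count matrix.

    Returns the imputed matrix in log-normalized space together with the
    cluster assignment, gene selection, per-block boundary vectors and
    solver convergence log.  Set ``skip_filter`` when the matrix has
    already been filtered (e.g. small fixtures below the default cell
    threshold).
    """
    if config is None:
        config = PBLRConfig()
    if not skip_filter:
        M = filter_matrix(M, config.min_cells_per_gene, config.min_genes_per_cell)
    N = normalize(M, config.scale_factor)
    sel = _select_genes(N, config)
    N_sel = N.values[sel.selected_indices]
    assignment, _ = cluster_cells(
        N_sel,
        strategy=config.strategy,
        cluster_count=config.cluster_count,
        rank_range=range(config.rank_range[0], config.rank_range[1] + 1),
        k_neighbors=config.k_neighbors,
        resolutions=list(config.resolutions),
        seed=config.seed,
    )
    blocks = split_submatrices(N, sel, assignment)
    params = ADMMParams(gamma=config.gamma, beta=config.beta, tol=config.tol,
                        max_iter=config.max_iter, svd_backend=config.svd_backend)
    solved: list[tuple[MaskedSubmatrix, np.ndarray]] = []
    boundaries: list[BoundaryVector] = []
    log: list = []
    for sub in blocks:
        bound = estimate_boundary(sub, config.boundary_method, config.radius,
                                  config.confidence)
        boundaries.append(bound)
        bounded = sub.with_gene_bounds(bound.U)
        try:
            imputed = admm_solve(bounded, params, log=log)
        except Exception as exc:
            raise RuntimeError(f"solver failed on block {sub.block_id}: {exc}") from exc
        solved.append((bounded, imputed))
    X = merge_submatrices(solved)
    # hard guarantees: shape, non-negativity, observed entries untouched
    assert X.shape == N.values.shape
    assert np.all(X >= 0)
    obs = N.values > 0
    assert np.array_equal(X[obs], N.values[obs])
    return ImputationResult(X, list(M.gene_ids), list(M.cell_ids), assignment,
                            sel, boundaries, N, log, config)
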