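"""Cell sub-population detection.

Two strategies produce a cell-cell consensus matrix that is cut by
average-linkage hierarchical clustering:

* the NMF ensemble — SymNMF on Pearson / Spearman / cosine affinity
  matrices plus incomplete NMF (zeros treated as missing) on the
  highly-variable-gene submatrix, combined by co-membership averaging;
* the SNN graph — Leiden community detection on a shared-nearest-neighbor
  graph swept over a range of resolutions.

The cluster count is either supplied or selected automatically
(consensus-stability maximization for the NMF route, the largest
singular-value gap of the consensus matrix for the SNN route).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .io_preprocess import GeneSelection, NormalizedMatrix
from .solver import MaskedSubmatrix

__all__ = [
    "ClusterAssignment",
    "pairwise_distances",
    "affinity_from_distance",
    "symnmf",
    "inmf",
    "consensus_from_labels",
    "hierarchical_cut",
    "nmf_ensemble_consensus",
    "select_rank_stability",
    "build_snn",
    "leiden_consensus",
    "select_rank_svd_gap",
    "split_submatrices",
    "cluster_cells",
]

METRICS = ("pearson", "spearman", "cosine")


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # integers 1..g
    g: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.g + 1)):
            raise ValueError(
                f"labels must cover 1..{self.g} with no empty cluster; got {present}"
            )


@dataclass
class FactorMatrix:
    """Non-negative factors with the final objective value.

    SymNMF stores H (n x r); INMF stores W (m x r) and Hc (r x n).
    """

    H: np.ndarray | None = None
    W: np.ndarray | None = None
    Hc: np.ndarray | None = None
    objective_value: float = np.nan
    objective_history: list[float] = field(default_factory=list)

    def labels(self) -> np.ndarray:
        """Hard cluster labels (1-based) by argmax over factors."""
        if self.H is not None:
            return self.H.argmax(axis=1) + 1
        return self.Hc.argmax(axis=0) + 1


# ---------------------------------------------------------------------------
# distances and affinities
# ---------------------------------------------------------------------------

def pairwise_distances(N_sel: np.ndarray | NormalizedMatrix, metric: str) -> np.ndarray:
    """Cell-cell distance matrix (1 - similarity) over matrix columns."""
    X = N_sel.values if isinstance(N_sel, NormalizedMatrix) else np.asarray(N_sel, float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if metric in ("pearson", "spearman"):
        if metric == "spearman":
            X = rankdata(X, axis=0)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            j = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(
                f"cell column {j} is constant; correlation distance undefined"
            )
        D = 1.0 - np.corrcoef(X, rowvar=False)
    else:  # cosine
        norms = np.linalg.norm(X, axis=0)
        if np.any(norms == 0):
            j = int(np.flatnonzero(norms == 0)[0])
            raise ValueError(f"cell column {j} is all zero; cosine undefined")
        Xn = X / norms
        D = 1.0 - Xn.T @ Xn
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    np.fill_diagonal(D, 0.0)
    return D


def affinity_from_distance(D: np.ndarray) -> np.ndarray:
    """A = exp(-D / max(D)); unit diagonal, entries in [e^-1, 1]."""
    D = np.asarray(D, dtype=float)
    dmax = D.max()
    if dmax <= 0:
        raise ValueError("all distances are zero; affinity undefined")
    A = np.exp(-D / dmax)
    np.fill_diagonal(A, 1.0)
    return A


# ---------------------------------------------------------------------------
# factorizations
# ---------------------------------------------------------------------------

def symnmf(A: np.ndarray, rank: int, seed: int = 0, max_iter: int = 1000,
           tol: float = 1e-5) -> FactorMatrix:
    """Symmetric NMF: minimize ||A - H H^T||_F^2 with H >= 0.

    Damped multiplicative updates (step 1/2), random non-negative
    initialization from ``seed``.  Cluster labels are the per-row argmax
    of H.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("symnmf requires a symmetric square matrix")
    if not 1 <= rank <= n:
        raise ValueError(f"rank must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    # scale init so that H H^T matches A in magnitude
    H = rng.uniform(0, 1, size=(n, rank)) * np.sqrt(A.mean() / rank)
    eps = 1e-12
    history = []
    prev = np.inf
    for _ in range(max_iter):
        AH = A @ H
        HHtH = H @ (H.T @ H)
        H = H * (0.5 + 0.5 * AH / (HHtH + eps))
        obj = float(np.linalg.norm(A - H @ H.T, "fro") ** 2)
        history.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(obj, 1.0):
            break
        prev = obj
    return FactorMatrix(H=H, objective_value=history[-1], objective_history=history)


def inmf(M_sel: np.ndarray | NormalizedMatrix, rank: int, seed: int = 0,
         max_iter: int = 1000, tol: float = 1e-5) -> FactorMatrix:
    """Incomplete NMF: masked factorization treating zeros as missing.

    Minimizes ||P_Omega(M - W Hc)||_F^2 over W, Hc >= 0 where Omega is
    the non-zero entry set, via weighted multiplicative updates.  Cell
    labels are the per-column argmax of Hc.
    """
    M = M_sel.values if isinstance(M_sel, NormalizedMatrix) else np.asarray(M_sel, float)
    if rank < 1:
        raise ValueError("rank must be >= 1")
    mask = (M > 0).astype(float)
    if np.any(mask.sum(axis=0) == 0):
        j = int(np.flatnonzero(mask.sum(axis=0) == 0)[0])
        raise ValueError(f"cell column {j} has no observed entries")
    m, n = M.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(M[mask > 0].mean() / rank)
    W = rng.uniform(0, 1, size=(m, rank)) * scale
    Hc = rng.uniform(0, 1, size=(rank, n)) * scale
    eps = 1e-12
    MM = mask * M
    history = []
    prev = np.inf
    for _ in range(max_iter):
        WH = mask * (W @ Hc)
        W = W * ((MM @ Hc.T) / (WH @ Hc.T + eps))
        WH = mask * (W @ Hc)
        Hc = Hc * ((W.T @ MM) / (W.T @ WH + eps))
        obj = float(np.linalg.norm(MM - mask * (W @ Hc), "fro") ** 2)
        history.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(obj, 1.0):
            break
        prev = obj
    return FactorMatrix(W=W, Hc=Hc, objective_value=history[-1],
                        objective_history=history)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus_from_labels(label_sets: list[np.ndarray]) -> np.ndarray:
    """Co-membership frequency matrix over a list of partitions."""
    if not label_sets:
        raise ValueError("need at least one label set")
    n = len(label_sets[0])
    C = np.zeros((n, n))
    for labels in label_sets:
        labels = np.asarray(labels)
        if labels.shape != (n,):
            raise ValueError("all label sets must have the same length")
        C += labels[:, None] == labels[None, :]
    C /= len(label_sets)
    np.fill_diagonal(C, 1.0)
    return C


def hierarchical_cut(C: np.ndarray, g: int) -> ClusterAssignment:
    """Average-linkage cut of the dissimilarity 1 - C into g clusters."""
    n = C.shape[0]
    if not 1 <= g <= n:
        raise ValueError(f"g must be in [1, {n}]")
    n_distinct = np.unique(np.round(C, 12), axis=0).shape[0]
    if g > n_distinct:
        raise ValueError(
            f"cannot cut into {g} clusters: only {n_distinct} distinct consensus rows"
        )
    if g == 1:
        return ClusterAssignment(np.ones(n, dtype=int), 1)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=g, criterion="maxclust")
    # relabel to 1..g in order of first appearance for determinism
    _, labels = np.unique(raw, return_inverse=True)
    return ClusterAssignment(labels + 1, int(labels.max()) + 1)


def nmf_ensemble_consensus(N_sel: np.ndarray | NormalizedMatrix, rank: int,
                           seed: int = 0, max_iter: int = 1000,
                           tol: float = 1e-5, n_restarts: int = 1) -> np.ndarray:
    """Consensus over four views: SymNMF on the three affinities + INMF.

    With ``n_restarts`` > 1 each view is re-run from several random
    initializations and the consensus averages all partitions, exposing
    splits that only some local minima produce.
    """
    X = N_sel.values if isinstance(N_sel, NormalizedMatrix) else np.asarray(N_sel, float)
    affinities = [
        affinity_from_distance(pairwise_distances(X, metric)) for metric in METRICS
    ]
    label_sets = []
    for rep in range(n_restarts):
        base = seed + 100 * rep
        for i, A in enumerate(affinities):
            label_sets.append(symnmf(A, rank, seed=base + i, max_iter=max_iter,
                                     tol=tol).labels())
        label_sets.append(inmf(X, rank, seed=base + len(METRICS),
                               max_iter=max_iter, tol=tol).labels())
    return consensus_from_labels(label_sets)


def _dispersion(C: np.ndarray) -> float:
    """Consensus dispersion: 1 for a binary matrix, 0 for all-0.5."""
    return float(np.mean(4.0 * (C - 0.5) ** 2))


def _cophenetic_score(C: np.ndarray) -> float:
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    d = squareform(D, checks=False)
    Z = linkage(d, method="average")
    c, _ = cophenet(Z, d)
    return float(c)


def select_rank_stability(N_sel: np.ndarray | NormalizedMatrix,
                          rank_range: range | list[int], seed: int = 0,
                          score: str = "dispersion", n_restarts: int = 3,
                          max_iter: int = 1000, tol: float = 1e-5) -> int:
    """Pick the factorization rank whose consensus is most stable.

    For each candidate rank a multi-restart four-view consensus matrix
    is built and scored (dispersion by default).  Restarts matter: a
    spurious extra split can be agreed on by every view from one
    initialization yet vary across initializations, and only the
    restart-averaged consensus exposes that instability.  The
    best-scoring rank wins, ties going to the smallest rank.
    """
    ranks = list(rank_range)
    if not ranks:
        raise ValueError("empty rank range")
    scorer = {"dispersion": _dispersion, "cophenetic": _cophenetic_score}[score]
    best_rank, best_score = None, -np.inf
    for r in ranks:
        C = nmf_ensemble_consensus(N_sel, r, seed=seed, max_iter=max_iter,
                                   tol=tol, n_restarts=n_restarts)
        s = scorer(C)
        if s > best_score + 1e-12:
            best_rank, best_score = r, s
    return int(best_rank)


# ---------------------------------------------------------------------------
# SNN + Leiden strategy
# ---------------------------------------------------------------------------

def build_snn(N_sel: np.ndarray | NormalizedMatrix, k: int = 20) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph on cells (columns).

    k-nearest neighbors by Euclidean distance on the HVG submatrix,
    ranking ties broken by cell index; the edge weight between i and j
    is |kNN(i) ∩ kNN(j)| / k for pairs where one is a neighbor of the
    other.
    """
    X = N_sel.values if isinstance(N_sel, NormalizedMatrix) else np.asarray(N_sel, float)
    n = X.shape[1]
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells ({n})")
    P = X.T  # cells as points
    sq = (P ** 2).sum(axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (P @ P.T), 0.0)
    np.fill_diagonal(D2, np.inf)  # exclude self
    idx = np.arange(n)
    neighbors = np.empty((n, k), dtype=int)
    for i in range(n):
        order = np.lexsort((idx, D2[i]))  # distance, then index
        neighbors[i] = order[:k]
    member = np.zeros((n, n), dtype=bool)
    member[np.repeat(idx, k), neighbors.ravel()] = True
    shared = (member.astype(np.int32) @ member.T.astype(np.int32))
    adjacency = member | member.T
    W = np.where(adjacency, shared / float(k), 0.0)
    np.fill_diagonal(W, 0.0)
    return sp.csr_matrix(W)


def leiden_consensus(G: sp.spmatrix, resolutions: list[float] | None = None,
                     seed: int = 0) -> np.ndarray:
    """Consensus matrix over Leiden partitions at several resolutions."""
    if resolutions is None:
        resolutions = [0.1, 0.2, 0.3, 0.4, 0.5]
    if not resolutions:
        raise ValueError("need at least one resolution")
    coo = sp.triu(sp.coo_matrix(G), k=1)
    graph = ig.Graph(
        n=G.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    label_sets = []
    for res in resolutions:
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=res,
            seed=seed,
            n_iterations=-1,
        )
        label_sets.append(np.asarray(part.membership) + 1)
    return consensus_from_labels(label_sets)


def select_rank_svd_gap(C: np.ndarray, max_g: int = 20) -> int:
    """Cluster count from the largest gap in the consensus singular values."""
    n = C.shape[0]
    if max_g < 2 or max_g >= n:
        raise ValueError(f"max_g must be in [2, {n - 1}]")
    k = max_g + 1
    if n <= 2000:
        sigma = np.linalg.svd(C, compute_uv=False)[:k]
    else:
        from sklearn.utils.extmath import randomized_svd

        _, sigma, _ = randomized_svd(C, n_components=k, n_iter=10, random_state=0)
    gaps = sigma[:-1] - sigma[1:]
    return int(np.argmax(gaps)) + 1  # ties -> smallest index via argmax


# ---------------------------------------------------------------------------
# submatrix split and orchestration
# ---------------------------------------------------------------------------

def split_submatrices(N: NormalizedMatrix, sel: GeneSelection,
                      assignment: ClusterAssignment) -> list[MaskedSubmatrix]:
    """Cut the matrix into g HVG-by-cluster blocks plus the remainder block.

    Blocks k = 1..g hold the selected genes restricted to cluster k's
    cells; block g+1 holds all remaining genes across every cell.  The
    blocks tile the full matrix exactly once; when every gene is
    selected the remainder block is empty and omitted.
    """
    labels = np.asarray(assignment.labels)
    if labels.size != N.values.shape[1]:
        raise ValueError("label vector length must equal the number of cells")
    sel_rows = np.asarray(sel.selected_indices, dtype=int)
    if sel_rows.size == 0:
        raise ValueError("gene selection is empty")
    rest_rows = np.setdiff1d(np.arange(N.values.shape[0]), sel_rows)
    blocks = []
    for g in range(1, assignment.g + 1):
        cols = np.flatnonzero(labels == g)
        if cols.size == 0:
            raise ValueError(f"cluster {g} is empty")
        blocks.append(MaskedSubmatrix.from_values(
            N.values[np.ix_(sel_rows, cols)], block_id=g,
            row_index_map=sel_rows, col_index_map=cols,
        ))
    if rest_rows.size:
        all_cols = np.arange(N.values.shape[1])
        blocks.append(MaskedSubmatrix.from_values(
            N.values[np.ix_(rest_rows, all_cols)], block_id=assignment.g + 1,
            row_index_map=rest_rows, col_index_map=all_cols,
        ))
    return blocks


def cluster_cells(N_sel: np.ndarray | NormalizedMatrix, strategy: str = "auto",
                  cluster_count: int | str = "auto",
                  rank_range: range | list[int] | None = None,
                  k_neighbors: int = 20, resolutions: list[float] | None = None,
                  seed: int = 0, max_g: int = 20) -> tuple[ClusterAssignment, np.ndarray]:
    """Run one sub-population strategy end to end.

    Returns the cluster assignment and the consensus matrix it was cut
    from.  ``strategy='auto'`` uses the NMF ensemble up to 5000 cells
    and the SNN graph above.
    """
    X = N_sel.values if isinstance(N_sel, NormalizedMatrix) else np.asarray(N_sel, float)
    n = X.shape[1]
    if strategy == "auto":
        strategy = "nmf" if n <= 5000 else "snn"
    if strategy == "nmf":
        if cluster_count == "auto":
            if rank_range is None:
                rank_range = range(2, min(7, n))
            g = select_rank_stability(X, rank_range, seed=seed)
        else:
            g = int(cluster_count)
        C = nmf_ensemble_consensus(X, g, seed=seed)
    elif strategy == "snn":
        G = build_snn(X, k=min(k_neighbors, n - 1))
        C = leiden_consensus(G, resolutions, seed=seed)
        if cluster_count == "auto":
            g = select_rank_svd_gap(C, max_g=min(max_g, n - 1))
        else:
            g = int(cluster_count)
    else:
        raise ValueError("strategy must be 'nmf', 'snn' or 'auto'")
    return hierarchical_cut(C, g), C
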