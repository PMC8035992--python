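"""Evaluation statistics for imputation quality.

SSE and per-cell Pearson correlation compare an imputed matrix to the
dropout-free ground truth; NMI scores cluster agreement; the pseudotime
order score (POS) measures pairwise concordance with a reference
ordering; the manifold preservation score measures how much of each
cell's low-dimensional neighborhood survives imputation.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "sse",
    "mean_column_pcc",
    "nmi",
    "pos",
    "manifold_preservation",
]


def sse(F: np.ndarray, X: np.ndarray) -> float:
    """Sum of squared entrywise differences."""
    F, X = np.asarray(F, float), np.asarray(X, float)
    if F.shape != X.shape:
        raise ValueError(f"shape mismatch: {F.shape} vs {X.shape}")
    return float(((F - X) ** 2).sum())


def mean_column_pcc(F: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """Pearson correlation per cell column; returns (mean, per-column).

    Columns constant in either matrix have undefined correlation and are
    recorded as NaN and excluded from the mean.
    """
    F, X = np.asarray(F, float), np.asarray(X, float)
    if F.shape != X.shape:
        raise ValueError(f"shape mismatch: {F.shape} vs {X.shape}")
    if F.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    Fc = F - F.mean(axis=0)
    Xc = X - X.mean(axis=0)
    fn = np.linalg.norm(Fc, axis=0)
    xn = np.linalg.norm(Xc, axis=0)
    ok = (fn > 0) & (xn > 0)
    pcc = np.full(F.shape[1], np.nan)
    pcc[ok] = (Fc[:, ok] * Xc[:, ok]).sum(axis=0) / (fn[ok] * xn[ok])
    if not ok.any():
        raise ValueError("every column is constant; correlation undefined")
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} constant columns excluded from mean PCC",
                      stacklevel=2)
    return float(np.nanmean(pcc)), pcc


def nmi(u, v) -> float:
    """Normalized mutual information 2 I(U,V) / (H(U) + H(V)).

    Natural-log entropies from the contingency table.  If both
    partitions are single-cluster (zero entropy) the partitions are
    identical and the score is 1; if exactly one is, the score is 0.
    """
    u = np.asarray(u).ravel()
    v = np.asarray(v).ravel()
    if u.shape != v.shape:
        raise ValueError("partitions must have the same length")
    n = u.size
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    table = np.zeros((ui.max() + 1, vi.max() + 1))
    np.add.at(table, (ui, vi), 1.0)
    pu = table.sum(axis=1) / n
    pv = table.sum(axis=0) / n
    hu = -np.sum(pu[pu > 0] * np.log(pu[pu > 0]))
    hv = -np.sum(pv[pv > 0] * np.log(pv[pv > 0]))
    if hu == 0 and hv == 0:
        return 1.0
    if hu == 0 or hv == 0:
        return 0.0
    pij = table / n
    mask = pij > 0
    mi = np.sum(pij[mask] * np.log(pij[mask] / np.outer(pu, pv)[mask]))
    return float(2.0 * mi / (hu + hv))


def pos(inferred, reference) -> float:
    """Pseudotime order score C / (C + N_c) over comparable cell pairs.

    A pair is concordant when the two orderings agree on its direction;
    pairs tied in either vector are excluded (Kendall-style).
    """
    x = np.asarray(inferred, float).ravel()
    y = np.asarray(reference, float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(x.size, k=1)
    prod = dx[iu] * dy[iu]
    concordant = int((prod > 0).sum())
    discordant = int((prod < 0).sum())
    if concordant + discordant == 0:
        raise ValueError("no comparable (untied) pairs")
    return concordant / (concordant + discordant)


def _knn_sets(coords: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbors per row (Euclidean, self excluded, index ties)."""
    n = coords.shape[0]
    sq = (coords ** 2).sum(axis=1)
    D2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * coords @ coords.T, 0.0)
    np.fill_diagonal(D2, np.inf)
    idx = np.arange(n)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        out[i] = np.lexsort((idx, D2[i]))[:k]
    return out


def manifold_preservation(E_full: np.ndarray, E_imp: np.ndarray, k: int = 20) -> float:
    """Mean fraction of shared k-nearest neighbors between two embeddings."""
    E_full = np.asarray(E_full, float)
    E_imp = np.asarray(E_imp, float)
    if E_full.shape[0] != E_imp.shape[0]:
        raise ValueError("embeddings must have the same number of cells")
    n = E_full.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    nn_full = _knn_sets(E_full, k)
    nn_imp = _knn_sets(E_imp, k)
    overlaps = [
        len(set(nn_full[i]) & set(nn_imp[i])) / k for i in range(n)
    ]
    return float(np.mean(overlaps))
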