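"""Bounded nuclear-norm matrix recovery by ADMM.

Each submatrix block is completed by solving

    min ||X||_*   s.t.  X_Omega = M,  0 <= X_{Omega^c} <= U,

where Omega is the set of observed (non-zero) entries and U caps the
imputed values per gene.  The ADMM splitting alternates a feasibility
projection (closed form), singular value thresholding at 1/beta, and a
relaxed multiplier step with factor gamma < (1+sqrt(5))/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

__all__ = [
    "MaskedSubmatrix",
    "ADMMParams",
    "project_feasible",
    "svt",
    "default_beta",
    "admm_solve",
]

GAMMA_MAX = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass
class MaskedSubmatrix:
    """One block of the expression matrix with its mask and bounds.

    ``omega`` is True exactly where the block value is observed (> 0);
    ``U`` holds per-entry upper bounds used on the unobserved set (in
    practice row-constant: one bound per gene).  ``row_index_map`` and
    ``col_index_map`` locate the block inside the full matrix.
    """

    M: np.ndarray
    omega: np.ndarray
    U: np.ndarray | None
    block_id: int = 0
    row_index_map: np.ndarray | None = None
    col_index_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.omega = np.asarray(self.omega, dtype=bool)
        if self.omega.shape != self.M.shape:
            raise ValueError("mask shape must match matrix shape")
        if self.U is not None:
            self.U = np.asarray(self.U, dtype=float)
            if self.U.shape != self.M.shape:
                raise ValueError("bound matrix shape must match matrix shape")
            hidden = ~self.omega
            if hidden.any() and not np.all(np.isfinite(self.U[hidden])):
                raise ValueError("bounds must be finite on every unobserved entry")

    @classmethod
    def from_values(cls, values: np.ndarray, block_id: int = 0,
                    row_index_map: np.ndarray | None = None,
                    col_index_map: np.ndarray | None = None,
                    U: np.ndarray | None = None) -> "MaskedSubmatrix":
        values = np.asarray(values, dtype=float)
        return cls(values, values > 0, U, block_id, row_index_map, col_index_map)

    def with_gene_bounds(self, per_gene_bound: np.ndarray) -> "MaskedSubmatrix":
        """Attach a row-constant bound matrix from a per-gene vector."""
        U = np.repeat(np.asarray(per_gene_bound, float)[:, None],
                      self.M.shape[1], axis=1)
        return MaskedSubmatrix(self.M, self.omega, U, self.block_id,
                               self.row_index_map, self.col_index_map)

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape


@dataclass
class ADMMParams:
    gamma: float = 1.6
    beta: float | None = None  # None -> default_beta(m, n)
    tol: float = 1e-6
    max_iter: int = 500
    svd_backend: str = "partial"  # {partial, dense}

    def __post_init__(self) -> None:
        if not 0 < self.gamma < GAMMA_MAX:
            raise ValueError(f"gamma must be in (0, {GAMMA_MAX:.4f})")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def default_beta(m: int, n: int, scale: float = 2.5) -> float:
    """Penalty parameter beta = scale / sqrt(m*n).

    The SVT threshold is 1/beta, so beta must grow the threshold with
    matrix size for the shrinkage to bite; the sqrt(mn) scaling keeps
    the solution invariant (beta trades speed, not the optimum).
    """
    if m < 1 or n < 1:
        raise ValueError("dimensions must be >= 1")
    return scale / np.sqrt(m * n)


def project_feasible(B: np.ndarray, sub: MaskedSubmatrix) -> np.ndarray:
    """Project onto the constraint set: equality on Omega, [0, U] clamp off it."""
    if B.shape != sub.M.shape:
        raise ValueError("shape mismatch")
    hidden = ~sub.omega
    Y = np.where(sub.omega, sub.M, np.clip(B, 0.0, None))
    if sub.U is not None and hidden.any():
        Y[hidden] = np.minimum(Y[hidden], sub.U[hidden])
    return Y


def _dense_svt(A: np.ndarray, tau: float) -> np.ndarray:
    V1, s, V2 = np.linalg.svd(A, full_matrices=False)
    shrunk = np.maximum(s - tau, 0.0)
    keep = shrunk > 0
    if not keep.any():
        return np.zeros_like(A)
    return (V1[:, keep] * shrunk[keep]) @ V2[keep]


def _svt_rank(A: np.ndarray, tau: float, partial: bool = True,
              rank_hint: int = 10, dense_below: int = 500) -> tuple[np.ndarray, int]:
    """SVT returning (result, retained rank)."""
    A = np.asarray(A, dtype=float)
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0:
        return A.copy(), min(A.shape)
    m, n = A.shape
    if not partial or min(m, n) < dense_below:
        X = _dense_svt(A, tau)
        s = np.linalg.svd(A, compute_uv=False)
        return X, int((s > tau).sum())
    k = max(2, min(rank_hint, min(m, n) - 1))
    kmax = min(m, n) - 1
    while True:
        V1, s, V2 = spla.svds(A, k=k)
        order = np.argsort(s)[::-1]
        s, V1, V2 = s[order], V1[:, order], V2[order]
        if s[-1] < tau or k == kmax:
            break
        k = min(2 * k, kmax)
    shrunk = np.maximum(s - tau, 0.0)
    keep = shrunk > 0
    if not keep.any():
        return np.zeros_like(A), 0
    return (V1[:, keep] * shrunk[keep]) @ V2[keep], int(keep.sum())


def svt(A: np.ndarray, tau: float, partial: bool = True,
        rank_hint: int = 10, dense_below: int = 500) -> np.ndarray:
    """Singular value thresholding: shrink singular values by tau.

    With ``partial=True`` only the singular triplets above the threshold
    are computed, starting from ``rank_hint`` and growing the truncation
    rank until the smallest retained singular value falls below tau;
    matrices whose smaller dimension is below ``dense_below`` use a
    dense SVD (cheaper than iterative solvers at that size).
    """
    X, _ = _svt_rank(A, tau, partial=partial, rank_hint=rank_hint,
                     dense_below=dense_below)
    return X


def admm_solve(sub: MaskedSubmatrix, params: ADMMParams | None = None,
               log: list | None = None) -> np.ndarray:
    """Solve the bounded nuclear-norm completion for one block.

    Iterates Y <- project(X - Z/beta); X <- svt(Y + Z/beta, 1/beta);
    Z <- Z - gamma*beta*(X - Y) from zero initial values, stopping when
    the relative primal residual ||X - Y||_F / max(1, ||M_Omega||_F)
    drops below tol.  Returns the feasible iterate Y.
    """
    if params is None:
        params = ADMMParams()
    m, n = sub.shape
    if sub.omega.all():
        return sub.M.copy()
    if not sub.omega.any():
        warnings.warn(f"block {sub.block_id}: no observed entries; returning zeros",
                      stacklevel=2)
        return project_feasible(np.zeros((m, n)), sub)
    beta = params.beta if params.beta is not None else default_beta(m, n)
    gamma, tau = params.gamma, 1.0 / beta
    partial = params.svd_backend == "partial"
    X = np.zeros((m, n))
    Z = np.zeros((m, n))
    denom = max(1.0, float(np.linalg.norm(sub.M[sub.omega])))
    Y = sub.M.copy()
    rank_hint = 10
    for t in range(1, params.max_iter + 1):
        Y = project_feasible(X - Z / beta, sub)
        X, rank = _svt_rank(Y + Z / beta, tau, partial=partial, rank_hint=rank_hint)
        rank_hint = rank + 5  # warm-start the next truncated SVD
        Z = Z - gamma * beta * (X - Y)
        res = float(np.linalg.norm(X - Y, "fro")) / denom
        if log is not None:
            log.append({"block": sub.block_id, "iter": t, "residual": res,
                        "rank": rank})
        if res < params.tol:
            break
    else:
        warnings.warn(
            f"block {sub.block_id}: ADMM reached max_iter={params.max_iter} "
            f"with residual {res:.3e}", stacklevel=2)
    return Y
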