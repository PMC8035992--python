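"""Per-gene upper bounds on dropout expression.

The chance that a transcript drops out falls with its true expression,
so a gene's observed zero ratio r and its mean observed (non-zero)
expression g constrain how large its imputed values may plausibly be.
Three estimators of the per-gene upper boundary U are provided:

* ``exp_boundary`` — fit r = exp(-lambda g^2) and invert the one-sided
  95% lower confidence bound on lambda;
* ``piecewise_simple`` — min / max of the observed means of genes with a
  similar zero ratio;
* ``piecewise_sophisticated`` (default) — a four-branch rule using
  quartiles of the neighbor means for intermediate zero ratios.

Genes with r = 0 need no bound (nothing to impute); genes with r = 1
are never observed and receive a conservative fallback bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .solver import MaskedSubmatrix

__all__ = [
    "GeneDropoutStats",
    "ExponentialBoundaryFit",
    "BoundaryVector",
    "dropout_stats",
    "exp_boundary",
    "piecewise_simple",
    "piecewise_sophisticated",
    "estimate_boundary",
    "reference_dropout_sample",
]


@dataclass
class GeneDropoutStats:
    """Per-gene zero ratio and mean of the observed (non-zero) entries."""

    mean_observed: np.ndarray  # g_i; 0 where nothing observed
    zero_ratio: np.ndarray     # r_i in [0, 1]

    @property
    def fittable(self) -> np.ndarray:
        """Genes with 0 < r < 1: the only ones informing the fits."""
        return (self.zero_ratio > 0) & (self.zero_ratio < 1)


@dataclass
class ExponentialBoundaryFit:
    lambda_hat: float
    lambda_se: float
    lambda_low: float
    per_gene_bound: np.ndarray


@dataclass
class BoundaryVector:
    U: np.ndarray
    method: str
    stats: GeneDropoutStats | None = None


def dropout_stats(Msub: MaskedSubmatrix | np.ndarray) -> GeneDropoutStats:
    """Compute (g_i, r_i) per gene row of a submatrix."""
    M = Msub.M if isinstance(Msub, MaskedSubmatrix) else np.asarray(Msub, float)
    if M.shape[1] < 1:
        raise ValueError("submatrix must have at least one cell")
    nz = M > 0
    counts = nz.sum(axis=1)
    r = 1.0 - counts / M.shape[1]
    g = np.zeros(M.shape[0])
    has = counts > 0
    g[has] = M.sum(axis=1)[has] / counts[has]
    return GeneDropoutStats(mean_observed=g, zero_ratio=r)


def _fallback_fill(U: np.ndarray, stats: GeneDropoutStats) -> np.ndarray:
    """Bounds for r=0 (unused) and r=1 (never observed) genes.

    r=1 genes get the minimum bound among fittable genes — a never-seen
    gene is presumed lowly expressed; r=0 genes keep their own mean (the
    bound is irrelevant: they have no zeros to impute).
    """
    fit = stats.fittable
    r1 = stats.zero_ratio >= 1.0
    r0 = stats.zero_ratio <= 0.0
    if fit.any():
        U[r1] = U[fit].min()
    else:
        observed = stats.mean_observed[r0]
        U[r1] = observed.max() if observed.size else 0.0
    U[r0] = stats.mean_observed[r0]
    return U


def exp_boundary(stats: GeneDropoutStats, confidence: float = 0.95,
                 lambda_floor: float = 1e-12) -> ExponentialBoundaryFit:
    """Exponential boundary: invert r = exp(-lambda g^2).

    lambda is the zero-intercept least-squares slope of -ln r on g^2;
    the one-sided lower confidence bound lambda_low = lambda - z*SE
    (floored at a small positive value) yields the per-gene upper bound
    U_i = sqrt(-ln r_i / lambda_low).
    """
    fit = stats.fittable
    if fit.sum() < 3:
        raise ValueError("need at least 3 genes with 0 < r < 1 to fit the boundary")
    x = stats.mean_observed[fit] ** 2
    y = -np.log(stats.zero_ratio[fit])
    sxx = float((x * x).sum())
    lam = float((x * y).sum() / sxx)
    if lam <= 0:
        raise ValueError(
            "fitted lambda <= 0: zero ratio does not decay with expression; "
            "use a piecewise boundary method instead"
        )
    resid = y - lam * x
    dof = max(int(fit.sum()) - 1, 1)
    se = float(np.sqrt((resid ** 2).sum() / dof / sxx))
    lam_low = max(lam - norm.ppf(confidence) * se, lambda_floor)
    U = np.zeros_like(stats.mean_observed)
    r = stats.zero_ratio
    U[fit] = np.sqrt(-np.log(r[fit]) / lam_low)
    U = _fallback_fill(U, stats)
    return ExponentialBoundaryFit(lam, se, lam_low, U)


def _neighbor_sets(stats: GeneDropoutStats, radius: float):
    """Yield (gene index, neighbor means gS) for every fittable gene."""
    fit_idx = np.flatnonzero(stats.fittable)
    r_fit = stats.zero_ratio[fit_idx]
    g_fit = stats.mean_observed[fit_idx]
    for i in fit_idx:
        ri = stats.zero_ratio[i]
        gS = g_fit[np.abs(r_fit - ri) < radius]  # always contains gene i itself
        yield i, ri, gS


def piecewise_simple(stats: GeneDropoutStats, radius: float = 0.05) -> BoundaryVector:
    """Two-branch boundary: min of neighbor means when r >= 0.8, else max."""
    U = np.zeros_like(stats.mean_observed)
    for i, ri, gS in _neighbor_sets(stats, radius):
        U[i] = gS.min() if ri >= 0.8 else gS.max()
    return BoundaryVector(_fallback_fill(U, stats), "simple", stats)


def piecewise_sophisticated(stats: GeneDropoutStats,
                            radius: float = 0.05) -> BoundaryVector:
    """Four-branch boundary with quartiles for intermediate zero ratios.

    U_i = min(gS) for r >= 0.8; Q1(gS) for 0.6 <= r < 0.8; Q3(gS) for
    0.4 <= r < 0.6; max(gS) otherwise.  Quantiles use linear
    interpolation between order statistics.
    """
    U = np.zeros_like(stats.mean_observed)
    for i, ri, gS in _neighbor_sets(stats, radius):
        if ri >= 0.8:
            U[i] = gS.min()
        elif ri >= 0.6:
            U[i] = np.quantile(gS, 0.25)
        elif ri >= 0.4:
            U[i] = np.quantile(gS, 0.75)
        else:
            U[i] = gS.max()
    return BoundaryVector(_fallback_fill(U, stats), "sophisticated", stats)


def estimate_boundary(Msub: MaskedSubmatrix | np.ndarray,
                      method: str = "sophisticated", radius: float = 0.05,
                      confidence: float = 0.95) -> BoundaryVector:
    """Per-gene bounds for one submatrix by the chosen method."""
    stats = dropout_stats(Msub)
    if method == "sophisticated":
        return piecewise_sophisticated(stats, radius)
    if method == "simple":
        return piecewise_simple(stats, radius)
    if method == "exponential":
        fit = exp_boundary(stats, confidence)
        return BoundaryVector(fit.per_gene_bound, "exponential", stats)
    raise ValueError("method must be sophisticated, simple or exponential")


def reference_dropout_sample(values: np.ndarray, seed: int = 0) -> np.ndarray:
    """Bernoulli-drop a copy of the matrix for boundary diagnostics.

    Each non-zero entry is zeroed independently with probability
    max(p0, 0.3) where p0 is the input's zero fraction, mimicking an
    extra round of dropout so the zero-ratio/mean relation can be
    inspected against a known reference.
    """
    values = np.asarray(values, dtype=float)
    p0 = float((values == 0).mean())
    p = max(p0, 0.3)
    rng = np.random.default_rng(seed)
    out = values.copy()
    nz = values > 0
    out[nz & (rng.uniform(size=values.shape) < p)] = 0.0
    return out
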