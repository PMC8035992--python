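"""Seeded synthetic fixtures.

A gamma-Poisson generator produces group-structured count matrices in
the style of scRNA-seq simulators: per-gene base means drawn from a
gamma distribution, per-group differential-expression fold factors,
log-normal library-size factors, Poisson counts.  A logistic
expression-dependent dropout then zeroes entries with a probability
that falls as expression rises, yielding paired (full, observed)
matrices with known labels and dropout mask.  A separate helper plants
exact low-rank matrices with hidden entries for solver tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import ExpressionMatrix
from .solver import MaskedSubmatrix

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "simulate_groups",
    "apply_logistic_dropout",
    "planted_lowrank",
    "default_fixture",
]


@dataclass
class SimulationSpec:
    """Parameters of the group-structured count simulation.

    Defaults are the canonical study conditions used throughout the
    test-suite: 3 groups of 600 genes x 300 cells with 30% of genes
    differentially expressed per group.
    """

    n_genes: int = 600
    n_cells: int = 300
    n_groups: int = 3
    group_proportions: list[float] | None = None
    de_prob: float = 0.3
    de_factor_log_sd: float = 1.0
    base_mean_shape: float = 0.6
    base_mean_rate: float = 0.3
    counts_per_gene: float = 6.0  # expected library size = this * n_genes
    library_log_sd: float = 0.2
    dropout_shape: float = -1.0
    dropout_midpoint: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_proportions is None:
            self.group_proportions = [1.0 / self.n_groups] * self.n_groups
        if len(self.group_proportions) != self.n_groups:
            raise ValueError("group_proportions length must equal n_groups")
        if not np.isclose(sum(self.group_proportions), 1.0):
            raise ValueError("group_proportions must sum to 1")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must be in [0, 1]")


@dataclass
class SimulatedDataset:
    full: ExpressionMatrix
    observed: ExpressionMatrix
    labels: np.ndarray
    dropout_mask: np.ndarray  # True where a positive entry was zeroed


def simulate_groups(spec: SimulationSpec) -> SimulatedDataset:
    """Generate dropout-free group-structured counts (observed == full).

    Per-gene base mean ~ Gamma(shape, rate); with probability de_prob a
    gene gets a log-normal fold factor per group.  Group means are
    normalized to proportions of a log-normal expected library size (so
    every cell spends a realistic sequencing budget), and counts are
    Poisson draws from the resulting per-entry means.
    """
    rng = np.random.default_rng(spec.seed)
    m, n, G = spec.n_genes, spec.n_cells, spec.n_groups
    base = rng.gamma(spec.base_mean_shape, 1.0 / spec.base_mean_rate, size=m)
    # group means: base mean times a per-(gene, group) DE factor
    group_means = np.tile(base[:, None], (1, G))
    for g in range(G):
        is_de = rng.uniform(size=m) < spec.de_prob
        factors = np.exp(rng.normal(0.0, spec.de_factor_log_sd, size=m))
        group_means[is_de, g] = base[is_de] * factors[is_de]
    # balanced-ish assignment by proportions, deterministic order
    counts = np.floor(np.asarray(spec.group_proportions) * n).astype(int)
    counts[: n - counts.sum()] += 1
    labels = np.repeat(np.arange(1, G + 1), counts)
    lib_mean = spec.counts_per_gene * m
    lib = np.exp(rng.normal(np.log(lib_mean), spec.library_log_sd, size=n))
    proportions = group_means / group_means.sum(axis=0, keepdims=True)
    mean_matrix = proportions[:, labels - 1] * lib[None, :]
    full = rng.poisson(mean_matrix).astype(float)
    gene_ids = [f"gene_{i}" for i in range(m)]
    cell_ids = [f"cell_{j}" for j in range(n)]
    fullM = ExpressionMatrix(full, gene_ids, cell_ids)
    obsM = ExpressionMatrix(full.copy(), list(gene_ids), list(cell_ids))
    return SimulatedDataset(fullM, obsM, labels, np.zeros((m, n), dtype=bool))


def apply_logistic_dropout(full: ExpressionMatrix, shape: float,
                           midpoint: float, seed: int = 0,
                           labels: np.ndarray | None = None) -> SimulatedDataset:
    """Zero entries with probability 1 / (1 + exp(-shape (ln(x+1) - mid))).

    With negative ``shape`` the dropout probability decreases as the
    expression x grows, the hallmark of scRNA-seq capture failure.
    Structural zeros of the input stay zero and are not marked dropped.
    """
    if shape == 0:
        raise ValueError("shape must be non-zero")
    values = full.values
    logx = np.log1p(values)
    p = 1.0 / (1.0 + np.exp(-shape * (logx - midpoint)))
    rng = np.random.default_rng(seed)
    drop = (values > 0) & (rng.uniform(size=values.shape) < p)
    observed = np.where(drop, 0.0, values)
    obsM = ExpressionMatrix(observed, list(full.gene_ids), list(full.cell_ids))
    if labels is None:
        labels = np.ones(values.shape[1], dtype=int)
    return SimulatedDataset(full, obsM, np.asarray(labels), drop)


def planted_lowrank(m: int, n: int, rank: int, hidden_fraction: float,
                    seed: int = 0) -> tuple[MaskedSubmatrix, np.ndarray]:
    """Exact low-rank positive matrix with a random hidden entry set.

    Truth = A B with positive uniform factors; a ``hidden_fraction`` of
    entries is zeroed and marked unobserved; the per-gene bound is the
    row max of the truth.  Returns (masked submatrix, truth).
    """
    if rank > min(m, n):
        raise ValueError("rank must be <= min(m, n)")
    if not 0.0 <= hidden_fraction < 1.0:
        raise ValueError("hidden_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.1, 1.0, size=(m, rank))
    B = rng.uniform(0.1, 1.0, size=(rank, n))
    truth = A @ B
    hidden = rng.uniform(size=(m, n)) < hidden_fraction
    M = np.where(hidden, 0.0, truth)
    omega = ~hidden
    U = np.repeat(truth.max(axis=1)[:, None], n, axis=1)
    sub = MaskedSubmatrix(M, omega, U)
    return sub, truth


def default_fixture(seed: int = 0) -> SimulatedDataset:
    """The canonical 3-group, 600 x 300 fixture with logistic dropout."""
    spec = SimulationSpec(seed=seed)
    ds = simulate_groups(spec)
    return apply_logistic_dropout(ds.full, spec.dropout_shape,
                                  spec.dropout_midpoint, seed=seed + 1,
                                  labels=ds.labels)
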