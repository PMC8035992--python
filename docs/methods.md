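# Methods

This note documents the model implemented by `pblr`, every default
parameter, the synthetic data generator used for validation, and the
numerical choices that matter for reproducing results.

## Preprocessing (`pblr.io_preprocess`)

Raw counts are filtered in a single pass: genes expressed in fewer than
`min_cells_per_gene = 3` cells are removed, then cells expressing fewer
than `min_genes_per_cell = 200` of the remaining genes. Counts are
log-normalized as `ln(1 + s·x/colsum)` with scale `s = 10 000`.

Highly variable genes are selected by the Fano factor
(variance / mean) computed on the normalized matrix. Genes are placed
into `n_bins = 20` equal-frequency bins of mean expression, the Fano
factor is z-scored within each bin, and genes with z-score above
`fano_threshold = 0.05` and mean inside `mean_range = (0.01, 3.5)` are
kept. A Gini-index alternative (`hvg_method="gini"`) is available.

## Sub-population detection (`pblr.subpopulation`)

Two strategies; `strategy="auto"` uses the NMF ensemble up to 5000
cells and the SNN graph above that.

**NMF ensemble.** Cell–cell distances are computed under Pearson,
Spearman and cosine metrics and turned into affinities
`A = exp(-D / max D)`. Symmetric NMF (`A ≈ HHᵀ`, multiplicative
updates damped as `H ← H (0.5 + 0.5·AH/(HHᵀH))`) is run on each
affinity, and an indicator NMF that treats zeros as missing is run on
the HVG expression matrix, giving four base partitions per restart.
Their co-membership matrices are averaged into a consensus `C`, and the
final assignment is an average-linkage hierarchical cut of `1 − C` into
`g` clusters.

**SNN graph.** A `k = 20` nearest-neighbour graph (Euclidean, ties
broken by index) is reweighted by the shared-neighbour fraction
`|kNN(i) ∩ kNN(j)|/k` and partitioned with Leiden
(RB-configuration objective) at resolutions 0.1–0.5; the runs are
combined into a consensus matrix as above.

**Choosing g.** On the NMF route, candidate ranks are scored by the
consensus dispersion `mean(4(C − ½)²)` over an ensemble of 3 restarts ×
4 views (12 partitions per rank); the most reproducible rank wins. On
the SNN route, `g` is the position of the largest gap in the singular
values of the consensus matrix.

The matrix is then cut into `g` blocks (HVG rows × that cluster's
cells) plus one remainder block (all other genes × all cells); the
blocks tile the matrix exactly once, and the remainder block is omitted
when every gene was selected.

## Dropout boundary (`pblr.boundary`)

Within a block, each gene contributes its zero ratio `r_i` and mean
observed (nonzero) expression `g_i`. Genes with `0 < r_i < 1` are
"fittable". Three estimators of the per-gene upper bound `U_i`:

- **exponential**: fit `r = exp(-λ g²)` by zero-intercept least squares
  of `−ln r` on `g²`; with `λ_low = max(λ̂ − z₀.₉₅·SE, 10⁻¹²)` the bound
  is `U_i = sqrt(−ln r_i / λ_low)`. Using the lower confidence envelope
  inflates the bounds when the fit is noisy; for non-decaying data
  `λ_low` collapses onto the floor and the bounds become vacuously
  large (prefer a piecewise method there).
- **simple**: with neighbours `S_i = {j : |r_j − r_i| < 0.05}` among
  fittable genes, `U_i = min g_S` if `r_i ≥ 0.8` else `max g_S`.
- **sophisticated** (default): `min`, first quartile, third quartile or
  `max` of the neighbour means as `r_i` crosses 0.8, 0.6 and 0.4.

Genes with `r_i = 1` receive the minimum bound over fittable genes;
genes with `r_i = 0` keep their own mean (they have nothing to impute).

## Bounded nuclear-norm completion (`pblr.solver`)

Per block, with `Ω` the observed entries and `U` the per-gene bounds:

    min ‖X‖₊  s.t.  X_Ω = M_Ω,  0 ≤ X ≤ U off Ω.

ADMM splitting `X = Y` with `Y` carrying the constraints:

    Y ← Π_feasible(X − Z/β)
    X ← SVT_{1/β}(Y + Z/β)
    Z ← Z − γβ(X − Y)

with relaxation `γ = 1.6` (validated below `(1+√5)/2`), penalty
`β = 2.5/√(mn)` by default, stopping when
`‖X − Y‖_F / max(1, ‖M_Ω‖_F) < 10⁻⁶` or after `max_iter = 500`
iterations. The feasible iterate `Y` is returned, so the constraints
hold exactly by construction. A fully observed block is returned as-is.

The singular-value thresholding step uses a truncated SVD (ARPACK) with
a rank hint warmed across iterations, growing the subspace until the
smallest computed singular value falls below the threshold; matrices
with a dimension below 500 use a dense SVD instead, which is faster at
that size and exact. Both paths agree to ≈10⁻¹³ and the choice is a
performance detail only.

## Synthetic generator (`pblr.synthetic`)

`simulate_groups` draws per-gene base means from Gamma(shape 0.6, rate
0.3), multiplies them in a random `de_prob = 0.3` subset of genes per
group by log-normal fold changes (log-sd 1.0), converts each cell's
means to proportions and scales by a log-normal library size (mean
`6.0 × n_genes` counts, log-sd 0.2), and samples Poisson counts.
`apply_logistic_dropout` then zeroes each positive entry independently
with probability `1/(1 + exp(−shape·(ln(x+1) − midpoint)))`; the
defaults `shape = −1`, `midpoint = 1.5` put the observed zero ratio of
the canonical 600 × 300, 3-group fixture at 0.58. The generator is a
deliberately simple Splatter-style mechanism: it has no batch effects,
trajectories, or gene–gene correlation beyond the group structure, and
is meant for validating the pipeline, not for benchmarking against
real-data complexity.

`planted_lowrank` builds exactly-rank-`r` positive matrices with a
known hidden mask for solver recovery tests.

## Evaluation (`pblr.metrics`)

Sum of squared errors; mean per-cell Pearson correlation (constant
columns excluded with a warning); normalized mutual information
(arithmetic mean normalization, natural logs; two degenerate
single-cluster partitions score 1, one scores 0); percentage of
ordered pairs preserved (Kendall-style, tied pairs excluded); and a
manifold-preservation score, the mean fraction of each cell's `k`
nearest neighbours shared between two embeddings.

## Numerical choices and limitations

- NMF updates run up to 1000 iterations at relative tolerance 10⁻⁵;
  symmetric NMF on ~300 cells typically needs 400–500 iterations, and
  stopping earlier degrades the consensus.
- Rank selection by dispersion uses restarts (3 per view); with a
  single restart per view, all views can agree on the same spurious
  extra split, which reproducibility across restarts filters out.
- Imputation happens in log-normalized space; counts are not
  back-transformed.
- All randomness flows from explicit integer seeds; repeated runs are
  bit-identical.
- The remainder block spans all cells, so genes outside the HVG set are
  completed without sub-population structure — faithful to the block
  design, but weaker for markers the HVG filter missed.
- The dropout boundary assumes dropout decreases with expression within
  a block; datasets violating this (e.g. strong batch effects) will
  yield loose bounds.
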