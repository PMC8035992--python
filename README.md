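# pblr

Bounded low-rank imputation of dropout zeros in single-cell RNA-seq
count matrices.

Single-cell RNA-seq measures the transcriptome of individual cells, but
a large fraction of the resulting counts are zero even for genes the
cell actually expresses ("dropouts"), obscuring cell-type structure and
downstream analyses. `pblr` imputes those zeros by exploiting two
observations: cells belong to a small number of sub-populations, within
which the expression matrix is approximately low-rank; and a gene's
dropout rate decays with its expression level, which caps how large an
imputed value can plausibly be.

## Model

Let `M` be the log-normalized expression matrix (genes × cells) and
`Ω` the set of observed (nonzero) entries. The method:

1. **Detects sub-populations** by consensus clustering of the cells on
   highly variable genes — either an ensemble of symmetric and
   indicator NMF runs over Pearson, Spearman and cosine affinities, or
   a shared-nearest-neighbour graph partitioned with Leiden. The
   number of sub-populations can be chosen automatically (consensus
   dispersion for the NMF route, the largest singular-value gap of the
   consensus matrix for the SNN route).
2. **Splits** the matrix into one block per sub-population (highly
   variable genes × that population's cells) plus one remainder block
   (all other genes × all cells).
3. **Estimates a per-gene upper bound** `U_i` within each block from
   the empirical relation between a gene's zero ratio `r_i` and its
   mean observed expression `g_i`. The parametric option fits
   `r = exp(-λ g²)` and inverts its lower confidence envelope; the
   default non-parametric option takes order statistics (min / Q1 /
   Q3 / max) of the mean expression of genes with similar zero ratios,
   switching branch as `r_i` crosses 0.8, 0.6 and 0.4.
4. **Completes each block** by bounded nuclear-norm minimization

       min ‖X‖₊  subject to  X_Ω = M_Ω,  0 ≤ X_ij ≤ U_i  off Ω

   solved with an ADMM scheme whose per-iteration cost is one
   (truncated) SVD, then reassembles the blocks.

Observed entries are preserved exactly; only zeros change, and every
imputed value respects its gene's bound.

## Worked example

Simulate a 3-group dataset with logistic dropout, impute it, and score
the result against the dropout-free truth:

```sh
$ pblr simulate --genes 200 --cells 80 --seed 3 --out sim/
wrote fixture to sim (observed zero ratio 0.498)

$ pblr impute --input sim/observed.csv --output imputed.csv \
      --clusters 3 --no-filter --seed 0
imputed 200 genes x 80 cells into 3 sub-populations -> imputed.csv

$ pblr evaluate --full sim/full.csv --raw sim/observed.csv \
      --imputed imputed.csv --labels imputed.labels.tsv \
      --ref-labels sim/labels.tsv
{
  "sse_raw": 43941.504256374945,
  "sse_imputed": 18446.668655525053,
  "pcc_raw": 0.7288811717183175,
  "pcc_imputed": 0.8741040613686483,
  "manifold_raw": 0.5818749999999999,
  "manifold_imputed": 0.753125,
  "nmi_clusters": 0.8907132433975565
}
```

Imputation halves the squared error against the truth, raises the mean
per-cell Pearson correlation from 0.73 to 0.87, and makes cell
neighbourhoods markedly more faithful to the dropout-free data.
`--no-filter` is used because this small fixture sits below the default
cell-quality thresholds. The same pipeline is available from Python:

```python
import pblr

ds = pblr.default_fixture(seed=0)                  # 600 x 300, 3 groups
res = pblr.pblr_impute(ds.observed,
                       pblr.PBLRConfig(min_genes_per_cell=10,
                                       cluster_count=3))
res.X             # imputed matrix, log-normalized space
res.labels.labels # detected sub-populations
res.boundaries    # per-block upper-bound vectors
```

Real data loads the same way: `pblr impute --input matrix.mtx ...`
accepts Matrix Market (with `genes.tsv`/`barcodes.tsv` alongside), CSV
or TSV genes-by-cells matrices.

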