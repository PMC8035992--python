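import numpy as np
import pytest

import pblr
from pblr.synthetic import SimulationSpec, default_fixture


@pytest.fixture(scope="session")
def fixture_ds():
    """Canonical 3-group 600x300 dataset with logistic dropout, seed 0."""
    return default_fixture(0)


@pytest.fixture(scope="session")
def fixture_hvg(fixture_ds):
    """Filtered / normalized / HVG view of the canonical dataset.

    Returns (filtered matrix, normalized, selection, HVG submatrix,
    planted labels restricted to the kept cells).
    """
    ds = fixture_ds
    M = pblr.filter_matrix(ds.observed, 3, 10)
    cell_pos = {c: j for j, c in enumerate(ds.observed.cell_ids)}
    truth = ds.labels[[cell_pos[c] for c in M.cell_ids]]
    N = pblr.normalize(M)
    sel = pblr.fano_hvg(N)
    return M, N, sel, N.values[sel.selected_indices], truth


@pytest.fixture(scope="session")
def pipeline_result(fixture_ds):
    """One full pipeline run on the canonical dataset (known g=3)."""
    config = pblr.PBLRConfig(min_genes_per_cell=10, cluster_count=3)
    return pblr.pblr_impute(fixture_ds.observed, config)


@pytest.fixture(scope="session")
def pipeline_truth(fixture_ds, pipeline_result):
    """Log-normalized ground truth aligned to the pipeline output."""
    ds, res = fixture_ds, pipeline_result
    gene_pos = {g: i for i, g in enumerate(ds.observed.gene_ids)}
    cell_pos = {c: j for j, c in enumerate(ds.observed.cell_ids)}
    gi = [gene_pos[g] for g in res.gene_ids]
    cj = [cell_pos[c] for c in res.cell_ids]
    fullv = ds.full.values[np.ix_(gi, cj)]
    F = pblr.normalize(pblr.ExpressionMatrix(fullv, res.gene_ids, res.cell_ids))
    return fullv, F.values, ds.labels[cj]
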