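import numpy as np
import pytest
import scipy.sparse as sp

import pblr
from pblr.subpopulation import (
    affinity_from_distance,
    build_snn,
    consensus_from_labels,
    hierarchical_cut,
    inmf,
    leiden_consensus,
    pairwise_distances,
    select_rank_svd_gap,
    split_submatrices,
    symnmf,
)


class TestDistances:
    def test_identical_columns_zero(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 2))
        for metric in ("pearson", "spearman", "cosine"):
            D = pairwise_distances(X, metric)
            assert D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_scaled_columns(self):
        x = np.array([1.0, 2.0, 5.0])
        X = np.column_stack([x, 2 * x])
        assert pairwise_distances(X, "cosine")[0, 1] == pytest.approx(0, abs=1e-12)
        assert pairwise_distances(X, "pearson")[0, 1] == pytest.approx(0, abs=1e-12)

    def test_anticorrelated_pearson_two(self):
        X = np.column_stack([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert pairwise_distances(X, "pearson")[0, 1] == pytest.approx(2.0)

    def test_constant_column_errors(self):
        X = np.column_stack([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="constant"):
            pairwise_distances(X, "pearson")


class TestAffinity:
    def test_endpoints_and_scale_invariance(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        A = affinity_from_distance(D)
        assert A[0, 0] == 1.0
        assert A[0, 2] == pytest.approx(np.exp(-1))
        np.testing.assert_allclose(affinity_from_distance(3.7 * D), A)

    def test_monotone_decreasing_in_distance(self):
        rng = np.random.default_rng(0)
        D = rng.uniform(0, 2, (5, 5))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        A = affinity_from_distance(D)
        i, j = np.unravel_index(np.argsort(D, axis=None), D.shape)
        a_sorted = A[i, j]
        assert np.all(np.diff(a_sorted) <= 1e-12)

    def test_zero_distances_error(self):
        with pytest.raises(ValueError):
            affinity_from_distance(np.zeros((3, 3)))


class TestSymNMF:
    def test_block_diagonal_recovery(self):
        A = np.zeros((6, 6))
        A[:3, :3] = 1
        A[3:, 3:] = 1
        f = symnmf(A, 2, seed=0)
        assert pblr.nmi(f.labels(), [1, 1, 1, 2, 2, 2]) == pytest.approx(1.0)

    def test_rank_one_single_label(self):
        A = affinity_from_distance(np.abs(np.subtract.outer(np.arange(4.0),
                                                            np.arange(4.0))))
        f = symnmf(A, 1, seed=0)
        assert len(set(f.labels())) == 1

    def test_objective_descends(self):
        rng = np.random.default_rng(1)
        B = rng.uniform(size=(8, 8))
        A = (B + B.T) / 2
        f = symnmf(A, 3, seed=2)
        assert f.objective_history[-1] <= f.objective_history[0]
        assert np.all(np.diff(f.objective_history) <= 1e-8)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            symnmf(np.arange(9.0).reshape(3, 3), 2)


class TestINMF:
    def test_rank_one_exact(self):
        rng = np.random.default_rng(1)
        M = np.outer(rng.uniform(0.5, 1, 12), rng.uniform(0.5, 1, 9))
        f = inmf(M, 1, seed=0, max_iter=5000, tol=1e-14)
        rel = np.linalg.norm(M - f.W @ f.Hc) / np.linalg.norm(M)
        assert rel < 1e-6

    def test_planted_gene_blocks(self):
        # two populations marked by near-disjoint gene blocks; a small
        # positive baseline keeps every entry observed (a fully disjoint
        # zero pattern is unidentifiable under zeros-as-missing)
        M = np.full((10, 8), 0.2)
        M[:5, :4] += 3.0 + np.arange(20).reshape(5, 4) * 0.1
        M[5:, 4:] += 3.0 + np.arange(20).reshape(5, 4) * 0.1
        f = inmf(M, 2, seed=0)
        assert pblr.nmi(f.labels(), [1] * 4 + [2] * 4) == pytest.approx(1.0)

    def test_masked_objective_descends(self):
        rng = np.random.default_rng(2)
        M = rng.uniform(size=(12, 10))
        M[rng.uniform(size=(12, 10)) < 0.3] = 0.0
        M[0, :] = 0.5  # keep every column observed somewhere
        f = inmf(M, 3, seed=1)
        assert np.all(np.diff(f.objective_history) <= 1e-8)

    def test_empty_column_errors(self):
        M = np.ones((4, 3))
        M[:, 1] = 0
        with pytest.raises(ValueError, match="no observed"):
            inmf(M, 2)


class TestConsensus:
    def test_identical_partitions_binary(self):
        lab = np.array([1, 1, 2, 2])
        C = consensus_from_labels([lab, lab])
        expected = (lab[:, None] == lab[None, :]).astype(float)
        np.testing.assert_array_equal(C, expected)

    def test_disagreement_half(self):
        C = consensus_from_labels([np.array([1, 1, 2]), np.array([1, 2, 2])])
        assert C[0, 1] == 0.5 and C[1, 2] == 0.5

    def test_relabel_invariance(self):
        a = np.array([1, 1, 2, 3, 3])
        b = np.array([3, 3, 1, 2, 2])  # same partition, renamed
        np.testing.assert_array_equal(
            consensus_from_labels([a]), consensus_from_labels([b])
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            consensus_from_labels([np.array([1, 2]), np.array([1, 2, 3])])


class TestHierarchicalCut:
    def test_perfect_consensus_blocks(self):
        lab = np.array([1, 1, 2, 2, 3, 3])
        C = consensus_from_labels([lab])
        out = hierarchical_cut(C, 3)
        assert pblr.nmi(out.labels, lab) == pytest.approx(1.0)

    @pytest.mark.parametrize("g", [1, 5])
    def test_degenerate_cuts(self, g):
        rng = np.random.default_rng(0)
        C = consensus_from_labels([rng.integers(1, 4, 5) for _ in range(7)])
        out = hierarchical_cut(C, g)
        assert out.g == g

    def test_too_many_clusters_error(self):
        C = consensus_from_labels([np.array([1, 1, 1, 1])])
        with pytest.raises(ValueError):
            hierarchical_cut(C, 3)


class TestSNN:
    @staticmethod
    def _brute_snn(P, k):
        """Independent O(n^2 log n) enumeration of the SNN weights."""
        n = P.shape[0]
        nbrs = []
        for i in range(n):
            d = [(np.linalg.norm(P[i] - P[j]), j) for j in range(n) if j != i]
            nbrs.append({j for _, j in sorted(d)[:k]})
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j and (j in nbrs[i] or i in nbrs[j]):
                    W[i, j] = len(nbrs[i] & nbrs[j]) / k
        return W

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 12))  # 6 genes x 12 cells
        W = build_snn(X, k=3).toarray()
        np.testing.assert_allclose(W, self._brute_snn(X.T, 3))

    def test_weight_range_and_symmetry(self):
        rng = np.random.default_rng(5)
        W = build_snn(rng.normal(size=(5, 30)), k=6).toarray()
        assert W.min() >= 0 and W.max() <= 1
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            build_snn(np.ones((3, 4)), k=4)


class TestLeiden:
    def test_two_cliques_binary_consensus(self):
        W = np.zeros((10, 10))
        W[:5, :5] = 1
        W[5:, 5:] = 1
        np.fill_diagonal(W, 0)
        C = leiden_consensus(sp.csr_matrix(W), seed=0)
        assert set(np.unique(C)) == {0.0, 1.0}
        assert C[:5, :5].min() == 1.0 and C[:5, 5:].max() == 0.0

    def test_single_resolution_binary(self):
        W = sp.csr_matrix(np.ones((4, 4)) - np.eye(4))
        C = leiden_consensus(W, resolutions=[0.3], seed=0)
        assert set(np.unique(C)) <= {0.0, 1.0}

    def test_entries_are_fifths_with_default_sweep(self):
        rng = np.random.default_rng(6)
        W = build_snn(rng.normal(size=(5, 40)), k=5)
        C = leiden_consensus(W, seed=0)
        np.testing.assert_allclose(C * 5, np.round(C * 5), atol=1e-12)


class TestSVDGap:
    def test_two_block_closed_form(self):
        C = np.zeros((6, 6))
        C[:3, :3] = 1
        C[3:, 3:] = 1
        assert select_rank_svd_gap(C, max_g=4) == 2

    def test_identity_tie_rule(self):
        assert select_rank_svd_gap(np.eye(10), max_g=5) == 1

    def test_randomized_matches_dense(self):
        rng = np.random.default_rng(7)
        labels = [rng.integers(1, 5, 50) for _ in range(6)]
        C = consensus_from_labels(labels)
        dense = np.linalg.svd(C, compute_uv=False)[:11]
        from sklearn.utils.extmath import randomized_svd

        _, srand, _ = randomized_svd(C, n_components=11, n_iter=10, random_state=0)
        np.testing.assert_allclose(srand, dense, atol=1e-6)


class TestSplit:
    def _setup(self):
        vals = np.arange(16.0).reshape(4, 4) + 1
        N = pblr.NormalizedMatrix(vals, list("abcd"), list("wxyz"))
        sel = pblr.GeneSelection(np.array([0, 2]), None, None)
        return N, sel

    def test_shapes_and_tiling(self):
        N, sel = self._setup()
        assignment = pblr.ClusterAssignment(np.array([1, 1, 2, 2]), 2)
        blocks = split_submatrices(N, sel, assignment)
        assert [b.shape for b in blocks] == [(2, 2), (2, 2), (2, 4)]
        total = sum(b.M.size for b in blocks)
        assert total == 16
        merged = pblr.merge_submatrices([(b, b.M) for b in blocks])
        np.testing.assert_array_equal(merged, N.values)

    def test_single_cluster_two_blocks(self):
        N, sel = self._setup()
        assignment = pblr.ClusterAssignment(np.ones(4, dtype=int), 1)
        blocks = split_submatrices(N, sel, assignment)
        assert [b.shape for b in blocks] == [(2, 4), (2, 4)]


class TestFixtureRecovery:
    def test_nmf_strategy_recovers_planted_groups(self, fixture_hvg):
        _, _, _, Ns, truth = fixture_hvg
        a, _ = pblr.cluster_cells(Ns, strategy="nmf", cluster_count=3, seed=0)
        assert pblr.nmi(a.labels, truth) >= 0.95

    def test_snn_strategy_recovers_planted_groups(self, fixture_hvg):
        _, _, _, Ns, truth = fixture_hvg
        a, C = pblr.cluster_cells(Ns, strategy="snn", cluster_count="auto", seed=0)
        assert a.g == 3
        assert pblr.nmi(a.labels, truth) >= 0.95
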