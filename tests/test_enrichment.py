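"""Kernel statistic, random-walk scores and the permutation test."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pdxnet import enrichment
from pdxnet.enrichment import (
    GeneSet,
    enrichment_score,
    kernel_cdf_statistic,
    permutation_frame,
    permutation_test,
    sample_random_set,
    scale_scores,
)
from pdxnet.io import ExpressionMatrix
from conftest import make_rank_stats
from oracles import brute_force_kernel_z, brute_force_walk


def expr_matrix(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i:03d}" for i in range(values.shape[0])]
    samples = [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale="log2_normalized"
    )


class TestKernelStatistic:
    def test_matches_double_loop_on_small_matrix(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 2, size=(3, 3))
        ranks = kernel_cdf_statistic(expr_matrix(X))
        np.testing.assert_allclose(ranks.z, brute_force_kernel_z(X), atol=1e-12)

    def test_z_ordering_matches_expression_ordering_within_gene(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6))
        ranks = kernel_cdf_statistic(expr_matrix(X))
        for i in range(10):
            assert np.array_equal(np.argsort(X[i]), np.argsort(ranks.z[i]))

    def test_location_invariance_per_gene(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 4))
        shifted = X.copy()
        shifted[2] += 100.0
        z0 = kernel_cdf_statistic(expr_matrix(X)).z
        z1 = kernel_cdf_statistic(expr_matrix(shifted)).z
        np.testing.assert_allclose(z1[2], z0[2], atol=1e-12)

    def test_ranks_are_permutations(self, rank_stats):
        p = rank_stats.n_genes
        for j in range(rank_stats.n_samples):
            assert sorted(rank_stats.rank[:, j]) == list(range(1, p + 1))

    def test_constant_matrix_ties_broken_by_gene_id(self):
        X = np.full((4, 3), 2.5)
        genes = ["DELTA", "ALPHA", "CHARLIE", "BRAVO"]
        ranks = kernel_cdf_statistic(expr_matrix(X, genes=genes))
        by_rank = [genes[i] for i in np.argsort(ranks.rank[:, 0])]
        assert by_rank == sorted(genes)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            kernel_cdf_statistic(expr_matrix(np.ones((4, 2))))


class TestEnrichmentScore:
    @given(st.data())
    def test_fast_walk_equals_brute_force(self, data):
        p = data.draw(st.integers(10, 50))
        k = data.draw(st.integers(1, 5))
        tau = data.draw(st.sampled_from([0.0, 0.5, 1.0]))
        mode = data.draw(st.sampled_from(["max_diff", "max_dev"]))
        seed = data.draw(st.integers(0, 2**20))
        rng = np.random.default_rng(seed)
        rank = np.column_stack([rng.permutation(p) + 1 for _ in range(3)])
        stats = make_rank_stats(rank)
        set_idx = rng.choice(p, size=k, replace=False)
        gene_set = GeneSet("t", [stats.gene_ids[i] for i in set_idx])
        fast = enrichment_score(stats, gene_set, tau=tau, mode=mode)
        for j in range(3):
            expected = brute_force_walk(rank[:, j], set_idx, tau, mode)
            assert fast.iloc[j] == pytest.approx(expected, abs=1e-12)

    def test_top_ranked_singleton_scores_positive(self):
        rank = np.column_stack([np.arange(1, 11)] * 4)
        stats = make_rank_stats(rank)
        top = GeneSet("top", [stats.gene_ids[0]])  # rank 1 everywhere
        assert (enrichment_score(stats, top) > 0).all()

    def test_tau_zero_is_unweighted_ks(self):
        rng = np.random.default_rng(3)
        rank = np.column_stack([rng.permutation(30) + 1 for _ in range(3)])
        stats = make_rank_stats(rank)
        idx = [4, 9, 17]
        gene_set = GeneSet("u", [stats.gene_ids[i] for i in idx])
        fast = enrichment_score(stats, gene_set, tau=0.0)
        for j in range(3):
            assert fast.iloc[j] == pytest.approx(
                brute_force_walk(rank[:, j], idx, 0.0, "max_diff"), abs=1e-12
            )

    def test_set_as_large_as_universe_rejected(self):
        stats = make_rank_stats(np.arange(1, 6).reshape(5, 1).repeat(3, axis=1))
        full = GeneSet("all", stats.gene_ids)
        with pytest.raises(ValueError):
            enrichment_score(stats, full)

    def test_unknown_member_rejected(self, rank_stats):
        with pytest.raises(ValueError, match="absent"):
            enrichment_score(rank_stats, GeneSet("x", ["NOT_A_GENE"]))


class TestScaleScores:
    def test_divides_by_max_abs(self):
        out = scale_scores(pd.Series([2.0, 4.0]))
        assert out.tolist() == [0.5, 1.0]

    def test_extreme_sample_maps_to_unit(self):
        out = scale_scores(pd.Series([-3.0, 1.5]))
        assert out.abs().max() == 1.0
        assert out.iloc[0] == -1.0

    def test_idempotent(self):
        s = pd.Series([0.3, -0.9, 0.6])
        once = scale_scores(s)
        pd.testing.assert_series_equal(scale_scores(once), once)

    def test_all_zero_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="zero"):
            out = scale_scores(pd.Series([0.0, 0.0]))
        assert out.tolist() == [0.0, 0.0]


class TestRandomSets:
    def test_same_rng_state_same_set(self):
        universe = [f"G{i}" for i in range(50)]
        s1 = sample_random_set(universe, 5, np.random.default_rng(42))
        s2 = sample_random_set(universe, 5, np.random.default_rng(42))
        assert s1.members == s2.members

    def test_boundary_size(self):
        universe = ["A", "B", "C"]
        s = sample_random_set(universe, 2, np.random.default_rng(0))
        assert len(s) == 2
        with pytest.raises(ValueError):
            sample_random_set(universe, 3, np.random.default_rng(0))

    def test_uniform_inclusion_frequencies(self):
        """10,000 draws of k = 2 from 5 genes: inclusion ~ 0.4 within 3 SE."""
        universe = list("ABCDE")
        rng = np.random.default_rng(7)
        counts = {g: 0 for g in universe}
        for _ in range(10_000):
            for g in sample_random_set(universe, 2, rng).members:
                counts[g] += 1
        se = np.sqrt(0.4 * 0.6 / 10_000)
        for g in universe:
            assert abs(counts[g] / 10_000 - 0.4) <= 3 * se


class TestPermutationTest:
    def test_dominant_set_reaches_smoothed_floor(self):
        """E above every one of 999 null scores gives smoothed p = 1/1000."""
        p, n = 40, 3
        rng = np.random.default_rng(5)
        rank = np.empty((p, n), dtype=int)
        for j in range(n):
            rank[:3, j] = [1, 2, 3]              # set genes always on top
            rank[3:, j] = rng.permutation(np.arange(4, p + 1))
        stats = make_rank_stats(rank)
        top = GeneSet("top", stats.gene_ids[:3])
        results = permutation_test(stats, top, iterations=999, seed=0, exclude_set=True)
        for r in results:
            assert r.exceed_count == 0
            assert r.p_value == pytest.approx(1 / 1000)

    def test_verbatim_mode_is_complementary_count(self, rank_stats, target_set):
        smoothed = permutation_test(rank_stats, target_set, iterations=300, seed=9)
        verbatim = permutation_test(
            rank_stats, target_set, iterations=300, seed=9, mode="verbatim"
        )
        for s, v in zip(smoothed, verbatim):
            assert s.exceed_count == v.exceed_count
            assert v.p_value == pytest.approx((300 - s.exceed_count) / 300)
            assert v.p_value + s.exceed_count / 300 == pytest.approx(1.0)

    def test_pvalues_invariant_to_sample_order(self, log2_cohort, target_set):
        perm = np.random.default_rng(1).permutation(log2_cohort.n_samples)
        shuffled = ExpressionMatrix(log2_cohort.data.iloc[:, perm], scale="log2_normalized")
        r1 = {r.sample_id: r.p_value
              for r in permutation_test(log2_cohort, target_set, iterations=200, seed=3)}
        r2 = {r.sample_id: r.p_value
              for r in permutation_test(shuffled, target_set, iterations=200, seed=3)}
        assert r1 == r2

    def test_pvalues_invariant_to_gene_relabeling(self, log2_cohort, target_set):
        relabeled = ExpressionMatrix(
            log2_cohort.data.rename(index=lambda g: f"X_{g}"), scale="log2_normalized"
        )
        new_set = GeneSet("t", [f"X_{g}" for g in target_set.members])
        r1 = [r.p_value for r in permutation_test(log2_cohort, target_set, iterations=200, seed=3)]
        r2 = [r.p_value for r in permutation_test(relabeled, new_set, iterations=200, seed=3)]
        assert r1 == r2

    def test_smoothed_pvalues_within_bounds(self, rank_stats, target_set):
        results = permutation_test(rank_stats, target_set, iterations=150, seed=2)
        for r in results:
            assert 1 / 151 <= r.p_value <= 1.0
            assert 0 <= r.exceed_count <= 150

    def test_frame_has_scaled_scores(self, rank_stats, target_set):
        frame = permutation_frame(permutation_test(rank_stats, target_set, iterations=100, seed=1))
        assert list(frame.columns) == ["E", "scaled_E", "exceed_count", "p_value"]
        assert frame["scaled_E"].abs().max() == pytest.approx(1.0)

    def test_invalid_iterations_rejected(self, rank_stats, target_set):
        with pytest.raises(ValueError):
            permutation_test(rank_stats, target_set, iterations=0, seed=1)
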