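import numpy as np
import pytest

from mvcbt import MultiViewPopulation, antivectorize
from mvcbt.discriminability import (
    FeatureWeightState,
    cumulative_difference,
    mkl_total_weights,
    rank_rois,
    ranking_overlap,
    roi_scores_from_difference,
    roi_scores_from_weights,
    svm_feature_weights,
)

from conftest import random_symmetric


class TestCumulativeDifference:
    def test_identical_lists_give_zero(self, rng):
        a = random_symmetric(rng, 4)
        assert np.all(cumulative_difference([a, a], [a, a]) == 0)

    def test_single_pair(self, rng):
        a, b = random_symmetric(rng, 4), random_symmetric(rng, 4)
        np.testing.assert_allclose(cumulative_difference([a], [b]), np.abs(a - b))

    def test_matches_triple_loop_oracle(self, rng):
        cbts_a = [random_symmetric(rng, 3) for _ in range(3)]
        cbts_b = [random_symmetric(rng, 3) for _ in range(3)]
        t = cumulative_difference(cbts_a, cbts_b)
        expected = np.zeros((3, 3))
        for a in cbts_a:
            for b in cbts_b:
                for i in range(3):
                    for j in range(3):
                        expected[i, j] += abs(a[i, j] - b[i, j])
        np.testing.assert_allclose(t, expected, atol=1e-12)

    def test_argument_symmetry(self, rng):
        cbts_a = [random_symmetric(rng, 4) for _ in range(2)]
        cbts_b = [random_symmetric(rng, 4) for _ in range(2)]
        np.testing.assert_allclose(
            cumulative_difference(cbts_a, cbts_b), cumulative_difference(cbts_b, cbts_a)
        )

    def test_empty_list_rejected(self, rng):
        with pytest.raises(ValueError):
            cumulative_difference([], [random_symmetric(rng, 3)])


class TestRoiScores:
    def test_zero_matrix_identity_ranking(self):
        alpha, ranking = roi_scores_from_difference(np.zeros((4, 4)))
        np.testing.assert_array_equal(alpha, 0.0)
        np.testing.assert_array_equal(ranking, [0, 1, 2, 3])

    def test_dominant_row_ranks_first(self, rng):
        t = random_symmetric(rng, 5)
        t[2] += 100.0
        _, ranking = roi_scores_from_difference(t)
        assert ranking[0] == 2

    def test_row_sum_oracle(self, rng):
        t = random_symmetric(rng, 6)
        alpha, ranking = roi_scores_from_difference(t)
        np.testing.assert_allclose(alpha, [t[i].sum() for i in range(6)])
        assert np.all(np.diff(alpha[ranking]) <= 1e-15)

    def test_permutation_equivariance(self, rng):
        t = random_symmetric(rng, 5)
        alpha, _ = roi_scores_from_difference(t)
        perm = rng.permutation(5)
        alpha_p, _ = roi_scores_from_difference(t[np.ix_(perm, perm)])
        np.testing.assert_allclose(alpha_p, alpha[perm])

    def test_weight_scores_row_sums(self, rng):
        vec = np.abs(rng.standard_normal(10))
        state = FeatureWeightState(x=vec, b=antivectorize(vec, 5))
        alpha, _ = roi_scores_from_weights(state)
        np.testing.assert_allclose(alpha, state.b.sum(axis=1))

    def test_single_edge_weight_scores_both_endpoints(self):
        b = np.zeros((4, 4))
        b[1, 3] = b[3, 1] = 2.5
        alpha, _ = roi_scores_from_weights(FeatureWeightState(x=None, b=b))
        np.testing.assert_allclose(alpha, [0.0, 2.5, 0.0, 2.5])

    def test_tie_break_by_index(self):
        assert rank_rois(np.array([1.0, 2.0, 2.0, 0.5])).tolist() == [1, 2, 0, 3]


class TestSvmWeights:
    def test_separating_feature_has_largest_weight(self):
        n = 20
        fa = np.zeros((n, 6))
        fb = np.zeros((n, 6))
        fa[:, 3] = 1.0
        fb[:, 3] = -1.0
        w = svm_feature_weights(fa, fb)
        assert np.argmax(w) == 3

    def test_sample_permutation_invariance(self, rng):
        fa = rng.standard_normal((10, 5))
        fb = rng.standard_normal((10, 5)) + 1.0
        w1 = svm_feature_weights(fa, fb)
        w2 = svm_feature_weights(fa[rng.permutation(10)], fb[rng.permutation(10)])
        # the separating direction is unique; residual is solver tolerance
        np.testing.assert_allclose(w1, w2, atol=1e-6)

    def test_duplicated_dataset_same_direction(self, rng):
        fa = rng.standard_normal((8, 4))
        fb = rng.standard_normal((8, 4)) + 2.0
        w1 = svm_feature_weights(fa, fb)
        w2 = svm_feature_weights(np.vstack([fa, fa]), np.vstack([fb, fb]))
        np.testing.assert_allclose(w1 / np.linalg.norm(w1), w2 / np.linalg.norm(w2), atol=1e-6)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            svm_feature_weights(rng.standard_normal((3, 4)), np.empty((0, 4)))


def _edge_population(rng, n, r, edge, delta):
    """Population whose networks differ from noise only on one edge."""
    nets = np.zeros((n, 1, r, r))
    for i in range(n):
        x = random_symmetric(rng, r) * 0.01
        x[edge] += delta
        x[edge[::-1]] += delta
        nets[i, 0] = x
    return MultiViewPopulation(networks=nets)


class TestMklWeights:
    def test_planted_edge_dominates(self, rng):
        edge = (1, 4)
        pop_a = _edge_population(rng, 12, 6, edge, 0.0)
        pop_b = _edge_population(rng, 12, 6, edge, 1.0)
        state = mkl_total_weights(pop_a, pop_b, k_folds=2, seed=0)
        i, j = np.unravel_index(np.argmax(state.b), state.b.shape)
        assert {i, j} == set(edge)
        alpha, ranking = roi_scores_from_weights(state)
        assert set(ranking[:2].tolist()) == set(edge)

    def test_degenerate_single_fold_single_view(self, rng):
        pop_a = _edge_population(rng, 6, 5, (0, 1), 0.0)
        pop_b = _edge_population(rng, 6, 5, (0, 1), 1.0)
        state = mkl_total_weights(pop_a, pop_b, k_folds=1, seed=0)
        feats = lambda p: np.stack(
            [p.networks[i, 0][np.triu_indices(5, 1)] for i in range(6)]
        )
        expected = svm_feature_weights(feats(pop_a), feats(pop_b))
        np.testing.assert_allclose(state.x, expected, atol=1e-10)

    def test_seeded_determinism(self, rng):
        pop_a = _edge_population(rng, 10, 5, (0, 2), 0.0)
        pop_b = _edge_population(rng, 10, 5, (0, 2), 0.5)
        s1 = mkl_total_weights(pop_a, pop_b, k_folds=2, seed=3)
        s2 = mkl_total_weights(pop_a, pop_b, k_folds=2, seed=3)
        np.testing.assert_array_equal(s1.x, s2.x)


class TestRankingOverlap:
    def test_identical_and_disjoint(self):
        r1 = np.arange(10)
        assert ranking_overlap(r1, r1, 5) == 100.0
        assert ranking_overlap(r1, r1[::-1], 5) == 0.0

    def test_partial_overlap_percentage(self):
        # 9 shared ROIs in the top 15 -> 60%
        a = np.arange(30)
        b = np.r_[np.arange(9), np.arange(20, 26), np.arange(9, 20), np.arange(26, 30)]
        assert ranking_overlap(a, b, 15) == pytest.approx(60.0)

    def test_top_k_too_large(self):
        with pytest.raises(ValueError):
            ranking_overlap(np.arange(5), np.arange(5), 6)
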