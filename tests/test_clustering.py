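import numpy as np
import pytest
from scipy.linalg import eigh
from sklearn.metrics import adjusted_rand_score

from mvcbt import MultiViewSpectralClustering
from mvcbt.clustering import (
    assign_clusters,
    clustering_objective,
    negative_gradient,
    optimize_joint_clustering,
    retract,
    tangent_projection,
)
from mvcbt.similarity import joint_laplacian, view_laplacian

from conftest import random_symmetric


def random_joint_laplacian(rng, n=12, m=2, beta=1.0):
    ls = [view_laplacian(random_symmetric(rng, n)) for _ in range(m)]
    return joint_laplacian(ls, beta=beta)


def random_stiefel(rng, n, k):
    return retract(rng.standard_normal((n, k)))


class TestObjectiveAndGradient:
    def test_eigenvector_objective_is_eigenvalue_sum(self, rng):
        l = random_joint_laplacian(rng)
        vals, vecs = eigh(l, subset_by_index=[0, 2])
        assert clustering_objective(vecs, l) == pytest.approx(vals.sum(), rel=1e-12)

    def test_zero_laplacian_gives_zero(self, rng):
        u = random_stiefel(rng, 10, 3)
        assert clustering_objective(u, np.zeros((10, 10))) == 0.0
        np.testing.assert_array_equal(negative_gradient(u, np.zeros((10, 10))), 0.0)

    def test_matches_elementwise_loop_oracle(self, rng):
        l = random_joint_laplacian(rng, n=6, m=2)
        u = random_stiefel(rng, 12, 3)
        uut = u @ u.T
        expected = sum(l[i, j] * uut[i, j] for i in range(12) for j in range(12))
        assert clustering_objective(u, l) == pytest.approx(expected, rel=1e-10)

    def test_gradient_matches_product_loop(self, rng):
        l = random_joint_laplacian(rng, n=5, m=2)
        u = random_stiefel(rng, 10, 2)
        z = negative_gradient(u, l)
        for i in range(10):
            for k in range(2):
                assert z[i, k] == pytest.approx(-np.dot(l[i], u[:, k]), abs=1e-12)

    def test_diagonal_laplacian_scales_columns(self):
        u = np.eye(4)[:, :2]
        l = np.diag([2.0, 3.0, 4.0, 5.0])
        np.testing.assert_allclose(negative_gradient(u, l), -l @ u)


class TestTangentProjection:
    def test_projecting_u_gives_zero(self, rng):
        u = random_stiefel(rng, 8, 3)
        np.testing.assert_allclose(tangent_projection(u, u), 0.0, atol=1e-12)

    def test_tangent_direction_unchanged(self, rng):
        u = random_stiefel(rng, 8, 3)
        skew = rng.standard_normal((3, 3))
        skew = skew - skew.T
        z = u @ skew  # U^T Z = skew -> already tangent
        np.testing.assert_allclose(tangent_projection(u, z), z, atol=1e-10)

    def test_result_satisfies_tangency(self, rng):
        u = random_stiefel(rng, 10, 3)
        eta = tangent_projection(u, rng.standard_normal((10, 3)))
        resid = u.T @ eta + eta.T @ u
        assert np.abs(resid).max() <= 1e-10

    def test_rejects_non_orthonormal(self, rng):
        with pytest.raises(ValueError):
            tangent_projection(2.0 * random_stiefel(rng, 6, 2), rng.standard_normal((6, 2)))


class TestRetraction:
    def test_orthonormal_fixed_point(self, rng):
        u = random_stiefel(rng, 7, 3)
        np.testing.assert_allclose(retract(u), u, atol=1e-12)

    def test_scaling_removed(self, rng):
        u = random_stiefel(rng, 7, 3)
        np.testing.assert_allclose(retract(2.0 * u), u, atol=1e-12)

    def test_polar_decomposition_oracle(self, rng):
        x = rng.standard_normal((9, 3))
        q = retract(x)
        assert np.abs(q.T @ q - np.eye(3)).max() <= 1e-10
        # polar factor X (X^T X)^{-1/2}
        vals, vecs = np.linalg.eigh(x.T @ x)
        inv_sqrt = vecs @ np.diag(vals**-0.5) @ vecs.T
        np.testing.assert_allclose(q, x @ inv_sqrt, atol=1e-10)
        # closest orthonormal matrix in Frobenius norm among random candidates
        best = np.linalg.norm(x - q)
        for _ in range(20):
            other = random_stiefel(rng, 9, 3)
            assert np.linalg.norm(x - other) >= best - 1e-10

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            retract(np.zeros((4, 2)))


class TestOptimizer:
    def test_disconnected_graph_reaches_zero(self):
        # two disconnected cliques: Laplacian has >= 2 zero eigenvalues
        s = np.zeros((6, 6))
        s[:3, :3] = 1.0
        s[3:, 3:] = 1.0
        np.fill_diagonal(s, 0.0)
        l = view_laplacian(s)
        res = optimize_joint_clustering(l, 2, seed=0, init="random")
        assert res.objective <= 1e-8

    @pytest.mark.parametrize("init", ["eigen", "random"])
    def test_reaches_analytic_minimum(self, rng, init):
        l = random_joint_laplacian(rng, n=20, m=2)
        target = eigh(l, eigvals_only=True, subset_by_index=[0, 2]).sum()
        res = optimize_joint_clustering(
            l, 3, n_views=2, seed=3, init=init, max_iter=3000, tol=1e-13
        )
        assert res.objective == pytest.approx(target, rel=1e-6)

    def test_objective_monotone_and_orthonormal(self, rng):
        l = random_joint_laplacian(rng, n=15, m=2)
        res = optimize_joint_clustering(l, 3, n_views=2, seed=5, init="random")
        assert np.all(np.diff(res.objective_trace) <= 1e-12)
        assert np.abs(res.u.T @ res.u - np.eye(3)).max() <= 1e-8

    def test_seeded_determinism(self, rng):
        l = random_joint_laplacian(rng, n=10, m=2)
        runs = [
            assign_clusters(
                optimize_joint_clustering(l, 2, n_views=2, seed=11, init="random"), 2, seed=11
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0], runs[1])


class TestAssignClusters:
    def test_planted_two_cliques_recovered(self):
        s = np.zeros((8, 8))
        s[:4, :4] = 1.0
        s[4:, 4:] = 1.0
        np.fill_diagonal(s, 0.0)
        l = view_laplacian(s)
        joint = joint_laplacian([l, l], beta=1.0)
        res = optimize_joint_clustering(joint, 2, n_views=2, seed=0)
        labels = assign_clusters(res, 2, seed=0)
        truth = [0, 0, 0, 0, 1, 1, 1, 1]
        for view in range(2):
            assert adjusted_rand_score(truth, labels[view]) == 1.0

    def test_single_cluster_trivial(self, rng):
        l = random_joint_laplacian(rng, n=6, m=1)
        res = optimize_joint_clustering(l, 1, seed=0)
        assert np.all(assign_clusters(res, 1, seed=0) == 0)

    def test_too_many_clusters_rejected(self, rng):
        l = random_joint_laplacian(rng, n=4, m=1)
        res = optimize_joint_clustering(l, 2, seed=0)
        res.n_subjects = 2
        with pytest.raises(ValueError):
            assign_clusters(res, 2, seed=0)


class TestEstimator:
    def test_consistent_views_agree_differential_differs(self):
        from mvcbt import SyntheticConfig, simulate_population

        cfg = SyntheticConfig(
            n_subjects=45, n_views=3, n_rois=15, n_clusters=3,
            differential_view=2, seed=3,
        )
        pop, truth = simulate_population(cfg)
        est = MultiViewSpectralClustering(n_clusters=3, random_state=3).fit(pop)
        # consistent views recover the shared partition
        for v in (0, 1):
            assert adjusted_rand_score(truth.labels[v], est.labels_[v]) == 1.0
        assert adjusted_rand_score(est.labels_[0], est.labels_[1]) == 1.0
        # the discordant view departs from exact agreement with the others,
        # but the alignment term pulls it toward the consensus partition
        a_consensus = adjusted_rand_score(est.labels_[2], est.labels_[0])
        assert a_consensus < 1.0
        assert a_consensus > adjusted_rand_score(est.labels_[2], truth.labels[2])

    def test_sklearn_param_interface(self):
        est = MultiViewSpectralClustering(n_clusters=4)
        assert est.get_params()["n_clusters"] == 4
        est.set_params(k_neighbors=7)
        assert est.k_neighbors == 7
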