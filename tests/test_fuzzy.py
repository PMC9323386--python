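"""Fuzzy clustering: membership formulas, convergence, GK geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fuzzynir import (ClusterParams, assign_labels, fcm_fit, fcm_membership,
                      gk_covariance, gk_fit, khm_fit, khm_membership)


PARAMS = ClusterParams()


def _column_stochastic(U, atol=1e-8):
    assert np.all(U >= 0) and np.all(U <= 1)
    np.testing.assert_allclose(U.sum(axis=0), 1.0, atol=atol)


class TestFCMMembership:
    def test_equidistant_sample_symmetric(self):
        U = fcm_membership(np.array([[0.5]]), np.array([[0.0], [1.0]]))
        np.testing.assert_allclose(U[:, 0], [0.5, 0.5], atol=1e-12)

    def test_sample_on_center_is_crisp(self):
        V = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        U = fcm_membership(V[[0]], V)
        np.testing.assert_allclose(U[:, 0], [1.0, 0.0, 0.0], atol=1e-12)

    def test_hand_worked_value(self):
        # d^2 = (0.0625, 0.5625): u1 = 1/(1 + 0.0625/0.5625) = 0.9
        U = fcm_membership(np.array([[0.25]]), np.array([[0.0], [1.0]]), m=2.0)
        np.testing.assert_allclose(U[:, 0], [0.9, 0.1], atol=1e-12)

    def test_duplicate_centers_split_uniformly(self):
        V = np.array([[0.0], [0.0], [5.0]])
        U = fcm_membership(np.array([[0.0]]), V)
        np.testing.assert_allclose(U[:, 0], [0.5, 0.5, 0.0], atol=1e-12)

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        V = rng.normal(size=(2, 2))
        for m in (1.5, 2.0, 3.0):
            U = fcm_membership(X, V, m=m)
            d2 = ((X[None, :, :] - V[:, None, :]) ** 2).sum(-1)
            expected = d2 ** (-1 / (m - 1)) / (d2 ** (-1 / (m - 1))).sum(0)
            np.testing.assert_allclose(U, expected, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fcm_membership(np.array([[np.nan]]), np.array([[0.0], [1.0]]))


class TestKHMMembership:
    def test_equidistant_sample_symmetric(self):
        U = khm_membership(np.array([[0.5]]), np.array([[0.0], [1.0]]))
        np.testing.assert_allclose(U[:, 0], [0.5, 0.5], atol=1e-12)

    def test_hand_worked_value(self):
        # distances (1, 2), p=2: 1^-4/(1^-4 + 2^-4) = 16/17
        U = khm_membership(np.array([[1.0]]), np.array([[0.0], [3.0]]), p=2.0)
        np.testing.assert_allclose(U[:, 0], [16 / 17, 1 / 17], atol=1e-12)

    def test_large_power_limit_crisp(self):
        U = khm_membership(np.array([[0.3]]), np.array([[0.0], [1.0]]), p=50.0)
        assert U[0, 0] > 1 - 1e-8

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 2)) * 2
        V = rng.normal(size=(2, 2))
        for p in (1.0, 2.0, 3.5):
            U = khm_membership(X, V, p=p)
            d = np.sqrt(((X[None, :, :] - V[:, None, :]) ** 2).sum(-1))
            expected = d ** (-p - 2) / (d ** (-p - 2)).sum(0)
            np.testing.assert_allclose(U, expected, atol=1e-12)


class TestFCMFit:
    def test_recovers_blob_means(self, blobs_2d):
        X, labels, means = blobs_2d
        part = fcm_fit(X, np.array([[1.0, 1.0], [9.0, 9.0]]), PARAMS)
        assert part.converged
        np.testing.assert_allclose(np.sort(part.V, axis=0),
                                   np.sort(means, axis=0), atol=1e-3)
        hard = assign_labels(part.U)
        assert np.array_equal(hard, labels) or np.array_equal(1 - hard, labels)

    def test_fixed_point_init_one_sweep(self, blobs_2d):
        X, _, _ = blobs_2d
        first = fcm_fit(X, np.array([[0.0, 0.0], [10.0, 10.0]]), PARAMS)
        again = fcm_fit(X, first.V, PARAMS)
        assert again.n_iter == 1 and again.converged

    def test_single_cluster_rejected(self, blobs_2d):
        X, _, _ = blobs_2d
        with pytest.raises(ValueError):
            fcm_fit(X, X[[0]], PARAMS)

    def test_objective_nonincreasing_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X = rng.normal(size=(rng.integers(20, 60), rng.integers(1, 4)))
            V0 = X[rng.choice(len(X), 3, replace=False)]
            part = fcm_fit(X, V0, ClusterParams(n_clusters=3))
            assert np.all(np.diff(part.objective_trace) <= 1e-10)

    def test_membership_convergence_flag(self, blobs_2d):
        X, _, _ = blobs_2d
        part = fcm_fit(X, np.array([[1.0, 2.0], [8.0, 9.0]]),
                       ClusterParams(convergence="memberships"))
        assert part.converged


class TestKHMFit:
    def test_recovers_blob_means(self, blobs_2d):
        X, _, means = blobs_2d
        part = khm_fit(X, np.array([[2.0, 1.0], [8.0, 9.0]]), PARAMS)
        assert part.converged
        np.testing.assert_allclose(np.sort(part.V, axis=0),
                                   np.sort(means, axis=0), atol=1e-3)

    def test_degenerate_point_mass(self):
        X = np.tile([1.0, -2.0], (8, 1))
        part = khm_fit(X, np.array([[0.0, 0.0], [3.0, 3.0]]),
                       ClusterParams(max_iter=200))
        np.testing.assert_allclose(part.V, np.tile([1.0, -2.0], (2, 1)),
                                   atol=1e-3)

    def test_init_insensitivity_on_separated_blobs(self):
        rng = np.random.default_rng(3)
        centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float)
        X = np.vstack([rng.normal(c, 0.3, size=(25, 2)) for c in centers])
        finals = []
        for _ in range(10):
            V0 = X[rng.choice(len(X), 4, replace=False)]
            part = khm_fit(X, V0, ClusterParams(n_clusters=4))
            finals.append(part.objective_trace[-1])
        finals = np.array(finals)
        assert np.mean(finals <= finals.min() * 1.01) >= 0.9


class TestGK:
    def test_covariance_crisp_reduces_to_scatter(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 10.0], [12.0, 10.0]])
        U = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=float)
        V = np.array([[1.0, 0.0], [11.0, 10.0]])
        F = gk_covariance(X, U, V, m=2.0, regularization=0.0)
        np.testing.assert_allclose(F[0], [[1.0, 0.0], [0.0, 0.0 + 1e-10]],
                                   atol=1e-8)

    def test_covariance_two_point_hand_value(self):
        # two points with unit membership: F = mean of outer products
        X = np.array([[1.0, 2.0], [-1.0, -2.0]])
        U = np.array([[1.0, 1.0], [1.0, 1.0]])  # both clusters see both points
        V = np.zeros((2, 2))
        F = gk_covariance(X, U, V, m=2.0, regularization=0.0)
        expected = (np.outer(X[0], X[0]) + np.outer(X[1], X[1])) / 2
        np.testing.assert_allclose(F[0], expected, atol=1e-10)
        np.testing.assert_allclose(F[1], expected, atol=1e-10)

    def test_spherical_data_near_isotropic_norm(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0.0, 1.0, size=(400, 3))
        U = np.vstack([np.full(400, 0.5), np.full(400, 0.5)])
        V = np.zeros((2, 3))
        F = gk_covariance(X, U, V, m=2.0)
        for i in range(2):
            diag = np.diag(F[i])
            off = F[i] - np.diag(diag)
            assert np.allclose(diag, diag.mean(), rtol=0.2)
            assert np.max(np.abs(off)) < 0.2 * diag.mean()

    def test_gk_matches_fcm_under_identity_norm(self, blobs_2d):
        X, _, _ = blobs_2d
        V0 = np.array([[2.0, 0.0], [7.0, 9.0]])
        p_id = ClusterParams(gk_cov_regularization=1.0)
        gk = gk_fit(X, V0, p_id)
        fcm = fcm_fit(X, V0, p_id)
        assert gk.n_iter == fcm.n_iter
        np.testing.assert_allclose(gk.U, fcm.U, atol=1e-8)
        np.testing.assert_allclose(gk.V, fcm.V, atol=1e-8)

    def test_elongated_clusters_recovered(self):
        # two parallel 10:1 ellipsoids; adaptive norms must separate them
        rng = np.random.default_rng(5)
        n = 150
        a = np.column_stack([rng.normal(0, 5.0, n), rng.normal(0.0, 0.5, n)])
        b = np.column_stack([rng.normal(0, 5.0, n), rng.normal(4.0, 0.5, n)])
        X = np.vstack([a, b])
        truth = np.repeat([0, 1], n)
        V0 = np.array([[0.0, 0.5], [0.0, 3.5]])
        part = gk_fit(X, V0, ClusterParams(max_iter=200))
        hard = assign_labels(part.U)
        acc = max(np.mean(hard == truth), np.mean(hard != truth))
        assert acc >= 0.99

    def test_cluster_collapse_raises(self):
        from fuzzynir import ClusterCollapseError
        X = np.array([[0.0], [1.0], [2.0]])
        U = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
        V = np.array([[1.0], [50.0]])
        with pytest.raises(ClusterCollapseError):
            gk_covariance(X, U, V, m=2.0)


class TestAssignLabels:
    def test_argmax_and_tie_rule(self):
        U = np.array([[0.9, 0.5, 0.2], [0.1, 0.5, 0.8]])
        np.testing.assert_array_equal(assign_labels(U), [0, 0, 1])

    def test_crisp_identity(self):
        U = np.eye(4)[:, [2, 0, 3, 1]]
        np.testing.assert_array_equal(assign_labels(U), [2, 0, 3, 1])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), c=st.integers(2, 5),
       n=st.integers(6, 40), q=st.integers(1, 4))
def test_membership_columns_sum_to_one_property(seed, c, n, q):
    """All three algorithms keep U column-stochastic at every sweep."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, q)) * rng.uniform(0.5, 3.0)
    V0 = X[rng.choice(n, c, replace=False)]
    params = ClusterParams(n_clusters=c, max_iter=15)

    def check(it, U, V):
        _column_stochastic(U)

    fcm_fit(X, V0, params, callback=check)
    khm_fit(X, V0, params, callback=check)
    if n > c:
        gk_fit(X, V0, params, callback=check)
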