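"""Thresholding M-step: prox, BB steps, solver convergence, re-weighting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sparsegrn.estep import QStatistics
from sparsegrn.mstep import (
    DivergenceError,
    SparsePrior,
    bb_step,
    iterative_thresholding,
    m_step,
    reweight,
    soft_threshold,
)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "u,a,expected",
        [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), ([2.0, -3.0, 0.1], [1, 1, 1], [1.0, -2.0, 0.0])],
    )
    def test_examples(self, u, a, expected):
        np.testing.assert_allclose(soft_threshold(np.asarray(u), np.asarray(a)), expected)

    def test_zero_threshold_is_identity(self):
        u = np.array([1.5, -2.0, 0.0])
        np.testing.assert_array_equal(soft_threshold(u, np.zeros(3)), u)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.ones(2), np.array([1.0, -0.1]))

    def test_matches_grid_search_prox_minimizer(self):
        # prox of a|z|: argmin 0.5 (z-u)^2 + a|z|
        rng = np.random.default_rng(0)
        grid = np.arange(-6.0, 6.0, 1e-4)
        for _ in range(200):
            u = rng.uniform(-4, 4)
            a = rng.uniform(0, 2)
            best = grid[np.argmin(0.5 * (grid - u) ** 2 + a * np.abs(grid))]
            assert abs(soft_threshold(np.array([u]), np.array([a]))[0] - best) < 2e-4

    @given(st.floats(-100, 100), st.floats(0, 100))
    def test_shrinks_magnitude_never_flips_sign(self, u, a):
        z = soft_threshold(np.array([u]), np.array([a]))[0]
        assert abs(z) <= abs(u) + 1e-12
        assert z * u >= 0.0


class TestBBStep:
    def test_direct_ratio(self):
        assert bb_step(np.array([1.0]), np.array([2.0])) == 2.0

    def test_equal_vectors_give_one(self):
        s = np.array([0.3, -0.4])
        assert bb_step(s, s) == 1.0

    def test_negative_curvature_safeguard(self):
        assert bb_step(np.array([1.0, 0.0]), np.array([-2.0, 0.0])) == 1.0

    def test_zero_step_safeguard(self):
        assert bb_step(np.zeros(3), np.ones(3)) == 1.0


def _quadratic(H, b):
    # 0.5 t'Ht - b't ; minimizer H^{-1} b
    def value(t):
        return float(0.5 * t @ H @ t - b @ t)

    def grad(t):
        return H @ t - b

    return value, grad


class TestIterativeThresholding:
    def test_unpenalized_reaches_quadratic_minimum(self):
        rng = np.random.default_rng(1)
        B = rng.standard_normal((6, 6))
        H = B @ B.T + 0.5 * np.eye(6)
        b = rng.standard_normal(6)
        value, grad = _quadratic(H, b)
        theta, info = iterative_thresholding(
            value, grad, np.zeros(6), np.zeros(6), tol=1e-14, max_iter=2000
        )
        np.testing.assert_allclose(theta, np.linalg.solve(H, b), atol=1e-6)

    def test_huge_penalty_returns_exact_zero(self):
        value, grad = _quadratic(np.eye(3), np.array([1.0, -2.0, 0.5]))
        theta, _ = iterative_thresholding(
            value, grad, 1e6 * np.ones(3), np.ones(3), tol=1e-12
        )
        np.testing.assert_array_equal(theta, np.zeros(3))

    def test_separable_prox_solved_in_one_step(self):
        # 0.5||t - u||^2 with alpha_0 = 1 from t0 = u: first iterate is the prox
        u = np.array([2.0, -0.3, 1.0, -4.0])
        lam = np.array([0.4, 0.4, 0.6, 0.1])

        def value(t):
            return float(0.5 * np.sum((t - u) ** 2))

        def grad(t):
            return t - u

        theta, info = iterative_thresholding(value, grad, lam, u.copy(), tol=1e-12)
        np.testing.assert_allclose(theta, soft_threshold(u, 2.0 * lam), atol=1e-9)

    def test_final_objective_not_above_start_on_convex_quadratic(self):
        rng = np.random.default_rng(2)
        B = rng.standard_normal((5, 5))
        H = B @ B.T + np.eye(5)
        b = rng.standard_normal(5)
        value, grad = _quadratic(H, b)
        lam = 0.3 * np.ones(5)
        t0 = rng.standard_normal(5)

        def J(t):
            return value(t) + 2 * np.sum(lam * np.abs(t))

        theta, _ = iterative_thresholding(value, grad, lam, t0, tol=1e-12, max_iter=1000)
        assert J(theta) <= J(t0) + 1e-10

    def test_divergence_reports_last_iterate(self):
        def value(t):
            return float(np.exp(t[0]) if t[0] < 700 else np.inf)

        def grad(t):
            return np.array([np.exp(min(t[0], 700))])

        with pytest.raises(DivergenceError):
            iterative_thresholding(value, grad, np.zeros(1), np.array([800.0]))


class TestReweight:
    @pytest.mark.parametrize("theta,eps,expected", [(0.0, 0.01, 100.0), (0.99, 0.01, 1.0)])
    def test_examples(self, theta, eps, expected):
        np.testing.assert_allclose(reweight(np.array([theta]), eps), [expected])

    def test_sign_invariant(self):
        t = np.array([0.5, -0.5])
        w = reweight(t, 0.01)
        assert w[0] == w[1]

    def test_requires_positive_eps(self):
        with pytest.raises(ValueError):
            reweight(np.ones(2), 0.0)


def _stats_from_matrices(Sxx, Sxg, Sgg, Uinv, n):
    return QStatistics(Sxx=Sxx, Sxg=Sxg, Sgg=Sgg, Uinv=Uinv, const=0.0, n=n)


class TestMStep:
    def _random_stats(self, seed=0, n=3):
        rng = np.random.default_rng(seed)
        G = rng.standard_normal((12, n))
        X = rng.standard_normal((12, n))
        return _stats_from_matrices(X.T @ X, X.T @ G, G.T @ G + 0.1 * np.eye(n),
                                    4.0 * np.eye(n), n)

    def test_unpenalized_equals_normal_equations(self):
        stats = self._random_stats()
        prior = SparsePrior(lam=np.zeros(9), mode="fixed")
        theta, info = m_step(stats, prior, np.zeros(9))
        expected = np.linalg.solve(stats.Sgg.T, stats.Sxg.T).T.reshape(-1)
        np.testing.assert_allclose(theta, expected, atol=1e-8)

    def test_reweighting_zeros_small_coordinates(self):
        # separable 2-D quadratic with one dominant coordinate; grid-search
        # oracle confirms the re-weighted solution keeps only the big one
        u = np.array([5.0, 0.05])

        def value(t):
            return float(np.sum((t - u) ** 2))

        def grad(t):
            return 2.0 * (t - u)

        lam = np.ones(2)
        theta = u.copy()
        for _ in range(6):
            theta, _ = iterative_thresholding(value, grad, lam, theta, tol=1e-12)
            lam = reweight(theta, 0.01)
        # oracle: coordinate-wise grid search of (t-u)^2 + 2 lam |t| at final lam
        grid = np.arange(-6, 6, 1e-4)
        for i in range(2):
            best = grid[np.argmin((grid - u[i]) ** 2 + 2 * lam[i] * np.abs(grid))]
            assert abs(theta[i] - best) < 2e-4
        # the re-weighted fixed point is u0 - 1/(u0 + eps) ~ 4.79; the small
        # coordinate is driven to an exact zero
        assert theta[1] == 0.0 and abs(theta[0] - 4.79) < 0.05

    def test_reweighted_mode_runs_and_is_deterministic(self):
        stats = self._random_stats(seed=3)
        prior = SparsePrior(lam=np.ones(9), mode="reweighted", eps_reweight=0.01)
        t1, i1 = m_step(stats, prior, np.zeros(9))
        t2, i2 = m_step(stats, prior, np.zeros(9))
        np.testing.assert_array_equal(t1, t2)
        assert i1["rounds"] >= 1

    def test_fixed_mode_penalized_objective_not_above_previous(self):
        stats = self._random_stats(seed=4)
        lam = 0.5 * np.ones(9)
        prior = SparsePrior(lam=lam, mode="fixed")
        rng = np.random.default_rng(5)
        theta_prev = rng.standard_normal(9)
        theta, _ = m_step(stats, prior, theta_prev)
        from sparsegrn.estep import q_value

        def J(t):
            return q_value(t, stats) + 2 * np.sum(lam * np.abs(t))

        assert J(theta) <= J(theta_prev) + 1e-8


class TestSparsePrior:
    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            SparsePrior(lam=np.array([-1.0]))

    def test_rejects_nonpositive_eps(self):
        with pytest.raises(ValueError):
            SparsePrior(lam=np.ones(2), eps_reweight=0.0)
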