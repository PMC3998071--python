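"""E-step statistics, objective and gradient against quadrature/FD oracles."""

import numpy as np
import pytest

from sparsegrn.estep import (
    finite_difference_gradient,
    q_gradient,
    q_statistics,
    q_value,
    q_value_direct,
)
from sparsegrn.filtering import forward_pass
from sparsegrn.model import grn_model, pack_theta, sigmoid_link
from sparsegrn.quadrature import GaussianBelief, ut_rule
from sparsegrn.simulate import simulate_grn
from sparsegrn.smoothing import SmoothTrace, backward_pass


def _grn_trace(n, K, seed, noise=0.01):
    """Smoothed trace from an actual low-noise GRN run (true-ish theta)."""
    rng = np.random.default_rng(seed)
    A = rng.normal(0, 1.0, (n, n))
    ds = simulate_grn(A, K, noise, noise, seed=seed)
    model = grn_model(n)
    rule = ut_rule(n, 0.0)
    U = noise * np.eye(n)
    R = noise * np.eye(n)
    init = GaussianBelief(ds.Y[0], R.copy())
    theta = pack_theta(A)
    fwd = forward_pass(ds.Y, model, theta, U, R, init, rule)
    trace = backward_pass(fwd, model, theta, rule)
    return trace, model, U, rule, theta


def _gh_joint_expectation(g, mean, cov, n_nodes=20):
    """Dense tensor Gauss-Hermite expectation under N(mean, cov)."""
    d = mean.size
    nodes, w = np.polynomial.hermite.hermgauss(n_nodes)
    L = np.linalg.cholesky(cov)
    node_grids = np.meshgrid(*([nodes] * d), indexing="ij")
    weight_grids = np.meshgrid(*([w] * d), indexing="ij")
    pts = np.stack([gg.reshape(-1) for gg in node_grids], axis=1)
    wts = np.prod(np.stack([gg.reshape(-1) for gg in weight_grids], axis=1), axis=1)
    x = mean + np.sqrt(2.0) * pts @ L.T
    vals = np.array([g(xx) for xx in x], dtype=float)
    return np.tensordot(wts, vals, axes=1) / np.pi ** (d / 2.0)


class TestQStatistics:
    def test_point_mass_joints_reduce_to_plugin_sums(self):
        n, K = 2, 5
        rng = np.random.default_rng(0)
        means = [rng.standard_normal(n) for _ in range(K)]
        trace = SmoothTrace(
            means=means,
            covs=[np.zeros((n, n))] * K,
            gains=[np.zeros((n, n))] * (K - 1),
            cross=[np.zeros((n, n))] * (K - 1),
        )
        model = grn_model(n)
        stats = q_statistics(trace, model, 0.1 * np.eye(n), ut_rule(n, 0.0))
        M = np.stack(means)
        G = sigmoid_link(M[:-1])
        np.testing.assert_allclose(stats.Sxx, M[1:].T @ M[1:], atol=1e-10)
        np.testing.assert_allclose(stats.Sxg, M[1:].T @ G, atol=1e-10)
        np.testing.assert_allclose(stats.Sgg, G.T @ G, atol=1e-10)

    def test_matches_dense_gauss_hermite_oracle(self):
        # low-noise 1-gene pipeline trace: joint covariances are small, so
        # the degree-3 rule must agree with a 20x20 Gauss-Hermite grid
        trace, model, U, rule, _ = _grn_trace(n=1, K=2, seed=4)
        stats = q_statistics(trace, model, U, rule)
        joint_mean = np.concatenate([trace.means[0], trace.means[1]])
        joint_cov = np.zeros((2, 2))
        joint_cov[0, 0] = trace.covs[0][0, 0]
        joint_cov[1, 1] = trace.covs[1][0, 0]
        c = (trace.gains[0] @ trace.covs[1])[0, 0]
        joint_cov[0, 1] = joint_cov[1, 0] = c
        ref_Sgg = _gh_joint_expectation(
            lambda z: sigmoid_link(z[:1])[0] ** 2, joint_mean, joint_cov
        )
        ref_Sxg = _gh_joint_expectation(
            lambda z: z[1] * sigmoid_link(z[:1])[0], joint_mean, joint_cov
        )
        ref_Sxx = _gh_joint_expectation(lambda z: z[1] ** 2, joint_mean, joint_cov)
        assert abs(stats.Sgg[0, 0] - ref_Sgg) < 1e-6
        assert abs(stats.Sxg[0, 0] - ref_Sxg) < 1e-6
        assert abs(stats.Sxx[0, 0] - ref_Sxx) < 1e-6

    def test_statistics_symmetric_psd(self):
        trace, model, U, rule, _ = _grn_trace(n=3, K=8, seed=1)
        stats = q_statistics(trace, model, U, rule)
        for M in (stats.Sxx, stats.Sgg):
            np.testing.assert_allclose(M, M.T, atol=1e-12)
            assert np.linalg.eigvalsh(M).min() > -1e-10

    def test_deterministic_given_trace(self):
        trace, model, U, rule, _ = _grn_trace(n=2, K=6, seed=2)
        s1 = q_statistics(trace, model, U, rule)
        s2 = q_statistics(trace, model, U, rule)
        np.testing.assert_array_equal(s1.Sxg, s2.Sxg)
        np.testing.assert_array_equal(s1.Sgg, s2.Sgg)


class TestQValue:
    def test_value_at_zero_is_trace_term_plus_constant(self):
        trace, model, U, rule, _ = _grn_trace(n=2, K=6, seed=3)
        stats = q_statistics(trace, model, U, rule)
        expected = np.trace(stats.Uinv @ stats.Sxx) + stats.const
        assert abs(q_value(np.zeros(4), stats) - expected) < 1e-10

    def test_value_above_unconstrained_minimum(self):
        trace, model, U, rule, _ = _grn_trace(n=2, K=6, seed=5)
        stats = q_statistics(trace, model, U, rule)
        vmin = q_value(stats.unconstrained_minimizer.reshape(-1), stats)
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert q_value(rng.standard_normal(4), stats) >= vmin - 1e-10

    def test_agrees_with_direct_quadrature_of_the_integrals(self):
        trace, model, U, rule, theta = _grn_trace(n=2, K=3, seed=6)
        stats = q_statistics(trace, model, U, rule)
        rng = np.random.default_rng(1)
        for _ in range(3):
            t = rng.standard_normal(4)
            direct = q_value_direct(t, trace, model, U, rule)
            assert abs(q_value(t, stats) - direct) < 1e-8

    def test_exactly_quadratic_along_any_line(self):
        trace, model, U, rule, _ = _grn_trace(n=2, K=6, seed=7)
        stats = q_statistics(trace, model, U, rule)
        rng = np.random.default_rng(2)
        t0, d = rng.standard_normal(4), rng.standard_normal(4)
        ts = [0.0, 1.0, 2.0]
        vals = [q_value(t0 + a * d, stats) for a in ts]
        # fit parabola through 3 points, predict a 4th
        coef = np.polyfit(ts, vals, 2)
        pred = np.polyval(coef, 3.0)
        assert abs(pred - q_value(t0 + 3.0 * d, stats)) < 1e-10 * max(abs(pred), 1.0)


class TestQGradient:
    def test_zero_at_unconstrained_minimizer(self):
        trace, model, U, rule, _ = _grn_trace(n=3, K=8, seed=8)
        stats = q_statistics(trace, model, U, rule)
        g = q_gradient(stats.unconstrained_minimizer.reshape(-1), stats)
        assert np.max(np.abs(g)) < 1e-8

    def test_matches_central_finite_differences(self):
        trace, model, U, rule, _ = _grn_trace(n=2, K=6, seed=9)
        stats = q_statistics(trace, model, U, rule)
        rng = np.random.default_rng(3)
        for _ in range(5):
            t = rng.standard_normal(4)
            g = q_gradient(t, stats)
            fd = finite_difference_gradient(lambda tt: q_value(tt, stats), t)
            np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-7)

    def test_directional_derivative(self):
        trace, model, U, rule, _ = _grn_trace(n=2, K=6, seed=10)
        stats = q_statistics(trace, model, U, rule)
        rng = np.random.default_rng(4)
        t, d = rng.standard_normal(4), rng.standard_normal(4)
        h = 1e-6
        num = (q_value(t + h * d, stats) - q_value(t - h * d, stats)) / (2 * h)
        assert abs(q_gradient(t, stats) @ d - num) < 1e-4 * max(abs(num), 1.0)

    def test_generic_model_requires_direct_path(self):
        trace, model, U, rule, _ = _grn_trace(n=2, K=4, seed=11)
        from dataclasses import replace

        no_basis = replace(model, basis=None)
        with pytest.raises(ValueError, match="basis"):
            q_statistics(trace, no_basis, U, rule)
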