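"""Shared fixtures: benchmark matrices and linear-Gaussian reference solvers.

The linear-Gaussian references are independent oracles: a textbook Kalman
filter written directly from the closed-form recursions, and a batch
smoother that builds the exact joint Gaussian of all states given all
observations and conditions it — no sigma points anywhere.  Sigma-point
recursions are exact for linear integrands, so the package must reproduce
these to high precision.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from sparsegrn.simulate import fixture_A

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def four_gene_A():
    return fixture_A("four_gene")


def make_stable_linear_system(n=4, K=50, seed=11):
    """Random stable linear-Gaussian system and one simulated trajectory."""
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, n))
    F *= 0.8 / np.max(np.abs(np.linalg.eigvals(F)))
    U = np.diag(rng.uniform(0.05, 0.2, n))
    R = np.diag(rng.uniform(0.05, 0.2, n))
    P0 = 0.3 * np.eye(n)
    x = rng.standard_normal(n)
    X = np.empty((K, n))
    Y = np.empty((K, n))
    X[0] = x
    Y[0] = x + np.sqrt(np.diag(R)) * rng.standard_normal(n)
    for k in range(1, K):
        X[k] = F @ X[k - 1] + np.sqrt(np.diag(U)) * rng.standard_normal(n)
        Y[k] = X[k] + np.sqrt(np.diag(R)) * rng.standard_normal(n)
    return {"F": F, "U": U, "R": R, "P0": P0, "X": X, "Y": Y}


@pytest.fixture(scope="session")
def linear_system():
    return make_stable_linear_system()


def kalman_filter_reference(Y, F, U, R, P0):
    """Textbook Kalman recursion; belief at k=0 is (y_0, P0), updates from k=1.

    Returns dicts of predicted/filtered means and covariances (lists over
    time; predicted[0] is the initial belief itself).
    """
    K, n = Y.shape
    mf = [Y[0].copy()]
    Pf = [P0.copy()]
    mp = [Y[0].copy()]
    Pp = [P0.copy()]
    for k in range(1, K):
        m_pred = F @ mf[-1]
        P_pred = F @ Pf[-1] @ F.T + U
        S = P_pred + R  # H = I
        gain = P_pred @ np.linalg.inv(S)
        m_filt = m_pred + gain @ (Y[k] - m_pred)
        P_filt = P_pred - gain @ P_pred
        mp.append(m_pred)
        Pp.append(P_pred)
        mf.append(m_filt)
        Pf.append((P_filt + P_filt.T) / 2)
    return {"pred_means": mp, "pred_covs": Pp, "filt_means": mf, "filt_covs": Pf}


def batch_smoother_reference(Y, F, U, R, P0):
    """Exact smoothed marginals and lag-one cross-covariances.

    Builds the joint Gaussian of x_{1..K} with prior x_1 ~ N(y_1, P0),
    conditions on y_{2..K} (y_k = x_k + v_k), and reads off the marginal
    blocks.  Entirely closed-form linear algebra; no recursions shared with
    the implementation under test.
    """
    K, n = Y.shape
    mu = np.empty((K, n))
    mu[0] = Y[0]
    for k in range(1, K):
        mu[k] = F @ mu[k - 1]
    Sigma = np.zeros((K, K, n, n))
    Sigma[0, 0] = P0
    for k in range(1, K):
        Sigma[k, k] = F @ Sigma[k - 1, k - 1] @ F.T + U
    for j in range(K):
        for k in range(j + 1, K):
            Sigma[j, k] = Sigma[j, k - 1] @ F.T
            Sigma[k, j] = Sigma[j, k].T
    big_mu = mu.reshape(-1)
    big_Sigma = np.block([[Sigma[j, k] for k in range(K)] for j in range(K)])
    obs = np.arange(n, K * n)  # condition on y_2..y_K
    Syy = big_Sigma[np.ix_(obs, obs)] + np.kron(np.eye(K - 1), R)
    Sxy = big_Sigma[:, obs]
    resid = Y[1:].reshape(-1) - big_mu[obs]
    sol = np.linalg.solve(Syy, resid)
    post_mu = big_mu + Sxy @ sol
    post_Sigma = big_Sigma - Sxy @ np.linalg.solve(Syy, Sxy.T)
    means = [post_mu[k * n : (k + 1) * n] for k in range(K)]
    covs = [post_Sigma[k * n : (k + 1) * n, k * n : (k + 1) * n] for k in range(K)]
    lag_one = [
        post_Sigma[k * n : (k + 1) * n, (k + 1) * n : (k + 2) * n]
        for k in range(K - 1)
    ]
    return {"means": means, "covs": covs, "lag_one": lag_one}


@pytest.fixture(scope="session")
def kalman_oracle():
    return kalman_filter_reference


@pytest.fixture(scope="session")
def batch_smoother_oracle():
    return batch_smoother_reference
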