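"""Comparison estimators: direct l1 trajectory fitting and BPDN-DF.

Both baselines reuse the iterative-thresholding engine from
:mod:`sparsegrn.mstep` as their inner convex solver.

l1 trajectory fit: build a deterministic reference trajectory from the
first observation, x_1 = y_1 and x_{k+1} = g(x_k) (the link applied with
no coefficient matrix; a flag switches to A g(x_k) with the running
estimate), then solve the l1-penalized least squares

    min_A  sum_{k=2..K} ||y_k - A g(x_{k-1})||^2 + lam ||theta||_1.

BPDN-DF: augment the state with the parameters, z_k = [x_k; theta_k], and
at each time solve

    min_z ||y_k - H z||^2 + ||lam o z||_1 + ||z - f_aug(z_{k-1})||^2

with H = [I_n, 0], f_aug(z) = [A(theta) g(x); theta], and lam zero on the
x-part (only theta is sparsified).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .model import pack_theta, sigmoid_link, unpack_theta
from .mstep import iterative_thresholding

__all__ = ["l1_trajectory_fit", "bpdn_df"]


def _check_Y(Y: np.ndarray) -> np.ndarray:
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] < 2:
        raise ValueError(f"need at least 2 time points, got {Y.shape[0]}")
    return Y


def l1_trajectory_fit(
    Y: np.ndarray,
    x1: Optional[np.ndarray] = None,
    lam: float = 0.1,
    *,
    reweighted: bool = False,
    reweight_eps: float = 0.01,
    propagate_with_A: bool = False,
    theta0: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    rw_max_rounds: int = 10,
) -> np.ndarray:
    """Direct l1-penalized fit of A on a deterministic trajectory.

    Deterministic given its inputs (no RNG).  ``propagate_with_A`` refits
    the reference trajectory with the current estimate, x_{k+1} = A g(x_k),
    iterating a few times; off by default.
    """
    Y = _check_Y(Y)
    K, n = Y.shape
    x1 = Y[0] if x1 is None else np.asarray(x1, dtype=float)
    theta = np.zeros(n * n) if theta0 is None else np.asarray(theta0, float).copy()

    def reference_trajectory(A: Optional[np.ndarray]) -> np.ndarray:
        X = np.empty((K, n))
        X[0] = x1
        for k in range(1, K):
            step = sigmoid_link(X[k - 1])
            X[k] = step if A is None else A @ step
        return X

    n_outer = 3 if propagate_with_A else 1
    for outer in range(n_outer):
        A_ref = unpack_theta(theta, n) if (propagate_with_A and outer > 0) else None
        X = reference_trajectory(A_ref)
        G = sigmoid_link(X[:-1])  # (K-1, n): g(x_{k-1}) for k = 2..K
        T = Y[1:]  # targets y_k
        Sgg = G.T @ G
        Sxg = T.T @ G

        if lam == 0.0 and not reweighted:
            # unpenalized case in closed form (minimum-norm least squares);
            # the trajectory design is often rank deficient, where first-order
            # iterations stall
            theta = np.linalg.lstsq(G, T, rcond=None)[0].T.reshape(-1)
            continue

        def value_fn(t):
            A = unpack_theta(t, n)
            resid = T - G @ A.T
            return float(np.sum(resid * resid))

        def grad_fn(t):
            A = unpack_theta(t, n)
            return (2.0 * (A @ Sgg - Sxg)).reshape(-1)

        lam_vec = np.full(n * n, lam / 2.0)  # engine penalty is 2||lam o t||_1
        theta, _ = iterative_thresholding(
            value_fn, grad_fn, lam_vec, theta, tol=tol, max_iter=max_iter
        )
        if reweighted:
            for _ in range(rw_max_rounds):
                lam_vec = (lam / 2.0) / (np.abs(theta) + reweight_eps)
                theta_new, _ = iterative_thresholding(
                    value_fn, grad_fn, lam_vec, theta, tol=tol, max_iter=max_iter
                )
                if np.max(np.abs(theta_new - theta)) < 1e-6:
                    theta = theta_new
                    break
                theta = theta_new
    return unpack_theta(theta, n)


def bpdn_df(
    Y: np.ndarray,
    lam: float | np.ndarray = 0.1,
    *,
    theta0: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> np.ndarray:
    """Sequential BPDN dynamic filtering on the augmented state.

    ``lam`` is the Laplace weight on the theta-part (scalar broadcast, or a
    full length n+n^2 vector whose first n entries must be zero).  Returns
    the final theta-part reshaped to an n-by-n matrix.
    """
    Y = _check_Y(Y)
    K, n = Y.shape
    m = n * n
    lam_arr = np.asarray(lam, dtype=float)
    if lam_arr.ndim == 0:
        lam_vec = np.concatenate([np.zeros(n), np.full(m, float(lam_arr))])
    else:
        if lam_arr.size != n + m:
            raise ValueError(f"lam vector must have length {n + m}")
        if np.any(lam_arr[:n] != 0):
            raise ValueError("lam entries for the state part must be zero")
        lam_vec = lam_arr.copy()
    theta = np.zeros(m) if theta0 is None else np.asarray(theta0, float).copy()
    z = np.concatenate([Y[0], theta])
    for k in range(1, K):
        y = Y[k]
        A_prev = unpack_theta(z[n:], n)
        c = np.concatenate([A_prev @ sigmoid_link(z[:n]), z[n:]])  # f_aug(z_{k-1})

        def value_fn(zz):
            r1 = y - zz[:n]
            r2 = zz - c
            return float(r1 @ r1 + r2 @ r2)

        def grad_fn(zz):
            g = 2.0 * (zz - c)
            g[:n] += 2.0 * (zz[:n] - y)
            return g

        # engine minimizes value + 2||w o z||_1, so pass lam/2
        z, _ = iterative_thresholding(
            value_fn, grad_fn, lam_vec / 2.0, c, tol=tol, max_iter=max_iter
        )
    return unpack_theta(z[n:], n)
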