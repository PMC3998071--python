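"""E-step: the expected complete-data objective and its gradient.

With known noise covariances and theta only in the transition, the
quantity minimized by the M-step is

    Qtilde(theta) = sum_{k=2..K} E[ (x_k - f(x_{k-1}, theta))^T U^{-1}
                                    (x_k - f(x_{k-1}, theta)) ]

with expectations under the smoothed pairwise joints p(x_{k-1}, x_k | Y^K).
For models linear in theta, f(x, theta) = A phi(x), Qtilde is an exact
quadratic in A and reduces to three sufficient-statistic matrices

    Sxx = sum E[x_k x_k^T],  Sxg = sum E[x_k phi(x_{k-1})^T],
    Sgg = sum E[phi(x_{k-1}) phi(x_{k-1})^T],

each evaluated by 2n-dimensional sigma-point quadrature over the joints
(exact for Sxx and Sxg-in-x; degree-3 approximate for the sigmoid basis).
A generic direct-quadrature path and a finite-difference gradient are
provided for models without the linear-in-theta structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import StateSpaceModel, unpack_theta
from .quadrature import QuadratureRule, matrix_sqrt, ut_rule
from .smoothing import SmoothTrace, pairwise_joint

__all__ = [
    "QStatistics",
    "q_statistics",
    "q_value",
    "q_gradient",
    "q_value_direct",
    "finite_difference_gradient",
]


@dataclass(frozen=True)
class QStatistics:
    """Sufficient statistics of the quadratic E-step objective."""

    Sxx: np.ndarray
    Sxg: np.ndarray
    Sgg: np.ndarray
    Uinv: np.ndarray
    const: float  # theta-independent 2*sum(c_k); diagnostics only
    n: int

    @property
    def unconstrained_minimizer(self) -> np.ndarray:
        """A* = Sxg Sgg^{-1}, the plain-EM (unpenalized) update."""
        return np.linalg.solve(self.Sgg.T, self.Sxg.T).T


def q_statistics(
    trace: SmoothTrace,
    model: StateSpaceModel,
    U: np.ndarray,
    rule: QuadratureRule,
) -> QStatistics:
    """Accumulate the E-step statistics from the smoothed trace.

    Requires a model with a ``basis`` (transition linear in theta).  The
    joint expectations use the UT rule in 2n dimensions with the same
    kappa as ``rule``.
    """
    if model.basis is None:
        raise ValueError(
            "q_statistics requires a model with a linear-in-theta basis; "
            "use q_value_direct for generic models"
        )
    n = model.state_dim
    joint_rule = ut_rule(2 * n, rule.kappa)
    w = joint_rule.weights
    Sxx = np.zeros((n, n))
    Sxg = np.zeros((n, n))
    Sgg = np.zeros((n, n))
    for k in range(trace.K - 1):
        joint = pairwise_joint(trace, k)
        S = matrix_sqrt(joint.cov)
        pts = joint.mean + joint_rule.points @ S.T
        prev = pts[:, :n]
        cur = pts[:, n:]
        phi = np.array([model.basis(x) for x in prev])
        Sxx += np.einsum("i,ij,ik->jk", w, cur, cur)
        Sxg += np.einsum("i,ij,ik->jk", w, cur, phi)
        Sgg += np.einsum("i,ij,ik->jk", w, phi, phi)
    Sxx = (Sxx + Sxx.T) / 2.0
    Sgg = (Sgg + Sgg.T) / 2.0
    U = np.asarray(U, dtype=float)
    Uinv = np.linalg.inv(U)
    sign, logdet = np.linalg.slogdet(U)
    const = (trace.K - 1) * (logdet + n * np.log(2.0 * np.pi))
    return QStatistics(Sxx=Sxx, Sxg=Sxg, Sgg=Sgg, Uinv=Uinv, const=const, n=n)


def q_value(theta: np.ndarray, stats: QStatistics) -> float:
    """Qtilde(theta) for the linear-in-theta model (to be minimized)."""
    A = unpack_theta(theta, stats.n)
    val = np.trace(
        stats.Uinv
        @ (stats.Sxx - A @ stats.Sxg.T - stats.Sxg @ A.T + A @ stats.Sgg @ A.T)
    )
    return float(val) + stats.const


def q_gradient(theta: np.ndarray, stats: QStatistics) -> np.ndarray:
    """Analytic gradient of :func:`q_value`: vec(2 U^{-1} (A Sgg - Sxg))."""
    A = unpack_theta(theta, stats.n)
    G = 2.0 * stats.Uinv @ (A @ stats.Sgg - stats.Sxg)
    return G.reshape(-1)


def q_value_direct(
    theta: np.ndarray,
    trace: SmoothTrace,
    model: StateSpaceModel,
    U: np.ndarray,
    rule: QuadratureRule,
) -> float:
    """Generic-path Qtilde: quadrature of the transition residual per joint.

    Works for any differentiable transition; used when no linear-in-theta
    basis exists and as an internal cross-check of the statistics path.
    """
    n = model.state_dim
    joint_rule = ut_rule(2 * n, rule.kappa)
    Uinv = np.linalg.inv(np.asarray(U, dtype=float))
    w = joint_rule.weights
    total = 0.0
    for k in range(trace.K - 1):
        joint = pairwise_joint(trace, k)
        S = matrix_sqrt(joint.cov)
        pts = joint.mean + joint_rule.points @ S.T
        for wi, z in zip(w, pts):
            resid = z[n:] - model.transition(z[:n], theta)
            total += wi * float(resid @ Uinv @ resid)
    sign, logdet = np.linalg.slogdet(np.asarray(U, dtype=float))
    return total + (trace.K - 1) * (logdet + n * np.log(2.0 * np.pi))


def finite_difference_gradient(value_fn, theta: np.ndarray, step: float = 1e-6):
    """Central finite differences; fallback for models without a Jacobian."""
    theta = np.asarray(theta, dtype=float)
    grad = np.empty_like(theta)
    for i in range(theta.size):
        e = np.zeros_like(theta)
        e[i] = step
        grad[i] = (value_fn(theta + e) - value_fn(theta - e)) / (2.0 * step)
    return grad
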