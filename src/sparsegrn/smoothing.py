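"""Backward Gaussian (RTS-type) smoother over a forward filter trace.

Produces smoothed marginals p(x_k | Y^K) and the smoother gains D_k needed
to assemble the pairwise joints p(x_k, x_{k+1} | Y^K) consumed by the
E-step.  The recursion initializes at the terminal filtered belief and runs
backward; cross-covariances between x_k and the one-step prediction are
computed by sigma-point quadrature, so the smoother handles nonlinear
transitions the same way the filter does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .filtering import FilterStep
from .model import StateSpaceModel
from .quadrature import GaussianBelief, QuadratureRule, matrix_sqrt

__all__ = [
    "SmoothTrace",
    "cross_covariance",
    "smooth_step",
    "backward_pass",
    "pairwise_joint",
]


def _sym(P: np.ndarray) -> np.ndarray:
    return (P + P.T) / 2.0


@dataclass(frozen=True)
class SmoothTrace:
    """Smoothed means/covariances for k = 1..K plus gains for k = 1..K-1.

    ``gains[k]`` is D_{k+1} in 1-based time (index k pairs states k and
    k+1 zero-based); ``cross[k]`` is the filtered-stage cross-covariance
    C_k used to build D_k.
    """

    means: List[np.ndarray]
    covs: List[np.ndarray]
    gains: List[np.ndarray]
    cross: List[np.ndarray]

    @property
    def K(self) -> int:
        return len(self.means)

    def belief(self, k: int) -> GaussianBelief:
        return GaussianBelief(mean=self.means[k], cov=self.covs[k])


def cross_covariance(
    filtered_k: GaussianBelief,
    predicted_next: GaussianBelief,
    model: StateSpaceModel,
    theta: np.ndarray,
    rule: QuadratureRule,
) -> np.ndarray:
    """C_k = E[(x - x_{k|k})(f(x) - x_{k+1|k})^T] under the filtered belief."""
    S = matrix_sqrt(filtered_k.cov)
    pts = filtered_k.mean + rule.points @ S.T
    fvals = np.array([model.transition(x, theta) for x in pts])
    dx = pts - filtered_k.mean
    df = fvals - predicted_next.mean
    return np.einsum("i,ij,ik->jk", rule.weights, dx, df)


def smooth_step(
    filtered_k: GaussianBelief,
    predicted_next: GaussianBelief,
    smoothed_next: GaussianBelief,
    C_k: np.ndarray,
):
    """One backward correction.

    D_k = C_k P_{k+1|k}^{-1};
    mean_k  = x_{k|k} + D_k (x~_{k+1} - x_{k+1|k});
    cov_k   = P_{k|k} + D_k (P~_{k+1} - P_{k+1|k}) D_k^T.
    """
    try:
        D = np.linalg.solve(predicted_next.cov.T, C_k.T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"predicted covariance P_k+1|k is singular: {exc}"
        ) from exc
    mean = filtered_k.mean + D @ (smoothed_next.mean - predicted_next.mean)
    cov = _sym(filtered_k.cov + D @ (smoothed_next.cov - predicted_next.cov) @ D.T)
    return GaussianBelief(mean=mean, cov=cov), D


def backward_pass(
    forward: List[FilterStep],
    model: StateSpaceModel,
    theta: np.ndarray,
    rule: QuadratureRule,
) -> SmoothTrace:
    """Backward recursion over a forward trace of length K >= 2.

    The terminal smoothed belief equals the terminal filtered belief
    exactly; gains and cross-covariances are stored for the pairwise
    joints.
    """
    K = len(forward)
    if K < 2:
        raise ValueError(f"need a forward pass of length >= 2, got {K}")
    means = [None] * K
    covs = [None] * K
    gains = [None] * (K - 1)
    cross = [None] * (K - 1)
    terminal = forward[-1].filtered
    means[-1], covs[-1] = terminal.mean, terminal.cov
    smoothed_next = terminal
    for k in range(K - 2, -1, -1):
        filtered_k = forward[k].filtered
        predicted_next = forward[k + 1].predicted
        C = cross_covariance(filtered_k, predicted_next, model, theta, rule)
        smoothed_k, D = smooth_step(filtered_k, predicted_next, smoothed_next, C)
        means[k], covs[k] = smoothed_k.mean, smoothed_k.cov
        gains[k], cross[k] = D, C
        smoothed_next = smoothed_k
    return SmoothTrace(means=means, covs=covs, gains=gains, cross=cross)


def pairwise_joint(trace: SmoothTrace, k: int, psd_tol: float = 1e-6) -> GaussianBelief:
    """Joint smoothed Gaussian of (x_{k}, x_{k+1}), zero-based k in [0, K-2].

    Cross block Cov(x_k, x_{k+1} | Y^K) = D_k P~_{k+1}; the assembled 2n
    covariance is symmetrized and checked for indefiniteness.
    """
    if not 0 <= k <= trace.K - 2:
        raise IndexError(f"pair index {k} out of range for K={trace.K}")
    n = trace.means[k].size
    mean = np.concatenate([trace.means[k], trace.means[k + 1]])
    cross = trace.gains[k] @ trace.covs[k + 1]
    cov = np.zeros((2 * n, 2 * n))
    cov[:n, :n] = trace.covs[k]
    cov[n:, n:] = trace.covs[k + 1]
    cov[:n, n:] = cross
    cov[n:, :n] = cross.T
    cov = _sym(cov)
    w = np.linalg.eigvalsh(cov)
    scale = max(np.max(np.abs(w)), 1.0)
    if w.min() < -psd_tol * scale:
        raise FloatingPointError(
            f"pairwise joint covariance at k={k} is indefinite "
            f"(min eigenvalue {w.min():.3e})"
        )
    return GaussianBelief(mean=mean, cov=cov)
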