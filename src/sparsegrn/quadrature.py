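"""Sigma-point quadrature for Gaussian expectations.

All Gaussian integrals in the filter, smoother and E-step are approximated
with the unscented-transform (UT) point set: for an n-dimensional standard
Gaussian the rule places one point at the origin and one pair at
``±sqrt(n + kappa)`` along each coordinate axis (2n+1 points in total).
The rule integrates polynomials up to total degree 3 exactly; expectations
under a general ``N(mean, cov)`` are obtained by the affine push-forward
``x = S @ gamma + mean`` with ``cov = S @ S.T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaussianBelief",
    "QuadratureRule",
    "InvalidRuleError",
    "NotPSDError",
    "ut_rule",
    "matrix_sqrt",
    "gaussian_expectation",
]


class InvalidRuleError(ValueError):
    """Raised when a sigma-point rule cannot be constructed."""


class NotPSDError(ValueError):
    """Raised when a matrix required to be positive semi-definite is not."""


@dataclass(frozen=True)
class GaussianBelief:
    """A Gaussian state density: mean vector and covariance matrix.

    The conditioning set (filtered, predicted, smoothed, ...) is implied by
    where the belief sits in a recursion, not stored here.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if cov.shape != (mean.size, mean.size):
            raise ValueError(
                f"covariance shape {cov.shape} does not match mean of size {mean.size}"
            )
        asym = np.max(np.abs(cov - cov.T)) if cov.size else 0.0
        scale = max(np.max(np.abs(cov)), 1.0) if cov.size else 1.0
        if asym > 1e-8 * scale:
            raise ValueError(f"covariance is not symmetric (max asymmetry {asym:.3e})")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", (cov + cov.T) / 2.0)

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class QuadratureRule:
    """Weighted point set approximating expectations under N(0, I_n)."""

    points: np.ndarray  # (N, dim)
    weights: np.ndarray  # (N,)
    kappa: float
    dim: int

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(pts)):
            raise InvalidRuleError("quadrature points must be finite")
        if abs(w.sum() - 1.0) > 1e-12:
            raise InvalidRuleError("quadrature weights must sum to 1")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)

    @property
    def n_points(self) -> int:
        return self.weights.size


def ut_rule(n: int, kappa: float = 0.0) -> QuadratureRule:
    """Construct the 2n+1-point unscented-transform rule.

    Point 0 sits at the origin with weight ``kappa / (n + kappa)``; points
    ``±sqrt(n + kappa) e_i`` carry weight ``1 / (2 (n + kappa))`` each.
    ``kappa = 0`` (the package default) zeroes the origin weight but the
    point is still generated, so the point-set shape is kappa-independent.

    Parameters
    ----------
    n : int
        State dimension, >= 1.
    kappa : float
        Spread parameter; must satisfy ``n + kappa > 0``.
    """
    n = int(n)
    if n < 1:
        raise InvalidRuleError(f"dimension must be >= 1, got {n}")
    if n + kappa <= 0:
        raise InvalidRuleError(
            f"ut_rule requires n + kappa > 0 (got n={n}, kappa={kappa})"
        )
    scale = np.sqrt(n + kappa)
    points = np.zeros((2 * n + 1, n))
    points[1 : n + 1] = scale * np.eye(n)
    points[n + 1 :] = -scale * np.eye(n)
    weights = np.full(2 * n + 1, 1.0 / (2.0 * (n + kappa)))
    weights[0] = kappa / (n + kappa)
    return QuadratureRule(points=points, weights=weights, kappa=float(kappa), dim=n)


def matrix_sqrt(P: np.ndarray) -> np.ndarray:
    """Factor a symmetric PSD matrix as ``P = S @ S.T``.

    Cholesky is attempted first; on failure a small diagonal jitter
    (1e-10 * trace(P)/n) is added and Cholesky retried; as a last resort the
    symmetric eigendecomposition factor ``V sqrt(max(w, 0)) `` is used.
    Deterministic for a given input.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    scale = max(np.max(np.abs(P)), 1.0)
    if np.max(np.abs(P - P.T)) > 1e-8 * scale:
        raise NotPSDError("matrix is not symmetric")
    P = (P + P.T) / 2.0
    try:
        return np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        pass
    n = P.shape[0]
    jitter = 1e-10 * np.trace(P) / n
    if jitter > 0:
        try:
            return np.linalg.cholesky(P + jitter * np.eye(n))
        except np.linalg.LinAlgError:
            pass
    w, V = np.linalg.eigh(P)
    norm = np.max(np.abs(w)) if w.size else 0.0
    if w.min() < -1e-8 * max(norm, 1.0):
        raise NotPSDError(
            f"matrix has eigenvalue {w.min():.3e} below the PSD tolerance"
        )
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def gaussian_expectation(g, belief: GaussianBelief, rule: QuadratureRule):
    """Approximate ``E[g(x)]`` for ``x ~ N(belief.mean, belief.cov)``.

    ``g`` may return a scalar, vector or matrix; the weighted sum
    ``sum_i w_i g(S gamma_i + mean)`` is returned with the same shape.
    """
    if rule.dim != belief.dim:
        raise ValueError(
            f"rule dimension {rule.dim} does not match belief dimension {belief.dim}"
        )
    S = matrix_sqrt(belief.cov)
    pts = belief.mean + rule.points @ S.T
    out = None
    for i, (w, x) in enumerate(zip(rule.weights, pts)):
        val = np.asarray(g(x), dtype=float)
        if not np.all(np.isfinite(val)):
            raise FloatingPointError(
                f"integrand returned non-finite value at quadrature point {i}"
            )
        out = w * val if out is None else out + w * val
    return out
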