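"""Forward sigma-point Gaussian filter.

Each step propagates the filtered belief through the transition
(prediction) and conditions on the new observation under a joint-Gaussian
assumption (update).  All expectations use the UT rule; every covariance is
symmetrized after assembly.

Time indexing follows k = 1..K: the step at k = 1 holds the initial belief
as its filtered density (no measurement update there; the initial mean is
conventionally set from the first observation) and the predict/update
recursion runs for k = 2..K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .model import StateSpaceModel
from .quadrature import GaussianBelief, QuadratureRule, matrix_sqrt

__all__ = ["FilterStep", "FilterDivergenceError", "predict", "update", "forward_pass"]


class FilterDivergenceError(RuntimeError):
    """Raised when the forward recursion produces a non-finite belief."""


@dataclass(frozen=True)
class FilterStep:
    """All per-time quantities the smoother and E-step need."""

    predicted: GaussianBelief  # (x_{k|k-1}, P_{k|k-1})
    filtered: GaussianBelief  # (x_{k|k}, P_{k|k})
    pred_obs: Optional[np.ndarray] = None  # y_{k|k-1}
    gain: Optional[np.ndarray] = None  # L_k
    Pxy: Optional[np.ndarray] = None
    Pyy: Optional[np.ndarray] = None


def _sigma_points(belief: GaussianBelief, rule: QuadratureRule) -> np.ndarray:
    S = matrix_sqrt(belief.cov)
    return belief.mean + rule.points @ S.T


def _sym(P: np.ndarray) -> np.ndarray:
    return (P + P.T) / 2.0


def predict(
    belief: GaussianBelief,
    model: StateSpaceModel,
    theta: np.ndarray,
    U: np.ndarray,
    rule: QuadratureRule,
) -> GaussianBelief:
    """Propagate a filtered belief one step through the transition.

    mean = E[f(x)], cov = E[(f(x)-mean)(f(x)-mean)^T] + U under the
    current belief, both by sigma-point quadrature.
    """
    pts = _sigma_points(belief, rule)
    fvals = np.array([model.transition(x, theta) for x in pts])
    if not np.all(np.isfinite(fvals)):
        raise FloatingPointError("transition returned non-finite values")
    w = rule.weights
    mean = w @ fvals
    dev = fvals - mean
    cov = np.einsum("i,ij,ik->jk", w, dev, dev) + np.asarray(U, dtype=float)
    return GaussianBelief(mean=mean, cov=_sym(cov))


def update(
    predicted: GaussianBelief,
    y: np.ndarray,
    model: StateSpaceModel,
    theta: np.ndarray,
    R: np.ndarray,
    rule: QuadratureRule,
) -> FilterStep:
    """Condition a predicted belief on observation ``y``.

    Kalman-type update with quadrature moments: gain
    ``L = Pxy (R + Pyy)^{-1}``, mean ``x + L (y - y_hat)``, covariance
    ``P - L Pxy^T`` (symmetrized).
    """
    y = np.asarray(y, dtype=float)
    pts = _sigma_points(predicted, rule)
    hvals = np.array([model.measurement(x, theta) for x in pts])
    w = rule.weights
    yhat = w @ hvals
    dx = pts - predicted.mean
    dy = hvals - yhat
    Pxy = np.einsum("i,ij,ik->jk", w, dx, dy)
    Pyy = _sym(np.einsum("i,ij,ik->jk", w, dy, dy))
    innov_cov = np.asarray(R, dtype=float) + Pyy
    try:
        # L = Pxy @ inv(innov_cov); solve on the transpose for conditioning
        L = np.linalg.solve(innov_cov.T, Pxy.T).T
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"innovation covariance R + Pyy is singular: {exc}"
        ) from exc
    mean = predicted.mean + L @ (y - yhat)
    cov = _sym(predicted.cov - L @ Pxy.T)
    return FilterStep(
        predicted=predicted,
        filtered=GaussianBelief(mean=mean, cov=cov),
        pred_obs=yhat,
        gain=L,
        Pxy=Pxy,
        Pyy=Pyy,
    )


def forward_pass(
    Y: np.ndarray,
    model: StateSpaceModel,
    theta: np.ndarray,
    U: np.ndarray,
    R: np.ndarray,
    init: GaussianBelief,
    rule: QuadratureRule,
) -> List[FilterStep]:
    """Run the filter over a K-by-obs_dim observation matrix.

    Step 1 stores ``init`` as both predicted and filtered belief; steps
    2..K alternate :func:`predict` / :func:`update`.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    K = Y.shape[0]
    if K < 2:
        raise ValueError(f"need at least 2 time points, got {K}")
    bad = np.argwhere(~np.isfinite(Y))
    if bad.size:
        k, j = bad[0]
        raise ValueError(f"non-finite observation at time index {k}, column {j}")
    steps: List[FilterStep] = [FilterStep(predicted=init, filtered=init)]
    for k in range(1, K):
        pred = predict(steps[-1].filtered, model, theta, U, rule)
        step = update(pred, Y[k], model, theta, R, rule)
        if not (
            np.all(np.isfinite(step.filtered.mean))
            and np.all(np.isfinite(step.filtered.cov))
        ):
            raise FilterDivergenceError(
                f"filter produced a non-finite belief at time index {k}"
            )
        steps.append(step)
    return steps
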