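"""EM / regularized-EM driver.

Each outer iteration runs the full Gaussian-approximation E-step (forward
filter, backward smoother, sufficient statistics) at the current theta and
then one M-step:

  mode 'em'    : unpenalized closed-form update (no sparsity),
  mode 'rem'   : l1-penalized thresholding at fixed Laplace rates lam,
  mode 'rem_w' : re-weighted thresholding (lam_i reset to 1 each M-step,
                 then lam_i = 1/(|theta_i| + eps) between inner runs).

The state is initialized from the first observation with covariance P0;
the recursion and the objective sums start at k = 2.  Noise covariances
are treated as known inputs — only theta is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from .estep import q_statistics, q_value
from .filtering import FilterDivergenceError, forward_pass
from .model import StateSpaceModel, unpack_theta
from .mstep import SparsePrior, m_step
from .quadrature import GaussianBelief, ut_rule
from .smoothing import backward_pass

__all__ = ["EMConfig", "EMResult", "initialize_theta", "run_em"]

VALID_MODES = ("em", "rem", "rem_w")


@dataclass(frozen=True)
class EMConfig:
    """Settings for one EM run; covariances may be scalars (times identity).

    ``P0`` is the covariance of the initial state belief, whose mean is the
    first observation.  ``None`` (the default) uses the measurement-noise
    covariance R — the actual uncertainty of a state read off one noisy
    measurement.  An overconfident or far-too-diffuse P0 biases the first
    smoothed pairwise joint and with it every parameter update.
    """

    mode: str = "rem_w"
    lam: float | np.ndarray = 1.0  # Laplace rate(s), 'rem' mode only
    kappa: float = 0.0
    U: float | np.ndarray = 0.01
    R: float | np.ndarray = 0.01
    P0: float | np.ndarray | None = None
    max_em_iters: int = 50
    em_tol: float = 1e-4
    seed: Optional[int] = 0
    init_sd: float = float(np.sqrt(2.0))
    inner_tol: float = 1e-6
    inner_max_iter: int = 500
    reweight_eps: float = 0.01
    rw_tol: float = 1e-6
    rw_max_rounds: int = 10

    def __post_init__(self):
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        for name in ("max_em_iters", "inner_max_iter", "rw_max_rounds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("em_tol", "inner_tol", "rw_tol", "reweight_eps", "init_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EMResult:
    theta_hat: np.ndarray
    A_hat: np.ndarray
    history: List[dict]  # length iterations + 1, entry 0 = initialization
    converged: bool
    iterations: int

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat.tolist(),
            "A_hat": self.A_hat.tolist(),
            "converged": self.converged,
            "iterations": self.iterations,
            "history": [
                {
                    "theta": h["theta"].tolist(),
                    "objective": h["objective"],
                    "inner_iterations": h["inner_iterations"],
                }
                for h in self.history
            ],
        }


def _as_cov(value, n: int) -> np.ndarray:
    value = np.asarray(value, dtype=float)
    if value.ndim == 0:
        return float(value) * np.eye(n)
    if value.shape != (n, n):
        raise ValueError(f"covariance shape {value.shape} incompatible with n={n}")
    return (value + value.T) / 2.0


def initialize_theta(m: int, init_sd: float, seed: Optional[int]) -> np.ndarray:
    """i.i.d. N(0, init_sd^2) initialization, reproducible by seed."""
    rng = np.random.default_rng(seed)
    return init_sd * rng.standard_normal(m)


def _penalized_objective(theta, stats, mode, lam_vec):
    if mode == "em":
        return q_value(theta, stats)
    return q_value(theta, stats) + 2.0 * float(np.abs(lam_vec * theta).sum())


def run_em(Y: np.ndarray, model: StateSpaceModel, config: EMConfig) -> EMResult:
    """Run EM/rEM/rEM_w on a K-by-n observation matrix; returns the fit."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    K, n_obs = Y.shape
    if K < 2:
        raise ValueError(f"need at least 2 time points, got {K}")
    n = model.state_dim
    m = model.theta_dim
    U = _as_cov(config.U, n)
    R = _as_cov(config.R, n_obs)
    P0 = R.copy() if config.P0 is None else _as_cov(config.P0, n)
    rule = ut_rule(n, config.kappa)
    init_belief = GaussianBelief(mean=Y[0], cov=P0)

    theta = initialize_theta(m, config.init_sd, config.seed)
    lam_vec = np.broadcast_to(np.asarray(config.lam, dtype=float), (m,)).copy()
    if config.mode == "em":
        prior = SparsePrior(lam=np.zeros(m), mode="fixed")
    elif config.mode == "rem":
        prior = SparsePrior(lam=lam_vec, mode="fixed")
    else:
        prior = SparsePrior(
            lam=np.ones(m), mode="reweighted", eps_reweight=config.reweight_eps
        )

    history = [{"theta": theta.copy(), "objective": None, "inner_iterations": 0}]
    converged = False
    iterations = 0
    for it in range(1, config.max_em_iters + 1):
        try:
            fwd = forward_pass(Y, model, theta, U, R, init_belief, rule)
        except (FilterDivergenceError, FloatingPointError) as exc:
            raise FilterDivergenceError(
                f"E-step failed at EM iteration {it}: {exc}"
            ) from exc
        trace = backward_pass(fwd, model, theta, rule)
        stats = q_statistics(trace, model, U, rule)
        theta_new, info = m_step(
            stats,
            prior,
            theta,
            tol=config.inner_tol,
            max_iter=config.inner_max_iter,
            rw_tol=config.rw_tol,
            rw_max_rounds=config.rw_max_rounds,
        )
        obj = _penalized_objective(theta_new, stats, config.mode, lam_vec)
        history.append(
            {
                "theta": theta_new.copy(),
                "objective": float(obj),
                "inner_iterations": info["iterations"],
            }
        )
        iterations = it
        rel = np.linalg.norm(theta_new - theta) / max(np.linalg.norm(theta), 1.0)
        theta = theta_new
        if rel <= config.em_tol:
            converged = True
            break
    return EMResult(
        theta_hat=theta,
        A_hat=unpack_theta(theta, int(round(np.sqrt(m)))) if m == n * n else theta.copy().reshape(1, -1),
        history=history,
        converged=converged,
        iterations=iterations,
    )
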