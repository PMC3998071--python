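"""scikit-learn-style estimators wrapping the inference engines.

Each estimator fits an n-by-n regulatory-coefficient matrix from a K-by-n
expression time series passed as ``X`` to :meth:`fit`; the fitted matrix is
exposed as ``coef_`` and ``predict`` returns the one-step-ahead expected
expression ``A g(x)``.  Estimators are stateless between fits, validate
their inputs, and compose with sklearn model selection via
``get_params`` / ``set_params``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .baselines import bpdn_df, l1_trajectory_fit
from .em import EMConfig, run_em
from .model import grn_model, grn_transition

__all__ = ["SparseEMNetwork", "L1TrajectoryNetwork", "BPDNDFNetwork"]


class _NetworkEstimator(BaseEstimator, RegressorMixin):
    """Shared validation and one-step-ahead prediction."""

    def _validate_series(self, X) -> np.ndarray:
        X = check_array(X, dtype=float, ensure_min_samples=2)
        return np.asarray(X)

    def predict(self, X) -> np.ndarray:
        """Expected next-step expression A g(x) for each row of ``X``."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return np.array([grn_transition(x, self.coef_) for x in X])


class SparseEMNetwork(_NetworkEstimator):
    """GRN inference by (regularized) EM in the sigmoid state-space model.

    Parameters
    ----------
    mode : {'em', 'rem', 'rem_w'}
        Plain EM (no sparsity), l1-regularized EM at fixed ``lam``, or
        re-weighted rEM (adaptive Laplace rates).
    lam : float
        Laplace rate for mode 'rem'.
    kappa : float
        UT spread parameter; 0 by default.
    process_noise, measurement_noise : float or (n, n) array
        Known noise covariances (scalars mean that multiple of identity).
    p0 : float, (n, n) array or None
        Initial state covariance around the first observation; None uses
        the measurement-noise covariance.
    init_sd : float
        SD of the Gaussian initialization of the coefficients.
    random_state : int or None
        Seed for the coefficient initialization.

    Attributes
    ----------
    coef_ : (n, n) ndarray
        Estimated regulatory-coefficient matrix.
    theta_ : (n*n,) ndarray
        Row-major vectorization of ``coef_``.
    n_iter_ : int
        Outer EM iterations used.
    converged_ : bool
    history_ : list of dict
        Per-iteration theta, penalized objective, inner-iteration counts.
    """

    def __init__(
        self,
        mode: str = "rem_w",
        lam: float = 1.0,
        kappa: float = 0.0,
        process_noise: float = 0.01,
        measurement_noise: float = 0.01,
        p0: Optional[float] = None,
        max_em_iters: int = 50,
        em_tol: float = 1e-4,
        init_sd: float = float(np.sqrt(2.0)),
        inner_tol: float = 1e-6,
        inner_max_iter: int = 500,
        reweight_eps: float = 0.01,
        random_state: Optional[int] = 0,
    ):
        self.mode = mode
        self.lam = lam
        self.kappa = kappa
        self.process_noise = process_noise
        self.measurement_noise = measurement_noise
        self.p0 = p0
        self.max_em_iters = max_em_iters
        self.em_tol = em_tol
        self.init_sd = init_sd
        self.inner_tol = inner_tol
        self.inner_max_iter = inner_max_iter
        self.reweight_eps = reweight_eps
        self.random_state = random_state

    def _config(self) -> EMConfig:
        return EMConfig(
            mode=self.mode,
            lam=self.lam,
            kappa=self.kappa,
            U=self.process_noise,
            R=self.measurement_noise,
            P0=self.p0,
            max_em_iters=self.max_em_iters,
            em_tol=self.em_tol,
            seed=self.random_state,
            init_sd=self.init_sd,
            inner_tol=self.inner_tol,
            inner_max_iter=self.inner_max_iter,
            reweight_eps=self.reweight_eps,
        )

    def fit(self, X, y=None):
        X = self._validate_series(X)
        n = X.shape[1]
        result = run_em(X, grn_model(n), self._config())
        self.coef_ = result.A_hat
        self.theta_ = result.theta_hat
        self.n_iter_ = result.iterations
        self.converged_ = result.converged
        self.history_ = result.history
        self.n_features_in_ = n
        return self


class L1TrajectoryNetwork(_NetworkEstimator):
    """Direct l1-penalized least-squares fit on a deterministic trajectory."""

    def __init__(
        self,
        lam: float = 0.1,
        reweighted: bool = False,
        reweight_eps: float = 0.01,
        propagate_with_A: bool = False,
    ):
        self.lam = lam
        self.reweighted = reweighted
        self.reweight_eps = reweight_eps
        self.propagate_with_A = propagate_with_A

    def fit(self, X, y=None):
        X = self._validate_series(X)
        self.coef_ = l1_trajectory_fit(
            X,
            lam=self.lam,
            reweighted=self.reweighted,
            reweight_eps=self.reweight_eps,
            propagate_with_A=self.propagate_with_A,
        )
        self.theta_ = self.coef_.reshape(-1)
        self.n_features_in_ = X.shape[1]
        return self


class BPDNDFNetwork(_NetworkEstimator):
    """BPDN dynamic filtering on the state augmented with the coefficients."""

    def __init__(self, lam: float = 0.1):
        self.lam = lam

    def fit(self, X, y=None):
        X = self._validate_series(X)
        self.coef_ = bpdn_df(X, lam=self.lam)
        self.theta_ = self.coef_.reshape(-1)
        self.n_features_in_ = X.shape[1]
        return self
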