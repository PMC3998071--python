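"""Evaluation metrics for inferred regulatory-coefficient matrices.

RMSE is entry-wise over all n^2 coefficients; the sparsity factor is the
ratio of estimated to true zero counts (1 ideal, > 1 over-sparse); matched
elements counts positions where the estimated and true supports agree; the
ROC curve ranks entries by estimated magnitude against the true support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "UndefinedMetricError",
    "rmse",
    "sparsity_factor",
    "support_matrix",
    "matched_elements",
    "roc_curve",
    "auroc",
    "metrics_report",
]

ZERO_TOL = 1e-12


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


def _pair(A, A_hat):
    A = np.asarray(A, dtype=float)
    A_hat = np.asarray(A_hat, dtype=float)
    if A.shape != A_hat.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {A_hat.shape}")
    return A, A_hat


def rmse(A: np.ndarray, A_hat: np.ndarray) -> float:
    """Root mean squared error over all matrix entries."""
    A, A_hat = _pair(A, A_hat)
    return float(np.sqrt(np.mean((A - A_hat) ** 2)))


def support_matrix(A: np.ndarray, zero_tol: float = ZERO_TOL) -> np.ndarray:
    """Binary support: 1 where |entry| > zero_tol."""
    return (np.abs(np.asarray(A, dtype=float)) > zero_tol).astype(int)


def sparsity_factor(A: np.ndarray, A_hat: np.ndarray, zero_tol: float = ZERO_TOL) -> float:
    """Estimated zero count over true zero count; > 1 means over-sparse."""
    A, A_hat = _pair(A, A_hat)
    phi = int(np.sum(np.abs(A) <= zero_tol))
    if phi == 0:
        raise UndefinedMetricError("true matrix has no zero entries; SF undefined")
    phi0 = int(np.sum(np.abs(A_hat) <= zero_tol))
    return phi0 / phi


def matched_elements(A: np.ndarray, A_hat: np.ndarray, zero_tol: float = ZERO_TOL) -> int:
    """Number of positions where the two supports agree."""
    A, A_hat = _pair(A, A_hat)
    diff = support_matrix(A, zero_tol) - support_matrix(A_hat, zero_tol)
    return int(np.sum(diff == 0))


def roc_curve(A: np.ndarray, A_hat: np.ndarray) -> List[Tuple[float, float]]:
    """(FPR, TPR) pairs from sweeping a magnitude threshold over |A_hat|.

    All n^2 entries participate; the curve includes (0, 0) and (1, 1) and
    both rates are non-decreasing along it.
    """
    A, A_hat = _pair(A, A_hat)
    truth = support_matrix(A).reshape(-1)
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise UndefinedMetricError("true support is empty; TPR undefined")
    if n_pos == truth.size:
        raise UndefinedMetricError("true support is full; FPR undefined")
    fpr, tpr, _ = _sk_roc_curve(truth, np.abs(A_hat).reshape(-1))
    return list(zip(fpr.tolist(), tpr.tolist()))


def auroc(A: np.ndarray, A_hat: np.ndarray) -> float:
    """Area under the magnitude-ranking ROC curve."""
    pts = roc_curve(A, A_hat)
    fpr = [p[0] for p in pts]
    tpr = [p[1] for p in pts]
    return float(_sk_auc(fpr, tpr))


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    sparsity_factor: float
    matched: int
    roc: List[Tuple[float, float]]
    counts: dict  # TP/FP/TN/FN at the zero-tolerance support threshold

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "sparsity_factor": self.sparsity_factor,
            "matched_elements": self.matched,
            "roc": [[float(f), float(t)] for f, t in self.roc],
            "counts": self.counts,
        }


def metrics_report(A: np.ndarray, A_hat: np.ndarray, zero_tol: float = ZERO_TOL) -> MetricsReport:
    """All metrics for one estimate; ROC omitted when degenerate."""
    A, A_hat = _pair(A, A_hat)
    s_true = support_matrix(A, zero_tol)
    s_hat = support_matrix(A_hat, zero_tol)
    counts = {
        "TP": int(np.sum((s_true == 1) & (s_hat == 1))),
        "FP": int(np.sum((s_true == 0) & (s_hat == 1))),
        "TN": int(np.sum((s_true == 0) & (s_hat == 0))),
        "FN": int(np.sum((s_true == 1) & (s_hat == 0))),
    }
    try:
        roc = roc_curve(A, A_hat)
    except UndefinedMetricError:
        roc = []
    return MetricsReport(
        rmse=rmse(A, A_hat),
        sparsity_factor=sparsity_factor(A, A_hat, zero_tol),
        matched=matched_elements(A, A_hat, zero_tol),
        roc=roc,
        counts=counts,
    )
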