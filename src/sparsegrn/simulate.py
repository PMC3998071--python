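"""Synthetic GRN trajectory generator and the benchmark coefficient matrices.

The simulator draws from the generative model the estimators assume:

    x_1 = x0,   x_k = A g(x_{k-1}) + u_k   (k >= 2),   y_k = x_k + v_k,

with independent zero-mean Gaussian process/measurement noise.  Three
benchmark regulatory matrices are shipped: a sparse 4-gene network (8 of 16
entries nonzero), a denser 4-gene variant, and an 8-gene network; the named
experiment presets bundle a matrix with the horizon and noise levels used
in the benchmark studies (process and measurement variances of 0.01 per
gene at low noise, 0.1 at high noise; horizons of 10-40 points).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import grn_transition

__all__ = [
    "Dataset",
    "ExperimentPreset",
    "fixture_A",
    "simulate_grn",
    "experiment_preset",
    "PRESET_NAMES",
]

_FOUR_GENE = np.array(
    [
        [3.0, 0.0, 0.0, -4.5],
        [-2.9, 0.0, 5.0, 0.0],
        [-6.0, 4.0, 0.0, 0.0],
        [0.0, -5.0, 2.0, 0.0],
    ]
)

_FOUR_GENE_DENSE = np.array(
    [
        [3.0, -1.0, 0.0, -4.5],
        [-2.9, 0.0, 5.0, 1.0],
        [-6.0, 4.0, 0.0, -1.0],
        [1.0, -5.0, 2.0, 0.0],
    ]
)

_EIGHT_GENE = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.4, 3.2],
        [0.0, 0.0, 0.0, 4.1, 0.0, -2.4, 0.0, 4.1],
        [-5.0, 2.1, -1.5, 0.0, 4.5, 0.0, 2.1, 0.0],
        [0.0, 1.3, 2.5, -3.7, 1.8, 0.0, 0.0, -3.1],
        [0.0, 0.0, 0.0, -2.6, -3.2, 0.0, -1.0, 4.0],
        [-1.5, -1.8, 0.0, 3.4, 1.4, 1.1, 0.0, 1.7],
        [-1.8, 0.0, 0.0, -3.0, 1.1, 2.4, 0.0, 0.0],
        [-1.3, 0.0, -1.0, 0.0, 2.1, 0.0, 0.0, 2.2],
    ]
)

_FIXTURES = {
    "four_gene": _FOUR_GENE,
    "four_gene_dense": _FOUR_GENE_DENSE,
    "eight_gene": _EIGHT_GENE,
}


def fixture_A(name: str) -> np.ndarray:
    """Return a copy of a benchmark regulatory-coefficient matrix."""
    try:
        return _FIXTURES[name].copy()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {sorted(_FIXTURES)}"
        ) from None


def _as_cov(noise, n: int) -> np.ndarray:
    noise = np.asarray(noise, dtype=float)
    if noise.ndim == 0:
        return float(noise) * np.eye(n)
    if noise.shape != (n, n):
        raise ValueError(f"covariance shape {noise.shape} incompatible with n={n}")
    return noise


def _sample_factor(cov: np.ndarray) -> np.ndarray:
    # eigen factor: tolerant of exactly singular (e.g. zero) covariances
    w, V = np.linalg.eigh((cov + cov.T) / 2.0)
    if w.min() < -1e-10 * max(abs(w).max(), 1.0):
        raise ValueError("noise covariance is not positive semi-definite")
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


@dataclass(frozen=True)
class Dataset:
    """Observations with optional ground truth, plus the generating settings."""

    Y: np.ndarray
    X: Optional[np.ndarray] = None
    A_true: Optional[np.ndarray] = None
    U: Optional[np.ndarray] = None
    R: Optional[np.ndarray] = None
    seed: Optional[int] = None

    @property
    def K(self) -> int:
        return self.Y.shape[0]

    @property
    def n_genes(self) -> int:
        return self.Y.shape[1]

    def gene_names(self) -> list[str]:
        return [f"g{i+1}" for i in range(self.n_genes)]

    def to_files(self, csv_path, sidecar_path=None) -> None:
        """Write the expression CSV and a JSON sidecar with the truth."""
        pd.DataFrame(self.Y, columns=self.gene_names()).to_csv(csv_path, index=False)
        if sidecar_path is not None:
            side = {
                "seed": self.seed,
                "A_true": None if self.A_true is None else self.A_true.tolist(),
                "U": None if self.U is None else self.U.tolist(),
                "R": None if self.R is None else self.R.tolist(),
                "X": None if self.X is None else self.X.tolist(),
            }
            Path(sidecar_path).write_text(json.dumps(side, indent=1, sort_keys=True))

    @classmethod
    def from_files(cls, csv_path, sidecar_path=None) -> "Dataset":
        Y = pd.read_csv(csv_path).to_numpy(dtype=float)
        if sidecar_path is None:
            return cls(Y=Y)
        side = json.loads(Path(sidecar_path).read_text())

        def arr(key):
            v = side.get(key)
            return None if v is None else np.asarray(v, dtype=float)

        return cls(Y=Y, X=arr("X"), A_true=arr("A_true"), U=arr("U"), R=arr("R"),
                   seed=side.get("seed"))


def simulate_grn(
    A: np.ndarray,
    K: int,
    U,
    R,
    x0: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> Dataset:
    """Simulate a K-step trajectory of the sigmoid GRN model.

    ``x0`` defaults to a standard-normal draw (recorded via the seed); the
    first observation is ``y_1 = x_1 + v_1``.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if K < 2:
        raise ValueError(f"need K >= 2, got {K}")
    Ucov = _as_cov(U, n)
    Rcov = _as_cov(R, n)
    Su = _sample_factor(Ucov)
    Sv = _sample_factor(Rcov)
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal(n) if x0 is None else np.asarray(x0, dtype=float)
    X = np.empty((K, n))
    X[0] = x0
    for k in range(1, K):
        X[k] = grn_transition(X[k - 1], A) + Su @ rng.standard_normal(n)
    Y = X + (Sv @ rng.standard_normal((K, n)).T).T
    return Dataset(Y=Y, X=X, A_true=A.copy(), U=Ucov, R=Rcov, seed=seed)


@dataclass(frozen=True)
class ExperimentPreset:
    """Bundle of generator + algorithm settings for a named benchmark."""

    name: str
    A: np.ndarray
    K: int
    noise: float  # shared process/measurement variance per gene
    init_sd: float  # SD of the Gaussian theta initialization

    @property
    def n_genes(self) -> int:
        return self.A.shape[0]

    def simulate(self, seed: Optional[int] = None) -> Dataset:
        return simulate_grn(self.A, self.K, self.noise, self.noise, seed=seed)


_PRESETS = {
    "four_gene_lownoise": ("four_gene", 20, 0.01, np.sqrt(2.0)),
    "four_gene_highnoise": ("four_gene", 20, 0.1, np.sqrt(2.0)),
    "four_gene_K10": ("four_gene", 10, 0.01, np.sqrt(2.0)),
    "four_gene_K20": ("four_gene", 20, 0.01, np.sqrt(2.0)),
    "four_gene_dense": ("four_gene_dense", 20, 0.01, np.sqrt(2.0)),
    "eight_gene_K40": ("eight_gene", 40, 0.01, 1.0),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def experiment_preset(name: str) -> ExperimentPreset:
    try:
        fixture, K, noise, init_sd = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {sorted(_PRESETS)}"
        ) from None
    return ExperimentPreset(
        name=name, A=fixture_A(fixture), K=K, noise=noise, init_sd=init_sd
    )
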