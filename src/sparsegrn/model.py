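"""State-space model contract and the gene-regulatory-network instantiation.

The generic model is

    x_k = f(x_{k-1}, theta) + u_k,      u_k ~ N(0, U)
    y_k = h(x_k, theta) + v_k,          v_k ~ N(0, R)

with unknown (sparse) parameters ``theta`` in the transition.  For GRN
inference the transition is ``f(x, theta) = A g(x)`` where ``A`` is the
n-by-n regulatory-coefficient matrix (entry ``a_ij`` = regulation of gene i
by gene j; positive activates, negative represses) and ``g`` is the
element-wise logistic sigmoid, so expression levels feed back through a
saturating link.  The measurement is the identity: expression is observed
directly, up to noise.

``theta`` is the row-major vectorization of ``A`` (edge j -> i at index
``i * n + j``); every module uses this one packing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StateSpaceModel",
    "sigmoid_link",
    "grn_transition",
    "grn_measurement",
    "pack_theta",
    "unpack_theta",
    "grn_model",
    "linear_model",
    "read_adjacency",
    "write_adjacency",
    "write_edge_list",
]


def sigmoid_link(x: np.ndarray) -> np.ndarray:
    """Element-wise logistic sigmoid 1 / (1 + exp(-x)), overflow-safe."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def pack_theta(A: np.ndarray) -> np.ndarray:
    """Row-major vectorization of the coefficient matrix."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {A.shape}")
    return A.reshape(-1).copy()


def unpack_theta(theta: np.ndarray, n: Optional[int] = None) -> np.ndarray:
    """Inverse of :func:`pack_theta`."""
    theta = np.asarray(theta, dtype=float).reshape(-1)
    if n is None:
        n = int(round(np.sqrt(theta.size)))
    if n * n != theta.size:
        raise ValueError(
            f"theta of length {theta.size} is not a vectorized square matrix"
        )
    return theta.reshape(n, n).copy()


def grn_transition(x: np.ndarray, A: np.ndarray) -> np.ndarray:
    """One deterministic GRN step ``A @ sigmoid(x)``."""
    x = np.asarray(x, dtype=float)
    A = np.asarray(A, dtype=float)
    if A.shape[1] != x.shape[-1]:
        raise ValueError(f"A of shape {A.shape} cannot act on state of size {x.size}")
    return A @ sigmoid_link(x)


def grn_measurement(x: np.ndarray) -> np.ndarray:
    """Identity observation map; noise is added by the simulator."""
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class StateSpaceModel:
    """Contract consumed by the filter, smoother and E-step.

    ``basis`` is optional: when the transition is linear in theta,
    ``f(x, theta) = unpack(theta) @ basis(x)``, the E-step can reduce the
    Q-function to exact sufficient statistics instead of generic quadrature.
    """

    transition: Callable[[np.ndarray, np.ndarray], np.ndarray]
    measurement: Callable[[np.ndarray, np.ndarray], np.ndarray]
    state_dim: int
    obs_dim: int
    theta_dim: int
    theta_in_measurement: bool = False
    basis: Optional[Callable[[np.ndarray], np.ndarray]] = None


def grn_model(n: int) -> StateSpaceModel:
    """The n-gene sigmoid regulatory model with identity measurement."""
    return StateSpaceModel(
        transition=lambda x, theta: unpack_theta(theta, n) @ sigmoid_link(x),
        measurement=lambda x, theta: grn_measurement(x),
        state_dim=n,
        obs_dim=n,
        theta_dim=n * n,
        theta_in_measurement=False,
        basis=sigmoid_link,
    )


def linear_model(n: int) -> StateSpaceModel:
    """Linear transition ``x_k = F x_{k-1}`` with identity measurement.

    Used for oracle checks: sigma-point recursions are exact here.
    """
    return StateSpaceModel(
        transition=lambda x, theta: unpack_theta(theta, n) @ np.asarray(x, float),
        measurement=lambda x, theta: np.asarray(x, dtype=float),
        state_dim=n,
        obs_dim=n,
        theta_dim=n * n,
        theta_in_measurement=False,
        basis=lambda x: np.asarray(x, dtype=float),
    )


def write_adjacency(path, A: np.ndarray, genes: Optional[Sequence[str]] = None) -> None:
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    genes = list(genes) if genes is not None else [f"g{i+1}" for i in range(n)]
    pd.DataFrame(A, index=genes, columns=genes).to_csv(path)


def read_adjacency(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_edge_list(path, A: np.ndarray, genes: Optional[Sequence[str]] = None,
                    zero_tol: float = 0.0) -> None:
    """Signed edge list (source, target, weight) as TSV; entry a_ij is j -> i."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    genes = list(genes) if genes is not None else [f"g{i+1}" for i in range(n)]
    rows = [
        (genes[j], genes[i], A[i, j])
        for i in range(n)
        for j in range(n)
        if abs(A[i, j]) > zero_tol
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )
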