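"""Least-squares support vector machine regression with an RBF kernel.

Training solves the (l+1)x(l+1) saddle-point linear system arising from the
KKT conditions of the equality-constrained least-squares SVM:

    [ 0    1^T        ] [ b     ]   [ 0 ]
    [ 1    K + I/g    ] [ alpha ] = [ y ]

and prediction evaluates y(x) = sum_i alpha_i K(x, x_i) + b.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

__all__ = [
    "Hyperparams",
    "LssvmModel",
    "NumericalError",
    "rbf_kernel",
    "kernel_matrix",
    "kernel_cross",
    "fit",
    "predict",
]

FORMAT_VERSION = 1

#: solves with an estimated condition number beyond this raise NumericalError
CONDITION_LIMIT = 1e12


class NumericalError(RuntimeError):
    """Raised when the training system is numerically unreliable."""


@dataclass(frozen=True)
class Hyperparams:
    """Regularization weight g and RBF kernel width sigma, both > 0."""

    g: float
    sigma: float

    def __post_init__(self) -> None:
        for name in ("g", "sigma"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive and finite")


def rbf_kernel(x: np.ndarray, xi: np.ndarray, sigma: float) -> float:
    """Gaussian kernel exp(-||x - xi||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(x, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if x.shape != xi.shape:
        raise ValueError("x and xi must have the same length")
    sq = float(np.sum((x - xi) ** 2))
    return float(np.exp(-sq / (2.0 * sigma**2)))


def kernel_matrix(X: np.ndarray, sigma: float) -> np.ndarray:
    """Gram matrix of the RBF kernel over the rows of X."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sq = cdist(X, X, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma**2))


def kernel_cross(Xq: np.ndarray, Xt: np.ndarray, sigma: float) -> np.ndarray:
    """Kernel evaluations between query rows and training rows."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
    Xt = np.atleast_2d(np.asarray(Xt, dtype=float))
    sq = cdist(Xq, Xt, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma**2))


@dataclass
class LssvmModel:
    train_inputs: np.ndarray  # (l, n_features)
    dual_coeffs: np.ndarray  # (l,)
    bias: float
    hyperparams: Hyperparams

    def predict(self, x: np.ndarray) -> np.ndarray | float:
        return predict(self, x)

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "g": self.hyperparams.g,
            "sigma": self.hyperparams.sigma,
            "bias": self.bias,
            "dual_coeffs": self.dual_coeffs.tolist(),
            "train_inputs": self.train_inputs.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LssvmModel":
        version = payload.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported model format_version: {version!r}")
        return cls(
            train_inputs=np.asarray(payload["train_inputs"], dtype=float),
            dual_coeffs=np.asarray(payload["dual_coeffs"], dtype=float),
            bias=float(payload["bias"]),
            hyperparams=Hyperparams(g=float(payload["g"]), sigma=float(payload["sigma"])),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "LssvmModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit(X: np.ndarray, y: np.ndarray, hp: Hyperparams) -> LssvmModel:
    """Train by a dense partial-pivoting solve of the saddle-point system.

    Raises :class:`NumericalError` when the estimated condition number of
    the system exceeds ``CONDITION_LIMIT`` (increase sigma or decrease g).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    l = X.shape[0]
    if y.size != l:
        raise ValueError("X and y must have the same number of rows")
    if l < 1:
        raise ValueError("need at least one training sample")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("training data must be finite")

    K = kernel_matrix(X, hp.sigma)
    system = np.zeros((l + 1, l + 1))
    system[0, 1:] = 1.0
    system[1:, 0] = 1.0
    system[1:, 1:] = K + np.eye(l) / hp.g
    rhs = np.concatenate(([0.0], y))

    lu, piv = scipy.linalg.lu_factor(system)
    anorm = np.linalg.norm(system, 1)
    rcond, _ = scipy.linalg.get_lapack_funcs(("gecon",), (system,))[0](lu, anorm)
    if not np.isfinite(rcond) or rcond < 1.0 / CONDITION_LIMIT:
        cond = np.inf if rcond == 0 else 1.0 / rcond
        raise NumericalError(
            f"training system ill-conditioned (condition estimate {cond:.2e} > "
            f"{CONDITION_LIMIT:.0e}); increase sigma or decrease g"
        )
    solution = scipy.linalg.lu_solve((lu, piv), rhs)
    return LssvmModel(
        train_inputs=X.copy(),
        dual_coeffs=solution[1:],
        bias=float(solution[0]),
        hyperparams=hp,
    )


def predict(model: LssvmModel, x: np.ndarray) -> np.ndarray | float:
    """Evaluate the dual predictor at one query vector or a matrix of rows."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Xq = np.atleast_2d(x)
    if Xq.shape[1] != model.train_inputs.shape[1]:
        raise ValueError(
            f"query has {Xq.shape[1]} features, model expects "
            f"{model.train_inputs.shape[1]}"
        )
    Kq = kernel_cross(Xq, model.train_inputs, model.hyperparams.sigma)
    out = Kq @ model.dual_coeffs + model.bias
    return float(out[0]) if single else out
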