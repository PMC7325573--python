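"""Soft-sensor identification: normalization, batch splitting, metaheuristic
hyperparameter tuning with holdout-RMSE fitness, and evaluation metrics.

The regressor maps the six same-time auxiliary channels
(T, pH, u1, DO, u2, u3) to product concentration P.  Optionally the
previous product sample can be appended as a seventh feature
(``include_lagged_output``), which gives the predictor an autoregressive
handle for multi-step control; this is off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import lssvm
from .lssvm import Hyperparams, LssvmModel
from .optimizers import OptimizerConfig, OptimizerResult, SearchSpace, minimize
from .plant_sim import BatchRecord

__all__ = [
    "FEATURE_COLUMNS",
    "TARGET_COLUMN",
    "DEFAULT_TUNING_BOUNDS",
    "NormalizationStats",
    "DatasetSplit",
    "SoftSensor",
    "TuningResult",
    "normalize",
    "assemble_regression_table",
    "rmse",
    "mae",
    "mape",
    "cv_fitness",
    "make_cv_fitness",
    "tune",
    "split_batches",
    "evaluate_sensor",
]

FEATURE_COLUMNS = ["T_C", "pH", "u1_rpm", "DO_pct", "u2_vvm", "u3_mlh"]
TARGET_COLUMN = "P_gL"

#: default hyperparameter search box, coordinate order (g, sigma)
DEFAULT_TUNING_BOUNDS = SearchSpace(lower=[1.0, 0.001], upper=[10000.0, 0.1])

_WORST_FITNESS = 1e12  # sentinel returned when a candidate fit fails numerically


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel min/max for the affine map onto [-1, 1]."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.minimum, dtype=float))
        hi = np.atleast_1d(np.asarray(self.maximum, dtype=float))
        object.__setattr__(self, "minimum", lo)
        object.__setattr__(self, "maximum", hi)
        if lo.shape != hi.shape:
            raise ValueError("minimum/maximum shape mismatch")
        if not np.all(hi > lo):
            bad = np.where(hi <= lo)[0]
            raise ValueError(
                f"constant channel(s) at index {bad.tolist()}: max must exceed min"
            )

    @classmethod
    def fit(cls, table: np.ndarray) -> "NormalizationStats":
        table = np.atleast_2d(np.asarray(table, dtype=float))
        return cls(minimum=table.min(axis=0), maximum=table.max(axis=0))

    def normalize(self, table: np.ndarray) -> np.ndarray:
        table = np.asarray(table, dtype=float)
        return 2.0 * (table - self.minimum) / (self.maximum - self.minimum) - 1.0

    def denormalize(self, table: np.ndarray) -> np.ndarray:
        table = np.asarray(table, dtype=float)
        return self.minimum + (table + 1.0) * (self.maximum - self.minimum) / 2.0

    def to_dict(self) -> dict:
        return {"minimum": self.minimum.tolist(), "maximum": self.maximum.tolist()}

    @classmethod
    def from_dict(cls, payload: dict) -> "NormalizationStats":
        return cls(minimum=payload["minimum"], maximum=payload["maximum"])


def normalize(table: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Map each channel affinely so stats.min -> -1 and stats.max -> +1.

    Values outside the fitted range map outside [-1, 1]; no clipping.
    """
    return stats.normalize(table)


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[int, ...]
    cv: tuple[int, ...]
    test: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "train", tuple(self.train))
        object.__setattr__(self, "cv", tuple(self.cv))
        object.__setattr__(self, "test", tuple(self.test))
        groups = (set(self.train), set(self.cv), set(self.test))
        if not self.train or not self.cv:
            raise ValueError("train and cv splits must be non-empty")
        total = sum(len(g) for g in groups)
        if len(groups[0] | groups[1] | groups[2]) != total:
            raise ValueError("splits must be pairwise disjoint")


def split_batches(
    n_batches: int,
    counts: tuple[int, int, int] = (6, 2, 2),
    rng: Optional[np.random.Generator] = None,
) -> DatasetSplit:
    """Random disjoint train/cv/test batch-index split (default 6/2/2)."""
    if sum(counts) > n_batches:
        raise ValueError(f"split {counts} needs more batches than available ({n_batches})")
    rng = rng or np.random.default_rng()
    order = rng.permutation(n_batches)
    a, b, c = counts
    return DatasetSplit(
        train=tuple(int(i) for i in order[:a]),
        cv=tuple(int(i) for i in order[a : a + b]),
        test=tuple(int(i) for i in order[a + b : a + b + c]),
    )


def assemble_regression_table(
    batches: Sequence[BatchRecord], include_lagged_output: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Stack batches into a design matrix X and target vector y.

    One row per 15-min sample, x = [T, pH, u1, DO, u2, u3] (plus P(t-1)
    when ``include_lagged_output``), y = P.  Batch order then time order.
    With the lagged feature the first sample of each batch is dropped.
    """
    if not batches:
        raise ValueError("no batches supplied")
    xs, ys = [], []
    for rec in batches:
        features = np.column_stack([rec.T, rec.pH, rec.u1, rec.DO, rec.u2, rec.u3])
        target = rec.P
        if include_lagged_output:
            features = np.column_stack([features[1:], target[:-1]])
            target = target[1:]
        xs.append(features)
        ys.append(target)
    return np.vstack(xs), np.concatenate(ys)


def rmse(actual: np.ndarray, predicted: np.ndarray) -> float:
    actual, predicted = _check_pair(actual, predicted)
    return float(np.sqrt(np.mean((actual - predicted) ** 2)))


def mae(actual: np.ndarray, predicted: np.ndarray) -> float:
    actual, predicted = _check_pair(actual, predicted)
    return float(np.mean(np.abs(actual - predicted)))


def mape(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute fractional error (no x100 factor)."""
    actual, predicted = _check_pair(actual, predicted)
    if np.any(actual == 0):
        raise ValueError("mape undefined when an actual value is zero")
    return float(np.mean(np.abs(actual - predicted) / np.abs(actual)))


def _check_pair(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.size != predicted.size or actual.size < 1:
        raise ValueError("actual and predicted must have equal length >= 1")
    return actual, predicted


def make_cv_fitness(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_cv: np.ndarray,
    y_cv: np.ndarray,
):
    """Fitness closure over (g, sigma) with cached pairwise distances.

    Only the kernel width changes between calls, so the squared-distance
    matrices are computed once; a numerically failed fit returns a large
    sentinel so the optimizer routes around it.
    """
    from scipy.spatial.distance import cdist
    import scipy.linalg

    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float).ravel()
    X_cv = np.atleast_2d(np.asarray(X_cv, dtype=float))
    y_cv = np.asarray(y_cv, dtype=float).ravel()
    l = X_train.shape[0]
    d_tt = cdist(X_train, X_train, metric="sqeuclidean")
    d_ct = cdist(X_cv, X_train, metric="sqeuclidean")
    rhs = np.concatenate(([0.0], y_train))

    def fitness(candidate: np.ndarray) -> float:
        g, sigma = float(candidate[0]), float(candidate[1])
        if g <= 0 or sigma <= 0:
            return _WORST_FITNESS
        denom = 2.0 * sigma**2
        system = np.zeros((l + 1, l + 1))
        system[0, 1:] = 1.0
        system[1:, 0] = 1.0
        system[1:, 1:] = np.exp(-d_tt / denom) + np.eye(l) / g
        try:
            solution = scipy.linalg.solve(system, rhs)
        except scipy.linalg.LinAlgError:
            return _WORST_FITNESS
        if not np.all(np.isfinite(solution)):
            return _WORST_FITNESS
        pred = np.exp(-d_ct / denom) @ solution[1:] + solution[0]
        return rmse(y_cv, pred)

    return fitness


def cv_fitness(
    candidate: np.ndarray,
    train_table: tuple[np.ndarray, np.ndarray],
    cv_table: tuple[np.ndarray, np.ndarray],
) -> float:
    """Holdout RMSE of an LSSVM fitted at candidate = (g, sigma).

    Tables are (X, y) pairs already on the normalized scale.
    """
    return make_cv_fitness(*train_table, *cv_table)(candidate)


@dataclass
class SoftSensor:
    """Trained predictor plus its normalization, operating in physical units."""

    model: LssvmModel
    stats: NormalizationStats  # channels: features then target (last)
    include_lagged_output: bool = False

    @property
    def n_features(self) -> int:
        return self.model.train_inputs.shape[1]

    def predict(self, X_physical: np.ndarray) -> np.ndarray | float:
        """Predict product concentration (physical units) from physical features."""
        X_physical = np.asarray(X_physical, dtype=float)
        single = X_physical.ndim == 1
        Xq = np.atleast_2d(X_physical)
        if Xq.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {Xq.shape[1]}"
            )
        feat_stats = NormalizationStats(
            self.stats.minimum[: self.n_features],
            self.stats.maximum[: self.n_features],
        )
        yn = np.atleast_1d(self.model.predict(feat_stats.normalize(Xq)))
        lo, hi = self.stats.minimum[-1], self.stats.maximum[-1]
        y = lo + (yn + 1.0) * (hi - lo) / 2.0
        return float(y[0]) if single else y

    def predict_normalized(self, X_normalized: np.ndarray) -> np.ndarray | float:
        return self.model.predict(X_normalized)

    def to_dict(self) -> dict:
        return {
            "format_version": lssvm.FORMAT_VERSION,
            "model": self.model.to_dict(),
            "stats": self.stats.to_dict(),
            "include_lagged_output": self.include_lagged_output,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SoftSensor":
        return cls(
            model=LssvmModel.from_dict(payload["model"]),
            stats=NormalizationStats.from_dict(payload["stats"]),
            include_lagged_output=bool(payload.get("include_lagged_output", False)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SoftSensor":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class TuningResult:
    best_hyperparams: Hyperparams
    cv_rmse: float  # on the normalized target scale
    optimizer_result: OptimizerResult
    sensor: SoftSensor


def tune(
    train_batches: Sequence[BatchRecord],
    cv_batches: Sequence[BatchRecord],
    bounds: SearchSpace = DEFAULT_TUNING_BOUNDS,
    opt_config: Optional[OptimizerConfig] = None,
    algorithm: str = "gwo",
    include_lagged_output: bool = False,
    max_train_rows: Optional[int] = None,
) -> TuningResult:
    """Search the (g, sigma) box for the LSSVM minimizing holdout RMSE.

    Normalization statistics are fitted on the training batches only, then
    applied to both tables.  The returned sensor is refitted on the training
    table at the best hyperparameters.  ``max_train_rows`` subsamples the
    training rows with a uniform stride (desk-scale speed knob; the full
    table is used when None).
    """
    if not train_batches or not cv_batches:
        raise ValueError("train and cv batch lists must be non-empty")
    if bounds.dim != 2:
        raise ValueError("tuning bounds must be 2-D with coordinates (g, sigma)")
    opt_config = opt_config or OptimizerConfig()

    X_train, y_train = assemble_regression_table(train_batches, include_lagged_output)
    X_cv, y_cv = assemble_regression_table(cv_batches, include_lagged_output)
    if max_train_rows is not None and X_train.shape[0] > max_train_rows:
        stride = int(np.ceil(X_train.shape[0] / max_train_rows))
        X_train, y_train = X_train[::stride], y_train[::stride]

    stats = NormalizationStats.fit(
        np.column_stack([X_train, y_train])
    )
    feat_stats = NormalizationStats(stats.minimum[:-1], stats.maximum[:-1])
    target_stats = NormalizationStats(stats.minimum[-1:], stats.maximum[-1:])
    Xtr_n = feat_stats.normalize(X_train)
    ytr_n = target_stats.normalize(y_train[:, None]).ravel()
    Xcv_n = feat_stats.normalize(X_cv)
    ycv_n = target_stats.normalize(y_cv[:, None]).ravel()

    fitness = make_cv_fitness(Xtr_n, ytr_n, Xcv_n, ycv_n)
    result = minimize(algorithm, fitness, bounds, opt_config)

    best = Hyperparams(g=float(result.best_position[0]), sigma=float(result.best_position[1]))
    model = lssvm.fit(Xtr_n, ytr_n, best)
    sensor = SoftSensor(
        model=model, stats=stats, include_lagged_output=include_lagged_output
    )
    return TuningResult(
        best_hyperparams=best,
        cv_rmse=float(result.best_fitness),
        optimizer_result=result,
        sensor=sensor,
    )


def evaluate_sensor(
    sensor: SoftSensor, batches: Sequence[BatchRecord]
) -> dict[str, dict[str, float]]:
    """RMSE/MAE/MAPE of a sensor on held-out batches, both scales.

    Returns ``{"physical": {...}, "normalized": {...}}``; MAPE is reported
    on the physical scale only (normalized targets cross zero).
    """
    X, y = assemble_regression_table(batches, sensor.include_lagged_output)
    pred = np.atleast_1d(sensor.predict(X))
    target_stats = NormalizationStats(sensor.stats.minimum[-1:], sensor.stats.maximum[-1:])
    yn = target_stats.normalize(y[:, None]).ravel()
    pn = target_stats.normalize(pred[:, None]).ravel()
    physical = {"rmse": rmse(y, pred), "mae": mae(y, pred)}
    try:
        physical["mape"] = mape(y, pred)
    except ValueError:
        physical["mape"] = float("nan")
    return {
        "physical": physical,
        "normalized": {"rmse": rmse(yn, pn), "mae": mae(yn, pn)},
    }
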