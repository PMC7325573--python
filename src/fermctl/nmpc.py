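"""Receding-horizon predictive control with a metaheuristic rolling optimizer.

Each sampling instant the controller minimizes

    J = sum_j q_out * (y_pred(t+j) - y_ref(t+j))^2  +  sum_j r_in * ||du_j||^2

over the admissible input-increment box using GWO (or PSO), applies only the
first increment u(t+1) = u(t) + du, and corrects predictions with an
additive output-feedback bias e = y_measured - y_predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .optimizers import OptimizerConfig, OptimizerResult, SearchSpace, minimize
from .softsensor import SoftSensor

__all__ = [
    "ControlConstraints",
    "ControllerConfig",
    "ControlState",
    "StepResult",
    "ClosedLoopLog",
    "Plant",
    "ModelPlant",
    "objective",
    "predict_corrected",
    "solve_step",
    "run_closed_loop",
    "step_reference",
    "sigmoid_reference",
    "load_reference_csv",
]

SAMPLE_DT_H = 0.25


@dataclass(frozen=True)
class ControlConstraints:
    """Boxes on inputs, input increments and the controlled output."""

    u_lower: np.ndarray = field(default_factory=lambda: np.array([316.0, 0.1, 51.0]))
    u_upper: np.ndarray = field(default_factory=lambda: np.array([345.0, 1.65, 110.0]))
    du_lower: np.ndarray = field(default_factory=lambda: np.array([-15.0, -1.0, -30.0]))
    du_upper: np.ndarray = field(default_factory=lambda: np.array([15.0, 1.0, 30.0]))
    y_lower: float = 0.0
    y_upper: float = 45.0

    def __post_init__(self) -> None:
        for name in ("u_lower", "u_upper", "du_lower", "du_upper"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        if self.u_lower.shape != self.u_upper.shape or self.u_lower.ndim != 1:
            raise ValueError("u bounds must be 1-D vectors of equal length")
        if not np.all(self.u_lower < self.u_upper):
            raise ValueError("u_lower < u_upper must hold componentwise")
        if not np.all(self.du_lower < self.du_upper):
            raise ValueError("du_lower < du_upper must hold componentwise")
        if not np.all(np.isfinite(self.du_lower)) or not np.all(np.isfinite(self.du_upper)):
            raise ValueError("increment bounds must be finite")
        if self.y_lower >= self.y_upper:
            raise ValueError("y_lower < y_upper must hold")

    @property
    def n_inputs(self) -> int:
        return self.u_lower.size


@dataclass(frozen=True)
class ControllerConfig:
    n_pred: int = 1
    n_con: int = 1
    q_out: float = 1.0
    r_in: float = 0.001
    constraints: ControlConstraints = field(default_factory=ControlConstraints)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    algorithm: str = "gwo"
    initial_u: np.ndarray = field(default_factory=lambda: np.array([326.0, 0.1, 88.0]))
    penalty_weight: float = 1e6  # soft-constraint weight for u/y box violations

    def __post_init__(self) -> None:
        object.__setattr__(self, "initial_u", np.asarray(self.initial_u, dtype=float))
        if self.n_pred < 1 or self.n_con < 1 or self.n_con > self.n_pred:
            raise ValueError("need 1 <= n_con <= n_pred")
        if self.q_out < 0 or self.r_in < 0:
            raise ValueError("q_out and r_in must be >= 0")
        c = self.constraints
        if np.any(self.initial_u < c.u_lower) or np.any(self.initial_u > c.u_upper):
            raise ValueError("initial_u must lie inside the input box")


@dataclass
class ControlState:
    current_u: np.ndarray
    last_measured_y: float = float("nan")
    bias: float = 0.0
    time_index: int = 0

    def __post_init__(self) -> None:
        self.current_u = np.asarray(self.current_u, dtype=float)


@dataclass
class StepResult:
    du: np.ndarray  # applied first increment (after any boundary clamping)
    new_u: np.ndarray
    predicted_y: float  # raw model prediction at the applied inputs
    corrected_y: float  # predicted_y + bias
    objective_value: float
    clamped: bool  # True when u(t)+du left the input box and was clamped
    optimizer_result: OptimizerResult


class Plant(Protocol):
    """Minimal closed-loop plant interface (one 15-min sample per step)."""

    def measure(self) -> dict[str, float]: ...

    def step(self, u: np.ndarray) -> None: ...


class ModelPlant:
    """Plant that IS the prediction model (plus an optional constant offset).

    Useful for perfect-model consistency checks: the measured output is the
    sensor's own prediction at the applied inputs with the auxiliary
    channels held fixed.
    """

    def __init__(
        self,
        sensor: SoftSensor,
        aux: Sequence[float],  # fixed (T, pH, DO)
        initial_u: np.ndarray,
        offset: float = 0.0,
    ) -> None:
        self.sensor = sensor
        self.aux = np.asarray(aux, dtype=float)
        self.offset = float(offset)
        self.u = np.asarray(initial_u, dtype=float).copy()

    def _features(self, u: np.ndarray) -> np.ndarray:
        t, ph, do = self.aux
        return np.array([t, ph, u[0], do, u[1], u[2]])

    def measure(self) -> dict[str, float]:
        y = float(self.sensor.predict(self._features(self.u))) + self.offset
        t, ph, do = self.aux
        return {"T": t, "pH": ph, "DO": do, "P": y}

    def step(self, u: np.ndarray) -> None:
        self.u = np.asarray(u, dtype=float).copy()


def predict_corrected(sensor: SoftSensor, aux_features: np.ndarray, bias: float) -> float:
    """Model prediction (physical units) plus the output-feedback bias."""
    return float(sensor.predict(np.asarray(aux_features, dtype=float))) + float(bias)


def _assemble_features(aux_now: Sequence[float], u: np.ndarray) -> np.ndarray:
    """Interleave fixed auxiliary measurements with candidate inputs.

    ``aux_now`` is (T, pH, DO); feature order is (T, pH, u1, DO, u2, u3).
    """
    t, ph, do = (float(v) for v in aux_now)
    return np.array([t, ph, u[0], do, u[1], u[2]])


def objective(
    du_candidate: np.ndarray,
    state: ControlState,
    yref_future: np.ndarray,
    sensor: SoftSensor,
    aux_now: Sequence[float],
    config: ControllerConfig,
) -> float:
    """Horizon cost of a stacked increment candidate (length 3 * n_con).

    Candidates whose accumulated inputs leave the input box, or whose
    corrected prediction leaves the output band, incur a quadratic penalty
    instead of being rejected, keeping the fitness total for the optimizer.
    """
    c = config.constraints
    m = c.n_inputs
    du = np.asarray(du_candidate, dtype=float).reshape(config.n_con, m)
    yref_future = np.asarray(yref_future, dtype=float)
    if yref_future.size < config.n_pred:
        raise ValueError("yref_future must cover the prediction horizon")

    cost = 0.0
    u = state.current_u.copy()
    penalty = 0.0
    for j in range(config.n_pred):
        if j < config.n_con:
            u = u + du[j]
            cost += config.r_in * float(du[j] @ du[j])
        over = np.maximum(u - c.u_upper, 0.0) + np.maximum(c.u_lower - u, 0.0)
        penalty += config.penalty_weight * float(over @ over)
        u_eval = np.clip(u, c.u_lower, c.u_upper)
        y_hat = predict_corrected(sensor, _assemble_features(aux_now, u_eval), state.bias)
        y_over = max(y_hat - c.y_upper, 0.0) + max(c.y_lower - y_hat, 0.0)
        penalty += config.penalty_weight * y_over**2
        cost += config.q_out * (y_hat - yref_future[j]) ** 2
    return cost + penalty


def solve_step(
    state: ControlState,
    yref_future: np.ndarray,
    sensor: SoftSensor,
    aux_now: Sequence[float],
    config: ControllerConfig,
    seed: Optional[int] = None,
) -> StepResult:
    """Optimize the increment box and apply the first increment.

    Returns the applied increment, the new (clamped-if-needed) inputs, and
    the raw/bias-corrected predictions at those inputs.  ``seed`` overrides
    the optimizer seed for per-step reproducibility.
    """
    c = config.constraints
    space = SearchSpace(
        lower=np.tile(c.du_lower, config.n_con),
        upper=np.tile(c.du_upper, config.n_con),
    )
    opt_config = config.optimizer if seed is None else replace(config.optimizer, seed=seed)

    def fitness(candidate: np.ndarray) -> float:
        return objective(candidate, state, yref_future, sensor, aux_now, config)

    result = minimize(config.algorithm, fitness, space, opt_config)
    du_first = result.best_position[: c.n_inputs]
    raw_u = state.current_u + du_first
    new_u = np.clip(raw_u, c.u_lower, c.u_upper)
    clamped = bool(np.any(np.abs(new_u - raw_u) > 1e-12))
    applied_du = new_u - state.current_u
    predicted = float(sensor.predict(_assemble_features(aux_now, new_u)))
    return StepResult(
        du=applied_du,
        new_u=new_u,
        predicted_y=predicted,
        corrected_y=predicted + state.bias,
        objective_value=float(result.best_fitness),
        clamped=clamped,
        optimizer_result=result,
    )


@dataclass
class ClosedLoopLog:
    """Per-step closed-loop records with CSV round-tripping."""

    time_h: list[float] = field(default_factory=list)
    yref: list[float] = field(default_factory=list)
    u1: list[float] = field(default_factory=list)
    u2: list[float] = field(default_factory=list)
    u3: list[float] = field(default_factory=list)
    du1: list[float] = field(default_factory=list)
    du2: list[float] = field(default_factory=list)
    du3: list[float] = field(default_factory=list)
    predicted_y: list[float] = field(default_factory=list)
    corrected_y: list[float] = field(default_factory=list)
    measured_y: list[float] = field(default_factory=list)
    objective: list[float] = field(default_factory=list)
    clamped: list[bool] = field(default_factory=list)

    def append(self, *, time_h, yref, u, du, predicted_y, corrected_y, measured_y,
               objective, clamped) -> None:
        self.time_h.append(float(time_h))
        self.yref.append(float(yref))
        self.u1.append(float(u[0]))
        self.u2.append(float(u[1]))
        self.u3.append(float(u[2]))
        self.du1.append(float(du[0]))
        self.du2.append(float(du[1]))
        self.du3.append(float(du[2]))
        self.predicted_y.append(float(predicted_y))
        self.corrected_y.append(float(corrected_y))
        self.measured_y.append(float(measured_y))
        self.objective.append(float(objective))
        self.clamped.append(bool(clamped))

    def __len__(self) -> int:
        return len(self.time_h)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time_h,
                "yref_gL": self.yref,
                "u1_rpm": self.u1,
                "u2_vvm": self.u2,
                "u3_mlh": self.u3,
                "du1_rpm": self.du1,
                "du2_vvm": self.du2,
                "du3_mlh": self.du3,
                "predicted_y_gL": self.predicted_y,
                "corrected_y_gL": self.corrected_y,
                "measured_y_gL": self.measured_y,
                "objective": self.objective,
                "clamped": self.clamped,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self, constraints: Optional[ControlConstraints] = None) -> dict:
        c = constraints or ControlConstraints()
        u = np.column_stack([self.u1, self.u2, self.u3])
        du = np.column_stack([self.du1, self.du2, self.du3])
        tol = 1e-9
        u_violations = int(
            np.sum(np.any((u < c.u_lower - tol) | (u > c.u_upper + tol), axis=1))
        )
        du_violations = int(
            np.sum(np.any((du < c.du_lower - tol) | (du > c.du_upper + tol), axis=1))
        )
        err = np.asarray(self.measured_y) - np.asarray(self.yref)
        return {
            "steps": len(self),
            "tracking_rmse": float(np.sqrt(np.mean(err**2))),
            "tracking_mae": float(np.mean(np.abs(err))),
            "u_violations": u_violations,
            "du_violations": du_violations,
            "clamped_steps": int(np.sum(self.clamped)),
        }


def run_closed_loop(
    plant: Plant,
    sensor: SoftSensor,
    reference: np.ndarray,
    config: ControllerConfig,
    steps: int,
    seed: Optional[int] = None,
) -> ClosedLoopLog:
    """Receding-horizon loop: measure, correct, optimize, apply, advance.

    ``reference`` indexes the desired output per sample; the preview
    ``yref_future`` is taken from it (held at the last value past the end).
    Only the first increment of every solve is applied.  Per-step optimizer
    seeds are spawned deterministically from ``seed``.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.size < steps + 1:
        reference = np.concatenate(
            [reference, np.full(steps + 1 - reference.size, reference[-1])]
        )
    state = ControlState(current_u=config.initial_u.copy())
    log = ClosedLoopLog()
    prev_raw_prediction: Optional[float] = None
    step_seeds = (
        np.random.SeedSequence(seed).spawn(steps) if seed is not None else [None] * steps
    )

    for t in range(steps):
        meas = plant.measure()
        state.last_measured_y = meas["P"]
        if prev_raw_prediction is not None:
            state.bias = meas["P"] - prev_raw_prediction
        aux_now = (meas["T"], meas["pH"], meas["DO"])
        horizon = reference[t + 1 : t + 1 + config.n_pred]
        if horizon.size < config.n_pred:
            horizon = np.concatenate(
                [horizon, np.full(config.n_pred - horizon.size, reference[-1])]
            )
        step_seed = (
            int(step_seeds[t].generate_state(1)[0]) if step_seeds[t] is not None else None
        )
        result = solve_step(state, horizon, sensor, aux_now, config, seed=step_seed)
        state.current_u = result.new_u
        plant.step(result.new_u)
        prev_raw_prediction = result.predicted_y
        log.append(
            time_h=t * SAMPLE_DT_H,
            yref=reference[t + 1],
            u=result.new_u,
            du=result.du,
            predicted_y=result.predicted_y,
            corrected_y=result.corrected_y,
            measured_y=meas["P"],
            objective=result.objective_value,
            clamped=result.clamped,
        )
        state.time_index += 1
    return log


def step_reference(
    n_steps: int,
    low: float = 8.0,
    high: float = 28.0,
    period_h: float = 8.0,
    switch_until_h: float = 44.0,
    dt_h: float = SAMPLE_DT_H,
) -> np.ndarray:
    """Piecewise-constant reference with periodic jumps over the first
    ``switch_until_h`` hours, then held at ``high``."""
    t = np.arange(n_steps + 1) * dt_h
    phase = np.floor(t / period_h).astype(int)
    ref = np.where(phase % 2 == 0, low, high)
    ref = np.where(t >= switch_until_h, high, ref)
    return ref.astype(float)


def sigmoid_reference(
    n_steps: int,
    y_start: float = 1.0,
    y_end: float = 34.0,
    midpoint_h: float = 24.0,
    rate: float = 0.12,
    dt_h: float = SAMPLE_DT_H,
) -> np.ndarray:
    """Smooth monotone (logistic) reference trajectory for the real case."""
    t = np.arange(n_steps + 1) * dt_h
    return y_start + (y_end - y_start) / (1.0 + np.exp(-rate * (t - midpoint_h)))


def load_reference_csv(path: str | Path) -> np.ndarray:
    """Two-column reference CSV (time_h, yref_gL) -> reference vector."""
    frame = pd.read_csv(path)
    for col in ("time_h", "yref_gL"):
        if col not in frame.columns:
            raise ValueError(f"reference CSV missing column: {col}")
    return frame["yref_gL"].to_numpy(float)
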