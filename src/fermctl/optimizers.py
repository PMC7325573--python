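"""Population-based bound-constrained minimizers.

Two swarm algorithms behind a single contract: the grey-wolf optimizer
(GWO), in which the pack moves toward the three best-so-far solutions
(alpha, beta, delta) with a stochastically shrinking step, and a canonical
global-best particle swarm (PSO) used as a baseline.  Both are elitist:
the reported best-so-far trace is non-increasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

Fitness = Callable[[np.ndarray], float]

__all__ = [
    "SearchSpace",
    "OptimizerConfig",
    "OptimizerResult",
    "control_parameter",
    "coefficient_vectors",
    "update_position",
    "clip_to_bounds",
    "gwo_minimize",
    "pso_minimize",
    "minimize",
]


@dataclass(frozen=True)
class SearchSpace:
    """A box [lower, upper] in R^dim."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.ndim != 1 or upper.shape != lower.shape:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if lower.size < 1:
            raise ValueError("search space must have dim >= 1")
        if not np.all(np.isfinite(lower)) or not np.all(np.isfinite(upper)):
            raise ValueError("bounds must be finite")
        if not np.all(lower < upper):
            raise ValueError("lower[i] < upper[i] must hold for every coordinate")

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, position: np.ndarray, atol: float = 1e-12) -> bool:
        p = np.asarray(position, dtype=float)
        return bool(
            np.all(p >= self.lower - atol) and np.all(p <= self.upper + atol)
        )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n uniform points in the box, one per row."""
        return self.lower + rng.random((n, self.dim)) * self.width


@dataclass(frozen=True)
class OptimizerConfig:
    population_size: int = 30
    max_iterations: int = 100
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class OptimizerResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness after each iteration
    evaluations: int

    def trace_records(self) -> list[dict]:
        """JSON-friendly per-iteration convergence records."""
        return [
            {"iteration": i, "best_fitness": float(f)}
            for i, f in enumerate(self.trace)
        ]


def control_parameter(iteration: int, max_iterations: int) -> float:
    """Exploration coefficient, decreasing linearly from 2 to 0."""
    if max_iterations < 1:
        raise ValueError("max_iterations must be positive")
    if iteration < 0 or iteration > max_iterations:
        raise ValueError(
            f"iteration must lie in [0, {max_iterations}], got {iteration}"
        )
    return 2.0 * (1.0 - iteration / max_iterations)


def coefficient_vectors(
    a: float, dim: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the stochastic step coefficients A = 2*a*r1 - a and C = 2*r2.

    Fresh uniform draws per component; callers draw separately per leader.
    A lies in [-a, a] componentwise, C in [0, 2].
    """
    if not 0.0 <= a <= 2.0:
        raise ValueError("a must lie in [0, 2]")
    r1 = rng.random(dim)
    r2 = rng.random(dim)
    return 2.0 * a * r1 - a, 2.0 * r2


def update_position(
    current: np.ndarray,
    alpha_pos: np.ndarray,
    beta_pos: np.ndarray,
    delta_pos: np.ndarray,
    a: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move one wolf toward the three leaders.

    For each leader L: D = |C * L - X|, candidate = L - A * D with fresh
    (A, C) per leader; the new position is the mean of the three candidates.
    """
    current = np.asarray(current, dtype=float)
    candidates = []
    for leader in (alpha_pos, beta_pos, delta_pos):
        leader = np.asarray(leader, dtype=float)
        if leader.shape != current.shape:
            raise ValueError("leader and current positions must share a shape")
        coeff_a, coeff_c = coefficient_vectors(a, current.size, rng)
        dist = np.abs(coeff_c * leader - current)
        candidates.append(leader - coeff_a * dist)
    return (candidates[0] + candidates[1] + candidates[2]) / 3.0


def clip_to_bounds(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    return np.clip(np.asarray(position, dtype=float), space.lower, space.upper)


def _safe_fitness(fitness: Fitness, position: np.ndarray) -> float:
    """Evaluate fitness; non-finite values become +inf so the search continues."""
    value = float(fitness(position))
    return value if math.isfinite(value) else math.inf


@dataclass
class _LeaderBoard:
    """Stable elitist top-k archive keyed by (fitness, evaluation order)."""

    k: int
    entries: list[tuple[float, int, np.ndarray]] = field(default_factory=list)

    def offer(self, fit: float, order: int, position: np.ndarray) -> None:
        self.entries.append((fit, order, position.copy()))
        self.entries.sort(key=lambda e: (e[0], e[1]))
        del self.entries[self.k :]

    @property
    def best(self) -> tuple[float, np.ndarray]:
        return self.entries[0][0], self.entries[0][2]


def gwo_minimize(
    fitness: Fitness, space: SearchSpace, config: OptimizerConfig
) -> OptimizerResult:
    """Grey-wolf minimization over a box.

    Positions are initialized uniformly at random; every iteration the pack
    is pulled toward the elitist alpha/beta/delta (the three best solutions
    ever evaluated), updated positions are clipped to the box and
    re-evaluated.  Deterministic under a fixed seed.
    """
    if config.population_size < 4:
        raise ValueError("GWO needs population_size >= 4 (three leaders + omega)")
    rng = np.random.default_rng(config.seed)
    n, dim = config.population_size, space.dim

    positions = space.sample(rng, n)
    board = _LeaderBoard(k=3)
    evaluations = 0
    for i in range(n):
        board.offer(_safe_fitness(fitness, positions[i]), evaluations, positions[i])
        evaluations += 1

    trace = np.empty(config.max_iterations)
    for t in range(config.max_iterations):
        a = control_parameter(t, config.max_iterations)
        alpha = board.entries[0][2]
        beta = board.entries[1][2] if len(board.entries) > 1 else alpha
        delta = board.entries[2][2] if len(board.entries) > 2 else beta
        new_positions = np.empty_like(positions)
        for leader_idx, leader in enumerate((alpha, beta, delta)):
            # fresh r1, r2 per component, per leader, per wolf
            r1 = rng.random((n, dim))
            r2 = rng.random((n, dim))
            coeff_a = 2.0 * a * r1 - a
            coeff_c = 2.0 * r2
            dist = np.abs(coeff_c * leader[None, :] - positions)
            candidate = leader[None, :] - coeff_a * dist
            if leader_idx == 0:
                new_positions = candidate / 3.0
            else:
                new_positions += candidate / 3.0
        positions = np.clip(new_positions, space.lower, space.upper)
        for i in range(n):
            board.offer(
                _safe_fitness(fitness, positions[i]), evaluations, positions[i]
            )
            evaluations += 1
        trace[t] = board.best[0]

    best_fit, best_pos = board.best
    return OptimizerResult(
        best_position=best_pos,
        best_fitness=best_fit,
        trace=trace,
        evaluations=evaluations,
    )


def pso_minimize(
    fitness: Fitness,
    space: SearchSpace,
    config: OptimizerConfig,
    *,
    inertia: tuple[float, float] = (0.9, 0.4),
    c1: float = 2.0,
    c2: float = 2.0,
    velocity_clamp: float = 0.2,
) -> OptimizerResult:
    """Canonical global-best PSO baseline.

    Inertia decreases linearly over iterations; velocities are clamped to
    ``velocity_clamp`` times the box width.  Same contract and determinism
    guarantees as :func:`gwo_minimize`.
    """
    rng = np.random.default_rng(config.seed)
    n, dim = config.population_size, space.dim
    vmax = velocity_clamp * space.width

    positions = space.sample(rng, n)
    velocities = rng.uniform(-vmax, vmax, size=(n, dim))
    fits = np.array([_safe_fitness(fitness, p) for p in positions])
    evaluations = n

    pbest = positions.copy()
    pbest_fits = fits.copy()
    g_idx = int(np.argmin(pbest_fits))
    gbest = pbest[g_idx].copy()
    gbest_fit = float(pbest_fits[g_idx])

    trace = np.empty(config.max_iterations)
    for t in range(config.max_iterations):
        frac = t / max(config.max_iterations - 1, 1)
        w = inertia[0] + (inertia[1] - inertia[0]) * frac
        r1 = rng.random((n, dim))
        r2 = rng.random((n, dim))
        velocities = (
            w * velocities
            + c1 * r1 * (pbest - positions)
            + c2 * r2 * (gbest[None, :] - positions)
        )
        velocities = np.clip(velocities, -vmax, vmax)
        positions = np.clip(positions + velocities, space.lower, space.upper)
        for i in range(n):
            f = _safe_fitness(fitness, positions[i])
            evaluations += 1
            if f < pbest_fits[i]:
                pbest_fits[i] = f
                pbest[i] = positions[i]
                if f < gbest_fit:
                    gbest_fit = f
                    gbest = positions[i].copy()
        trace[t] = gbest_fit

    return OptimizerResult(
        best_position=gbest,
        best_fitness=gbest_fit,
        trace=trace,
        evaluations=evaluations,
    )


_ALGORITHMS = {"gwo": gwo_minimize, "pso": pso_minimize}


def minimize(
    algorithm: str, fitness: Fitness, space: SearchSpace, config: OptimizerConfig
) -> OptimizerResult:
    """Dispatch by algorithm name ('gwo' or 'pso')."""
    try:
        fn = _ALGORITHMS[algorithm.lower()]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; expected one of {sorted(_ALGORITHMS)}"
        ) from None
    return fn(fitness, space, config)
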