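"""Shared fixtures: synthetic batch sets and a deliberately input-sensitive
soft sensor for closed-loop checks.  Everything is generated at test time."""

import warnings

import numpy as np
import pytest

from fermctl import lssvm, plant_sim, softsensor
from fermctl.optimizers import OptimizerConfig


@pytest.fixture(autouse=True)
def _quiet_do_clip_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="DO clipped")
        yield


@pytest.fixture(scope="session")
def ten_batches():
    return plant_sim.generate_batches(10, master_seed=42)


@pytest.fixture(scope="session")
def tuned_sensor(ten_batches):
    """Sensor tuned on 6 train / 2 cv batches with a reduced search budget."""
    result = softsensor.tune(
        ten_batches[:6],
        ten_batches[6:8],
        opt_config=OptimizerConfig(population_size=10, max_iterations=20, seed=7),
        max_train_rows=700,
    )
    return result


def make_input_sensitive_sensor(seed: int = 0, n: int = 300) -> softsensor.SoftSensor:
    """Sensor trained across the whole input box so predictions respond to u.

    The batch-trained sensor only covers a narrow operating tube; for
    controller consistency checks we need a model whose output genuinely
    moves with the manipulated inputs.
    """
    rng = np.random.default_rng(seed)
    T = 32.0 + rng.normal(0, 0.1, n)
    pH = 7.05 + rng.normal(0, 0.05, n)
    DO = 85.0 + rng.normal(0, 1.0, n)
    u1 = rng.uniform(316, 345, n)
    u2 = rng.uniform(0.1, 1.65, n)
    u3 = rng.uniform(51, 110, n)
    X = np.column_stack([T, pH, u1, DO, u2, u3])
    y = (
        5.0
        + 20.0 * (u1 - 316.0) / 29.0
        + 8.0 * (u2 - 0.1) / 1.55
        + 7.0 * (u3 - 51.0) / 59.0
    )
    stats = softsensor.NormalizationStats.fit(np.column_stack([X, y]))
    feat_stats = softsensor.NormalizationStats(stats.minimum[:-1], stats.maximum[:-1])
    target_stats = softsensor.NormalizationStats(stats.minimum[-1:], stats.maximum[-1:])
    model = lssvm.fit(
        feat_stats.normalize(X),
        target_stats.normalize(y[:, None]).ravel(),
        lssvm.Hyperparams(g=1000.0, sigma=1.0),
    )
    return softsensor.SoftSensor(model=model, stats=stats)


@pytest.fixture(scope="session")
def input_sensitive_sensor():
    return make_input_sensitive_sensor()
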