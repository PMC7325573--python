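import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fermctl import lssvm, plant_sim, softsensor
from fermctl.optimizers import OptimizerConfig, SearchSpace
from fermctl.softsensor import (
    DatasetSplit,
    NormalizationStats,
    assemble_regression_table,
    cv_fitness,
    mae,
    mape,
    make_cv_fitness,
    rmse,
    split_batches,
    tune,
)


class TestNormalizationStats:
    def test_endpoints_and_midpoint(self):
        stats = NormalizationStats(minimum=[0.0], maximum=[10.0])
        assert stats.normalize(np.array([0.0]))[0] == -1.0
        assert stats.normalize(np.array([10.0]))[0] == 1.0
        assert stats.normalize(np.array([5.0]))[0] == 0.0

    def test_affine_extension_no_clipping(self):
        stats = NormalizationStats(minimum=[0.0], maximum=[10.0])
        assert stats.normalize(np.array([15.0]))[0] == pytest.approx(2.0)

    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        table = rng.uniform(-5, 20, size=(40, 3))
        stats = NormalizationStats.fit(table)
        assert np.allclose(stats.denormalize(stats.normalize(table)), table, atol=1e-12)

    def test_rejects_constant_channel(self):
        table = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="constant"):
            NormalizationStats.fit(table)

    @settings(max_examples=30, deadline=None)
    @given(
        values=arrays(np.float64, (10, 2), elements=st.floats(-100, 100, width=32)),
    )
    def test_roundtrip_property(self, values):
        if np.any(values.max(axis=0) - values.min(axis=0) < 1e-6):
            return
        stats = NormalizationStats.fit(values)
        assert np.allclose(stats.denormalize(stats.normalize(values)), values, atol=1e-9)


class TestDatasetSplit:
    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            DatasetSplit(train=(0, 1), cv=(1,), test=(2,))

    def test_nonempty_enforced(self):
        with pytest.raises(ValueError):
            DatasetSplit(train=(), cv=(1,), test=(2,))

    def test_split_batches_shape(self):
        split = split_batches(10, rng=np.random.default_rng(1))
        assert len(split.train) == 6 and len(split.cv) == 2 and len(split.test) == 2
        assert len(set(split.train) | set(split.cv) | set(split.test)) == 10

    def test_split_too_small(self):
        with pytest.raises(ValueError):
            split_batches(5, counts=(6, 2, 2))


class TestAssembleRegressionTable:
    def test_shapes_and_order(self, ten_batches):
        X, y = assemble_regression_table(ten_batches[:1])
        assert X.shape == (289, 6)
        assert y.shape == (289,)
        X2, y2 = assemble_regression_table(ten_batches[:2])
        assert X2.shape == (578, 6)
        assert np.array_equal(X2[:289], X)

    def test_feature_column_order(self, ten_batches):
        rec = ten_batches[0]
        X, y = assemble_regression_table([rec])
        assert np.array_equal(X[:, 0], rec.T)
        assert np.array_equal(X[:, 2], rec.u1)
        assert np.array_equal(X[:, 5], rec.u3)
        assert np.array_equal(y, rec.P)

    def test_empty_list(self):
        with pytest.raises(ValueError):
            assemble_regression_table([])

    def test_lagged_output(self, ten_batches):
        X, y = assemble_regression_table(ten_batches[:1], include_lagged_output=True)
        assert X.shape == (288, 7)
        assert np.array_equal(X[:, 6], ten_batches[0].P[:-1])
        assert np.array_equal(y, ten_batches[0].P[1:])


class TestMetrics:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert rmse(v, v) == 0.0
        assert mae(v, v) == 0.0
        assert mape(v, v) == 0.0

    def test_hand_values(self):
        actual = np.array([1.0, 1.0])
        predicted = np.array([0.0, 2.0])
        assert rmse(actual, predicted) == pytest.approx(1.0)
        assert mae(actual, predicted) == pytest.approx(1.0)
        assert mape(actual, predicted) == pytest.approx(1.0)

    def test_mape_is_fractional(self):
        # 10% error on every sample -> 0.1, not 10
        actual = np.full(5, 50.0)
        assert mape(actual, actual * 1.1) == pytest.approx(0.1)

    def test_mape_zero_actual_raises(self):
        with pytest.raises(ValueError):
            mape(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))

    @settings(max_examples=50, deadline=None)
    @given(
        actual=arrays(np.float64, 8, elements=st.floats(-50, 50, width=32)),
        predicted=arrays(np.float64, 8, elements=st.floats(-50, 50, width=32)),
    )
    def test_rmse_dominates_mae(self, actual, predicted):
        assert rmse(actual, predicted) >= mae(actual, predicted) - 1e-12


class TestCvFitness:
    def _tables(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(n, 2))
        y = np.tanh(X[:, 0]) + 0.5 * X[:, 1]
        return (X, y)

    def test_interpolation_limit_on_train(self):
        table = self._tables()
        fit = cv_fitness(np.array([1e8, 0.08]), table, table)
        assert fit < 1e-3

    def test_deterministic(self):
        train, cv = self._tables(0), self._tables(1)
        c = np.array([100.0, 0.05])
        assert cv_fitness(c, train, cv) == cv_fitness(c, train, cv)

    def test_noise_floor_for_unlearnable_target(self):
        rng = np.random.default_rng(5)
        X_train = rng.uniform(-1, 1, size=(60, 2))
        y_train = rng.normal(0, 1, 60)
        X_cv = rng.uniform(-1, 1, size=(40, 2))
        y_cv = rng.normal(0, 1, 40)
        fit = cv_fitness(np.array([10.0, 0.05]), (X_train, y_train), (X_cv, y_cv))
        # cannot beat the cv target's own spread; sanity band around stdev
        assert 0.5 * np.std(y_cv) < fit < 2.0 * np.std(y_cv)

    def test_invalid_candidate_gets_sentinel(self):
        table = self._tables()
        assert make_cv_fitness(*table, *table)(np.array([-1.0, 0.05])) >= 1e12


class TestTune:
    def test_result_within_bounds(self, ten_batches):
        result = tune(
            ten_batches[:2],
            ten_batches[2:3],
            opt_config=OptimizerConfig(population_size=6, max_iterations=8, seed=0),
            max_train_rows=150,
        )
        assert 1.0 <= result.best_hyperparams.g <= 10000.0
        assert 0.001 <= result.best_hyperparams.sigma <= 0.1
        assert np.all(np.diff(result.optimizer_result.trace) <= 0)
        assert result.cv_rmse == result.optimizer_result.best_fitness

    def test_gwo_and_pso_share_contract(self, ten_batches):
        for algorithm in ("gwo", "pso"):
            result = tune(
                ten_batches[:2],
                ten_batches[2:3],
                opt_config=OptimizerConfig(population_size=6, max_iterations=6, seed=1),
                algorithm=algorithm,
                max_train_rows=120,
            )
            assert np.isfinite(result.cv_rmse)

    def test_empty_split_rejected(self, ten_batches):
        with pytest.raises(ValueError):
            tune([], ten_batches[:1])

    def test_beats_random_search(self, ten_batches):
        # tuned cv rmse must not lose to 25 random in-bounds candidates
        train, cv = ten_batches[:3], ten_batches[3:4]
        opt = OptimizerConfig(population_size=10, max_iterations=15, seed=3)
        result = tune(train, cv, opt_config=opt, max_train_rows=250)

        X_train, y_train = assemble_regression_table(train)
        X_cv, y_cv = assemble_regression_table(cv)
        X_train, y_train = X_train[::4], y_train[::4]
        stats = NormalizationStats.fit(np.column_stack([X_train, y_train]))
        fs = NormalizationStats(stats.minimum[:-1], stats.maximum[:-1])
        ts = NormalizationStats(stats.minimum[-1:], stats.maximum[-1:])
        fitness = make_cv_fitness(
            fs.normalize(X_train),
            ts.normalize(y_train[:, None]).ravel(),
            fs.normalize(X_cv),
            ts.normalize(y_cv[:, None]).ravel(),
        )
        rng = np.random.default_rng(99)
        space = softsensor.DEFAULT_TUNING_BOUNDS
        random_best = min(
            fitness(space.lower + rng.random(2) * (space.upper - space.lower))
            for _ in range(25)
        )
        assert result.cv_rmse <= random_best + 1e-9

    def test_single_sample_cv(self, ten_batches):
        rec = ten_batches[0]
        tiny = plant_sim.BatchRecord(
            time_h=rec.time_h[:2],
            T=rec.T[:2],
            pH=rec.pH[:2],
            u1=rec.u1[:2],
            DO=rec.DO[:2],
            u2=rec.u2[:2],
            u3=rec.u3[:2],
            P=rec.P[:2],
        )
        result = tune(
            ten_batches[:1],
            [tiny],
            opt_config=OptimizerConfig(population_size=6, max_iterations=4, seed=0),
            max_train_rows=100,
        )
        assert np.isfinite(result.cv_rmse)

    def test_normalization_from_train_only(self, ten_batches):
        result = tune(
            ten_batches[:2],
            ten_batches[2:3],
            opt_config=OptimizerConfig(population_size=6, max_iterations=4, seed=0),
            max_train_rows=200,
        )
        X_train, y_train = assemble_regression_table(ten_batches[:2])
        stride = int(np.ceil(X_train.shape[0] / 200))
        stats = NormalizationStats.fit(
            np.column_stack([X_train[::stride], y_train[::stride]])
        )
        assert np.allclose(result.sensor.stats.minimum, stats.minimum)
        assert np.allclose(result.sensor.stats.maximum, stats.maximum)


class TestSoftSensor:
    def test_physical_scale_prediction(self, tuned_sensor, ten_batches):
        sensor = tuned_sensor.sensor
        X, y = assemble_regression_table(ten_batches[8:])
        pred = sensor.predict(X)
        assert pred.shape == y.shape
        # predictions on physical g/L scale, inside a sane band
        assert np.all(pred > -5) and np.all(pred < 50)

    def test_serialization_roundtrip(self, tuned_sensor, tmp_path):
        sensor = tuned_sensor.sensor
        path = tmp_path / "sensor.json"
        sensor.save(path)
        restored = softsensor.SoftSensor.load(path)
        x = np.array([32.0, 7.0, 330.0, 80.0, 1.0, 80.0])
        assert restored.predict(x) == pytest.approx(sensor.predict(x))

    def test_feature_count_check(self, tuned_sensor):
        with pytest.raises(ValueError):
            tuned_sensor.sensor.predict(np.zeros(4))


def test_evaluate_sensor_reports_both_scales(tuned_sensor, ten_batches):
    metrics = softsensor.evaluate_sensor(tuned_sensor.sensor, ten_batches[8:])
    assert set(metrics) == {"physical", "normalized"}
    assert metrics["physical"]["rmse"] >= metrics["physical"]["mae"]
    assert metrics["normalized"]["rmse"] >= 0


def test_end_to_end_determinism(ten_batches):
    kwargs = dict(
        opt_config=OptimizerConfig(population_size=6, max_iterations=6, seed=5),
        max_train_rows=150,
    )
    r1 = tune(ten_batches[:2], ten_batches[2:3], **kwargs)
    r2 = tune(ten_batches[:2], ten_batches[2:3], **kwargs)
    assert r1.best_hyperparams == r2.best_hyperparams
    assert r1.cv_rmse == r2.cv_rmse
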