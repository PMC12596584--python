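import numpy as np
import pytest

from geoloci import (
    CoordinateSet,
    FeatureMatrix,
    ModelSpec,
    TrainConfig,
    build_model,
    compute_loss,
    predict,
    resolve_width,
    train,
)
from geoloci.errors import ConfigError, GeolociError, InputError
from geoloci.evaluate import haversine_km
from geoloci.geometry import unproject_km


class TestResolveWidth:
    @pytest.mark.parametrize(
        "initial,rows,cols,expected",
        [
            (64, 100, 50, 64),  # already within bound
            (256, 8, 10, 66),  # 256→204→163→130→104→83→66
            (81, 8, 10, 64),  # single ×0.8 step past 80
        ],
    )
    def test_recursion(self, initial, rows, cols, expected):
        assert resolve_width(initial, rows, cols) == expected

    def test_idempotent_and_bounded(self):
        w = resolve_width(512, 9, 7)
        assert resolve_width(w, 9, 7) == w
        assert w <= 63

    def test_too_small_model(self):
        with pytest.raises(GeolociError):
            resolve_width(100, 1, 1)


class TestBuildModel:
    def test_parameter_count(self):
        spec = ModelSpec(input_dim=3, n_hidden_layers=1, initial_width=4,
                         resolved_width=4, dropout=0.0)
        model = build_model(spec)
        # bn gamma+beta (3+3) + hidden (3·4+4) + output (4·2+2)
        assert model.n_parameters() == 6 + 16 + 10

    def test_eval_forward_deterministic(self, rng):
        spec = ModelSpec(input_dim=5, resolved_width=8, dropout=0.0)
        model = build_model(spec, seed=0)
        X = rng.normal(size=(7, 5))
        a, _ = model.forward(X)
        b, _ = model.forward(X)
        np.testing.assert_array_equal(a, b)

    def test_state_dict_round_trip(self, rng):
        spec = ModelSpec(input_dim=5, resolved_width=8)
        m1 = build_model(spec, seed=0)
        m2 = build_model(spec, seed=99)
        m2.load_state_dict(m1.state_dict())
        X = rng.normal(size=(4, 5))
        np.testing.assert_array_equal(m1.forward(X)[0], m2.forward(X)[0])


class TestComputeLoss:
    @pytest.mark.parametrize("kind", ["rmse", "huber", "drms"])
    def test_zero_at_equality(self, kind, rng):
        y = rng.normal(size=(10, 2))
        assert compute_loss(y, y, kind) == 0.0
        assert compute_loss(y + 0.5, y, kind) > 0.0

    def test_closed_form_single_sample(self):
        pred = np.array([[3.0, 4.0]])
        target = np.zeros((1, 2))
        assert compute_loss(pred, target, "rmse") == pytest.approx(np.sqrt(12.5))
        assert compute_loss(pred, target, "drms") == pytest.approx(5.0)
        assert compute_loss(pred, target, "huber", delta=1.0) == pytest.approx(3.0)

    @pytest.mark.parametrize("kind", ["rmse", "huber", "drms"])
    def test_uniform_weights_equal_unweighted(self, kind, rng):
        pred = rng.normal(size=(16, 2))
        target = rng.normal(size=(16, 2))
        w = np.full(16, 3.7)
        assert abs(
            compute_loss(pred, target, kind, weights=w)
            - compute_loss(pred, target, kind)
        ) < 1e-12

    def test_huber_limits_to_half_mse(self, rng):
        pred = rng.uniform(-2, 2, size=(32, 2))
        target = rng.uniform(-2, 2, size=(32, 2))
        mse = ((pred - target) ** 2).mean()
        assert abs(compute_loss(pred, target, "huber", delta=1e6) - mse / 2) < 1e-9

    def test_weight_length_mismatch(self, rng):
        y = rng.normal(size=(4, 2))
        with pytest.raises(GeolociError):
            compute_loss(y, y, "rmse", weights=np.ones(3))


def _linear_toy(n=200, seed=0):
    """Coordinates are a noiseless linear map of 2 features (~500 km span)."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, size=(n, 2))
    xy_km = X * 250.0
    lonlat = unproject_km(xy_km, np.array([-92.0, 36.0]))
    ids = np.array([f"s{i}" for i in range(n)], dtype=object)
    return X, lonlat, ids


class TestTrain:
    def test_learns_noiseless_linear_map(self):
        X, lonlat, ids = _linear_toy()
        spec = ModelSpec(input_dim=2, resolved_width=resolve_width(64, 150, 2),
                         n_hidden_layers=2, dropout=0.0)
        model = build_model(spec, seed=0)
        cfg = TrainConfig(max_epochs=500, patience=100, batch_size=32, seed=0)
        fitted = train(model, X[:150], lonlat[:150], X[150:], lonlat[150:], config=cfg)
        # final training RMSE in standardized units
        Xs = (X[:150] - fitted.feature_mean) / fitted.feature_std
        pred, _ = fitted.model.forward(Xs)
        z = (lonlat[:150] - fitted.target_mean) / fitted.target_std
        assert compute_loss(pred, z, "rmse") < 0.05

    def test_predict_recovers_targets_in_km(self):
        X, lonlat, ids = _linear_toy()
        spec = ModelSpec(input_dim=2, resolved_width=resolve_width(64, 150, 2), dropout=0.0)
        # full-batch: batch-norm statistics are exact, so the noiseless
        # map is recovered to well under the km scale
        fitted = train(
            build_model(spec, seed=0), X[:150], lonlat[:150], X[150:], lonlat[150:],
            config=TrainConfig(max_epochs=2000, patience=300, learning_rate=1e-2,
                               batch_size=150, seed=0),
        )
        F = FeatureMatrix(ids[:150], X[:150])
        pred = predict(fitted, F)
        err = haversine_km(pred.lonlat, lonlat[:150])
        assert np.mean(err) < 5.0

    def test_plateau_early_stop_epoch_count(self):
        X, lonlat, _ = _linear_toy(60)
        spec = ModelSpec(input_dim=2, resolved_width=4, dropout=0.0)
        # learning rate so small that no validation improvement can register
        cfg = TrainConfig(max_epochs=500, patience=7, learning_rate=1e-30,
                          batch_size=60, seed=0)
        fitted = train(build_model(spec, seed=0), X[:40], lonlat[:40],
                       X[40:], lonlat[40:], config=cfg)
        assert len(fitted.history["epoch"]) == 1 + cfg.patience
        assert fitted.best_epoch == 1

    def test_seed_reproducible_history(self):
        X, lonlat, _ = _linear_toy(80)
        spec = ModelSpec(input_dim=2, resolved_width=8, dropout=0.3)
        cfg = TrainConfig(max_epochs=40, patience=40, batch_size=16, seed=3)
        h1 = train(build_model(spec, seed=3), X[:60], lonlat[:60], X[60:],
                   lonlat[60:], config=cfg).history
        spec2 = ModelSpec(input_dim=2, resolved_width=8, dropout=0.3)
        h2 = train(build_model(spec2, seed=3), X[:60], lonlat[:60], X[60:],
                   lonlat[60:], config=cfg).history
        np.testing.assert_array_equal(h1["train_loss"], h2["train_loss"])
        np.testing.assert_array_equal(h1["val_loss"], h2["val_loss"])

    def test_best_epoch_is_validation_minimum(self):
        X, lonlat, _ = _linear_toy(100)
        spec = ModelSpec(input_dim=2, resolved_width=8, dropout=0.0)
        cfg = TrainConfig(max_epochs=100, patience=30, batch_size=25, seed=1)
        fitted = train(build_model(spec, seed=1), X[:70], lonlat[:70], X[70:],
                       lonlat[70:], config=cfg)
        vals = np.asarray(fitted.history["val_loss"])
        assert vals[fitted.best_epoch - 1] <= vals.min() + 1e-9

    def test_empty_training_set_rejected(self):
        spec = ModelSpec(input_dim=2, resolved_width=4)
        with pytest.raises(InputError):
            train(build_model(spec), np.empty((0, 2)), np.empty((0, 2)),
                  np.ones((2, 2)), np.ones((2, 2)))


class TestPredict:
    def test_standardize_round_trip(self):
        from geoloci.nn import standardize_targets, unstandardize_targets

        lonlat = np.array([[-92.1, 35.5], [-90.0, 36.7]])
        mean, std = lonlat.mean(0), lonlat.std(0)
        z = standardize_targets(lonlat, mean, std)
        np.testing.assert_allclose(unstandardize_targets(z, mean, std), lonlat, atol=1e-9)

    def test_single_sample_equals_batch_row(self):
        X, lonlat, ids = _linear_toy(100)
        spec = ModelSpec(input_dim=2, resolved_width=8, dropout=0.2)
        fitted = train(
            build_model(spec, seed=0), X[:70], lonlat[:70], X[70:], lonlat[70:],
            config=TrainConfig(max_epochs=50, patience=50, batch_size=16, seed=0),
        )
        batch = predict(fitted, FeatureMatrix(ids[:10], X[:10]))
        single = predict(fitted, FeatureMatrix(ids[:1], X[:1]))
        assert batch.lon[0] == single.lon[0] and batch.lat[0] == single.lat[0]

    def test_dimension_mismatch(self):
        X, lonlat, ids = _linear_toy(60)
        spec = ModelSpec(input_dim=2, resolved_width=4)
        fitted = train(build_model(spec, seed=0), X[:40], lonlat[:40], X[40:],
                       lonlat[40:], config=TrainConfig(max_epochs=5, batch_size=16))
        with pytest.raises(InputError):
            predict(fitted, FeatureMatrix(ids[:3], np.ones((3, 5))))


class TestSpecValidation:
    def test_bad_dropout(self):
        with pytest.raises(ConfigError):
            ModelSpec(input_dim=2, dropout=1.0)

    def test_bad_config(self):
        with pytest.raises(ConfigError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ConfigError):
            TrainConfig(loss_kind="mae")
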