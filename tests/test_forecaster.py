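import numpy as np
import pytest

from gaitcast.errors import ValidationError
from gaitcast.forecaster import (
    ForecastConfig,
    build_model,
    discount_weights,
    discounted_ce_loss,
    discounted_mse_loss,
    grid_search,
    split_validation,
    train,
)
from gaitcast.phase_labeling import N_PHASES
from gaitcast.windowing import WindowedDataset


def loop_discounted_mse(y_true, y_pred, alpha):
    """Brute-force double loop over frames and channels, one window."""
    total = 0.0
    for i in range(y_true.shape[0]):
        for d in range(y_true.shape[1]):
            total += alpha**i * (y_true[i, d] - y_pred[i, d]) ** 2
    return total


def _dataset(rng, n, p, f, N, D, phase=False):
    targets_phase = np.zeros((n, f, N_PHASES))
    labels = rng.integers(0, N_PHASES, size=(n, f))
    targets_phase[
        np.arange(n)[:, None], np.arange(f)[None, :], labels
    ] = 1.0
    return WindowedDataset(
        inputs=rng.standard_normal((n, p, N)),
        targets_trajectory=rng.standard_normal((n, f, D)),
        targets_phase=targets_phase,
        subjects=np.full(n, "x"),
        speeds=np.ones(n, dtype=int),
        starts=np.arange(n),
        target_channel_names=tuple(f"c{i}" for i in range(D)),
    )


class TestDiscountWeights:
    @pytest.mark.parametrize(
        "alpha,f,expected",
        [
            (1.0, 3, [1.0, 1.0, 1.0]),
            (0.5, 3, [1.0, 0.5, 0.25]),
            (0.0, 2, [1.0, 0.0]),
        ],
    )
    def test_hand_values(self, alpha, f, expected):
        np.testing.assert_allclose(discount_weights(alpha, f), expected)

    def test_non_increasing_for_any_alpha(self, rng):
        for alpha in rng.uniform(0, 1, size=20):
            w = discount_weights(float(alpha), 8)
            assert (np.diff(w) <= 1e-15).all()

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            discount_weights(1.5, 3)


class TestDiscountedMseLoss:
    def test_alpha_one_equals_plain_sum_of_squares(self, rng):
        for _ in range(25):
            f, D = rng.integers(1, 8), rng.integers(1, 5)
            y = rng.standard_normal((f, D))
            y_hat = rng.standard_normal((f, D))
            assert discounted_mse_loss(y, y_hat, alpha=1.0) == pytest.approx(
                loop_discounted_mse(y, y_hat, 1.0), abs=1e-9
            )

    def test_matches_loop_oracle_for_random_alpha(self, rng):
        for _ in range(25):
            f, D = rng.integers(1, 8), rng.integers(1, 5)
            alpha = float(rng.uniform(0, 1))
            y = rng.standard_normal((f, D))
            y_hat = rng.standard_normal((f, D))
            assert discounted_mse_loss(y, y_hat, alpha) == pytest.approx(
                loop_discounted_mse(y, y_hat, alpha), abs=1e-9
            )

    def test_hand_examples(self):
        # unweighted: errors 1 and 2 -> 1 + 4 = 5
        assert discounted_mse_loss(
            np.array([[1.0], [2.0]]), np.array([[0.0], [0.0]]), alpha=1.0
        ) == pytest.approx(5.0)
        # alpha = 0.5 on unit per-frame errors -> 1 + 0.5
        assert discounted_mse_loss(
            np.array([[1.0], [1.0]]), np.array([[0.0], [0.0]]), alpha=0.5
        ) == pytest.approx(1.5)
        # zero error, pure penalty: 0.1 * (|2| + |-3|)
        theta = [np.array([2.0, -3.0])]
        assert discounted_mse_loss(
            np.zeros((2, 1)), np.zeros((2, 1)), alpha=1.0, lambda_l1=0.1, theta=theta
        ) == pytest.approx(0.5)

    def test_batch_is_mean_over_windows_plus_single_penalty(self, rng):
        y = rng.standard_normal((6, 3, 2))
        y_hat = rng.standard_normal((6, 3, 2))
        theta = [rng.standard_normal((4, 4))]
        per_window = [loop_discounted_mse(y[j], y_hat[j], 0.7) for j in range(6)]
        expected = np.mean(per_window) + 0.01 * np.abs(theta[0]).sum()
        assert discounted_mse_loss(y, y_hat, 0.7, 0.01, theta) == pytest.approx(expected)

    def test_invariant_to_window_permutation(self, rng):
        y = rng.standard_normal((10, 4, 2))
        y_hat = rng.standard_normal((10, 4, 2))
        perm = rng.permutation(10)
        a = discounted_mse_loss(y, y_hat, 0.8)
        b = discounted_mse_loss(y[perm], y_hat[perm], 0.8)
        assert a == pytest.approx(b, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            discounted_mse_loss(np.zeros((2, 3)), np.zeros((3, 2)), 1.0)


class TestDiscountedCeLoss:
    def test_perfect_prediction_leaves_only_penalty(self):
        t = np.array([[0.0, 1.0, 0.0, 0.0, 0.0]])
        theta = [np.array([1.0, -1.0])]
        loss = discounted_ce_loss(t, t, alpha=1.0, lambda_l1=0.1, theta=theta)
        assert loss == pytest.approx(0.2)

    def test_uniform_prediction_closed_form(self):
        t = np.array([[1.0, 0.0, 0.0, 0.0, 0.0]])
        p = np.full((1, 5), 0.2)
        assert discounted_ce_loss(t, p, alpha=1.0) == pytest.approx(-np.log(0.2))

    def test_alpha_zero_uses_only_first_frame(self, rng):
        t = np.zeros((3, 5))
        t[:, 0] = 1.0
        p = rng.dirichlet(np.ones(5), size=3)
        full = discounted_ce_loss(t, p, alpha=0.0)
        first = discounted_ce_loss(t[:1], p[:1], alpha=1.0)
        assert full == pytest.approx(first)

    def test_unnormalized_rows_rejected(self):
        t = np.array([[1.0, 0, 0, 0, 0]])
        p = np.array([[0.5, 0.1, 0.1, 0.1, 0.1]])
        with pytest.raises(ValidationError):
            discounted_ce_loss(t, p, alpha=1.0)


class TestBuildModel:
    @pytest.mark.parametrize("f,units,heads", [(10, 50, 10), (5, 25, 5), (1, 5, 1)])
    def test_units_and_heads_scale_with_horizon(self, f, units, heads):
        cfg = ForecastConfig(p=4, f=f, task="trajectory")
        model = build_model(cfg, n_features=6, n_targets=3)
        assert cfg.units == units
        assert model.params["Wx0"].shape == (6, 4 * units)
        assert sum(1 for k in model.params if k.startswith("Wy")) == heads

    def test_phase_heads_emit_probability_rows(self, rng):
        cfg = ForecastConfig(p=3, f=4, task="phase")
        model = build_model(cfg, n_features=5)
        out = model.predict(rng.standard_normal((7, 3, 5)))
        assert out.shape == (7, 4, 5)
        np.testing.assert_allclose(out.sum(axis=2), 1.0, atol=1e-6)

    def test_argmax_tie_break_prefers_lowest_index(self):
        probs = np.array([[[0.2, 0.2, 0.2, 0.2, 0.2]]])
        assert np.argmax(probs, axis=2)[0, 0] == 0
        probs = np.array([[[0.1, 0.15, 0.15, 0.2, 0.4]]])
        assert np.argmax(probs, axis=2)[0, 0] == 4

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValidationError):
            build_model(ForecastConfig(p=3, f=2), n_features=0, n_targets=1)

    def test_input_shape_validated(self, rng):
        model = build_model(ForecastConfig(p=3, f=2), n_features=4, n_targets=1)
        with pytest.raises(ValidationError):
            model.predict(rng.standard_normal((5, 4, 4)))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        """BPTT gradients agree with central finite differences."""
        for task in ("trajectory", "phase"):
            cfg = ForecastConfig(p=3, f=2, units_multiplier=2, task=task,
                                 alpha=0.7, lambda_l1=0.0, seed=3)
            D = 5 if task == "phase" else 2
            model = build_model(cfg, n_features=3, n_targets=D)
            X = rng.standard_normal((4, 3, 3))
            if task == "phase":
                targets = np.zeros((4, 2, 5))
                targets[:, :, 1] = 1.0
            else:
                targets = rng.standard_normal((4, 2, 2))
            _, grads = model._loss_and_grads(X, targets)
            eps = 1e-6
            for key in ("Wx0", "Wh0", "b0", "Wy0", "by1"):
                flat_idx = rng.integers(0, model.params[key].size, size=4)
                for fi in flat_idx:
                    orig = model.params[key].flat[fi]
                    model.params[key].flat[fi] = orig + eps
                    out, _, _ = model._forward(X)
                    lp = model.batch_loss(out, targets, include_penalty=False)
                    model.params[key].flat[fi] = orig - eps
                    out, _, _ = model._forward(X)
                    lm = model.batch_loss(out, targets, include_penalty=False)
                    model.params[key].flat[fi] = orig
                    fd = (lp - lm) / (2 * eps)
                    assert grads[key].flat[fi] == pytest.approx(fd, abs=1e-5)


class TestTraining:
    def _sine_dataset(self, n=300, p=6, f=2, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n + p + f) / 10.0
        sig = np.sin(2 * np.pi * 0.5 * t)
        X = np.stack([sig[i : i + p] for i in range(n)])[:, :, None]
        Y = np.stack([sig[i + p : i + p + f] for i in range(n)])[:, :, None]
        ds = WindowedDataset(
            inputs=X + noise * rng.standard_normal(X.shape),
            targets_trajectory=Y,
            targets_phase=np.tile(np.eye(5)[0], (n, f, 1)),
            subjects=np.full(n, "s"),
            speeds=np.ones(n, dtype=int),
            starts=np.arange(n),
            target_channel_names=("sig",),
        )
        return ds

    def test_validation_rmse_halves_on_noiseless_sinusoid(self):
        ds = self._sine_dataset()
        fit, val = split_validation(ds, 0.2, seed=0)
        cfg = ForecastConfig(p=6, f=2, task="trajectory", alpha=1.0,
                             lambda_l1=0.0, max_epochs=30, batch_size=32, seed=0)
        model = build_model(cfg, 1, 1)
        train(model, fit, val)
        history = model.history["val_loss"]
        assert min(history) <= 0.5 * history[0]

    def test_identical_seed_gives_identical_history(self):
        ds = self._sine_dataset(n=120)
        fit, val = split_validation(ds, 0.2, seed=0)
        cfg = ForecastConfig(p=6, f=2, max_epochs=5, batch_size=32, seed=42)
        runs = []
        for _ in range(2):
            model = build_model(cfg, 1, 1)
            train(model, fit, val)
            runs.append(model.history["train_loss"])
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_early_stop_restores_best_epoch_weights(self):
        ds = self._sine_dataset(n=150)
        fit, val = split_validation(ds, 0.2, seed=0)
        cfg = ForecastConfig(p=6, f=2, max_epochs=60, patience=3,
                             batch_size=32, seed=1)
        model = build_model(cfg, 1, 1)
        train(model, fit, val)
        best = min(model.history["val_loss"])
        assert model.evaluate_loss(val) == pytest.approx(best, rel=1e-6)

    def test_empty_dataset_rejected(self):
        ds = self._sine_dataset(n=50)
        cfg = ForecastConfig(p=6, f=2)
        model = build_model(cfg, 1, 1)
        with pytest.raises(ValidationError):
            train(model, ds.subset(np.array([], dtype=int)), ds)

    def test_checkpoint_round_trip(self, tmp_path):
        from gaitcast.forecaster import ForecastModel

        ds = self._sine_dataset(n=80)
        fit, val = split_validation(ds, 0.2, seed=0)
        cfg = ForecastConfig(p=6, f=2, max_epochs=2, batch_size=32, seed=5)
        model = build_model(cfg, 1, 1)
        train(model, fit, val)
        path = tmp_path / "model.npz"
        model.save(path)
        back = ForecastModel.load(path)
        np.testing.assert_allclose(back.predict(ds.inputs), model.predict(ds.inputs))
        assert back.config == model.config


class TestGridSearch:
    def _tiny(self, rng):
        ds = TestTraining()._sine_dataset(n=100)
        return ds

    def test_singleton_grid_returns_that_config(self, rng):
        ds = self._tiny(rng)
        base = ForecastConfig(p=6, f=2, max_epochs=2, batch_size=32)
        best, results = grid_search({"alpha": [0.9]}, ds, base, n_features=1, n_targets=1)
        assert best.alpha == 0.9
        assert len(results) == 1

    def test_two_by_two_grid_is_exhaustive(self, rng):
        ds = self._tiny(rng)
        base = ForecastConfig(p=6, f=2, max_epochs=2, batch_size=32)
        best, results = grid_search(
            {"alpha": [0.8, 1.0], "batch_size": [32, 64]},
            ds, base, n_features=1, n_targets=1,
        )
        assert len(results) == 4
        assert {(r["alpha"], r["batch_size"]) for r in results} == {
            (0.8, 32), (0.8, 64), (1.0, 32), (1.0, 64)
        }

    def test_empty_candidate_list_rejected(self, rng):
        ds = self._tiny(rng)
        base = ForecastConfig(p=6, f=2)
        with pytest.raises(ValidationError):
            grid_search({"alpha": []}, ds, base, n_features=1, n_targets=1)
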