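import numpy as np
import pytest

from afloc.driver_cnn import (
    Conv2D,
    Dense,
    Flatten,
    Sequential,
    Softmax,
    TrainConfig,
    build_custom_cnn,
    load_model,
    predict,
    save_model,
    train_model,
    weighted_cross_entropy,
)

SMALL = (30, 30, 1)  # smallest shape that survives the conv/pool stack


class TestBuildCustomCnn:
    def test_forward_gives_probabilities(self, rng):
        _, model = build_custom_cnn((78, 192, 1), rng_seed=0)
        x = rng.standard_normal((2, 78, 192, 1)).astype(np.float32)
        probs = model.forward(x)
        assert probs.shape == (2, 8)
        assert (probs >= 0).all() and (probs <= 1).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_layer_audit(self):
        spec, model = build_custom_cnn(SMALL, rng_seed=0)
        convs = [l for l in model.layers if isinstance(l, Conv2D)]
        assert [c.w.shape[-1] for c in convs] == [32, 64, 64]
        assert all(c.w.shape[:2] == (3, 3) for c in convs)
        denses = [l for l in model.layers if isinstance(l, Dense)]
        assert [d.w.shape[1] for d in denses] == [128, 64, 8]
        assert spec.dropout_rate == 0.6

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="30x30"):
            build_custom_cnn((4, 4, 1))

    def test_three_channel_input(self, rng):
        _, model = build_custom_cnn((150, 152, 3), rng_seed=0)
        probs = model.forward(rng.standard_normal((1, 150, 152, 3)).astype(np.float32))
        assert probs.shape == (1, 8)


class TestGradients:
    def test_finite_difference_check(self, rng):
        # tiny conv net; verify backprop against central differences
        conv = Conv2D(1, 2, 3, rng=rng)
        dense = Dense(2 * 4 * 4, 3, rng=rng)
        model = Sequential([conv, Flatten(), dense, Softmax()])
        x = rng.standard_normal((4, 6, 6, 1)).astype(np.float32)
        y = np.array([0, 1, 2, 1])

        def loss_value():
            probs = model.forward(x.astype(np.float32))
            return weighted_cross_entropy(probs, y, reduction="mean")

        logits = model.forward_logits(x, train=True)
        z = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = z / z.sum(axis=1, keepdims=True)
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(y)), y] = 1.0
        model.backward_from_logits((probs - onehot) / len(y))

        eps = 1e-3
        for param, grad in [(conv.w, conv.dw), (conv.b, conv.db), (dense.w, dense.dw)]:
            flat_p = param.reshape(-1)
            flat_g = grad.reshape(-1)
            for idx in rng.choice(flat_p.size, size=min(5, flat_p.size), replace=False):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                up = loss_value()
                flat_p[idx] = orig - eps
                down = loss_value()
                flat_p[idx] = orig
                fd = (up - down) / (2 * eps)
                assert flat_g[idx] == pytest.approx(fd, abs=2e-3)


def _toy_constant_dataset(n_per_class=8, shape=SMALL):
    xs, ys = [], []
    for c in range(8):
        for _ in range(n_per_class):
            xs.append(np.full(shape, (c - 3.5) / 4.0, dtype=np.float32))
            ys.append(c)
    return np.stack(xs), np.array(ys)


class TestTraining:
    def test_separable_toy_reaches_full_accuracy(self):
        # dropout off: with constant images the 0.6-rate dropout noise
        # dominates the (tiny) class signal and stalls the sanity check
        x, y = _toy_constant_dataset()
        _, model = build_custom_cnn(SMALL, rng_seed=1,
                                    spec_overrides={"dropout_rate": 0.0})
        cfg = TrainConfig(max_epochs=50, early_stop_patience=49,
                          learning_rate=3e-3, rng_seed=1)
        trained = train_model(model, x, y, config=cfg)
        _, pred = predict(trained.model, x)
        assert (pred == y).mean() == 1.0

    def test_seeded_determinism(self):
        x, y = _toy_constant_dataset(n_per_class=3)
        histories = []
        for _ in range(2):
            _, model = build_custom_cnn(SMALL, rng_seed=5)
            cfg = TrainConfig(max_epochs=3, early_stop_patience=2, rng_seed=5)
            trained = train_model(model, x, y, config=cfg)
            histories.append(trained.history["train_loss"])
        np.testing.assert_array_equal(histories[0], histories[1])

    def test_checkpoint_restores_best(self):
        x, y = _toy_constant_dataset(n_per_class=3)
        _, model = build_custom_cnn(SMALL, rng_seed=2)
        cfg = TrainConfig(max_epochs=8, early_stop_patience=7, rng_seed=2)
        trained = train_model(model, x, y, config=cfg)
        assert trained.best_monitor_value == min(trained.history["train_loss"])
        assert trained.history["train_loss"][trained.best_epoch] == trained.best_monitor_value

    def test_single_class_rejected(self):
        x, y = _toy_constant_dataset(n_per_class=2)
        y[:] = 4
        _, model = build_custom_cnn(SMALL, rng_seed=0)
        with pytest.raises(ValueError, match="2 classes"):
            train_model(model, x, y, config=TrainConfig(max_epochs=2, early_stop_patience=1))

    def test_empty_train_rejected(self):
        _, model = build_custom_cnn(SMALL, rng_seed=0)
        with pytest.raises(ValueError):
            train_model(model, np.zeros((0,) + SMALL, dtype=np.float32), np.zeros(0, dtype=int),
                        config=TrainConfig(max_epochs=2, early_stop_patience=1))

    def test_memorizes_random_labels(self):
        # capacity check: 64 random-label samples learned to accuracy 1.0
        rng = np.random.default_rng(0)
        x = rng.standard_normal((64,) + SMALL).astype(np.float32)
        y = rng.integers(0, 8, 64)
        _, model = build_custom_cnn(SMALL, rng_seed=3,
                                    spec_overrides={"dropout_rate": 0.0})
        cfg = TrainConfig(max_epochs=150, early_stop_patience=149,
                          learning_rate=3e-3, rng_seed=3)
        trained = train_model(model, x, y, config=cfg)
        assert max(trained.history["train_acc"]) == 1.0

    def test_lr_reduction_applies(self):
        x, y = _toy_constant_dataset(n_per_class=2)
        _, model = build_custom_cnn(SMALL, rng_seed=0)
        cfg = TrainConfig(max_epochs=30, early_stop_patience=29, lr_patience=2,
                          learning_rate=1e-3, rng_seed=0)
        trained = train_model(model, x, y, config=cfg)
        assert min(trained.history["lr"]) <= cfg.learning_rate

    def test_alt_images_identity_when_equal(self):
        # alternating onto an identical copy must not change the trajectory
        x, y = _toy_constant_dataset(n_per_class=3)
        runs = []
        for alt in (None, x.copy()):
            _, model = build_custom_cnn(SMALL, rng_seed=4)
            cfg = TrainConfig(max_epochs=5, early_stop_patience=4, rng_seed=4)
            tr = train_model(model, x, y, config=cfg, alt_images=alt, alt_every=2)
            runs.append(tr.history["train_loss"])
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_alt_images_must_align(self):
        x, y = _toy_constant_dataset(n_per_class=2)
        _, model = build_custom_cnn(SMALL, rng_seed=0)
        with pytest.raises(ValueError, match="align"):
            train_model(model, x, y, config=TrainConfig(max_epochs=2, early_stop_patience=1),
                        alt_images=x[:3])

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_factor=1.5)
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=10, early_stop_patience=10)


class TestClassWeighting:
    def test_duplication_equals_weighting_in_total_loss(self, rng):
        probs = rng.dirichlet(np.ones(8), size=6)
        y = rng.integers(0, 8, 6)
        k = 4
        dup_probs = np.concatenate([probs] + [probs[:1]] * (k - 1))
        dup_y = np.concatenate([y, np.repeat(y[:1], k - 1)])
        loss_dup = weighted_cross_entropy(dup_probs, dup_y, reduction="sum")
        w = np.ones(6)
        w[0] = k
        loss_weighted = weighted_cross_entropy(probs, y, sample_weights=w, reduction="sum")
        assert loss_dup == pytest.approx(loss_weighted, abs=1e-6)


@pytest.fixture(scope="module")
def trained_small():
    x, y = _toy_constant_dataset(n_per_class=2)
    spec, model = build_custom_cnn(SMALL, rng_seed=0)
    cfg = TrainConfig(max_epochs=2, early_stop_patience=1, rng_seed=0)
    return train_model(model, x, y, config=cfg, spec=spec)


class TestPredict:
    def test_rows_sum_to_one(self, trained_small, rng):
        probs, labels = predict(trained_small.model, rng.standard_normal((5,) + SMALL))
        assert probs.shape == (5, 8)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert labels.shape == (5,)

    def test_deterministic_inference(self, trained_small, rng):
        x = rng.standard_normal((3,) + SMALL)
        p1, _ = predict(trained_small.model, x)
        p2, _ = predict(trained_small.model, x)
        np.testing.assert_array_equal(p1, p2)

    def test_shape_mismatch_rejected(self, trained_small, rng):
        with pytest.raises(ValueError, match="does not match"):
            predict(trained_small.model, rng.standard_normal((2, 30, 30, 3)))

    def test_empty_batch(self, trained_small):
        probs, labels = predict(trained_small.model, np.zeros((0,) + SMALL))
        assert probs.shape == (0, 8)
        assert labels.shape == (0,)

    def test_save_load_roundtrip(self, trained_small, tmp_path, rng):
        save_model(trained_small, tmp_path / "model")
        back = load_model(tmp_path / "model")
        x = rng.standard_normal((2,) + SMALL)
        np.testing.assert_allclose(
            predict(back.model, x)[0], predict(trained_small.model, x)[0], atol=1e-7
        )
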