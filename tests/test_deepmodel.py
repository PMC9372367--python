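"""Two-block CNN: architecture contracts, training recipe, LOO CV."""

import numpy as np
import pytest

from fetalcoupling._nn import softmax, weighted_xent
from fetalcoupling.beat_series import encode_segment
from fetalcoupling.coupling_label import SUPPORTED_RATIOS, CouplingRatio
from fetalcoupling.deepmodel import (
    CLASS_ORDER,
    CouplingClassifier,
    ModelConfig,
    Prediction,
    TrainingError,
    build_model,
    class_weights,
    loo_cv,
    predict,
    scaled_kernel,
    train,
)
from tests.conftest import make_segment


class TestArchitecture:
    def test_kernel_scaling_preserves_duration(self):
        assert scaled_kernel(1024, 1000) == 1024
        assert scaled_kernel(512, 1000) == 512
        assert scaled_kernel(1024, 250) == 256
        assert scaled_kernel(512, 250) == 128

    def test_native_rate_shapes(self):
        cfg = ModelConfig(fs=1000.0)
        assert cfg.L == 60000 and cfg.kernels == (1024, 512)

    def test_final_activation_aligned_to_input(self):
        cfg = ModelConfig(fs=25.0, seed=0)  # L = 1500
        model = build_model(cfg)
        x = np.zeros((2, 2, cfg.L), dtype=np.float32)
        act = model.conv_activation(x)
        assert act.shape == (2, cfg.filters[1], cfg.L)

    def test_zero_input_probabilities_on_simplex(self):
        cfg = ModelConfig(fs=25.0, seed=1)
        model = build_model(cfg)
        proba = model.predict_proba(np.zeros((3, 2, cfg.L), dtype=np.float32))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(proba >= 0)

    def test_kernel_longer_than_input_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            ModelConfig(fs=1000.0, window_length=0.5)

    def test_parameter_count_reported(self):
        cfg = ModelConfig(fs=25.0)
        model = build_model(cfg)
        # conv1 + bn1 + conv2 + bn2 + head, counted directly from shapes
        k1, k2 = cfg.kernels
        expected = (2 * 8 * k1 + 8) + 2 * 8 + (8 * 12 * k2 + 12) + 2 * 12 + (12 * cfg.L * 3 + 3)
        assert model.n_parameters() == expected


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        labels = [r for r in CLASS_ORDER for _ in range(100)]
        np.testing.assert_allclose(class_weights(labels), [1.0, 1.0, 1.0])

    def test_inverse_frequency_formula(self):
        # combined cohort-scale counts: w_c = T / (3 * T_c)
        labels = (
            [CouplingRatio(1, 2)] * 519 + [CouplingRatio(2, 3)] * 183 + [CouplingRatio(3, 5)] * 171
        )
        w = class_weights(labels)
        np.testing.assert_allclose(w, [873 / (3 * 519), 873 / (3 * 183), 873 / (3 * 171)])
        np.testing.assert_allclose(w, [0.561, 1.590, 1.702], atol=5e-4)

    def test_missing_class_is_error(self):
        labels = [CouplingRatio(1, 2)] * 10 + [CouplingRatio(3, 5)] * 10
        with pytest.raises(ValueError, match="absent"):
            class_weights(labels)

    def test_unit_weights_match_unweighted_loss(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(12, 3))
        y = rng.integers(0, 3, 12)
        loss_w, _ = weighted_xent(logits, y, np.ones(3))
        p = softmax(logits)
        loss_plain = float(-np.log(p[np.arange(12), y]).mean())
        assert loss_w == pytest.approx(loss_plain, abs=1e-9)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Central-difference check of every layer's parameter gradients."""
        cfg = ModelConfig(fs=2.0, window_length=32.0, filters=(3, 4), dtype="float64", seed=0)
        model = CouplingClassifier(cfg)
        rng = np.random.default_rng(1)
        X = (rng.random((6, 2, cfg.L)) < 0.1).astype(np.float64)
        y = np.array([0, 1, 2, 0, 1, 2])
        w = np.ones(3)

        def loss_at():
            return weighted_xent(model.forward(X, training=True), y, w)

        _, grad = loss_at()
        g = model.head.backward(grad).reshape(6, cfg.filters[1], cfg.L)
        g = model.relu2.backward(g)
        g = model.bn2.backward(g)
        g = model.conv2.backward(g)
        g = model.relu1.backward(g)
        g = model.bn1.backward(g)
        model.conv1.backward(g)

        eps = 1e-6
        checks = [
            (model.conv1, "w"), (model.conv2, "w"), (model.head, "w"), (model.head, "b"),
            (model.bn1, "gamma"), (model.bn1, "beta"), (model.bn2, "gamma"), (model.bn2, "beta"),
        ]
        for layer, name in checks:
            p = layer.params[name]
            for _ in range(4):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = loss_at()
                p[idx] = orig - eps
                lm, _ = loss_at()
                p[idx] = orig
                fd = (lp - lm) / (2 * eps)
                an = layer.grads[name][idx]
                assert abs(fd - an) <= 1e-5 * max(abs(fd), abs(an)) + 1e-7, (name, fd, an)


class TestTraining:
    def test_separable_data_reaches_full_training_accuracy(self, trained_tiny_model, separable_dataset):
        X, y, _ = separable_dataset
        proba = trained_tiny_model.predict_proba(X)
        assert (proba.argmax(axis=1) == y).mean() == 1.0

    def test_fixed_seed_reproduces_training_exactly(self, tiny_config, separable_dataset):
        X, y, _ = separable_dataset
        idx = np.r_[0:4, 10:14, 20:24]  # four segments of each class
        cfg = ModelConfig(fs=tiny_config.fs, seed=5, max_epochs=2)
        m1 = CouplingClassifier(cfg).fit(X[idx], y[idx])
        m2 = CouplingClassifier(cfg).fit(X[idx], y[idx])
        assert m1.training_log == m2.training_log
        np.testing.assert_array_equal(m1.head.params["w"], m2.head.params["w"])

    def test_single_class_dataset_rejected(self, tiny_config, separable_dataset):
        X, y, _ = separable_dataset
        model = CouplingClassifier(tiny_config)
        with pytest.raises(TrainingError, match="classes"):
            model.fit(X[y == 0], y[y == 0])

    def test_training_log_has_one_entry_per_epoch(self, trained_tiny_model, tiny_config):
        assert len(trained_tiny_model.training_log) == tiny_config.max_epochs
        assert all(np.isfinite(v) for v in trained_tiny_model.training_log)


class TestPrediction:
    def test_probabilities_on_simplex(self, trained_tiny_model, separable_dataset):
        _, _, encs = separable_dataset
        pred = predict(trained_tiny_model, encs[0])
        assert pred.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_model_recovers_planted_ratios_on_fresh_records(self, generalizing_model, tiny_config):
        hits = total = 0
        for ci, ratio in enumerate(SUPPORTED_RATIOS):
            for seed in range(8):
                seg = make_segment(ratio, jitter=0.02, seed=7000 + 100 * ci + seed)
                enc = encode_segment(seg, fs=tiny_config.fs)
                hits += predict(generalizing_model, enc).predicted == ratio
                total += 1
        assert hits / total >= 0.8

    def test_batch_equals_per_item_prediction(self, trained_tiny_model, separable_dataset):
        X, _, _ = separable_dataset
        batch = trained_tiny_model.predict_proba(X[:8])
        singles = np.stack([trained_tiny_model.predict_proba(X[i : i + 1])[0] for i in range(8)])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_shape_mismatch_rejected(self, trained_tiny_model):
        with pytest.raises(ValueError, match="shape"):
            trained_tiny_model.predict_proba(np.zeros((1, 2, 77), dtype=np.float32))

    def test_save_load_round_trip(self, trained_tiny_model, separable_dataset, tmp_path):
        X, _, _ = separable_dataset
        path = tmp_path / "model.npz"
        trained_tiny_model.save(path)
        loaded = CouplingClassifier.load(path)
        np.testing.assert_allclose(
            loaded.predict_proba(X[:5]), trained_tiny_model.predict_proba(X[:5]), atol=1e-7
        )


class TestLooCv:
    def _dataset(self, fs, n_per_class=3):
        from fetalcoupling.beat_series import segment_minutes
        from fetalcoupling.synth import GeneratorConfig, generate_pair

        out = []
        for ci, ratio in enumerate(SUPPORTED_RATIOS):
            for i in range(n_per_class):
                m, f, _ = generate_pair(
                    GeneratorConfig(
                        ratio=ratio, phase_jitter_sd=0.0, seed=500 + 10 * ci + i,
                        subject_id=f"s{ci}_{i}",
                    )
                )
                enc = encode_segment(segment_minutes(m, f)[0], fs=fs)
                out.append((enc, ratio))
        return out

    def test_each_item_predicted_exactly_once(self):
        cfg = ModelConfig(fs=25.0, seed=3, max_epochs=2)
        dataset = self._dataset(cfg.fs)
        preds = loo_cv(dataset, cfg, grouping="segment")
        assert len(preds) == len(dataset)
        assert all(isinstance(p, Prediction) for p in preds)

    def test_subject_grouping_folds(self):
        cfg = ModelConfig(fs=25.0, seed=3, max_epochs=1)
        dataset = self._dataset(cfg.fs, n_per_class=2)  # 6 subjects, one segment each
        preds = loo_cv(dataset, cfg, grouping="subject")
        assert len(preds) == 6 and all(isinstance(p, Prediction) for p in preds)

    def test_fold_with_missing_class_skipped_and_logged(self):
        cfg = ModelConfig(fs=25.0, seed=3, max_epochs=1)
        dataset = self._dataset(cfg.fs, n_per_class=1)  # 3 subjects, one class each
        with pytest.warns(UserWarning, match="missing"):
            preds = loo_cv(dataset, cfg, grouping="subject")
        # leaving any subject out removes an entire class -> all folds skipped
        assert all(p is None for p in preds)

    def test_loo_predictions_are_deterministic(self):
        cfg = ModelConfig(fs=25.0, seed=6, max_epochs=1)
        dataset = self._dataset(cfg.fs, n_per_class=2)
        p1 = loo_cv(dataset, cfg, grouping="segment")
        p2 = loo_cv(dataset, cfg, grouping="segment")
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.probabilities, b.probabilities)

    def test_too_small_dataset_rejected(self):
        cfg = ModelConfig(fs=25.0)
        with pytest.raises(ValueError, match="3"):
            loo_cv(self._dataset(cfg.fs, n_per_class=1)[:2], cfg)
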