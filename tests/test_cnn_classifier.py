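"""CNN architecture anchors, gradients, training behaviour, inference."""

import numpy as np
import pytest

from tdprisk import synth_fixtures
from tdprisk.cnn_classifier import (
    Adam,
    ArchitectureSpec,
    CNNClassifier,
    ConfigurationError,
    TrainConfig,
    cross_entropy,
    layer_out_len,
    softmax,
    train,
)
from tdprisk.dataset import APDataset


class TestLayerOutLen:
    @pytest.mark.parametrize("args,expected", [
        ((1000, 32, 2), 485),
        ((10, 3, 1), 8),
        ((17, 1, 1), 17),
        ((485, 4, 1), 482),
        ((482, 16, 2), 234),
        ((234, 8, 2), 114),
        ((114, 8, 1), 107),
    ])
    def test_valid_convolution_lengths(self, args, expected):
        assert layer_out_len(*args) == expected

    def test_kernel_exceeding_input_rejected(self):
        with pytest.raises(ConfigurationError):
            layer_out_len(5, 6, 1)


class TestArchitecture:
    def test_default_chain_and_anchors(self):
        spec = ArchitectureSpec()
        assert spec.length_chain() == [1000, 485, 482, 234, 114, 107]
        assert spec.n_features == 214

    def test_bad_chain_fails_loudly_with_chain_printed(self):
        with pytest.raises(ConfigurationError, match=r"\[1000, 485, 482,"):
            ArchitectureSpec(pool2=(8, 3))

    def test_anchor_enforcement_can_be_disabled(self):
        spec = ArchitectureSpec(pool2=(8, 3), enforce_anchors=False)
        assert spec.n_features != 214

    def test_seeded_build_reproducible(self):
        a = CNNClassifier(seed=3)
        b = CNNClassifier(seed=3)
        assert a.n_params() == b.n_params()
        for pa, pb in zip(a.params, b.params):
            assert np.array_equal(pa, pb)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of every parameter match central differences
        on a shrunken network (training mode, dropout off)."""
        spec = ArchitectureSpec(
            input_len=60, conv_kernels=(8, 4, 3), conv_strides=(2, 1, 1),
            pool1=(3, 1), pool2=(2, 2), dropout_rate=0.0, hidden_units=4,
            enforce_anchors=False)
        model = CNNClassifier(spec, seed=0)
        rng = np.random.default_rng(1)
        x = rng.normal(-40, 30, size=(3, 60))
        y = np.eye(3)[rng.integers(0, 3, size=3)]

        def loss():
            return cross_entropy(softmax(model._forward(x, True, None)), y)

        base_probs = softmax(model._forward(x, True, None))
        model._backward((base_probs - y) / len(x))
        analytic = [g.copy() for g in model.grads]

        eps = 1e-6
        for p, g in zip(model.params, analytic):
            flat_p = p.ravel()
            flat_g = g.ravel()
            idx = np.random.default_rng(2).choice(
                p.size, size=min(10, p.size), replace=False)
            for i in idx:
                orig = flat_p[i]
                flat_p[i] = orig + eps
                lp = loss()
                flat_p[i] = orig - eps
                lm = loss()
                flat_p[i] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(flat_g[i], rel=1e-4, abs=1e-7)


class TestInference:
    def test_forward_rows_sum_to_one(self):
        model = CNNClassifier(seed=0)
        probs = model.predict_proba(np.zeros((4, 1000)))
        assert probs.shape == (4, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_repeat_prediction_identical(self):
        model = CNNClassifier(seed=0)
        x = np.random.default_rng(0).normal(-40, 30, (5, 1000))
        assert np.array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_batch_matches_singletons(self):
        model = CNNClassifier(seed=0)
        x = np.random.default_rng(1).normal(-40, 30, (6, 1000))
        batch = model.predict_proba(x)
        singles = np.vstack([model.predict_proba(x[i:i + 1]) for i in range(6)])
        assert np.allclose(batch, singles, atol=1e-5)

    def test_zeroed_final_layer_gives_uniform(self):
        model = CNNClassifier(seed=0)
        model.layers[-1].w[...] = 0.0
        model.layers[-1].b[...] = 0.0
        probs = model.predict_proba(np.random.default_rng(2).normal(0, 1, (3, 1000)))
        assert np.allclose(probs, 1.0 / 3.0, atol=1e-12)

    def test_wrong_length_rejected_not_cropped(self):
        model = CNNClassifier(seed=0)
        with pytest.raises(ValueError, match="length"):
            model.predict_proba(np.zeros((2, 999)))
        with pytest.raises(ValueError, match="length"):
            model.predict_proba(np.zeros((2, 1001)))


class TestTraining:
    def test_overfits_separable_surrogates(self, surrogate_ds):
        model = CNNClassifier(seed=0)
        hist = model.fit(surrogate_ds.x, surrogate_ds.y, epochs=30, lr=0.01,
                         batch_size=32, rng=np.random.default_rng(0))
        probs = model.predict_proba(surrogate_ds.x)
        acc = (probs.argmax(axis=1) == surrogate_ds.labels).mean()
        assert acc >= 0.95

    def test_loss_descends_after_first_epoch(self, surrogate_ds):
        model = CNNClassifier(seed=1)
        initial = cross_entropy(model.predict_proba(surrogate_ds.x),
                                surrogate_ds.y)
        hist = model.fit(surrogate_ds.x, surrogate_ds.y, epochs=1, lr=0.01,
                         batch_size=32, rng=np.random.default_rng(1))
        after = cross_entropy(model.predict_proba(surrogate_ds.x),
                              surrogate_ds.y)
        assert after < initial

    def test_permuted_labels_give_chance_accuracy(self, surrogate_ds):
        rng = np.random.default_rng(7)
        y_perm = surrogate_ds.y[rng.permutation(len(surrogate_ds))]
        n_val = 60
        model = CNNClassifier(seed=2)
        model.fit(surrogate_ds.x[n_val:], y_perm[n_val:], epochs=10, lr=0.01,
                  batch_size=32, rng=np.random.default_rng(2))
        probs = model.predict_proba(surrogate_ds.x[:n_val])
        acc = (probs.argmax(axis=1) == y_perm[:n_val].argmax(axis=1)).mean()
        assert abs(acc - 1.0 / 3.0) <= 0.15

    def test_cv_train_records_histories(self, surrogate_ds):
        cfg = TrainConfig(epochs=2, folds=2, seed=0)
        result = train(surrogate_ds, cfg)
        assert len(result.fold_histories) == 2
        assert all(len(h) == 2 for h in result.fold_histories)
        assert all("val_acc" in h[-1] for h in result.fold_histories)

    def test_single_class_dataset_rejected(self, surrogate_ds):
        idx = np.flatnonzero(surrogate_ds.labels == 0)
        with pytest.raises(ValueError, match="class"):
            train(surrogate_ds.subset(idx), TrainConfig(epochs=1, folds=2))


def test_model_save_load_round_trip(tmp_path, surrogate_ds):
    model = CNNClassifier(seed=0)
    model.fit(surrogate_ds.x[:64], surrogate_ds.y[:64], epochs=1, lr=0.01,
              batch_size=16, rng=np.random.default_rng(0))
    path = tmp_path / "m.npz"
    model.save(path)
    back = CNNClassifier.load(path)
    x = surrogate_ds.x[:10]
    assert np.array_equal(model.predict_proba(x), back.predict_proba(x))
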