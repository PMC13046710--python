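"""Network construction, shape algebra, parameter accounting, gradient
correctness and training behaviour."""

import numpy as np
import pytest

from dermatex.nn import layers as ly
from dermatex.nn.model import (SDNetConfig, TrainingConfig, build_model,
                               count_parameters, predict, train)


def tiny_config(**kw):
    base = dict(num_classes=3, conv2d_filters=(4, 6), conv1d_filters=(4, 6),
                input_image_size=(8, 8), input_vector_length=12)
    base.update(kw)
    return SDNetConfig(**base)


class TestShapes:
    def test_branch_flatten_lengths_follow_pooling_algebra(self):
        """For any config the flatten lengths equal the halving chain
        (with floor) times the last filter count."""
        for filters, size, veclen in [((64, 128, 256), (256, 256), 34_596),
                                      ((8, 16), (64, 48), 1001),
                                      ((4, 4, 4), (40, 40), 37)]:
            cfg = SDNetConfig(num_classes=4, conv2d_filters=filters,
                              conv1d_filters=filters, input_image_size=size,
                              input_vector_length=veclen)
            m = build_model(cfg, seed=0)
            h, w = size
            length = veclen
            for _ in filters:
                h, w, length = h // 2, w // 2, length // 2
            assert m.flatten2d == h * w * filters[-1]
            assert m.flatten1d == length * filters[-1]
            assert m.fusion_length == m.flatten2d + m.flatten1d

    def test_forward_probability_contract(self, rng):
        m = build_model(tiny_config(), seed=1)
        probs = m.forward(rng.random((5, 8, 8, 3)), rng.random((5, 12)))
        assert probs.shape == (5, 3)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_deterministic(self, rng):
        m = build_model(tiny_config(), seed=1)
        imgs, feats = rng.random((3, 8, 8, 3)), rng.random((3, 12))
        np.testing.assert_array_equal(m.forward(imgs, feats),
                                      m.forward(imgs, feats))

    def test_fresh_model_near_uniform_on_average(self):
        """Averaged over a seeded batch of 64 random inputs, a freshly
        initialized net predicts close to the uniform distribution."""
        rng = np.random.default_rng(0)
        m = build_model(tiny_config(num_classes=5), seed=3)
        probs = m.forward(rng.random((64, 8, 8, 3)), rng.random((64, 12)))
        np.testing.assert_allclose(probs.mean(axis=0), 0.2, atol=0.15)


class TestParameterCounting:
    @pytest.mark.parametrize("filters,veclen", [((4, 8), 20), ((3, 5, 7), 33)])
    def test_closed_form_per_layer(self, filters, veclen):
        cfg = SDNetConfig(num_classes=3, conv2d_filters=filters,
                          conv1d_filters=filters, input_image_size=(16, 16),
                          input_vector_length=veclen)
        m = build_model(cfg, seed=0)
        table = dict(count_parameters(m)[0])
        c_in = 3
        for i, c_out in enumerate(filters, start=1):
            assert table[f"conv2d_{i}"] == 3 * 3 * c_in * c_out + c_out
            assert table[f"batchnorm2d_{i}"] == 2 * c_out
            c_in = c_out
        c_in = 1
        for i, c_out in enumerate(filters, start=1):
            assert table[f"conv1d_{i}"] == 3 * c_in * c_out + c_out
            assert table[f"batchnorm1d_{i}"] == 2 * c_out
            c_in = c_out
        assert table["fc"] == m.fusion_length * 3 + 3

    def test_total_is_sum_of_layers(self):
        m = build_model(tiny_config(), seed=0)
        table, total = count_parameters(m)
        assert total == sum(c for _, c in table)
        assert total == sum(p.size for p in m.params())


class TestGradients:
    """Finite-difference checks per layer (directional derivatives)."""

    @staticmethod
    def directional_check(layer, x, train, rng, eps=1e-3, tol=5e-3):
        out = layer.forward(x, train=train)
        R = rng.standard_normal(out.shape).astype(np.float32)
        for p in layer.params():
            p.grad[...] = 0.0
        dx = layer.backward(R)
        d = rng.standard_normal(x.shape).astype(np.float32)
        num = ((layer.forward(x + eps * d, train=train) * R).sum()
               - (layer.forward(x - eps * d, train=train) * R).sum()) / (2 * eps)
        ana = (dx * d).sum()
        assert abs(num - ana) <= tol * (abs(num) + abs(ana) + 1.0)
        for p in layer.params():
            dp = rng.standard_normal(p.value.shape).astype(np.float32)
            orig = p.value.copy()
            p.value = orig + eps * dp
            lp = (layer.forward(x, train=train) * R).sum()
            p.value = orig - eps * dp
            lm = (layer.forward(x, train=train) * R).sum()
            p.value = orig
            layer.forward(x, train=train)
            for q in layer.params():
                q.grad[...] = 0.0
            layer.backward(R)
            num = (lp - lm) / (2 * eps)
            ana = (p.grad * dp).sum()
            assert abs(num - ana) <= tol * (abs(num) + abs(ana) + 1.0), p.name

    @pytest.mark.parametrize("name", ["conv2d", "conv1d", "bn_train",
                                      "bn_eval", "relu", "pool2d", "pool1d",
                                      "dense"])
    def test_layer_gradients(self, name):
        rng = np.random.default_rng(hash(name) % 2**31)
        init = np.random.default_rng(1)
        layers = {
            "conv2d": (ly.Conv2D(3, 4, 3, rng=init),
                       rng.random((2, 6, 6, 3)).astype(np.float32), True),
            "conv1d": (ly.Conv1D(2, 4, 3, rng=init),
                       rng.random((2, 10, 2)).astype(np.float32), True),
            "bn_train": (ly.BatchNorm(3),
                         rng.random((4, 5, 5, 3)).astype(np.float32), True),
            "bn_eval": (ly.BatchNorm(3),
                        rng.random((4, 5, 5, 3)).astype(np.float32), False),
            # keep inputs away from the kink at 0 for finite differences
            "relu": (ly.ReLU(),
                     (np.sign(rng.random((3, 5, 5, 2)) - 0.5)
                      * (0.1 + rng.random((3, 5, 5, 2)))).astype(np.float32),
                     True),
            "pool2d": (ly.MaxPool2D(),
                       rng.random((2, 6, 6, 2)).astype(np.float32), True),
            "pool1d": (ly.MaxPool1D(),
                       rng.random((2, 9, 2)).astype(np.float32), True),
            "dense": (ly.Dense(5, 3, rng=init),
                      rng.random((4, 5)).astype(np.float32), True),
        }
        layer, x, train = layers[name]
        self.directional_check(layer, x, train, rng)

    def test_softmax_cross_entropy_gradient(self):
        rng = np.random.default_rng(5)
        logits = rng.standard_normal((4, 3))
        y = np.array([0, 1, 2, 0])
        loss, g = ly.softmax_cross_entropy(logits, y)
        d = rng.standard_normal(logits.shape)
        eps = 1e-5
        num = (ly.softmax_cross_entropy(logits + eps * d, y)[0]
               - ly.softmax_cross_entropy(logits - eps * d, y)[0]) / (2 * eps)
        assert abs(num - (g * d).sum()) < 1e-6 * (1 + abs(num))

    def test_odd_length_pool_floors(self):
        x = np.arange(2 * 9 * 1, dtype=np.float32).reshape(2, 9, 1)
        out = ly.MaxPool1D().forward(x)
        assert out.shape == (2, 4, 1)   # 9 -> 4, last element dropped


class TestTraining:
    @staticmethod
    def make_separable(n_per_class=10, rng=None):
        rng = rng or np.random.default_rng(0)
        imgs, feats, ys = [], [], []
        for label, level in enumerate((0.2, 0.8)):
            for _ in range(n_per_class):
                imgs.append(np.full((8, 8, 3), level)
                            + 0.02 * rng.standard_normal((8, 8, 3)))
                feats.append(np.full(12, level)
                             + 0.02 * rng.standard_normal(12))
                ys.append(label)
        return (np.stack(imgs).astype(np.float32),
                np.stack(feats).astype(np.float32), np.array(ys))

    def test_overfits_separable_toy(self):
        imgs, feats, y = self.make_separable()
        m = build_model(tiny_config(num_classes=2), seed=0)
        tc = TrainingConfig(epochs=30, batch_size=8, seed=0)
        result = train(m, imgs, feats, y, tc)
        assert result.history[-1]["train_accuracy"] == 1.0
        assert result.history[-1]["train_loss"] < 0.5 * result.history[0]["train_loss"]

    def test_history_reproducible_across_runs(self):
        imgs, feats, y = self.make_separable()
        tc = TrainingConfig(epochs=5, batch_size=8, seed=3)
        h1 = train(build_model(tiny_config(num_classes=2), seed=2),
                   imgs, feats, y, tc).history
        h2 = train(build_model(tiny_config(num_classes=2), seed=2),
                   imgs, feats, y, tc).history
        assert h1 == h2

    def test_learning_rate_decays_on_schedule(self):
        imgs, feats, y = self.make_separable(n_per_class=5)
        tc = TrainingConfig(epochs=7, decay_every=3, decay_rate=0.5,
                            batch_size=8, seed=0)
        hist = train(build_model(tiny_config(num_classes=2), seed=0),
                     imgs, feats, y, tc).history
        lrs = [h["lr"] for h in hist]
        assert lrs[2] == pytest.approx(1e-3)
        assert lrs[3] == pytest.approx(5e-4)
        assert lrs[6] == pytest.approx(2.5e-4)

    def test_single_class_dataset_rejected(self):
        imgs, feats, y = self.make_separable(n_per_class=5)
        with pytest.raises(ValueError):
            train(build_model(tiny_config(num_classes=2), seed=0),
                  imgs, feats, np.zeros_like(y), TrainingConfig(epochs=1))

    @pytest.mark.parametrize("branch", ["2d", "1d"])
    def test_single_branch_ablations_train(self, branch):
        imgs, feats, y = self.make_separable()
        m = build_model(tiny_config(num_classes=2, branch=branch), seed=0)
        # the image-only variant needs more steps: batch normalization
        # re-centers the nearly constant maps each step
        tc = TrainingConfig(epochs=60, batch_size=8, seed=0)
        result = train(m, imgs, feats, y, tc)
        assert result.history[-1]["train_accuracy"] == 1.0


class TestPredict:
    def test_argmax_and_order(self, rng):
        m = build_model(tiny_config(), seed=4)
        imgs, feats = rng.random((6, 8, 8, 3)), rng.random((6, 12))
        labels, probs = predict(m, imgs, feats, batch_size=4)
        np.testing.assert_array_equal(labels, probs.argmax(axis=1))
        np.testing.assert_allclose(probs, m.forward(imgs, feats), atol=1e-6)

    def test_empty_batch(self):
        m = build_model(tiny_config(), seed=0)
        labels, probs = predict(m, np.zeros((0, 8, 8, 3)), np.zeros((0, 12)))
        assert labels.size == 0 and probs.shape == (0, 3)
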