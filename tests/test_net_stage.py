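"""Network tests: pooling-index mechanics, gradients, training contracts."""

import numpy as np
import pytest

from segfuse.exceptions import ConfigError, InferenceError, TrainingError
from segfuse.net_stage import (
    NetConfig,
    SegmentationNet,
    _softmax,
    build_network,
    extract_score_maps,
    max_pool_with_indices,
    max_unpool,
    predict_argmax,
    train_segmentation,
)


class TestPoolUnpool:
    def test_hand_enumerated_4x4_toy(self):
        x = np.array(
            [
                [1.0, 2.0, 5.0, 3.0],
                [4.0, 3.0, 2.0, 1.0],
                [0.0, 1.0, 1.0, 2.0],
                [2.0, 1.0, 0.0, 4.0],
            ]
        )[None, None]
        pooled, idx = max_pool_with_indices(x)
        np.testing.assert_array_equal(pooled[0, 0], [[4.0, 5.0], [2.0, 4.0]])
        # block-local argmax positions: (1,0)->2, (0,0)->0, (1,0)->2, (1,1)->3
        np.testing.assert_array_equal(idx[0, 0], [[2, 0], [2, 3]])
        restored = max_unpool(pooled, idx)
        expect = np.array(
            [
                [0.0, 0.0, 5.0, 0.0],
                [4.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 0.0],
                [2.0, 0.0, 0.0, 4.0],
            ]
        )
        np.testing.assert_array_equal(restored[0, 0], expect)

    def test_unpool_restores_maxima_only(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 3, 8, 8))
        pooled, idx = max_pool_with_indices(x)
        restored = max_unpool(pooled, idx)
        # nonzeros only at argmax positions, with the pooled values
        assert (restored != 0).sum() <= pooled.size
        mask = restored != 0
        np.testing.assert_array_equal(np.sort(restored[mask]), np.sort(pooled.ravel()))
        # and each nonzero sits at the max of its own 2x2 block
        blocks = x.reshape(2, 3, 4, 2, 4, 2).max(axis=(3, 5))
        np.testing.assert_array_equal(blocks, pooled)

    def test_odd_size_rejected(self):
        with pytest.raises(ConfigError):
            max_pool_with_indices(np.zeros((1, 1, 5, 4)))


class TestBuild:
    def test_output_shape_contract(self):
        net = build_network(NetConfig(in_channels=3, n_classes=4, depth=2))
        out = net.forward(np.zeros((1, 3, 192, 192), dtype=np.float32))
        assert out.shape == (1, 4, 192, 192)

    def test_same_seed_identical_parameters(self):
        a = build_network(NetConfig(in_channels=1, n_classes=2, seed=5))
        b = build_network(NetConfig(in_channels=1, n_classes=2, seed=5))
        for la, lb in zip(a._layers(), b._layers()):
            np.testing.assert_array_equal(la.weight, lb.weight)
            np.testing.assert_array_equal(la.bias, lb.bias)

    def test_indivisible_input_rejected(self):
        net = build_network(NetConfig(in_channels=1, n_classes=2, depth=2))
        with pytest.raises(ConfigError):
            net.forward(np.zeros((1, 1, 190, 192)))

    def test_invalid_config(self):
        with pytest.raises(ConfigError):
            NetConfig(in_channels=1, n_classes=3)
        with pytest.raises(ConfigError):
            NetConfig(in_channels=1, n_classes=2, depth=1)

    def test_parameter_count_positive(self):
        net = build_network(NetConfig(in_channels=1, n_classes=2))
        # enc 1->8, 8->16; dec 16->8, 8->8; head 8->2
        expect = (8 * 9 + 8) + (16 * 8 * 9 + 16) + (8 * 16 * 9 + 8) + (8 * 8 * 9 + 8) + (2 * 8 + 2)
        assert net.n_parameters == expect


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        net = build_network(NetConfig(in_channels=2, n_classes=2, base_width=4, seed=3))
        for layer in net._layers():
            layer.weight = layer.weight.astype(np.float64)
            layer.bias = layer.bias.astype(np.float64)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 2, 8, 8))
        y = rng.integers(0, 2, (2, 8, 8))

        def loss():
            p = _softmax(net.forward(x, keep=True))
            lp = np.log(np.take_along_axis(p, y[:, None], axis=1)[:, 0])
            return float(-lp.mean()), p

        _, p = loss()
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, y[:, None], 1.0, axis=1)
        grads = net.backward((p - onehot) / y.size)
        params = [q for layer in net._layers() for q in layer.params]
        eps = 1e-6
        for param, grad in zip(params, grads):
            flat = param.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp_, _ = loss()
                flat[i] = orig - eps
                lm_, _ = loss()
                flat[i] = orig
                numeric = (lp_ - lm_) / (2 * eps)
                assert numeric == pytest.approx(grad.ravel()[i], rel=1e-4, abs=1e-8)


def _toy_task(seed=0, n=4, size=16):
    """Tiny binary blobs task for fast training tests."""
    rng = np.random.default_rng(seed)
    images = rng.normal(0, 0.1, (n, 1, size, size)).astype(np.float32)
    labels = np.zeros((n, size, size), dtype=np.int64)
    for i in range(n):
        cy, cx = rng.integers(4, size - 4, 2)
        yy, xx = np.mgrid[0:size, 0:size]
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= 9
        labels[i][blob] = 1
        images[i, 0][blob] += 1.0
    return images, labels


class TestTraining:
    def test_loss_decreases(self):
        images, labels = _toy_task()
        net = build_network(
            NetConfig(in_channels=1, n_classes=2, base_width=4, epochs=30, seed=0)
        )
        trace = train_segmentation(net, images, labels)
        assert trace[-1] < trace[0]

    def test_label_space_mismatch(self):
        images, labels = _toy_task()
        net = build_network(NetConfig(in_channels=1, n_classes=2))
        with pytest.raises(TrainingError):
            train_segmentation(net, images, labels + 3)

    def test_constant_label_cohort_predicts_that_label(self):
        images, _ = _toy_task()
        labels = np.ones((images.shape[0], *images.shape[2:]), dtype=np.int64)
        net = build_network(
            NetConfig(in_channels=1, n_classes=2, base_width=4, epochs=15, seed=0)
        )
        train_segmentation(net, images, labels)
        pred = predict_argmax(extract_score_maps(net, images[0]))
        assert (pred == 1).all()

    def test_same_seed_identical_final_parameters(self):
        images, labels = _toy_task()
        nets = []
        for _ in range(2):
            net = build_network(
                NetConfig(in_channels=1, n_classes=2, base_width=4, epochs=5, seed=9)
            )
            train_segmentation(net, images, labels)
            nets.append(net)
        for la, lb in zip(nets[0]._layers(), nets[1]._layers()):
            np.testing.assert_array_equal(la.weight, lb.weight)

    def test_overfit_single_subject(self, phantom_subjects):
        # capacity check: >= 0.99 pixel accuracy on its own training image
        sub = phantom_subjects[0]
        images = sub.stack.data[0:1][None].astype(np.float32)
        labels = (sub.labels != 0).astype(np.int64)[None]
        net = build_network(
            NetConfig(
                in_channels=1,
                n_classes=2,
                epochs=60,
                learning_rate=2e-2,
                class_weights="inverse",
                seed=0,
            )
        )
        train_segmentation(net, images, labels)
        pred = predict_argmax(extract_score_maps(net, images[0]))
        assert (pred == labels[0]).mean() >= 0.99


class TestScoreMaps:
    def test_simplex_invariant(self, phantom_subjects):
        images, labels = _toy_task()
        net = build_network(NetConfig(in_channels=1, n_classes=2, base_width=4, epochs=2))
        train_segmentation(net, images, labels)
        maps = extract_score_maps(net, images[0])
        assert maps.min() >= 0 and maps.max() <= 1
        np.testing.assert_allclose(maps.sum(axis=0), 1.0, atol=1e-5)

    def test_four_class_order_and_count(self):
        net = build_network(NetConfig(in_channels=3, n_classes=4, base_width=4))
        maps = extract_score_maps(net, np.zeros((3, 16, 16), dtype=np.float32))
        assert maps.shape == (4, 16, 16)

    def test_channel_mismatch(self):
        net = build_network(NetConfig(in_channels=3, n_classes=4))
        with pytest.raises(InferenceError):
            extract_score_maps(net, np.zeros((2, 16, 16)))

    def test_near_tied_scores_representable(self):
        maps = np.array([0.4186, 0.4119, 0.1, 0.0695]).reshape(4, 1, 1)
        assert predict_argmax(maps)[0, 0] == 0
        assert maps[0, 0, 0] != maps[1, 0, 0]


class TestArgmax:
    def test_basic(self):
        scores = np.array([0.1, 0.2, 0.3, 0.4]).reshape(4, 1, 1)
        assert predict_argmax(scores)[0, 0] == 3

    def test_tie_breaks_to_lowest_index(self):
        scores = np.full((4, 2, 2), 0.25)
        assert (predict_argmax(scores) == 0).all()

    def test_matches_per_pixel_brute_force(self):
        rng = np.random.default_rng(1)
        scores = rng.random((4, 6, 6))
        got = predict_argmax(scores)
        for y in range(6):
            for x in range(6):
                best = max(range(4), key=lambda c: scores[c, y, x])
                assert got[y, x] == best


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        net = build_network(NetConfig(in_channels=1, n_classes=2, base_width=4, seed=2))
        path = tmp_path / "models" / "net.npz"
        net.save(path)
        loaded = SegmentationNet.load(path)
        assert loaded.config == net.config
        x = np.random.default_rng(0).normal(size=(1, 1, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), loaded.forward(x))
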