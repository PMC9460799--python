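"""Network primitives and exact parameter accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from drowsinet.nn import (
    INPUT_SHAPES,
    batch_norm,
    build_model,
    build_spec,
    conv2d,
    count_parameters,
    flatten_size,
    leaky_relu,
    same_padding,
    softmax,
)

# Published per-variant totals: (trainable, grand total, dense-layer weights)
PUBLISHED_COUNTS = {
    "face": (1_629_320, 1_630_542, 1_606_144),
    "eye": (4_217_992, 4_219_214, 4_194_816),
    "fusion": (6_315_144, 6_316_366, 6_291_968),
}


class TestSamePadding:
    @pytest.mark.parametrize("k,p", [(5, 2), (3, 1), (1, 0)])
    def test_values(self, k, p):
        assert same_padding(k) == p

    @pytest.mark.parametrize("k", [0, 2, 4])
    def test_even_or_degenerate_rejected(self, k):
        with pytest.raises(ValueError):
            same_padding(k)


class TestConv2d:
    def test_identity_kernel(self, rng):
        img = rng.random((6, 7))
        kernel = np.zeros((3, 3))
        kernel[1, 1] = 1.0
        assert np.allclose(conv2d(img, kernel), img)

    def test_ones_kernel_interior_sums(self):
        img = np.full((5, 5), 2.0)
        out = conv2d(img, np.ones((3, 3)))
        assert out[2, 2] == pytest.approx(18.0)  # 9 * 2 at an interior pixel

    def test_matches_bruteforce_double_sum(self, rng):
        """Cross-correlation sliding-window oracle on random 8x8 inputs."""
        img = rng.random((8, 8, 2))
        kernels = rng.random((3, 3, 2, 4))
        bias = rng.random(4)
        out = conv2d(img, kernels, bias)
        padded = np.pad(img, ((1, 1), (1, 1), (0, 0)))
        expected = np.zeros((8, 8, 4))
        for m in range(8):
            for n in range(8):
                for co in range(4):
                    acc = bias[co]
                    for j in range(3):
                        for k in range(3):
                            for ci in range(2):
                                acc += padded[m + j, n + k, ci] * kernels[j, k, ci, co]
                    expected[m, n, co] = acc
        assert np.allclose(out, expected, atol=1e-10)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            conv2d(rng.random((5, 5, 2)), rng.random((3, 3, 3, 4)))


class TestActivations:
    @pytest.mark.parametrize("x,expected", [(2.0, 2.0), (-10.0, -3.0), (0.0, 0.0)])
    def test_leaky_relu_values(self, x, expected):
        assert leaky_relu(x) == pytest.approx(expected)

    def test_softmax_symmetry_and_hand_value(self):
        assert np.allclose(softmax(np.zeros(2)), [0.5, 0.5])
        e = np.exp([1.0, 2.0, 3.0])
        assert np.allclose(softmax(np.array([1.0, 2.0, 3.0])), e / e.sum())

    def test_softmax_shift_invariance_and_overflow_safety(self, rng):
        x = rng.normal(size=6)
        assert np.allclose(softmax(x), softmax(x + 1234.5))
        assert np.all(np.isfinite(softmax(np.array([1e4, -1e4]))))

    @given(arrays(np.float64, 8, elements=st.floats(-50, 50)))
    @settings(max_examples=100, deadline=None)
    def test_softmax_normalization(self, x):
        out = softmax(x)
        assert abs(out.sum() - 1.0) < 1e-12
        assert np.all(out > 0)


class TestBatchNorm:
    def test_standardizes_batch(self, rng):
        x = rng.normal(3.0, 2.0, size=(64, 5))
        out = batch_norm(x, np.ones(5), np.zeros(5))
        assert np.allclose(out.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(out.var(axis=0), 1, atol=2e-2)  # eps shrinks slightly

    def test_constant_channel_maps_to_beta(self):
        x = np.full((10, 3), 7.0)
        beta = np.array([1.0, 2.0, 3.0])
        out = batch_norm(x, np.ones(3), beta)
        assert np.allclose(out, np.broadcast_to(beta, (10, 3)))


class TestArchitecture:
    @pytest.mark.parametrize("shape,size", [
        ((28, 28, 3), 3136), ((32, 64, 3), 8192), ((32, 96, 3), 12288)])
    def test_flatten_sizes(self, shape, size):
        assert flatten_size(shape) == size

    def test_layer_order_fixed(self):
        kinds = [l.kind for l in build_spec((28, 28, 3)).layers]
        assert kinds == ["input_bn", "conv", "bn", "maxpool", "conv", "bn",
                         "maxpool", "flatten", "dense", "bn", "dense"]

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            build_spec((3, 10, 3))
        with pytest.raises(ValueError):
            build_spec((10, 10, 1))

    def test_spec_json_roundtrip(self):
        spec = build_spec((32, 64, 3))
        from drowsinet.nn import ModelSpec

        assert ModelSpec.from_json(spec.to_json()) == spec


class TestParameterCounts:
    @pytest.mark.parametrize("variant", ["face", "eye", "fusion"])
    def test_published_totals(self, variant):
        trainable, total, dense_w = PUBLISHED_COUNTS[variant]
        pc = count_parameters(build_spec(INPUT_SHAPES[variant]))
        assert pc.per_layer[:8] == [12, 2432, 128, 0, 18496, 256, 0, 0]
        assert pc.per_layer[8:] == [dense_w, 2048, 1026]
        assert pc.trainable == trainable
        assert pc.total == total

    @pytest.mark.parametrize("shape", [(28, 28, 3), (32, 64, 3), (32, 96, 3), (16, 16, 3)])
    def test_analytic_counts_match_live_weight_enumeration(self, shape):
        """Oracle: walk the concrete model's weight arrays and sum sizes."""
        analytic = count_parameters(build_spec(shape))
        live = build_model(shape, seed=0).count_parameters()
        assert analytic.trainable == live.trainable
        assert analytic.non_trainable == live.non_trainable
        assert analytic.total == live.total


class TestNetworkBehavior:
    def test_spatial_preservation_and_halving(self, rng):
        net = build_model((16, 16, 3), seed=0, dtype=np.float64)
        x = rng.random((2, 16, 16, 3))
        net.forward(x)
        # last conv output: one pool applied -> 8x8, 64 channels
        assert net.last_conv_output.shape == (2, 8, 8, 64)
        assert net.fc1_activation.shape == (2, 512)

    def test_forward_is_deterministic(self, rng):
        net = build_model((16, 16, 3), seed=1)
        x = rng.random((3, 16, 16, 3)).astype(np.float32)
        assert np.array_equal(net.forward(x), net.forward(x))

    def test_predict_proba_rows_sum_to_one(self, rng):
        net = build_model((16, 16, 3), seed=1)
        p = net.predict_proba(rng.random((5, 16, 16, 3)).astype(np.float32))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert p.shape == (5, 2)

    def test_weight_gradients_match_finite_differences(self, rng):
        """Central finite differences of the full loss on a small float64 net."""
        net = build_model((8, 8, 3), seed=3, dtype=np.float64)
        x = rng.random((4, 8, 8, 3))
        y = np.eye(2)[rng.integers(0, 2, 4)]
        net.loss_and_backward(x, y)
        worst = 0.0
        for layer in net.layers:
            for (_, p), (_, g) in zip(layer.params(), layer.grads()):
                flat, gflat = p.reshape(-1), g.copy().reshape(-1)
                for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                    h = 1e-6
                    old = flat[i]
                    flat[i] = old + h
                    lp = net.loss_and_backward(x, y)
                    flat[i] = old - h
                    lm = net.loss_and_backward(x, y)
                    flat[i] = old
                    fd = (lp - lm) / (2 * h)
                    denom = max(1e-8, abs(fd) + abs(gflat[i]))
                    worst = max(worst, abs(fd - gflat[i]) / denom)
        assert worst < 1e-4

    def test_weights_roundtrip(self, rng, tmp_path):
        net = build_model((16, 16, 3), seed=4)
        x = rng.random((2, 16, 16, 3)).astype(np.float32)
        ref = net.forward(x)
        path = tmp_path / "w.npz"
        net.save_weights(path)
        other = build_model((16, 16, 3), seed=99)
        other.load_weights(path)
        assert np.array_equal(other.forward(x), ref)
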