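"""Grad-CAM: alpha weights, attention maps, exact gradients, scoring."""

import numpy as np
import pytest

from drowsinet.gradcam import (
    AttentionScore,
    FeatureActivations,
    GradCAMHeatmap,
    alpha_weights,
    attention_fraction,
    class_gradients,
    compute_gradcam,
    gradcam_map,
    render_overlay,
    upsample_map,
)
from drowsinet.nn import build_model


class TestAlphaWeights:
    def test_constant_gradient_gives_that_constant(self):
        A = np.zeros((3, 4, 2))
        grads = np.stack([np.full((3, 4), 0.7), np.full((3, 4), -1.2)], axis=-1)
        assert np.allclose(alpha_weights(A, grads), [0.7, -1.2])

    def test_zero_gradient_gives_zero(self):
        A = np.ones((2, 2, 3))
        assert np.allclose(alpha_weights(A, np.zeros_like(A)), 0.0)

    def test_hand_worked_2x2x2_example(self):
        grads = np.empty((2, 2, 2))
        grads[..., 0] = [[1.0, 2.0], [3.0, 4.0]]  # mean 2.5
        grads[..., 1] = [[-1.0, 0.0], [1.0, 8.0]]  # mean 2.0
        alpha = alpha_weights(np.zeros((2, 2, 2)), grads)
        assert np.allclose(alpha, [2.5, 2.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            alpha_weights(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


class TestGradcamMap:
    def test_single_channel_identity(self):
        A = np.abs(np.random.default_rng(0).normal(size=(3, 3, 1)))
        assert np.allclose(gradcam_map(A, np.array([1.0])), A[..., 0])

    def test_all_negative_sum_annihilated(self):
        A = np.ones((2, 2, 2))
        assert np.allclose(gradcam_map(A, np.array([-1.0, -0.5])), 0.0)

    def test_hand_worked_mixed_sign_example(self):
        A = np.empty((2, 2, 3))
        A[..., 0] = [[1.0, -1.0], [2.0, 0.0]]
        A[..., 1] = [[0.0, 3.0], [-2.0, 1.0]]
        A[..., 2] = [[1.0, 1.0], [1.0, 1.0]]
        alpha = np.array([2.0, -1.0, 0.5])
        weighted = 2.0 * A[..., 0] - A[..., 1] + 0.5 * A[..., 2]
        assert np.allclose(gradcam_map(A, alpha), np.maximum(weighted, 0.0))

    def test_positive_homogeneity(self, rng):
        A = rng.normal(size=(4, 5, 6))
        alpha = rng.normal(size=6)
        assert np.allclose(gradcam_map(3.5 * A, alpha), 3.5 * gradcam_map(A, alpha))


@pytest.fixture(scope="module")
def toy_net():
    net = build_model((8, 8, 3), seed=2, dtype=np.float64)
    # populate running statistics so inference mode is well-defined
    net.forward(np.random.default_rng(0).random((8, 8, 8, 3)), training=True)
    return net


class TestClassGradients:

    def test_gradients_match_finite_differences(self, toy_net, rng):
        img = rng.random((8, 8, 3))
        for cls in (0, 1):
            g = class_gradients(toy_net, img, cls)
            toy_net.forward(img[None])
            A0 = toy_net.last_conv_output[0]
            h = 1e-5
            for _ in range(10):
                i, j, k = (int(rng.integers(0, s)) for s in A0.shape)
                ap, am = A0.copy(), A0.copy()
                ap[i, j, k] += h
                am[i, j, k] -= h
                fd = (toy_net.head_forward(ap)[0, cls]
                      - toy_net.head_forward(am)[0, cls]) / (2 * h)
                assert abs(fd - g[i, j, k]) < 1e-4

    def test_class_gradients_differ_between_heads(self, toy_net, rng):
        img = rng.random((8, 8, 3))
        g0 = class_gradients(toy_net, img, 0)
        g1 = class_gradients(toy_net, img, 1)
        assert not np.allclose(g0, g1)

    def test_zero_input_gradients_finite(self, toy_net):
        g = class_gradients(toy_net, np.zeros((8, 8, 3)), 0)
        assert np.all(np.isfinite(g))

    def test_out_of_range_class_rejected(self, toy_net, rng):
        with pytest.raises(IndexError):
            class_gradients(toy_net, rng.random((8, 8, 3)), 5)

    def test_heatmaps_nonnegative_on_random_inputs(self, toy_net, rng):
        for _ in range(100):
            hm = compute_gradcam(toy_net, rng.random((8, 8, 3)))
            assert np.all(hm.raw_map >= 0)
            assert np.all(hm.upsampled_map >= 0)


class TestUpsample:
    def test_constant_map_stays_constant(self):
        up = upsample_map(np.full((2, 2), 3.0), (8, 8))
        assert np.allclose(up, 3.0)

    def test_one_by_one_map_broadcasts(self):
        up = upsample_map(np.array([[2.5]]), (6, 10))
        assert up.shape == (6, 10) and np.allclose(up, 2.5)

    def test_2x2_bilinear_hand_values(self):
        up = upsample_map(np.array([[0.0, 1.0], [1.0, 0.0]]), (4, 4))
        # edge-padded bilinear: corners keep source values; the (1,1) cell sits
        # at input coords (0.25, 0.25): 0.5625*0 + 0.1875*1 + 0.1875*1 + 0.0625*0
        assert up[0, 0] == pytest.approx(0.0)
        assert up[0, 3] == pytest.approx(1.0)
        assert up[0, 1] == pytest.approx(0.25)
        assert up[1, 1] == pytest.approx(0.375, abs=1e-9)

    def test_negative_map_rejected(self):
        with pytest.raises(ValueError):
            upsample_map(np.array([[-1.0, 0.0], [0.0, 0.0]]), (4, 4))

    def test_overlay_of_flat_map_is_valid_image(self, rng):
        img = rng.random((8, 8, 3))
        out = render_overlay(np.zeros((8, 8)), img)
        assert out.shape == (8, 8, 3) and out.dtype == np.uint8


class TestAttentionFraction:
    def test_full_mask_fraction_one(self, rng):
        hmap = rng.random((6, 6))
        score = attention_fraction(hmap, np.ones((6, 6), bool))
        assert score.mask_fraction == pytest.approx(1.0)
        assert score.mask_area_fraction == pytest.approx(1.0)

    def test_disjoint_support_fraction_zero(self):
        hmap = np.zeros((4, 4))
        hmap[:2] = 1.0
        mask = np.zeros((4, 4), bool)
        mask[2:] = True
        assert attention_fraction(hmap, mask).mask_fraction == 0.0

    def test_matches_bruteforce_summation(self, rng):
        for _ in range(20):
            hmap = rng.random((5, 7))
            mask = rng.random((5, 7)) > 0.5
            score = attention_fraction(hmap, mask)
            expected = sum(hmap[i, j] for i in range(5) for j in range(7) if mask[i, j])
            assert score.mask_fraction == pytest.approx(expected / hmap.sum())
            assert score.mask_area_fraction == pytest.approx(mask.mean())

    def test_zero_heatmap_flagged(self):
        score = attention_fraction(np.zeros((3, 3)), np.ones((3, 3), bool))
        assert score.empty_heatmap and score.mask_fraction == 0.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            AttentionScore(mask_fraction=1.5, mask_area_fraction=0.2)


class TestCamSpecialCase:
    def test_gradcam_reduces_to_cam_under_global_average_pooling(self, rng):
        """For a GAP classification head y^c = sum_k w_k mean_ij(A_k), the
        class gradient is the constant w_k/Z per channel, so the Grad-CAM map
        is exactly the ReLU'd CAM (w-weighted channel sum) scaled by 1/Z."""
        A = rng.normal(size=(4, 6, 3))
        w = rng.normal(size=3)
        Z = 4 * 6
        grads = np.broadcast_to(w / Z, (4, 6, 3)).copy()
        alpha = alpha_weights(A, grads)
        assert np.allclose(alpha, w / Z)
        cam = np.maximum(np.tensordot(A, w, axes=([2], [0])), 0.0)
        assert np.allclose(gradcam_map(A, alpha), cam / Z)


class TestFeatureActivations:
    def test_z_is_spatial_area(self):
        fa = FeatureActivations(np.zeros((4, 6, 8)))
        assert fa.Z == 24

    def test_nonfinite_rejected(self):
        bad = np.zeros((2, 2, 1))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            FeatureActivations(bad)
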