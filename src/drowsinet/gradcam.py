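"""Grad-CAM: gradient-weighted class activation maps from the last convolution.

For a class score :math:`y^c` (the pre-softmax logit by default) and the last
convolution's output grid :math:`A` (spatial i x j, channels k), the channel
weights are the spatial means of the backpropagated gradients,

.. math:: \\alpha_k^c = \\frac{1}{Z} \\sum_i \\sum_j
          \\frac{\\partial y^c}{\\partial A_{i,j}^k},  \\qquad Z = i \\cdot j,

and the attention map is the pixelwise ReLU of the alpha-weighted channel sum,
:math:`\\mathrm{ReLU}(\\sum_k \\alpha_k^c A^k)`, up-sampled bilinearly to the
input size for display. ReLU keeps only evidence *for* the class.

``attention_fraction`` quantifies where attention falls: the share of total
heatmap mass inside a region mask, with the mask's area fraction as the
chance baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from .nn import Network

__all__ = [
    "FeatureActivations",
    "GradCAMHeatmap",
    "AttentionScore",
    "alpha_weights",
    "gradcam_map",
    "class_gradients",
    "compute_gradcam",
    "upsample_map",
    "render_overlay",
    "attention_fraction",
]


@dataclass(frozen=True)
class FeatureActivations:
    """Last-convolution output for one input: (i, j, k) grid; Z = i*j."""

    A: np.ndarray

    def __post_init__(self):
        if self.A.ndim != 3 or not np.all(np.isfinite(self.A)):
            raise ValueError("A must be a finite (i, j, k) array")

    @property
    def Z(self) -> int:
        return self.A.shape[0] * self.A.shape[1]


@dataclass
class GradCAMHeatmap:
    raw_map: np.ndarray  # (i, j) non-negative
    upsampled_map: np.ndarray  # input-sized, non-negative
    class_index: int


@dataclass(frozen=True)
class AttentionScore:
    mask_fraction: float  # share of heatmap mass inside the mask
    mask_area_fraction: float  # chance baseline: mask area / image area
    empty_heatmap: bool = False  # True when the heatmap sums to zero

    def __post_init__(self):
        for v in (self.mask_fraction, self.mask_area_fraction):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"fractions must lie in [0, 1], got {v}")


def alpha_weights(activations: FeatureActivations | np.ndarray,
                  gradients: np.ndarray) -> np.ndarray:
    """Channel weights: spatial mean of the class-score gradient per channel."""
    A = activations.A if isinstance(activations, FeatureActivations) else activations
    if gradients.shape != A.shape:
        raise ValueError(f"gradient shape {gradients.shape} != activation shape {A.shape}")
    return gradients.mean(axis=(0, 1))


def gradcam_map(activations: FeatureActivations | np.ndarray,
                alpha: np.ndarray) -> np.ndarray:
    """Pixelwise ReLU of the alpha-weighted channel sum."""
    A = activations.A if isinstance(activations, FeatureActivations) else activations
    if alpha.shape != (A.shape[2],):
        raise ValueError(f"alpha must have one weight per channel ({A.shape[2]})")
    return np.maximum(A @ alpha, 0.0)


def class_gradients(network: Network, image: np.ndarray, class_index: int,
                    use_softmax_score: bool = False) -> np.ndarray:
    """Exact gradients of the class score w.r.t. the last conv output, (i, j, k).

    ``image`` is a single input in [0, 1], shape (rows, cols, 3).
    """
    grads = network.conv_gradients(image[None], class_index,
                                   use_softmax_score=use_softmax_score)
    return grads[0]


def upsample_map(raw_map: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear up-sampling of the raw heatmap to the input's spatial shape."""
    if np.any(raw_map < 0):
        raise ValueError("raw heatmap must be non-negative")
    if raw_map.shape == tuple(out_shape):
        return raw_map.copy()
    return np.maximum(
        _sk_resize(raw_map.astype(float), out_shape, order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True),
        0.0,
    )


def compute_gradcam(network: Network, image: np.ndarray,
                    class_index: int | None = None,
                    use_softmax_score: bool = False) -> GradCAMHeatmap:
    """Full Grad-CAM for one input image (in [0, 1]).

    ``class_index`` defaults to the predicted class.
    """
    if class_index is None:
        class_index = int(np.argmax(network.forward(image[None], training=False)[0]))
    grads = class_gradients(network, image, class_index,
                            use_softmax_score=use_softmax_score)
    A = network.last_conv_output[0]
    raw = gradcam_map(A, alpha_weights(A, grads))
    return GradCAMHeatmap(
        raw_map=raw,
        upsampled_map=upsample_map(raw, image.shape[:2]),
        class_index=class_index,
    )


def render_overlay(upsampled_map: np.ndarray, image: np.ndarray,
                   alpha: float = 0.5, cmap: str = "jet") -> np.ndarray:
    """Blend the min-max-normalized heatmap (blue = low, red = high with the
    default colormap) over the input image; returns a uint8 RGB image."""
    lo, hi = float(upsampled_map.min()), float(upsampled_map.max())
    norm = (upsampled_map - lo) / (hi - lo) if hi > lo else np.zeros_like(upsampled_map)
    colors = colormaps[cmap](norm)[..., :3]
    base = image.astype(float)
    if base.max() <= 1.0:
        base = base * 255.0
    out = (1 - alpha) * base + alpha * colors * 255.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def attention_fraction(heatmap: GradCAMHeatmap | np.ndarray,
                       mask: np.ndarray) -> AttentionScore:
    """Share of heatmap mass falling inside a boolean region mask.

    A zero-total heatmap yields fraction 0 with ``empty_heatmap`` set.
    """
    hmap = heatmap.upsampled_map if isinstance(heatmap, GradCAMHeatmap) else heatmap
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != hmap.shape:
        raise ValueError(f"mask shape {mask.shape} != heatmap shape {hmap.shape}")
    total = float(hmap.sum())
    area = float(mask.mean())
    if total <= 0.0:
        return AttentionScore(0.0, area, empty_heatmap=True)
    return AttentionScore(float(hmap[mask].sum() / total), area)
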