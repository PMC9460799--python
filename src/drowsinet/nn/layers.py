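"""Layer primitives for the drowsiness CNN.

Everything here is plain numpy. Each layer implements ``forward`` (caching
what backward needs) and ``backward`` (returning the gradient with respect to
its input and accumulating parameter gradients). Tensors are batched NHWC:
``(n, rows, cols, channels)`` for spatial layers, ``(n, features)`` after
flattening.

The functional helpers at the top (:func:`same_padding`, :func:`conv2d`,
:func:`leaky_relu`, :func:`softmax`, :func:`batch_norm`) are the single-sample
reference forms used directly by tests and by thin call sites; the layer
classes reuse the same math in batched form.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "same_padding",
    "conv2d",
    "leaky_relu",
    "softmax",
    "batch_norm",
    "Layer",
    "BatchNorm",
    "Conv2D",
    "LeakyReLU",
    "MaxPool2x2",
    "Flatten",
    "Dense",
]

#: Negative-side slope of LeakyReLU used throughout the model.
LEAKY_ALPHA = 0.3

#: Variance floor of batch normalization.
BN_EPS = 1e-3


def same_padding(kernel_size: int) -> int:
    """Padding width so that stride-1 convolution preserves spatial size.

    Only odd kernels are supported (the model uses 5 and 3); an even kernel
    cannot be padded symmetrically to preserve size.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    return (kernel_size - 1) // 2


def conv2d(image: np.ndarray, kernels: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Same-padded stride-1 2-D cross-correlation of one image.

    Parameters
    ----------
    image : (rows, cols, c_in) or (rows, cols)
        Input plane(s).  A 2-D array is treated as single-channel.
    kernels : (kh, kw, c_in, c_out) or (kh, kw)
        Filter bank; a 2-D array is a single filter on a single channel.
    bias : (c_out,), optional
        Per-filter bias, defaults to zero.

    Returns
    -------
    (rows, cols, c_out) array (or (rows, cols) if both inputs were 2-D).
    """
    squeeze = image.ndim == 2 and kernels.ndim == 2
    if image.ndim == 2:
        image = image[:, :, None]
    if kernels.ndim == 2:
        kernels = kernels[:, :, None, None]
    kh, kw, c_in, c_out = kernels.shape
    if image.shape[2] != c_in:
        raise ValueError(
            f"channel mismatch: image has {image.shape[2]} channels, kernels expect {c_in}"
        )
    ph, pw = same_padding(kh), same_padding(kw)
    padded = np.pad(image, ((ph, ph), (pw, pw), (0, 0)))
    # windows: (rows, cols, kh, kw, c_in)
    windows = sliding_window_view(padded, (kh, kw), axis=(0, 1)).transpose(0, 1, 3, 4, 2)
    out = np.tensordot(windows, kernels, axes=([2, 3, 4], [0, 1, 2]))
    if bias is not None:
        out = out + bias
    return out[:, :, 0] if squeeze else out


def leaky_relu(x, alpha: float = LEAKY_ALPHA):
    """LeakyReLU: identity for non-negative input, slope ``alpha`` below zero."""
    x = np.asarray(x)
    return np.where(x >= 0, x, alpha * x)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Overflow-safe softmax along ``axis`` (max-shifted exponentials)."""
    x = np.asarray(x, dtype=float)
    shifted = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def batch_norm(
    x: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    eps: float = BN_EPS,
) -> np.ndarray:
    """Training-mode batch normalization over all axes but the last.

    Standardizes each channel by its batch mean and variance, then applies the
    learned affine ``gamma * xhat + beta``. ``eps`` keeps zero-variance
    channels finite.
    """
    axes = tuple(range(x.ndim - 1))
    mean = x.mean(axis=axes)
    var = x.var(axis=axes)
    return gamma * (x - mean) / np.sqrt(var + eps) + beta


class Layer:
    """Base class: parameterless identity bookkeeping."""

    #: (name, array) pairs of trainable parameters, aligned with ``grads``.
    def params(self) -> list[tuple[str, np.ndarray]]:
        return []

    def grads(self) -> list[tuple[str, np.ndarray]]:
        return []

    def non_trainable(self) -> list[tuple[str, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class BatchNorm(Layer):
    """Per-channel batch normalization (channels-last).

    Training mode normalizes with batch statistics and updates exponential
    running statistics; inference mode uses the running statistics. ``gamma``
    and ``beta`` are trainable; the running mean/variance are not, which is
    why each channel carries 4 parameters but only 2 trainable ones.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = BN_EPS, dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def grads(self):
        return [("gamma", self.dgamma), ("beta", self.dbeta)]

    def non_trainable(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[:] = m * self.running_mean + (1 - m) * mean
            self.running_var[:] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, axes, training)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv_std, axes, training = self._cache
        self.dgamma[:] = np.sum(dout * xhat, axis=axes)
        self.dbeta[:] = np.sum(dout, axis=axes)
        if not training:
            return dout * self.gamma * inv_std
        # full batch-statistics backward; m as python float so float32 survives
        m = float(np.prod([xhat.shape[a] for a in axes]))
        dxhat = dout * self.gamma
        return (
            inv_std
            / m
            * (m * dxhat - np.sum(dxhat, axis=axes) - xhat * np.sum(dxhat * xhat, axis=axes))
        )


class Conv2D(Layer):
    """Same-padded stride-1 convolution (cross-correlation), im2col backed."""

    def __init__(self, kernel_size: int, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        k = kernel_size
        fan_in = k * k * c_in
        fan_out = k * k * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.w = rng.uniform(-limit, limit, size=(k, k, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k = k
        self.pad = same_padding(k)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [("w", self.dw), ("b", self.db)]

    def forward(self, x, training):
        n, h, w, c_in = x.shape
        k, p = self.k, self.pad
        padded = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (n, h, w, k, k, c_in) -> im2col matrix
        windows = sliding_window_view(padded, (k, k), axis=(1, 2)).transpose(0, 1, 2, 4, 5, 3)
        cols = np.ascontiguousarray(windows).reshape(n * h * w, k * k * c_in)
        self._cols = cols
        self._x_shape = x.shape
        c_out = self.w.shape[-1]
        out = cols @ self.w.reshape(-1, c_out) + self.b
        return out.reshape(n, h, w, c_out)

    def backward(self, dout):
        n, h, w, c_in = self._x_shape
        k, p = self.k, self.pad
        c_out = self.w.shape[-1]
        dflat = dout.reshape(-1, c_out)
        self.dw[:] = (self._cols.T @ dflat).reshape(self.w.shape)
        self.db[:] = dflat.sum(axis=0)
        dcols = (dflat @ self.w.reshape(-1, c_out).T).reshape(n, h, w, k, k, c_in)
        # col2im: scatter-add each kernel offset back onto the padded plane
        dpad = np.zeros((n, h + 2 * p, w + 2 * p, c_in), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dpad[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dpad[:, p : p + h, p : p + w, :]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = LEAKY_ALPHA):
        self.alpha = alpha

    def forward(self, x, training):
        self._neg = x < 0
        out = x.copy()
        np.multiply(out, out.dtype.type(self.alpha), where=self._neg, out=out)
        return out

    def backward(self, dout):
        out = dout.copy()
        np.multiply(out, out.dtype.type(self.alpha), where=self._neg, out=out)
        return out


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; trailing odd rows/cols are dropped."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
        out = xt.max(axis=(2, 4))
        # ties (rare with continuous activations) split gradient across maxima
        self._mask = xt == out[:, :, None, :, None, :]
        self._x_shape = x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._x_shape
        h2, w2 = h // 2, w // 2
        counts = self._mask.sum(axis=(2, 4), keepdims=True).astype(dout.dtype)
        dx_t = self._mask * (dout[:, :, None, :, None, :] / counts)
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        dx[:, : 2 * h2, : 2 * w2, :] = dx_t.reshape(n, 2 * h2, 2 * w2, c)
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [("w", self.dw), ("b", self.db)]

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw[:] = self._x.T @ dout
        self.db[:] = dout.sum(axis=0)
        return dout @ self.w.T
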