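"""The drowsiness CNN: declarative spec, exact parameter accounting, and a
concrete trainable network.

Architecture (identical for every input variant; only the input size and the
resulting flatten width differ)::

    BN(input) -> Conv 32@5x5 (same, stride 1) + LeakyReLU -> BN -> MaxPool 2x2
              -> Conv 64@3x3 (same, stride 1) + LeakyReLU -> BN -> MaxPool 2x2
              -> Flatten -> Dense 512 + LeakyReLU -> BN -> Dense 2 + SoftMax

The admissible production input shapes are (28, 28, 3) for face thumbnails,
(32, 64, 3) for stacked eye pairs, (32, 96, 3) for fusion images and
(37, 64, 3) for the gender-signal variant; any shape with >= 4 rows/cols and
3 channels builds fine (used by tests at toy sizes).

Batch-normalization channels carry 4 parameters each (scale, shift, running
mean, running variance) of which only scale and shift are trainable — this is
what separates the trainable total from the grand total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .layers import (
    BatchNorm,
    Conv2D,
    Dense,
    Flatten,
    Layer,
    LeakyReLU,
    MaxPool2x2,
    softmax,
)

__all__ = ["LayerSpec", "ModelSpec", "ParameterCount", "build_spec", "count_parameters",
           "build_model", "Network"]

INPUT_SHAPES = {
    "face": (28, 28, 3),
    "eye": (32, 64, 3),
    "fusion": (32, 96, 3),
    "eye+gender": (37, 64, 3),
}


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # input_bn | conv | bn | maxpool | flatten | dense | softmax_dense
    kernel: tuple[int, int] | None = None
    channels_out: int | None = None
    activation: str = "none"  # leaky_relu | softmax | none
    stride: int = 1


@dataclass(frozen=True)
class ModelSpec:
    input_shape: tuple[int, int, int]
    layers: tuple[LayerSpec, ...]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        layers = tuple(
            LayerSpec(
                kind=l["kind"],
                kernel=tuple(l["kernel"]) if l["kernel"] else None,
                channels_out=l["channels_out"],
                activation=l["activation"],
                stride=l["stride"],
            )
            for l in d["layers"]
        )
        return cls(input_shape=tuple(d["input_shape"]), layers=layers)


@dataclass
class ParameterCount:
    per_layer: list[int]
    trainable: int
    non_trainable: int

    @property
    def total(self) -> int:
        return self.trainable + self.non_trainable

    def to_dict(self) -> dict:
        return {
            "per_layer": self.per_layer,
            "trainable": self.trainable,
            "non_trainable": self.non_trainable,
            "total": self.total,
        }


def build_spec(input_shape: tuple[int, int, int]) -> ModelSpec:
    """The fixed layer sequence for a given input shape."""
    rows, cols, ch = input_shape
    if ch != 3:
        raise ValueError(f"input must have 3 channels, got {ch}")
    if rows < 4 or cols < 4:
        raise ValueError(f"input spatial size must be >= 4, got {rows}x{cols}")
    layers = (
        LayerSpec("input_bn"),
        LayerSpec("conv", kernel=(5, 5), channels_out=32, activation="leaky_relu"),
        LayerSpec("bn"),
        LayerSpec("maxpool", stride=2),
        LayerSpec("conv", kernel=(3, 3), channels_out=64, activation="leaky_relu"),
        LayerSpec("bn"),
        LayerSpec("maxpool", stride=2),
        LayerSpec("flatten"),
        LayerSpec("dense", channels_out=512, activation="leaky_relu"),
        LayerSpec("bn"),
        LayerSpec("dense", channels_out=2, activation="softmax"),
    )
    return ModelSpec(input_shape=tuple(input_shape), layers=layers)


def flatten_size(input_shape: tuple[int, int, int]) -> int:
    """Width of the flattened tensor after the two 2x2 poolings: ⌊r/4⌋·⌊c/4⌋·64."""
    rows, cols, _ = input_shape
    return (rows // 4) * (cols // 4) * 64


def count_parameters(spec: ModelSpec) -> ParameterCount:
    """Analytic per-layer parameter counts for a model spec.

    conv: k·k·c_in·c_out + c_out; dense: n_in·n_out + n_out; batch norm:
    4 per channel (2 trainable). Pooling/flatten contribute nothing.
    """
    rows, cols, ch = spec.input_shape
    per_layer: list[int] = []
    trainable = 0
    non_trainable = 0
    width = ch  # current channel/feature width
    for layer in spec.layers:
        if layer.kind in ("input_bn", "bn"):
            per_layer.append(4 * width)
            trainable += 2 * width
            non_trainable += 2 * width
        elif layer.kind == "conv":
            kh, kw = layer.kernel
            n = kh * kw * width * layer.channels_out + layer.channels_out
            per_layer.append(n)
            trainable += n
            width = layer.channels_out
        elif layer.kind == "maxpool":
            per_layer.append(0)
            rows, cols = rows // 2, cols // 2
        elif layer.kind == "flatten":
            per_layer.append(0)
            width = rows * cols * width
        elif layer.kind == "dense":
            n = width * layer.channels_out + layer.channels_out
            per_layer.append(n)
            trainable += n
            width = layer.channels_out
        else:  # pragma: no cover
            raise ValueError(f"unknown layer kind {layer.kind}")
    return ParameterCount(per_layer=per_layer, trainable=trainable, non_trainable=non_trainable)


class Network:
    """Concrete trainable network built from a :class:`ModelSpec`.

    Beyond plain forward/backward, the network exposes the two internal
    tensors the analysis stages need:

    * the activated output of the last convolution, the ``A`` grid that
      Grad-CAM weights — :meth:`forward` caches it, :meth:`conv_gradients`
      backpropagates a class score to it, and :meth:`head_forward` recomputes
      the logits from a given ``A`` (used by finite-difference checks);
    * the post-LeakyReLU output of the 512-unit dense layer, the feature
      vector used for PCA and KNN-Sigma (:meth:`forward` caches it as
      ``fc1_activation``).
    """

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        rows, cols, ch = spec.input_shape
        width = ch
        self.layers: list[Layer] = []
        self._last_conv_index = -1  # index in self.layers of the last Conv2D
        self._fc1_act_index = -1  # index of the LeakyReLU after Dense 512
        fr, fc = rows, cols
        for ls in spec.layers:
            if ls.kind in ("input_bn", "bn"):
                self.layers.append(BatchNorm(width, dtype=dtype))
            elif ls.kind == "conv":
                self.layers.append(Conv2D(ls.kernel[0], width, ls.channels_out, rng, dtype=dtype))
                width = ls.channels_out
                if ls.activation == "leaky_relu":
                    self.layers.append(LeakyReLU())
                # "last conv output" = the conv layer's activated output,
                # matching the framework convention of fused conv+activation
                self._last_conv_index = len(self.layers) - 1
            elif ls.kind == "maxpool":
                self.layers.append(MaxPool2x2())
                fr, fc = fr // 2, fc // 2
            elif ls.kind == "flatten":
                self.layers.append(Flatten())
                width = fr * fc * width
            elif ls.kind == "dense":
                self.layers.append(Dense(width, ls.channels_out, rng, dtype=dtype))
                width = ls.channels_out
                if ls.activation == "leaky_relu":
                    self.layers.append(LeakyReLU())
                    self._fc1_act_index = len(self.layers) - 1
            else:  # pragma: no cover
                raise ValueError(ls.kind)
        self.last_conv_output: np.ndarray | None = None
        self.fc1_activation: np.ndarray | None = None

    # ------------------------------------------------------------------ core
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the network; returns logits (pre-softmax scores), shape (n, 2)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, training)
            if i == self._last_conv_index:
                self.last_conv_output = x
            elif i == self._fc1_act_index:
                self.fc1_activation = x
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False), axis=-1)

    def loss_and_backward(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        """Mean categorical cross-entropy + full backward pass (fills grads)."""
        logits = self.forward(x, training=True)
        probs = softmax(logits, axis=-1)
        n = probs.shape[0]
        eps = 1e-12
        loss = -np.sum(y_onehot * np.log(probs + eps)) / n
        dlogits = ((probs - y_onehot) / n).astype(self.dtype)
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return float(loss)

    def sgd_step(self, lr: float) -> None:
        for layer in self.layers:
            for (_, p), (_, g) in zip(layer.params(), layer.grads()):
                p -= lr * g.astype(p.dtype)

    # ------------------------------------------------------- analysis hooks
    def head_forward(self, conv_out: np.ndarray, training: bool = False) -> np.ndarray:
        """Logits computed from a given last-conv output tensor.

        Runs only the layers after the last convolution (inference-mode batch
        norm unless ``training``). Used by Grad-CAM finite-difference checks.
        """
        x = np.asarray(conv_out, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        for layer in self.layers[self._last_conv_index + 1 :]:
            x = layer.forward(x, training)
        return x

    def conv_gradients(self, x: np.ndarray, class_index: int,
                       use_softmax_score: bool = False) -> np.ndarray:
        """Gradient of the class score w.r.t. the last convolution's output.

        The score is the pre-softmax logit of ``class_index`` by default
        (standard Grad-CAM practice); with ``use_softmax_score`` the softmax
        probability is differentiated instead.
        """
        logits = self.forward(x, training=False)
        n, k = logits.shape
        if not 0 <= class_index < k:
            raise IndexError(f"class index {class_index} out of range for {k} classes")
        if use_softmax_score:
            probs = softmax(logits, axis=-1)
            # d p_c / d logit_j = p_c (delta_cj - p_j)
            dlogits = probs[:, class_index : class_index + 1] * (
                np.eye(k, dtype=self.dtype)[class_index] - probs
            )
        else:
            dlogits = np.zeros_like(logits)
            dlogits[:, class_index] = 1.0
        grad = dlogits.astype(self.dtype)
        for layer in reversed(self.layers[self._last_conv_index + 1 :]):
            grad = layer.backward(grad)
        return grad

    # -------------------------------------------------------- introspection
    def parameter_arrays(self) -> list[tuple[str, np.ndarray, bool]]:
        """(name, array, trainable) for every parameter array in layer order."""
        out = []
        for i, layer in enumerate(self.layers):
            for name, p in layer.params():
                out.append((f"{i}:{type(layer).__name__}:{name}", p, True))
            for name, p in layer.non_trainable():
                out.append((f"{i}:{type(layer).__name__}:{name}", p, False))
        return out

    def count_parameters(self) -> ParameterCount:
        """Parameter count by enumerating the live weight arrays."""
        per_layer: dict[int, int] = {}
        trainable = 0
        non_trainable = 0
        for name, p, is_trainable in self.parameter_arrays():
            idx = int(name.split(":")[0])
            per_layer[idx] = per_layer.get(idx, 0) + p.size
            if is_trainable:
                trainable += p.size
            else:
                non_trainable += p.size
        counts = [per_layer.get(i, 0) for i in range(len(self.layers))]
        return ParameterCount(per_layer=[c for c in counts if True],
                              trainable=trainable, non_trainable=non_trainable)

    # -------------------------------------------------------- serialization
    def save_weights(self, path) -> None:
        arrays = {name: p for name, p, _ in self.parameter_arrays()}
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        data = np.load(path)
        for name, p, _ in self.parameter_arrays():
            p[:] = data[name]


def build_model(input_shape: tuple[int, int, int] | str, seed: int = 0,
                dtype=np.float32) -> Network:
    """Build the concrete network for an input shape or a named input type.

    ``input_shape`` may be a (rows, cols, 3) tuple or one of
    ``"face" | "eye" | "fusion" | "eye+gender"``.
    """
    if isinstance(input_shape, str):
        input_shape = INPUT_SHAPES[input_shape]
    return Network(build_spec(tuple(input_shape)), seed=seed, dtype=dtype)
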