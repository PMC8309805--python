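"""Network architecture: declarative layer stacks and the separable-conv primitive.

Two sibling architectures are defined. The depthwise-separable network
(``build_fc_dscnn``) is a VGG-style stack of six separable convolutions
with filter schedule 32, 64, 64, 128, 128, 128 — each followed by batch
normalization, with 2x2 max-pooling closing each of the three blocks — then
flatten, dropout 0.5, a 256-unit dense layer and a 2-way softmax. The
baseline (``build_dcnn``) is topologically identical with standard
convolutions substituted for separable ones.

A depthwise-separable convolution factors a standard convolution into a
per-channel spatial (depthwise) stage followed by a 1x1 cross-channel
(pointwise) stage, cutting the convolutional parameter count from
``kh*kw*C*F`` to ``kh*kw*C + C*F``. :func:`depthwise_separable_conv` is the
reference single-tensor definition; the trainable engine in
:mod:`mammocad.nn` consumes the declarative specs built here.

Shapes follow the channels-last ``H x W x C`` convention throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "depthwise_separable_conv",
    "conv2d",
    "build_fc_dscnn",
    "build_dcnn",
    "shape_trace",
    "conv_stage_param_count",
]

_KINDS = {
    "separable_conv",
    "conv2d",
    "batch_norm",
    "max_pool",
    "flatten",
    "dropout",
    "dense",
    "softmax",
}


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a declarative network description."""

    kind: str
    n_filters: Optional[int] = None
    kernel: Optional[Tuple[int, int]] = None
    stride: Tuple[int, int] = (1, 1)
    activation: str = "none"
    rate: Optional[float] = None  # dropout only
    units: Optional[int] = None  # dense/softmax only

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("separable_conv", "conv2d"):
            if not self.n_filters or self.n_filters <= 0:
                raise ValueError(f"{self.kind} requires a positive n_filters")
            if self.kernel is None or min(self.kernel) <= 0:
                raise ValueError(f"{self.kind} requires a positive kernel")
        if self.kind == "max_pool" and (self.kernel is None or min(self.kernel) <= 0):
            raise ValueError("max_pool requires a positive kernel")
        if self.kind == "dropout" and not (self.rate is not None and 0 <= self.rate < 1):
            raise ValueError("dropout requires a rate in [0, 1)")
        if self.kind in ("dense", "softmax") and (not self.units or self.units <= 0):
            raise ValueError(f"{self.kind} requires positive units")
        if min(self.stride) <= 0:
            raise ValueError("stride must be positive")
        if self.activation not in ("relu", "none"):
            raise ValueError("activation must be 'relu' or 'none'")


@dataclass(frozen=True)
class NetworkSpec:
    """A named, ordered layer stack with a fixed input shape."""

    name: str
    input_shape: Tuple[int, int, int]  # (H, W, C)
    layers: Tuple[LayerSpec, ...]
    n_classes: int = 2

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("network must have at least one layer")
        last = self.layers[-1]
        if last.kind != "softmax" or last.units != self.n_classes:
            raise ValueError("last layer must be a softmax with n_classes outputs")

    # -- lossless JSON round-trip ------------------------------------------
    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "n_classes": self.n_classes,
            "layers": [
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(layer).items() if v is not None}
                for layer in self.layers
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        payload = json.loads(text)
        layers = []
        for entry in payload["layers"]:
            entry = dict(entry)
            for key in ("kernel", "stride"):
                if key in entry and entry[key] is not None:
                    entry[key] = tuple(entry[key])
            layers.append(LayerSpec(**entry))
        return cls(
            name=payload["name"],
            input_shape=tuple(payload["input_shape"]),
            layers=tuple(layers),
            n_classes=payload["n_classes"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "NetworkSpec":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# functional primitives ("same" padding, channels-last)
# ---------------------------------------------------------------------------

def _same_pad(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    ph, pw = kh // 2, kw // 2
    pad = [(ph, ph), (pw, pw)] + [(0, 0)] * (x.ndim - 2)
    return np.pad(x, pad, mode="constant")


def _window_view(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(H, W, C) -> (H', W', C, kh, kw) sliding windows after same-padding."""
    padded = _same_pad(x, kh, kw)
    return np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(0, 1))


def depthwise_separable_conv(
    x: np.ndarray,
    depthwise_kernels: np.ndarray,
    pointwise_kernels: np.ndarray,
    stride: Tuple[int, int] = (1, 1),
) -> np.ndarray:
    """Two-stage separable convolution of a single ``(H, W, C)`` tensor.

    Stage 1 (depthwise) convolves each input channel independently with its
    own ``kh x kw`` filter from ``depthwise_kernels`` of shape
    ``(kh, kw, C)``. Stage 2 (pointwise) mixes channels at every pixel with
    1x1 filters given by ``pointwise_kernels`` of shape ``(C, F)``,
    producing ``F`` output maps. Padding is "same", so at stride (1, 1) the
    spatial dimensions are preserved; larger strides subsample the output.
    """
    x = np.asarray(x, dtype=np.float64)
    dk = np.asarray(depthwise_kernels, dtype=np.float64)
    pk = np.asarray(pointwise_kernels, dtype=np.float64)
    if x.ndim != 3 or dk.ndim != 3 or pk.ndim != 2:
        raise ValueError("expected x (H,W,C), depthwise (kh,kw,C), pointwise (C,F)")
    kh, kw, c = dk.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel dimensions must be odd")
    if x.shape[2] != c or pk.shape[0] != c:
        raise ValueError(
            f"channel mismatch: input has {x.shape[2]}, depthwise {c}, "
            f"pointwise {pk.shape[0]}"
        )
    view = _window_view(x, kh, kw)  # (H, W, C, kh, kw)
    depthwise = np.einsum("hwcij,ijc->hwc", view, dk)
    out = np.einsum("hwc,cf->hwf", depthwise, pk)
    sh, sw = stride
    return out[::sh, ::sw]


def conv2d(
    x: np.ndarray, kernels: np.ndarray, stride: Tuple[int, int] = (1, 1)
) -> np.ndarray:
    """Standard ``(H, W, C) -> (H', W', F)`` convolution, kernels ``(kh, kw, C, F)``."""
    x = np.asarray(x, dtype=np.float64)
    k = np.asarray(kernels, dtype=np.float64)
    kh, kw, c, _ = k.shape
    if x.shape[2] != c:
        raise ValueError(f"channel mismatch: input has {x.shape[2]}, kernel {c}")
    view = _window_view(x, kh, kw)
    out = np.einsum("hwcij,ijcf->hwf", view, k)
    sh, sw = stride
    return out[::sh, ::sw]


# ---------------------------------------------------------------------------
# architecture builders
# ---------------------------------------------------------------------------

#: filter schedule of the six convolutional layers, grouped into pooling blocks
_CONV_BLOCKS = ((32,), (64, 64), (128, 128, 128))


def _vgg_stack(conv_kind: str, input_shape, name: str) -> NetworkSpec:
    layers: List[LayerSpec] = []
    for block in _CONV_BLOCKS:
        for n_filters in block:
            layers.append(
                LayerSpec(
                    kind=conv_kind,
                    n_filters=n_filters,
                    kernel=(3, 3),
                    stride=(1, 1),
                    activation="relu",
                )
            )
            layers.append(LayerSpec(kind="batch_norm"))
        layers.append(LayerSpec(kind="max_pool", kernel=(2, 2), stride=(2, 2)))
    layers += [
        LayerSpec(kind="flatten"),
        LayerSpec(kind="dropout", rate=0.5),
        LayerSpec(kind="dense", units=256, activation="relu"),
        LayerSpec(kind="softmax", units=2),
    ]
    return NetworkSpec(name=name, input_shape=tuple(input_shape), layers=tuple(layers))


def build_fc_dscnn(input_shape: Tuple[int, int, int] = (240, 320, 3)) -> NetworkSpec:
    """The depthwise-separable network: 6 separable convs + 2 FC layers."""
    return _vgg_stack("separable_conv", input_shape, "fc-dscnn")


def build_dcnn(input_shape: Tuple[int, int, int] = (240, 320, 3)) -> NetworkSpec:
    """The standard-convolution baseline with identical topology."""
    return _vgg_stack("conv2d", input_shape, "dcnn")


# ---------------------------------------------------------------------------
# symbolic shape propagation and parameter counting
# ---------------------------------------------------------------------------

def shape_trace(spec: NetworkSpec) -> List[Tuple[LayerSpec, Tuple[int, ...]]]:
    """Propagate the input shape through every layer.

    Convolutions use "same" padding (spatial dims preserved at stride 1,
    ceil-divided otherwise); pooling floor-divides the spatial dims. Raises
    on the first layer whose input is inconsistent, naming it.
    """
    shape: Tuple[int, ...] = tuple(spec.input_shape)
    trace: List[Tuple[LayerSpec, Tuple[int, ...]]] = []
    for i, layer in enumerate(spec.layers):
        where = f"layer {i} ({layer.kind})"
        if layer.kind in ("separable_conv", "conv2d"):
            if len(shape) != 3:
                raise ValueError(f"{where}: expected a 3-D input, got {shape}")
            h, w, _ = shape
            sh, sw = layer.stride
            shape = (-(-h // sh), -(-w // sw), layer.n_filters)
        elif layer.kind == "batch_norm":
            if len(shape) != 3:
                raise ValueError(f"{where}: expected a 3-D input, got {shape}")
        elif layer.kind == "max_pool":
            if len(shape) != 3:
                raise ValueError(f"{where}: expected a 3-D input, got {shape}")
            h, w, c = shape
            kh, kw = layer.kernel
            shape = (h // kh, w // kw, c)
        elif layer.kind == "flatten":
            shape = (int(np.prod(shape)),)
        elif layer.kind == "dropout":
            pass
        elif layer.kind in ("dense", "softmax"):
            if len(shape) != 1:
                raise ValueError(f"{where}: expected a flat input, got {shape}")
            shape = (layer.units,)
        trace.append((layer, shape))
    return trace


def _layer_param_count(layer: LayerSpec, in_shape: Tuple[int, ...]) -> int:
    if layer.kind == "separable_conv":
        kh, kw = layer.kernel
        c = in_shape[2]
        return kh * kw * c + c * layer.n_filters + layer.n_filters  # dw + pw + bias
    if layer.kind == "conv2d":
        kh, kw = layer.kernel
        c = in_shape[2]
        return kh * kw * c * layer.n_filters + layer.n_filters
    if layer.kind == "batch_norm":
        return 2 * in_shape[-1]  # gamma + beta
    if layer.kind in ("dense", "softmax"):
        return in_shape[0] * layer.units + layer.units
    return 0


def conv_stage_param_count(spec: NetworkSpec) -> int:
    """Trainable parameters of the convolutional stage (conv layers only)."""
    total = 0
    shape = tuple(spec.input_shape)
    for layer, out_shape in shape_trace(spec):
        if layer.kind in ("separable_conv", "conv2d"):
            total += _layer_param_count(layer, shape)
        shape = out_shape
    return total
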