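"""A small trainable CNN engine in NumPy.

This module turns the declarative :class:`~mammocad.netcore.NetworkSpec`
stacks into runnable models: batched channels-last forward passes, exact
analytic backpropagation for every layer kind, a sample-weighted softmax
cross-entropy head (the "sparse categorical cross-entropy" loss — integer
labels, no one-hot encoding) and an AdaGrad optimizer. Everything is plain
float64 NumPy, so runs are bit-reproducible for a fixed seed on fixed
hardware.

Conventions: batches are ``(N, H, W, C)``; convolutions use "same" padding
at stride 1; max-pooling floor-divides spatial dims; batch normalization
follows the common framework defaults (momentum 0.99, epsilon 1e-3, batch
statistics during training, running statistics at inference); dropout is
inverted (activations scaled at train time, identity at inference).
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .netcore import LayerSpec, NetworkSpec

__all__ = ["Model", "AdaGrad", "build_model", "softmax", "sparse_ce_loss"]


def _window_view(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, C, kh, kw) sliding windows, same-padded."""
    ph, pw = kh // 2, kw // 2
    padded = np.pad(x, [(0, 0), (ph, ph), (pw, pw), (0, 0)], mode="constant")
    return np.lib.stride_tricks.sliding_window_view(padded, (kh, kw), axis=(1, 2))


class _Layer:
    """Base: trainable arrays live in ``params`` with matching ``grads``."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _ReluMixin:
    def _activate(self, z: np.ndarray) -> np.ndarray:
        if self.relu:
            self._mask = z > 0
            return z * self._mask
        return z

    def _deactivate(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask if self.relu else dout


class SeparableConv2D(_Layer, _ReluMixin):
    """Depthwise (per-channel kh x kw) then pointwise (1x1) convolution."""

    def __init__(self, c_in: int, n_filters: int, kernel: Tuple[int, int],
                 relu: bool, rng: np.random.Generator) -> None:
        super().__init__()
        kh, kw = kernel
        self.kh, self.kw = kh, kw
        self.relu = relu
        # He initialization per stage: fan-in kh*kw for depthwise, c_in for pointwise
        self.params = {
            "dw": rng.normal(0, np.sqrt(2.0 / (kh * kw)), size=(kh, kw, c_in)),
            "pw": rng.normal(0, np.sqrt(2.0 / c_in), size=(c_in, n_filters)),
            "b": np.zeros(n_filters),
        }

    def forward(self, x, training):
        self._view = _window_view(x, self.kh, self.kw)  # (N,H,W,C,kh,kw)
        self._depth = np.einsum(
            "nhwcij,ijc->nhwc", self._view, self.params["dw"], optimize=True
        )
        z = np.einsum("nhwc,cf->nhwf", self._depth, self.params["pw"],
                      optimize=True) + self.params["b"]
        return self._activate(z)

    def backward(self, dout):
        dout = self._deactivate(dout)
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        self.grads["pw"] = np.einsum(
            "nhwc,nhwf->cf", self._depth, dout, optimize=True
        )
        ddepth = np.einsum("nhwf,cf->nhwc", dout, self.params["pw"], optimize=True)
        self.grads["dw"] = np.einsum(
            "nhwcij,nhwc->ijc", self._view, ddepth, optimize=True
        )
        dview = _window_view(ddepth, self.kh, self.kw)
        flipped = self.params["dw"][::-1, ::-1]
        return np.einsum("nhwcij,ijc->nhwc", dview, flipped, optimize=True)


class Conv2D(_Layer, _ReluMixin):
    """Standard same-padded convolution, kernels ``(kh, kw, C, F)``."""

    def __init__(self, c_in: int, n_filters: int, kernel: Tuple[int, int],
                 relu: bool, rng: np.random.Generator) -> None:
        super().__init__()
        kh, kw = kernel
        self.kh, self.kw = kh, kw
        self.relu = relu
        fan_in = kh * kw * c_in
        self.params = {
            "k": rng.normal(0, np.sqrt(2.0 / fan_in), size=(kh, kw, c_in, n_filters)),
            "b": np.zeros(n_filters),
        }

    def forward(self, x, training):
        self._view = _window_view(x, self.kh, self.kw)
        z = np.einsum("nhwcij,ijcf->nhwf", self._view, self.params["k"],
                      optimize=True) + self.params["b"]
        return self._activate(z)

    def backward(self, dout):
        dout = self._deactivate(dout)
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        self.grads["k"] = np.einsum(
            "nhwcij,nhwf->ijcf", self._view, dout, optimize=True
        )
        dview = _window_view(dout, self.kh, self.kw)
        flipped = self.params["k"][::-1, ::-1]
        return np.einsum("nhwfij,ijcf->nhwc", dview, flipped, optimize=True)


class BatchNorm(_Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._seen_batch = False

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            if not self._seen_batch:
                # seed the running statistics from the first batch so short
                # runs are not biased toward the (0, 1) initialization
                self.running_mean, self.running_var = mu, var
                self._seen_batch = True
            else:
                self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
                self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mu) / self._std
            self._m = x.size // x.shape[-1]
            return self.params["gamma"] * self._xhat + self.params["beta"]
        return (
            self.params["gamma"] * (x - self.running_mean)
            / np.sqrt(self.running_var + self.eps)
            + self.params["beta"]
        )

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        self.grads["beta"] = dout.sum(axis=axes)
        self.grads["gamma"] = (dout * self._xhat).sum(axis=axes)
        m = self._m
        dxhat = dout * self.params["gamma"]
        return (
            dxhat - dxhat.mean(axis=axes)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class MaxPool2x2(_Layer):
    """2x2 max-pooling with stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        cropped = x[:, : 2 * h2, : 2 * w2]
        win = cropped.reshape(n, h2, 2, w2, 2, c)
        out = win.max(axis=(2, 4))
        # gradient mask; ties share the gradient equally
        eq = win == out[:, :, None, :, None, :]
        self._mask = eq / eq.sum(axis=(2, 4), keepdims=True)
        return out

    def backward(self, dout):
        n, h2, w2, c = dout.shape
        dwin = self._mask * dout[:, :, None, :, None, :]
        dx = np.zeros(self._in_shape)
        dx[:, : 2 * h2, : 2 * w2] = dwin.reshape(n, 2 * h2, 2 * w2, c)
        return dx


class Flatten(_Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(_Layer, _ReluMixin):
    def __init__(self, d_in: int, units: int, relu: bool,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.relu = relu
        self.params = {
            "w": rng.normal(0, np.sqrt(2.0 / d_in), size=(d_in, units)),
            "b": np.zeros(units),
        }

    def forward(self, x, training):
        self._x = x
        return self._activate(x @ self.params["w"] + self.params["b"])

    def backward(self, dout):
        dout = self._deactivate(dout)
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sparse_ce_loss(
    logits: np.ndarray,
    y: np.ndarray,
    sample_weight: Optional[np.ndarray] = None,
) -> Tuple[float, np.ndarray]:
    """Weighted sparse categorical cross-entropy and its logit gradient."""
    n = logits.shape[0]
    p = softmax(logits)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    logp = np.log(np.clip(p[np.arange(n), y], 1e-300, None))
    loss = float(-(w * logp).sum() / w.sum())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad


class Model:
    """A runnable layer stack built from a :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec, layers: List[_Layer]) -> None:
        self.spec = spec
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x  # logits (softmax head applied in the loss / predict_proba)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], training=False)))
        return np.concatenate(out) if out else np.empty((0, self.spec.n_classes))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def iter_params(self) -> Iterator[Tuple[_Layer, str]]:
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def n_params(self) -> int:
        return sum(layer.params[n].size for layer, n in self.iter_params())


def build_model(spec: NetworkSpec, seed: int = 0) -> Model:
    """Instantiate a trainable model (He-initialized) from a declarative spec."""
    rng = np.random.default_rng(seed)
    layers: List[_Layer] = []
    shape: Tuple[int, ...] = tuple(spec.input_shape)
    for ls in spec.layers:
        relu = ls.activation == "relu"
        if ls.kind == "separable_conv":
            layers.append(SeparableConv2D(shape[2], ls.n_filters, ls.kernel, relu, rng))
            shape = (shape[0], shape[1], ls.n_filters)
        elif ls.kind == "conv2d":
            layers.append(Conv2D(shape[2], ls.n_filters, ls.kernel, relu, rng))
            shape = (shape[0], shape[1], ls.n_filters)
        elif ls.kind == "batch_norm":
            layers.append(BatchNorm(shape[-1]))
        elif ls.kind == "max_pool":
            layers.append(MaxPool2x2())
            shape = (shape[0] // 2, shape[1] // 2, shape[2])
        elif ls.kind == "flatten":
            layers.append(Flatten())
            shape = (int(np.prod(shape)),)
        elif ls.kind == "dropout":
            layers.append(Dropout(ls.rate, rng))
        elif ls.kind in ("dense", "softmax"):
            # the softmax spec layer is a linear map; the softmax itself is
            # fused into the loss / predict_proba for numerical stability
            layers.append(Dense(shape[0], ls.units, relu, rng))
            shape = (ls.units,)
        else:  # pragma: no cover - LayerSpec validates kinds
            raise ValueError(f"unsupported layer kind {ls.kind!r}")
    return Model(spec, layers)


class AdaGrad:
    """AdaGrad in its classic form: zero-initialized squared-gradient
    accumulator, update ``w -= lr * g / (sqrt(acc) + eps)``."""

    def __init__(self, model: Model, initial_accumulator: float = 0.0,
                 eps: float = 1e-7) -> None:
        self.model = model
        self.eps = eps
        self.acc = {
            (id(layer), name): np.full_like(layer.params[name], initial_accumulator)
            for layer, name in model.iter_params()
        }

    def step(self, lr: float) -> None:
        for layer, name in self.model.iter_params():
            g = layer.grads.get(name)
            if g is None:
                continue
            acc = self.acc[(id(layer), name)]
            acc += g * g
            layer.params[name] -= lr * g / (np.sqrt(acc) + self.eps)
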