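"""Minimal CPU layers with explicit forward/backward passes.

All spatial tensors are NHWC.  Convolutions use "same" padding with output
size ``ceil(H/stride)``; im2col patches are built by stacking strided slices
(one per kernel offset), which keeps both passes as large matrix products.
Parameters are float32 by default; gradient-check tests instantiate layers in
float64.

Each layer exposes ``forward(x, train)``, ``backward(grad)`` (returning the
gradient w.r.t. its input and stashing parameter gradients), and ``params()``
yielding ``Param`` slots for the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ValidationError


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray
    state: dict = field(default_factory=dict)   # optimizer slots


def _same_pad(size: int, stride: int, kernel: int) -> tuple[int, int, int]:
    """Return (out_size, pad_before, pad_after) for SAME padding."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    before = total // 2
    return out, before, total - before


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2D(Layer):
    """KxK convolution, SAME padding, He-initialized, optional bias."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32):
        fan_in = kernel * kernel * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(kernel, kernel, c_in, c_out))
        self.w = Param(w.astype(dtype), np.zeros_like(w, dtype=dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype),
                       np.zeros(c_out, dtype=dtype))
        self.kernel, self.stride = kernel, stride
        self.c_in, self.c_out = c_in, c_out
        self.dtype = dtype
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w_, c = x.shape
        if c != self.c_in:
            raise ValidationError(f"expected {self.c_in} channels, got {c}")
        k, s = self.kernel, self.stride
        if k == 1:
            # pointwise conv: a plain matrix product, no patch extraction
            xs = x if s == 1 else x[:, ::s, ::s, :]
            oh, ow = xs.shape[1], xs.shape[2]
            cols2 = np.ascontiguousarray(xs).reshape(n * oh * ow, c)
            out = cols2 @ self.w.value.reshape(c, self.c_out) + self.b.value
            if train:
                self._cache = (cols2, x.shape, None, (0, 0), (oh, ow))
            return out.reshape(n, oh, ow, self.c_out)
        oh, pt, pb = _same_pad(h, s, k)
        ow, pl, pr = _same_pad(w_, s, k)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cols = np.empty((n, oh, ow, k * k, c), dtype=x.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            cols[:, :, :, idx, :] = xp[:, i:i + s * oh:s, j:j + s * ow:s, :]
        cols2 = cols.reshape(n * oh * ow, k * k * c)
        w_mat = self.w.value.reshape(k * k * c, self.c_out)
        out = cols2 @ w_mat + self.b.value
        if train:
            self._cache = (cols2, x.shape, xp.shape, (pt, pl), (oh, ow))
        return out.reshape(n, oh, ow, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols2, x_shape, xp_shape, (pt, pl), (oh, ow) = self._cache
        n, h, w_, c = x_shape
        k, s = self.kernel, self.stride
        g2 = np.ascontiguousarray(grad).reshape(n * oh * ow, self.c_out)
        self.w.grad[...] = (cols2.T @ g2).reshape(self.w.value.shape)
        self.b.grad[...] = g2.sum(axis=0)
        dcols = g2 @ self.w.value.reshape(k * k * c, self.c_out).T
        self._cache = None
        if k == 1:
            if s == 1:
                return dcols.reshape(n, h, w_, c)
            dx = np.zeros(x_shape, dtype=grad.dtype)
            dx[:, ::s, ::s, :] = dcols.reshape(n, oh, ow, c)
            return dx
        dcols = dcols.reshape(n, oh, ow, k * k, c)
        dxp = np.zeros(xp_shape, dtype=grad.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            dxp[:, i:i + s * oh:s, j:j + s * ow:s, :] += dcols[:, :, :, idx, :]
        return dxp[:, pt:pt + h, pl:pl + w_, :]

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Affine(Layer):
    """Fixed elementwise ``scale * x + shift`` (no trainable state).

    Used to center [0, 1] image inputs to [-1, 1] so the He-initialized stem
    sees zero-mean activations.
    """

    def __init__(self, scale: float, shift: float):
        self.scale, self.shift = scale, shift

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x * np.asarray(self.scale, dtype=x.dtype) + \
            np.asarray(self.shift, dtype=x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * np.asarray(self.scale, dtype=grad.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2D(Layer):
    """KxK max pooling with SAME padding (pad value -inf)."""

    def __init__(self, kernel: int = 3, stride: int = 2):
        self.kernel, self.stride = kernel, stride

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w_, c = x.shape
        k, s = self.kernel, self.stride
        oh, pt, pb = _same_pad(h, s, k)
        ow, pl, pr = _same_pad(w_, s, k)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)),
                    constant_values=-np.inf)
        out = None
        for idx in range(k * k):
            i, j = divmod(idx, k)
            window = xp[:, i:i + s * oh:s, j:j + s * ow:s, :]
            out = window.copy() if out is None else np.maximum(out, window)
        if train:
            self._cache = (xp, out, x.shape, (pt, pl), (oh, ow))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        # grad of an output cell is split equally among all window positions
        # attaining the max (a valid, deterministic subgradient under ties)
        xp, out, x_shape, (pt, pl), (oh, ow) = self._cache
        n, h, w_, c = x_shape
        k, s = self.kernel, self.stride
        count = np.zeros_like(grad)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            count += xp[:, i:i + s * oh:s, j:j + s * ow:s, :] == out
        share = grad / count
        dxp = np.zeros(xp.shape, dtype=grad.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            window = xp[:, i:i + s * oh:s, j:j + s * ow:s, :]
            dxp[:, i:i + s * oh:s, j:j + s * ow:s, :] += \
                np.where(window == out, share, 0)
        self._cache = None
        return dxp[:, pt:pt + h, pl:pl + w_, :]


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w_, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w_),
                               self._shape).astype(grad.dtype)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValidationError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return grad
        return grad * self._mask


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out))
        self.w = Param(w.astype(dtype), np.zeros_like(w, dtype=dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype),
                       np.zeros(c_out, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad[...] = self._x.T @ grad
        self.b.grad[...] = grad.sum(axis=0)
        return grad @ self.w.value.T

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


class ResidualBlock(Layer):
    """Two stride-preserving 3x3 convs (ReLU each) plus a 1x1 projection skip.

    The first body conv and the skip both use ``stride`` (2 by default), so
    the block halves the spatial map while changing the channel count.
    """

    def __init__(self, c_in: int, n_filters: int, rng: np.random.Generator,
                 stride: int = 2, kernel: int = 3, dtype=np.float32):
        self.body = Sequential([
            Conv2D(c_in, n_filters, kernel, stride, rng, dtype), ReLU(),
            Conv2D(n_filters, n_filters, kernel, 1, rng, dtype), ReLU(),
        ])
        self.skip = Conv2D(c_in, n_filters, 1, stride, rng, dtype)
        self.n_filters = n_filters

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.body.forward(x, train) + self.skip.forward(x, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.body.backward(grad) + self.skip.backward(grad)

    def params(self) -> list[Param]:
        return self.body.params() + self.skip.params()


class InceptionBlock(Layer):
    """Classical 4-branch inception block, channel-concatenated.

    Branches: 1x1 (f1); 1x1 reduce (f2) -> 3x3 (f3); 1x1 reduce (f4) ->
    5x5 (f5); 3x3 max pool (stride 1) -> 1x1 projection (f6).  Every
    convolution is followed by ReLU.  Output channels = f1 + f3 + f5 + f6.
    """

    def __init__(self, c_in: int, filters: tuple[int, int, int, int, int, int],
                 rng: np.random.Generator, dtype=np.float32):
        f1, f2, f3, f4, f5, f6 = filters
        self.branches = [
            Sequential([Conv2D(c_in, f1, 1, 1, rng, dtype), ReLU()]),
            Sequential([Conv2D(c_in, f2, 1, 1, rng, dtype), ReLU(),
                        Conv2D(f2, f3, 3, 1, rng, dtype), ReLU()]),
            Sequential([Conv2D(c_in, f4, 1, 1, rng, dtype), ReLU(),
                        Conv2D(f4, f5, 5, 1, rng, dtype), ReLU()]),
            Sequential([MaxPool2D(3, 1),
                        Conv2D(c_in, f6, 1, 1, rng, dtype), ReLU()]),
        ]
        self.filters = filters
        self._splits = (f1, f3, f5, f6)

    @property
    def c_out(self) -> int:
        return sum(self._splits)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.concatenate(
            [b.forward(x, train) for b in self.branches], axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        edges = np.cumsum((0,) + self._splits)
        total = None
        for b, lo, hi in zip(self.branches, edges[:-1], edges[1:]):
            g = b.backward(np.ascontiguousarray(grad[..., lo:hi]))
            total = g if total is None else total + g
        return total

    def params(self) -> list[Param]:
        return [p for b in self.branches for p in b.params()]
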