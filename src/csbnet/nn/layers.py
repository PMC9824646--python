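"""Minimal numpy neural-network layers with explicit backward passes.

Convolutions use im2col so the heavy lifting is a single BLAS matmul per
layer; every layer caches what its backward pass needs during forward.
All arithmetic is float32.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base layer: forward(x) -> y, backward(dy) -> dx."""

    name: str = ""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad.fill(0.0)


def _uniform_init(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, gain: float = 2.0
) -> np.ndarray:
    # Uniform with Var = gain/fan_in: gain 2 (He) keeps activation variance
    # constant through ReLU layers, gain 1 through purely affine layers.
    bound = np.sqrt(3.0 * gain / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold (N,C,H,W) into (N, C*k*k, oh*ow) patch columns."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow), oh, ow


def col2im(
    dcols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
    oh: int,
    ow: int,
) -> np.ndarray:
    """Adjoint of im2col: scatter-add patch gradients back to image layout."""
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        gain: float = 2.0,
        name: str = "",
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.name = name
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_uniform_init(rng, (out_channels, fan_in), fan_in, gain))
        self.bias = (
            Parameter(_uniform_init(rng, (out_channels,), fan_in, 0.5)) if bias else None
        )
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cols, oh, ow = im2col(x, self.kernel_size, self.stride, self.padding)
        out = np.matmul(self.weight.value, cols)  # (N, out, oh*ow)
        if self.bias is not None:
            out += self.bias.value[None, :, None]
        self._cache = (cols, x.shape, oh, ow)
        return out.reshape(x.shape[0], self.out_channels, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, oh, ow = self._cache
        n = grad.shape[0]
        g = grad.reshape(n, self.out_channels, oh * ow)
        self.weight.grad += np.einsum("nol,ncl->oc", g, cols, optimize=True)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.value.T, g)  # (N, C*k*k, L)
        return col2im(dcols, x_shape, self.kernel_size, self.stride, self.padding, oh, ow)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        gain: float = 2.0,
        name: str = "",
    ) -> None:
        self.in_features = in_features
        self.out_features = out_features
        self.name = name
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(
            _uniform_init(rng, (out_features, in_features), in_features, gain)
        )
        self.bias = (
            Parameter(_uniform_init(rng, (out_features,), in_features, 0.5))
            if bias
            else None
        )
        self._x = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        out = x @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class ReLU(Module):
    def __init__(self, name: str = "") -> None:
        self.name = name
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 3, stride: int = 2, name: str = "") -> None:
        self.kernel_size = kernel_size
        self.stride = stride
        self.name = name
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.kernel_size, self.stride
        oh = (h - k) // s + 1
        ow = (w - k) // s + 1
        cols = np.empty((n, c, k * k, oh, ow), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i * k + j] = x[:, :, i : i + s * oh : s, j : j + s * ow : s]
        arg = cols.argmax(axis=2)
        out = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]
        self._cache = (arg, x.shape, oh, ow)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        arg, x_shape, oh, ow = self._cache
        k, s = self.kernel_size, self.stride
        dx = np.zeros(x_shape, dtype=grad.dtype)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            mask = arg == idx
            dx[:, :, i : i + s * oh : s, j : j + s * ow : s] += np.where(mask, grad, 0.0)
        return dx


class UpsampleNearest(Module):
    """Nearest-neighbour spatial up-sampling; adds no trainable parameters."""

    def __init__(self, factor: int = 2, name: str = "") -> None:
        self.factor = factor
        self.name = name
        self._in_shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        f = self.factor
        if f == 1:
            return x
        return np.repeat(np.repeat(x, f, axis=2), f, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        f = self.factor
        if f == 1:
            return grad
        return grad.reshape(n, c, h, f, w, f).sum(axis=(3, 5))


class AdaptiveAvgPool2d(Module):
    """Average pooling to a fixed output size with torch-style bin edges."""

    def __init__(self, output_size: int = 2, name: str = "") -> None:
        self.output_size = output_size
        self.name = name
        self._cache = None

    @staticmethod
    def _edges(size: int, out: int) -> list[tuple[int, int]]:
        return [
            (int(np.floor(i * size / out)), int(np.ceil((i + 1) * size / out)))
            for i in range(out)
        ]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        o = self.output_size
        rows, cols = self._edges(h, o), self._edges(w, o)
        out = np.empty((n, c, o, o), dtype=x.dtype)
        for i, (r0, r1) in enumerate(rows):
            for j, (c0, c1) in enumerate(cols):
                out[:, :, i, j] = x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
        self._cache = (x.shape, rows, cols)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, rows, cols = self._cache
        dx = np.zeros(x_shape, dtype=grad.dtype)
        for i, (r0, r1) in enumerate(rows):
            for j, (c0, c1) in enumerate(cols):
                area = (r1 - r0) * (c1 - c0)
                dx[:, :, r0:r1, c0:c1] += grad[:, :, i, j, None, None] / area
        return dx


class Flatten(Module):
    def __init__(self, name: str = "") -> None:
        self.name = name
        self._in_shape = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class Dropout(Module):
    """Inverted dropout; active only in training mode with an rng attached."""

    def __init__(self, p: float = 0.5, name: str = "") -> None:
        self.p = p
        self.name = name
        self.rng: np.random.Generator | None = None
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0 or self.rng is None:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Module):
    def __init__(self, layers: list[Module], name: str = "") -> None:
        self.layers = list(layers)
        self.name = name

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def modules(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.modules()
            else:
                yield layer


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
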