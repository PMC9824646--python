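"""Channel/spatial attention stages: squeeze-and-excitation (SE), efficient
channel attention (ECA) and the convolutional block attention module (CBAM).

Each stage maps a feature map (N, C, H, W) to a reweighted map of identical
shape; all gate values pass through a sigmoid and therefore lie strictly in
(0, 1).
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, Linear, Module, Parameter, sigmoid


def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive 1-D kernel size: nearest odd integer to (log2(C)+b)/gamma, >= 3."""
    if channels < 1:
        raise ValueError(f"channels must be >= 1, got {channels}")
    t = (np.log2(channels) + b) / gamma
    k = int(round(t))
    if k % 2 == 0:
        k += 1 if t >= k else -1
    return max(k, 3)


class SEBlock(Module):
    """Global-average squeeze, two-FC bottleneck excitation, channel rescale."""

    def __init__(
        self,
        channels: int,
        reduction: int = 16,
        rng: np.random.Generator | None = None,
        name: str = "se",
    ) -> None:
        if channels % reduction:
            raise ValueError(f"channels={channels} not divisible by reduction={reduction}")
        self.channels = channels
        self.reduction = reduction
        self.name = name
        hidden = channels // reduction
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(channels, hidden, rng=rng, name=f"{name}.fc1")
        self.fc2 = Linear(hidden, channels, rng=rng, name=f"{name}.fc2")
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return self.fc1.parameters() + self.fc2.parameters()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        s = x.mean(axis=(2, 3))
        h = np.maximum(self.fc1.forward(s), 0.0)
        z = h @ self.fc2.weight.value.T + self.fc2.bias.value
        g = sigmoid(z)
        self._cache = (x, s, h, g)
        return x * g[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, s, h, g = self._cache
        hw = x.shape[2] * x.shape[3]
        dx = grad * self._cache[3][:, :, None, None]
        dg = (grad * x).sum(axis=(2, 3))
        dz = dg * g * (1.0 - g)
        self.fc2.weight.grad += dz.T @ h
        self.fc2.bias.grad += dz.sum(axis=0)
        dh = dz @ self.fc2.weight.value
        dh = np.where(h > 0, dh, 0.0)
        self.fc1.weight.grad += dh.T @ s
        self.fc1.bias.grad += dh.sum(axis=0)
        ds = dh @ self.fc1.weight.value
        dx += ds[:, :, None, None] / hw
        return dx


class ECABlock(Module):
    """Weight-shared 1-D convolution over the pooled channel descriptor."""

    def __init__(
        self,
        channels: int,
        gamma: int = 2,
        b: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "eca",
    ) -> None:
        self.channels = channels
        self.kernel_size = eca_kernel_size(channels, gamma, b)
        self.name = name
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(self.kernel_size)
        self.weight = Parameter(rng.uniform(-bound, bound, self.kernel_size))
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k = self.kernel_size
        pad = k // 2
        s = x.mean(axis=(2, 3))
        sp = np.pad(s, ((0, 0), (pad, pad)))
        t = np.zeros_like(s)
        for j in range(k):
            t += self.weight.value[j] * sp[:, j : j + self.channels]
        g = sigmoid(t)
        self._cache = (x, sp, g)
        return x * g[:, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, sp, g = self._cache
        k = self.kernel_size
        pad = k // 2
        c = self.channels
        hw = x.shape[2] * x.shape[3]
        dx = grad * g[:, :, None, None]
        dg = (grad * x).sum(axis=(2, 3))
        dt = dg * g * (1.0 - g)
        dsp = np.zeros_like(sp)
        for j in range(k):
            self.weight.grad[j] += float((dt * sp[:, j : j + c]).sum())
            dsp[:, j : j + c] += self.weight.value[j] * dt
        ds = dsp[:, pad : pad + c]
        dx += ds[:, :, None, None] / hw
        return dx


class CBAMBlock(Module):
    """Channel gate (shared MLP over avg+max descriptors) then spatial gate."""

    def __init__(
        self,
        channels: int,
        reduction: int = 16,
        spatial_kernel: int = 3,
        rng: np.random.Generator | None = None,
        name: str = "cbam",
    ) -> None:
        if channels % reduction:
            raise ValueError(f"channels={channels} not divisible by reduction={reduction}")
        if spatial_kernel % 2 == 0:
            raise ValueError(f"spatial kernel must be odd, got {spatial_kernel}")
        self.channels = channels
        self.reduction = reduction
        self.name = name
        hidden = channels // reduction
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(channels, hidden, rng=rng, name=f"{name}.fc1")
        self.fc2 = Linear(hidden, channels, rng=rng, name=f"{name}.fc2")
        self.spatial_conv = Conv2d(
            2, 1, spatial_kernel, stride=1, padding=spatial_kernel // 2,
            rng=rng, name=f"{name}.spatial",
        )
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return (
            self.fc1.parameters() + self.fc2.parameters() + self.spatial_conv.parameters()
        )

    def _mlp(self, s: np.ndarray):
        h = np.maximum(s @ self.fc1.weight.value.T + self.fc1.bias.value, 0.0)
        z = h @ self.fc2.weight.value.T + self.fc2.bias.value
        return h, z

    def _mlp_backward(self, dz: np.ndarray, s: np.ndarray, h: np.ndarray) -> np.ndarray:
        self.fc2.weight.grad += dz.T @ h
        self.fc2.bias.grad += dz.sum(axis=0)
        dh = np.where(h > 0, dz @ self.fc2.weight.value, 0.0)
        self.fc1.weight.grad += dh.T @ s
        self.fc1.bias.grad += dh.sum(axis=0)
        return dh @ self.fc1.weight.value

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, hgt, wid = x.shape
        # channel gate
        avg = x.mean(axis=(2, 3))
        flat = x.reshape(n, c, hgt * wid)
        sp_idx = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, sp_idx[:, :, None], axis=2)[:, :, 0]
        h_avg, z_avg = self._mlp(avg)
        h_max, z_max = self._mlp(mx)
        gc = sigmoid(z_avg + z_max)
        x1 = x * gc[:, :, None, None]
        # spatial gate
        am = x1.mean(axis=1)
        ch_idx = x1.argmax(axis=1)
        mm = np.take_along_axis(x1, ch_idx[:, None], axis=1)[:, 0]
        u = np.stack([am, mm], axis=1)
        v = self.spatial_conv.forward(u, training=training)
        gs = sigmoid(v)
        self._cache = (x, avg, mx, sp_idx, h_avg, h_max, gc, x1, ch_idx, gs)
        return x1 * gs

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, avg, mx, sp_idx, h_avg, h_max, gc, x1, ch_idx, gs = self._cache
        n, c, hgt, wid = x.shape
        # spatial gate
        dx1 = grad * gs
        dgs = (grad * x1).sum(axis=1, keepdims=True)
        dv = dgs * gs * (1.0 - gs)
        du = self.spatial_conv.backward(dv)
        dx1 += du[:, 0][:, None] / c
        onehot = ch_idx[:, None] == np.arange(c)[None, :, None, None]
        dx1 += np.where(onehot, du[:, 1][:, None], 0.0)
        # channel gate
        dx = dx1 * gc[:, :, None, None]
        dgc = (dx1 * x).sum(axis=(2, 3))
        dz = dgc * gc * (1.0 - gc)
        davg = self._mlp_backward(dz, avg, h_avg)
        dmx = self._mlp_backward(dz, mx, h_max)
        dx += davg[:, :, None, None] / (hgt * wid)
        scat = np.zeros((n, c, hgt * wid), dtype=dx.dtype)
        np.put_along_axis(scat, sp_idx[:, :, None], dmx[:, :, None], axis=2)
        dx += scat.reshape(n, c, hgt, wid)
        return dx


def build_attention(
    kind: str,
    channels: int,
    se_reduction: int = 16,
    eca_gamma: int = 2,
    eca_b: int = 1,
    cbam_spatial_kernel: int = 3,
    rng: np.random.Generator | None = None,
) -> Module | None:
    """Instantiate the attention stage named by ``kind`` (or None)."""
    if kind == "se":
        return SEBlock(channels, se_reduction, rng=rng)
    if kind == "eca":
        return ECABlock(channels, eca_gamma, eca_b, rng=rng)
    if kind == "cbam":
        return CBAMBlock(channels, se_reduction, cbam_spatial_kernel, rng=rng)
    if kind == "none":
        return None
    raise ValueError(f"unknown attention kind {kind!r}")
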