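"""The CS-Block: a learned measurement operator replacing the classical
compressed-sensing matrix.

Three 3x3 stride-2 convolutions (3 -> 64 -> 64 -> 64) halve the spatial size
224 -> 112 -> 56 -> 28, a 1x1 convolution projects to X = round(192 * SR)
measurement channels, and a nearest-neighbour up-sampling stage enlarges the
map so downstream kernels fit.  There is *no* nonlinearity between the four
convolutions: the composite is an affine map, i.e. a single (learned)
measurement matrix plus bias when flattened, which is exactly what lets a
convolution stack stand in for the sensing matrix of classical CS.  The
pre-upsample map (N, X, 28, 28) holds 28*28*X elements against the input's
224*224*3, an element-count ratio of X/192 — the effective sensing rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, SensingRate
from .nn import Conv2d, Sequential, UpsampleNearest


@dataclass
class MeasurementMap:
    """CS-Block output: the compressed-domain representation of a batch."""

    values: np.ndarray  # (N, X, s, s) with s = 28 * upsample_factor post-upsample
    sr: SensingRate
    upsampled: bool

    @property
    def x_channels(self) -> int:
        return self.values.shape[1]

    @property
    def effective_sr(self) -> float:
        if self.upsampled:
            raise ValueError("effective SR is defined on the pre-upsample map")
        n, x, h, w = self.values.shape
        return (h * w * x) / (224 * 224 * 3)


def build_cs_block(
    config: ModelConfig, rng: np.random.Generator | None = None
) -> Sequential:
    """Assemble the four-convolution measurement stack plus up-sampling."""
    w1, w2, w3 = config.cs_widths
    x = config.x_channels
    rng = rng or np.random.default_rng(0)
    # gain 1: the stack is purely affine (no ReLU), so variance-preserving
    # rather than He initialization.
    layers = [
        Conv2d(3, w1, 3, stride=2, padding=1, rng=rng, gain=1.0, name="cs.conv1"),
        Conv2d(w1, w2, 3, stride=2, padding=1, rng=rng, gain=1.0, name="cs.conv2"),
        Conv2d(w2, w3, 3, stride=2, padding=1, rng=rng, gain=1.0, name="cs.conv3"),
        Conv2d(w3, x, 1, stride=1, padding=0, rng=rng, gain=1.0, name="cs.proj"),
        UpsampleNearest(config.upsample_factor, name="cs.upsample"),
    ]
    return Sequential(layers, name="cs_block")


def cs_block_forward(
    pixels: np.ndarray,
    config: ModelConfig,
    block: Sequential | None = None,
    upsample: bool = True,
) -> MeasurementMap:
    """Run the measurement operator on a normalized (N, 3, 224, 224) batch."""
    if pixels.ndim != 4 or pixels.shape[1:] != (3, 224, 224):
        raise ValueError(f"expected (N, 3, 224, 224) input, got {pixels.shape}")
    block = block if block is not None else build_cs_block(config)
    stack = block.layers[:-1] if not upsample else block.layers
    out = np.asarray(pixels, dtype=np.float32)
    for layer in stack:
        out = layer.forward(out)
    return MeasurementMap(out, SensingRate(config.sr), upsampled=upsample)


def cs_block_param_count(config: ModelConfig) -> int:
    """Closed-form trainable-parameter count of the measurement stack.

    With the default widths (64, 64, 64) this is 75648 + 65*X; up-sampling
    contributes nothing.
    """
    w1, w2, w3 = config.cs_widths
    x = config.x_channels
    return (
        (9 * 3 + 1) * w1
        + (9 * w1 + 1) * w2
        + (9 * w2 + 1) * w3
        + (w3 + 1) * x
    )


def materialize_measurement_matrix(
    block: Sequential, side: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Explicitly build the (M, N) matrix A and bias b with y = A x + b.

    Probes the (pre-upsample) CS-Block with the canonical basis of a
    side x side RGB image; feasible only at toy sizes.  Used to verify that
    the convolution stack really is a single affine measurement operator.
    """
    stack = [l for l in block.layers if isinstance(l, Conv2d)]

    def run(img: np.ndarray) -> np.ndarray:
        out = img
        for layer in stack:
            out = layer.forward(out)
        return out

    zero = np.zeros((1, 3, side, side), dtype=np.float32)
    bias = run(zero).reshape(-1).copy()
    n_in = 3 * side * side
    cols = np.empty((bias.size, n_in), dtype=np.float32)
    for i in range(n_in):
        e = np.zeros((1, 3 * side * side), dtype=np.float32)
        e[0, i] = 1.0
        cols[:, i] = run(e.reshape(1, 3, side, side)).reshape(-1) - bias
    return cols, bias
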