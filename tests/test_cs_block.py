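"""The learned measurement operator: shapes, affinity, parameter counts."""

import numpy as np
import pytest

from csbnet.config import ModelConfig, channels_for_sr
from csbnet.cs_block import (
    build_cs_block,
    cs_block_forward,
    cs_block_param_count,
    materialize_measurement_matrix,
)

PAPER_SR_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)


def test_shape_trace_at_half_rate():
    config = ModelConfig(sr=0.5, num_classes=4)
    x = np.zeros((1, 3, 224, 224), dtype=np.float32)
    pre = cs_block_forward(x, config, upsample=False)
    post = cs_block_forward(x, config, upsample=True)
    assert pre.values.shape == (1, 96, 28, 28)
    assert post.values.shape == (1, 96, 56, 56)


def test_rejects_non_224_input():
    config = ModelConfig(sr=0.5)
    with pytest.raises(ValueError):
        cs_block_forward(np.zeros((1, 3, 128, 128), np.float32), config)


def test_zero_input_gives_pure_bias_response():
    config = ModelConfig(sr=0.2)
    block = build_cs_block(config, rng=np.random.default_rng(3))
    zero = cs_block_forward(np.zeros((1, 3, 224, 224), np.float32), config, block=block)
    img = np.random.default_rng(1).uniform(-1, 1, (1, 3, 224, 224)).astype(np.float32)
    out = cs_block_forward(img, config, block=block)
    # bias response is independent of image content
    zero2 = cs_block_forward(np.zeros((1, 3, 224, 224), np.float32), config, block=block)
    assert np.array_equal(zero.values, zero2.values)
    assert not np.allclose(out.values, zero.values)


def test_homogeneity_of_centred_response():
    # With no nonlinearity, F(ax) - F(0) = a (F(x) - F(0)).
    config = ModelConfig(sr=0.1)
    block = build_cs_block(config, rng=np.random.default_rng(5))
    x = np.random.default_rng(2).uniform(-1, 1, (1, 3, 224, 224)).astype(np.float32)
    f0 = cs_block_forward(np.zeros_like(x), config, block=block).values
    fx = cs_block_forward(x, config, block=block).values
    fax = cs_block_forward(2.5 * x, config, block=block).values
    assert np.allclose(fax - f0, 2.5 * (fx - f0), atol=1e-3)


def test_additivity_of_centred_response():
    config = ModelConfig(sr=0.1)
    block = build_cs_block(config, rng=np.random.default_rng(8))
    rng = np.random.default_rng(4)
    x = rng.uniform(-1, 1, (1, 3, 224, 224)).astype(np.float32)
    y = rng.uniform(-1, 1, (1, 3, 224, 224)).astype(np.float32)
    f = lambda v: cs_block_forward(v, config, block=block).values
    f0 = f(np.zeros_like(x))
    assert np.allclose(f(x + y) - f0, (f(x) - f0) + (f(y) - f0), atol=1e-3)


def test_materialized_matrix_matches_block_on_toy_input():
    # The four-conv stack equals a single matrix-vector product plus bias
    # when flattened: the defining property of a measurement operator.
    config = ModelConfig(sr=0.05)
    block = build_cs_block(config, rng=np.random.default_rng(11))
    a, b = materialize_measurement_matrix(block, side=16)
    rng = np.random.default_rng(7)
    for _ in range(3):
        img = rng.uniform(-1, 1, (1, 3, 16, 16)).astype(np.float32)
        out = img
        for layer in block.layers[:-1]:
            out = layer.forward(out)
        assert np.allclose(out.reshape(-1), a @ img.reshape(-1) + b, atol=1e-4)


@pytest.mark.parametrize(
    "x,expected", [(134, 84_358), (192, 88_128), (1, 75_713)]
)
def test_param_count_closed_form(x, expected):
    config = ModelConfig(sr=x / 192, num_classes=4, attention="none")
    assert config.x_channels == x
    assert cs_block_param_count(config) == expected == 75_648 + 65 * x


def test_param_count_matches_per_layer_arithmetic():
    for sr in (0.05, 0.5, 1.0):
        config = ModelConfig(sr=sr, attention="none")
        block = build_cs_block(config)
        actual = sum(p.size for p in block.parameters())
        assert actual == cs_block_param_count(config)


def test_effective_sr_element_count_identity():
    x_img = np.zeros((1, 3, 224, 224), np.float32)
    for sr in PAPER_SR_GRID:
        config = ModelConfig(sr=sr)
        pre = cs_block_forward(x_img, config, upsample=False)
        assert pre.effective_sr == channels_for_sr(sr) / 192
        assert pre.values.size / x_img.size == pre.effective_sr


def test_upsampling_adds_no_parameters():
    config = ModelConfig(sr=0.5)
    block = build_cs_block(config)
    assert sum(p.size for p in block.layers[-1].parameters()) == 0
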