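"""Network assembly, parameter ledger, and width reconstruction."""

import numpy as np
import pytest

from csbnet.config import ModelConfig
from csbnet.model import (
    Network,
    build_network,
    count_params,
    param_total,
    pin_se_config,
    reconstruct_widths,
)

TOTAL_WITH_SE = 6_003_328
TOTAL_WITHOUT_SE = 6_001_144


def test_forward_output_shape():
    net = build_network(ModelConfig(sr=0.7, num_classes=4))
    out = net.forward(np.zeros((2, 3, 224, 224), np.float32))
    assert out.shape == (2, 4)


@pytest.mark.parametrize("sr", [0.05, 0.3, 1.0])
def test_forward_valid_and_finite_across_rates(sr):
    net = build_network(ModelConfig(sr=sr, num_classes=3), seed=1)
    x = np.random.default_rng(0).uniform(-1, 1, (1, 3, 224, 224)).astype(np.float32)
    out = net.forward(x)
    assert out.shape == (1, 3)
    assert np.isfinite(out).all()


def test_ledger_totals_match_closed_form():
    for kwargs in (
        {"sr": 0.7, "attention": "se"},
        {"sr": 0.7, "attention": "none"},
        {"sr": 0.2, "attention": "eca"},
        {"sr": 0.5, "attention": "cbam", "num_classes": 6},
    ):
        config = ModelConfig(**kwargs)
        assert count_params(build_network(config)).total == param_total(config)


def test_ledger_is_weight_independent():
    config = ModelConfig(sr=0.4)
    a = count_params(build_network(config, seed=0))
    b = count_params(build_network(config, seed=99))
    assert a.total == b.total
    assert [r.params for r in a.rows] == [r.params for r in b.rows]


def test_se_is_the_only_ledger_difference():
    with_se = count_params(build_network(ModelConfig(sr=0.7, attention="se")))
    without = count_params(build_network(ModelConfig(sr=0.7, attention="none")))
    names_with = {r.layer: r.params for r in with_se.rows}
    names_without = {r.layer: r.params for r in without.rows}
    extra = set(names_with) - set(names_without)
    assert extra == {"se"}
    assert names_with["se"] == 2_184
    for name in names_without:
        assert names_with[name] == names_without[name]


def test_classifier_stack_count():
    # 512->1024->2048->4 biased: 525,312 + 2,099,200 + 8,196
    config = ModelConfig(sr=0.7, num_classes=4)
    ledger = count_params(build_network(config))
    clf = sum(r.params for r in ledger.rows if r.layer.startswith("clf."))
    assert clf == 2_632_708


def test_extra_class_costs_2049_params():
    t4 = param_total(ModelConfig(sr=0.7, num_classes=4))
    t5 = param_total(ModelConfig(sr=0.7, num_classes=5))
    assert t5 - t4 == 2_049  # only the last FC depends on K


def test_total_is_affine_in_x_with_slope_2417():
    # CS-Block 1x1 conv adds 65 per channel, the 7x7x48 first feature conv
    # adds 49*48 = 2352; nothing else sees X.
    totals = {}
    for sr in (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7):
        config = ModelConfig(sr=sr)
        totals[config.x_channels] = param_total(config)
    xs = sorted(totals)
    for a, b in zip(xs, xs[1:]):
        assert (totals[b] - totals[a]) == 2_417 * (b - a)


def test_params_size_mb_float32_accounting():
    ledger = count_params(build_network(ModelConfig(sr=0.7, num_classes=4)))
    assert ledger.params_size_mb == round(ledger.total * 4 / 2**20, 2)


def test_se_delta_pins_128_16():
    # Brute force over (C, r): the printed-total difference of 2,184 admits
    # exactly one biased two-FC solution.
    hits = pin_se_config(TOTAL_WITH_SE - TOTAL_WITHOUT_SE)
    assert hits == [(128, 16)]


def test_reconstruct_widths_recovers_published_totals():
    res = reconstruct_widths(TOTAL_WITH_SE, TOTAL_WITHOUT_SE)
    assert res.exact and res.residual == 0
    assert res.config.feat_widths[3] == 128
    assert res.config.se_reduction == 16
    assert param_total(res.config) == TOTAL_WITH_SE
    no_se = ModelConfig(**{**_kwargs(res.config), "attention": "none"})
    assert param_total(no_se) == TOTAL_WITHOUT_SE


def test_reconstruct_widths_single_point_grid():
    c2, c3, c4 = 408, 344, 286
    res = reconstruct_widths(
        TOTAL_WITH_SE, TOTAL_WITHOUT_SE,
        c2_grid=range(c2, c2 + 1), c3_grid=range(c3, c3 + 1), c4_grid=range(c4, c4 + 1),
    )
    assert res.exact and res.config.feat_widths[:3] == (c2, c3, c4)


def test_reconstruct_widths_unsatisfiable_flags_residual():
    res = reconstruct_widths(
        TOTAL_WITH_SE, TOTAL_WITHOUT_SE,
        c2_grid=range(8, 9), c3_grid=range(8, 9), c4_grid=range(8, 9),
    )
    assert not res.exact
    assert res.residual != 0


def test_reconstruct_widths_empty_grid():
    with pytest.raises(ValueError):
        reconstruct_widths(TOTAL_WITH_SE, TOTAL_WITHOUT_SE, c2_grid=range(0))


def test_checkpoint_round_trip(tmp_path):
    config = ModelConfig(sr=0.1, num_classes=3)
    net = build_network(config, seed=4)
    x = np.random.default_rng(1).uniform(-1, 1, (1, 3, 224, 224)).astype(np.float32)
    before = net.forward(x)
    path = tmp_path / "model.csbnet"
    net.save(path)
    loaded = Network.load(path)
    assert loaded.config == config
    assert np.allclose(loaded.forward(x), before, atol=1e-6)


def _kwargs(config: ModelConfig) -> dict:
    from csbnet.config import config_to_dict

    d = config_to_dict(config)
    for key in ("cs_widths", "feat_widths", "fc_dims"):
        d[key] = tuple(d[key])
    return d
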