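"""CSBNet assembly, per-layer parameter accounting, and reconstruction of
the interior feature widths from published parameter totals.

The network is CS-Block -> AlexNet-derived feature extractor -> channel
attention -> three-FC classifier.  The feature extractor applies a 7x7
stride-4 convolution with 48 filters to the up-sampled measurement map,
then max-pool (k3 s2), a 5x5 convolution, max-pool, three 3x3 convolutions
ending at 128 channels, and an adaptive average pool to 2x2 — so the
flattened classifier input is 128*2*2 = 512 regardless of sensing rate.
ReLU follows every feature convolution; the CS-Block stays purely affine.

The widths of feature convolutions 2-4 are not pinned by the architecture
itself; :func:`reconstruct_widths` recovers them by exhaustive search
against a pair of published parameter totals (with and without the SE
stage).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, ModelConfig, channels_for_sr, derive_seed, model_config_from_dict
from .cs_block import build_cs_block, cs_block_param_count
from .nn import (
    AdaptiveAvgPool2d,
    Conv2d,
    Dropout,
    Flatten,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    build_attention,
)


@dataclass
class LedgerRow:
    layer: str
    kind: str
    kernel: str
    in_channels: int
    out_channels: int
    params: int


@dataclass
class ParamLedger:
    """Per-layer trainable-parameter breakdown (float32 accounting)."""

    rows: list[LedgerRow]

    @property
    def total(self) -> int:
        return sum(r.params for r in self.rows)

    @property
    def params_size_mb(self) -> float:
        return round(self.total * 4 / 2**20, 2)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "layers": [vars(r) for r in self.rows],
                "total": self.total,
                "params_size_mb": self.params_size_mb,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


class Network:
    """A trainable CSBNet instance mapping (N,3,224,224) -> (N,K) scores."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(derive_seed(seed, "init"))
        c2, c3, c4, c5 = config.feat_widths
        f1 = config.first_feat_filters
        x = config.x_channels
        self.cs_block = build_cs_block(config, rng=rng)
        self.features = Sequential(
            [
                Conv2d(x, f1, 7, stride=4, padding=2, rng=rng, name="feat.conv1"),
                ReLU(name="feat.relu1"),
                MaxPool2d(3, 2, name="feat.pool1"),
                Conv2d(f1, c2, 5, stride=1, padding=2, rng=rng, name="feat.conv2"),
                ReLU(name="feat.relu2"),
                MaxPool2d(3, 2, name="feat.pool2"),
                Conv2d(c2, c3, 3, stride=1, padding=1, rng=rng, name="feat.conv3"),
                ReLU(name="feat.relu3"),
                Conv2d(c3, c4, 3, stride=1, padding=1, rng=rng, name="feat.conv4"),
                ReLU(name="feat.relu4"),
                Conv2d(c4, c5, 3, stride=1, padding=1, rng=rng, name="feat.conv5"),
                ReLU(name="feat.relu5"),
                AdaptiveAvgPool2d(2, name="feat.pool3"),
            ],
            name="features",
        )
        self.attention = build_attention(
            config.attention,
            c5,
            se_reduction=config.se_reduction,
            eca_gamma=config.eca_gamma,
            eca_b=config.eca_b,
            cbam_spatial_kernel=config.cbam_spatial_kernel,
            rng=rng,
        )
        d0, d1, d2 = config.fc_dims
        self.classifier = Sequential(
            [
                Flatten(name="clf.flatten"),
                Dropout(config.dropout_p, name="clf.drop1"),
                Linear(d0, d1, rng=rng, name="clf.fc1"),
                ReLU(name="clf.relu1"),
                Dropout(config.dropout_p, name="clf.drop2"),
                Linear(d1, d2, rng=rng, name="clf.fc2"),
                ReLU(name="clf.relu2"),
                Dropout(config.dropout_p, name="clf.drop3"),
                Linear(d2, config.num_classes, rng=rng, name="clf.fc3"),
            ],
            name="classifier",
        )

    # -- plumbing ---------------------------------------------------------
    def stages(self) -> list[Module]:
        out: list[Module] = [self.cs_block, self.features]
        if self.attention is not None:
            out.append(self.attention)
        out.append(self.classifier)
        return out

    def parameters(self):
        return [p for stage in self.stages() for p in stage.parameters()]

    def named_layers(self):
        for stage in self.stages():
            if isinstance(stage, Sequential):
                yield from stage.modules()
            else:
                yield stage

    def set_dropout_rng(self, rng: np.random.Generator | None) -> None:
        for layer in self.classifier.modules():
            if isinstance(layer, Dropout):
                layer.rng = rng

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad.fill(0.0)

    # -- computation ------------------------------------------------------
    def forward(self, pixels: np.ndarray, training: bool = False) -> np.ndarray:
        if pixels.ndim != 4 or pixels.shape[1:] != (3, 224, 224):
            raise ValueError(f"expected (N, 3, 224, 224) input, got {pixels.shape}")
        out = np.asarray(pixels, dtype=np.float32)
        for stage in self.stages():
            out = stage.forward(out, training=training)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for stage in reversed(self.stages()):
            grad = stage.backward(grad)
        return grad

    def predict_scores(self, pixels: np.ndarray, batch_size: int = 16) -> np.ndarray:
        chunks = [
            self.forward(pixels[i : i + batch_size])
            for i in range(0, pixels.shape[0], batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights plus the embedded ModelConfig."""
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(_config_dict(self.config)))
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "Network":
        with zipfile.ZipFile(path) as zf:
            config = model_config_from_dict(json.loads(zf.read("config.json")))
            data = np.load(io.BytesIO(zf.read("weights.npz")))
            net = cls(config, seed=seed)
            params = net.parameters()
            if len(params) != len(data.files):
                raise ConfigError("checkpoint does not match the architecture")
            for i, p in enumerate(params):
                arr = data[f"p{i}"]
                if arr.shape != p.value.shape:
                    raise ConfigError("checkpoint weight shapes do not match")
                p.value[...] = arr
        return net


def _config_dict(config: ModelConfig) -> dict:
    from .config import config_to_dict

    return config_to_dict(config)


def build_network(config: ModelConfig, seed: int = 0) -> Network:
    return Network(config, seed=seed)


_KIND_LABELS = {
    Conv2d: "conv",
    Linear: "fc",
}


def count_params(net: Network) -> ParamLedger:
    """Exact per-layer accounting; pool/upsample/dropout contribute zero."""
    rows: list[LedgerRow] = []
    for layer in net.named_layers():
        n = sum(p.size for p in layer.parameters())
        if n == 0:
            continue
        if isinstance(layer, Conv2d):
            rows.append(
                LedgerRow(layer.name, "conv", f"{layer.kernel_size}x{layer.kernel_size}",
                          layer.in_channels, layer.out_channels, n)
            )
        elif isinstance(layer, Linear):
            rows.append(
                LedgerRow(layer.name, "fc", "-", layer.in_features, layer.out_features, n)
            )
        else:  # attention stage: one aggregate entry
            c = getattr(layer, "channels", 0)
            rows.append(LedgerRow(layer.name or "attention", "attention", "-", c, c, n))
    return ParamLedger(rows)


def attention_param_count(config: ModelConfig) -> int:
    c = config.feat_widths[3]
    if config.attention == "se":
        h = c // config.se_reduction
        return (c * h + h) + (h * c + c)
    if config.attention == "eca":
        from .nn import eca_kernel_size

        return eca_kernel_size(c, config.eca_gamma, config.eca_b)
    if config.attention == "cbam":
        h = c // config.se_reduction
        k = config.cbam_spatial_kernel
        return (c * h + h) + (h * c + c) + (k * k * 2 + 1)
    return 0


def param_total(config: ModelConfig) -> int:
    """Closed-form total trainable-parameter count for a config.

    Cross-checked against :func:`count_params` on built networks; used by the
    width-reconstruction search where building 250k networks would be absurd.
    """
    c2, c3, c4, c5 = config.feat_widths
    f1 = config.first_feat_filters
    x = config.x_channels
    feat = (
        (49 * x + 1) * f1
        + (25 * f1 + 1) * c2
        + (9 * c2 + 1) * c3
        + (9 * c3 + 1) * c4
        + (9 * c4 + 1) * c5
    )
    d0, d1, d2 = config.fc_dims
    clf = (d0 + 1) * d1 + (d1 + 1) * d2 + (d2 + 1) * config.num_classes
    return cs_block_param_count(config) + feat + attention_param_count(config) + clf


def pin_se_config(
    delta: int,
    c_grid: range = range(8, 513),
    r_grid: tuple[int, ...] = (2, 4, 8, 16, 32),
) -> list[tuple[int, int]]:
    """All (channels, reduction) whose biased 2-FC SE stage has ``delta`` params."""
    hits = []
    for c in c_grid:
        for r in r_grid:
            if c % r:
                continue
            h = c // r
            if (c * h + h) + (h * c + c) == delta:
                hits.append((c, r))
    return hits


@dataclass
class ReconstructionResult:
    config: ModelConfig
    exact: bool
    residual: int
    candidates: list[tuple[int, int, int]] = field(default_factory=list)


#: AlexNet's conv2-4 widths; the tie-break anchor for the width search.
ALEXNET_WIDTHS = (192, 384, 256)


def reconstruct_widths(
    target_with_se: int,
    target_without_se: int,
    c2_grid: range = range(8, 513),
    c3_grid: range = range(8, 513),
    c4_grid: range = range(8, 513),
    sr: float = 0.7,
    num_classes: int = 4,
) -> ReconstructionResult:
    """Recover the interior feature widths (c2, c3, c4) from two published
    totals (with and without the SE stage) by exhaustive integer search.

    The SE stage itself is pinned first from the difference of the targets;
    then every (c2, c3, c4) on the grid is scored against the no-SE total.
    Exact matches are ranked by L1 distance to AlexNet's (192, 384, 256); if
    none exists the nearest-achievable configuration is returned flagged
    non-exact with its residual.
    """
    if not (len(c2_grid) and len(c3_grid) and len(c4_grid)):
        raise ValueError("empty width grid")
    se_delta = target_with_se - target_without_se
    se_hits = pin_se_config(se_delta)
    if len(se_hits) == 1:
        c5, reduction = se_hits[0]
    else:
        c5, reduction = 128, 16  # fall back to the architectural default

    x = channels_for_sr(sr)
    base = ModelConfig(sr=sr, num_classes=num_classes, attention="none",
                       feat_widths=(8, 8, 8, c5), fc_dims=(c5 * 4, 1024, 2048))
    # constant part: everything that does not involve c2, c3, c4
    const = param_total(base) - (
        (25 * base.first_feat_filters + 1) * 8 + (9 * 8 + 1) * 8 + (9 * 8 + 1) * 8
        + (9 * 8 + 1) * c5
    )
    needed = target_without_se - const

    c3s = np.asarray(list(c3_grid), dtype=np.int64)
    c4s = np.asarray(list(c4_grid), dtype=np.int64)
    inner = (9 * c3s[:, None] + 1) * c4s[None, :] + (9 * c4s + 1)[None, :] * c5
    a2 = 25 * base.first_feat_filters + 1

    exact: list[tuple[int, int, int]] = []
    best = None  # (abs residual, signed residual, c2, c3, c4)
    for c2 in c2_grid:
        totals = a2 * c2 + (9 * c2 + 1) * c3s[:, None] + inner
        diff = totals - needed
        hits = np.argwhere(diff == 0)
        for i, j in hits:
            exact.append((c2, int(c3s[i]), int(c4s[j])))
        k = np.abs(diff).argmin()
        i, j = divmod(int(k), diff.shape[1])
        cand = (abs(int(diff[i, j])), int(diff[i, j]), c2, int(c3s[i]), int(c4s[j]))
        if best is None or cand[0] < best[0]:
            best = cand

    def make(c2: int, c3: int, c4: int, attention: str = "se") -> ModelConfig:
        return ModelConfig(
            sr=sr, num_classes=num_classes, attention=attention,
            feat_widths=(c2, c3, c4, c5), se_reduction=reduction,
            fc_dims=(c5 * 4, 1024, 2048),
        )

    if exact:
        winner = min(exact, key=lambda w: sum(abs(a - b) for a, b in zip(w, ALEXNET_WIDTHS)))
        return ReconstructionResult(make(*winner), exact=True, residual=0, candidates=exact)
    _, signed, c2, c3, c4 = best
    return ReconstructionResult(make(c2, c3, c4), exact=False, residual=signed, candidates=[])
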