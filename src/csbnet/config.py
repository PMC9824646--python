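"""Typed configuration and sensing-rate arithmetic.

The sensing rate SR is the ratio of sampled data volume to original data
volume.  For a 224x224x3 input compressed by the CS-Block to a 28x28xX
measurement map (before up-sampling), that ratio is

    (28 * 28 * X) / (224 * 224 * 3) = X / 192,

so the measurement channel count is X = 192 * SR, rounded half-up to an
integer.  Because of the rounding, the *effective* sensing rate X/192 can
differ slightly from the nominal SR; both are always reported.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

#: Channel budget of a full-rate (SR = 1) measurement map: 224*224*3 / (28*28).
FULL_RATE_CHANNELS = 192

#: Input geometry assumed by every shape computation in the package.
INPUT_SHAPE = (3, 224, 224)

ATTENTION_KINDS = ("se", "eca", "cbam", "none")

# Stable per-purpose codes mixed into the master seed so that data
# generation, weight init, shuffling, dropout and augmentation each get an
# independent but reproducible stream.
_SEED_TAGS = {"data": 11, "init": 23, "shuffle": 37, "dropout": 53, "augment": 71}


class InvalidSensingRateError(ValueError):
    pass


class ConfigError(ValueError):
    pass


def channels_for_sr(sr: float) -> int:
    """Measurement channel count X = round_half_up(192 * SR).

    Raises :class:`InvalidSensingRateError` unless 0 < sr <= 1.
    """
    if not (0.0 < sr <= 1.0):
        raise InvalidSensingRateError(f"sensing rate must lie in (0, 1], got {sr!r}")
    x = int(math.floor(FULL_RATE_CHANNELS * sr + 0.5))
    return max(x, 1)


def effective_sr(x_channels: int) -> float:
    """Element-count ratio of the pre-upsample measurement map to the input."""
    if x_channels < 1:
        raise ConfigError(f"channel count must be >= 1, got {x_channels}")
    return x_channels / FULL_RATE_CHANNELS


def derive_seed(seed: int, purpose: str) -> int:
    """Derive an independent sub-seed (< 2**31) for one purpose."""
    if purpose not in _SEED_TAGS:
        raise KeyError(f"unknown seed purpose {purpose!r}")
    ss = np.random.SeedSequence([int(seed), _SEED_TAGS[purpose]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SensingRate:
    """A sensing rate in (0, 1] with its derived channel count."""

    value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.value <= 1.0):
            raise InvalidSensingRateError(
                f"sensing rate must lie in (0, 1], got {self.value!r}"
            )

    @property
    def channels(self) -> int:
        return channels_for_sr(self.value)

    @property
    def effective(self) -> float:
        return effective_sr(self.channels)


@dataclass
class ModelConfig:
    """Everything that determines the network architecture.

    ``feat_widths`` are the output widths of feature convolutions 2-5
    (c2, c3, c4, c5); c5 is fixed at 128 by the published parameter totals,
    and the default (c2, c3, c4) = (408, 344, 286) is the configuration
    recovered by :func:`csbnet.model.reconstruct_widths` from those totals.
    """

    sr: float = 0.7
    num_classes: int = 4
    cs_widths: tuple[int, int, int] = (64, 64, 64)
    feat_widths: tuple[int, int, int, int] = (408, 344, 286, 128)
    first_feat_filters: int = 48
    fc_dims: tuple[int, int, int] = (512, 1024, 2048)
    attention: str = "se"
    se_reduction: int = 16
    eca_gamma: int = 2
    eca_b: int = 1
    cbam_spatial_kernel: int = 3
    dropout_p: float = 0.5
    upsample_factor: int = 2

    def __post_init__(self) -> None:
        self.cs_widths = tuple(int(w) for w in self.cs_widths)
        self.feat_widths = tuple(int(w) for w in self.feat_widths)
        self.fc_dims = tuple(int(d) for d in self.fc_dims)
        SensingRate(self.sr)  # validates the range
        if self.num_classes < 2:
            raise ConfigError(f"need at least 2 classes, got {self.num_classes}")
        if self.attention not in ATTENTION_KINDS:
            raise ConfigError(
                f"attention must be one of {ATTENTION_KINDS}, got {self.attention!r}"
            )
        if len(self.cs_widths) != 3 or any(w < 1 for w in self.cs_widths):
            raise ConfigError(f"cs_widths must be 3 positive ints, got {self.cs_widths}")
        if len(self.feat_widths) != 4 or any(w < 1 for w in self.feat_widths):
            raise ConfigError(
                f"feat_widths must be 4 positive ints, got {self.feat_widths}"
            )
        if len(self.fc_dims) != 3:
            raise ConfigError(f"fc_dims must be 3 ints, got {self.fc_dims}")
        # The classifier input is the attention-stage output flattened from a
        # 2x2 adaptive pool over c5 channels.
        if self.fc_dims[0] != self.feat_widths[3] * 2 * 2:
            raise ConfigError(
                f"fc_dims[0]={self.fc_dims[0]} must equal feat_widths[3]*4="
                f"{self.feat_widths[3] * 4} (flatten dimension)"
            )
        if self.attention in ("se", "cbam") and self.feat_widths[3] % self.se_reduction:
            raise ConfigError(
                f"c5={self.feat_widths[3]} not divisible by se_reduction="
                f"{self.se_reduction}"
            )
        if not (0.0 <= self.dropout_p < 1.0):
            raise ConfigError(f"dropout_p must lie in [0, 1), got {self.dropout_p}")
        if self.upsample_factor < 1:
            raise ConfigError(f"upsample_factor must be >= 1, got {self.upsample_factor}")

    @property
    def x_channels(self) -> int:
        return channels_for_sr(self.sr)

    @property
    def effective_sr(self) -> float:
        return effective_sr(self.x_channels)


@dataclass
class TrainConfig:
    """Optimizer and loop settings (Adam, learning rate 1e-4 by default)."""

    learning_rate: float = 1e-4
    epochs: int = 5
    batch_size: int = 8
    seed: int = 0
    optimizer: str = "adam"
    augment: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.epochs < 1:
            raise ConfigError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ConfigError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.optimizer != "adam":
            raise ConfigError(f"only the adam optimizer is supported, got {self.optimizer!r}")


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def config_to_dict(config: ModelConfig | TrainConfig) -> dict[str, Any]:
    return _to_plain(config)


def _from_dict(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def model_config_from_dict(data: dict[str, Any]) -> ModelConfig:
    return _from_dict(ModelConfig, data)


def train_config_from_dict(data: dict[str, Any]) -> TrainConfig:
    return _from_dict(TrainConfig, data)


def save_config(config: ModelConfig | TrainConfig, path: str | Path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        raise ConfigError(f"unsupported config format {path.suffix!r}")


def load_config(path: str | Path, kind: str = "model") -> ModelConfig | TrainConfig:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
    elif path.suffix == ".json":
        data = json.loads(path.read_text())
    else:
        raise ConfigError(f"unsupported config format {path.suffix!r}")
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not hold a mapping")
    if kind == "model":
        return model_config_from_dict(data)
    if kind == "train":
        return train_config_from_dict(data)
    raise ConfigError(f"kind must be 'model' or 'train', got {kind!r}")
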