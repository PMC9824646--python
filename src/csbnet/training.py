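"""Cross-entropy training loop (Adam, LR 1e-4) and the sensing-rate sweep.

The loss is the cross-entropy H(p, q) = -sum_x p(x) log q(x) (natural log)
between the one-hot label distribution p and the softmax output q, with an
epsilon floor of 1e-12 inside the logarithm so that a confidently wrong
prediction yields a large finite loss rather than an infinity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig, TrainConfig, derive_seed
from .metrics import MetricsReport, confusion, score
from .model import Network, build_network
from .preprocessing import ImageBatch, augment

logger = logging.getLogger(__name__)

LOG_EPS = 1e-12


def cross_entropy(predicted: np.ndarray, true: np.ndarray, eps: float = LOG_EPS) -> float:
    """H(p, q) = -sum p log q for two distributions over the same support."""
    p = np.asarray(true, dtype=np.float64)
    q = np.asarray(predicted, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"distribution shapes disagree: {p.shape} vs {q.shape}")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("distributions must be non-negative")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-6) or not np.allclose(
        q.sum(axis=-1), 1.0, atol=1e-6
    ):
        raise ValueError("distributions must sum to 1")
    return float(-(p * np.log(np.maximum(q, eps))).sum(axis=-1).mean())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against integer labels, plus
    the gradient with respect to the logits."""
    n = logits.shape[0]
    q = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.maximum(q[np.arange(n), labels], LOG_EPS)).mean())
    grad = q.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_accuracy: float


@dataclass
class History:
    """Per-epoch training record plus the final evaluation report."""

    epochs: list[EpochRecord] = field(default_factory=list)
    final_report: MetricsReport | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.epochs])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def evaluate(net: Network, batch: ImageBatch, batch_size: int = 16) -> MetricsReport:
    scores = net.predict_scores(batch.pixels, batch_size=batch_size)
    preds = scores.argmax(axis=1)
    cm = confusion(batch.labels, preds, batch.num_classes, batch.class_names)
    return score(cm)


def train(
    net: Network,
    train_batch: ImageBatch,
    val_batch: ImageBatch,
    tc: TrainConfig,
    log_every: int = 0,
) -> History:
    """Minibatch Adam on mean cross-entropy with online seeded augmentation.

    The same seed yields an identical History on identical hardware and
    thread settings.
    """
    from .nn import Adam

    if len(train_batch) == 0:
        raise ValueError("training set is empty")
    if train_batch.num_classes != net.config.num_classes:
        raise ValueError(
            f"dataset has {train_batch.num_classes} classes but the network "
            f"outputs {net.config.num_classes}"
        )
    opt = Adam(net.parameters(), lr=tc.learning_rate)
    shuffle_rng = np.random.default_rng(derive_seed(tc.seed, "shuffle"))
    dropout_rng = np.random.default_rng(derive_seed(tc.seed, "dropout"))
    net.set_dropout_rng(dropout_rng)
    history = History()
    n = len(train_batch)
    for epoch in range(tc.epochs):
        if tc.augment:
            epoch_batch = augment(train_batch, derive_seed(tc.seed, "augment") + epoch)
        else:
            epoch_batch = train_batch
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xb = epoch_batch.pixels[idx]
            yb = epoch_batch.labels[idx]
            logits = net.forward(xb, training=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start // tc.batch_size}"
                )
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        report = evaluate(net, val_batch) if len(val_batch) else None
        val_acc = report.accuracy if report else float("nan")
        history.epochs.append(EpochRecord(epoch, float(np.mean(losses)), val_acc))
        if log_every and (epoch % log_every == 0):
            logger.info(
                "epoch %d: loss %.4f, val accuracy %.4f",
                epoch, history.epochs[-1].train_loss, val_acc,
            )
    net.set_dropout_rng(None)
    if len(val_batch):
        history.final_report = evaluate(net, val_batch)
    return history


def train_model(
    config: ModelConfig,
    train_batch: ImageBatch,
    val_batch: ImageBatch,
    tc: TrainConfig,
) -> tuple[Network, History]:
    """Build a fresh network from ``config`` (seeded) and train it."""
    net = build_network(config, seed=tc.seed)
    history = train(net, train_batch, val_batch, tc)
    return net, history


#: The sensing-rate grid used throughout the experiments.
DEFAULT_SR_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)


def sr_sweep(
    srs: tuple[float, ...],
    train_batch: ImageBatch,
    val_batch: ImageBatch,
    tc: TrainConfig,
    base_config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Train one fresh network per sensing rate and tabulate accuracies."""
    rows = []
    for sr in sorted(srs):
        config = ModelConfig(
            **{
                **(
                    _config_kwargs(base_config)
                    if base_config is not None
                    else {"num_classes": train_batch.num_classes}
                ),
                "sr": sr,
            }
        )
        _, history = train_model(config, train_batch, val_batch, tc)
        report = history.final_report
        rows.append(
            {
                "sr": sr,
                "effective_sr": config.effective_sr,
                "x_channels": config.x_channels,
                "accuracy": report.accuracy,
                "macro_precision": report.macro_precision,
                "macro_recall": report.macro_recall,
                "macro_f1": report.macro_f1,
            }
        )
    return pd.DataFrame(rows)


def _config_kwargs(config: ModelConfig) -> dict:
    from .config import config_to_dict

    d = config_to_dict(config)
    for key in ("cs_widths", "feat_widths", "fc_dims"):
        d[key] = tuple(d[key])
    return d
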