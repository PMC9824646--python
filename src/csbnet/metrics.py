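"""Confusion-matrix construction and classification metrics.

Accuracy is trace/total of the confusion matrix; precision, recall and F1
are computed one-vs-rest per class from TP/FP/FN counts and averaged
without weights (macro).  A metric whose denominator is zero — e.g. the
precision of a class that was never predicted — is reported as 0 with a
warning, which is the honest convention at very low sensing rates where a
class can disappear from the predictions entirely.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    class_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": name, "precision": p, "recall": r, "f1": f}
            for name, p, r, f in zip(self.class_names, self.precision, self.recall, self.f1)
        ]
        rows.append(
            {
                "class": "macro",
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            }
        )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["accuracy"] = self.accuracy
        df.to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "accuracy": self.accuracy,
                "per_class": {
                    name: {"precision": float(p), "recall": float(r), "f1": float(f)}
                    for name, p, r, f in zip(
                        self.class_names, self.precision, self.recall, self.f1
                    )
                },
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall,
                "macro_f1": self.macro_f1,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def confusion(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    num_classes: int,
    class_names: list[str] | None = None,
) -> ConfusionMatrix:
    """Tally counts[i, j] = #{samples with true class i predicted as j}."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"label arrays disagree: {t.shape} vs {p.shape}")
    if t.size and not (
        0 <= t.min() and t.max() < num_classes and 0 <= p.min() and p.max() < num_classes
    ):
        raise ValueError(f"labels must lie in [0, {num_classes})")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    names = class_names or [str(i) for i in range(num_classes)]
    return ConfusionMatrix(counts, list(names))


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if not ok.all():
        warnings.warn(f"{what} undefined for {int((~ok).sum())} class(es); reported as 0")
    return out


def score(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy plus one-vs-rest precision/recall/F1 with macro averages."""
    if cm.total == 0:
        raise ValueError("cannot score an empty confusion matrix")
    counts = cm.counts.astype(np.float64)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "F1")
    return MetricsReport(
        accuracy=float(tp.sum() / cm.total),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        class_names=list(cm.class_names),
    )


def accuracy_from_correct_counts(correct: list[int], total: int) -> float:
    """Accuracy from per-class correct-prediction counts (worked examples)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return sum(correct) / total
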