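"""Train/test splitting and agreement metrics for the surname classifiers.

The evaluation protocol holds out a fraction of the reference
surname-ancestry pairs (20% by default), scores the classifier on the
held-out pairs, and reports the row-normalized confusion matrix, overall
accuracy (trace / total) and Cohen's kappa (chance-corrected agreement).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .labels import CLASS_ORDER, AncestryLabel

__all__ = [
    "ConfusionMatrix",
    "split_train_test",
    "confusion",
    "accuracy",
    "cohen_kappa",
    "evaluation_report",
]


def split_train_test(
    pairs: Sequence,
    test_fraction: float,
    seed: int,
    stratify: bool = False,
) -> tuple[list, list]:
    """Seeded uniform random split without replacement.

    The test side receives round(N * test_fraction) items (per class when
    ``stratify`` is set); every item lands on exactly one side.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cannot split an empty list")
    rng = np.random.default_rng(seed)
    if stratify:
        by_class: dict = {}
        for idx, (_, label) in enumerate(pairs):
            by_class.setdefault(label, []).append(idx)
        test_idx: set[int] = set()
        for label in sorted(by_class, key=lambda c: c.value):
            idx = np.array(by_class[label])
            k = int(round(len(idx) * test_fraction))
            test_idx.update(idx[rng.permutation(len(idx))[:k]].tolist())
    else:
        n_test = int(round(len(pairs) * test_fraction))
        test_idx = set(rng.permutation(len(pairs))[:n_test].tolist())
    train = [p for i, p in enumerate(pairs) if i not in test_idx]
    test = [p for i, p in enumerate(pairs) if i in test_idx]
    return train, test


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts indexed [observed, predicted] in a fixed class order."""

    counts: np.ndarray
    labels: tuple[AncestryLabel, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("confusion matrix shape does not match label count")
        if (counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_predictions(
        cls,
        observed: Sequence[AncestryLabel],
        predicted: Sequence[AncestryLabel],
        labels: tuple[AncestryLabel, ...] = CLASS_ORDER,
    ) -> "ConfusionMatrix":
        if len(observed) != len(predicted):
            raise ValueError("observed and predicted lengths differ")
        index = {label: i for i, label in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for obs, pred in zip(observed, predicted):
            counts[index[obs], index[pred]] += 1
        return cls(counts=counts, labels=labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Row-normalized shares; rows with zero observations stay zero."""
        row_sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            shares = np.where(row_sums > 0, self.counts / row_sums, 0.0)
        return shares


def confusion(
    predicted: Sequence[AncestryLabel],
    observed: Sequence[AncestryLabel],
    labels: tuple[AncestryLabel, ...] = CLASS_ORDER,
) -> ConfusionMatrix:
    """Confusion matrix with rows = observed class, columns = predicted."""
    return ConfusionMatrix.from_predictions(observed, predicted, labels)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy: correct predictions over total observations."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement (trace/total) and p_e the agreement
    expected by chance from the row and column margins.  The degenerate
    case p_e = 1 is defined as 0 with a warning.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / total
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    p_e = float((rows * cols).sum()) / total**2
    if p_e >= 1.0 - 1e-15:
        warnings.warn("chance agreement p_e = 1; kappa defined as 0")
        return 0.0
    return float((p_o - p_e) / (1 - p_e))


def evaluation_report(
    cm: ConfusionMatrix,
    seed: int | None = None,
    config: dict | None = None,
    path: str | Path | None = None,
) -> dict:
    """JSON-serializable report: counts, normalized matrix, accuracy, kappa.

    Normalized shares are rounded to 2 decimals for presentation; raw
    counts are always included.
    """
    report = {
        "labels": [c.value for c in cm.labels],
        "counts": cm.counts.tolist(),
        "normalized": np.round(cm.normalized(), 2).tolist(),
        "accuracy": accuracy(cm),
        "kappa": cohen_kappa(cm),
        "n_test": cm.total,
        "seed": seed,
        "config": config or {},
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=1), "utf-8")
    return report
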