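"""Confusion matrices, support-weighted metrics, and permutation importance."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from bleatkit.models import TrainedModel, predict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """True-class x predicted-class counts under a fixed label order."""

    counts: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.labels)
        if counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", list(self.labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def normalized(self) -> np.ndarray:
        """Row-stochastic view; zero-support rows stay all-zero."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(np.float64)
        return np.divide(self.counts, sums, out=np.zeros_like(self.counts, dtype=np.float64), where=sums > 0)


@dataclass(frozen=True)
class MetricsReport:
    """Support-weighted accuracy/precision/recall/F1 plus Cohen's kappa."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    per_class: dict

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "kappa": self.kappa,
            "per_class": self.per_class,
        }


def confusion(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Count matrix with rows = true labels, columns = predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if labels is None:
        labels = sorted(np.unique(y_true).tolist())
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=list(labels))


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class one-vs-rest P/R/F1, support-weighted averages, and kappa.

    0/0 cases (never-predicted or absent classes) contribute 0 with a logged
    warning; kappa uses Pr(e) = sum_c rowsum_c * colsum_c / total^2.
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    fp = col - tp
    fn = row - tp

    with np.errstate(divide="ignore", invalid="ignore"):
        precision_c = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall_c = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr_sum = precision_c + recall_c
        f1_c = np.where(pr_sum > 0, 2 * precision_c * recall_c / np.where(pr_sum > 0, pr_sum, 1.0), 0.0)
    if np.any((tp + fp) == 0) or np.any((tp + fn) == 0):
        logger.warning("metrics: undefined per-class precision/recall set to 0")

    weights = row / total
    accuracy = float(tp.sum() / total)
    pr_e = float((row * col).sum() / total**2)
    kappa = 0.0 if pr_e >= 1.0 else float((accuracy - pr_e) / (1.0 - pr_e))

    per_class = {
        str(lab): {
            "precision": float(precision_c[i]),
            "recall": float(recall_c[i]),
            "f1": float(f1_c[i]),
            "support": int(row[i]),
        }
        for i, lab in enumerate(cm.labels)
    }
    return MetricsReport(
        accuracy=accuracy,
        precision=float((weights * precision_c).sum()),
        recall=float((weights * recall_c).sum()),
        f1=float((weights * f1_c).sum()),
        kappa=kappa,
        per_class=per_class,
    )


def permutation_importance(
    m: TrainedModel,
    X_test,
    y_test,
    n_repeats: int = 5,
    seed: int = 0,
    per_class: bool = False,
) -> list[dict]:
    """Mean accuracy drop per shuffled feature column, sorted descending.

    With ``per_class=True`` the drop in per-class recall is reported too,
    giving class-conditional importance without model internals.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X_test, dtype=np.float64)
    y = np.asarray(y_test)
    rng = np.random.default_rng(seed)

    base_pred = predict(m, X)
    base_acc = float(np.mean(base_pred == y))
    classes = list(m.classes)
    base_recall = {c: float(np.mean(base_pred[y == c] == c)) if np.any(y == c) else 0.0 for c in classes}

    names = m.feature_names or [f"feature_{j}" for j in range(X.shape[1])]
    results = []
    for j in range(X.shape[1]):
        drops = np.zeros(n_repeats)
        class_drops = {c: np.zeros(n_repeats) for c in classes} if per_class else None
        for r in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            pred = predict(m, Xp)
            drops[r] = base_acc - float(np.mean(pred == y))
            if per_class:
                for c in classes:
                    mask = y == c
                    if mask.any():
                        class_drops[c][r] = base_recall[c] - float(np.mean(pred[mask] == c))
        entry = {"feature": names[j], "index": j, "importance": float(drops.mean()), "std": float(drops.std())}
        if per_class:
            entry["per_class"] = {str(c): float(v.mean()) for c, v in class_drops.items()}
        results.append(entry)
    return sorted(results, key=lambda e: -e["importance"])
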