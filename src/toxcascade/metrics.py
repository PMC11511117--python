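"""Evaluation: confusion matrices, multiclass MCC, split statistics, t-test.

The Matthews correlation coefficient is computed in its multi-category
generalization directly from the confusion matrix: with ``c`` the trace,
``s`` the total, ``p_k`` the predicted-column sums and ``t_k`` the
actual-row sums,

    MCC = (c*s - sum_k p_k t_k)
          / sqrt((s^2 - sum_k p_k^2) * (s^2 - sum_k t_k^2))

It is 1 for a perfect diagonal, 0 when predictions carry no information
about the actual classes, and bounded in [-1, 1].  A degenerate matrix
(zero denominator, e.g. all predictions in one column) returns 0 by
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are actual classes, columns predicted."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} labels"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        """Actual class frequencies."""
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        """Predicted class frequencies."""
        return self.counts.sum(axis=0)

    def per_class_accuracy(self) -> dict[str, float]:
        """Diagonal over row sum per class (recall); NaN for empty classes."""
        out = {}
        for i, lab in enumerate(self.labels):
            row = self.counts[i].sum()
            out[lab] = float(self.counts[i, i] / row) if row else float("nan")
        return out

    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total) if self.total else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=[str(c) for c in df.columns], counts=df.to_numpy())


def confusion(
    actual: Sequence[str],
    predicted: Sequence[str],
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Count co-occurrences of actual (rows) and predicted (columns) labels.

    ``labels`` fixes the class ordering; by default it is the sorted union
    of observed labels.  Labels outside ``labels`` raise ``ValueError``.
    """
    if len(actual) != len(predicted):
        raise ValueError(
            f"actual has {len(actual)} items, predicted {len(predicted)}"
        )
    if labels is None:
        labels = sorted(set(actual) | set(predicted))
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            unknown = a if a not in index else p
            raise ValueError(f"label {unknown!r} not in label set {labels}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def multiclass_mcc(cm: ConfusionMatrix) -> float:
    """Multi-category Matthews correlation coefficient of a confusion matrix."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    C = cm.counts.astype(np.float64)
    s = C.sum()
    c = np.trace(C)
    t = C.sum(axis=1)  # actual
    p = C.sum(axis=0)  # predicted
    cov_xy = c * s - p @ t
    cov_xx = s * s - p @ p
    cov_yy = s * s - t @ t
    denom = math.sqrt(cov_xx) * math.sqrt(cov_yy)
    if denom == 0.0:
        return 0.0
    return float(cov_xy / denom)


def split_stats(per_split_accuracies: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of per-split
    validation accuracies; the convention matching published per-class
    split-variance rows."""
    x = np.asarray(per_split_accuracies, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 split accuracies")
    return float(x.mean()), float(x.std(ddof=1))


def two_sample_t(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test on per-species annotation counts.

    Welch's unequal-variance form by default (species sets differ between
    analyses); a paired option is exposed.  Two identical zero-variance
    samples return (0.0, 1.0) — the no-difference answer — where the raw
    formula is 0/0.
    """
    a = np.asarray(counts_a, dtype=np.float64)
    b = np.asarray(counts_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal-length samples")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t) and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    return t, p
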