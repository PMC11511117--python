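"""Class-wise stratified train/validation splitting.

Two rules cover the imbalanced venom-peptide training material:

``capped_fraction`` — per class, a 0.25 validation fraction is drawn first
(validation count = ceil(0.25 * N); ceiling is the only rounding that
reproduces all published per-class counts simultaneously).  If the remaining
training members exceed the cap of 150, the surplus is moved to validation,
so abundant classes never dominate training.  A class of 627 yields
150 train / 477 validation; a class of 89 yields 66 / 23.

``fixed_train`` — per class, exactly ``fixed_train_n`` members (default 32)
are taken for training with no prior validation split; the rest validate.
Used for the sodium-toxin functional dataset where two of the three classes
have only 42 members.

Membership is assigned uniformly at random per class under a recorded seed,
so repeated splits with different seeds give identical counts but different
memberships — the basis of split-variance reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import LabeledDataset


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of the stratified split."""

    val_fraction: float = 0.25
    train_cap: int = 150
    mode: str = "capped_fraction"  # or "fixed_train"
    fixed_train_n: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.train_cap < 1 or self.fixed_train_n < 1:
            raise ValueError("train_cap and fixed_train_n must be >= 1")
        if self.mode not in ("capped_fraction", "fixed_train"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SplitResult:
    """Per-class memberships plus a count summary.

    ``train_ids``/``val_ids`` map class label to the record ids assigned to
    each partition; ``summary`` maps class label to
    ``(total, n_train, n_val)``.
    """

    train_ids: dict[str, list[str]]
    val_ids: dict[str, list[str]]
    summary: dict[str, tuple[int, int, int]]

    def all_train_ids(self) -> list[str]:
        return [i for ids in self.train_ids.values() for i in ids]

    def all_val_ids(self) -> list[str]:
        return [i for ids in self.val_ids.values() for i in ids]

    def train_subset(self, dataset: LabeledDataset) -> LabeledDataset:
        return dataset.subset_by_ids(self.all_train_ids())

    def val_subset(self, dataset: LabeledDataset) -> LabeledDataset:
        return dataset.subset_by_ids(self.all_val_ids())

    def to_manifest(self, path: str | Path) -> None:
        """Write an audit CSV: sequence id, class, partition."""
        rows = []
        for cls, ids in self.train_ids.items():
            rows += [(i, cls, "train") for i in ids]
        for cls, ids in self.val_ids.items():
            rows += [(i, cls, "val") for i in ids]
        pd.DataFrame(rows, columns=["id", "class", "partition"]).to_csv(
            path, index=False
        )


def capped_counts(n: int, val_fraction: float, train_cap: int) -> tuple[int, int]:
    """Training/validation counts for one class of size ``n`` under the
    capped-fraction rule.  Pure arithmetic, exposed for audit."""
    n_val_initial = math.ceil(val_fraction * n)
    n_train = min(n - n_val_initial, train_cap)
    return n_train, n - n_train


def capped_fraction_split(dataset: LabeledDataset, spec: SplitSpec) -> SplitResult:
    """Stratified split with a validation fraction and a training cap."""
    return _split(dataset, spec, _capped_rule)


def fixed_train_split(dataset: LabeledDataset, spec: SplitSpec) -> SplitResult:
    """Stratified split taking exactly ``fixed_train_n`` training members
    per class, the rest to validation."""
    return _split(dataset, spec, _fixed_rule)


def split(dataset: LabeledDataset, spec: SplitSpec) -> SplitResult:
    """Dispatch on ``spec.mode``."""
    if spec.mode == "fixed_train":
        return fixed_train_split(dataset, spec)
    return capped_fraction_split(dataset, spec)


def _capped_rule(cls: str, n: int, spec: SplitSpec) -> int:
    if n < 2:
        raise ValueError(f"class {cls!r} has {n} member(s); need at least 2")
    n_train, _ = capped_counts(n, spec.val_fraction, spec.train_cap)
    return n_train

def _fixed_rule(cls: str, n: int, spec: SplitSpec) -> int:
    if n < spec.fixed_train_n + 1:
        raise ValueError(
            f"class {cls!r} has {n} member(s); need at least "
            f"{spec.fixed_train_n + 1} for a fixed-{spec.fixed_train_n} split"
        )
    return spec.fixed_train_n


def _split(dataset: LabeledDataset, spec: SplitSpec, rule) -> SplitResult:
    rng = np.random.default_rng(spec.seed)
    by_class: dict[str, list[str]] = {c: [] for c in dataset.class_labels}
    for rec, label in zip(dataset.records, dataset.labels):
        by_class[label].append(rec.id)

    train_ids: dict[str, list[str]] = {}
    val_ids: dict[str, list[str]] = {}
    summary: dict[str, tuple[int, int, int]] = {}
    for cls in dataset.class_labels:
        ids = by_class[cls]
        n = len(ids)
        n_train = rule(cls, n, spec)
        perm = rng.permutation(n)
        train_ids[cls] = [ids[i] for i in perm[:n_train]]
        val_ids[cls] = [ids[i] for i in perm[n_train:]]
        summary[cls] = (n, n_train, n - n_train)
    return SplitResult(train_ids=train_ids, val_ids=val_ids, summary=summary)
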