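"""Labeled sequence collections used for training and evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .seq_io import (
    SequenceRecord,
    read_training_table,
    write_training_table,
)


@dataclass
class LabeledDataset:
    """Sequences with class labels plus the ordered class vocabulary.

    ``class_labels`` fixes the output ordering of every classifier trained
    on the dataset; by default it is the sorted set of observed labels.
    """

    records: list[SequenceRecord]
    labels: list[str]
    class_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        if not self.class_labels:
            self.class_labels = sorted(set(self.labels))
        unknown = set(self.labels) - set(self.class_labels)
        if unknown:
            raise ValueError(f"labels outside class vocabulary: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in self.class_labels}

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            records=[self.records[i] for i in indices],
            labels=[self.labels[i] for i in indices],
            class_labels=list(self.class_labels),
        )

    def subset_by_ids(self, ids: Sequence[str]) -> "LabeledDataset":
        index = {r.id: i for i, r in enumerate(self.records)}
        return self.subset([index[i] for i in ids])

    def to_csv(self, path: str | Path) -> None:
        """Write as the two-column training table (class, spaced residues)."""
        write_training_table(self.records, self.labels, path)

    @classmethod
    def from_csv(cls, path: str | Path, class_labels: Sequence[str] | None = None) -> "LabeledDataset":
        labels, residue_strings = read_training_table(path)
        records = [
            SequenceRecord(id=f"seq{i}", residues=s)
            for i, s in enumerate(residue_strings)
        ]
        return cls(records, labels, list(class_labels) if class_labels else [])
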