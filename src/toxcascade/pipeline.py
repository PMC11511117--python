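"""The three-stage classification cascade.

Stage 1 (housekeeping filter) labels every sequence toxin or non-toxin by
argmax — no probability cutoff — and drops the non-toxins.  Stage 2 assigns
each surviving sequence to one of the four toxin classes (ICK, KTx, NaTx,
venom).  Stage 3 runs only on NaTx-labeled sequences: an ensemble of three
identically configured functional classifiers, trained on different splits,
must *unanimously* agree on insect-only / mammal-only / both; any
disagreement discards the sequence.  The cascade conserves its input: every
record ends exactly one of classified, filtered_out or
discarded_by_consensus.

Input is one FASTA per invocation — transcriptomes are processed one
species at a time; batching across species is the caller's concern.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .model import TrainedClassifier
from .seq_io import SequenceRecord, write_fasta

TOXIN_LABEL = "toxin"
STATUS_CLASSIFIED = "classified"
STATUS_FILTERED = "filtered_out"
STATUS_DISCARDED = "discarded_by_consensus"


def consensus(predictions: Sequence[str]) -> str | None:
    """Unanimous vote of exactly three ensemble predictions.

    Returns the common label if all three agree, else ``None`` (discard).
    Permutation-invariant by construction.
    """
    if len(predictions) != 3:
        raise ValueError(f"consensus needs exactly 3 predictions, got {len(predictions)}")
    return predictions[0] if predictions[0] == predictions[1] == predictions[2] else None


@dataclass
class RecordOutcome:
    """Cascade outcome for one input sequence."""

    id: str
    stage1_label: str
    stage2_label: str | None = None
    stage3_label: str | None = None
    status: str = STATUS_CLASSIFIED


@dataclass
class PipelineResult:
    """Per-record outcomes plus label tallies.

    Invariant: every input record appears exactly once, and
    ``classified + filtered_out + discarded == n_input``.
    """

    outcomes: list[RecordOutcome]
    tallies: dict[str, int]

    @property
    def n_input(self) -> int:
        return len(self.outcomes)

    def labels(self, stage: int = 2) -> dict[str, str]:
        """Mapping id -> stage label for classified records."""
        attr = f"stage{stage}_label"
        return {
            o.id: getattr(o, attr)
            for o in self.outcomes
            if o.status == STATUS_CLASSIFIED and getattr(o, attr) is not None
        }

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [
                (o.id, o.stage1_label, o.stage2_label or "", o.stage3_label or "", o.status)
                for o in self.outcomes
            ],
            columns=["id", "stage1", "stage2", "stage3", "status"],
        )
        df.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_input": self.n_input, "tallies": self.tallies}, fh, indent=2)

    def write_class_fastas(
        self, records: Sequence[SequenceRecord], out_dir: str | Path
    ) -> list[Path]:
        """Re-emit classified sequences as one FASTA per stage-2 class."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        by_id = {r.id: r for r in records}
        groups: dict[str, list[SequenceRecord]] = {}
        for o in self.outcomes:
            if o.status == STATUS_CLASSIFIED and o.stage2_label:
                groups.setdefault(o.stage2_label, []).append(by_id[o.id])
        paths = []
        for label, recs in sorted(groups.items()):
            p = out_dir / f"{label}.fasta"
            write_fasta(recs, p)
            paths.append(p)
        return paths


def run_cascade(
    records: Sequence[SequenceRecord],
    housekeeping_model: TrainedClassifier | None,
    toxin_model: TrainedClassifier,
    ensemble: Sequence[TrainedClassifier] | None = None,
    natx_label: str = "NaTx",
) -> PipelineResult:
    """Run the full cascade over one species' sequences.

    ``housekeeping_model`` may be ``None`` to skip stage 1 (the entry point
    for inputs already pre-selected by a similarity screen).  ``ensemble``
    may be ``None`` to stop after stage 2; when given it must hold exactly
    three classifiers.
    """
    if ensemble is not None and len(ensemble) != 3:
        raise ValueError(
            f"functional stage needs exactly 3 ensemble members, got {len(ensemble)}"
        )
    records = list(records)
    outcomes = {r.id: RecordOutcome(id=r.id, stage1_label=TOXIN_LABEL) for r in records}

    # Stage 1: toxin / non-toxin filter.
    survivors = records
    if housekeeping_model is not None and records:
        stage1 = housekeeping_model.predict(records)
        survivors = []
        for rec, lab in zip(records, stage1):
            outcomes[rec.id].stage1_label = lab
            if lab == TOXIN_LABEL:
                survivors.append(rec)
            else:
                outcomes[rec.id].status = STATUS_FILTERED

    # Stage 2: four-class toxin classification.
    if survivors:
        stage2 = toxin_model.predict(survivors)
        for rec, lab in zip(survivors, stage2):
            outcomes[rec.id].stage2_label = lab

    # Stage 3: functional ensemble on NaTx only, unanimous consensus.
    if ensemble is not None and survivors:
        natx_records = [r for r in survivors if outcomes[r.id].stage2_label == natx_label]
        if natx_records:
            votes = [m.predict(natx_records) for m in ensemble]
            for i, rec in enumerate(natx_records):
                label = consensus([votes[0][i], votes[1][i], votes[2][i]])
                if label is None:
                    outcomes[rec.id].status = STATUS_DISCARDED
                else:
                    outcomes[rec.id].stage3_label = label

    ordered = [outcomes[r.id] for r in records]
    tallies: Counter = Counter()
    for o in ordered:
        if o.status != STATUS_CLASSIFIED:
            tallies[o.status] += 1
        elif o.stage3_label is not None:
            tallies[o.stage3_label] += 1
        elif o.stage2_label is not None:
            tallies[o.stage2_label] += 1
        else:
            tallies[o.stage1_label] += 1
    return PipelineResult(outcomes=ordered, tallies=dict(tallies))
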