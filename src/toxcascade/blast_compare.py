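"""BLAST tabular parsing and BLAST-vs-pipeline concordance.

Similarity annotation assigns each transcript the class of its best BLAST
hit (lowest e-value, ties by highest bitscore, then first occurrence in the
file).  Cross-classifying those labels against the cascade's predictions
gives the change-of-annotation matrix: rows are the BLAST ("expected")
classes, columns the pipeline ("predicted") classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .metrics import ConfusionMatrix, confusion

#: Standard 12 columns of BLAST tabular output (-outfmt 6).
OUTFMT6_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]

#: Default acceptance cutoff: the weak end of the e-value range typically
#: seen on accepted toxin annotations (1e-10 .. 1e-60).
DEFAULT_MAX_EVALUE = 1e-10


@dataclass(frozen=True)
class BlastHit:
    """One line of BLAST -outfmt 6."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")


def parse_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse a 12-column BLAST tabular file (scientific e-values included).

    Lines with a wrong column count raise ``ValueError`` naming the line.
    An empty file yields an empty list.
    """
    path = Path(path)
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated "
                    f"columns, found {len(fields)}"
                )
            hits.append(
                BlastHit(
                    query_id=_trim_id(fields[0]),
                    subject_id=_trim_id(fields[1]),
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return hits


def write_blast_tab(hits: Sequence[BlastHit], path: str | Path) -> None:
    """Write hits back out as 12-column tab-separated text."""
    df = pd.DataFrame([[getattr(h, c) for c in OUTFMT6_COLUMNS] for h in hits],
                      columns=OUTFMT6_COLUMNS)
    df.to_csv(path, sep="\t", header=False, index=False)


def _trim_id(raw: str) -> str:
    # Ids are matched after trimming at the first whitespace, mirroring
    # FASTA header handling.
    return raw.split()[0] if raw.split() else raw


def best_hit_labels(
    hits: Sequence[BlastHit],
    subject_classes: Mapping[str, str],
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> dict[str, str]:
    """Per query, the class of its best hit at or below ``max_evalue``.

    Best = lowest e-value, ties by highest bitscore, then first occurrence.
    Queries with no retained hit are absent from the result.  A retained hit
    whose subject is missing from ``subject_classes`` raises ``KeyError``
    listing the offenders.
    """
    retained = [h for h in hits if h.evalue <= max_evalue]
    missing = sorted({h.subject_id for h in retained} - set(subject_classes))
    if missing:
        raise KeyError(f"subjects missing from class mapping: {missing}")
    best: dict[str, tuple[float, float, int]] = {}
    chosen: dict[str, str] = {}
    for pos, h in enumerate(retained):
        key = (h.evalue, -h.bitscore, pos)
        if h.query_id not in best or key < best[h.query_id]:
            best[h.query_id] = key
            chosen[h.query_id] = subject_classes[h.subject_id]
    return chosen


def read_subject_classes(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV mapping subject id to class (header optional)."""
    df = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {df.shape[1]}")
    first = [s.lower() for s in df.iloc[0]]
    if first in (["subject_id", "class"], ["subject", "class"], ["id", "class"]):
        df = df.iloc[1:]
    return {_trim_id(s): c for s, c in zip(df.iloc[:, 0], df.iloc[:, 1])}


def cross_classification(
    blast_labels: Mapping[str, str],
    pipeline_labels: Mapping[str, str],
    labels: Sequence[str] | None = None,
) -> tuple[ConfusionMatrix, dict[str, int]]:
    """Cross-classify BLAST (rows, expected) vs pipeline (columns, predicted)
    over the intersection of query ids.

    Returns the confusion matrix plus a tally of ids present in only one
    mapping: ``{"blast_only": ..., "pipeline_only": ...}``.
    """
    shared = sorted(set(blast_labels) & set(pipeline_labels))
    actual = [blast_labels[q] for q in shared]
    predicted = [pipeline_labels[q] for q in shared]
    cm = confusion(actual, predicted, labels=labels)
    extras = {
        "blast_only": len(set(blast_labels) - set(pipeline_labels)),
        "pipeline_only": len(set(pipeline_labels) - set(blast_labels)),
    }
    return cm, extras
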