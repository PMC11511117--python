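"""FASTA and training-table I/O for venom peptide sequences.

The pipeline's universal unit is the :class:`SequenceRecord`: a protein
sequence identified by its FASTA header (up to the first whitespace).
Residues are uppercase symbols over the 20 canonical amino acids plus the
ambiguity/rare codes B, Z, X, U, O.  Characters outside that alphabet are
mapped to ``X`` with a warning rather than rejected, so that batch runs over
transcriptome translations (which routinely contain odd symbols) do not
abort.

Training material for the classifiers is exchanged as a two-column CSV
(``class,sequence``) in which the residues of each sequence are separated by
single spaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: 20 canonical amino acids.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity and rare translated symbols accepted alongside the canonical 20.
EXTENDED_AA = "BZXUO"
#: Full residue alphabet of the package.
ALPHABET = CANONICAL_AA + EXTENDED_AA

_ALPHABET_SET = frozenset(ALPHABET)

#: Width used when wrapping sequence lines on FASTA output.
FASTA_WRAP = 60


@dataclass(frozen=True)
class SequenceRecord:
    """One identified peptide sequence.

    Parameters
    ----------
    id:
        FASTA header token up to the first whitespace; unique within one
        parsed file.
    residues:
        Uppercase residue string over :data:`ALPHABET`; never empty.
    description:
        Optional free text following the id on the header line.
    """

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


def clean_residues(raw: str, *, record_id: str = "?") -> str:
    """Uppercase ``raw``, strip terminal stop-codon asterisks and map any
    symbol outside the residue alphabet to ``X`` (with a logged warning)."""
    seq = raw.upper().rstrip("*")
    if not set(seq) <= _ALPHABET_SET:
        bad = sorted(set(seq) - _ALPHABET_SET)
        logger.warning(
            "record %s: mapping non-alphabet characters %s to X", record_id, bad
        )
        seq = "".join(c if c in _ALPHABET_SET else "X" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into a list of :class:`SequenceRecord`.

    Records come back in file order; wrapped sequence lines are
    concatenated, terminal ``*`` stop symbols stripped, and non-alphabet
    characters mapped to ``X``.  Duplicate ids or a sequence line before any
    header raise ``ValueError``.
    """
    path = Path(path)
    _check_leading_garbage(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = clean_residues(str(rec.seq), record_id=rec.id)
        if not residues:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    return records


def _check_leading_garbage(path: Path) -> None:
    # Bio.SeqIO silently skips text before the first '>'; the contract here
    # is to fail loudly, naming the offending line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return
            raise ValueError(
                f"{path}: line {lineno}: sequence data before any FASTA header"
            )


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as multi-FASTA, wrapping sequence lines at 60 columns."""
    bio_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(bio_records)


def filter_by_length(
    records: Sequence[SequenceRecord], max_len: int
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition ``records`` into (kept, removed) at ``max_len`` residues.

    A record of exactly ``max_len`` residues is kept.  Order is preserved in
    both partitions.  This is the pre-classification size screen applied at
    200 residues in the published workflow, where removing long transcripts
    made no significant difference to annotation counts.
    """
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")
    kept = [r for r in records if len(r) <= max_len]
    removed = [r for r in records if len(r) > max_len]
    return kept, removed


def write_training_table(
    records: Sequence[SequenceRecord],
    labels: Sequence[str],
    path: str | Path,
) -> None:
    """Write the two-column training CSV (``class,sequence``).

    Column 1 is the class label; column 2 is the residue string with single
    spaces between symbols.  A header row ``class,sequence`` is always
    written.
    """
    if len(records) != len(labels):
        raise ValueError(
            f"{len(records)} records but {len(labels)} labels"
        )
    df = pd.DataFrame(
        {
            "class": list(labels),
            "sequence": [" ".join(r.residues) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_training_table(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a two-column training CSV back to (labels, residue strings).

    Accepts files with or without the ``class,sequence`` header row.
    """
    df = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns, found {df.shape[1]}")
    if list(df.iloc[0]) == ["class", "sequence"]:
        df = df.iloc[1:]
    labels = df.iloc[:, 0].tolist()
    residues = [s.replace(" ", "") for s in df.iloc[:, 1].tolist()]
    return labels, residues
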