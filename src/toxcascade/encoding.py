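"""Fixed-length integer tokenization of residue strings, plus IntDropout.

Each residue maps to an integer index; sequences are truncated (keeping the
N-terminal prefix) or padded to a fixed length so that a convolutional
classifier sees a constant-shape input.  Index 0 is the padding sentinel and
index 1 the out-of-vocabulary sentinel; real residues start at 2.  The
vocabulary is the fixed canonical 25-symbol alphabet rather than a
data-derived frequency ordering, so tokenization is reproducible across
datasets.

``IntDropout`` is a training-time regularizer that masks integer residue
tokens to the pad index *before* embedding, forcing the network not to rely
on any single residue position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq_io import ALPHABET

PAD_INDEX = 0
OOV_INDEX = 1

#: Fixed lengths at which classifier inputs are commonly evaluated.
SUPPORTED_LENGTHS = (16, 32, 64, 128, 256)


@dataclass(frozen=True)
class EncoderSpec:
    """Tokenization contract: fixed length and vocabulary.

    ``fixed_length`` defaults to 128 residues, the working point at which
    the truncation-length sweep plateaus.  ``vocabulary`` excludes the pad
    and OOV sentinels; residue ``vocabulary[i]`` maps to token ``i + 2``.
    """

    fixed_length: int = 128
    vocabulary: tuple[str, ...] = tuple(ALPHABET)
    pad_index: int = PAD_INDEX
    oov_index: int = OOV_INDEX

    def __post_init__(self) -> None:
        if self.fixed_length < 1:
            raise ValueError("fixed_length must be positive")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary symbols must be unique")

    @property
    def vocab_size(self) -> int:
        """Total token-table size including the two sentinels."""
        return len(self.vocabulary) + 2

    def token_of(self, residue: str) -> int:
        try:
            return self.vocabulary.index(residue) + 2
        except ValueError:
            return self.oov_index

    def to_dict(self) -> dict:
        return {
            "fixed_length": self.fixed_length,
            "vocabulary": "".join(self.vocabulary),
            "pad_index": self.pad_index,
            "oov_index": self.oov_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderSpec":
        return cls(
            fixed_length=int(d["fixed_length"]),
            vocabulary=tuple(d["vocabulary"]),
            pad_index=int(d["pad_index"]),
            oov_index=int(d["oov_index"]),
        )


def tokenize(residues: str, spec: EncoderSpec) -> np.ndarray:
    """Map a residue string to an integer vector of ``spec.fixed_length``.

    Position ``i`` holds the token of residue ``i`` for
    ``i < min(len(residues), fixed_length)``; the remainder is pad.  Longer
    sequences are truncated at the C-terminal end (the prefix carries the
    signal/propeptide and the start of the mature region).  Unknown symbols
    become the OOV token.
    """
    if not residues:
        raise ValueError("cannot tokenize an empty residue string")
    lut = _token_lut(spec)
    out = np.full(spec.fixed_length, spec.pad_index, dtype=np.int64)
    n = min(len(residues), spec.fixed_length)
    codes = np.frombuffer(residues[:n].encode("ascii"), dtype=np.uint8)
    out[:n] = lut[codes]
    return out


def tokenize_batch(residue_strings, spec: EncoderSpec) -> np.ndarray:
    """Tokenize many residue strings into a (n, fixed_length) int matrix."""
    return np.stack([tokenize(s, spec) for s in residue_strings])


_LUT_CACHE: dict[tuple, np.ndarray] = {}


def _token_lut(spec: EncoderSpec) -> np.ndarray:
    key = (spec.vocabulary, spec.pad_index, spec.oov_index)
    lut = _LUT_CACHE.get(key)
    if lut is None:
        lut = np.full(256, spec.oov_index, dtype=np.int64)
        for i, sym in enumerate(spec.vocabulary):
            lut[ord(sym)] = i + 2
        _LUT_CACHE[key] = lut
    return lut


def int_dropout(
    tokens: np.ndarray,
    rate: float,
    training: bool,
    rng: np.random.Generator,
    pad_index: int = PAD_INDEX,
) -> np.ndarray:
    """Randomly mask integer residue tokens to the pad index.

    At inference (``training=False``) or ``rate == 0`` the input is returned
    unchanged.  Otherwise each non-pad token is independently replaced by
    ``pad_index`` with probability ``rate``; pad positions are never
    touched.  The masked token shares the pad embedding, i.e. carries no
    information — a deliberate choice over a dedicated mask token.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"dropout rate must be in [0, 1], got {rate}")
    if not training or rate == 0.0:
        return tokens
    mask = (rng.random(tokens.shape) < rate) & (tokens != pad_index)
    out = tokens.copy()
    out[mask] = pad_index
    return out
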