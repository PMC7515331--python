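"""Sequence containers and FASTA ingestion.

Sequences are stored uppercase over {A, C, G, T}; any other character
(N, IUPAC ambiguity codes, gaps) is kept in the string but masked out of
l-mer enumeration, so no window spanning it is ever considered.

Coordinates are 0-based half-open internally; user-facing reports convert
to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

__all__ = ["SequenceDataset", "LMerOccurrence", "load_fasta"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MASK = 255  # sentinel code for non-ACGT positions
_BASES = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A,C,G,T -> 0..3, others -> 255)."""
    arr = np.full(len(seq), _MASK, dtype=np.uint8)
    for base, code in _CODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


@dataclass(frozen=True)
class LMerOccurrence:
    """An l-mer with its provenance: (sequence ordinal, 0-based offset)."""

    seq_index: int
    offset: int
    text: str

    @property
    def end(self) -> int:
        return self.offset + len(self.text)


class SequenceDataset:
    """Ordered DNA sequences with identifiers; the motif-search universe.

    Order matters: the first h = t - q + 1 sequences serve as reference
    sequences during candidate generation.
    """

    def __init__(self, sequences: list[str], ids: list[str] | None = None):
        if not sequences:
            raise ValueError("dataset must contain at least one sequence")
        if any(len(s) == 0 for s in sequences):
            raise ValueError("sequences must be non-empty")
        self.sequences = [s.upper() for s in sequences]
        self.ids = ids if ids is not None else [f"seq{i + 1}" for i in range(len(sequences))]
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence identifiers")
        self._codes = [encode(s) for s in self.sequences]

    @property
    def t(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def length_of(self, seq_index: int) -> int:
        return len(self.sequences[seq_index])

    def codes(self, seq_index: int) -> np.ndarray:
        return self._codes[seq_index]

    def windows(self, seq_index: int, l: int) -> tuple[np.ndarray, np.ndarray]:
        """All l-windows of one sequence as a (n-l+1, l) code matrix.

        Returns ``(matrix, valid)`` where ``valid[j]`` is False for windows
        containing masked (non-ACGT) positions.  A sequence shorter than l
        yields zero windows.
        """
        codes = self._codes[seq_index]
        if len(codes) < l:
            return np.empty((0, l), dtype=np.uint8), np.empty(0, dtype=bool)
        win = np.lib.stride_tricks.sliding_window_view(codes, l)
        valid = ~(win == _MASK).any(axis=1)
        return win, valid

    def lmer_at(self, seq_index: int, offset: int, l: int) -> LMerOccurrence:
        text = self.sequences[seq_index][offset : offset + l]
        if len(text) != l:
            raise ValueError(f"window [{offset}, {offset + l}) exceeds sequence {seq_index}")
        return LMerOccurrence(seq_index, offset, text)

    def iter_lmers(self, seq_index: int, l: int) -> Iterator[LMerOccurrence]:
        _, valid = self.windows(seq_index, l)
        seq = self.sequences[seq_index]
        for j in np.flatnonzero(valid):
            yield LMerOccurrence(seq_index, int(j), seq[j : j + l])


def load_fasta(path: str | Path) -> SequenceDataset:
    """Read a (possibly line-wrapped, mixed-case) multi-FASTA file.

    File order is preserved.  Raises on an empty file or duplicate record
    identifiers.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate record identifiers in {path}")
    return SequenceDataset([str(r.seq).upper() for r in records], ids)
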