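"""Protein sequences with UniProt-style (1-based, offset) residue numbering.

The package ships a synthetic stand-in sequence for the 112-residue
microtubule-binding domain (MTBD, residues 59-170) used throughout the
synthetic-data generators; see :func:`load_mtbd_sequence`.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterator

from Bio import SeqIO

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

MTBD_START = 59
MTBD_END = 170


class SequenceParseError(ValueError):
    """Raised when a sequence string contains a non-canonical character."""


@dataclass(frozen=True)
class Residue:
    number: int
    code: str  # one-letter amino-acid code


class ProteinSequence:
    """An ordered stretch of residues with strictly consecutive numbering."""

    def __init__(self, text: str, start_number: int):
        text = text.strip().upper()
        for i, ch in enumerate(text):
            if ch not in CANONICAL_AA:
                raise SequenceParseError(
                    f"non-canonical residue {ch!r} at position {i} "
                    f"(residue number {start_number + i})"
                )
        self._text = text
        self._start = start_number

    @property
    def start(self) -> int:
        return self._start

    @property
    def end(self) -> int:
        """Number of the last residue (inclusive); start - 1 when empty."""
        return self._start + len(self._text) - 1

    @property
    def one_letter(self) -> str:
        return self._text

    def __len__(self) -> int:
        return len(self._text)

    def __iter__(self) -> Iterator[Residue]:
        for i, ch in enumerate(self._text):
            yield Residue(self._start + i, ch)

    def __contains__(self, number: int) -> bool:
        return self._start <= number <= self.end

    def __getitem__(self, number: int) -> str:
        """One-letter code of residue *number* (UniProt numbering, not index)."""
        if number not in self:
            raise KeyError(f"residue {number} outside [{self._start}, {self.end}]")
        return self._text[number - self._start]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProteinSequence)
            and self._text == other._text
            and self._start == other._start
        )

    def write(self) -> str:
        return self._text


def parse_sequence(text: str, start_number: int) -> ProteinSequence:
    """Parse a one-letter sequence string; numbering begins at *start_number*."""
    return ProteinSequence(text, start_number)


def load_mtbd_sequence() -> ProteinSequence:
    """Packaged synthetic stand-in for MTBD residues 59-170 (length 112).

    The true construct sequence is not redistributed here; the stand-in
    preserves every residue identity referenced by the analyses (e.g. the
    82-AAREIVW-88 and 141-AVVRRT-146 stretches, the single Ile and Trp)
    and the exact construct numbering.
    """
    ref = importlib.resources.files("mtdyn.data") / "mtbd_synthetic.fasta"
    with importlib.resources.as_file(ref) as path:
        record = next(SeqIO.parse(str(path), "fasta"))
    return ProteinSequence(str(record.seq), MTBD_START)
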