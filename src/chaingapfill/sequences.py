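"""Soft-mask-aware sequence storage and strand-aware subsequence retrieval.

Repeat annotation is carried as letter case (soft-masking): lowercase bases
were marked repetitive by the masker.  The store preserves case on load so
that downstream code can both honor the masking (first-pass seeding) and
deliberately discard it (gap re-alignment, where masking is removed before
the sequences are handed to the aligner).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .chain_io import GenomicInterval, open_text

__all__ = ["SequenceStore", "load_sequences", "reverse_complement"]

_VALID_RE = re.compile(r"^[ACGTNacgtn]*$")

_COMPLEMENT = str.maketrans(
    "ACGTNacgtn",
    "TGCANtgcan",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case; N stays N."""
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceStore:
    """Named nucleotide sequences with case (soft-mask) preserved."""

    def __init__(self, sequences: Mapping[str, str]):
        for name, seq in sequences.items():
            _check_alphabet(name, seq)
        self._seqs = dict(sequences)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def names(self) -> list[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        return len(self._seq(name))

    def sequence(self, name: str) -> str:
        return self._seq(name)

    def _seq(self, name: str) -> str:
        try:
            return self._seqs[name]
        except KeyError:
            raise KeyError(f"unknown sequence {name!r}") from None

    def fetch(
        self,
        name: str,
        start: int,
        end: int,
        strand: str = "+",
        unmask: bool = False,
    ) -> str:
        """Return the subsequence [start, end) on the given strand.

        Minus-strand coordinates address the reverse-complemented sequence
        (chain convention): position 0 on '-' is the last plus-strand base.
        With ``unmask=True`` the result is uppercased (soft-masking removed);
        N is preserved either way.
        """
        seq = self._seq(name)
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"interval [{start}, {end}) out of bounds for {name!r} "
                f"(length {len(seq)})"
            )
        if strand == "+":
            sub = seq[start:end]
        elif strand == "-":
            size = len(seq)
            sub = reverse_complement(seq[size - end:size - start])
        else:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return sub.upper() if unmask else sub

    def fetch_interval(self, interval: GenomicInterval, unmask: bool = False) -> str:
        return self.fetch(
            interval.seq_name, interval.start, interval.end, interval.strand, unmask
        )


def _check_alphabet(name: str, seq: str) -> None:
    if len(seq) == 0:
        raise ValueError(f"sequence {name!r} is empty")
    if not _VALID_RE.match(seq):
        bad = sorted(set(re.sub(r"[ACGTNacgtn]", "", seq)))
        raise ValueError(
            f"sequence {name!r} contains non-nucleotide symbols {bad}"
        )


def load_sequences(source: str | Path | Iterable[str]) -> SequenceStore:
    """Load a (possibly gzipped) soft-masked FASTA into a SequenceStore."""
    if isinstance(source, (str, Path)):
        with open_text(source) as fh:
            return _from_handle(fh)
    return _from_handle(source)


def _from_handle(handle) -> SequenceStore:
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(handle, "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA header {record.id!r}")
        seqs[record.id] = str(record.seq)
    if not seqs:
        raise ValueError("FASTA source contains no records")
    return SequenceStore(seqs)
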