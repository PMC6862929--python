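"""Reading, writing and validating UCSC chain files.

A chain describes one co-linear pairwise alignment between a *target*
(reference) interval and a *query* interval as a header line ::

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id

followed by one line per ungapped aligned block, ``size [dt dq]``, where
``dt`` and ``dq`` count unaligned target/query bases between this block and
the next.  The final block line carries only ``size``.  Coordinates are
0-based half-open.  Query coordinates of a minus-strand chain are expressed
on the reverse-complemented query sequence; the target strand is always
``+`` by convention, and this module rejects anything else.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

__all__ = [
    "GenomicInterval",
    "AlignBlock",
    "Chain",
    "ChainFormatError",
    "ChainInvariantError",
    "parse_chain_file",
    "write_chain_file",
    "open_text",
]


class ChainFormatError(ValueError):
    """Malformed chain text; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ChainInvariantError(ValueError):
    """A Chain object violates a structural invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a named sequence.

    Minus-strand coordinates follow the chain convention: they address the
    reverse-complemented sequence, so the plus-strand equivalent of
    ``[start, end)`` on ``-`` is ``[size - end, size - start)``.
    """

    seq_name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_name}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignBlock:
    """One ungapped aligned block; dt/dq are the gap to the next block."""

    size: int
    dt: int = 0
    dq: int = 0

    def __post_init__(self):
        if self.size < 1:
            raise ValueError(f"block size must be >= 1, got {self.size}")
        if self.dt < 0 or self.dq < 0:
            raise ValueError("block gaps dt/dq must be non-negative")


@dataclass
class Chain:
    """A scored co-linear chain of ungapped blocks (one UCSC chain record)."""

    score: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: list[AlignBlock] = field(default_factory=list)

    @property
    def t_interval(self) -> GenomicInterval:
        return GenomicInterval(self.t_name, self.t_start, self.t_end, "+")

    @property
    def q_interval(self) -> GenomicInterval:
        return GenomicInterval(self.q_name, self.q_start, self.q_end, self.q_strand)

    @property
    def aligned_bases(self) -> int:
        return sum(b.size for b in self.blocks)

    def block_coords(self) -> Iterator[tuple[int, int, int]]:
        """Yield (t_start, q_start, size) of each block in chain coordinates.

        Query starts are on the chain's query strand (i.e. directly
        comparable with ``q_start``/``q_end`` of the header).
        """
        t, q = self.t_start, self.q_start
        for b in self.blocks:
            yield t, q, b.size
            t += b.size + b.dt
            q += b.size + b.dq

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield every aligned (t_pos, q_pos) base pair, query-strand coords."""
        for t, q, size in self.block_coords():
            for k in range(size):
                yield t + k, q + k

    def validate(self) -> None:
        """Raise ChainInvariantError unless all structural invariants hold."""
        if self.q_strand not in ("+", "-"):
            raise ChainInvariantError(
                f"chain {self.chain_id}: bad query strand {self.q_strand!r}"
            )
        if not self.blocks:
            raise ChainInvariantError(f"chain {self.chain_id}: no blocks")
        if not (0 <= self.t_start <= self.t_end <= self.t_size):
            raise ChainInvariantError(
                f"chain {self.chain_id}: target span out of bounds"
            )
        if not (0 <= self.q_start <= self.q_end <= self.q_size):
            raise ChainInvariantError(
                f"chain {self.chain_id}: query span out of bounds"
            )
        last = self.blocks[-1]
        if last.dt != 0 or last.dq != 0:
            raise ChainInvariantError(
                f"chain {self.chain_id}: last block must have dt = dq = 0"
            )
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start:
            raise ChainInvariantError(
                f"chain {self.chain_id}: target span {self.t_end - self.t_start} "
                f"!= blocks+gaps {t_span}"
            )
        if q_span != self.q_end - self.q_start:
            raise ChainInvariantError(
                f"chain {self.chain_id}: query span {self.q_end - self.q_start} "
                f"!= blocks+gaps {q_span}"
            )
        # strict co-linearity follows from size >= 1 and dt/dq >= 0, which the
        # AlignBlock constructor enforces; re-check defensively for mutated lists
        for b in self.blocks:
            if b.size < 1 or b.dt < 0 or b.dq < 0:
                raise ChainInvariantError(
                    f"chain {self.chain_id}: invalid block {b}"
                )


def open_text(path: str | Path, mode: str = "rt") -> TextIO:
    """Open plain or gzip-compressed text, judged by the .gz suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _as_lines(source) -> tuple[Iterable[str], TextIO | None]:
    if isinstance(source, (str, Path)):
        handle = open_text(source)
        return handle, handle
    return source, None


def parse_chain_file(source) -> list[Chain]:
    """Parse chain records from a path, open text handle, or iterable of lines.

    Returns chains in file order; every returned chain passes
    :meth:`Chain.validate`.  Raises :class:`ChainFormatError` with the
    offending line number on malformed input.
    """
    lines, handle = _as_lines(source)
    chains: list[Chain] = []
    current: Chain | None = None
    header_line = 0
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                if current is not None:
                    _finish(current, header_line)
                    chains.append(current)
                    current = None
                continue
            if line.startswith("chain"):
                if current is not None:
                    _finish(current, header_line)
                    chains.append(current)
                current = _parse_header(line, lineno)
                header_line = lineno
                continue
            if current is None:
                raise ChainFormatError("block line outside a chain record", lineno)
            current.blocks.append(_parse_block(line, lineno))
        if current is not None:
            _finish(current, header_line)
            chains.append(current)
    finally:
        if handle is not None:
            handle.close()
    return chains


def _parse_header(line: str, lineno: int) -> Chain:
    tokens = line.split()
    if len(tokens) != 13:
        raise ChainFormatError(
            f"chain header has {len(tokens)} fields, expected 13", lineno
        )
    try:
        score = int(tokens[1])
        t_size, t_start, t_end = int(tokens[3]), int(tokens[5]), int(tokens[6])
        q_size, q_start, q_end = int(tokens[8]), int(tokens[10]), int(tokens[11])
    except ValueError as exc:
        raise ChainFormatError(f"non-integer header field: {exc}", lineno) from None
    t_strand, q_strand = tokens[4], tokens[9]
    if t_strand != "+":
        raise ChainFormatError(
            f"target strand must be '+', got {t_strand!r}", lineno
        )
    if q_strand not in ("+", "-"):
        raise ChainFormatError(f"bad query strand {q_strand!r}", lineno)
    return Chain(
        score=score,
        t_name=tokens[2], t_size=t_size, t_start=t_start, t_end=t_end,
        q_name=tokens[7], q_size=q_size, q_strand=q_strand,
        q_start=q_start, q_end=q_end,
        chain_id=tokens[12],
    )


def _parse_block(line: str, lineno: int) -> AlignBlock:
    tokens = line.split()
    if len(tokens) not in (1, 3):
        raise ChainFormatError(
            f"block line has {len(tokens)} fields, expected 1 or 3", lineno
        )
    try:
        values = [int(t) for t in tokens]
    except ValueError:
        raise ChainFormatError(f"non-integer block field in {line!r}", lineno) from None
    try:
        if len(values) == 1:
            return AlignBlock(values[0])
        return AlignBlock(*values)
    except ValueError as exc:
        raise ChainFormatError(str(exc), lineno) from None


def _finish(chain: Chain, header_line: int) -> None:
    try:
        chain.validate()
    except ChainInvariantError as exc:
        raise ChainFormatError(str(exc), header_line) from None


def write_chain_file(chains: Iterable[Chain], dest: str | Path | TextIO | None = None) -> str:
    """Serialize chains to chain-format text; optionally write to *dest*.

    Chains are emitted in input order, each validated first; the final block
    line carries only its size, and records are blank-line separated.
    """
    parts: list[str] = []
    for chain in chains:
        chain.validate()
        header = (
            f"chain {chain.score} {chain.t_name} {chain.t_size} + "
            f"{chain.t_start} {chain.t_end} {chain.q_name} {chain.q_size} "
            f"{chain.q_strand} {chain.q_start} {chain.q_end} {chain.chain_id}"
        )
        parts.append(header)
        for b in chain.blocks[:-1]:
            parts.append(f"{b.size} {b.dt} {b.dq}")
        parts.append(f"{chain.blocks[-1].size}")
        parts.append("")
    text = "\n".join(parts)
    if parts:
        text += "\n"
    if dest is not None:
        if isinstance(dest, (str, Path)):
            with open_text(dest, "wt") as fh:
                fh.write(text)
        else:
            dest.write(text)
    return text
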