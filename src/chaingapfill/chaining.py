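"""Combine local alignments into the best co-linear chain under gap costs.

Fragment chaining follows the classic axtChain recipe: fragments are
ordered by start coordinate and dynamic programming picks, for each
fragment, the predecessor that maximizes cumulative score minus the cost
of the connecting gap.  Gap costs come from a piecewise-linear schedule
(the "loose" table by default) with separate columns for one-sided gaps
and gaps on both genomes.  All arithmetic is exact integer arithmetic.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .aligner import LocalAlignment, Segment
from .chain_io import Chain
from .scoring import ScoringScheme, encode
from .sequences import SequenceStore

__all__ = ["GapCostTable", "default_gap_costs", "MiniChain", "chain_fragments", "score_chain"]


@dataclass(frozen=True)
class GapCostTable:
    """Piecewise-linear gap cost schedule.

    ``single`` costs apply when only one genome has unaligned bases (dt or
    dq), evaluated at that size; ``both`` costs apply when both do,
    evaluated at dt+dq.  Costs are linearly interpolated between the
    tabulated sizes and extrapolated with the final slope beyond them.
    """

    sizes: tuple[int, ...]
    single: tuple[int, ...]
    both: tuple[int, ...]
    name: str = ""

    def __post_init__(self):
        if not (len(self.sizes) == len(self.single) == len(self.both) >= 2):
            raise ValueError("gap cost table needs >= 2 rows of equal length")
        if self.sizes[0] != 0 or self.single[0] != 0 or self.both[0] != 0:
            raise ValueError("gap cost table must start at size 0 with cost 0")
        if any(b >= a for a, b in zip(self.sizes[1:], self.sizes)):
            raise ValueError("gap sizes must be strictly increasing")
        for costs in (self.single, self.both):
            if any(b > a for a, b in zip(costs[1:], costs)):
                raise ValueError("gap costs must be non-decreasing")

    def _interp(self, costs: tuple[int, ...], x: int) -> int:
        sizes = self.sizes
        if x >= sizes[-1]:
            s0, s1 = sizes[-2], sizes[-1]
            c0, c1 = costs[-2], costs[-1]
            return c1 + (c1 - c0) * (x - s1) // (s1 - s0)
        i = bisect_right(sizes, x)
        s0, s1 = sizes[i - 1], sizes[i]
        c0, c1 = costs[i - 1], costs[i]
        return c0 + (c1 - c0) * (x - s0) // (s1 - s0)

    def cost(self, dt: int, dq: int) -> int:
        """Cost of connecting across dt unaligned target / dq query bases."""
        if dt < 0 or dq < 0:
            raise ValueError(f"negative gap size (dt={dt}, dq={dq})")
        if dt == 0 and dq == 0:
            return 0
        if dt > 0 and dq > 0:
            return self._interp(self.both, dt + dq)
        return self._interp(self.single, dt + dq)

    @classmethod
    def from_file(cls, path: str | Path) -> "GapCostTable":
        return cls._from_text(Path(path).read_text(), name=str(path))

    @classmethod
    def _from_text(cls, text: str, name: str = "") -> "GapCostTable":
        sizes: list[int] = []
        single: list[int] = []
        both: list[int] = []
        for line in text.splitlines():
            if line.startswith("# schedule:"):
                name = line.split(":", 1)[1].strip()
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 3:
                raise ValueError(f"gap cost row needs 3 columns: {line!r}")
            sizes.append(int(tokens[0]))
            single.append(int(tokens[1]))
            both.append(int(tokens[2]))
        return cls(tuple(sizes), tuple(single), tuple(both), name=name)


def default_gap_costs() -> GapCostTable:
    """The packaged 'loose' schedule used for cross-species chaining."""
    ref = resources.files("chaingapfill.data") / "linear_gap_loose.tsv"
    return GapCostTable._from_text(ref.read_text())


@dataclass(frozen=True)
class MiniChain:
    """Best co-linear chain of local alignments from one gap region."""

    members: tuple[LocalAlignment, ...]
    score: int

    @property
    def t_start(self) -> int:
        return self.members[0].t_start

    @property
    def t_end(self) -> int:
        return self.members[-1].t_end

    @property
    def q_start(self) -> int:
        return self.members[0].q_start

    @property
    def q_end(self) -> int:
        return self.members[-1].q_end

    def all_segments(self) -> list[Segment]:
        return [s for a in self.members for s in a.segments]

    @property
    def aligned_columns(self) -> int:
        return sum(a.aligned_columns for a in self.members)


def _trim_leading(
    aln: LocalAlignment,
    min_t: int,
    min_q: int,
    scorer,
) -> LocalAlignment | None:
    """Drop leading aligned columns until both starts reach the minima.

    ``scorer(segment, n)`` returns the score contribution of the first n
    columns of a segment; the trimmed alignment's score is reduced by the
    removed contribution.  Returns None if nothing remains.
    """
    if aln.t_start >= min_t and aln.q_start >= min_q:
        return aln
    segments = list(aln.segments)
    score = aln.score
    out: list[Segment] = []
    for i, seg in enumerate(segments):
        cut = max(min_t - seg.t_start, min_q - seg.q_start, 0)
        if cut <= 0:
            out.extend(segments[i:])
            break
        if cut >= seg.length:
            score -= scorer(seg, seg.length)
            continue
        score -= scorer(seg, cut)
        out.append(Segment(seg.t_start + cut, seg.q_start + cut, seg.length - cut))
        out.extend(segments[i + 1:])
        break
    if not out:
        return None
    return LocalAlignment(tuple(out), score)


def _scorer_factory(ref, query, scheme):
    """Build a per-fragment trim scorer: exact when sequences are given,
    proportional to the trimmed column count otherwise."""
    if ref is not None and query is not None and scheme is not None:
        ct, cq = encode(ref), encode(query)
        mat = scheme.matrix

        def for_alignment(aln: LocalAlignment):
            def scorer(seg: Segment, n: int) -> int:
                return int(
                    mat[ct[seg.t_start:seg.t_start + n],
                        cq[seg.q_start:seg.q_start + n]].sum()
                )
            return scorer
        return for_alignment

    def for_alignment(aln: LocalAlignment):
        total = aln.aligned_columns

        def scorer(seg: Segment, n: int) -> int:
            return round(aln.score * n / total)
        return scorer
    return for_alignment


def chain_fragments(
    alignments: list[LocalAlignment],
    table: GapCostTable,
    *,
    ref: str | None = None,
    query: str | None = None,
    scheme: ScoringScheme | None = None,
    max_lookback: int | None = None,
) -> MiniChain | None:
    """Best-scoring co-linear chain of fragments under the gap cost table.

    Fragments are sorted by start; for each, the best predecessor maximizes
    cumulative score minus the connection's gap cost.  A successor that
    overlaps its predecessor on either genome is trimmed from its start,
    with its score reduced by the trimmed columns' contribution (computed
    from sequence when ref/query/scheme are supplied, else proportionally).
    Returns the single best chain, or None for an empty input.
    ``max_lookback`` bounds the predecessor search window (genome-scale use).
    """
    if not alignments:
        return None
    frags = sorted(
        alignments,
        key=lambda a: (a.t_start, a.q_start, -a.score,
                       tuple((s.t_start, s.q_start, s.length) for s in a.segments)),
    )
    n = len(frags)
    scorer_for = _scorer_factory(ref, query, scheme)
    value = [f.score for f in frags]
    back: list[int | None] = [None] * n
    chosen: list[LocalAlignment] = list(frags)
    for i in range(1, n):
        fi = frags[i]
        scorer = scorer_for(fi)
        j_lo = 0 if max_lookback is None else max(0, i - max_lookback)
        for j in range(i - 1, j_lo - 1, -1):
            pred = chosen[j]
            if pred.t_start >= fi.t_start or pred.q_start >= fi.q_start:
                continue
            trimmed = _trim_leading(fi, pred.t_end, pred.q_end, scorer)
            if trimmed is None:
                continue
            dt = trimmed.t_start - pred.t_end
            dq = trimmed.q_start - pred.q_end
            cand = value[j] + trimmed.score - table.cost(dt, dq)
            if cand > value[i]:
                value[i] = cand
                back[i] = j
                chosen[i] = trimmed
    best = max(range(n), key=lambda i: (value[i], -i))
    members: list[LocalAlignment] = []
    at: int | None = best
    while at is not None:
        members.append(chosen[at])
        at = back[at]
    members.reverse()
    return MiniChain(tuple(members), int(value[best]))


def score_chain(
    chain: Chain,
    t_store: SequenceStore,
    q_store: SequenceStore,
    scheme: ScoringScheme,
    table: GapCostTable,
) -> int:
    """Score a chain from sequence: matrix sum over aligned columns minus
    gap costs over interior gaps; masking is ignored (uppercased)."""
    t_seq = t_store.fetch_interval(chain.t_interval, unmask=True)
    q_seq = q_store.fetch_interval(chain.q_interval, unmask=True)
    ct, cq = encode(t_seq), encode(q_seq)
    mat = scheme.matrix
    total = 0
    t_off = q_off = 0
    for i, block in enumerate(chain.blocks):
        total += int(
            mat[ct[t_off:t_off + block.size], cq[q_off:q_off + block.size]].sum()
        )
        if i < len(chain.blocks) - 1:
            total -= table.cost(block.dt, block.dq)
        t_off += block.size + block.dt
        q_off += block.size + block.dq
    return total
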