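"""Fill repeat-induced gaps in alignment chains by local re-alignment.

The method: take every sufficiently high-scoring chain, walk its interior
gaps, and for each gap whose unaligned span on *both* genomes is within
configured bounds, re-align the two gap sequences with soft-masking
removed and a more sensitive ungapped threshold.  The local alignments
found in a gap are combined into a mini chain; if the mini chain scores
high enough its blocks are spliced into the parent chain at the gap, and
the chain's score is recomputed from sequence.  Gaps are only ever
subdivided — original aligned blocks are never moved or removed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

from .aligner import align_region
from .chain_io import (
    AlignBlock,
    Chain,
    GenomicInterval,
    open_text,
    parse_chain_file,
)
from .chaining import (
    GapCostTable,
    MiniChain,
    chain_fragments,
    default_gap_costs,
    score_chain,
)
from .scoring import ScoringScheme, default_scoring
from .sequences import SequenceStore, load_sequences

__all__ = [
    "FillConfig",
    "GapContext",
    "ChainFillStats",
    "FillReport",
    "enumerate_gaps",
    "fill_gap",
    "insert_mini_chain",
    "fill_all",
    "summarize_overlap",
]


@dataclass
class FillConfig:
    """Parameters of the gap-filling pass.

    Defaults are the method's standard settings: gaps of 30–20,000 bp on
    both genomes, chains scoring strictly more than 25,000, mini chains
    kept from a score of 5,000, and re-alignment with ungapped threshold
    K = 2,000 (gapped threshold L = 3,000, Y-drop 9,400).
    """

    min_gap: int = 30
    max_gap: int = 20_000
    min_chain_score: int = 25_000
    min_mini_score: int = 5_000
    scheme: ScoringScheme | None = None
    table: GapCostTable | None = None
    seed_k: int = 12
    seed_cap: int = 50_000
    rng_seed: int = 0

    def __post_init__(self):
        if self.min_gap < 1 or self.min_gap > self.max_gap:
            raise ValueError("need 1 <= min_gap <= max_gap")
        if self.scheme is None:
            self.scheme = default_scoring(hsp_threshold=2000)
        if self.table is None:
            self.table = default_gap_costs()


@dataclass(frozen=True)
class GapContext:
    """One fillable unaligned region, bounded by aligned blocks."""

    chain_id: str
    block_index: int  # index of the block preceding the gap
    t_gap: GenomicInterval
    q_gap: GenomicInterval


@dataclass
class ChainFillStats:
    chain_id: str
    gaps_examined: int = 0
    gaps_filled: int = 0
    minis_rejected: int = 0
    bases_added: int = 0
    score_before: int = 0
    score_after: int = 0


@dataclass
class FillReport:
    """Per-chain and total accounting of a filling run."""

    rows: list[ChainFillStats] = field(default_factory=list)
    new_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    overlap_breakdown: dict[str, int] | None = None

    @property
    def gaps_examined(self) -> int:
        return sum(r.gaps_examined for r in self.rows)

    @property
    def gaps_filled(self) -> int:
        return sum(r.gaps_filled for r in self.rows)

    @property
    def minis_rejected(self) -> int:
        return sum(r.minis_rejected for r in self.rows)

    @property
    def bases_added(self) -> int:
        return sum(r.bases_added for r in self.rows)

    def to_tsv(self) -> str:
        header = (
            "chain_id\tgaps_examined\tgaps_filled\tminis_rejected\t"
            "bases_added\tscore_before\tscore_after"
        )
        lines = [header]
        for r in self.rows:
            lines.append(
                f"{r.chain_id}\t{r.gaps_examined}\t{r.gaps_filled}\t"
                f"{r.minis_rejected}\t{r.bases_added}\t"
                f"{r.score_before}\t{r.score_after}"
            )
        lines.append(
            f"total\t{self.gaps_examined}\t{self.gaps_filled}\t"
            f"{self.minis_rejected}\t{self.bases_added}\t.\t."
        )
        if self.overlap_breakdown is not None:
            lines.append("")
            lines.append("repeat_class\tnew_bases")
            for cls, count in sorted(self.overlap_breakdown.items()):
                lines.append(f"{cls}\t{count}")
        return "\n".join(lines) + "\n"


def enumerate_gaps(chain: Chain, config: FillConfig) -> list[GapContext]:
    """Interior gaps with both dt and dq in [min_gap, max_gap].

    Chains whose score is not strictly above ``min_chain_score`` yield no
    gaps.  Gaps are never chain-terminal: each is bounded by an aligned
    block on both sides by construction.
    """
    if chain.score <= config.min_chain_score:
        return []
    gaps: list[GapContext] = []
    for index, (t, q, size) in enumerate(chain.block_coords()):
        block = chain.blocks[index]
        if index == len(chain.blocks) - 1:
            break
        if (config.min_gap <= block.dt <= config.max_gap
                and config.min_gap <= block.dq <= config.max_gap):
            gaps.append(GapContext(
                chain_id=chain.chain_id,
                block_index=index,
                t_gap=GenomicInterval(
                    chain.t_name, t + size, t + size + block.dt, "+"
                ),
                q_gap=GenomicInterval(
                    chain.q_name, q + size, q + size + block.dq, chain.q_strand
                ),
            ))
    return gaps


def _gap_salt(gap: GapContext, rng_seed: int) -> int:
    key = f"{gap.chain_id}:{gap.block_index}:{rng_seed}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _fill_gap(
    gap: GapContext,
    t_store: SequenceStore,
    q_store: SequenceStore,
    config: FillConfig,
) -> tuple[MiniChain | None, bool]:
    """Returns (mini chain or None, rejected-by-score flag)."""
    t_frag = t_store.fetch_interval(gap.t_gap, unmask=True)
    q_frag = q_store.fetch_interval(gap.q_gap, unmask=True)
    alignments = align_region(
        t_frag, q_frag, config.scheme,
        k=config.seed_k,
        seed_cap=config.seed_cap,
        cap_seed=_gap_salt(gap, config.rng_seed),
    )
    mini = chain_fragments(
        alignments, config.table,
        ref=t_frag, query=q_frag, scheme=config.scheme,
    )
    if mini is None:
        return None, False
    if mini.score < config.min_mini_score:
        return None, True
    return mini, False


def fill_gap(
    gap: GapContext,
    t_store: SequenceStore,
    q_store: SequenceStore,
    config: FillConfig,
) -> MiniChain | None:
    """Re-align one gap (unmasked, chain orientation) and return its mini
    chain if it scores at least ``min_mini_score``, else None."""
    mini, _ = _fill_gap(gap, t_store, q_store, config)
    return mini


def _apply_fills(
    chain: Chain,
    fills: dict[int, tuple[GapContext, MiniChain]],
) -> Chain:
    """Splice mini chains into the parent chain at their gaps."""
    new_blocks: list[AlignBlock] = []
    for index, block in enumerate(chain.blocks):
        if index not in fills:
            new_blocks.append(block)
            continue
        gap, mini = fills[index]
        segs = mini.all_segments()
        t_len, q_len = gap.t_gap.length, gap.q_gap.length
        for seg in segs:
            if not (0 <= seg.t_start and seg.t_end <= t_len
                    and 0 <= seg.q_start and seg.q_end <= q_len):
                raise AssertionError(
                    f"inserted block escapes its gap (chain {chain.chain_id}, "
                    f"block {index}): {seg} vs gap {t_len}x{q_len}"
                )
        new_blocks.append(AlignBlock(block.size, segs[0].t_start, segs[0].q_start))
        for cur, nxt in zip(segs, segs[1:]):
            new_blocks.append(AlignBlock(
                cur.length, nxt.t_start - cur.t_end, nxt.q_start - cur.q_end
            ))
        last = segs[-1]
        new_blocks.append(AlignBlock(
            last.length, t_len - last.t_end, q_len - last.q_end
        ))
    # merge adjacent blocks separated by zero gap on both genomes
    merged: list[AlignBlock] = []
    for block in new_blocks:
        if merged and merged[-1].dt == 0 and merged[-1].dq == 0:
            prev = merged.pop()
            merged.append(AlignBlock(prev.size + block.size, block.dt, block.dq))
        else:
            merged.append(block)
    out = Chain(
        score=chain.score,
        t_name=chain.t_name, t_size=chain.t_size,
        t_start=chain.t_start, t_end=chain.t_end,
        q_name=chain.q_name, q_size=chain.q_size, q_strand=chain.q_strand,
        q_start=chain.q_start, q_end=chain.q_end,
        chain_id=chain.chain_id,
        blocks=merged,
    )
    out.validate()
    return out


def insert_mini_chain(chain: Chain, gap: GapContext, mini: MiniChain) -> Chain:
    """Splice one mini chain (gap-fragment offsets) into the parent chain.

    Flanking and new blocks get recomputed dt/dq; blocks left with zero
    gap on both genomes are merged.  The result passes the full validator.
    """
    return _apply_fills(chain, {gap.block_index: (gap, mini)})


def fill_all(
    chains,
    target,
    query,
    config: FillConfig | None = None,
) -> tuple[list[Chain], FillReport]:
    """Run the filling pass over a whole chain file.

    ``chains`` may be a path or a list of Chain objects; ``target`` and
    ``query`` may be FASTA paths or SequenceStore objects.  Chains are
    processed and emitted in input order; chains that receive insertions
    get their score recomputed from sequence, untouched chains are
    returned unchanged.  Deterministic for a fixed config.
    """
    if config is None:
        config = FillConfig()
    if not isinstance(chains, list):
        chains = parse_chain_file(chains)
    t_store = target if isinstance(target, SequenceStore) else load_sequences(target)
    q_store = query if isinstance(query, SequenceStore) else load_sequences(query)

    for chain in chains:
        for store, name, end, side in (
            (t_store, chain.t_name, chain.t_end, "target"),
            (q_store, chain.q_name, chain.q_end, "query"),
        ):
            if name not in store:
                raise KeyError(
                    f"chain {chain.chain_id}: {side} sequence {name!r} "
                    f"not found in the supplied FASTA"
                )
            if end > store.length(name):
                raise ValueError(
                    f"chain {chain.chain_id}: {side} span ends at {end} but "
                    f"{name!r} is only {store.length(name)} bp"
                )

    out_chains: list[Chain] = []
    report = FillReport()
    for chain in chains:
        stats = ChainFillStats(
            chain_id=chain.chain_id,
            score_before=chain.score,
            score_after=chain.score,
        )
        fills: dict[int, tuple[GapContext, MiniChain]] = {}
        for gap in enumerate_gaps(chain, config):
            stats.gaps_examined += 1
            mini, rejected = _fill_gap(gap, t_store, q_store, config)
            if rejected:
                stats.minis_rejected += 1
            if mini is None:
                continue
            fills[gap.block_index] = (gap, mini)
            stats.gaps_filled += 1
            stats.bases_added += mini.aligned_columns
            for seg in mini.all_segments():
                report.new_intervals.append((
                    chain.t_name,
                    gap.t_gap.start + seg.t_start,
                    gap.t_gap.start + seg.t_end,
                ))
        if fills:
            chain = _apply_fills(chain, fills)
            chain.score = score_chain(
                chain, t_store, q_store, config.scheme, config.table
            )
            stats.score_after = chain.score
        out_chains.append(chain)
        report.rows.append(stats)
    return out_chains, report


def _parse_bed(source) -> dict[str, list[tuple[int, int, str]]]:
    if isinstance(source, (str, Path)):
        with open_text(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        tokens = line.split("\t") if "\t" in line else line.split()
        if len(tokens) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        try:
            start, end = int(tokens[1]), int(tokens[2])
        except ValueError:
            raise ValueError(f"BED line {lineno}: non-integer coordinates") from None
        if start < 0 or end < start:
            raise ValueError(f"BED line {lineno}: invalid interval [{start}, {end})")
        label = tokens[3] if len(tokens) > 3 else "repeat"
        by_chrom.setdefault(tokens[0], []).append((start, end, label))
    for ivs in by_chrom.values():
        ivs.sort()
    return by_chrom


NON_REPETITIVE = "non-repetitive"


def summarize_overlap(
    new_intervals: list[tuple[str, int, int]],
    bed_source,
) -> dict[str, int]:
    """Classify newly aligned reference bases by repeat annotation.

    Every base of ``new_intervals`` is assigned to exactly one category:
    the class label of a covering BED interval (ties broken by the first
    covering interval in sorted order) or ``non-repetitive``.  Counts sum
    to the total number of new bases.
    """
    bed = _parse_bed(bed_source)
    counts: dict[str, int] = {}
    for chrom, start, end in new_intervals:
        labels = [NON_REPETITIVE] * (end - start)
        # later-sorted intervals first, so the first-sorted one wins
        for b_start, b_end, label in reversed(bed.get(chrom, [])):
            lo, hi = max(start, b_start), min(end, b_end)
            for pos in range(lo, hi):
                labels[pos - start] = label
        for label in labels:
            counts[label] = counts.get(label, 0) + 1
    return counts
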