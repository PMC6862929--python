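"""Synthetic genome pairs with planted repeats and a first-pass chain.

The generator emulates the situation the gap filler addresses: an
ancestral sequence carries copies of a few repeat families; two
descendants diverge by substitutions and small indels; the repeat copies
are soft-masked (lowercase); and a first-pass alignment computed with
*masked* seeding cannot start alignments inside repeats, so the resulting
chain has gaps precisely over the orthologous repeat copies.  A ground
truth map of orthologous base pairs makes recall and precision of the
filler well-defined.

All randomness flows through one generator seeded once per dataset, so a
fixed seed reproduces every file byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .aligner import LocalAlignment, Segment, find_hsps
from .chain_io import Chain, write_chain_file
from .chaining import GapCostTable, chain_fragments, default_gap_costs
from .filler import FillConfig, enumerate_gaps
from .scoring import ScoringScheme, default_scoring
from .sequences import SequenceStore

__all__ = [
    "RepeatFamily",
    "SimConfig",
    "TruthMap",
    "generate_ancestor",
    "evolve",
    "first_pass_chain",
    "generate_dataset",
    "SimDataset",
    "evaluate_fill",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}


@dataclass(frozen=True)
class RepeatFamily:
    """One planted repeat family: consensus length, copy count, and the
    per-copy substitution divergence from the consensus."""

    length: int
    copies: int
    divergence: float

    def __post_init__(self):
        if self.length <= 0 or self.copies < 0:
            raise ValueError("repeat family length/copies must be positive")
        if not (0 <= self.divergence < 1):
            raise ValueError("divergence must be in [0, 1)")


@dataclass
class SimConfig:
    """Study conditions of the default simulation.

    1 Mb ancestor; three repeat families spanning 300–1,500 bp consensi;
    substitutions at 0.05/site per lineage (about 10% pairwise divergence)
    and indels at 0.005/site per lineage with geometric mean length 3.
    """

    ancestor_length: int = 1_000_000
    repeat_families: tuple[RepeatFamily, ...] = (
        RepeatFamily(300, 20, 0.03),
        RepeatFamily(800, 14, 0.03),
        RepeatFamily(1500, 8, 0.03),
    )
    substitution_rate: float = 0.05
    indel_rate: float = 0.005
    indel_length_mean: float = 3.0
    rng_seed: int = 0
    t_name: str = "target1"
    q_name: str = "query1"

    def __post_init__(self):
        self.repeat_families = tuple(
            f if isinstance(f, RepeatFamily) else RepeatFamily(*f)
            for f in self.repeat_families
        )
        if self.ancestor_length <= 0:
            raise ValueError("ancestor_length must be positive")
        for rate in (self.substitution_rate, self.indel_rate):
            if not (0 <= rate < 1):
                raise ValueError("rates must be in [0, 1)")
        if self.indel_length_mean < 1:
            raise ValueError("indel_length_mean must be >= 1")


def _decode(codes: np.ndarray, lower: np.ndarray) -> str:
    chars = _BASE_BYTES[codes].copy()
    chars[lower] += 32
    return chars.tobytes().decode("ascii")


def _encode_acgt(seq: str) -> tuple[np.ndarray, np.ndarray]:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lower = (raw >= 97) & (raw <= 122)
    upper = np.where(lower, raw - 32, raw)
    codes = np.zeros(len(raw), dtype=np.uint8)
    for byte, code in _CODE.items():
        codes[upper == byte] = code
    return codes, lower


def generate_ancestor(
    config: SimConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int, str]]]:
    """Uniform background with planted, soft-masked repeat copies.

    Returns the ancestral sequence (copies lowercase) and the sorted list
    of (start, end, family_name) annotation intervals.
    """
    n = config.ancestor_length
    codes = rng.integers(0, 4, n).astype(np.uint8)
    lower = np.zeros(n, dtype=bool)
    placed: list[tuple[int, int, str]] = []
    occupied = np.zeros(n, dtype=bool)
    for fam_idx, family in enumerate(config.repeat_families, start=1):
        name = f"fam{fam_idx}"
        consensus = rng.integers(0, 4, family.length).astype(np.uint8)
        for _ in range(family.copies):
            pos = _place_copy(rng, occupied, n, family.length)
            copy = consensus.copy()
            if family.divergence > 0:
                mut = rng.random(family.length) < family.divergence
                shift = rng.integers(1, 4, int(mut.sum())).astype(np.uint8)
                copy[mut] = (copy[mut] + shift) % 4
            codes[pos:pos + family.length] = copy
            lower[pos:pos + family.length] = True
            occupied[pos:pos + family.length] = True
            placed.append((pos, pos + family.length, name))
    placed.sort()
    return _decode(codes, lower), placed


def _place_copy(rng, occupied, n, length, max_tries=1000) -> int:
    if length > n:
        raise RuntimeError("repeat copy longer than the ancestor")
    for _ in range(max_tries):
        pos = int(rng.integers(0, n - length + 1))
        if not occupied[pos:pos + length].any():
            return pos
    raise RuntimeError(
        f"could not place a {length} bp repeat copy without overlap "
        f"after {max_tries} tries"
    )


def evolve(
    sequence: str, config: SimConfig, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Derive a descendant by substitutions and indels.

    Substitutions (uniform among the three alternatives) preserve case;
    indels have geometric lengths, insertions copy the local case, and
    deletions never cross a case boundary (so planted repeats are never
    structurally disrupted).  Returns the derived sequence and a
    coordinate map: for each ancestral position, its position in the
    derived sequence, or -1 if deleted.
    """
    codes, lower = _encode_acgt(sequence)
    n = len(codes)
    # substitutions
    sub = rng.random(n) < config.substitution_rate
    shift = rng.integers(1, 4, int(sub.sum())).astype(np.uint8)
    codes = codes.copy()
    codes[sub] = (codes[sub] + shift) % 4
    # indel events
    ev = np.flatnonzero(rng.random(n) < config.indel_rate)
    is_ins = rng.random(len(ev)) < 0.5
    lengths = rng.geometric(1.0 / config.indel_length_mean, len(ev))
    # case-run boundaries (planted-repeat boundaries)
    change = np.flatnonzero(np.diff(lower.astype(np.int8)) != 0) + 1
    run_ends = np.concatenate([change, [n]])

    out_codes: list[np.ndarray] = []
    out_lower: list[np.ndarray] = []
    coord = np.full(n, -1, dtype=np.int64)
    out_pos = 0
    prev = 0
    for pos, ins, length in zip(ev, is_ins, lengths):
        pos, length = int(pos), int(length)
        if pos < prev:
            continue  # swallowed by an earlier deletion
        coord[prev:pos] = np.arange(out_pos, out_pos + (pos - prev))
        out_codes.append(codes[prev:pos])
        out_lower.append(lower[prev:pos])
        out_pos += pos - prev
        prev = pos
        if ins:
            ins_codes = rng.integers(0, 4, length).astype(np.uint8)
            out_codes.append(ins_codes)
            out_lower.append(np.full(length, bool(lower[pos]), dtype=bool))
            out_pos += length
        else:
            run_end = int(run_ends[np.searchsorted(run_ends, pos, side="right")])
            dl = min(length, run_end - pos)
            prev = pos + dl
    coord[prev:n] = np.arange(out_pos, out_pos + (n - prev))
    out_codes.append(codes[prev:n])
    out_lower.append(lower[prev:n])
    derived = _decode(np.concatenate(out_codes), np.concatenate(out_lower))
    return derived, coord


@dataclass
class TruthMap:
    """Co-linear orthologous interval pairs between the two descendants.

    Each pair maps ref [t_start, t_end) onto query [q_start, q_end) base
    for base; ``label`` is the repeat family name or 'background'.
    """

    pairs: list[tuple[int, int, int, int, str]] = field(default_factory=list)

    def ref_mask(self, length: int, repeat_only: bool = False) -> np.ndarray:
        mask = np.zeros(length, dtype=bool)
        for t0, t1, _, _, label in self.pairs:
            if repeat_only and label == "background":
                continue
            mask[t0:t1] = True
        return mask

    def to_tsv(self) -> str:
        lines = ["t_start\tt_end\tq_start\tq_end\tlabel"]
        for t0, t1, q0, q1, label in self.pairs:
            lines.append(f"{t0}\t{t1}\t{q0}\t{q1}\t{label}")
        return "\n".join(lines) + "\n"


def build_truth(
    ref_map: np.ndarray,
    qry_map: np.ndarray,
    annotations: list[tuple[int, int, str]],
) -> TruthMap:
    """Condense surviving orthologous base pairs into labeled intervals."""
    n = len(ref_map)
    label_idx = np.zeros(n, dtype=np.int32)
    names = ["background"]
    for start, end, name in annotations:
        if name not in names:
            names.append(name)
        label_idx[start:end] = names.index(name)
    ok = (ref_map >= 0) & (qry_map >= 0)
    idx = np.flatnonzero(ok)
    truth = TruthMap()
    if len(idx) == 0:
        return truth
    breaks = np.flatnonzero(
        (np.diff(idx) != 1)
        | (np.diff(ref_map[idx]) != 1)
        | (np.diff(qry_map[idx]) != 1)
        | (np.diff(label_idx[idx]) != 0)
    ) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(idx)]])
    for s, e in zip(starts, ends):
        a0, a1 = idx[s], idx[e - 1]
        truth.pairs.append((
            int(ref_map[a0]), int(ref_map[a1]) + 1,
            int(qry_map[a0]), int(qry_map[a1]) + 1,
            names[label_idx[a0]],
        ))
    return truth


def first_pass_chain(
    ref: str,
    query: str,
    scheme: ScoringScheme | None = None,
    table: GapCostTable | None = None,
    *,
    k: int = 12,
    t_name: str = "target1",
    q_name: str = "query1",
    max_lookback: int = 100,
) -> list[Chain]:
    """Compute a first-pass chain with repeat-masked seeding.

    Seeds are taken only where both k-mers are fully uppercase, so no
    alignment can start inside a soft-masked repeat; extensions may still
    run into repeats, just as a production aligner's do.  Ungapped HSPs
    are chained into a single co-linear chain per run of compatible
    fragments, leaving unaligned gaps over the repeat interiors.
    """
    if scheme is None:
        scheme = default_scoring()
    if table is None:
        table = default_gap_costs()
    hsps = find_hsps(
        ref, query, scheme, k=k, respect_mask=True, seed_cap=50_000_000
    )
    fragments = [
        LocalAlignment(
            (Segment(h.t_start, h.q_start, h.t_end - h.t_start),), h.score
        )
        for h in hsps
    ]
    mini = chain_fragments(
        fragments, table,
        ref=ref, query=query, scheme=scheme,
        max_lookback=max_lookback,
    )
    if mini is None:
        return []
    segs = mini.all_segments()
    blocks = []
    from .chain_io import AlignBlock
    for cur, nxt in zip(segs, segs[1:]):
        blocks.append(AlignBlock(
            cur.length, nxt.t_start - cur.t_end, nxt.q_start - cur.q_end
        ))
    blocks.append(AlignBlock(segs[-1].length))
    chain = Chain(
        score=mini.score,
        t_name=t_name, t_size=len(ref),
        t_start=segs[0].t_start, t_end=segs[-1].t_end,
        q_name=q_name, q_size=len(query), q_strand="+",
        q_start=segs[0].q_start, q_end=segs[-1].q_end,
        chain_id="1",
        blocks=blocks,
    )
    chain.validate()
    return [chain]


@dataclass
class SimDataset:
    """In-memory handles plus file paths of one generated dataset."""

    config: SimConfig
    ref: str
    query: str
    truth: TruthMap
    annotations: list[tuple[int, int, str]]
    chains: list[Chain]
    out_dir: Path | None = None

    @property
    def target_store(self) -> SequenceStore:
        return SequenceStore({self.config.t_name: self.ref})

    @property
    def query_store(self) -> SequenceStore:
        return SequenceStore({self.config.q_name: self.query})

    def path(self, name: str) -> Path:
        if self.out_dir is None:
            raise ValueError("dataset was generated without an output directory")
        return self.out_dir / name


def _wrap_fasta(name: str, seq: str, width: int = 60) -> str:
    lines = [f">{name}"]
    for i in range(0, len(seq), width):
        lines.append(seq[i:i + width])
    return "\n".join(lines) + "\n"


def _ref_repeat_bed(
    t_name: str,
    ref_map: np.ndarray,
    annotations: list[tuple[int, int, str]],
) -> str:
    lines = []
    for start, end, name in annotations:
        surviving = ref_map[start:end]
        surviving = surviving[surviving >= 0]
        if len(surviving) == 0:
            continue
        breaks = np.flatnonzero(np.diff(surviving) != 1) + 1
        for s, e in zip(
            np.concatenate([[0], breaks]),
            np.concatenate([breaks, [len(surviving)]]),
        ):
            lines.append(
                f"{t_name}\t{surviving[s]}\t{surviving[e - 1] + 1}\t{name}\t0\t+"
            )
    lines.sort(key=lambda l: int(l.split("\t")[1]))
    return "\n".join(lines) + ("\n" if lines else "")


def generate_dataset(
    config: SimConfig | None = None,
    out_dir: str | Path | None = None,
) -> SimDataset:
    """Generate the full test bed; optionally write it to ``out_dir``.

    Files written: target.fa, query.fa (soft-masked FASTA), in.chain
    (first-pass chain with masked seeding), truth.bed (surviving repeat
    copies in reference coordinates), truth_pairs.tsv (orthology map),
    and manifest.json recording the configuration and seed.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.rng_seed)
    ancestor, annotations = generate_ancestor(config, rng)
    ref, ref_map = evolve(ancestor, config, rng)
    query, qry_map = evolve(ancestor, config, rng)
    truth = build_truth(ref_map, qry_map, annotations)
    chains = first_pass_chain(
        ref, query, t_name=config.t_name, q_name=config.q_name
    )
    dataset = SimDataset(
        config=config, ref=ref, query=query, truth=truth,
        annotations=annotations, chains=chains,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        dataset.out_dir = out_dir
        (out_dir / "target.fa").write_text(_wrap_fasta(config.t_name, ref))
        (out_dir / "query.fa").write_text(_wrap_fasta(config.q_name, query))
        write_chain_file(chains, out_dir / "in.chain")
        (out_dir / "truth.bed").write_text(
            _ref_repeat_bed(config.t_name, ref_map, annotations)
        )
        (out_dir / "truth_pairs.tsv").write_text(truth.to_tsv())
        manifest = asdict(config)
        manifest["repeat_families"] = [
            [f.length, f.copies, f.divergence] for f in config.repeat_families
        ]
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n"
        )
    return dataset


def _aligned_ref_mask(chains: list[Chain], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for chain in chains:
        for t, _, size in chain.block_coords():
            mask[t:t + size] = True
    return mask


def evaluate_fill(
    dataset: SimDataset,
    out_chains: list[Chain],
    config: FillConfig | None = None,
) -> dict[str, float]:
    """Recall/precision of a filling run against the planted ground truth.

    Recall: fraction of reference bases that (a) carry a repeat-labeled
    orthologous truth pair and (b) lie inside a qualifying gap of the
    input chain, which the run newly aligned.  Off-target: fraction of
    newly aligned reference bases with no orthologous truth pair at all.
    """
    if config is None:
        config = FillConfig()
    t_len = len(dataset.ref)
    before = _aligned_ref_mask(dataset.chains, t_len)
    after = _aligned_ref_mask(out_chains, t_len)
    new = after & ~before
    ortho = dataset.truth.ref_mask(t_len)
    repeat = dataset.truth.ref_mask(t_len, repeat_only=True)
    in_gaps = np.zeros(t_len, dtype=bool)
    for chain in dataset.chains:
        for gap in enumerate_gaps(chain, config):
            in_gaps[gap.t_gap.start:gap.t_gap.end] = True
    target = repeat & in_gaps
    n_target = int(target.sum())
    n_new = int(new.sum())
    recall = 100.0 * int((new & target).sum()) / n_target if n_target else float("nan")
    offtarget = 100.0 * int((new & ~ortho).sum()) / n_new if n_new else 0.0
    return {
        "recall_pct": recall,
        "offtarget_pct": offtarget,
        "new_aligned_bases": n_new,
        "target_bases": n_target,
        "aligned_before": int(before.sum()),
        "aligned_after": int(after.sum()),
    }
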