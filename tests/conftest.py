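"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

import chaingapfill as cgf

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def mutate(rng: np.random.Generator, seq: str, sub_rate: float) -> str:
    """Substitute each base with probability sub_rate (uniform alternative)."""
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < sub_rate):
        out[i] = BASES[(BASES.index(out[i].upper()) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def sw_oracle(scheme: cgf.ScoringScheme):
    """Biopython affine-gap local aligner as an independent score oracle."""
    m = substitution_matrices.Array(BASES, dims=2)
    for i, a in enumerate(BASES):
        for j, b in enumerate(BASES):
            m[a, b] = scheme.matrix[i, j]
    pa = Align.PairwiseAligner()
    pa.substitution_matrix = m
    pa.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    pa.extend_gap_score = -scheme.gap_extend
    pa.mode = "local"
    return lambda a, b: int(pa.score(a, b))


def random_chain(rng: np.random.Generator, max_blocks: int = 12) -> cgf.Chain:
    """A structurally valid random chain record."""
    n_blocks = int(rng.integers(1, max_blocks + 1))
    blocks = []
    for i in range(n_blocks):
        size = int(rng.integers(1, 200))
        if i == n_blocks - 1:
            blocks.append(cgf.AlignBlock(size))
        else:
            blocks.append(cgf.AlignBlock(
                size, int(rng.integers(0, 300)), int(rng.integers(0, 300))
            ))
    t_span = sum(b.size + b.dt for b in blocks)
    q_span = sum(b.size + b.dq for b in blocks)
    t_start = int(rng.integers(0, 1000))
    q_start = int(rng.integers(0, 1000))
    return cgf.Chain(
        score=int(rng.integers(0, 10**7)),
        t_name=f"t{int(rng.integers(1, 4))}",
        t_size=t_start + t_span + int(rng.integers(0, 500)),
        t_start=t_start, t_end=t_start + t_span,
        q_name=f"q{int(rng.integers(1, 4))}",
        q_size=q_start + q_span + int(rng.integers(0, 500)),
        q_strand="+" if rng.random() < 0.5 else "-",
        q_start=q_start, q_end=q_start + q_span,
        chain_id=str(int(rng.integers(1, 10**6))),
        blocks=blocks,
    )


@pytest.fixture(scope="session")
def scheme() -> cgf.ScoringScheme:
    return cgf.default_scoring()


@pytest.fixture(scope="session")
def table() -> cgf.GapCostTable:
    return cgf.default_gap_costs()


@pytest.fixture(scope="session")
def small_dataset() -> cgf.SimDataset:
    """100 kb dataset: fast enough for per-test use, repeats of all sizes."""
    config = cgf.SimConfig(
        ancestor_length=100_000,
        repeat_families=(
            cgf.RepeatFamily(300, 4, 0.03),
            cgf.RepeatFamily(800, 3, 0.03),
            cgf.RepeatFamily(1500, 2, 0.03),
        ),
        rng_seed=7,
    )
    return cgf.generate_dataset(config)


@pytest.fixture(scope="session")
def small_filled(small_dataset):
    config = cgf.FillConfig(rng_seed=7)
    out_chains, report = cgf.fill_all(
        small_dataset.chains,
        small_dataset.target_store,
        small_dataset.query_store,
        config,
    )
    return out_chains, report, config


@pytest.fixture(scope="session")
def default_dataset() -> cgf.SimDataset:
    """The default study conditions: 1 Mb ancestor, three repeat families."""
    return cgf.generate_dataset(cgf.SimConfig(rng_seed=11))


@pytest.fixture(scope="session")
def default_filled(default_dataset):
    config = cgf.FillConfig(rng_seed=11)
    out_chains, report = cgf.fill_all(
        default_dataset.chains,
        default_dataset.target_store,
        default_dataset.query_store,
        config,
    )
    return out_chains, report, config
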