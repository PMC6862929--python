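"""Gap enumeration, mini-chain insertion, whole-file filling, reporting."""

import io

import numpy as np
import pytest

import chaingapfill as cgf
from chaingapfill.aligner import LocalAlignment, Segment
from chaingapfill.chaining import MiniChain
from conftest import mutate, random_dna


def make_chain(block_spec, score=30_000, q_strand="+"):
    """Chain from (size, dt, dq) triples; sizes derived automatically."""
    blocks = [cgf.AlignBlock(*spec) for spec in block_spec[:-1]]
    blocks.append(cgf.AlignBlock(block_spec[-1][0]))
    t_span = sum(b.size + b.dt for b in blocks)
    q_span = sum(b.size + b.dq for b in blocks)
    chain = cgf.Chain(score, "t", t_span + 100, 0, t_span,
                      "q", q_span + 100, q_strand, 0, q_span, "1", blocks)
    chain.validate()
    return chain


class TestEnumerateGaps:
    def test_size_bounds_inclusive_on_both_sides(self):
        config = cgf.FillConfig()
        below = make_chain([(10, 29, 35), (10,)])
        assert cgf.enumerate_gaps(below, config) == []
        at = make_chain([(10, 30, 30), (10,)])
        assert len(cgf.enumerate_gaps(at, config)) == 1
        above = make_chain([(10, 20_001, 5000), (10,)])
        assert cgf.enumerate_gaps(above, config) == []
        at_max = make_chain([(10, 20_000, 20_000), (10,)])
        assert len(cgf.enumerate_gaps(at_max, config)) == 1

    def test_one_sided_gap_excluded(self):
        chain = make_chain([(10, 40, 10), (10,)])
        assert cgf.enumerate_gaps(chain, cgf.FillConfig()) == []

    def test_single_block_chain_has_no_gaps(self):
        chain = make_chain([(50,)])
        assert cgf.enumerate_gaps(chain, cgf.FillConfig()) == []

    def test_chain_score_filter_is_strict(self):
        config = cgf.FillConfig()
        for score, expected in [(24_999, 0), (25_000, 0), (25_001, 1)]:
            chain = make_chain([(10, 50, 50), (10,)], score=score)
            assert len(cgf.enumerate_gaps(chain, config)) == expected

    def test_gap_coordinates_and_strand(self):
        chain = make_chain([(10, 50, 60), (10,)], q_strand="-")
        (gap,) = cgf.enumerate_gaps(chain, cgf.FillConfig())
        assert (gap.t_gap.start, gap.t_gap.end) == (10, 60)
        assert (gap.q_gap.start, gap.q_gap.end) == (10, 70)
        assert gap.q_gap.strand == "-"
        assert gap.block_index == 0


def single_gap_context(t_len, q_len):
    return cgf.GapContext(
        "1", 0,
        cgf.GenomicInterval("t", 0, t_len, "+"),
        cgf.GenomicInterval("q", 0, q_len, "+"),
    )


class TestFillGap:
    def test_planted_repeat_recovered(self):
        """A shared ~10%-diverged 300 bp repeat inside unrelated flanks is
        re-aligned over at least 80% of its length."""
        rng = np.random.default_rng(99)
        repeat = random_dna(rng, 300)
        t_frag = random_dna(rng, 100) + repeat.lower() + random_dna(rng, 100)
        q_frag = (random_dna(rng, 80)
                  + mutate(rng, repeat, 0.1).lower()
                  + random_dna(rng, 90))
        t_store = cgf.SequenceStore({"t": t_frag})
        q_store = cgf.SequenceStore({"q": q_frag})
        gap = single_gap_context(len(t_frag), len(q_frag))
        config = cgf.FillConfig(rng_seed=1)
        mini = cgf.fill_gap(gap, t_store, q_store, config)
        assert mini is not None and mini.score >= config.min_mini_score
        covered = sum(
            max(0, min(s.t_end, 400) - max(s.t_start, 100))
            for s in mini.all_segments()
        )
        assert covered >= 0.8 * 300

    def test_unrelated_sequences_yield_nothing(self):
        rng = np.random.default_rng(100)
        t_store = cgf.SequenceStore({"t": random_dna(rng, 400)})
        q_store = cgf.SequenceStore({"q": random_dna(rng, 400)})
        gap = single_gap_context(400, 400)
        assert cgf.fill_gap(gap, t_store, q_store, cgf.FillConfig()) is None

    def test_mini_score_threshold_is_inclusive(self):
        """A mini chain is returned at exactly min_mini_score, rejected
        one point above its own score."""
        rng = np.random.default_rng(101)
        repeat = random_dna(rng, 120)
        t_frag = random_dna(rng, 50) + repeat + random_dna(rng, 50)
        q_frag = random_dna(rng, 40) + mutate(rng, repeat, 0.05) + random_dna(rng, 60)
        t_store = cgf.SequenceStore({"t": t_frag})
        q_store = cgf.SequenceStore({"q": q_frag})
        gap = single_gap_context(len(t_frag), len(q_frag))
        probe = cgf.fill_gap(
            gap, t_store, q_store, cgf.FillConfig(min_mini_score=1)
        )
        assert probe is not None
        score = probe.score
        at = cgf.FillConfig(min_mini_score=score)
        above = cgf.FillConfig(min_mini_score=score + 1)
        assert cgf.fill_gap(gap, t_store, q_store, at) is not None
        assert cgf.fill_gap(gap, t_store, q_store, above) is None


def mini_of(segments, score=10_000):
    return MiniChain((LocalAlignment(tuple(segments), score),), score)


class TestInsertMiniChain:
    def test_centered_block_splits_gap_conserving_spans(self):
        chain = make_chain([(10, 200, 200), (10,)])
        (gap,) = cgf.enumerate_gaps(chain, cgf.FillConfig())
        mini = mini_of([Segment(75, 80, 50)])
        out = cgf.insert_mini_chain(chain, gap, mini)
        out.validate()
        assert [b.size for b in out.blocks] == [10, 50, 10]
        b0, b1, _ = out.blocks
        assert (b0.dt, b0.dq) == (75, 80)
        assert b0.dt + 50 + b1.dt == 200
        assert b0.dq + 50 + b1.dq == 200

    def test_flush_block_merges_into_upstream(self):
        chain = make_chain([(10, 200, 200), (10,)])
        (gap,) = cgf.enumerate_gaps(chain, cgf.FillConfig())
        mini = mini_of([Segment(0, 0, 50)])
        out = cgf.insert_mini_chain(chain, gap, mini)
        out.validate()
        assert [b.size for b in out.blocks] == [60, 10]
        assert (out.blocks[0].dt, out.blocks[0].dq) == (150, 150)

    def test_escaping_block_is_an_internal_error(self):
        chain = make_chain([(10, 100, 100), (10,)])
        (gap,) = cgf.enumerate_gaps(chain, cgf.FillConfig())
        with pytest.raises(AssertionError):
            cgf.insert_mini_chain(chain, gap, mini_of([Segment(80, 80, 30)]))

    @pytest.mark.parametrize("trial", range(10))
    def test_fuzzed_insertions_preserve_original_pairs(self, trial):
        rng = np.random.default_rng(5000 + trial)
        chain = make_chain([
            (int(rng.integers(5, 40)), int(rng.integers(40, 300)),
             int(rng.integers(40, 300)))
            for _ in range(int(rng.integers(2, 6)))
        ] + [(int(rng.integers(5, 40)),)])
        config = cgf.FillConfig()
        gaps = cgf.enumerate_gaps(chain, config)
        if not gaps:
            return
        gap = gaps[int(rng.integers(0, len(gaps)))]
        t_len, q_len = gap.t_gap.length, gap.q_gap.length
        size = int(rng.integers(1, min(t_len, q_len)))
        t_off = int(rng.integers(0, t_len - size + 1))
        q_off = int(rng.integers(0, q_len - size + 1))
        out = cgf.insert_mini_chain(chain, gap, mini_of([Segment(t_off, q_off, size)]))
        out.validate()
        before = set(chain.aligned_pairs())
        after = set(out.aligned_pairs())
        assert before <= after
        assert len(after) == len(before) + size


class TestFillAll:
    def test_no_qualifying_gaps_leaves_input_untouched(self, small_dataset):
        config = cgf.FillConfig(min_chain_score=10**9)
        out, report = cgf.fill_all(
            small_dataset.chains,
            small_dataset.target_store,
            small_dataset.query_store,
            config,
        )
        assert out == small_dataset.chains
        assert report.gaps_filled == 0 and report.bases_added == 0

    def test_bases_added_matches_inserted_blocks(self, small_dataset, small_filled):
        out_chains, report, _ = small_filled
        gained = sum(c.aligned_bases for c in out_chains) \
            - sum(c.aligned_bases for c in small_dataset.chains)
        assert report.bases_added == gained > 0
        assert report.bases_added == sum(
            e - s for _, s, e in report.new_intervals
        )

    def test_filled_chains_rescored_from_sequence(
        self, small_dataset, small_filled, scheme, table
    ):
        out_chains, report, config = small_filled
        for chain, row in zip(out_chains, report.rows):
            if row.gaps_filled:
                expected = cgf.score_chain(
                    chain,
                    small_dataset.target_store,
                    small_dataset.query_store,
                    config.scheme,
                    config.table,
                )
                assert chain.score == expected == row.score_after

    def test_report_tsv_layout(self, small_filled):
        _, report, _ = small_filled
        lines = report.to_tsv().splitlines()
        assert lines[0].startswith("chain_id\t")
        assert lines[-1].startswith("total\t")


class TestSummarizeOverlap:
    def test_all_blocks_inside_one_class(self):
        bed = io.StringIO("t\t0\t1000\tSINE\t0\t+\n")
        counts = cgf.summarize_overlap([("t", 100, 150), ("t", 200, 220)], bed)
        assert counts == {"SINE": 70}

    def test_empty_bed_is_all_nonrepetitive(self):
        counts = cgf.summarize_overlap([("t", 0, 50)], io.StringIO(""))
        assert counts == {"non-repetitive": 50}

    def test_malformed_bed_rejected(self):
        with pytest.raises(ValueError, match="line 1"):
            cgf.summarize_overlap([("t", 0, 5)], io.StringIO("t\tx\t5\tL\n"))

    @pytest.mark.parametrize("trial", range(10))
    def test_fuzzed_counts_match_per_base_classification(self, trial):
        rng = np.random.default_rng(6000 + trial)
        classes = ["SINE", "LINE", "LTR"]
        bed_rows = []
        for _ in range(int(rng.integers(1, 8))):
            start = int(rng.integers(0, 500))
            bed_rows.append((
                "t", start, start + int(rng.integers(1, 120)),
                classes[int(rng.integers(0, 3))],
            ))
        blocks = []
        for _ in range(int(rng.integers(1, 6))):
            start = int(rng.integers(0, 500))
            blocks.append(("t", start, start + int(rng.integers(1, 80))))
        bed_text = "\n".join(f"{c}\t{s}\t{e}\t{l}" for c, s, e, l in bed_rows)
        counts = cgf.summarize_overlap(blocks, io.StringIO(bed_text))
        # brute force: classify every base independently
        expected: dict[str, int] = {}
        srt = sorted((s, e, l) for _, s, e, l in bed_rows)
        for _, b_start, b_end in blocks:
            for pos in range(b_start, b_end):
                label = "non-repetitive"
                for s, e, l in srt:
                    if s <= pos < e:
                        label = l
                        break
                expected[label] = expected.get(label, 0) + 1
        assert counts == expected
        assert sum(counts.values()) == sum(e - s for _, s, e in blocks)
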