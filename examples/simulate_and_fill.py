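"""End-to-end run on a synthetic genome pair.

Generates a 200 kb ancestor with planted, soft-masked repeat copies,
evolves two descendants, computes a first-pass chain with repeat-masked
seeding (so the repeats sit in alignment gaps), then runs the gap filler
and scores the result against the planted ground truth.
"""

from chaingapfill import (
    FillConfig,
    RepeatFamily,
    SimConfig,
    evaluate_fill,
    fill_all,
    generate_dataset,
)

config = SimConfig(
    ancestor_length=200_000,
    repeat_families=(
        RepeatFamily(300, 6, 0.03),
        RepeatFamily(800, 4, 0.03),
        RepeatFamily(1500, 3, 0.03),
    ),
    rng_seed=42,
)
dataset = generate_dataset(config)
print(f"first-pass chain: {dataset.chains[0].aligned_bases} aligned bases "
      f"in {len(dataset.chains[0].blocks)} blocks")

fill_config = FillConfig(rng_seed=42)
out_chains, report = fill_all(
    dataset.chains, dataset.target_store, dataset.query_store, fill_config
)
print(f"filled {report.gaps_filled} of {report.gaps_examined} qualifying gaps, "
      f"adding {report.bases_added} aligned reference bases")

metrics = evaluate_fill(dataset, out_chains, fill_config)
print(f"recall of planted repeat bases in qualifying gaps: "
      f"{metrics['recall_pct']:.1f}%")
print(f"newly aligned bases outside orthologous regions: "
      f"{metrics['offtarget_pct']:.2f}%")
print("High recall with sub-percent off-target means the filler recovers "
      "the planted orthologous repeats, not spurious alignments.")
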