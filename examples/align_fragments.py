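"""Seed-and-extend alignment of two diverged fragments.

Builds a 400 bp fragment and a copy diverged by ~8% substitutions plus one
small deletion, then runs the full seeding -> ungapped -> gapped pipeline.
Each reported alignment is a list of ungapped segments with a score in
substitution-matrix units (a perfect match column scores 91 or 100, the
affine gap penalty is 400 + 30/base).
"""

import numpy as np

from chaingapfill import align_region, default_scoring

rng = np.random.default_rng(0)
BASES = "ACGT"

ref = "".join(BASES[i] for i in rng.integers(0, 4, 400))
query = list(ref)
for i in np.flatnonzero(rng.random(400) < 0.08):
    query[i] = BASES[(BASES.index(query[i]) + int(rng.integers(1, 4))) % 4]
del query[200:205]  # a 5 bp deletion in the query
query = "".join(query)

scheme = default_scoring(hsp_threshold=2000)  # the sensitive fill-step K
alignments = align_region(ref, query, scheme)

print(f"{len(alignments)} alignment(s) above the gapped threshold "
      f"L={scheme.gapped_threshold}")
for aln in alignments:
    print(f"  score {aln.score}, {aln.aligned_columns} aligned columns:")
    for seg in aln.segments:
        print(f"    ref[{seg.t_start}:{seg.t_end}) ~ query[{seg.q_start}:{seg.q_end})")
print("The segment break marks the deletion; the score is the column sum "
      "minus one affine gap penalty.")
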