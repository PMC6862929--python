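# Methods

## Scope and model

`chaingapfill` operates on UCSC chain files: co-linear lists of ungapped
aligned blocks between a reference ("target") interval and a query
interval, with gaps given as unaligned base counts dt (target) and dq
(query) between consecutive blocks.  Coordinates are 0-based half-open;
minus-strand query coordinates address the reverse-complemented query
sequence; the target strand must be `+` (chains with a `-` target are
rejected as invalid input rather than normalized, since reference-built
chain sets use `+` targets throughout).

The method assumes the input chains are correct where they align: it
never moves, splits or re-scores existing blocks except to subdivide a
gap, and orthology of new alignments is argued from co-linear context,
not from sequence alone.  Gaps larger than the configured maximum are
deliberately ignored — without nearby flanking blocks, the chance that a
repeat-overlapping alignment is paralogous rises sharply.

## Alignment engine

The built-in aligner is a faithful small-scale seed-and-extend pipeline:

* **Seeds** — contiguous exact 12-mers by default (configurable length
  ≥ 4).  Matching is case-insensitive; windows containing N never seed;
  in masked-seeding mode (used by the simulator's first pass) windows
  touching lowercase on either side never seed.  A production aligner
  uses spaced seeds and transition tolerance; contiguous exact seeds are
  a documented simplification that only affects sensitivity at high
  divergence, not the contract of any downstream stage.
* **Ungapped extension** — symmetric X-drop walk along the seed's
  diagonal; the maximal-scoring sub-segment containing the seed is kept
  if it scores ≥ K.  The X-drop bound is not a standard published
  constant; the default is 10× the largest diagonal matrix entry (910),
  large enough that truncation never occurs before ~8 consecutive
  mismatches.  Seeds falling inside an already-extended HSP on the same
  diagonal are skipped.
* **Gapped extension** — affine-gap dynamic programming anchored at the
  HSP's maximum-scoring point and run independently leftward and
  rightward.  Cells whose best score falls more than Y below the best
  seen are abandoned (Y-drop); the live band is carried row to row and
  extended along horizontal gap runs still within Y.  All arithmetic is
  64-bit integer.  Traceback prefers diagonal over up over left, so
  identical inputs give byte-identical output on any platform.  An
  alignment is reported if its score is ≥ L.  With Y effectively
  unbounded and an anchor on the optimal path, this equals the
  affine-gap Smith–Waterman optimum — the test suite checks exact
  equality against an independent implementation (Biopython's
  `PairwiseAligner`) on hundreds of fragment pairs, and the ≤-optimum
  bound at default thresholds.
* **Scoring** — the standard cross-species nucleotide matrix (HOXD70
  values) with gap open 400 and extend 30, shipped as an editable
  score file in the conventional score-file syntax.  Any column
  involving N scores the worst matrix entry (−125).  The inner-alignment
  threshold H that some aligners expose is parsed from score files for
  compatibility but unused: the inner-alignment stage is out of scope,
  and at gap scale (≤ 20 kb fragments) it would have nothing to do.

Default thresholds are K = 2,400, L = 3,000, Y = 9,400 for first-pass
alignment; the filler lowers K to 2,000 (the method's "slightly more
sensitive" setting).  A seed-explosion guard caps the seed list at
50,000 per gap, keeping a uniform subsample drawn from a generator
seeded by (chain id, block index, run seed) — the only stochastic
element of the filler, and fully reproducible.

## Fragment chaining

Local alignments within one gap are combined by dynamic programming over
fragments sorted by start coordinate: each fragment's best predecessor
maximizes cumulative score minus the connection's gap cost.  A successor
overlapping its predecessor on either genome is trimmed from its start;
the trimmed columns' score contribution is recomputed from sequence when
the fragments' sequences are at hand, else removed proportionally.
Because trimming changes only the successor's start (never its end), the
pairwise decomposition remains exact and the DP matches exhaustive
enumeration over co-linear subsets (tested to 6 fragments).  Only the
single best mini chain per gap is kept.

Gap costs follow the piecewise-linear "loose" schedule used for
chaining distantly related genomes, shipped as a three-column data file
(size, one-sided cost, both-sided cost; both-sided gaps are charged at
dt+dq).  Interpolation between breakpoints is exact integer arithmetic
with floor division; beyond the last breakpoint the final slope
extrapolates.  Note that this schedule is *not* globally concave (its
per-base cost rises between gap sizes ~20,000 and ~23,550), so merging
two adjacent gaps is not always cheaper than keeping them separate; the
subadditivity guarantee holds only for concave tables and is tested on
one.

## Filling pass

A gap qualifies when **both** dt and dq lie in [30, 20,000] — the
both-sides reading of the size rule: a gap below the minimum on one side
has essentially nothing to align against and invites spurious overlap
with the flanks.  The chain score filter is strict (> 25,000), the mini
chain score filter inclusive (≥ 5,000), both exactly as printed in the
method's description.  Gaps are processed independently left to right;
results do not depend on processing order.  One pass only: gaps created
by an insertion are not re-examined (the original tool's behavior on
this point is unspecified; one pass keeps the output a pure refinement
of the input).  Chains that received no insertion are emitted verbatim,
score included.

Structural guarantees, enforced by the validator and asserted in tests:
reference and query span sums are invariant; original aligned base
pairs are preserved exactly; inserted blocks lie inside their gap on
both genomes; blocks left adjacent with zero gap are merged.

## Simulator

The generator emulates exactly the features the method needs and nothing
more: an i.i.d. uniform ancestor; repeat families planted as diverged
copies of a per-family consensus at uniformly sampled non-overlapping
positions, lowercase (soft-masked); two descendants derived
independently by per-site substitutions (uniform among alternatives,
case preserved) and indels with geometric lengths.  Deletions never
cross a mask-run boundary, so planted copies are never structurally
disrupted — the filler assumes co-linearity, and inversions or
translocations are out of scope.  A coordinate map per lineage yields a
ground-truth orthology map (interval pairs labeled by repeat family or
background).

The first-pass chain is built from masked-seeded ungapped HSPs chained
genome-wide (with a bounded predecessor search window of 100, ample for
co-linear data).  Extensions may run into repeats — as production
aligners' do — but no alignment can start inside one, which reproduces
the regime of interest: in the default dataset ≥ 95% of orthologous
repeat bases end up inside chain gaps.

Default conditions: 1 Mb ancestor; three families (300 bp × 20, 800 bp
× 14, 1,500 bp × 8 copies) at 3% copy-to-consensus divergence;
substitution rate 0.05/site per lineage (≈ 10% pairwise divergence,
i.e. a moderately diverged mammalian pair); indel rate 0.005/site per
lineage with geometric mean length 3 (≈ 1:10 indel-to-substitution
ratio).  These sizes keep a full simulate-plus-fill run under a minute
on one CPU while leaving ~500 kb of background between repeats.

What passing tests on this simulator do **not** show: behavior on real
repeat biology (nested/fragmented elements, target-site duplications,
segmental duplications), on paralog-rich gaps where several family
copies compete within one gap, or on rearranged regions.  The
simulator's repeats are clean single copies in co-linear context, which
is the regime the method is designed for and claims to handle.

## Measured quantities

`scripts/acceptance.py` regenerates the default dataset and reports:
recall (% of reference bases carrying a repeat-labeled orthologous truth
pair and lying inside a qualifying gap that the run newly aligned),
off-target rate (% of newly aligned reference bases with no orthologous
truth pair — inserted or deleted material aligned by force), total new
aligned bases, % of new bases overlapping the repeat annotation, and
gaps filled.  Off-target bases are dominated by lineage-specific
insertions inside filled gaps, which bounds the expected rate near the
inserted-base fraction (~0.75%) from above.

## Known limitations

* Contiguous exact seeding loses sensitivity above ~15% pairwise
  divergence sooner than a spaced-seed aligner would.
* Only the best mini chain per gap is inserted; a gap containing two
  independent co-linear alignable stretches separated by an expensive
  connection keeps only the better one.
* The gap-cost table's tail (> 3 Mb gaps) is linear extrapolation; at
  filler scale (≤ 20 kb) this is irrelevant.
* No iterative re-filling of subdivided gaps.
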