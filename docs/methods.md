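# Methods

This note documents the models, parameter choices and numerical conventions
of `livemapper`, and what the synthetic studies do and do not demonstrate.

## Reference model and index

The aligner works on a *doubled text*: the forward sequence of every
reference record, then the reverse complement of every record, with a
separator character between segments and a unique terminal sentinel.
Extension is therefore always rightward in text coordinates and the engine
is strand-oblivious; conversion to forward-strand 1-based SAM coordinates
happens only at output (for a reverse-strand hit, POS derives from the text
offset of the *last* aligned base). `N` bases are replaced by the separator
code in the indexed text, so no anchor can span them and read `N`s never
match — a deliberately conservative treatment.

The FM-index stores the BWT, the C array, occurrence checkpoints every 128
BWT positions and suffix-array samples for every text position divisible by
32 (both configurable). locate() resolves a row by LF-walking to the nearest
sample, so it costs at most 32 LF steps. The suffix array is built by
prefix doubling (O(n log² n), vectorized), which is ample at the package's
intended desk scale (references up to a few Mb). An interval wider than
`locate_cap` (default 100) is declared repetitive and yields no anchors:
unbounded repeat loci would otherwise dominate per-read work, as in any
practical seed-based mapper. Reads whose every anchor is capped are simply
reported unmapped.

## Engine parameters

The five mode presets set (anchor length k, seeding interval s, error
interval e, min-score fraction f):

| mode          | k  | s  | e  | f    |
|---------------|----|----|----|------|
| very-fast     | 14 | 10 | 24 | 0.45 |
| fast          | 12 | 8  | 20 | 0.50 |
| balanced      | 12 | 6  | 16 | 0.55 |
| accurate      | 12 | 4  | 12 | 0.65 |
| very-accurate | 12 | 3  | 10 | 0.70 |

Reads of at most 60 cycles use k−2, s−2, e−4 (floored at 8/1/1), which
makes first output possible by cycle 30 even for 2×50 bp runs. The numbers
were chosen to reproduce the qualitative speed↔accuracy ordering of the
mode names: s ≤ k guarantees overlapping anchors, smaller s and e mean more
rescue opportunities and a tighter error leash. Scoring is +1 match,
−2 mismatch, −3 gap open, −1 gap extend; these values make the min-score
fraction directly interpretable (an alignment must look at least half like
a perfect match in `fast` mode). Indels are bounded at 3 bp by default —
longer gaps cost quadratically more branching for rapidly diminishing
returns on Illumina data.

Two length conventions matter and are easy to conflate:

- `allowed_errors` uses the **aligned** length (cycles minus softclip):
  ⌊(L_aligned − k)/e⌋, zero at the anchor. The budget is enforced *along
  the path* — the j-th error may only occur once the aligned length has
  reached k + j·e — not merely on the final count.
- `min_score` uses the **sequenced** length: ⌈f · match · L_seq⌉. A deeply
  softclipped rescue of a very erroneous read therefore fails reporting,
  which is intended: such an alignment carries little information and its
  placement confidence is low.

## Seed hypotheses and deduplication

A hypothesis is identified by (diagonal, softclip, open-insertion run
length). The first two components are the placement identity; the third is
needed because a seed in the middle of an insertion run and a seed whose
gap is closed can tie on score on the same diagonal yet have different
extension futures — merging them can discard the eventual optimum (split
insertions). Keeping the gap state bounds live seeds per diagonal at
1 + max_indel, preserving near-linear work per cycle. Within one key, the
better hypothesis is the higher score, then fewer errors, then the leftmost
text position; the identical ordering (plus longer aligned length and
lexicographic placement) breaks ties at output selection, with the tie
count driving MAPQ (37 unique / 0 tied). Deletions are applied as one
atomic D-run followed by the M consuming the current base; insertions are
stateful (opened, then extended one cycle at a time). Either run costs
gap_open + gap_extend·(len−1) score and one error in total.

A consequence of the error schedule worth knowing when interpreting
pileups: a read whose variant lies in its first ~(k + e) cycles loses its
initial seed before the budget opens and is rescued with the variant region
softclipped, so roughly the first third of a 100-cycle read contributes no
alternate-allele evidence at that locus. Coverage from reads carrying the
locus later makes up for it — the motivation for evaluating calls at
moderate (≥ 20×) coverage.

## Output, checkpointing, streaming

SAM is written through pysam with a fixed header (no timestamps), records
sorted by (reference, position, name) and unmapped records last, so output
is a deterministic byte stream. NM holds the engine's error count
(mismatches plus one per gap run), AS the score, XC the output cycle. Mate
fields and TLEN are filled only when both mates mapped to the same
reference at the same output cycle. Checkpoints serialize a tile's full
read state keyed by a settings digest; resuming reproduces all later
output byte-identically, and an already-processed cycle can be re-emitted
(e.g. all-mapper instead of one-best) without recomputation. Live mode
polls the run folder and consumes a cycle when every tile's file has its
self-declared size (4 + count bytes); cycles are consumed strictly in
order, so streaming and batch replay are equivalent by construction.

## SNP caller and evaluator

The caller is deliberately minimal: only CIGAR M bases contribute to the
pileup; a column is called when depth ≥ 5 and the top non-reference allele
reaches 25% of depth; QUAL is the Phred-scaled exact binomial tail
P(X ≥ alt | depth, error_rate = 0.01), computed by direct summation and
capped at 999. Ploidy is ignored throughout — the synthetic donor is
haploid and the evaluator matches squash-ploidy style. Indels are aligned
but not called.

Evaluation is exact (CHROM, POS, REF, ALT) matching after atomization
(multi-allelic split, same-length MNP decomposition; indel records are
skipped). The APR uses the step rule Σ (R_i − R_{i−1})·P_i over descending
QUAL thresholds with R_0 = 0 — chosen over trapezoids for threshold
stability, and stated here so numbers are comparable across runs. With no
calls, precision is reported as 1.0; with empty truth, recall is NA.

## Synthetic data

The generator emulates a haploid resequencing experiment at desk scale:
uniform-composition reference (GC 0.5) with optional tandem repeat tracts
(default two units of 200 bp × 3 copies), implanted SNVs (rate 0.002) and
short indels (rate 1e-4, ≤ 3 bp — matching the aligner's indel bound),
uniform paired fragments (300 ± 30 bp), and a per-cycle substitution rate
rising linearly from 0.001 to 0.01 along the read, with base qualities
encoding that rate. The rising error rate reproduces the real-data effect
that late cycles are noisier — precisely what the error-interval mechanism
is built for. The high-confidence BED excludes repeat tracts and ±5 bp
around implanted indels, the desk-scale analog of restricting evaluation to
high-confidence regions. All randomness flows through seeded
`numpy.random.default_rng`, so artifacts are bit-reproducible.

Not emulated: diploidy/zygosity, capture bias, PCR and optical duplicates,
structural variants, quality miscalibration, and cluster-density effects.
Passing tests therefore demonstrate the correctness and the qualitative
live-curve behavior of the algorithm, not calling performance on real
human data.

## Problem sizes

The standard study used by the acceptance checks and `scripts/acceptance.py`
is a 100 kb reference at 30× (15,000 pairs of 2×100 bp on 64 tiles); the
engine-vs-oracle comparison uses 500 reads on a repeat-free 50 kb
reference; unit fixtures are 2–20 kb. These sizes keep every check at
desk scale while leaving each statistic (200 truth SNVs, ≥ 400
oracle-checked reads) large enough to be meaningful.

## Known limitations

- The engine is single-threaded; tiles are independent by construction,
  so parallelism is possible but not implemented.
- min-score against sequenced length means very late rescues of erroneous
  reads go unreported even when their placement is correct.
- The all-mapper enumerates hypotheses within the searched space only:
  placements whose every anchor was repetitive-capped are absent.
- The caller has no genotype model; it is a stand-in for a real variant
  caller in the live workflow, not a replacement.
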