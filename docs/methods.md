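# Methods

This note records the model behind each pipeline stage, the parameter
choices, and the places where the design was genuinely open.

## Coordinate conventions

All internal coordinates are 1-based inclusive; a junction `(s, e)` spans the
circle `s..e` and `predicted_length = e − s + 1`. BED output is converted to
0-based half-open, so `bed_end − bed_start` equals the predicted length
exactly. Paired-end mates are treated as independent single-end reads: a
51-nt mate either spans a circular junction or it does not, and junction
counts are per read.

## Junction detection

A circular junction leaves a characteristic signature in a short read: two
exact same-strand genome matches in inverse genomic order. Detection
enumerates every split `s` with `min_segment_len ≤ s ≤ len − min_segment_len`
(default 20 nt, so a 51-nt read has 12 admissible splits) and locates both
parts with a k-mer-seeded exact matcher (seed length = `min_segment_len`,
full-match verification against the genome string; equivalent to a naive
scan of both strands, which is how it is tested). Matching is exact — no
mismatches — because inputs are assumed quality-trimmed and exactness makes
the detector equal to a brute-force enumeration oracle. Minus-strand
geometry is computed by running the same forward-frame algorithm on the
read's reverse complement and labelling the hits `-`.

Decisions where the problem itself is underdetermined:

- **Linear veto.** A read that places contiguously anywhere (either strand)
  is linear, even if a split interpretation also exists. This is
  conservative: the inverse-order signature is only trusted when no
  colinear explanation exists. It is also the fast path — most reads are
  linear and cost one or two hash lookups.
- **Ambiguity.** Per split, if *both* parts are multi-placed the split is
  discarded (repeat-derived junction pairs would explode combinatorially);
  if at least one part is unique, one hit per placement pair is emitted.
  Multiplicity is counted among forward-frame placements within the strand
  pass being evaluated.
- **Micro-homology.** When the genomic neighbourhood of the closure point
  repeats the circle's terminal bases, several splits of one read describe
  the same junction — these are deduplicated per read (leftmost split kept).
  Shifted variants `(s±δ, e±δ)` that are genuinely distinct exact
  interpretations are all emitted; the ±5-nt clustering downstream absorbs
  them, and the modal (true) junction wins the representative because reads
  with the shortest admissible arm support only it. Cluster read counts are
  therefore junction *observations*, and the conservation invariant is
  Σ cluster counts = number of emitted hits.

## Aggregation and filtering

Grouping "similar junctions within five nucleotide variations" is
implemented as greedy count-weighted seeding: the highest-count unassigned
junction (ties: smaller start, then end) becomes a representative and
absorbs unassigned junctions with both endpoint deltas ≤ 5 on the same
chrom/strand. Seeding was chosen over single-linkage because chaining could
merge junctions arbitrarily far apart; the representative is the modal
junction, matching how a group is reported as a single coordinate pair.
Filters follow the library type: total-RNA clusters need ≥100 reads;
small-RNA clusters need ≥20 reads and a predicted length ≤10 kb (the length
cap applies only to small-RNA libraries, where a multi-kb "circle" is
almost always a rearrangement artefact rather than a small RNA). Failed
clusters are kept with their reason, never silently dropped.

## Knockout comparison

The published comparison labels loci "absent or significantly reduced"
without a numeric rule; with one biological replicate per strain no
statistical test is available. The package operationalizes it as
`circ_ko < depletion_ratio × circ_wt` with `depletion_ratio = 0.05`. On the
packaged 31-locus survey this reproduces the published 24/7 split exactly,
and the split is insensitive to the threshold anywhere in [0.05, 0.40]
(largest depleted ratio 0.044, smallest retained 0.419), so the call does
not hinge on the specific value. WT loci that passed filters are matched to
knockout clusters within the grouping tolerance *regardless of the knockout
cluster's own filter status*: residual knockout counts below the count floor
are exactly the signal being measured. Only small-RNA counts drive the call.

Expression comparison uses RPKM = count × 10⁹ / (total_mapped × length),
with the companion rules: RPKM < 1 floored to 0; genes < 2 RPKM in both
samples omitted; differential expression strictly >2-fold (a floored 0 on
one side takes its direction from the other side, which omission guarantees
is ≥ 2). Gene counting uses the package's own contiguous exact full-length
placement, fractional (1/n) for multi-placed reads; it does not replicate
any particular external counter's overlap semantics. Coverage tracks use the
same placement rule, and a knockout track can be rescaled by the ratio of
total placed reads so both tracks sit on the wild-type scale.

## C/D box annotation and terminal stems

Motif scanning is a literal consensus match (C box RUGAUGA with R ∈ {A,G};
D box CUGA), overlaps allowed. Box roles are assigned positionally: a C box
must start in the 5′ third and a D box in the 3′ third for the locus to be
called a C/D box sRNA; internal consensus matches become C′/D′. The thirds
rule is this package's choice — box positions in the source material are
marked but not given a rule.

The terminal stem is scored as the gapless outermost-in run of complementary
pairs between the 5′ window and the reversed 3′ window (default window 8 nt,
termini of these sRNAs being short GC-rich stems), not as a thermodynamic
fold: the quantity of interest is an integer pairing count feeding a ≥3
vs ≤2 dichotomy, and no gapped/energy model is needed to express it. G:U
wobble pairs count by default (RNA duplex chemistry) and can be switched
off. Note an asymmetry worth knowing: with Watson–Crick pairs only, the
score is exactly invariant under reverse complement (the termini swap and
complement, and WC pairing is preserved); with wobble enabled it is not, as
a G:U pair maps to C:A. The invariance property is therefore stated and
tested for the Watson–Crick-only setting.

## Synthetic data

The generator emulates the study conditions: a 100-kb random genome; 20
circular C/D-box-like loci of 61–71 nt with GC-rich designed stems of 3–6
Watson–Crick pairs terminated by a guaranteed non-pair (so the designed and
measured stem counts agree exactly, wobble or not), C box immediately after
the 5′ stem, D box just inside the 3′ stem; 10 non-circular C/D loci with
stems broken to 0–2 pairs; 50 linear genes of 200–1000 nt; and one 1.2-kb
rRNA-like locus whose central 40 nt are excluded from read generation,
mimicking the coverage hole left by an excised helix. Loci are placed
non-overlapping with 30-nt padding and either strand; every k-mer of a
circular locus is forced unique genome-wide (regenerating the locus on
collision) so planted junctions are unambiguous by construction.

Reads are 51-nt single-end. Each locus has unit abundance; a circular locus
splits its weight between junction-spanning reads (fraction 0.5 — a read
drawn uniformly from a ~66-nt circle crosses the closure point about three
quarters of the time, and 0.5 keeps both read classes deep) and contiguous
reads. Junction reads are rotations of the circle with both arms ≥ 20 nt,
exactly the geometry the detector inverts. The knockout sample multiplies
circular-locus junction weight by `ko_circ_ratio = 0.01`, leaving everything
else untouched — matching the near-total loss of C/D box circles with a
small residue. Default 200,000 reads per sample gives ≈1,200 wild-type
junction reads per circle (well above the count floor of 20) and a knockout
ratio ≈0.011, comfortably inside the depletion threshold. Per-base
substitution errors default to 0 so planted truth is exact; an error mode
exists for sensitivity exploration only. Base-call errors are drawn from a
stream separate from position sampling, so enabling them perturbs sequences
without moving where reads were drawn.

What the simulation does *not* model: base-quality profiles, ligation or
structure-dependent coverage bias, paired-end fragment geometry, expression
heterogeneity between loci, and real intergenic transcription. Passing the
planted-truth tests therefore demonstrates correctness of the algorithms
under clean, unique-sequence conditions, not performance on real libraries
with repeats, errors and uneven coverage.

## Problem sizes and determinism

The test suite runs the full default simulation (100-kb genome, 2 × 200k
reads) end to end; the oracle-equivalence suite covers 1,000 random
genome/read cases up to 20 kb. All randomness flows from explicit seeds
(numpy `default_rng`); identical configurations are bit-reproducible, and
hypothesis-based property tests run derandomized.

## Known limitations

- Exact matching only: a single sequencing error in either segment loses the
  read. This is deliberate (oracle-exactness) but underestimates counts at
  realistic error rates.
- The depletion rule is a ratio threshold, not a test; with one replicate,
  counts near the threshold (or tiny wild-type counts) produce fragile calls.
- The stem score ignores bulged or interrupted stems; a locus pairing
  3+ bases after a single terminal mismatch scores 0.
- Junction counts include micro-homology variants of the same read (see
  above); they are comparable across samples but are not exact read tallies
  at loci with repetitive closure points.
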