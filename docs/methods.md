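# Methods

## Region model and peak classification

A gene set partitions each chromosome into five classes. For a gene with
TSS *t* on the + strand, Up2k is the closed interval [*t* − 2000, *t* − 1]:
strictly upstream, so the TSS itself belongs to the gene body (exon).
Down2k is [tes + 1, tes + 2000]. Minus-strand genes mirror both. Exons and
the introns between them tile the body; every uncovered position is
intergenic. Flanks are clipped at chromosome ends.

Where regions of different genes overlap, a position takes the
highest-priority class in the order Up2k > Down2k > exon > intron >
intergenic. The rationale is biological: the question these classifications
answer is "is this a promoter peak?", so promoter assignment must win ties.
Under this rule the five classes partition the genome exactly (property
test: index lookups equal a brute-force per-position scan over all gene
features).

A peak is classified by its midpoint, `(start + end) // 2` in 1-based
coordinates. Midpoint classification is deterministic, respects the
partition, and is insensitive to peak-width conventions; any-overlap rules
would let one peak carry several classes.

Coordinates on the public dataclasses are 1-based fully closed — the
convention of genome browsers and of `assembly:chrom:start:end:strand`
strings, whose length is end − start + 1. The interval index converts to
0-based half-open internally (intervaltree convention).

## Fold filtering and intersection

Fold enrichment is the depth-normalised count ratio with a pseudocount
(default 1) added to both counts, which keeps the ratio finite when the
control count is zero at minimal bias. "Over 2-fold" is implemented as
strictly greater than the threshold, with an `inclusive` switch.

The two filtered sets (fold vs IgG, fold vs input) are intersected by
genomic overlap of at least `min_overlap` bp (default 1). Pairing is
greedy: candidate pairs sorted by overlap length descending, then leftmost
start, then peak id; each peak joins at most one pair. The ordering makes
the result independent of input order. Raising the threshold is monotone:
it can only shrink the pass sets and the intersection.

## Degenerate motif algebra

A pattern is an ordered tuple of allowed-base sets; bracket groups keep
their written base order so parse and render round-trip. A set containing
all four bases is canonically the wildcard (`x`). The reverse complement
reverses position order and complements each set, an involution. Note the
strict reverse complement of `CCTC[AT][GC]CC[TA]CC[CT]` is
`[GA]GG[AT]GG[CG][TA]GAGG`; the looser published form
`[GA][GA][GC][AT]GG[CG]xxAGG` can be supplied verbatim as its own pattern,
and both are exercised in the tests — the strict algebra and the published
matching claim are different patterns and are kept distinct rather than
reconciled.

Scanning tests every window of pattern length on the forward strand and,
for double-stranded scans, the reverse-complement pattern with hits mapped
to forward coordinates. `N` in a target satisfies only wildcard positions.
Sequence classification is EXACT on any full-length hit; otherwise the
longest contiguous run of satisfied pattern positions over all alignments
(pattern overhangs allowed) decides PARTIAL at `partial_min` (default 7,
the length of the shortest published partial promoter hit) versus NONE.
Ties break to the longest run, smallest offset, then the + strand.

## Lectin-array protocol

Background statistics are computed per block by default (matching the
per-block normalization; per-slide scope is a flag — which scope the
original protocol used is not derivable from its description, and the two
differ only by block-mean differences). The validity rule is implemented
as: a spot is effective iff raw foreground ≥ mean(background) + k·SD
(k = 2 default). A "± 2 SD" removal cannot define a single cut; the + side
is the conventional microarray effectiveness criterion, and k is exposed.
A single background point leaves SD undefined; it is treated as 0 with a
warning. Raising k never increases the effective-spot count.

Per block, each lectin's median over effective corrected spots is divided
by the block's sum of medians, giving NFIs that sum to 1 (checked to 1e−12
over random blocks) and are invariant to scaling all foregrounds of a
block. Blocks with zero effective spots are dropped with a logged reason.
Aggregation reports mean, sample SD (ddof = 1), and block count per lectin
over the nine blocks of the default 3-slide × 3-block design.

Differential calls compare mean NFIs (treatment/control) and test the
per-block paired differences with a two-sided paired t-test, pairing
blocks by (slide, block) index — block-level pairing (n = 9) rather than
slide-level (n = 3) because the replicate unit of the normalization is the
block. A lectin is UP or DOWN only when the tier's fold criterion and
p < 0.05 both hold. Two tiers are first-class: STRICT (≥ 2.0 / ≤ 0.5,
inclusive) and REPORTED (> 1.5 / < 0.67, exclusive). No multiple-testing
correction is applied by default, matching bench practice for 37 features
with planted-effect validation; this is a known limitation for discovery
use.

Because NFIs are compositional, planting a raw fold *f* on one lectin
changes the block sum: the recoverable NFI fold is
*f* · (Σ control medians / Σ treatment medians). The generator's truth
record carries both the raw planted folds and these expected NFI folds,
and exact-recovery tests assert against the latter.

## Quantification formulas

2^−ΔΔCt averages replicates on the Ct scale before differencing
(ΔCt = target − reference per condition, ΔΔCt = treated − control). The
result is invariant to a common Ct shift and is exactly the planted ratio
on zero-noise synthetic tables. ChIP-qPCR enrichment is
2^(Ct_IgG − Ct_IP); the percent-input path
(2^(Ct_input − Ct_arm) per arm, then the ratio) is provided and equals the
direct form whenever the input is shared — verified numerically on random
Ct triples. Whether the original workflow normalised to input first is not
stated; both paths give identical answers under a shared input, so the
choice is immaterial there. Dual-luciferase activity divides both firefly
and Renilla by (cells/1000) before the firefly/Renilla ratio — the scaling
cancels within a well, and relative activities are invariant to common
per-well scaling; the control construct is 1 by definition.

## Synthetic-data generators

Each generator draws from an independent stream (`default_rng([tag, seed])`),
so generator calls never perturb one another and identical (parameters,
seed) give identical output.

*Gene models*: bodies of 3–9 kb with 1–4 exons (intron-containing genes
are the majority), placed with a minimum body gap of 4,000 bp so that the
2 kb flanks of neighbours can never overlap — planted region classes are
then unambiguous. Requests exceeding chromosome capacity raise an explicit
error.

*Peak experiments*: peak loci of 100–400 bp placed wholly inside candidate
intervals of their class, mutually non-overlapping so that set
intersection cannot mispair them. Signal folds are drawn from [2.5, 8.0]
and sub-threshold folds from [0.5, 1.9] — conventions, since no noise or
depth characteristics of the original experiment are published. A class
count may be an integer (split by `frac_common`) or an explicit
(common, M1-only, M2-only) triple; an "M1-only" locus appears in the M2
list with a sub-threshold fold, the way a real peak fails one contrast.

*Lectin arrays*: 37 lectins × 3 slides × 3 blocks × 3 spots, per-lectin
base signal log-uniform over 10^3–10^4.5 a.u., background Normal(100, 10)
a.u., multiplicative Gaussian spot noise at CV 5% by default. Each block's
foregrounds carry that block's realised mean measured background, so
averaged-background subtraction is exact by construction and the zero-noise
limit recovers planted folds to machine precision. What the generator does
not emulate: spatial gradients within slides, saturated or smeared spots,
lectin-specific background binding, and print-batch effects — recovery
results on synthetic data therefore bound algorithmic correctness, not
robustness to those artefacts.

*Ct tables*: a planted ratio *r* enters as a −log₂ *r* shift of the target
Ct in the treated condition over a per-gene baseline 2–8 cycles above the
reference gene (base Ct 18), with per-replicate Gaussian noise in cycles.

*Motif sequences*: uniform-background sequences with pattern realisations
planted at non-overlapping random offsets and strands. Chance background
matches can occur in addition to the plants; the guarantee is that every
planted occurrence is present and recorded.

## Problem sizes

The test suite and the acceptance script run the pipeline at reduced but
structure-preserving sizes chosen as a deliberate design point: hundreds of
genes on megabase-scale chromosomes, a few hundred planted peaks, 200
random 500-bp sequences for the scan oracle, 100 Monte-Carlo seeds for the
differential-call rate, 1,000 random blocks/patterns for the algebraic
properties. All properties asserted are size-free (partitions, involutions,
exact recovery), so nothing about them depends on the reduced scale.
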