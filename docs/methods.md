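# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic data do and do not emulate, and the
problem sizes used by the test suite and the acceptance script.

## Catalog and coordinates

A hairpin catalog is a list of pre-miRNA loci, each with a sequence and
up to two mature-arm intervals, 1-based inclusive, on the hairpin.
Arms are named 5p/3p by position (the earlier-starting arm is 5p); a
source annotation whose declared arm name contradicts its position is
rejected rather than silently renamed, because arm-switch detection is
meaningless if positional identity drifts. Two annotation dialects
(GFF3 with `miRNA` children of `miRNA_primary_transcript`, and a flat
six-column TSV) normalize to the same internal object, and writers
round-trip exactly.

## Quantification

Trimming removes the 3′ sequencing adapter — a full-adapter hit
anywhere in the read, else the longest read-suffix/adapter-prefix
overlap of ≥ 8 nt — then trims 3′ bases with Phred quality below 20,
and keeps reads of 18–33 nt (the insert range of the small-RNA library
protocol). The 8-nt minimum overlap keeps the false-positive rate of
suffix clipping below 4⁻⁸ per read while still catching adapters
truncated by quality trimming.

Assignment aligns the read ungapped at every offset of every hairpin
(sense strand only; small-RNA libraries are stranded) and keeps hits
with ≤ 2 substitutions, fewest-mismatch first. "Two mismatches" is read
as substitutions because the read is matched *within* the hairpin;
indel-tolerant matching is reserved for the genomic motif scan, where
cross-species divergence makes it necessary. A hit is attributed to an
arm when the read 5′ end lies within 3 nt of the annotated arm start —
wide enough for common 5′ isomiRs, narrow enough that the two arms of a
hairpin are never confusable (arms are ≥ 20 nt apart). Hits inside the
hairpin but outside both arm windows (e.g. loop fragments) are counted
as unassigned. Equal-mismatch hits on different loci are resolved by a
seeded uniform draw so that counts remain integers for the NB stage;
fractional assignment would break the count model downstream.
`reads_kept = assigned + unassigned` holds per sample by construction
and is asserted in tests.

## Differential expression

Size factors follow the median-of-ratios convention: the reference for
each arm is its geometric mean across samples (over arms with no zero),
each sample's factor is the median ratio to the reference, and factors
are rescaled to geometric mean 1. When no arm is positive everywhere, a
pseudo-reference over arms positive in ≥ 50% of samples is used with
zeros skipped. The median is taken in ratio space (for an even number
of arms this differs in the ~4th digit from exponentiating a log-space
median; the ratio-space form is the stated formula and is what the
brute-force oracle computes).

The test is a per-arm NB Wald test. Dispersion α (var = μ + αμ²) is
estimated by moments from the pooled within-group variance of
normalized counts (unbiased, df = n_a + n_b − 2), floored at 1e-8, and
shrunk 50/50 toward a trend α(μ) = a₀ + a₁/μ fitted by least squares
across arms — a parametric mean–dispersion trend in the spirit of
standard RNA-seq practice, which stabilizes the noisy 15-sample moment
estimates. log₂FC uses group means of normalized counts with a +0.5
pseudo-count so all-zero groups stay finite; its variance comes from
the NB variance of a group mean (Var(k̄) = Σⱼ(μ/sfⱼ + αμ²)/n²) by the
delta method, and the two-sided p from the normal reference. Arms at
zero in both groups carry p = 1. Measured on 1000 null arms (8 vs 7,
α = 0.1) the type-I error at p < 0.05 is ≈ 0.06 — the normal reference
is mildly anticonservative at this sample size, within the intended
0.05 ± 0.02 calibration band.

Activity is strict: mean normalized count over the union of the
compared samples > 10. The "mean across samples" reading (rather than
per-sample) is a declared choice; the activity filter runs before
testing and BH adjustment runs over the tested arms only. No
fold-change threshold is applied anywhere.

## Arm switches

A locus is called a switch when the locus-level (5p+3p) test is
non-significant (BH p_adj ≥ 0.05), both arms are individually
significant, and the arm log₂FCs have opposite signs. The stability
criterion is deliberately a non-significance test, not an equivalence
test — it mirrors treating a locus-level p of 0.43 as "no change"; a
TOST-style equivalence variant would need an equivalence margin no one
has stated. A stricter `dominance_flip` flag (the prevalent arm
actually changes between groups) is reported alongside. Loci with a
single annotated or single active arm are excluded and listed, not
treated as infinite switches.

## Convergence and enrichment

Signed-set overlap splits shared ids into concordant/discordant by
direction and attaches the hypergeometric upper-tail p of the total
overlap against a stated background universe (default: arms active in
either comparison; the choice of universe is configurable since no
canonical one exists). PCA runs on feature-centered log₂(normalized
count + 1), scores from SVD; each component's sign is fixed so its
first nonzero loading is non-negative, making ordinations reproducible
across BLAS implementations.

The hypergeometric tail is computed term-by-term in log-space (lgamma)
and summed with compensated summation; the printed factorial form
overflows naively around N ≈ 170. An exact rational mode exists for
small N and is cross-checked against full enumeration of all C(N,n)
draws up to N = 12, and against scipy at scale. Per-miRNA enrichment
uses the genes-with-any-target-site universe; DEMs with no mapped
targets get p = 1 and a flag rather than being dropped silently.

## miR-430 copy number

Motif scanning uses infix (semi-global) edit distance ≤ 2 via the edlib
library — substitutions *and* indels, matching the behavior of an
edit-distance engine and cross-checked in tests against a hand-rolled
per-position DP. Both strands are searched and a read counts at most
once. The estimator is

    copies per haploid genome = h · g / l,     SE = √h · g / l,

with h motif-containing reads, l total read bases, g genome size; h and
l are additive over batches of reads.

**Validity condition.** The estimator implicitly assumes every read
overlapping a motif copy is counted, but a read only matches when it
covers at least motif length − max_edits bases of the copy — overlap
≥ 20 nt of a 22-nt motif at ≤ 2 edits. The expected estimate is
therefore biased by the factor (L − k + 1 + 2e)/L for read length L,
motif length k and edit budget e: about 0.83 at L = 100, 0.98 at
L = 1000. Recovery experiments in this package use 1000-nt error-free
reads so that this edge term stays below the Poisson noise; the
generator's default stays at Illumina-like 100 nt, where users should
expect the corresponding underestimate on real short reads (a caveat
that applies equally to any h·g/l-style estimate).

The recovery experiment plants 20 copies of one motif in a 1 Mb
uniform-ACGT genome at 10× coverage and scores each of 20 seeds against
± 3 Poisson SE of the planted value (√(20/coverage) ≈ 1.41, a fixed
band) plus a bias bound of 1 copy on the across-seed mean. The
background genome is uniform i.i.d. ACGT with non-overlapping
insertions — no repeats, GC skew or quality model — which makes the
spurious-hit probability of a 20–22-nt motif at ≤ 2 edits negligible
(< 10⁻⁴ per megabase-read-set) and planted truth exactly scorable.

Group comparisons use a two-sided Wilcoxon rank-sum test. W is the
Mann–Whitney U of the first group; the exact null distribution of U is
built by the standard counting recurrence (dynamic programming over
C(n+m, n) rank assignments), used whenever there are no ties and
n + m ≤ 30, with p = min(1, 2·min(tails)). With ties or larger samples
the normal approximation with tie and continuity correction is used.
The exact path reproduces the published genus-contrast p-values to all
printed digits — 0.002089 for group sizes (10, 10) at W = 11 and
0.01176 for (4, 14) at W = 5; note these are the sizes consistent with
those p-values.

## Synthetic counts

The count generator draws per-arm baselines log-normally
(log₂ mean 6, sd 2 by default — spanning the low/moderate/high
expression tiers seen in small-RNA libraries), NB dispersion per arm
log-uniform on [0.01, 0.5] (typical small-RNA overdispersion) or fixed
for calibration, and samples counts by a gamma–Poisson mixture.
Planted DEMs multiply the group_a mean by 2^±lfc (default lfc = 2);
planted switches set the 5p fraction of a locus to 0.7 in group_b and
0.15 in group_a while the locus total mean is preserved exactly — a
dominance inversion, the pattern the switch detector is meant to find.
The default design is 8 vs 7 samples, the study's annual-diapause vs
non-annual library counts. The FASTQ generator emits each arm's reads
at exactly its requested abundance (deterministic, so end-to-end
quantification recovery can be checked exactly), with the RA3 adapter
appended and Q38 qualities (optionally degraded 3′ tails); it does not
model ligation bias, PCR duplication or chimeras.

What passing these simulations shows is that each stage recovers what
it is defined to recover under its own model assumptions — NB counts,
uniform errors, stranded single-locus reads. Real libraries add
cross-mapping between paralogous loci, composition-dependent biases and
non-NB dispersion structure, so planted-truth recall here is an upper
bound on real-data performance, not an estimate of it.

## Problem sizes and determinism

The default test suite runs in under a minute on one CPU: DE
calibration uses 1000 arms (500 loci), switch recovery 520 loci with 20
planted switches, copy-number recovery 20 seeds of a 1 Mb genome at
10×, quantification ~1000 reads over a 25-locus catalog. Every
generator takes an explicit seed; the pipeline derives per-stage seeds
from the global one through a fixed affine map, so stages can be rerun
independently and a fixed config reproduces byte-identical outputs
(hashed in the run manifest).
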