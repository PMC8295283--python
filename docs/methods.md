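# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind each module. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinates and gene models

All intervals are 0-based half-open internally; GTF import/export
translates to 1-based inclusive, and BED export stays 0-based half-open.
A gene model holds one or more transcripts, each with sorted
non-overlapping exons and a CDS contained in them; each transcript's CDS
length must be positive and divisible by 3. A gene's *length* is the span
from its first transcription start to its last transcription end across
all isoforms — the definition used for ChIP gene-body normalization.
Constitutive exons are the maximal intervals present in every isoform's
exon set.

## Guide design

Candidate sites are all 20-nt protospacers, on either strand, with an NGG
PAM and a blunt cut (3 bp 5′ of the PAM, between protospacer positions 17
and 18) falling strictly inside the gene's exonic CDS. The CDS-percent of
a cut is the number of coding bases 5′ of it in translation order divided
by total CDS length, evaluated on the longest-CDS transcript containing
the cut; it is evaluated at the cut site, not the spacer span, because the
lesion forms at the cut.

Off-target profiling counts genomic NGG-adjacent sites at 0, 1 and 2
mismatches over the 20 protospacer bases (PAM N free). The on-target site
is included in the 0-mismatch count, so a unique guide reads (1, 0, 0).
Genomic N bases never match any spacer base (conservative). The counting
index is a vectorized mismatch matrix over all PAM-adjacent windows; a
naive full-genome scan is kept in the test suite as the oracle.

The microhomology out-of-frame score enumerates all repeats of length ≥ 2
straddling the cut within a ±30 nt window (truncated at contig edges).
A repeat at left position *i* and right position *j* of length *k*
implies a deletion of length *j − i* and scores
`100 · exp(−(j−i)/20) · (#AT + 2·#GC)`; repeats wholly contained in a
longer repeat with the same implied deletion are dropped. The score is
100 × (sum over deletions with length mod 3 ≠ 0) / (sum over all), i.e.
the predicted fraction of microhomology-mediated deletion products that
shift the reading frame. The 30-nt flank matches the context length the
original scoring tool uses; the score is invariant under
reverse-complementing the window (property-tested).

Selection applies five rules in order, each only if fewer than six guides
have been found: (1) constitutive exon, CDS 5–50%, mismatches (1,0,0),
out-of-frame > 60; (2) constitutive, CDS 5–80%, (1,N,N), OOF > 60;
(3) any exon, CDS 5–80%, (1,N,N), OOF > 60; (4) any exon, CDS 5–80%,
(N,N,N), OOF > 60; (5) no constraints. Within a tier, candidates are
ordered by out-of-frame score descending, then CDS-percent ascending,
then genomic coordinate — a deterministic tie-break preferring
frameshift-prone, 5′-biased cuts. Genes with no candidate after tier 5
are flagged undesignable.

Oligos are exactly 80 nt: fixed PCR handles, two SapI cassettes, and the
spacer with a 5′ G prepended *only when it does not already start with G*
(the alternative — unconditional 21-mers — is equally consistent with the
protocol text; the conditional form keeps the assayed spacer literal).
Simulated SapI digestion (cut 1 nt beyond the recognition site, 3-nt 5′
overhangs) must release the insert with the defined overhangs; spacers
containing a SapI site are rejected as self-cleaving. Non-targeting
controls are random 20-mers verified to have zero 0/1/2-mismatch hits in
the design genome.

## Screen deconvolution

Reads yield a spacer when the 5′ vector adapter occurs (≤ 1 mismatch) and
is followed by ≥ 20 nt preceding the gRNA scaffold (≤ 1 mismatch); the
variable region between the anchors is the (possibly G-extended) spacer.
Counting is an exact dictionary match against the designed 20-mers, with
a 21-mer starting with G matched on its trailing 20 bases; unmatched
spacers are tallied as unassigned, so reads = assigned + unassigned +
discarded per sample. Dictionary matching replaces alignment + interval
coverage; for uniquely designed spacers the two are equivalent and the
aligner dependency disappears.

Sample QC applies three criteria whose numeric thresholds are package
defaults (the published analysis names the criteria but not the numbers):
positive-control log2 enrichment ≥ 1 in sorted samples (summed normalized
abundance of the spiked guides versus the input mean), clustering margin
> 0 (mean Pearson r with own role group minus mean r with the other, on
log1p median-of-ratios-normalized counts), and detected-guide fraction
≥ 0.5. All three are exposed in `QCThresholds`. A role with a single
sample leaves the clustering metric undefined and flagged rather than
failed. Note that a sample replaced by a random permutation of
another-role sample decorrelates from *both* groups, so its clustering
margin is sign-indeterminate; it reliably fails QC through the
control-enrichment criterion instead, and the clustering criterion is
exercised with a mislabeled (other-role-like) sample.

## Guide and gene statistics

Size factors are median-of-ratios: per sample, the median over
all-nonzero feature rows of count / row geometric mean (falling back,
with a warning, to rows nonzero in ≥ 90% of samples). The guide test is a
negative-binomial log-linear model with sample role as the only
covariate. Dispersion is estimated per guide by method of moments within
each role group (pooled, weighted by degrees of freedom), then shrunk
50/50 in log space toward a log-linear mean–dispersion trend and clipped
to [1e−8, 20]. Group means are exact MLEs at fixed dispersion via Fisher
scoring; the Wald statistic is log2FC divided by its information-based
standard error, tested against a normal null, with BH correction across
testable guides. No pseudo-counts: guides that are all-zero overall or
within a group are flagged (`all_zero`/`group_zero`) and excluded from
the BH denominator. Cook's filtering, LFC shrinkage and independent
filtering are deliberately out of scope — the screen readout rests on the
Wald core.

Two numerical caveats are inherent to this model class and documented by
tests rather than hidden: (i) multiplying one sample's counts by a
constant is absorbed by its size factor only up to terms of order the
score-weight change, so statistics agree to ~1e−2, not machine precision;
(ii) in a screen with many strongly enriched guides, median-of-ratios
leaves a small compositional shift on null guides (the median guide is no
longer strictly unchanged) — the type-I error band is therefore defined
on a null screen, where the measured rate at nominal 0.05 is ≈ 0.05–0.06.

Gene aggregation is α-restricted robust rank aggregation: guides are
ranked by one-sided p (from the signed Wald statistic) across the whole
library, controls included; for a gene with *m* guides of which *j* pass
the α threshold, ρ = min over k ≤ j of the Beta(k, m−k+1) CDF at the k-th
smallest normalized rank, and the gene p-value is the fraction of
permuted same-size guide sets (guide-to-gene assignment permuted,
guides-per-gene preserved, seeded; exhaustive enumeration available for
small instances) with ρ at least as small, with a +1 correction. The
uniformity of the permutation p under a null library is verified with all
guides contributing (α = 1): with the screen's operating α = 0.001 almost
no null guide passes the restriction, every gene collapses to ρ = 1, and
no p-value distribution could be uniform — the restricted score is a
detection statistic, not a calibrated null test.

## ChIP scoring

H2Bub1: size factors are computed jointly across all ChIP replicates and
inputs of all stages (so stages share a scale), counts are divided by
gene length in kb, replicates averaged, and the identically processed
input subtracted; a gene is occupied when its signal is positive, and the
maturational delta is adult minus neonatal signal. Negative
post-subtraction signals are retained (no clipping) so deltas stay
linear. Because the median-of-ratios reference is the median gene,
subtraction zeroes the median gene; occupancy is therefore meaningful
when a substantial background (non-enriched) gene population exists, as
in real annotations. Input subtraction happens after replicate averaging
for every mark, applying the one explicitly stated ordering uniformly.

H3K4me3 works on per-TSS maximum per-base window coverage (±1 kb),
converted to the RPKM scale as coverage × 1e9 / library size, replicate
averaged, input subtracted; each gene keeps its best TSS and is retained
above 500 RPKM. H3K36me3 is gene-body RPKM (count × 1e9 / (library size ×
gene length)), replicate averaged, optionally input subtracted (the
published scheme does not subtract input for this mark; the argument is
accepted for interface symmetry); the retained set is the top 20% by
score with ties broken by gene id, giving exactly ⌊0.2·n⌉ genes. Both
RPKM schemes are exactly invariant to scaling a library's counts and
size together.

## Integration

Maturational and knockout fold changes reuse the NB-Wald core on gene
counts. The adult- and neonatal-specific sets are the top/bottom 100
genes by maturational log2FC (ties by gene id). Preranked GSEA uses the
weighted running sum with weight exponent 1; the null permutes gene
labels (random same-size sets), the nominal p compares against same-sign
null ES values, and NES divides ES by the mean same-sign null magnitude.
The running-sum extremum is evaluated only adjacent to hits, with
equal-magnitude ties resolved to the first extremum in ranking order.
The ≥ 30-member floor is enforced at the API with an override for
small-instance verification.

Quadrant classification requires |KO log2FC| > 1 ("more than 2-fold"),
KO adjusted p < 0.05 (the display is restricted to differentially
expressed genes; both thresholds configurable), and both maturational
deltas defined; quadrants follow the signs of (ΔRNA, ΔH2Bub1). For each
quadrant the 2×2 tables of KO-down (and KO-up) inside versus outside are
emitted with Fisher exact results: the standard two-sided p (sum of
table probabilities ≤ observed) plus both one-sided tails, since the
published tests' sidedness is unstated; odds ratios use the Haldane 0.5
correction when a cell is zero. ΔRNA binning uses left-open right-closed
intervals and box summaries with whiskers at quartile ± 1.5 IQR.

## Synthetic data

One root seed spawns an independent child stream per artifact, so the
same seed reproduces every output byte and adding an artifact never
perturbs the others. Negative-binomial draws are gamma–Poisson mixtures
with var = μ + αμ².

The generated genome packs non-overlapping genes on alternating strands
with ≥ 1 kb spacing; exons are fully coding with lengths divisible by 3
(so any exon subset is a valid CDS), and extra isoforms drop one internal
cassette exon, guaranteeing non-trivial constitutive-exon structure.

The default screen is 500 genes × 6 guides + 7 non-targeting controls,
50 hit genes at log2FC 3 with per-guide Gaussian efficacy noise (sd 0.5,
making rank aggregation non-trivial), a 4-guide spiked positive-control
"gene" at log2FC 5 (the analogue of the spiked dual-gene positive-control
virus), NB dispersion 0.1 across screen samples and one million reads per
sample. Guide representation varies log-normally around the even pool,
and sorted means are input means × 2^(true log2FC) without
renormalization, so non-hit and control guides keep equal expected
representation in both roles. Effect sizes are recovery-test
placeholders, not estimates of the underlying biology, which the source
data do not constrain.

The multi-omics generator draws per-gene (ΔH2Bub1, ΔRNA) from a bivariate
Gaussian with correlation 0.4 by default (the simulation analogue of the
observed between-stage correlation of 0.39); the neonatal H2Bub1 level is
log-normal and the adult level adds the delta, floored at a small
positive value (the floor touches ~1% of genes and moves the realized
correlation by < 0.01). Under the `oppose_maturation` knockout rule, the
KO log2FC is −0.8 × ΔRNA plus noise, planting the upper-right-quadrant
KO-down enrichment. ChIP replicates use dispersion 0.02 and RNA
replicates 0.05 — biological replicates of these assays correlate far
better than independent screen samples — with ~10M gene-body ChIP reads
and ~5M RNA reads per sample. H3K4me3 promoter coverage is log-normal,
calibrated so ~20% of genes clear the 500-RPKM floor after input
subtraction. The generator does not emulate sequence composition effects
(GC bias, mappability), read-level ChIP/RNA data (counts are drawn
directly; only screen reads are emitted as FASTQ to exercise trimming),
isoform-level expression, or spatially structured background — so
passing recovery tests demonstrates correctness of the estimators under
the stated count model, not robustness to alignment artifacts or
batch structure in real data.

## Problem sizes

The test suite and acceptance script run at: 10-gene / 80-kb genomes for
design, ≤ 1 Mb genomes for off-target oracles, a 1000-guide null screen
(14 vs 11 samples), the 500-gene default screen with 10,000 RRA
permutations, 5000-gene multi-omics simulations, and a 35,000-gene table
for the top-quintile cardinality check. These sizes keep the full suite
in the low minutes on one CPU while leaving every statistical check
well-powered.
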