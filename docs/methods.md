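# Methods

## The model

`dartk` treats the two cohorts of a differential-expression contrast as
two populations of diploid genotypes observed at SNP loci called from
the RNA-seq reads themselves. At each locus the group's allele content
is summarised by the proportion vector over the four bases, with `2n`
alleles reported for `n` genotypes called — allele counts come from
genotype calls only, never from read-depth (AD) fields, because the
quantity of interest is between-group *representation* of alleles, not
within-sample expression imbalance; an AD-based mode would conflate the
two and is deliberately not offered.

The differential allelic representation between groups is the Euclidean
distance between their proportion vectors divided by √2. The divisor is
the exact maximum of that distance over the 4-simplex (attained only by
two distinct vertices), which gives the metric its interpretable [0, 1]
range: 0 means identical allele proportions, 1 means the groups are
fixed for different bases. The metric is symmetric, zero only at equal
proportions, and maximal only at distinct fixations; the test suite
verifies all three properties and checks the computation against a
direct brute-force evaluation on 10⁴ random simplex pairs.

## Site filtering

Before the metric is computed, loci pass an exclusion cascade with
these defaults:

| rule | default | removes a locus when |
|---|---|---|
| strand bias (FS) | 60 | FS > 60 |
| quality by depth (QD) | 2 | QD < 2 |
| RMS mapping quality (MQ) | 40 | MQ < 40 |
| strand odds ratio (SOR) | 4 | SOR > 4 |
| SNP selection | — | REF or any ALT is not a single base |
| cluster artefacts | 3 SNPs / 35 bp | it lies in any 35 bp window holding > 3 SNPs |
| uninformative | — | no sample reports a non-reference allele |
| missingness | 0.5 | missing-call fraction > 0.5 in either group |

All numeric comparisons are strict, so a locus sitting exactly on every
bound survives. Two readings were genuinely open and were resolved as
follows. The QD rule is applied as a *fail-low* condition (QD < 2),
consistent with the convention of the variant-calling toolkit these
annotations come from, where low quality-by-depth marks unreliable
sites. The per-group missingness rule removes a locus when *either*
group exceeds 50% missing: a locus whose proportions are unusable in
one group cannot contribute a two-group comparison regardless of the
other group's completeness. Absent annotations pass the hard filters
(many VCFs omit SOR or QD); absences are logged rather than fatal.
The cluster filter removes flagged loci by default — dense local
variation usually reflects misalignment around diverged sequence rather
than real polymorphism — but a flag-only mode exists.

## Smoothing and gene assignment

Raw per-locus DAR is noisy and leaves variant-free genes unscored. The
elastic window averages each locus with up to `half_width` (default 5)
nearest variant loci per side, counted by rank along the sorted track
within one chromosome. Near chromosome ends the window truncates — no
padding, no wrapping — so terminal windows shrink from 11 down to
`half_width + 1` loci. Rank distance is unique, so no tie-breaking rule
is needed. Each smoothed value is materialised as the genomic span of
its window's outermost loci; this anchors regions on variant evidence
rather than on arbitrary fixed widths.

A gene's DAR is the unweighted mean of the smoothed regions whose
spans intersect the gene's `[start, end]` interval (1-based inclusive
throughout; the only 0-based conversion happens in the optional BED
export). Unweighted averaging is the simplest defensible rule; an
overlap-length-weighted variant was considered and rejected because
region lengths are artefacts of local variant density, not of evidence
strength. Genes overlapping no region carry an *absent* DAR — absence
of variant evidence is not evidence of allelic divergence — so they are
never excluded by thresholding and receive weight factor 1.

## Enrichment

The ranking statistic is `sign(log2FC) × −log10(p)` with `sign(0) = 0`;
p-values of exactly 0 in the input table are clamped to the smallest
positive double so the transform stays defined. The raw (not
FDR-adjusted) p-value feeds the statistic. DAR weighting multiplies the
statistic by `(1 − DAR)`. Exclusion removes genes whose DAR strictly
exceeds the threshold; the sweep runs thresholds 0.1–1.0 in 0.1 steps,
and at 1.0 nothing is excluded since 1 is the metric's maximum.

Gene-set significance uses classic permutation preranked GSEA: a
weighted Kolmogorov–Smirnov running sum with weight exponent 1 on the
absolute statistic, and a null of `n_perm` (default 10 000) random
same-size gene sets drawn without replacement from the ranked universe.
The p-value is `(1 + k) / (m + 1)` where `k` counts same-sign permuted
scores at least as extreme and `m` is the same-sign permutation count;
NES divides the observed score by the mean same-sign permuted
magnitude; FDR is Benjamini–Hochberg across tested sets; the leading
edge is the members at or before (after, for negative scores) the
running-sum extremum. Set-size bounds default to [5, 500]. Degenerate
cases: a zero enrichment score, or a sign with no permuted
representatives, yields p = 1 and NES = 0. When the positive and
negative excursions of the running sum tie in magnitude exactly (small
lists), the earliest rank within 1e−9 of the extremum wins, so the
choice cannot flip on floating-point rounding. This transparent engine
is the package's own; a split-sampling multilevel estimator and
rotation-based tests are intentionally out of scope, since the DAR
exclusion/weighting operates upstream of any enrichment engine.

Chromosomal co-location of DE genes is tested per chromosome with a
one-sided Fisher's exact test (hypergeometric upper tail — enrichment
direction only) over the expressed-gene universe, Bonferroni-adjusted
by the number of chromosomes holding at least one expressed gene.

Determinism: all orderings break ties by gene id ascending, every
stochastic step takes an explicit seed, permutation nulls are cached
per set size with sets processed in name order, and a full pipeline run
writes no timestamps — identical config and inputs give byte-identical
output bundles.

## The synthetic-data generator

The generator emulates the genetic structure the method targets: a
near-isogenic background (default divergence 0.05) with one linked
haplotype block of strong divergence (default 0.9 across
chr1:3,000,001–7,000,000), two groups of 8 diploid samples, 800 loci
over two 10 Mb chromosomes, 5% missing calls, 200 genes, and a DE table
with 15 eQTL-positioned and 15 unlinked true-response DE genes among
nulls. Group allele frequencies are set analytically from the target
divergence `d`: at a biallelic locus the per-allele frequency
difference is `d`, so the Euclidean distance is `d·√2` and the expected
DAR is exactly `d`. Allele counts per group are rounded expected counts
rather than binomial draws, so `d = 0` and `d = 1` produce raw DAR of
exactly 0 and 1; residual randomness comes from locus placement, base
identities, the frequency centre, genotype shuffling and missingness.

eQTL-type DE genes draw slightly smaller p-values (10^−U(5,9)) than
response genes (10^−U(3,6)), and DE fold-changes default to a coherent
(upregulated) direction. This models the regime the method exists for —
strong eQTL-driven signals competing with the true response at the same
end of the ranked list — and is the worst case for unweighted GSEA.

What the generator does *not* emulate: read-level noise, linkage
disequilibrium decay within blocks, multiallelic variation (simulated
loci are biallelic to keep the divergence-to-DAR inversion exact;
multiallelic handling is covered by hand-written micro-fixtures in the
tests), genotyping-error correlation with coverage, and realistic gene
density. Passing tests therefore demonstrate correctness of the
computational chain and its discrimination behaviour under idealised
genetics, not variant-calling robustness on real reads.

## Problem sizes and numerical choices

Tests and the acceptance script run the full synthetic pipeline at
800 loci × 16 samples × 200 genes with 100–1000 permutations, and the
statistical calibration checks pool 300 null gene sets at 200
permutations each — sizes chosen so the whole suite completes in a few
seconds while keeping binomial error bars meaningful (calibration
asserts use ±3 binomial SEs). Proportion vectors must sum to 1 within
1e−9; oracle equivalences are asserted at 1e−12; the DAR value is
clipped into [0, 1] against floating-point overshoot of the √2
division.

## Known limitations

Ploidy is fixed at two; haploid or polyploid calls are rejected at
parse time. Whole-file streaming (no index) bounds practical VCF size
but is ample at transcriptome-variant scale. Gene assignment is purely
positional; strand is read and carried but never used. The permutation
p-value floor is `1/(n_perm + 1)`, so very small FDRs require large
`n_perm`.
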