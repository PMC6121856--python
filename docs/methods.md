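# Methods

## Windowed differentiation

Input is a per-site table of alternate-allele counts for one population
pair (`chrom, pos, ac1, n1, ac2, n2[, depth]`, positions 1-based).  Windows
are fixed-size (default 100 kb), 0-based half-open, keyed `(chrom, start)`;
the last window of a chromosome may be short.

**F_ST.**  Per site, Hudson's components with sample-size correction:

    num = (p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)

combined per window as a ratio of averages, `Σnum / Σden` over the SNPs in
the window.  This single allele-frequency-based estimator applies both to
individual-based and pooled allele counts.  Sites with fewer than two
sampled alleles in either population are skipped (no within-population
variance information).  Negative window values are retained by default —
they carry the rank information the correlation analyses use — with an
optional clamp at 0.  Under Balding–Nichols sampling the ratio-of-averages
form is nearly unbiased for the planted F: with F = 0.1, 50 alleles per
population and 200 SNPs per window the mean window estimate is within
±0.02 of 0.1 (checked in the acceptance suite).

**d_XY.**  Per SNP, `p1(1−p2) + p2(1−p1)`; per window, the sum over SNPs
divided by the number of *callable* sites (variant and invariant).  A site
is callable when `3·sample_size ≤ depth ≤ 3·mean_depth` (mean over the
whole dataset): roughly three reads per individual at the low end, and a
copy-number guard at the high end.  Windows with ≤ 5000 callable sites are
reported missing — d_XY is highly variable when normalized by few sites.
Windows with no SNPs but sufficient callable sites are genuine zeros.
The windowed value equals the mean pairwise between-population difference
per callable site computed by direct haplotype enumeration (exact
identity, tested against the enumeration oracle).

**LD.**  Mean r² per window from a SNP-pair table; each pair is assigned
to the window containing the midpoint of its two positions, pairs more
than 100 kb apart are excluded, and a MAF > 0.05 filter applies when MAF
columns are present (otherwise it is assumed upstream).  LD is used only
as a GLM predictor; no MAF filter is applied to F_ST/d_XY inputs.

**Harmonization.**  All cross-pair analyses run on the intersection of
windows non-missing in every contributing pair, separately per statistic.
A pair with no data at all for a statistic (e.g. a reduced-representation
dataset that never clears the callable filter for d_XY) is dropped from
that statistic's analyses only.

## Repeatability

**Correlations.**  Pearson by default (its square is the variance
explained; Spearman available).  The bundled eight-pair example matrix
gives max r = 0.18 → 3% for F_ST and max r = 0.51 → 26% for d_XY.

**Outliers and overlap.**  Outliers are windows beyond a pair's own
empirical 5% tail (upper for F_ST, lower for d_XY), computed on the
harmonized universe with order-statistic thresholds so boundary ties are
included (the outlier fraction may slightly exceed 5%).  For two pairs
with a and b outliers on a shared universe of N windows, the observed
overlap k is compared with a hypergeometric null in which every window is
equally likely to be an outlier: E = ab/N, Var = ab(N−a)(N−b)/(N²(N−1)),
z = (k−E)/√Var, one-sided p = P(X ≥ k).  The hypergeometric variance was
chosen over the simpler binomial form.  Holm correction by default
(Benjamini–Hochberg optional) across the pair-of-pairs family.

**Peaks.**  Because adjacent outlier windows are not independent, maximal
runs of adjacent outliers on one chromosome are merged into peaks.  The
shared-peak statistic (count of A-peaks intersecting any B-peak; a
shared-window variant is available — the intersecting-peak count is the
default) is tested by relocating every peak of both sets uniformly at
random on its own chromosome, holding peak number and lengths constant,
1000 times, with the add-one p estimator `(1 + #{perm ≥ obs})/(n_perm+1)`.
Uniform non-overlapping placement uses compressed coordinates: offsets of
the (shuffled) blocks are sorted iid draws on `{0..free}`.  Keeping peaks
on their original chromosome preserves chromosome-level structure;
genome-wide placement is not implemented.

**Calibration of discrete p-values.**  One-sided p-values of discrete
statistics are sub-uniform by construction, so calibration tests assess
the randomization-smoothed transform `p* = P(X > k) + U·P(X = k)` (and the
Monte-Carlo analogue with randomized tie-breaking for permutation tests),
which is exactly Uniform(0,1) for a correctly calibrated test.  The
reported p-values themselves remain the conservative unsmoothed versions.

## Speciation continuum

Scalar proxies per pair — hybrid-zone width (km), percent hybrids, cytb
p-distance, autosomal tree distance — are expanded to symmetric matrices.
The default entry (i, j) is the *mean* of the two scalars: the hypothesis
concerns joint progression, so an entry should be small when both pairs
are far along the continuum; absolute difference is available.  Both are
design choices, not reconstructions of any particular study's procedure.

Mantel tests use Spearman correlation of vectorized lower triangles with
joint row/column permutations (appropriate at small n, here 8 pairs).  The
partial Mantel statistic correlates the residuals of A and B after
regressing each triangle vector (ranks under Spearman) on the control's;
permutations relabel A; the CI is a percentile bootstrap over label
resampling, with triangle entries touching a duplicated label excluded
(they index the undefined diagonal).  Repeatability matrices enter as
similarities (correlation coefficients) without conversion to distances;
the expected sign is therefore *negative* against hybrid-zone width and
percent hybrids and *positive* against genetic distance and stage.  The
p-distance helper computes the mean over cross-group sequence pairs of the
proportion of differing sites, excluding sites with gaps or ambiguity in
either member.

## Feature GLMs

Response: per-window repeatability count (number of pairs in which the
window is an outlier), bounded by the number of contributing pairs.
Predictors: GC fraction, d_s (consumed as a precomputed column), gene
count, mean LD r², chromosome size class (micro < 20 Mb, macro > 40 Mb;
intermediate 20–40 Mb windows are excluded from the binary contrast by
default and can be kept as a third level), standardized position (the k-th
window from the nearer end scores k/⌈W/2⌉, rising to 1 at the center), and
centromere overlap (0/1 indicator by default; a continuous
1 − standardized-distance proximity score is available since the encoding
of "proximity" is a modelling choice).  Continuous predictors are z-scored,
so estimates are per-SD effects on the log mean and are invariant to
rescaling the raw feature.  The model is a Poisson GLM with log link
(statsmodels IRLS); per-predictor significance is an analysis-of-deviance
chi-square, sequential (type-I, in predictor order) by default to match
base-R `anova.glm`, with marginal drop-one tests available.  Model fit is
summarized as the Pearson correlation of observed counts with fitted
means.  One model is fitted per species pair's feature set while the
response is shared across models; the resulting non-independence is
flagged in the CLI report.  An all-zero response is returned as an
explicit degenerate intercept-only fit rather than a failed IRLS run.

## Synthetic landscapes

The generator is phenomenological — fields over windows, not a coalescent
simulation — because the analyses consume window statistics and field
level control makes planted structure exact and cheap.  Defaults describe
the study conditions the package is aimed at: eight pairs, 100-kb windows,
a mix of macro (50–150 Mb, one centromeric interval each) and micro
(5–19 Mb, more GC-rich by +0.03) chromosomes, Gaussian-smoothed GC /
gene-count / LD fields (autocorrelation scale 10 windows), d_s positively
correlated with GC (both track recombination in birds), baseline F_ST 0.1,
baseline d_XY 0.01 per site.

A latent constraint field L is a planted linear combination of scaled
features (gene count +1.0, GC −1.0, centromere +0.8, position +0.6),
standardized.  Pair p with stage s_p ∈ (0,1] gets

    logit F_ST field:  logit(0.1) + 0.6 · [ s_p·w·L + √(1−w²)·ε_p ]
    d_XY field:        0.01 · (1 − 0.5·max(L,0)) + 0.002·η_p,  truncated ≥ 0

with ε, η standard normal.  The shared weight w sets the cross-pair
correlation; the stage multiplies only the shared F_ST component, so F_ST
repeatability grows along the continuum while the d_XY field is identical
in expectation for every pair — low-d_XY outliers co-locate regardless of
stage, encoding the view that absolute divergence carries accumulated
ancestral processes.  Stages default to `linspace(0.2, 1, n_pairs)`.
Continuum metadata maps stages linearly onto widths (600 km at stage 0 →
0 km at stage 1), percent hybrids (70% → 0%), and increasing genetic
distances; the phylogenetic control matrix is a random ultrametric built
by random pair coalescence, independent of stage.  One pair can be flagged
`no_dxy` to exercise harmonization.

The Balding–Nichols site layer draws, per window with target F, SNP
ancestral frequencies Uniform(0.05, 0.95), population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) and binomial allele counts (50 alleles per
population by default).  F = 1 is rejected (degenerate Beta); F = 0 uses
the ancestral frequency directly.  Depth records are emitted at SNP
positions in a band that passes the callable filter (a dense per-bp table
is available for small layouts; at genome scale it would be ~10⁹ rows).

What the generator does *not* emulate: linkage between SNPs within a
window, shared ancestral polymorphism between pairs, gene flow, selection
at specific loci, or reference/mapping artefacts.  Passing tests therefore
demonstrate that the statistical machinery recovers planted structure of
the assumed form, not that real datasets satisfy those assumptions.

## Problem sizes and determinism

All generators take integer seeds (numpy `default_rng`); no time-based
state.  The validation suites use the sizes at which the properties are
sharp but cheap: hypergeometric exactness is enumerated for all universes
N ≤ 20; null calibration uses 2000 windows × 1000 replicates (overlap) and
250 replicates × 199 permutations (peaks); estimator recovery uses 200
SNPs × 100 windows; landscape recovery 8 pairs × ~10⁴ windows × 20 seeds ×
three shared weights; continuum recovery 100 replicates of 8 pairs ×
~2×10³ windows with 499 permutations; GLM recovery 20 seeds × 5000 windows
plus 300 null replicates at 1000 windows.

## Known limitations

* The Mantel family is known to be permissive under spatial/phylogenetic
  autocorrelation of the matrices themselves; with 8 labels the
  permutation space is small (8! orderings) and p-values saturate at
  1/(n_perm+1).
* Peak permutation keeps each peak's chromosome fixed; if outliers are
  concentrated on few chromosomes the null is conservative for
  genome-level clustering questions.
* The GLM treats windows as independent observations; spatial
  autocorrelation of features and counts inflates deviance significance
  on real data (the synthetic null calibration uses independent windows).
* d_XY for pooled data uses the same callable-normalized sum as
  individual data; no separate pooled estimator is implemented.
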