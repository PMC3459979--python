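# Methods

## Statistical model and assumptions

Counts are modelled as negative binomial: for gene g in sample j,
K_gj ~ NB(mean s_j·q_gj, variance s_j·q_gj + α_g·(s_j·q_gj)²), where
s_j is a library size factor and α_g a gene dispersion. All group
comparisons are of domesticated vs wild status; the design is
hierarchical (samples nested in species pairs), and every cross-pair
analysis treats the pair as the dominant nuisance factor. Sexes are
modelled additively where both are present.

### Normalization

Size factors are median-of-ratios: s_j = median over genes (with no
zero in any sample) of K_gj divided by the gene's geometric mean. This
assumes most genes are not differentially expressed between libraries.

### Dispersion

The direct per-gene estimate is method-of-moments on normalized counts,
pooled within status groups: α̂ = (v − μ·ξ)/μ², where v is the pooled
within-group variance, μ the normalized mean, and ξ the mean reciprocal
size factor (the shot-noise correction on the normalized scale);
negative values are floored at 0. A curve α(μ) = a₀ + a₁/μ is fitted
across genes by non-negative least squares, and each gene uses
max(direct, fitted). Taking the maximum deliberately over-disperses
borderline genes: the exact test becomes conservative (measured type-I
error ≈ 0.035 at nominal 0.05 on null simulations), which we accept in
exchange for robustness at small n.

### Exact test

The test conditions on the total count T of a gene and enumerates every
split (a, T−a) between the groups. Group-sum null distributions are NB
with mean q₀·Σs_j and variance q₀·Σs_j + α·q₀²·Σs_j² per group (Poisson
when the dispersion term vanishes). The p-value sums the probabilities
of all splits no more likely than the observed one, renormalized over
all splits; ties with the observed probability are included (a relative
tolerance of 1e-12 guards floating-point ties). All-zero genes get
p = 1. Fold changes add a pseudocount (default 1) to both normalized
group means so genes expressed in only one group remain reportable;
the pseudocount is configurable.

### Variance-stabilizing transform

The VST is the antiderivative of 1/√(u + a₀u²) evaluated at normalized
counts, which has the closed form (2/√a₀)·asinh(√(a₀u)); we use the
analytic expression rather than quadrature since it is exact and fast.
Only the asymptotic dispersion a₀ enters: for large counts the NB
variance is dominated by a₀μ², and the transform approaches
log₂(u) after the affine rescaling t·√a₀/ln2 − log₂(4a₀), which is the
scale on which results are reported. A floor of a₀ ≥ 1e-8 keeps the
rescaling finite for near-Poisson fits.

### Variance explained and permutation tests

Per gene, the domestication variance fraction is the partial R²,
1 − RSS_full/RSS_null, from OLS of expression on sex + domestication
(sex omitted where absent or single-sex); constant genes are assigned 0.
Exhaustive permutation tests enumerate all C(n, n_dom) assignments of
the domesticated labels — the observed assignment included, so p > 0 —
and report the fraction of arrangements whose statistic matches or
exceeds the observed one. Complementary assignments are distinct
arrangements (C(4,2) = 6 for a 2v2 design). The DE-count permutation
statistic holds size factors fixed (they do not depend on labels) and
re-estimates dispersions per arrangement, the conservative choice.

### Cross-pair tests

All overlap tests run on the universe of 1:1 orthologues expressed in
both events. One-sided Fisher tests use the hypergeometric tail; the
reported odds ratio is the sample cross-product ad/bc (0 when a·d = 0,
infinite when only b·c = 0). Direction of change is the sign of
(median domesticated − median wild) on the VST scale; genes with an
exactly zero difference are excluded from directional universes and
counted. The directional test is asymmetric and is run in both
directions, reporting the more significant. The Spearman permutation
test permutes status labels independently within each event and
includes the observed arrangement in the denominator.

### Joint models and the screen

The joint gene-wise model is expression ~ pair + sex + domestication.
Variance fractions are sequential (type-I) sums of squares in the fixed
order pair → sex → domestication, each divided by the total sum of
squares; the order is configurable, and the pig-style pair with a
single recorded sex is handled by the sex factor's "unknown" level.
Structured permutations randomize the pair factor across all samples
but sex and domestication only *within* pairs; permuting domestication
freely would correlate it with the large pair effect and make the test
anticonservative. The permutation statistic is the median variance
fraction across genes by default. The median is robust but nearly
powerless when a small fraction of genes carries the effect (the
unaffected bulk pins the median, and permutation noise does not shrink
with gene count because all genes share each permuted labelling); a
`statistic="mean"` option is provided and is the right choice for
sparse-effect settings.

The NB GLM fits a log-link model with offset log s_j by batched IRLS.
Dispersions maximize a Cox–Reid adjusted profile likelihood
(log-likelihood minus ½·log det X'WX) on a 31-point log-spaced grid
from 1e-4 to 10, with fitted means held fixed from a pilot fit at
α = 0.1 (means depend only weakly on the dispersion). Each gene's
objective is its own APL plus `prior_weight` (default 10) times the
across-gene average APL, shrinking noisy gene-wise estimates toward the
common value. The likelihood-ratio statistic for dropping domestication
is referred to χ²(1); on null simulations the p-values are uniform to
KS distance < 0.02 at 2,500 genes. Non-converged genes (50 IRLS
iterations, tolerance 1e-8) are flagged and get p = NA.

A gene is "domestication-related" when p < α (default 0.05) in all
three models *and* its per-pair direction signs are identical and
nonzero. Requiring all three models is the strict conjunctive reading;
because the models test the same contrast on the same data they are
highly correlated, so the conjunction tightens calibration only
modestly — under a 5%-shared-genes simulation the screen's false
discovery rate among selected genes is ≈ 0.3 at α = 0.05. The screen
is a ranking device to be validated against the extreme-permutation
curves and hold-out prediction, not an FDR-controlled gene list.

### Extreme permutations

Flip patterns are canonicalized by fixing the first pair unflipped
(a global label swap is equivalent to the identity for the
domestication contrast), giving 2^(k−1) − 1 non-identity patterns in
binary-counting order. Under any flip, each pair's per-gene |median
difference| is unchanged by construction. Significance curves count
consistent-direction genes at each p threshold; a threshold of 1 counts
direction agreement alone. Hold-out validation re-selects, per flip, an
equally sized gene set by summed p-value ranks across the three models
among consistent-direction genes with an expressed held-out orthologue,
so permutation odds ratios are comparable to the observed one. The
training-side direction of an unselected gene is the sign of its summed
per-pair signs; balanced genes are excluded.

## SNV filtering and population genetics

Site discovery keeps candidates with total read support ≥ 8, no other
SNV within 10 bp (distance ≤ 10 excluded; the genotyping-stage variant
of the rule, ≤ 2 SNVs per window, is the `max_snvs_in_window` setting),
nearest indel farther than 10 bp, and position outside repeat
intervals (BED, 0-based half-open; VCF positions 1-based). Genotypes
are retained per individual only when coverage ≥ 8, consensus
quality ≥ 30 and RMS mapping quality ≥ 25, all boundaries inclusive;
failures become missing. Classification and all summaries use
complete-data sites by default. π uses the unbiased per-site estimator
n/(n−1)·2p̂(1−p̂) with n = 2·(group size) alleles and p̂ from non-missing
calls, summed and scaled per 1,000 callable bases. Divergence counts a
position as different when two individuals' diploid genotypes are not
identical (heterozygote vs homozygote counts as a difference) and
reports the median over all cross-group individual pairs; an
allele-dosage alternative can be had by comparing dosages directly.
PCA centres 0/1/2 dosages per site and takes scores from the SVD.

## Synthetic data

The expression generator draws log-normal gene baselines (default
e^N(5, 1.2²), i.e. typical counts of a few hundred), per-gene pair
shifts N(0, 1) and sex shifts N(0, 0.1²) on the log2 scale, dispersions
from α(μ) = a₀ + a₁/μ (defaults 0.05 + 2/μ), and library size factors
e^N(0, 0.15²). Shared domestication effects draw one sign per gene and
a magnitude |N(1, 0.25²)| log2 units applied to every pair;
pair-specific effects draw sign and magnitude independently per pair.
Defaults (3 pairs, 5 vs 5 per pair, 5,000 genes) match the scale of a
realistic multi-pair brain RNA-seq design. Sexes alternate within each
group so both are present per pair. The generator emulates NB sampling
and the factorial design only — no batch effects, no length/GC bias,
no correlated genes, no mapping artefacts — so passing tests
demonstrate correctness of the statistics under the assumed model, not
robustness to real-data pathologies.

The genotype generator labels sites fixed / shared / private by
construction and draws coverage (NB, mean 25), consensus quality and
mapping quality (normal) independently of the genotype, so filters can
be exercised orthogonally to truth labels. Genotypes are unlinked and
Hardy–Weinberg-like within groups; there is no linkage, selection or
demography.

## Problem sizes and runtime choices

Test-suite and acceptance-script simulations use 2,000–5,000 genes and
the default 5 vs 5 design per pair; calibration checks use ≥ 2,000
genes and 100+ replicates for permutation super-uniformity; the screen
recovery summary uses 5–10 seeds at 5,000 genes. These sizes give
Monte-Carlo error comfortably below the asserted tolerances while
keeping a full run in minutes on one CPU.

## Known limitations

- The exact test is conservative by design (dispersion maximum rule).
- The NB GLM dispersion shrinkage emulates weighted Cox–Reid profile
  likelihood with a fixed prior weight; it is not a byte-level
  re-implementation of any particular GLM package's estimator.
- The screen's conjunction of three correlated models does not control
  FDR; treat selections as candidates for external validation.
- Sampled (non-exhaustive) permutation p-values include the observed
  arrangement in the denominator, so their resolution is 1/(B+1).
- FPKM without supplied gene lengths uses 1 kb for every gene, making
  it a counts-per-million rate; supply real lengths when available.
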