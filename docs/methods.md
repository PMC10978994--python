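# Methods

`rankmeth` implements a window-based differential DNA-methylation analysis
for capture (MBD-Seq) count data, together with the synthetic-data
generator used to exercise it end to end. In MBD-Seq the read depth over a
genomic region is a proxy for its methylation level, so "differential
methylation" is tested as differential read abundance.

## Count model and window-level test

The genome is tiled into consecutive 300-bp windows (the terminal window of
a contig is truncated and kept). Windows with fewer than 10 reads summed
over samples, or with positive counts in fewer than 10 samples, are
removed; per-sample library sizes L_i are the column totals of the
*unfiltered* matrix and are never redefined by filtering.

Counts Y_wi for window w in sample i follow a negative-binomial GLM with
log link:

    log mu_wi = beta_0w + beta_aw [age_i = cub] + beta_rw [rank_i = low] + log(L_i f_i)

with Var(Y) = mu + phi mu^2. phi is the reciprocal of the shape of the
gamma mixing distribution of the gamma-Poisson representation; phi = 0 is
the Poisson limit. Reference levels are adult and high-ranking, so the rank
coefficient is the low-ranking effect and logFC = beta_rw / ln 2 > 0 means
hypermethylated in low-ranking animals. f_i are TMM normalization factors
(below). The rank effect is tested with a 1-df likelihood-ratio test of the
full model against the age-only model, fitted by a vectorized IRLS (all
windows simultaneously against the shared design; convergence when the
deviance change falls below 1e-8 relative, at most 50 iterations, with
step-halving on deviance increase; start values from least squares on
log(y + 0.5) minus the offset). p-values use the upper chi-square(1) tail;
Benjamini-Hochberg adjustment is applied once, genome-wide, over all
filtered windows. Windows whose fits fail to converge carry NA p-values
and never enter DMR calling.

## Dispersion estimation

A common dispersion maximizes the mean Cox-Reid adjusted profile
log-likelihood (APL: the NB log-likelihood at the fitted means minus
0.5 log det X'WX) over windows; the scalar search is bounded on
[1e-6, 10] and values at the lower bound report as 0. Tagwise dispersions
maximize the weighted likelihood

    APL_w(phi) + prior_df * mean-APL(phi)

on a 15-point log-spaced grid spanning a factor of 2^±4 around the common
value, with quadratic interpolation at the grid maximum. The shared
likelihood therefore carries the weight of `prior_df` windows (default
10), so individual windows escape the common value only on strong
evidence; `prior_df -> inf` collapses every tagwise estimate to the common
one. This weighting was chosen over a per-residual-degree-of-freedom
weighting because, at the cohort size modelled here (42 samples), the
weaker shrinkage leaves tagwise estimates noisy enough to visibly inflate
the null rejection rate (measured 5.3% at nominal 5%, against 4.9% under
the common value).

## TMM normalization

Trimmed mean of M-values, the canonical recipe: the reference sample is the
one whose library-size-scaled 75th percentile is closest to the mean of
those percentiles; for each other sample M = log2 ratio of depth-scaled
proportions against the reference and A = the average log2 proportion,
computed over windows positive in both samples; M is trimmed 30% two-sided
and A 5%; the retained M are averaged with inverse delta-method variance
weights; the factor is 2 to that mean, and factors are centred to product
1. Pure depth differences are carried by L_i, not the factors. CPM is
Y / (L_i f_i) * 1e6 with no pseudo-count. The implementation is verified in
the test suite both against a from-the-definition reevaluation and against
Bioconductor edgeR's `calcNormFactors`.

The per-sample "mean DNA methylation" covariate is the normalized library
size: the sum of counts over all windows divided by f_i.

## DMR calling

Windows with q <= 0.05 are significant. Maximal runs of grid-adjacent
significant windows sharing one effect direction merge into a DMR
(adjacency = consecutive grid windows on the same contig; a filtered-out
window in between breaks the run; logFC exactly 0 joins neither
direction). The DMR's summary effect is the unweighted mean of member
logFCs and its significance summary the minimum q. Significance is decided
first, the direction partition second.

## Annotation

From a gene model (single-isoform assumption; multi-exon genes in genome
order): TSS = 5'-most transcribed base of the first exon (strand-aware,
1-bp interval); promoter = 2 kb immediately upstream of the TSS on the
gene's strand, truncated at contig bounds (minus-strand promoters extend to
higher coordinates; a strand-naive switch exists because conventions
differ); introns = gene span minus exon union. A DMR overlapping >= 1 bp
of any gene-linked feature is intragenic. Coordinates are 0-based half-open
internally; GFF3 I/O converts to 1-based inclusive, BED stays 0-based.

## Subsample-coherence selection

Samples are randomly partitioned into 6 near-equal groups under the
constraint that every group holds at least one sample of each rank class
and each age class (rejection sampling, deterministic per seed); subset k
omits group k, giving 6 subsets of 35 when n = 42. Each subset reruns the
full analysis — TMM, dispersion estimation, both fits and the LRT — on its
own samples, with the window set frozen to the full-data filtered windows.
A candidate DMR is *selected* only if every member window has p <= 0.05 in
every subset with an identical logFC sign across subsets that also matches
the full-data sign (the full-data-sign requirement can be relaxed to
among-subset agreement only); otherwise it is *excluded* with the violating
cells recorded, along with the min-max logFC range over member windows and
subsets.

## Discriminative power

Random-forest classifiers of rank class on age plus one CPM feature per
DMR (member-window counts summed, then CPM-scaled; a per-window variant
exists) or on the single mean-methylation covariate. Forests use bootstrap
bags of size n with replacement, sqrt(p) features per split, Gini
impurity, unlimited depth (scikit-learn's RandomForestClassifier; its
out-of-bag aggregation averages per-tree class probabilities rather than
taking a strict majority vote of hard predictions — the two coincide in
expectation and the contrast measured here is insensitive to the choice).
Each repetition derives a fresh RNG stream from (seed, repetition index)
and yields one oob error; reports carry the min-max range and mean over
repetitions. Defaults are 2000 trees x 1000 repetitions; the analysis
scripts and acceptance checks run a scaled-down 500 x 50.

The chance band used for assertions is the proportional-guessing error
2p(1-p) (p = class proportion) +/- 3 binomial standard errors at the cohort
size. Proportional guessing, not the majority-class error, is the right
baseline for forests on uninformative features: each out-of-bag sample's
bags underrepresent its own class, so noise predictions land near (and
slightly above) 2p(1-p) — measured ~0.67 at the 18/24 cohort, against a
majority-class error of 0.43. A matched-size random-location control draws
pseudo-DMRs uniformly (without replacement) from the window pool, optionally
excluding designated windows.

## Age-class concordance and mitochondrial contrasts

Rank-only NB models (own TMM factors and dispersions) are fitted separately
within cubs and within adults, evaluated at the candidate DMR windows.
Pearson's r between the two logFC vectors is compared against r recomputed
on 1000 uniform random window subsets of equal size drawn without
replacement from all filtered windows; the empirical p is one-sided with
the +1 correction, p = (1 + #{r_null >= r_obs}) / (1 + B), so it can never
be 0 and its floor at B = 1000 is ~0.001.

Mitochondrial-vs-nuclear abundance uses, per individual, the mean CPM over
mitochondrial windows against the mean over nuclear windows (methylation)
and likewise over genes (expression; a gene's region is its exon union and
counts are summed over it). These paired comparisons use the Wilcoxon
signed-rank test: zero differences are dropped, the null is exact for
n <= 25 (full sign-assignment distribution computed by dynamic programming,
tied ranks included), and a normal approximation with tie and continuity
correction otherwise; an all-zero difference vector reports p = 1 by
convention. Rank-class contrasts of overall mean CPM use the two-sided
Wilcoxon rank-sum test (normal approximation with continuity correction by
default, exact on request). A Z value accompanies each test.

## Synthetic-data generator

The generator emulates the study conditions: a 9/9/15/9 cohort over
(high, low) x (cub, adult); NB counts with mean
lambda_w (L_i/1e6) 2^(beta_w [low] + gamma_w [cub]) and variance
mu + phi mu^2. Defaults, fixed a priori (the source study reports no
dispersion or abundance estimates, so these are free parameters chosen to
be realistic for capture data at ~1M reads per sample):

- per-window baseline lambda_w: log-normal, log2 mean 5 and sd 1
  (median ~30 reads per window), drawn once and fixed across samples —
  windows differ in capture propensity;
- dispersion phi = 0.2; library sizes log-uniform in [8e5, 1.2e6], drawn
  once and conditioned on (L_i is an offset, not per-window randomness);
- planted DMRs: contiguous window runs with |log2 effect| 2; the random
  placer alternates effect directions by default, since the study observed
  both hyper- and hypomethylated regions and one-sided planting of 10% of
  windows would shift library composition by ~30% in one class — a regime
  the trimmed-mean normalization only partly absorbs (measured residual
  -0.13 log2 shift at null windows);
- an optional per-window age effect gamma_w ~ N(0, sd), default 0;
- a mitochondrial contig whose windows and genes get lambda scaled by
  mito_multiplier (default 8), emulating elevated mitochondrial abundance;
- expression counts per gene with region length = summed exon length.

Each matrix draws from its own PRNG stream derived from (seed, role
offset), so generating the expression matrix never perturbs the
methylation draws; identical configs give byte-identical outputs. The
truth ledger records planted coordinates and the per-window true effect
vector.

What the generator does **not** emulate: read-level artefacts (FASTQ,
mapping, duplicates), capture-efficiency or GC bias, contaminating
non-host DNA, relatedness or other genetic covariance between samples, and
spatial autocorrelation of methylation beyond the planted runs. Passing
tests therefore demonstrate correctness and calibration of the statistical
machinery under the stated model, not robustness to those artefacts.

## Problem sizes and numerical choices

Simulation-backed tests run at 2,000-5,000 windows x 42 samples with 20
replicates where replication is asserted, and the discriminative-power
contrast at 500 trees x 50 repetitions; these sizes were chosen as the
smallest at which the Monte-Carlo margins quoted in the tests are
comfortably resolved. Null-uniformity is asserted on p-values pooled over
three independent replicates because all windows of one replicate share
estimated normalization factors, which inflates the variance of a
single-replicate KS statistic (observed up to 0.026 across seeds even with
the true dispersion; ~0.011 pooled). Degenerate inputs fail loudly:
all-zero samples in TMM, non-full-rank designs, infeasible subset
constraints, planted-DMR overlaps, and out-of-range p-values all raise
errors naming the offender.

## Known limitations

- The LRT is the plain chi-square test; quasi-likelihood F-tests are out of
  scope, so very small cohorts would be anticonservative.
- The dispersion model has no abundance trend (an option point, not
  implemented); data with a strong mean-dispersion trend would be
  mis-shrunk.
- Coherence selection freezes the candidate window set from the full data,
  as specified, so it quantifies stability of those candidates rather than
  re-discovery.
- The promoter definition is a fixed 2-kb upstream interval; no
  CpG-island or bidirectional-promoter handling.
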