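# Methods

## Count model

All inference assumes gene counts are negative binomial (NB) with
mean/dispersion parameterization `Var(Y) = mu + phi * mu^2`.  The square
root of the dispersion, `sigma = sqrt(phi)`, is the biological
coefficient of variation (BCOV): the relative standard deviation of a
gene's true expression between biological replicates.  Counts may be
fractional (transcript-level quantification summarized to genes yields
non-integer estimated counts) and are passed to every estimator
unrounded; NB probability terms are evaluated with gamma functions, which
extend smoothly to non-integer arguments.

## Normalization and filtering

Between-sample scaling uses trimmed mean of M-values (TMM).  For each
sample against a reference (the sample whose 75th-percentile CPM is
closest to the mean of those percentiles), gene-wise log2 abundance
ratios (M) and average log abundances (A) are computed over genes
positive in both samples; the most extreme 30% of M on each side and 5%
of A on each side are discarded (rank window `floor(0.3n)+1 … n-floor(0.3n)`),
and the surviving M values are averaged with inverse asymptotic binomial
variance weights.  Factors are renormalized to geometric mean 1.
Because of the precision weights, TMM factors are invariant to scaling a
library only up to small weight effects (exact invariance would require
unweighted trimming).

CPM is `count / (lib_size * factor) * 1e6` with no offset, so the
expression filter "CPM > 0 in at least m samples" (m = the smaller group
size of the comparison, counted over the comparison's samples only) is
exactly "count > 0 in at least m samples" and is never perturbed by a
pseudocount.  Display/clustering values use
`log2((count + 0.5) / (effective_lib + 1) * 1e6)`.  Variable-gene
selection ranks genes by the raw row median absolute deviation of
log2CPM (descending, stable ties); the scale constant of the MAD is
irrelevant to ranking and omitted.

## Dispersion estimation (qCML)

The common dispersion is estimated by quantile-adjusted conditional
maximum likelihood:

1. **Library-size equalization.**  Counts are mapped to pseudo-counts on
   the geometric-mean effective library size by matching quantiles of
   per-sample NB distributions at the current dispersion.  The quantile
   map averages a normal and a gamma approximation (both matched in mean
   and variance), which is accurate across the count range and smooth in
   the count.  Effective (TMM-corrected) library sizes are used so that
   composition differences are not mistaken for depth.
2. **Conditional likelihood.**  With equal library sizes the group sum is
   sufficient for the group mean, and the likelihood of the counts given
   their group sums depends only on `phi`.  The pooled conditional
   log-likelihood is maximized on a log grid over [1e-6, 10] refined by
   golden section (tolerance 1e-6 on log phi).
3. **Iteration.**  Starting from a method-of-moments value, equalization
   and maximization alternate until self-consistent (at least two
   passes, capped at ten).  Iterating to a fixed point (rather than a
   fixed two passes) makes the tagwise shrinkage target coincide with
   the common estimate to numerical tolerance.

Tagwise (per-gene) dispersions maximize the gene's own conditional
log-likelihood plus `prior_df / residual_df` times the average
conditional log-likelihood over all genes (weighted-likelihood empirical
Bayes, no abundance trend).  `prior_df` defaults to 10; `prior_df = 0`
gives unshrunk per-gene MLEs, `prior_df -> inf` collapses all genes onto
the common value.  The shared likelihood curve is precomputed on a dense
log grid and interpolated with a cubic spline during per-gene
refinement.  Shrinkage at the default prior is deliberately strong: on a
bimodal fixture with true dispersions 0.01 and 0.25 (six samples per
group) the class means separate by a factor ~2.8 at `prior_df = 10` and
~25 (essentially the truth) at `prior_df = 0`; analyses that need
per-gene dispersion contrast should lower `prior_df`.

## Power

Single-gene power for a two-group comparison with `n` samples per group,
fold change `Delta`, two-sided level `alpha`, coverage `mu` (expected
reads per gene per sample) and BCOV `sigma` is

    power = Phi( sqrt( n (ln Delta)^2 / (2 (1/mu + sigma^2)) ) - z_{1-alpha/2} ),

the closed-form solution of the classical RNA-seq sample-size identity
`(z_{1-alpha/2} + z_beta)^2 = n (ln Delta)^2 / (2 (1/mu + sigma^2))`,
with rejection mass counted in the tail favored by the true effect; at
`Delta = 1` it degenerates to `alpha/2` exactly.  Sample size solving is
an increment search from `n = 2` (cap 1000, error reports the asymptote).

**Units of `mu`.**  At the dataset level `mu` is the average library size
expressed in millions of reads, used directly as the coverage parameter
(e.g. 41.72 for a 41.72M-read experiment); this reproduces the published
power values for that convention.  At the gene level `mu_g` is the
gene's mean raw count across the comparison's samples (equivalently CPM
times library size in millions), which keeps `1/mu` in count space; it
is overridable (`mu_override`).

**Multiple testing.**  For `m` genes with expected true-positive
fraction `pi1` and target FDR `f`, the per-test level is
`alpha* = r1 f / (m0 (1 - f))` with `r1 = pi1 m` (all true positives
expected rejected — the simplest reading) and `m0 = (1 - pi1) m`; both
are exposed for override, and configurations with `alpha* >= 1` raise.
Gene-wise power uses `alpha*`, `n` = the smaller group's size
(conservative under unequal groups), the configured `Delta`, and the
tagwise `sigma_g`; `power >= 0.8` marks a gene detectable.

## Differential expression

**Exact test** (two groups, no covariates): library sizes are equalized
per gene at its tagwise dispersion; conditional on the (rounded) total
pseudo-count, the split between the group sums — two NB sums with
dispersions `phi/n_A`, `phi/n_B` and a common per-sample mean estimated
from the total — has a distribution free of the mean, and the two-sided
p-value sums the probabilities of all splits no more likely than the
observed one (minimum-likelihood rule, capped at 1).  Enumeration is
windowed to the region holding all conditional mass beyond 1e-14 per
tail.  log2 fold changes are pseudo-count group-mean ratios stabilized
with +0.5; no fold-change shrinkage is applied.

**Quasi-likelihood GLM** (with covariates): per gene, an NB log-linear
model with the tagwise dispersion fixed and offset = log effective
library size is fit by IRLS (via statsmodels); the quasi-dispersion is
the residual deviance over its degrees of freedom, squeezed toward a
common value by empirical Bayes (prior df and location from the
scaled-F moments of the log residual variances — a constant prior, no
abundance trend), and the group coefficient is tested with an F
statistic on the deviance drop with `1` and `residual_df + prior_df`
degrees of freedom.

p-values are Benjamini-Hochberg adjusted within one comparison; separate
comparisons are not jointly corrected.  Triage crosses the DE call
(FDR < 0.05 by default) with detectability (power >= 0.8): DE / NDE&DT /
NDE&NDT partition the analyzed genes.  Signatures include genes with
FDR < 0.01 plus non-significant genes with power >= 0.7 (cutoffs
configurable), i.e. likely true positives plus confident negatives.

## Exploration

Sample correlation matrices are Pearson correlations of log2CPM columns
(zero-variance columns are an error).  Hierarchical clustering uses
1 - Pearson (or Euclidean) distances with average (or complete) linkage
via scipy; agglomeration is deterministic with ties resolved to the
smallest index pair.  PCA projects samples onto the principal components
of the gene-centered (not variance-scaled) log2CPM matrix — centering
without scaling matches the convention of mean-centered expression
heatmaps.  t-SNE is delegated to scikit-learn with a fixed seed
(deterministic per seed) and requires perplexity < (samples - 1)/3.

## Simulator

`simulate_counts` draws NB counts gamma-Poisson style: per-gene
relative abundances are log-normal (log-sd 1.8 by default, spanning
roughly 1–10^4 counts), normalized to sum one and scaled by per-sample
library sizes (log-normal around 30 million reads, CV 0.15 — the depth
regime where gene quantification saturates); DE genes (10% by default)
carry a two-fold multiplicative change in the second group, split
50/50 up/down (the split is the deterministic rounded count); BCOV
defaults to 0.21, a well-controlled cell-line experiment.  A planted
1-fold "change" is relabeled null.  Column sums are not renormalized
after planting fold changes — the induced composition shift is exactly
what TMM normalization is for, and balanced up/down splits keep it
small.

**Coverage calibration mode.**  For validating the closed-form power
model, `de_coverage` pins per-gene baselines so that each DE gene's two
group coverages have *harmonic mean* equal to the target and null genes
sit at the target exactly.  The harmonic mean is the coverage the power
formula refers to: its counting-noise term `2/mu` equals
`1/mu_A + 1/mu_B` precisely.  Under this calibration the analytic power
and the empirical exact-test rejection rate agree to ~0.01–0.03 over
(n, sigma) in {2,4,8} x {0.1, 0.3}; the residual gap at small n comes
from TMM estimation noise and the discreteness of the conditional test.

`make_use_case_fixture` builds a 32-sample dataset with four crossed
two-level factors (two cell lines, oxygen level, mTOR-inhibitor
treatment, total vs polysome mRNA fraction; two replicates per cell) and
a planted effect hierarchy cell line (30% of genes, log2-effect sd 2.0)
> fraction (15%, sd 1.2) > oxygen (10%, sd 1.0) > treatment (8%,
sd 0.8), plus a mild replicate batch shift (sd 0.05 on all genes).  The
default fixture uses 4,000 genes at ~2 million reads per sample so the
full pipeline runs in tens of seconds; these sizes are scaled-down study
stand-ins chosen to keep the qualitative structure (cell line dominates
every embedding) while remaining cheap.

**What the simulations do and do not show.**  The generator matches the
power model's own assumptions (independent NB genes, shared dispersion
scale, multiplicative effects), so passing tests demonstrate internal
consistency and correct implementation — not robustness to features of
real data the generator omits: correlated genes, dispersion-abundance
trends, outlier samples, length biases, or sparse single-cell counts.

## Numerical choices

- Dispersion search bounds [1e-6, 10], golden-section tolerance 1e-6 on
  log dispersion; tagwise grid: 141 log-spaced points.
- Exact-test two-sided inclusion uses a 1e-7 log-likelihood tolerance so
  ties with the observed outcome's probability are counted.
- Quantile-map percentiles are clipped at 1 - 1e-14 to keep the inverse
  gamma CDF finite; pseudo-counts are floored at 0.
- Quasi-dispersion squeezing floors residual variances at 1e-10 and
  falls back to an infinite prior (common value) when the moment
  estimate of the prior variance is non-positive.
- The power formula clips to [0, 1]; round-tripping power back to the
  identity is exact to 1e-9 away from saturation.
- Empirical rejection-rate standard errors use the binomial formula; at
  saturated rates the Agresti-Coull adjusted rate keeps them positive.

## Limitations

- The exact test and qCML are two-group procedures; richer designs go
  through the GLM path, which fixes the NB dispersion at the tagwise
  estimate rather than re-estimating it under the design.
- QL moderation uses a constant prior (no abundance trend), which can
  over- or under-moderate when quasi-dispersion varies with expression.
- The closed-form power model is a normal approximation: against the
  exact conditional test it is accurate to ~0.01–0.03 in absolute power
  under matched coverage conventions, and noticeably optimistic if the
  coverage parameter is mapped to the arithmetic rather than harmonic
  mean of unequal group depths.
- Gene identifiers are opaque strings; no annotation, length correction,
  or cross-species handling is attempted.
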