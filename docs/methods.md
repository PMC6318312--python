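# Methods

This note records the statistical models the package implements, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where more than one
reasonable option existed.

## Meta-analysis model

Per-study inputs are per-variant allelic effect estimates and standard
errors from additive-model linear regression; the association Z-score is
their ratio. Because contributing studies may report effects on different
trait scales, the primary aggregation is the sample-size-weighted Z
(Stouffer) statistic; inverse-variance pooling of effects is provided
separately for sets of studies sharing a scale. K, the contributing-study
count entering the Bayes-factor approximation, is counted per variant, since
studies genuinely miss variants.

Genomic control estimates inflation as the median of Z² over the median of
a 1-df chi-square (0.4549…) and deflates only when λ > 1: deflation targets
residual population structure, and "correcting" a deflated scan would
manufacture false positives. The correction can be applied at the study
level and is applied at the meta level; each λ is recorded in the run log.
The conditional meta-analyses reuse the unconditional λ rather than
re-estimating per iteration — conditional statistics at a single locus give
no stable genome-wide median — with the value exposed as an argument.

Study overlap between components (the same individuals contributing twice)
cannot be inferred from summary statistics; it is handled as an explicit
exclusion list plus an `overlap` term in the combined-N arithmetic.

Locus definition is greedy by ascending p among genome-wide-significant
variants with a 500 kb minimum separation between leads; loci are the
±500 kb flanks, merged on overlap keeping the smallest-p lead. Ties in p
break by (chromosome, position, effect allele) so results are reproducible
across library versions.

## Conditional analysis

Conditioning works on the standardized (Z, correlation) scale:
`z_cond = (z_j − R_jS R_SS⁻¹ z_S)/√(1 − R_jS R_SS⁻¹ R_Sj)`. This is
equivalent to conditioning on allele counts when genotypes are standardized,
and the test suite pins the agreement against full multiple regression on
simulated genotypes (maximum |ΔZ| ≤ 0.15 at n = 20,000, in practice ≤0.01).
Working on this scale avoids needing per-study genotype variances, which
summary data do not carry.

Numerical safeguards: conditioning-set members in near-perfect LD
(r² ≥ 0.99) are pruned; `R_SS` receives a 1e-8 ridge jitter when its
condition number exceeds 1e8 (reference-panel noise); variants whose
variance is explained beyond a collinearity threshold of 0.9 by the
conditioning set are flagged invalid rather than returned as ±∞. All three
constants are arguments. A study missing any conditioning variant is
excluded from that iteration's meta-analysis; iteration stops when no
variant attains locus-wide significance (p < 1e-5) or after 10 rounds
(a bound against adversarial input, configurable).

## Heterogeneity meta-regression

The distance between two studies is the mean absolute difference in
effect-allele frequency over their shared variants (mean squared difference
available via `metric=`; both separate the four ancestry groups on drifted
synthetic panels — the absolute form is the default as the most direct
reading of a "mean frequency difference"). Axes come from classical
(Torgerson) MDS — double-centre −D²/2, eigendecompose, scale by √eigenvalue
— with the sign convention that each axis's largest-magnitude loading is
positive. Metric-stress MDS was the alternative; classical MDS is
deterministic, closed-form and sufficient to separate ancestry groups, and
the choice is recorded here and in run metadata.

Per variant, weighted least squares of per-study betas on [1, axes] with
weights 1/se² partitions the intercept-only Cochran Q additively:
Q_ancestry = Q_total − RSS_full on T degrees of freedom, and residual
heterogeneity RSS_full on K − T − 1. With T = 0 the regression reduces
exactly to fixed-effects IVW. Studies missing a variant are dropped from
that variant's regression (complete case); variants with fewer than T + 2
informative studies return NaN. The Bonferroni screen for
ancestry-correlated heterogeneity uses α = 0.05 / number of signals.

## Enrichment model

The evidence summary is the approximate Bayes factor
`Λ = exp[(Z² − ln K)/2]`, kept in log space throughout; per-signal totals
use log-sum-exp and the log-odds uses a log1p form, so |Z| up to 50 stays
finite. The enrichment regression treats the per-variant posterior fraction
π_raw = Λ/T as a fractional response with a logit link, per-signal
fixed-effect intercepts and shared annotation coefficients — the linear
predictor is then literally the signal log-odds, and the annotation
coefficient is the log-fold enrichment in the odds of association. The
alternative, plain least squares on the finite log-odds, is available via
`method="wls_logodds"`.

Estimation uses iteratively reweighted least squares with the per-signal
intercepts concentrated out of each weighted step (within-signal weighted
centring), making cost linear in variants regardless of signal count; a
test cross-checks the coefficients and standard errors against a dense GLM
fit with explicit dummies. Standard errors use the Pearson-χ² dispersion
(quasi-binomial), since the fractional response is not Bernoulli.
Responses are clipped to [1e-12, 1 − 1e-12]: a signal whose posterior mass
collapses onto one variant would otherwise produce infinite logits.
Annotations with no contrast, or collinear with the signal intercepts or
with already-included annotations, are excluded and reported with a reason;
a coefficient diverging past |β| = 30 is treated as separation and likewise
excluded.

Forward selection runs within each annotation category, refitting the joint
model at every step and adding the smallest-Wald-p candidate while p < 0.05
(exact ties break lexicographically); the union of selections across
categories enters one final joint model whose coefficients define the
fine-mapping prior. Marginal screening was the alternative to joint
refitting; joint refitting matches the "jointly enriched" selection target.

The variant universe for each signal's T_i is every variant at the locus
passing the coverage filter; at multi-signal loci the Z entering Λ is the
signal's leave-one-out conditional meta-analysis Z, at single-signal loci
the marginal meta-analysis Z.

## Fine-mapping

Posteriors are softmax(ln Λ + ln γ) with ln γ = Σ β̂_k z_k (uniform when no
annotation was selected); within-signal prior normalisation is immaterial
because softmax is scale-invariant. The 99% credible set is the minimal
prefix of the π-descending ranking reaching 0.99, with exact ties in π
broken by ascending position; high confidence requires a single variant
with π strictly greater than 0.5. Both tie rules are fixed for determinism.

## Mendelian randomisation

Harmonisation matches variants on (chromosome, position), flips outcome
effects recorded on the opposite allele orientation, excludes palindromic
(A/T, C/G) variants outright, and orients the exposure effect allele to the
trait-decreasing allele. The radial modified-Q screen uses first-order
weights (β_exp/se_out)² — second-order weights are a config option — with
per-instrument significance at α = 0.05 against χ²₁, iterating removal and
refit until no new outliers (single-pass available). When several
meta-analysis components are analysed, the union of outliers across
components is removed from all components.

IVW is the zero-intercept weighted regression of outcome on exposure
effects (weights 1/se_out²) with multiplicative random-effects dispersion
√(Q/(n−1)) applied when over-dispersed; a single instrument degrades to its
Wald ratio. The weighted median uses 1/se(r)² weights and a parametric
bootstrap (2,000 draws, caller-supplied generator) for its standard error.
MR-Egger orients all exposure effects positive, fits a free intercept, uses
a dispersion floor of 1 and t-based p-values on n − 2 df; its intercept is
the directional-pleiotropy test. Binary outcomes are taken on the log-odds
scale as supplied. Significance is flagged at 0.05/12 for the default
twelve-outcome screen.

## Power

The 1-df chi-square test of a variant explaining fraction v of trait
variance has noncentrality n·v/(1 − v) (the n·v approximation differs by
<0.02% at the variance fractions of interest; the exact form costs
nothing). The minimum detectable standardized effect at allele frequency f
is √(v/(2f(1−f))).

## Synthetic data: what it emulates, and what it does not

The generator produces every input the pipeline consumes, seeded and
byte-reproducible:

- **Frequencies.** Ancestral frequencies Uniform(0.05, 0.95); per-ancestry
  Balding–Nichols drift (defaults AFR 0.14, EAS 0.11, EUR 0.09, HIS 0.07,
  roughly ordering continental differentiation); per-study jitter
  F = 0.003; clipped to [0.01, 0.99].
- **LD.** AR(1) within locus, r = ρ^|i−j| between adjacent variants, with
  ancestry-specific ρ (AFR 0.55, EAS/EUR 0.75, HIS 0.65 — weaker LD in
  African-ancestry panels); loci independent of each other.
- **Association.** Causal variants drawn with probability ∝ exp(Σ ln-fold ·
  membership) — the generative twin of the fine-mapping prior — with
  standardized effects shared across all studies (the homogeneous-effect
  model the heterogeneity analysis tests for). Per study,
  Z ~ Normal(√n R β, R), so marginal and joint statistics are internally
  consistent; emitted tables carry allelic-scale betas recovered through the
  trait SD (default 15, an eGFR-like scale) and each study's frequency.
  Default panel: 4 ancestries × 2 studies × 12,500 individuals (100,000
  total), 20 loci × 50 variants spaced 20 kb, causal standardized effects
  of magnitude ~0.05 (±20%), oriented trait-decreasing, one four-fold
  enriched cell-type annotation covering 10% of variants, and 4,000
  unassociated background variants that anchor the genomic-control median
  as in a genome-wide scan. These sizes keep a full panel run under a few
  seconds while leaving per-variant evidence (√n·β ≈ 16 at the meta level)
  comfortably above the locus-wide threshold.
- **Genotypes.** A Gaussian-copula haplotype generator backs the oracle
  tests of the conditional analysis (two haplotypes thresholded from a
  latent AR(1) normal); it is not used by the summary-level pipeline.
- **MR.** 94 instruments, 3 with palindromic alleles, exposure effects
  Normal(0, 0.15²) truncated away from zero, outcome noise SE 0.05, causal
  effect −0.3, pleiotropic offsets ±0.5 for a configurable fraction.

Not emulated: realistic human LD maps or haplotype sharing between
ancestries beyond the shared causal model; allele-frequency–dependent
effect-size architecture; imputation error (info is 1.0 in generated
tables); overlapping samples between studies; strand errors. Passing tests
therefore demonstrate that the estimators recover truth under the stated
generative model, not that any particular real dataset would yield the same
estimates.

## Problem sizes used in the checks

The calibration and recovery suites run at: conditional-analysis oracle,
three 50-variant loci × 20,000 individuals; enrichment recovery, 25
replicates of 200 signals × 250 variants per fold in {1, 2, 4};
credible-set coverage, 1,000 signals of 100 variants; meta-regression
type-I error, 10,000 null variants × 19 studies; modified-Q calibration,
200 panels of 50 instruments; MR estimator recovery, 500 replicates of 50
instruments. These sizes give Monte-Carlo error comfortably inside each
check's tolerance.

## Known limitations

- Conditional analysis assumes the LD reference matches the study sample;
  mismatch inflates conditional statistics, and the only mitigations here
  are the ridge jitter and collinearity flagging.
- The enrichment model treats signals as independent; overlapping loci
  would violate this, but loci are non-overlapping by construction.
- One causal variant per signal is assumed downstream of dissection (the
  fine-mapping is single-causal per conditional slice); allelic series
  within a single haplotype block beyond the dissection resolution are not
  modelled.
- The weighted-median standard error is a bootstrap estimate and inherits
  its draw count; 2,000 draws put the SE's own noise near 1–2%.
- Palindromic variants are flagged but retained in the meta-analysis stages
  (only MR excludes them); cross-study strand errors at palindromic sites
  would therefore pass through undetected.
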