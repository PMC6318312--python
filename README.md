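# transgwas

A summary-statistics-native toolkit for multi-ancestry GWAS of quantitative
traits, built around the analysis strategy used for large trans-ethnic
studies of kidney function (eGFR): aggregate per-study association results
across ancestry groups, dissect each associated locus into distinct signals,
test whether allelic effects are heterogeneous across ancestries, learn which
genomic annotations are enriched for association, fine-map each signal under
an annotation-informed prior, and probe causal effects of the trait on
clinical outcomes by two-sample Mendelian randomisation.

It is aimed at statistical geneticists who work from per-study summary
statistics (no individual-level genotypes) plus per-ancestry LD reference
matrices, and who want every stage of the pipeline available as a plain
Python function.

## The statistics at the core

**Meta-analysis.** Studies reporting effects on different trait scales are
combined by sample-size-weighted Z-scores (Stouffer):
`Z_meta = Σ_i √n_i Z_i / √(Σ_i n_i)`, with genomic-control deflation by
`λ_GC = median(Z²)/median(χ²₁)` whenever `λ_GC > 1`. Where scales agree,
allelic effects are pooled by inverse-variance weighting. Loci are defined as
±500 kb flanks of genome-wide-significant leads (p < 5×10⁻⁸) separated by at
least 500 kb, merged when they overlap.

**Signal dissection.** Working from Z-scores and an ancestry-matched LD
reference R, the conditional statistic of variant j given a set S is

    z_cond,j = (z_j − R_jS R_SS⁻¹ z_S) / √(1 − R_jS R_SS⁻¹ R_Sj)

Per-study conditional Z-scores are Stouffer-combined (studies missing any
conditioning variant are excluded per iteration) and the strongest residual
association joins the conditioning set while it attains locus-wide
significance (p < 10⁻⁵). Leave-one-out conditioning defines one index
variant per signal.

**Heterogeneity.** Classical MDS of mean allele-frequency differences
between studies yields axes of genetic variation; per-variant weighted
regression of allelic effects on the axes partitions Cochran's Q into an
ancestry-correlated component (χ² on T axes) and a residual.

**Enrichment and fine-mapping.** Per variant j at signal i, the approximate
Bayes factor is `Λ_ij = exp[(Z_ij² − ln K)/2]` over K contributing studies.
The log-odds `ln[Λ_ij/(T_i − Λ_ij)]`, with `T_i = Σ_j Λ_ij`, is modelled as
a per-signal intercept plus log-fold enrichments β_k of binary annotations
(fractional-logit regression with quasi-likelihood errors; per-category
forward selection, then one joint model). Posteriors follow as
`π_ij ∝ γ_ij Λ_ij` with prior `γ_ij = exp[Σ_k β̂_k z_ijk]`; 99% credible
sets collect the top-ranked variants, and a signal is high-confidence when
one variant carries π > 0.5.

**Mendelian randomisation.** Non-palindromic lead variants instrument the
trait. Radial modified-Q statistics `Q_j = w_j (r_j − μ̂)²` (Wald ratios
r_j, first-order weights) flag pleiotropic outliers, iterating to
convergence, with the union of outliers across meta-analysis components
removed from all of them. Estimators: inverse-variance-weighted regression
(primary), weighted median and MR-Egger.

All inputs can be produced by the seeded generators in
`transgwas.simulate`: ancestry-drifted allele frequencies (Balding–Nichols),
autoregressive LD with ancestry-specific decay, causal variants placed with
annotation-dependent probability and shared standardized effects, and MR
instrument sets with a controllable pleiotropic fraction.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/06_power.py` prints

```
combined sample size across components: 312,468
fold increase over the largest component: 2.2

power to detect a variant explaining 0.0127% of variance
at genome-wide significance (alpha = 5e-8): 80.2%
minimum detectable standardized effect at MAF 5%: 0.0366 SD per allele
minimum detectable standardized effect at MAF 0.5%: 0.113 SD per allele
```

i.e. at the combined sample size of the three meta-analysis components
(minus their known overlap) the design has just over 80% power for variants
explaining ≥0.0127% of trait variance — equivalently, standardized allelic
effects of ≥0.0366 SD at MAF ≥5% or ≥0.113 SD at MAF ≥0.5%.

`python examples/05_mendelian_randomisation.py` runs the full MR stage on a
simulated instrument set with a planted causal effect of −0.3 and 10%
pleiotropic outliers:

```
instruments: 94 simulated, 91 after palindrome exclusion
modified-Q outliers removed: 13 (planted pleiotropic: 9, detected: 9)
              ivw: estimate -0.322 (se 0.036, p 8.26e-19)
  weighted_median: estimate -0.341 (se 0.053, p 9.81e-11)
            egger: estimate -0.344 (se 0.071, p 6.37e-06); intercept +0.0040 (p 0.72)

planted causal effect: -0.3
```

All three estimators recover the planted effect within their standard
errors once the radial screen has removed the pleiotropic instruments.

## Layout

- `transgwas.sumstats` — summary-statistics/BED/LD readers and writers,
  record validation, allele harmonisation, annotation membership
- `transgwas.meta` — Stouffer meta-analysis, genomic control, coverage
  filtering, inverse-variance effect pooling, locus definition
- `transgwas.signals` — approximate conditional analysis and signal
  dissection
- `transgwas.ancestry` — frequency distances, MDS axes, heterogeneity
  meta-regression
- `transgwas.enrichment` — Bayes factors, signal log-odds, enrichment model
  with forward selection
- `transgwas.finemap` — annotation-informed posteriors, credible sets,
  high-confidence calls
- `transgwas.mr` — harmonisation, radial outlier screen, IVW / weighted
  median / Egger
- `transgwas.power` — design power and minimum detectable effects
- `transgwas.simulate` — seeded generators for every input above
- `transgwas.pipeline` — end-to-end glue over a panel of studies

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
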