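"""Analytic design calculations for a multi-ancestry GWAS of kidney function.

Computes detection power for a variant explaining a given fraction of trait
variance, and the minimum detectable standardized allelic effect at common
and low allele frequencies, at consortium scale.
"""

from transgwas.power import combined_sample_size, min_detectable_beta, power

n = combined_sample_size([81_829, 110_517, 143_658], overlap=23_536)
print(f"combined sample size across components: {n:,.0f}")
print(f"fold increase over the largest component: {n / 143_658:.1f}")

v = 0.000127  # fraction of trait variance explained
p = power(n=n, var_explained=v, alpha=5e-8)
print(f"\npower to detect a variant explaining {100 * v:.4f}% of variance")
print(f"at genome-wide significance (alpha = 5e-8): {100 * p:.1f}%")

for maf in (0.05, 0.005):
    beta = min_detectable_beta(v, maf)
    print(f"minimum detectable standardized effect at MAF {100 * maf:g}%: "
          f"{beta:.3g} SD per allele")
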