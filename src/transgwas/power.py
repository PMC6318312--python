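"""Analytic study-design calculations for quantitative-trait GWAS.

Under an additive model, a variant explaining a fraction v of trait variance
is tested with a 1-df chi-square whose noncentrality in a sample of n
individuals is n v / (1 - v).  Detection power at significance level alpha
follows directly; conversely, the variance fraction fixes the minimum
detectable standardized allelic effect at a given allele frequency through
v = 2 f (1 - f) beta^2.
"""

from __future__ import annotations

from scipy import stats

__all__ = [
    "power",
    "min_detectable_beta",
    "variance_explained",
    "combined_sample_size",
]


def power(n: float, var_explained: float, alpha: float) -> float:
    """Power of the 1-df association test.

    Noncentrality ncp = n v / (1 - v); power = P(chi2_1(ncp) > critical
    value at alpha).  With v = 0 the power equals alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 <= var_explained < 1:
        raise ValueError("var_explained must lie in [0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    crit = stats.chi2.ppf(1 - alpha, df=1)
    ncp = n * var_explained / (1 - var_explained)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else alpha


def min_detectable_beta(var_explained: float, maf: float) -> float:
    """Standardized allelic effect explaining ``var_explained`` at ``maf``.

    beta = sqrt(v / (2 maf (1 - maf))) in trait standard deviations per
    allele; strictly decreasing in maf on (0, 0.5].
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    if not 0 <= var_explained < 1:
        raise ValueError("var_explained must lie in [0, 1)")
    return (var_explained / (2.0 * maf * (1.0 - maf))) ** 0.5


def variance_explained(beta: float, maf: float) -> float:
    """Trait-variance fraction 2 maf (1 - maf) beta^2 (inverse of the above)."""
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    return 2.0 * maf * (1.0 - maf) * beta**2


def combined_sample_size(components: list[float], overlap: float = 0.0) -> float:
    """Total N across meta-analysis components minus known overlapping samples."""
    total = float(sum(components)) - float(overlap)
    if total <= 0:
        raise ValueError("combined sample size must be positive")
    return total
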