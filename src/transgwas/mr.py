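"""Two-sample Mendelian randomisation with radial outlier exclusion.

Lead variants at trait loci serve as instruments: each contributes a Wald
ratio (outcome effect over exposure effect).  Heterogeneity in the ratios is
screened with modified (radial) Q-statistics — per-instrument contributions
Q_j = w_j (r_j - mu)^2 with first-order weights w_j = (beta_exp / se_out)^2
and mu the inverse-variance-weighted estimate — iterating removal of
instruments whose Q_j exceeds the chi-square(1) critical value until none
remain.  When the analysis is repeated across several meta-analysis
components (effect sizes on different scales), the union of outliers across
components is removed from all of them.

Estimators: inverse-variance-weighted regression (primary; multiplicative
random-effects dispersion when Q/(n-1) > 1), the weighted median (parametric
bootstrap standard error) and MR-Egger regression, whose intercept tests for
directional pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MRResult",
    "harmonize",
    "wald_ratio",
    "ivw",
    "modified_q_filter",
    "weighted_median",
    "mr_egger",
    "run_mr",
]

PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}

INSTRUMENT_COLUMNS = [
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta_exp",
    "se_exp",
    "beta_out",
    "se_out",
]


@dataclass
class MRResult:
    component: str
    outcome: str
    method: str
    estimate: float
    se: float
    p: float
    n_instruments: int
    outliers_removed: list = field(default_factory=list)
    egger_intercept: tuple[float, float, float] | None = None
    significant: bool | None = None


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Build the instrument table shared by exposure and outcome.

    Variants are matched on (chrom, pos); outcome records on the opposite
    allele orientation have their effect sign flipped.  Palindromic (A/T and
    C/G) variants are excluded, since their strand cannot be resolved from
    alleles alone.  Finally the exposure effect allele is oriented to the
    trait-decreasing allele (beta_exp < 0), flipping both effects together
    where needed.  An empty result is an error.
    """
    exp = exposure.set_index(["chrom", "pos"])
    out = outcome.set_index(["chrom", "pos"])
    shared = exp.index.intersection(out.index)
    rows = []
    for key in shared:
        e, o = exp.loc[key], out.loc[key]
        if frozenset((e["effect_allele"], e["other_allele"])) in PALINDROMIC:
            continue
        if (o["effect_allele"], o["other_allele"]) == (
            e["effect_allele"],
            e["other_allele"],
        ):
            b_out = o["beta"]
        elif (o["other_allele"], o["effect_allele"]) == (
            e["effect_allele"],
            e["other_allele"],
        ):
            b_out = -o["beta"]
        else:
            continue  # unresolvable allele mismatch
        b_exp, ea, oa = e["beta"], e["effect_allele"], e["other_allele"]
        if b_exp > 0:  # orient to the trait-decreasing allele
            b_exp, b_out, ea, oa = -b_exp, -b_out, oa, ea
        rows.append((key[0], key[1], ea, oa, b_exp, e["se"], b_out, o["se"]))
    if not rows:
        raise ValueError("no shared non-palindromic instruments")
    return pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)


def wald_ratio(beta_exp: float, beta_out: float, se_out: float) -> tuple[float, float]:
    """Single-instrument causal estimate beta_out / beta_exp.

    First-order standard error se_out / |beta_exp|.  A null exposure effect
    leaves the ratio undefined.
    """
    if beta_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    return beta_out / beta_exp, se_out / abs(beta_exp)


def _ratios(instr: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    bx = instr["beta_exp"].to_numpy(dtype=float)
    by = instr["beta_out"].to_numpy(dtype=float)
    so = instr["se_out"].to_numpy(dtype=float)
    return by / bx, so / np.abs(bx)


def ivw(instr: pd.DataFrame, component: str = "", outcome: str = "") -> MRResult:
    """Inverse-variance-weighted regression estimate of the causal effect.

    Zero-intercept weighted regression of beta_out on beta_exp with weights
    1/se_out^2 — equivalently the 1/se^2-weighted mean of the Wald ratios.
    The standard error is inflated by the multiplicative random-effects
    dispersion sqrt(Q/(n-1)) when over-dispersed.  With a single instrument
    the Wald ratio is returned.
    """
    n = len(instr)
    if n == 0:
        raise ValueError("no instruments")
    if n == 1:
        est, se = wald_ratio(
            instr["beta_exp"].iloc[0], instr["beta_out"].iloc[0], instr["se_out"].iloc[0]
        )
        p = 2 * stats.norm.sf(abs(est / se))
        return MRResult(component, outcome, "wald_ratio", est, se, p, 1)
    bx = instr["beta_exp"].to_numpy(dtype=float)
    by = instr["beta_out"].to_numpy(dtype=float)
    w = 1.0 / instr["se_out"].to_numpy(dtype=float) ** 2
    est = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    var_fixed = 1.0 / np.sum(w * bx**2)
    q = float(np.sum(w * (by - est * bx) ** 2))
    phi = max(1.0, q / (n - 1))
    se = float(np.sqrt(phi * var_fixed))
    p = 2 * stats.norm.sf(abs(est / se))
    return MRResult(component, outcome, "ivw", est, se, p, n)


def modified_q_filter(
    instr: pd.DataFrame, alpha: float = 0.05, iterate: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Radial modified-Q screen for outlying (pleiotropic) instruments.

    Q_j = w_j (r_j - mu)^2 with r_j the Wald ratio, first-order weights
    w_j = (beta_exp / se_out)^2 and mu the IVW estimate.  Instruments with
    Q_j above the chi-square(1) upper-alpha point are flagged; by default the
    screen refits and re-tests until no new outliers emerge.  Returns
    (retained, outliers, Q_j for the retained instruments at convergence).
    Flagging every instrument is a degenerate-heterogeneity error.
    """
    if len(instr) < 3:
        raise ValueError("need at least 3 instruments for the modified-Q screen")
    crit = stats.chi2.ppf(1 - alpha, df=1)
    retained = instr.reset_index(drop=True)
    flagged = []
    while True:
        r, _ = _ratios(retained)
        w = (retained["beta_exp"] / retained["se_out"]).to_numpy(dtype=float) ** 2
        mu = float(np.sum(w * r) / np.sum(w))
        qj = w * (r - mu) ** 2
        new = qj > crit
        if not new.any():
            break
        flagged.append(retained[new])
        retained = retained[~new].reset_index(drop=True)
        if retained.empty:
            raise ValueError("all instruments flagged as heterogeneous")
        if not iterate:
            r, _ = _ratios(retained)
            w = (retained["beta_exp"] / retained["se_out"]).to_numpy(dtype=float) ** 2
            mu = float(np.sum(w * r) / np.sum(w))
            qj = w * (r - mu) ** 2
            break
    outliers = (
        pd.concat(flagged, ignore_index=True)
        if flagged
        else instr.iloc[0:0].reset_index(drop=True)
    )
    return retained, outliers, qj


def weighted_median(
    instr: pd.DataFrame,
    component: str = "",
    outcome: str = "",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> MRResult:
    """Weighted-median estimate of the causal effect.

    The median of the instrument Wald ratios under weights 1/se(r_j)^2,
    consistent while instruments carrying at least half the weight are valid.
    Standard error by parametric bootstrap (``n_boot`` draws of the exposure
    and outcome effects from their sampling distributions).
    """
    n = len(instr)
    if n < 3:
        raise ValueError("need at least 3 instruments")
    rng = rng if rng is not None else np.random.default_rng(0)
    r, se_r = _ratios(instr)
    est = _weighted_median(r, 1.0 / se_r**2)
    bx = instr["beta_exp"].to_numpy(dtype=float)
    by = instr["beta_out"].to_numpy(dtype=float)
    sx = instr["se_exp"].to_numpy(dtype=float)
    so = instr["se_out"].to_numpy(dtype=float)
    bx_b = rng.normal(bx, sx, size=(n_boot, n))
    by_b = rng.normal(by, so, size=(n_boot, n))
    r_b = by_b / bx_b
    w_b = (bx_b / so) ** 2
    boots = np.array([_weighted_median(r_b[i], w_b[i]) for i in range(n_boot)])
    se = float(np.std(boots, ddof=1))
    p = 2 * stats.norm.sf(abs(est / se))
    return MRResult(component, outcome, "weighted_median", float(est), se, p, n)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(0.5, cum, v))


def mr_egger(instr: pd.DataFrame, component: str = "", outcome: str = "") -> MRResult:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with intercept.

    All exposure effects are oriented positive first; weights are 1/se_out^2.
    The slope estimates the causal effect and the intercept tests for
    directional pleiotropy.  Standard errors use a dispersion floor of 1 and
    t-based p-values on n - 2 degrees of freedom.
    """
    n = len(instr)
    if n < 3:
        raise ValueError("need at least 3 instruments")
    sign = np.sign(instr["beta_exp"].to_numpy(dtype=float))
    sign[sign == 0] = 1.0
    bx = instr["beta_exp"].to_numpy(dtype=float) * sign
    by = instr["beta_out"].to_numpy(dtype=float) * sign
    if np.ptp(bx) == 0:
        raise ValueError("no variation in exposure effects; Egger slope undefined")
    w = 1.0 / instr["se_out"].to_numpy(dtype=float) ** 2
    x = np.column_stack([np.ones(n), bx])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(x * sw[:, None], by * sw, rcond=None)
    resid = by - x @ coef
    sigma2 = float(np.sum(w * resid**2) / (n - 2))
    cov = np.linalg.inv(x.T @ (x * w[:, None])) * max(1.0, sigma2)
    se_int, se_slope = np.sqrt(np.diag(cov))
    slope, intercept = float(coef[1]), float(coef[0])
    p_slope = 2 * stats.t.sf(abs(slope / se_slope), df=n - 2)
    p_int = 2 * stats.t.sf(abs(intercept / se_int), df=n - 2)
    return MRResult(
        component,
        outcome,
        "egger",
        slope,
        float(se_slope),
        float(p_slope),
        n,
        egger_intercept=(intercept, float(se_int), float(p_int)),
    )


def run_mr(
    instruments: dict[str, pd.DataFrame],
    outcome: str = "",
    n_traits: int = 12,
    q_alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[list[MRResult], pd.DataFrame]:
    """Per-component MR for one outcome with cross-component outlier union.

    ``instruments`` maps component label to its harmonised instrument table.
    The modified-Q screen runs within each component; the union of flagged
    variants across components is removed from all of them before the IVW
    (primary), weighted-median and Egger (sensitivity) estimators.
    Significance is flagged at the Bonferroni level 0.05 / n_traits.
    Returns (results, outlier table with component of origin).
    """
    if not instruments:
        raise ValueError("no components supplied")
    rng = rng if rng is not None else np.random.default_rng(0)
    outlier_frames = []
    for comp, instr in instruments.items():
        _, outliers, _ = modified_q_filter(instr, alpha=q_alpha)
        if not outliers.empty:
            outlier_frames.append(outliers.assign(component=comp))
    outliers_all = (
        pd.concat(outlier_frames, ignore_index=True)
        if outlier_frames
        else pd.DataFrame(columns=INSTRUMENT_COLUMNS + ["component"])
    )
    bad = set(zip(outliers_all["chrom"], outliers_all["pos"]))
    threshold = 0.05 / n_traits
    results: list[MRResult] = []
    for comp, instr in instruments.items():
        keep = ~instr.apply(lambda r: (r["chrom"], r["pos"]) in bad, axis=1)
        kept = instr[keep].reset_index(drop=True)
        removed = sorted(set(zip(instr["chrom"], instr["pos"])) & bad)
        for fit in (
            ivw(kept, comp, outcome),
            weighted_median(kept, comp, outcome, rng=rng),
            mr_egger(kept, comp, outcome),
        ):
            fit.outliers_removed = removed
            fit.significant = fit.p < threshold
            results.append(fit)
    return results, outliers_all
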