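"""Trans-ethnic meta-analysis of summary statistics and locus definition.

Primary aggregation is fixed-effects meta-analysis with sample-size weighting
of Z-scores (Stouffer's method), the right tool when contributing studies
report allelic effects on different trait scales.  Effect sizes themselves
are pooled separately, where scales agree, by inverse-variance weighting.
Residual population structure is corrected by genomic control: the inflation
factor lambda is the median of the squared Z-scores divided by the median of
a 1-df chi-square, and statistics are deflated only when lambda exceeds 1.

Genome-wide significant lead variants separated by at least 500 kb define
loci as lead +/- 500 kb flanks; overlapping loci merge, keeping the smallest
p-value lead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import StudySumStats, harmonise_studies

__all__ = [
    "CHI2_MEDIAN_1DF",
    "stouffer_meta",
    "genomic_control",
    "coverage_filter",
    "ivw_effect_meta",
    "meta_analyse",
    "Locus",
    "define_loci",
]

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_MEDIAN_1DF = float(stats.chi2.median(1))  # 0.4549364...


def stouffer_meta(z, n):
    """Sample-size-weighted Z meta-analysis of one variant across K studies.

    z_meta = sum_i sqrt(n_i) z_i / sqrt(sum_i n_i).  Returns
    (z_meta, n_total, k_studies).
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if z.size == 0:
        raise ValueError("at least one study required")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    n_total = float(n.sum())
    z_meta = float(np.sum(np.sqrt(n) * z) / np.sqrt(n_total))
    return z_meta, n_total, int(z.size)


def genomic_control(z):
    """Genomic-control correction of a Z-score vector.

    lambda_gc = median(z^2) / median(chi^2_1); the vector is deflated by
    sqrt(lambda_gc) only when lambda_gc > 1 (no inflation correction is ever
    applied in the deflated direction).
    """
    z = np.asarray(z, dtype=float)
    finite = np.isfinite(z)
    if not finite.any():
        raise ValueError("no finite Z-scores")
    lam = float(np.median(z[finite] ** 2) / CHI2_MEDIAN_1DF)
    corrected = z / np.sqrt(lam) if lam > 1.0 else z.copy()
    return lam, corrected


def coverage_filter(meta: pd.DataFrame, combined_n: float, fraction: float = 0.5) -> pd.DataFrame:
    """Retain variants reported in at least ``fraction`` of the combined N."""
    if combined_n <= 0:
        raise ValueError("combined_n must be positive")
    return meta[meta["n_total"] >= fraction * combined_n].reset_index(drop=True)


def ivw_effect_meta(beta, se):
    """Fixed-effects inverse-variance-weighted pooling of allelic effects.

    Returns (beta_pooled, se_pooled) with weights 1/se^2.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    return float(np.sum(w * beta) / np.sum(w)), float(1.0 / np.sqrt(np.sum(w)))


def _p_from_z(z: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def meta_analyse(
    studies: list[StudySumStats],
    gc_study_level: bool = False,
    gc_meta_level: bool = True,
    coverage_fraction: float = 0.5,
    combined_n: float | None = None,
    exclude_studies: set[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Trans-ethnic Stouffer meta-analysis across studies.

    Studies listed in ``exclude_studies`` (e.g. a component duplicated in
    another contributing resource) are removed before aggregation.  Effect
    alleles are harmonised to the first study's orientation.  Genomic control
    can be applied at the study level (per configuration) and is applied to
    the meta-analysis Z-scores; each lambda is recorded in the returned run
    log.  Variants reported in less than ``coverage_fraction`` of the combined
    sample size are dropped.

    Returns a (meta table, run log) pair; the meta table has one row per
    variant with z_meta, p, n_total and the per-variant contributing-study
    count k_studies, plus per-ancestry mean effect-allele frequencies.
    """
    if exclude_studies:
        studies = [s for s in studies if s.study_id not in exclude_studies]
    if not studies:
        raise ValueError("no studies to meta-analyse")
    studies, harmonisation = harmonise_studies(studies)
    log: dict = {"harmonisation": harmonisation, "lambda_study": {}}

    frames = []
    for ss in studies:
        t = ss.table
        z = (t["beta"] / t["se"]).to_numpy()
        if gc_study_level:
            lam, z = genomic_control(z)
            log["lambda_study"][ss.study_id] = lam
        frames.append(
            pd.DataFrame(
                {
                    "chrom": t["chrom"],
                    "pos": t["pos"],
                    "effect_allele": t["effect_allele"],
                    "other_allele": t["other_allele"],
                    "rsid": t["rsid"],
                    "eaf": t["eaf"],
                    "z": z,
                    "n": t["n"],
                    "ancestry": ss.ancestry_group,
                }
            )
        )
    long = pd.concat(frames, ignore_index=True)
    key = ["chrom", "pos", "effect_allele", "other_allele"]
    sqrt_n = np.sqrt(long["n"])
    long = long.assign(_wz=sqrt_n * long["z"])
    agg = long.groupby(key, sort=True).agg(
        wz=("_wz", "sum"),
        n_total=("n", "sum"),
        k_studies=("z", "size"),
        rsid=("rsid", "first"),
    )
    agg["z_meta"] = agg["wz"] / np.sqrt(agg["n_total"])
    meta = agg.reset_index().drop(columns="wz")

    if gc_meta_level:
        lam_meta, corrected = genomic_control(meta["z_meta"].to_numpy())
        meta["z_meta"] = corrected
    else:
        lam_meta = float("nan")
    log["lambda_meta"] = lam_meta
    meta["p"] = _p_from_z(meta["z_meta"].to_numpy())

    eaf = (
        long.groupby(key + ["ancestry"])["eaf"].mean().unstack("ancestry")
    )
    eaf.columns = [f"eaf_{c}" for c in eaf.columns]
    meta = meta.merge(eaf.reset_index(), on=key, how="left")

    if combined_n is None:
        combined_n = float(sum(s.table["n"].max() for s in studies))
    log["combined_n"] = combined_n
    n_before = len(meta)
    meta = coverage_filter(meta, combined_n, coverage_fraction)
    log["coverage_dropped"] = n_before - len(meta)
    cols = key + ["rsid", "z_meta", "p", "n_total", "k_studies"]
    other = [c for c in meta.columns if c not in cols]
    return meta[cols + other], log


@dataclass
class Locus:
    """A genomic interval anchored at a genome-wide-significant lead variant."""

    chrom: str
    start: int
    end: int
    lead_pos: int
    lead_p: float
    lead_effect_allele: str = ""
    lead_other_allele: str = ""
    lead_rsid: str = ""

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def define_loci(
    meta: pd.DataFrame,
    p_threshold: float = 5e-8,
    flank: int = 500_000,
    min_separation: int = 500_000,
) -> list[Locus]:
    """Define association loci from genome-wide-significant lead variants.

    Leads are selected greedily by ascending p-value, enforcing at least
    ``min_separation`` bp between any two leads on a chromosome.  Each lead
    is extended by ``flank`` bp either side (clipped at position 1); loci that
    overlap are combined, keeping the lead with the smallest p-value.  Ties in
    p break by (chromosome, position, effect allele) for determinism.
    """
    sig = meta[meta["p"] < p_threshold]
    if sig.empty:
        return []
    sig = sig.sort_values(
        ["p", "chrom", "pos", "effect_allele"], kind="stable"
    )
    leads: list[pd.Series] = []
    for _, row in sig.iterrows():
        if all(
            row["chrom"] != l["chrom"] or abs(row["pos"] - l["pos"]) >= min_separation
            for l in leads
        ):
            leads.append(row)
    loci = [
        Locus(
            chrom=l["chrom"],
            start=max(1, int(l["pos"]) - flank),
            end=int(l["pos"]) + flank,
            lead_pos=int(l["pos"]),
            lead_p=float(l["p"]),
            lead_effect_allele=l["effect_allele"],
            lead_other_allele=l["other_allele"],
            lead_rsid=l.get("rsid", ""),
        )
        for l in leads
    ]
    loci.sort(key=lambda l: (l.chrom, l.start))
    merged: list[Locus] = []
    for loc in loci:
        if merged and merged[-1].chrom == loc.chrom and loc.start <= merged[-1].end:
            prev = merged[-1]
            best = prev if prev.lead_p <= loc.lead_p else loc
            merged[-1] = Locus(
                chrom=prev.chrom,
                start=min(prev.start, loc.start),
                end=max(prev.end, loc.end),
                lead_pos=best.lead_pos,
                lead_p=best.lead_p,
                lead_effect_allele=best.lead_effect_allele,
                lead_other_allele=best.lead_other_allele,
                lead_rsid=best.lead_rsid,
            )
        else:
            merged.append(loc)
    return merged
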