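"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analyses assume, so the
whole pipeline is testable without any consortium download:

* K studies drawn from four ancestry groups (AFR, EAS, EUR, HIS), with
  ancestral allele frequencies drifted per ancestry under a Balding-Nichols
  model and jittered per study;
* per-locus LD that decays autoregressively between adjacent variants, with
  ancestry-specific decay (weaker LD in African-ancestry panels) and
  independence between loci;
* causal variants shared across all studies with homogeneous standardized
  effects, placed with probability proportional to exp(sum_k ln-fold * z_k)
  over configured annotations — the generative twin of the fine-mapping
  prior;
* per-study Z-scores drawn as Z ~ Normal(sqrt(n) R beta_std, R), so marginal
  and joint statistics are internally consistent; allelic-scale betas in the
  output tables are recovered as trait_sd * z * se_allelic with
  se_allelic = trait_sd / sqrt(2 p (1 - p) n), exercising unit handling;
* Mendelian-randomisation instrument sets with a controllable pleiotropic
  outlier fraction;
* a four-variable MDRD equation for generating plausible eGFR phenotypes in
  end-to-end fixtures.

Identical configuration (including the seed) yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import AnnotationTrack, LDMatrix, StudySumStats

__all__ = [
    "AnnotationSpec",
    "MRConfig",
    "SimConfig",
    "ar1_ld",
    "simulate_frequencies",
    "simulate_locus",
    "simulate_panel",
    "simulate_genotype_locus",
    "simulate_mr",
    "mdrd_egfr",
    "LocusSim",
    "PanelSim",
]

ANCESTRIES = ("AFR", "EAS", "EUR", "HIS")

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class AnnotationSpec:
    """One simulated annotation track and its true causal-placement enrichment."""

    name: str
    category: str
    fold: float  # true fold enrichment of causal placement
    coverage: float = 0.1  # fraction of variants carrying the annotation


@dataclass(frozen=True)
class MRConfig:
    n_instruments: int = 94
    n_palindromic: int = 3
    causal_effect: float = -0.3
    pleiotropy_fraction: float = 0.0
    pleiotropy_scale: float = 0.5
    exposure_effect_sd: float = 0.15
    se_exp: float = 0.01
    se_out: float = 0.05


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic multi-ancestry panel.

    Defaults give 4 ancestry groups x 2 studies of 12,500 individuals
    (100,000 in total), 20 one-signal-or-two loci of 50 variants spanning
    ~1 Mb each, ancestry-specific LD decay and allele-frequency drift, and a
    single four-fold-enriched cell-type annotation — the conditions the
    recovery and calibration tests run under.
    """

    seed: int = 0
    studies_per_ancestry: int = 2
    n_per_study: int = 12_500
    n_loci: int = 20
    snvs_per_locus: int = 50
    spacing_bp: int = 20_000
    #: adjacent-variant LD correlation per ancestry
    ld_decay: dict = field(
        default_factory=lambda: {"AFR": 0.55, "EAS": 0.75, "EUR": 0.75, "HIS": 0.65}
    )
    #: Balding-Nichols drift per ancestry
    fst_drift: dict = field(
        default_factory=lambda: {"AFR": 0.14, "EAS": 0.11, "EUR": 0.09, "HIS": 0.07}
    )
    study_jitter_fst: float = 0.003
    causal_per_locus: int = 1
    #: unassociated background variants spread over the autosomes, away from
    #: the loci; they anchor the genomic-control median at ~1 as in a real
    #: genome-wide scan and provide shared variants for frequency distances
    n_null_variants: int = 4000
    effect_sd: float = 0.05  # standardized causal effect magnitude scale
    trait_sd: float = 15.0  # eGFR-like raw trait SD (ml/min/1.73m^2)
    annotations: tuple = (
        AnnotationSpec("kidney_histone", "cell_type_histone", 4.0, 0.1),
    )
    mr: MRConfig = field(default_factory=MRConfig)

    @property
    def ancestries(self) -> tuple:
        return ANCESTRIES

    @property
    def study_ids(self) -> list[str]:
        return [
            f"{anc}_{i + 1}"
            for anc in ANCESTRIES
            for i in range(self.studies_per_ancestry)
        ]

    @property
    def total_n(self) -> int:
        return self.n_per_study * self.studies_per_ancestry * len(ANCESTRIES)


def ar1_ld(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix: r_ij = rho^|i-j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _balding_nichols(rng, p0: np.ndarray, fst: float) -> np.ndarray:
    if fst <= 0:
        return p0.copy()
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 0.01, 0.99)


def simulate_frequencies(
    config: SimConfig, rng: np.random.Generator, n_snvs: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Ancestral and per-study effect-allele frequencies for ``n_snvs`` variants.

    Ancestral frequencies are Uniform(0.05, 0.95); each ancestry drifts under
    a Balding-Nichols model with its configured drift, and each study jitters
    around its ancestry mean.  With zero drift all ancestries share the
    ancestral frequencies exactly.  All outputs are clipped to [0.01, 0.99].
    """
    p0 = rng.uniform(0.05, 0.95, size=n_snvs)
    cols = {}
    for anc in ANCESTRIES:
        p_anc = _balding_nichols(rng, p0, config.fst_drift[anc])
        for i in range(config.studies_per_ancestry):
            cols[f"{anc}_{i + 1}"] = _balding_nichols(
                rng, p_anc, config.study_jitter_fst
            )
    return p0, pd.DataFrame(cols)


COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _draw_alleles(
    rng, m: int, allow_palindromic: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    ea = rng.choice(NUCLEOTIDES, size=m)
    shift = rng.integers(1, 4, size=m)
    oa = NUCLEOTIDES[(np.searchsorted(NUCLEOTIDES, ea) + shift) % 4]
    if not allow_palindromic:
        # shift by 2 never complements (A<->G, C<->T): strand-resolvable pairs
        pal = oa == np.vectorize(COMPLEMENT.get)(ea)
        oa[pal] = NUCLEOTIDES[(np.searchsorted(NUCLEOTIDES, ea[pal]) + 2) % 4]
    return ea, oa


@dataclass
class LocusSim:
    """One simulated locus: variants, per-study rows, LD and ground truth."""

    variants: pd.DataFrame
    study_tables: dict[str, pd.DataFrame]
    ld: dict[str, LDMatrix]  # per ancestry
    membership: np.ndarray  # (m, n_annotations) binary
    causal_idx: np.ndarray
    causal_beta: np.ndarray  # standardized effects at causal_idx
    lead_idx: int


def _place_causals(
    rng, membership: np.ndarray, folds: np.ndarray, k: int, r_ref: np.ndarray
) -> np.ndarray:
    """Draw k distinct causal indices with annotation-proportional weights.

    Rejection-samples until the causal set is mutually in low LD (|r| < 0.3
    in the reference ancestry) so multi-signal loci are dissectable, as real
    secondary signals arise from distinct haplotypes.
    """
    weights = np.exp(membership @ np.log(folds))
    prob = weights / weights.sum()
    m = membership.shape[0]
    for _ in range(200):
        idx = rng.choice(m, size=k, replace=False, p=prob)
        if k == 1 or np.all(
            np.abs(r_ref[np.ix_(idx, idx)][~np.eye(k, dtype=bool)]) < 0.3
        ):
            return np.sort(idx)
    return np.sort(idx)


def simulate_locus(
    config: SimConfig,
    rng: np.random.Generator,
    chrom: str = "1",
    center: int = 50_000_000,
    n_causal: int | None = None,
) -> LocusSim:
    """Simulate one locus across all studies of the panel.

    Per study in ancestry a with sample size n:
    Z ~ Normal(sqrt(n) R_a beta_std, R_a), so the marginal Z of the causal
    variant has expectation sqrt(n) beta and correlated noise matches the LD.
    Standardized effects are shared across studies (the homogeneous-effect
    model); allelic effects in the emitted tables are scaled by the trait SD
    and each study's allele frequency.
    """
    m = config.snvs_per_locus
    k = config.causal_per_locus if n_causal is None else n_causal
    start = center - (m // 2) * config.spacing_bp
    pos = start + np.arange(m) * config.spacing_bp
    ea, oa = _draw_alleles(rng, m)
    variants = pd.DataFrame(
        {
            "chrom": str(chrom),
            "pos": pos.astype(np.int64),
            "effect_allele": ea,
            "other_allele": oa,
            "rsid": [f"rs{chrom}_{p}" for p in pos],
        }
    )
    _, eaf = simulate_frequencies(config, rng, m)

    membership = np.column_stack(
        [rng.random(m) < spec.coverage for spec in config.annotations]
    ).astype(np.int8)
    folds = np.array([spec.fold for spec in config.annotations])
    ld = {
        anc: LDMatrix(
            variants[["chrom", "pos", "effect_allele", "other_allele"]].copy(),
            ar1_ld(m, config.ld_decay[anc]),
            anc,
        )
        for anc in ANCESTRIES
    }
    causal_idx = _place_causals(rng, membership, folds, k, ld["EUR"].r)
    # eGFR-decreasing orientation: standardized effects are negative, with
    # magnitudes spread +/-20% around the configured scale
    causal_beta = -config.effect_sd * rng.uniform(0.8, 1.2, size=k)
    beta_std = np.zeros(m)
    beta_std[causal_idx] = causal_beta

    study_tables: dict[str, pd.DataFrame] = {}
    chol = {anc: np.linalg.cholesky(ld[anc].r) for anc in ANCESTRIES}
    n = config.n_per_study
    for sid in config.study_ids:
        anc = sid.split("_")[0]
        mean = np.sqrt(n) * ld[anc].r @ beta_std
        z = mean + chol[anc] @ rng.standard_normal(m)
        p_eff = eaf[sid].to_numpy()
        se_allelic = config.trait_sd / np.sqrt(2 * p_eff * (1 - p_eff) * n)
        table = variants.copy()
        table["eaf"] = p_eff
        table["se"] = se_allelic
        table["beta"] = z * se_allelic
        table["n"] = n
        table["info"] = 1.0
        study_tables[sid] = table
    lead = int(causal_idx[np.argmax(np.abs(causal_beta))])
    return LocusSim(variants, study_tables, ld, membership, causal_idx, causal_beta, lead)


@dataclass
class PanelSim:
    """A full synthetic multi-ancestry panel over several independent loci."""

    config: SimConfig
    studies: list[StudySumStats]
    tracks: list[AnnotationTrack]
    loci: list[LocusSim]

    @property
    def annotation_names(self) -> list[str]:
        return [t.name for t in self.tracks]

    def ld_for(self, locus) -> dict[str, LDMatrix]:
        """Per-ancestry LD references for the simulated locus overlapping ``locus``.

        Accepts any object with ``chrom``/``start``/``end`` attributes (e.g. a
        defined association locus) and matches it to the simulated locus whose
        variants fall inside.
        """
        for loc in self.loci:
            if loc.variants["chrom"].iloc[0] != str(locus.chrom):
                continue
            pos = loc.variants["pos"]
            if (pos.between(locus.start, locus.end)).any():
                return loc.ld
        raise KeyError(f"no simulated locus overlaps {locus.chrom}:{locus.start}-{locus.end}")


def simulate_panel(
    config: SimConfig, causal_counts: list[int] | None = None
) -> PanelSim:
    """Simulate the full panel: studies, annotation tracks and truth records.

    Loci are placed on distinct chromosomes (cycling through the autosomes
    with well-separated centres) so they never merge.  ``causal_counts``
    optionally fixes the number of causal variants per locus.  Annotation
    BED tracks are constructed from the drawn memberships (one single-base
    interval per member variant), so interval lookup reproduces the truth.
    """
    rng = np.random.default_rng(config.seed)
    loci: list[LocusSim] = []
    for i in range(config.n_loci):
        chrom = str(i % 22 + 1)
        center = 30_000_000 + (i // 22) * 10_000_000
        k = causal_counts[i] if causal_counts is not None else config.causal_per_locus
        loci.append(simulate_locus(config, rng, chrom=chrom, center=center, n_causal=k))

    null_tables = _simulate_null_background(config, rng)

    studies = []
    for sid in config.study_ids:
        frames = [loc.study_tables[sid] for loc in loci]
        if len(null_tables[sid]):
            frames.append(null_tables[sid])
        table = pd.concat(frames, ignore_index=True).sort_values(
            ["chrom", "pos"], kind="stable"
        ).reset_index(drop=True)
        studies.append(StudySumStats(sid, sid.split("_")[0], table))

    tracks = []
    for a, spec in enumerate(config.annotations):
        rows = []
        for loc in loci:
            member_pos = loc.variants["pos"].to_numpy()[loc.membership[:, a] == 1]
            chrom = loc.variants["chrom"].iloc[0]
            rows += [(chrom, int(p) - 1, int(p)) for p in member_pos]
        intervals = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        intervals = intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        tracks.append(AnnotationTrack(spec.name, spec.category, intervals))
    return PanelSim(config, studies, tracks, loci)


def _simulate_null_background(
    config: SimConfig, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """Per-study tables for the unassociated background variants.

    Variants sit far from any locus (independent of each other and of every
    locus), with drifted frequencies and standard-normal Z per study.
    """
    m = config.n_null_variants
    if m == 0:
        empty = pd.DataFrame(
            columns=["chrom", "pos", "effect_allele", "other_allele", "rsid",
                     "eaf", "se", "beta", "n", "info"]
        )
        return {sid: empty.copy() for sid in config.study_ids}
    chrom = np.array([str(i % 22 + 1) for i in range(m)])
    pos = (200_000_000 + (np.arange(m) // 22) * 5_000).astype(np.int64)
    ea, oa = _draw_alleles(rng, m)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "rsid": [f"rsnull_{i}" for i in range(m)],
        }
    )
    _, eaf = simulate_frequencies(config, rng, m)
    n = config.n_per_study
    tables = {}
    for sid in config.study_ids:
        z = rng.standard_normal(m)
        p_eff = eaf[sid].to_numpy()
        se_allelic = config.trait_sd / np.sqrt(2 * p_eff * (1 - p_eff) * n)
        table = variants.copy()
        table["eaf"] = p_eff
        table["se"] = se_allelic
        table["beta"] = z * se_allelic
        table["n"] = n
        table["info"] = 1.0
        tables[sid] = table
    return tables


def simulate_genotype_locus(
    rng: np.random.Generator,
    n_individuals: int,
    freqs: np.ndarray,
    rho: float,
    beta_std: np.ndarray,
    noise_sd: float = 1.0,
):
    """Individual-level generator for oracle tests of conditional analysis.

    Genotypes arise from two haplotypes drawn via a Gaussian copula with
    AR(1) latent correlation ``rho``; the phenotype regresses on the
    standardized genotypes with coefficients ``beta_std`` plus Gaussian
    noise.  Returns (genotypes, standardized genotypes, phenotype).
    """
    m = freqs.size
    chol = np.linalg.cholesky(ar1_ld(m, rho))
    thresh = _norm_ppf(freqs)
    g = np.zeros((n_individuals, m), dtype=np.int8)
    for _ in range(2):
        latent = rng.standard_normal((n_individuals, m)) @ chol.T
        g += (latent < thresh).astype(np.int8)
    g_std = (g - g.mean(axis=0)) / g.std(axis=0)
    y = g_std @ beta_std + noise_sd * rng.standard_normal(n_individuals)
    return g, g_std, y


def _norm_ppf(p):
    from scipy.stats import norm

    return norm.ppf(p)


def simulate_mr(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Exposure/outcome summary statistics for two-sample MR, with truth.

    Instrument exposure effects are Normal(0, sd^2) truncated away from zero
    (|beta| > 0.5 sd); outcome effects are causal_effect * beta_exp plus a
    pleiotropic offset for the configured fraction of instruments plus noise
    at the stated standard error.  A configured number of instruments get
    palindromic (A/T or C/G) alleles, and roughly half the outcome records
    are emitted on the opposite allele orientation to exercise
    harmonisation.  Truth records the planted outlier variants.
    """
    mc = config.mr
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = mc.n_instruments
    chrom = np.array([(i % 22) + 1 for i in range(n)], dtype=str)
    pos = 1_000_000 + 2_000_000 * np.arange(n, dtype=np.int64)

    ea, oa = _draw_alleles(rng, n, allow_palindromic=False)
    pal_idx = rng.choice(n, size=mc.n_palindromic, replace=False)
    pal_pairs = [("A", "T"), ("C", "G"), ("T", "A"), ("G", "C")]
    for j, i in enumerate(pal_idx):
        ea[i], oa[i] = pal_pairs[j % 4]

    raw = rng.normal(0.0, mc.exposure_effect_sd, size=n)
    sign = np.where(raw == 0, 1.0, np.sign(raw))
    beta_exp = sign * np.maximum(np.abs(raw), 0.5 * mc.exposure_effect_sd)

    n_out = int(round(mc.pleiotropy_fraction * n))
    non_pal = np.setdiff1d(np.arange(n), pal_idx)
    outlier_idx = (
        rng.choice(non_pal, size=min(n_out, non_pal.size), replace=False)
        if n_out
        else np.array([], dtype=int)
    )
    pleio = np.zeros(n)
    pleio[outlier_idx] = mc.pleiotropy_scale * rng.choice([-1.0, 1.0], size=outlier_idx.size)
    beta_out = (
        mc.causal_effect * beta_exp + pleio + rng.normal(0.0, mc.se_out, size=n)
    )

    exposure = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "beta": beta_exp,
            "se": mc.se_exp,
        }
    )
    flip = rng.random(n) < 0.5
    outcome = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "effect_allele": np.where(flip, oa, ea),
            "other_allele": np.where(flip, ea, oa),
            "beta": np.where(flip, -beta_out, beta_out),
            "se": mc.se_out,
        }
    )
    truth = {
        "causal_effect": mc.causal_effect,
        "outlier_idx": np.sort(outlier_idx),
        "outlier_pos": set(zip(chrom[outlier_idx], pos[outlier_idx])),
        "palindromic_idx": np.sort(pal_idx),
    }
    return exposure, outcome, truth


def mdrd_egfr(scr, age, female=False, black=False):
    """Four-variable MDRD estimate of GFR (ml/min/1.73 m^2).

    eGFR = 175 * Scr^-1.154 * age^-0.203 * 0.742^female * 1.212^black, with
    serum creatinine in mg/dL and age in years.  Used only to generate
    plausible phenotypes for end-to-end fixtures.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("serum creatinine and age must be positive")
    egfr = 175.0 * scr**-1.154 * age**-0.203
    egfr = egfr * np.where(np.asarray(female, dtype=bool), 0.742, 1.0)
    egfr = egfr * np.where(np.asarray(black, dtype=bool), 1.212, 1.0)
    return egfr if egfr.shape else float(egfr)
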