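"""Approximate conditional dissection of association signals at a locus.

Loci often harbour more than one underlying causal variant.  Working only
from per-study summary statistics and an ancestry-matched LD reference, the
iterative approximate conditional approach (in the style of GCTA-COJO, on the
standardized Z/correlation scale) residualises each variant's Z-score on a
conditioning set S:

    z_cond,j = (z_j - R_jS R_SS^-1 z_S) / sqrt(1 - R_jS R_SS^-1 R_Sj)

Starting from the lead variant, per-study conditional Z-scores are combined
by sample-size-weighted meta-analysis (studies missing any conditioning
variant are excluded from that iteration), deflated by the unconditional
genomic-control lambda, and the strongest residual association is appended to
the conditioning set while it attains locus-wide significance (p < 1e-5).
Index variants for each signal are then defined by leave-one-out
conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import LDMatrix

__all__ = [
    "DegenerateConditioningError",
    "ConditionalZ",
    "LocusData",
    "Signal",
    "SignalSet",
    "conditional_z",
    "conditional_meta",
    "dissect_locus",
    "index_variants",
]


class DegenerateConditioningError(ValueError):
    """The conditioning set is numerically singular even after pruning."""


@dataclass
class ConditionalZ:
    """Per-variant conditional Z-scores with validity flags.

    ``valid`` is False for variants in (or collinear with) the conditioning
    set, whose conditional statistic is undefined rather than infinite.
    """

    z_cond: np.ndarray
    valid: np.ndarray


@dataclass
class LocusData:
    """Aligned per-study inputs for one locus.

    ``z`` and ``n`` are (n_studies, n_variants) arrays with NaN where a study
    did not report the variant; ``ld`` maps each study index to its
    ancestry-matched LD reference over the same variant ordering.
    """

    variants: "object"  # DataFrame with chrom/pos/effect_allele/other_allele
    study_ids: list[str]
    z: np.ndarray
    n: np.ndarray
    ld: dict[int, LDMatrix]

    @property
    def n_variants(self) -> int:
        return self.z.shape[1]


@dataclass
class Signal:
    signal_id: str
    index: int  # column index of the index variant within the locus
    z_cond: np.ndarray  # signal-specific conditional meta Z across the locus
    p_cond: np.ndarray
    valid: np.ndarray


@dataclass
class SignalSet:
    conditional_set: list[int]
    signals: list[Signal] = field(default_factory=list)

    @property
    def n_signals(self) -> int:
        return len(self.conditional_set)


def _prune_conditioning(r: np.ndarray, cond: list[int], r2_prune: float = 0.99) -> list[int]:
    """Drop later conditioning members in near-perfect LD with earlier ones."""
    kept: list[int] = []
    for j in cond:
        if all(r[j, k] ** 2 < r2_prune for k in kept):
            kept.append(j)
    return kept


def conditional_z(
    z: np.ndarray,
    ld: LDMatrix | np.ndarray,
    condition_set: list[int],
    collinearity_threshold: float = 0.9,
    ridge: float = 1e-8,
    max_condition_number: float = 1e8,
) -> ConditionalZ:
    """Conditional Z-scores for all variants given a conditioning set.

    Variants whose LD with the conditioning set explains more than
    ``collinearity_threshold`` of their variance are flagged invalid, as are
    the conditioning variants themselves.  ``R_SS`` receives a ridge jitter on
    the diagonal when ill-conditioned (reference-panel noise); a matrix that
    stays singular after pruning raises :class:`DegenerateConditioningError`.
    """
    r = ld.r if isinstance(ld, LDMatrix) else np.asarray(ld, dtype=float)
    z = np.asarray(z, dtype=float)
    m = z.size
    if r.shape != (m, m):
        raise ValueError("LD dimension does not match Z vector")
    cond = _prune_conditioning(r, list(condition_set))
    if not cond:
        raise ValueError("empty conditioning set")
    r_ss = r[np.ix_(cond, cond)].copy()
    if np.linalg.cond(r_ss) > max_condition_number:
        r_ss[np.diag_indices_from(r_ss)] += ridge
    try:
        chol = np.linalg.cholesky(r_ss)
    except np.linalg.LinAlgError:
        pair = _most_collinear_pair(r, cond)
        raise DegenerateConditioningError(
            f"conditioning set singular after pruning; offending pair {pair}"
        ) from None
    r_js = r[:, cond]  # (m, |S|)
    alpha = _chol_solve(chol, z[cond])
    q = np.einsum("ij,ij->i", r_js, _chol_solve(chol, r_js.T).T)
    with np.errstate(invalid="ignore", divide="ignore"):
        zc = (z - r_js @ alpha) / np.sqrt(np.clip(1.0 - q, 0.0, None))
    valid = (q <= collinearity_threshold) & np.isfinite(zc)
    valid[cond] = False
    zc[~valid] = np.nan
    return ConditionalZ(z_cond=zc, valid=valid)


def _chol_solve(chol: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    y = solve_triangular(chol, b, lower=True)
    return solve_triangular(chol.T, y, lower=False)


def _most_collinear_pair(r: np.ndarray, cond: list[int]) -> tuple[int, int]:
    best, pair = -1.0, (cond[0], cond[0])
    for a in range(len(cond)):
        for b in range(a + 1, len(cond)):
            v = abs(r[cond[a], cond[b]])
            if v > best:
                best, pair = v, (cond[a], cond[b])
    return pair


def conditional_meta(
    locus: LocusData,
    condition_set: list[int],
    lambda_gc: float = 1.0,
    collinearity_threshold: float = 0.9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stouffer-combined conditional Z across studies for one conditioning set.

    A study missing summary statistics for any variant in the conditioning
    set is excluded from the meta-analysis at this iteration; a study whose
    conditioning degenerates numerically is likewise excluded.  The combined
    Z is deflated by ``sqrt(lambda_gc)`` when ``lambda_gc > 1`` (the
    unconditional genomic-control factor is reused, matching the treatment of
    the unconditional scan).  Returns (z_meta, p, valid).
    """
    m = locus.n_variants
    num = np.zeros(m)
    den = np.zeros(m)
    any_valid = np.zeros(m, dtype=bool)
    for s in range(locus.z.shape[0]):
        zs = locus.z[s]
        ns = locus.n[s]
        if np.any(~np.isfinite(zs[condition_set])):
            continue  # study lacks a conditioning variant
        try:
            cz = conditional_z(
                np.nan_to_num(zs),
                locus.ld[s],
                condition_set,
                collinearity_threshold=collinearity_threshold,
            )
        except DegenerateConditioningError:
            continue
        ok = cz.valid & np.isfinite(zs) & np.isfinite(ns) & (ns > 0)
        num[ok] += np.sqrt(ns[ok]) * cz.z_cond[ok]
        den[ok] += ns[ok]
        any_valid |= ok
    with np.errstate(invalid="ignore", divide="ignore"):
        z_meta = num / np.sqrt(den)
    if lambda_gc > 1.0:
        z_meta = z_meta / np.sqrt(lambda_gc)
    z_meta[~any_valid] = np.nan
    p = 2.0 * stats.norm.sf(np.abs(z_meta))
    p[~any_valid] = np.nan
    return z_meta, p, any_valid


def dissect_locus(
    locus: LocusData,
    lead: int,
    p_locuswide: float = 1e-5,
    lambda_gc: float = 1.0,
    max_iter: int = 10,
    collinearity_threshold: float = 0.9,
) -> SignalSet:
    """Iteratively dissect a locus into distinct association signals.

    The conditioning set starts as {lead}.  Each iteration computes the
    conditional meta-analysis given the current set and appends the variant
    with the strongest residual association if it attains locus-wide
    significance; iteration stops when no variant does (or at ``max_iter``).
    """
    cond = [lead]
    for _ in range(max_iter - 1):
        _, p, valid = conditional_meta(
            locus, cond, lambda_gc, collinearity_threshold
        )
        p = np.where(valid, p, np.inf)
        j = int(np.argmin(p))
        if p[j] < p_locuswide:
            cond.append(j)
        else:
            break
    return SignalSet(conditional_set=cond)


def index_variants(
    locus: LocusData,
    signal_set: SignalSet,
    lambda_gc: float = 1.0,
    collinearity_threshold: float = 0.9,
) -> SignalSet:
    """Define per-signal index variants by leave-one-out conditioning.

    For each member s of the conditioning set, all locus variants are
    conditioned on the remaining members; the variant with the strongest
    residual association is the signal's index.  A single-member conditioning
    set falls back to the marginal meta-analysis.
    """
    cond = signal_set.conditional_set
    signals: list[Signal] = []
    for i, s in enumerate(cond):
        rest = [c for c in cond if c != s]
        if rest:
            z_meta, p, valid = conditional_meta(
                locus, rest, lambda_gc, collinearity_threshold
            )
        else:
            num = np.nansum(np.sqrt(locus.n) * locus.z, axis=0)
            den = np.nansum(np.where(np.isfinite(locus.z), locus.n, np.nan), axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                z_meta = num / np.sqrt(den)
            if lambda_gc > 1.0:
                z_meta = z_meta / np.sqrt(lambda_gc)
            valid = np.isfinite(z_meta)
            p = 2.0 * stats.norm.sf(np.abs(z_meta))
            p[~valid] = np.nan
        p_sel = np.where(valid, p, np.inf)
        index = int(np.argmin(p_sel))
        signals.append(
            Signal(signal_id=f"signal_{i + 1}", index=index, z_cond=z_meta, p_cond=p, valid=valid)
        )
    return SignalSet(conditional_set=list(cond), signals=signals)
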