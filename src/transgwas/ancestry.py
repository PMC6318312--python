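"""Axes of genetic variation and meta-regression heterogeneity partitioning.

Studies are embedded in a low-dimensional space by classical (Torgerson)
multidimensional scaling of a matrix of mean effect-allele-frequency
differences between each pair of studies; two axes suffice to separate the
four major ancestry groups.  Per-variant allelic effects are then modelled by
weighted least squares on the axes (weights 1/se^2), which partitions
between-study heterogeneity into an ancestry-correlated component (the axes,
a chi-square test on T degrees of freedom) and a residual component (the
full-model weighted residual sum of squares on K - T - 1 degrees of
freedom).  The two statistics sum to the total Cochran Q of the
intercept-only model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AncestryAxes",
    "MetaRegressionResult",
    "freq_distance_matrix",
    "mds_axes",
    "meta_regression",
    "meta_regression_scan",
    "heterogeneity_screen",
]


@dataclass
class AncestryAxes:
    """Per-study coordinates on T centred axes of genetic variation."""

    study_ids: list[str]
    coords: np.ndarray  # (n_studies, T)
    eigenvalues: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]


@dataclass
class MetaRegressionResult:
    beta0: float
    axis_coeffs: np.ndarray
    q_ancestry: float
    q_residual: float
    p_het_ancestry: float
    p_het_residual: float
    k_studies: int


def freq_distance_matrix(
    eaf: pd.DataFrame, metric: str = "mean_abs"
) -> np.ndarray:
    """Pairwise allele-frequency distances between studies.

    ``eaf`` is variants x studies (NaN where a study lacks the variant).
    The distance between two studies is the mean absolute difference in
    effect-allele frequency over the variants both report ("mean_sq" gives
    the mean squared difference instead).  A pair with no shared variants is
    an error.
    """
    k = eaf.shape[1]
    if k < 2:
        raise ValueError("need at least two studies")
    vals = eaf.to_numpy(dtype=float)
    d = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            shared = np.isfinite(vals[:, a]) & np.isfinite(vals[:, b])
            if not shared.any():
                raise ValueError(
                    f"no shared variants between studies "
                    f"{eaf.columns[a]!r} and {eaf.columns[b]!r}"
                )
            diff = vals[shared, a] - vals[shared, b]
            d[a, b] = d[b, a] = (
                np.mean(np.abs(diff)) if metric == "mean_abs" else np.mean(diff**2)
            )
    return d


def mds_axes(d: np.ndarray, study_ids: list[str] | None = None, n_axes: int = 2) -> AncestryAxes:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centre -D^2/2, eigendecompose, and return the top ``n_axes``
    coordinates scaled by the square root of the eigenvalue.  The sign of
    each axis is fixed so its largest-magnitude loading is positive.
    """
    d = np.asarray(d, dtype=float)
    k = d.shape[0]
    if study_ids is None:
        study_ids = [f"study_{i}" for i in range(k)]
    j = np.eye(k) - np.ones((k, k)) / k
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = int(np.sum(evals > 1e-10 * max(1.0, evals[0])))
    if n_axes > positive:
        raise ValueError(
            f"requested {n_axes} axes but the distance matrix supports only {positive}"
        )
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    for t in range(n_axes):
        i = int(np.argmax(np.abs(coords[:, t])))
        if coords[i, t] < 0:
            coords[:, t] = -coords[:, t]
    return AncestryAxes(list(study_ids), coords, eigenvalues=evals[:n_axes])


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted least squares; returns (coefficients, weighted RSS)."""
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(x * sw[:, None], y * sw, rcond=None)
    resid = y - x @ coef
    return coef, float(np.sum(w * resid**2))


def meta_regression(
    beta: np.ndarray,
    se: np.ndarray,
    axes: np.ndarray,
) -> MetaRegressionResult:
    """Per-variant meta-regression of allelic effects on the ancestry axes.

    Weighted least squares of per-study betas on [1, axes] with weights
    1/se^2.  The ancestry-correlated heterogeneity statistic is the drop in
    weighted RSS from the intercept-only model to the full model, referred to
    chi^2_T; residual heterogeneity is the full-model weighted RSS referred
    to chi^2_{K-T-1}.  With T = 0 axes this reduces exactly to fixed-effects
    inverse-variance meta-analysis.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    if axes.shape[0] != beta.size:
        axes = axes.T
    k = beta.size
    t = axes.shape[1] if axes.size else 0
    if k < t + 2:
        raise ValueError(f"need at least {t + 2} studies for {t} axes, got {k}")
    w = 1.0 / se**2
    x_full = np.column_stack([np.ones(k), axes]) if t else np.ones((k, 1))
    beta0_only = np.sum(w * beta) / np.sum(w)
    q_total = float(np.sum(w * (beta - beta0_only) ** 2))
    coef, q_resid = _wls(x_full, beta, w)
    q_anc = max(q_total - q_resid, 0.0)
    return MetaRegressionResult(
        beta0=float(coef[0]),
        axis_coeffs=coef[1:],
        q_ancestry=q_anc,
        q_residual=q_resid,
        p_het_ancestry=float(stats.chi2.sf(q_anc, t)) if t else 1.0,
        p_het_residual=float(stats.chi2.sf(q_resid, k - t - 1)),
        k_studies=k,
    )


def meta_regression_scan(
    beta: np.ndarray,
    se: np.ndarray,
    axes: np.ndarray,
) -> pd.DataFrame:
    """Vectorised meta-regression over many variants.

    ``beta`` and ``se`` are (n_variants, n_studies) with NaN for studies
    missing a variant (complete-case per variant); ``axes`` is
    (n_studies, T).  Variants with fewer than T + 2 informative studies get
    NaN results.  Returns a DataFrame with one row per variant.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    axes = np.asarray(axes, dtype=float)
    n_var, k = beta.shape
    t = axes.shape[1]
    out = {
        "beta0": np.full(n_var, np.nan),
        "q_ancestry": np.full(n_var, np.nan),
        "q_residual": np.full(n_var, np.nan),
        "p_het_ancestry": np.full(n_var, np.nan),
        "p_het_residual": np.full(n_var, np.nan),
        "k_studies": np.zeros(n_var, dtype=int),
    }
    complete = np.isfinite(beta) & np.isfinite(se)
    for v in range(n_var):
        mask = complete[v]
        kk = int(mask.sum())
        out["k_studies"][v] = kk
        if kk < t + 2:
            continue
        res = meta_regression(beta[v, mask], se[v, mask], axes[mask])
        out["beta0"][v] = res.beta0
        out["q_ancestry"][v] = res.q_ancestry
        out["q_residual"][v] = res.q_residual
        out["p_het_ancestry"][v] = res.p_het_ancestry
        out["p_het_residual"][v] = res.p_het_residual
    return pd.DataFrame(out)


def heterogeneity_screen(
    p_het_ancestry: np.ndarray, n_signals: int, alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Bonferroni screen for ancestry-correlated heterogeneity.

    Returns (flags, threshold) with threshold = alpha / n_signals.
    """
    if n_signals < 1:
        raise ValueError("n_signals must be >= 1")
    threshold = alpha / n_signals
    p = np.asarray(p_het_ancestry, dtype=float)
    return p < threshold, threshold
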