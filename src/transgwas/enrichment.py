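"""Approximate Bayes factors and annotation enrichment of association signals.

For the j-th variant at the i-th distinct signal, the evidence for
association given the meta-analysis Z-score across K contributing studies is
approximated by the Bayes factor

    Lambda_ij = exp[(Z_ij^2 - ln K) / 2],

and the log-odds that the variant drives the signal is
ln[Lambda_ij / (T_i - Lambda_ij)] with T_i = sum_j Lambda_ij.  Everything is
kept in log space (log-sum-exp, log1p) so |Z| up to 50 stays finite.

Enrichment of signals in genomic annotations is estimated by regressing the
per-variant posterior fraction pi_ij = Lambda_ij / T_i on binary annotation
membership in a fractional-response logistic model with per-signal fixed
intercepts, so the linear predictor is exactly the log-odds above plus
annotation shifts; the annotation coefficient beta_k is the log-fold
enrichment in the odds of association.  Annotations are screened per
category by forward selection at nominal significance, then combined in one
joint model whose estimates feed the fine-mapping prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy import stats

__all__ = [
    "SignalABF",
    "EnrichmentModel",
    "ln_abf",
    "signal_log_odds",
    "fit_enrichment",
    "forward_select",
    "joint_model",
]

# Posterior fractions are clipped here before the logit fit: a signal whose
# posterior mass collapses onto one variant would otherwise produce infinite
# logits.
PI_CLIP = 1e-12


def ln_abf(z, k):
    """Log approximate Bayes factor (Z^2 - ln K) / 2 for K >= 1 studies.

    Strictly increasing in Z^2 and decreasing in K; never exponentiated.
    """
    z = np.asarray(z, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(k < 1):
        raise ValueError("contributing-study count must be >= 1")
    if np.any(~np.isfinite(z)):
        raise ValueError("Z-scores must be finite")
    return (z**2 - np.log(k)) / 2.0


@dataclass
class SignalABF:
    """Per-variant Bayes-factor summaries for one distinct signal."""

    signal_id: str
    ln_abf: np.ndarray
    ln_total: float
    log_odds: np.ndarray
    pi_raw: np.ndarray


def signal_log_odds(ln_abf_vec: np.ndarray, signal_id: str = "") -> SignalABF:
    """Log-odds of association and raw posterior fractions for one signal.

    log_odds_j = ln Lambda_j - ln(T - Lambda_j), computed stably as
    ln_abf_j - (ln_total + log1p(-exp(ln_abf_j - ln_total))); pi_raw is the
    softmax of the log Bayes factors and sums to one.  A signal needs at
    least two variants for the odds to be defined.
    """
    la = np.asarray(ln_abf_vec, dtype=float)
    if la.size < 2:
        raise ValueError("log-odds undefined for a single-variant signal")
    ln_total = float(logsumexp(la))
    delta = la - ln_total  # <= 0, == 0 only if one variant carries all mass
    with np.errstate(divide="ignore"):
        log_rest = ln_total + np.log1p(-np.exp(delta))
    log_odds = la - log_rest
    pi_raw = np.exp(delta)
    pi_raw /= pi_raw.sum()
    return SignalABF(signal_id, la, ln_total, log_odds, pi_raw)


@dataclass
class EnrichmentModel:
    """Log-fold enrichment estimates for a set of annotations.

    ``excluded`` lists annotations that could not be estimated (no contrast
    across variants, or separation driving the coefficient to infinity).
    """

    annotations: list[str]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    category: list[str] = field(default_factory=list)
    stage: str = "category-selected"
    excluded: dict[str, str] = field(default_factory=dict)

    def fold(self) -> np.ndarray:
        return np.exp(self.beta)

    def coef(self, name: str) -> float:
        return float(self.beta[self.annotations.index(name)])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "annotation": self.annotations,
                "category": self.category or [""] * len(self.annotations),
                "beta": self.beta,
                "fold": self.fold(),
                "se": self.se,
                "p": self.p,
                "stage": self.stage,
            }
        )


def _stack(signal_abfs, z_by_signal, cols):
    """Stacked response/design across signals for the chosen annotation columns."""
    pi = np.concatenate([s.pi_raw for s in signal_abfs])
    z = np.concatenate([np.asarray(z)[:, cols] for z in z_by_signal], axis=0)
    sizes = [s.pi_raw.size for s in signal_abfs]
    groups = np.repeat(np.arange(len(sizes)), sizes)
    return np.clip(pi, PI_CLIP, 1 - PI_CLIP), z.astype(float), groups


def _group_wmean(values: np.ndarray, w: np.ndarray, groups: np.ndarray, n_groups: int):
    """Weighted per-group means, broadcast back to rows."""
    sw = np.bincount(groups, weights=w, minlength=n_groups)
    if values.ndim == 1:
        m = np.bincount(groups, weights=w * values, minlength=n_groups) / sw
        return m[groups], m
    m = np.column_stack(
        [
            np.bincount(groups, weights=w * values[:, j], minlength=n_groups) / sw
            for j in range(values.shape[1])
        ]
    )
    return m[groups], m


def _fit_fractional_logit(
    y: np.ndarray,
    x: np.ndarray,
    groups: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-10,
):
    """Quasi-binomial IRLS with per-group fixed-effect intercepts absorbed.

    Solves the same score equations as a GLM of ``y`` on group dummies plus
    ``x`` with a logit link, but concentrates the intercepts out of every
    weighted-least-squares step (within-group weighted centring), so cost is
    linear in rows regardless of the number of signals.  Standard errors use
    the Pearson chi-square dispersion.  Returns (beta, se, converged).
    """
    n, k = x.shape
    n_groups = int(groups.max()) + 1
    beta = np.zeros(k)
    # start intercepts at the within-group logit of the mean response
    _, mean_y = _group_wmean(y, np.ones(n), groups, n_groups)
    alpha = np.log(mean_y / (1 - mean_y))
    converged = False
    for _ in range(max_iter):
        eta = alpha[groups] + x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-300, None)
        u = eta + (y - mu) / w
        u_c, u_means = _group_wmean(u, w, groups, n_groups)
        x_c, x_means = _group_wmean(x, w, groups, n_groups)
        xt = x - x_c
        ut = u - u_c
        xtwx = (xt * w[:, None]).T @ xt
        xtwu = (xt * w[:, None]).T @ ut
        new_beta = np.linalg.solve(xtwx, xtwu)
        alpha = u_means - x_means @ new_beta
        if np.max(np.abs(new_beta - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = new_beta
            converged = True
            break
        beta = new_beta
    eta = alpha[groups] + x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-300, None)
    pearson = float(np.sum((y - mu) ** 2 / w))
    dof = max(n - n_groups - k, 1)
    phi = pearson / dof
    x_c, _ = _group_wmean(x, w, groups, n_groups)
    xt = x - x_c
    cov = phi * np.linalg.inv((xt * w[:, None]).T @ xt)
    se = np.sqrt(np.diag(cov))
    return beta, se, converged


def fit_enrichment(
    signal_abfs: list[SignalABF],
    z_by_signal: list[np.ndarray],
    annotations: list[str],
    subset: list[str] | None = None,
    categories: dict[str, str] | None = None,
    stage: str = "category-selected",
    method: str = "fractional_logit",
) -> EnrichmentModel:
    """Fit the annotation-enrichment model across signals.

    The response is the per-variant posterior fraction pi_raw with a logit
    link and per-signal fixed-effect intercepts; annotation coefficients are
    shared across signals.  Standard errors use a quasi-likelihood (Pearson
    chi-square) dispersion, with Wald p-values.  ``method="wls_logodds"``
    instead fits ordinary least squares on the finite log-odds.

    Annotations with no contrast (all variants in or all out) are excluded
    with reason "no_contrast"; a coefficient diverging to +/-inf (separation)
    is excluded with reason "separation".
    """
    if len(signal_abfs) < 2:
        raise ValueError("need at least two signals to estimate enrichment")
    names = list(annotations)
    use = names if subset is None else list(subset)
    cols = [names.index(a) for a in use]
    excluded: dict[str, str] = {}

    pi, z, groups = _stack(signal_abfs, z_by_signal, cols)
    if z.shape[1] == 0:
        return EnrichmentModel(
            [], np.array([]), np.array([]), np.array([]), [], stage, excluded
        )
    n_groups = int(groups.max()) + 1
    keep: list[int] = []
    # within-signal centred columns: a column collinear with the signal
    # intercepts (or with an earlier annotation) cannot be estimated
    z_c, _ = _group_wmean(z, np.ones(z.shape[0]), groups, n_groups)
    zt = z - z_c
    basis: list[np.ndarray] = []
    for i, a in enumerate(use):
        col = zt[:, i]
        norm = np.linalg.norm(col)
        if z[:, i].min() == z[:, i].max() or norm < 1e-12:
            excluded[a] = "no_contrast"
            continue
        resid = col.copy()
        for b in basis:
            resid -= (resid @ b) * b
        if np.linalg.norm(resid) < 1e-8 * norm:
            excluded[a] = "collinear"
            continue
        basis.append(resid / np.linalg.norm(resid))
        keep.append(i)
    use = [use[i] for i in keep]
    z = z[:, keep]

    if not use:
        return EnrichmentModel(
            [], np.array([]), np.array([]), np.array([]),
            [], stage, excluded,
        )

    if method == "fractional_logit":
        beta, se, _ = _fit_fractional_logit(pi, z, groups)
    elif method == "wls_logodds":
        n_sig = len(signal_abfs)
        intercepts = np.zeros((pi.size, n_sig))
        intercepts[np.arange(pi.size), groups] = 1.0
        x = np.column_stack([intercepts, z])
        y = np.concatenate([s.log_odds for s in signal_abfs])
        finite = np.isfinite(y)
        coef, *_ = np.linalg.lstsq(x[finite], y[finite], rcond=None)
        resid = y[finite] - x[finite] @ coef
        dof = max(finite.sum() - x.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.pinv(x[finite].T @ x[finite])
        beta = coef[n_sig:]
        se = np.sqrt(sigma2 * np.diag(xtx_inv)[n_sig:])
    else:
        raise ValueError(f"unknown method {method!r}")

    final_names, fb, fs = [], [], []
    for a, b, s in zip(use, beta, se):
        if not np.isfinite(b) or not np.isfinite(s) or abs(b) > 30:
            excluded[a] = "separation"
        else:
            final_names.append(a)
            fb.append(b)
            fs.append(s)
    fb = np.asarray(fb)
    fs = np.asarray(fs)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(fb / fs))
    cats = [categories.get(a, "") for a in final_names] if categories else []
    return EnrichmentModel(final_names, fb, fs, p, cats, stage, excluded)


def forward_select(
    signal_abfs: list[SignalABF],
    z_by_signal: list[np.ndarray],
    annotations: list[str],
    category_annotations: list[str],
    alpha: float = 0.05,
    categories: dict[str, str] | None = None,
) -> list[str]:
    """Forward selection of jointly enriched annotations within one category.

    At each step every remaining candidate is refitted jointly with the
    current selection; the candidate with the smallest Wald p-value is added
    while that p-value is below ``alpha``.  Ties break by lexicographic
    annotation label; candidates that become inestimable alongside the
    current selection (e.g. perfectly collinear) are skipped.  Deterministic
    given the data; may select nothing.
    """
    selected: list[str] = []
    remaining = sorted(category_annotations)
    while remaining:
        best_name, best_p = None, np.inf
        for cand in remaining:
            model = fit_enrichment(
                signal_abfs,
                z_by_signal,
                annotations,
                subset=selected + [cand],
                categories=categories,
            )
            if cand not in model.annotations:
                continue
            p = float(model.p[model.annotations.index(cand)])
            if p < best_p:  # strict: lexicographic order wins exact ties
                best_name, best_p = cand, p
        if best_name is None or best_p >= alpha:
            break
        selected.append(best_name)
        remaining.remove(best_name)
    return selected


def joint_model(
    signal_abfs: list[SignalABF],
    z_by_signal: list[np.ndarray],
    annotations: list[str],
    selected: list[str],
    categories: dict[str, str] | None = None,
) -> EnrichmentModel:
    """Final joint fit of all selected annotations across categories.

    The resulting log-fold enrichments are the coefficients that define the
    annotation-informed fine-mapping prior.  With no selected annotations an
    empty model is returned and downstream priors stay uniform.
    """
    if not selected:
        return EnrichmentModel(
            [], np.array([]), np.array([]), np.array([]), [], "joint", {}
        )
    model = fit_enrichment(
        signal_abfs,
        z_by_signal,
        annotations,
        subset=selected,
        categories=categories,
        stage="joint",
    )
    model.stage = "joint"
    return model
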