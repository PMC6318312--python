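"""Annotation-informed fine-mapping: posteriors, credible sets, high confidence.

For each distinct signal the posterior probability that variant j drives the
association is pi_j proportional to gamma_j * Lambda_j, where Lambda_j is the
approximate Bayes factor and the relative annotation-informed prior is
gamma_j = exp[sum_k beta_k z_jk] over the jointly enriched annotations (a
uniform prior when none were selected).  The 99% credible set is the minimal
prefix of the pi-descending ranking whose cumulative posterior attains the
target mass; a signal whose top variant carries more than 50% of the
posterior is called high-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .enrichment import EnrichmentModel

__all__ = [
    "FineMapResult",
    "annotation_prior",
    "posterior",
    "credible_set",
    "high_confidence",
    "finemap_signal",
]


def annotation_prior(z: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Log relative prior ln gamma = sum_k beta_k z_k per variant.

    ``z`` is (n_variants, n_annotations) binary membership restricted to the
    selected annotations; with no annotations the prior is uniform (0).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    beta = np.asarray(beta, dtype=float)
    if beta.size == 0:
        return np.zeros(z.shape[0])
    if z.shape[1] != beta.size:
        raise ValueError(
            f"membership has {z.shape[1]} annotations but model has {beta.size}"
        )
    return z @ beta


def posterior(ln_abf: np.ndarray, ln_prior: np.ndarray | None = None) -> np.ndarray:
    """Posterior probabilities pi = softmax(ln_abf + ln_prior).

    Computed via log-sum-exp; invariant to adding any constant to the log
    Bayes factors.  With a uniform prior this equals the raw posterior
    fraction Lambda_j / T.
    """
    la = np.asarray(ln_abf, dtype=float)
    if la.size < 1:
        raise ValueError("empty signal")
    if ln_prior is not None:
        la = la + np.asarray(ln_prior, dtype=float)
    if np.all(np.isneginf(la)):
        raise ValueError("all variants carry -inf evidence")
    pi = np.exp(la - logsumexp(la))
    return pi / pi.sum()


def credible_set(
    pi: np.ndarray,
    mass: float = 0.99,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the minimal credible set at the given posterior mass.

    Variants are ranked by descending pi (exact ties by ascending position
    when ``positions`` is given, else by index) and included until the
    cumulative posterior attains or exceeds ``mass``.
    """
    pi = np.asarray(pi, dtype=float)
    if not np.isclose(pi.sum(), 1.0, atol=1e-6):
        raise ValueError("posterior probabilities must sum to 1")
    tiebreak = np.asarray(positions) if positions is not None else np.arange(pi.size)
    order = np.lexsort((tiebreak, -pi))
    cum = np.cumsum(pi[order])
    k = int(np.searchsorted(cum, mass - 1e-12) + 1)
    return order[: min(k, pi.size)]


def high_confidence(pi: np.ndarray, threshold: float = 0.5) -> int | None:
    """Index of the unique variant with pi strictly above ``threshold``, if any."""
    pi = np.asarray(pi, dtype=float)
    j = int(np.argmax(pi))
    return j if pi[j] > threshold else None


@dataclass
class FineMapResult:
    """Fine-mapping output for one distinct signal."""

    signal_id: str
    ln_abf: np.ndarray
    ln_prior: np.ndarray
    pi: np.ndarray
    credible_set: np.ndarray  # variant indices, descending pi
    cumulative_pi: np.ndarray
    high_confidence: tuple[int, float] | None

    @property
    def credible_set_size(self) -> int:
        return self.credible_set.size


def finemap_signal(
    ln_abf_vec: np.ndarray,
    z: np.ndarray,
    model: EnrichmentModel,
    mass: float = 0.99,
    positions: np.ndarray | None = None,
    signal_id: str = "",
    hc_threshold: float = 0.5,
) -> FineMapResult:
    """Fine-map one signal under the annotation-informed prior.

    ``z`` is the binary membership matrix over the joint model's annotations
    (same variant universe as the Bayes factors — all variants at the locus
    passing the coverage filter).
    """
    beta = model.beta if model is not None else np.array([])
    ln_prior = annotation_prior(z, beta)
    pi = posterior(ln_abf_vec, ln_prior)
    cs = credible_set(pi, mass=mass, positions=positions)
    hc = high_confidence(pi, threshold=hc_threshold)
    return FineMapResult(
        signal_id=signal_id,
        ln_abf=np.asarray(ln_abf_vec, dtype=float),
        ln_prior=ln_prior,
        pi=pi,
        credible_set=cs,
        cumulative_pi=np.cumsum(pi[cs]),
        high_confidence=(hc, float(pi[hc])) if hc is not None else None,
    )
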