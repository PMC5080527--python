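"""Measurement diagnostics: dimensionality, item fit, local independence.

Three screens, each against a published-practice default threshold that is a
configurable argument, never a constant:

* **Parallel analysis** — observed eigenvalues of the inter-item Pearson
  (phi) correlation matrix against eigenvalues from data with the same
  margins but no inter-item structure (independent column permutations of
  the observed matrix). A component is retained while its eigenvalue exceeds
  the 95th percentile of the simulated ones; the count stops at the first
  failure. Adjusted eigenvalues are reported as observed - (simulated mean - 1).
* **Infit mean square** — information-weighted average squared standardized
  residual per item; 1 under model fit, flagged outside (0.91, 1.09) by
  default. A standardized form (infit t) is reported via the Wilson-Hilferty
  cube-root transformation.
* **Residual correlations (Yen's Q3)** — Pearson correlations of standardized
  residual columns; each pair tested with chi^2 = n * r^2 on 1 df, Holm
  step-down adjustment over all pairs as one family; a pair is flagged when
  both r > 0.2 and adjusted p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ResponseMatrix
from .errors import ValidationError
from .rasch import ItemParameters, PersonAbility, _conditional_item_probs

__all__ = [
    "ParallelAnalysisResult",
    "ItemFitResult",
    "LocalDependenceResult",
    "parallel_analysis",
    "infit",
    "residual_correlations",
]


@dataclass
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    random_mean: np.ndarray
    random_p95: np.ndarray
    adjusted_eigenvalues: np.ndarray
    n_retained: int
    n_sims: int
    seed: int


@dataclass
class ItemFitResult:
    labels: list[str]
    infit_msq: np.ndarray
    infit_t: np.ndarray
    bounds: tuple[float, float]
    misfit_flags: np.ndarray


@dataclass
class LocalDependenceResult:
    labels: list[str]
    pair_correlations: np.ndarray  # symmetric Q3 matrix, unit diagonal
    chi2: np.ndarray  # condensed upper-triangle order
    p_raw: np.ndarray
    p_holm: np.ndarray
    pairs: list[tuple[str, str]]
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)


def parallel_analysis(
    data: ResponseMatrix,
    n_sims: int = 5000,
    seed: int = 0,
    percentile: float = 95.0,
) -> ParallelAnalysisResult:
    """Horn-style parallel analysis for dichotomous items.

    The null eigenvalue distribution comes from independently permuting each
    column of the observed matrix, which preserves the binary item margins
    (which alone distort eigenvalues) while destroying inter-item structure.
    """
    if data.n_items < 2:
        raise ValidationError("parallel analysis needs at least 2 items")
    if n_sims < 100:
        raise ValidationError("n_sims must be at least 100")
    x = data.responses.astype(float)
    if np.any(x.std(axis=0) == 0):
        bad = [data.item_labels[i] for i in np.flatnonzero(x.std(axis=0) == 0)]
        raise ValidationError(f"constant column(s) {bad}: correlation undefined")
    k = data.n_items
    observed = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sims, k))
    for b in range(n_sims):
        perm = rng.permuted(x, axis=0)
        sims[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(perm, rowvar=False)))[::-1]
    random_mean = sims.mean(axis=0)
    random_p95 = np.percentile(sims, percentile, axis=0)
    exceeds = observed > random_p95
    n_retained = int(np.argmin(exceeds)) if not exceeds.all() else k
    adjusted = observed - (random_mean - 1.0)
    return ParallelAnalysisResult(
        observed_eigenvalues=observed,
        random_mean=random_mean,
        random_p95=random_p95,
        adjusted_eigenvalues=adjusted,
        n_retained=n_retained,
        n_sims=n_sims,
        seed=seed,
    )


def _model_probs_nonextreme(
    data: ResponseMatrix, items: ItemParameters, persons: PersonAbility
) -> tuple[np.ndarray, np.ndarray]:
    """Responses and fitted probabilities restricted to non-extreme persons.

    The expected probability for person v on item i is the score-conditional
    expectation E[x_vi | raw score r_v] from the elementary symmetric
    functions. Unlike probabilities evaluated at a per-person ability
    estimate, these are exactly the model's conditional means, so the mean
    squared standardized residual is calibrated to 1 under the model rather
    than deflated by the ability-estimation degrees of freedom.
    """
    k = data.n_items
    keep = (persons.raw_score > 0) & (persons.raw_score < k)
    x = data.responses[keep].astype(float)
    pi = _conditional_item_probs(-items.beta)  # (k, k+1) indexed by raw score
    p = pi[:, persons.raw_score[keep]].T
    return x, p


def infit(
    data: ResponseMatrix,
    items: ItemParameters,
    persons: PersonAbility,
    bounds: tuple[float, float] = (0.91, 1.09),
) -> ItemFitResult:
    """Information-weighted mean-square fit per item, over non-extreme persons."""
    x, p = _model_probs_nonextreme(data, items, persons)
    w = p * (1 - p)
    resid2 = (x - p) ** 2
    msq = resid2.sum(axis=0) / w.sum(axis=0)
    # Wilson-Hilferty standardization: kurtosis-based variance of the weighted msq
    c = w * (p**3 + (1 - p) ** 3)
    q2 = np.clip((c - w**2).sum(axis=0) / w.sum(axis=0) ** 2, 1e-12, None)
    q = np.sqrt(q2)
    t = (np.cbrt(msq) - 1.0) * (3.0 / q) + q / 3.0
    lo, hi = bounds
    flags = (msq < lo) | (msq > hi)
    return ItemFitResult(
        labels=list(items.labels), infit_msq=msq, infit_t=t, bounds=bounds, misfit_flags=flags
    )


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (one family)."""
    return multipletests(np.asarray(p_values, float), method="holm")[1]


def residual_correlations(
    data: ResponseMatrix,
    items: ItemParameters,
    persons: PersonAbility,
    r_threshold: float = 0.2,
    alpha: float = 0.05,
) -> LocalDependenceResult:
    """Yen's Q3 screen for local dependence between item pairs.

    Standardized residuals ``z = (x - P) / sqrt(P(1-P))`` are correlated
    across items; the pair statistic is ``chi^2 = n * r^2`` on 1 df and the
    pair family is Holm-adjusted. A pair is flagged only when the correlation
    exceeds ``r_threshold`` AND the adjusted p-value is at most ``alpha``.
    """
    x, p = _model_probs_nonextreme(data, items, persons)
    z = (x - p) / np.sqrt(p * (1 - p))
    n_eff = z.shape[0]
    q3 = np.corrcoef(z, rowvar=False)
    k = data.n_items
    iu, ju = np.triu_indices(k, 1)
    r = q3[iu, ju]
    chi2 = n_eff * r**2
    p_raw = stats.chi2.sf(chi2, df=1)
    p_holm = holm_adjust(p_raw)
    pairs = [(items.labels[i], items.labels[j]) for i, j in zip(iu, ju)]
    flagged = [
        pairs[m] for m in range(len(pairs)) if r[m] > r_threshold and p_holm[m] <= alpha
    ]
    return LocalDependenceResult(
        labels=list(items.labels),
        pair_correlations=q3,
        chi2=chi2,
        p_raw=p_raw,
        p_holm=p_holm,
        pairs=pairs,
        flagged_pairs=flagged,
    )
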