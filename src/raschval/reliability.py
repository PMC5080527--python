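"""Internal consistency and person separation.

Two reliability summaries with the conventional acceptance thresholds as
configurable defaults:

* **Cronbach's alpha** (> 0.8): ``alpha = k/(k-1) * (1 - sum var_i / var_total)``
  with n-1 denominators.
* **Person Separation Index** (> 0.7): the share of observed person-measure
  variance not attributable to estimation error,
  ``PSI = (var(theta_hat) - mean(se^2)) / var(theta_hat)``. Computed over all
  persons — the weighted-likelihood ability estimates are finite for extreme
  scorers, so nobody is excluded by default. PSI can be negative when the
  error variance exceeds the observed spread; it is reported unclipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ResponseMatrix
from .errors import ValidationError
from .rasch import PersonAbility

__all__ = ["ReliabilityResult", "cronbach_alpha", "person_separation_index", "reliability_summary"]


@dataclass
class ReliabilityResult:
    alpha: float
    psi: float
    n_items: int
    n_persons_used: int
    pass_alpha: bool
    pass_psi: bool


def cronbach_alpha(data: ResponseMatrix) -> float:
    """Cronbach's alpha for the item set (sample variances, n-1 denominator)."""
    if data.n_items < 2:
        raise ValidationError("Cronbach alpha needs at least 2 items")
    x = data.responses.astype(float)
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValidationError("total score has zero variance; alpha undefined")
    k = data.n_items
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def person_separation_index(persons: PersonAbility, exclude_extreme: bool = False) -> float:
    """PSI = (var(theta_hat) - mean(se^2)) / var(theta_hat).

    ``exclude_extreme`` drops persons with zero or perfect raw scores before
    computing, for parity with software that cannot estimate them.
    """
    theta, se, raw = persons.theta, persons.se, persons.raw_score
    if exclude_extreme:
        k = raw.max()
        keep = (raw > 0) & (raw < k)
        theta, se = theta[keep], se[keep]
    if theta.size < 2:
        raise ValidationError("PSI needs at least 2 persons")
    obs_var = float(np.var(theta, ddof=1))
    if obs_var == 0:
        raise ValidationError("person measures have zero variance; PSI undefined")
    err_var = float(np.mean(se**2))
    return (obs_var - err_var) / obs_var


def reliability_summary(
    data: ResponseMatrix,
    persons: PersonAbility,
    alpha_threshold: float = 0.8,
    psi_threshold: float = 0.7,
) -> ReliabilityResult:
    """Alpha and PSI with strict-inequality pass flags."""
    a = cronbach_alpha(data)
    psi = person_separation_index(persons)
    return ReliabilityResult(
        alpha=a,
        psi=psi,
        n_items=data.n_items,
        n_persons_used=data.n_persons,
        pass_alpha=bool(a > alpha_threshold),
        pass_psi=bool(psi > psi_threshold),
    )
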