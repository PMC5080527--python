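"""Differential item and test functioning for a binary grouping covariate.

Persons are stratified by their total raw score on all items (the Rasch
sufficient statistic for ability), and each item is tested for

* **uniform DIF** with the Mantel-Haenszel chi-square (continuity corrected):
  does one group endorse the item more at every ability level?
* **non-uniform DIF** with the Breslow-Day homogeneity-of-odds-ratios test
  (Tarone corrected): does the group gap change across ability levels?

An item is flagged when either test is significant. Scale-level differential
test functioning is summarized by tau^2, the weighted between-item variance of
the Mantel-Haenszel log odds ratios, banded small / medium / large at 0.07 and
0.14. The moment estimator can be negative (no truncation); a negative value
simply means less dispersion than sampling error alone would produce.

The Mantel-Haenszel and Breslow-Day statistics themselves are computed by
``statsmodels.stats.contingency_tables.StratifiedTable``; this module owns the
score stratification, the zero-margin stratum handling, the flag rule and the
tau^2 estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.contingency_tables import StratifiedTable

from .data_io import ResponseMatrix
from .errors import ValidationError

__all__ = [
    "DifResult",
    "DtfResult",
    "mantel_haenszel",
    "breslow_day",
    "dif_decision",
    "dif_analysis",
    "dtf_tau_squared",
]


@dataclass
class DifResult:
    """Per-item DIF statistics for one grouping covariate."""

    item: str
    mh_chi2: float = np.nan
    mh_p: float = np.nan
    mh_log_or: float = np.nan
    mh_log_or_var: float = np.nan
    bd_chi2: float = np.nan
    bd_df: int = 0
    bd_p: float = np.nan
    n_strata: int = 0
    flagged: bool = False
    untestable: list = None

    def __post_init__(self) -> None:
        if self.untestable is None:
            self.untestable = []


@dataclass
class DtfResult:
    """Scale-level DIF variance with effect band."""

    tau2: float
    effect_band: str  # small / medium / large

    @staticmethod
    def band(tau2: float, small: float = 0.07, large: float = 0.14) -> str:
        # boundaries fall to the lower band
        if tau2 <= small:
            return "small"
        if tau2 <= large:
            return "medium"
        return "large"


def _strata_tables(
    data: ResponseMatrix, item: str, group: str, min_margin: int = 0
) -> np.ndarray:
    """2x2 tables (rows: group 1/0, cols: item response 0/1) per raw-score stratum.

    Row order puts group 1 first so the pooled log odds ratio measures the
    endorsement odds of group 0 relative to group 1 — i.e. a difficulty shift
    of +delta logits for group 1 appears as a log odds ratio near +delta.

    Strata with a zero margin (only one group present, or no variation in the
    response) carry no information about the odds ratio and are dropped. With
    ``min_margin > 0``, adjacent score strata are first pooled until every
    stratum's smallest group/response margin reaches ``min_margin``; the
    homogeneity test needs reasonably filled tables per stratum, whereas the
    Mantel-Haenszel pooled test does not.
    """
    if group not in data.covariates:
        raise ValidationError(f"covariate {group!r} not present in data")
    g = data.covariates[group]
    if len(np.unique(g)) < 2:
        raise ValidationError(f"covariate {group!r} has a single level")
    i = data.item_labels.index(item)
    x = data.responses[:, i]
    score = data.raw_scores()
    raw = []
    for s in np.unique(score):
        m = score == s
        raw.append(
            np.array(
                [
                    [np.sum((g == 1) & (x == 0) & m), np.sum((g == 1) & (x == 1) & m)],
                    [np.sum((g == 0) & (x == 0) & m), np.sum((g == 0) & (x == 1) & m)],
                ],
                dtype=float,
            )
        )
    if min_margin > 0:
        merged, cur = [], None
        for tab in raw:
            cur = tab if cur is None else cur + tab
            if min(cur.sum(axis=0).min(), cur.sum(axis=1).min()) >= min_margin:
                merged.append(cur)
                cur = None
        if cur is not None:
            if merged:
                merged[-1] += cur
            else:
                merged.append(cur)
        raw = merged
    tables = [
        t for t in raw if t.sum(axis=0).min() > 0 and t.sum(axis=1).min() > 0
    ]
    return np.array(tables)


def mantel_haenszel(data: ResponseMatrix, item: str, group: str) -> DifResult:
    """Mantel-Haenszel uniform-DIF test for one item, stratified by raw score.

    Returns the continuity-corrected chi-square, the pooled (common) log odds
    ratio and its Robins-Breslow-Greenland variance.
    """
    tables = _strata_tables(data, item, group)
    if len(tables) == 0:
        raise ValidationError(f"DIF untestable for item {item!r}: no informative strata")
    st = StratifiedTable(tables.transpose(1, 2, 0))
    res = st.test_null_odds(correction=True)
    return DifResult(
        item=item,
        mh_chi2=float(res.statistic),
        mh_p=float(res.pvalue),
        mh_log_or=float(st.logodds_pooled),
        mh_log_or_var=float(st.logodds_pooled_se) ** 2,
        n_strata=len(tables),
    )


def breslow_day(
    data: ResponseMatrix, item: str, group: str, min_stratum_margin: int = 10
) -> DifResult:
    """Breslow-Day non-uniform-DIF (odds-ratio homogeneity) test, Tarone corrected.

    Adjacent sparse score strata are pooled until every stratum's smallest
    margin reaches ``min_stratum_margin``; the homogeneity statistic is badly
    behaved on near-empty tables. With fewer than two informative strata the
    test is undefined and the item is reported as untestable rather than
    raising.
    """
    tables = _strata_tables(data, item, group, min_margin=min_stratum_margin)
    out = DifResult(item=item, n_strata=len(tables))
    if len(tables) < 2:
        out.untestable.append("breslow_day")
        return out
    st = StratifiedTable(tables.transpose(1, 2, 0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = st.test_equal_odds(adjust=True)
    out.bd_chi2 = float(res.statistic)
    out.bd_df = len(tables) - 1
    out.bd_p = float(res.pvalue)
    return out


def dif_decision(mh_p: float, bd_p: float, alpha: float = 0.05) -> bool:
    """Combined flag rule: flagged when either test is significant (strict <).

    An untestable component (NaN p-value) is treated as non-significant.
    """
    mh_sig = bool(np.isfinite(mh_p) and mh_p < alpha)
    bd_sig = bool(np.isfinite(bd_p) and bd_p < alpha)
    return mh_sig or bd_sig


def dif_analysis(
    data: ResponseMatrix, group: str, alpha: float = 0.05
) -> tuple[list[DifResult], "DtfResult"]:
    """Run MH + BD on every item for one covariate, plus scale-level tau^2."""
    results = []
    for item in data.item_labels:
        mh = mantel_haenszel(data, item, group)
        bd = breslow_day(data, item, group)
        mh.bd_chi2, mh.bd_df, mh.bd_p = bd.bd_chi2, bd.bd_df, bd.bd_p
        mh.untestable = bd.untestable
        mh.flagged = dif_decision(mh.mh_p, mh.bd_p, alpha)
        results.append(mh)
    effects = [
        (r.mh_log_or, r.mh_log_or_var)
        for r in results
        if np.isfinite(r.mh_log_or) and np.isfinite(r.mh_log_or_var) and r.mh_log_or_var > 0
    ]
    dtf = dtf_tau_squared(effects)
    return results, dtf


def dtf_tau_squared(items: list[tuple[float, float]]) -> DtfResult:
    """Weighted method-of-moments variance of item DIF effects.

    With weights ``w_i = 1 / v_i`` and the weighted mean ``lam_bar``,

        tau2 = (sum w_i^2 (lam_i - lam_bar)^2 - sum w_i) / sum w_i^2

    Not truncated at zero: a negative estimate indicates the observed
    dispersion is below its sampling expectation.
    """
    if len(items) < 2:
        raise ValidationError("tau^2 needs at least 2 items with finite DIF effects")
    lam = np.array([l for l, _ in items], float)
    v = np.array([x for _, x in items], float)
    if np.any(v <= 0) or not np.all(np.isfinite(lam)) or not np.all(np.isfinite(v)):
        raise ValidationError("DIF effects and variances must be finite with v > 0")
    w = 1.0 / v
    lam_bar = np.sum(w * lam) / np.sum(w)
    tau2 = float((np.sum(w**2 * (lam - lam_bar) ** 2) - np.sum(w)) / np.sum(w**2))
    return DtfResult(tau2=tau2, effect_band=DtfResult.band(tau2))
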