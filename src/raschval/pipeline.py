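"""End-to-end scale validation with an auditable item-elimination trail.

The pipeline mirrors standard Rasch scale-validation practice on a
calibration/validation pair of samples:

1. split the input into two disjoint random samples (calibration/validation);
2. parallel analysis of the full item set in each sample;
3. local-independence pass — a Q3-flagged pair that replicates in both
   samples loses the member with the larger mean absolute residual
   correlation against all other items (tie-break: worse ``|ln infit_msq|``),
   one item at a time with refitting;
4. iterative item-fit elimination — remove the single worst item whose infit
   lies outside the bounds in the same direction in both samples (worst
   first by the calibration ``|ln infit_msq|``), refitting after each
   removal; passes 3 and 4 repeat until neither eliminates;
5. parallel analysis again on the retained set;
6. DIF screening per covariate (Mantel-Haenszel + Breslow-Day + tau^2 DTF)
   on both samples; DIF items are flagged and reported, never auto-removed —
   group-dependent endorsement is a finding about the item, not by itself a
   reason to shorten the scale;
7. reliability (alpha, PSI) for the initial set, the retained set, and any
   user-named subsets, in both samples;
8. every elimination decision replayed on the validation sample and the
   statistics recorded.

Elimination order and the choice of which item goes are driven by the
calibration sample; the validation sample can veto (a finding that does not
replicate is reported, not acted on) but never initiates an elimination.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import dif as dif_mod
from .data_io import ResponseMatrix, SampleSplit, split_samples
from .diagnostics import (
    LocalDependenceResult,
    infit,
    parallel_analysis,
    residual_correlations,
)
from .errors import EstimationError, ValidationError
from .rasch import estimate_abilities, fit_cml
from .reliability import reliability_summary

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "wright_map"]


@dataclass
class PipelineConfig:
    """All thresholds of the validation protocol, serializable to YAML."""

    n_per_sample: int = 500
    pa_sims: int = 5000
    infit_bounds: tuple[float, float] = (0.91, 1.09)
    q3_threshold: float = 0.2
    alpha_level: float = 0.05
    dif_covariates: list[str] = field(default_factory=list)
    alpha_threshold: float = 0.8
    psi_threshold: float = 0.7
    reliability_subsets: dict[str, list[str]] = field(default_factory=dict)
    min_items: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.infit_bounds
        if not (0 < lo < 1 < hi):
            raise ValidationError(f"infit bounds {self.infit_bounds} must straddle 1")
        if not (0 < self.alpha_level < 1):
            raise ValidationError("alpha_level must be in (0, 1)")
        if not (0 < self.q3_threshold < 1):
            raise ValidationError("q3_threshold must be in (0, 1)")
        self.infit_bounds = tuple(self.infit_bounds)

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["infit_bounds"] = list(d["infit_bounds"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, TypeError):
                d = yaml.safe_load(source)
        d["infit_bounds"] = tuple(d.get("infit_bounds", (0.91, 1.09)))
        return cls(**d)


@dataclass
class Elimination:
    stage: str  # "item_fit" or "local_dependence"
    item: str
    reason: str
    statistic: float
    item_set_before: list[str]


@dataclass
class PipelineResult:
    config: PipelineConfig
    elimination_log: list[Elimination]
    retained_items: list[str]
    initial_items: list[str]
    pa_initial: dict
    pa_retained: dict
    final_infit: dict
    final_q3: dict
    dif_reports: dict  # covariate -> {sample -> {items: [...], tau2, band}}
    reliability: dict  # subset name -> {sample -> ReliabilityResult dict}
    validation_agreement: list[dict]
    wright_map_data: dict

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return clean(asdict(obj))
            return obj

        return clean(
            {
                "config": asdict(self.config),
                "elimination_log": [asdict(e) for e in self.elimination_log],
                "retained_items": self.retained_items,
                "initial_items": self.initial_items,
                "pa_initial": self.pa_initial,
                "pa_retained": self.pa_retained,
                "final_infit": self.final_infit,
                "final_q3": self.final_q3,
                "dif_reports": self.dif_reports,
                "reliability": self.reliability,
                "validation_agreement": self.validation_agreement,
                "wright_map_data": self.wright_map_data,
            }
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _fit_all(sample: ResponseMatrix, labels: list[str], bounds):
    sub = sample.subset_items(labels)
    items = fit_cml(sub)
    persons = estimate_abilities(sub, items)
    fit = infit(sub, items, persons, bounds=bounds)
    return sub, items, persons, fit


def _pa_dict(res) -> dict:
    return {
        "observed_eigenvalues": res.observed_eigenvalues,
        "random_mean": res.random_mean,
        "random_p95": res.random_p95,
        "adjusted_eigenvalues": res.adjusted_eigenvalues,
        "n_retained": res.n_retained,
        "n_sims": res.n_sims,
    }


def _q3_victim(ld: LocalDependenceResult, fit, pair: tuple[str, str]) -> tuple[str, float]:
    """Choose which member of a dependent pair to drop.

    The member with the larger mean |Q3| against all other items goes; ties
    break toward the worse ``|ln infit_msq|``.
    """
    labels = ld.labels
    q3 = np.abs(ld.pair_correlations.copy())
    np.fill_diagonal(q3, np.nan)
    scores = {}
    for lab in pair:
        i = labels.index(lab)
        scores[lab] = float(np.nanmean(q3[i]))
    a, b = pair
    if not np.isclose(scores[a], scores[b]):
        victim = a if scores[a] > scores[b] else b
    else:
        msq = {lab: abs(np.log(fit.infit_msq[fit.labels.index(lab)])) for lab in pair}
        victim = a if msq[a] >= msq[b] else b
    return victim, scores[victim]


def run_pipeline(data: ResponseMatrix, config: PipelineConfig) -> PipelineResult:
    """Run the full validation protocol; see the module docstring for stages."""
    for cov in config.dif_covariates:
        if cov not in data.covariates:
            raise ValidationError(f"requested DIF covariate {cov!r} not in data")

    split = split_samples(data, config.n_per_sample, config.seed)
    cal, val = split.calibration, split.validation
    initial_items = list(data.item_labels)
    log: list[Elimination] = []

    # stage 2: dimensionality of the full set, both samples
    pa_initial = {
        "calibration": _pa_dict(
            parallel_analysis(cal, n_sims=config.pa_sims, seed=config.seed + 1)
        ),
        "validation": _pa_dict(
            parallel_analysis(val, n_sims=config.pa_sims, seed=config.seed + 2)
        ),
    }

    # stages 3 and 5: iterative elimination, driven by the calibration sample
    # and confirmed by the validation sample. An item (or dependent pair) is
    # only actionable when the finding is consistent in BOTH samples — a
    # borderline flag that does not replicate is reported but not eliminated.
    # Two subtleties:
    # * local dependence inflates the apparent discrimination of both members
    #   of a dependent pair, pushing their infit BELOW the lower bound, and a
    #   strongly dependent pair also drags every other item's infit upward;
    #   so flagged pairs are resolved before item-fit decisions, and an
    #   overfitting item that sits in a flagged pair is never eliminated for
    #   "misfit" — the pathology is redundancy, not a broken Guttman pattern;
    # * within each pass, one item is removed at a time (worst first by the
    #   calibration statistic) and everything is refit before the next look.
    def _check_floor(item: str) -> None:
        if len(current) - 1 < config.min_items:
            raise EstimationError(
                f"eliminating {item!r} would leave fewer than {config.min_items} "
                f"items; aborting with partial log ({len(log)} eliminations)"
            )

    lo, hi = config.infit_bounds
    current = list(initial_items)
    changed = True
    while changed:
        changed = False
        # local-independence pass: pair must be Q3-flagged in both samples
        while True:
            sub, items, persons, fit = _fit_all(cal, current, config.infit_bounds)
            ld = residual_correlations(
                sub, items, persons, r_threshold=config.q3_threshold, alpha=config.alpha_level
            )
            vsub, vitems, vpersons, vfit = _fit_all(val, current, config.infit_bounds)
            vld = residual_correlations(
                vsub, vitems, vpersons, r_threshold=config.q3_threshold, alpha=config.alpha_level
            )
            vpairs = {tuple(sorted(p)) for p in vld.flagged_pairs}
            both = [p for p in ld.flagged_pairs if tuple(sorted(p)) in vpairs]
            if not both:
                break
            # handle the most correlated flagged pair first
            pair = max(
                both,
                key=lambda pr: abs(
                    ld.pair_correlations[ld.labels.index(pr[0]), ld.labels.index(pr[1])]
                ),
            )
            victim, _ = _q3_victim(ld, fit, pair)
            _check_floor(victim)
            r_pair = ld.pair_correlations[ld.labels.index(pair[0]), ld.labels.index(pair[1])]
            log.append(
                Elimination(
                    stage="local_dependence",
                    item=victim,
                    reason=f"Q3={r_pair:.3f} with pair {pair} in both samples; larger mean |Q3|",
                    statistic=float(r_pair),
                    item_set_before=list(current),
                )
            )
            current.remove(victim)
            changed = True
        # item-fit pass: infit outside bounds, same direction, in both samples
        while True:
            sub, items, persons, fit = _fit_all(cal, current, config.infit_bounds)
            ld = residual_correlations(
                sub, items, persons, r_threshold=config.q3_threshold, alpha=config.alpha_level
            )
            vsub, vitems, vpersons, vfit = _fit_all(val, current, config.infit_bounds)
            vld = residual_correlations(
                vsub, vitems, vpersons, r_threshold=config.q3_threshold, alpha=config.alpha_level
            )
            in_flagged_pair = {lab for res in (ld, vld) for pr in res.flagged_pairs for lab in pr}
            offenders = []
            for j, lab in enumerate(fit.labels):
                mc, mv = fit.infit_msq[j], vfit.infit_msq[j]
                consistent = (mc > hi and mv > hi) or (mc < lo and mv < lo)
                if consistent and not (mc < lo and lab in in_flagged_pair):
                    offenders.append((lab, mc))
            if not offenders:
                break
            worst, msq = max(offenders, key=lambda t: abs(np.log(t[1])))
            _check_floor(worst)
            log.append(
                Elimination(
                    stage="item_fit",
                    item=worst,
                    reason=f"infit_msq {msq:.3f} outside {config.infit_bounds} in both samples",
                    statistic=float(msq),
                    item_set_before=list(current),
                )
            )
            current.remove(worst)
            changed = True

    retained = list(current)

    # stage 4 (after eliminations, as re-check): dimensionality of the retained set
    pa_retained = {
        "calibration": _pa_dict(
            parallel_analysis(
                cal.subset_items(retained), n_sims=config.pa_sims, seed=config.seed + 3
            )
        ),
        "validation": _pa_dict(
            parallel_analysis(
                val.subset_items(retained), n_sims=config.pa_sims, seed=config.seed + 4
            )
        ),
    }

    # final calibration fit on the retained set
    sub_cal, items_cal, persons_cal, fit_cal = _fit_all(cal, retained, config.infit_bounds)
    ld_cal = residual_correlations(
        sub_cal, items_cal, persons_cal, r_threshold=config.q3_threshold, alpha=config.alpha_level
    )
    final_infit = {
        "labels": fit_cal.labels,
        "infit_msq": fit_cal.infit_msq,
        "infit_t": fit_cal.infit_t,
        "beta": items_cal.beta,
        "beta_se": items_cal.se,
    }
    final_q3 = {
        "labels": ld_cal.labels,
        "pair_correlations": ld_cal.pair_correlations,
        "flagged_pairs": ld_cal.flagged_pairs,
    }

    # stage 6: DIF screening on the retained set, both samples; never eliminates
    dif_reports: dict = {}
    for cov in config.dif_covariates:
        dif_reports[cov] = {}
        for name, sample in (("calibration", cal), ("validation", val)):
            results, dtf = dif_mod.dif_analysis(
                sample.subset_items(retained), cov, alpha=config.alpha_level
            )
            dif_reports[cov][name] = {
                "items": [asdict(r) for r in results],
                "tau2": dtf.tau2,
                "effect_band": dtf.effect_band,
            }

    # stage 7: reliability for initial, retained, and user-named subsets
    subsets = {"initial": initial_items, "retained": retained}
    subsets.update(config.reliability_subsets)
    reliability: dict = {}
    for name, labels in subsets.items():
        reliability[name] = {}
        for sname, sample in (("calibration", cal), ("validation", val)):
            sub = sample.subset_items(labels)
            it = fit_cml(sub)
            pers = estimate_abilities(sub, it)
            rel = reliability_summary(
                sub, pers, config.alpha_threshold, config.psi_threshold
            )
            reliability[name][sname] = asdict(rel)

    # stage 8: replay every elimination decision on the validation sample
    validation_agreement = []
    for e in log:
        vsub, vitems, vpersons, vfit = _fit_all(val, e.item_set_before, config.infit_bounds)
        if e.stage == "item_fit":
            j = vfit.labels.index(e.item)
            agrees = bool(vfit.misfit_flags[j])
            vstat = float(vfit.infit_msq[j])
        else:
            vld = residual_correlations(
                vsub, vitems, vpersons,
                r_threshold=config.q3_threshold, alpha=config.alpha_level,
            )
            agrees = any(e.item in pr for pr in vld.flagged_pairs)
            i = vld.labels.index(e.item)
            off_diag = np.delete(np.abs(vld.pair_correlations[i]), i)
            vstat = float(off_diag.max())
        validation_agreement.append(
            {
                "stage": e.stage,
                "item": e.item,
                "calibration_statistic": e.statistic,
                "validation_statistic": vstat,
                "agrees": agrees,
            }
        )

    # Wright-map data: persons and retained items on the shared logit axis
    hist, edges = np.histogram(persons_cal.theta, bins=20)
    wright = {
        "person_theta": persons_cal.theta,
        "person_se": persons_cal.se,
        "person_raw_score": persons_cal.raw_score,
        "hist_counts": hist,
        "hist_edges": edges,
        "item_labels": list(items_cal.labels),
        "item_beta": items_cal.beta,
        "item_beta_se": items_cal.se,
    }

    return PipelineResult(
        config=config,
        elimination_log=log,
        retained_items=retained,
        initial_items=initial_items,
        pa_initial=pa_initial,
        pa_retained=pa_retained,
        final_infit=final_infit,
        final_q3=final_q3,
        dif_reports=dif_reports,
        reliability=reliability,
        validation_agreement=validation_agreement,
        wright_map_data=wright,
    )


def wright_map_text(result: PipelineResult) -> str:
    """Plain-text person/item map on one logit axis."""
    w = result.wright_map_data
    theta = np.asarray(w["person_theta"], float)
    if theta.size == 0:
        raise ValidationError("no persons to map")
    beta = np.asarray(w["item_beta"], float)
    labels = list(w["item_labels"])
    lo = min(theta.min(), beta.min()) - 0.5
    hi = max(theta.max(), beta.max()) + 0.5
    edges = np.linspace(lo, hi, 25)
    counts, _ = np.histogram(theta, bins=edges)
    scale = max(1, counts.max() // 40 + 1)
    lines = ["logit      persons" + " " * 42 + "items", "-" * 72]
    order = np.argsort(beta)
    for b in range(len(edges) - 2, -1, -1):
        mid = 0.5 * (edges[b] + edges[b + 1])
        bar = "#" * (counts[b] // scale)
        here = [labels[i] for i in order if edges[b] <= beta[i] < edges[b + 1]]
        lines.append(f"{mid:+6.2f}  | {bar:<48} | {', '.join(here)}")
    lines.append("-" * 72)
    lines.append(f"each # = {scale} person(s); items placed at their difficulty")
    return "\n".join(lines)


def wright_map(result: PipelineResult, out=None):
    """Render the person-item map; returns (figure, text table).

    Both renderings derive from the same arrays in ``wright_map_data``. If
    ``out`` is given the PNG is written there and a ``.txt`` sibling holds the
    text rendering.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    text = wright_map_text(result)  # validates non-empty person set
    w = result.wright_map_data
    theta = np.asarray(w["person_theta"], float)
    beta = np.asarray(w["item_beta"], float)
    labels = list(w["item_labels"])
    fig, (ax1, ax2) = plt.subplots(
        1, 2, sharey=True, figsize=(8, 6), gridspec_kw={"width_ratios": [2, 1]}
    )
    ax1.hist(theta, bins=20, orientation="horizontal", color="steelblue", alpha=0.8)
    ax1.set_xlabel("persons")
    ax1.set_ylabel("latent trait (logits)")
    ax1.invert_xaxis()
    order = np.argsort(beta)
    ax2.scatter(np.zeros(beta.size), beta, marker="x", color="firebrick")
    for i in order:
        ax2.annotate(labels[i], (0.05, beta[i]), fontsize=8, va="center")
    ax2.set_xlim(-0.2, 1.0)
    ax2.set_xticks([])
    ax2.set_xlabel("items")
    fig.suptitle("Person-item map")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
        from pathlib import Path

        Path(str(out)).with_suffix(".txt").write_text(text)
        plt.close(fig)
    return fig, text
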