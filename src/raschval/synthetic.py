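"""Synthetic dichotomous response data with known ground truth.

The generator draws a unimodal latent trait and produces Bernoulli item
responses under a Rasch model, with optional planted violations of each model
assumption so every diagnostic has a test bed with known truth:

* ``misfit_slopes`` — per-item discrimination ``a_i`` (1 for all = Rasch;
  a low slope yields underfit/noise, a high slope overfit).
* ``dif_spec`` — uniform DIF as a symmetric difficulty split ``beta_i ± delta/2``
  between the two covariate groups (so the pooled difficulty is unchanged),
  and/or non-uniform DIF as a group-specific slope ratio (what a
  homogeneity-of-odds-ratios test is sensitive to).
* ``dependence_spec`` — local dependence by copying one item's response onto
  another with probability ``rho``.
* ``second_dim_spec`` — a second, independent latent dimension loading a
  subset of items.

The default configuration emulates an 11-item binary depression-symptom
inventory: difficulties spanning roughly -0.8 to +2.3 logits (irritability
easiest, mood instability hardest), 500 persons, trait ~ Normal(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ResponseMatrix
from .errors import ValidationError

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_responses", "DEFAULT_ITEMS"]

# 11-item depression-symptom profile: (label, difficulty in logits).
# Easiest item is irritability, hardest is mood instability.
DEFAULT_ITEMS: list[tuple[str, float]] = [
    ("sad", 0.05),
    ("no_interest", 1.60),
    ("weight_appetite", 0.72),
    ("sleep", 0.17),
    ("agitation_retardation", 2.23),
    ("fatigue", -0.25),
    ("self_blame", 2.23),
    ("cognition", 0.39),
    ("suicidal_ideas", 1.14),
    ("mood_instability", 2.33),
    ("irritability", -0.77),
]


@dataclass
class DifSpec:
    """Planted differential item functioning for one item against one covariate.

    ``uniform_shift`` is the total difficulty gap delta between groups (split
    symmetrically, ``beta ± delta/2``); ``nonuniform_slope_ratio`` multiplies
    the item slope in group 1 only (1.0 = none).
    """

    item: str
    covariate: str = "group"
    uniform_shift: float = 0.0
    nonuniform_slope_ratio: float = 1.0


@dataclass
class DependenceSpec:
    """Planted local dependence: item_j copies item_i with probability rho."""

    item_i: str
    item_j: str
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError(f"copy probability rho={self.rho} outside [0, 1]")


@dataclass
class SecondDimSpec:
    """A second latent dimension theta2 ~ Normal(0, theta2_sd) loading `items` with weight `loading`."""

    items: list[str]
    loading: float = 1.0
    theta2_sd: float = 1.0


@dataclass
class SyntheticConfig:
    """Full generative specification; the seed determines the output exactly."""

    n_persons: int = 500
    item_labels: list[str] = field(default_factory=lambda: [l for l, _ in DEFAULT_ITEMS])
    item_difficulties: list[float] = field(default_factory=lambda: [b for _, b in DEFAULT_ITEMS])
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    misfit_slopes: list[float] | None = None
    dif_spec: list[DifSpec] = field(default_factory=list)
    dependence_spec: list[DependenceSpec] = field(default_factory=list)
    second_dim_spec: SecondDimSpec | None = None
    covariate_names: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.item_labels) != len(self.item_difficulties):
            raise ValidationError("item_labels and item_difficulties lengths differ")
        beta = np.asarray(self.item_difficulties, float)
        if not np.all(np.isfinite(beta)):
            raise ValidationError("item difficulties must be finite")
        if self.misfit_slopes is not None and len(self.misfit_slopes) != len(self.item_labels):
            raise ValidationError("misfit_slopes length must equal the number of items")
        # every covariate a DIF spec mentions is generated
        for d in self.dif_spec:
            if d.item not in self.item_labels:
                raise ValidationError(f"DIF spec names unknown item {d.item!r}")
            if d.covariate not in self.covariate_names:
                self.covariate_names.append(d.covariate)
        for dep in self.dependence_spec:
            for lab in (dep.item_i, dep.item_j):
                if lab not in self.item_labels:
                    raise ValidationError(f"dependence spec names unknown item {lab!r}")
        if self.second_dim_spec is not None:
            for lab in self.second_dim_spec.items:
                if lab not in self.item_labels:
                    raise ValidationError(f"second-dimension spec names unknown item {lab!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["dif_spec"] = [DifSpec(**x) for x in d.get("dif_spec", [])]
        d["dependence_spec"] = [DependenceSpec(**x) for x in d.get("dependence_spec", [])]
        if d.get("second_dim_spec"):
            d["second_dim_spec"] = SecondDimSpec(**d["second_dim_spec"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Everything planted: kept alongside the data for test assertions."""

    theta: np.ndarray
    theta2: np.ndarray | None
    beta: np.ndarray
    slopes: np.ndarray
    covariates: dict[str, np.ndarray]
    config: SyntheticConfig


def generate_responses(config: SyntheticConfig) -> tuple[ResponseMatrix, SyntheticTruth]:
    """Draw a response matrix from the configured generative model.

    Responses are Bernoulli with
    ``logit P_vi = a_vi * (theta_v + lambda2 * theta2_v * [i in dim-2 set]
    - beta_i - shift_vi)`` where ``a_vi`` and ``shift_vi`` carry the planted
    misfit and DIF, followed by the dependence copy step.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_persons, len(config.item_labels)
    beta = np.asarray(config.item_difficulties, float)
    theta = rng.normal(config.theta_mean, config.theta_sd, size=n)

    # balanced random binary covariates (half 0, half 1, shuffled)
    covariates: dict[str, np.ndarray] = {}
    for name in config.covariate_names:
        vec = np.zeros(n, dtype=np.int8)
        vec[: n // 2] = 1
        rng.shuffle(vec)
        covariates[name] = vec

    base_slopes = (
        np.ones(k) if config.misfit_slopes is None else np.asarray(config.misfit_slopes, float)
    )
    slopes = np.broadcast_to(base_slopes, (n, k)).copy()  # per person x item
    shift = np.zeros((n, k))
    for d in config.dif_spec:
        i = config.item_labels.index(d.item)
        g = covariates[d.covariate]
        # symmetric split keeps the pooled difficulty unchanged
        shift[:, i] += np.where(g == 1, d.uniform_shift / 2.0, -d.uniform_shift / 2.0)
        if d.nonuniform_slope_ratio != 1.0:
            slopes[g == 1, i] *= d.nonuniform_slope_ratio

    eta = theta[:, None] - beta[None, :] - shift
    theta2 = None
    if config.second_dim_spec is not None:
        sd2 = config.second_dim_spec
        theta2 = rng.normal(0.0, sd2.theta2_sd, size=n)
        idx2 = [config.item_labels.index(l) for l in sd2.items]
        eta[:, idx2] += sd2.loading * theta2[:, None]
    prob = 1.0 / (1.0 + np.exp(-slopes * eta))
    x = (rng.random((n, k)) < prob).astype(np.int8)

    for dep in config.dependence_spec:
        i = config.item_labels.index(dep.item_i)
        j = config.item_labels.index(dep.item_j)
        copy = rng.random(n) < dep.rho
        x[copy, j] = x[copy, i]

    data = ResponseMatrix(x, list(config.item_labels), covariates)
    truth = SyntheticTruth(
        theta=theta,
        theta2=theta2,
        beta=beta,
        slopes=base_slopes,
        covariates=covariates,
        config=config,
    )
    return data, truth
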