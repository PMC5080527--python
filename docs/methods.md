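# Methods

## Measurement model

All operations assume the dichotomous Rasch model,
`logit P(X_vi = 1) = θ_v − β_i`, with persons and items on one logit scale.

**Item calibration (CML).** Difficulties maximize the likelihood of the
responses conditional on each person's raw score. Conditioning removes the
person parameters, so estimates are consistent in n for a fixed item count
and insensitive to the shape of the trait distribution. The conditional
likelihood's normalizing constants are the elementary symmetric functions
γ_r of the easiness terms ε_i = exp(−β_i), computed by the summation
recursion entirely in log space (stable for at least 50 items; for the 11-item
scales here the direct recursion would also do). Newton–Raphson runs on an
orthonormal basis of the sum-to-zero subspace (the conditional likelihood is
invariant to a common shift of all β, so identification is Σβ_i = 0), with
step halving, a gradient-norm tolerance of 1e−8, and a cap of 100 iterations.
Standard errors come from the observed conditional information matrix,
projected onto the same subspace. Persons with extreme raw scores (0 or all
items) carry no information about β and are excluded from calibration; items
with no variation among the remaining persons are reported as inestimable
rather than guessed.

**Person measures (WLE).** Abilities are Warm weighted-likelihood estimates:
the ML score equation plus the bias-correction term J/(2I), solved by
bracketed root finding once per observed raw score (the raw score is
sufficient). WLE keeps estimates and standard errors finite at scores 0 and
k, which the Person Separation Index requires — excluding extreme scorers is
available as an option but is not the default. SE(θ̂) = 1/√I(θ̂).

## Residuals: a calibration subtlety

Infit and the Q3 residual correlations need an expected probability per cell.
Evaluating P at the per-person ability estimate deflates the residuals —
each person's residuals then nearly sum to zero by construction, biasing the
mean square to roughly 1 − 1/k (≈ 0.93 at k = 11), enough to break a
(0.91, 1.09) acceptance band on perfectly fitting data. This package instead
uses the score-conditional expectations E[X_vi | r_v] = ε_i γ_{r−1}^{(i)}/γ_r
from the same ESF machinery as the calibration. Conditional on the raw
score, X_vi is exactly Bernoulli with that mean under the model, so the
infit mean square is calibrated to 1 with no degrees-of-freedom correction
(simulated null mean ≈ 1.00). Infit t is the Wilson–Hilferty cube-root
transform using the Bernoulli fourth-moment variance of the weighted mean
square.

One consequence: conditional residuals within a person sum exactly to zero,
so null Q3 correlations center slightly below zero (≈ −1/(k−1)) rather than
at zero. The flag rule (r > 0.2 AND Holm-adjusted p ≤ 0.05, one family over
all pairs) is one-sided in the positive direction, so this shifts the null
away from the threshold and is conservative.

## The screens

**Parallel analysis.** Observed eigenvalues of the phi (Pearson) correlation
matrix of the binary items, against a null built by independently permuting
each column of the observed data — preserving the binary margins that alone
inflate eigenvalues, destroying inter-item structure. A component is
retained while its eigenvalue exceeds the 95th percentile of the null,
stopping at the first failure; adjusted eigenvalues are reported as
observed − (null mean − 1). Phi was chosen over tetrachoric because it is
always defined and conservative for this use; the correlation type is an
argument, not a constant.

**Item fit.** Information-weighted mean square of the standardized
conditional residuals per item, over non-extreme persons; acceptance band
(0.91, 1.09) by default, both bounds configurable. Underfit (msq above the
band) means responses track the trait too weakly — noise; overfit (below)
means too deterministically — redundancy.

**Local independence.** Yen's Q3: Pearson correlations of the standardized
residual columns. Each pair is tested with χ² = n·r² on 1 df — the score-test
form matching the 1-df pair chi-squares this style of analysis reports — and
the k(k−1)/2 pairs are Holm-adjusted as one family. A pair must fail both
the magnitude and the significance criterion to be flagged.

**DIF.** Persons are stratified by total raw score on all items (the Rasch
sufficient statistic; no purification by default, available as an option).
Per stratum, a 2×2 group × response table. Uniform DIF: Mantel–Haenszel χ²
with continuity correction, with the MH common odds ratio and its
Robins–Breslow–Greenland variance; strata with a zero margin are dropped
(they carry no information). Non-uniform DIF: Breslow–Day with the Tarone
correction. The homogeneity statistic is unreliable on near-empty tables, so
for Breslow–Day only, adjacent score strata are pooled until every stratum's
smallest margin reaches 10 (simulation: raises detection of a slope-ratio-2.5
crossing effect from ~0.42 to ~0.58 at n = 500 while the null rejection rate
stays at ~0.03–0.06); the Mantel–Haenszel test needs no such pooling and
keeps the finer stratification, where its type-I error sits at ~0.04. An
item is flagged when either test is significant (strict inequality at
α = 0.05); an untestable component counts as non-significant, with a
warning in the result. The statistics themselves are computed by
`statsmodels`' `StratifiedTable`; stratification, merging, orientation and
the flag rule are this package's. The pooled log odds ratio is oriented so
that a planted difficulty shift of +δ for group 1 appears as +δ.

**DTF (τ²).** Weighted method-of-moments variance of the per-item MH log
odds ratios: with w_i = 1/v_i, τ̂² = (Σw_i²(λ_i−λ̄)² − Σw_i)/Σw_i². Not
truncated at zero — a negative value means less dispersion than sampling
error alone would produce, and reporting it preserves that information.
Bands: small ≤ 0.07 < medium ≤ 0.14 < large, boundaries assigned downward.

**Reliability.** Cronbach's α with n−1 variances; PSI =
(var(θ̂) − mean(se²))/var(θ̂) over all persons, unclipped. Pass thresholds
(α > 0.8, PSI > 0.7) use strict inequality and are configuration defaults.

## The pipeline

`run_pipeline` splits the input into disjoint calibration and validation
samples of `n_per_sample` (default 500) and alternates two elimination
passes until stable, followed by DIF and reliability reporting:

1. *Local dependence first.* A strongly dependent pair acts like one
   double-weighted item: both members overfit, and — less obviously — every
   other item's infit is dragged upward, so acting on fit statistics while a
   flagged pair is unresolved removes the wrong items (in simulation, a
   ρ = 0.9 pair left in place leads to runaway elimination of sound items).
   Flagged pairs therefore go first, and an overfitting item that belongs to
   a flagged pair is never removed as "misfit" — its pathology is
   redundancy. Of a flagged pair, the member with the larger mean |Q3|
   against all other items is removed (tie-break: worse |ln infit|). When
   the pair is a near-duplicate the two members are statistically
   exchangeable and the choice is genuinely arbitrary — removing either
   resolves the dependence.
2. *Item fit.* The single worst item (largest |ln infit_msq| on the
   calibration sample) outside the band is removed, with a full refit before
   the next look.
3. *Replication required.* An item is eliminated only when the finding holds
   in both samples — the same pair flagged, or infit outside the band in the
   same direction. Single-sample borderline flags are reported but not acted
   on; at n = 500 this roughly halves spurious eliminations without
   sacrificing detection of genuinely broken items. The calibration sample
   decides order and victims; the validation sample can only veto.
4. DIF screening per covariate on the retained set (both samples, τ² per
   sample) — reported, never eliminating. Reliability for the initial set,
   the retained set, and any user-named subsets. Every elimination is
   replayed on the validation sample and both statistics recorded.

Elimination stops with an error if it would leave fewer than `min_items`
(default 3). All thresholds live in `PipelineConfig`, which round-trips
through YAML. Results serialize to deterministic JSON; the Wright map
(person histogram and item locations on the shared logit axis) renders to
PNG and plain text from the same arrays.

## Synthetic data

The generator emulates an 11-item binary depression-symptom inventory:
difficulties spanning −0.77 to +2.33 logits (irritability easiest, mood
instability hardest), trait ~ Normal(0, 1), default n = 500 — a short
community-survey screen in which roughly a third of respondents endorse the
median item. Plantable violations, each parameterized by its own mechanism:

- **misfit**: per-item discrimination a_i ≠ 1 (low = noise, high =
  over-discrimination); 2PL-style slopes exist only inside the generator and
  are never estimated;
- **uniform DIF**: a symmetric difficulty split β_i ± δ/2 between covariate
  groups, so the pooled difficulty is unchanged and δ maps directly onto the
  MH log odds ratio;
- **non-uniform DIF**: a group-specific slope ratio — odds-ratio
  heterogeneity across score strata, which is what Breslow–Day tests;
- **local dependence**: response copying with probability ρ, which directly
  controls the residual correlation and is trivial to verify by brute force;
- **multidimensionality**: an independent second trait loading a named item
  subset.

Covariates are balanced random binary assignments. What the generator does
*not* emulate: survey design effects and weights, item nonresponse,
polytomous or longitudinal items, and trait distributions other than the
normal. Passing tests therefore demonstrate that the estimators and screens
behave correctly under the stated mechanisms at these sizes — not that any
particular real survey satisfies the model.

## Problem sizes and numerical choices

Simulation-based tests use n = 500 persons (n = 1000 for null infit
calibration and dimensionality, where the sharper criteria warrant it),
11 items, and 20 replicate seeds; parallel analysis inside tests uses
500 null simulations (the operational default is 5000); the Mantel–Haenszel
type-I error check uses 1000 replicates. Degenerate inputs fail loudly:
non-binary cells, duplicate labels, constant columns in parallel analysis,
inestimable items, zero-variance totals in α, zero-variance measures in PSI,
single-level DIF covariates. Missing data are handled once, at load time, by
listwise deletion with a reported count; no imputation is offered.

## Known limitations

- CML with the full observed information is comfortable for tens of items,
  not hundreds (the pair-deletion ESF derivatives are O(k⁴)).
- The Q3 null distribution is approximated by χ² = n·r²; with very few items
  the negative null center makes this conservative but slightly miscalibrated.
- τ² inherits the sampling noise of the per-item MH log odds ratios; at
  n = 500 its banding is indicative, not inferential.
- The two members of a near-duplicate item pair cannot be distinguished by
  any statistic; which one is removed is a tie-break, not a discovery.
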