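# raschval

Rasch-based validation of dichotomous symptom scales.

Checklists of yes/no symptoms — depression inventories being the canonical
case — are routinely summed into a severity score. That sum is only a
defensible measure if the items behave like marks on a ruler: they must tap a
single attribute, order persons and items consistently, respond independently
given the trait, work the same way across sexes and age groups, and separate
respondents reliably. `raschval` implements the full audit of those five
requirements for binary response data, together with a synthetic-data
generator that can plant each specific violation, so every screen in the
pipeline can be tested against known truth.

## The model and the screens

Responses follow the dichotomous Rasch model: person *v* with ability
θ_v endorses item *i* of difficulty β_i with probability

    P(X_vi = 1) = 1 / (1 + exp(−(θ_v − β_i)))

Both parameters live on one logit scale; the person's raw score is sufficient
for θ. Item difficulties are estimated by **conditional maximum likelihood**
(CML), conditioning on raw scores so the person parameters drop out via the
elementary symmetric functions γ_r of the easiness terms exp(−β_i); person
abilities are **Warm weighted-likelihood estimates** (WLE), finite even for
zero and perfect scores. On top of the measurement core sit five screens:

| requirement        | statistic                                   | default criterion          |
|--------------------|---------------------------------------------|----------------------------|
| unidimensionality  | parallel analysis (permutation null)        | eigenvalue > 95th pct of null |
| Guttman pattern    | infit mean square per item                  | within (0.91, 1.09)        |
| local independence | Q3 residual correlations, Holm-adjusted     | r ≤ 0.2 or p_holm > 0.05   |
| invariance         | Mantel–Haenszel + Breslow–Day per item; τ² DTF | neither test significant; τ² ≤ 0.07 small |
| reliability        | Cronbach α, Person Separation Index         | α > 0.8, PSI > 0.7         |

`run_pipeline` orchestrates them on a calibration/validation split with
iterative item elimination: an item is removed only when the finding
replicates in both samples, dependence findings are resolved before fit
findings, and DIF is reported but never triggers removal (an item that works
differently across groups is a finding to understand, not to delete).

## A worked example

`examples/04_full_pipeline.py` builds a 10-item inventory — 7 well-behaved
items at difficulties from −0.75 to +2.29 logits, two noise items whose
responses barely track the trait (discrimination 0.3), and one item copying
`cognition` 90% of the time — and runs the full pipeline:

```
elimination log:
  [local_dependence] near_duplicate: Q3=0.890 with pair ('cognition', 'near_duplicate') in both samples; larger mean |Q3|
  [item_fit] noisy1: infit_msq 1.199 outside (0.91, 1.09) in both samples
  [item_fit] noisy2: infit_msq 1.159 outside (0.91, 1.09) in both samples

retained items: sad, no_interest, sleep, cognition, suicidal_ideas, mood_instability, irritability
retained set dimensionality: 1 component(s)
reliability (initial): alpha = 0.63, PSI = 0.52
reliability (retained): alpha = 0.57, PSI = 0.39
```

Each planted pathology is caught by the stage designed for it: the
near-duplicate by the residual-correlation pass (Q3 = 0.89 far above the
0.2 bound), the two noise items by infit above the 1.09 bound. The retained
7-item scale is unidimensional and fits — yet its PSI of 0.39 is far below
the 0.7 reliability criterion, the characteristic verdict for short symptom
screens: items can fit the model perfectly and still not separate persons.

The other examples cover calibration (`01`), the individual diagnostics
(`02`), and DIF/DTF (`03`). A thin CLI mirrors the library:
`raschval simulate`, `raschval split`, `raschval run`.

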