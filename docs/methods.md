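# Methods

## Model

`migraine_cua` implements a three-state Markov cohort model for comparing
two preventive migraine therapies — an injectable anti-CGRP antibody
(Erenumab 70 mg, 290 USD per 4-weekly dose plus a 1.50 USD injection fee)
and oral Topiramate (100 mg/day, 0.06 USD/day) — from a societal
perspective with Iranian unit costs (USD at a fixed 285,000 IRR/USD).

States are *on-treatment*, *off-treatment* (discontinued; acute palliative
care only) and *dead*. The cohort starts fully on-treatment and is iterated
over 60 monthly cycles (5 years). Within a cycle, death is applied first
and treatment withdrawal to survivors, so the on-treatment row of the
transition matrix is

    on -> on    (1 - p_die)(1 - p_withdraw)
    on -> off   (1 - p_die) p_withdraw
    on -> dead  p_die

off-treatment patients never re-initiate preventive therapy, and death is
absorbing. The ordering is a convention; at these magnitudes
(p_die ≈ 4e-4/cycle) the alternative ordering changes totals in the fifth
decimal.

### Probabilities

Printed probabilities are moved onto the cycle length with the
constant-hazard identities `p(t) = 1 − exp(−r t)` and
`p2 = 1 − (1 − p1)^(t2/t1)`. The six-month cumulative withdrawal
probabilities (10.6% Erenumab, 38.9% Topiramate) become monthly
probabilities of 0.01850 and 0.07883; the annual background mortality
(default 0.005, age-standardised adult mortality — the model is not
age-structured because five years of ageing is immaterial at this scale)
becomes 1 − 0.995^(1/12).

**Withdrawal window.** The discontinuation data cover only the first six
months of therapy. By default the withdrawal hazard therefore applies to
cycles 1–6 only (`settings.withdrawal_cycles: 6`); setting it to `null`
extrapolates the constant hazard over the whole horizon. The windowed
default reproduces the published discounted cost totals and break-even
price; extrapolation reduces on-treatment exposure by roughly a third and
makes the published intervention cost unreachable. The two options bracket
the structural uncertainty; they are both one config key away.

### Utilities and QALYs

A month with `m` migraine days has mean per-day utility

    u(m) = (m · 0.44 + (30 − m) · 0.933) / 30

with 0.44/0.933 the utilities of a migraine day and a migraine-free day. A
30-day month reproduces the published annual state utilities at two
decimals (4.54 → 0.86, 6.38 → 0.83, 10.4 → 0.76); a 28-day month does not,
which fixes `days_per_month = 30`. Off-treatment (and baseline) severity is
10.4 monthly migraine days.

Serious adverse events (fatigue, dizziness, paresthesia, attention
deficit) are assumed to last one week around treatment initiation: each
contributes `rate × annual_disutility × 7/365.25` as a one-off QALY
decrement in the first cycle. The average-year denominator (365.25)
reproduces all four published weekly-disutility cells at four decimals.
The decrement is of order 1e-4 QALYs and is immaterial to the results.

Cycle QALYs are occupancy-weighted utilities times cycle length in years;
cycle costs are occupancy-weighted state costs. Half-cycle correction is
implemented as trapezoid occupancy weighting (average of start- and
end-of-cycle occupancy) together with mid-cycle discounting, and can be
switched off. Costs discount at 5.8%/year, QALYs at 5%/year.

### Costs

State costs are micro-costed per cycle. On-treatment: preventive drug +
administration + acute medication + visits + travel + productivity loss.
Off-treatment: the same minus drug and administration, evaluated at the
off-treatment severity. Acute medication costs one course per migraine day,
5% of courses parenteral (2.48 USD) and the rest oral (0.12 USD). Each
cycle includes one specialist visit (3.28 USD) plus travel (0.70 USD).
Productivity loss applies the 2023 minimum daily wage (6.21 USD) to every
migraine day (`working_day_fraction = 1.0`): the wage input is quoted per
working day and no weekday adjustment is applied. These resource-use
quantities (doses per migraine day, visit frequency, parenteral share,
working-day fraction) are not published anywhere and are the model's
explicit assumptions; all are config fields. The GP-visit unit price is
carried in the config but the default visit mix is specialist-only, so it
is inert in the base case (its tornado range is zero).

Adverse-event treatment costs are excluded (discontinuation, not
treatment, is the modelled consequence of AEs).

## Incremental statistics

ICER = ΔC/ΔE on unrounded discounted totals, intervention minus comparator,
with standard dominance flags when the signs oppose. NMB = λ·E − C at a
configurable willingness-to-pay λ (default 2,456 USD/QALY). The break-even
intervention price solves ICER(price) = λ by bisecting ΔC − λ·ΔE (linear
and increasing in price) to a 0.01 USD bracket.

## Sensitivity analysis

**One-way DSA** varies each scalar input ±20% (probabilities and utilities
capped at their natural bounds, MMDs at 30) one at a time and records the
ICER range, sorted descending (tornado).

**PSA** samples every configured distribution independently by
method-of-moments: normal (mean, sd); lognormal with
σ² = ln(1 + sd²/mean²), μ = ln(mean) − σ²/2; beta with
α = m(m(1−m)/sd² − 1), β = (1−m)(m(1−m)/sd² − 1) (requiring
sd² < m(1−m)). Draws are truncated to natural supports (probabilities and
utilities below 1, MMDs to [0, 30]). The published annual state utilities
are beta-distributed and are sampled as direct utility overrides, so in PSA
draws the lognormal MMD draws drive costs while the beta draws drive
QALYs. Withdrawal probabilities keep their published lognormal family
despite its unbounded support; the truncation at 1 is never hit in practice
at these moments. No correlation structure is imposed (none is published).
One consequence of independent per-arm sampling: the intervention's QALY
gain is negative in roughly a third of draws, so the CEAC plateaus below 1
at large λ. Default 1,000 draws, seeded and reproducible.

## Synthetic trial generator

`simulate_trial` emulates the patient-level structure behind the published
arm summaries: baseline MMD ~ truncated normal(10.4, 3.9) on [4, 30]
(trial entry requires ≥ 4 monthly migraine days; ≥ 15 classifies chronic
migraine), on-treatment MMD ~ lognormal moment-matched to the arm summary
and truncated at the patient's baseline (treatment assumed non-harmful per
patient), withdrawal as a constant monthly hazard over months 1–6 matched
to the six-month cumulative probability, and independent Bernoulli adverse
events. Limitations, deliberate: no within-patient correlation between
baseline severity and treatment response, no placebo response, no
patient-level utility instrument — so parameter-recovery tests exercise the
estimation path, not the realism of any particular trial. The truncation
at baseline biases the recovered on-treatment arm mean a few percent low
(~6% for the intervention arm); the full
simulate → summarise → re-parameterise → model loop still returns the
truth ICER within 10% at 1e5 patients per arm.

## Numerical conventions

- Occupancy rows are validated to sum to 1 within 1e-10; the dead state is
  checked non-decreasing.
- ICER is `None`/flagged rather than infinite on zero or sign-opposed
  increments; tornado entries propagate ±inf for dominance draws.
- Problem sizes in the test-suite: 1e5 patients for the Monte-Carlo
  cross-check (3 standard errors), 1e5 patients per arm for trial
  recovery, 1,000 PSA draws, 1e6 standalone sampler draws for moment
  checks.

## Known limitations

- The published base-case table cannot be reproduced in full by any single
  transition structure we could construct: its cost column implies
  withdrawal confined to the first six months, while its QALY column
  implies continued attrition. With the windowed default this package
  reproduces the cost column (within 9%) and the break-even price (within
  14%), and overshoots the published QALYs by ≈ 0.06–0.08 per arm, leaving
  its ICER ≈ 19% below the published one. Both structures are exposed via
  `settings.withdrawal_cycles`.
- Published NMB values imply a willingness-to-pay near 20,850 USD/QALY
  rather than the stated 2,456; NMB here always uses the configured λ.
- Cohort proportions only — no patient-level heterogeneity in the Markov
  model itself (the episodic/chronic split is recorded but both groups are
  pooled through a single mean MMD, as in the source data).
- Costs and rates are time-homogeneous within the horizon apart from the
  withdrawal window.
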