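# migraine-cua

A Markov cohort cost-utility model for preventive migraine therapy,
comparing an injectable CGRP-receptor antibody (Erenumab 70 mg) against
oral Topiramate from a societal perspective with Iranian unit costs. Built
for health-economics analysts who want the published decision problem as a
tested, configurable, scriptable package rather than a closed spreadsheet
or TreeAge file: every input is a config field, every analysis is a
function, and every number is reproducible from a seed.

## The model

Three states — on-treatment, off-treatment, dead — iterated over 60
monthly cycles (5 years), cohort starting fully on-treatment:

- transition probabilities from printed summaries via the constant-hazard
  conversions `p(t) = 1 − e^(−rt)` and `p₂ = 1 − (1 − p₁)^(t₂/t₁)`
  (six-month withdrawal 10.6%/38.9% → monthly 0.0185/0.0788; the hazard
  applies to the first six cycles by default, matching the span of the
  source data);
- utilities from monthly migraine days (MMD):
  `u(m) = (0.44·m + 0.933·(30−m))/30`, giving 0.86 (Erenumab, 4.54 MMD),
  0.83 (Topiramate, 6.38 MMD) and 0.76 (off treatment, 10.4 MMD), plus a
  one-week disutility per serious adverse event at treatment start;
- micro-costed cycle costs (preventive drug, injection, acute medication,
  specialist visits, travel, productivity loss at the minimum daily wage);
- discounting at 5.8%/yr (costs) and 5%/yr (QALYs) with half-cycle
  correction (trapezoid occupancy + mid-cycle discounting);
- ICER = ΔC/ΔE on unrounded totals, NMB = λ·E − C at a configurable
  willingness-to-pay (default λ = 2,456 USD/QALY), bisection for the
  break-even intervention price, ±20% one-way tornado, and a seeded
  moment-matched PSA (normal/lognormal/beta) with CEAC output.

A synthetic-trial module generates patient-level data with the same
statistical structure (truncated-normal baseline MMD, lognormal
on-treatment MMD, geometric withdrawal, Bernoulli adverse events) and
estimators that close the simulate → summarise → re-parameterise → model
loop, so the whole derivation path is testable without external data.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```sh
migraine-cua run --out out/base
```

prints (log line elided):

```
  strategy         cost  incremental_cost    qalys  incremental_qalys        icer dominance          nmb
topiramate  2883.161305               NaN 3.523620                NaN         NaN            5770.850103
  erenumab 15467.414513      12584.253208 3.720658           0.197037 63867.34774           -6329.479363
```

Reading it: over five years a Topiramate patient costs 2,883 USD and
accrues 3.52 QALYs; an Erenumab patient costs 15,467 USD for 3.72 QALYs.
The extra 0.197 QALYs cost 12,584 USD, an ICER of ≈ 63,900 USD per QALY —
twenty-six times the 2,456 USD/QALY willingness-to-pay threshold, so
Erenumab is not cost-effective at its reference price (its NMB is negative
while Topiramate's is positive). The command also writes `cea_results.csv`
/ `.json`, per-cycle trace CSVs and a run manifest. Follow-ups:

```sh
migraine-cua threshold --out out/thr            # break-even price ≈ 29.77 USD/cycle
migraine-cua dsa --out out/dsa                  # ±20% tornado (CSV + PNG)
migraine-cua psa --seed 1 --out out/psa         # 1,000 draws, scatter + CEAC
migraine-cua simulate --seed 1 --out out/sim    # synthetic trial + recovered config
```

All commands accept `--config your.yaml`; the packaged default
(`src/migraine_cua/data/default_config.yaml`) documents every field and
unit. The same API is available in Python:

```python
import migraine_cua as m
cfg = m.default_paper_config()
res = m.run_base_case(cfg)
print(res.icer)            # 63867.34773982825
print(m.threshold_price(cfg))   # 29.767...
```

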