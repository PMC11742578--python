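# Base-case configuration: Erenumab 70 mg vs Topiramate 100 mg/day for
# migraine prevention, Iranian unit costs (USD at 285,000 IRR/USD),
# societal perspective, 5-year horizon of monthly cycles.
#
# Units: costs in USD; MMD in migraine days per 30-day month; withdrawal is
# the cumulative probability over the first 6 months of therapy;
# disutilities are annual-scale utility decrements (applied for one week).

strategies:
- name: erenumab                  # intervention (listed first)
  drug_cost_per_cycle: 290.0      # USD per 4-weekly 70 mg dose
  admin_cost_per_cycle: 1.5       # USD injection fee per cycle
  mmd_on_treatment: 4.54          # mean MMD on therapy
  mmd_sd: 2.18
  withdrawal_prob_6mo: 0.106      # cumulative over months 1-6
  withdrawal_sd: 0.043
  ae_profile:                     # serious AE incidence and annual disutility
  - {name: fatigue, rate: 0.023, annual_disutility: -0.06}
  - {name: dizziness, rate: 0.01, annual_disutility: -0.01}
  - {name: paresthesia, rate: 0.0, annual_disutility: -0.012}
  - {name: attention_deficit, rate: 0.093, annual_disutility: -0.098}
  utility_on_override: null       # set only by PSA draws
- name: topiramate                # comparator
  drug_cost_per_cycle: 1.8        # 0.06 USD/day x 30-day cycle
  admin_cost_per_cycle: 0.0       # oral: no administration fee
  mmd_on_treatment: 6.38
  mmd_sd: 1.82
  withdrawal_prob_6mo: 0.389
  withdrawal_sd: 0.144
  ae_profile:
  - {name: fatigue, rate: 0.075, annual_disutility: -0.06}
  - {name: dizziness, rate: 0.054, annual_disutility: -0.01}
  - {name: paresthesia, rate: 0.098, annual_disutility: -0.012}
  - {name: attention_deficit, rate: 0.018, annual_disutility: -0.098}
  utility_on_override: null

cohort:
  n_patients: 1000                # reporting metadata; the model is proportion-based
  episodic_fraction: 0.889        # < 15 MMD; chronic = 1 - episodic
  baseline_mmd: 10.4              # untreated mean MMD
  baseline_sd: 3.9
  off_treatment_mmd: 10.4         # after discontinuation, MMD reverts to baseline
  off_treatment_sd: 3.9
  annual_mortality: 0.005         # age-standardised natural mortality, per year

costs:                            # unit prices (USD) and resource-use assumptions
  oral_acute: 0.12                # per oral acute dose
  parenteral_acute: 2.48          # per parenteral acute dose
  gp_visit: 1.79                  # per visit (not used by the default costing mix)
  specialist_visit: 3.28          # per visit
  injection: 1.5                  # unit price of one injection service
  trip: 0.7                       # direct non-medical travel cost per visit
  productivity_loss_per_day: 6.21 # 2023 minimum daily wage
  oral_acute_doses_per_mmd: 1.0   # acute doses per migraine day
  parenteral_fraction: 0.05       # share of acute doses given parenterally
  visits_per_cycle: 1.0           # specialist-visit equivalents per cycle
  working_day_fraction: 1.0       # migraine days costing a day's wage

utilities:
  u_migraine_day: 0.44            # utility of a day with a migraine attack
  u_free_day: 0.933               # utility of a migraine-free day
  days_per_month: 30.0
  utility_off_override: null      # set only by PSA draws

settings:
  n_cycles: 60                    # 60 monthly cycles = 5 years
  cycle_length_years: 0.08333333333333333  # 1/12 year
  discount_cost_annual: 0.058
  discount_qaly_annual: 0.05
  wtp: 2456.0                     # USD per QALY
  half_cycle_correction: true
  withdrawal_cycles: 6            # hazard applies to the first 6 cycles; null = whole horizon
  irr_per_usd: 285000.0           # metadata: fixed exchange rate behind the USD prices

distributions:                    # PSA families, natural-scale mean/sd (moment-matched)
- {target: cohort.baseline_mmd, family: normal, mean: 10.4, sd: 3.9}
- {target: strategies.erenumab.mmd_on_treatment, family: lognormal, mean: 4.54, sd: 2.18}
- {target: strategies.topiramate.mmd_on_treatment, family: lognormal, mean: 6.38, sd: 1.82}
- {target: cohort.off_treatment_mmd, family: lognormal, mean: 10.4, sd: 3.9}
- {target: strategies.erenumab.withdrawal_prob_6mo, family: lognormal, mean: 0.106, sd: 0.043}
- {target: strategies.topiramate.withdrawal_prob_6mo, family: lognormal, mean: 0.389, sd: 0.144}
- {target: strategies.erenumab.utility_on_override, family: beta, mean: 0.86, sd: 0.085}
- {target: strategies.topiramate.utility_on_override, family: beta, mean: 0.83, sd: 0.079}
- {target: utilities.utility_off_override, family: beta, mean: 0.76, sd: 0.08}
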