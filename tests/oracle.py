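"""Independent patient-level Monte-Carlo oracle.

Simulates individual patients through the same three-state transition rules
as the cohort engine (death first, withdrawal among survivors, withdrawal
hazard limited to its configured window) and accumulates discounted rewards
per patient. Implemented directly from the configuration with its own
probability conversions so it shares no code path with the cohort engine.
"""

from __future__ import annotations

import numpy as np

from migraine_cua.config import ModelConfig, StrategyParams

ON, OFF, DEAD = 0, 1, 2


def _per_cycle_prob(p: float, months_observed: float, months_per_cycle: float) -> float:
    return 1.0 - (1.0 - p) ** (months_per_cycle / months_observed)


def simulate_patients(
    config: ModelConfig, strategy: StrategyParams, n_patients: int, seed: int
) -> dict:
    """Per-patient discounted totals under the cohort model's rules.

    Returns mean cost/QALYs with their Monte-Carlo standard errors.
    """
    st = config.settings
    rng = np.random.default_rng(seed)
    months = st.cycle_length_years * 12.0
    p_w = _per_cycle_prob(strategy.withdrawal_prob_6mo, 6.0, months)
    p_d = _per_cycle_prob(config.cohort.annual_mortality, 12.0, months)

    u = config.utilities
    dpm = u.days_per_month

    def mmd_utility(mmd: float) -> float:
        return (mmd * u.u_migraine_day + (dpm - mmd) * u.u_free_day) / dpm

    c = config.costs
    acute_unit = (1 - c.parenteral_fraction) * c.oral_acute + c.parenteral_fraction * c.parenteral_acute

    def living_cost(mmd: float) -> float:
        return (
            mmd * c.oral_acute_doses_per_mmd * acute_unit
            + c.visits_per_cycle * (c.specialist_visit + c.trip)
            + mmd * c.working_day_fraction * c.productivity_loss_per_day
        )

    off_mmd = config.cohort.off_mmd
    state_cost = np.array(
        [
            living_cost(strategy.mmd_on_treatment)
            + strategy.drug_cost_per_cycle
            + strategy.admin_cost_per_cycle,
            living_cost(off_mmd),
            0.0,
        ]
    )
    if strategy.utility_on_override is not None:
        u_on = strategy.utility_on_override
    else:
        u_on = mmd_utility(strategy.mmd_on_treatment)
    if u.utility_off_override is not None:
        u_off = u.utility_off_override
    else:
        u_off = mmd_utility(off_mmd)
    state_util = np.array([u_on, u_off, 0.0])

    ae_decrement = sum(
        ae.rate * ae.annual_disutility * 7.0 / 365.25 for ae in strategy.ae_profile
    )

    states = np.zeros(n_patients, dtype=np.int8)
    cost_tot = np.zeros(n_patients)
    qaly_tot = np.zeros(n_patients)
    for k in range(st.n_cycles):
        before = states.copy()
        alive = states != DEAD
        dies = alive & (rng.random(n_patients) < p_d)
        states[dies] = DEAD
        wd_active = st.withdrawal_cycles is None or k < st.withdrawal_cycles
        if wd_active and p_w > 0:
            withdraws = (states == ON) & (before == ON) & (rng.random(n_patients) < p_w)
            states[withdraws] = OFF
        if st.half_cycle_correction:
            cost_k = 0.5 * (state_cost[before] + state_cost[states])
            qaly_k = 0.5 * (state_util[before] + state_util[states]) * st.cycle_length_years
        else:
            cost_k = state_cost[before]
            qaly_k = state_util[before] * st.cycle_length_years
        if k == 0:
            qaly_k = qaly_k + ae_decrement
        t = (k + (0.5 if st.half_cycle_correction else 0.0)) * st.cycle_length_years
        cost_tot += cost_k * (1 + st.discount_cost_annual) ** -t
        qaly_tot += qaly_k * (1 + st.discount_qaly_annual) ** -t

    return {
        "cost_mean": float(cost_tot.mean()),
        "cost_se": float(cost_tot.std(ddof=1) / np.sqrt(n_patients)),
        "qaly_mean": float(qaly_tot.mean()),
        "qaly_se": float(qaly_tot.std(ddof=1) / np.sqrt(n_patients)),
    }
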