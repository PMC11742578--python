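"""Three-state Markov cohort engine.

States: 0 = on-treatment, 1 = off-treatment, 2 = dead. The cohort starts
fully on-treatment; each cycle, death is applied first and withdrawal to
survivors, so the on-treatment row of the transition matrix is
``(1-p_die)(1-p_withdraw), (1-p_die) p_withdraw, p_die``. Off-treatment
patients never re-initiate preventive therapy; death is absorbing.

Rewards are state-based. With half-cycle correction, cycle rewards weight
the average of start- and end-of-cycle occupancy (trapezoid) and discounting
is evaluated mid-cycle; without it, start-of-cycle occupancy and
start-of-cycle discounting are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, StrategyParams
from .derivations import CycleInputs, build_cycle_inputs

__all__ = [
    "STATES",
    "CohortTrace",
    "StrategyOutcome",
    "transition_matrix",
    "discount_factor",
    "run_cohort",
]

STATES = ("on_treatment", "off_treatment", "dead")
_OCC_TOL = 1e-10


def transition_matrix(ci: CycleInputs, withdrawal_active: bool = True) -> np.ndarray:
    """3x3 row-stochastic transition matrix for one cycle."""
    p_w = ci.p_withdraw if withdrawal_active else 0.0
    p_d = ci.p_die
    m = np.array(
        [
            [(1.0 - p_d) * (1.0 - p_w), (1.0 - p_d) * p_w, p_d],
            [0.0, 1.0 - p_d, p_d],
            [0.0, 0.0, 1.0],
        ]
    )
    if (m < 0).any():
        raise ValueError("transition matrix has a negative entry")
    return m


def discount_factor(
    cycle_index: int,
    annual_rate: float,
    cycle_length_years: float,
    half_cycle: bool = True,
) -> float:
    """Discount factor for cycle ``cycle_index`` (0-based): ``(1+r)^-t``
    with ``t`` at the cycle midpoint when ``half_cycle`` is on."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    t = (cycle_index + (0.5 if half_cycle else 0.0)) * cycle_length_years
    return float((1.0 + annual_rate) ** -t)


@dataclass
class CohortTrace:
    """Per-cycle record of a cohort run: state occupancy at each cycle
    boundary and the undiscounted/discounted cost and QALY streams."""

    occupancy: np.ndarray  # (n_cycles+1, 3)
    cycle_costs: np.ndarray
    cycle_costs_discounted: np.ndarray
    cycle_qalys: np.ndarray
    cycle_qalys_discounted: np.ndarray

    def validate(self) -> None:
        occ = self.occupancy
        if not np.allclose(occ.sum(axis=1), 1.0, atol=_OCC_TOL):
            raise AssertionError("occupancy rows do not sum to 1")
        if (occ < -_OCC_TOL).any() or (occ > 1 + _OCC_TOL).any():
            raise AssertionError("occupancy outside [0, 1]")
        if (np.diff(occ[:, 2]) < -_OCC_TOL).any():
            raise AssertionError("dead-state occupancy decreased")

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.cycle_costs)
        return pd.DataFrame(
            {
                "cycle": np.arange(n),
                "on_treatment": self.occupancy[:n, 0],
                "off_treatment": self.occupancy[:n, 1],
                "dead": self.occupancy[:n, 2],
                "cost": self.cycle_costs,
                "cost_discounted": self.cycle_costs_discounted,
                "qaly": self.cycle_qalys,
                "qaly_discounted": self.cycle_qalys_discounted,
            }
        )


@dataclass
class StrategyOutcome:
    """Totals of one cohort run (discounted)."""

    strategy: str
    total_cost: float
    total_qalys: float
    trace: CohortTrace


def run_cohort(config: ModelConfig, strategy: StrategyParams) -> StrategyOutcome:
    """Run the cohort model for one arm and accumulate discounted totals.

    Per-cycle QALYs are ``occupancy-weighted mean utility x cycle length in
    years``; the expected adverse-event decrement is added once, in the
    first cycle. Per-cycle costs are occupancy-weighted state costs.
    """
    ci = build_cycle_inputs(config, strategy)
    st = config.settings
    n = st.n_cycles
    hcc = st.half_cycle_correction

    occ = np.zeros((n + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    costs = np.zeros(n)
    qalys = np.zeros(n)
    costs_d = np.zeros(n)
    qalys_d = np.zeros(n)

    state_cost = np.array([ci.cost_on, ci.cost_off, 0.0])
    state_util = np.array([ci.u_on, ci.u_off, 0.0])

    for k in range(n):
        active = ci.withdrawal_cycles is None or k < ci.withdrawal_cycles
        m = transition_matrix(ci, withdrawal_active=active)
        occ[k + 1] = occ[k] @ m
        weight = 0.5 * (occ[k] + occ[k + 1]) if hcc else occ[k]
        cost_k = float(weight @ state_cost)
        qaly_k = float(weight @ state_util) * st.cycle_length_years
        if k == 0:
            qaly_k += ci.first_cycle_disutility
        costs[k] = cost_k
        qalys[k] = qaly_k
        costs_d[k] = cost_k * discount_factor(k, st.discount_cost_annual, st.cycle_length_years, hcc)
        qalys_d[k] = qaly_k * discount_factor(k, st.discount_qaly_annual, st.cycle_length_years, hcc)

    trace = CohortTrace(occ, costs, costs_d, qalys, qalys_d)
    trace.validate()
    return StrategyOutcome(
        strategy=strategy.name,
        total_cost=float(costs_d.sum()),
        total_qalys=float(qalys_d.sum()),
        trace=trace,
    )
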