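"""Derived per-cycle model quantities.

Translates printed clinical summaries — mean monthly migraine days (MMD),
six-month withdrawal probabilities, annual mortality, per-day utilities,
unit costs — into the per-cycle transition probabilities, state utilities
and state costs the cohort engine consumes.

The central conversions are the constant-rate identities

    p(t) = 1 - exp(-r t)          (rate to probability)
    p2   = 1 - (1 - p1)^(t2/t1)   (probability rescaling)

used to move the six-month withdrawal probability and the annual mortality
probability onto the model's cycle length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .config import CostInputs, ModelConfig, StrategyParams, UtilityInputs

__all__ = [
    "CycleInputs",
    "rate_to_probability",
    "probability_to_rate",
    "probability_rescale",
    "utility_from_mmd",
    "one_week_disutility",
    "expected_ae_disutility",
    "state_cost_per_cycle",
    "build_cycle_inputs",
]

# one week as a fraction of an average (Julian) year; 365.25 rather than
# 365 days so the published 4-dp weekly disutility cells reproduce exactly
WEEKS_PER_YEAR_DAYS = 7.0 / 365.25


def rate_to_probability(rate: float, t: float) -> float:
    """Probability of at least one event in time ``t`` under a constant
    hazard ``rate``: ``1 - exp(-rate * t)``."""
    if rate < 0 or t < 0:
        raise ValueError(f"rate and t must be >= 0, got rate={rate}, t={t}")
    return -math.expm1(-rate * t)


def probability_to_rate(p: float, t: float) -> float:
    """Inverse of :func:`rate_to_probability`: ``-ln(1 - p) / t``."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if t <= 0:
        raise ValueError(f"t must be > 0, got {t}")
    return -math.log1p(-p) / t


def probability_rescale(p: float, from_t: float, to_t: float) -> float:
    """Re-express a probability observed over ``from_t`` on a ``to_t``
    interval assuming a constant underlying hazard."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if from_t <= 0 or to_t <= 0:
        raise ValueError("time intervals must be > 0")
    return -math.expm1(math.log1p(-p) * to_t / from_t)


def utility_from_mmd(mmd: float, u: UtilityInputs) -> float:
    """Mean per-day utility of a month with ``mmd`` migraine days,
    mixing the migraine-day and migraine-free-day utilities."""
    if not 0.0 <= mmd <= u.days_per_month:
        raise ValueError(f"mmd {mmd} outside [0, {u.days_per_month}]")
    return (mmd * u.u_migraine_day + (u.days_per_month - mmd) * u.u_free_day) / u.days_per_month


def one_week_disutility(annual_disutility: float) -> float:
    """QALY decrement of experiencing an annual-scale disutility for one
    week (7/365.25 of a year)."""
    if annual_disutility > 0:
        raise ValueError(f"annual_disutility must be <= 0, got {annual_disutility}")
    return annual_disutility * WEEKS_PER_YEAR_DAYS


def expected_ae_disutility(strategy: StrategyParams) -> float:
    """Expected one-off QALY decrement from serious adverse events at
    treatment initiation: incidence-weighted sum of one-week disutilities
    over the arm's AE profile."""
    return sum(ae.rate * one_week_disutility(ae.annual_disutility) for ae in strategy.ae_profile)


def state_cost_per_cycle(
    state: str,
    strategy: StrategyParams,
    mmd: float,
    costs: CostInputs,
) -> float:
    """Micro-costed USD per cycle for one health state.

    Both states accrue acute-medication costs (one course per migraine day,
    split between oral and parenteral routes), specialist visits with travel,
    and productivity loss per migraine day. The on-treatment state adds the
    preventive drug and its administration fee; the off-treatment state
    receives acute (palliative) care only.
    """
    if state not in ("on", "off"):
        raise ValueError(f"unknown state {state!r}; expected 'on' or 'off'")
    acute_unit = (
        (1.0 - costs.parenteral_fraction) * costs.oral_acute
        + costs.parenteral_fraction * costs.parenteral_acute
    )
    total = mmd * costs.oral_acute_doses_per_mmd * acute_unit
    total += costs.visits_per_cycle * (costs.specialist_visit + costs.trip)
    total += mmd * costs.working_day_fraction * costs.productivity_loss_per_day
    if state == "on":
        total += strategy.drug_cost_per_cycle + strategy.admin_cost_per_cycle
    return total


@dataclass(frozen=True)
class CycleInputs:
    """Everything the cohort engine needs for one strategy: per-cycle
    transition probabilities, state utilities (per-day scale, applied pro
    rata to cycle length), state costs, the one-off first-cycle adverse-event
    QALY decrement, and how many cycles the withdrawal hazard applies for."""

    p_withdraw: float
    p_die: float
    u_on: float
    u_off: float
    cost_on: float
    cost_off: float
    first_cycle_disutility: float
    withdrawal_cycles: Optional[int]

    def __post_init__(self) -> None:
        for name in ("p_withdraw", "p_die"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} {p} outside [0, 1]")
        for name in ("u_on", "u_off"):
            u = getattr(self, name)
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} {u} outside [0, 1]")
        if self.first_cycle_disutility > 0:
            raise ValueError("first_cycle_disutility must be <= 0")


def build_cycle_inputs(config: ModelConfig, strategy: StrategyParams) -> CycleInputs:
    """Assemble :class:`CycleInputs` for one arm of a validated config.

    The six-month withdrawal probability and the annual mortality are
    rescaled to the cycle length under a constant-hazard assumption; state
    utilities come from the MMD mixture (unless a PSA override is set) and
    state costs from micro-costing.
    """
    months_per_cycle = config.settings.cycle_length_years * 12.0
    p_withdraw = probability_rescale(strategy.withdrawal_prob_6mo, 6.0, months_per_cycle)
    p_die = probability_rescale(config.cohort.annual_mortality, 12.0, months_per_cycle)
    if strategy.utility_on_override is not None:
        u_on = strategy.utility_on_override
    else:
        u_on = utility_from_mmd(strategy.mmd_on_treatment, config.utilities)
    if config.utilities.utility_off_override is not None:
        u_off = config.utilities.utility_off_override
    else:
        u_off = utility_from_mmd(config.cohort.off_mmd, config.utilities)
    return CycleInputs(
        p_withdraw=p_withdraw,
        p_die=p_die,
        u_on=u_on,
        u_off=u_off,
        cost_on=state_cost_per_cycle("on", strategy, strategy.mmd_on_treatment, config.costs),
        cost_off=state_cost_per_cycle("off", strategy, config.cohort.off_mmd, config.costs),
        first_cycle_disutility=expected_ae_disutility(strategy),
        withdrawal_cycles=config.settings.withdrawal_cycles,
    )
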