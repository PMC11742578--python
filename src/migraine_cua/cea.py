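"""Incremental cost-effectiveness statistics and threshold-price search.

Conventions: the incremental comparison is intervention minus comparator on
unrounded discounted totals. ICER = ΔC/ΔE when ΔE ≠ 0; when the signs of ΔC
and ΔE disagree one strategy dominates and the ICER is flagged rather than
reported. Net monetary benefit at willingness-to-pay λ is λ·E − C per
strategy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .config import ModelConfig
from .engine import StrategyOutcome, run_cohort

__all__ = ["CEAResult", "compare", "run_base_case", "threshold_price", "BracketError"]

_EPS_QALY = 1e-12


class BracketError(ValueError):
    """The threshold-price search bounds do not bracket the target ICER."""


@dataclass
class CEAResult:
    """Pairwise comparison of two strategies at willingness-to-pay ``wtp``.

    ``icer`` is None when undefined (ΔE = 0) or when a dominance flag is
    set: ``dominance`` is ``"intervention_dominant"`` when the intervention
    is cheaper and more effective, ``"intervention_dominated"`` in the
    reverse case, and None when a finite ICER applies.
    """

    intervention: str
    comparator: str
    cost: dict[str, float]
    qalys: dict[str, float]
    incremental_cost: float
    incremental_qalys: float
    icer: Optional[float]
    dominance: Optional[str]
    wtp: float
    nmb: dict[str, float]

    @property
    def cost_effective(self) -> bool:
        """Whether the intervention is preferred at ``wtp`` (by NMB)."""
        return self.nmb[self.intervention] > self.nmb[self.comparator]

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular summary, one row per strategy (comparator first)."""
        rows = []
        for name in (self.comparator, self.intervention):
            inc = name == self.intervention
            rows.append(
                {
                    "strategy": name,
                    "cost": self.cost[name],
                    "incremental_cost": self.incremental_cost if inc else math.nan,
                    "qalys": self.qalys[name],
                    "incremental_qalys": self.incremental_qalys if inc else math.nan,
                    "icer": (self.icer if self.icer is not None else math.nan) if inc else math.nan,
                    "dominance": (self.dominance or "") if inc else "",
                    "nmb": self.nmb[name],
                }
            )
        return pd.DataFrame(rows)


def compare(a: StrategyOutcome, b: StrategyOutcome, wtp: float) -> CEAResult:
    """Compare intervention ``a`` against comparator ``b`` at ``wtp``."""
    d_cost = a.total_cost - b.total_cost
    d_qaly = a.total_qalys - b.total_qalys
    icer: Optional[float] = None
    dominance: Optional[str] = None
    if abs(d_qaly) <= _EPS_QALY:
        icer = None  # undefined: no effect difference
    elif d_qaly > 0 and d_cost < 0:
        dominance = "intervention_dominant"
    elif d_qaly < 0 and d_cost > 0:
        dominance = "intervention_dominated"
    else:
        icer = d_cost / d_qaly
    nmb = {
        a.strategy: wtp * a.total_qalys - a.total_cost,
        b.strategy: wtp * b.total_qalys - b.total_cost,
    }
    return CEAResult(
        intervention=a.strategy,
        comparator=b.strategy,
        cost={a.strategy: a.total_cost, b.strategy: b.total_cost},
        qalys={a.strategy: a.total_qalys, b.strategy: b.total_qalys},
        incremental_cost=d_cost,
        incremental_qalys=d_qaly,
        icer=icer,
        dominance=dominance,
        wtp=wtp,
        nmb=nmb,
    )


def run_base_case(config: ModelConfig, wtp: Optional[float] = None) -> CEAResult:
    """Run both arms of ``config`` and compare them (intervention first)."""
    a = run_cohort(config, config.intervention)
    b = run_cohort(config, config.comparator)
    return compare(a, b, config.settings.wtp if wtp is None else wtp)


def _nmb_gap(config: ModelConfig, price: float, wtp: float) -> float:
    """ΔC − λ·ΔE at a given intervention drug price; positive when the
    intervention is NOT cost-effective. Monotone increasing in price."""
    cfg = config.copy()
    cfg.intervention.drug_cost_per_cycle = price
    res = run_base_case(cfg, wtp)
    return res.incremental_cost - wtp * res.incremental_qalys


def threshold_price(
    config: ModelConfig,
    wtp: Optional[float] = None,
    price_bounds: tuple[float, float] = (0.0, 290.0),
    tol: float = 0.01,
) -> float:
    """Break-even intervention drug price per cycle at which the ICER equals
    the willingness-to-pay threshold.

    Bisects ``ΔC − λ·ΔE`` (monotone increasing in price, zero exactly when
    ICER = λ) on ``price_bounds`` until the bracket is narrower than ``tol``
    USD. Raises :class:`BracketError` when the bounds do not bracket the
    break-even point.
    """
    if wtp is None:
        wtp = config.settings.wtp
    lo, hi = price_bounds
    if not lo < hi:
        raise ValueError("price_bounds must satisfy lo < hi")
    f_lo = _nmb_gap(config, lo, wtp)
    f_hi = _nmb_gap(config, hi, wtp)
    if f_lo > 0 or f_hi < 0:
        raise BracketError(
            f"no break-even price in [{lo}, {hi}]: gap({lo})={f_lo:.4g}, gap({hi})={f_hi:.4g}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _nmb_gap(config, mid, wtp) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
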