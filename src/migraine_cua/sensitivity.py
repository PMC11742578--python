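"""Deterministic and probabilistic sensitivity analysis.

One-way DSA perturbs each scalar input ±20% (by default) and records the
ICER range (tornado). PSA samples every configured parameter distribution
by method-of-moments (normal, lognormal, beta), re-derives the cycle inputs
and reruns both arms per draw; the cost-effectiveness acceptability curve
(CEAC) is the fraction of draws with positive incremental net monetary
benefit as a function of willingness-to-pay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig, ParamDistribution, get_param, iter_param_paths, set_param
from .cea import run_base_case

__all__ = [
    "TornadoEntry",
    "oneway_dsa",
    "default_dsa_parameters",
    "moment_match",
    "PSAResult",
    "run_psa",
    "ceac",
]

_PROB_CAP = 1.0 - 1e-9

# fields whose values are probabilities or utilities and must stay <= 1
# (and MMD fields capped at 30 days) when scaled in a one-way DSA
_FIELD_CAPS = {
    "withdrawal_prob_6mo": _PROB_CAP,
    "annual_mortality": _PROB_CAP,
    "episodic_fraction": 1.0,
    "parenteral_fraction": 1.0,
    "working_day_fraction": 1.0,
    "u_migraine_day": 1.0,
    "u_free_day": 1.0,
    "utility_on_override": 1.0,
    "utility_off_override": 1.0,
    "mmd_on_treatment": 30.0,
    "baseline_mmd": 30.0,
    "off_treatment_mmd": 30.0,
}


@dataclass
class TornadoEntry:
    """One-way DSA result for a single parameter."""

    parameter: str
    base_value: float
    low_value: float
    high_value: float
    icer_low: float
    icer_high: float

    @property
    def range(self) -> float:
        return abs(self.icer_high - self.icer_low)


def default_dsa_parameters(config: ModelConfig) -> list[str]:
    """Every scalar clinical, cost and utility input plus mortality."""
    return [p for p in iter_param_paths(config) if get_param(config, p) is not None]


def _cap(path: str, value: float) -> float:
    leaf = path.rsplit(".", 1)[-1]
    cap = _FIELD_CAPS.get(leaf)
    return min(value, cap) if cap is not None else value


def _icer_at(config: ModelConfig, path: str, value: float) -> float:
    cfg = config.copy()
    set_param(cfg, path, _cap(path, value))
    res = run_base_case(cfg)
    if res.icer is not None:
        return res.icer
    if res.dominance == "intervention_dominant":
        return -math.inf
    if res.dominance == "intervention_dominated":
        return math.inf
    return math.nan  # zero QALY difference


def oneway_dsa(
    config: ModelConfig,
    parameters: Optional[Sequence[str]] = None,
    delta: float = 0.2,
) -> list[TornadoEntry]:
    """One-way deterministic sensitivity analysis.

    Each parameter is set to base×(1−delta) and base×(1+delta) in turn
    (probabilities, utilities and MMDs capped at their natural upper
    bounds), the model is re-run, and entries are returned sorted by
    descending ICER range.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if parameters is None:
        parameters = default_dsa_parameters(config)
    entries = []
    for path in parameters:
        base = get_param(config, path)  # raises KeyError if unresolvable
        low_v = _cap(path, base * (1.0 - delta))
        high_v = _cap(path, base * (1.0 + delta))
        entries.append(
            TornadoEntry(
                parameter=path,
                base_value=base,
                low_value=low_v,
                high_value=high_v,
                icer_low=_icer_at(config, path, low_v),
                icer_high=_icer_at(config, path, high_v),
            )
        )
    entries.sort(key=lambda e: e.range, reverse=True)
    return entries


def tornado_to_dataframe(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "base_value": [e.base_value for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "range": [e.range for e in entries],
        }
    )


def moment_match(dist: ParamDistribution):
    """Frozen scipy distribution matching ``dist``'s natural-scale moments.

    normal: (mean, sd). lognormal: σ² = ln(1 + sd²/mean²), μ = ln(mean) −
    σ²/2. beta: α = m(m(1−m)/sd² − 1), β = (1−m)(m(1−m)/sd² − 1), requiring
    sd² < m(1−m).
    """
    dist.validate()
    if dist.family == "normal":
        return stats.norm(loc=dist.mean, scale=dist.sd)
    if dist.family == "lognormal":
        sigma2 = math.log1p((dist.sd / dist.mean) ** 2)
        mu = math.log(dist.mean) - sigma2 / 2.0
        return stats.lognorm(s=math.sqrt(sigma2), scale=math.exp(mu))
    # beta
    m, v = dist.mean, dist.sd**2
    k = m * (1.0 - m) / v - 1.0
    return stats.beta(a=m * k, b=(1.0 - m) * k)


def _truncation_bounds(path: str) -> tuple[float, float] | None:
    leaf = path.rsplit(".", 1)[-1]
    cap = _FIELD_CAPS.get(leaf)
    if cap is None:
        return None
    return (0.0, cap)


@dataclass
class PSAResult:
    """Probabilistic sensitivity analysis output.

    ``draws`` has one row per draw: the sampled parameter values plus
    ``cost_<strategy>``, ``qalys_<strategy>``, ``incremental_cost`` and
    ``incremental_qalys``.
    """

    draws: pd.DataFrame
    intervention: str
    comparator: str
    seed: int

    def cost_effective_fraction(self, wtp: float) -> float:
        """Fraction of draws where the intervention has positive
        incremental net monetary benefit at ``wtp``."""
        gain = wtp * self.draws["incremental_qalys"] - self.draws["incremental_cost"]
        return float((gain > 0).mean())


def run_psa(config: ModelConfig, n_draws: int = 1000, seed: int = 0) -> PSAResult:
    """Monte-Carlo PSA: sample all configured distributions independently,
    truncate to natural supports (probabilities/utilities below 1, MMDs to
    [0, 30]), rerun both arms per draw. Reproducible for a given seed."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not config.distributions:
        raise ValueError("config has no parameter distributions")
    rng = np.random.default_rng(seed)
    samplers = [(d.target, moment_match(d)) for d in config.distributions]
    records = []
    for _ in range(n_draws):
        cfg = config.copy()
        row: dict[str, float] = {}
        for target, sampler in samplers:
            value = float(sampler.rvs(random_state=rng))
            bounds = _truncation_bounds(target)
            if bounds is not None:
                value = min(max(value, bounds[0]), bounds[1])
            set_param(cfg, target, value)
            row[target] = value
        res = run_base_case(cfg)
        row[f"cost_{res.intervention}"] = res.cost[res.intervention]
        row[f"cost_{res.comparator}"] = res.cost[res.comparator]
        row[f"qalys_{res.intervention}"] = res.qalys[res.intervention]
        row[f"qalys_{res.comparator}"] = res.qalys[res.comparator]
        row["incremental_cost"] = res.incremental_cost
        row["incremental_qalys"] = res.incremental_qalys
        records.append(row)
    return PSAResult(
        draws=pd.DataFrame.from_records(records),
        intervention=config.intervention.name,
        comparator=config.comparator.name,
        seed=seed,
    )


def ceac(psa: PSAResult, lambda_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: P(intervention cost-effective)
    over a willingness-to-pay grid."""
    if psa.draws.empty:
        raise ValueError("PSA has no draws")
    return pd.DataFrame(
        {
            "wtp": list(lambda_grid),
            "p_cost_effective": [psa.cost_effective_fraction(l) for l in lambda_grid],
        }
    )
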