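"""Model configuration: typed parameter containers, validation, YAML/JSON I/O.

The configuration describes one two-arm cost-utility analysis of preventive
migraine therapy: an intervention strategy and a comparator, a migraine
cohort, unit costs and resource-use assumptions, per-day utilities, global
model settings (horizon, cycle length, discount rates, willingness-to-pay),
and the parameter distributions used by probabilistic sensitivity analysis.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Optional

import yaml

__all__ = [
    "AdverseEvent",
    "StrategyParams",
    "CohortParams",
    "CostInputs",
    "UtilityInputs",
    "Settings",
    "ParamDistribution",
    "ModelConfig",
    "ConfigError",
    "SchemaError",
    "ValidationError",
    "load_config",
    "save_config",
    "default_paper_config",
    "get_param",
    "set_param",
]


class ConfigError(ValueError):
    """Base class for configuration problems."""


class SchemaError(ConfigError):
    """A required field is missing or an unknown field is present."""


class ValidationError(ConfigError):
    """A field value violates a model invariant."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class AdverseEvent:
    """One serious adverse event: incidence over the trial period and the
    annual utility decrement suffered while it lasts (negative)."""

    name: str
    rate: float
    annual_disutility: float

    def validate(self) -> None:
        _check(0.0 <= self.rate <= 1.0, f"AE {self.name!r}: rate {self.rate} outside [0, 1]")
        _check(
            self.annual_disutility <= 0.0,
            f"AE {self.name!r}: annual_disutility {self.annual_disutility} must be <= 0",
        )


@dataclass
class StrategyParams:
    """One treatment arm.

    ``drug_cost_per_cycle`` and ``admin_cost_per_cycle`` are USD per model
    cycle; ``mmd_on_treatment`` is the arm's mean monthly migraine days while
    on therapy; ``withdrawal_prob_6mo`` is the cumulative probability of
    discontinuation over the first six months. ``utility_on_override``, when
    set, replaces the MMD-derived on-treatment utility (used by PSA draws of
    the health-related quality-of-life distributions).
    """

    name: str
    drug_cost_per_cycle: float
    admin_cost_per_cycle: float
    mmd_on_treatment: float
    mmd_sd: float
    withdrawal_prob_6mo: float
    withdrawal_sd: float
    ae_profile: list[AdverseEvent] = field(default_factory=list)
    utility_on_override: Optional[float] = None

    def validate(self) -> None:
        _check(self.drug_cost_per_cycle >= 0, f"{self.name}: drug_cost_per_cycle < 0")
        _check(self.admin_cost_per_cycle >= 0, f"{self.name}: admin_cost_per_cycle < 0")
        _check(
            0.0 <= self.mmd_on_treatment <= 30.0,
            f"{self.name}: mmd_on_treatment {self.mmd_on_treatment} outside [0, 30]",
        )
        _check(self.mmd_sd > 0, f"{self.name}: mmd_sd must be > 0")
        _check(
            0.0 <= self.withdrawal_prob_6mo < 1.0,
            f"{self.name}: withdrawal_prob_6mo {self.withdrawal_prob_6mo} outside [0, 1)",
        )
        _check(self.withdrawal_sd > 0, f"{self.name}: withdrawal_sd must be > 0")
        if self.utility_on_override is not None:
            _check(
                0.0 <= self.utility_on_override <= 1.0,
                f"{self.name}: utility_on_override outside [0, 1]",
            )
        for ae in self.ae_profile:
            ae.validate()


@dataclass
class CohortParams:
    """The modelled cohort. ``n_patients`` is reporting metadata only — the
    cohort model tracks proportions. ``off_treatment_mmd`` defaults to the
    baseline MMD (patients who discontinue revert to their untreated attack
    frequency)."""

    n_patients: int = 1000
    episodic_fraction: float = 0.889
    baseline_mmd: float = 10.4
    baseline_sd: float = 3.9
    off_treatment_mmd: Optional[float] = None
    off_treatment_sd: float = 3.9
    annual_mortality: float = 0.005

    @property
    def chronic_fraction(self) -> float:
        return 1.0 - self.episodic_fraction

    @property
    def off_mmd(self) -> float:
        return self.baseline_mmd if self.off_treatment_mmd is None else self.off_treatment_mmd

    def validate(self) -> None:
        _check(self.n_patients >= 1, "n_patients must be >= 1")
        _check(0.0 <= self.episodic_fraction <= 1.0, "episodic_fraction outside [0, 1]")
        _check(0.0 <= self.baseline_mmd <= 30.0, "baseline_mmd outside [0, 30]")
        _check(self.baseline_sd > 0, "baseline_sd must be > 0")
        _check(0.0 <= self.off_mmd <= 30.0, "off_treatment_mmd outside [0, 30]")
        _check(0.0 <= self.annual_mortality < 1.0, "annual_mortality outside [0, 1)")


@dataclass
class CostInputs:
    """Unit costs (USD) and resource-use assumptions for micro-costing.

    Unit prices are per dose/visit/trip/working day; resource-use fields
    translate monthly migraine days into quantities per cycle:
    ``oral_acute_doses_per_mmd`` acute doses per migraine day,
    ``parenteral_fraction`` of acute doses given parenterally,
    ``visits_per_cycle`` specialist-visit equivalents per cycle, and
    ``working_day_fraction`` of migraine days that cost a day's wage.
    """

    oral_acute: float = 0.12
    parenteral_acute: float = 2.48
    gp_visit: float = 1.79
    specialist_visit: float = 3.28
    injection: float = 1.50
    trip: float = 0.70
    productivity_loss_per_day: float = 6.21
    oral_acute_doses_per_mmd: float = 1.0
    parenteral_fraction: float = 0.05
    visits_per_cycle: float = 1.0
    working_day_fraction: float = 1.0

    def validate(self) -> None:
        for f in (
            "oral_acute",
            "parenteral_acute",
            "gp_visit",
            "specialist_visit",
            "injection",
            "trip",
            "productivity_loss_per_day",
            "oral_acute_doses_per_mmd",
            "visits_per_cycle",
        ):
            _check(getattr(self, f) >= 0, f"costs.{f} must be >= 0")
        _check(0.0 <= self.parenteral_fraction <= 1.0, "parenteral_fraction outside [0, 1]")
        _check(0.0 <= self.working_day_fraction <= 1.0, "working_day_fraction outside [0, 1]")


@dataclass
class UtilityInputs:
    """Per-day health-state utilities: a day with a migraine attack and a
    migraine-free day, combined over a ``days_per_month``-day month.
    ``utility_off_override`` replaces the MMD-derived off-treatment utility
    when set (PSA use)."""

    u_migraine_day: float = 0.44
    u_free_day: float = 0.933
    days_per_month: float = 30.0
    utility_off_override: Optional[float] = None

    def validate(self) -> None:
        _check(
            0.0 <= self.u_migraine_day < self.u_free_day <= 1.0,
            f"require 0 <= u_migraine_day < u_free_day <= 1, "
            f"got {self.u_migraine_day}, {self.u_free_day}",
        )
        _check(self.days_per_month > 0, "days_per_month must be > 0")
        if self.utility_off_override is not None:
            _check(0.0 <= self.utility_off_override <= 1.0, "utility_off_override outside [0, 1]")


@dataclass
class Settings:
    """Global model settings.

    The horizon is ``n_cycles`` cycles of ``cycle_length_years`` each
    (default 60 monthly cycles = 5 years). Costs and QALYs are discounted at
    separate annual rates. ``withdrawal_cycles`` limits the treatment-
    discontinuation hazard to the first N cycles (None extrapolates the
    constant hazard over the whole horizon). ``irr_per_usd`` is metadata
    recording the fixed exchange rate behind the USD unit costs.
    """

    n_cycles: int = 60
    cycle_length_years: float = 1.0 / 12.0
    discount_cost_annual: float = 0.058
    discount_qaly_annual: float = 0.05
    wtp: float = 2456.0
    half_cycle_correction: bool = True
    withdrawal_cycles: Optional[int] = 6
    irr_per_usd: float = 285_000.0

    def validate(self) -> None:
        _check(self.n_cycles >= 1, "n_cycles must be >= 1")
        _check(self.cycle_length_years > 0, "cycle_length_years must be > 0")
        _check(self.discount_cost_annual >= 0, "discount_cost_annual must be >= 0")
        _check(self.discount_qaly_annual >= 0, "discount_qaly_annual must be >= 0")
        _check(self.wtp >= 0, "wtp must be >= 0")
        if self.withdrawal_cycles is not None:
            _check(self.withdrawal_cycles >= 0, "withdrawal_cycles must be >= 0")


_FAMILIES = ("normal", "lognormal", "beta")


@dataclass
class ParamDistribution:
    """Distribution assigned to one scalar model input for PSA, specified by
    its natural-scale mean and SD (moment-matched at sampling time)."""

    target: str
    family: str
    mean: float
    sd: float

    def validate(self) -> None:
        _check(self.family in _FAMILIES, f"{self.target}: unknown family {self.family!r}")
        _check(self.sd > 0, f"{self.target}: sd must be > 0")
        if self.family == "lognormal":
            _check(self.mean > 0, f"{self.target}: lognormal mean must be > 0")
        if self.family == "beta":
            _check(0.0 < self.mean < 1.0, f"{self.target}: beta mean must be in (0, 1)")
            _check(
                self.sd**2 < self.mean * (1.0 - self.mean),
                f"{self.target}: beta variance {self.sd**2:.4g} >= mean(1-mean) "
                f"{self.mean * (1 - self.mean):.4g} (infeasible moments)",
            )


@dataclass
class ModelConfig:
    """Complete parameter set for one two-strategy analysis. ``strategies``
    holds exactly (intervention, comparator), in that order."""

    strategies: list[StrategyParams]
    cohort: CohortParams = field(default_factory=CohortParams)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    settings: Settings = field(default_factory=Settings)
    distributions: list[ParamDistribution] = field(default_factory=list)

    def validate(self) -> "ModelConfig":
        _check(len(self.strategies) == 2, f"exactly two strategies required, got {len(self.strategies)}")
        for s in self.strategies:
            s.validate()
        _check(
            self.strategies[0].name != self.strategies[1].name,
            "strategy names must be distinct",
        )
        self.cohort.validate()
        self.costs.validate()
        self.utilities.validate()
        self.settings.validate()
        for d in self.distributions:
            d.validate()
            get_param(self, d.target)  # raises if the path does not resolve
        return self

    @property
    def intervention(self) -> StrategyParams:
        return self.strategies[0]

    @property
    def comparator(self) -> StrategyParams:
        return self.strategies[1]

    def strategy(self, name: str) -> StrategyParams:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# dotted parameter paths (shared by DSA/PSA)

def _resolve(config: ModelConfig, path: str) -> tuple[Any, str]:
    """Resolve a dotted path like ``strategies.erenumab.mmd_on_treatment``
    or ``cohort.annual_mortality`` to (owner object, attribute name)."""
    parts = path.split(".")
    obj: Any = config
    for i, part in enumerate(parts[:-1]):
        if part == "strategies":
            obj = config.strategy(parts[i + 1])
            return _descend(obj, parts[i + 2 :], path)
        if not hasattr(obj, part):
            raise KeyError(f"cannot resolve parameter path {path!r} at {part!r}")
        obj = getattr(obj, part)
    return _descend_leaf(obj, parts[-1], path)


def _descend(obj: Any, rest: list[str], path: str) -> tuple[Any, str]:
    for part in rest[:-1]:
        if not hasattr(obj, part):
            raise KeyError(f"cannot resolve parameter path {path!r} at {part!r}")
        obj = getattr(obj, part)
    return _descend_leaf(obj, rest[-1], path)


def _descend_leaf(obj: Any, leaf: str, path: str) -> tuple[Any, str]:
    if not hasattr(obj, leaf):
        raise KeyError(f"cannot resolve parameter path {path!r}: no field {leaf!r}")
    return obj, leaf


def get_param(config: ModelConfig, path: str) -> float:
    obj, leaf = _resolve(config, path)
    value = getattr(obj, leaf)
    if value is not None and not isinstance(value, (int, float)):
        raise KeyError(f"parameter path {path!r} is not numeric (got {type(value).__name__})")
    return value


def set_param(config: ModelConfig, path: str, value: float) -> None:
    obj, leaf = _resolve(config, path)
    setattr(obj, leaf, value)


def iter_param_paths(config: ModelConfig) -> Iterator[str]:
    """All numeric scalar paths a sensitivity analysis may touch."""
    for s in config.strategies:
        for f in (
            "drug_cost_per_cycle",
            "admin_cost_per_cycle",
            "mmd_on_treatment",
            "withdrawal_prob_6mo",
        ):
            yield f"strategies.{s.name}.{f}"
    for f in ("baseline_mmd", "off_treatment_mmd", "annual_mortality"):
        yield f"cohort.{f}"
    for f in (
        "oral_acute",
        "parenteral_acute",
        "gp_visit",
        "specialist_visit",
        "injection",
        "trip",
        "productivity_loss_per_day",
    ):
        yield f"costs.{f}"
    for f in ("u_migraine_day", "u_free_day"):
        yield f"utilities.{f}"


# ---------------------------------------------------------------------------
# serialization

def _to_dict(config: ModelConfig) -> dict:
    return dataclasses.asdict(config)


_SECTION_TYPES = {
    "cohort": CohortParams,
    "costs": CostInputs,
    "utilities": UtilityInputs,
    "settings": Settings,
}


def _build_section(cls: type, data: dict, where: str) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"{where}: unknown field(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:  # missing required field
        raise SchemaError(f"{where}: {exc}") from None


def _from_dict(data: dict) -> ModelConfig:
    if not isinstance(data, dict):
        raise SchemaError("config root must be a mapping")
    if "strategies" not in data:
        raise SchemaError("missing required section 'strategies'")
    strategies = []
    for raw in data["strategies"]:
        raw = dict(raw)
        aes = [_build_section(AdverseEvent, dict(a), "ae_profile") for a in raw.pop("ae_profile", [])]
        s = _build_section(StrategyParams, raw, f"strategy {raw.get('name', '?')!r}")
        s.ae_profile = aes
        strategies.append(s)
    kwargs: dict[str, Any] = {"strategies": strategies}
    for section, cls in _SECTION_TYPES.items():
        if section in data:
            kwargs[section] = _build_section(cls, dict(data[section]), section)
    kwargs["distributions"] = [
        _build_section(ParamDistribution, dict(d), "distributions")
        for d in data.get("distributions", [])
    ]
    extra = set(data) - set(_SECTION_TYPES) - {"strategies", "distributions"}
    if extra:
        raise SchemaError(f"unknown top-level section(s) {sorted(extra)}")
    return ModelConfig(**kwargs).validate()


def load_config(path: str | Path) -> ModelConfig:
    """Read and validate a model configuration from a YAML (or JSON) file."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)
    return _from_dict(data)


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration to YAML; ``load_config`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(_to_dict(config), sort_keys=False))


def config_to_json(config: ModelConfig) -> str:
    return json.dumps(_to_dict(config), indent=2)


# ---------------------------------------------------------------------------
# packaged base case

#: Alternative per-cycle price for the 140 mg dose, kept as a preset only.
ERENUMAB_140MG_COST = 348.0


def default_paper_config() -> ModelConfig:
    """The packaged base case: Erenumab 70 mg (290 USD/cycle + 1.50
    injection) versus Topiramate 100 mg/day (0.06 USD/day), HER-MES-derived
    efficacy and withdrawal, Iranian unit costs and a 2,456 USD/QALY
    willingness-to-pay threshold."""
    erenumab = StrategyParams(
        name="erenumab",
        drug_cost_per_cycle=290.0,
        admin_cost_per_cycle=1.50,
        mmd_on_treatment=4.54,
        mmd_sd=2.18,
        withdrawal_prob_6mo=0.106,
        withdrawal_sd=0.043,
        ae_profile=[
            AdverseEvent("fatigue", 0.023, -0.06),
            AdverseEvent("dizziness", 0.010, -0.01),
            AdverseEvent("paresthesia", 0.000, -0.012),
            AdverseEvent("attention_deficit", 0.093, -0.098),
        ],
    )
    topiramate = StrategyParams(
        name="topiramate",
        drug_cost_per_cycle=1.80,  # 0.06 USD/day x 30-day cycle
        admin_cost_per_cycle=0.0,
        mmd_on_treatment=6.38,
        mmd_sd=1.82,
        withdrawal_prob_6mo=0.389,
        withdrawal_sd=0.144,
        ae_profile=[
            AdverseEvent("fatigue", 0.075, -0.06),
            AdverseEvent("dizziness", 0.054, -0.01),
            AdverseEvent("paresthesia", 0.098, -0.012),
            AdverseEvent("attention_deficit", 0.018, -0.098),
        ],
    )
    distributions = [
        ParamDistribution("cohort.baseline_mmd", "normal", 10.4, 3.9),
        ParamDistribution("strategies.erenumab.mmd_on_treatment", "lognormal", 4.54, 2.18),
        ParamDistribution("strategies.topiramate.mmd_on_treatment", "lognormal", 6.38, 1.82),
        ParamDistribution("cohort.off_treatment_mmd", "lognormal", 10.4, 3.9),
        ParamDistribution("strategies.erenumab.withdrawal_prob_6mo", "lognormal", 0.106, 0.043),
        ParamDistribution("strategies.topiramate.withdrawal_prob_6mo", "lognormal", 0.389, 0.144),
        ParamDistribution("strategies.erenumab.utility_on_override", "beta", 0.86, 0.085),
        ParamDistribution("strategies.topiramate.utility_on_override", "beta", 0.83, 0.079),
        ParamDistribution("utilities.utility_off_override", "beta", 0.76, 0.08),
    ]
    cfg = ModelConfig(
        strategies=[erenumab, topiramate],
        cohort=CohortParams(off_treatment_mmd=10.4),
        costs=CostInputs(),
        utilities=UtilityInputs(),
        settings=Settings(),
        distributions=distributions,
    )
    return cfg.validate()


def packaged_config_path() -> Path:
    """Path of the YAML file shipping the base case."""
    return Path(str(resources.files("migraine_cua").joinpath("data/default_config.yaml")))
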