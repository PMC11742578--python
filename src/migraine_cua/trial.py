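"""Synthetic head-to-head trial generator and parameter recovery.

Emulates the patient-level structure behind the published arm summaries a
decision model is parameterised from: per-patient baseline and on-treatment
monthly migraine days (MMD), discontinuation within the first six months
under a constant monthly hazard, and Bernoulli serious-adverse-event
incidence. Companion estimators recover arm-level summaries and rebuild a
model configuration from them, closing the simulate → summarise →
re-parameterise → model loop for end-to-end testing.

Patients are returned as a :class:`pandas.DataFrame` with columns

    patient_id   int, unique within the trial
    arm          strategy name
    subtype      "episodic" (baseline MMD < 15) or "chronic" (>= 15)
    baseline_mmd float, days/month in [4, 30] (trial entry requires >= 4)
    on_treatment_mmd float, days/month in [0, baseline_mmd]
    withdrawal_month int, 1..6, or <NA> if the patient completed 6 months
    ae_<name>    0/1 flag per adverse event in the arm's profile
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig, StrategyParams
from .derivations import probability_rescale
from .sensitivity import moment_match
from .config import ParamDistribution

__all__ = [
    "CHRONIC_MMD_CUTOFF",
    "MIN_TRIAL_MMD",
    "simulate_trial",
    "summarize_trial",
    "ArmSummary",
    "TrialSummary",
    "config_from_summary",
]

#: 15 or more monthly migraine days classifies a patient as chronic.
CHRONIC_MMD_CUTOFF = 15.0
#: Trial entry requires at least four monthly migraine days.
MIN_TRIAL_MMD = 4.0
_TRIAL_MONTHS = 6


def _truncated_normal(mean: float, sd: float, lo: float, hi: float):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def _sample_on_treatment_mmd(
    rng: np.random.Generator, strategy: StrategyParams, baseline: np.ndarray
) -> np.ndarray:
    """Lognormal draws moment-matched to the arm summary, truncated to
    [0, baseline] per patient by resampling (final clip as a guard)."""
    sampler = moment_match(
        ParamDistribution("on_mmd", "lognormal", strategy.mmd_on_treatment, strategy.mmd_sd)
    )
    values = np.asarray(sampler.rvs(size=baseline.size, random_state=rng), dtype=float)
    for _ in range(100):
        bad = values > baseline
        if not bad.any():
            break
        values[bad] = sampler.rvs(size=int(bad.sum()), random_state=rng)
    return np.minimum(values, baseline)


def simulate_trial(n_per_arm: int, truth: ModelConfig, seed: int) -> pd.DataFrame:
    """Simulate a two-arm randomized trial of ``n_per_arm`` patients per arm
    from the clinical parameters in ``truth``; fully seeded."""
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    baseline_dist = _truncated_normal(
        truth.cohort.baseline_mmd, truth.cohort.baseline_sd, MIN_TRIAL_MMD, 30.0
    )
    frames = []
    offset = 0
    for strategy in truth.strategies:
        baseline = np.asarray(baseline_dist.rvs(size=n_per_arm, random_state=rng), dtype=float)
        on_mmd = _sample_on_treatment_mmd(rng, strategy, baseline)
        hazard = probability_rescale(strategy.withdrawal_prob_6mo, 6.0, 1.0)
        months = rng.geometric(hazard, size=n_per_arm) if hazard > 0 else np.full(n_per_arm, 10**9)
        withdrawal = pd.array(months, dtype="Int64")
        withdrawal[months > _TRIAL_MONTHS] = pd.NA
        frame = pd.DataFrame(
            {
                "patient_id": np.arange(offset, offset + n_per_arm),
                "arm": strategy.name,
                "subtype": np.where(baseline >= CHRONIC_MMD_CUTOFF, "chronic", "episodic"),
                "baseline_mmd": baseline,
                "on_treatment_mmd": on_mmd,
                "withdrawal_month": withdrawal,
            }
        )
        for ae in strategy.ae_profile:
            frame[f"ae_{ae.name}"] = (rng.random(n_per_arm) < ae.rate).astype(int)
        frames.append(frame)
        offset += n_per_arm
    return pd.concat(frames, ignore_index=True)


@dataclass
class ArmSummary:
    """Published-style summary of one trial arm."""

    arm: str
    n: int
    baseline_mmd_mean: float
    baseline_mmd_sd: float
    on_mmd_mean: float
    on_mmd_sd: float
    withdrawal_prob_6mo: float
    withdrawal_se: float
    ae_incidence: dict[str, float]


@dataclass
class TrialSummary:
    arms: dict[str, ArmSummary]
    episodic_fraction: float


def summarize_trial(patients: pd.DataFrame) -> TrialSummary:
    """Arm-wise moments, six-month withdrawal proportion with binomial SE,
    and adverse-event incidences."""
    if patients.empty:
        raise ValueError("empty trial")
    arms = {}
    for arm, grp in patients.groupby("arm", sort=False):
        n = len(grp)
        p_wd = float(grp["withdrawal_month"].notna().mean())
        arms[arm] = ArmSummary(
            arm=str(arm),
            n=n,
            baseline_mmd_mean=float(grp["baseline_mmd"].mean()),
            baseline_mmd_sd=float(grp["baseline_mmd"].std(ddof=1)) if n > 1 else 0.0,
            on_mmd_mean=float(grp["on_treatment_mmd"].mean()),
            on_mmd_sd=float(grp["on_treatment_mmd"].std(ddof=1)) if n > 1 else 0.0,
            withdrawal_prob_6mo=p_wd,
            withdrawal_se=float(np.sqrt(p_wd * (1 - p_wd) / n)),
            ae_incidence={
                c.removeprefix("ae_"): float(grp[c].mean())
                for c in grp.columns
                if c.startswith("ae_") and grp[c].notna().all()
            },
        )
    return TrialSummary(
        arms=arms,
        episodic_fraction=float((patients["subtype"] == "episodic").mean()),
    )


def config_from_summary(summary: TrialSummary, base: ModelConfig) -> ModelConfig:
    """Replace the clinical parameters of ``base`` with trial estimates.

    Cost, utility and settings sections are untouched; strategy MMD and
    withdrawal moments, AE rates, the cohort baseline MMD moments and the
    episodic fraction are re-estimated. Distribution entries keep their
    families but take the estimated moments.
    """
    cfg = base.copy()
    pooled_baseline_mean = float(
        np.mean([a.baseline_mmd_mean for a in summary.arms.values()])
    )
    pooled_baseline_sd = float(np.mean([a.baseline_mmd_sd for a in summary.arms.values()]))
    cfg.cohort.baseline_mmd = pooled_baseline_mean
    cfg.cohort.baseline_sd = max(pooled_baseline_sd, 1e-9)
    if cfg.cohort.off_treatment_mmd is not None:
        cfg.cohort.off_treatment_mmd = pooled_baseline_mean
    cfg.cohort.episodic_fraction = summary.episodic_fraction
    for strategy in cfg.strategies:
        if strategy.name not in summary.arms:
            raise KeyError(f"trial summary has no arm {strategy.name!r}")
        arm = summary.arms[strategy.name]
        strategy.mmd_on_treatment = arm.on_mmd_mean
        strategy.mmd_sd = max(arm.on_mmd_sd, 1e-9)
        strategy.withdrawal_prob_6mo = arm.withdrawal_prob_6mo
        strategy.withdrawal_sd = max(arm.withdrawal_se, 1e-9)
        for ae in strategy.ae_profile:
            if ae.name in arm.ae_incidence:
                ae.rate = arm.ae_incidence[ae.name]
    for dist in cfg.distributions:
        leaf = dist.target.rsplit(".", 1)[-1]
        if leaf in ("baseline_mmd", "off_treatment_mmd"):
            dist.mean, dist.sd = cfg.cohort.baseline_mmd, cfg.cohort.baseline_sd
        elif dist.target.startswith("strategies."):
            name = dist.target.split(".")[1]
            arm_s = cfg.strategy(name)
            if leaf == "mmd_on_treatment":
                dist.mean, dist.sd = arm_s.mmd_on_treatment, arm_s.mmd_sd
            elif leaf == "withdrawal_prob_6mo":
                dist.mean, dist.sd = arm_s.withdrawal_prob_6mo, arm_s.withdrawal_sd
    return cfg.validate()
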