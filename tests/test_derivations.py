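"""Derived quantities: probability conversions, utilities, AE decrements,
state costs, assembled cycle inputs."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as hs

from migraine_cua.config import UtilityInputs
from migraine_cua.derivations import (
    build_cycle_inputs,
    expected_ae_disutility,
    one_week_disutility,
    probability_rescale,
    rate_to_probability,
    state_cost_per_cycle,
    utility_from_mmd,
)


class TestRateProbability:
    def test_zero_rate_gives_zero_probability(self):
        assert rate_to_probability(0.0, 5.0) == 0.0

    @pytest.mark.parametrize(
        "p6",
        [0.106, 0.389],
        ids=["erenumab_withdrawal", "topiramate_withdrawal"],
    )
    def test_six_month_withdrawal_to_monthly(self, p6):
        # oracle: constant hazard => monthly p = 1 - (1-p6)^(1/6)
        rate = -math.log(1.0 - p6) / 6.0
        expected = 1.0 - (1.0 - p6) ** (1.0 / 6.0)
        assert rate_to_probability(rate, 1.0) == pytest.approx(expected, abs=1e-12)
        assert probability_rescale(p6, 6.0, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_monthly_values(self):
        assert probability_rescale(0.106, 6.0, 1.0) == pytest.approx(0.0185024, abs=1e-6)
        assert probability_rescale(0.389, 6.0, 1.0) == pytest.approx(0.0788291, abs=1e-6)
        assert probability_rescale(0.005, 12.0, 1.0) == pytest.approx(
            1.0 - 0.995 ** (1.0 / 12.0), abs=1e-12
        )

    def test_rescale_identity(self):
        assert probability_rescale(0.3, 7.0, 7.0) == pytest.approx(0.3, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-0.1, 1.0)
        with pytest.raises(ValueError):
            probability_rescale(1.0, 6.0, 1.0)

    @given(
        rate=hs.floats(0.0, 1.0),
        big_t=hs.floats(0.1, 6.0),
        small_t=hs.floats(0.01, 6.0),
    )
    def test_conversion_and_rescaling_are_mutually_consistent(self, rate, big_t, small_t):
        p_big = rate_to_probability(rate, big_t)
        assert probability_rescale(p_big, big_t, small_t) == pytest.approx(
            rate_to_probability(rate, small_t), abs=1e-12
        )


class TestUtilities:
    U = UtilityInputs()

    def test_extremes(self):
        assert utility_from_mmd(0.0, self.U) == pytest.approx(0.933)
        assert utility_from_mmd(30.0, self.U) == pytest.approx(0.44)

    @pytest.mark.parametrize(
        "mmd,rounded",
        [(4.54, 0.86), (6.38, 0.83), (10.4, 0.76)],
        ids=["erenumab", "topiramate", "baseline"],
    )
    def test_reproduces_published_state_utilities_with_30_day_month(self, mmd, rounded):
        assert round(utility_from_mmd(mmd, self.U), 2) == rounded

    def test_28_day_month_fails_the_cross_check(self):
        # documents why the utility mixture uses a 30-day month
        u28 = UtilityInputs(days_per_month=28.0)
        assert round(utility_from_mmd(4.54, u28), 2) != 0.86

    @given(a=hs.floats(0.0, 30.0), b=hs.floats(0.0, 30.0))
    def test_strictly_decreasing_in_mmd(self, a, b):
        ua, ub = utility_from_mmd(a, self.U), utility_from_mmd(b, self.U)
        if a == b:
            assert ua == ub
        elif a < b:
            assert ua >= ub
            if b - a > 1e-9:  # strict once the gap is representable
                assert ua > ub
        else:
            assert ua <= ub
            if a - b > 1e-9:
                assert ua < ub

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            utility_from_mmd(31.0, self.U)


class TestAEDisutility:
    @pytest.mark.parametrize(
        "annual,weekly",
        [(-0.06, -0.0011), (-0.01, -0.0002), (-0.012, -0.0002), (-0.098, -0.0019)],
        ids=["fatigue", "dizziness", "paresthesia", "attention_deficit"],
    )
    def test_one_week_decrement_matches_published_cells(self, annual, weekly):
        assert round(one_week_disutility(annual), 4) == weekly

    def test_zero_and_sign_handling(self):
        assert one_week_disutility(0.0) == 0.0
        with pytest.raises(ValueError):
            one_week_disutility(0.01)

    @pytest.mark.parametrize("idx", [0, 1], ids=["erenumab", "topiramate"])
    def test_expected_decrement_is_rate_weighted_sum(self, base_config, idx):
        strategy = base_config.strategies[idx]
        brute = sum(ae.rate * ae.annual_disutility * 7.0 / 365.25 for ae in strategy.ae_profile)
        assert expected_ae_disutility(strategy) == pytest.approx(brute, abs=1e-15)
        assert brute < 0

    def test_empty_profile_gives_zero(self, base_config):
        strategy = base_config.intervention
        strategy.ae_profile = []
        assert expected_ae_disutility(strategy) == 0.0


class TestStateCosts:
    def test_all_unit_costs_zero(self, base_config):
        c = base_config.costs
        for f in (
            "oral_acute",
            "parenteral_acute",
            "specialist_visit",
            "trip",
            "productivity_loss_per_day",
        ):
            setattr(c, f, 0.0)
        s = base_config.intervention
        s.drug_cost_per_cycle = 0.0
        s.admin_cost_per_cycle = 0.0
        assert state_cost_per_cycle("on", s, 4.54, c) == 0.0

    def test_on_treatment_composition(self, base_config):
        s, c = base_config.intervention, base_config.costs
        acute = 4.54 * (0.95 * 0.12 + 0.05 * 2.48)
        expected = 290 + 1.50 + acute + (3.28 + 0.70) + 4.54 * 1.0 * 6.21
        assert state_cost_per_cycle("on", s, 4.54, c) == pytest.approx(expected)

    def test_off_treatment_has_no_drug_component(self, base_config):
        s, c = base_config.intervention, base_config.costs
        off = state_cost_per_cycle("off", s, 10.4, c)
        s.drug_cost_per_cycle = 0.0
        s.admin_cost_per_cycle = 0.0
        assert state_cost_per_cycle("on", s, 10.4, c) == pytest.approx(off)

    def test_unknown_state_rejected(self, base_config):
        with pytest.raises(ValueError, match="unknown state"):
            state_cost_per_cycle("cured", base_config.intervention, 5.0, base_config.costs)


class TestCycleInputs:
    def test_base_case_erenumab(self, base_config):
        ci = build_cycle_inputs(base_config, base_config.intervention)
        assert ci.p_withdraw == pytest.approx(0.0185024, abs=1e-6)
        assert ci.p_die == pytest.approx(1 - 0.995 ** (1 / 12), abs=1e-12)
        assert round(ci.u_on, 2) == 0.86
        assert ci.first_cycle_disutility < 0

    def test_base_case_topiramate_utility(self, base_config):
        ci = build_cycle_inputs(base_config, base_config.comparator)
        assert round(ci.u_on, 2) == 0.83
        assert round(ci.u_off, 2) == 0.76

    def test_zero_mortality_override(self, base_config):
        base_config.cohort.annual_mortality = 0.0
        ci = build_cycle_inputs(base_config, base_config.intervention)
        assert ci.p_die == 0.0

    def test_utility_overrides_take_precedence(self, base_config):
        base_config.intervention.utility_on_override = 0.9
        base_config.utilities.utility_off_override = 0.7
        ci = build_cycle_inputs(base_config, base_config.intervention)
        assert ci.u_on == 0.9
        assert ci.u_off == 0.7
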