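"""Costing, exposure, outcome and cost-effectiveness arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wardsim.economics import (
    CostParameters,
    EffectEstimates,
    PlanComparison,
    ExposureSummary,
    cost_effectiveness,
    exposure_summary,
    implied_cross_nnt,
    outcome_effects,
    recost,
    reference_levels,
    sensitivity_grid,
    staffing_cost_summary,
)
from wardsim.errors import ConfigurationError, InputError
from wardsim.roster_planner import PlanKind, build_establishment
from wardsim.shift_engine import SimulatorConfig, run_scenario
from wardsim.synthetic_hospital import availability_preset


def _cell_frame(rows):
    return pd.DataFrame(rows, columns=["role", "source", "shift", "daytype", "hours"])


class TestStaffingCost:
    def test_single_cell_hand_arithmetic(self):
        # 10 RN substantive hours at £20/h on a weekday night with a 1.3
        # unsocial multiplier = £260; 2 patient days -> £130/patient-day
        costs = CostParameters(
            hourly_cost={
                ("RN", "substantive"): 20.0,
                ("RN", "bank"): 20.0,
                ("RN", "agency"): 20.0,
                ("NA", "substantive"): 10.0,
                ("NA", "bank"): 10.0,
                ("NA", "agency"): 10.0,
            },
            unsocial_multiplier={
                (s, d): (1.3 if s == "night" else 1.0)
                for s in ("early", "late", "night")
                for d in ("weekday", "weekend")
            },
        )
        frame = _cell_frame([("RN", "substantive", "night", "weekday", 10.0)])
        priced = recost(frame, costs)
        assert priced["cost"].sum() == pytest.approx(260.0)
        assert priced["cost"].sum() / 2 == pytest.approx(130.0)

    def test_agency_hours_cost_strictly_more_than_substantive(self, costs):
        sub = recost(_cell_frame([("RN", "substantive", "early", "weekday", 10.0)]), costs)
        ag = recost(_cell_frame([("RN", "agency", "early", "weekday", 10.0)]), costs)
        assert ag["cost"].sum() > sub["cost"].sum()

    def test_default_rate_ordering_bank_below_substantive_below_agency(self, costs):
        for role in ("RN", "NA"):
            assert (
                costs.hourly_cost[(role, "bank")]
                <= costs.hourly_cost[(role, "substantive")]
                <= costs.hourly_cost[(role, "agency")]
            )

    def test_zero_hours_zero_cost(self, costs, ten_unit_hospital):
        cfg = SimulatorConfig(
            master_seed=2, days=10, absence_rates={"RN": 0.0, "NA": 0.0},
            allow_floating=False,
        )
        plan = build_establishment(ten_unit_hospital.units, PlanKind.STANDARD, 2)
        result = run_scenario(ten_unit_hospital, plan, availability_preset("none"), cfg)
        summary = staffing_cost_summary(result, costs)
        assert summary.total > 0  # rostered hours are worked and paid
        assert summary.breakdown.query("source != 'substantive'")["cost"].sum() == 0


@pytest.fixture(scope="module")
def std_run(ten_unit_hospital):
    cfg = SimulatorConfig(master_seed=3, days=60)
    plan = build_establishment(ten_unit_hospital.units, PlanKind.STANDARD, 3)
    return run_scenario(ten_unit_hospital, plan, availability_preset("limited"), cfg)


class TestReferenceAndExposure:
    def test_reference_is_mean_of_daily_hppd(self, std_run):
        refs = reference_levels(std_run)
        hppd = std_run.hppd()
        i = 0
        expect = np.nanmean(hppd[i])
        assert refs[std_run.unit_ids[i]] == pytest.approx(expect)

    def test_reference_computed_twice_identical(self, std_run):
        assert reference_levels(std_run) == reference_levels(std_run)

    def test_days_exactly_at_reference_are_not_low(self, std_run):
        refs = {u: 0.0 for u in std_run.unit_ids}  # everything >= 0 = reference
        exp = exposure_summary(std_run, refs)
        assert exp.prop_low_staffed == 0.0

    def test_high_temporary_threshold_is_strict(self, std_run):
        # set the threshold so high nothing can exceed it
        exp = exposure_summary(std_run, reference_levels(std_run), threshold_high_temp=1e9)
        assert exp.prop_high_temporary == 0.0

    def test_missing_reference_rejected(self, std_run):
        with pytest.raises(InputError):
            exposure_summary(std_run, {})


class TestOutcomeEffects:
    def test_null_risk_ratio_means_no_deaths(self, effects):
        eff = EffectEstimates(rr_death_per_low_day=1.0)
        d_deaths, _ = outcome_effects(-0.5, 0.0, eff, admissions=10_000)
        assert d_deaths == 0.0

    def test_hand_worked_default_form(self):
        eff = EffectEstimates(rr_death_per_low_day=1.03, baseline_mortality_risk=0.03)
        d_deaths, _ = outcome_effects(-0.5, 0.0, eff, admissions=10_000)
        # 0.03 x 10000 x 0.03 x (-0.5) = -4.5 deaths
        assert d_deaths == pytest.approx(-4.5)

    def test_zero_exposure_change_zero_effects(self, effects):
        d_deaths, d_bed_days = outcome_effects(0.0, 0.0, effects, admissions=5000)
        assert d_deaths == 0.0 and d_bed_days == 0.0

    def test_temporary_effect_only_in_secondary_variant(self, effects):
        d1, _ = outcome_effects(0.0, -1.0, effects, 1000, "low_staffing_only")
        d2, _ = outcome_effects(0.0, -1.0, effects, 1000, "including_temporary_effects")
        assert d1 == 0.0 and d2 < 0.0

    def test_invalid_variant_rejected(self, effects):
        with pytest.raises(ConfigurationError):
            outcome_effects(0.0, 0.0, effects, 1000, "everything")


class TestCostEffectiveness:
    def test_nnt_times_arr_is_exactly_one(self):
        res = cost_effectiveness(
            "a vs b", "limited", "low_staffing_only",
            d_staff_cost=1e5, d_bed_days=-100.0, d_deaths=-10.0,
            admissions=6650.0, excess_bed_day_cost=337.0,
        )
        assert res.nnt_kind == "NNT"
        assert res.nnt * res.risk_change == pytest.approx(1.0, rel=1e-15)
        assert res.staff_cost_per_life == pytest.approx(1e4)

    def test_arr_of_1_in_665_gives_nnt_665(self):
        res = cost_effectiveness(
            "a vs b", "limited", "low_staffing_only",
            d_staff_cost=0.0, d_bed_days=0.0, d_deaths=-1.0,
            admissions=665.0, excess_bed_day_cost=337.0,
        )
        assert res.nnt == pytest.approx(665.0)

    def test_increased_deaths_reported_as_nnh(self):
        res = cost_effectiveness(
            "a vs b", "none", "low_staffing_only",
            d_staff_cost=-5.0, d_bed_days=10.0, d_deaths=4.0,
            admissions=1000.0, excess_bed_day_cost=337.0,
        )
        assert res.nnt_kind == "NNH"
        assert res.nnt == pytest.approx(250.0)

    def test_zero_mortality_difference_yields_no_effect_marker(self):
        res = cost_effectiveness(
            "a vs b", "none", "low_staffing_only",
            d_staff_cost=100.0, d_bed_days=0.0, d_deaths=0.0,
            admissions=1000.0, excess_bed_day_cost=337.0,
        )
        assert res.nnt_kind == "no-effect"
        assert res.nnt is None and res.net_cost_per_life is None

    def test_bed_day_offset_reduces_net_cost(self):
        res = cost_effectiveness(
            "a vs b", "limited", "low_staffing_only",
            d_staff_cost=1000.0, d_bed_days=-2.0, d_deaths=-1.0,
            admissions=100.0, excess_bed_day_cost=337.0,
        )
        assert res.net_cost_per_life == pytest.approx(1000.0 - 2 * 337.0)
        assert res.net_cost_per_life < res.staff_cost_per_life

    @settings(deadline=None, max_examples=100)
    @given(
        d_deaths=st.floats(-50, 50).filter(lambda x: abs(x) > 1e-6),
        admissions=st.floats(100, 1e6),
    )
    def test_reciprocal_identity_property(self, d_deaths, admissions):
        res = cost_effectiveness(
            "a vs b", "none", "low_staffing_only",
            0.0, 0.0, d_deaths, admissions, 337.0,
        )
        assert res.nnt * res.risk_change == pytest.approx(1.0, rel=1e-12)


class TestImpliedCrossNnt:
    def test_shared_baseline_identity_matches_printed_pair(self):
        # NNT 665 at -4.5% risk change implies NNH 361 at +8.3%
        assert round(implied_cross_nnt(665.0, -4.5, 8.3)) == 361

    def test_zero_second_effect_rejected(self):
        with pytest.raises(InputError):
            implied_cross_nnt(665.0, -4.5, 0.0)


def _toy_comparison():
    """A fully synthetic comparison with simple stored ledgers."""
    bh = _cell_frame(
        [
            ("RN", "substantive", "early", "weekday", 1000.0),
            ("RN", "agency", "night", "weekend", 0.0),
            ("NA", "bank", "late", "weekday", 100.0),
        ]
    )
    bl = _cell_frame(
        [
            ("RN", "substantive", "early", "weekday", 800.0),
            ("RN", "agency", "night", "weekend", 0.0),
            ("NA", "bank", "late", "weekday", 150.0),
        ]
    )
    eh = ExposureSummary("resilient", "limited", 5000.0, 0.30, 0.01)
    el = ExposureSummary("standard", "limited", 5000.0, 0.45, 0.02)
    return PlanComparison("resilient vs standard", "limited", bh, bl, eh, el, 5000.0)


class TestSensitivityGrid:
    def test_identity_perturbation_changes_nothing(self, costs, effects):
        comp = _toy_comparison()
        grid = sensitivity_grid(comp, costs, effects, ("identity",))
        assert grid["change_vs_base"].iloc[0] == 0.0

    def test_recosting_unperturbed_parameters_is_bit_stable(self, costs, effects):
        comp = _toy_comparison()
        a = comp.evaluate(costs, effects)
        b = comp.evaluate(costs, effects)
        assert a.net_cost_per_life == b.net_cost_per_life
        assert a.to_dict() == b.to_dict()

    def test_all_costs_up_25pct_with_zero_bed_day_offset_scales_exactly(self, effects):
        comp = _toy_comparison()
        costs = CostParameters(excess_bed_day_cost=0.0)
        base = comp.evaluate(costs, effects).net_cost_per_life
        grid = sensitivity_grid(comp, costs, effects, ("all_costs_plus25",))
        assert grid["net_cost_per_life"].iloc[0] == pytest.approx(1.25 * base, rel=1e-12)

    def test_agency_cost_perturbation_is_noop_without_agency_hours(self, costs, effects):
        comp = _toy_comparison()  # agency hours are zero by construction
        grid = sensitivity_grid(comp, costs, effects, ("agency_cost_plus25",))
        assert grid["change_vs_base"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_mortality_ci_bounds_move_cost_in_opposite_directions(self, costs, effects):
        comp = _toy_comparison()
        grid = sensitivity_grid(
            comp, costs, effects, ("mortality_rr_upper", "mortality_rr_lower")
        )
        upper, lower = grid["change_vs_base"]
        assert upper < 0 < lower  # stronger effect -> cheaper per life saved

    def test_unknown_perturbation_rejected(self, costs, effects):
        with pytest.raises(ConfigurationError):
            sensitivity_grid(_toy_comparison(), costs, effects, ("halve_everything",))

    def test_no_floating_requires_resimulated_comparison(self, costs, effects):
        with pytest.raises(ConfigurationError):
            sensitivity_grid(_toy_comparison(), costs, effects, ("no_floating",))
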