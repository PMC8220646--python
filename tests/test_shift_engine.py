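"""Shift engine: absences, classification, floating, hiring, scenarios."""

import numpy as np
import pytest

from wardsim.errors import ConfigurationError, InputError
from wardsim.roster_planner import PlanKind, build_establishment
from wardsim.shift_engine import (
    SimulatorConfig,
    classify_status,
    draw_absences,
    fill_target,
    float_staff,
    hire_temporary,
    resolve_shift,
    run_scenario,
    run_shift,
)
from wardsim.synthetic_hospital import availability_preset


class TestDrawAbsences:
    def test_zero_rate_nobody_absent(self, rng):
        assert all(draw_absences(10.0, 0.0, rng) == 0 for _ in range(100))

    def test_rate_one_everyone_absent(self, rng):
        assert draw_absences(7.5, 1.0, rng) == 7.5

    def test_expectation_matches_headcount_times_rate(self, rng):
        draws = np.array([draw_absences(10.0, 0.03, rng) for _ in range(100_000)])
        se = np.sqrt(10 * 0.03 * (1 - 0.03 / 2) / len(draws))  # conservative
        assert abs(draws.mean() - 0.3) < 3 * se

    def test_half_person_granularity(self, rng):
        draws = [draw_absences(3.5, 0.5, rng) for _ in range(200)]
        assert all((2 * d) == int(2 * d) for d in draws)
        assert max(draws) <= 3.5

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            draw_absences(2.0, 1.5, rng)

    def test_fractional_non_half_headcount_rejected(self, rng):
        with pytest.raises(InputError):
            draw_absences(2.3, 0.1, rng)


class TestClassifyStatus:
    def test_sixteen_percent_shortfall_triggers(self):
        status, shortfall, _ = classify_status(100.0, 84.0, 0.15)
        assert status == "understaffed"
        assert shortfall == pytest.approx(16.0)

    def test_fourteen_percent_shortfall_is_adequate(self):
        status, shortfall, _ = classify_status(100.0, 86.0, 0.15)
        assert status == "adequate"
        assert shortfall == pytest.approx(14.0)

    def test_exact_match_is_adequate_with_zero_shortfall(self):
        status, shortfall, surplus = classify_status(50.0, 50.0, 0.15)
        assert (status, shortfall, surplus) == ("adequate", 0.0, 0.0)

    def test_surplus_is_overstaffed(self):
        status, _, surplus = classify_status(40.0, 48.0, 0.15)
        assert status == "overstaffed"
        assert surplus == pytest.approx(8.0)

    def test_zero_demand_never_understaffed(self):
        assert classify_status(0.0, 0.0, 0.15)[0] == "adequate"
        assert classify_status(0.0, 4.0, 0.15)[0] == "overstaffed"


class TestFloatStaff:
    def test_no_overstaffed_units_no_transfers(self):
        transfers, fin, fout = float_staff(
            np.array([40.0, 40.0]), np.array([30.0, 32.0]), 0.15, 4.0
        )
        assert transfers == []
        assert fin.sum() == fout.sum() == 0

    def test_two_unit_donation_reaches_tolerance_band(self):
        # A: required 40, available 48 (surplus 8 h = 2 blocks);
        # B: required 40, available 32 (20% shortfall, triggered).
        # B is filled back to the 34-h tolerance boundary: one 4-h block.
        transfers, fin, fout = float_staff(
            np.array([40.0, 40.0]), np.array([48.0, 32.0]), 0.15, 4.0
        )
        assert transfers == [(0, 1, 4.0)]
        assert fout[0] == 4.0 and fin[1] == 4.0
        assert 32.0 + fin[1] >= fill_target(40.0, 0.15)

    def test_donor_never_drops_below_own_requirement(self):
        # donor surplus 3 h < one block: cannot donate at all
        transfers, _, fout = float_staff(
            np.array([40.0, 40.0]), np.array([43.0, 20.0]), 0.15, 4.0
        )
        assert transfers == []
        # donor surplus 9 h -> only 2 whole blocks despite recipient need
        transfers, fin, fout = float_staff(
            np.array([40.0, 40.0]), np.array([49.0, 10.0]), 0.15, 4.0
        )
        assert fout[0] == 8.0
        assert 49.0 - fout[0] >= 40.0

    def test_net_float_hours_are_zero(self):
        req = np.array([40.0, 40.0, 40.0, 40.0])
        avail = np.array([60.0, 30.0, 20.0, 44.0])
        _, fin, fout = float_staff(req, avail, 0.15, 4.0)
        assert fin.sum() == pytest.approx(fout.sum())
        assert (avail + fin - fout)[1:3].min() >= 20.0


class TestHireTemporary:
    def test_zero_shortfall_no_hires(self, rng):
        assert hire_temporary(0.0, 1.0, 1.0, rng.random(8), rng.random(8), 4.0) == (0.0, 0.0)

    def test_no_availability_no_hires(self, rng):
        bank, agency = hire_temporary(10.0, 0.0, 0.0, rng.random(8), rng.random(8), 4.0)
        assert bank == agency == 0.0

    def test_certain_agency_fills_every_block(self, rng):
        bank, agency = hire_temporary(10.0, 0.0, 1.0, rng.random(8), rng.random(8), 4.0)
        assert bank == 0.0
        assert agency == 12.0  # ceil(10/4) = 3 blocks

    def test_bank_first_then_agency(self):
        u_bank = np.array([0.1, 0.9, 0.9])
        u_agency = np.array([0.0, 0.1, 0.9])
        bank, agency = hire_temporary(12.0, 0.5, 0.5, u_bank, u_agency, 4.0)
        assert bank == 4.0  # block 1 via bank
        assert agency == 4.0  # block 2 via agency; block 3 unfilled

    def test_binomial_fill_fraction_at_half_probability(self, rng):
        fills = [
            hire_temporary(4.0, 0.5, 0.0, rng.random(1), rng.random(1), 4.0)[0] / 4.0
            for _ in range(10_000)
        ]
        se = np.sqrt(0.25 / len(fills))
        assert abs(np.mean(fills) - 0.5) < 3 * se


def _uniform_providers(n_units, n_roles, depth, rng):
    u_b = rng.random((n_units, n_roles, depth))
    u_a = rng.random((n_units, n_roles, depth))
    return (lambda i, r, k: u_b[i, r, :k]), (lambda i, r, k: u_a[i, r, :k])


class TestResolveShift:
    def test_conservation_and_invariants_random_instances(self, rng):
        for _ in range(200):
            n = rng.integers(2, 5)
            req = rng.uniform(0, 60, size=(n, 2)).round(1)
            avail = (rng.integers(0, 16, size=(n, 2)) * 4.0)
            groups = rng.integers(0, 2, size=n)
            ub, ua = _uniform_providers(n, 2, 32, rng)
            res = resolve_shift(
                req, avail, groups, 0.15, 4.0,
                np.array([0.5, 0.5]), np.array([0.8, 0.8]), ub, ua, True,
            )
            achieved = res["achieved"]
            recon = (
                avail
                - res["floated_out"]
                + res["floated_in"]
                + res["bank"]
                + res["agency"]
            )
            np.testing.assert_allclose(achieved, recon, atol=1e-9)
            # floats cancel within the whole shift
            assert res["floated_in"].sum() == pytest.approx(res["floated_out"].sum())
            # all fill quantities in half-shift blocks
            for key in ("floated_in", "floated_out", "bank", "agency"):
                assert np.allclose(res[key] / 4.0, np.round(res[key] / 4.0))
            # no fills for untriggered units
            untriggered = res["status_pre"] != 1
            assert res["floated_in"][untriggered].sum() == 0
            assert res["bank"][untriggered].sum() == 0
            assert res["agency"][untriggered].sum() == 0


def _tiny_scenario(n_units=4, days=30, seed=11, **cfg_kwargs):
    cfg = SimulatorConfig(master_seed=seed, days=days, **cfg_kwargs)
    from wardsim.synthetic_hospital import GeneratorConfig, generate_hospital

    hospital = generate_hospital(
        GeneratorConfig(n_hospitals=1, units_per_hospital=n_units, groups_per_hospital=1),
        seed,
    )
    plan = build_establishment(
        hospital.units, PlanKind.STANDARD, seed, shift_length_hours=cfg.shift_length_hours
    )
    return hospital, plan, cfg


class TestRunScenario:
    def test_identity_limit_no_absence_no_fills(self):
        hospital, plan, cfg = _tiny_scenario(
            absence_rates={"RN": 0.0, "NA": 0.0}, allow_floating=False
        )
        result = run_scenario(hospital, plan, availability_preset("none"), cfg)
        np.testing.assert_allclose(result.achieved, result.rostered)
        assert result.bank.sum() == result.agency.sum() == 0

    def test_determinism_two_runs_identical(self):
        hospital, plan, cfg = _tiny_scenario()
        a = run_scenario(hospital, plan, availability_preset("limited"), cfg)
        b = run_scenario(hospital, plan, availability_preset("limited"), cfg)
        np.testing.assert_array_equal(a.achieved, b.achieved)
        np.testing.assert_array_equal(a.census, b.census)

    def test_record_count_matches_units_days_shifts(self):
        hospital, plan, cfg = _tiny_scenario(n_units=3, days=10)
        result = run_scenario(hospital, plan, availability_preset("none"), cfg)
        frame = result.to_frame()
        assert len(frame) == 3 * 10 * 3 * 2  # units x days x shifts x roles

    def test_conservation_holds_on_every_shift(self):
        hospital, plan, cfg = _tiny_scenario(days=60)
        result = run_scenario(hospital, plan, availability_preset("higher"), cfg)
        assert result.conservation_residual() < 1e-9
        assert result.float_imbalance() < 1e-9

    def test_crn_demand_and_absence_shared_across_plans(self):
        hospital, _, cfg = _tiny_scenario(days=40)
        plans = {
            k: build_establishment(hospital.units, k, cfg.master_seed) for k in PlanKind
        }
        results = {
            k: run_scenario(hospital, plans[k], availability_preset("none"), cfg)
            for k in PlanKind
        }
        np.testing.assert_array_equal(
            results[PlanKind.FLEXIBLE].census, results[PlanKind.RESILIENT].census
        )
        np.testing.assert_array_equal(
            results[PlanKind.FLEXIBLE].required, results[PlanKind.RESILIENT].required
        )
        # absence slots are shared: where rosters agree, absences agree
        same = np.isclose(
            plans[PlanKind.FLEXIBLE].headcount, plans[PlanKind.STANDARD].headcount
        )
        mask = np.broadcast_to(
            same[:, None, :, :], results[PlanKind.FLEXIBLE].absent.shape
        )
        np.testing.assert_array_equal(
            results[PlanKind.FLEXIBLE].absent[mask],
            results[PlanKind.STANDARD].absent[mask],
        )

    def test_plan_dominance_without_fills(self, ten_unit_hospital):
        """Higher baselines weakly dominate achieved hours when no fills act."""
        cfg = SimulatorConfig(master_seed=5, days=100, allow_floating=False)
        plans = {
            k: build_establishment(ten_unit_hospital.units, k, 5) for k in PlanKind
        }
        res = {
            k: run_scenario(ten_unit_hospital, plans[k], availability_preset("none"), cfg)
            for k in PlanKind
        }
        assert (
            res[PlanKind.RESILIENT].achieved >= res[PlanKind.STANDARD].achieved - 1e-9
        ).all()
        assert (
            res[PlanKind.STANDARD].achieved >= res[PlanKind.FLEXIBLE].achieved - 1e-9
        ).all()

    def test_mean_achieved_ordering_with_floating_and_hires(self, ten_unit_hospital):
        cfg = SimulatorConfig(master_seed=5, days=100)
        plans = {
            k: build_establishment(ten_unit_hospital.units, k, 5) for k in PlanKind
        }
        for avail in ("none", "limited", "unlimited"):
            res = {
                k: run_scenario(
                    ten_unit_hospital, plans[k], availability_preset(avail), cfg
                )
                for k in PlanKind
            }
            assert (
                res[PlanKind.RESILIENT].mean_hppd()
                >= res[PlanKind.STANDARD].mean_hppd()
                >= res[PlanKind.FLEXIBLE].mean_hppd()
            )

    def test_availability_monotonicity_unit_by_unit(self, ten_unit_hospital):
        """Raising every fulfilment probability weakly raises achieved hours."""
        cfg = SimulatorConfig(master_seed=5, days=100)
        plan = build_establishment(ten_unit_hospital.units, PlanKind.FLEXIBLE, 5)
        prev = None
        for avail in ("none", "limited", "higher", "unlimited"):
            res = run_scenario(ten_unit_hospital, plan, availability_preset(avail), cfg)
            if prev is not None:
                assert (res.achieved >= prev.achieved - 1e-9).all()
            prev = res

    def test_run_shift_slice_matches_scenario(self):
        hospital, plan, cfg = _tiny_scenario(n_units=3, days=5)
        frame = run_shift(hospital, 2, "late", plan, availability_preset("limited"), cfg)
        full = run_scenario(hospital, plan, availability_preset("limited"), cfg).to_frame()
        expect = full[(full["day"] == 2) & (full["shift"] == "late")].reset_index(drop=True)
        assert frame.equals(expect)


class TestSimulatorConfigValidation:
    def test_bad_tolerance_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulatorConfig(tolerance=1.0)

    def test_bad_granularity_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulatorConfig(deployment_granularity="quarter")

    def test_block_hours_follow_granularity(self):
        assert SimulatorConfig().block_hours == 4.0
        assert SimulatorConfig(deployment_granularity="full").block_hours == 8.0
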