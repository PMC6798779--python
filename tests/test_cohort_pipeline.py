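"""Effect estimation, life-years, lost-income PV and the sensitivity grid."""

import numpy as np
import pytest

from stemi_econ import (
    EconomicParams,
    Patient,
    ValidationError,
    calibrate_income,
    cohort_life_years,
    economic_gain,
    effect_estimate,
    effect_from_rates,
    headline_metrics,
    life_years_saved_patient,
    present_value_income,
    pv_lost_income,
    sensitivity_analysis,
    sensitivity_from_aggregates,
)
from stemi_econ.demography import WorkingYearsTable

from conftest import toy_cohort


def params(i0=100.0, **kw):
    return EconomicParams(income_now=i0, **kw)


def flat_work_years(value: float, max_age: int = 100):
    """Hand-built constant-T tables for both sexes (zero from retirement)."""
    ages = np.arange(0, max_age + 1)
    T = np.where(ages < 70, value, 0.0)
    return {
        sex: WorkingYearsTable(sex=sex, ages=ages, T=T.copy())
        for sex in ("male", "female")
    }


def _mixed_cohort():
    return toy_cohort(
        [
            ("p1", 50, "male", "pre", True),
            ("p2", 60, "female", "pre", False),
            ("p3", 75, "male", "pre", True),
            ("p4", 40, "male", "post", True),
            ("p5", 55, "female", "post", False),
            ("p6", 65, "female", "post", False),
        ],
        enrollment_days=365,
    )


class TestEffectEstimate:
    def test_published_rates_give_nnt_30(self):
        eff = effect_from_rates(0.176, 0.142, annualized_n=2265.0)
        assert eff.arr == pytest.approx(0.034)
        assert eff.nnt == 30
        assert eff.deaths_averted_annualized == pytest.approx(77.01)
        assert eff.deaths_averted == 78

    def test_identical_arms_leave_nnt_undefined(self):
        eff = effect_from_rates(0.15, 0.15, annualized_n=1000.0)
        assert eff.arr == 0.0
        assert eff.nnt is None
        assert eff.deaths_averted == 0

    def test_counts_from_patient_table(self):
        rows = [(f"a{i}", 50, "male", "pre", i < 2) for i in range(10)]
        rows += [(f"b{i}", 50, "male", "post", i < 1) for i in range(10)]
        cohort = toy_cohort(rows, enrollment_days=365)
        eff = effect_estimate(cohort, days_per_year=365.0)
        assert eff.mortality_pre == pytest.approx(0.2)
        assert eff.mortality_post == pytest.approx(0.1)
        assert eff.annualized_n == pytest.approx(20.0)
        assert eff.deaths_averted_annualized == pytest.approx(2.0)

    def test_empty_arm_rejected(self):
        cohort = toy_cohort([("a", 50, "male", "pre", True)], enrollment_days=100)
        with pytest.raises(ValidationError):
            effect_estimate(cohort)


class TestLifeYears:
    def test_death_past_life_expectancy_saves_nothing(self):
        p = Patient("x", 70, "male", "pre", died_1yr=True)
        assert life_years_saved_patient(p, params()) == 0.0

    def test_survivor_contributes_nothing(self):
        p = Patient("x", 40, "female", "pre", died_1yr=False)
        assert life_years_saved_patient(p, params()) == 0.0

    def test_female_subtraction_against_life_expectancy(self):
        p = Patient("x", 62, "female", "pre", died_1yr=True)
        assert life_years_saved_patient(p, params()) == pytest.approx(10.7)

    def test_no_deaths_gives_zero_triple(self):
        cohort = toy_cohort(
            [("a", 50, "male", "pre", False), ("b", 50, "male", "post", False)],
            enrollment_days=365,
        )
        p = params(days_per_year=365.0)
        assert cohort_life_years(cohort, p) == (0.0, 0.0, 0.0)

    def test_hand_oracle_with_common_annualized_base(self):
        # deceased: male 50 pre (18.6 y), male 75 pre (0 y), male 40 post (28.6 y)
        # per-arm means over n=3 each, scaled to the common base of 6 patients
        cohort = _mixed_cohort()
        p = params(days_per_year=365.0)
        pre, post, saved = cohort_life_years(cohort, p)
        assert pre == pytest.approx(18.6 / 3 * 6)
        assert post == pytest.approx(28.6 / 3 * 6)
        assert saved == pytest.approx(pre - post)


class TestPVLostIncome:
    def test_all_survivors_give_zero(self):
        cohort = toy_cohort(
            [("a", 50, "male", "pre", False), ("b", 50, "male", "post", False)],
            enrollment_days=365,
        )
        p = params(days_per_year=365.0)
        assert pv_lost_income(cohort, flat_work_years(5.0), p) == (0.0, 0.0)

    def test_death_at_seventy_contributes_single_income_term(self):
        cohort = toy_cohort(
            [("a", 72, "male", "pre", True), ("b", 50, "male", "post", False)],
            enrollment_days=365,
        )
        p = params(days_per_year=365.0)
        pre, post = pv_lost_income(cohort, flat_work_years(9.0), p)
        # T = 0 past retirement: exactly I_0, scaled to the 2-patient base
        assert pre == pytest.approx(p.income_now * 2.0)
        assert post == 0.0

    def test_matches_explicit_per_patient_loop(self):
        cohort = _mixed_cohort()
        p = params(i0=85_000.0, days_per_year=365.0)
        wy = flat_work_years(7.3)
        pre, post = pv_lost_income(cohort, wy, p)
        # brute force: loop patients, loop years
        def pv_loop(T):
            ratio = (1 + p.growth_rate) / (1 + p.discount_rate)
            whole = int(np.floor(T))
            total = sum(p.income_now * ratio**i for i in range(whole + 1))
            return total + (T - whole) * p.income_now * ratio ** (whole + 1)

        expected_pre = (pv_loop(7.3) + pv_loop(0.0)) / 3 * 6  # ages 50 and 75
        expected_post = pv_loop(7.3) / 3 * 6                  # age 40
        assert pre == pytest.approx(expected_pre, rel=1e-9)
        assert post == pytest.approx(expected_post, rel=1e-9)

    def test_gain_conservation_and_sign_flag(self):
        assert economic_gain(228.7, 175.6) + 175.6 == pytest.approx(228.7)
        assert economic_gain(10.0, 25.0) == pytest.approx(-15.0)

    def test_scale_equivariance_in_income(self):
        cohort = _mixed_cohort()
        wy = flat_work_years(4.0)
        p1 = params(i0=50_000.0, days_per_year=365.0)
        p2 = params(i0=100_000.0, days_per_year=365.0)
        a = pv_lost_income(cohort, wy, p1)
        b = pv_lost_income(cohort, wy, p2)
        assert b[0] == pytest.approx(2 * a[0], rel=1e-12)
        assert b[1] == pytest.approx(2 * a[1], rel=1e-12)

    def test_calibrate_income_hits_target_gain(self):
        cohort = _mixed_cohort()
        wy = flat_work_years(6.0)
        p = params(days_per_year=365.0)
        # pre has 2 deaths vs 1 post at equal T, so the gain is positive
        i0 = calibrate_income(cohort, wy, p, target_gain=1e6)
        pre, post = pv_lost_income(cohort, wy, p.replace(income_now=i0))
        assert pre - post == pytest.approx(1e6, rel=1e-9)


class TestHeadlineMetrics:
    def test_cost_ratios_and_conservation(self):
        eff = effect_from_rates(0.2, 0.1, annualized_n=500.0)  # 50 deaths averted
        rep = headline_metrics(eff, (1000.0, 400.0, 600.0), (9e6, 5e6), 2e6)
        assert rep.cost_per_life_saved == pytest.approx(2e6 / 50)
        assert rep.cost_per_life_saved * eff.deaths_averted == pytest.approx(2e6)
        assert rep.cost_per_life_year == pytest.approx(2e6 / 600.0)
        assert rep.benefit_cost_ratio == pytest.approx(4e6 / 2e6)
        assert rep.years_per_death_averted == 12  # 600/50

    def test_no_benefit_metrics_undefined_not_zero(self):
        eff = effect_from_rates(0.1, 0.1, annualized_n=500.0)
        rep = headline_metrics(eff, (100.0, 100.0, 0.0), (5e6, 5e6), 2e6)
        assert rep.cost_per_life_saved is None
        assert rep.cost_per_life_year is None
        assert rep.years_per_death_averted is None
        assert rep.benefit_cost_ratio == 0.0

    def test_zero_gain_gives_zero_ratio(self):
        eff = effect_from_rates(0.2, 0.1, annualized_n=500.0)
        rep = headline_metrics(eff, (10.0, 5.0, 5.0), (3e6, 3e6), 2e6)
        assert rep.benefit_cost_ratio == 0.0


class TestSensitivity:
    def test_single_cell_equals_headline_ratio(self):
        cohort = _mixed_cohort()
        wy = flat_work_years(6.0)
        p = params(i0=80_000.0, days_per_year=365.0)
        pre, post = pv_lost_income(cohort, wy, p)
        grid = sensitivity_analysis(cohort, wy, p, [0.03], [0.06], 1e5)
        assert grid.ratio[0, 0] == pytest.approx((pre - post) / 1e5, rel=1e-12)

    def test_grid_matches_independent_runs(self):
        cohort = _mixed_cohort()
        wy = flat_work_years(6.0)
        p = params(i0=80_000.0, days_per_year=365.0)
        gs, rs = [0.02, 0.08], [0.03, 0.09]
        grid = sensitivity_analysis(cohort, wy, p, gs, rs, 1e5)
        for gi, g in enumerate(gs):
            for ri, r in enumerate(rs):
                pre, post = pv_lost_income(
                    cohort, wy, p.replace(growth_rate=g, discount_rate=r)
                )
                assert grid.ratio[gi, ri] == pytest.approx((pre - post) / 1e5, rel=1e-12)

    def test_monotone_for_positive_gain_cohort(self):
        cohort = _mixed_cohort()
        wy = flat_work_years(6.0)
        p = params(i0=80_000.0, days_per_year=365.0)
        grid = sensitivity_analysis(
            cohort, wy, p, [0.0, 0.03, 0.06, 0.09], [0.02, 0.05, 0.08], 1e5
        )
        assert np.all(np.diff(grid.ratio, axis=0) >= -1e-12)  # growth rows rise
        assert np.all(np.diff(grid.ratio, axis=1) <= 1e-12)   # discount cols fall

    def test_unsorted_rates_rejected(self):
        cohort = _mixed_cohort()
        with pytest.raises(ValidationError):
            sensitivity_analysis(
                cohort, flat_work_years(5.0), params(), [0.06, 0.03], [0.04], 1e5
            )

    def test_aggregate_calibration_reproduces_baseline_cell(self, fx):
        p = params(i0=85_662.37)
        cost = 15.11e6
        grid = sensitivity_from_aggregates(
            fx.pv_lost_pre, fx.pv_lost_post,
            fx.annualized_n * fx.mortality_pre,
            fx.annualized_n * fx.mortality_post,
            p, [0.03], [0.06], cost,
        )
        assert grid.ratio[0, 0] == pytest.approx(
            (fx.pv_lost_pre - fx.pv_lost_post) / cost, rel=1e-9
        )
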