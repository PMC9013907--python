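"""Calibration fitting, homoscedasticity and linearity tests, back-calculation."""

import numpy as np
import pytest

from conftest import make_cal_table
from hairetg import (
    CalibrationModel,
    back_calculate,
    determine_loq,
    fisher_homoscedasticity_test,
    fit_calibration,
    lack_of_fit_test,
    mandel_test,
    select_range,
)
from hairetg.calibration import HIGH_RANGE, LOW_RANGE
from hairetg.errors import ConfigurationError, InsufficientDataError
from hairetg.simulate import CalibrationSimSpec, simulate_calibration


class TestFit:
    def test_exact_line(self, linear_cal_table):
        fit = fit_calibration(linear_cal_table)
        assert fit.slope == pytest.approx(0.01, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_ols_oracle(self):
        # (1,1),(2,2),(3,2): slope 0.5, intercept 2/3 by normal equations
        fit = fit_calibration(make_cal_table([1, 2, 3], [1, 2, 2]))
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(2.0 / 3.0)

    def test_shift_changes_intercept_only(self, noisy_cal_table):
        base = fit_calibration(noisy_cal_table)
        shifted = noisy_cal_table.copy()
        shifted["response_ratio"] += 0.5
        fit2 = fit_calibration(shifted)
        assert fit2.slope == pytest.approx(base.slope, rel=1e-9)
        assert fit2.intercept == pytest.approx(base.intercept + 0.5, rel=1e-9)

    def test_too_few_levels_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration(make_cal_table([1, 1, 2, 2], [1, 1.1, 2, 2.1]))


class TestFisher:
    def test_identical_variances_pass(self):
        table = make_cal_table([1, 1, 5, 10, 10], [1.0, 1.2, 3.0, 5.0, 5.2])
        F, ok = fisher_homoscedasticity_test(table)
        assert F == pytest.approx(1.0)
        assert ok

    def test_variance_ratio_100_fails_at_alpha_001(self):
        # F-critical(2, 2, 0.99) = 99 < 100
        table = make_cal_table(
            [1, 1, 1, 5, 10, 10, 10], [0.0, 0.1, 0.2, 0.5, 0.0, 1.0, 2.0]
        )
        F, ok = fisher_homoscedasticity_test(table, alpha=0.01)
        assert F == pytest.approx(100.0)
        assert not ok

    def test_heteroscedastic_simulation_fails(self):
        table = simulate_calibration(
            CalibrationSimSpec(
                levels=(1.0, 10.0, 100.0),
                replicates_per_level=30,
                slope=0.01,
                noise_model="proportional_cv",
                noise_param=0.10,
                seed=9,
            )
        )
        _, ok = fisher_homoscedasticity_test(table, alpha=0.01)
        assert not ok

    def test_missing_extreme_replicates_raise(self):
        with pytest.raises(InsufficientDataError):
            fisher_homoscedasticity_test(make_cal_table([1, 5, 10, 10], [1, 2, 3, 3.1]))


class TestLackOfFit:
    def test_zero_noise_zero_curvature(self, linear_cal_table):
        fit = fit_calibration(linear_cal_table)
        F, _, ok = lack_of_fit_test(linear_cal_table, fit)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert ok

    def test_quadratic_structure_fails(self):
        spec = CalibrationSimSpec(
            slope=0.01, curvature=5e-4, noise_param=1e-4, noise_model="constant_sd", seed=3
        )
        table = simulate_calibration(spec)
        fit = fit_calibration(table)
        # SS decomposition oracle: lack-of-fit SS dominated by curvature
        F, (df1, df2), ok = lack_of_fit_test(table, fit)
        assert (df1, df2) == (3, 10)
        assert F > 100
        assert not ok

    def test_no_replication_raises(self):
        table = make_cal_table([1, 2, 3, 4], [1, 2, 3, 4.1])
        fit = fit_calibration(table)
        with pytest.raises(InsufficientDataError):
            lack_of_fit_test(table, fit)


class TestMandel:
    def test_exact_line_F_zero(self, linear_cal_table):
        F, _, ok = mandel_test(linear_cal_table)
        assert F == pytest.approx(0.0, abs=1e-6)
        assert ok

    def test_exact_parabola_fails(self):
        table = make_cal_table([1, 2, 3, 4, 5], [1, 4, 9, 16, 25])
        F, _, ok = mandel_test(table)
        assert F > 1e6
        assert not ok

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            mandel_test(make_cal_table([1, 2, 3], [1, 2, 3]))


class TestBackCalculate:
    def test_basic_inversion(self, linear_cal_table):
        fit = fit_calibration(linear_cal_table)
        assert back_calculate(fit, 0.20).concentration == pytest.approx(20.0)

    def test_dilution_scaling(self, linear_cal_table):
        fit = fit_calibration(linear_cal_table)
        assert back_calculate(fit, 0.20, dilution_factor=5).concentration == pytest.approx(100.0)

    def test_mass_scaling(self, linear_cal_table):
        fit = fit_calibration(linear_cal_table)
        # 25 mg aliquot doubles the per-mg concentration (reference is 50 mg)
        r = back_calculate(fit, 0.20, sample_mass_mg=25.0)
        assert r.concentration == pytest.approx(40.0)

    def test_ratio_at_intercept_gives_zero(self, linear_cal_table):
        fit = fit_calibration(linear_cal_table)
        r = back_calculate(fit, fit.intercept)
        assert r.concentration == pytest.approx(0.0, abs=1e-12)
        assert not r.below_zero

    def test_negative_flagged_not_clamped(self, linear_cal_table):
        fit = fit_calibration(linear_cal_table)
        r = back_calculate(fit, -0.01)
        assert r.below_zero and r.concentration < 0

    def test_forward_backward_identity(self, linear_cal_table):
        fit = fit_calibration(linear_cal_table)
        for conc in (6.0, 10.0, 20.0, 30.0, 60.0):
            ratio = fit.intercept + fit.slope * conc
            assert back_calculate(fit, ratio).concentration == pytest.approx(conc, rel=1e-9)

    def test_nonpositive_slope_rejected(self, linear_cal_table):
        fit = fit_calibration(linear_cal_table)
        fit.slope = 0.0
        with pytest.raises(ConfigurationError):
            back_calculate(fit, 0.2)


class TestRangeAndLoq:
    @pytest.fixture()
    def curves(self, linear_cal_table):
        low = fit_calibration(linear_cal_table, cal_range=LOW_RANGE)
        high = fit_calibration(linear_cal_table, cal_range=HIGH_RANGE)
        return low, high

    @pytest.mark.parametrize(
        "estimate, decision",
        [(45.0, "low"), (127.0, "high"), (400.0, "dilution_required")],
    )
    def test_dual_range_rule(self, curves, estimate, decision):
        sel = select_range(estimate, *curves)
        assert sel.decision == decision

    def test_loq_is_lowest_qualifying_level(self):
        assert determine_loq([(6.0, 11.0, 6.0), (10.0, 8.0, 4.0)]) == 6.0

    def test_loq_undefined_when_all_fail(self):
        assert determine_loq([(6.0, 25.0, 5.0), (10.0, 25.0, 5.0)]) is None

    def test_loq_skips_failing_lowest(self):
        assert determine_loq([(6.0, 21.0, 5.0), (10.0, 8.0, 4.0)]) == 10.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            determine_loq([])


class TestModelResults:
    def test_fit_results_carry_diagnostics_and_summary(self, noisy_cal_table):
        res = CalibrationModel(noisy_cal_table).fit()
        assert res.linearity.lof_pass and res.linearity.mandel_pass
        assert res.linearity.fisher_pass
        text = res.summary()
        assert "slope" in text and "Mandel" in text
        assert res.back_calculate(0.2).concentration == pytest.approx(20.0, abs=2.0)

    def test_quadratic_data_rejected_by_both_tests(self):
        table = simulate_calibration(
            CalibrationSimSpec(slope=0.01, curvature=5e-4, noise_param=1e-4, seed=1)
        )
        res = CalibrationModel(table).fit()
        assert not res.linearity.mandel_pass
        assert not res.linearity.lof_pass
        assert not res.linearity.linear
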