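"""Speed-limit model: Arrhenius rate, doubling-time law, cohorts, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldlife import core_model as cm
from coldlife.errors import CalibrationError, InsufficientDataError, InvalidInputError
from coldlife.units import days, hours, kelvin, years

ALPHA = 0.77
T5, T1 = kelvin(5.0), kelvin(1.0)


class TestArrheniusRate:
    def test_identity_at_reference_temperature(self, params):
        assert cm.arrhenius_rate(params.T_ref, params) == pytest.approx(params.r_ref)

    @given(st.floats(min_value=270.0, max_value=310.0), st.floats(min_value=0.1, max_value=30.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_temperature(self, T, dT):
        p = cm.default_params()
        assert cm.arrhenius_rate(T + dT, p) > cm.arrhenius_rate(T, p)

    def test_calibrated_rate_ratio_matches_anchor_doubling_times(self, params):
        # the 5C/1C rate ratio must invert the power law on the two printed
        # minimum-doubling-time anchors (3 d at 5C, 28.4 d at 1C)
        ratio = cm.arrhenius_rate(T5, params) / cm.arrhenius_rate(T1, params)
        assert ratio == pytest.approx((28.4 / 3.0) ** (1.0 / ALPHA), rel=1e-9)

    def test_nonpositive_temperature_rejected(self, params):
        with pytest.raises(InvalidInputError):
            cm.arrhenius_rate(-1.0, params)


class TestMinDoublingTime:
    def test_halving_rate_multiplies_time_by_2_to_alpha(self, params):
        r = 1.7
        t1 = cm.min_doubling_time(r, params)
        t2 = cm.min_doubling_time(r / 2.0, params)
        assert t2 / t1 == pytest.approx(2.0**ALPHA, rel=1e-12)

    def test_calibrated_floors_hit_printed_anchors(self, params):
        assert cm.min_doubling_time(cm.arrhenius_rate(T5, params), params) == pytest.approx(
            hours(3.0), rel=1e-9
        )
        assert cm.min_doubling_time(cm.arrhenius_rate(T1, params), params) == pytest.approx(
            hours(28.4), rel=1e-9
        )

    def test_nonpositive_rate_rejected(self, params):
        with pytest.raises(InvalidInputError):
            cm.min_doubling_time(0.0, params)


class TestRosDelay:
    def test_zero_ros_gives_base_delay(self, params):
        assert cm.ros_delay(0.0, 2.0, params) == pytest.approx(params.c_delta / 2.0)

    def test_delay_inverse_in_rate(self, params):
        assert cm.ros_delay(500.0, 2.0, params) == pytest.approx(
            cm.ros_delay(500.0, 1.0, params) / 2.0
        )

    def test_threshold_delay_is_tau_max_delay_term(self, params):
        r = cm.arrhenius_rate(T5, params)
        lim = cm.speed_limits(T5, params)
        assert cm.ros_delay(params.ros_threshold, r, params) == pytest.approx(
            lim.tau_max - lim.tau_min
        )

    def test_negative_ros_rejected(self, params):
        with pytest.raises(InvalidInputError):
            cm.ros_delay(-1.0, 1.0, params)


class TestDoublingTime:
    @given(st.floats(min_value=0.0, max_value=5999.0), st.floats(min_value=1.0, max_value=5999.0))
    @settings(max_examples=50, deadline=None)
    def test_nondecreasing_in_ros(self, ros, dros):
        p = cm.default_params()
        assert cm.doubling_time(ros + dros, T5, p) >= cm.doubling_time(ros, T5, p)

    def test_threshold_cell_sits_at_tau_max(self, params):
        assert cm.doubling_time(params.ros_threshold, T5, params) == pytest.approx(
            cm.speed_limits(T5, params).tau_max
        )


class TestSpeedLimits:
    def test_limits_ordered_and_decreasing_in_temperature(self, params):
        prev = None
        for tc in (1.0, 5.0, 10.0, 20.0, 30.0):
            lim = cm.speed_limits(kelvin(tc), params)
            assert lim.tau_min < lim.tau_max
            if prev is not None:
                assert lim.tau_min < prev.tau_min
                assert lim.tau_max < prev.tau_max
            prev = lim

    def test_calibrated_5C_limits_match_anchors(self, params):
        lim = cm.speed_limits(T5, params)
        assert days(lim.tau_min) == pytest.approx(3.0, rel=1e-9)
        assert days(lim.tau_max) == pytest.approx(35.0, rel=1e-9)

    def test_delay_gap_scales_as_inverse_rate(self, params):
        lim1, lim5 = cm.speed_limits(T1, params), cm.speed_limits(T5, params)
        r1, r5 = cm.arrhenius_rate(T1, params), cm.arrhenius_rate(T5, params)
        assert (lim5.tau_max - lim5.tau_min) * (r5 / r1) == pytest.approx(
            lim1.tau_max - lim1.tau_min, rel=1e-12
        )

    def test_limits_collapse_when_delay_vanishes(self, params):
        import dataclasses

        tiny = dataclasses.replace(params, c_delta=1e-12, ros_threshold=1e-9)
        lim = cm.speed_limits(T5, tiny)
        assert lim.tau_max / lim.tau_min == pytest.approx(1.0, abs=1e-9)


class TestSimulateCohort:
    DIST = cm.RosDistribution(mu_log=math.log(2000.0), sigma_log=1.0, label="low")

    def test_divider_fraction_matches_lognormal_cdf(self, params):
        n = 10_000
        res = cm.simulate_cohort(n, T5, self.DIST, params, seed=1)
        p = self.DIST.divider_fraction(params.ros_threshold)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(res.divider_fraction - p) <= 3 * se

    def test_every_divider_tau_within_limits(self, params):
        res = cm.simulate_cohort(5000, T5, self.DIST, params, seed=2)
        lim = cm.speed_limits(T5, params)
        taus = res.cells.loc[res.cells.divides, "tau_h"]
        assert (taus >= lim.tau_min).all()
        assert (taus <= lim.tau_max).all()

    def test_degenerate_distribution_all_divide_identically(self, params):
        dist = cm.RosDistribution(mu_log=math.log(100.0), sigma_log=0.0)
        res = cm.simulate_cohort(50, T5, dist, params, seed=3)
        assert res.divider_fraction == 1.0
        assert res.cells["tau_h"].nunique() == 1

    def test_deterministic_for_fixed_seed(self, params):
        a = cm.simulate_cohort(100, T5, self.DIST, params, seed=7)
        b = cm.simulate_cohort(100, T5, self.DIST, params, seed=7)
        assert a.cells.equals(b.cells)

    def test_invalid_cohort_size_rejected(self, params):
        with pytest.raises(InvalidInputError):
            cm.simulate_cohort(0, T5, self.DIST, params, seed=1)


class TestProbSlowerThan:
    DIST = TestSimulateCohort.DIST

    def test_above_tau_max_is_impossible(self, params):
        tau_max = cm.speed_limits(T5, params).tau_max
        assert cm.prob_slower_than(tau_max, T5, self.DIST, params) == 0.0

    def test_below_tau_min_covers_all_dividers(self, params):
        tau_min = cm.speed_limits(T5, params).tau_min
        assert cm.prob_slower_than(0.5 * tau_min, T5, self.DIST, params) == pytest.approx(
            self.DIST.divider_fraction(params.ros_threshold)
        )

    @pytest.mark.parametrize("tau0_days", [4.0, 10.0, 25.0])
    def test_matches_monte_carlo_exceedance(self, params, tau0_days):
        n = 100_000
        tau0 = hours(tau0_days)
        res = cm.simulate_cohort(n, T5, self.DIST, params, seed=11)
        emp = float(((res.cells.divides) & (res.cells.tau_h > tau0)).mean())
        p = cm.prob_slower_than(tau0, T5, self.DIST, params)
        se = math.sqrt(max(p * (1 - p), 1e-12) / n)
        assert abs(emp - p) <= 4 * se


class TestFitPowerLaw:
    def test_noiseless_identity(self):
        r = np.geomspace(0.1, 10.0, 12)
        fit = cm.fit_power_law(r, 5.0 * r**-0.77)
        assert fit.exponent == pytest.approx(0.77, abs=1e-12)
        assert fit.prefactor == pytest.approx(5.0, rel=1e-9)
        assert fit.correlation == pytest.approx(1.0, abs=1e-9)

    def test_calibrated_model_grid_returns_printed_exponent(self, params):
        temps = [kelvin(tc) for tc in (1, 5, 10, 15, 20, 25, 30)]
        rates = [cm.arrhenius_rate(T, params) for T in temps]
        times = [cm.min_doubling_time(r, params) for r in rates]
        fit = cm.fit_power_law(rates, times)
        assert fit.exponent == pytest.approx(0.77, abs=0.01)
        assert fit.correlation > 0.999

    def test_exponent_invariant_under_rate_rescaling(self):
        r = np.geomspace(0.5, 8.0, 9)
        t = 3.0 * r**-1.2
        assert cm.fit_power_law(r, t).exponent == pytest.approx(
            cm.fit_power_law(10.0 * r, t).exponent, rel=1e-9
        )

    def test_input_validation(self):
        with pytest.raises(InsufficientDataError):
            cm.fit_power_law([1.0, 2.0], [1.0, 0.5])
        with pytest.raises(InvalidInputError):
            cm.fit_power_law([1.0, -2.0, 3.0], [1.0, 0.5, 0.3])


class TestCalibrate:
    def test_round_trip_is_exact(self, params):
        anchors = cm.CalibrationAnchors(
            t_anchors={
                T5: cm.speed_limits(T5, params).tau_min,
                T1: cm.speed_limits(T1, params).tau_min,
            },
            tau_max_anchor=(T5, cm.speed_limits(T5, params).tau_max),
            ros_threshold=params.ros_threshold,
            alpha=params.alpha,
            s_ros=params.s_ros,
        )
        again = cm.calibrate(anchors)
        for name in ("alpha", "r_ref", "T_ref", "E_a", "c_t", "c_delta", "s_ros", "ros_threshold"):
            assert getattr(again, name) == pytest.approx(getattr(params, name), rel=1e-9)

    def test_default_anchors_give_multi_year_low_speed_limit_at_1C(self, params):
        tau_max_years = years(cm.speed_limits(T1, params).tau_max)
        assert 1.5 <= tau_max_years <= 4.5

    def test_missing_anchor_named_in_error(self):
        with pytest.raises(CalibrationError, match="2 temperatures"):
            cm.calibrate(
                cm.CalibrationAnchors(
                    t_anchors={T5: 72.0}, tau_max_anchor=(T5, 840.0)
                )
            )

    def test_inconsistent_tau_max_rejected(self):
        with pytest.raises(CalibrationError, match="exceed"):
            cm.calibrate(
                cm.CalibrationAnchors(
                    t_anchors={T5: 72.0, T1: 681.6}, tau_max_anchor=(T5, 10.0)
                )
            )
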