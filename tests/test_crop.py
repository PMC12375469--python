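"""Canopy, stress, demand, biomass and yield formation."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tuberflow.crop import (
    CropCalendar,
    CropParams,
    accumulate_biomass,
    canopy_decline,
    canopy_growth_step,
    canopy_unstressed,
    daily_demands,
    harvest_yield,
    relative_depletion,
    root_deepening,
    stress_coefficient,
    thermal_time,
)


class TestThermalTime:
    @pytest.mark.parametrize(
        "tmax,tmin,expected",
        [
            (26.0, 14.0, 18.0),  # mean 20, base 2
            (40.0, 30.0, 24.0),  # mean 35 capped at 26
            (2.0, 0.0, 0.0),  # mean 1 below base
        ],
    )
    def test_formula(self, tmax, tmin, expected):
        assert thermal_time(tmax, tmin, 2.0, 26.0) == expected

    def test_rejects_inverted(self):
        with pytest.raises(ValueError):
            thermal_time(5.0, 10.0)


class TestCanopy:
    def test_starts_at_initial_cover(self, crop_params):
        assert canopy_unstressed(0.0, crop_params) == pytest.approx(0.6)

    def test_exponential_phase_value(self, crop_params):
        # cc0 * exp(cgc * tau) while below half of maximum cover
        assert canopy_unstressed(100.0, crop_params) == pytest.approx(
            0.6 * math.exp(1.8), rel=1e-12
        )

    def test_plateaus_at_maximum_cover(self, crop_params):
        assert canopy_unstressed(1500.0, crop_params) == pytest.approx(92.0, abs=1e-6)

    def test_growth_step_matches_analytic_curve_unstressed(self, crop_params):
        cc, tau = crop_params.cc0, 0.0
        for _ in range(40):
            cc = canopy_growth_step(cc, 18.0, crop_params, ks_exp=1.0)
            tau += 18.0
            assert cc == pytest.approx(canopy_unstressed(tau, crop_params), rel=1e-9)

    def test_stress_scales_the_increment(self, crop_params):
        full = canopy_growth_step(10.0, 18.0, crop_params, ks_exp=1.0)
        half = canopy_growth_step(10.0, 18.0, crop_params, ks_exp=0.5)
        none = canopy_growth_step(10.0, 18.0, crop_params, ks_exp=0.0)
        assert none == 10.0
        assert half - 10.0 == pytest.approx((full - 10.0) / 2)

    def test_decline_reaches_zero_and_never_grows(self, crop_params):
        cc_sen = 92.0
        prev = cc_sen
        for tau in range(0, 500, 20):
            cc = canopy_decline(cc_sen, float(tau), crop_params)
            assert 0.0 <= cc <= prev + 1e-12
            prev = cc
        assert canopy_decline(cc_sen, 1e4, crop_params) == 0.0


class TestStress:
    def test_no_stress_below_upper_threshold(self):
        assert stress_coefficient(0.0, 3.0) == 1.0

    def test_full_stress_at_lower_threshold(self):
        assert stress_coefficient(1.0, 3.0) == pytest.approx(0.0, abs=1e-12)

    def test_halfway_closed_form(self):
        expected = 1.0 - (math.exp(1.5) - 1.0) / (math.exp(3.0) - 1.0)
        assert stress_coefficient(0.5, 3.0) == pytest.approx(expected, abs=1e-15)

    @given(
        shape=st.floats(0.1, 10.0),
        a=st.floats(0.01, 0.99),
        b=st.floats(0.01, 0.99),
    )
    def test_strictly_decreasing_between_thresholds(self, shape, a, b):
        if abs(a - b) < 1e-6:
            return
        lo, hi = min(a, b), max(a, b)
        assert stress_coefficient(lo, shape) > stress_coefficient(hi, shape)

    def test_threshold_mapping(self):
        # depletion below the upper threshold is no stress; beyond the lower
        # threshold it saturates at full stress
        assert relative_depletion(0.20, 0.22, 0.10, 0.26, 0.66) == 0.0
        assert relative_depletion(0.10, 0.22, 0.10, 0.26, 0.66) == 1.0
        mid = relative_depletion(0.1648, 0.22, 0.10, 0.26, 0.66)
        assert 0.0 < mid < 1.0

    def test_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            stress_coefficient(0.5, 0.0)


class TestDemands:
    def test_no_canopy_no_transpiration(self, crop_params):
        tr, _ = daily_demands(0.0, 5.0, crop_params)
        assert tr == 0.0

    def test_full_canopy_scales_et0_by_kctr(self, crop_params):
        # cc* -> 1 at full cover (1.72 - 1 + 0.3 = 1.02 at cc = 100%)
        tr, _ = daily_demands(100.0, 5.0, crop_params, ks_sto=1.0)
        assert tr == pytest.approx(1.10 * 1.02 * 5.0)

    def test_zero_et0_zero_demands(self, crop_params):
        tr, e = daily_demands(50.0, 0.0, crop_params)
        assert tr == 0.0 and e == 0.0

    def test_evaporation_shrinks_as_canopy_shades(self, crop_params):
        _, e_open = daily_demands(5.0, 5.0, crop_params)
        _, e_closed = daily_demands(90.0, 5.0, crop_params)
        assert e_open > e_closed


class TestBiomassAndYield:
    def test_increment_is_wp_times_normalised_transpiration(self):
        assert accumulate_biomass(0.0, 4.75, 5.0, 19.0) == pytest.approx(18.05)

    def test_zero_transpiration_zero_increment(self):
        assert accumulate_biomass(100.0, 0.0, 5.0, 19.0) == 100.0

    def test_degenerate_et0_skips_increment(self):
        assert accumulate_biomass(100.0, 1.0, 0.0, 19.0) == 100.0

    def test_linear_in_seasonal_sum(self):
        b = 0.0
        for _ in range(60):
            b = accumulate_biomass(b, 5.0, 5.0, 19.0)
        assert b == pytest.approx(19.0 * 60.0)

    def test_full_season_yield(self, crop_params, calendar):
        # full HI build: Y = fHI * HI0 * B, in t/ha
        assert harvest_yield(1000.0, 135, crop_params, calendar) == pytest.approx(7.5)

    def test_no_biomass_no_yield(self, crop_params, calendar):
        assert harvest_yield(0.0, 135, crop_params, calendar) == 0.0

    def test_harvest_before_tuber_initiation_yields_nothing(self, crop_params, calendar):
        assert harvest_yield(1000.0, 40, crop_params, calendar) == 0.0

    def test_midway_harvest_interpolates_hi(self, crop_params, calendar):
        # DAP 77 is 34 of the 69 days from tuber initiation to vine kill
        expected = 1.0 * (0.75 * 34 / 69) * 1000.0 * 0.01
        assert harvest_yield(1000.0, 77, crop_params, calendar) == pytest.approx(expected)


class TestRootDeepening:
    def test_constant_before_emergence(self, calendar):
        assert root_deepening(10, calendar, 0.15, 0.47) == 0.15

    def test_maximum_from_mid_bulk_onward(self, calendar):
        assert root_deepening(71, calendar, 0.15, 0.47) == 0.47
        assert root_deepening(120, calendar, 0.15, 0.47) == 0.47

    def test_midpoint_power_curve(self, calendar):
        day = (calendar.emergence + calendar.mid_bulk) // 2  # midpoint, DAP 46
        expected = 0.15 + (0.47 - 0.15) * 0.5**1.5
        assert root_deepening(day, calendar, 0.15, 0.47) == pytest.approx(expected)


class TestParamValidation:
    def test_canopy_bounds(self):
        with pytest.raises(ValueError):
            CropParams(cc0=5.0, ccx=4.0)

    def test_extraction_pattern_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CropParams(extraction_pattern=(0.5, 0.3, 0.2, 0.2))

    def test_calendar_must_increase(self):
        with pytest.raises(ValueError):
            CropCalendar(emergence=50, tuber_initiation=43)
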