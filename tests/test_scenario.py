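"""Season classification, the daily simulation loop and trade-off analysis."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from tuberflow.irrigation import IrrigationPolicy
from tuberflow.scenario import (
    classification_thresholds,
    classify_season,
    lnrr,
    pearson_r,
    run_grid,
    run_season,
    stage_correlation_matrix,
    tradeoff_table,
)
from tuberflow.weather import SeasonSpec, synthesize_season


class TestClassification:
    @pytest.mark.parametrize(
        "total,expected",
        [(340.0, "wet"), (250.0, "dry"), (284.5, "normal"), (312.95, "normal"),
         (312.96, "wet"), (256.0, "dry")],
    )
    def test_labels(self, total, expected):
        assert classify_season(total, 284.5, 0.10) == expected

    def test_printed_thresholds(self):
        wet, dry = classification_thresholds(284.5, 0.10)
        assert wet == 312.9
        assert dry == 256.0

    def test_every_total_gets_exactly_one_label(self):
        for total in np.linspace(0, 600, 1201):
            assert classify_season(float(total)) in ("wet", "normal", "dry")

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            classify_season(300.0, 284.5, 1.5)


class TestLnRR:
    def test_control_against_itself_is_zero(self):
        assert lnrr(5.0, 5.0) == 0.0

    def test_doubling_gives_log_two(self):
        assert lnrr(10.0, 5.0) == pytest.approx(math.log(2))

    @given(st.floats(0.01, 1e3), st.floats(0.01, 1e3))
    def test_antisymmetric(self, a, b):
        assert lnrr(a, b) == pytest.approx(-lnrr(b, a), abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            lnrr(0.0, 1.0)


class TestPearson:
    def test_exact_plus_minus_one_on_linear_data(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1) == 1.0
        assert pearson_r(x, -x) == -1.0

    def test_three_year_hand_example(self):
        # n=3: sums 60, 9, 220, 1400, 41 -> r = 120/sqrt(600*42) = 2/sqrt(7)
        assert pearson_r([10, 20, 30], [2, 1, 6]) == pytest.approx(2 / math.sqrt(7))

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x, y = rng.normal(size=8), rng.normal(size=8)
            assert pearson_r(x, y) == pytest.approx(
                scipy.stats.pearsonr(x, y).statistic, abs=1e-12
            )

    def test_flat_series_is_undefined(self):
        assert math.isnan(pearson_r([1, 1, 1], [1, 2, 3]))


class TestRunSeason:
    def test_irrigation_beats_rainfed_on_dry_season(
        self, dry_season, montcalm, crop_params, calendar
    ):
        rf = run_season(dry_season, montcalm, crop_params, calendar,
                        IrrigationPolicy(mode="rainfed"))
        irr = run_season(dry_season, montcalm, crop_params, calendar,
                         IrrigationPolicy(threshold=0.50))
        assert irr.yield_t_ha > rf.yield_t_ha
        assert rf.irrigation.count == 0

    def test_field_like_fixed_schedule_closes_mass_balance(
        self, season_2023like, montcalm, crop_params, calendar
    ):
        policy = IrrigationPolicy(
            mode="fixed", schedule=((30, 16.0), (55, 16.0), (80, 16.0))
        )
        res = run_season(season_2023like, montcalm, crop_params, calendar, policy)
        assert len(res.trace) == 135
        assert res.trace["closure_error_mm"].max() <= 1e-9
        assert res.irrigation.total == pytest.approx(48.0)

    def test_generous_irrigation_never_hits_stomatal_stress(
        self, dry_season, montcalm, crop_params, calendar
    ):
        res = run_season(dry_season, montcalm, crop_params, calendar,
                         IrrigationPolicy(threshold=0.90))
        assert (res.trace["ks_sto"] == 1.0).all()

    def test_crop_state_invariants_on_trace(
        self, season_2023like, montcalm, crop_params, calendar
    ):
        res = run_season(season_2023like, montcalm, crop_params, calendar,
                         IrrigationPolicy(threshold=0.50))
        tr = res.trace
        assert ((0 <= tr["cc_pct"]) & (tr["cc_pct"] <= crop_params.ccx)).all()
        assert tr["biomass_g_m2"].is_monotonic_increasing
        assert tr["hi"].is_monotonic_increasing
        assert tr["cc_pct"].iloc[-1] == 0.0  # vine kill completed
        assert res.yield_t_ha <= crop_params.hi0 * res.biomass_g_m2 * 0.01 + 1e-12

    def test_short_weather_rejected(self, montcalm, crop_params, calendar):
        short = synthesize_season(SeasonSpec(n_days=100, seed=1))
        with pytest.raises(ValueError, match="135"):
            run_season(short, montcalm, crop_params, calendar,
                       IrrigationPolicy(mode="rainfed"))

    def test_deterministic(self, season_2023like, montcalm, crop_params, calendar):
        a = run_season(season_2023like, montcalm, crop_params, calendar,
                       IrrigationPolicy(threshold=0.6))
        b = run_season(season_2023like, montcalm, crop_params, calendar,
                       IrrigationPolicy(threshold=0.6))
        assert a.yield_t_ha == b.yield_t_ha
        pd.testing.assert_frame_equal(a.trace, b.trace)


@pytest.fixture(scope="module")
def small_grid(montcalm, crop_params, calendar):
    years = {
        f"Y{i}": synthesize_season(SeasonSpec(target_rain_mm=t, seed=100 + i))
        for i, t in enumerate([340.0, 280.0, 230.0, 250.0])
    }
    policies = [IrrigationPolicy(mode="rainfed")] + [
        IrrigationPolicy(threshold=t) for t in (0.3, 0.5, 0.7)
    ]
    return run_grid(years, {"montcalm": montcalm}, crop_params, calendar, policies)


class TestGridAndTradeoff:
    def test_one_row_per_combination(self, small_grid):
        assert len(small_grid) == 4 * 4  # 4 years x (3 thresholds + rainfed)

    def test_permuting_year_order_leaves_table_unchanged(
        self, montcalm, crop_params, calendar, small_grid
    ):
        years = {
            f"Y{i}": synthesize_season(SeasonSpec(target_rain_mm=t, seed=100 + i))
            for i, t in [(2, 230.0), (0, 340.0), (3, 250.0), (1, 280.0)]
        }
        policies = [IrrigationPolicy(mode="rainfed")] + [
            IrrigationPolicy(threshold=t) for t in (0.3, 0.5, 0.7)
        ]
        again = run_grid(years, {"montcalm": montcalm}, crop_params, calendar, policies)
        pd.testing.assert_frame_equal(again, small_grid)

    def test_control_maps_to_origin(self, small_grid):
        tab = tradeoff_table(small_grid, "50% FC", "all")
        ctrl = tab[tab["policy"] == "50% FC"].iloc[0]
        assert ctrl["lnrr_yield"] == 0.0 and ctrl["lnrr_wpc"] == 0.0
        assert ctrl["quadrant"] == "win-win"

    @pytest.mark.parametrize(
        "ly,lw,expected",
        [(0.10, 0.05, "win-win"), (-0.10, 0.20, "lose-win"),
         (0.10, -0.05, "win-lose"), (-0.10, -0.20, "lose-lose")],
    )
    def test_quadrant_signs(self, ly, lw, expected):
        from tuberflow.scenario import _quadrant

        assert _quadrant(ly, lw) == expected

    def test_missing_control_rejected(self, small_grid):
        with pytest.raises(ValueError, match="control"):
            tradeoff_table(small_grid, "55% FC", "all")

    def test_stage_correlations_bounded_and_shaped(self, small_grid, calendar):
        mat = stage_correlation_matrix(small_grid, calendar, soil="montcalm")
        stages = list(calendar.stage_windows())
        assert list(mat.columns) == stages
        values = mat.to_numpy(dtype=float)
        finite = values[~np.isnan(values)]
        assert ((-1 <= finite) & (finite <= 1)).all()
        # rainfed row has no irrigation variance anywhere: all undefined
        assert np.isnan(mat.loc["rainfed"].to_numpy(dtype=float)).all()

    def test_too_few_years_rejected(self, montcalm, crop_params, calendar):
        years = {
            "A": synthesize_season(SeasonSpec(seed=1)),
            "B": synthesize_season(SeasonSpec(seed=2)),
        }
        grid = run_grid(years, {"montcalm": montcalm}, crop_params, calendar,
                        [IrrigationPolicy(threshold=0.5)])
        with pytest.raises(ValueError, match="three years"):
            stage_correlation_matrix(grid, calendar)
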