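"""Season simulation, multi-year scenario grids, and trade-off analysis.

``run_season`` couples the weather series, the soil water balance, the crop
engine and an irrigation policy into the daily loop; ``run_grid`` sweeps
(year x soil x policy) combinations. Seasons are classed wet / normal / dry
by their growing-season rainfall total against a long-term mean with a
+/-10% band. Policy effects are summarised as log response ratios (LnRR) of
yield and crop water productivity against a control policy and mapped onto
win/lose quadrants; a stage-resolved Pearson correlation matrix relates
stage irrigation totals to seasonal yield across years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crop as _crop
from . import soil as _soil
from .irrigation import IrrigationLog, IrrigationPolicy, decide_irrigation
from .metrics import crop_water_productivity
from .weather import SeasonSpec, synthesize_season

__all__ = [
    "classify_season",
    "classification_thresholds",
    "SeasonResult",
    "run_season",
    "run_grid",
    "lnrr",
    "tradeoff_table",
    "stage_correlation_matrix",
    "pearson_r",
    "default_decade_specs",
    "DEFAULT_SEASON_RAIN_MEAN",
    "DEFAULT_SEASON_RAIN_BAND",
]

DEFAULT_SEASON_RAIN_MEAN = 284.5  # long-term growing-season rainfall, mm
DEFAULT_SEASON_RAIN_BAND = 0.10

#: Fixed rainfall targets (mm) of the synthetic decade: 4 wet, 4 normal, 3 dry.
DECADE_TARGETS = (
    ("Y01", 320.0), ("Y02", 340.0), ("Y03", 355.0), ("Y04", 330.0),
    ("Y05", 285.0), ("Y06", 270.0), ("Y07", 300.0), ("Y08", 260.0),
    ("Y09", 230.0), ("Y10", 250.0), ("Y11", 210.0),
)


def classify_season(
    total_rain_mm: float,
    mean_mm: float = DEFAULT_SEASON_RAIN_MEAN,
    band: float = DEFAULT_SEASON_RAIN_BAND,
) -> str:
    """Label a season wet / normal / dry by its rainfall total.

    Wet above ``mean*(1+band)``, dry below ``mean*(1-band)``, normal between
    (boundaries inclusive in the normal class). Every total gets exactly one
    label.
    """
    if mean_mm <= 0:
        raise ValueError("mean rainfall must be positive")
    if not 0.0 < band < 1.0:
        raise ValueError("band must be a fraction in (0, 1)")
    if total_rain_mm > mean_mm * (1.0 + band):
        return "wet"
    if total_rain_mm < mean_mm * (1.0 - band):
        return "dry"
    return "normal"


def classification_thresholds(
    mean_mm: float = DEFAULT_SEASON_RAIN_MEAN,
    band: float = DEFAULT_SEASON_RAIN_BAND,
    decimals: int = 1,
) -> tuple[float, float]:
    """(wet, dry) boundaries as conventionally printed.

    Values are truncated (floored) at ``decimals`` places: 284.5 mm with a
    10% band gives 312.9 and 256.0 mm.
    """
    scale = 10.0**decimals
    wet = math.floor(mean_mm * (1.0 + band) * scale) / scale
    dry = math.floor(mean_mm * (1.0 - band) * scale) / scale
    return wet, dry


@dataclass
class SeasonResult:
    """Outcome of one simulated season."""

    yield_t_ha: float  # tuber yield, dry matter
    biomass_g_m2: float
    wpc_kg_m3: float
    rain_total_mm: float
    irrigation: IrrigationLog
    season_class: str
    stage_irrigation_mm: dict[str, float]
    max_closure_mm: float = 0.0  # worst daily water-ledger error
    trace: pd.DataFrame | None = None

    @property
    def yield_kg_ha(self) -> float:
        return self.yield_t_ha * 1000.0


def run_season(
    weather: pd.DataFrame,
    profile: _soil.SoilProfile,
    params: _crop.CropParams,
    calendar: _crop.CropCalendar,
    policy: IrrigationPolicy,
    initial_fraction_of_fc: float = 1.0,
    tau: float = 0.5,
    keep_trace: bool = True,
) -> SeasonResult:
    """Simulate one growing season day by day.

    Daily order: rain infiltrates (virtually) to evaluate the irrigation
    trigger and the stress level, then rain + irrigation, drainage, soil
    evaporation and root extraction run through the water balance; the
    canopy then advances (expansion scaled by the expansion-stress
    coefficient, decline after senescence onset or the vine kill), and
    biomass accumulates from the realised normalised transpiration.
    """
    if len(weather) < calendar.harvest:
        raise ValueError(
            f"weather covers {len(weather)} days but the season needs {calendar.harvest}"
        )
    et0_col = "et0_mm"
    if et0_col not in weather.columns:
        raise ValueError("weather series must include the et0_mm column")

    water = profile.initial_state(initial_fraction_of_fc)
    state = _crop.CropState(zr=params.zr_min)
    log = IrrigationLog()
    rows = [] if keep_trace else None
    max_closure = 0.0

    for day, wrow in enumerate(weather.itertuples(index=False), start=1):
        if day > calendar.harvest:
            break
        gdd = _crop.thermal_time(wrow.tmax_c, wrow.tmin_c, params.t_base, params.t_upper)
        state.zr = _crop.root_deepening(day, calendar, params.zr_min, params.zr_max)

        # rain infiltrates before the trigger and stress are evaluated
        post_rain, _ = _soil.step_water_balance(
            water, profile, wrow.rain_mm, 0.0, 0.0, 0.0, state.zr, tau=0.0
        )
        full_mode_active = policy.mode == "full" and day >= (
            policy.start_dap if policy.start_dap is not None else calendar.emergence
        )
        if full_mode_active:
            irr = 0.0  # the refill inside the balance step books the depth
            post_rain, _ = _soil.step_water_balance(
                post_rain, profile, 0.0, 0.0, 0.0, 0.0, state.zr, tau=0.0,
                refill_root_zone_to_fc=True,
            )
        else:
            irr = decide_irrigation(
                post_rain, profile, state.zr, policy, day, log, calendar.emergence
            )
            if irr > 0:
                log.add(day, irr)
                post_rain, _ = _soil.step_water_balance(
                    post_rain, profile, 0.0, irr, 0.0, 0.0, state.zr, tau=0.0
                )

        # stress only exists once there is a crop to experience it
        if day >= calendar.emergence:
            theta_bar = _soil.mean_theta(post_rain, profile, state.zr)
            fc_bar = _soil.mean_field_capacity(profile, state.zr)
            wp_bar = _soil.mean_wilting_point(profile, state.zr)
            d_exp = _crop.relative_depletion(
                theta_bar, fc_bar, wp_bar, params.p_exp_upper, params.p_exp_lower
            )
            d_sto = _crop.relative_depletion(theta_bar, fc_bar, wp_bar, params.p_sto_upper)
            d_sen = _crop.relative_depletion(theta_bar, fc_bar, wp_bar, params.p_sen_upper)
            ks_exp = _crop.stress_coefficient(d_exp, params.shape_exp)
            ks_sto = _crop.stress_coefficient(d_sto, params.shape_sto)
            ks_sen = _crop.stress_coefficient(d_sen, params.shape_sen)
        else:
            ks_exp = ks_sto = ks_sen = 1.0

        # two-stage soil evaporation: full rate above wilting point, then a
        # linear fall to zero at air-dry
        surf = profile.overlap(0.0, profile.evaporation_depth)
        theta_surf = float(np.sum(post_rain.theta * surf) / np.sum(surf))
        wp_surf = float(np.sum(profile.theta_wp_c * surf) / np.sum(surf))
        ad_surf = float(np.sum(profile.theta_air_dry_c * surf) / np.sum(surf))
        if theta_surf >= wp_surf:
            kr = 1.0
        else:
            kr = max((theta_surf - ad_surf) / (wp_surf - ad_surf), 0.0)

        cc_for_demand = state.cc if day >= calendar.emergence else 0.0
        tr_dem, e_dem = _crop.daily_demands(cc_for_demand, wrow.et0_mm, params, ks_sto, kr)

        water, fluxes = _soil.step_water_balance(
            water, profile, wrow.rain_mm, irr, e_dem, tr_dem, state.zr,
            params.extraction_pattern, tau=tau,
            refill_root_zone_to_fc=full_mode_active,
        )
        if full_mode_active and fluxes.irrigation > 0:
            log.add(day, fluxes.irrigation)
        max_closure = max(max_closure, fluxes.closure_error)

        # canopy development
        if day == calendar.emergence:
            state.cc = params.cc0
        if day >= calendar.emergence:
            state.tau_gdd += gdd
            if not state.in_decline and day >= calendar.senescence_onset:
                state.in_decline = True
                state.cc_at_decline = state.cc
            if state.in_decline:
                state.tau_decline_gdd += gdd
                state.cc = _crop.canopy_decline(
                    state.cc_at_decline, state.tau_decline_gdd, params
                )
            else:
                # severe depletion browns canopy; rewetting lets it regrow
                if ks_sen < 1.0:
                    state.cc = _crop.stress_senescence_step(state.cc, gdd, params, ks_sen)
                state.cc = _crop.canopy_growth_step(state.cc, gdd, params, ks_exp)
        if day >= calendar.vine_kill:
            if state.vine_kill_days == 0:
                state.cc_at_vine_kill = state.cc
            state.vine_kill_days += 1
            ramp = max(1.0 - state.vine_kill_days / 3.0, 0.0)
            state.cc = min(state.cc, state.cc_at_vine_kill * ramp)

        state.b = _crop.accumulate_biomass(state.b, fluxes.transpiration, wrow.et0_mm, params.wp)
        state.hi = params.hi0 * _crop.harvest_index_fraction(day, calendar)

        if rows is not None:
            rows.append(
                {
                    "day": day,
                    "rain_mm": fluxes.rain,
                    "irrigation_mm": fluxes.irrigation,
                    "runoff_mm": fluxes.runoff,
                    "drainage_mm": fluxes.drainage,
                    "evaporation_mm": fluxes.evaporation,
                    "transpiration_mm": fluxes.transpiration,
                    "tr_demand_mm": tr_dem,
                    "closure_error_mm": fluxes.closure_error,
                    "theta_bar": _soil.mean_theta(water, profile, state.zr),
                    "root_zone_water_mm": _soil.root_zone_water(water, profile, state.zr),
                    "zr_m": state.zr,
                    "cc_pct": state.cc,
                    "ks_exp": ks_exp,
                    "ks_sto": ks_sto,
                    "biomass_g_m2": state.b,
                    "hi": state.hi,
                }
            )

    season_rain = float(weather["rain_mm"].iloc[: calendar.harvest].sum())
    yield_t = _crop.harvest_yield(state.b, calendar.harvest, params, calendar)
    total_water = season_rain + log.total
    wpc = (
        crop_water_productivity(yield_t * 1000.0, season_rain, log.total).wpc_kg_m3
        if total_water > 0
        else 0.0
    )
    stage_irr = {
        name: log.total_in_window(start, end)
        for name, (start, end) in calendar.stage_windows().items()
    }
    return SeasonResult(
        yield_t_ha=yield_t,
        biomass_g_m2=state.b,
        wpc_kg_m3=wpc,
        rain_total_mm=season_rain,
        irrigation=log,
        season_class=classify_season(season_rain),
        stage_irrigation_mm=stage_irr,
        max_closure_mm=max_closure,
        trace=pd.DataFrame(rows) if rows is not None else None,
    )


def run_grid(
    years: dict[str, pd.DataFrame],
    soils: dict[str, _soil.SoilProfile],
    params: _crop.CropParams,
    calendar: _crop.CropCalendar,
    policies: list[IrrigationPolicy],
    keep_traces: bool = False,
) -> pd.DataFrame:
    """One row per (year x soil x policy), sorted deterministically."""
    if not years or not policies or not soils:
        raise ValueError("need at least one year, one soil and one policy")
    stage_names = list(calendar.stage_windows())
    records = []
    for soil_id in sorted(soils):
        for pol in policies:
            for year_id in sorted(years):
                res = run_season(
                    years[year_id], soils[soil_id], params, calendar, pol,
                    keep_trace=keep_traces,
                )
                rec = {
                    "year": year_id,
                    "soil": soil_id,
                    "policy": pol.label,
                    "season_class": res.season_class,
                    "rain_mm": res.rain_total_mm,
                    "irrigation_count": res.irrigation.count,
                    "irrigation_mm": res.irrigation.total,
                    "yield_t_ha": res.yield_t_ha,
                    "wpc_kg_m3": res.wpc_kg_m3,
                }
                for name in stage_names:
                    rec[f"irr_{name}_mm"] = res.stage_irrigation_mm[name]
                records.append(rec)
    frame = pd.DataFrame.from_records(records)
    return frame.sort_values(["soil", "policy", "year"], kind="stable").reset_index(drop=True)


def lnrr(x_treatment: float, x_control: float) -> float:
    """Log response ratio ln(xi/xc); antisymmetric under swapping the pair."""
    if x_treatment <= 0 or x_control <= 0:
        raise ValueError("log response ratio needs strictly positive values")
    return math.log(x_treatment) - math.log(x_control)


def _quadrant(lnrr_yield: float, lnrr_wpc: float) -> str:
    """Sign quadrant; an exact zero on an axis counts as the win half."""
    y = "win" if lnrr_yield >= 0 else "lose"
    w = "win" if lnrr_wpc >= 0 else "lose"
    return f"{y}-{w}"


def tradeoff_table(
    results: pd.DataFrame,
    control_policy: str = "50% FC",
    group: str = "all",
    soil: str | None = None,
) -> pd.DataFrame:
    """Per-policy LnRR of mean yield and mean WPc against the control.

    ``group`` restricts to a season class (``wet``/``normal``/``dry``) or
    uses every year (``all``); group means per policy are compared, matching
    single-point-per-treatment quadrant plots. The control maps to (0, 0).
    """
    if group not in ("all", "wet", "normal", "dry"):
        raise ValueError("group must be one of all/wet/normal/dry")
    sub = results if soil is None else results[results["soil"] == soil]
    if group != "all":
        sub = sub[sub["season_class"] == group]
    if control_policy not in set(sub["policy"]):
        raise ValueError(f"control policy {control_policy!r} absent from the group")
    means = sub.groupby("policy")[["yield_t_ha", "wpc_kg_m3"]].mean()
    cy = means.loc[control_policy, "yield_t_ha"]
    cw = means.loc[control_policy, "wpc_kg_m3"]
    out = []
    for policy, row in means.iterrows():
        ly = lnrr(row["yield_t_ha"], cy)
        lw = lnrr(row["wpc_kg_m3"], cw)
        out.append(
            {
                "policy": policy,
                "group": group,
                "lnrr_yield": ly,
                "lnrr_wpc": lw,
                "quadrant": _quadrant(ly, lw),
            }
        )
    return pd.DataFrame(out).sort_values("policy", kind="stable").reset_index(drop=True)


def pearson_r(x, y) -> float:
    """Pearson correlation from the raw-sum formula; NaN if either side is flat.

    ``r = (n*Sxy - Sx*Sy) / sqrt((n*Sxx - Sx^2)(n*Syy - Sy^2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length series of size >= 2")
    n = x.size
    sx, sy = x.sum(), y.sum()
    num = n * float(np.sum(x * y)) - sx * sy
    vx = n * float(np.sum(x * x)) - sx * sx
    vy = n * float(np.sum(y * y)) - sy * sy
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(np.clip(num / math.sqrt(vx * vy), -1.0, 1.0))


def stage_correlation_matrix(
    results: pd.DataFrame,
    calendar: _crop.CropCalendar,
    soil: str | None = None,
) -> pd.DataFrame:
    """Pearson r per (policy x stage): stage irrigation total vs seasonal yield.

    Correlations run across years within each policy; cells without variance
    (e.g. a stage never irrigated under that policy) are NaN. Requires at
    least three years per cell.
    """
    sub = results if soil is None else results[results["soil"] == soil]
    stages = list(calendar.stage_windows())
    policies = sorted(sub["policy"].unique())
    mat = pd.DataFrame(index=policies, columns=stages, dtype=float)
    for policy in policies:
        rows = sub[sub["policy"] == policy]
        if len(rows) < 3:
            raise ValueError("need at least three years per policy for correlations")
        for stage in stages:
            mat.loc[policy, stage] = pearson_r(
                rows[f"irr_{stage}_mm"], rows["yield_t_ha"]
            )
    mat.index.name = "policy"
    return mat


def default_decade_specs(seed: int = 0, **spec_overrides) -> dict[str, SeasonSpec]:
    """The packaged synthetic decade: 4 wet, 4 normal and 3 dry seasons.

    Rainfall targets are fixed; per-year generator seeds derive from
    ``seed`` so the whole decade is reproducible from one integer.
    """
    return {
        year: SeasonSpec(
            target_rain_mm=target, seed=(seed * 1009 + i) % (2**31 - 1), **spec_overrides
        )
        for i, (year, target) in enumerate(DECADE_TARGETS)
    }


def synthesize_decade(seed: int = 0, **spec_overrides) -> dict[str, pd.DataFrame]:
    """Generate the weather series of the packaged synthetic decade."""
    return {
        year: synthesize_season(spec)
        for year, spec in default_decade_specs(seed, **spec_overrides).items()
    }
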