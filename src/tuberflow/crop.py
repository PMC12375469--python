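"""Daily canopy, root, stress, transpiration/biomass engine for potato.

The engine is water-driven: canopy cover (CC, % ground shaded) develops in
thermal time, transpiration scales with CC and reference evapotranspiration
(ET0), biomass accumulates in proportion to the normalised transpiration
``WP * Tr/ET0``, and tuber yield is the harvest-index fraction of biomass.
Water shortage acts through three stress processes, each driven by the
relative depletion of the root zone between field capacity and wilting
point: canopy expansion slows first (upper threshold 0.26), stomata close
next (0.65), and early senescence is triggered last (0.69).

Canopy growth and decay coefficients are expressed per growing-degree-day
(base 2 degC, cap 26 degC): the calibrated magnitudes close the canopy about
three to four weeks after emergence, consistent with tuber initiation on
day 43 after planting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CropParams",
    "CropCalendar",
    "CropState",
    "thermal_time",
    "canopy_unstressed",
    "canopy_growth_step",
    "canopy_decline",
    "stress_coefficient",
    "relative_depletion",
    "daily_demands",
    "accumulate_biomass",
    "harvest_index_fraction",
    "harvest_yield",
    "root_deepening",
]


@dataclass(frozen=True)
class CropParams:
    """Calibrated crop parameters (packaged defaults: 2023 potato season)."""

    cc0: float = 0.6  # initial canopy cover, %
    ccx: float = 92.0  # maximum canopy cover, %
    cgc: float = 0.018  # canopy growth coefficient, fraction GDD-1
    cdc: float = 0.80  # canopy decline coefficient, % GDD-1
    t_base: float = 2.0  # degC
    t_upper: float = 26.0  # degC
    zr_min: float = 0.15  # root depth at emergence, m
    zr_max: float = 0.47  # maximum effective root depth, m
    kctr: float = 1.10  # crop transpiration coefficient
    hi0: float = 0.75  # reference harvest index, fraction
    wp: float = 19.0  # normalised water productivity, g m-2
    extraction_pattern: tuple[float, float, float, float] = (0.40, 0.30, 0.20, 0.10)
    p_exp_upper: float = 0.26
    p_exp_lower: float = 0.66
    p_sto_upper: float = 0.65
    p_sen_upper: float = 0.69
    shape_exp: float = 3.0
    shape_sto: float = 3.0
    shape_sen: float = 3.0
    ks_cold: float = 1.0  # cold stress multiplier on Tr (fixed: not modelled)
    f_hi: float = 1.0  # harvest-index stress multiplier (fixed)
    ke_max: float = 1.10  # soil evaporation coefficient ceiling
    dry_matter_fraction: float = 0.20  # optional fresh-matter conversion

    def __post_init__(self) -> None:
        if not 0.0 < self.cc0 < self.ccx <= 100.0:
            raise ValueError("need 0 < cc0 < ccx <= 100")
        if not 0.0 <= self.hi0 <= 1.0:
            raise ValueError("hi0 must be a fraction in [0, 1]")
        if abs(sum(self.extraction_pattern) - 1.0) > 1e-9:
            raise ValueError("extraction pattern must sum to 1")
        if not 0.0 <= self.p_exp_upper < self.p_exp_lower <= 1.0:
            raise ValueError("need 0 <= p_exp_upper < p_exp_lower <= 1")
        for s in (self.shape_exp, self.shape_sto, self.shape_sen):
            if s <= 0:
                raise ValueError("stress shape factors must be > 0")


@dataclass(frozen=True)
class CropCalendar:
    """Phenology in days after planting (DAP); 2023 season defaults."""

    emergence: int = 21
    tuber_initiation: int = 43
    early_bulk: int = 56
    mid_bulk: int = 71
    late_bulk: int = 85
    senescence_onset: int = 99
    vine_kill: int = 112
    harvest: int = 135

    def __post_init__(self) -> None:
        seq = (
            self.emergence, self.tuber_initiation, self.early_bulk,
            self.mid_bulk, self.late_bulk, self.senescence_onset,
            self.vine_kill, self.harvest,
        )
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError("calendar DAPs must be strictly increasing")

    def stage_windows(self) -> dict[str, tuple[int, int]]:
        """Half-open DAP windows [start, end) of the developmental stages."""
        return {
            "prior_emergence": (1, self.emergence),
            "emergence": (self.emergence, self.tuber_initiation),
            "tuber_initiation": (self.tuber_initiation, self.early_bulk),
            "early_tuber_bulk": (self.early_bulk, self.mid_bulk),
            "mid_tuber_bulk": (self.mid_bulk, self.late_bulk),
            "late_tuber_bulk": (self.late_bulk, self.senescence_onset),
            "senescence": (self.senescence_onset, self.harvest + 1),
        }


@dataclass
class CropState:
    """Mutable daily crop state carried through a season run."""

    cc: float = 0.0  # canopy cover, %
    zr: float = 0.15  # current root depth, m
    tau_gdd: float = 0.0  # thermal time since emergence, degC d
    b: float = 0.0  # aboveground biomass, g m-2
    hi: float = 0.0  # current harvest index, fraction
    in_decline: bool = False
    cc_at_decline: float = 0.0
    tau_decline_gdd: float = 0.0
    vine_kill_days: int = 0
    cc_at_vine_kill: float = 0.0


def thermal_time(tmax: float, tmin: float, t_base: float = 2.0, t_upper: float = 26.0) -> float:
    """Growing-degree-days: mean temperature capped at t_upper, base t_base."""
    if tmax < tmin:
        raise ValueError("tmax must be >= tmin")
    return max(0.0, min((tmax + tmin) / 2.0, t_upper) - t_base)


def canopy_unstressed(tau_gdd: float, params: CropParams) -> float:
    """Analytic unstressed canopy cover (%) at thermal time tau since emergence.

    Exponential growth ``cc0 * exp(cgc*tau)`` up to half cover, then
    exponential approach ``ccx - 0.25*(ccx^2/cc0)*exp(-cgc*tau)``.
    """
    if tau_gdd < 0:
        return 0.0
    cc = params.cc0 * math.exp(params.cgc * tau_gdd)
    if cc > params.ccx / 2.0:
        cc = params.ccx - 0.25 * params.ccx**2 / params.cc0 * math.exp(-params.cgc * tau_gdd)
    return min(max(cc, 0.0), params.ccx)


def canopy_growth_step(cc: float, gdd: float, params: CropParams, ks_exp: float = 1.0) -> float:
    """One day of canopy expansion; water stress scales the increment.

    Integrates the growth ODE (dcc = cgc*cc below half cover, then
    dcc = cgc*(ccx - cc)) exactly across the day, handling the phase
    crossover, and applies ``ks_exp`` to the daily increment.
    """
    if gdd <= 0 or cc >= params.ccx:
        return cc
    half = params.ccx / 2.0
    c = max(cc, params.cc0)
    remaining = gdd
    if c <= half:
        tau_to_half = math.log(half / c) / params.cgc
        if tau_to_half >= remaining:
            c = c * math.exp(params.cgc * remaining)
            remaining = 0.0
        else:
            c = half
            remaining -= tau_to_half
    if remaining > 0:
        c = params.ccx - (params.ccx - c) * math.exp(-params.cgc * remaining)
    increment = c - cc
    return min(cc + max(ks_exp, 0.0) * increment, params.ccx)


def canopy_decline(cc_at_onset: float, tau_since_onset_gdd: float, params: CropParams) -> float:
    """Canopy cover (%) in the senescence decline phase."""
    if cc_at_onset <= 0:
        return 0.0
    # exponent capped: past ~exp(30) the bracket is hugely negative anyway
    exponent = min(params.cdc / cc_at_onset * tau_since_onset_gdd, 30.0)
    cc = cc_at_onset * (1.0 - 0.05 * (math.exp(exponent) - 1.0))
    return min(max(cc, 0.0), cc_at_onset)


def stress_senescence_step(cc: float, gdd: float, params: CropParams, ks_sen: float) -> float:
    """One day of water-stress-driven canopy loss; recoverable on rewetting.

    Beyond the senescence depletion threshold the canopy browns at a rate
    proportional to the stress severity, ``(1 - Ks_sen) * cdc * gdd``,
    scaled by the relative cover. Unlike calendar senescence the crop can
    re-green through the ordinary expansion step once the root zone rewets.
    """
    loss = (1.0 - min(max(ks_sen, 0.0), 1.0)) * params.cdc * gdd * (cc / params.ccx)
    return max(cc - loss, 0.0)


def relative_depletion(
    theta_bar: float, theta_fc: float, theta_wp: float, p_upper: float, p_lower: float = 1.0
) -> float:
    """Relative depletion of the root zone mapped through stress thresholds.

    Depletion ``D = (theta_fc - theta_bar)/(theta_fc - theta_wp)`` is rescaled
    to ``(D - p_upper)/(p_lower - p_upper)`` and clipped to [0, 1]. Stomatal
    closure and senescence use ``p_lower = 1`` (full stress at wilting point).
    """
    if theta_fc <= theta_wp:
        raise ValueError("theta_fc must exceed theta_wp")
    if not 0.0 <= p_upper < p_lower <= 1.0:
        raise ValueError("need 0 <= p_upper < p_lower <= 1")
    d = (theta_fc - theta_bar) / (theta_fc - theta_wp)
    return min(max((d - p_upper) / (p_lower - p_upper), 0.0), 1.0)


def stress_coefficient(depletion_rel: float, shape: float) -> float:
    """Convex stress coefficient Ks in [0, 1].

    ``Ks = 1 - (exp(Drel*shape) - 1)/(exp(shape) - 1)``: 1 with no relative
    depletion, 0 at full depletion, strictly decreasing in between.
    """
    if shape <= 0:
        raise ValueError("shape factor must be > 0")
    d = min(max(depletion_rel, 0.0), 1.0)
    return 1.0 - (math.exp(d * shape) - 1.0) / (math.exp(shape) - 1.0)


def _cc_star(cc_pct: float) -> float:
    """Canopy cover adjusted for micro-advection (fraction)."""
    c = min(max(cc_pct, 0.0), 100.0) / 100.0
    return 1.72 * c - c**2 + 0.30 * c**3


def daily_demands(
    cc_pct: float,
    et0: float,
    params: CropParams,
    ks_sto: float = 1.0,
    kr: float = 1.0,
) -> tuple[float, float]:
    """Potential transpiration and soil evaporation for the day (mm).

    ``Tr = Ks_sto * KsTr * KcTr * cc* * ET0`` and
    ``E = Kr * Ke_max * (1 - cc*) * ET0`` with cc* the advection-adjusted
    canopy fraction.
    """
    if not 0.0 <= cc_pct <= 100.0:
        raise ValueError("canopy cover % must be in [0, 100]")
    cstar = _cc_star(cc_pct)
    tr = max(ks_sto, 0.0) * params.ks_cold * params.kctr * cstar * max(et0, 0.0)
    e = max(kr, 0.0) * params.ke_max * max(1.0 - cstar, 0.0) * max(et0, 0.0)
    return max(tr, 0.0), max(e, 0.0)


def accumulate_biomass(b: float, tr_realized: float, et0: float, wp: float) -> float:
    """Add the day's normalised-transpiration biomass: ``b + wp * Tr/ET0``.

    A day with transpiration but zero ET0 is degenerate; the increment is
    skipped (biomass never decreases).
    """
    if tr_realized < 0:
        raise ValueError("transpiration must be >= 0")
    if tr_realized == 0.0 or et0 <= 0.0:
        return b
    return b + wp * tr_realized / et0


def harvest_index_fraction(day: int, calendar: CropCalendar) -> float:
    """HI build-up fraction: 0 at tuber initiation, 1 at vine kill (linear)."""
    span = calendar.vine_kill - calendar.tuber_initiation
    return min(max((day - calendar.tuber_initiation) / span, 0.0), 1.0)


def harvest_yield(b: float, day: int, params: CropParams, calendar: CropCalendar) -> float:
    """Tuber yield (t ha-1, dry matter): ``Y = fHI * HI0 * hi_frac * B``."""
    hi = params.hi0 * harvest_index_fraction(day, calendar)
    return params.f_hi * hi * b * 0.01  # g m-2 -> t ha-1


def root_deepening(day: int, calendar: CropCalendar, zr_min: float, zr_max: float) -> float:
    """Effective root depth (m): power-1.5 growth from emergence to mid-bulk."""
    if day < calendar.emergence:
        return zr_min
    if day >= calendar.mid_bulk:
        return zr_max
    frac = (day - calendar.emergence) / (calendar.mid_bulk - calendar.emergence)
    return zr_min + (zr_max - zr_min) * frac**1.5
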