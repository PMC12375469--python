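"""Synthetic growing-season weather and FAO-56 reference evapotranspiration.

A growing season is represented as a :class:`pandas.DataFrame` with one row
per day and the columns

``date, tmax_c, tmin_c, rain_mm, rhmax_pct, rhmin_pct, wind_ms, srad_mj``

plus ``et0_mm`` once reference evapotranspiration has been computed. Wind is
stored at the 2 m standard height; station wind measured at another height is
converted with the FAO-56 logarithmic profile before use.

The generator emulates a humid temperate potato season: a first-order
two-state occurrence chain with gamma-distributed wet-day amounts gives the
rainfall its wet/dry spell structure, and the season total is then rescaled
multiplicatively so that the sum matches the requested target exactly. This
makes the wet/normal/dry season class directly controllable. Temperatures
follow a day-of-year sinusoid peaking in early August (the late tuber-bulking
window) with bounded noise; defaults are tuned so that the season means are
close to 25.7 / 12.9 degC for Tmax / Tmin.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WEATHER_COLUMNS",
    "SeasonSpec",
    "synthesize_season",
    "compute_et0",
    "wind_to_2m",
    "read_weather",
    "write_weather",
]

#: Required columns of a weather file / frame (et0_mm is optional on input).
WEATHER_COLUMNS = (
    "date",
    "tmax_c",
    "tmin_c",
    "rain_mm",
    "rhmax_pct",
    "rhmin_pct",
    "wind_ms",
    "srad_mj",
)

_SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
_STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 day-1
_ALBEDO = 0.23  # grass reference surface


@dataclass(frozen=True)
class SeasonSpec:
    """Parameters controlling one synthetic growing season.

    Identical specs produce bitwise-identical series (seeded generator).
    """

    planting_date: _dt.date = _dt.date(2023, 5, 10)
    n_days: int = 135
    latitude: float = 43.35  # degrees north
    elevation_m: float = 290.0
    target_rain_mm: float = 284.5
    #: two-state rain occurrence chain: P(wet | dry) and P(wet | wet)
    p_wet_after_dry: float = 0.30
    p_wet_after_wet: float = 0.55
    #: gamma distribution of wet-day amounts (mm)
    rain_gamma_shape: float = 0.85
    rain_gamma_scale: float = 7.0
    #: seasonal mean targets and sinusoid semi-amplitudes (degC)
    tmax_mean: float = 25.7
    tmin_mean: float = 12.9
    tmax_amplitude: float = 5.5
    tmin_amplitude: float = 5.0
    temp_noise: float = 2.0  # bounded uniform +/- noise, degC
    peak_doy: int = 220  # early August: late tuber-bulking window
    wind_mean_3m: float = 2.7  # station anemometer height 3 m
    #: within-season rainfall profile: relative wet-day odds per phenological
    #: window (DAP boundaries and factors). The station climatology is wet
    #: around emergence and the mid/late tuber-bulking weeks and dry through
    #: early bulking and senescence.
    rain_stage_boundaries: tuple[int, ...] = (21, 43, 56, 71, 85, 99)
    rain_stage_factors: tuple[float, ...] = (1.25, 1.0, 0.55, 1.35, 1.2, 0.6)
    seed: int = 0
    max_rain_retries: int = 10

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("season length must be >= 1 day")
        if self.target_rain_mm < 0:
            raise ValueError("target rainfall must be >= 0")
        for name in ("p_wet_after_dry", "p_wet_after_wet"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def replace(self, **kw) -> "SeasonSpec":
        return dataclasses.replace(self, **kw)


def wind_to_2m(speed: float, measurement_height_m: float) -> float:
    """Convert wind speed to the 2 m standard height (FAO-56 log profile).

    ``u2 = uz * 4.87 / ln(67.8 z - 5.42)``; identity at z = 2 m.
    """
    if measurement_height_m <= 0.08:
        raise ValueError("measurement height must exceed 0.08 m")
    if measurement_height_m == 2.0:
        return float(speed)
    return float(speed) * 4.87 / math.log(67.8 * measurement_height_m - 5.42)


def _saturation_vp(t: np.ndarray | float) -> np.ndarray | float:
    """Saturation vapour pressure (kPa) at air temperature t (degC)."""
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def extraterrestrial_radiation(latitude: float, day_of_year) -> np.ndarray | float:
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1)."""
    doy = np.asarray(day_of_year, dtype=float)
    phi = math.radians(latitude)
    dr = 1 + 0.033 * np.cos(2 * np.pi / 365 * doy)
    dec = 0.409 * np.sin(2 * np.pi / 365 * doy - 1.39)
    x = np.clip(-np.tan(phi) * np.tan(dec), -1.0, 1.0)
    ws = np.arccos(x)
    ra = (
        24 * 60 / np.pi
        * _SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.sin(ws))
    )
    return ra if ra.shape else float(ra)


def compute_et0(
    tmax: float,
    tmin: float,
    rhmax: float,
    rhmin: float,
    wind_2m: float,
    srad: float,
    latitude: float,
    day_of_year: int,
    elevation_m: float = 290.0,
) -> float:
    """Daily grass-reference evapotranspiration, FAO-56 Penman-Monteith (mm).

    Net radiation is derived from measured solar radiation (albedo 0.23,
    clear-sky envelope from extraterrestrial radiation), the psychrometric
    constant from station elevation, and soil heat flux is taken as zero at
    the daily time step. The result is clipped at zero.
    """
    if tmax < tmin:
        raise ValueError("tmax must be >= tmin")
    if not (0 <= rhmin <= rhmax <= 100):
        raise ValueError("need 0 <= rhmin <= rhmax <= 100")
    if wind_2m < 0 or srad < 0:
        raise ValueError("wind and solar radiation must be >= 0")

    tmean = (tmax + tmin) / 2.0
    es = (_saturation_vp(tmax) + _saturation_vp(tmin)) / 2.0
    ea = (_saturation_vp(tmin) * rhmax / 100.0 + _saturation_vp(tmax) * rhmin / 100.0) / 2.0
    delta = 4098.0 * _saturation_vp(tmean) / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26
    gamma = 0.000665 * pressure

    ra = extraterrestrial_radiation(latitude, day_of_year)
    rso = (0.75 + 2e-5 * elevation_m) * ra
    rns = (1.0 - _ALBEDO) * srad
    rel = min(srad / rso, 1.0) if rso > 0 else 1.0
    # cloudiness factor floored at 0: the sky never radiatively warms the
    # daily budget in this formulation (overcast days just lose nothing)
    rnl = (
        _STEFAN_BOLTZMANN
        * (((tmax + 273.16) ** 4 + (tmin + 273.16) ** 4) / 2.0)
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
        * max(1.35 * rel - 0.35, 0.0)
    )
    rn = rns - rnl

    num = 0.408 * delta * rn + gamma * 900.0 / (tmean + 273.0) * wind_2m * (es - ea)
    et0 = num / (delta + gamma * (1.0 + 0.34 * wind_2m))
    return max(0.0, float(et0))


def add_et0(series: pd.DataFrame, latitude: float, elevation_m: float = 290.0) -> pd.DataFrame:
    """Return a copy of the weather frame with the ``et0_mm`` column filled."""
    out = series.copy()
    doy = pd.to_datetime(out["date"]).dt.dayofyear.to_numpy()
    out["et0_mm"] = [
        compute_et0(
            row.tmax_c, row.tmin_c, row.rhmax_pct, row.rhmin_pct,
            row.wind_ms, row.srad_mj, latitude, int(d), elevation_m,
        )
        for row, d in zip(out.itertuples(), doy)
    ]
    return out


def _stage_factor(day: int, spec: SeasonSpec) -> float:
    """Relative wet-day odds for DAP ``day`` (1-based)."""
    factors = spec.rain_stage_factors
    if len(factors) != len(spec.rain_stage_boundaries):
        raise ValueError("need one rain stage factor per boundary")
    for bound, factor in zip(spec.rain_stage_boundaries, factors):
        if day < bound:
            return factor
    return factors[-1]


def _draw_rain(rng: np.random.Generator, spec: SeasonSpec) -> np.ndarray:
    wet = np.zeros(spec.n_days, dtype=bool)
    state = rng.random() < spec.p_wet_after_dry
    for i in range(spec.n_days):
        wet[i] = state
        p = spec.p_wet_after_wet if state else spec.p_wet_after_dry
        state = rng.random() < min(p * _stage_factor(i + 1, spec), 0.95)
    amounts = np.zeros(spec.n_days)
    n_wet = int(wet.sum())
    if n_wet:
        amounts[wet] = rng.gamma(spec.rain_gamma_shape, spec.rain_gamma_scale, n_wet)
    return amounts


def synthesize_season(spec: SeasonSpec) -> pd.DataFrame:
    """Generate one growing season of daily weather, ET0 included.

    Rainfall is rescaled multiplicatively so the season total equals
    ``spec.target_rain_mm`` exactly (when the target is positive). If the
    occurrence chain draws zero wet days against a positive target, drawing
    is retried up to ``spec.max_rain_retries`` times before failing.
    """
    rng = np.random.default_rng(spec.seed)
    dates = pd.date_range(spec.planting_date, periods=spec.n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)

    rain = _draw_rain(rng, spec)
    if spec.target_rain_mm > 0:
        tries = 0
        while rain.sum() == 0.0:
            tries += 1
            if tries > spec.max_rain_retries:
                raise RuntimeError(
                    "no wet days drawn for a positive rainfall target "
                    f"after {spec.max_rain_retries} retries"
                )
            rain = _draw_rain(rng, spec)
        rain *= spec.target_rain_mm / rain.sum()
        # pin the sum exactly despite float rescaling
        rain[rain.argmax()] += spec.target_rain_mm - rain.sum()
    else:
        rain = np.zeros(spec.n_days)
    wet = rain > 0

    seasonal = np.cos(2 * np.pi * (doy - spec.peak_doy) / 365.0)
    tmax = (
        spec.tmax_mean - spec.tmax_amplitude * seasonal.mean()
        + spec.tmax_amplitude * seasonal
        + rng.uniform(-spec.temp_noise, spec.temp_noise, spec.n_days)
    )
    tmin = (
        spec.tmin_mean - spec.tmin_amplitude * seasonal.mean()
        + spec.tmin_amplitude * seasonal
        + rng.uniform(-spec.temp_noise, spec.temp_noise, spec.n_days)
    )
    tmax = np.maximum(tmax, tmin + 2.0)  # keep a plausible diurnal range

    rhmax = np.clip(np.where(wet, 96.0, 88.0) + rng.uniform(-4, 4, spec.n_days), 40, 100)
    rhmin = np.clip(np.where(wet, 65.0, 48.0) + rng.uniform(-8, 8, spec.n_days), 5, 100)
    rhmin = np.minimum(rhmin, rhmax)

    ra = extraterrestrial_radiation(spec.latitude, doy)
    rso = (0.75 + 2e-5 * spec.elevation_m) * np.asarray(ra)
    cloud = np.where(wet, 0.40, 0.72) + rng.uniform(-0.08, 0.08, spec.n_days)
    srad = np.clip(rso * cloud, 1.0, rso)

    wind3 = np.clip(rng.gamma(4.0, spec.wind_mean_3m / 4.0, spec.n_days), 0.3, 10.0)
    wind2 = np.array([wind_to_2m(u, 3.0) for u in wind3])

    frame = pd.DataFrame(
        {
            "date": dates.date,
            "tmax_c": tmax,
            "tmin_c": tmin,
            "rain_mm": rain,
            "rhmax_pct": rhmax,
            "rhmin_pct": rhmin,
            "wind_ms": wind2,
            "srad_mj": srad,
        }
    )
    return add_et0(frame, spec.latitude, spec.elevation_m)


# ---------------------------------------------------------------------------
# file I/O: comma-delimited, one header row, ISO-8601 dates, '#' comments
# ---------------------------------------------------------------------------

def read_weather(path) -> pd.DataFrame:
    """Read a weather file, validating columns, dates and value ranges."""
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"weather file missing column(s): {', '.join(missing)}")
    dates = pd.to_datetime(frame["date"]).dt.date
    frame["date"] = dates
    deltas = pd.Series(dates).diff().dropna()
    if any(d != _dt.timedelta(days=1) for d in deltas):
        raise ValueError("non-contiguous dates in weather file")
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header = line 1
        if row.rain_mm < 0:
            raise ValueError(f"negative rainfall at row {i}")
        if row.tmax_c < row.tmin_c:
            raise ValueError(f"tmax < tmin at row {i}")
    return frame


def write_weather(path, series: pd.DataFrame, header_comments: tuple[str, ...] = ()) -> None:
    """Write a weather frame (6 significant digits; read/write round-trips)."""
    cols = [c for c in (*WEATHER_COLUMNS, "et0_mm") if c in series.columns]
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        series[cols].to_csv(fh, index=False, float_format="%.6g")
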