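# Methods

This note records the model equations as implemented, the default parameter
values with their rationale, what the synthetic-weather generator does and
does not emulate, and the design choices made where the design was genuinely
open.

## Reference evapotranspiration

`weather.compute_et0` implements the daily FAO-56 Penman–Monteith equation
for the standard grass reference:

ET₀ = [0.408·Δ·(Rn − G) + γ·(900/(T+273))·u₂·(es − ea)] / [Δ + γ·(1 + 0.34·u₂)]

with Δ the slope of the saturation-vapour-pressure curve at the daily mean
temperature, γ the psychrometric constant from station pressure (elevation
default 290 m), G = 0 at the daily step, es the mean of the saturation
pressures at Tmax and Tmin, and ea from RHmax/RHmin. Net radiation is
Rn = 0.77·Rs − Rnl with Rnl the standard longwave term; the cloudiness
factor 1.35·Rs/Rso − 0.35 is clipped to [0, 1] so that a dark day cannot
radiatively warm the daily budget, and ET₀ is clipped at zero. Station wind
measured at 3 m is converted to 2 m with u₂ = u_z·4.87/ln(67.8z − 5.42).

## Synthetic weather

The generator produces one growing season (default: planting 10 May,
135 days, latitude 43.35°) per `SeasonSpec`, bitwise-reproducibly from its
seed.

- **Rainfall**: a first-order two-state occurrence chain (P(wet|dry) = 0.30,
  P(wet|wet) = 0.55) with gamma-distributed wet-day amounts (shape 0.85,
  scale 7 mm). Wet-day odds are modulated by phenological window
  (×1.25 before/through emergence, ×0.55 in early tuber bulking, ×1.35 and
  ×1.2 in mid/late bulking, ×0.6 in senescence), reproducing the station
  climatology of a wet emergence period, a dry early-bulking stretch and
  rainy mid/late bulking. Amounts are rescaled multiplicatively so the
  season total equals the target exactly; the default target 284.5 mm is the
  long-term growing-season mean used for wet/normal/dry classification.
- **Temperature**: a day-of-year sinusoid peaking on DOY 220 (the late
  tuber-bulking window) with bounded ±2 °C uniform noise, the intercept set
  so the season means equal 25.7 °C (Tmax) and 12.9 °C (Tmin), the station's
  2014–2024 growing-season means; a 2 °C minimum diurnal range is enforced.
- **Humidity, radiation, wind**: bounded-noise values around wet/dry-day
  baselines; solar radiation is a clear-sky fraction (0.72 dry, 0.40 wet) of
  the elevation-corrected clear-sky envelope; wind is gamma-distributed
  around 2.7 m s⁻¹ at 3 m and converted to 2 m.

The generator emulates the *statistical* structure of one humid temperate
season — totals, means, spell structure, stage profile. It does not emulate
multi-day synoptic persistence in temperature, humidity–temperature
covariance, or any specific historical year, so tests passing on synthetic
decades show internal consistency of the pipeline under realistic forcing,
not agreement with the 2014–2024 station record (whose absolute yields and
soil-water magnitudes are out of scope).

## Soil water balance

The profile is discretised into 0.05 m compartments; hydraulic constants
come from a packaged, per-layer-overridable texture lookup — sandy loam
θ_sat/θ_fc/θ_wp = 0.41/0.22/0.10, loamy sand 0.38/0.16/0.08, air-dry =
θ_wp/2 — standard class values, since the field description gives texture
and bulk density but no water-retention constants (absolute soil-water
magnitudes are therefore not reproducible, only dynamics). The two packaged
profiles ("montcalm" sandy loam, "mecosta" loamy sand) carry the measured
per-layer bulk densities; the described 0–0.45 m profile is extended to
0.60 m with the same texture so it covers the 0.47 m maximum root depth.

Daily order of operations: infiltration (top-down to saturation, excess →
runoff — no curve-number runoff, as saturation excess is the only mechanism
parameterised), drainage (each compartment sheds τ = 0.5 of its above-FC
excess per day, cascading downward; bottom outflow → percolation), soil
evaporation (top 0.10 m, floored at air-dry; Kr = 1 above θ_wp, then linear
to 0 at air-dry — a two-stage model, since only the coefficient names are
given), transpiration. Capillary rise is zero (water table at 9.14 m).

Root water uptake uses the 40–30–20–10 pattern over root-zone quarters as a
*preference*: a quarter that cannot supply its share (typically a surface
layer dried below wilting point by evaporation) passes the shortfall to the
remaining root-zone water above wilting point, because roots draw from
depth; only a zone-wide shortage reduces realised transpiration. A hard
per-quarter cap was rejected: it strands demand behind a dry 5 cm surface
layer while deeper compartments sit at field capacity, and lets lumpy
surface doses out-perform a root zone held at field capacity — violating
the dominance property any water-limited production model should satisfy.

Mass closure — ΔW = rain + irrigation − runoff − E − Tr − drainage — is
checked every day; the worst daily error is carried in the season result
and stays at float-rounding level (~1e−13 mm), against a 1e−9 mm test bound.

## Crop engine

Thermal time is GDD = max(0, min((Tmax+Tmin)/2, 26) − 2) °C·d. The canopy
growth and decay coefficients are interpreted **per growing-degree-day**
(CGC = 0.018 GDD⁻¹, CDC = 0.80 % GDD⁻¹): the printed "per day" unit cannot
close the canopy within the observed phenology (emergence day 21, tuber
initiation day 43), whereas per-GDD closure lands 3–4 weeks after emergence.
Growth integrates dCC = CGC·CC (below CCₓ/2) then dCC = CGC·(CCₓ−CC)
exactly across each day, the daily increment scaled by the expansion-stress
coefficient. Calendar senescence (day 99) follows
CC = CC_sen·[1 − 0.05(e^((CDC/CC_sen)·τ) − 1)]; vine kill (day 112) forces
cover to zero within three days.

Water-stress senescence is continuous and recoverable: while depletion
exceeds the 0.69 threshold the canopy browns at (1 − Ks_sen)·CDC·GDD·(CC/CCₓ)
per day and may regrow through the normal expansion step once the root zone
rewets. A latched "5 bad days kill the crop" rule was rejected: it makes
rainfed crops collapse entirely while any policy that fires at all rescues
them completely, an all-or-nothing response with no support in the gradual
deficit-yield losses this class of model produces.

Stress enters three processes with the calibrated thresholds (expansion
0.26–0.66, stomata 0.65, senescence 0.69, shapes 3.0); stress is evaluated
from emergence onward — bare soil before emergence is not crop stress. Cold
stress and the harvest-index stress multiplier are fixed at 1 (no
parameters are given for them), keeping Y = fHI·HI₀·B exact and testable.
Roots deepen from 0.15 m at emergence (a conventional planting-depth value;
not otherwise specified) to 0.47 m at mid-bulking (day 71) along a
power-1.5 curve. Yield is tuber **dry matter**; a 20 % dry-matter fraction
is provided for converting to fresh-market magnitudes but all internal
comparisons stay on the model's own scale.

## Irrigation scheduling

The threshold trigger is the ratio of the thickness-weighted root-zone θ to
field capacity ("irrigate at X % FC"), evaluated after the day's rain has
infiltrated and before extraction, one event of 15.24 mm per day at most,
starting at emergence. With the class hydraulics above, θ_wp/θ_fc ≈ 0.5 for
both textures, so 20–40 % FC triggers are reachable only through surface
evaporation drying and those treatments behave like rainfed cropping — which
is precisely how they cluster in the trade-off analysis, and why the 50 % FC
control fires only a handful of events in a wet season (the field experiment
recorded 3). An alternative reading (fraction of plant-available water,
MAD-style) was implemented and rejected: it turns every threshold into an
active policy and erases that clustering. The `full` mode raises every
root-zone compartment to field capacity inside the balance step daily
(booked as irrigation) and serves as the non-limiting-water reference;
15.24 mm surface doses are not such a reference because they reach depth
only through the one-day-lagged drainage cascade. Fixed mode replicates the
field treatments (e.g. 3 × 16 mm = 48 mm for 50 % FC).

## Evaluation metrics and analyses

RMSE = √(Σ(M−P)²/N); MBE = Σ(P−M)/N (positive = overestimation);
IA = 1 − Σ(M−P)²/Σ(|P−M̄|+|M−M̄|)²; NSE = 1 − Σ(M−P)²/Σ(M−M̄)². IA and NSE
are reported as explicitly undefined for N = 1 or a constant measured series
rather than forced to a number — a single simulated-vs-observed yield pair
has RMSE and MBE but no defensible IA/NSE. Composite available water is
defined (the source plots it without defining it) as water above wilting
point summed over the monitored 0–15/15–30/30–45 cm intervals. Crop water
productivity is yield divided by TWU = 10·(rain + irrigation) m³ ha⁻¹.

Season classification: wet above mean·(1+band), dry below mean·(1−band),
normal between, with mean 284.5 mm and band 0.10; the conventionally
printed boundaries (312.9, 256) are the exact products truncated at one
decimal, and the classifier itself uses the exact products. Trade-off
tables compare group-mean yield and WPc per policy against the 50 % FC
control via LnRR, one point per treatment per group (all/wet/normal/dry);
an LnRR of exactly zero on an axis counts as the "win" half so the control
sits at the origin as win–win rather than as a loss. The stage-correlation
matrix is, per policy and developmental stage, the Pearson correlation
across years between the stage's irrigation total and the seasonal yield —
the correlated pair is an interpretation (the source names the axes but not
the variables); cells without variance (rainfed rows, never-irrigated
stages) are NaN, and at least three years are required.

## Problem sizes and determinism

The packaged synthetic decade is 11 years (4 wet / 4 normal / 3 dry fixed
rainfall targets between 210 and 355 mm); the scenario grid is 11 years ×
2 soils × 9 policies = 198 season runs, and the property suites use 20
seeded seasons and 100–1000 random series. These sizes make every
distributional claim in the tests a statement about seeded, reproducible
ensembles; all randomness flows from explicit integer seeds.

## Known limitations

- Absolute yields and soil-water contents are not calibrated to any field
  record; only relative responses across policies, soils and season classes
  are meaningful.
- Event counts respond to a real canopy–evaporation feedback (a stressed,
  smaller canopy dries the surface faster and can trigger 1–3 extra
  events), so per-season counts are only monotone in the threshold on
  average across seasons.
- No waterlogging or aeration stress: more water never directly harms the
  crop, only the water-productivity denominator.
- Phenology is prescribed by calendar, not predicted from temperature;
  CO₂, salinity, fertility and pest effects are out of scope.
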