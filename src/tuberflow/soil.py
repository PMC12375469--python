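"""Layered soil profile and the daily root-zone water balance.

The profile is discretised into thin compartments (default 0.05 m). Each
simulated day applies, in order: (1) infiltration of rain + irrigation,
filling compartments top-down to saturation with saturation excess leaving
as runoff; (2) drainage of every compartment above field capacity toward
field capacity at a daily fraction ``tau``, cascading downward with the
bottom outflow leaving as deep percolation; (3) soil evaporation extracted
from the surface evaporation layer down to an air-dry floor; (4) crop
transpiration extracted from the four root-zone quarters with the
40-30-20-10 weighting, floored at wilting point. Capillary rise is zero
(deep water table) and runoff is saturation excess only.

Every step closes its water ledger: the profile storage change equals
inflows minus outflows to well below 1e-9 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "WaterState",
    "DailyFluxes",
    "TEXTURE_CLASSES",
    "profile_from_texture",
    "root_zone_water",
    "step_water_balance",
]

#: Pedotransfer lookup by texture class: volumetric water contents (m3 m-3).
#: Standard class values; overridable per layer for calibration.
TEXTURE_CLASSES = {
    "sandy loam": {"theta_sat": 0.41, "theta_fc": 0.22, "theta_wp": 0.10},
    "loamy sand": {"theta_sat": 0.38, "theta_fc": 0.16, "theta_wp": 0.08},
}


@dataclass(frozen=True)
class SoilLayer:
    """One horizon: depth bounds (m), texture, and hydraulic constants."""

    top: float
    bottom: float
    texture: str
    bulk_density: float  # g cm-3
    theta_sat: float
    theta_fc: float
    theta_wp: float
    gravel_pct: float = 0.0  # volume %

    def __post_init__(self) -> None:
        if self.bottom <= self.top:
            raise ValueError("layer bottom must be below its top")
        if not 0.0 < self.theta_wp < self.theta_fc < self.theta_sat < 1.0:
            raise ValueError("need 0 < theta_wp < theta_fc < theta_sat < 1")
        if not 0.0 <= self.gravel_pct < 100.0:
            raise ValueError("gravel volume % must be in [0, 100)")

    @property
    def theta_air_dry(self) -> float:
        """Air-dry floor for surface evaporation (half of wilting point)."""
        return self.theta_wp / 2.0


@dataclass(frozen=True)
class SoilProfile:
    """Contiguous layers from the surface, discretised into compartments."""

    layers: tuple[SoilLayer, ...]
    dz: float = 0.05  # compartment thickness, m
    evaporation_depth: float = 0.10  # surface layer subject to E, m

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        if abs(self.layers[0].top) > 1e-12:
            raise ValueError("profile must start at the surface (top = 0)")
        for upper, lower in zip(self.layers, self.layers[1:]):
            if abs(upper.bottom - lower.top) > 1e-12:
                raise ValueError("layers must be contiguous")
        if self.dz <= 0:
            raise ValueError("compartment thickness must be positive")

    @property
    def depth(self) -> float:
        return self.layers[-1].bottom

    @property
    def n_compartments(self) -> int:
        return int(round(self.depth / self.dz))

    def compartment_bounds(self) -> np.ndarray:
        return np.linspace(0.0, self.n_compartments * self.dz, self.n_compartments + 1)

    def layer_at(self, depth: float) -> SoilLayer:
        for layer in self.layers:
            if depth < layer.bottom + 1e-12:
                return layer
        return self.layers[-1]

    def _per_compartment(self, attr: str) -> np.ndarray:
        mids = (self.compartment_bounds()[:-1] + self.compartment_bounds()[1:]) / 2
        return np.array([getattr(self.layer_at(m), attr) for m in mids])

    @property
    def theta_sat_c(self) -> np.ndarray:
        return self._per_compartment("theta_sat")

    @property
    def theta_fc_c(self) -> np.ndarray:
        return self._per_compartment("theta_fc")

    @property
    def theta_wp_c(self) -> np.ndarray:
        return self._per_compartment("theta_wp")

    @property
    def theta_air_dry_c(self) -> np.ndarray:
        return self._per_compartment("theta_air_dry")

    @property
    def gravel_c(self) -> np.ndarray:
        return self._per_compartment("gravel_pct")

    def initial_state(self, fraction_of_fc: float = 1.0) -> "WaterState":
        theta = np.clip(self.theta_fc_c * fraction_of_fc, 0.0, self.theta_sat_c)
        return WaterState(theta=theta, day=0)

    def overlap(self, z_top: float, z_bottom: float) -> np.ndarray:
        """Thickness (m) of each compartment inside [z_top, z_bottom]."""
        bounds = self.compartment_bounds()
        return np.clip(
            np.minimum(bounds[1:], z_bottom) - np.maximum(bounds[:-1], z_top), 0.0, None
        )


@dataclass
class WaterState:
    """Per-compartment volumetric water content on a given day."""

    theta: np.ndarray
    day: int = 0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.theta < 0) or np.any(self.theta > 1):
            raise ValueError("theta must lie in [0, 1]")

    def copy(self) -> "WaterState":
        return WaterState(theta=self.theta.copy(), day=self.day)

    def storage_mm(self, profile: SoilProfile) -> float:
        return float(np.sum(self.theta) * profile.dz * 1000.0)


@dataclass(frozen=True)
class DailyFluxes:
    """One day's water fluxes (mm); all non-negative, ET = E + Tr."""

    rain: float = 0.0
    irrigation: float = 0.0
    runoff: float = 0.0
    drainage: float = 0.0
    evaporation: float = 0.0
    transpiration: float = 0.0
    closure_error: float = 0.0  # |dW - (in - out)|, mm

    @property
    def et(self) -> float:
        return self.evaporation + self.transpiration


def profile_from_texture(rows, dz: float = 0.05, extend_to: float = 0.60) -> SoilProfile:
    """Build a profile from (top, bottom, texture, bulk density) records.

    Hydraulic constants come from the :data:`TEXTURE_CLASSES` pedotransfer
    lookup; a record may override them with explicit ``theta_*``/``gravel_pct``
    keys. The bottom layer is extended to ``extend_to`` so the profile covers
    the crop's maximum root depth.
    """
    layers = []
    for row in rows:
        row = dict(row)
        texture = row["texture"].strip().lower()
        if texture not in TEXTURE_CLASSES:
            raise ValueError(f"unknown texture class: {row['texture']!r}")
        hyd = dict(TEXTURE_CLASSES[texture])
        for key in ("theta_sat", "theta_fc", "theta_wp"):
            if key in row:
                hyd[key] = float(row[key])
        layers.append(
            SoilLayer(
                top=float(row["top"]),
                bottom=float(row["bottom"]),
                texture=texture,
                bulk_density=float(row["bulk_density"]),
                gravel_pct=float(row.get("gravel_pct", 0.0)),
                **hyd,
            )
        )
    if extend_to is not None and layers and layers[-1].bottom < extend_to:
        layers[-1] = replace(layers[-1], bottom=float(extend_to))
    return SoilProfile(layers=tuple(layers), dz=dz)


def mean_theta(state: WaterState, profile: SoilProfile, zr: float) -> float:
    """Thickness-weighted mean water content over [0, zr]."""
    if zr <= 0 or zr > profile.depth + 1e-9:
        raise ValueError("root depth must lie within the profile")
    w = profile.overlap(0.0, zr)
    return float(np.sum(state.theta * w) / np.sum(w))


def mean_field_capacity(profile: SoilProfile, zr: float) -> float:
    w = profile.overlap(0.0, zr)
    return float(np.sum(profile.theta_fc_c * w) / np.sum(w))


def mean_wilting_point(profile: SoilProfile, zr: float) -> float:
    w = profile.overlap(0.0, zr)
    return float(np.sum(profile.theta_wp_c * w) / np.sum(w))


def root_zone_water(state: WaterState, profile: SoilProfile, zr: float) -> float:
    """Root-zone stored water as an equivalent depth (mm).

    ``Wr = 1000 * theta_bar * zr * (1 - gravel% / 100)`` with the mean taken
    thickness-weighted over [0, zr] and the gravel correction applied per
    compartment.
    """
    if zr <= 0 or zr > profile.depth + 1e-9:
        raise ValueError("root depth must lie within the profile")
    w = profile.overlap(0.0, zr)
    return float(np.sum(1000.0 * state.theta * w * (1.0 - profile.gravel_c / 100.0)))


def step_water_balance(
    state: WaterState,
    profile: SoilProfile,
    rain_mm: float,
    irrigation_mm: float,
    e_demand_mm: float,
    tr_demand_mm: float,
    zr: float,
    extraction_weights: tuple[float, float, float, float] = (0.40, 0.30, 0.20, 0.10),
    tau: float = 0.5,
    refill_root_zone_to_fc: bool = False,
) -> tuple[WaterState, DailyFluxes]:
    """Advance the soil water state by one day; returns the realised fluxes.

    Evaporation and transpiration demands may go unmet when the respective
    stores hit their floors; the realised amounts are what the fluxes report.
    With ``refill_root_zone_to_fc`` every root-zone compartment is raised to
    field capacity after infiltration and drainage (the idealised
    non-limiting-water reference treatment); the added depth is booked as
    irrigation.
    """
    if min(rain_mm, irrigation_mm, e_demand_mm, tr_demand_mm) < 0:
        raise ValueError("water inputs and demands must be >= 0")
    if abs(sum(extraction_weights) - 1.0) > 1e-9:
        raise ValueError("extraction weights must sum to 1")
    if not 0.0 <= tau <= 1.0:
        raise ValueError("drainage fraction tau must be in [0, 1]")

    dz_mm = profile.dz * 1000.0
    w = state.theta * dz_mm  # per-compartment storage, mm
    w_sat = profile.theta_sat_c * dz_mm
    w_fc = profile.theta_fc_c * dz_mm
    w0 = float(w.sum())

    # (1) infiltration, top-down to saturation; excess is runoff
    remaining = rain_mm + irrigation_mm
    for i in range(w.size):
        take = min(remaining, w_sat[i] - w[i])
        if take > 0:
            w[i] += take
            remaining -= take
        if remaining <= 0:
            break
    runoff = max(remaining, 0.0)

    # (2) drainage cascade: each compartment sheds tau of its above-FC excess
    carry = 0.0
    for i in range(w.size):
        absorb = min(carry, w_sat[i] - w[i])
        w[i] += absorb
        passthrough = carry - absorb
        out = tau * max(w[i] - w_fc[i], 0.0)
        w[i] -= out
        carry = out + passthrough
    drainage = carry

    # (2b) optional idealised refill of the root zone to field capacity
    irrigation_total = irrigation_mm
    if refill_root_zone_to_fc and zr > 0:
        rz = profile.overlap(0.0, zr)
        for i in range(w.size):
            if rz[i] <= 0:
                continue
            add = max(w_fc[i] - w[i], 0.0) * rz[i] / profile.dz
            w[i] += add
            irrigation_total += add

    # (3) evaporation from the surface layer, floored at air-dry
    e_real = 0.0
    if e_demand_mm > 0:
        need = e_demand_mm
        ev = profile.overlap(0.0, profile.evaporation_depth)
        floors = profile.theta_air_dry_c * dz_mm
        for i in range(w.size):
            if ev[i] <= 0 or need <= 0:
                continue
            frac = ev[i] / profile.dz
            avail = max(w[i] - floors[i], 0.0) * frac
            take = min(need, avail)
            w[i] -= take
            need -= take
            e_real += take

    # (4) transpiration from root-zone quarters, 40-30-20-10, floored at WP.
    # The pattern is a preference, not a hard cap: a quarter that cannot
    # supply its share (e.g. a surface layer dried by evaporation) passes the
    # shortfall to wherever root-zone water remains above wilting point, as
    # roots draw from depth; only a zone-wide shortage reduces realised Tr.
    tr_real = 0.0
    if tr_demand_mm > 0 and zr > 0:
        floors = profile.theta_wp_c * dz_mm
        quarter = zr / 4.0
        unmet = 0.0
        for q, weight in enumerate(extraction_weights):
            need = weight * tr_demand_mm
            ov = profile.overlap(q * quarter, (q + 1) * quarter)
            for i in range(w.size):
                if ov[i] <= 0 or need <= 0:
                    continue
                frac = ov[i] / profile.dz
                avail = max(w[i] - floors[i], 0.0) * frac
                take = min(need, avail)
                w[i] -= take
                need -= take
                tr_real += take
            unmet += need
        if unmet > 0:
            rz = profile.overlap(0.0, zr)
            for i in range(w.size):
                if rz[i] <= 0 or unmet <= 0:
                    continue
                frac = rz[i] / profile.dz
                avail = max(w[i] - floors[i], 0.0) * frac
                take = min(unmet, avail)
                w[i] -= take
                unmet -= take
                tr_real += take

    dw = float(w.sum()) - w0
    closure = abs(dw - (rain_mm + irrigation_total - runoff - drainage - e_real - tr_real))
    fluxes = DailyFluxes(
        rain=rain_mm,
        irrigation=irrigation_total,
        runoff=runoff,
        drainage=drainage,
        evaporation=e_real,
        transpiration=tr_real,
        closure_error=closure,
    )
    new_state = WaterState(theta=w / dz_mm, day=state.day + 1)
    return new_state, fluxes
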