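"""Model-evaluation statistics and crop water productivity.

RMSE and MBE carry the units of the compared variable; the index of
agreement (IA) and the Nash-Sutcliffe efficiency (NSE) are dimensionless and
bounded above by 1. Both IA and NSE divide by the spread of the measured
series, so they are reported as explicitly undefined (``None`` plus a
reason) for a single pair or a constant measured series rather than being
forced to a number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .soil import SoilProfile, WaterState

__all__ = [
    "MetricSet",
    "WaterProductivity",
    "compute_metrics",
    "crop_water_productivity",
    "composite_available_water",
]


@dataclass(frozen=True)
class MetricSet:
    """RMSE, MBE, IA and NSE for one measured/predicted series pair."""

    rmse: float
    mbe: float
    ia: float | None
    nse: float | None
    n: int
    undefined_reason: str | None = None

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mbe": self.mbe,
            "ia": self.ia,
            "nse": self.nse,
            "n": self.n,
        }


@dataclass(frozen=True)
class WaterProductivity:
    """Yield per unit of total water used."""

    yield_kg_ha: float
    twu_m3_ha: float  # total water used
    wpc_kg_m3: float  # crop water productivity


def compute_metrics(measured, predicted) -> MetricSet:
    """Evaluate predictions against measurements.

    RMSE = sqrt(mean((M-P)^2)); MBE = mean(P-M) (positive = overestimation);
    IA = 1 - sum((M-P)^2) / sum((|P-Mbar| + |M-Mbar|)^2);
    NSE = 1 - sum((M-P)^2) / sum((M-Mbar)^2).
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ValueError("measured and predicted series must have equal length")
    n = m.size
    if n == 0:
        raise ValueError("need at least one paired sample")
    sq = float(np.sum((m - p) ** 2))
    rmse = float(np.sqrt(sq / n))
    mbe = float(np.mean(p - m))
    mbar = float(np.mean(m))
    ia: float | None
    nse: float | None
    reason = None
    denom_nse = float(np.sum((m - mbar) ** 2))
    if denom_nse == 0.0:
        ia = nse = None
        reason = (
            "single pair" if n == 1 else "constant measured series"
        ) + ": IA/NSE denominators vanish"
    else:
        nse = 1.0 - sq / denom_nse
        denom_ia = float(np.sum((np.abs(p - mbar) + np.abs(m - mbar)) ** 2))
        ia = 1.0 - sq / denom_ia if denom_ia > 0 else None
    return MetricSet(rmse=rmse, mbe=mbe, ia=ia, nse=nse, n=n, undefined_reason=reason)


def crop_water_productivity(
    yield_kg_ha: float, rain_mm: float, irrigation_mm: float
) -> WaterProductivity:
    """WPc = yield / TWU, with TWU = (rain + irrigation) in m3 ha-1.

    1 mm of water over a hectare is 10 m3, so TWU = 10 * (rain + irrigation).
    """
    total_mm = rain_mm + irrigation_mm
    if total_mm <= 0:
        raise ValueError("total water used must be positive")
    if yield_kg_ha < 0:
        raise ValueError("yield must be >= 0")
    twu = total_mm * 10.0
    return WaterProductivity(
        yield_kg_ha=yield_kg_ha, twu_m3_ha=twu, wpc_kg_m3=yield_kg_ha / twu
    )


def composite_available_water(
    state: WaterState,
    profile: SoilProfile,
    intervals: tuple[tuple[float, float], ...] = ((0.0, 0.15), (0.15, 0.30), (0.30, 0.45)),
) -> float:
    """Plant-available water (mm) summed over monitored depth intervals.

    CAW = sum over intervals of 1000 * max(0, theta - theta_wp) * thickness,
    i.e. the water held above wilting point where the sensors sit.
    """
    total = 0.0
    for top, bottom in intervals:
        if top < -1e-12 or bottom > profile.depth + 1e-9 or bottom <= top:
            raise ValueError(f"interval ({top}, {bottom}) outside the profile")
        ov = profile.overlap(top, bottom)
        total += float(
            np.sum(1000.0 * np.maximum(state.theta - profile.theta_wp_c, 0.0) * ov)
        )
    return total
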