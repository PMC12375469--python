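"""Irrigation scheduling: field-capacity-threshold, fixed-schedule, rainfed.

The threshold rule mirrors sensor-based scheduling against field capacity:
an event of fixed depth (15.24 mm by default) is applied whenever the
thickness-weighted root-zone water content falls below the threshold
fraction of field capacity (``theta_bar < threshold * theta_fc``).
Thresholds at or below the wilting-point-to-FC ratio are only reachable
through surface evaporation drying, so the low end of the 20-90% range
behaves like rainfed cropping, which is exactly how those treatments
cluster in the scenario analysis. Events respect a minimum spacing and a
start day, and the trigger is evaluated after the day's rain has
infiltrated and before crop extraction, so a rain day that restores the
root zone suppresses the event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .soil import SoilProfile, WaterState, mean_field_capacity, mean_theta

__all__ = ["IrrigationPolicy", "IrrigationLog", "decide_irrigation", "summarize_log"]


@dataclass(frozen=True)
class IrrigationPolicy:
    """Scheduling rule: one of ``threshold``, ``fixed`` or ``rainfed``."""

    mode: str = "threshold"  # threshold | fixed | rainfed | full
    threshold: float = 0.50  # trigger as a fraction of field capacity
    dose_mm: float = 15.24  # depth per event
    min_interval_days: int = 1
    start_dap: int | None = None  # default: crop emergence
    schedule: tuple[tuple[int, float], ...] = ()  # fixed mode: (DAP, mm)

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "fixed", "rainfed", "full"):
            raise ValueError(f"invalid irrigation mode: {self.mode!r}")
        if self.mode == "threshold" and not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be a fraction in (0, 1)")
        if self.dose_mm <= 0:
            raise ValueError("dose must be positive")
        if self.min_interval_days < 1:
            raise ValueError("minimum interval must be >= 1 day")

    @property
    def label(self) -> str:
        if self.mode in ("rainfed", "fixed", "full"):
            return self.mode
        return f"{round(self.threshold * 100)}% FC"


@dataclass
class IrrigationLog:
    """Realised irrigation events of one season."""

    events: list[tuple[int, float]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.events)

    @property
    def total(self) -> float:
        return sum(depth for _, depth in self.events)

    @property
    def last_day(self) -> int | None:
        return self.events[-1][0] if self.events else None

    def add(self, day: int, depth_mm: float) -> None:
        self.events.append((day, depth_mm))

    def total_in_window(self, start_dap: int, end_dap: int) -> float:
        """Depth applied in the half-open DAP window [start, end)."""
        return sum(d for dap, d in self.events if start_dap <= dap < end_dap)


def decide_irrigation(
    state: WaterState,
    profile: SoilProfile,
    zr: float,
    policy: IrrigationPolicy,
    day: int,
    log: IrrigationLog,
    emergence_dap: int = 21,
) -> float:
    """Depth to apply today (mm): the policy dose or zero.

    ``state`` should reflect the root zone after today's rain infiltration.
    """
    if policy.mode == "rainfed":
        return 0.0
    if policy.mode == "fixed":
        return sum(depth for dap, depth in policy.schedule if dap == day)

    start = policy.start_dap if policy.start_dap is not None else emergence_dap
    if day < start:
        return 0.0
    if policy.mode == "full":
        # refill the root zone to field capacity: demand is fully met daily
        ov = profile.overlap(0.0, zr)
        deficit = float(
            np.sum(np.maximum(profile.theta_fc_c - state.theta, 0.0) * ov * 1000.0)
        )
        return deficit if deficit > 1e-12 else 0.0
    last = log.last_day
    if last is not None and day - last < policy.min_interval_days:
        return 0.0
    theta_bar = mean_theta(state, profile, zr)
    if theta_bar < policy.threshold * mean_field_capacity(profile, zr):
        return policy.dose_mm
    return 0.0


def summarize_log(log: IrrigationLog) -> tuple[int, float]:
    """(number of events, total depth in mm)."""
    return log.count, log.total
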