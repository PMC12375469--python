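"""Packaged fixtures: soils, crop parameters, calendar and a season spec.

Fixtures are small YAML files shipped inside the package; ``load_fixture``
returns a typed object and ``serialize_fixture`` regenerates the packaged
text, so loading and re-serialising round-trips exactly.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import asdict
from importlib import resources

import yaml

from .crop import CropCalendar, CropParams
from .soil import SoilProfile, profile_from_texture
from .weather import SeasonSpec

__all__ = ["FIXTURE_NAMES", "load_fixture", "serialize_fixture", "fixture_text"]

FIXTURE_NAMES = ("montcalm", "mecosta", "potato_2023", "calendar_2023", "season_2023like")

_CALENDAR_KEYS = (
    "emergence", "tuber_initiation", "early_bulk", "mid_bulk",
    "late_bulk", "senescence_onset", "vine_kill", "harvest",
)


def fixture_text(name: str) -> str:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture: {name!r} (have {', '.join(FIXTURE_NAMES)})")
    return (resources.files("tuberflow.data") / f"{name}.yaml").read_text()


def load_fixture(name: str):
    """Load a packaged fixture by name into its domain object."""
    doc = yaml.safe_load(fixture_text(name))
    kind = doc.get("kind")
    if kind == "soil_profile":
        return profile_from_texture(
            doc["layers"], dz=doc.get("dz", 0.05), extend_to=doc.get("extend_to", 0.60)
        )
    if kind == "crop_params":
        fields = {k: v for k, v in doc.items() if k not in ("kind", "name")}
        if "extraction_pattern" in fields:
            fields["extraction_pattern"] = tuple(fields["extraction_pattern"])
        return CropParams(**fields)
    if kind == "crop_calendar":
        return CropCalendar(**{k: doc[k] for k in _CALENDAR_KEYS})
    if kind == "season_spec":
        fields = {k: v for k, v in doc.items() if k not in ("kind", "name")}
        if isinstance(fields.get("planting_date"), str):
            fields["planting_date"] = _dt.date.fromisoformat(fields["planting_date"])
        return SeasonSpec(**fields)
    raise ValueError(f"fixture {name!r} has unknown kind {kind!r}")


def _soil_doc(name: str, profile: SoilProfile) -> dict:
    raw = yaml.safe_load(fixture_text(name))  # keep site label and raw layer depths
    return raw


def serialize_fixture(name: str, obj) -> str:
    """Serialise a fixture object back to the packaged YAML text."""
    if isinstance(obj, SoilProfile):
        doc = _soil_doc(name, obj)
    elif isinstance(obj, CropParams):
        doc = {"kind": "crop_params", "name": name}
        d = asdict(obj)
        d["extraction_pattern"] = list(d["extraction_pattern"])
        for drop in ("sen_trigger_days", "dry_matter_fraction"):
            d.pop(drop, None)
        doc.update(d)
    elif isinstance(obj, CropCalendar):
        doc = {"kind": "crop_calendar", "name": name}
        doc.update({k: getattr(obj, k) for k in _CALENDAR_KEYS})
    elif isinstance(obj, SeasonSpec):
        doc = {"kind": "season_spec", "name": name}
        doc.update(
            {
                "planting_date": obj.planting_date,
                "n_days": obj.n_days,
                "latitude": obj.latitude,
                "elevation_m": obj.elevation_m,
                "target_rain_mm": obj.target_rain_mm,
                "seed": obj.seed,
            }
        )
    else:
        raise TypeError(f"cannot serialise fixture object of type {type(obj)!r}")
    return yaml.safe_dump(doc, sort_keys=False)
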