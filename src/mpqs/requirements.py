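"""Per-meal essential-amino-acid thresholds for a user profile.

Thresholds are absolute mg amounts per meal, obtained by multiplying a
requirement pattern (mg per kg body weight per meal, per EAA) by the user's
body weight.  The pattern ships as data, never hard-coded logic: requirement
values for optimal muscle protein synthesis are an active research area and
dietitians must be able to override them per client.

The default pattern splits the FAO/WHO/UNU (2007) adult daily EAA
requirements evenly over the three main meals.  The daily values, in
mg per kg body weight per day, are: his 10, ile 20, leu 39, lys 30,
SAA (Met+Cys) 15, AAA (Phe+Tyr) 25, thr 15, trp 4, val 26, alongside the
safe protein intake of 0.83 g/kg/day.  An even three-way split is a
documented stand-in; any per-slot weighting can be supplied as data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .config import Config, DEFAULT_CONFIG
from .food_db import EAAVector, FoodDataError, MG_ABSOLUTE

MEAL_SLOTS = ("breakfast", "lunch", "dinner")

#: FAO/WHO/UNU 2007 adult daily EAA requirements, mg per kg body weight per day.
_FAO_DAILY_MG_PER_KG = {
    "his": 10.0,
    "ile": 20.0,
    "leu": 39.0,
    "lys": 30.0,
    "saa": 15.0,
    "aaa": 25.0,
    "thr": 15.0,
    "trp": 4.0,
    "val": 26.0,
}

#: Safe level of protein intake for adults, g per kg body weight per day.
_FAO_PROTEIN_G_PER_KG_DAY = 0.83


class RequirementError(ValueError):
    """Raised for invalid profiles, patterns, or threshold edits."""


@dataclass(frozen=True)
class UserProfile:
    """Personal data determining requirement thresholds and food exclusions."""

    age: float
    sex: str
    body_weight: float  # kg
    custom_protein_requirement: Optional[float] = None  # g per kg per day
    exclusions: tuple[str, ...] = ()  # food codes or group tags to never suggest

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise RequirementError(f"body weight must be > 0 kg, got {self.body_weight}")
        if self.age < 0:
            raise RequirementError(f"age must be >= 0, got {self.age}")
        if self.custom_protein_requirement is not None and self.custom_protein_requirement <= 0:
            raise RequirementError("custom protein requirement must be > 0 g/kg/day")
        object.__setattr__(self, "exclusions", tuple(self.exclusions))

    @classmethod
    def from_json(cls, path: str | Path) -> "UserProfile":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            age=float(data["age"]),
            sex=str(data["sex"]),
            body_weight=float(data["body_weight"]),
            custom_protein_requirement=(
                float(data["custom_protein_requirement"])
                if data.get("custom_protein_requirement") is not None
                else None
            ),
            exclusions=tuple(data.get("exclusions", ())),
        )


@dataclass(frozen=True)
class RequirementPattern:
    """Per-kg, per-meal EAA requirements, optionally differing by meal slot.

    ``per_meal_mg_per_kg`` maps EAA name to mg/kg/meal applied to every slot;
    ``slot_overrides`` may replace the whole vector for individual slots.
    ``protein_g_per_kg_day`` is the reference protein requirement against
    which a user's custom requirement rescales the thresholds.
    """

    per_meal_mg_per_kg: Mapping[str, float]
    protein_g_per_kg_day: float = _FAO_PROTEIN_G_PER_KG_DAY
    slot_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        base = dict(self.per_meal_mg_per_kg)
        for eaa, value in base.items():
            if not math.isfinite(value) or value <= 0:
                raise RequirementError(f"pattern value for {eaa!r} must be > 0, got {value}")
        if self.protein_g_per_kg_day <= 0:
            raise RequirementError("pattern protein requirement must be > 0 g/kg/day")
        overrides = {slot: dict(vals) for slot, vals in self.slot_overrides.items()}
        for slot, vals in overrides.items():
            if slot not in MEAL_SLOTS:
                raise RequirementError(f"unknown meal slot {slot!r} in pattern")
            for eaa, value in vals.items():
                if value <= 0:
                    raise RequirementError(
                        f"pattern override for {eaa!r} at {slot!r} must be > 0"
                    )
        object.__setattr__(self, "per_meal_mg_per_kg", base)
        object.__setattr__(self, "slot_overrides", overrides)

    def for_slot(self, slot: str, eaa_list: Sequence[str]) -> dict[str, float]:
        if slot not in MEAL_SLOTS:
            raise RequirementError(f"unknown meal slot {slot!r}")
        values = dict(self.per_meal_mg_per_kg)
        values.update(self.slot_overrides.get(slot, {}))
        missing = [e for e in eaa_list if e not in values]
        if missing:
            raise RequirementError(f"pattern is missing required EAAs: {missing}")
        return {e: values[e] for e in eaa_list}

    @classmethod
    def from_file(cls, path: str | Path) -> "RequirementPattern":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(
            per_meal_mg_per_kg={k: float(v) for k, v in data["per_meal_mg_per_kg"].items()},
            protein_g_per_kg_day=float(
                data.get("protein_g_per_kg_day", _FAO_PROTEIN_G_PER_KG_DAY)
            ),
            slot_overrides={
                slot: {k: float(v) for k, v in vals.items()}
                for slot, vals in data.get("slot_overrides", {}).items()
            },
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_meal_mg_per_kg": dict(self.per_meal_mg_per_kg),
            "protein_g_per_kg_day": self.protein_g_per_kg_day,
            "slot_overrides": {s: dict(v) for s, v in self.slot_overrides.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def default_pattern() -> RequirementPattern:
    """FAO/WHO/UNU 2007 adult requirements split evenly over three meals."""
    return RequirementPattern(
        per_meal_mg_per_kg={e: v / 3.0 for e, v in _FAO_DAILY_MG_PER_KG.items()},
        protein_g_per_kg_day=_FAO_PROTEIN_G_PER_KG_DAY,
    )


@dataclass(frozen=True)
class EAAThresholds:
    """Absolute per-meal EAA requirements (mg) for one meal slot."""

    per_meal: EAAVector  # mg_absolute
    meal_slot: str

    def __post_init__(self) -> None:
        if self.meal_slot not in MEAL_SLOTS:
            raise RequirementError(f"unknown meal slot {self.meal_slot!r}")
        if self.per_meal.unit != MG_ABSOLUTE:
            raise RequirementError("thresholds must be absolute mg amounts")
        for eaa, value in self.per_meal.values.items():
            if value <= 0:
                raise RequirementError(f"threshold for {eaa!r} must be > 0, got {value}")

    def __getitem__(self, eaa: str) -> float:
        return self.per_meal[eaa]


def thresholds_for(
    profile: UserProfile,
    slot: str,
    pattern: Optional[RequirementPattern] = None,
    config: Config = DEFAULT_CONFIG,
) -> EAAThresholds:
    """Absolute per-meal thresholds: body weight x pattern, rescaled when the
    profile carries a custom protein requirement.

    The rescaling is proportional: custom requirement / pattern reference
    requirement, applied uniformly to every EAA.
    """
    pattern = pattern or default_pattern()
    per_kg = pattern.for_slot(slot, config.eaa_list)
    scale = 1.0
    if profile.custom_protein_requirement is not None:
        scale = profile.custom_protein_requirement / pattern.protein_g_per_kg_day
    values = {e: profile.body_weight * per_kg[e] * scale for e in config.eaa_list}
    return EAAThresholds(EAAVector(values, MG_ABSOLUTE), slot)


def override_thresholds(
    base: EAAThresholds, edits: Mapping[str, float]
) -> EAAThresholds:
    """Copy of ``base`` with selected per-EAA thresholds replaced.

    Edits must target configured EAAs and be strictly positive; untouched
    entries are carried over identically.
    """
    values = dict(base.per_meal.values)
    for eaa, value in edits.items():
        if eaa not in values:
            raise RequirementError(f"cannot override unknown EAA {eaa!r}")
        if value <= 0:
            raise RequirementError(f"override for {eaa!r} must be > 0, got {value}")
        values[eaa] = float(value)
    return EAAThresholds(EAAVector(values, MG_ABSOLUTE), base.meal_slot)
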