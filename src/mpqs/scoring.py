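"""Digestibility-corrected per-meal EAA intake and the Meal Protein Quality Score.

The MPQS expresses how fully a meal's digestible essential-amino-acid intake
meets per-meal thresholds, on a 0-100 scale anchored at both ends: 0 when at
least one EAA is completely absent from the meal, 100 when every EAA meets or
exceeds its threshold.  The default score is the capped limiting-ratio form

    MPQS = 100 * min_e min(1, intake_e / threshold_e)

which is the limiting-amino-acid convention of protein-quality scoring and
the simplest function satisfying both anchors.  A capped-mean variant
(100 * mean_e min(1, ratio_e)) is available behind configuration for
sensitivity analysis; it does not satisfy the zero anchor and is not the
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .config import Config, DEFAULT_CONFIG
from .food_db import EAAVector, FoodItem, FoodTable, MG_ABSOLUTE
from .requirements import EAAThresholds, MEAL_SLOTS, RequirementError


class ScoringError(ValueError):
    """Raised when a meal cannot be scored."""


class UnresolvedFoodsError(ScoringError):
    """A meal references foods missing from the table or lacking annotation.

    Carries the offending codes so callers can route them to the
    missing-product feedback flow instead of crashing.
    """

    def __init__(self, message: str, codes: Sequence[str]):
        super().__init__(f"{message}: {sorted(codes)}")
        self.codes = tuple(sorted(codes))


@dataclass(frozen=True)
class Portion:
    """An amount of one food in a meal."""

    code: str
    grams: float

    def __post_init__(self) -> None:
        if self.grams < 0:
            raise ScoringError(f"portion of {self.code!r} has negative grams: {self.grams}")


@dataclass(frozen=True)
class Meal:
    """Foods consumed at one meal slot."""

    slot: str
    portions: tuple[Portion, ...]

    def __post_init__(self) -> None:
        if self.slot not in MEAL_SLOTS:
            raise ScoringError(f"unknown meal slot {self.slot!r}")
        object.__setattr__(self, "portions", tuple(self.portions))

    @classmethod
    def from_pairs(cls, slot: str, pairs: Sequence[tuple[str, float]]) -> "Meal":
        return cls(slot, tuple(Portion(str(c), float(g)) for c, g in pairs))

    @classmethod
    def from_json(cls, path: str | Path) -> "Meal":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls.from_pairs(data["slot"], [(c, g) for c, g in data["portions"]])

    def to_dict(self) -> dict:
        return {"slot": self.slot, "portions": [[p.code, p.grams] for p in self.portions]}

    @property
    def total_grams(self) -> float:
        return sum(p.grams for p in self.portions)

    def with_portion_replaced(self, target_code: str, new_code: str) -> "Meal":
        """Same meal with one food swapped at identical grams."""
        portions = tuple(
            Portion(new_code, p.grams) if p.code == target_code else p for p in self.portions
        )
        return Meal(self.slot, portions)

    def with_added(self, code: str, grams: float) -> "Meal":
        return Meal(self.slot, self.portions + (Portion(code, grams),))

    def with_grams(self, grams_by_code: Mapping[str, float]) -> "Meal":
        portions = tuple(
            Portion(p.code, grams_by_code.get(p.code, p.grams)) for p in self.portions
        )
        return Meal(self.slot, portions)


@dataclass(frozen=True)
class DayIntake:
    """All meals of one day, at most one per slot."""

    meals: tuple[Meal, ...]

    def __post_init__(self) -> None:
        slots = [m.slot for m in self.meals]
        if len(set(slots)) != len(slots):
            raise ScoringError(f"duplicate meal slots in day: {slots}")
        object.__setattr__(self, "meals", tuple(self.meals))

    @classmethod
    def from_json(cls, path: str | Path) -> "DayIntake":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            tuple(
                Meal.from_pairs(m["slot"], [(c, g) for c, g in m["portions"]])
                for m in data["meals"]
            )
        )


@dataclass(frozen=True)
class PerEAABreakdown:
    intake_mg: float
    threshold_mg: float
    ratio: float


@dataclass(frozen=True)
class MealScore:
    """MPQS with its per-EAA breakdown, suitable for radar-chart rendering."""

    mpqs: float
    per_eaa: Mapping[str, PerEAABreakdown]
    limiting_eaa: Optional[str]
    slot: str

    def to_dict(self) -> dict:
        return {
            "slot": self.slot,
            "mpqs": self.mpqs,
            "limiting_eaa": self.limiting_eaa,
            "per_eaa": {
                e: {
                    "intake_mg": b.intake_mg,
                    "threshold_mg": b.threshold_mg,
                    "ratio": b.ratio,
                }
                for e, b in self.per_eaa.items()
            },
        }


def per_gram_contribution(item: FoodItem, config: Config = DEFAULT_CONFIG) -> dict[str, float]:
    """Digestible mg of each EAA contributed by one gram of the food.

    contribution_e = (protein g / g food) x (aa mg / g protein) x digestibility.
    Shared by intake computation and every alternative algorithm so that
    predicted and recomputed scores agree bit-for-bit.
    """
    if item.aa_profile is None or item.digestibility is None:
        raise UnresolvedFoodsError("food lacks amino-acid annotation", [item.code])
    factor = (item.protein / 100.0) * item.digestibility
    return {e: factor * item.aa_profile[e] for e in config.eaa_list}


def digestible_eaa_intake(
    meal: Meal, table: FoodTable, config: Config = DEFAULT_CONFIG
) -> EAAVector:
    """Total digestibility-corrected EAA intake of a meal, in absolute mg.

    intake_e = sum over portions of grams x (protein/100) x profile_e x
    digestibility.  Portions referencing unknown or unannotated foods abort
    scoring with the full list of offending codes.
    """
    missing = [p.code for p in meal.portions if p.code not in table]
    if missing:
        raise UnresolvedFoodsError("meal references unknown food codes", missing)
    unannotated = [p.code for p in meal.portions if not table[p.code].is_scoreable]
    if unannotated:
        raise UnresolvedFoodsError(
            "meal references foods without amino-acid annotation", unannotated
        )
    totals = {e: 0.0 for e in config.eaa_list}
    for portion in meal.portions:
        contrib = per_gram_contribution(table[portion.code], config)
        for e in config.eaa_list:
            totals[e] += portion.grams * contrib[e]
    return EAAVector(totals, MG_ABSOLUTE)


def mpqs_score(
    intake: EAAVector,
    thresholds: EAAThresholds,
    config: Config = DEFAULT_CONFIG,
) -> MealScore:
    """Score a digestible EAA intake vector against per-meal thresholds.

    The limiting EAA is the one with the smallest intake/threshold ratio
    (ties broken by configured EAA order); it is ``None`` when every ratio
    reaches 1, i.e. at a score of 100 under the default variant.
    """
    if intake.unit != MG_ABSOLUTE:
        raise ScoringError(f"intake must be absolute mg, got unit {intake.unit}")
    intake.validate_keys(config.eaa_list)
    per_eaa: dict[str, PerEAABreakdown] = {}
    capped: list[float] = []
    limiting: Optional[str] = None
    min_ratio = float("inf")
    for e in config.eaa_list:
        t = thresholds[e]
        if t <= 0:
            raise ScoringError(f"threshold for {e!r} must be > 0")
        ratio = intake[e] / t
        per_eaa[e] = PerEAABreakdown(intake_mg=intake[e], threshold_mg=t, ratio=ratio)
        capped.append(min(1.0, ratio))
        if ratio < min_ratio:
            min_ratio = ratio
            limiting = e
    if config.score_variant == "limiting":
        score = 100.0 * min(capped)
    else:
        score = 100.0 * sum(capped) / len(capped)
    if min_ratio >= 1.0:
        limiting = None
    return MealScore(mpqs=score, per_eaa=per_eaa, limiting_eaa=limiting, slot=thresholds.meal_slot)


def score_meal(
    meal: Meal,
    table: FoodTable,
    thresholds: EAAThresholds,
    config: Config = DEFAULT_CONFIG,
) -> MealScore:
    """Convenience: digestible intake then MPQS in one call."""
    if meal.slot != thresholds.meal_slot:
        raise ScoringError(
            f"meal slot {meal.slot!r} does not match thresholds slot {thresholds.meal_slot!r}"
        )
    return mpqs_score(digestible_eaa_intake(meal, table, config), thresholds, config)


@dataclass(frozen=True)
class DaySummary:
    """Per-meal scores plus the whole-day aggregate."""

    meal_scores: Mapping[str, MealScore]  # keyed by slot
    aggregate: float
    aggregate_kind: str

    def to_dict(self) -> dict:
        return {
            "aggregate_mpqs": self.aggregate,
            "aggregate_kind": self.aggregate_kind,
            "meals": {slot: score.to_dict() for slot, score in self.meal_scores.items()},
        }


def day_summary(
    day: DayIntake,
    table: FoodTable,
    thresholds_by_slot: Mapping[str, EAAThresholds],
    config: Config = DEFAULT_CONFIG,
) -> DaySummary:
    """Score each meal of the day and aggregate (mean by default, min optionally)."""
    if not day.meals:
        raise ScoringError("day contains no meals")
    scores: dict[str, MealScore] = {}
    for meal in day.meals:
        if meal.slot not in thresholds_by_slot:
            raise RequirementError(f"no thresholds supplied for slot {meal.slot!r}")
        scores[meal.slot] = score_meal(meal, table, thresholds_by_slot[meal.slot], config)
    values = [s.mpqs for s in scores.values()]
    if config.day_aggregate == "mean":
        aggregate = sum(values) / len(values)
    else:
        aggregate = min(values)
    return DaySummary(meal_scores=scores, aggregate=aggregate, aggregate_kind=config.day_aggregate)
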