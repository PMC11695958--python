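"""Synthetic food tables, meals and demo bundles.

Real national food-composition databases are licensing-bound, so every part
of the package is exercised against generated tables instead.  The default
group templates encode the protein-complementarity structure the improvement
algorithms rely on: cereals are lysine-poor, legumes are poor in the sulfur
amino acids, dairy and fish are well balanced, vegetables are low-protein.
Per-food amino-acid amounts get multiplicative lognormal noise around the
template mean (a given coefficient of variation), which keeps amounts
positive without truncation artifacts.  Generated items carry profile and
digestibility directly (provenance ``native``) and clear the 1 EN%
annotation filter by construction.

The templates emulate the *structure* of a real table at toy scale, not its
statistical distributions.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .config import Config, DEFAULT_CONFIG
from .food_db import (
    EAAVector,
    FoodItem,
    FoodTable,
    MG_PER_G_PROTEIN,
    write_food_table,
)
from .requirements import UserProfile, default_pattern, thresholds_for
from .scoring import Meal, digestible_eaa_intake, mpqs_score


class FixtureError(ValueError):
    """Raised when a requested fixture cannot be constructed."""


@dataclass(frozen=True)
class GroupTemplate:
    """Generative template for one food group."""

    food_group: str
    mean_profile: EAAVector  # mg per g protein
    noise_cv: float
    digestibility_range: tuple[float, float]
    protein_range: tuple[float, float]  # g per 100 g
    energy_range: tuple[float, float]   # kcal per 100 g

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise FixtureError("noise_cv must be >= 0")
        for lo, hi, what in (
            (*self.digestibility_range, "digestibility_range"),
            (*self.protein_range, "protein_range"),
            (*self.energy_range, "energy_range"),
        ):
            if lo > hi:
                raise FixtureError(f"{what} is not ordered: ({lo}, {hi})")
        if not (0 <= self.digestibility_range[0] and self.digestibility_range[1] <= 1):
            raise FixtureError("digestibility_range must lie within [0, 1]")
        if self.mean_profile.unit != MG_PER_G_PROTEIN:
            raise FixtureError("template profiles must be in mg per g protein")


def _profile(values: dict[str, float]) -> EAAVector:
    return EAAVector(values, MG_PER_G_PROTEIN)


def default_templates() -> list[GroupTemplate]:
    """Four groups with group-typical EAA patterns (mg per g protein).

    Values are in the range of published composition data for wheat-based
    cereals, pulses, dairy and mixed vegetables; exactness is not the point —
    the lysine/sulfur-amino-acid complementarity between cereals and legumes
    is.
    """
    return [
        GroupTemplate(
            food_group="cereals",
            mean_profile=_profile({
                "his": 23.0, "ile": 35.0, "leu": 68.0, "lys": 26.0, "saa": 39.0,
                "aaa": 78.0, "thr": 29.0, "trp": 12.0, "val": 44.0,
            }),
            noise_cv=0.12,
            digestibility_range=(0.80, 0.90),
            protein_range=(8.0, 14.0),
            energy_range=(300.0, 380.0),
        ),
        GroupTemplate(
            food_group="legumes",
            mean_profile=_profile({
                "his": 28.0, "ile": 45.0, "leu": 76.0, "lys": 66.0, "saa": 20.0,
                "aaa": 83.0, "thr": 39.0, "trp": 10.0, "val": 47.0,
            }),
            noise_cv=0.12,
            digestibility_range=(0.70, 0.85),
            protein_range=(7.0, 24.0),
            energy_range=(90.0, 350.0),
        ),
        GroupTemplate(
            food_group="dairy",
            mean_profile=_profile({
                "his": 28.0, "ile": 50.0, "leu": 95.0, "lys": 78.0, "saa": 33.0,
                "aaa": 100.0, "thr": 44.0, "trp": 14.0, "val": 62.0,
            }),
            noise_cv=0.08,
            digestibility_range=(0.90, 0.98),
            protein_range=(3.0, 25.0),
            energy_range=(45.0, 350.0),
        ),
        GroupTemplate(
            food_group="vegetables",
            mean_profile=_profile({
                "his": 21.0, "ile": 40.0, "leu": 60.0, "lys": 52.0, "saa": 28.0,
                "aaa": 70.0, "thr": 38.0, "trp": 11.0, "val": 49.0,
            }),
            noise_cv=0.15,
            digestibility_range=(0.65, 0.80),
            protein_range=(1.5, 4.0),
            energy_range=(20.0, 60.0),
        ),
    ]


def generate_food_table(
    n_per_group: int,
    templates: Optional[Sequence[GroupTemplate]] = None,
    seed: int = 0,
    config: Config = DEFAULT_CONFIG,
) -> FoodTable:
    """Deterministically generate ``n_per_group`` annotated foods per template."""
    if templates is None:
        templates = default_templates()
    if not templates:
        raise FixtureError("template list must not be empty")
    if n_per_group < 1:
        raise FixtureError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    items: list[FoodItem] = []
    code = 1000
    for template in templates:
        template.mean_profile.validate_keys(config.eaa_list)
        # lognormal multiplier with unit mean and the template's CV
        sigma = math.sqrt(math.log(1.0 + template.noise_cv**2))
        for i in range(n_per_group):
            protein = float(rng.uniform(*template.protein_range))
            energy = float(rng.uniform(*template.energy_range))
            # guarantee the item clears the annotation filter
            max_energy_for_en = 100.0 * protein * config.protein_energy_factor / max(
                config.en_threshold, 1e-9
            )
            energy = min(energy, max_energy_for_en)
            digestibility = float(rng.uniform(*template.digestibility_range))
            noise = np.exp(rng.normal(0.0, sigma, size=len(config.eaa_list)) - sigma**2 / 2.0)
            values = {
                e: float(template.mean_profile[e] * noise[j])
                for j, e in enumerate(config.eaa_list)
            }
            items.append(
                FoodItem(
                    code=str(code),
                    name=f"{template.food_group} item {i + 1}",
                    food_group=template.food_group,
                    protein=protein,
                    energy=energy,
                    aa_profile=EAAVector(values, MG_PER_G_PROTEIN),
                    digestibility=digestibility,
                    provenance="native",
                )
            )
            code += 1
    return FoodTable.from_items(items, source="fixtures", seed=seed)


DEFAULT_PROFILE = UserProfile(age=72, sex="female", body_weight=75.0)


def default_thresholds(slot: str = "lunch", config: Config = DEFAULT_CONFIG):
    """Per-meal thresholds for the default 75 kg fixture profile."""
    return thresholds_for(DEFAULT_PROFILE, slot, default_pattern(), config)


def _poor_groups(
    target_eaa: str,
    templates: Sequence[GroupTemplate],
    relative_cutoff: float = 0.75,
) -> list[str]:
    """Groups whose template is markedly poor in the target EAA: below
    ``relative_cutoff`` x the median across templates."""
    levels = sorted(t.mean_profile[target_eaa] for t in templates)
    median = levels[len(levels) // 2] if len(levels) % 2 else (
        0.5 * (levels[len(levels) // 2 - 1] + levels[len(levels) // 2])
    )
    return [
        t.food_group
        for t in templates
        if t.mean_profile[target_eaa] < relative_cutoff * median
    ]


def generate_deficient_meal(
    table: FoodTable,
    target_eaa: str,
    seed: int = 0,
    slot: str = "lunch",
    templates: Optional[Sequence[GroupTemplate]] = None,
    config: Config = DEFAULT_CONFIG,
    target_ratio: float = 0.6,
    max_tries: int = 200,
) -> Meal:
    """A meal whose limiting EAA is ``target_eaa`` with a score below 100.

    Draws 2-3 foods from groups poor in the target EAA, then rescales the
    gram amounts so the limiting ratio sits at ``target_ratio`` of the
    default fixture thresholds.  Which EAA is limiting depends only on the
    meal's composition, not its size, so the rescaling never changes it.
    """
    if target_eaa not in config.eaa_list:
        raise FixtureError(f"unknown EAA {target_eaa!r}")
    templates = list(templates) if templates is not None else default_templates()
    poor = _poor_groups(target_eaa, templates)
    if not poor:
        raise FixtureError(f"no fixture group is poor in {target_eaa!r}")
    pool = [item for item in table if item.food_group in poor and item.is_scoreable]
    if not pool:
        raise FixtureError(f"table has no annotated items from groups poor in {target_eaa!r}")
    rng = np.random.default_rng(seed)
    thresholds = default_thresholds(slot, config)
    for _ in range(max_tries):
        n = int(rng.integers(2, 4))
        chosen = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
        portions = [(pool[int(i)].code, float(rng.uniform(40.0, 150.0))) for i in chosen]
        meal = Meal.from_pairs(slot, portions)
        intake = digestible_eaa_intake(meal, table, config)
        score = mpqs_score(intake, thresholds, config)
        if score.limiting_eaa != target_eaa:
            continue
        ratio = intake[target_eaa] / thresholds[target_eaa]
        if ratio <= 0:
            continue
        factor = target_ratio / ratio
        meal = Meal.from_pairs(slot, [(c, g * factor) for c, g in portions])
        final = mpqs_score(digestible_eaa_intake(meal, table, config), thresholds, config)
        if final.limiting_eaa == target_eaa and final.mpqs < 100.0:
            return meal
    raise FixtureError(
        f"could not compose a meal limited by {target_eaa!r} from the given table"
    )


def generate_random_meal(
    table: FoodTable,
    rng: np.random.Generator,
    slot: str = "lunch",
    n_items: tuple[int, int] = (2, 5),
    grams: tuple[float, float] = (20.0, 150.0),
) -> Meal:
    """A random meal of annotated foods, for stress-testing the algorithms."""
    pool = [item.code for item in table if item.is_scoreable]
    if not pool:
        raise FixtureError("table has no annotated items")
    n = int(rng.integers(n_items[0], n_items[1] + 1))
    chosen = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
    return Meal.from_pairs(
        slot, [(pool[int(i)], float(rng.uniform(*grams))) for i in chosen]
    )


def generate_coconsumption(
    table: FoodTable, seed: int = 0, density: float = 0.15
) -> dict[tuple[str, str], float]:
    """Sparse symmetric co-consumption frequencies over the table's foods."""
    rng = np.random.default_rng(seed)
    codes = sorted(table.items)
    result: dict[tuple[str, str], float] = {}
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            if rng.random() < density:
                result[(a, b)] = float(rng.uniform(0.05, 1.0))
    return result


def write_demo_bundle(
    outdir: str | Path, seed: int = 0, n_per_group: int = 5, config: Config = DEFAULT_CONFIG
) -> dict[str, Path]:
    """Write a complete demo dataset: annotated food table, co-consumption
    file, requirement pattern, user profile, and sample meals."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = generate_food_table(n_per_group, seed=seed, config=config)
    paths = {
        "food_table": outdir / "food_table.csv",
        "coconsumption": outdir / "coconsumption.tsv",
        "pattern": outdir / "requirement_pattern.json",
        "profile": outdir / "profile.json",
        "meal": outdir / "meal.json",
        "day": outdir / "day.json",
    }
    write_food_table(table, paths["food_table"], config=config)
    with paths["coconsumption"].open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["code_a", "code_b", "frequency"])
        for (a, b), freq in sorted(generate_coconsumption(table, seed=seed).items()):
            writer.writerow([a, b, repr(freq)])
    default_pattern().to_json(paths["pattern"])
    paths["profile"].write_text(
        json.dumps(
            {
                "age": DEFAULT_PROFILE.age,
                "sex": DEFAULT_PROFILE.sex,
                "body_weight": DEFAULT_PROFILE.body_weight,
                "custom_protein_requirement": None,
                "exclusions": [],
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    meal = generate_deficient_meal(table, "lys", seed=seed, config=config)
    paths["meal"].write_text(json.dumps(meal.to_dict(), indent=2), encoding="utf-8")
    rng = np.random.default_rng(seed + 1)
    day_meals = [meal.to_dict()]
    for other_slot in ("breakfast", "dinner"):
        m = generate_random_meal(table, rng, slot=other_slot)
        day_meals.append(m.to_dict())
    day_meals.sort(key=lambda m: m["slot"])
    paths["day"].write_text(json.dumps({"meals": day_meals}, indent=2), encoding="utf-8")
    return paths
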