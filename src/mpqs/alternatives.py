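"""Meal-improvement algorithms: replacement, completion, and reproportioning.

Three ways to raise a meal's protein-quality score:

* **gram-by-gram** — replace one food with a similar one at the exact same
  gram amount, keeping every other portion fixed; rank candidates by the
  score of the modified meal.
* **missing piece** — find foods that, added to the meal in the right
  amount, lift the score to exactly 100; rank by how few grams are needed.
* **proportion adjustment** — keep the foods but shift their amounts by
  linear programming, conserving the meal's total weight and keeping every
  portion within 50%-200% of its current amount.

Every suggestion carries a predicted score that is recomputed from the
modified meal by the same code path as ordinary scoring, so predictions and
reality cannot drift apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .config import Config, DEFAULT_CONFIG
from .food_db import FoodItem, FoodTable
from .requirements import EAAThresholds
from .scoring import (
    Meal,
    MealScore,
    digestible_eaa_intake,
    mpqs_score,
    per_gram_contribution,
    score_meal,
)


class AlternativeError(ValueError):
    """Raised for invalid requests to the improvement algorithms."""


INFEASIBLE = float("inf")


@dataclass(frozen=True)
class SimilarityModel:
    """Weighted similarity between foods: shared food category plus empirical
    co-consumption with the rest of the meal.

    Taste similarity is a documented extension point: supply a
    ``taste_weight``/``taste`` hook via subclassing once taste data exists;
    no such data ships here.  ``exclusions`` (food codes or group names from
    the user profile, e.g. allergens or animal products) force similarity to
    zero regardless of weights.
    """

    category_weight: float = 1.0
    coconsumption_weight: float = 1.0
    coconsumption: Mapping[tuple[str, str], float] = field(default_factory=dict)
    exclusions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category_weight < 0 or self.coconsumption_weight < 0:
            raise AlternativeError("similarity weights must be >= 0")
        if self.category_weight == 0 and self.coconsumption_weight == 0:
            raise AlternativeError("at least one similarity weight must be positive")
        coco = {}
        for (a, b), freq in dict(self.coconsumption).items():
            if freq < 0:
                raise AlternativeError(f"co-consumption frequency for {(a, b)} must be >= 0")
            coco[(a, b)] = float(freq)
        object.__setattr__(self, "coconsumption", coco)
        object.__setattr__(self, "exclusions", tuple(self.exclusions))

    def frequency(self, a: str, b: str) -> float:
        return self.coconsumption.get((a, b), self.coconsumption.get((b, a), 0.0))

    @property
    def max_frequency(self) -> float:
        return max(self.coconsumption.values(), default=0.0)


def similarity(
    a: FoodItem,
    b: FoodItem,
    model: SimilarityModel,
    meal: Meal,
) -> float:
    """Similarity of candidate ``b`` to meal item ``a`` in the context of ``meal``.

    Normalized weighted sum of a same-food-group indicator and the mean
    normalized co-consumption frequency of ``b`` with the *other* foods of
    the meal.  Excluded foods score exactly 0.
    """
    if a.code == b.code:
        raise AlternativeError("similarity is defined only between distinct foods")
    if b.code in model.exclusions or b.food_group in model.exclusions:
        return 0.0
    category = 1.0 if a.food_group == b.food_group else 0.0
    others = [p.code for p in meal.portions if p.code != a.code]
    max_freq = model.max_frequency
    if others and max_freq > 0:
        cocon = sum(model.frequency(b.code, o) for o in others) / (len(others) * max_freq)
    else:
        cocon = 0.0
    total_weight = model.category_weight + model.coconsumption_weight
    return (model.category_weight * category + model.coconsumption_weight * cocon) / total_weight


@dataclass(frozen=True)
class AlternativeSuggestion:
    """A proposed meal change with its recomputed predicted score."""

    kind: str  # replace | add | reproportion
    payload: object
    predicted_mpqs: float
    rationale: str
    algorithm: str = ""
    similarity: float = 0.0
    grams: float = 0.0

    def to_dict(self) -> dict:
        payload: object
        if self.kind == "replace":
            target, replacement = self.payload  # type: ignore[misc]
            payload = {"target": target, "replacement": replacement}
        elif self.kind == "add":
            code, grams = self.payload  # type: ignore[misc]
            payload = {"code": code, "grams": grams}
        else:
            payload = {"new_grams": dict(self.payload)}  # type: ignore[arg-type]
        return {
            "kind": self.kind,
            "algorithm": self.algorithm,
            "payload": payload,
            "predicted_mpqs": self.predicted_mpqs,
            "rationale": self.rationale,
        }


def apply_suggestion(meal: Meal, suggestion: AlternativeSuggestion) -> Meal:
    """The modified meal a suggestion describes."""
    if suggestion.kind == "replace":
        target, replacement = suggestion.payload  # type: ignore[misc]
        return meal.with_portion_replaced(target, replacement)
    if suggestion.kind == "add":
        code, grams = suggestion.payload  # type: ignore[misc]
        return meal.with_added(code, grams)
    if suggestion.kind == "reproportion":
        return meal.with_grams(suggestion.payload)  # type: ignore[arg-type]
    raise AlternativeError(f"unknown suggestion kind {suggestion.kind!r}")


def gram_by_gram(
    meal: Meal,
    target_code: str,
    table: FoodTable,
    thresholds: EAAThresholds,
    model: SimilarityModel,
    k: int = 5,
    config: Config = DEFAULT_CONFIG,
) -> list[AlternativeSuggestion]:
    """Replace one meal item, at identical grams, by each similar food in turn.

    Every candidate with positive similarity is simulated; the ``k`` (default
    5) replacements with the highest resulting MPQS are returned, ties broken
    by higher similarity and then by code order.  All other portions are kept
    bit-identical, so total meal weight is conserved exactly.
    """
    if k < 1:
        raise AlternativeError("k must be >= 1")
    if all(p.code != target_code for p in meal.portions):
        raise AlternativeError(f"target code {target_code!r} is not in the meal")
    target = table[target_code]
    results: list[tuple[float, float, str, AlternativeSuggestion]] = []
    for candidate in table:
        if candidate.code == target_code or not candidate.is_scoreable:
            continue
        sim = similarity(target, candidate, model, meal)
        if sim <= 0.0:
            continue
        new_meal = meal.with_portion_replaced(target_code, candidate.code)
        new_score = score_meal(new_meal, table, thresholds, config)
        suggestion = AlternativeSuggestion(
            kind="replace",
            payload=(target_code, candidate.code),
            predicted_mpqs=new_score.mpqs,
            rationale=(
                f"Replace {target.name or target_code} with {candidate.name or candidate.code} "
                f"at the same amount; meal would score {new_score.mpqs:.1f}."
            ),
            algorithm="gram_by_gram",
            similarity=sim,
        )
        results.append((-new_score.mpqs, -sim, candidate.code, suggestion))
    results.sort(key=lambda r: (r[0], r[1], r[2]))
    return [r[3] for r in results[:k]]


def minimal_grams_to_complete(
    meal: Meal,
    candidate: FoodItem,
    table: FoodTable,
    thresholds: EAAThresholds,
    config: Config = DEFAULT_CONFIG,
) -> float:
    """Fewest grams of ``candidate`` that, added to the meal, reach a score of 100.

    With per-EAA deficits d_e = max(0, T_e - intake_e) and the candidate's
    per-gram digestible contributions c_e, the answer is max over deficient
    EAAs of d_e / c_e — infinite (infeasible) when the candidate wholly lacks
    a deficient EAA, 0 when there is no deficit.  The closed form is nudged
    up by at most a few float ulps so that rescoring the augmented meal
    reaches 100 exactly rather than one rounding error short.
    """
    intake = digestible_eaa_intake(meal, table, config)
    contrib = per_gram_contribution(candidate, config)
    deficits = {e: max(0.0, thresholds[e] - intake[e]) for e in config.eaa_list}
    grams = 0.0
    for e, d in deficits.items():
        if d <= 0:
            continue
        if contrib[e] <= 0:
            return INFEASIBLE
        grams = max(grams, d / contrib[e])
    if grams == 0.0:
        return 0.0
    # intake_e + grams * c_e may round a hair below T_e; bump by ulps until
    # every deficit is covered under the exact arithmetic scoring will use.
    for _ in range(64):
        if all(
            intake[e] + grams * contrib[e] >= thresholds[e]
            for e in config.eaa_list
            if deficits[e] > 0
        ):
            break
        grams = math.nextafter(grams, math.inf)
    return grams


def missing_piece(
    meal: Meal,
    table: FoodTable,
    thresholds: EAAThresholds,
    max_results: int = 5,
    max_grams: Optional[float] = None,
    config: Config = DEFAULT_CONFIG,
) -> list[AlternativeSuggestion]:
    """Foods that complete the meal to a score of 100, fewest grams first.

    Evaluates :func:`minimal_grams_to_complete` for every annotated food,
    drops infeasible candidates, sorts ascending by grams (ties by code) and
    truncates to ``max_results``.  ``max_grams`` optionally drops suggestions
    demanding implausibly large portions.  An already-complete meal yields no
    suggestions: there is nothing to add.
    """
    if max_results < 1:
        raise AlternativeError("max_results must be >= 1")
    base = score_meal(meal, table, thresholds, config)
    if base.mpqs >= 100.0:
        return []
    ranked: list[tuple[float, str, AlternativeSuggestion]] = []
    for candidate in table:
        if not candidate.is_scoreable:
            continue
        grams = minimal_grams_to_complete(meal, candidate, table, thresholds, config)
        if not math.isfinite(grams) or grams <= 0.0:
            continue
        if max_grams is not None and grams > max_grams:
            continue
        new_meal = meal.with_added(candidate.code, grams)
        new_score = score_meal(new_meal, table, thresholds, config)
        suggestion = AlternativeSuggestion(
            kind="add",
            payload=(candidate.code, grams),
            predicted_mpqs=new_score.mpqs,
            rationale=(
                f"Add {grams:.1f} g of {candidate.name or candidate.code} to cover the "
                f"remaining essential amino acid deficit and reach a score of 100."
            ),
            algorithm="missing_piece",
            grams=grams,
        )
        ranked.append((grams, candidate.code, suggestion))
    ranked.sort(key=lambda r: (r[0], r[1]))
    return [r[2] for r in ranked[:max_results]]


def _deviation_lp(
    grams: np.ndarray,
    contrib: np.ndarray,
    t_star: float,
    thresholds_vec: np.ndarray,
) -> np.ndarray:
    """Second LP pass: among gram vectors achieving objective ``t_star``,
    minimize total absolute deviation from the current amounts."""
    n = len(grams)
    total = float(grams.sum())
    # variables: x_0..x_{n-1}, u_0..u_{n-1} with u_i >= |x_i - g_i|
    c = np.concatenate([np.zeros(n), np.ones(n)])
    a_eq = np.zeros((1, 2 * n))
    a_eq[0, :n] = 1.0
    b_eq = np.array([total])
    rows = []
    rhs = []
    for i in range(n):
        row = np.zeros(2 * n)
        row[i] = 1.0
        row[n + i] = -1.0
        rows.append(row)
        rhs.append(grams[i])
        row = np.zeros(2 * n)
        row[i] = -1.0
        row[n + i] = -1.0
        rows.append(row)
        rhs.append(-grams[i])
    # keep the achieved quality level (tiny slack absorbs solver round-off)
    t_floor = t_star - 1e-9
    for e in range(contrib.shape[1]):
        row = np.zeros(2 * n)
        row[:n] = -contrib[:, e]
        rows.append(row)
        rhs.append(-t_floor * thresholds_vec[e])
    bounds = [(0.5 * g, 2.0 * g) for g in grams] + [(0.0, None)] * n
    res = linprog(
        c,
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise AlternativeError(f"deviation-minimizing pass failed: {res.message}")
    return res.x[:n]


def proportion_adjustment(
    meal: Meal,
    table: FoodTable,
    thresholds: EAAThresholds,
    config: Config = DEFAULT_CONFIG,
) -> AlternativeSuggestion:
    """Reproportion the meal's foods by linear programming.

    Maximize t subject to: the total weight of the meal is unchanged; each
    portion stays within 50% to 200% of its current amount; the digestible
    intake of every EAA reaches at least t x its threshold; 0 <= t <= 1.
    The cap t <= 1 encodes the score's ceiling of 100 and keeps the problem
    a pure LP — valid only for the default limiting-ratio score; the
    capped-mean variant refuses this algorithm.  Among optimal solutions, a
    second pass picks the one minimizing total |change in grams|, so a meal
    already at 100 is returned unchanged.  x = current grams is always
    feasible, so the score can never decrease.
    """
    if config.score_variant != "limiting":
        raise AlternativeError(
            "proportion adjustment requires the limiting-ratio score variant; "
            f"config uses {config.score_variant!r}"
        )
    active = [p for p in meal.portions if p.grams > 0]
    if len(active) < 2:
        base = score_meal(meal, table, thresholds, config)
        return AlternativeSuggestion(
            kind="reproportion",
            payload={p.code: p.grams for p in meal.portions},
            predicted_mpqs=base.mpqs,
            rationale=(
                "Proportions cannot be adjusted: with fewer than two foods the "
                "fixed total weight leaves no freedom to shift amounts."
            ),
            algorithm="proportion_adjustment",
        )
    codes = [p.code for p in active]
    grams = np.array([p.grams for p in active], dtype=float)
    thresholds_vec = np.array([thresholds[e] for e in config.eaa_list], dtype=float)
    contrib = np.array(
        [
            [per_gram_contribution(table[c], config)[e] for e in config.eaa_list]
            for c in codes
        ],
        dtype=float,
    )
    n = len(codes)
    n_eaa = len(config.eaa_list)
    # variables: x_0..x_{n-1}, t ; maximize t
    c = np.zeros(n + 1)
    c[n] = -1.0
    a_eq = np.zeros((1, n + 1))
    a_eq[0, :n] = 1.0
    b_eq = np.array([grams.sum()])
    a_ub = np.zeros((n_eaa, n + 1))
    for e in range(n_eaa):
        a_ub[e, :n] = -contrib[:, e]
        a_ub[e, n] = thresholds_vec[e]
    b_ub = np.zeros(n_eaa)
    bounds = [(0.5 * g, 2.0 * g) for g in grams] + [(0.0, 1.0)]
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        # x = g, t = current capped min ratio is feasible, so this signals a
        # numerical failure, not genuine infeasibility.
        raise AlternativeError(f"proportion-adjustment LP failed: {res.message}")
    t_star = float(res.x[n])
    x = _deviation_lp(grams, contrib, t_star, thresholds_vec)
    # box bounds are hard constraints; clip away solver round-off (~1e-12)
    x = np.clip(x, 0.5 * grams, 2.0 * grams)
    new_grams = {p.code: p.grams for p in meal.portions}
    new_grams.update({code: float(xi) for code, xi in zip(codes, x)})
    new_meal = meal.with_grams(new_grams)
    new_score = score_meal(new_meal, table, thresholds, config)
    changed = any(abs(new_grams[c_] - g) > 1e-9 for c_, g in zip(codes, grams))
    if changed:
        rationale = (
            f"Shift the amounts of the current foods (total weight unchanged, each "
            f"within 50%-200% of its current amount) to score {new_score.mpqs:.1f}."
        )
    else:
        rationale = "Current proportions are already optimal within the allowed bounds."
    return AlternativeSuggestion(
        kind="reproportion",
        payload=new_grams,
        predicted_mpqs=new_score.mpqs,
        rationale=rationale,
        algorithm="proportion_adjustment",
    )


def read_coconsumption(path, delimiter: str = "\t") -> dict[tuple[str, str], float]:
    """Read a 3-column co-consumption file: code_a, code_b, frequency."""
    import csv
    from pathlib import Path

    result: dict[tuple[str, str], float] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader, None)
        if header is None:
            return result
        for row in reader:
            if not row or not row[0].strip():
                continue
            a, b, freq = row[0].strip(), row[1].strip(), float(row[2])
            result[(a, b)] = freq
    return result
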