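"""Improvement algorithms checked against independent brute-force oracles."""

import math

import numpy as np
import pytest

from mpqs import (
    AlternativeError,
    SimilarityModel,
    apply_suggestion,
    gram_by_gram,
    minimal_grams_to_complete,
    missing_piece,
    proportion_adjustment,
    score_meal,
    similarity,
)
from mpqs.config import Config, DEFAULT_EAA_LIST
from mpqs.scoring import Meal, digestible_eaa_intake, mpqs_score, per_gram_contribution
from mpqs import fixtures


@pytest.fixture(scope="module")
def fixture_table():
    return fixtures.generate_food_table(8, seed=11)


@pytest.fixture(scope="module")
def fixture_thresholds():
    return fixtures.default_thresholds("lunch")


class TestSimilarity:
    def test_same_group_category_only(self, toy_table):
        model = SimilarityModel(category_weight=1.0, coconsumption_weight=0.0)
        meal = Meal.from_pairs("lunch", [("C1", 100.0)])
        # C1 vs another cereal-like item: same group indicator = 1
        sim = similarity(toy_table["C1"], toy_table["L1"], model, meal)
        assert sim == 0.0  # different groups
        model2 = SimilarityModel(category_weight=1.0, coconsumption_weight=0.0)
        assert (
            similarity(toy_table["L1"], toy_table["D1"], model2, meal) == 0.0
        )

    def test_same_group_scores_one_under_category_weight(self, toy_table):
        from mpqs import FoodItem
        from conftest import profile

        other_cereal = FoodItem(
            code="C2", name="", food_group="cereals", protein=12.0, energy=340.0,
            aa_profile=profile(), digestibility=0.8, provenance="native",
        )
        model = SimilarityModel(category_weight=1.0, coconsumption_weight=0.0)
        meal = Meal.from_pairs("lunch", [("C1", 100.0)])
        assert similarity(toy_table["C1"], other_cereal, model, meal) == 1.0

    def test_coconsumption_with_other_meal_items(self, toy_table):
        model = SimilarityModel(
            category_weight=0.0,
            coconsumption_weight=1.0,
            coconsumption={("L1", "D1"): 4.0, ("C1", "D1"): 2.0},
        )
        meal = Meal.from_pairs("lunch", [("C1", 50.0), ("D1", 50.0)])
        # candidate L1 replacing C1: other item is D1; freq(L1, D1)=4, max=4
        assert similarity(toy_table["C1"], toy_table["L1"], model, meal) == 1.0

    def test_exclusion_dominates(self, toy_table):
        model = SimilarityModel(exclusions=("legumes",))
        meal = Meal.from_pairs("lunch", [("C1", 100.0)])
        assert similarity(toy_table["C1"], toy_table["L1"], model, meal) == 0.0
        model2 = SimilarityModel(exclusions=("L1",))
        assert similarity(toy_table["C1"], toy_table["L1"], model2, meal) == 0.0

    def test_self_similarity_undefined(self, toy_table):
        model = SimilarityModel()
        meal = Meal.from_pairs("lunch", [("C1", 100.0)])
        with pytest.raises(AlternativeError):
            similarity(toy_table["C1"], toy_table["C1"], model, meal)


class TestGramByGram:
    def make_model(self):
        # flat positive similarity for every pair: co-consumption of 1 between
        # all fixture codes is cumbersome, so weight category only and put all
        # candidates in one group via a custom check -> instead use
        # coconsumption with every pair at equal frequency.
        return SimilarityModel(category_weight=1.0, coconsumption_weight=0.0)

    def test_lysine_rich_legume_beats_cereal_brute_force(self, toy_table):
        from mpqs import EAAThresholds, EAAVector, FoodItem, FoodTable, MG_ABSOLUTE
        from conftest import profile

        # a second cereal gives the target a same-group candidate; the legume
        # is reachable through co-consumption with the dairy side dish
        table = FoodTable.from_items(
            list(toy_table)
            + [
                FoodItem(
                    code="C2", name="other cereal", food_group="cereals",
                    protein=12.0, energy=340.0,
                    aa_profile=profile(lys=20.0, saa=40.0),
                    digestibility=0.8, provenance="native",
                )
            ]
        )
        thresholds = EAAThresholds(
            EAAVector({e: 5000.0 for e in DEFAULT_EAA_LIST}, MG_ABSOLUTE), "lunch"
        )
        model = SimilarityModel(
            category_weight=1.0,
            coconsumption_weight=1.0,
            coconsumption={("L1", "D1"): 1.0},
        )
        meal = Meal.from_pairs("lunch", [("C1", 300.0), ("D1", 50.0)])
        suggestions = gram_by_gram(meal, "C1", table, thresholds, model, k=5)
        assert suggestions, "expected candidates with positive similarity"
        # brute force: simulate every non-target annotated item
        best_code, best_score = None, -1.0
        for item in table:
            if item.code == "C1":
                continue
            sim = similarity(table["C1"], item, model, meal)
            if sim <= 0:
                continue
            new = score_meal(
                meal.with_portion_replaced("C1", item.code), table, thresholds
            )
            if new.mpqs > best_score:
                best_code, best_score = item.code, new.mpqs
        top = suggestions[0]
        assert top.payload[1] == "L1" == best_code
        assert top.predicted_mpqs == pytest.approx(best_score)
        baseline = score_meal(meal, table, thresholds)
        assert top.predicted_mpqs > baseline.mpqs

    def test_total_weight_conserved_and_others_untouched(self, fixture_table, fixture_thresholds):
        meal = fixtures.generate_deficient_meal(fixture_table, "lys", seed=5)
        model = SimilarityModel(category_weight=1.0, coconsumption_weight=0.0)
        target = meal.portions[0].code
        for s in gram_by_gram(meal, target, fixture_table, fixture_thresholds, model):
            new_meal = apply_suggestion(meal, s)
            assert new_meal.total_grams == meal.total_grams
            for old, new in zip(meal.portions, new_meal.portions):
                assert new.grams == old.grams
                if old.code != target:
                    assert new.code == old.code

    def test_predicted_score_matches_recomputation(self, fixture_table, fixture_thresholds):
        meal = fixtures.generate_deficient_meal(fixture_table, "saa", seed=7)
        model = SimilarityModel(category_weight=1.0, coconsumption_weight=0.0)
        for s in gram_by_gram(meal, meal.portions[0].code,
                              fixture_table, fixture_thresholds, model):
            recomputed = score_meal(apply_suggestion(meal, s), fixture_table, fixture_thresholds)
            assert abs(s.predicted_mpqs - recomputed.mpqs) <= 1e-9

    def test_target_not_in_meal_is_error(self, toy_table, flat_thresholds):
        meal = Meal.from_pairs("lunch", [("C1", 100.0)])
        with pytest.raises(AlternativeError, match="L1"):
            gram_by_gram(meal, "L1", toy_table, flat_thresholds, SimilarityModel())

    def test_empty_candidate_pool_gives_empty_list(self, toy_table, flat_thresholds):
        meal = Meal.from_pairs("lunch", [("C1", 100.0)])
        # category-only similarity and no other cereal in the table
        out = gram_by_gram(
            meal, "C1", toy_table, flat_thresholds,
            SimilarityModel(category_weight=1.0, coconsumption_weight=0.0),
        )
        assert out == []


def bisect_completion_grams(meal, candidate, table, thresholds, tol=1e-9):
    """Oracle: smallest grams g with score(meal + g of candidate) = 100,
    found by doubling then bisection on the monotone score function."""
    def complete(g):
        return score_meal(meal.with_added(candidate.code, g), table, thresholds).mpqs >= 100.0

    if complete(0.0):
        return 0.0
    hi = 1.0
    for _ in range(64):
        if complete(hi):
            break
        hi *= 2.0
    else:
        return math.inf
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if complete(mid):
            hi = mid
        else:
            lo = mid
    return hi


class TestMissingPiece:
    def test_hand_computed_single_deficit(self, flat_thresholds):
        from mpqs import FoodItem, FoodTable
        from conftest import profile

        # base food covers everything except lysine; candidate supplies
        # 10 mg digestible lysine per gram
        base = FoodItem(
            code="B", name="", food_group="g", protein=20.0, energy=100.0,
            aa_profile=profile(lys=0.0, **{e: 500.0 for e in DEFAULT_EAA_LIST if e != "lys"}),
            digestibility=1.0, provenance="native",
        )
        candidate = FoodItem(
            code="K", name="", food_group="g", protein=25.0, energy=100.0,
            aa_profile=profile(lys=40.0),
            digestibility=1.0, provenance="native",
        )
        table = FoodTable.from_items([base, candidate])
        meal = Meal.from_pairs("lunch", [("B", 100.0)])
        grams = minimal_grams_to_complete(meal, candidate, table, flat_thresholds)
        assert grams == pytest.approx(100.0)  # deficit 1000 mg / 10 mg per g

    def test_complete_meal_needs_zero_grams(self, toy_table, flat_thresholds):
        meal = Meal.from_pairs("lunch", [("D1", 100.0)])
        grams = minimal_grams_to_complete(
            meal, toy_table["L1"], toy_table, flat_thresholds
        )
        assert grams == 0.0

    def test_candidate_lacking_deficient_eaa_is_infeasible(self, flat_thresholds):
        from mpqs import FoodItem, FoodTable
        from conftest import profile

        base = FoodItem(
            code="B", name="", food_group="g", protein=20.0, energy=100.0,
            aa_profile=profile(lys=0.0), digestibility=1.0, provenance="native",
        )
        candidate = FoodItem(
            code="K", name="", food_group="g", protein=20.0, energy=100.0,
            aa_profile=profile(lys=0.0), digestibility=1.0, provenance="native",
        )
        table = FoodTable.from_items([base, candidate])
        meal = Meal.from_pairs("lunch", [("B", 10.0)])
        assert math.isinf(
            minimal_grams_to_complete(meal, candidate, table, flat_thresholds)
        )

    def test_matches_bisection_oracle_on_random_candidates(
        self, fixture_table, fixture_thresholds
    ):
        rng = np.random.default_rng(23)
        meal = fixtures.generate_deficient_meal(fixture_table, "lys", seed=23)
        codes = sorted(fixture_table.items)
        for code in rng.choice(codes, size=12, replace=False):
            candidate = fixture_table[str(code)]
            closed = minimal_grams_to_complete(
                meal, candidate, fixture_table, fixture_thresholds
            )
            oracle = bisect_completion_grams(
                meal, candidate, fixture_table, fixture_thresholds
            )
            if math.isinf(closed):
                assert math.isinf(oracle)
            else:
                assert closed == pytest.approx(oracle, abs=1e-6)

    def test_sorted_ascending_and_all_complete_to_100(
        self, fixture_table, fixture_thresholds
    ):
        meal = fixtures.generate_deficient_meal(fixture_table, "saa", seed=31)
        suggestions = missing_piece(
            meal, fixture_table, fixture_thresholds, max_results=10
        )
        assert suggestions
        grams = [s.grams for s in suggestions]
        assert grams == sorted(grams)
        for s in suggestions:
            rescored = score_meal(
                apply_suggestion(meal, s), fixture_table, fixture_thresholds
            )
            assert rescored.mpqs == 100.0

    def test_two_candidate_order_hand_computed(self, flat_thresholds):
        from mpqs import FoodItem, FoodTable
        from conftest import profile

        base = FoodItem(
            code="B", name="", food_group="g", protein=20.0, energy=100.0,
            aa_profile=profile(lys=0.0, **{e: 500.0 for e in DEFAULT_EAA_LIST if e != "lys"}),
            digestibility=1.0, provenance="native",
        )
        slow = FoodItem(  # 10 mg lys per g -> needs 100 g
            code="S", name="", food_group="g", protein=25.0, energy=100.0,
            aa_profile=profile(lys=40.0), digestibility=1.0, provenance="native",
        )
        fast = FoodItem(  # 25 mg lys per g -> needs 40 g
            code="F", name="", food_group="g", protein=25.0, energy=100.0,
            aa_profile=profile(lys=100.0), digestibility=1.0, provenance="native",
        )
        table = FoodTable.from_items([base, slow, fast])
        meal = Meal.from_pairs("lunch", [("B", 100.0)])
        suggestions = missing_piece(meal, table, flat_thresholds, max_results=5)
        assert [s.payload[0] for s in suggestions] == ["F", "S"]
        assert suggestions[0].grams == pytest.approx(40.0)
        assert suggestions[1].grams == pytest.approx(100.0)

    def test_complete_meal_yields_no_suggestions(self, toy_table, flat_thresholds):
        meal = Meal.from_pairs("lunch", [("D1", 100.0)])
        assert missing_piece(meal, toy_table, flat_thresholds) == []

    def test_all_infeasible_gives_empty_list(self, flat_thresholds):
        from mpqs import FoodItem, FoodTable
        from conftest import profile

        items = [
            FoodItem(
                code=str(i), name="", food_group="g", protein=20.0, energy=100.0,
                aa_profile=profile(lys=0.0), digestibility=1.0, provenance="native",
            )
            for i in range(3)
        ]
        table = FoodTable.from_items(items)
        meal = Meal.from_pairs("lunch", [("0", 50.0)])
        assert missing_piece(meal, table, flat_thresholds) == []


def grid_search_two_item(meal, table, thresholds, resolution=0.01):
    """Oracle: exhaustive search over the first portion's grams at fixed
    total weight, within the 50%-200% band of both items."""
    (c1, g1), (c2, g2) = [(p.code, p.grams) for p in meal.portions]
    total = g1 + g2
    lo = max(0.5 * g1, total - 2.0 * g2)
    hi = min(2.0 * g1, total - 0.5 * g2)
    best = -1.0
    x = lo
    while x <= hi + 1e-12:
        m = meal.with_grams({c1: x, c2: total - x})
        s = score_meal(m, table, thresholds)
        if s.mpqs > best:
            best = s.mpqs
        x += resolution
    return best


class TestProportionAdjustment:
    def test_meal_at_100_returned_unchanged(self, toy_table, flat_thresholds):
        meal = Meal.from_pairs("lunch", [("D1", 80.0), ("L1", 80.0)])
        assert score_meal(meal, toy_table, flat_thresholds).mpqs == 100.0
        out = proportion_adjustment(meal, toy_table, flat_thresholds)
        assert out.predicted_mpqs == 100.0
        for p in meal.portions:
            assert out.payload[p.code] == pytest.approx(p.grams, abs=1e-7)

    def test_single_item_meal_unchanged_with_rationale(self, toy_table, flat_thresholds):
        meal = Meal.from_pairs("lunch", [("C1", 100.0)])
        out = proportion_adjustment(meal, toy_table, flat_thresholds)
        assert out.payload == {"C1": 100.0}
        assert "fewer than two foods" in out.rationale

    def test_capped_mean_variant_refused(self, toy_table, flat_thresholds):
        cfg = Config(score_variant="capped_mean")
        meal = Meal.from_pairs("lunch", [("C1", 100.0), ("L1", 100.0)])
        with pytest.raises(AlternativeError, match="limiting"):
            proportion_adjustment(meal, toy_table, flat_thresholds, cfg)

    def test_two_item_lp_matches_grid_search(self, toy_table, flat_thresholds):
        meal = Meal.from_pairs("lunch", [("C1", 150.0), ("L1", 100.0)])
        out = proportion_adjustment(meal, toy_table, flat_thresholds)
        oracle = grid_search_two_item(meal, toy_table, flat_thresholds)
        assert out.predicted_mpqs >= oracle - 0.05  # grid resolution slack

    def test_constraints_and_never_worse_on_random_meals(
        self, fixture_table, fixture_thresholds
    ):
        rng = np.random.default_rng(97)
        for _ in range(30):
            meal = fixtures.generate_random_meal(fixture_table, rng)
            base = score_meal(meal, fixture_table, fixture_thresholds)
            out = proportion_adjustment(meal, fixture_table, fixture_thresholds)
            new_grams = out.payload
            assert abs(sum(new_grams.values()) - meal.total_grams) <= 1e-6
            for p in meal.portions:
                assert 0.5 * p.grams - 1e-9 <= new_grams[p.code] <= 2.0 * p.grams + 1e-9
            assert out.predicted_mpqs >= base.mpqs - 1e-9
            recomputed = score_meal(
                apply_suggestion(meal, out), fixture_table, fixture_thresholds
            )
            assert abs(out.predicted_mpqs - recomputed.mpqs) <= 1e-9

    def test_lp_at_least_grid_optimum_on_random_two_item_meals(
        self, fixture_table, fixture_thresholds
    ):
        rng = np.random.default_rng(41)
        for _ in range(20):
            meal = fixtures.generate_random_meal(
                fixture_table, rng, n_items=(2, 2), grams=(30.0, 120.0)
            )
            out = proportion_adjustment(meal, fixture_table, fixture_thresholds)
            oracle = grid_search_two_item(meal, fixture_table, fixture_thresholds)
            assert out.predicted_mpqs >= oracle - 0.05
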