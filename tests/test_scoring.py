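import datetime as dt
import math

import numpy as np
import pytest

from nutrirank.ffq import NutrientStatusProfile
from nutrirank.model import SCORED_NUTRIENTS, OrderEvent, FeedbackEvent, ValidationError
from nutrirank.scoring import (
    HybridWeights,
    TasteVector,
    WeightTable,
    build_taste_vector,
    collaborative_scores,
    content_score,
    history_days,
    hybrid_rank,
    knowledge_scores,
    normalize_nutrients,
)

from conftest import make_meal, make_menu, oracle_rank

TODAY = dt.date(2022, 2, 14)


def profile(user="u1", **statuses):
    status = {n: "Normal" for n in SCORED_NUTRIENTS}
    status.update(statuses)
    return NutrientStatusProfile(user, status)


class TestNormalization:
    def test_endpoints(self):
        meals = [make_meal("a", fiber=2.0), make_meal("b", fiber=6.0)]
        norm = normalize_nutrients(meals)
        assert norm.loc["a", "fiber"] == 0.0
        assert norm.loc["b", "fiber"] == 1.0

    def test_constant_column_is_half(self):
        meals = [make_meal("a"), make_meal("b"), make_meal("c")]
        norm = normalize_nutrients(meals)
        assert (norm.to_numpy() == 0.5).all()

    def test_random_meals_span_unit_interval(self):
        rng = np.random.default_rng(7)
        meals = [
            make_meal(f"m{i}", **{n: float(rng.uniform(1, 50))
                                  for n in SCORED_NUTRIENTS})
            for i in range(10)
        ]
        norm = normalize_nutrients(meals)
        assert norm.min(axis=0).tolist() == pytest.approx([0.0] * 12)
        assert norm.max(axis=0).tolist() == pytest.approx([1.0] * 12)
        assert ((norm >= 0) & (norm <= 1)).all().all()


class TestKnowledgeScore:
    def test_all_normal_profile_is_neutral(self):
        meals = [make_meal("a", fiber=1.0), make_meal("b", fiber=9.0)]
        raw, scaled = knowledge_scores(normalize_nutrients(meals), profile(),
                                       WeightTable())
        assert raw.tolist() == [0.0, 0.0]
        assert scaled.tolist() == [0.5, 0.5]

    def test_low_fiber_marginal_effect_is_5(self):
        # two meals differing only in fiber: raw score difference = weight 5
        meals = [make_meal("a", fiber=2.0), make_meal("b", fiber=8.0)]
        raw, scaled = knowledge_scores(
            normalize_nutrients(meals), profile(fiber="Low"), WeightTable()
        )
        assert raw["b"] - raw["a"] == pytest.approx(5.0)
        assert scaled["b"] == 1.0 and scaled["a"] == 0.0

    def test_high_polyunsaturated_fat_discounted(self):
        meals = [make_meal("a", polyunsaturated_fat=1.0),
                 make_meal("b", polyunsaturated_fat=11.0)]
        raw, _ = knowledge_scores(
            normalize_nutrients(meals), profile(polyunsaturated_fat="High"),
            WeightTable(),
        )
        assert raw["b"] - raw["a"] == pytest.approx(-0.5)

    def test_missing_table_entry_rejected(self):
        table = {(n, s): 0.0 for n in SCORED_NUTRIENTS for s in ("Low", "Normal", "High")}
        del table[("fiber", "Low")]
        with pytest.raises(ValidationError, match="fiber"):
            WeightTable(weights=table)

    def test_low_fiber_score_increases_with_fiber(self):
        meals = [make_meal(f"m{i}", fiber=float(i)) for i in range(1, 6)]
        raw, _ = knowledge_scores(
            normalize_nutrients(meals), profile(fiber="Low"), WeightTable()
        )
        assert all(raw.iloc[i] < raw.iloc[i + 1] for i in range(4))


class TestTasteVector:
    def test_no_events_zero_vector(self):
        taste = build_taste_vector("u1", [], [], {})
        assert taste.is_cold()

    def test_order_counts_ingredients(self):
        meal = make_meal("m1", ingredients=("pasta", "tomato"))
        taste = build_taste_vector(
            "u1", [OrderEvent("u1", "m1", TODAY)], [], {"m1": meal}
        )
        assert taste.weights == {"pasta": 1.0, "tomato": 1.0}

    def test_thumbs_down_hits_only_listed_ingredients(self):
        meal = make_meal("m1", ingredients=("coriander", "rice", "chicken"))
        fb = [FeedbackEvent("u1", "m1", TODAY, "down",
                            disliked_ingredients=("coriander",))]
        taste = build_taste_vector("u1", [], fb, {"m1": meal})
        assert taste.weights == {"coriander": -2.0}

    def test_thumbs_up_counts_like_order(self):
        meal = make_meal("m1", ingredients=("rice",))
        fb = [FeedbackEvent("u1", "m1", TODAY, "up")]
        taste = build_taste_vector("u1", [OrderEvent("u1", "m1", TODAY)], fb,
                                   {"m1": meal})
        assert taste.weights == {"rice": 2.0}

    def test_unknown_meal_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            taste = build_taste_vector("u1", [OrderEvent("u1", "ghost", TODAY)], [], {})
        assert taste.is_cold()
        assert "ghost" in caplog.text

    def test_other_users_events_ignored(self):
        meal = make_meal("m1", ingredients=("rice",))
        taste = build_taste_vector("u1", [OrderEvent("u2", "m1", TODAY)], [],
                                   {"m1": meal})
        assert taste.is_cold()


class TestContentScore:
    def test_own_ingredient_vector_scores_1(self):
        meal = make_meal("m1", ingredients=("a", "b", "c"))
        taste = TasteVector("u1", {"a": 1.0, "b": 1.0, "c": 1.0})
        assert content_score(meal, taste) == pytest.approx(1.0)

    def test_disjoint_positive_taste_is_neutral(self):
        meal = make_meal("m1", ingredients=("a", "b"))
        taste = TasteVector("u1", {"x": 2.0, "y": 1.0})
        assert content_score(meal, taste) == pytest.approx(0.5)

    def test_cold_user_neutral(self):
        meal = make_meal("m1", ingredients=("a",))
        assert content_score(meal, TasteVector("u1", {})) == 0.5

    def test_three_ingredient_hand_oracle(self):
        meal = make_meal("m1", ingredients=("pasta", "tomato", "basil"))
        taste = TasteVector("u1", {"pasta": 2.0, "tomato": -1.0, "cheese": 3.0})
        dot = 2.0 - 1.0  # pasta + tomato; basil and cheese do not overlap
        cosine = dot / (math.sqrt(3) * math.sqrt(4 + 1 + 9))
        assert content_score(meal, taste) == pytest.approx((cosine + 1) / 2, abs=1e-12)

    def test_disliked_ingredients_lower_score(self):
        meal_with = make_meal("m1", ingredients=("coriander", "rice"))
        meal_without = make_meal("m2", ingredients=("pasta", "rice"))
        taste = TasteVector("u1", {"coriander": -2.0, "rice": 1.0})
        assert content_score(meal_with, taste) < content_score(meal_without, taste)


class TestCollaborative:
    def orders(self):
        # 5 users, 16 days of history
        start = TODAY - dt.timedelta(days=15)
        out = []
        ordered = {
            "u1": ["a", "b"], "u2": ["a", "b"], "u3": ["a", "c"],
            "u4": ["c", "d"], "u5": ["d", "e"],
        }
        for i, (uid, meals) in enumerate(sorted(ordered.items())):
            for j, mid in enumerate(meals):
                out.append(OrderEvent(uid, mid, start + dt.timedelta(days=i + j)))
        return out

    def test_inactive_before_activation_days(self):
        meals = [make_meal("a"), make_meal("b")]
        orders = [OrderEvent("u1", "a", TODAY - dt.timedelta(days=4))]
        scores, info = collaborative_scores(meals, "u1", orders, TODAY)
        assert not info.active
        assert set(scores.values()) == {0.0}

    def test_history_days_counting(self):
        orders = [OrderEvent("u1", "a", TODAY - dt.timedelta(days=13))]
        assert history_days(orders, TODAY) == 14

    def test_inactive_user_without_orders(self):
        meals = [make_meal("a")]
        scores, info = collaborative_scores(meals, "newbie", self.orders(), TODAY)
        assert not info.active and scores["a"] == 0.0

    def test_all_neighbors_ordered_gives_1(self):
        meals = [make_meal("a")]
        scores, info = collaborative_scores(meals, "u1", self.orders(), TODAY, k=2)
        # u1's most similar users are u2 (identical) and u3 (shares "a"),
        # and both ordered meal "a"
        assert info.active
        assert info.neighbor_ids == ("u2", "u3")
        assert scores["a"] == pytest.approx(1.0)

    def test_matches_all_pairs_oracle(self):
        meals = [make_meal(m) for m in ("a", "b", "c", "d", "e")]
        orders = self.orders()
        scores, info = collaborative_scores(meals, "u3", orders, TODAY, k=2)
        _, oracle_final = oracle_rank(
            meals, {n: "Normal" for n in SCORED_NUTRIENTS}, WeightTable().weights,
            {}, orders, "u3", TODAY, hybrid=(0.0, 0.0, 1.0), k=2,
        )
        for m in meals:
            assert scores[m.meal_id] == pytest.approx(oracle_final[m.meal_id])


class TestHybridRank:
    def test_single_candidate_first(self):
        res = hybrid_rank([make_meal("only")], profile(), TasteVector("u1", {}),
                          [], TODAY)
        assert res.scores[0].meal_id == "only"

    def test_weights_decide_65_vs_35(self):
        # component scores (1,0,0) vs (0,1,1): finals 0.65 vs 0.35
        w = HybridWeights()
        f1 = w.knowledge * 1 + w.content * 0 + w.collaborative * 0
        f2 = w.knowledge * 0 + w.content * 1 + w.collaborative * 1
        assert f1 == pytest.approx(0.65) and f2 == pytest.approx(0.35)
        # realized end-to-end: meal "a" maximizes knowledge, "b" taste+popularity
        meals = [make_meal("a", fiber=9.0, ingredients=("kale",)),
                 make_meal("b", fiber=1.0, ingredients=("fries",))]
        start = TODAY - dt.timedelta(days=20)
        orders = [OrderEvent("u1", "b", start)]
        orders += [OrderEvent(f"n{i}", "b", start + dt.timedelta(days=1))
                   for i in range(5)]
        taste = TasteVector("u1", {"fries": 1.0})
        res = hybrid_rank(meals, profile(fiber="Low"), taste, orders, TODAY)
        a, b = res.for_meal("a"), res.for_meal("b")
        assert (a.knowledge, a.content, a.collaborative) == (1.0, 0.5, 0.0)
        assert b.knowledge == 0.0 and b.content == 1.0 and b.collaborative == 1.0
        assert a.final == pytest.approx(0.65 * 1 + 0.25 * 0.5)
        assert b.final == pytest.approx(0.25 * 1 + 0.10 * 1)
        assert res.scores[0].meal_id == "a"

    def test_final_is_exact_weighted_sum(self, small_world):
        menu = small_world.menus[15]
        today = menu.date
        prof = small_world.planted_profiles[small_world.users[1].user_id]
        from nutrirank.model import meal_archive
        from nutrirank.scoring import build_taste_vector

        archive = meal_archive(small_world.menus)
        orders = [e for e in small_world.events.orders if e.date <= today]
        taste = build_taste_vector(small_world.users[1].user_id, orders,
                                   small_world.events.feedback, archive)
        res = hybrid_rank(list(menu.meals), prof, taste, orders, today)
        for s in res.scores:
            assert s.final == pytest.approx(
                0.65 * s.knowledge + 0.25 * s.content + 0.10 * s.collaborative,
                abs=1e-12,
            )
            assert 0 <= s.knowledge <= 1 and 0 <= s.content <= 1
            assert 0 <= s.collaborative <= 1 and 0 <= s.final <= 1

    def test_linearity_finite_difference_recovers_weights(self):
        """Perturbing one component by eps moves the final by weight*eps."""
        w = HybridWeights()
        rng = np.random.default_rng(3)
        for _ in range(20):
            kn, co, cf = rng.uniform(0, 1, 3)
            base = w.knowledge * kn + w.content * co + w.collaborative * cf
            eps = 1e-6
            d_k = (w.knowledge * (kn + eps) + w.content * co + w.collaborative * cf
                   - base) / eps
            d_c = (w.knowledge * kn + w.content * (co + eps) + w.collaborative * cf
                   - base) / eps
            d_f = (w.knowledge * kn + w.content * co + w.collaborative * (cf + eps)
                   - base) / eps
            assert d_k == pytest.approx(0.65, abs=1e-9)
            assert d_c == pytest.approx(0.25, abs=1e-9)
            assert d_f == pytest.approx(0.10, abs=1e-9)

    def test_neutral_final_is_045(self):
        """All-Normal profile + empty histories: every final is
        0.65*0.5 + 0.25*0.5 + 0.10*0 = 0.45."""
        meals = [make_meal(f"m{i}", fiber=float(i + 1)) for i in range(4)]
        res = hybrid_rank(meals, profile(), TasteVector("u1", {}), [], TODAY)
        for s in res.scores:
            assert s.final == pytest.approx(0.45, abs=1e-12)
        # ranking of identical scores falls back to meal_id order
        assert [s.meal_id for s in res.scores] == ["m0", "m1", "m2", "m3"]

    def test_low_fiber_monotonicity(self):
        """For a Low-fiber user, increasing only a meal's fiber never lowers
        its rank."""
        rng = np.random.default_rng(11)
        base_meals = [
            make_meal(f"m{i}", fiber=float(rng.uniform(1, 9)),
                      ingredients=("rice",))
            for i in range(5)
        ]
        prof = profile(fiber="Low")
        taste = TasteVector("u1", {})
        res1 = hybrid_rank(base_meals, prof, taste, [], TODAY)
        rank1 = [s.meal_id for s in res1.scores].index("m2")
        import dataclasses

        from nutrirank.model import NutrientVector

        boosted = []
        for m in base_meals:
            if m.meal_id == "m2":
                vals = m.nutrients.as_dict()
                vals["fiber"] = vals["fiber"] + 3.0
                m = dataclasses.replace(m, nutrients=NutrientVector.from_mapping(vals))
            boosted.append(m)
        res2 = hybrid_rank(boosted, prof, taste, [], TODAY)
        rank2 = [s.meal_id for s in res2.scores].index("m2")
        assert rank2 <= rank1

    def test_oracle_equivalence_on_random_worlds(self):
        """Full pipeline ranking equals an independent brute-force
        recomputation on 200 random menus of <= 6 meals."""
        rng = np.random.default_rng(20260929)
        table = WeightTable()
        ingredients = ["rice", "pasta", "tomato", "kale", "beef", "tofu", "egg"]
        for trial in range(200):
            n = int(rng.integers(2, 7))
            meals = [
                make_meal(
                    f"m{i}",
                    ingredients=tuple(
                        rng.choice(ingredients, size=int(rng.integers(1, 4)),
                                   replace=False)
                    ),
                    **{nu: float(rng.uniform(0, 40)) for nu in SCORED_NUTRIENTS},
                )
                for i in range(n)
            ]
            status = {
                nu: str(rng.choice(["Low", "Normal", "High"])) for nu in SCORED_NUTRIENTS
            }
            prof = NutrientStatusProfile("u1", status)
            taste_weights = {
                ing: float(rng.choice([-2.0, 0.0, 1.0, 2.0])) for ing in ingredients
            }
            taste_weights = {k: v for k, v in taste_weights.items() if v != 0}
            start = TODAY - dt.timedelta(days=int(rng.integers(0, 30)))
            orders = []
            for u in range(int(rng.integers(0, 5))):
                for _ in range(int(rng.integers(1, 4))):
                    orders.append(
                        OrderEvent(
                            f"u{u}",
                            f"m{int(rng.integers(0, n))}",
                            start + dt.timedelta(days=int(rng.integers(0, 10))),
                        )
                    )
            result = hybrid_rank(
                meals, prof, TasteVector("u1", taste_weights), orders, TODAY, k=3
            )
            expected_order, expected_final = oracle_rank(
                meals, status, table.weights, taste_weights, orders, "u1", TODAY, k=3
            )
            assert [s.meal_id for s in result.scores] == expected_order, f"trial {trial}"
            for s in result.scores:
                assert s.final == pytest.approx(expected_final[s.meal_id], abs=1e-12)

    def test_invalid_hybrid_weights_rejected(self):
        with pytest.raises(ValidationError):
            HybridWeights(0.6, 0.25, 0.10)
        with pytest.raises(ValidationError):
            HybridWeights(-0.1, 1.0, 0.1)
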