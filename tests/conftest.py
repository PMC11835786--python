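import datetime as dt
import math

import pytest

from nutrirank.model import (
    SCORED_NUTRIENTS,
    Ingredient,
    Meal,
    Menu,
    NutrientVector,
)


@pytest.fixture
def toy():
    from nutrirank.synthetic import generate_toy_worked_example

    return generate_toy_worked_example()


@pytest.fixture(scope="session")
def small_world():
    from nutrirank.synthetic import GeneratorConfig, generate_world

    return generate_world(GeneratorConfig(seed=20260929, n_users=12, n_days=21))


def make_meal(
    meal_id,
    date=dt.date(2022, 1, 17),
    location="hq",
    ingredients=(),
    allergen_tags=(),
    lifestyle_tags=(),
    opaque=False,
    **nutrients,
):
    """Convenience meal builder: unspecified nutrients default to 10."""
    vals = {n: 10.0 for n in SCORED_NUTRIENTS}
    vals.update(nutrients)
    ings = [Ingredient(name=n) for n in ingredients]
    if opaque:
        ings.append(Ingredient(name="mystery sauce", is_composite_opaque=True))
    return Meal(
        meal_id=meal_id,
        name=meal_id,
        course="main",
        date=date,
        location=location,
        nutrients=NutrientVector.from_mapping(vals),
        ingredients=tuple(ings),
        allergen_tags=frozenset(allergen_tags),
        lifestyle_tags=frozenset(lifestyle_tags),
        nutriscore="C",
    )


def make_menu(meals):
    return Menu(date=meals[0].date, location=meals[0].location, meals=tuple(meals))


# ------------------------------------------------------------------------
# Independent brute-force ranking oracle: recomputes the whole pipeline with
# plain Python loops, sharing no code with the implementation under test.
# ------------------------------------------------------------------------

def oracle_rank(meals, status, weight_table, taste_weights, orders, user_id, today,
                hybrid=(0.65, 0.25, 0.10), k=5, activation_days=14):
    """Return (ordered meal_ids, {meal_id: final}) computed from scratch."""
    w_k, w_c, w_f = hybrid

    # min-max normalization per nutrient
    norm = {}
    for n in SCORED_NUTRIENTS:
        vals = [getattr(m.nutrients, n) for m in meals]
        lo, hi = min(vals), max(vals)
        for m in meals:
            x = getattr(m.nutrients, n)
            norm[(m.meal_id, n)] = 0.5 if hi == lo else (x - lo) / (hi - lo)

    # knowledge: weighted sum then min-max rescale
    raw = {
        m.meal_id: sum(
            weight_table[(n, status[n])] * norm[(m.meal_id, n)] for n in SCORED_NUTRIENTS
        )
        for m in meals
    }
    lo, hi = min(raw.values()), max(raw.values())
    knowledge = {
        mid: (0.5 if hi == lo else (v - lo) / (hi - lo)) for mid, v in raw.items()
    }

    # content: cosine of binary ingredient vector with taste vector -> [0,1]
    tn = math.sqrt(sum(v * v for v in taste_weights.values()))
    content = {}
    for m in meals:
        ings = {i.name for i in m.ingredients}
        if tn == 0 or not ings:
            content[m.meal_id] = 0.5
        else:
            dot = sum(taste_weights.get(i, 0.0) for i in ings)
            content[m.meal_id] = (dot / (math.sqrt(len(ings)) * tn) + 1) / 2

    # collaborative: top-k cosine neighbours over order counts
    past = [o for o in orders if o.date <= today]
    days = 0 if not past else (today - min(o.date for o in past)).days + 1
    mine = [o for o in past if o.user_id == user_id]
    collab = {m.meal_id: 0.0 for m in meals}
    if days >= activation_days and mine:
        counts = {}
        for o in past:
            counts.setdefault(o.user_id, {}).setdefault(o.meal_id, 0)
            counts[o.user_id][o.meal_id] += 1

        def cos(a, b):
            d = sum(v * b.get(kk, 0) for kk, v in a.items())
            na = math.sqrt(sum(v * v for v in a.values()))
            nb = math.sqrt(sum(v * v for v in b.values()))
            return 0.0 if na == 0 or nb == 0 else d / (na * nb)

        own = counts.get(user_id, {})
        others = sorted(u for u in counts if u != user_id)
        neighbors = sorted(others, key=lambda u: (-cos(own, counts[u]), u))[:k]
        if neighbors:
            for m in meals:
                collab[m.meal_id] = sum(
                    m.meal_id in counts[nb] for nb in neighbors
                ) / len(neighbors)

    final = {
        m.meal_id: w_k * knowledge[m.meal_id]
        + w_c * content[m.meal_id]
        + w_f * collab[m.meal_id]
        for m in meals
    }
    order = sorted(
        final, key=lambda mid: (-final[mid], -knowledge[mid], mid)
    )
    return order, final
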