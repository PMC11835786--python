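"""Deterministic synthetic worlds: menus, users, FFQ data and interaction
histories for testing every stage of the engine without any external data.

The generator emulates a workplace-catering deployment: a restaurant with a
fixed meal pool, 10–20 meals offered per day, a small vegan share, users with
heterogeneous allergies/lifestyle preferences, baseline and post FFQ
responses, and multi-week order/feedback logs.

Two construction guarantees matter for testing:

* **Profile planting** — FFQ responses are built analytically so that
  ``classify_status(compute_intake(...))`` recovers each user's planted
  Low/Normal/High profile exactly. The item bank carries one pure
  single-nutrient "concentrated source" item per scored nutrient
  (synthetic, flagged by the ``conc_`` id prefix); the random multi-item
  base response is scaled below every Low bound, then each Normal/High
  nutrient is topped up through its concentrated item, which touches no
  other nutrient.
* **Taste planting** — order histories are biased (4:1 odds by default)
  toward meals containing a user's planted preferred ingredients.

All composition values are drawn from plausible food-composition-table-like
per-100 g ranges hard-coded below; they are synthetic, not measured.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .config import load_reference_ranges
from .ffq import (
    FOOD_GROUPS,
    FfqAnswer,
    FfqItem,
    FfqResponse,
    FoodCompositionEntry,
    NutrientStatusProfile,
    ReferenceRange,
    write_composition_table,
    write_ffq_responses,
)
from .io import write_events, write_menu, write_users
from .model import (
    SCORED_NUTRIENTS,
    COURSES,
    EventLog,
    FeedbackEvent,
    Ingredient,
    Meal,
    Menu,
    NutrientVector,
    OrderEvent,
    RecommendationRecord,
    UserProfile,
    ValidationError,
)

# ingredient name -> (allergen tags, vegan-compatible)
INGREDIENT_POOL: dict[str, tuple[tuple[str, ...], bool]] = {
    "tomato": ((), True),
    "spinach": ((), True),
    "lentils": (("legume pulse",), True),
    "chickpeas": (("legume pulse",), True),
    "rice": ((), True),
    "pasta": (("gluten", "wheat"), True),
    "bread": (("gluten", "wheat"), True),
    "potato": ((), True),
    "carrot": ((), True),
    "zucchini": ((), True),
    "bell pepper": ((), True),
    "onion": ((), True),
    "garlic": ((), True),
    "mushroom": ((), True),
    "broccoli": ((), True),
    "quinoa": ((), True),
    "tofu": (("soy",), True),
    "coriander": ((), True),
    "olive oil": ((), True),
    "walnuts": (("walnuts", "nut"), True),
    "almonds": (("almonds", "nut"), True),
    "peanut sauce": (("peanut",), True),
    "sesame seeds": (("sesame", "seeds"), True),
    "chicken": ((), False),
    "beef steak": ((), False),
    "pork loin": ((), False),
    "salmon": (("fish",), False),
    "cod": (("fish",), False),
    "shrimp": (("shellfish",), False),
    "egg": (("egg",), False),
    "cheese": (("lactose", "milk dairy"), False),
    "yogurt": (("lactose", "milk dairy"), False),
    "butter": (("lactose", "milk dairy"), False),
    "cream": (("lactose", "milk dairy"), False),
    "mustard": (("mustard",), True),
    "celery": (("celery",), True),
    "oats": (("oats", "gluten"), True),
}

# per-portion nutrient ranges for generated meals (unit as in NutrientVector)
MEAL_NUTRIENT_RANGES: dict[str, tuple[float, float]] = {
    "fiber": (0.5, 12.0),
    "vitamin_a": (20.0, 600.0),
    "vitamin_b12": (0.0, 3.0),
    "vitamin_c": (0.0, 90.0),
    "monounsaturated_fat": (1.0, 20.0),
    "polyunsaturated_fat": (0.5, 12.0),
    "protein": (4.0, 45.0),
    "total_fat": (3.0, 40.0),
    "calcium": (20.0, 450.0),
    "iron": (0.3, 7.0),
    "saturated_fat": (0.5, 16.0),
    "carbohydrate": (10.0, 95.0),
}

# per-100 g composition ranges for generated FFQ items, by food group
GROUP_COMPOSITION_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "vegetables": {"fiber": (1.5, 4), "vitamin_c": (10, 80), "vitamin_a": (30, 400),
                   "carbohydrate": (3, 10), "protein": (1, 3)},
    "fruit": {"fiber": (1, 3), "vitamin_c": (20, 60), "carbohydrate": (8, 20)},
    "potatoes_rice_pasta": {"carbohydrate": (15, 30), "fiber": (1, 3),
                            "protein": (2, 5), "iron": (0.3, 1.2)},
    "bread_savory_biscuits": {"carbohydrate": (40, 55), "fiber": (3, 8),
                              "protein": (7, 12), "iron": (1, 3)},
    "dairy": {"calcium": (100, 250), "protein": (3, 10), "vitamin_b12": (0.3, 1.5),
              "saturated_fat": (1, 8), "total_fat": (2, 12)},
    "meat_fish": {"protein": (18, 28), "iron": (0.5, 3), "vitamin_b12": (0.5, 4),
                  "total_fat": (3, 20), "saturated_fat": (1, 7),
                  "monounsaturated_fat": (1, 8), "polyunsaturated_fat": (0.5, 4)},
    "fats_spreads": {"total_fat": (40, 82), "saturated_fat": (8, 50),
                     "monounsaturated_fat": (10, 60), "polyunsaturated_fat": (5, 30)},
    "sweets_snacks": {"carbohydrate": (50, 70), "saturated_fat": (5, 18),
                      "total_fat": (10, 30)},
    "drinks": {"carbohydrate": (0, 12), "vitamin_c": (0, 30)},
    "other": {"carbohydrate": (5, 30), "protein": (2, 10), "total_fat": (1, 10)},
}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_users: int = 20
    n_days: int = 35
    meals_per_day: tuple[int, int] = (10, 20)
    meal_pool_size: int = 40
    fraction_vegan_meals: float = 0.15
    allergy_prevalence: float = 0.3
    ffq_items: int = 60
    order_probability: float = 0.75
    taste_bias: float = 4.0  # odds multiplier for meals with preferred ingredients
    start_date: dt.date = dt.date(2022, 1, 17)
    location: str = "hq"
    planted_profile: Mapping[str, Mapping[str, str]] | None = None
    planted_taste: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if self.n_users < 1 or self.n_days < 1 or self.ffq_items < 1:
            raise ValidationError("all counts must be >= 1")
        lo, hi = self.meals_per_day
        if not (1 <= lo <= hi <= 50):
            raise ValidationError("meals_per_day must satisfy 1 <= lo <= hi <= 50")
        for p in (self.fraction_vegan_meals, self.allergy_prevalence,
                  self.order_probability):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")


@dataclass
class World:
    """A complete synthetic deployment."""

    config: GeneratorConfig
    menus: list[Menu]
    users: list[UserProfile]
    items: list[FfqItem]
    composition: list[FoodCompositionEntry]
    responses: list[FfqResponse]
    events: EventLog
    planted_profiles: dict[str, NutrientStatusProfile]
    planted_tastes: dict[str, tuple[str, ...]]
    reference_ranges: dict[str, ReferenceRange]

    def menu_for(self, date: dt.date) -> Menu | None:
        for menu in self.menus:
            if menu.date == date:
                return menu
        return None

    def write(self, directory: str | Path) -> None:
        base = Path(directory)
        (base / "menus").mkdir(parents=True, exist_ok=True)
        for menu in self.menus:
            write_menu(menu, base / "menus" / f"menu_{menu.date.isoformat()}.json")
        write_users(self.users, base / "users.json")
        write_events(self.events, base / "events.csv")
        write_ffq_responses(self.responses, base / "ffq_responses.csv")
        write_composition_table(self.items, self.composition, base / "composition.csv")
        planted = {
            uid: dict(p.status) for uid, p in sorted(self.planted_profiles.items())
        }
        (base / "planted_profiles.json").write_text(json.dumps(planted, indent=2) + "\n")


def _make_meal_pool(rng: np.random.Generator, config: GeneratorConfig) -> list[Meal]:
    names = sorted(INGREDIENT_POOL)
    vegan_names = [n for n in names if INGREDIENT_POOL[n][1]]
    pool: list[Meal] = []
    n_vegan = max(1, round(config.fraction_vegan_meals * config.meal_pool_size))
    for i in range(config.meal_pool_size):
        vegan = i < n_vegan
        source = vegan_names if vegan else names
        k = int(rng.integers(2, 6))
        chosen = list(rng.choice(source, size=min(k, len(source)), replace=False))
        opaque = (not vegan) and rng.random() < 0.1
        ingredients = [
            Ingredient(name=n, allergen_tags=frozenset(INGREDIENT_POOL[n][0]))
            for n in chosen
        ]
        if opaque:
            ingredients.append(Ingredient(name="house sauce", is_composite_opaque=True))
        nutrients = {
            n: float(rng.uniform(lo, hi)) for n, (lo, hi) in MEAL_NUTRIENT_RANGES.items()
        }
        nutrients["energy_kcal"] = float(rng.uniform(250, 900))
        tags = {"vegan", "vegetarian"} if vegan else set()
        pool.append(
            Meal(
                meal_id=f"meal{i:03d}",
                name=f"dish {i:03d}",
                course=COURSES[int(rng.integers(0, len(COURSES)))],
                date=config.start_date,
                location=config.location,
                nutrients=NutrientVector.from_mapping(nutrients),
                ingredients=tuple(ingredients),
                allergen_tags=frozenset(),
                lifestyle_tags=frozenset(tags),
                nutriscore="ABCDE"[int(rng.integers(0, 5))],
            )
        )
    return pool


def _make_menus(
    rng: np.random.Generator, config: GeneratorConfig, pool: list[Meal]
) -> list[Menu]:
    menus = []
    lo, hi = config.meals_per_day
    for d in range(config.n_days):
        date = config.start_date + dt.timedelta(days=d)
        n = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(pool), size=min(n, len(pool)), replace=False)
        meals = tuple(
            dataclasses.replace(pool[i], date=date) for i in sorted(chosen)
        )
        menus.append(Menu(date=date, location=config.location, meals=meals))
    return menus


def _make_users(rng: np.random.Generator, config: GeneratorConfig) -> list[UserProfile]:
    # allergens limited to those actually occurring in the ingredient pool so
    # that allergy filters bite; preferences sampled sparsely
    pool_allergens = sorted({t for tags, _ in INGREDIENT_POOL.values() for t in tags})
    users = []
    for i in range(config.n_users):
        allergies: set[str] = set()
        if rng.random() < config.allergy_prevalence:
            allergies.add(str(rng.choice(pool_allergens)))
        preferences: set[str] = set()
        r = rng.random()
        if r < 0.10:
            preferences.add("vegan")
        elif r < 0.25:
            preferences.add("vegetarian")
        if rng.random() < 0.15:
            preferences.add("coriander")  # avoidance tag: ingredient-level
        users.append(
            UserProfile(
                user_id=f"u{i:03d}",
                allergies=frozenset(allergies),
                preferences=frozenset(preferences),
                location=config.location,
            )
        )
    return users


def _make_item_bank(
    rng: np.random.Generator, config: GeneratorConfig
) -> tuple[list[FfqItem], list[FoodCompositionEntry]]:
    items: list[FfqItem] = []
    comp: list[FoodCompositionEntry] = []
    for i in range(config.ffq_items):
        group = FOOD_GROUPS[i % len(FOOD_GROUPS)]
        ranges = GROUP_COMPOSITION_RANGES[group]
        per100 = {n: 0.0 for n in SCORED_NUTRIENTS}
        for n, (lo, hi) in ranges.items():
            per100[n] = float(rng.uniform(lo, hi))
        # trace amounts of everything else so intakes are generic positives
        for n in SCORED_NUTRIENTS:
            if per100[n] == 0.0:
                per100[n] = float(rng.uniform(0.0, 0.5))
        items.append(
            FfqItem(
                item_id=f"item{i:03d}",
                food_name=f"food {i:03d}",
                food_group=group,
                standard_portion_g=float(rng.choice([50, 100, 150, 200, 250])),
            )
        )
        comp.append(FoodCompositionEntry(item_id=f"item{i:03d}", nutrients_per_100g=per100))
    # pure single-nutrient concentrated sources used for analytic profile
    # planting (synthetic constructs, not foods)
    ranges = load_reference_ranges()
    for n in SCORED_NUTRIENTS:
        per100 = {m: 0.0 for m in SCORED_NUTRIENTS}
        per100[n] = ranges[n].upper_bound  # one 100 g portion/day ~= upper bound
        items.append(
            FfqItem(
                item_id=f"conc_{n}",
                food_name=f"concentrated {n} source (synthetic)",
                food_group="other",
                standard_portion_g=100.0,
            )
        )
        comp.append(FoodCompositionEntry(item_id=f"conc_{n}", nutrients_per_100g=per100))
    return items, comp


def _plant_response(
    rng: np.random.Generator,
    user_id: str,
    timepoint: str,
    target: Mapping[str, str],
    items: Sequence[FfqItem],
    composition: Sequence[FoodCompositionEntry],
    ranges: Mapping[str, ReferenceRange],
) -> FfqResponse:
    """Build an FFQ response whose computed intake classifies exactly as
    ``target`` (Low/Normal/High per nutrient)."""
    from .ffq import compute_intake

    regular = [it for it in items if not it.item_id.startswith("conc_")]
    n_base = min(15, len(regular))
    chosen = rng.choice(len(regular), size=n_base, replace=False)
    base = [
        FfqAnswer(
            item_id=regular[i].item_id,
            frequency_per_day=float(rng.uniform(0.1, 1.5)),
            portion_multiplier=float(rng.uniform(0.5, 2.0)),
        )
        for i in sorted(chosen)
    ]
    intake = compute_intake(
        FfqResponse(user_id, timepoint, tuple(base)), list(items), list(composition)
    ).daily_intake

    # scale the base response so every Low-target nutrient sits safely below
    # its lower bound and no Normal-target nutrient overshoots its midpoint
    s = 1.0
    for n in SCORED_NUTRIENTS:
        if intake[n] <= 0:
            continue
        r = ranges[n]
        if target[n] == "Low":
            s = min(s, 0.8 * r.lower_bound / intake[n])
        elif target[n] == "Normal":
            s = min(s, 0.5 * (r.lower_bound + r.upper_bound) / intake[n])
    answers = [
        dataclasses.replace(a, frequency_per_day=a.frequency_per_day * s) for a in base
    ]

    # top up Normal/High nutrients through the pure concentrated items
    conc = {c.item_id: c.nutrients_per_100g for c in composition}
    for n in SCORED_NUTRIENTS:
        r = ranges[n]
        scaled = intake[n] * s
        if target[n] == "Normal":
            goal = 0.5 * (r.lower_bound + r.upper_bound)
        elif target[n] == "High":
            goal = 1.25 * r.upper_bound
        else:
            continue
        delta = goal - scaled
        if delta <= 0:
            continue
        per100 = conc[f"conc_{n}"][n]
        answers.append(
            FfqAnswer(item_id=f"conc_{n}", frequency_per_day=delta / per100,
                      portion_multiplier=1.0)
        )
    return FfqResponse(user_id=user_id, timepoint=timepoint, answers=tuple(answers))


def _random_profile(rng: np.random.Generator) -> dict[str, str]:
    return {
        n: str(rng.choice(["Low", "Normal", "High"], p=[0.35, 0.45, 0.20]))
        for n in SCORED_NUTRIENTS
    }


def _make_events(
    rng: np.random.Generator,
    config: GeneratorConfig,
    menus: Sequence[Menu],
    users: Sequence[UserProfile],
    tastes: Mapping[str, tuple[str, ...]],
) -> EventLog:
    log = EventLog()
    for user in users:
        preferred = frozenset(tastes.get(user.user_id, ()))
        for menu in menus:
            if rng.random() >= config.order_probability:
                continue
            weights = np.array(
                [
                    config.taste_bias
                    if preferred and (preferred & m.ingredient_names())
                    else 1.0
                    for m in menu.meals
                ]
            )
            probs = weights / weights.sum()
            meal = menu.meals[int(rng.choice(len(menu.meals), p=probs))]
            log.orders.append(OrderEvent(user.user_id, meal.meal_id, menu.date))
            fb = rng.random()
            if fb < 0.15:
                log.feedback.append(
                    FeedbackEvent(user.user_id, meal.meal_id, menu.date, "up")
                )
            elif fb < 0.23:
                other = menu.meals[int(rng.integers(0, len(menu.meals)))]
                if other.ingredients:
                    disliked = str(
                        rng.choice(sorted(other.ingredient_names()))
                    )
                    log.feedback.append(
                        FeedbackEvent(
                            user.user_id, other.meal_id, menu.date, "down",
                            disliked_ingredients=(disliked,),
                        )
                    )
            shown = rng.choice(
                len(menu.meals), size=min(5, len(menu.meals)), replace=False
            )
            log.recommendations.append(
                RecommendationRecord(
                    user.user_id, menu.date,
                    tuple(menu.meals[i].meal_id for i in shown),
                )
            )
    return log.sort()


def generate_world(config: GeneratorConfig) -> World:
    """Generate a complete, deterministic synthetic deployment.

    The same config (including seed) always yields byte-identical serialized
    output; sub-generators draw from split seed streams so, e.g., adding
    users does not perturb the menus.
    """
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_menu, rng_users, rng_ffq, rng_orders = (
        np.random.default_rng(s) for s in streams
    )

    pool = _make_meal_pool(rng_menu, config)
    menus = _make_menus(rng_menu, config, pool)
    users = _make_users(rng_users, config)
    items, composition = _make_item_bank(rng_ffq, config)
    ranges = load_reference_ranges()

    planted_profiles: dict[str, NutrientStatusProfile] = {}
    responses: list[FfqResponse] = []
    for user in users:
        if config.planted_profile and user.user_id in config.planted_profile:
            target = dict(config.planted_profile[user.user_id])
        else:
            target = _random_profile(rng_ffq)
        planted_profiles[user.user_id] = NutrientStatusProfile(user.user_id, target)
        for timepoint in ("baseline", "post"):
            responses.append(
                _plant_response(
                    rng_ffq, user.user_id, timepoint, target, items, composition, ranges
                )
            )

    tastes: dict[str, tuple[str, ...]] = {}
    for user in users:
        if config.planted_taste and user.user_id in config.planted_taste:
            tastes[user.user_id] = tuple(config.planted_taste[user.user_id])
        else:
            names = sorted(INGREDIENT_POOL)
            tastes[user.user_id] = tuple(
                sorted(rng_orders.choice(names, size=3, replace=False))
            )
    events = _make_events(rng_orders, config, menus, users, tastes)

    return World(
        config=config,
        menus=menus,
        users=users,
        items=items,
        composition=composition,
        responses=responses,
        events=events,
        planted_profiles=planted_profiles,
        planted_tastes=tastes,
        reference_ranges=dict(ranges),
    )


# ------------------------------------------------------------ toy example

@dataclass(frozen=True)
class ToyExample:
    """Fixed 2-user, 3-meal, fully hand-checkable bundle.

    Construction (all other nutrients equal across meals, so they normalize
    to the neutral 0.5 and contribute identically):

    ========  ======  ========  =======================  ==================
    meal      fiber   protein   normalized (fib, prot)   ingredients
    ========  ======  ========  =======================  ==================
    toy-m1    8       10        (1.0, 0.0)               lentils, tomato, spinach
    toy-m2    2       30        (0.0, 1.0)               chicken, rice
    toy-m3    5       20        (0.5, 0.5)               tomato, pasta
    ========  ======  ========  =======================  ==================

    User ``alice`` is Low fiber (weight 5), High protein (weight −0.3),
    Normal otherwise; raw knowledge = 5·fib − 0.3·prot:
    m1 = 5.0, m2 = −0.3, m3 = 2.35 → min–max rescaled 1.0, 0.0, 0.5.
    Alice once ordered ``toy-past`` (lentils, tomato), so her taste vector is
    {lentils: 1, tomato: 1}; content scores are (cos+1)/2 with cosines
    2/√6 (m1), 0 (m2), 1/2 (m3). Her one order is 7 days old, so the
    collaborative component is inactive (0 everywhere) and finals are

        m1: 0.65·1.0 + 0.25·(2/√6+1)/2  ≈ 0.877062
        m3: 0.65·0.5 + 0.25·0.75        =  0.5125
        m2: 0.65·0.0 + 0.25·0.5         =  0.125

    User ``bob`` is all-Normal with no history: every component is neutral
    (knowledge 0.5, content 0.5, collaborative 0) and every final is 0.45.
    """

    today: dt.date
    menu: Menu
    past_menu: Menu
    users: tuple[UserProfile, UserProfile]
    profiles: dict[str, NutrientStatusProfile]
    events: EventLog
    expected_finals: dict[str, dict[str, float]]
    expected_ranking: dict[str, tuple[str, ...]]


def generate_toy_worked_example() -> ToyExample:
    import math

    today = dt.date(2022, 1, 17)
    location = "hq"
    base = {n: 10.0 for n in SCORED_NUTRIENTS}

    def nv(fiber: float, protein: float) -> NutrientVector:
        vals = dict(base)
        vals["fiber"], vals["protein"] = fiber, protein
        return NutrientVector.from_mapping(vals)

    def meal(mid: str, fiber: float, protein: float, ingredients: tuple[str, ...],
             date: dt.date) -> Meal:
        return Meal(
            meal_id=mid, name=mid, course="main", date=date, location=location,
            nutrients=nv(fiber, protein),
            ingredients=tuple(Ingredient(name=n) for n in ingredients),
            nutriscore="B",
        )

    menu = Menu(
        date=today, location=location,
        meals=(
            meal("toy-m1", 8, 10, ("lentils", "tomato", "spinach"), today),
            meal("toy-m2", 2, 30, ("chicken", "rice"), today),
            meal("toy-m3", 5, 20, ("tomato", "pasta"), today),
        ),
    )
    past_date = today - dt.timedelta(days=7)
    past_menu = Menu(
        date=past_date, location=location,
        meals=(meal("toy-past", 6, 15, ("lentils", "tomato"), past_date),),
    )
    alice = UserProfile(user_id="alice", location=location)
    bob = UserProfile(user_id="bob", location=location)
    status = {n: "Normal" for n in SCORED_NUTRIENTS}
    status["fiber"], status["protein"] = "Low", "High"
    profiles = {
        "alice": NutrientStatusProfile("alice", status),
        "bob": NutrientStatusProfile.all_normal("bob"),
    }
    events = EventLog(orders=[OrderEvent("alice", "toy-past", past_date)]).sort()

    c1 = (2 / math.sqrt(6) + 1) / 2
    expected_finals = {
        "alice": {
            "toy-m1": 0.65 * 1.0 + 0.25 * c1,
            "toy-m2": 0.25 * 0.5,
            "toy-m3": 0.65 * 0.5 + 0.25 * 0.75,
        },
        "bob": {m: 0.65 * 0.5 + 0.25 * 0.5 for m in ("toy-m1", "toy-m2", "toy-m3")},
    }
    expected_ranking = {
        "alice": ("toy-m1", "toy-m3", "toy-m2"),
        "bob": ("toy-m1", "toy-m2", "toy-m3"),  # all tied -> meal_id order
    }
    return ToyExample(
        today=today, menu=menu, past_menu=past_menu, users=(alice, bob),
        profiles=profiles, events=events,
        expected_finals=expected_finals, expected_ranking=expected_ranking,
    )
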