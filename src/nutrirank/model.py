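"""Domain types for menus, meals, users, and interaction events.

The scored nutrient set is fixed: twelve nutrients, stored **per portion**
(not per 100 g) because both the weighting scheme and the food-frequency
arithmetic operate on consumed portions. Tags (allergens, lifestyle
preferences) come from two closed controlled vocabularies shipped with the
package and are normalized to lowercase with internal spaces preserved;
matching is exact after normalization.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

#: Canonical order of the scored nutrients. Units per portion:
#: fiber g, vitamin_a µg RE, vitamin_b12 µg, vitamin_c mg, fats/protein/
#: carbohydrate g, calcium mg, iron mg.
SCORED_NUTRIENTS: tuple[str, ...] = (
    "fiber",
    "vitamin_a",
    "vitamin_b12",
    "vitamin_c",
    "monounsaturated_fat",
    "polyunsaturated_fat",
    "protein",
    "total_fat",
    "calcium",
    "iron",
    "saturated_fat",
    "carbohydrate",
)

COURSES: tuple[str, ...] = ("soup", "salad", "main", "side", "dessert", "sandwich")
NUTRISCORE_LETTERS: tuple[str, ...] = ("A", "B", "C", "D", "E")

#: Lifestyle tags treated as required diet tags (meal must carry them);
#: every other preference tag is an avoidance tag (meal must not carry it,
#: as a lifestyle tag or as an ingredient name).
REQUIRED_DIET_TAGS: frozenset[str] = frozenset({"vegan", "vegetarian", "halal", "kosher"})


class ValidationError(ValueError):
    """Raised when an input violates a schema invariant or vocabulary."""


def normalize_tag(tag: str) -> str:
    return " ".join(tag.strip().lower().split())


def _check_tags(tags: Iterable[str], vocabulary: frozenset[str], what: str) -> frozenset[str]:
    out = frozenset(normalize_tag(t) for t in tags)
    unknown = out - vocabulary
    if unknown:
        raise ValidationError(f"unknown {what} tag(s): {sorted(unknown)}")
    return out


@dataclass(frozen=True)
class Vocabulary:
    """Ordered set of canonical lowercase tags."""

    name: str
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        norm = tuple(normalize_tag(t) for t in self.tags)
        if len(set(norm)) != len(norm):
            dupes = sorted({t for t in norm if norm.count(t) > 1})
            raise ValidationError(f"duplicate tag(s) in {self.name} vocabulary: {dupes}")
        if not norm:
            raise ValidationError(f"{self.name} vocabulary is empty")
        object.__setattr__(self, "tags", norm)

    def __contains__(self, tag: str) -> bool:
        return normalize_tag(tag) in self.as_set()

    def __len__(self) -> int:
        return len(self.tags)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.tags)


def _load_vocab_file(path_or_text: str, name: str) -> Vocabulary:
    lines = [ln.strip() for ln in path_or_text.splitlines()]
    tags = tuple(ln for ln in lines if ln and not ln.startswith("#"))
    if not tags:
        raise ValidationError(f"{name} vocabulary file is empty")
    return Vocabulary(name=name, tags=tags)


def load_vocabularies(config_dir: str | None = None) -> tuple[Vocabulary, Vocabulary]:
    """Load the allergen and preference vocabularies.

    With ``config_dir=None`` the canonical vocabularies bundled with the
    package are used (34 allergen tags, 31 preference tags). A directory
    containing ``allergens.txt`` and ``preferences.txt`` (one tag per line,
    ``#`` comments allowed) may be supplied to override them.
    """
    if config_dir is None:
        pkg = resources.files("nutrirank.data")
        allergen_text = (pkg / "allergens.txt").read_text()
        pref_text = (pkg / "preferences.txt").read_text()
    else:
        from pathlib import Path

        base = Path(config_dir)
        allergen_text = (base / "allergens.txt").read_text()
        pref_text = (base / "preferences.txt").read_text()
    return (
        _load_vocab_file(allergen_text, "allergen"),
        _load_vocab_file(pref_text, "preference"),
    )


@dataclass(frozen=True)
class NutrientVector:
    """Per-portion amounts of the twelve scored nutrients (+ display energy)."""

    fiber: float
    vitamin_a: float
    vitamin_b12: float
    vitamin_c: float
    monounsaturated_fat: float
    polyunsaturated_fat: float
    protein: float
    total_fat: float
    calcium: float
    iron: float
    saturated_fat: float
    carbohydrate: float
    energy_kcal: float | None = None

    def __post_init__(self) -> None:
        for n in SCORED_NUTRIENTS:
            v = getattr(self, n)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"nutrient {n!r} must be finite and >= 0, got {v}")

    @classmethod
    def from_mapping(cls, values: dict) -> "NutrientVector":
        missing = [n for n in SCORED_NUTRIENTS if n not in values or values[n] is None]
        if missing:
            raise ValidationError(f"missing scored nutrient(s): {missing}")
        kwargs = {n: float(values[n]) for n in SCORED_NUTRIENTS}
        if values.get("energy_kcal") is not None:
            kwargs["energy_kcal"] = float(values["energy_kcal"])
        return cls(**kwargs)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SCORED_NUTRIENTS], dtype=float)

    def as_dict(self) -> dict[str, float]:
        d = {n: getattr(self, n) for n in SCORED_NUTRIENTS}
        if self.energy_kcal is not None:
            d["energy_kcal"] = self.energy_kcal
        return d


@dataclass(frozen=True)
class Ingredient:
    """One ingredient of a meal.

    ``is_composite_opaque`` marks unresolved composites (e.g. a ready-made
    sauce whose constituents are unknown); in strict safety mode such a meal
    is treated as unsafe for any user with at least one allergy.
    """

    name: str
    allergen_tags: frozenset[str] = frozenset()
    sub_ingredients: tuple[str, ...] = ()
    is_composite_opaque: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", normalize_tag(self.name))
        object.__setattr__(
            self, "allergen_tags", frozenset(normalize_tag(t) for t in self.allergen_tags)
        )
        object.__setattr__(
            self, "sub_ingredients", tuple(normalize_tag(s) for s in self.sub_ingredients)
        )


@dataclass(frozen=True)
class Meal:
    meal_id: str
    name: str
    course: str
    date: dt.date
    location: str
    nutrients: NutrientVector
    ingredients: tuple[Ingredient, ...] = ()
    allergen_tags: frozenset[str] = frozenset()
    lifestyle_tags: frozenset[str] = frozenset()
    nutriscore: str = "C"

    def __post_init__(self) -> None:
        if self.course not in COURSES:
            raise ValidationError(f"meal {self.meal_id!r}: unknown course {self.course!r}")
        if self.nutriscore not in NUTRISCORE_LETTERS:
            raise ValidationError(
                f"meal {self.meal_id!r}: nutriscore must be one of {NUTRISCORE_LETTERS}, "
                f"got {self.nutriscore!r}"
            )
        object.__setattr__(
            self, "allergen_tags", frozenset(normalize_tag(t) for t in self.allergen_tags)
        )
        object.__setattr__(
            self, "lifestyle_tags", frozenset(normalize_tag(t) for t in self.lifestyle_tags)
        )
        object.__setattr__(self, "ingredients", tuple(self.ingredients))

    def all_allergen_tags(self) -> frozenset[str]:
        """Meal-level plus ingredient-level allergen tags."""
        tags = set(self.allergen_tags)
        for ing in self.ingredients:
            tags |= ing.allergen_tags
        return frozenset(tags)

    def ingredient_names(self) -> frozenset[str]:
        return frozenset(ing.name for ing in self.ingredients)

    def has_opaque_composite(self) -> bool:
        return any(ing.is_composite_opaque for ing in self.ingredients)


@dataclass(frozen=True)
class Menu:
    date: dt.date
    location: str
    meals: tuple[Meal, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "meals", tuple(self.meals))
        if not 1 <= len(self.meals) <= 50:
            raise ValidationError(f"menu must have 1-50 meals, got {len(self.meals)}")
        ids = [m.meal_id for m in self.meals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate meal_id(s) in menu: {dupes}")
        for m in self.meals:
            if m.date != self.date or m.location != self.location:
                raise ValidationError(
                    f"meal {m.meal_id!r} date/location does not match menu "
                    f"({m.date}/{m.location} vs {self.date}/{self.location})"
                )

    def validate_vocabulary(self, allergens: Vocabulary, preferences: Vocabulary) -> None:
        av, pv = allergens.as_set(), preferences.as_set()
        for m in self.meals:
            _check_tags(m.all_allergen_tags(), av, "allergen")
            _check_tags(m.lifestyle_tags, pv, "preference")


@dataclass(frozen=True)
class UserProfile:
    user_id: str
    allergies: frozenset[str] = frozenset()
    preferences: frozenset[str] = frozenset()
    location: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "allergies", frozenset(normalize_tag(t) for t in self.allergies)
        )
        object.__setattr__(
            self, "preferences", frozenset(normalize_tag(t) for t in self.preferences)
        )

    def validate_vocabulary(self, allergens: Vocabulary, preferences: Vocabulary) -> None:
        _check_tags(self.allergies, allergens.as_set(), "allergen")
        _check_tags(self.preferences, preferences.as_set(), "preference")


@dataclass(frozen=True)
class OrderEvent:
    user_id: str
    meal_id: str
    date: dt.date


@dataclass(frozen=True)
class FeedbackEvent:
    user_id: str
    meal_id: str
    date: dt.date
    polarity: str  # "up" | "down"
    disliked_ingredients: tuple[str, ...] = ()
    text: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("up", "down"):
            raise ValidationError(f"unknown feedback polarity {self.polarity!r}")
        object.__setattr__(
            self,
            "disliked_ingredients",
            tuple(normalize_tag(i) for i in self.disliked_ingredients),
        )
        if self.polarity == "up" and self.disliked_ingredients:
            raise ValidationError("thumbs-up feedback must not carry disliked ingredients")


@dataclass(frozen=True)
class RecommendationRecord:
    user_id: str
    date: dt.date
    meal_ids: tuple[str, ...] = ()  # ranked list actually shown

    def __post_init__(self) -> None:
        object.__setattr__(self, "meal_ids", tuple(self.meal_ids))


@dataclass
class EventLog:
    """All interaction events, kept sorted by date (stable within a day)."""

    orders: list[OrderEvent] = field(default_factory=list)
    feedback: list[FeedbackEvent] = field(default_factory=list)
    recommendations: list[RecommendationRecord] = field(default_factory=list)

    def sort(self) -> "EventLog":
        self.orders.sort(key=lambda e: (e.date, e.user_id, e.meal_id))
        self.feedback.sort(key=lambda e: (e.date, e.user_id, e.meal_id))
        self.recommendations.sort(key=lambda e: (e.date, e.user_id))
        return self

    def __len__(self) -> int:
        return len(self.orders) + len(self.feedback) + len(self.recommendations)


def parse_date(value: str | dt.date) -> dt.date:
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"invalid ISO-8601 date {value!r}") from exc


def meal_archive(menus: Sequence[Menu]) -> dict[str, Meal]:
    """Index all meals across menus by meal_id (later menus win on collision)."""
    archive: dict[str, Meal] = {}
    for menu in menus:
        for meal in menu.meals:
            archive[meal.meal_id] = meal
    return archive
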