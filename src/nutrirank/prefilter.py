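"""Contextual prefilter: restrict a menu to safe, relevant, non-repetitive
candidates before any scoring.

Exclusion passes run in a fixed order — location mismatch, allergen safety,
lifestyle constraints, recency — and every removal is logged with its first
triggering reason. Lifestyle preferences split into *required diet tags*
(vegan, vegetarian, halal, kosher: the meal must carry the tag) and
*avoidance tags* (everything else, e.g. "coriander" or "caffeine": the meal
must not carry the tag or contain an ingredient of that name).

Allergen safety is conservative: in strict composite mode a meal containing
an unresolved composite ingredient (constituents unknown) is unsafe for any
user with at least one allergy. If filtering leaves fewer than
``min_candidates`` meals, recency exclusions are restored (most stale first)
— safety and lifestyle exclusions are never restored.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

from .model import (
    REQUIRED_DIET_TAGS,
    Meal,
    Menu,
    OrderEvent,
    RecommendationRecord,
    UserProfile,
    ValidationError,
)

EXCLUSION_REASONS = ("location", "allergen", "lifestyle", "recency")


@dataclass(frozen=True)
class FilterConfig:
    recency_window: int = 3  # days
    recency_source: str = "recommendations"  # recommendations | orders | both
    strict_composite_mode: bool = True
    min_candidates: int = 3

    def __post_init__(self) -> None:
        if self.recency_window < 0:
            raise ValidationError("recency_window must be >= 0")
        if self.min_candidates < 1:
            raise ValidationError("min_candidates must be >= 1")
        if self.recency_source not in ("recommendations", "orders", "both"):
            raise ValidationError(f"unknown recency_source {self.recency_source!r}")


@dataclass(frozen=True)
class CandidateSet:
    date: dt.date
    user_id: str
    meals: tuple[Meal, ...]
    exclusion_log: tuple[tuple[str, str], ...] = ()  # (meal_id, reason)

    def excluded_ids(self) -> frozenset[str]:
        return frozenset(mid for mid, _ in self.exclusion_log)

    def reason_for(self, meal_id: str) -> str | None:
        for mid, reason in self.exclusion_log:
            if mid == meal_id:
                return reason
        return None


def allergen_match(meal: Meal, allergies: frozenset[str] | set[str],
                   strict_composite: bool = True) -> bool:
    """True when the meal is unsafe for a user with the given allergies.

    Unsafe if any meal- or ingredient-level allergen tag intersects the
    allergies, or — in strict composite mode — if the meal contains an
    unresolved composite ingredient and the user has any allergy at all
    (unknown composition is treated as unsafe).
    """
    allergies = frozenset(allergies)
    if not allergies:
        return False
    if meal.all_allergen_tags() & allergies:
        return True
    if strict_composite and meal.has_opaque_composite():
        return True
    return False


def lifestyle_match(meal: Meal, preferences: frozenset[str] | set[str]) -> bool:
    """True when the meal violates a lifestyle preference (and must be excluded)."""
    for tag in preferences:
        if tag in REQUIRED_DIET_TAGS:
            if tag not in meal.lifestyle_tags:
                return True
        else:
            if tag in meal.lifestyle_tags or tag in meal.ingredient_names():
                return True
    return False


def _recent_dates(today: dt.date, window: int) -> tuple[dt.date, dt.date] | None:
    if window <= 0:
        return None
    return (today - dt.timedelta(days=window), today - dt.timedelta(days=1))


def recency_excluded(
    meal_id: str,
    user_id: str,
    recommendations: Sequence[RecommendationRecord],
    orders: Sequence[OrderEvent],
    today: dt.date,
    config: FilterConfig,
) -> bool:
    """True iff the meal was shown/ordered to this user within the window
    [today − recency_window, today − 1] (calendar dates)."""
    return _last_seen(meal_id, user_id, recommendations, orders, today, config) is not None


def _last_seen(
    meal_id: str,
    user_id: str,
    recommendations: Sequence[RecommendationRecord],
    orders: Sequence[OrderEvent],
    today: dt.date,
    config: FilterConfig,
) -> dt.date | None:
    """Most recent in-window date the meal was recommended/ordered, or None."""
    span = _recent_dates(today, config.recency_window)
    if span is None:
        return None
    start, end = span
    seen: list[dt.date] = []
    if config.recency_source in ("recommendations", "both"):
        seen += [
            r.date
            for r in recommendations
            if r.user_id == user_id and meal_id in r.meal_ids and start <= r.date <= end
        ]
    if config.recency_source in ("orders", "both"):
        seen += [
            o.date
            for o in orders
            if o.user_id == user_id and o.meal_id == meal_id and start <= o.date <= end
        ]
    return max(seen) if seen else None


def apply_prefilter(
    menu: Menu,
    user: UserProfile,
    today: dt.date,
    recommendations: Sequence[RecommendationRecord] = (),
    orders: Sequence[OrderEvent] = (),
    config: FilterConfig | None = None,
) -> CandidateSet:
    """Filter a menu down to the candidate set for one user.

    Passes apply in order (location, allergen, lifestyle, recency); the
    exclusion log records each removed meal with its first triggering reason,
    so candidates plus log partition the input menu. When fewer than
    ``min_candidates`` survive, recency exclusions are restored most-stale
    first (safety/lifestyle exclusions never are).
    """
    if not menu.meals:
        raise ValidationError("cannot prefilter an empty menu")
    config = config or FilterConfig()

    kept: list[Meal] = []
    log: list[tuple[str, str]] = []
    recency_pool: list[tuple[dt.date, str, Meal]] = []  # (last_seen, meal_id, meal)

    for meal in menu.meals:
        if user.location and meal.location != user.location:
            log.append((meal.meal_id, "location"))
            continue
        if allergen_match(meal, user.allergies, config.strict_composite_mode):
            log.append((meal.meal_id, "allergen"))
            continue
        if lifestyle_match(meal, user.preferences):
            log.append((meal.meal_id, "lifestyle"))
            continue
        last = _last_seen(
            meal.meal_id, user.user_id, recommendations, orders, today, config
        )
        if last is not None:
            log.append((meal.meal_id, "recency"))
            recency_pool.append((last, meal.meal_id, meal))
            continue
        kept.append(meal)

    # variety fallback: restore recency exclusions, most stale first, but
    # never a safety or lifestyle exclusion
    if len(kept) < config.min_candidates and recency_pool:
        recency_pool.sort(key=lambda t: (t[0], t[1]))  # oldest sighting first
        while len(kept) < config.min_candidates and recency_pool:
            _, mid, meal = recency_pool.pop(0)
            kept.append(meal)
            log.remove((mid, "recency"))

    order = {m.meal_id: i for i, m in enumerate(menu.meals)}
    kept.sort(key=lambda m: order[m.meal_id])
    return CandidateSet(
        date=menu.date, user_id=user.user_id, meals=tuple(kept), exclusion_log=tuple(log)
    )
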