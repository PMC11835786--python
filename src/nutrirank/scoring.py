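"""The three component scorers and their fixed-weight hybrid combination.

The final ranking score of a candidate meal is a convex combination of three
components, each in [0, 1]:

    final = 0.65 * knowledge + 0.25 * content + 0.10 * collaborative

* **knowledge** — how well the meal's nutrients address the user's
  Low/Normal/High nutrient-status profile, via a per-(nutrient, status)
  weight table. Nutrient amounts are min–max normalized across today's
  candidate set, the weighted sum is taken, and the raw sums are min–max
  rescaled to [0, 1] across the same candidates (rank-preserving).
* **content** — cosine similarity between the meal's binary ingredient
  vector and the user's taste vector accumulated from orders (+1 per
  ingredient), thumbs-up (+1) and thumbs-down (−2 on the explicitly
  disliked ingredients only), mapped from [−1, 1] to [0, 1].
* **collaborative** — among the user's k nearest neighbours (cosine over
  meal-order-count vectors), the fraction who ever ordered the meal. Inactive
  (0 for every meal, rank-neutral) until the system has accumulated
  ``activation_days`` (default 14) days of order history or while the user
  has no orders.

All ties are broken deterministically so identical inputs always give
identical rankings.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ffq import NutrientStatusProfile, STATUSES
from .model import (
    SCORED_NUTRIENTS,
    EventLog,
    FeedbackEvent,
    Meal,
    OrderEvent,
    ValidationError,
)
from .prefilter import CandidateSet

logger = logging.getLogger(__name__)

#: Default hybrid mixture: nutritional alignment dominates at 65%, user taste
#: contributes 25%, and meal popularity among similar users only 10%.
DEFAULT_HYBRID = (0.65, 0.25, 0.10)

#: Default (low, normal, high) scoring weights per nutrient. "Normal" is
#: always 0: a nutrient the user already consumes at the recommended level
#: neither promotes nor demotes a meal.
DEFAULT_WEIGHTS: dict[str, tuple[float, float, float]] = {
    "fiber": (5, 0, 0),
    "vitamin_a": (2, 0, 0),
    "vitamin_b12": (3, 0, 0),
    "vitamin_c": (5, 0, 0),
    "monounsaturated_fat": (1, 0, 0),
    "polyunsaturated_fat": (3, 0, -0.5),
    "protein": (3, 0, -0.3),
    "total_fat": (-1, 0, -1),
    "calcium": (5, 0, 0),
    "iron": (2, 0, 0),
    "saturated_fat": (0, 0, -1),
    "carbohydrate": (3, 0, -0.5),
}


@dataclass(frozen=True)
class WeightTable:
    """Mapping (nutrient, status) -> scoring weight."""

    weights: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            (n, s): w
            for n, (lo, no, hi) in DEFAULT_WEIGHTS.items()
            for s, w in zip(STATUSES, (lo, no, hi))
        }
    )

    def __post_init__(self) -> None:
        for n in SCORED_NUTRIENTS:
            for s in STATUSES:
                if (n, s) not in self.weights:
                    raise ValidationError(f"weight table missing entry ({n}, {s})")

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.weights[key]

    @classmethod
    def from_mapping(cls, doc: Mapping[str, Mapping[str, float]]) -> "WeightTable":
        """Build from a nested mapping ``{nutrient: {low/normal/high: w}}``."""
        weights = {}
        for n, row in doc.items():
            for s in STATUSES:
                weights[(n, s)] = float(row[s.lower()])
        return cls(weights=weights)


@dataclass(frozen=True)
class HybridWeights:
    knowledge: float = DEFAULT_HYBRID[0]
    content: float = DEFAULT_HYBRID[1]
    collaborative: float = DEFAULT_HYBRID[2]

    def __post_init__(self) -> None:
        vals = (self.knowledge, self.content, self.collaborative)
        if any(v < 0 for v in vals):
            raise ValidationError("hybrid weights must be >= 0")
        if abs(sum(vals) - 1.0) > 1e-12:
            raise ValidationError(f"hybrid weights must sum to 1, got {sum(vals)!r}")


@dataclass(frozen=True)
class ComponentScores:
    meal_id: str
    knowledge: float
    content: float
    collaborative: float
    final: float


@dataclass(frozen=True)
class TasteVector:
    """Per-user weights over ingredient names learned from interaction events."""

    user_id: str
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not math.isfinite(w) for w in self.weights.values()):
            raise ValidationError("taste vector weights must be finite")

    def is_cold(self) -> bool:
        return not any(self.weights.values())

    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))


@dataclass(frozen=True)
class NeighborInfo:
    """Collaborative-filter context for one user on one day (for explanations)."""

    active: bool
    neighbor_ids: tuple[str, ...] = ()
    ordered_fraction: Mapping[str, float] = field(default_factory=dict)  # meal_id -> frac


def normalize_nutrients(candidates: CandidateSet | Sequence[Meal]) -> pd.DataFrame:
    """Min–max normalize each scored nutrient across the candidate set.

    Returns a meals × nutrients frame in [0, 1] indexed by meal_id. A
    constant column maps to 0.5 everywhere (no information, neutral).
    """
    meals = list(candidates.meals if isinstance(candidates, CandidateSet) else candidates)
    if not meals:
        raise ValidationError("cannot normalize an empty candidate set")
    raw = pd.DataFrame(
        [m.nutrients.as_array() for m in meals],
        index=[m.meal_id for m in meals],
        columns=list(SCORED_NUTRIENTS),
        dtype=float,
    )
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    span = hi - lo
    out = raw.copy()
    constant = span <= 0
    out.loc[:, constant] = 0.5
    vary = ~constant
    out.loc[:, vary] = (raw.loc[:, vary] - lo[vary]) / span[vary]
    return out


def _minmax_rescale(values: pd.Series) -> pd.Series:
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        return pd.Series(0.5, index=values.index)
    return (values - lo) / (hi - lo)


def knowledge_scores(
    meal_norm: pd.DataFrame, profile: NutrientStatusProfile, table: WeightTable
) -> tuple[pd.Series, pd.Series]:
    """Raw and [0, 1]-rescaled knowledge scores for every candidate.

    raw[meal] = sum over nutrients of table[nutrient, status] * normalized
    amount; the scaled series is the min–max rescaling of raw across the
    candidate set (constant -> 0.5). Rescaling preserves the ranking the
    hybrid weight acts on.
    """
    w = np.array([table[(n, profile.status[n])] for n in SCORED_NUTRIENTS])
    raw = pd.Series(meal_norm.to_numpy() @ w, index=meal_norm.index)
    return raw, _minmax_rescale(raw)


def knowledge_score(
    meal_norm_row: Mapping[str, float] | pd.Series,
    profile: NutrientStatusProfile,
    table: WeightTable,
) -> float:
    """Raw knowledge score of a single normalized meal row."""
    return float(
        sum(table[(n, profile.status[n])] * meal_norm_row[n] for n in SCORED_NUTRIENTS)
    )


def build_taste_vector(
    user_id: str,
    orders: Sequence[OrderEvent],
    feedback: Sequence[FeedbackEvent],
    menu_archive: Mapping[str, Meal],
) -> TasteVector:
    """Accumulate a user's ingredient taste vector from their events.

    Each ordered meal adds +1 to each of its ingredient names; a thumbs-up
    does likewise; a thumbs-down adds −2 to each explicitly disliked
    ingredient (and nothing else — a dislike is about those ingredients, not
    the whole meal). Events on meals absent from the archive are skipped with
    a warning.
    """
    weights: dict[str, float] = {}
    for ev in orders:
        if ev.user_id != user_id:
            continue
        meal = menu_archive.get(ev.meal_id)
        if meal is None:
            logger.warning("order references unknown meal %r; skipped", ev.meal_id)
            continue
        for name in meal.ingredient_names():
            weights[name] = weights.get(name, 0.0) + 1.0
    for ev in feedback:
        if ev.user_id != user_id:
            continue
        if ev.polarity == "up":
            meal = menu_archive.get(ev.meal_id)
            if meal is None:
                logger.warning("feedback references unknown meal %r; skipped", ev.meal_id)
                continue
            for name in meal.ingredient_names():
                weights[name] = weights.get(name, 0.0) + 1.0
        else:
            for name in ev.disliked_ingredients:
                weights[name] = weights.get(name, 0.0) - 2.0
    return TasteVector(user_id=user_id, weights=weights)


def content_score(meal: Meal, taste: TasteVector) -> float:
    """Cosine similarity of the meal's ingredients with the taste vector,
    mapped from [−1, 1] to [0, 1]; a cold (zero) taste vector is neutral 0.5.
    """
    ingredients = meal.ingredient_names()
    taste_norm = taste.norm()
    if taste_norm == 0 or not ingredients:
        return 0.5
    dot = sum(taste.weights.get(name, 0.0) for name in ingredients)
    cosine = dot / (math.sqrt(len(ingredients)) * taste_norm)
    return (cosine + 1.0) / 2.0


def _order_count_vectors(orders: Sequence[OrderEvent]) -> dict[str, dict[str, int]]:
    vectors: dict[str, dict[str, int]] = {}
    for ev in orders:
        vectors.setdefault(ev.user_id, {}).setdefault(ev.meal_id, 0)
        vectors[ev.user_id][ev.meal_id] += 1
    return vectors


def _cosine_counts(a: Mapping[str, int], b: Mapping[str, int]) -> float:
    dot = sum(v * b.get(k, 0) for k, v in a.items())
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    if na == 0 or nb == 0:
        return 0.0
    return dot / (na * nb)


def nearest_neighbors(
    user_id: str, orders: Sequence[OrderEvent], k: int
) -> tuple[str, ...]:
    """Top-k other users by cosine similarity of meal-order-count vectors,
    ties broken by alphabetical user_id."""
    vectors = _order_count_vectors(orders)
    own = vectors.get(user_id, {})
    others = sorted(uid for uid in vectors if uid != user_id)
    ranked = sorted(others, key=lambda uid: (-_cosine_counts(own, vectors[uid]), uid))
    return tuple(ranked[:k])


def history_days(orders: Sequence[OrderEvent], today: dt.date) -> int:
    """Calendar days of accumulated order history, counting the first order's
    day as day 1. Zero when the log is empty."""
    if not orders:
        return 0
    first = min(ev.date for ev in orders)
    return max((today - first).days + 1, 0)


def collaborative_scores(
    candidates: Sequence[Meal],
    user_id: str,
    orders: Sequence[OrderEvent],
    today: dt.date,
    k: int = 5,
    activation_days: int = 14,
) -> tuple[dict[str, float], NeighborInfo]:
    """Fraction of the user's k nearest neighbours who ever ordered each
    candidate meal.

    Rank-neutral cold start: before ``activation_days`` days of system
    history, or while the user has no orders of their own, every meal scores
    0 and the component is reported inactive.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    past = [ev for ev in orders if ev.date <= today]
    user_orders = [ev for ev in past if ev.user_id == user_id]
    if history_days(past, today) < activation_days or not user_orders:
        return {m.meal_id: 0.0 for m in candidates}, NeighborInfo(active=False)
    neighbors = nearest_neighbors(user_id, past, k)
    if not neighbors:
        return {m.meal_id: 0.0 for m in candidates}, NeighborInfo(active=False)
    ordered_by: dict[str, set[str]] = {}
    for ev in past:
        ordered_by.setdefault(ev.user_id, set()).add(ev.meal_id)
    fractions = {
        m.meal_id: sum(m.meal_id in ordered_by.get(nb, set()) for nb in neighbors)
        / len(neighbors)
        for m in candidates
    }
    return fractions, NeighborInfo(
        active=True, neighbor_ids=neighbors, ordered_fraction=fractions
    )


@dataclass(frozen=True)
class RankingResult:
    """Full per-candidate scoring context, as needed by the explainer."""

    scores: tuple[ComponentScores, ...]  # descending by final score
    meal_norm: pd.DataFrame
    knowledge_raw: pd.Series
    neighbor_info: NeighborInfo
    weights: HybridWeights

    def __iter__(self):
        return iter(self.scores)

    def for_meal(self, meal_id: str) -> ComponentScores:
        for s in self.scores:
            if s.meal_id == meal_id:
                return s
        raise KeyError(meal_id)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": i + 1,
                "meal_id": s.meal_id,
                "knowledge": s.knowledge,
                "content": s.content,
                "collaborative": s.collaborative,
                "final": s.final,
            }
            for i, s in enumerate(self.scores)
        ]
        return pd.DataFrame(rows)


def hybrid_rank(
    candidates: CandidateSet | Sequence[Meal],
    profile: NutrientStatusProfile,
    taste: TasteVector,
    orders: Sequence[OrderEvent],
    today: dt.date,
    weights: HybridWeights | None = None,
    table: WeightTable | None = None,
    k: int = 5,
    activation_days: int = 14,
) -> RankingResult:
    """Score and rank the candidate set.

    final = w_knowledge * knowledge + w_content * content +
    w_collaborative * collaborative, sorted descending; ties broken by higher
    knowledge score, then lexicographic meal_id.
    """
    meals = list(candidates.meals if isinstance(candidates, CandidateSet) else candidates)
    if not meals:
        raise ValidationError("cannot rank an empty candidate set")
    weights = weights or HybridWeights()
    table = table or WeightTable()
    user_id = (
        candidates.user_id if isinstance(candidates, CandidateSet) else taste.user_id
    )

    meal_norm = normalize_nutrients(meals)
    raw, scaled = knowledge_scores(meal_norm, profile, table)
    content = {m.meal_id: content_score(m, taste) for m in meals}
    collab, ninfo = collaborative_scores(
        meals, user_id, orders, today, k=k, activation_days=activation_days
    )

    scores = []
    for m in meals:
        kn, co, cf = float(scaled[m.meal_id]), content[m.meal_id], collab[m.meal_id]
        final = weights.knowledge * kn + weights.content * co + weights.collaborative * cf
        scores.append(ComponentScores(m.meal_id, kn, co, cf, final))
    scores.sort(key=lambda s: (-s.final, -s.knowledge, s.meal_id))
    return RankingResult(
        scores=tuple(scores),
        meal_norm=meal_norm,
        knowledge_raw=raw,
        neighbor_info=ninfo,
        weights=weights,
    )
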