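"""Structured explanations attached to every recommendation.

Each recommended meal carries three payloads, in fixed order:

1. **nutritional alignment** — which nutrients of the user's status profile
   the meal addresses, with the per-nutrient weight, normalized amount and
   contribution (their product); the headline states the knowledge
   component's share of the final score.
2. **past choices** — the previously ordered/liked meals most similar to
   this one by ingredient cosine similarity.
3. **popularity** — the fraction of the user's nearest neighbours who
   ordered the meal, with the caveat that popularity only carries a small
   share of the score (popular is not the same as healthy).

Every number rendered in a payload is recomputable from the scoring context
(faithfulness); headline strings are per-locale templates, so a configured
hybrid weight change propagates into the rendered percentages.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import yaml

from .ffq import NutrientStatusProfile
from .model import SCORED_NUTRIENTS, Meal
from .scoring import (
    ComponentScores,
    HybridWeights,
    NeighborInfo,
    RankingResult,
    TasteVector,
    WeightTable,
)

EXPLANATION_KINDS = ("nutritional_alignment", "past_choices", "popularity")


def load_templates(locale: str = "en", template_dir: str | None = None) -> dict[str, str]:
    if template_dir is not None:
        from pathlib import Path

        text = (Path(template_dir) / f"{locale}.yaml").read_text()
    else:
        text = (resources.files("nutrirank.data") / "templates" / f"{locale}.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class ExplanationPayload:
    kind: str
    meal_id: str
    headline: str
    details: Mapping = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "meal_id": self.meal_id,
                "headline": self.headline,
                "details": self.details,
            },
            indent=2,
        )

    def render_text(self) -> str:
        lines = [self.headline]
        if self.kind == "nutritional_alignment":
            for row in self.details["rows"]:
                lines.append(
                    f"  {row['nutrient']} ({row['status']}): weight {row['weight']:g} x "
                    f"normalized amount {row['normalized_amount']:.3f} = "
                    f"{row['contribution']:+.3f}"
                )
        elif self.kind == "past_choices":
            for row in self.details["similar_meals"]:
                lines.append(f"  {row['meal_id']}: similarity {row['similarity']:.3f}")
        elif self.kind == "popularity":
            if self.details.get("active"):
                lines.append(
                    f"  {self.details['neighbors_ordered']} of "
                    f"{self.details['neighbor_count']} similar users ordered this meal "
                    f"({self.details['ordered_percent']:g}%)."
                )
        return "\n".join(lines)


def _pct(x: float) -> int:
    return round(100 * x)


def explain_nutritional(
    scores: ComponentScores,
    profile: NutrientStatusProfile,
    table: WeightTable,
    meal_norm_row: Mapping[str, float],
    weights: HybridWeights,
    templates: Mapping[str, str] | None = None,
) -> ExplanationPayload:
    """Knowledge-based payload: one row per nutrient with a nonzero weight
    under the user's status, sorted by |contribution| descending; the rows'
    contributions sum to the meal's raw knowledge score."""
    templates = templates or load_templates()
    rows = []
    for n in SCORED_NUTRIENTS:
        w = table[(n, profile.status[n])]
        if w == 0:
            continue
        amount = float(meal_norm_row[n])
        rows.append(
            {
                "nutrient": n,
                "status": profile.status[n],
                "weight": w,
                "normalized_amount": amount,
                "contribution": w * amount,
            }
        )
    rows.sort(key=lambda r: (-abs(r["contribution"]), r["nutrient"]))
    return ExplanationPayload(
        kind="nutritional_alignment",
        meal_id=scores.meal_id,
        headline=templates["nutritional_headline"].format(
            knowledge_pct=_pct(weights.knowledge)
        ),
        details={
            "component_percent": _pct(weights.knowledge),
            "knowledge_score": scores.knowledge,
            "rows": rows,
        },
    )


def _ingredient_cosine(a: frozenset[str], b: frozenset[str]) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / math.sqrt(len(a) * len(b))


def explain_past_choices(
    scores: ComponentScores,
    taste: TasteVector,
    past_meals: Sequence[Meal],
    meal: Meal,
    weights: HybridWeights,
    m: int = 3,
    templates: Mapping[str, str] | None = None,
) -> ExplanationPayload:
    """Content-based payload: the ``m`` previously ordered/liked meals most
    similar (binary-ingredient cosine) to this one; a cold user gets an empty
    list and the fallback sentence."""
    templates = templates or load_templates()
    if taste.is_cold() or not past_meals:
        return ExplanationPayload(
            kind="past_choices",
            meal_id=scores.meal_id,
            headline=templates["past_choices_cold"],
            details={
                "component_percent": _pct(weights.content),
                "content_score": scores.content,
                "similar_meals": [],
            },
        )
    sims = [
        (pm.meal_id, _ingredient_cosine(pm.ingredient_names(), meal.ingredient_names()))
        for pm in {p.meal_id: p for p in past_meals}.values()
    ]
    sims.sort(key=lambda t: (-t[1], t[0]))
    return ExplanationPayload(
        kind="past_choices",
        meal_id=scores.meal_id,
        headline=templates["past_choices_headline"],
        details={
            "component_percent": _pct(weights.content),
            "content_score": scores.content,
            "similar_meals": [
                {"meal_id": mid, "similarity": sim} for mid, sim in sims[:m]
            ],
        },
    )


def explain_popularity(
    scores: ComponentScores,
    neighbor_info: NeighborInfo,
    weights: HybridWeights,
    activation_days: int = 14,
    templates: Mapping[str, str] | None = None,
) -> ExplanationPayload:
    """Collaborative payload: neighbour count and the fraction who ordered
    the meal; before activation it states that popularity is not yet used."""
    templates = templates or load_templates()
    if not neighbor_info.active:
        return ExplanationPayload(
            kind="popularity",
            meal_id=scores.meal_id,
            headline=templates["popularity_inactive"].format(
                activation_days=activation_days
            ),
            details={
                "component_percent": _pct(weights.collaborative),
                "active": False,
                "collaborative_score": scores.collaborative,
            },
        )
    n = len(neighbor_info.neighbor_ids)
    frac = neighbor_info.ordered_fraction.get(scores.meal_id, scores.collaborative)
    return ExplanationPayload(
        kind="popularity",
        meal_id=scores.meal_id,
        headline=templates["popularity_headline"].format(
            collaborative_pct=_pct(weights.collaborative)
        ),
        details={
            "component_percent": _pct(weights.collaborative),
            "active": True,
            "neighbor_count": n,
            "neighbors_ordered": round(frac * n),
            "ordered_percent": 100.0 * frac,
            "collaborative_score": scores.collaborative,
        },
    )


def explain_all(
    result: RankingResult,
    meal: Meal,
    profile: NutrientStatusProfile,
    taste: TasteVector,
    table: WeightTable,
    past_meals: Sequence[Meal] = (),
    activation_days: int = 14,
    m: int = 3,
    templates: Mapping[str, str] | None = None,
) -> tuple[ExplanationPayload, ExplanationPayload, ExplanationPayload]:
    """The three payloads for one ranked meal, in the fixed order
    nutritional / past choices / popularity."""
    templates = templates or load_templates()
    scores = result.for_meal(meal.meal_id)
    return (
        explain_nutritional(
            scores, profile, table, result.meal_norm.loc[meal.meal_id],
            result.weights, templates,
        ),
        explain_past_choices(
            scores, taste, past_meals, meal, result.weights, m=m, templates=templates
        ),
        explain_popularity(
            scores, result.neighbor_info, result.weights,
            activation_days=activation_days, templates=templates,
        ),
    )
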