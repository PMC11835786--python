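"""Food-frequency-questionnaire intake estimation and nutrient-status profiling.

A food frequency questionnaire (FFQ) records, per food item, how often it is
consumed and in what portion. Combined with a food-composition table
(nutrients per 100 g), standard FFQ arithmetic yields an estimated daily
intake per nutrient:

    intake[n] = sum over items of
        frequency_per_day * portion_multiplier * standard_portion_g / 100
        * nutrients_per_100g[n]

Each nutrient's intake is then classified Low / Normal / High against a
per-nutrient daily reference range: strictly below the lower bound is Low,
strictly above the upper bound is High, and the bounds themselves count as
Normal (a user at exactly the recommended intake is not flagged). The
resulting :class:`~nutrirank.model`-level status profile is what drives the
knowledge-based scorer.

Food-group contribution analysis attributes the total intake of one
macronutrient (carbohydrate, protein or total fat) to the ten FFQ food
groups, which is how dietary shifts between questionnaire timepoints are
summarised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import SCORED_NUTRIENTS, ValidationError

logger = logging.getLogger(__name__)

FOOD_GROUPS: tuple[str, ...] = (
    "vegetables",
    "fruit",
    "potatoes_rice_pasta",
    "bread_savory_biscuits",
    "dairy",
    "meat_fish",
    "fats_spreads",
    "sweets_snacks",
    "drinks",
    "other",
)

MACRONUTRIENTS: tuple[str, ...] = ("carbohydrate", "protein", "total_fat")

STATUSES: tuple[str, ...] = ("Low", "Normal", "High")


@dataclass(frozen=True)
class FfqItem:
    item_id: str
    food_name: str
    food_group: str
    standard_portion_g: float

    def __post_init__(self) -> None:
        if self.food_group not in FOOD_GROUPS:
            raise ValidationError(
                f"item {self.item_id!r}: unknown food group {self.food_group!r}"
            )
        if not self.standard_portion_g > 0:
            raise ValidationError(f"item {self.item_id!r}: portion must be > 0 g")


@dataclass(frozen=True)
class FfqAnswer:
    item_id: str
    frequency_per_day: float
    portion_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not (self.frequency_per_day >= 0 and self.frequency_per_day < float("inf")):
            raise ValidationError("frequency_per_day must be finite and >= 0")
        if not self.portion_multiplier > 0:
            raise ValidationError("portion_multiplier must be > 0")


@dataclass(frozen=True)
class FfqResponse:
    user_id: str
    timepoint: str  # "baseline" | "post"
    answers: tuple[FfqAnswer, ...]

    def __post_init__(self) -> None:
        if self.timepoint not in ("baseline", "post"):
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        object.__setattr__(self, "answers", tuple(self.answers))


@dataclass(frozen=True)
class FoodCompositionEntry:
    """Nutrient content of one FFQ item per 100 g (edible portion)."""

    item_id: str
    nutrients_per_100g: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [n for n in SCORED_NUTRIENTS if n not in self.nutrients_per_100g]
        if missing:
            raise ValidationError(
                f"composition entry {self.item_id!r}: missing nutrient(s) {missing}"
            )
        for n in SCORED_NUTRIENTS:
            if self.nutrients_per_100g[n] < 0:
                raise ValidationError(
                    f"composition entry {self.item_id!r}: negative {n}"
                )
        object.__setattr__(
            self,
            "nutrients_per_100g",
            {n: float(self.nutrients_per_100g[n]) for n in SCORED_NUTRIENTS},
        )


@dataclass(frozen=True)
class IntakeEstimate:
    user_id: str
    timepoint: str
    daily_intake: Mapping[str, float]  # nutrient units per day

    def __post_init__(self) -> None:
        missing = [n for n in SCORED_NUTRIENTS if n not in self.daily_intake]
        if missing:
            raise ValidationError(f"intake estimate missing nutrient(s) {missing}")


@dataclass(frozen=True)
class ReferenceRange:
    nutrient: str
    lower_bound: float
    upper_bound: float

    def __post_init__(self) -> None:
        if not self.lower_bound < self.upper_bound:
            raise ValidationError(
                f"{self.nutrient}: lower_bound must be < upper_bound"
            )


@dataclass(frozen=True)
class NutrientStatusProfile:
    """Per-nutrient Low/Normal/High classification for one user."""

    user_id: str
    status: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [n for n in SCORED_NUTRIENTS if n not in self.status]
        if missing:
            raise ValidationError(f"profile missing nutrient(s) {missing}")
        bad = {n: s for n, s in self.status.items() if s not in STATUSES}
        if bad:
            raise ValidationError(f"invalid status value(s): {bad}")

    @classmethod
    def all_normal(cls, user_id: str) -> "NutrientStatusProfile":
        return cls(user_id=user_id, status={n: "Normal" for n in SCORED_NUTRIENTS})


def _index_items(items: Iterable[FfqItem]) -> dict[str, FfqItem]:
    return {i.item_id: i for i in items}


def _index_composition(
    composition: Iterable[FoodCompositionEntry],
) -> dict[str, FoodCompositionEntry]:
    return {c.item_id: c for c in composition}


def compute_intake(
    response: FfqResponse,
    items: Sequence[FfqItem],
    composition: Sequence[FoodCompositionEntry],
) -> IntakeEstimate:
    """Estimate daily nutrient intake from one FFQ response.

    Additive over answers and linear in the reported frequencies; an
    unresolvable item id raises :class:`ValidationError` naming the id.
    """
    item_idx = _index_items(items)
    comp_idx = _index_composition(composition)
    intake = {n: 0.0 for n in SCORED_NUTRIENTS}
    for ans in response.answers:
        if ans.item_id not in item_idx:
            raise ValidationError(f"FFQ answer references unknown item {ans.item_id!r}")
        if ans.item_id not in comp_idx:
            raise ValidationError(
                f"item {ans.item_id!r} has no food-composition entry"
            )
        grams = ans.frequency_per_day * ans.portion_multiplier * item_idx[ans.item_id].standard_portion_g
        per100 = comp_idx[ans.item_id].nutrients_per_100g
        for n in SCORED_NUTRIENTS:
            intake[n] += grams / 100.0 * per100[n]
    return IntakeEstimate(response.user_id, response.timepoint, intake)


def classify_status(
    intake: IntakeEstimate, ranges: Mapping[str, ReferenceRange] | Sequence[ReferenceRange]
) -> NutrientStatusProfile:
    """Classify each nutrient Low/Normal/High against its reference range.

    Low iff intake < lower_bound; High iff intake > upper_bound; the bounds
    themselves are Normal.
    """
    if not isinstance(ranges, Mapping):
        ranges = {r.nutrient: r for r in ranges}
    missing = [n for n in SCORED_NUTRIENTS if n not in ranges]
    if missing:
        raise ValidationError(f"missing reference range(s) for {missing}")
    status: dict[str, str] = {}
    for n in SCORED_NUTRIENTS:
        v, r = intake.daily_intake[n], ranges[n]
        if v < r.lower_bound:
            status[n] = "Low"
        elif v > r.upper_bound:
            status[n] = "High"
        else:
            status[n] = "Normal"
    return NutrientStatusProfile(intake.user_id, status)


def food_group_contributions(
    response: FfqResponse,
    items: Sequence[FfqItem],
    composition: Sequence[FoodCompositionEntry],
    macronutrient: str,
) -> tuple[dict[str, float], str]:
    """Percent of total daily ``macronutrient`` intake contributed by each
    food group, plus the top contributing group.

    Percentages sum to 100 (within floating-point error); the top group is
    the argmax with an alphabetical tie-break. A zero total intake raises
    :class:`ValidationError` (the contribution is undefined).
    """
    if macronutrient not in MACRONUTRIENTS:
        raise ValidationError(
            f"macronutrient must be one of {MACRONUTRIENTS}, got {macronutrient!r}"
        )
    item_idx = _index_items(items)
    comp_idx = _index_composition(composition)
    by_group = {g: 0.0 for g in FOOD_GROUPS}
    for ans in response.answers:
        if ans.item_id not in item_idx:
            raise ValidationError(f"FFQ answer references unknown item {ans.item_id!r}")
        item = item_idx[ans.item_id]
        grams = ans.frequency_per_day * ans.portion_multiplier * item.standard_portion_g
        by_group[item.food_group] += (
            grams / 100.0 * comp_idx[ans.item_id].nutrients_per_100g[macronutrient]
        )
    total = sum(by_group.values())
    if total <= 0:
        raise ValidationError(
            f"total {macronutrient} intake is zero; contributions undefined"
        )
    percents = {g: 100.0 * v / total for g, v in by_group.items()}
    top = min(
        (g for g in FOOD_GROUPS if percents[g] == max(percents.values())),
    )
    return percents, top


def compare_profiles(
    baseline: Mapping[str, str], post: Mapping[str, str]
) -> dict[str, tuple[int, int]]:
    """Count users whose top contributing food group is each group, at both
    questionnaire timepoints.

    ``baseline`` and ``post`` map user_id -> top food group. Users present at
    only one timepoint are excluded with a logged warning; per timepoint the
    counts sum to the number of shared users.
    """
    shared = set(baseline) & set(post)
    dropped = (set(baseline) | set(post)) - shared
    if dropped:
        logger.warning(
            "excluding %d user(s) present at only one timepoint: %s",
            len(dropped), sorted(dropped),
        )
    counts = {g: [0, 0] for g in FOOD_GROUPS}
    for uid in shared:
        counts[baseline[uid]][0] += 1
        counts[post[uid]][1] += 1
    return {g: (c[0], c[1]) for g, c in counts.items()}


# ------------------------------------------------------------- interchange

def read_ffq_responses(path) -> list[FfqResponse]:
    """Read FFQ responses from CSV
    (``user_id,timepoint,item_id,frequency_per_day,portion_multiplier``)."""
    import csv
    from pathlib import Path

    rows: dict[tuple[str, str], list[FfqAnswer]] = {}
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                key = (row["user_id"], row["timepoint"])
                rows.setdefault(key, []).append(
                    FfqAnswer(
                        item_id=row["item_id"],
                        frequency_per_day=float(row["frequency_per_day"]),
                        portion_multiplier=float(row.get("portion_multiplier") or 1.0),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return [
        FfqResponse(user_id=uid, timepoint=tp, answers=tuple(answers))
        for (uid, tp), answers in sorted(rows.items())
    ]


def write_ffq_responses(responses: Sequence[FfqResponse], path) -> None:
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["user_id", "timepoint", "item_id", "frequency_per_day", "portion_multiplier"]
        )
        for resp in sorted(responses, key=lambda r: (r.user_id, r.timepoint)):
            for ans in resp.answers:
                writer.writerow(
                    [resp.user_id, resp.timepoint, ans.item_id,
                     repr(ans.frequency_per_day), repr(ans.portion_multiplier)]
                )


def read_composition_table(path) -> tuple[list[FfqItem], list[FoodCompositionEntry]]:
    """Read the combined item bank + composition CSV.

    Columns: ``item_id,food_name,food_group,portion_g`` followed by one
    column per scored nutrient holding its content per 100 g.
    """
    import csv
    from pathlib import Path

    items: list[FfqItem] = []
    comp: list[FoodCompositionEntry] = []
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                items.append(
                    FfqItem(
                        item_id=row["item_id"],
                        food_name=row.get("food_name") or row["item_id"],
                        food_group=row["food_group"],
                        standard_portion_g=float(row["portion_g"]),
                    )
                )
                comp.append(
                    FoodCompositionEntry(
                        item_id=row["item_id"],
                        nutrients_per_100g={n: float(row[n]) for n in SCORED_NUTRIENTS},
                    )
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return items, comp


def write_composition_table(
    items: Sequence[FfqItem], composition: Sequence[FoodCompositionEntry], path
) -> None:
    import csv
    from pathlib import Path

    comp_idx = _index_composition(composition)
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["item_id", "food_name", "food_group", "portion_g"]
                        + list(SCORED_NUTRIENTS))
        for item in sorted(items, key=lambda i: i.item_id):
            per100 = comp_idx[item.item_id].nutrients_per_100g
            writer.writerow(
                [item.item_id, item.food_name, item.food_group,
                 repr(item.standard_portion_g)]
                + [repr(per100[n]) for n in SCORED_NUTRIENTS]
            )
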