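"""Readers and writers for the CSV/JSON interchange formats.

JSON is the lossless canonical menu format (nested ingredients with their own
allergen tags). The flat CSV menu carries one row per meal with ingredients as
a ``;``-joined name list (a trailing ``*`` marks a composite-opaque
ingredient) and tags ``|``-joined; ingredient-level allergen tags and
sub-ingredient lists are not representable in CSV. Events live in a single
CSV with header ``event_type,user_id,meal_id,date,polarity,
disliked_ingredients,text``.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
from pathlib import Path
from typing import Sequence

from .model import (
    SCORED_NUTRIENTS,
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
    parse_date,
)

logger = logging.getLogger(__name__)

EVENTS_HEADER = [
    "event_type",
    "user_id",
    "meal_id",
    "date",
    "polarity",
    "disliked_ingredients",
    "text",
]


class ParseError(ValidationError):
    """Malformed interchange file; the message names the offending line/field."""


# ---------------------------------------------------------------- menus

def _meal_to_json(meal: Meal) -> dict:
    return {
        "meal_id": meal.meal_id,
        "name": meal.name,
        "course": meal.course,
        "nutriscore": meal.nutriscore,
        "nutrients": meal.nutrients.as_dict(),
        "ingredients": [
            {
                "name": ing.name,
                "allergen_tags": sorted(ing.allergen_tags),
                "sub_ingredients": list(ing.sub_ingredients),
                "is_composite_opaque": ing.is_composite_opaque,
            }
            for ing in meal.ingredients
        ],
        "allergen_tags": sorted(meal.allergen_tags),
        "lifestyle_tags": sorted(meal.lifestyle_tags),
    }


def _meal_from_json(rec: dict, date: dt.date, location: str) -> Meal:
    try:
        nutrients = NutrientVector.from_mapping(rec["nutrients"])
        ingredients = tuple(
            Ingredient(
                name=i["name"],
                allergen_tags=frozenset(i.get("allergen_tags", ())),
                sub_ingredients=tuple(i.get("sub_ingredients", ())),
                is_composite_opaque=bool(i.get("is_composite_opaque", False)),
            )
            for i in rec.get("ingredients", ())
        )
        return Meal(
            meal_id=str(rec["meal_id"]),
            name=rec.get("name", str(rec["meal_id"])),
            course=rec.get("course", "main"),
            date=date,
            location=location,
            nutrients=nutrients,
            ingredients=ingredients,
            allergen_tags=frozenset(rec.get("allergen_tags", ())),
            lifestyle_tags=frozenset(rec.get("lifestyle_tags", ())),
            nutriscore=rec.get("nutriscore", "C"),
        )
    except KeyError as exc:
        raise ParseError(f"meal record missing field {exc.args[0]!r}") from exc


def _ingredients_to_csv(meal: Meal) -> str:
    parts = []
    for ing in meal.ingredients:
        parts.append(ing.name + ("*" if ing.is_composite_opaque else ""))
    return ";".join(parts)


def _ingredients_from_csv(cell: str) -> tuple[Ingredient, ...]:
    out = []
    for raw in cell.split(";"):
        raw = raw.strip()
        if not raw:
            continue
        opaque = raw.endswith("*")
        out.append(Ingredient(name=raw.rstrip("*"), is_composite_opaque=opaque))
    return tuple(out)


def read_menu(path: str | Path, format: str | None = None) -> Menu:
    """Read and validate a menu from a JSON or flat CSV file.

    Unknown nutrient columns are ignored with a logged warning; a missing
    scored nutrient raises a :class:`ValidationError` naming it. A CSV may
    instead supply per-100 g nutrient columns (``<nutrient>_per_100g``)
    together with an explicit ``portion_g`` column; values are converted to
    per-portion amounts at load.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
        date = parse_date(doc["date"])
        location = str(doc["location"])
        meals = tuple(_meal_from_json(rec, date, location) for rec in doc["meals"])
        return Menu(date=date, location=location, meals=meals)
    if fmt != "csv":
        raise ValueError(f"unknown menu format {fmt!r}")

    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty CSV")
        fields = set(reader.fieldnames)
        per100 = {n for n in SCORED_NUTRIENTS if f"{n}_per_100g" in fields}
        direct = {n for n in SCORED_NUTRIENTS if n in fields}
        missing = [n for n in SCORED_NUTRIENTS if n not in direct | per100]
        if missing:
            raise ValidationError(f"{path}: missing scored nutrient column(s): {missing}")
        if per100 - direct and "portion_g" not in fields:
            raise ValidationError(
                f"{path}: per-100g nutrient columns require a 'portion_g' column"
            )
        known = (
            {"meal_id", "name", "course", "date", "location", "nutriscore",
             "ingredients", "allergen_tags", "lifestyle_tags", "energy_kcal",
             "portion_g"}
            | {n for n in SCORED_NUTRIENTS}
            | {f"{n}_per_100g" for n in SCORED_NUTRIENTS}
        )
        unknown_cols = fields - known
        if unknown_cols:
            logger.warning("ignoring unknown menu column(s): %s", sorted(unknown_cols))

        meals: list[Meal] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                values: dict[str, float] = {}
                for n in SCORED_NUTRIENTS:
                    if n in direct and row.get(n, "") != "":
                        values[n] = float(row[n])
                    else:
                        values[n] = (
                            float(row[f"{n}_per_100g"]) * float(row["portion_g"]) / 100.0
                        )
                if row.get("energy_kcal"):
                    values["energy_kcal"] = float(row["energy_kcal"])
                meals.append(
                    Meal(
                        meal_id=row["meal_id"],
                        name=row.get("name") or row["meal_id"],
                        course=row.get("course") or "main",
                        date=parse_date(row["date"]),
                        location=row.get("location", ""),
                        nutrients=NutrientVector.from_mapping(values),
                        ingredients=_ingredients_from_csv(row.get("ingredients", "")),
                        allergen_tags=frozenset(
                            t for t in row.get("allergen_tags", "").split("|") if t
                        ),
                        lifestyle_tags=frozenset(
                            t for t in row.get("lifestyle_tags", "").split("|") if t
                        ),
                        nutriscore=row.get("nutriscore") or "C",
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not meals:
        raise ValidationError(f"{path}: menu contains no meals")
    return Menu(date=meals[0].date, location=meals[0].location, meals=tuple(meals))


def write_menu(menu: Menu, path: str | Path, format: str | None = None) -> None:
    """Write a menu in canonical order (meals sorted by meal_id)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    meals = sorted(menu.meals, key=lambda m: m.meal_id)
    if fmt == "json":
        doc = {
            "date": menu.date.isoformat(),
            "location": menu.location,
            "meals": [_meal_to_json(m) for m in meals],
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        return
    if fmt != "csv":
        raise ValueError(f"unknown menu format {fmt!r}")
    header = (
        ["meal_id", "name", "course", "date", "location", "nutriscore",
         "ingredients", "allergen_tags", "lifestyle_tags"]
        + list(SCORED_NUTRIENTS)
        + ["energy_kcal"]
    )
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for m in meals:
            writer.writerow(
                [m.meal_id, m.name, m.course, m.date.isoformat(), m.location,
                 m.nutriscore, _ingredients_to_csv(m),
                 "|".join(sorted(m.allergen_tags)), "|".join(sorted(m.lifestyle_tags))]
                + [repr(getattr(m.nutrients, n)) for n in SCORED_NUTRIENTS]
                + [("" if m.nutrients.energy_kcal is None else repr(m.nutrients.energy_kcal))]
            )


# ---------------------------------------------------------------- events

def read_events(path: str | Path, today: dt.date | None = None) -> EventLog:
    """Read a typed event CSV into an :class:`EventLog`, sorted by date.

    Events dated after ``today`` (when given) are retained with a logged
    warning — clocks drift, data should not silently vanish.
    """
    path = Path(path)
    log = EventLog()
    n_future = 0
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "event_type" not in reader.fieldnames:
            raise ParseError(f"{path}: expected header {','.join(EVENTS_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                etype = row["event_type"]
                date = parse_date(row["date"])
                if today is not None and date > today:
                    n_future += 1
                if etype == "order":
                    log.orders.append(OrderEvent(row["user_id"], row["meal_id"], date))
                elif etype == "feedback":
                    disliked = tuple(
                        t for t in (row.get("disliked_ingredients") or "").split("|") if t
                    )
                    log.feedback.append(
                        FeedbackEvent(
                            user_id=row["user_id"],
                            meal_id=row["meal_id"],
                            date=date,
                            polarity=row["polarity"],
                            disliked_ingredients=disliked,
                            text=row.get("text") or "",
                        )
                    )
                elif etype == "recommendation":
                    ids = tuple(t for t in (row.get("meal_id") or "").split("|") if t)
                    log.recommendations.append(
                        RecommendationRecord(row["user_id"], date, ids)
                    )
                else:
                    raise ParseError(f"{path}:{lineno}: unknown event_type {etype!r}")
            except ValidationError:
                raise
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if n_future:
        logger.warning(
            "%s: %d event(s) dated after today=%s retained", path, n_future, today
        )
    return log.sort()


def write_events(log: EventLog, path: str | Path) -> None:
    log.sort()
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENTS_HEADER)
        for o in log.orders:
            writer.writerow(["order", o.user_id, o.meal_id, o.date.isoformat(), "", "", ""])
        for f in log.feedback:
            writer.writerow(
                ["feedback", f.user_id, f.meal_id, f.date.isoformat(), f.polarity,
                 "|".join(f.disliked_ingredients), f.text]
            )
        for r in log.recommendations:
            writer.writerow(
                ["recommendation", r.user_id, "|".join(r.meal_ids),
                 r.date.isoformat(), "", "", ""]
            )


# ---------------------------------------------------------------- users

def read_users(path: str | Path) -> list[UserProfile]:
    doc = json.loads(Path(path).read_text())
    return [
        UserProfile(
            user_id=str(rec["user_id"]),
            allergies=frozenset(rec.get("allergies", ())),
            preferences=frozenset(rec.get("preferences", ())),
            location=rec.get("location", ""),
        )
        for rec in doc
    ]


def write_users(users: Sequence[UserProfile], path: str | Path) -> None:
    doc = [
        {
            "user_id": u.user_id,
            "allergies": sorted(u.allergies),
            "preferences": sorted(u.preferences),
            "location": u.location,
        }
        for u in sorted(users, key=lambda u: u.user_id)
    ]
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
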