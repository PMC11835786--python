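"""Configuration: bundled defaults (scoring weight table, reference ranges,
explanation templates) and the application config tying a data directory to
engine parameters."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .ffq import ReferenceRange
from .model import SCORED_NUTRIENTS, ValidationError
from .prefilter import FilterConfig
from .scoring import HybridWeights, WeightTable


def _bundled(name: str) -> str:
    return (resources.files("nutrirank.data") / name).read_text()


def load_weight_table(path: str | Path | None = None) -> WeightTable:
    """Load the (nutrient, status) -> weight table; defaults to the bundled
    table when no path is given."""
    text = _bundled("weight_table.yaml") if path is None else Path(path).read_text()
    return WeightTable.from_mapping(yaml.safe_load(text))


def load_reference_ranges(path: str | Path | None = None) -> dict[str, ReferenceRange]:
    """Load daily-intake reference ranges (YAML ``{nutrient: {lower, upper}}``).

    The bundled defaults are non-clinical placeholders in dietary-reference-
    value style; deployments should supply population-appropriate ranges.
    """
    text = _bundled("reference_ranges.yaml") if path is None else Path(path).read_text()
    doc = yaml.safe_load(text)
    missing = [n for n in SCORED_NUTRIENTS if n not in doc]
    if missing:
        raise ValidationError(f"reference ranges missing nutrient(s): {missing}")
    return {
        n: ReferenceRange(n, float(doc[n]["lower"]), float(doc[n]["upper"]))
        for n in SCORED_NUTRIENTS
    }


@dataclass
class AppConfig:
    """Paths and engine parameters for the command-line application."""

    data_dir: Path = Path(".")
    menu_dir: Path | None = None  # default: <data_dir>/menus
    events_file: Path | None = None  # default: <data_dir>/events.csv
    users_file: Path | None = None  # default: <data_dir>/users.json
    composition_file: Path | None = None  # default: <data_dir>/composition.csv
    ffq_file: Path | None = None  # default: <data_dir>/ffq_responses.csv
    reference_ranges_file: Path | None = None  # default: bundled
    weight_table_file: Path | None = None  # default: bundled
    vocab_dir: Path | None = None  # default: bundled
    hybrid: HybridWeights = field(default_factory=HybridWeights)
    filter: FilterConfig = field(default_factory=FilterConfig)
    k_neighbors: int = 5
    activation_days: int = 14
    locale: str = "en"

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.menu_dir = Path(self.menu_dir) if self.menu_dir else self.data_dir / "menus"
        self.events_file = (
            Path(self.events_file) if self.events_file else self.data_dir / "events.csv"
        )
        self.users_file = (
            Path(self.users_file) if self.users_file else self.data_dir / "users.json"
        )
        self.composition_file = (
            Path(self.composition_file)
            if self.composition_file
            else self.data_dir / "composition.csv"
        )
        self.ffq_file = (
            Path(self.ffq_file) if self.ffq_file else self.data_dir / "ffq_responses.csv"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AppConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        base = Path(path).parent
        kwargs: dict = {}
        for key in ("data_dir", "menu_dir", "events_file", "users_file",
                    "composition_file", "ffq_file", "reference_ranges_file",
                    "weight_table_file", "vocab_dir"):
            if key in doc and doc[key] is not None:
                p = Path(doc[key])
                kwargs[key] = p if p.is_absolute() else base / p
        if "hybrid" in doc:
            kwargs["hybrid"] = HybridWeights(**doc["hybrid"])
        if "filter" in doc:
            kwargs["filter"] = FilterConfig(**doc["filter"])
        for key in ("k_neighbors", "activation_days", "locale"):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)

    def weight_table(self) -> WeightTable:
        return load_weight_table(self.weight_table_file)

    def reference_ranges(self) -> dict[str, ReferenceRange]:
        return load_reference_ranges(self.reference_ranges_file)
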