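"""Food-composition data model and I/O.

The central object is the :class:`FoodTable`, a validated collection of
:class:`FoodItem` records. Each item describes one serve of a food: its
nutrient content (:class:`NutrientVector`), its cooked and retail serve
weights, its origin (animal vs plant, which decides heme-iron handling
downstream), and the environmental intensity of producing one kilogram of
it at retail weight (:class:`EnvIntensity`).

A bundled fixture table covers beef and thirteen lower-emission
alternatives, each scaled to the energy of one standard cooked beef serve
(471 kJ), together with the pregnancy nutrient-reference-value table and a
ranking table of the foods contributing most daily energy and protein in
an Australian pregnancy cohort.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import FoodLookupError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Origin",
    "NutrientVector",
    "EnvIntensity",
    "FoodItem",
    "FoodTable",
    "IntakeContribution",
    "FOOD_TABLE_COLUMNS",
    "load_food_table",
    "write_food_table",
    "energy_density",
    "rank_contributors",
    "load_contributions",
    "bundled_food_table",
    "bundled_contributions",
    "bundled_absorbed_iron_printed",
]


class Origin(str, Enum):
    """Whether a food is animal- or plant-derived (controls heme-iron share)."""

    ANIMAL = "animal"
    PLANT = "plant"


@dataclass(frozen=True)
class NutrientVector:
    """Nutrient content of a quantity of food.

    Units: protein, saturated fat and dietary fiber in g; iron and zinc in
    mg; calcium in mg; iodine and folate (dietary folate equivalents, DFE)
    in µg; energy in kJ. The vector supports componentwise addition,
    subtraction and scalar scaling; signed vectors are legitimate as
    *deltas* (differences between two foods), but food-composition inputs
    must be non-negative (see :meth:`validate_nonnegative`).
    """

    protein: float = 0.0
    saturated_fat: float = 0.0
    dietary_fiber: float = 0.0
    iron: float = 0.0
    zinc: float = 0.0
    calcium: float = 0.0
    iodine: float = 0.0
    folate_dfe: float = 0.0
    energy: float = 0.0

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(**{
            f.name: getattr(self, f.name) + getattr(other, f.name)
            for f in fields(self)
        })

    def __sub__(self, other: "NutrientVector") -> "NutrientVector":
        return self + (other * -1.0)

    def __mul__(self, factor: float) -> "NutrientVector":
        return NutrientVector(**{
            f.name: getattr(self, f.name) * factor for f in fields(self)
        })

    __rmul__ = __mul__

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def validate_nonnegative(self, context: str = "") -> "NutrientVector":
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                where = f" for {context}" if context else ""
                raise ValidationError(f"negative {f.name} ({v}){where}")
        return self


@dataclass(frozen=True)
class EnvIntensity:
    """Environmental cost of producing 1 kg retail weight of a food.

    ghg in kg CO2 eq, land in m2 (by years occupied), acidifying emissions
    in g SO2 eq, eutrophying emissions in g PO4(3-) eq, stress-weighted
    water use in L; all per kg and non-negative.
    """

    ghg: float
    land: float
    acidifying: float
    eutrophying: float
    water: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValidationError(f"negative intensity {f.name}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class FoodItem:
    """One food with its per-serve nutrient profile and per-kg footprint.

    ``serve_weight_cooked`` is the as-eaten serve in grams;
    ``serve_weight_retail`` is the purchasable mass in kilograms on which
    environmental intensities are expressed.
    """

    name: str
    origin: Origin
    serve_weight_cooked: float  # g
    serve_weight_retail: float  # kg
    per_serve: NutrientVector
    intensity: EnvIntensity

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("food name must be non-empty")
        if self.serve_weight_cooked <= 0:
            raise ValidationError(f"non-positive cooked serve weight for {self.name}")
        if self.serve_weight_retail <= 0:
            raise ValidationError(f"non-positive retail serve weight for {self.name}")
        self.per_serve.validate_nonnegative(context=self.name)
        if self.per_serve.energy <= 0:
            raise ValidationError(f"per-serve energy must be positive for {self.name}")


class FoodTable:
    """A name-keyed, validated collection of :class:`FoodItem`."""

    def __init__(self, items: Iterable[FoodItem]):
        self._items: dict[str, FoodItem] = {}
        for item in items:
            if item.name in self._items:
                raise ValidationError(f"duplicate food name: {item.name!r}")
            self._items[item.name] = item

    def __getitem__(self, name: str) -> FoodItem:
        try:
            return self._items[name]
        except KeyError:
            raise FoodLookupError(name) from None

    def __contains__(self, name: str) -> bool:
        return name in self._items

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self._items.values())

    def __len__(self) -> int:
        return len(self._items)

    @property
    def names(self) -> list[str]:
        return list(self._items)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for it in self:
            rows.append({
                "name": it.name,
                "origin": it.origin.value,
                "serve_weight_cooked_g": it.serve_weight_cooked,
                "serve_weight_retail_kg": it.serve_weight_retail,
                "energy_kj": it.per_serve.energy,
                "protein_g": it.per_serve.protein,
                "sfa_g": it.per_serve.saturated_fat,
                "fiber_g": it.per_serve.dietary_fiber,
                "iron_mg": it.per_serve.iron,
                "zinc_mg": it.per_serve.zinc,
                "calcium_mg": it.per_serve.calcium,
                "iodine_ug": it.per_serve.iodine,
                "folate_dfe_ug": it.per_serve.folate_dfe,
                "ghg_kgco2e_per_kg": it.intensity.ghg,
                "land_m2_per_kg": it.intensity.land,
                "acid_gso2e_per_kg": it.intensity.acidifying,
                "eutroph_gpo4e_per_kg": it.intensity.eutrophying,
                "water_l_per_kg": it.intensity.water,
            })
        return pd.DataFrame(rows, columns=list(FOOD_TABLE_COLUMNS))


#: Canonical food-table CSV header (UTF-8, header row required).
FOOD_TABLE_COLUMNS: tuple[str, ...] = (
    "name", "origin", "serve_weight_cooked_g", "serve_weight_retail_kg",
    "energy_kj", "protein_g", "sfa_g", "fiber_g", "iron_mg", "zinc_mg",
    "calcium_mg", "iodine_ug", "folate_dfe_ug", "ghg_kgco2e_per_kg",
    "land_m2_per_kg", "acid_gso2e_per_kg", "eutroph_gpo4e_per_kg",
    "water_l_per_kg",
)

_NUTRIENT_COLS = {
    "protein": "protein_g",
    "saturated_fat": "sfa_g",
    "dietary_fiber": "fiber_g",
    "iron": "iron_mg",
    "zinc": "zinc_mg",
    "calcium": "calcium_mg",
    "iodine": "iodine_ug",
    "folate_dfe": "folate_dfe_ug",
    "energy": "energy_kj",
}


def _frame_to_table(df: pd.DataFrame, source: str) -> FoodTable:
    missing = [c for c in FOOD_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {', '.join(missing)}")
    items = []
    for _, row in df.iterrows():
        try:
            origin = Origin(str(row["origin"]).strip().lower())
        except ValueError:
            raise ValidationError(
                f"{source}: unknown origin {row['origin']!r} for {row['name']!r}"
            ) from None
        nutrients = NutrientVector(**{
            field: float(row[col]) for field, col in _NUTRIENT_COLS.items()
        })
        intensity = EnvIntensity(
            ghg=float(row["ghg_kgco2e_per_kg"]),
            land=float(row["land_m2_per_kg"]),
            acidifying=float(row["acid_gso2e_per_kg"]),
            eutrophying=float(row["eutroph_gpo4e_per_kg"]),
            water=float(row["water_l_per_kg"]),
        )
        items.append(FoodItem(
            name=str(row["name"]),
            origin=origin,
            serve_weight_cooked=float(row["serve_weight_cooked_g"]),
            serve_weight_retail=float(row["serve_weight_retail_kg"]),
            per_serve=nutrients,
            intensity=intensity,
        ))
    return FoodTable(items)


def load_food_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> FoodTable:
    """Read a food-composition CSV into a validated :class:`FoodTable`.

    ``dialect`` optionally maps canonical column names (see
    :data:`FOOD_TABLE_COLUMNS`) to the column names actually used in the
    file. Lines starting with ``#`` are treated as comments.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"food table not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    table = _frame_to_table(df, str(path))
    logger.info("loaded %d foods from %s", len(table), path)
    return table


def write_food_table(table: FoodTable, path: str | Path) -> None:
    """Write a :class:`FoodTable` to CSV in the canonical column layout."""
    table.to_dataframe().to_csv(path, index=False)


def energy_density(food: FoodItem) -> float:
    """Energy density of the cooked food, kJ per g."""
    if food.serve_weight_cooked <= 0:
        raise ValidationError(f"non-positive cooked weight for {food.name}")
    return food.per_serve.energy / food.serve_weight_cooked


@dataclass(frozen=True)
class IntakeContribution:
    """Daily energy (kJ) and protein (g) a food contributes to mean intake."""

    food: str
    energy_per_day: float = 0.0
    protein_per_day: float = 0.0

    def __post_init__(self) -> None:
        if self.energy_per_day < 0 or self.protein_per_day < 0:
            raise ValidationError(f"negative contribution for {self.food}")


def rank_contributors(
    intakes: Sequence[IntakeContribution], by: str, top_n: int
) -> list[IntakeContribution]:
    """Top contributors to daily energy or protein intake.

    Descending, stable (ties keep input order), truncated to ``top_n``.
    """
    if by not in ("energy", "protein"):
        raise ValidationError(f"unknown sort key {by!r}; expected 'energy' or 'protein'")
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    key = "energy_per_day" if by == "energy" else "protein_per_day"
    ranked = sorted(intakes, key=lambda c: -getattr(c, key))  # stable
    return ranked[:top_n]


def load_contributions(path: str | Path) -> list[IntakeContribution]:
    """Read a contribution-ranking CSV (food, energy_kj_per_day, protein_g_per_day)."""
    df = pd.read_csv(path, comment="#")
    for col in ("food", "energy_kj_per_day", "protein_g_per_day"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column(s) {col}")
    return [
        IntakeContribution(
            food=str(r["food"]),
            energy_per_day=float(r["energy_kj_per_day"]) if pd.notna(r["energy_kj_per_day"]) else 0.0,
            protein_per_day=float(r["protein_g_per_day"]) if pd.notna(r["protein_g_per_day"]) else 0.0,
        )
        for _, r in df.iterrows()
    ]


def _data_path(name: str):
    return resources.files("sustainaswap.data").joinpath(name)


def bundled_food_table() -> FoodTable:
    """The bundled beef-comparison food table (14 foods, isoenergetic serves)."""
    with resources.as_file(_data_path("beef_comparison_foods.csv")) as p:
        return load_food_table(p)


def bundled_contributions() -> list[IntakeContribution]:
    """Bundled daily energy/protein contribution ranking for the cohort."""
    with resources.as_file(_data_path("intake_contributions.csv")) as p:
        return load_contributions(p)


def bundled_absorbed_iron_printed() -> dict[str, float]:
    """Published per-serve absorbed-iron estimates, for fixture auditing."""
    with resources.as_file(_data_path("absorbed_iron_printed.csv")) as p:
        df = pd.read_csv(p, comment="#")
    return dict(zip(df["name"], df["printed_absorbed_fe_mg"]))
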