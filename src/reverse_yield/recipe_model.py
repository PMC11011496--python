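"""Recipe configuration: categories, ingredient links, process constants.

Categorization of composite foods (dried / salted / pickled / fermented /
mixed) is expert input, not something inferred from nutrient data, so this
module reads it from a structured YAML config.  It also decides, per recipe,
whether a reverse-yield factor is computable at all and, when it is not,
which of the three failure taxa applies: unknown ingredients, too many
ingredients for the available marker nutrients, or processing too
complicated to describe as a simple disassembly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .composition_io import CompositionTable, NUTRIENT_FIELDS

__all__ = [
    "Category",
    "RecipeSpec",
    "ProcessConstants",
    "FailureReason",
    "RecipeError",
    "DEFAULT_CONSTANTS",
    "load_recipes",
    "load_constants",
    "classify_failure",
    "required_nutrients",
    "effective_markers",
    "usable_markers",
]


class RecipeError(Exception):
    """Malformed recipe configuration."""


class Category(str, enum.Enum):
    """Processing category of a composite food."""

    DRIED = "dried"
    SALTED = "salted"
    PICKLE_RICE_BRAN = "pickle-rice-bran"
    PICKLE_VINEGAR = "pickle-vinegar"
    PICKLE_SOY = "pickle-soy"
    PICKLE_MISO = "pickle-miso"
    FERMENTED_ALCOHOL = "fermented-alcohol"
    FERMENTED_ACETIC = "fermented-acetic"
    FERMENTED_LACTIC = "fermented-lactic"
    MIXED_KNOWN_RATIO = "mixed-known-ratio"
    MIXED = "mixed"
    UNCOOKED = "uncooked"
    COOKED = "cooked"

    @classmethod
    def parse(cls, s: str) -> "Category":
        try:
            return cls(str(s).strip().lower())
        except ValueError:
            valid = ", ".join(c.value for c in cls)
            raise RecipeError(
                f"unknown category {s!r}; expected one of: {valid}"
            ) from None


class FailureReason(str, enum.Enum):
    """Why an RF could not be calculated for a composite food."""

    INGREDIENTS_UNKNOWN = "ingredients-unknown"
    TOO_MANY_INGREDIENTS = "too-many-ingredients"
    COMPLICATED_PROCESSING = "complicated-processing"


@dataclass(frozen=True)
class ProcessConstants:
    """Fixed marker contents and fermentation stoichiometry.

    Marker contents are per 100 g of the processing medium: rice-bran paste
    thiamine (mg), vinegar acetate (%), refined sugar sucrose (%), soy-sauce
    and miso protein (%), soy-sauce/miso sucrose (%).  Fermentation
    constants: 0.42 kg ethanol per kg glucose consumed (≈20% of glucose is
    lost to yeast growth and CO2 beyond the stoichiometric split), hence
    1/0.42 ≈ 2.38 g glucose per g ethanol, rounded into the integer
    coefficient 238 of the fermentation equation.  Acetic-acid fermentation
    theoretically yields 60/46 ≈ 1.304 kg acetic acid per kg ethanol; the
    working assumption, allowing for Acetobacter growth, is 1:1 by mass.
    """

    thiamine_rice_bran: float = 3.12     # mg/100 g
    acetate_vinegar: float = 4.2         # g/100 g
    sucrose_sugar: float = 99.3          # g/100 g
    protein_soy_sauce: float = 7.7       # g/100 g
    protein_miso: float = 12.5           # g/100 g
    sucrose_soy_sauce: float = 0.1       # g/100 g
    sucrose_miso: float = 0.0            # g/100 g
    ethanol_yield: float = 0.42                    # kg ethanol / kg glucose
    glucose_per_ethanol: float = 2.38              # g glucose / g ethanol
    ferment_constant: int = 238                    # 100 x glucose_per_ethanol
    acetic_per_ethanol_theoretical: float = 60.0 / 46.0  # = 1.304 kg/kg
    acetic_per_ethanol_assumed: float = 1.0              # working 1:1 mass

    def __post_init__(self) -> None:
        for name in (
            "thiamine_rice_bran",
            "acetate_vinegar",
            "sucrose_sugar",
            "protein_soy_sauce",
            "protein_miso",
            "sucrose_soy_sauce",
            "ethanol_yield",
            "glucose_per_ethanol",
            "ferment_constant",
            "acetic_per_ethanol_theoretical",
            "acetic_per_ethanol_assumed",
        ):
            v = getattr(self, name)
            if name != "sucrose_soy_sauce" and v <= 0:
                raise RecipeError(f"constant {name} must be > 0, got {v}")
            if name == "sucrose_soy_sauce" and v < 0:
                raise RecipeError(f"constant {name} must be >= 0, got {v}")
        if self.sucrose_miso != 0.0:
            raise RecipeError("sucrose_miso must be 0")
        if abs(self.glucose_per_ethanol - 1.0 / self.ethanol_yield) > 0.005:
            raise RecipeError(
                "glucose_per_ethanol must equal 1/ethanol_yield within 0.005"
            )
        if self.ferment_constant != round(100 * self.glucose_per_ethanol):
            raise RecipeError(
                "ferment_constant must equal round(100 * glucose_per_ethanol)"
            )

    def with_overrides(self, **overrides: float) -> "ProcessConstants":
        return replace(self, **overrides)


DEFAULT_CONSTANTS = ProcessConstants()


@dataclass(frozen=True)
class RecipeSpec:
    """One composite food's category and ingredient linkage.

    ``ingredients`` are the candidate ingredient food ids, ordered; for
    mixed foods ``markers`` are the nutrient names whose balances give the
    rows of the linear system (at least as many as there are ingredients;
    surplus candidates are pruned at solve time).  ``known_ratios``, when
    present, are grams of each ingredient per 100 g of composite and bypass
    the solver.  ``complicated`` flags foods the config declares
    non-disaggregable (complex fermentations and the like).
    """

    composite_id: str
    category: Category
    ingredients: tuple[str, ...] = ()
    markers: tuple[str, ...] = ()
    known_ratios: tuple[float, ...] | None = None
    complicated: bool = False

    def validate(self) -> None:
        if not self.composite_id:
            raise RecipeError("composite_id must be non-empty")
        for m in self.markers:
            if m not in NUTRIENT_FIELDS:
                raise RecipeError(
                    f"recipe {self.composite_id}: unknown marker nutrient {m!r}"
                )
        if self.category is Category.MIXED:
            if len(self.markers) < len(self.ingredients):
                raise RecipeError(
                    f"recipe {self.composite_id}: mixed food needs at least as "
                    f"many marker nutrients ({len(self.markers)}) as "
                    f"ingredients ({len(self.ingredients)})"
                )
        if self.known_ratios is not None:
            if len(self.known_ratios) != len(self.ingredients):
                raise RecipeError(
                    f"recipe {self.composite_id}: known_ratios count "
                    f"({len(self.known_ratios)}) != ingredient count "
                    f"({len(self.ingredients)})"
                )
            if any(r < 0 for r in self.known_ratios):
                raise RecipeError(
                    f"recipe {self.composite_id}: known_ratios must be >= 0"
                )
        if self.category is Category.MIXED_KNOWN_RATIO and self.known_ratios is None:
            raise RecipeError(
                f"recipe {self.composite_id}: category mixed-known-ratio "
                "requires known_ratios"
            )


def load_recipes(path: str | Path) -> list[RecipeSpec]:
    """Load recipe specs from a YAML config.

    The file is either a top-level list of recipe mappings or a mapping with
    a ``recipes`` key.  Keys per recipe: ``composite`` (id), ``category``,
    ``ingredients`` (list of ids), ``markers`` (list of nutrient names),
    ``known_ratios`` (optional list of g/100 g), ``complicated`` (bool).
    """
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if doc is None:
        return []
    raw = doc.get("recipes", []) if isinstance(doc, dict) else doc
    specs = []
    for entry in raw:
        spec = RecipeSpec(
            composite_id=str(entry["composite"]),
            category=Category.parse(entry["category"]),
            ingredients=tuple(str(i) for i in entry.get("ingredients", [])),
            markers=tuple(entry.get("markers", [])),
            known_ratios=(
                tuple(float(r) for r in entry["known_ratios"])
                if entry.get("known_ratios") is not None
                else None
            ),
            complicated=bool(entry.get("complicated", False)),
        )
        spec.validate()
        specs.append(spec)
    seen: set[str] = set()
    for s in specs:
        if s.composite_id in seen:
            raise RecipeError(f"duplicate recipe for composite {s.composite_id}")
        seen.add(s.composite_id)
    return specs


def load_constants(path: str | Path) -> ProcessConstants:
    """Load :class:`ProcessConstants` overrides from a YAML mapping."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(doc, dict):
        raise RecipeError("constants file must be a mapping")
    return DEFAULT_CONSTANTS.with_overrides(**doc)


# ---------------------------------------------------------------------------
# Nutrient requirements per category and failure classification

# (composite nutrients, per-ingredient nutrients by position) needed to
# evaluate each category's RF equations.  Pickle ingredient order is
# (vegetable, medium[, sugar]); fermented categories take the single raw
# material first.
_CATEGORY_NEEDS: dict[Category, tuple[tuple[str, ...], tuple[tuple[str, ...], ...]]] = {
    Category.DRIED: (("water_pct",), (("water_pct",),)),
    Category.SALTED: (("water_pct", "salt_eq_g"), (("water_pct",),)),
    Category.PICKLE_RICE_BRAN: (
        ("water_pct", "salt_eq_g", "thiamine_mg"),
        (("water_pct",),),
    ),
    Category.PICKLE_VINEGAR: (
        ("water_pct", "salt_eq_g", "acetic_acid_g", "sucrose_g"),
        (("water_pct", "sucrose_g"),),
    ),
    Category.PICKLE_SOY: (
        ("water_pct", "salt_eq_g", "protein_g", "sucrose_g"),
        (("water_pct", "sucrose_g"),),
    ),
    Category.PICKLE_MISO: (
        ("water_pct", "salt_eq_g", "protein_g", "sucrose_g"),
        (("water_pct", "sucrose_g"),),
    ),
    Category.FERMENTED_ALCOHOL: (
        ("ethanol_g", "avail_carb_g"),
        (("avail_carb_g",),),
    ),
    Category.FERMENTED_ACETIC: (
        ("acetic_acid_g", "avail_carb_g"),
        (("avail_carb_g",),),
    ),
}


def required_nutrients(spec: RecipeSpec) -> tuple[tuple[str, ...], list[tuple[str, ...]]]:
    """Nutrients the RF equations need: (composite's, per-ingredient's).

    The per-ingredient list is aligned with ``spec.ingredients``;
    ingredients beyond the first for fixed-form categories (added salt, the
    pickling medium, sugar) need no table values because their markers enter
    through the process constants.
    """
    cat = spec.category
    k = len(spec.ingredients)
    if cat in (Category.MIXED, Category.FERMENTED_LACTIC):
        markers = effective_markers(spec)
        # With surplus candidate markers, no single one is individually
        # required; a shortfall is classified via the usable-marker count.
        if len(markers) > k:
            return (), [()] * k
        return tuple(markers), [tuple(markers)] * k
    if cat in (Category.MIXED_KNOWN_RATIO, Category.UNCOOKED, Category.COOKED):
        return (), [()] * k
    comp_needs, ing_needs = _CATEGORY_NEEDS[cat]
    per_ing = [ing_needs[i] if i < len(ing_needs) else () for i in range(k)]
    return comp_needs, per_ing


def effective_markers(spec: RecipeSpec) -> tuple[str, ...]:
    """Candidate markers, defaulting to (carbohydrate, calcium) for lactic."""
    if spec.markers:
        return spec.markers
    if spec.category is Category.FERMENTED_LACTIC:
        return ("avail_carb_g", "calcium_mg")
    return ()


def usable_markers(spec: RecipeSpec, table: CompositionTable) -> tuple[str, ...]:
    """Markers whose value is present in the composite and every ingredient."""
    comp = table.get(spec.composite_id)
    if comp is None:
        return ()
    out = []
    for m in effective_markers(spec):
        if comp.profile.get(m) is None:
            continue
        if all(
            (it := table.get(i)) is not None and it.profile.get(m) is not None
            for i in spec.ingredients
        ):
            out.append(m)
    return tuple(out)


def classify_failure(
    spec: RecipeSpec, table: CompositionTable
) -> FailureReason | None:
    """Decide whether a recipe's RF is computable; if not, say why.

    Returns ``None`` when the downstream RF computation has all the
    information it needs.  Precedence when several reasons apply:
    unknown ingredients > too many ingredients > complicated processing.
    """
    if spec.category in (Category.UNCOOKED, Category.COOKED):
        return None

    # Unknown/absent ingredients or missing marker values.
    if not spec.ingredients or any(not i.strip() for i in spec.ingredients):
        return FailureReason.INGREDIENTS_UNKNOWN
    if spec.composite_id not in table or any(
        i not in table for i in spec.ingredients
    ):
        return FailureReason.INGREDIENTS_UNKNOWN
    comp_needs, per_ing = required_nutrients(spec)
    if not table[spec.composite_id].profile.has(*comp_needs):
        return FailureReason.INGREDIENTS_UNKNOWN
    for ing_id, needs in zip(spec.ingredients, per_ing):
        if not table[ing_id].profile.has(*needs):
            return FailureReason.INGREDIENTS_UNKNOWN

    # Marker-count accounting for solver-based categories: a missing value
    # on a *required* marker (no surplus candidates) is an information gap;
    # too few usable markers among surplus candidates means the ingredient
    # count exceeds what the data can separate.
    if spec.category in (Category.MIXED, Category.FERMENTED_LACTIC):
        k = len(spec.ingredients)
        usable = usable_markers(spec, table)
        if len(usable) < k:
            if len(effective_markers(spec)) == k:
                return FailureReason.INGREDIENTS_UNKNOWN
            return FailureReason.TOO_MANY_INGREDIENTS
        # Independence: markers that cannot separate the ingredients (a
        # rank-deficient marker matrix) leave the system underdetermined.
        matrix = np.array(
            [
                [table[i].profile.get(m) for i in spec.ingredients]
                for m in usable
            ],
            dtype=float,
        )
        if k and np.linalg.matrix_rank(matrix) < k:
            return FailureReason.TOO_MANY_INGREDIENTS

    if spec.complicated:
        return FailureReason.COMPLICATED_PROCESSING
    return None
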