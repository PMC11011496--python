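"""Forward simulation of composition tables from known processing parameters.

Every RF engine in this package inverts a processing model: drying removes
water, salting adds salt, fermentation turns carbohydrate into ethanol (and
ethanol into acetic acid), mixing blends ingredient profiles linearly.
This module runs those models *forward* from ground-truth raw-commodity
profiles and processing parameters, producing a composition table, the
matching recipe config and the analytically known per-edge RFs — so the
whole pipeline is testable by parameter recovery without any external
dataset.

Two modelling points matter for exactness.  First, the fermentation
forward model consumes glucose at 1 g ethanol per 2.38 g glucose — the
yield the RF equation's integer coefficient 238 encodes — rather than the
underlying rounded 0.42 kg/kg figure; mass lost to CO2 and biomass is
tracked explicitly so the balance closes.  Second, pickled foods are
constructed by the inverse of the pickle equations themselves (marker
nutrients attributed wholly to the medium, sucrose to sugar and vegetable),
because those equations idealise away the medium's bulk mass; a literal
mixing simulation would not satisfy them exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .composition_io import (
    CompositionTable,
    FoodItem,
    NutrientProfile,
    write_composition_table,
)
from .recipe_model import (
    Category,
    DEFAULT_CONSTANTS,
    FailureReason,
    ProcessConstants,
    RecipeSpec,
)

__all__ = [
    "ProcessScript",
    "Dry",
    "SaltStep",
    "FermentAlcohol",
    "FermentAcetic",
    "Mix",
    "Corpus",
    "SimulationError",
    "generate_rpc_profiles",
    "simulate_processing",
    "simulate_pickle",
    "generate_corpus",
    "write_corpus",
    "DEFAULT_CATEGORY_MIX",
]


class SimulationError(ValueError):
    """A processing step is infeasible for its input."""


# ---------------------------------------------------------------------------
# Process steps

@dataclass(frozen=True)
class Dry:
    """Remove water down to ``target_water_pct`` percent."""

    target_water_pct: float


@dataclass(frozen=True)
class SaltStep:
    """Add ``salt_g`` grams of salt per 100 g of product; adjust water to
    ``target_water_pct``."""

    salt_g: float
    target_water_pct: float
    salt_id: str = ""


@dataclass(frozen=True)
class FermentAlcohol:
    """Ferment ``fraction`` of the available carbohydrate to ethanol.

    Ethanol yield is 1 g per ``glucose_per_ethanol`` g of glucose; the
    remainder leaves the batch as CO2 and biomass.  ``added_water_g`` is
    absolute grams of water blended in afterwards (dilution, as in brewing).
    """

    fraction: float
    added_water_g: float = 0.0


@dataclass(frozen=True)
class FermentAcetic:
    """Oxidise ``fraction`` of the ethanol to acetic acid at 1:1 mass."""

    fraction: float


@dataclass(frozen=True)
class Mix:
    """Blend ingredients (grams each) plus ``water_g`` of added water."""

    components: tuple[tuple[str, float], ...]
    water_g: float = 0.0


Step = Union[Dry, SaltStep, FermentAlcohol, FermentAcetic, Mix]

_MASS_KEYS = (
    "water",
    "protein",
    "carb",
    "sucrose",
    "acetic",
    "ethanol",
    "salt",
)


@dataclass(frozen=True)
class ProcessScript:
    """One composite food's forward recipe: a source (or mix) plus steps.

    ``truth`` — the per-edge RFs the parameters imply — is recomputed by
    :func:`simulate_processing` from the steps alone; it is never stored.
    """

    composite_id: str
    steps: tuple[Step, ...]
    source_id: str | None = None
    name: str = ""
    group: int = 1
    markers: tuple[str, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.steps:
            raise SimulationError(f"{self.composite_id}: empty step list")
        first_is_mix = isinstance(self.steps[0], Mix)
        if first_is_mix == (self.source_id is not None):
            raise SimulationError(
                f"{self.composite_id}: scripts start either from a source "
                "item or from a Mix step, not both"
            )
        for st in self.steps:
            if isinstance(st, (FermentAlcohol, FermentAcetic)):
                if not (0.0 <= st.fraction <= 1.0):
                    raise SimulationError(
                        f"{self.composite_id}: fraction must be in [0, 1]"
                    )
            if isinstance(st, Mix) and any(g <= 0 for _, g in st.components):
                raise SimulationError(
                    f"{self.composite_id}: mix weights must be > 0"
                )


class _Batch:
    """Absolute component masses (g; thiamine mg, calcium mg) of one batch."""

    def __init__(self) -> None:
        self.masses = {k: 0.0 for k in _MASS_KEYS}
        self.thiamine_mg = 0.0
        self.calcium_mg = 0.0
        self.total = 0.0

    @classmethod
    def from_item(cls, item: FoodItem, grams: float) -> "_Batch":
        b = cls()
        p = item.profile
        vals = {
            "water": p.water_pct,
            "protein": p.protein_g,
            "carb": p.avail_carb_g,
            "sucrose": p.sucrose_g,
            "acetic": p.acetic_acid_g,
            "ethanol": p.ethanol_g,
            "salt": p.salt_eq_g,
        }
        for k, v in vals.items():
            if v is None:
                raise SimulationError(
                    f"source item {item.food_id} is missing {k}; cannot simulate"
                )
            b.masses[k] = grams * v / 100.0
        b.thiamine_mg = grams * (p.thiamine_mg or 0.0) / 100.0
        b.calcium_mg = grams * (p.calcium_mg or 0.0) / 100.0
        b.total = grams
        return b

    def add(self, other: "_Batch") -> None:
        for k in _MASS_KEYS:
            self.masses[k] += other.masses[k]
        self.thiamine_mg += other.thiamine_mg
        self.calcium_mg += other.calcium_mg
        self.total += other.total

    def add_water(self, grams: float) -> None:
        self.masses["water"] += grams
        self.total += grams

    def profile(self) -> NutrientProfile:
        f = 100.0 / self.total
        return NutrientProfile(
            water_pct=self.masses["water"] * f,
            protein_g=self.masses["protein"] * f,
            avail_carb_g=self.masses["carb"] * f,
            sucrose_g=self.masses["sucrose"] * f,
            acetic_acid_g=self.masses["acetic"] * f,
            ethanol_g=self.masses["ethanol"] * f,
            salt_eq_g=self.masses["salt"] * f,
            thiamine_mg=self.thiamine_mg * f,
            calcium_mg=self.calcium_mg * f,
        )


def _apply_step(
    batch: _Batch, step: Step, table: CompositionTable, constants: ProcessConstants
) -> None:
    if isinstance(step, Dry):
        a = 100.0 * batch.masses["water"] / batch.total
        b = step.target_water_pct
        if b > a + 1e-12:
            raise SimulationError(
                f"drying cannot raise water content from {a:.2f}% to {b:.2f}%"
            )
        non_water = batch.total - batch.masses["water"]
        new_total = non_water / (1.0 - b / 100.0)
        batch.masses["water"] = new_total - non_water
        batch.total = new_total
    elif isinstance(step, SaltStep):
        s, b = step.salt_g, step.target_water_pct
        if s + b >= 100.0:
            raise SimulationError(f"salt ({s} g) + water ({b}%) >= 100 g product")
        base = batch.total - batch.masses["water"] + 0.0  # non-water mass
        new_total = base * 100.0 / (100.0 - s - b)
        batch.masses["salt"] += s * new_total / 100.0
        batch.masses["water"] = b * new_total / 100.0
        batch.total = new_total
    elif isinstance(step, FermentAlcohol):
        glucose = step.fraction * batch.masses["carb"]
        ethanol = glucose / constants.glucose_per_ethanol
        batch.masses["carb"] -= glucose
        batch.masses["sucrose"] = min(batch.masses["sucrose"], batch.masses["carb"])
        batch.masses["ethanol"] += ethanol
        batch.total -= glucose - ethanol  # CO2 + biomass leave the batch
        if step.added_water_g:
            batch.add_water(step.added_water_g)
    elif isinstance(step, FermentAcetic):
        oxidised = step.fraction * batch.masses["ethanol"]
        batch.masses["ethanol"] -= oxidised
        batch.masses["acetic"] += oxidised * constants.acetic_per_ethanol_assumed
        # 1:1 mass assumption: total mass unchanged
    elif isinstance(step, Mix):
        for fid, grams in step.components:
            batch.add(_Batch.from_item(table[fid], grams))
        if step.water_g:
            batch.add_water(step.water_g)
    else:  # pragma: no cover
        raise SimulationError(f"unknown step {step!r}")


def _category_of(script: ProcessScript) -> Category:
    kinds = tuple(type(s) for s in script.steps)
    if kinds == (Dry,):
        return Category.DRIED
    if kinds == (SaltStep,):
        return Category.SALTED
    if all(k in (FermentAlcohol, FermentAcetic) for k in kinds):
        return (
            Category.FERMENTED_ACETIC
            if FermentAcetic in kinds
            else Category.FERMENTED_ALCOHOL
        )
    if kinds == (Mix,):
        return Category.MIXED
    raise SimulationError(
        f"{script.composite_id}: step pattern {kinds} has no recipe category"
    )


def simulate_processing(
    script: ProcessScript,
    table: CompositionTable,
    constants: ProcessConstants = DEFAULT_CONSTANTS,
) -> tuple[FoodItem, RecipeSpec, dict[str, float]]:
    """Run a script forward; return the composite, its recipe and true RFs.

    The truth dict maps ingredient id to grams of that ingredient per gram
    of the finished composite, computed by exact mass bookkeeping.
    """
    if script.source_id is not None:
        batch = _Batch.from_item(table[script.source_id], 100.0)
        initial = 100.0
    else:
        batch = _Batch()
        initial = 0.0
    for step in script.steps:
        _apply_step(batch, step, table, constants)

    category = _category_of(script)
    truth: dict[str, float] = {}
    ingredients: list[str] = []
    if script.source_id is not None:
        truth[script.source_id] = initial / batch.total
        ingredients.append(script.source_id)
        for st in script.steps:
            if isinstance(st, SaltStep) and st.salt_id:
                truth[st.salt_id] = st.salt_g / 100.0
                ingredients.append(st.salt_id)
    else:
        mix = script.steps[0]
        assert isinstance(mix, Mix)
        for fid, grams in mix.components:
            truth[fid] = grams / batch.total
            ingredients.append(fid)

    item = FoodItem(
        food_id=script.composite_id,
        name=script.name or f"synthetic {category.value} {script.composite_id}",
        group=script.group,
        profile=batch.profile(),
        is_rpc=False,
    )
    spec = RecipeSpec(
        composite_id=script.composite_id,
        category=category,
        ingredients=tuple(ingredients),
        markers=script.markers,
    )
    spec.validate()
    return item, spec, truth


def simulate_pickle(
    composite_id: str,
    vegetable: FoodItem,
    medium_kind: str,
    rf_vegetable: float,
    rf_medium: float,
    rf_sugar: float,
    salt_g: float,
    medium_id: str,
    sugar_id: str | None,
    constants: ProcessConstants = DEFAULT_CONSTANTS,
    name: str = "",
    group: int = 6,
) -> tuple[FoodItem, RecipeSpec, dict[str, float]]:
    """Construct a pickled food whose profile encodes the given true RFs.

    Inverse of the pickle equations: the product's water follows the
    salted-food balance, its medium marker (thiamine / acetate / protein)
    is wholly attributed to the medium, and its sucrose is the sum of the
    sugar, vegetable and (for soy sauce) medium contributions.
    """
    a = vegetable.profile.water_pct
    if a is None:
        raise SimulationError(f"vegetable {vegetable.food_id} has no water value")
    b = 100.0 - salt_g - rf_vegetable * (100.0 - a)
    if not (0.0 <= b < 100.0):
        raise SimulationError(
            f"{composite_id}: infeasible water balance (b = {b:.2f}%)"
        )
    veg_sucrose = vegetable.profile.sucrose_g or 0.0
    sucrose = rf_sugar * constants.sucrose_sugar + rf_vegetable * veg_sucrose
    thiamine = 0.0
    acetic = 0.0
    protein = rf_vegetable * 0.0  # medium marker assumption: veg protein ignored
    if medium_kind == "rice-bran":
        category = Category.PICKLE_RICE_BRAN
        thiamine = rf_medium * constants.thiamine_rice_bran
    elif medium_kind == "vinegar":
        category = Category.PICKLE_VINEGAR
        acetic = rf_medium * constants.acetate_vinegar
    elif medium_kind == "soy":
        category = Category.PICKLE_SOY
        protein = rf_medium * constants.protein_soy_sauce
        sucrose += rf_medium * constants.sucrose_soy_sauce
    elif medium_kind == "miso":
        category = Category.PICKLE_MISO
        protein = rf_medium * constants.protein_miso
    else:
        raise SimulationError(f"unknown pickle medium {medium_kind!r}")

    # Added sugar is carbohydrate too; the vegetable's carb scales with it.
    carb = rf_vegetable * (vegetable.profile.avail_carb_g or 0.0) + (
        rf_sugar * constants.sucrose_sugar
    )
    profile = NutrientProfile(
        water_pct=b,
        protein_g=protein,
        avail_carb_g=carb,
        sucrose_g=sucrose,
        acetic_acid_g=acetic,
        ethanol_g=0.0,
        salt_eq_g=salt_g,
        thiamine_mg=thiamine,
        calcium_mg=rf_vegetable * (vegetable.profile.calcium_mg or 0.0),
    )
    item = FoodItem(
        food_id=composite_id,
        name=name or f"synthetic {category.value} {composite_id}",
        group=group,
        profile=profile,
    )
    ingredients = [vegetable.food_id, medium_id]
    truth = {vegetable.food_id: rf_vegetable, medium_id: rf_medium}
    if sugar_id is not None and category is not Category.PICKLE_RICE_BRAN:
        ingredients.append(sugar_id)
        truth[sugar_id] = rf_sugar
    spec = RecipeSpec(
        composite_id=composite_id,
        category=category,
        ingredients=tuple(ingredients),
    )
    return item, spec, truth


# ---------------------------------------------------------------------------
# RPC generation

def generate_rpc_profiles(seed: int, n: int, id_prefix: str = "R") -> list[FoodItem]:
    """Reproducible pseudo-random raw-primary-commodity items.

    Water spans 5–96%, other nutrients are non-negative with mass closure
    inside 100 g.  Salt, acetic acid and ethanol are zero — raw
    commodities carry none, and the salted/fermented equations attribute
    those entirely to processing.  Same seed, same output.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n):
        water = float(rng.uniform(5.0, 96.0))
        dry = 100.0 - water
        protein = float(rng.uniform(0.0, 0.35)) * dry
        carb = float(rng.uniform(0.05, 0.8)) * (dry - protein)
        sucrose = float(rng.uniform(0.0, 0.5)) * carb
        profile = NutrientProfile(
            water_pct=water,
            protein_g=protein,
            avail_carb_g=carb,
            sucrose_g=sucrose,
            acetic_acid_g=0.0,
            ethanol_g=0.0,
            salt_eq_g=0.0,
            thiamine_mg=float(rng.uniform(0.01, 0.5)),
            calcium_mg=float(rng.uniform(2.0, 250.0)),
        )
        item = FoodItem(
            food_id=f"{id_prefix}{i + 1:04d}",
            name=f"synthetic RPC {id_prefix}{i + 1:04d}",
            group=int(rng.integers(1, 18)),
            profile=profile,
            is_rpc=True,
        )
        item.validate()
        items.append(item)
    return items


def _veg_rpc(rng: np.random.Generator, food_id: str) -> FoodItem:
    """High-water vegetable-like RPC suitable for pickling."""
    water = float(rng.uniform(84.0, 94.0))
    carb = float(rng.uniform(1.5, min(6.0, 100.0 - water - 1.0)))
    sucrose = float(rng.uniform(0.2, 0.9)) * carb
    return FoodItem(
        food_id=food_id,
        name=f"synthetic vegetable {food_id}",
        group=6,
        profile=NutrientProfile(
            water_pct=water,
            protein_g=float(rng.uniform(0.3, 1.5)),
            avail_carb_g=carb,
            sucrose_g=sucrose,
            acetic_acid_g=0.0,
            ethanol_g=0.0,
            salt_eq_g=0.0,
            thiamine_mg=float(rng.uniform(0.01, 0.06)),
            calcium_mg=float(rng.uniform(10.0, 60.0)),
        ),
        is_rpc=True,
    )


def _grain_rpc(rng: np.random.Generator, food_id: str) -> FoodItem:
    """Low-water, carbohydrate-rich RPC suitable for fermentation."""
    water = float(rng.uniform(10.0, 16.0))
    carb = float(rng.uniform(60.0, 78.0))
    protein = float(rng.uniform(5.0, min(12.0, 100.0 - water - carb - 1.0)))
    return FoodItem(
        food_id=food_id,
        name=f"synthetic grain {food_id}",
        group=1,
        profile=NutrientProfile(
            water_pct=water,
            protein_g=protein,
            avail_carb_g=carb,
            sucrose_g=float(rng.uniform(0.0, 1.5)),
            acetic_acid_g=0.0,
            ethanol_g=0.0,
            salt_eq_g=0.0,
            thiamine_mg=float(rng.uniform(0.1, 0.6)),
            calcium_mg=float(rng.uniform(3.0, 30.0)),
        ),
        is_rpc=True,
    )


# ---------------------------------------------------------------------------
# Corpus generation

DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "dried": 0.12,
    "salted": 0.12,
    "pickle-rice-bran": 0.07,
    "pickle-vinegar": 0.07,
    "pickle-soy": 0.07,
    "pickle-miso": 0.07,
    "fermented-alcohol": 0.10,
    "fermented-acetic": 0.06,
    "fermented-lactic": 0.05,
    "mixed": 0.15,
    "mixed-known-ratio": 0.07,
    "failing": 0.05,
}


@dataclass
class Corpus:
    """A self-contained synthetic test corpus.

    ``truth`` maps (composite_id, ingredient_id) to the generating RF;
    ``expected_failures`` maps deliberately broken composites to their
    failure reason.
    """

    table: CompositionTable
    recipes: list[RecipeSpec]
    truth: dict[tuple[str, str], float]
    expected_failures: dict[str, FailureReason]
    constants: ProcessConstants = DEFAULT_CONSTANTS


def _blend_profile(
    components: list[tuple[FoodItem, float]], water_g: float
) -> NutrientProfile:
    total = sum(g for _, g in components) + water_g
    vals = {n: 0.0 for n in (
        "water_pct", "protein_g", "avail_carb_g", "sucrose_g", "acetic_acid_g",
        "ethanol_g", "salt_eq_g", "thiamine_mg", "calcium_mg",
    )}
    for item, g in components:
        for n in vals:
            vals[n] += g * (item.profile.get(n) or 0.0) / 100.0
    vals["water_pct"] += water_g
    return NutrientProfile(**{n: v * 100.0 / total for n, v in vals.items()})


def _register(
    corpus: Corpus,
    item: FoodItem,
    spec: RecipeSpec | None,
    truth: dict[str, float] | None,
) -> None:
    corpus.table.add(item)
    if spec is not None:
        corpus.recipes.append(spec)
    if truth and spec is not None:
        for ing, rf in truth.items():
            corpus.truth[(spec.composite_id, ing)] = rf


def _base_items(corpus: Corpus) -> dict[str, FoodItem]:
    """Fixed ingredients every corpus carries: salt, sugar, staple RPCs and
    the four pickling media, each medium with its own (tier-adding) recipe
    consistent with the process constants."""
    c = corpus.constants
    items: dict[str, FoodItem] = {}

    def add_rpc(fid: str, name: str, group: int, **nutrients: float) -> FoodItem:
        defaults = dict(
            water_pct=0.0, protein_g=0.0, avail_carb_g=0.0, sucrose_g=0.0,
            acetic_acid_g=0.0, ethanol_g=0.0, salt_eq_g=0.0,
            thiamine_mg=0.0, calcium_mg=0.0,
        )
        defaults.update(nutrients)
        item = FoodItem(fid, name, group, NutrientProfile(**defaults), is_rpc=True)
        corpus.table.add(item)
        items[fid] = item
        return item

    add_rpc("S0001", "salt", 17, water_pct=0.1, salt_eq_g=99.5)
    add_rpc(
        "S0002", "refined sugar", 3,
        water_pct=0.7, avail_carb_g=c.sucrose_sugar, sucrose_g=c.sucrose_sugar,
    )
    rice = add_rpc(
        "S0010", "polished rice", 1,
        water_pct=14.0, protein_g=6.1, avail_carb_g=77.0, sucrose_g=0.2,
        thiamine_mg=0.08, calcium_mg=5.0,
    )
    bran = add_rpc(
        "S0011", "rice bran", 1,
        water_pct=10.0, protein_g=13.4, avail_carb_g=27.0, sucrose_g=3.0,
        thiamine_mg=5.2, calcium_mg=35.0,
    )
    soybean = add_rpc(
        "S0012", "soybean", 4,
        water_pct=12.4, protein_g=33.0, avail_carb_g=12.0, sucrose_g=0.35,
        thiamine_mg=0.7, calcium_mg=180.0,
    )
    wheat = add_rpc(
        "S0013", "wheat", 1,
        water_pct=12.5, protein_g=10.5, avail_carb_g=72.0,
        thiamine_mg=0.4, calcium_mg=20.0,
    )
    add_rpc(
        "S0014", "miso soybean", 4,
        water_pct=12.4, protein_g=33.0, avail_carb_g=12.0,
        thiamine_mg=0.7, calcium_mg=180.0,
    )
    add_rpc(
        "S0015", "milk", 13,
        water_pct=87.4, protein_g=3.3, avail_carb_g=4.8, sucrose_g=0.0,
        thiamine_mg=0.04, calcium_mg=110.0,
    )
    add_rpc(
        "S0016", "skim milk powder", 13,
        water_pct=3.8, protein_g=34.0, avail_carb_g=53.3,
        thiamine_mg=0.3, calcium_mg=1100.0,
    )

    # Rice-bran pickling paste: exact blend of bran + salt + water, with
    # thiamine hitting the constant 3.12 mg/100 g.
    w_bran = 100.0 * c.thiamine_rice_bran / bran.profile.thiamine_mg  # -> 60 g
    w_salt = 8.0
    blend = [(bran, w_bran), (items["S0001"], w_salt)]
    water_g = 100.0 - w_bran - w_salt
    paste = FoodItem(
        "M0001", "rice bran paste", 17, _blend_profile(blend, water_g)
    )
    spec = RecipeSpec(
        composite_id="M0001",
        category=Category.MIXED,
        ingredients=("S0011", "S0001"),
        markers=("thiamine_mg", "salt_eq_g"),
    )
    _register(corpus, paste, spec, {"S0011": w_bran / 100.0, "S0001": w_salt / 100.0})
    items["M0001"] = paste

    # Soy sauce: blend of soybean + wheat + salt with protein pinned to
    # 7.7 g/100 g and sucrose to 0.1 g/100 g.
    w_soy = 20.0
    w_wheat = (
        100.0 * c.protein_soy_sauce - w_soy * soybean.profile.protein_g
    ) / wheat.profile.protein_g
    # choose wheat sucrose so the blend sucrose equals the constant
    wheat_sucrose = (
        100.0 * c.sucrose_soy_sauce - w_soy * soybean.profile.sucrose_g
    ) / w_wheat
    wheat = FoodItem(
        wheat.food_id, wheat.name, wheat.group,
        NutrientProfile(
            **{
                **{n: wheat.profile.get(n) for n in (
                    "water_pct", "protein_g", "avail_carb_g", "acetic_acid_g",
                    "ethanol_g", "salt_eq_g", "thiamine_mg", "calcium_mg",
                )},
                "sucrose_g": wheat_sucrose,
            }
        ),
        is_rpc=True,
    )
    corpus.table._items["S0013"] = wheat  # replace with pinned-sucrose profile
    items["S0013"] = wheat
    w_salt = 14.0
    blend = [(soybean, w_soy), (wheat, w_wheat), (items["S0001"], w_salt)]
    water_g = 100.0 - w_soy - w_wheat - w_salt
    soy_sauce = FoodItem("M0002", "soy sauce", 17, _blend_profile(blend, water_g))
    spec = RecipeSpec(
        composite_id="M0002",
        category=Category.MIXED,
        ingredients=("S0012", "S0013", "S0001"),
        markers=("protein_g", "avail_carb_g", "salt_eq_g"),
    )
    _register(
        corpus, soy_sauce, spec,
        {"S0012": w_soy / 100.0, "S0013": w_wheat / 100.0, "S0001": w_salt / 100.0},
    )
    items["M0002"] = soy_sauce

    # Miso: soybean (sucrose-free variant) + rice + salt, protein pinned to
    # 12.5 g/100 g.
    w_soy = 30.0
    w_rice = (
        100.0 * c.protein_miso - w_soy * items["S0014"].profile.protein_g
    ) / rice.profile.protein_g
    w_salt = 12.0
    blend = [(items["S0014"], w_soy), (rice, w_rice), (items["S0001"], w_salt)]
    water_g = max(0.0, 100.0 - w_soy - w_rice - w_salt)
    total = w_soy + w_rice + w_salt + water_g
    miso = FoodItem("M0003", "miso", 17, _blend_profile(blend, water_g))
    spec = RecipeSpec(
        composite_id="M0003",
        category=Category.MIXED,
        ingredients=("S0014", "S0010", "S0001"),
        markers=("protein_g", "avail_carb_g", "salt_eq_g"),
    )
    _register(
        corpus, miso, spec,
        {"S0014": w_soy / total, "S0010": w_rice / total, "S0001": w_salt / total},
    )
    items["M0003"] = miso

    # Grain vinegar: acetic fermentation of rice, acetate pinned to
    # 4.2 g/100 g, fully oxidised.
    acetic = c.acetate_vinegar
    glucose = acetic / c.acetic_per_ethanol_assumed * c.glucose_per_ethanol
    residual = 0.5
    m = (glucose + residual) * 100.0 / rice.profile.avail_carb_g
    vinegar_profile = NutrientProfile(
        water_pct=m * rice.profile.water_pct / 100.0
        + (100.0 - m + (glucose - acetic / c.acetic_per_ethanol_assumed)),
        protein_g=m * rice.profile.protein_g / 100.0,
        avail_carb_g=residual,
        sucrose_g=0.0,
        acetic_acid_g=acetic,
        ethanol_g=0.0,
        salt_eq_g=0.0,
        thiamine_mg=m * rice.profile.thiamine_mg / 100.0,
        calcium_mg=m * rice.profile.calcium_mg / 100.0,
    )
    vinegar = FoodItem("M0004", "grain vinegar", 17, vinegar_profile)
    spec = RecipeSpec(
        composite_id="M0004",
        category=Category.FERMENTED_ACETIC,
        ingredients=("S0010",),
    )
    _register(corpus, vinegar, spec, {"S0010": m / 100.0})
    items["M0004"] = vinegar
    return items


def _pick_markers(
    rng: np.random.Generator, components: list[FoodItem], k: int
) -> tuple[str, ...] | None:
    """A k-marker subset whose matrix is comfortably nonsingular."""
    candidates = ["protein_g", "avail_carb_g", "sucrose_g", "thiamine_mg", "calcium_mg"]
    rng.shuffle(candidates)
    for subset in itertools.combinations(candidates, k):
        m = np.array(
            [[it.profile.get(mk) or 0.0 for it in components] for mk in subset]
        )
        if np.linalg.matrix_rank(m) == k and np.linalg.cond(m) < 1e6:
            return tuple(subset)
    return None


def generate_corpus(
    seed: int,
    n_foods: int = 220,
    category_mix: dict[str, float] | None = None,
    constants: ProcessConstants = DEFAULT_CONSTANTS,
) -> Corpus:
    """Generate a full synthetic corpus spanning every category.

    ``n_foods`` is the approximate number of composite recipes; the mix of
    categories follows ``category_mix`` (fractions summing to 1, including
    a ``failing`` share of deliberately non-computable foods).  Multi-tier
    chains are built in: the pickling media carry their own recipes
    (tier 2–3 via soy sauce, miso, bran paste, vinegar) and a six-step
    mix-on-mix chain exercises the maximum depth.  Same seed, same corpus.
    """
    mix = dict(DEFAULT_CATEGORY_MIX if category_mix is None else category_mix)
    total_frac = sum(mix.values())
    if abs(total_frac - 1.0) > 1e-9:
        raise ValueError(f"category_mix fractions must sum to 1, got {total_frac}")
    rng = np.random.default_rng(seed)
    corpus = Corpus(
        table=CompositionTable(),
        recipes=[],
        truth={},
        expected_failures={},
        constants=constants,
    )
    items = _base_items(corpus)
    rpcs = generate_rpc_profiles(int(rng.integers(1, 2**31 - 1)), max(20, n_foods // 4))
    for it in rpcs:
        corpus.table.add(it)

    counts = {k: max(1, round(v * n_foods)) for k, v in mix.items()}
    cid = 0

    def next_id() -> str:
        nonlocal cid
        cid += 1
        return f"C{cid:04d}"

    def register_script(script: ProcessScript) -> None:
        item, spec, truth = simulate_processing(script, corpus.table, constants)
        _register(corpus, item, spec, truth)

    # --- dried -----------------------------------------------------------
    for _ in range(counts["dried"]):
        src = rpcs[int(rng.integers(0, len(rpcs)))]
        a = src.profile.water_pct
        b = float(rng.uniform(1.0, 0.8 * a)) if a > 2 else 0.5 * a
        register_script(
            ProcessScript(next_id(), (Dry(b),), source_id=src.food_id, group=src.group)
        )

    # --- salted ----------------------------------------------------------
    veg_pool = [_veg_rpc(rng, f"V{i + 1:04d}") for i in range(30)]
    for v in veg_pool:
        corpus.table.add(v)
    for _ in range(counts["salted"]):
        src = veg_pool[int(rng.integers(0, len(veg_pool)))]
        a = src.profile.water_pct
        s = float(rng.uniform(2.0, 8.0))
        lo, hi = max(5.0, a - 25.0), min(94.0 - s, a + 4.0)
        b = float(rng.uniform(lo, hi))
        register_script(
            ProcessScript(
                next_id(), (SaltStep(s, b, salt_id="S0001"),),
                source_id=src.food_id, group=6,
            )
        )

    # --- pickles ---------------------------------------------------------
    pickle_plans = [
        ("pickle-rice-bran", "rice-bran", "M0001"),
        ("pickle-vinegar", "vinegar", "M0004"),
        ("pickle-soy", "soy", "M0002"),
        ("pickle-miso", "miso", "M0003"),
    ]
    for key, medium_kind, medium_id in pickle_plans:
        for _ in range(counts[key]):
            veg = veg_pool[int(rng.integers(0, len(veg_pool)))]
            item, spec, truth = simulate_pickle(
                next_id(),
                veg,
                medium_kind,
                rf_vegetable=float(rng.uniform(0.6, 2.0)),
                rf_medium=float(rng.uniform(0.05, 0.25)),
                rf_sugar=float(rng.uniform(0.0, 0.02)),
                salt_g=float(rng.uniform(4.0, 7.0)),
                medium_id=medium_id,
                sugar_id="S0002",
                constants=constants,
            )
            _register(corpus, item, spec, truth)

    # --- fermented -------------------------------------------------------
    grain_pool = [_grain_rpc(rng, f"G{i + 1:04d}") for i in range(12)]
    for g in grain_pool:
        corpus.table.add(g)
    for key, acetic in (("fermented-alcohol", False), ("fermented-acetic", True)):
        for _ in range(counts[key]):
            src = grain_pool[int(rng.integers(0, len(grain_pool)))]
            r = float(rng.uniform(0.30, 0.55))
            phi = float(rng.uniform(0.5, 0.9))
            # run on 100 g of source, then dilute so the product mass is 100/r
            m = 100.0
            glucose = phi * m * src.profile.avail_carb_g / 100.0
            ethanol = glucose / constants.glucose_per_ethanol
            water_add = m / r - (m - (glucose - ethanol))
            if water_add < 0:
                water_add = 0.0
            steps: list[Step] = [FermentAlcohol(phi, added_water_g=water_add)]
            if acetic:
                steps.append(FermentAcetic(1.0))
            register_script(
                ProcessScript(
                    next_id(), tuple(steps), source_id=src.food_id, group=16
                )
            )

    # --- lactic-fermented (2x2 carb/calcium system) ----------------------
    for _ in range(counts["fermented-lactic"]):
        w_milk = float(rng.uniform(20.0, 60.0))
        w_powder = float(rng.uniform(2.0, 12.0))
        blend = [(items["S0015"], w_milk), (items["S0016"], w_powder)]
        water_g = 100.0 - w_milk - w_powder
        comp_id = next_id()
        item = FoodItem(
            comp_id, f"synthetic lactic beverage {comp_id}", 13,
            _blend_profile(blend, water_g),
        )
        spec = RecipeSpec(
            composite_id=comp_id,
            category=Category.FERMENTED_LACTIC,
            ingredients=("S0015", "S0016"),
        )
        _register(
            corpus, item, spec,
            {"S0015": w_milk / 100.0, "S0016": w_powder / 100.0},
        )

    # --- mixed (solver) and known-ratio ----------------------------------
    def make_mix(comp_id: str, known_ratio: bool, extra_marker: bool) -> None:
        k = int(rng.integers(2, 5))
        idx = rng.choice(len(rpcs), size=k, replace=False)
        components = [rpcs[int(i)] for i in idx]
        markers = _pick_markers(rng, components, k)
        if markers is None:
            return
        weights = rng.uniform(5.0, 30.0, size=k)
        weights *= min(1.0, 95.0 / weights.sum())
        mix_step = Mix(
            components=tuple(
                (c.food_id, float(w)) for c, w in zip(components, weights)
            ),
            water_g=float(100.0 - weights.sum()),
        )
        item, spec, truth = simulate_processing(
            ProcessScript(comp_id, (mix_step,), markers=markers),
            corpus.table,
            constants,
        )
        if known_ratio:
            spec = RecipeSpec(
                composite_id=comp_id,
                category=Category.MIXED_KNOWN_RATIO,
                ingredients=spec.ingredients,
                known_ratios=tuple(float(w) for w in weights),
            )
        elif extra_marker:
            pool = [
                m
                for m in (
                    "protein_g", "avail_carb_g", "sucrose_g",
                    "thiamine_mg", "calcium_mg",
                )
                if m not in markers
            ]
            if pool:
                spec = RecipeSpec(
                    composite_id=comp_id,
                    category=Category.MIXED,
                    ingredients=spec.ingredients,
                    markers=markers + (pool[0],),
                )
        _register(corpus, item, spec, truth)

    for i in range(counts["mixed"]):
        make_mix(next_id(), known_ratio=False, extra_marker=(i % 3 == 0))
    for _ in range(counts["mixed-known-ratio"]):
        make_mix(next_id(), known_ratio=True, extra_marker=False)

    # --- multi-tier mix chain (depth 6) ----------------------------------
    base = grain_pool[0]
    chain_prev = next_id()
    register_script(
        ProcessScript(
            chain_prev, (Dry(max(1.0, base.profile.water_pct * 0.5)),),
            source_id=base.food_id,
        )
    )
    for _ in range(5):
        partner = rpcs[int(rng.integers(0, len(rpcs)))]
        comp_id = next_id()
        prev_item = corpus.table[chain_prev]
        markers = _pick_markers(rng, [prev_item, partner], 2)
        if markers is None:
            markers = ("avail_carb_g", "calcium_mg")
        w1, w2 = float(rng.uniform(20.0, 45.0)), float(rng.uniform(10.0, 30.0))
        mix_step = Mix(
            components=((chain_prev, w1), (partner.food_id, w2)),
            water_g=100.0 - w1 - w2,
        )
        register_script(
            ProcessScript(comp_id, (mix_step,), markers=markers)
        )
        chain_prev = comp_id

    # --- deliberately failing foods --------------------------------------
    fail_kinds = ["unknown-id", "missing-marker", "too-many", "singular", "complicated"]
    for i in range(counts["failing"]):
        kind = fail_kinds[i % len(fail_kinds)]
        comp_id = next_id()
        if kind == "unknown-id":
            item = FoodItem(
                comp_id, f"synthetic failing {comp_id}", 15,
                _blend_profile([(rpcs[0], 50.0)], 50.0),
            )
            spec = RecipeSpec(
                composite_id=comp_id,
                category=Category.MIXED,
                ingredients=(rpcs[0].food_id, "Z9999"),
                markers=("protein_g", "avail_carb_g"),
            )
            reason = FailureReason.INGREDIENTS_UNKNOWN
        elif kind == "missing-marker":
            profile = _blend_profile([(rpcs[1], 40.0), (rpcs[2], 30.0)], 30.0)
            profile = NutrientProfile(
                **{
                    **{n: profile.get(n) for n in (
                        "water_pct", "avail_carb_g", "sucrose_g", "acetic_acid_g",
                        "ethanol_g", "salt_eq_g", "thiamine_mg", "calcium_mg",
                    )},
                    "protein_g": None,  # required marker value absent
                }
            )
            item = FoodItem(comp_id, f"synthetic failing {comp_id}", 15, profile)
            spec = RecipeSpec(
                composite_id=comp_id,
                category=Category.MIXED,
                ingredients=(rpcs[1].food_id, rpcs[2].food_id),
                markers=("protein_g", "avail_carb_g"),
            )
            reason = FailureReason.INGREDIENTS_UNKNOWN
        elif kind == "too-many":
            # three ingredients, four candidate markers, but two marker
            # values missing across ingredients -> only two usable
            comps = [rpcs[3], rpcs[4], rpcs[5]]
            item = FoodItem(
                comp_id, f"synthetic failing {comp_id}", 15,
                _blend_profile([(c, 20.0) for c in comps], 40.0),
            )
            broken = comps[0]
            stripped = NutrientProfile(
                **{
                    **{n: broken.profile.get(n) for n in (
                        "water_pct", "protein_g", "avail_carb_g", "sucrose_g",
                        "acetic_acid_g", "ethanol_g", "salt_eq_g",
                    )},
                    "thiamine_mg": None,
                    "calcium_mg": None,
                }
            )
            replacement = FoodItem(
                f"{comp_id}X", broken.name + " (partial data)", broken.group,
                stripped, is_rpc=True,
            )
            corpus.table.add(replacement)
            spec = RecipeSpec(
                composite_id=comp_id,
                category=Category.MIXED,
                ingredients=(replacement.food_id, comps[1].food_id, comps[2].food_id),
                markers=("protein_g", "avail_carb_g", "thiamine_mg", "calcium_mg"),
            )
            reason = FailureReason.TOO_MANY_INGREDIENTS
        elif kind == "singular":
            # duplicate ingredient profiles: markers cannot separate them
            twin = FoodItem(
                f"{comp_id}X", rpcs[6].name + " (twin)", rpcs[6].group,
                rpcs[6].profile, is_rpc=True,
            )
            corpus.table.add(twin)
            item = FoodItem(
                comp_id, f"synthetic failing {comp_id}", 15,
                _blend_profile([(rpcs[6], 30.0), (twin, 20.0)], 50.0),
            )
            spec = RecipeSpec(
                composite_id=comp_id,
                category=Category.MIXED,
                ingredients=(rpcs[6].food_id, twin.food_id),
                markers=("protein_g", "avail_carb_g"),
            )
            reason = FailureReason.TOO_MANY_INGREDIENTS
        else:  # complicated
            item = FoodItem(
                comp_id, f"synthetic complex fermentation {comp_id}", 15,
                _blend_profile([(rpcs[7], 60.0)], 40.0),
            )
            spec = RecipeSpec(
                composite_id=comp_id,
                category=Category.MIXED,
                ingredients=(rpcs[7].food_id,),
                markers=("avail_carb_g",),
                complicated=True,
            )
            reason = FailureReason.COMPLICATED_PROCESSING
        corpus.table.add(item)
        corpus.recipes.append(spec)
        corpus.expected_failures[comp_id] = reason

    # --- uncooked / cooked passthroughs ----------------------------------
    for cat in (Category.UNCOOKED, Category.COOKED):
        comp_id = next_id()
        item = FoodItem(
            comp_id, f"synthetic {cat.value} item {comp_id}", 6,
            _blend_profile([(veg_pool[0], 100.0)], 0.0),
        )
        corpus.table.add(item)
        corpus.recipes.append(
            RecipeSpec(composite_id=comp_id, category=cat)
        )
    return corpus


def write_corpus(corpus: Corpus, out_dir: str | Path) -> dict[str, Path]:
    """Write a corpus as the delimited-text and YAML formats the readers
    consume, plus a TSV of ground-truth RFs.  Byte-identical for the same
    corpus."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table_path = out / "composition_table.tsv"
    recipes_path = out / "recipes.yaml"
    truth_path = out / "truth.tsv"
    write_composition_table(corpus.table, table_path)
    doc = {
        "recipes": [
            {
                "composite": s.composite_id,
                "category": s.category.value,
                "ingredients": list(s.ingredients),
                **({"markers": list(s.markers)} if s.markers else {}),
                **(
                    {"known_ratios": [float(r) for r in s.known_ratios]}
                    if s.known_ratios is not None
                    else {}
                ),
                **({"complicated": True} if s.complicated else {}),
            }
            for s in corpus.recipes
        ]
    }
    recipes_path.write_text(
        yaml.safe_dump(doc, sort_keys=False), encoding="utf-8"
    )
    with truth_path.open("w", encoding="utf-8") as fh:
        fh.write("composite_id\tingredient_id\trf\n")
        for (comp, ing), rf in sorted(corpus.truth.items()):
            fh.write(f"{comp}\t{ing}\t{rf!r}\n")
    return {"table": table_path, "recipes": recipes_path, "truth": truth_path}
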