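"""Reverse-yield factors for alcohol-, acetic-acid- and lactic-fermented foods.

Alcoholic fermentation converts glucose to ethanol and CO2; with roughly
20% of the glucose diverted to yeast growth the practical yield is 0.42 kg
ethanol per kg glucose, i.e. 1/0.42 ≈ 2.38 g glucose per g ethanol.  For a
product carrying ``a`` g ethanol and ``b`` g residual available carbohydrate
per 100 g, made from a raw material with ``c`` g available carbohydrate per
100 g, the raw mass per 100 g of product is 238·a/c + 100·b/c grams (the
integer 238 = round(100 × 2.38) folds the yield into the coefficient), so

    RF_alcohol = (238 a/c + 100 b/c) / 100.

Acetic-acid fermentation oxidises ethanol to acetic acid
(C2H5OH + O2 → CH3COOH + H2O; theoretical yield 60/46 ≈ 1.304 kg/kg), but
because Acetobacter consumes part of the ethanol for growth the working
assumption is 1 kg acetic acid per 1 kg ethanol metabolised, which makes
the acetic equation formally identical with the acetic mass ``d`` in the
ethanol slot.

Lactic-fermented beverages with two ingredients are solved as a 2×2
nutrient-balance system on available carbohydrate and calcium (lactic
pickles route through the salted-food equation instead and are categorised
as salted in the recipe config).
"""

from __future__ import annotations

from dataclasses import dataclass

from .composition_io import NutrientProfile
from .recipe_model import DEFAULT_CONSTANTS, FailureReason, ProcessConstants
from .rf_simple import RFComputationError

__all__ = [
    "FermentInput",
    "MissingMarkerError",
    "rf_alcohol_fermented",
    "rf_acetic_fermented",
    "glucose_equiv_ethanol",
    "glucose_equiv_acetate",
    "theoretical_acetic_yield",
    "rf_lactic_fermented",
]

# Molar masses (g/mol) behind the stoichiometric helpers.
_M_GLUCOSE = 180.0
_M_ETHANOL = 46.0
_M_ACETIC = 60.0


class MissingMarkerError(RFComputationError):
    """A marker nutrient needed by the fermentation equations is absent."""

    reason = FailureReason.INGREDIENTS_UNKNOWN


@dataclass(frozen=True)
class FermentInput:
    """Inputs to the fermentation RF equations, all g/100 g.

    ``ethanol_g`` and ``acetic_g`` are the product's alcohol and acetic-acid
    masses; ``residual_carb_g`` the product's remaining available
    carbohydrate; ``raw_carb_g`` the raw material's available carbohydrate.
    """

    ethanol_g: float = 0.0
    acetic_g: float = 0.0
    residual_carb_g: float = 0.0
    raw_carb_g: float = 0.0

    def validate(self, raw_name: str = "raw material") -> None:
        for name in ("ethanol_g", "acetic_g", "residual_carb_g", "raw_carb_g"):
            v = getattr(self, name)
            if v < 0:
                raise RFComputationError(f"{name} must be >= 0, got {v}")
        if self.raw_carb_g == 0:
            raise RFComputationError(
                f"available carbohydrate of {raw_name} is zero; the "
                "fermentation RF is undefined"
            )


def rf_alcohol_fermented(
    ethanol_g: float,
    residual_carb_g: float,
    raw_carb_g: float,
    constants: ProcessConstants = DEFAULT_CONSTANTS,
    raw_name: str = "raw material",
) -> float:
    """RF of an alcohol-fermented food: (238 a/c + 100 b/c)/100."""
    FermentInput(
        ethanol_g=ethanol_g, residual_carb_g=residual_carb_g, raw_carb_g=raw_carb_g
    ).validate(raw_name)
    k = constants.ferment_constant
    return (k * ethanol_g / raw_carb_g + 100.0 * residual_carb_g / raw_carb_g) / 100.0


def rf_acetic_fermented(
    acetic_g: float,
    residual_carb_g: float,
    raw_carb_g: float,
    constants: ProcessConstants = DEFAULT_CONSTANTS,
    raw_name: str = "raw material",
) -> float:
    """RF of an acetic-acid-fermented food: (238 d/c + 100 b/c)/100.

    Uses the 1:1 acetic-acid-to-ethanol mass assumption, under which the
    acetic mass stands in for the ethanol that was metabolised to make it;
    a different assumed yield rescales the acetic term linearly via
    ``constants.acetic_per_ethanol_assumed``.
    """
    FermentInput(
        acetic_g=acetic_g, residual_carb_g=residual_carb_g, raw_carb_g=raw_carb_g
    ).validate(raw_name)
    k = constants.ferment_constant
    ethanol_equiv = acetic_g / constants.acetic_per_ethanol_assumed
    return (k * ethanol_equiv / raw_carb_g + 100.0 * residual_carb_g / raw_carb_g) / 100.0


def glucose_equiv_ethanol(ethanol_g: float) -> float:
    """Glucose (g) stoichiometrically behind ``ethanol_g`` g of ethanol.

    One mole of glucose (180 g) yields two moles of ethanol (2 × 46 g), so
    the theoretical requirement is a/46 × 1/2 × 180 = (45/23)·a grams —
    distinct from the yield-adjusted practical factor 2.38.
    """
    if ethanol_g < 0:
        raise RFComputationError(f"ethanol must be >= 0, got {ethanol_g}")
    return ethanol_g / _M_ETHANOL * 0.5 * _M_GLUCOSE


def glucose_equiv_acetate(acetic_g: float) -> float:
    """Glucose (g) stoichiometrically behind ``acetic_g`` g of acetic acid.

    Via ethanol: b/60 × 1/2 × 180 = (3/2)·b grams.
    """
    if acetic_g < 0:
        raise RFComputationError(f"acetic acid must be >= 0, got {acetic_g}")
    return acetic_g / _M_ACETIC * 0.5 * _M_GLUCOSE


def theoretical_acetic_yield() -> float:
    """Theoretical kg of acetic acid per kg of ethanol oxidised: 60/46."""
    return _M_ACETIC / _M_ETHANOL


def rf_lactic_fermented(
    product: NutrientProfile,
    ingredient_a: NutrientProfile,
    ingredient_b: NutrientProfile,
    pivot_tol: float = 1e-10,
) -> tuple[float, float]:
    """RFs of a two-ingredient lactic-fermented food.

    Solved as a square nutrient-balance system on available carbohydrate
    and calcium, both assumed conserved through lactic fermentation.
    Raises :class:`MissingMarkerError` when either marker is absent for the
    product or an ingredient — the insufficient-information failure mode.
    """
    from .rf_mixed import LinearSystem, gauss_jordan_solve  # avoid import cycle

    markers = ("avail_carb_g", "calcium_mg")
    for label, prof in (
        ("product", product),
        ("ingredient 1", ingredient_a),
        ("ingredient 2", ingredient_b),
    ):
        if not prof.has(*markers):
            missing = [m for m in markers if prof.get(m) is None]
            raise MissingMarkerError(
                f"{label} is missing marker value(s): {', '.join(missing)}"
            )
    system = LinearSystem.from_profiles(
        [ingredient_a, ingredient_b], product, markers
    )
    result = gauss_jordan_solve(system, pivot_tol=pivot_tol)
    if result.singular:
        raise RFComputationError(
            "ingredient profiles are collinear on (carbohydrate, calcium); "
            "the lactic system is singular"
        )
    w1, w2 = result.solution
    return (w1 / 100.0, w2 / 100.0)
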