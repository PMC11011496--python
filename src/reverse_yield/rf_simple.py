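"""Closed-form reverse-yield factors for dried, salted and pickled foods.

All equations are per-100 g mass balances.  For a dried food with product
water content ``b`` (%) made from a raw primary commodity (RPC) of water
content ``a`` (%), the dry matter is conserved, so the RPC mass needed per
100 g of product is ``100 (100 - b)/(100 - a)`` and

    RF_dried = (100 - b) / (100 - a).

Salting adds ``s`` grams of (assumed anhydrous) salt per 100 g of product,
so the non-water, non-salt mass balance gives

    RF_salted = (100 - s - b) / (100 - a),

which can be below 1 when the food gains water during brining.

Pickles add a processing medium (salty rice-bran paste, vinegar, soy sauce
or miso) and optionally sugar.  The vegetable RF uses the salted-food water
balance; the medium RF is read off a marker nutrient assumed to come only
from the medium (thiamine for rice bran, acetate for vinegar, protein for
soy sauce/miso); the sugar RF is a sucrose balance: product sucrose minus
the sucrose contributed by the vegetable (and soy sauce), divided by the
sucrose content of refined sugar (99.3 g/100 g).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

from .recipe_model import DEFAULT_CONSTANTS, ProcessConstants

__all__ = [
    "RFComputationError",
    "InfeasibleError",
    "WaterBalance",
    "PickleRF",
    "rf_dried",
    "rf_salted",
    "rf_pickle_rice_bran",
    "rf_pickle_vinegar",
    "rf_pickle_soy_miso",
]

logger = logging.getLogger(__name__)

# Negative implied-sugar values within this magnitude clamp to zero;
# anything larger is a recipe misconfiguration and raises.
NEGATIVE_CLAMP_TOL = 1e-9


class RFComputationError(ValueError):
    """An RF equation's preconditions are violated."""


class InfeasibleError(RFComputationError):
    """Inputs imply a physically impossible mass balance."""


@dataclass(frozen=True)
class WaterBalance:
    """Water/salt bookkeeping for one drying or salting step.

    ``w_g`` is the grams of water removed (negative when water is taken up)
    per 100 g of product; ``a_pct``/``b_pct`` the RPC and product water
    percentages; ``s_g`` the added salt grams per 100 g product (0 for
    dried foods).
    """

    a_pct: float
    b_pct: float
    s_g: float = 0.0

    @property
    def w_g(self) -> float:
        # From a/100 = (b + w)/(100 + w - s): w = (100 a - s a - 100 b)/(100 - a)
        return (100.0 * self.a_pct - self.s_g * self.a_pct - 100.0 * self.b_pct) / (
            100.0 - self.a_pct
        )

    @property
    def rf(self) -> float:
        return (100.0 + self.w_g - self.s_g) / 100.0


@dataclass(frozen=True)
class PickleRF:
    """Component RFs of a pickled food: vegetable, medium, optional sugar.

    Each value is dimensionless — grams of the ingredient per gram of
    product.  ``rf_sugar`` is ``None`` for rice-bran pickles, whose
    equations carry no sugar term.
    """

    rf_vegetable: float
    rf_medium: float
    rf_sugar: float | None = None
    medium: str = ""


def _check_water(a_pct: float, b_pct: float) -> None:
    if not (0.0 <= a_pct < 100.0):
        raise RFComputationError(
            f"RPC water content a must be in [0, 100), got {a_pct}"
            + (" (undefined ratio: no dry matter)" if a_pct >= 100 else "")
        )
    if not (0.0 <= b_pct < 100.0):
        raise RFComputationError(
            f"product water content b must be in [0, 100), got {b_pct}"
        )


def rf_dried(a_pct: float, b_pct: float) -> float:
    """RF of a dried food: (100 - b)/(100 - a).

    ``a_pct`` is the RPC water content (%), ``b_pct`` the dried product's.
    Drying can only remove water, so ``b_pct <= a_pct`` and RF >= 1.
    """
    _check_water(a_pct, b_pct)
    if b_pct > a_pct:
        raise RFComputationError(
            f"drying cannot add water: product water {b_pct}% exceeds "
            f"RPC water {a_pct}%"
        )
    return (100.0 - b_pct) / (100.0 - a_pct)


def rf_salted(a_pct: float, b_pct: float, s_g: float) -> float:
    """RF of a salted food: (100 - s - b)/(100 - a).

    ``s_g`` is the added salt (NaCl-equivalent grams per 100 g product),
    assumed anhydrous.  RF < 1 is legitimate (water uptake during brining).
    """
    _check_water(a_pct, b_pct)
    if not (0.0 <= s_g < 100.0):
        raise RFComputationError(f"added salt s must be in [0, 100), got {s_g}")
    numerator = 100.0 - s_g - b_pct
    if numerator < 0.0:
        raise InfeasibleError(
            f"salt ({s_g} g) plus water ({b_pct} g) exceed 100 g of product"
        )
    return numerator / (100.0 - a_pct)


def _sugar_balance(implied: float, sucrose_sugar: float, context: str) -> float:
    """Sucrose mass balance -> sugar RF, clamping tiny negatives."""
    if implied < -NEGATIVE_CLAMP_TOL:
        raise InfeasibleError(
            f"{context}: implied sugar sucrose is negative ({implied:.3g} g); "
            "other ingredients contribute more sucrose than the product holds"
        )
    if implied < 0.0:
        logger.debug("%s: clamping implied sugar %.3g to 0", context, implied)
        implied = 0.0
    return implied / sucrose_sugar


def rf_pickle_rice_bran(
    a_pct: float,
    b_pct: float,
    s_g: float,
    c_thiamine: float,
    constants: ProcessConstants = DEFAULT_CONSTANTS,
) -> PickleRF:
    """Component RFs for vegetables pickled in salty rice-bran paste.

    Thiamine in raw vegetables is negligible while rice-bran paste is rich
    in it (3.12 mg/100 g), so the product's thiamine ``c_thiamine``
    (mg/100 g) fixes the paste RF directly.
    """
    if c_thiamine < 0:
        raise RFComputationError(f"thiamine must be >= 0, got {c_thiamine}")
    return PickleRF(
        rf_vegetable=rf_salted(a_pct, b_pct, s_g),
        rf_medium=c_thiamine / constants.thiamine_rice_bran,
        rf_sugar=None,
        medium="rice-bran-paste",
    )


def rf_pickle_vinegar(
    a_pct: float,
    b_pct: float,
    s_g: float,
    d_acetate: float,
    e_sucrose_product: float,
    f_sucrose_veg: float,
    constants: ProcessConstants = DEFAULT_CONSTANTS,
) -> PickleRF:
    """Component RFs for vegetables pickled in vinegar (plus sugar).

    The product's acetate ``d_acetate`` (g/100 g) is assumed to come only
    from vinegar (4.2 g acetate/100 g), and its sucrose only from added
    sugar and the vegetable itself.
    """
    for name, v in (("acetate", d_acetate), ("product sucrose", e_sucrose_product),
                    ("vegetable sucrose", f_sucrose_veg)):
        if v < 0:
            raise RFComputationError(f"{name} must be >= 0, got {v}")
    rf_veg = rf_salted(a_pct, b_pct, s_g)
    implied_sugar = e_sucrose_product - rf_veg * f_sucrose_veg
    return PickleRF(
        rf_vegetable=rf_veg,
        rf_medium=d_acetate / constants.acetate_vinegar,
        rf_sugar=_sugar_balance(implied_sugar, constants.sucrose_sugar, "vinegar pickle"),
        medium="vinegar",
    )


def rf_pickle_soy_miso(
    a_pct: float,
    b_pct: float,
    s_g: float,
    protein_product: float,
    i_sucrose_product: float,
    j_sucrose_veg: float,
    medium: Literal["soy", "miso"],
    constants: ProcessConstants = DEFAULT_CONSTANTS,
) -> PickleRF:
    """Component RFs for vegetables pickled in soy sauce or miso.

    The protein of the product (assumed to come from the medium alone)
    fixes the medium RF: soy sauce holds 7.7 g protein/100 g, miso 12.5.
    The sugar RF subtracts both the vegetable's and the medium's sucrose
    contribution (soy sauce: 0.1 g/100 g; miso: none).
    """
    for name, v in (("protein", protein_product), ("product sucrose", i_sucrose_product),
                    ("vegetable sucrose", j_sucrose_veg)):
        if v < 0:
            raise RFComputationError(f"{name} must be >= 0, got {v}")
    if medium == "soy":
        protein_medium = constants.protein_soy_sauce
        sucrose_medium = constants.sucrose_soy_sauce
    elif medium == "miso":
        protein_medium = constants.protein_miso
        sucrose_medium = constants.sucrose_miso
    else:
        raise RFComputationError(f"medium must be 'soy' or 'miso', got {medium!r}")
    rf_veg = rf_salted(a_pct, b_pct, s_g)
    rf_medium = protein_product / protein_medium
    implied_sugar = (
        i_sucrose_product - rf_veg * j_sucrose_veg - rf_medium * sucrose_medium
    )
    return PickleRF(
        rf_vegetable=rf_veg,
        rf_medium=rf_medium,
        rf_sugar=_sugar_balance(
            implied_sugar, constants.sucrose_sugar, f"{medium} pickle"
        ),
        medium="soy-sauce" if medium == "soy" else "miso",
    )
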