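"""Nutrient-balance linear systems for mixed foods, solved by Gauss–Jordan.

A mixed composite made from k ingredients C_1..C_k is modelled through k
marker nutrients assumed to survive processing unchanged.  With W_i the
grams of C_i per 100 g of composite, R_ij the content of marker j per
100 g of C_i, and P_j the composite's content of marker j per 100 g, mass
balance on each marker gives the square system

    sum_i (R_ij / 100) * W_i = P_j        (j = 1..k)

and the reverse-yield factor of each ingredient is RF_i = W_i / 100.

The elimination is written out explicitly (reduced row echelon with partial
pivoting) rather than delegated to a library solver: the solve itself is
the auditable core of the method, and a singular pivot must be reported as
a structured "markers cannot separate these ingredients" diagnosis, not a
generic numerical error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .composition_io import CompositionTable, NutrientProfile
from .recipe_model import (
    Category,
    FailureReason,
    RecipeSpec,
    effective_markers,
    usable_markers,
)
from .rf_simple import NEGATIVE_CLAMP_TOL, RFComputationError

__all__ = [
    "LinearSystem",
    "GaussJordanResult",
    "SingularSystemError",
    "MixedFoodError",
    "build_nutrient_system",
    "gauss_jordan_solve",
    "solve_mixed_rf",
    "DEFAULT_PIVOT_TOL",
    "RESIDUAL_TOL",
]

DEFAULT_PIVOT_TOL = 1e-10
RESIDUAL_TOL = 1e-8

# Exhaustive marker-subset search is limited to small systems; beyond this
# the first k usable markers are taken in listed order.
_EXHAUSTIVE_K_MAX = 6


class MixedFoodError(RFComputationError):
    """A mixed-food system cannot be built or solved."""

    def __init__(self, message: str, reason: FailureReason | None = None):
        super().__init__(message)
        self.reason = reason


class SingularSystemError(MixedFoodError):
    """The marker matrix is singular: markers cannot separate ingredients."""

    def __init__(self, message: str, dependent_columns: list[str]):
        super().__init__(message, reason=FailureReason.TOO_MANY_INGREDIENTS)
        self.dependent_columns = dependent_columns


@dataclass(frozen=True)
class LinearSystem:
    """The square marker-balance system of one mixed food.

    ``matrix`` has one row per marker and one column per ingredient:
    ``matrix[j, i]`` is marker j's content per 100 g of ingredient i.
    ``target`` is the composite's marker vector P (per 100 g).  The model
    solved is ``(matrix / 100) @ W = target`` with W in grams per 100 g of
    composite.
    """

    matrix: np.ndarray
    target: np.ndarray
    markers: tuple[str, ...]
    ingredient_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        p = np.asarray(self.target, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "target", p)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise MixedFoodError(
                f"marker matrix must be square, got shape {m.shape}"
            )
        if p.shape != (m.shape[0],):
            raise MixedFoodError(
                f"target length {p.shape} does not match matrix {m.shape}"
            )
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(p))):
            raise MixedFoodError("marker matrix and target must be finite")

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_profiles(
        cls,
        ingredient_profiles: list[NutrientProfile],
        composite_profile: NutrientProfile,
        markers: tuple[str, ...] | list[str],
        ingredient_ids: tuple[str, ...] | None = None,
    ) -> "LinearSystem":
        markers = tuple(markers)
        k = len(ingredient_profiles)
        if len(markers) != k:
            raise MixedFoodError(
                f"need exactly {k} markers for {k} ingredients, got {len(markers)}"
            )
        matrix = np.empty((k, k))
        target = np.empty(k)
        for j, m in enumerate(markers):
            p = composite_profile.get(m)
            if p is None:
                raise MixedFoodError(
                    f"composite is missing marker {m!r}",
                    reason=FailureReason.INGREDIENTS_UNKNOWN,
                )
            target[j] = p
            for i, prof in enumerate(ingredient_profiles):
                v = prof.get(m)
                if v is None:
                    raise MixedFoodError(
                        f"ingredient {i} is missing marker {m!r}",
                        reason=FailureReason.INGREDIENTS_UNKNOWN,
                    )
                matrix[j, i] = v
        return cls(
            matrix=matrix,
            target=target,
            markers=markers,
            ingredient_ids=ingredient_ids or tuple(str(i) for i in range(k)),
        )

    def residual(self, solution: np.ndarray) -> float:
        """Max-norm residual of ``(matrix/100) @ W - P``."""
        r = (self.matrix / 100.0) @ np.asarray(solution, dtype=float) - self.target
        return float(np.max(np.abs(r))) if r.size else 0.0


@dataclass(frozen=True)
class GaussJordanResult:
    """Outcome of one elimination: a solution or a singularity report."""

    solution: np.ndarray | None
    residual_norm: float
    singular: bool = False
    dependent_columns: tuple[str, ...] = ()


def _select_markers(
    spec: RecipeSpec, table: CompositionTable, candidates: tuple[str, ...]
) -> tuple[str, ...]:
    """Prune surplus candidate markers down to a square system.

    The subset minimising the condition number of the marker matrix is
    chosen by exhaustive search for small systems (k <= 6); larger systems
    take the first k usable markers in listed order.  The system is always
    square — surplus markers are pruned, never least-squares-fitted.
    """
    k = len(spec.ingredients)
    if len(candidates) == k:
        return candidates
    if k > _EXHAUSTIVE_K_MAX:
        return candidates[:k]
    profiles = [table[i].profile for i in spec.ingredients]
    best: tuple[float, tuple[str, ...]] | None = None
    for subset in itertools.combinations(candidates, k):
        m = np.array(
            [[profiles[i].get(mk) for i in range(k)] for mk in subset], dtype=float
        )
        cond = float(np.linalg.cond(m))
        if best is None or cond < best[0]:
            best = (cond, subset)
    assert best is not None
    return best[1]


def build_nutrient_system(
    spec: RecipeSpec, table: CompositionTable
) -> LinearSystem:
    """Assemble the square marker-balance system for one mixed food.

    Rows follow the (selected) marker order, columns the ingredient order
    of the recipe.  Requires a computable spec; missing marker values raise
    a :class:`MixedFoodError` tagged insufficient-information.
    """
    k = len(spec.ingredients)
    if k == 0:
        raise MixedFoodError(
            f"recipe {spec.composite_id} has no ingredients",
            reason=FailureReason.INGREDIENTS_UNKNOWN,
        )
    if spec.composite_id not in table:
        raise MixedFoodError(
            f"composite {spec.composite_id} is not in the table",
            reason=FailureReason.INGREDIENTS_UNKNOWN,
        )
    for i in spec.ingredients:
        if i not in table:
            raise MixedFoodError(
                f"ingredient {i} of {spec.composite_id} is not in the table",
                reason=FailureReason.INGREDIENTS_UNKNOWN,
            )
    usable = usable_markers(spec, table)
    if len(usable) < k:
        if len(effective_markers(spec)) == k:
            raise MixedFoodError(
                f"recipe {spec.composite_id}: required marker values are missing",
                reason=FailureReason.INGREDIENTS_UNKNOWN,
            )
        raise MixedFoodError(
            f"recipe {spec.composite_id}: {k} ingredients but only "
            f"{len(usable)} usable markers",
            reason=FailureReason.TOO_MANY_INGREDIENTS,
        )
    markers = _select_markers(spec, table, usable)
    return LinearSystem.from_profiles(
        [table[i].profile for i in spec.ingredients],
        table[spec.composite_id].profile,
        markers,
        ingredient_ids=spec.ingredients,
    )


def gauss_jordan_solve(
    system: LinearSystem, pivot_tol: float = DEFAULT_PIVOT_TOL
) -> GaussJordanResult:
    """Solve the marker system by Gauss–Jordan elimination.

    Reduces the augmented matrix ``[matrix/100 | P]`` to reduced row
    echelon form with partial (row) pivoting.  A pivot magnitude below
    ``pivot_tol`` marks its column dependent; any dependent column yields a
    singularity report naming the ingredients that cannot be separated.
    """
    n = system.k
    aug = np.hstack(
        [system.matrix / 100.0, system.target.reshape(-1, 1)]
    ).astype(float)
    pivot_row_of_col: list[int | None] = [None] * n
    row = 0
    for col in range(n):
        if row >= n:
            pivot = 0.0
        else:
            p = row + int(np.argmax(np.abs(aug[row:, col])))
            pivot = abs(aug[p, col])
        if pivot < pivot_tol:
            continue  # dependent column
        if p != row:
            aug[[row, p]] = aug[[p, row]]
        aug[row] /= aug[row, col]
        for r in range(n):
            if r != row and aug[r, col] != 0.0:
                aug[r] -= aug[r, col] * aug[row]
        pivot_row_of_col[col] = row
        row += 1

    dependent = [
        system.ingredient_ids[c] for c in range(n) if pivot_row_of_col[c] is None
    ]
    if dependent:
        return GaussJordanResult(
            solution=None,
            residual_norm=float("inf"),
            singular=True,
            dependent_columns=tuple(dependent),
        )
    solution = np.array(
        [aug[pivot_row_of_col[c], n] for c in range(n)], dtype=float
    )
    return GaussJordanResult(
        solution=solution, residual_norm=system.residual(solution)
    )


def solve_mixed_rf(
    spec: RecipeSpec,
    table: CompositionTable,
    pivot_tol: float = DEFAULT_PIVOT_TOL,
) -> list:
    """RF entries for a mixed food: RF_i = W_i / 100.

    Known-ratio recipes bypass the solver (RF_i = ratio_i/100).  A singular
    system raises :class:`SingularSystemError` (too-many-ingredients
    failure).  Negative solution components beyond -1e-9 mark the whole
    entry set infeasible — a recipe misspecification signal, never silently
    clamped; components within [-1e-9, 0) clamp to 0.
    """
    from .disaggregation import RFEntry  # avoid import cycle

    if spec.known_ratios is not None:
        return [
            RFEntry(
                composite_id=spec.composite_id,
                ingredient_id=ing,
                rf=ratio / 100.0,
                tier=1,
                method="known-ratio",
                status="ok",
            )
            for ing, ratio in zip(spec.ingredients, spec.known_ratios)
        ]

    system = build_nutrient_system(spec, table)
    result = gauss_jordan_solve(system, pivot_tol=pivot_tol)
    if result.singular:
        raise SingularSystemError(
            f"recipe {spec.composite_id}: markers {system.markers} cannot "
            f"separate ingredients {result.dependent_columns}",
            dependent_columns=list(result.dependent_columns),
        )
    assert result.solution is not None
    if result.residual_norm > RESIDUAL_TOL:
        raise MixedFoodError(
            f"recipe {spec.composite_id}: residual {result.residual_norm:.3g} "
            f"exceeds {RESIDUAL_TOL}"
        )
    w = result.solution.copy()
    infeasible = bool(np.any(w < -NEGATIVE_CLAMP_TOL))
    w[(w < 0) & (w >= -NEGATIVE_CLAMP_TOL)] = 0.0
    status = "infeasible" if infeasible else "ok"
    method = "mixed/gauss-jordan"
    return [
        RFEntry(
            composite_id=spec.composite_id,
            ingredient_id=ing,
            rf=float(wi) / 100.0,
            tier=1,
            method=method,
            status=status,
        )
        for ing, wi in zip(spec.ingredients, w)
    ]
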