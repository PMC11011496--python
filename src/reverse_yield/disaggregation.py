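"""Chaining per-step reverse-yield factors down to raw primary commodities.

One RF edge relates a composite food to one direct ingredient.  Because an
ingredient may itself be composite (soy sauce inside a pickle, sake behind
rice vinegar), overall RFs are products of per-step RFs along the chain:
disaggregating 100 g of a food into RPC masses multiplies edge RFs from the
root down to each RPC leaf.  A tier is one disaggregation step; tier 1 is
the first step of a composite, and a food's tier count is the number of
steps needed to reach RPCs on its deepest branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .composition_io import CompositionTable, UnknownFoodError
from .recipe_model import (
    Category,
    DEFAULT_CONSTANTS,
    FailureReason,
    ProcessConstants,
    RecipeSpec,
    classify_failure,
)
from .rf_fermented import rf_acetic_fermented, rf_alcohol_fermented, rf_lactic_fermented
from .rf_mixed import DEFAULT_PIVOT_TOL, SingularSystemError, solve_mixed_rf
from .rf_simple import (
    InfeasibleError,
    rf_dried,
    rf_pickle_rice_bran,
    rf_pickle_soy_miso,
    rf_pickle_vinegar,
    rf_salted,
)

__all__ = [
    "RFEntry",
    "DisaggregationNode",
    "CyclicRecipeError",
    "compute_all_rfs",
    "disaggregate",
    "rpc_summary",
    "tier_statistics",
    "DEFAULT_MAX_DEPTH",
]

#: Deepest chain expanded by default; six tiers covers observed recipes.
DEFAULT_MAX_DEPTH = 6


class CyclicRecipeError(ValueError):
    """The ingredient graph contains a cycle."""


@dataclass(frozen=True)
class RFEntry:
    """One (composite, ingredient) edge of the RF database.

    ``rf`` is dimensionless: grams of the ingredient per gram of the
    composite.  ``tier`` is the composite's tier count (steps on its
    deepest branch down to RPCs).  ``status`` is ``ok``, ``infeasible``
    (negative solver weight — recipe misspecification) or
    ``failed(<reason>)``.
    """

    composite_id: str
    ingredient_id: str
    rf: float | None
    tier: int
    method: str
    status: str

    def __post_init__(self) -> None:
        if self.status == "ok" and (self.rf is None or self.rf < 0):
            raise ValueError(
                f"ok entry {self.composite_id}->{self.ingredient_id} must "
                f"have rf >= 0, got {self.rf}"
            )
        if self.tier < 1:
            raise ValueError(f"tier must be >= 1, got {self.tier}")

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class DisaggregationNode:
    """A node of the disaggregation tree rooted at one food.

    ``cumulative_rf`` multiplies the edge RFs from the root (root = 1);
    100 × cumulative_rf is the grams of this food behind 100 g of the
    root.  Leaves are RPCs, failed edges, or truncation points.
    """

    food_id: str
    cumulative_rf: float
    depth: int
    children: list["DisaggregationNode"] = field(default_factory=list)
    is_rpc_leaf: bool = False
    truncated: bool = False
    status: str = "ok"

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["DisaggregationNode"]:
        if self.is_leaf:
            return [self]
        out: list[DisaggregationNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def completeness(self) -> float:
        """Fraction of leaves that terminate at an RPC."""
        lv = self.leaves()
        return sum(1 for n in lv if n.is_rpc_leaf) / len(lv)

    def to_dict(self) -> dict:
        """Nested plain-data export (YAML/JSON friendly)."""
        d: dict = {
            "food_id": self.food_id,
            "cumulative_rf": self.cumulative_rf,
            "depth": self.depth,
            "status": self.status,
        }
        if self.is_rpc_leaf:
            d["is_rpc_leaf"] = True
        if self.truncated:
            d["truncated"] = True
        if self.children:
            d["children"] = [c.to_dict() for c in self.children]
        return d


# ---------------------------------------------------------------------------
# Computing all edges

_COARSE_CLASS = {
    "dried": "dried",
    "salted": "salted",
    "pickle-rice-bran": "salted",
    "pickle-vinegar": "salted",
    "pickle-soy": "salted",
    "pickle-miso": "salted",
    "fermented-alcohol": "fermented",
    "fermented-acetic": "fermented",
    "fermented-lactic": "fermented",
    "mixed/gauss-jordan": "mixed",
    "known-ratio": "mixed",
}


def _check_acyclic(recipes: list[RecipeSpec]) -> None:
    g = nx.DiGraph()
    for spec in recipes:
        if spec.category in (Category.UNCOOKED, Category.COOKED):
            continue
        for ing in spec.ingredients:
            if ing:
                g.add_edge(spec.composite_id, ing)
    try:
        cycle = nx.find_cycle(g, orientation="original")
    except nx.NetworkXNoCycle:
        return
    path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
    raise CyclicRecipeError(f"cyclic ingredient references: {path}")


def _profile(table: CompositionTable, food_id: str):
    return table[food_id].profile


def _edges_for(
    spec: RecipeSpec,
    table: CompositionTable,
    constants: ProcessConstants,
    pivot_tol: float,
) -> list[RFEntry]:
    """Dispatch one computable recipe to the matching RF engine.

    Tier is filled with a placeholder 1 and rewritten once the whole edge
    set is known.
    """
    comp = _profile(table, spec.composite_id)
    cat = spec.category

    def entry(ing: str, rf: float | None, method: str, status: str = "ok") -> RFEntry:
        return RFEntry(
            composite_id=spec.composite_id,
            ingredient_id=ing,
            rf=rf,
            tier=1,
            method=method,
            status=status,
        )

    if cat is Category.DRIED:
        raw = _profile(table, spec.ingredients[0])
        rf = rf_dried(raw.water_pct, comp.water_pct)
        return [entry(spec.ingredients[0], rf, "dried")]

    if cat is Category.SALTED:
        raw = _profile(table, spec.ingredients[0])
        s = comp.salt_eq_g
        rf = rf_salted(raw.water_pct, comp.water_pct, s)
        out = [entry(spec.ingredients[0], rf, "salted")]
        if len(spec.ingredients) > 1:  # added salt as an explicit edge
            out.append(entry(spec.ingredients[1], s / 100.0, "salted"))
        return out

    if cat is Category.PICKLE_RICE_BRAN:
        veg = _profile(table, spec.ingredients[0])
        res = rf_pickle_rice_bran(
            veg.water_pct, comp.water_pct, comp.salt_eq_g, comp.thiamine_mg, constants
        )
        out = [entry(spec.ingredients[0], res.rf_vegetable, "pickle-rice-bran")]
        if len(spec.ingredients) > 1:
            out.append(entry(spec.ingredients[1], res.rf_medium, "pickle-rice-bran"))
        return out

    if cat is Category.PICKLE_VINEGAR:
        veg = _profile(table, spec.ingredients[0])
        res = rf_pickle_vinegar(
            veg.water_pct,
            comp.water_pct,
            comp.salt_eq_g,
            comp.acetic_acid_g,
            comp.sucrose_g,
            veg.sucrose_g,
            constants,
        )
        out = [entry(spec.ingredients[0], res.rf_vegetable, "pickle-vinegar")]
        if len(spec.ingredients) > 1:
            out.append(entry(spec.ingredients[1], res.rf_medium, "pickle-vinegar"))
        if len(spec.ingredients) > 2 and res.rf_sugar is not None:
            out.append(entry(spec.ingredients[2], res.rf_sugar, "pickle-vinegar"))
        return out

    if cat in (Category.PICKLE_SOY, Category.PICKLE_MISO):
        veg = _profile(table, spec.ingredients[0])
        medium = "soy" if cat is Category.PICKLE_SOY else "miso"
        res = rf_pickle_soy_miso(
            veg.water_pct,
            comp.water_pct,
            comp.salt_eq_g,
            comp.protein_g,
            comp.sucrose_g,
            veg.sucrose_g,
            medium,
            constants,
        )
        tag = f"pickle-{medium}"
        out = [entry(spec.ingredients[0], res.rf_vegetable, tag)]
        if len(spec.ingredients) > 1:
            out.append(entry(spec.ingredients[1], res.rf_medium, tag))
        if len(spec.ingredients) > 2 and res.rf_sugar is not None:
            out.append(entry(spec.ingredients[2], res.rf_sugar, tag))
        return out

    if cat is Category.FERMENTED_ALCOHOL:
        raw = _profile(table, spec.ingredients[0])
        rf = rf_alcohol_fermented(
            comp.ethanol_g, comp.avail_carb_g, raw.avail_carb_g, constants,
            raw_name=spec.ingredients[0],
        )
        return [entry(spec.ingredients[0], rf, "fermented-alcohol")]

    if cat is Category.FERMENTED_ACETIC:
        raw = _profile(table, spec.ingredients[0])
        rf = rf_acetic_fermented(
            comp.acetic_acid_g, comp.avail_carb_g, raw.avail_carb_g, constants,
            raw_name=spec.ingredients[0],
        )
        return [entry(spec.ingredients[0], rf, "fermented-acetic")]

    if cat is Category.FERMENTED_LACTIC:
        a, b = spec.ingredients[0], spec.ingredients[1]
        rf_a, rf_b = rf_lactic_fermented(
            comp, _profile(table, a), _profile(table, b), pivot_tol=pivot_tol
        )
        return [
            entry(a, rf_a, "fermented-lactic"),
            entry(b, rf_b, "fermented-lactic"),
        ]

    if cat in (Category.MIXED, Category.MIXED_KNOWN_RATIO):
        return solve_mixed_rf(spec, table, pivot_tol=pivot_tol)

    raise AssertionError(f"unhandled category {cat}")  # pragma: no cover


def _assign_tiers(
    entries: list[RFEntry], recipes: list[RecipeSpec]
) -> list[RFEntry]:
    """Rewrite each edge's tier as its composite's deepest chain length."""
    children: dict[str, list[str]] = {}
    for spec in recipes:
        if spec.category in (Category.UNCOOKED, Category.COOKED):
            continue
        children[spec.composite_id] = [i for i in spec.ingredients if i]

    memo: dict[str, int] = {}

    def tier_of(food: str) -> int:
        if food in memo:
            return memo[food]
        memo[food] = 1  # placeholder guards against unexpected recursion
        subs = [tier_of(i) for i in children.get(food, []) if i in children]
        memo[food] = 1 + (max(subs) if subs else 0)
        return memo[food]

    out = []
    for e in entries:
        t = tier_of(e.composite_id)
        out.append(
            RFEntry(e.composite_id, e.ingredient_id, e.rf, t, e.method, e.status)
        )
    return out


def compute_all_rfs(
    table: CompositionTable,
    recipes: list[RecipeSpec],
    constants: ProcessConstants = DEFAULT_CONSTANTS,
    pivot_tol: float = DEFAULT_PIVOT_TOL,
) -> list[RFEntry]:
    """Compute every (composite, ingredient) RF edge of a corpus.

    Recipes are dispatched by category to the matching engine.
    Non-computable recipes yield ``failed(<reason>)`` entries; infeasible
    mass balances yield ``infeasible`` entries; neither disturbs other
    recipes.  Output order is deterministic: by composite id, then by the
    recipe's ingredient order.  Cyclic ingredient references raise
    :class:`CyclicRecipeError` naming the cycle.
    """
    _check_acyclic(recipes)
    entries: list[RFEntry] = []
    for spec in sorted(recipes, key=lambda s: s.composite_id):
        if spec.category in (Category.UNCOOKED, Category.COOKED):
            continue
        reason = classify_failure(spec, table)
        if reason is not None:
            targets = [i for i in spec.ingredients if i] or ["(unknown)"]
            entries.extend(
                RFEntry(
                    composite_id=spec.composite_id,
                    ingredient_id=ing,
                    rf=None,
                    tier=1,
                    method=spec.category.value,
                    status=f"failed({reason.value})",
                )
                for ing in targets
            )
            continue
        try:
            entries.extend(_edges_for(spec, table, constants, pivot_tol))
        except SingularSystemError as exc:
            entries.extend(
                RFEntry(
                    composite_id=spec.composite_id,
                    ingredient_id=ing,
                    rf=None,
                    tier=1,
                    method=spec.category.value,
                    status=f"failed({FailureReason.TOO_MANY_INGREDIENTS.value})",
                )
                for ing in spec.ingredients
            )
        except InfeasibleError:
            entries.extend(
                RFEntry(
                    composite_id=spec.composite_id,
                    ingredient_id=ing,
                    rf=None,
                    tier=1,
                    method=spec.category.value,
                    status="infeasible",
                )
                for ing in spec.ingredients
            )
    return _assign_tiers(entries, recipes)


# ---------------------------------------------------------------------------
# Tree expansion

def disaggregate(
    food_id: str,
    entries: list[RFEntry],
    max_depth: int = DEFAULT_MAX_DEPTH,
    table: CompositionTable | None = None,
) -> DisaggregationNode:
    """Expand a food into its disaggregation tree, multiplying RFs.

    Expansion stops at foods with no edges (RPC leaves), at failed or
    infeasible edges (the branch is marked, the rest of the tree remains
    usable) and at ``max_depth`` (nodes flagged truncated).  A food with no
    edges at all — an RPC — returns a single leaf with cumulative RF 1.
    """
    if max_depth < 1:
        raise ValueError(f"max_depth must be >= 1, got {max_depth}")
    by_composite: dict[str, list[RFEntry]] = {}
    known: set[str] = set()
    for e in entries:
        by_composite.setdefault(e.composite_id, []).append(e)
        known.add(e.composite_id)
        known.add(e.ingredient_id)
    if food_id not in known and (table is None or food_id not in table):
        raise UnknownFoodError(f"no food with id {food_id!r} in the RF entries")

    def expand(fid: str, cum: float, depth: int) -> DisaggregationNode:
        edges = by_composite.get(fid)
        if not edges:
            return DisaggregationNode(
                food_id=fid, cumulative_rf=cum, depth=depth, is_rpc_leaf=True
            )
        if depth >= max_depth:
            return DisaggregationNode(
                food_id=fid, cumulative_rf=cum, depth=depth, truncated=True,
                status="truncated",
            )
        node = DisaggregationNode(food_id=fid, cumulative_rf=cum, depth=depth)
        for e in edges:
            if not e.ok:
                node.children.append(
                    DisaggregationNode(
                        food_id=e.ingredient_id,
                        cumulative_rf=float("nan"),
                        depth=depth + 1,
                        status=e.status,
                    )
                )
            else:
                node.children.append(expand(e.ingredient_id, cum * e.rf, depth + 1))
        return node

    return expand(food_id, 1.0, 0)


def rpc_summary(root: DisaggregationNode) -> pd.DataFrame:
    """Flatten a tree to total RPC masses behind 100 g of the root.

    The same RPC reached through several paths is summed (exposure
    assessment needs the total mass).  Columns: ``food_id`` (root),
    ``rpc_id``, ``cumulative_rf``, ``complete`` ("yes" when no branch of
    the whole tree failed or was truncated).
    """
    totals: dict[str, float] = {}
    for leaf in root.leaves():
        if leaf.is_rpc_leaf:
            totals[leaf.food_id] = totals.get(leaf.food_id, 0.0) + leaf.cumulative_rf
    complete = "yes" if root.completeness() == 1.0 else "no"
    rows = [
        {
            "food_id": root.food_id,
            "rpc_id": rpc,
            "cumulative_rf": rf,
            "complete": complete,
        }
        for rpc, rf in sorted(totals.items())
    ]
    return pd.DataFrame(rows, columns=["food_id", "rpc_id", "cumulative_rf", "complete"])


def tier_statistics(entries: list[RFEntry]) -> pd.DataFrame:
    """Counts and percentages of composites by class × tier × status.

    One row per (class, tier, status) with the number of composite foods
    and the percentage within the class; percentages sum to 100 within
    each class up to rounding.  Classes are the coarse processing types
    (dried, salted incl. pickles, fermented, mixed); failed composites
    keep their category string as the class.
    """
    per_comp: dict[str, dict] = {}
    for e in entries:
        rec = per_comp.setdefault(
            e.composite_id, {"tier": e.tier, "methods": set(), "statuses": set()}
        )
        rec["methods"].add(e.method)
        rec["statuses"].add(e.status)
    rows = []
    for comp, rec in per_comp.items():
        method = sorted(rec["methods"])[0]
        klass = _COARSE_CLASS.get(method, method)
        statuses = rec["statuses"]
        if any(s.startswith("failed") for s in statuses):
            status = sorted(s for s in statuses if s.startswith("failed"))[0]
        elif "infeasible" in statuses:
            status = "infeasible"
        else:
            status = "ok"
        rows.append(
            {"composite_id": comp, "class": klass, "tier": rec["tier"], "status": status}
        )
    if not rows:
        return pd.DataFrame(columns=["class", "tier", "status", "count", "pct"])
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["class", "tier", "status"], as_index=False)
        .agg(count=("composite_id", "size"))
        .sort_values(["class", "tier", "status"])
        .reset_index(drop=True)
    )
    totals = counts.groupby("class")["count"].transform("sum")
    counts["pct"] = 100.0 * counts["count"] / totals
    return counts
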