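"""Reading, validating and writing food-composition tables and RF exports.

A composition table holds one row per food item with per-100 g edible-portion
nutrient values.  The nutrients carried are exactly those that drive
reverse-yield-factor (RF) calculations: water, protein, available
carbohydrate, sucrose, acetic acid, ethanol, salt (NaCl equivalent),
thiamine and calcium.  Missing values are explicit (``None``) and are never
silently treated as zero: downstream RF engines turn them into
"insufficient information" failures.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "NutrientProfile",
    "FoodItem",
    "CompositionTable",
    "CompositionError",
    "ValidationError",
    "DuplicateIdError",
    "UnknownFoodError",
    "NUTRIENT_FIELDS",
    "COLUMN_SCHEMA",
    "read_composition_table",
    "write_composition_table",
    "write_rf_database",
    "read_rf_database",
]

# Mass-closure slack (g) for water + protein + carbohydrate + ethanol <= 100.
MASS_CLOSURE_TOL = 0.5

#: Nutrient columns, in schema order.  All per 100 g edible portion.
NUTRIENT_FIELDS = (
    "water_pct",
    "protein_g",
    "avail_carb_g",
    "sucrose_g",
    "acetic_acid_g",
    "ethanol_g",
    "salt_eq_g",
    "thiamine_mg",
    "calcium_mg",
)

#: Full fixed column schema of a composition table file.
COLUMN_SCHEMA = ("food_id", "name", "group", "is_rpc") + NUTRIENT_FIELDS


class CompositionError(Exception):
    """Base class for composition-table errors."""


class ValidationError(CompositionError):
    """A row or field violates the nutrient-profile invariants."""


class DuplicateIdError(CompositionError):
    """Two rows share a food id."""


class UnknownFoodError(CompositionError, KeyError):
    """Lookup of a food id that is not in the table."""


@dataclass(frozen=True)
class NutrientProfile:
    """Per-100 g nutrient vector of a food item.

    Every field is optional; ``None`` marks a value the source table does
    not report.  Units: ``water_pct`` in percent mass, ``*_g`` in g/100 g,
    ``*_mg`` in mg/100 g.  ``salt_eq_g`` is the NaCl-equivalent mass used as
    the added-salt symbol in the salted-food equations.
    """

    water_pct: float | None = None
    protein_g: float | None = None
    avail_carb_g: float | None = None
    sucrose_g: float | None = None
    acetic_acid_g: float | None = None
    ethanol_g: float | None = None
    salt_eq_g: float | None = None
    thiamine_mg: float | None = None
    calcium_mg: float | None = None

    def get(self, nutrient: str) -> float | None:
        if nutrient not in NUTRIENT_FIELDS:
            raise KeyError(f"unknown nutrient {nutrient!r}")
        return getattr(self, nutrient)

    def has(self, *nutrients: str) -> bool:
        """True when every named nutrient is present (not missing)."""
        return all(self.get(n) is not None for n in nutrients)

    def validate(self, context: str = "") -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        where = f" in {context}" if context else ""
        w = self.water_pct
        if w is not None and not (0.0 <= w <= 100.0):
            raise ValidationError(
                f"water_pct must be within [0, 100], got {w}{where}"
            )
        for name in NUTRIENT_FIELDS:
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v):
                raise ValidationError(f"{name} is not finite ({v}){where}")
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}{where}")
        bulk = (self.water_pct, self.protein_g, self.avail_carb_g, self.ethanol_g)
        if all(v is not None for v in bulk):
            total = sum(bulk)  # type: ignore[arg-type]
            if total > 100.0 + MASS_CLOSURE_TOL:
                raise ValidationError(
                    "mass closure violated: water + protein + carbohydrate + "
                    f"ethanol = {total:.2f} g > 100 g{where}"
                )


@dataclass(frozen=True)
class FoodItem:
    """One row of a composition table.

    ``food_id`` is a stable string identifier (5-digit codes in the style of
    the Japanese standard tables are typical but not required).  ``group``
    is the food-group number 1–17.  ``is_rpc`` flags raw primary
    commodities, the leaves of any disaggregation.
    """

    food_id: str
    name: str
    group: int
    profile: NutrientProfile
    is_rpc: bool = False

    def validate(self) -> None:
        if not self.food_id or not str(self.food_id).strip():
            raise ValidationError("food_id must be non-empty")
        if not (1 <= int(self.group) <= 17):
            raise ValidationError(
                f"group must be in 1..17, got {self.group} for food {self.food_id}"
            )
        self.profile.validate(context=f"food {self.food_id}")


class CompositionTable:
    """A keyed collection of :class:`FoodItem`, unique by ``food_id``."""

    def __init__(self, items: Iterable[FoodItem] = ()):
        self._items: dict[str, FoodItem] = {}
        for item in items:
            self.add(item)

    def add(self, item: FoodItem) -> None:
        item.validate()
        if item.food_id in self._items:
            raise DuplicateIdError(f"duplicate food_id {item.food_id!r}")
        self._items[item.food_id] = item

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._items

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self._items.values())

    def __getitem__(self, food_id: str) -> FoodItem:
        try:
            return self._items[food_id]
        except KeyError:
            raise UnknownFoodError(f"no food with id {food_id!r}") from None

    def get(self, food_id: str) -> FoodItem | None:
        return self._items.get(food_id)

    def ids(self) -> list[str]:
        return list(self._items)

    def to_frame(self) -> pd.DataFrame:
        """Render the table as a DataFrame in schema column order."""
        rows = []
        for it in self:
            row: dict[str, object] = {
                "food_id": it.food_id,
                "name": it.name,
                "group": it.group,
                "is_rpc": int(it.is_rpc),
            }
            for n in NUTRIENT_FIELDS:
                row[n] = it.profile.get(n)
            rows.append(row)
        return pd.DataFrame(rows, columns=list(COLUMN_SCHEMA))


def _parse_cell(raw: object, trace_as_zero: bool) -> float | None:
    """One nutrient cell -> float or explicit missing (None).

    Blank cells are missing, never zero.  ``Tr`` (trace) entries map to 0 by
    default; with ``trace_as_zero=False`` they are treated as missing.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s == "-":
        return None
    if s.lower() in ("tr", "trace", "(tr)"):
        return 0.0 if trace_as_zero else None
    return float(s)


def read_composition_table(
    path: str | Path | io.TextIOBase,
    *,
    trace_as_zero: bool = True,
) -> CompositionTable:
    """Read a delimited-text composition table.

    The delimiter (comma or tab) is auto-detected from the header line.
    Extra columns are ignored; blank nutrient cells become explicit missing
    values.  Raises :class:`ValidationError` naming the row number and field
    on any malformed row and :class:`DuplicateIdError` on repeated ids.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = path.read()
    lines = text.splitlines()
    if not lines:
        raise ValidationError("empty composition file")
    sep = "\t" if "\t" in lines[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMN_SCHEMA if c not in df.columns]
    if missing_cols:
        raise ValidationError(
            f"header is missing required columns: {', '.join(missing_cols)}"
        )

    table = CompositionTable()
    for idx, rec in enumerate(df.to_dict("records"), start=2):  # 1 = header line
        try:
            nutrients = {
                n: _parse_cell(rec[n], trace_as_zero) for n in NUTRIENT_FIELDS
            }
            item = FoodItem(
                food_id=str(rec["food_id"]).strip(),
                name=str(rec["name"]).strip(),
                group=int(str(rec["group"]).strip()),
                is_rpc=_parse_bool(rec["is_rpc"]),
                profile=NutrientProfile(**nutrients),
            )
            item.validate()
        except DuplicateIdError:
            raise
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
        table.add(item)
    return table


def _parse_bool(raw: object) -> bool:
    s = str(raw).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n", ""):
        return False
    raise ValueError(f"cannot parse boolean flag from {raw!r}")


def _format_cell(v: float | None) -> str:
    if v is None:
        return ""
    return repr(float(v))  # shortest round-trippable representation


def write_composition_table(table: CompositionTable, path: str | Path) -> None:
    """Write a table in the same tab-delimited schema ``read`` accepts.

    Numeric cells use the shortest representation that round-trips exactly,
    so ``read(write(x)) == x`` holds field-for-field.
    """
    out = Path(path)
    with out.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(COLUMN_SCHEMA) + "\n")
        for it in table:
            cells = [it.food_id, it.name, str(it.group), str(int(it.is_rpc))]
            cells += [_format_cell(it.profile.get(n)) for n in NUTRIENT_FIELDS]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# RF-database export

RF_COLUMNS = ("composite_id", "ingredient_id", "rf", "tier", "method", "status")


def write_rf_database(entries: Iterable, path: str | Path) -> None:
    """Export RF entries as a flat tab-delimited database.

    Columns: composite_id, ingredient_id, rf (full precision), tier, method,
    status, plus ``rf_display`` rounded to 3 decimals for human readers.
    Failed entries have an empty rf cell.
    """
    out = Path(path)
    with out.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(RF_COLUMNS + ("rf_display",)) + "\n")
        for e in entries:
            rf_full = "" if e.rf is None else repr(float(e.rf))
            rf_disp = "" if e.rf is None else f"{e.rf:.3f}"
            fh.write(
                "\t".join(
                    [
                        e.composite_id,
                        e.ingredient_id,
                        rf_full,
                        str(e.tier),
                        e.method,
                        e.status,
                        rf_disp,
                    ]
                )
                + "\n"
            )


def read_rf_database(path: str | Path) -> list:
    """Read back an RF database written by :func:`write_rf_database`."""
    from .disaggregation import RFEntry  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = []
    for rec in df.to_dict("records"):
        rf = float(rec["rf"]) if rec["rf"] != "" else None
        entries.append(
            RFEntry(
                composite_id=rec["composite_id"],
                ingredient_id=rec["ingredient_id"],
                rf=rf,
                tier=int(rec["tier"]),
                method=rec["method"],
                status=rec["status"],
            )
        )
    return entries
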