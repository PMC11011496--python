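# reverse-yield

Reverse-yield factors (RFs) for disaggregating composite foods into their
raw primary commodity (RPC) ingredients, computed from a food-composition
table.

## The problem

Dietary exposure to residues — pesticides, veterinary drugs, contaminants —
is assessed at the level of raw primary commodities, because that is where
residues are monitored and where maximum residue limits are set. Food
consumption surveys, however, record what people actually eat: dried,
salted, pickled, fermented and mixed foods. Bridging the two needs, for
each composite food, the grams of each ingredient (ultimately each RPC)
behind one gram of the food as consumed. That dimensionless ratio is the
reverse-yield factor: RF > 1 means mass was lost in processing (drying),
RF < 1 means mass was gained (brining, dilution). Multi-step processing
chains multiply per-step RFs.

This package is for exposure assessors and food-composition researchers
who need to build or audit such an RF database from per-100 g composition
data (water, protein, available carbohydrate, sucrose, acetic acid,
ethanol, salt equivalent, thiamine, calcium).

## The model

All equations are per-100 g mass balances on nutrients assumed conserved
through processing ("marker" nutrients):

- **Dried foods** — dry matter is conserved:
  `RF = (100 − b) / (100 − a)` with `a`, `b` the water contents (%) of the
  RPC and the product.
- **Salted foods** — `s` grams of (anhydrous) salt are added per 100 g:
  `RF = (100 − s − b) / (100 − a)`.
- **Pickled vegetables** — the vegetable RF uses the salted-food balance;
  the medium RF reads a marker attributed wholly to the medium (thiamine
  3.12 mg/100 g for rice-bran paste, acetate 4.2 g/100 g for vinegar,
  protein 7.7 / 12.5 g/100 g for soy sauce / miso); added sugar closes the
  sucrose balance against sugar's 99.3 g sucrose/100 g.
- **Fermented foods** — alcoholic fermentation yields 0.42 kg ethanol per
  kg glucose (≈20 % of the glucose feeds the yeast), i.e. 2.38 g glucose
  per g ethanol, giving
  `RF = (238 a/c + 100 b/c) / 100`
  for a product with `a` g ethanol and `b` g residual available
  carbohydrate per 100 g, from a raw material with `c` g available
  carbohydrate per 100 g. Acetic fermentation oxidises ethanol to acetic
  acid (theoretical yield 60/46 ≈ 1.304 kg/kg, assumed 1:1 by mass to
  allow for *Acetobacter* growth), so the acetic mass `d` slots into the
  same equation.
- **Mixed foods** — with `W_i` the grams of ingredient `C_i` per 100 g of
  composite and `R_ij` the content of marker `j` per 100 g of `C_i`, the
  marker balances form the square system
  `Σ_i (R_ij / 100) W_i = P_j`, solved by Gauss–Jordan elimination (with
  partial pivoting), and `RF_i = W_i / 100`.
- **Disaggregation** — edges chain multiplicatively down to RPC leaves;
  tier 1 is a food's first disaggregation step.

Foods whose RFs cannot be computed are classified: ingredients unknown,
too many ingredients for the usable independent markers, or processing too
complicated for simple disassembly.

## Worked example

```python
from reverse_yield import (
    CompositionTable, FoodItem, NutrientProfile, RecipeSpec, Category,
    rf_alcohol_fermented, solve_mixed_rf,
)

# Sake from polished rice: the product holds 12.8 g ethanol and 2.5 g
# residual carbohydrate per 100 g; polished rice holds 83.1 g carbohydrate.
rf = rf_alcohol_fermented(12.8, 2.5, 83.1)
print(round(rf * 100, 2))          # 39.67  (grams of rice per 100 g sake)

# Udon noodles from flour and salt: carbohydrate and salt balances.
table = CompositionTable([
    FoodItem("01018", "wheat flour", 1, NutrientProfile(
        water_pct=14.0, protein_g=8.3, avail_carb_g=75.1, salt_eq_g=0.0),
        is_rpc=True),
    FoodItem("17012", "salt", 17, NutrientProfile(
        water_pct=0.1, avail_carb_g=0.0, salt_eq_g=99.5), is_rpc=True),
    FoodItem("01038", "udon, raw", 1, NutrientProfile(
        water_pct=33.0, avail_carb_g=56.8, salt_eq_g=2.5)),
])
spec = RecipeSpec("01038", Category.MIXED, ("01018", "17012"),
                  ("avail_carb_g", "salt_eq_g"))
for e in solve_mixed_rf(spec, table):
    print(e.ingredient_id, round(e.rf, 5))
# 01018 0.75632   -> 75.6 g flour per 100 g of udon
# 17012 0.02513   ->  2.5 g salt per 100 g of udon
```

So 100 g of sake takes 39.67 g of polished rice, and 100 g of raw udon
takes 75.6 g of flour plus 2.5 g of salt (the rest is water).

## Command line

```sh
reverse-yield simulate --seed 7 --n-foods 220 --out corpus/
reverse-yield compute --table corpus/composition_table.tsv \
    --recipes corpus/recipes.yaml --out rf_database.tsv
reverse-yield disaggregate C0042 --rf-db rf_database.tsv
reverse-yield stats --table corpus/composition_table.tsv \
    --recipes corpus/recipes.yaml
```

`simulate` forward-simulates a composition table from known RPC profiles
and processing parameters (with the ground-truth RFs written alongside),
so the whole engine can be validated by parameter recovery.

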