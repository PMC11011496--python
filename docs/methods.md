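# Methods

## Scope and assumptions

The package computes reverse-yield factors (RFs): grams of an ingredient
per gram of a derived food, per 100 g edible portion throughout. The core
assumption behind every equation is that a small set of marker nutrients
passes through processing unchanged — dry matter for drying, dry
non-salt matter for salting, thiamine/acetate/protein for the pickling
media, available carbohydrate (via fixed fermentation stoichiometry) for
fermented foods, and any conserved nutrient pair/tuple for mixed foods.
Retention losses during cooking, recipe-to-recipe variation and water in
added salt are all outside the model: salt is treated as anhydrous, and a
composite's category (dried, salted, pickled, fermented, mixed) is expert
input supplied in the recipe config, never inferred from the data.

Missing values are explicit end-to-end. A blank cell in a composition
table is `None`, never zero; any equation that needs it classifies the
food as non-computable (reason: ingredients unknown) instead of silently
producing a biased RF.

## Equations

Dried: `RF = (100 − b)/(100 − a)`, `a`/`b` = RPC/product water (%).
Requires `b ≤ a < 100`; `a = 100` has no dry matter and is an error.

Salted: `RF = (100 − s − b)/(100 − a)`, `s` = added salt (NaCl-equivalent
g per 100 g product, read from the salt-equivalent column directly rather
than derived from sodium). RF < 1 is legitimate (brine uptake); a negative
numerator (`s + b > 100`) is an infeasibility error.

Pickles: the vegetable RF is the salted-food balance. The medium RF reads
the product marker against the medium's fixed content: thiamine
3.12 mg/100 g (rice-bran paste), acetate 4.2 g/100 g (vinegar), protein
7.7 g/100 g (soy sauce) or 12.5 g/100 g (miso). The sugar RF is a sucrose
mass balance, `(product sucrose − contributions of the other
ingredients)/99.3` — the grouping that is dimensionally consistent with
the marker equations; soy sauce contributes 0.1 g sucrose/100 g, miso
none. These marker equations idealise the medium as the sole source of
its marker and the vegetable as thiamine/protein-free.

Fermented: `RF = (238·a/c + 100·b/c)/100` with `a` the product's ethanol
(or, for acetic fermentation, acetic acid under the 1:1 mass assumption),
`b` its residual available carbohydrate, and `c` the raw material's
available carbohydrate, all per 100 g. The coefficient 238 is
`round(100 × 2.38)` where 2.38 g glucose per g ethanol is `1/0.42`, the
practical fermentation yield after ~20 % of the glucose feeds the yeast.
The theoretical stoichiometric helpers (45/23 g glucose per g ethanol,
3/2 g glucose per g acetic acid, 60/46 kg acetic acid per kg ethanol) are
exposed separately; the theoretical 1.304 acetic yield is available as a
config alternative (`acetic_per_ethanol_assumed`) for sensitivity
analysis, with 1.0 as the default.

Lactic-fermented beverages with two ingredients are solved as a 2×2
system on available carbohydrate and calcium; lactic *pickles* are
categorised as salted in the config and take the salted-food equation.

Mixed: the square marker-balance system `Σ_i (R_ij/100)·W_i = P_j`,
`RF_i = W_i/100`. The Gauss–Jordan elimination is written out explicitly
(reduced row echelon, partial pivoting) because the solve is the
auditable core of the method and singularity must surface as a
structured "these markers cannot separate these ingredients" report.
Recipes carrying a known content ratio bypass the solver
(`RF_i = ratio_i/100`).

## Tunable parameters

| parameter | default | units | notes |
|---|---|---|---|
| `pivot_tol` | 1e-10 | — | pivot magnitude below this marks a dependent column |
| residual tolerance | 1e-8 | g/100 g | max-norm of `(R/100)W − P` accepted on a solution |
| negative clamp | 1e-9 | g or RF | solver weights / implied sugar in `[−1e-9, 0)` clamp to 0; anything more negative is infeasible (misspecified recipe), never clamped |
| `max_depth` | 6 | tiers | deepest chain expanded; six covers observed recipes |
| `trace_as_zero` | true | — | composition-table "Tr" (trace) cells read as 0; set false to treat them as missing |
| process constants | see `ProcessConstants` | per 100 g | all config-overridable; internal consistency (2.38 ≈ 1/0.42 within 0.005, 238 = round(100 × 2.38)) is enforced at load |

Marker selection: when a mixed recipe lists more candidate markers than
ingredients, the square subset minimising the condition number of the
marker matrix is chosen by exhaustive search (k ≤ 6; larger systems take
the first k usable markers). Surplus markers are pruned, never
least-squares-fitted — the method solves square systems only.

Failure precedence when several reasons apply: ingredients unknown >
too many ingredients > complicated processing. A missing value on a
*required* marker (listed markers exactly match the ingredient count, as
in the lactic carb/calcium pair) counts as an information gap; a
shortfall of usable or independent markers among surplus candidates —
including rank-deficient (collinear) marker matrices — counts as too many
ingredients.

## The synthetic generator

`generate_corpus` forward-simulates every category from pseudo-random RPC
profiles: drying and salting by exact water/salt bookkeeping, fermentation
by explicit glucose→ethanol(→acetic) conversion with CO2/biomass mass
loss tracked, mixing by exact linear blending with added water. Two
deliberate modelling choices keep the recovery property exact rather than
vacuous:

- The forward fermentation consumes glucose at 1 g ethanol per 2.38 g
  glucose — the ratio the equation coefficient 238 encodes — not at the
  rounded 0.42 kg/kg yield (which differs by 4×10⁻⁴ relative and would
  break 1e-6 recovery).
- Pickles are constructed by the *inverse of the pickle equations*
  (markers attributed wholly to the medium, sucrose closed against sugar
  and vegetable), because the equations idealise away the medium's bulk
  mass; a literal mixing simulation would not satisfy them exactly.

The corpus spans all categories, includes the four pickling media with
their own recipes (so pickle chains reach tiers 2–3), a six-step
mix-on-mix chain, deliberately failing foods for each failure reason, and
uncooked/cooked passthroughs. Default size is 220 composite recipes.
Everything is driven by one integer seed through `numpy`'s PCG64
generator; the same seed yields byte-identical corpus files.

What the generator does **not** emulate: real nutrient correlations,
measurement noise and rounding in published tables, retention losses, or
the diversity of actual recipes. Passing recovery tests therefore shows
the engines invert their own processing model exactly — not that the
model captures any particular real food. An optional noise path is
deliberately absent from the defaults: exact blends are what make
parameter recovery a meaningful test.

For salted foods the water-balance equation yields only the raw
commodity's RF; when the recipe lists the salt itself as an ingredient,
the package also emits a salt edge with `rf = s/100`, the trivial mass
balance the equation already assumes.

## Numerical notes

- Singularity is decided by an absolute pivot threshold (`pivot_tol`)
  during elimination; classification additionally checks the rank of the
  usable marker matrix so collinear ingredients are caught before
  solving.
- Table round-trips are exact: numeric cells are written with the
  shortest representation that parses back to the identical float.
- The sake worked example uses ethanol 12.8 g/100 g, the value from which
  the reference figure 39.67 g derives; published composition tables list
  sake ethanol nearer 12.3 g/100 g, which would give 38.24 g by the same
  equation. The discrepancy lies in the source data, not the arithmetic;
  the package keeps 12.8 in examples and tests for continuity with the
  reference figure.
- Cycles in the ingredient graph are rejected up front with the cycle
  named; failed or truncated branches prune only their subtree, and each
  disaggregation reports a completeness fraction (share of leaves that
  reach an RPC).

## Limitations

RFs computed from average per-100 g composition values inherit those
averages' variability; mixed-food RFs are only as good as the assumption
that the chosen markers survive processing; and negative solver weights —
reported as infeasible, never clamped — usually indicate a misassigned
ingredient list rather than a numerical problem. The package ships no
food data: composition tables and recipe configs are user inputs, and the
synthetic corpus exists for validation, not as a stand-in for real
measurements.
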