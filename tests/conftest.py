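import pytest

from reverse_yield import (
    CompositionTable,
    FoodItem,
    NutrientProfile,
    RecipeSpec,
    Category,
    compute_all_rfs,
    generate_corpus,
)

CORPUS_SEED = 7
CORPUS_N_FOODS = 220


@pytest.fixture(scope="session")
def corpus():
    """The shared synthetic corpus: every category, tiers up to 6,
    deliberately failing foods included."""
    return generate_corpus(CORPUS_SEED, n_foods=CORPUS_N_FOODS)


@pytest.fixture(scope="session")
def corpus_entries(corpus):
    return compute_all_rfs(corpus.table, corpus.recipes, corpus.constants)


def _item(food_id, name, group, is_rpc=False, **nutrients):
    defaults = dict(
        water_pct=0.0, protein_g=0.0, avail_carb_g=0.0, sucrose_g=0.0,
        acetic_acid_g=0.0, ethanol_g=0.0, salt_eq_g=0.0,
        thiamine_mg=0.0, calcium_mg=0.0,
    )
    defaults.update(nutrients)
    return FoodItem(food_id, name, group, NutrientProfile(**defaults), is_rpc=is_rpc)


@pytest.fixture()
def udon_table():
    """Thick wheat noodles made from flour and salt: the canonical
    two-ingredient mixed food (markers: carbohydrate and salt)."""
    return CompositionTable(
        [
            _item("01018", "wheat flour", 1, is_rpc=True,
                  water_pct=14.0, protein_g=8.3, avail_carb_g=75.1),
            _item("17012", "salt", 17, is_rpc=True,
                  water_pct=0.1, salt_eq_g=99.5),
            _item("01038", "udon noodles, raw", 1,
                  water_pct=33.0, protein_g=6.1, avail_carb_g=56.8,
                  salt_eq_g=2.5),
        ]
    )


@pytest.fixture()
def udon_spec():
    return RecipeSpec(
        composite_id="01038",
        category=Category.MIXED,
        ingredients=("01018", "17012"),
        markers=("avail_carb_g", "salt_eq_g"),
    )
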