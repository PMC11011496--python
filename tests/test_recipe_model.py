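import pytest

from reverse_yield import (
    Category,
    CompositionTable,
    FailureReason,
    FoodItem,
    NutrientProfile,
    ProcessConstants,
    RecipeSpec,
    classify_failure,
    load_recipes,
)
from reverse_yield.recipe_model import RecipeError

from conftest import _item


class TestProcessConstants:
    def test_defaults_are_internally_consistent(self):
        c = ProcessConstants()
        assert abs(c.glucose_per_ethanol - 1.0 / c.ethanol_yield) <= 0.005
        assert c.ferment_constant == round(100 * c.glucose_per_ethanol)

    @pytest.mark.parametrize(
        "overrides",
        [
            {"glucose_per_ethanol": 2.5},        # breaks the 1/yield link
            {"ferment_constant": 240},           # breaks the rounding link
            {"acetate_vinegar": -1.0},
            {"sucrose_miso": 0.5},
        ],
    )
    def test_inconsistent_overrides_rejected(self, overrides):
        with pytest.raises(RecipeError):
            ProcessConstants(**overrides)


class TestLoadRecipes:
    def test_udon_two_ingredient_spec_loads(self, tmp_path):
        p = tmp_path / "recipes.yaml"
        p.write_text(
            "recipes:\n"
            "- composite: '01038'\n"
            "  category: mixed\n"
            "  ingredients: ['01018', '17012']\n"
            "  markers: [avail_carb_g, salt_eq_g]\n"
        )
        (spec,) = load_recipes(p)
        assert spec.category is Category.MIXED
        assert spec.ingredients == ("01018", "17012")
        assert spec.markers == ("avail_carb_g", "salt_eq_g")

    def test_fewer_markers_than_ingredients_is_an_error(self, tmp_path):
        p = tmp_path / "recipes.yaml"
        p.write_text(
            "recipes:\n"
            "- composite: X1\n"
            "  category: mixed\n"
            "  ingredients: [a, b, c]\n"
            "  markers: [protein_g, avail_carb_g]\n"
        )
        with pytest.raises(RecipeError, match="X1"):
            load_recipes(p)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "recipes.yaml"
        p.write_text("")
        assert load_recipes(p) == []

    def test_unknown_category_rejected(self, tmp_path):
        p = tmp_path / "recipes.yaml"
        p.write_text("- {composite: X, category: quantum}\n")
        with pytest.raises(RecipeError, match="quantum"):
            load_recipes(p)


class TestClassifyFailure:
    def _table(self, **overrides):
        items = [
            _item("A", "a", 1, is_rpc=True, water_pct=10, protein_g=8,
                  avail_carb_g=70, thiamine_mg=0.2, calcium_mg=30),
            _item("B", "b", 1, is_rpc=True, water_pct=80, protein_g=2,
                  avail_carb_g=10, thiamine_mg=0.1, calcium_mg=90),
            _item("C", "comp", 1, water_pct=40, protein_g=5,
                  avail_carb_g=40, thiamine_mg=0.15, calcium_mg=60),
        ]
        return CompositionTable(items)

    def test_unknown_ingredient_id(self):
        spec = RecipeSpec("C", Category.MIXED, ("A", "ZZ"),
                          ("protein_g", "avail_carb_g"))
        assert classify_failure(spec, self._table()) is FailureReason.INGREDIENTS_UNKNOWN

    def test_too_many_ingredients_for_usable_markers(self):
        # four ingredients, five candidate markers but only three carry
        # values everywhere -> the data cannot separate four unknowns
        items = [
            _item(f"I{i}", f"i{i}", 1, is_rpc=True, water_pct=10 + i,
                  protein_g=5 + i, avail_carb_g=50 - 3 * i, calcium_mg=20 + 7 * i)
            for i in range(4)
        ]
        comp = FoodItem("C", "comp", 1, NutrientProfile(
            water_pct=30, protein_g=6, avail_carb_g=40, calcium_mg=40))
        table = CompositionTable(items + [comp])
        spec = RecipeSpec(
            "C", Category.MIXED, tuple(f"I{i}" for i in range(4)),
            ("protein_g", "avail_carb_g", "calcium_mg", "thiamine_mg", "sucrose_g"),
        )
        assert classify_failure(spec, table) is FailureReason.TOO_MANY_INGREDIENTS

    def test_missing_required_marker_is_an_information_gap(self):
        # exactly as many listed markers as ingredients: a missing value is
        # a data gap, not an over-specified recipe
        items = [
            _item("A", "a", 1, is_rpc=True, protein_g=8, avail_carb_g=40),
            _item("B", "b", 1, is_rpc=True, protein_g=2, avail_carb_g=70),
        ]
        comp = FoodItem("C", "comp", 1, NutrientProfile(
            water_pct=30, protein_g=None, avail_carb_g=50))
        table = CompositionTable(items + [comp])
        spec = RecipeSpec("C", Category.MIXED, ("A", "B"),
                          ("protein_g", "avail_carb_g"))
        assert classify_failure(spec, table) is FailureReason.INGREDIENTS_UNKNOWN

    def test_collinear_ingredients_cannot_be_separated(self):
        items = [
            _item("A", "a", 1, is_rpc=True, protein_g=8, avail_carb_g=40),
            _item("B", "b", 1, is_rpc=True, protein_g=8, avail_carb_g=40),
            _item("C", "comp", 1, protein_g=6, avail_carb_g=30),
        ]
        spec = RecipeSpec("C", Category.MIXED, ("A", "B"),
                          ("protein_g", "avail_carb_g"))
        assert (
            classify_failure(spec, CompositionTable(items))
            is FailureReason.TOO_MANY_INGREDIENTS
        )

    def test_complicated_flag(self):
        spec = RecipeSpec("C", Category.MIXED, ("A",), ("avail_carb_g",),
                          complicated=True)
        assert (
            classify_failure(spec, self._table())
            is FailureReason.COMPLICATED_PROCESSING
        )

    def test_unknown_dominates_complicated(self):
        spec = RecipeSpec("C", Category.MIXED, ("ZZ",), ("avail_carb_g",),
                          complicated=True)
        assert classify_failure(spec, self._table()) is FailureReason.INGREDIENTS_UNKNOWN

    def test_computable_udon_is_none(self, udon_table, udon_spec):
        assert classify_failure(udon_spec, udon_table) is None


def test_classification_matches_downstream_computability(corpus, corpus_entries):
    """classify_failure is none exactly when the RF engines produce
    non-failed entries for the recipe (consistency contract over the
    synthetic corpus)."""
    by_comp = {}
    for e in corpus_entries:
        by_comp.setdefault(e.composite_id, []).append(e)
    for spec in corpus.recipes:
        if spec.category in (Category.UNCOOKED, Category.COOKED):
            continue
        reason = classify_failure(spec, corpus.table)
        statuses = {e.status for e in by_comp[spec.composite_id]}
        if reason is None:
            assert not any(s.startswith("failed") for s in statuses), spec.composite_id
        else:
            assert statuses == {f"failed({reason.value})"}, spec.composite_id
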