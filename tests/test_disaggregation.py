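import math

import pytest

from reverse_yield import (
    Category,
    CompositionTable,
    RecipeSpec,
    RFEntry,
    compute_all_rfs,
    disaggregate,
    rpc_summary,
    tier_statistics,
)
from reverse_yield.composition_io import UnknownFoodError
from reverse_yield.disaggregation import CyclicRecipeError

from conftest import _item


def entry(comp, ing, rf, tier=1, method="mixed/gauss-jordan", status="ok"):
    return RFEntry(comp, ing, rf, tier, method, status)


class TestDisaggregate:
    def test_rpc_is_a_single_leaf(self):
        entries = [entry("A", "B", 0.5)]
        node = disaggregate("B", entries)
        assert node.is_rpc_leaf and node.is_leaf
        assert node.cumulative_rf == 1.0

    def test_multiplicative_chaining(self):
        entries = [entry("A", "B", 0.5), entry("B", "C", 2.0, tier=1)]
        node = disaggregate("A", entries)
        leaf = node.children[0].children[0]
        assert leaf.food_id == "C"
        assert leaf.cumulative_rf == pytest.approx(1.0)

    def test_cumulative_rf_equals_path_product(self, corpus_entries):
        """Every leaf's cumulative RF equals the product of edge RFs along
        its path, checked by an independent re-walk of the edges."""
        rf_of = {(e.composite_id, e.ingredient_id): e.rf
                 for e in corpus_entries if e.ok}
        roots = {e.composite_id for e in corpus_entries}
        children = {c for c, _ in rf_of} & {i for _, i in rf_of}

        def walk(node, product):
            if node.is_leaf:
                if node.is_rpc_leaf:
                    assert node.cumulative_rf == pytest.approx(product, rel=1e-12)
                return
            for child in node.children:
                edge = rf_of.get((node.food_id, child.food_id))
                walk(child, product * edge if edge is not None else float("nan"))

        for root in sorted(roots - children)[:40]:
            walk(disaggregate(root, corpus_entries), 1.0)

    def test_truncation_at_max_depth(self):
        entries = [entry("A", "B", 0.5), entry("B", "C", 2.0)]
        node = disaggregate("A", entries, max_depth=1)
        child = node.children[0]
        assert child.truncated and child.status == "truncated"
        assert node.completeness() == 0.0

    def test_failed_branch_is_isolated(self):
        entries = [
            entry("A", "B", 0.5),
            entry("A", "X", None, status="failed(ingredients-unknown)"),
        ]
        node = disaggregate("A", entries)
        statuses = {c.food_id: c.status for c in node.children}
        assert statuses["B"] == "ok" and statuses["X"].startswith("failed")
        assert node.completeness() == 0.5

    def test_unknown_food_raises(self):
        with pytest.raises(UnknownFoodError):
            disaggregate("nope", [entry("A", "B", 1.0)])

    def test_rpc_summary_sums_repeated_commodities(self):
        # the same RPC C reached directly and through B
        entries = [
            entry("A", "B", 0.5),
            entry("A", "C", 0.2),
            entry("B", "C", 3.0),
        ]
        node = disaggregate("A", entries)
        summary = rpc_summary(node)
        row = summary[summary.rpc_id == "C"].iloc[0]
        assert row.cumulative_rf == pytest.approx(0.2 + 0.5 * 3.0)
        assert row.complete == "yes"


class TestComputeAllRFs:
    def test_edge_counts_forced_by_recipe_structure(self):
        table = CompositionTable([
            _item("R1", "r1", 1, is_rpc=True, water_pct=80.0, avail_carb_g=10.0,
                  protein_g=2.0),
            _item("R2", "r2", 1, is_rpc=True, water_pct=10.0, avail_carb_g=70.0,
                  protein_g=9.0),
            _item("D1", "dried", 1, water_pct=20.0, avail_carb_g=40.0,
                  protein_g=8.0),
            _item("S1", "salted", 6, water_pct=70.0, salt_eq_g=5.0,
                  avail_carb_g=2.0),
            # exact 40 g + 40 g blend of R1 and R2 with 20 g added water
            _item("M1", "mixed", 1, water_pct=56.0, avail_carb_g=32.0,
                  protein_g=4.4),
        ])
        recipes = [
            RecipeSpec("D1", Category.DRIED, ("R1",)),
            RecipeSpec("S1", Category.SALTED, ("R1",)),
            RecipeSpec("M1", Category.MIXED, ("R1", "R2"),
                       ("avail_carb_g", "protein_g")),
        ]
        entries = compute_all_rfs(table, recipes)
        assert len(entries) == 1 + 1 + 2
        assert all(e.ok for e in entries)

    def test_failed_recipe_does_not_disturb_others(self):
        table = CompositionTable([
            _item("R1", "r1", 1, is_rpc=True, water_pct=80.0),
            _item("D1", "dried", 1, water_pct=20.0),
            _item("B1", "broken", 1, water_pct=30.0),
        ])
        recipes = [
            RecipeSpec("D1", Category.DRIED, ("R1",)),
            RecipeSpec("B1", Category.DRIED, ("MISSING",)),
        ]
        entries = compute_all_rfs(table, recipes)
        by_comp = {e.composite_id: e for e in entries}
        assert by_comp["D1"].ok
        assert by_comp["B1"].status == "failed(ingredients-unknown)"

    def test_empty_recipe_set(self, corpus):
        assert compute_all_rfs(corpus.table, []) == []

    def test_cycle_detection_names_the_cycle(self):
        table = CompositionTable([
            _item("A", "a", 1, water_pct=10.0),
            _item("B", "b", 1, water_pct=20.0),
        ])
        recipes = [
            RecipeSpec("A", Category.DRIED, ("B",)),
            RecipeSpec("B", Category.DRIED, ("A",)),
        ]
        with pytest.raises(CyclicRecipeError, match="A"):
            compute_all_rfs(table, recipes)

    def test_deterministic_output_order(self, corpus):
        a = compute_all_rfs(corpus.table, corpus.recipes, corpus.constants)
        b = compute_all_rfs(corpus.table, corpus.recipes, corpus.constants)
        assert a == b
        assert [e.composite_id for e in a] == sorted(
            [e.composite_id for e in a]
        )


class TestTierStatistics:
    def test_known_tier_design(self):
        entries = [entry(f"C{i}", "R", 0.5, tier=1, method="dried")
                   for i in range(4)]
        entries.append(entry("C9", "R", 0.5, tier=2, method="dried"))
        stats = tier_statistics(entries)
        pct = {int(r.tier): r.pct for r in stats.itertuples()}
        assert pct[1] == pytest.approx(80.0)
        assert pct[2] == pytest.approx(20.0)

    def test_percentages_sum_to_100_per_class(self, corpus_entries):
        stats = tier_statistics(corpus_entries)
        sums = stats.groupby("class")["pct"].sum()
        assert all(abs(s - 100.0) < 1e-9 for s in sums)

    def test_empty_entries(self):
        assert tier_statistics([]).empty

    def test_all_failed_corpus(self):
        entries = [
            entry("C1", "R", None, method="mixed",
                  status="failed(ingredients-unknown)"),
        ]
        stats = tier_statistics(entries)
        assert stats.iloc[0].status == "failed(ingredients-unknown)"
        assert stats.iloc[0].pct == pytest.approx(100.0)


def test_tiers_reach_six_in_corpus(corpus_entries):
    assert {e.tier for e in corpus_entries} >= {1, 2, 3, 5, 6}
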