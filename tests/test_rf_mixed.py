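import numpy as np
import pytest

from reverse_yield import (
    Category,
    CompositionTable,
    LinearSystem,
    NutrientProfile,
    RecipeSpec,
    build_nutrient_system,
    gauss_jordan_solve,
    solve_mixed_rf,
)
from reverse_yield.rf_mixed import MixedFoodError, SingularSystemError

from conftest import _item


def cramer_solve(matrix, target):
    """Brute-force Cramer's-rule oracle via cofactor-expansion determinants,
    independent of the elimination path (and of numpy.linalg)."""

    def det(m):
        n = len(m)
        if n == 1:
            return m[0][0]
        total = 0.0
        for j in range(n):
            minor = [row[:j] + row[j + 1:] for row in m[1:]]
            total += ((-1) ** j) * m[0][j] * det(minor)
        return total

    a = [[v / 100.0 for v in row] for row in matrix]
    d = det(a)
    out = []
    for i in range(len(target)):
        ai = [row[:i] + [t] + row[i + 1:] for row, t in zip(a, target)]
        out.append(det(ai) / d)
    return out


class TestBuildSystem:
    def test_udon_system_layout(self, udon_table, udon_spec):
        system = build_nutrient_system(udon_spec, udon_table)
        assert system.markers == ("avail_carb_g", "salt_eq_g")
        assert system.matrix.tolist() == [[75.1, 0.0], [0.0, 99.5]]
        assert system.target.tolist() == [56.8, 2.5]

    def test_single_ingredient_system(self):
        table = CompositionTable([
            _item("A", "a", 1, is_rpc=True, avail_carb_g=80.0),
            _item("C", "c", 1, avail_carb_g=40.0),
        ])
        spec = RecipeSpec("C", Category.MIXED, ("A",), ("avail_carb_g",))
        system = build_nutrient_system(spec, table)
        assert system.matrix.shape == (1, 1)

    def test_absent_ingredient_is_information_failure(self, udon_table, udon_spec):
        spec = RecipeSpec("01038", Category.MIXED, ("01018", "nope"),
                          ("avail_carb_g", "salt_eq_g"))
        with pytest.raises(MixedFoodError, match="nope"):
            build_nutrient_system(spec, udon_table)

    def test_surplus_markers_pruned_to_best_conditioned_square(self, udon_table):
        spec = RecipeSpec(
            "01038", Category.MIXED, ("01018", "17012"),
            ("avail_carb_g", "salt_eq_g", "protein_g"),
        )
        system = build_nutrient_system(spec, udon_table)
        assert system.matrix.shape == (2, 2)
        # protein cannot separate salt (salt has none); the well-conditioned
        # pair is (carbohydrate, salt)
        assert set(system.markers) == {"avail_carb_g", "salt_eq_g"}


class TestGaussJordan:
    def test_identity_times_hundred_returns_target(self):
        system = LinearSystem(np.eye(3) * 100.0, [7.0, 8.0, 9.0],
                              ("m1", "m2", "m3"), ("a", "b", "c"))
        res = gauss_jordan_solve(system)
        assert res.solution == pytest.approx([7.0, 8.0, 9.0], rel=1e-14)
        assert res.residual_norm <= 1e-8

    def test_udon_matches_closed_form(self, udon_table, udon_spec):
        system = build_nutrient_system(udon_spec, udon_table)
        res = gauss_jordan_solve(system)
        assert res.solution[0] == pytest.approx(100 * 56.8 / 75.1, rel=1e-12)
        assert res.solution[1] == pytest.approx(100 * 2.5 / 99.5, rel=1e-12)

    def test_agrees_with_cramer_oracle_on_seeded_systems(self):
        rng = np.random.default_rng(12345)
        n_checked = 0
        while n_checked < 1000:
            k = int(rng.integers(1, 5))
            matrix = rng.uniform(1.0, 100.0, size=(k, k))
            if abs(np.linalg.det(matrix / 100.0)) < 1e-6:
                continue
            target = rng.uniform(0.1, 50.0, size=k)
            system = LinearSystem(matrix, target,
                                  tuple(f"m{i}" for i in range(k)),
                                  tuple(f"c{i}" for i in range(k)))
            res = gauss_jordan_solve(system)
            expected = cramer_solve(matrix.tolist(), target.tolist())
            assert res.solution == pytest.approx(expected, rel=1e-10)
            assert res.residual_norm <= 1e-8
            n_checked += 1

    def test_singular_system_names_dependent_ingredients(self):
        matrix = [[10.0, 20.0], [5.0, 10.0]]  # rank 1
        system = LinearSystem(np.array(matrix), [3.0, 1.5],
                              ("m1", "m2"), ("flour", "starch"))
        res = gauss_jordan_solve(system)
        assert res.singular
        assert res.solution is None
        assert "starch" in res.dependent_columns

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(99)
        matrix = rng.uniform(1, 50, size=(3, 3))
        target = rng.uniform(1, 30, size=3)
        base = gauss_jordan_solve(
            LinearSystem(matrix, target, ("a", "b", "c"), ("x", "y", "z"))
        ).solution
        perm = [2, 0, 1]
        permuted = gauss_jordan_solve(
            LinearSystem(matrix[:, perm], target, ("a", "b", "c"), ("z", "x", "y"))
        ).solution
        assert permuted == pytest.approx(base[perm], rel=1e-10)

    def test_row_scaling_invariance(self):
        rng = np.random.default_rng(5)
        matrix = rng.uniform(1, 50, size=(3, 3))
        target = rng.uniform(1, 30, size=3)
        base = gauss_jordan_solve(
            LinearSystem(matrix, target, ("a", "b", "c"), ("x", "y", "z"))
        ).solution
        scaled_m = matrix.copy()
        scaled_t = target.copy()
        scaled_m[1] *= 37.5
        scaled_t[1] *= 37.5
        scaled = gauss_jordan_solve(
            LinearSystem(scaled_m, scaled_t, ("a", "b", "c"), ("x", "y", "z"))
        ).solution
        assert scaled == pytest.approx(base, rel=1e-10)


class TestSolveMixedRF:
    def test_udon_rfs(self, udon_table, udon_spec):
        entries = solve_mixed_rf(udon_spec, udon_table)
        rf = {e.ingredient_id: e.rf for e in entries}
        assert rf["01018"] == pytest.approx(56.8 / 75.1, rel=1e-12)
        assert rf["17012"] == pytest.approx(2.5 / 99.5, rel=1e-12)
        assert all(e.method == "mixed/gauss-jordan" and e.ok for e in entries)

    def test_known_ratio_bypasses_solver(self, udon_table):
        spec = RecipeSpec("01038", Category.MIXED_KNOWN_RATIO,
                          ("01018", "17012"), known_ratios=(60.0, 40.0))
        entries = solve_mixed_rf(spec, udon_table)
        assert [e.rf for e in entries] == pytest.approx([0.6, 0.4])
        assert all(e.method == "known-ratio" for e in entries)

    def test_negative_component_marks_infeasible_without_clamp(self):
        table = CompositionTable([
            _item("A", "a", 1, is_rpc=True, protein_g=10.0, avail_carb_g=10.0),
            _item("B", "b", 1, is_rpc=True, protein_g=10.0, avail_carb_g=40.0),
            # protein demands more A+B than carbohydrate allows -> negative B
            _item("C", "c", 1, protein_g=9.0, avail_carb_g=3.0),
        ])
        spec = RecipeSpec("C", Category.MIXED, ("A", "B"),
                          ("protein_g", "avail_carb_g"))
        entries = solve_mixed_rf(spec, table)
        assert {e.status for e in entries} == {"infeasible"}
        assert min(e.rf for e in entries) < -1e-9  # reported, not clamped

    def test_singular_raises_too_many_ingredients(self):
        table = CompositionTable([
            _item("A", "a", 1, is_rpc=True, protein_g=8.0, avail_carb_g=40.0),
            _item("B", "b", 1, is_rpc=True, protein_g=4.0, avail_carb_g=20.0),
            _item("C", "c", 1, protein_g=6.0, avail_carb_g=30.0),
        ])
        spec = RecipeSpec("C", Category.MIXED, ("A", "B"),
                          ("protein_g", "avail_carb_g"))
        with pytest.raises(SingularSystemError):
            solve_mixed_rf(spec, table)


def test_exact_blend_parameter_recovery():
    """Composites built as exact linear blends give back the generating
    weights to 1e-9 relative — the solver's core recovery property."""
    rng = np.random.default_rng(2024)
    for _ in range(50):
        k = int(rng.integers(2, 5))
        profiles = rng.uniform(1.0, 80.0, size=(k, k))
        weights = rng.uniform(5.0, 40.0, size=k)
        if abs(np.linalg.det(profiles)) < 1e-3:
            continue
        target = (profiles / 100.0).T @ weights  # marker content of the blend
        system = LinearSystem(profiles.T, target,
                              tuple(f"m{j}" for j in range(k)),
                              tuple(f"c{i}" for i in range(k)))
        res = gauss_jordan_solve(system)
        assert res.solution == pytest.approx(weights, rel=1e-9)
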