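"""Likelihood-of-occurrence statistic and the Grubbs outlier screen."""
import math

import numpy as np
import pytest

from acedyad.enrichment import (
    RegulationSet,
    condition_screen,
    grubbs_critical,
    grubbs_statistic,
    grubbs_test,
    likelihood,
)
from acedyad.synthetic_data import generate_condition_sets


def regset(genes, universe, condition="cond", direction="up"):
    return RegulationSet(condition, direction, frozenset(genes), frozenset(universe))


class TestLikelihood:
    def test_direct_arithmetic(self):
        universe = [f"g{i}" for i in range(100)]
        A = universe[:20]
        B5 = universe[10:20]
        reg = regset(A, universe)
        res = likelihood(reg, {5: set(B5)}, max_spacer=5)
        # X = |A n B|/|B| = 10/10 = 1.0, Y = 0.2 -> L(5) = 5.0
        assert res.per_N[5] == pytest.approx(5.0)
        B5 = set(universe[16:26])  # |A n B| = 4 of 10
        res = likelihood(reg, {5: B5}, max_spacer=5)
        assert res.per_N[5] == pytest.approx((4 / 10) / (20 / 100)) == pytest.approx(2.0)

    def test_equivalent_count_formula(self):
        universe = [f"g{i}" for i in range(60)]
        reg = regset(universe[:15], universe)
        B = set(universe[10:30])
        res = likelihood(reg, {0: B}, max_spacer=0)
        nab = len(set(universe[:15]) & B)
        assert res.per_N[0] == pytest.approx(nab * len(universe) / (15 * len(B)))

    def test_A_equal_universe_forces_unit_likelihood(self):
        universe = [f"g{i}" for i in range(50)]
        reg = regset(universe, universe)
        res = likelihood(reg, {n: set(universe[n : n + 10]) for n in range(3)}, max_spacer=3)
        assert np.allclose(res.per_N[:3], 1.0)
        assert math.isnan(res.per_N[3])  # empty B(3) undefined
        assert res.overall == pytest.approx(1.0)

    def test_empty_regulated_set_rejected(self):
        universe = [f"g{i}" for i in range(10)]
        with pytest.raises(ValueError):
            likelihood(regset([], universe), {0: set(universe)}, max_spacer=0)

    def test_scale_free_under_duplication(self):
        universe = [f"g{i}" for i in range(40)]
        A, B = universe[:10], set(universe[5:20])
        res1 = likelihood(regset(A, universe), {0: B}, max_spacer=0)
        dup = universe + [f"h{i}" for i in range(40)]
        A2 = A + [f"h{i}" for i in range(10)]
        B2 = B | {f"h{i}" for i in range(5, 20)}
        res2 = likelihood(regset(A2, dup), {0: B2}, max_spacer=0)
        assert res1.overall == pytest.approx(res2.overall)

    def test_independent_sets_concentrate_near_one(self):
        universe = [f"g{i}" for i in range(20000)]
        dyad = set(universe[:2000])
        reg = generate_condition_sets(universe, dyad, 0.2, 1.0, seed=7)
        res = likelihood(reg, {0: dyad}, max_spacer=0)
        assert res.overall == pytest.approx(1.0, abs=0.08)


class TestGrubbsStatistic:
    def test_hand_computed_example(self):
        G, idx = grubbs_statistic([1, 1, 1, 1, 1, 1, 1, 1, 2])
        assert G == pytest.approx(8 / 3, abs=1e-9)
        assert idx == 8

    def test_symmetric_tie_broken_to_lowest_index(self):
        G, idx = grubbs_statistic([-1.0, 0.0, 1.0])
        assert G == pytest.approx(1.0)
        assert idx == 0

    def test_affine_invariance(self, rng):
        x = rng.normal(size=9)
        G1, i1 = grubbs_statistic(x)
        G2, i2 = grubbs_statistic(5.0 * x - 3.0)
        assert G1 == pytest.approx(G2) and i1 == i2

    def test_never_exceeds_theoretical_bound(self, rng):
        for _ in range(50):
            x = rng.normal(size=9)
            G, _ = grubbs_statistic(x)
            assert G <= (9 - 1) / math.sqrt(9) + 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            grubbs_statistic([1.0, 1.0])
        with pytest.raises(ValueError):
            grubbs_statistic([2.0, 2.0, 2.0])


class TestGrubbsCritical:
    def test_classical_table_values(self):
        assert grubbs_critical(9, 0.05, "two_sided") == pytest.approx(2.21, abs=0.01)
        assert grubbs_critical(9, 0.05, "one_sided") == pytest.approx(2.11, abs=0.01)
        assert grubbs_critical(3, 0.05, "two_sided") == pytest.approx(1.15, abs=0.01)

    def test_decreasing_in_alpha_increasing_in_n(self):
        assert grubbs_critical(9, 0.01) > grubbs_critical(9, 0.05) > grubbs_critical(9, 0.10)
        crits = [grubbs_critical(n) for n in range(3, 40)]
        assert all(a < b for a, b in zip(crits, crits[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            grubbs_critical(2)
        with pytest.raises(ValueError):
            grubbs_critical(9, 0.05, "sideways")


class TestConditionScreen:
    @staticmethod
    def build_panel(universe, rng, n_motifs=9, frac=0.1):
        motifs = ["ACGT"] + [f"CTRL{i}" for i in range(n_motifs - 1)]
        size = int(frac * len(universe))
        panel = {}
        for m in motifs:
            genes = set(rng.choice(universe, size=size, replace=False))
            panel[m] = {0: genes}
        return panel

    def test_planted_enrichment_flagged_significant(self, rng):
        universe = [f"g{i}" for i in range(8000)]
        panel = self.build_panel(universe, rng)
        reg = generate_condition_sets(
            universe, panel["ACGT"][0], 0.2, 2.0, seed=11, condition="planted"
        )
        rows = condition_screen([reg], panel, max_spacer=0)
        assert rows[0].gated and rows[0].significant
        assert rows[0].likelihoods["ACGT"] == pytest.approx(2.0, abs=0.2)

    def test_independent_condition_not_flagged(self, rng):
        universe = [f"g{i}" for i in range(8000)]
        panel = self.build_panel(universe, rng)
        reg = generate_condition_sets(
            universe, set(), 0.2, 1.0, seed=13, condition="null"
        )
        rows = condition_screen([reg], panel, max_spacer=0)
        assert not rows[0].significant

    def test_cutoff_gate_blocks_grubbs_stage(self, rng):
        universe = [f"g{i}" for i in range(2000)]
        panel = self.build_panel(universe, rng)
        reg = generate_condition_sets(universe, set(), 0.3, 1.0, seed=5)
        rows = condition_screen([reg], panel, cutoff=1.30, max_spacer=0)
        if rows[0].likelihoods["ACGT"] <= 1.30:
            assert not rows[0].gated and rows[0].grubbs is None

    def test_control_outlier_never_flags_condition(self):
        universe = [f"g{i}" for i in range(100)]
        A = universe[:50]
        panel = {
            "ACGT": {0: set(universe[25:75])},   # half in A -> L = 1
            "CTRL0": {0: set(universe[:20])},    # fully inside A -> L = 2 (outlier)
            "CTRL1": {0: set(universe[20:72])},  # close to L = 1
        }
        reg = regset(A, universe)
        rows = condition_screen([reg], panel, max_spacer=0, cutoff=0.0)
        assert rows[0].grubbs is not None
        assert rows[0].grubbs.extreme_index != 0
        assert not rows[0].significant

    def test_panel_validation(self):
        reg = regset(["g1"], ["g1", "g2"])
        with pytest.raises(ValueError, match="test motif"):
            condition_screen([reg], {"TAGC": {0: set()}})
        with pytest.raises(ValueError, match="controls"):
            condition_screen([reg], {"ACGT": {0: set()}, "TAGC": {0: set()}})

    def test_grubbs_test_requires_test_motif_extreme(self):
        res = grubbs_test([1.0, 1.1, 0.9, 1.0, 5.0], test_index=0)
        assert res.extreme_index == 4 and not res.significant
        res = grubbs_test([5.0, 1.0, 1.1, 0.9, 1.0], test_index=0)
        assert res.extreme_index == 0 and res.significant == (res.G > res.critical)
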