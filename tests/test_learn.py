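"""Structure learning: BIC score, hill climbing, bootstrap averaging, CPTs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnzoom.cohort import CohortTable
from bnzoom.learn import (
    ArcStrengthTable,
    average_network,
    bic_score,
    bootstrap_arc_strength,
    fit_cpts,
    hill_climb,
)
from bnzoom.network import DAG
from bnzoom.schema import BCS, BCSR
from helpers import all_dags_3, make_cohort, make_schema

XY = make_schema({"X": ("a", "b"), "T": (BCS, BCSR)})
XYZ = make_schema({"X": ("a", "b"), "Y": ("a", "b"), "T": (BCS, BCSR)})


def _binary_cohort(schema, columns: dict[str, np.ndarray]):
    maps = {name: schema[name].categories for name in columns}
    rows = [
        {name: maps[name][int(col[i])] for name, col in columns.items()}
        for i in range(len(next(iter(columns.values()))))
    ]
    return make_cohort(schema, rows)


class TestBicScore:
    def test_single_balanced_binary_closed_form(self):
        single = make_schema({"T": (BCS, BCSR)})
        col = np.array([0, 1] * 4)
        table = _binary_cohort(single, {"T": col})
        score = bic_score(DAG(("T",), ()), table)
        expected = -8 * math.log(2) - 0.5 * math.log(8)
        assert score == pytest.approx(expected, abs=1e-9)
        assert score == pytest.approx(-6.5849, abs=1e-4)

    def test_independent_arc_never_helps(self):
        # Y's conditional frequencies equal its marginal: likelihood unchanged,
        # penalty grows, so the arc strictly lowers BIC
        for n in (8, 64, 512):
            x = np.tile([0, 0, 1, 1], n // 4)
            y = np.tile([0, 1, 0, 1], n // 4)
            table = _binary_cohort(XY, {"X": x, "T": y})
            empty = bic_score(DAG(("X", "T"), ()), table)
            arc = bic_score(DAG(("X", "T"), (("X", "T"),)), table)
            assert arc < empty

    def test_exact_copy_arc_improves(self):
        x = np.array([0, 1] * 50)
        table = _binary_cohort(XY, {"X": x, "T": x})
        empty = bic_score(DAG(("X", "T"), ()), table)
        arc = bic_score(DAG(("X", "T"), (("X", "T"),)), table)
        assert arc > empty

    def test_decomposability(self):
        rng = np.random.default_rng(3)
        cols = {name: rng.integers(0, 2, 300) for name in ("X", "Y", "T")}
        table = _binary_cohort(XYZ, cols)
        dag = DAG(("X", "Y", "T"), (("X", "Y"), ("Y", "T")))
        # family-wise recomputation through single-node DAGs
        total = 0.0
        for node, parents in (("X", ()), ("Y", ("X",)), ("T", ("Y",))):
            sub = DAG(("X", "Y", "T"), tuple((p, node) for p in parents))
            # family score of `node` = score(sub) - scores of the other
            # (parentless) families; isolate by differencing empty DAG
            total += bic_score(sub, table) - bic_score(DAG(("X", "Y", "T"), ()), table)
        total += bic_score(DAG(("X", "Y", "T"), ()), table)
        assert total == pytest.approx(bic_score(dag, table), abs=1e-9)

    def test_missing_node_raises(self):
        table = _binary_cohort(XY, {"X": np.zeros(4, int), "T": np.zeros(4, int)})
        with pytest.raises(ValueError):
            bic_score(DAG(("X", "T", "Q"), ()), table)


class TestHillClimb:
    def test_independent_uniform_gives_empty_dag(self):
        rng = np.random.default_rng(0)
        cols = {n: rng.integers(0, 2, 5000) for n in ("X", "Y", "T")}
        dag = hill_climb(_binary_cohort(XYZ, cols))
        assert dag.arcs == ()

    def test_noisy_copy_recovers_skeleton(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 2000)
        y = np.where(rng.random(2000) < 0.05, 1 - x, x)
        table = _binary_cohort(XY, {"X": x, "T": y})
        dag = hill_climb(table)
        assert dag.skeleton() == {frozenset({"X", "T"})}

    def test_noisy_or_collider_recovered_and_matches_exhaustive_optimum(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 5000)
        y = rng.integers(0, 2, 5000)
        z = np.where(rng.random(5000) < 0.1, rng.integers(0, 2, 5000), x | y)
        table = _binary_cohort(XYZ, {"X": x, "Y": y, "T": z})
        dag = hill_climb(table)
        assert dag.skeleton() == {frozenset({"X", "T"}), frozenset({"Y", "T"})}
        best = max(all_dags_3(("X", "Y", "T")), key=lambda d: bic_score(d, table))
        assert bic_score(dag, table) == pytest.approx(
            bic_score(best, table), abs=1e-9
        )

    def test_pure_xor_collider_is_a_known_greedy_blind_spot(self):
        # Z = XOR(X, Y) leaves Z marginally independent of each parent, so
        # no single arc addition improves the score and greedy ascent stays
        # at the empty graph even though the collider scores far higher.
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 5000)
        y = rng.integers(0, 2, 5000)
        table = _binary_cohort(XYZ, {"X": x, "Y": y, "T": x ^ y})
        dag = hill_climb(table)
        assert dag.arcs == ()
        collider = DAG(("X", "Y", "T"), (("X", "T"), ("Y", "T")))
        assert bic_score(collider, table) > bic_score(dag, table)

    def test_output_acyclic_on_random_cohorts(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            cols = {n: rng.integers(0, 2, 200) for n in ("X", "Y", "T")}
            hill_climb(_binary_cohort(XYZ, cols))  # DAG constructor asserts acyclicity


class TestBootstrap:
    def test_constant_replicates_give_strength_one(self):
        x = np.array([0, 1] * 200)
        table = _binary_cohort(XY, {"X": x, "T": x})
        st_ = bootstrap_arc_strength(table, replicates=10, seed=0)
        assert st_.strength("X", "T") == 1.0

    def test_independent_variables_strengths_below_threshold(self):
        rng = np.random.default_rng(5)
        cols = {n: rng.integers(0, 2, 2000) for n in ("X", "Y", "T")}
        st_ = bootstrap_arc_strength(
            _binary_cohort(XYZ, cols), replicates=100, seed=5
        )
        strengths = [v[0] for v in st_.entries.values()] or [0.0]
        assert max(strengths) < 0.25

    def test_single_replicate_strengths_are_zero_or_one(self):
        rng = np.random.default_rng(6)
        cols = {n: rng.integers(0, 2, 500) for n in ("X", "Y", "T")}
        st_ = bootstrap_arc_strength(
            _binary_cohort(XYZ, cols), replicates=1, seed=6
        )
        assert all(v[0] in (0.0, 1.0) for v in st_.entries.values())


class TestAverageNetwork:
    def test_threshold_filters_weak_pairs(self):
        st_ = ArcStrengthTable(
            ("A", "B", "C"), 100,
            {("A", "B"): (0.9, 1.0), ("B", "C"): (0.24, 0.6)},
        )
        dag = average_network(st_, 0.25)
        assert dag.arcs == (("A", "B"),)

    def test_unanimous_replicates_reproduce_common_dag(self):
        st_ = ArcStrengthTable(
            ("A", "B", "C"), 50,
            {("A", "B"): (1.0, 1.0), ("B", "C"): (1.0, 1.0)},
        )
        dag = average_network(st_, 0.25)
        assert set(dag.arcs) == {("A", "B"), ("B", "C")}

    def test_two_cycle_repaired_by_dropping_weaker_arc(self):
        # majority orientations A->B (0.6) and B->A (0.5) cannot coexist;
        # entries on distinct pairs forming a directed 2-node cycle need a
        # 3-node example: A->B, B->C, C->A with strengths 0.6/0.5/0.55
        st_ = ArcStrengthTable(
            ("A", "B", "C"), 100,
            {
                ("A", "B"): (0.6, 1.0),   # A->B
                ("B", "C"): (0.5, 1.0),   # B->C
                ("A", "C"): (0.55, 0.0),  # C->A
            },
        )
        dag = average_network(st_, 0.25)
        assert ("B", "C") not in dag.arcs  # weakest dropped
        assert set(dag.arcs) == {("A", "B"), ("C", "A")}

    def test_bad_threshold_raises(self):
        st_ = ArcStrengthTable(("A", "B"), 1, {})
        with pytest.raises(ValueError):
            average_network(st_, 0.0)


class TestFitCpts:
    def _table(self, pairs):
        rows = [{"X": x, "T": t} for x, t in pairs]
        return make_cohort(XY, rows)

    def test_maximum_likelihood_rows(self):
        table = self._table([("a", BCS)] * 3 + [("a", BCSR)])
        bn = fit_cpts(DAG(("X", "T"), (("X", "T"),)), table, pseudo_count=0)
        np.testing.assert_allclose(bn.cpts["T"].table[0], [0.75, 0.25])

    def test_unseen_configuration_uniform(self):
        table = self._table([("a", BCS)] * 4)  # X=b never observed
        bn = fit_cpts(DAG(("X", "T"), (("X", "T"),)), table, pseudo_count=0)
        np.testing.assert_allclose(bn.cpts["T"].table[1], [0.5, 0.5])

    def test_laplace_smoothing(self):
        table = self._table([("a", BCS)] * 2)
        bn = fit_cpts(DAG(("X", "T"), (("X", "T"),)), table, pseudo_count=1)
        np.testing.assert_allclose(bn.cpts["T"].table[0], [0.75, 0.25])
        np.testing.assert_allclose(bn.cpts["T"].table[1], [0.5, 0.5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 50), min_size=4, max_size=4),
        pseudo=st.floats(0.0, 5.0),
    )
    def test_rows_always_sum_to_one(self, counts, pseudo):
        pairs = (
            [("a", BCS)] * counts[0] + [("a", BCSR)] * counts[1]
            + [("b", BCS)] * counts[2] + [("b", BCSR)] * counts[3]
        )
        if not pairs:
            pairs = [("a", BCS)]
        bn = fit_cpts(
            DAG(("X", "T"), (("X", "T"),)), self._table(pairs), pseudo_count=pseudo
        )
        sums = bn.cpts["T"].table.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
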