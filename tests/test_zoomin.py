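"""The zoom-in heuristic: signed differences, scans, traces, branching."""

import numpy as np
import pytest

from bnzoom.learn import fit_cpts
from bnzoom.network import load_detroit_dag
from bnzoom.schema import BCS, BCSR
from bnzoom.synth import (
    detroit_reference_network,
    plant_divergence,
    sample_records,
    treatment_null_network,
)
from bnzoom.zoomin import (
    Condition,
    TableBackend,
    find_candidates,
    signed_difference,
    stage_controlled_run,
    zoomin_branch,
    zoomin_run,
)
from helpers import make_bn, make_schema


@pytest.fixture(scope="module")
def detroit_tables():
    return TableBackend.load_detroit()


def null_bn():
    """Treatment independent of the single covariate."""
    schema = make_schema({"S": ("0", "I"), "G": ("low", "high"), "T": (BCS, BCSR)})
    return make_bn(
        schema,
        [("S", "G")],
        {
            "S": [[0.5, 0.5]],
            "G": [[0.7, 0.3], [0.2, 0.8]],
            "T": [[0.2, 0.8]],
        },
    )


class TestSignedDifference:
    def test_grade_undetermined_stage0_published_value(self, detroit_tables):
        d = signed_difference(
            detroit_tables, Condition("G", "Undetermined"), "0", BCS
        )
        assert d == pytest.approx(0.512 - 0.083, abs=1e-12)

    def test_grade_ii_stage0_is_negative(self, detroit_tables):
        d = signed_difference(detroit_tables, Condition("G", "II"), "0", BCS)
        assert d == pytest.approx(0.226 - 0.405, abs=1e-12)
        assert d < 0  # favors the non-target treatment

    def test_identical_distributions_give_zero(self):
        d = signed_difference(null_bn(), Condition("G", "low"), "0", BCS)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_already_conditioned_variable_rejected(self, detroit_tables):
        with pytest.raises(ValueError):
            signed_difference(
                detroit_tables, Condition("G", "II"), "0", BCS,
                conditions=[Condition("G", "Undetermined")],
            )


class TestFindCandidates:
    def test_age_qualifies_in_all_early_stages(self, detroit_tables):
        found = find_candidates(
            detroit_tables, ["A"], ("I", "IIA", "IIB"), BCSR
        )
        by_cat = {c.category: d for c, d in found}
        assert set(by_cat) == {"51−75", "26−50"}
        assert by_cat["51−75"] == pytest.approx(0.155, abs=1e-9)
        assert by_cat["26−50"] == pytest.approx(0.069, abs=1e-9)
        assert by_cat["51−75"] > by_cat["26−50"]

    def test_grade_ii_given_age_qualifies(self, detroit_tables):
        found = find_candidates(
            detroit_tables, ["G"], ("I", "IIA", "IIB"), BCSR,
            conditions=[Condition("A", "51−75")],
        )
        assert [(c.variable, c.category) for c, _ in found] == [("G", "II")]
        assert found[0][1] == pytest.approx(0.041, abs=1e-9)

    def test_unattainable_tolerance_gives_empty(self, detroit_tables):
        assert find_candidates(
            detroit_tables, ["G"], ("0",), BCS, tolerance=1.0
        ) == []


class TestZoomInRun:
    def test_in_situ_published_selections(self, detroit_tables):
        trace = zoomin_run(detroit_tables, ("0",), BCS)
        assert [(c.variable, c.category) for c in trace.selected] == [
            ("G", "Undetermined"), ("H", "8520"), ("A", "26−50"),
        ]
        assert trace.terminated == "no-candidates"

    def test_early_invasive_published_selections(self, detroit_tables):
        trace = zoomin_run(detroit_tables, ("I", "IIA", "IIB"), BCSR)
        assert [(c.variable, c.category) for c in trace.selected] == [
            ("A", "51−75"), ("G", "II"),
        ]

    def test_treatment_independent_network_selects_nothing(self):
        trace = zoomin_run(null_bn(), ("0",), BCS)
        assert trace.selected == ()
        assert trace.terminated == "no-candidates"

    def test_every_selection_exceeds_tolerance_and_variables_distinct(self):
        bn = fit_cpts(
            load_detroit_dag(),
            sample_records(detroit_reference_network(), 5000, seed=8),
        )
        trace = zoomin_run(bn, ("0",), BCS)
        seen = set()
        for it in trace.iterations:
            if it.selection is None:
                continue
            assert it.selection.variable not in seen
            seen.add(it.selection.variable)
            chosen = next(
                c for c in it.candidates if c.condition == it.selection
            )
            assert chosen.min_difference > trace.tolerance
            # maximal among qualifying candidates of that iteration
            best = max(c.min_difference for c in it.candidates if c.qualifies)
            assert chosen.min_difference == best

    def test_iteration_count_bounded_by_scannable_variables(self):
        bn = fit_cpts(
            load_detroit_dag(),
            sample_records(detroit_reference_network(), 3000, seed=9),
        )
        trace = zoomin_run(bn, ("0",), BCS)
        assert len(trace.selected) <= 12

    def test_trace_serializes(self, detroit_tables):
        trace = zoomin_run(detroit_tables, ("0",), BCS)
        import json
        obj = trace.to_json()
        json.dumps(obj, ensure_ascii=False)
        assert obj["selected"][0] == {"variable": "G", "category": "Undetermined"}

    def test_bad_arguments(self, detroit_tables):
        with pytest.raises(ValueError):
            zoomin_run(detroit_tables, (), BCS)
        with pytest.raises(ValueError):
            zoomin_run(detroit_tables, ("0",), BCS, tolerance=0.0)


class TestBranch:
    def test_dcis_branch_finds_no_further_conditions(self, detroit_tables):
        base = zoomin_run(detroit_tables, ("0",), BCS)
        branched = zoomin_branch(detroit_tables, base, Condition("H", "8500"), 1)
        assert branched.selected == (
            Condition("G", "Undetermined"), Condition("H", "8500"),
        )
        assert branched.terminated == "no-candidates"

    def test_self_branch_reproduces_base_selections(self, detroit_tables):
        base = zoomin_run(detroit_tables, ("0",), BCS)
        branched = zoomin_branch(detroit_tables, base, base.selected[1], 1)
        assert branched.selected == base.selected
        assert branched.terminated == base.terminated

    def test_branch_on_already_conditioned_variable_rejected(self, detroit_tables):
        base = zoomin_run(detroit_tables, ("0",), BCS)
        with pytest.raises(ValueError):
            zoomin_branch(detroit_tables, base, Condition("G", "II"), 1)

    def test_divergence_planted_inside_branch_stratum_recovered(self):
        # effect on A exists only within the H=8500 stratum
        schema = make_schema({
            "H": ("8500", "8520"),
            "A": ("young", "old"),
            "T": (BCS, BCSR),
        })
        bn = make_bn(
            schema,
            [("T", "H"), ("H", "A"), ("T", "A")],
            {
                "T": [[0.3, 0.7]],
                "H": [[0.5, 0.5], [0.5, 0.5]],
                # rows over (H, T): divergence of 0.3 only when H=8500
                "A": [
                    [0.8, 0.2],   # H=8500, T=BCS
                    [0.5, 0.5],   # H=8500, T=BCSR
                    [0.4, 0.6],   # H=8520, T=BCS
                    [0.4, 0.6],   # H=8520, T=BCSR
                ],
            },
        )
        base = zoomin_run(bn, (None,), BCS, stage_variable="S")
        branched = zoomin_branch(bn, base, Condition("H", "8500"), 0)
        assert Condition("A", "young") in branched.selected


class TestStageControlled:
    def test_planted_stage0_effect_recovered(self):
        null = treatment_null_network()
        planted = plant_divergence(
            null, Condition("H", "8520"), ("0",), BCS, 0.4
        )
        cohort = sample_records(planted, 20000, seed=21)
        trace = stage_controlled_run(
            cohort, "0", BCS, learn_config={"dag": load_detroit_dag()}
        )
        assert Condition("H", "8520") in trace.selected

    def test_controlled_schema_excludes_stage(self):
        cohort = sample_records(detroit_reference_network(), 3000, seed=22)
        trace = stage_controlled_run(
            cohort, "0", BCS, learn_config={"dag": load_detroit_dag()}
        )
        assert all(c.variable != "S" for c in trace.selected)
        assert trace.stage_set == (None,)

    def test_independent_stage_subset_selects_nothing(self):
        bn = null_bn()
        cohort = sample_records(bn, 4000, seed=23)
        trace = stage_controlled_run(cohort, "0", BCS, learn_config={})
        assert trace.selected == ()
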