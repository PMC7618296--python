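"""Decision-tree triage logic, stage shift and primary-care costing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovatriage.accuracy import AgeGroup, TestId
from ovatriage.decision_tree import (
    Branch,
    PathwayDefinition,
    PathwayMode,
    PopulationStratum,
    StageShiftParams,
    UnitCosts,
    apply_stage_shift,
    branch_probabilities,
    evaluate_pathway,
    expected_primary_care_cost,
    fp_secondary_cost,
    primary_care_cost,
    standard_pathways,
)

from _oracles import enumerate_pathway


class _FlatAccuracy:
    """Accuracy stub serving fixed (sens, spec) per (test, label)."""

    def __init__(self, table):
        self.table = table

    def lookup(self, test_id, age_group, label):
        return self.table[(TestId(test_id), label)]


def _stratum(prev=0.0105, late=0.72, age_group=AgeGroup.GE50):
    return PopulationStratum(
        age_group=age_group, n_women=1000, oc_prevalence=prev, late_stage_prop=late
    )


prob = st.floats(0.02, 0.98)


@pytest.mark.parametrize("pathway_id", [1, 2, 3, 4, 5, 6])
@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    s_mod=prob, sp_mod=prob, s_high=prob, sp_high=prob,
    s_uss=prob, sp_uss=prob, prev=st.floats(1e-4, 0.2),
)
def test_pathway_agrees_with_enumeration_oracle(
    pathway_id, s_mod, sp_mod, s_high, sp_high, s_uss, sp_uss, prev
):
    """Four-class probabilities match exhaustive enumeration of joint atoms."""
    # order the band thresholds to respect ROC monotonicity
    s_mod, s_high = max(s_mod, s_high), min(s_mod, s_high)
    sp_mod, sp_high = min(sp_mod, sp_high), max(sp_mod, sp_high)
    pathway = standard_pathways()[pathway_id]
    table = {
        (pathway.first_test, pathway.high_label): (s_high, sp_high),
        (TestId.USS, "abnormal"): (s_uss, sp_uss),
    }
    if pathway.moderate_label is not None:
        table[(pathway.first_test, pathway.moderate_label)] = (s_mod, sp_mod)
    accuracy = _FlatAccuracy(table)
    stratum = _stratum(prev=prev)
    out = evaluate_pathway(pathway, accuracy, stratum)
    oracle = enumerate_pathway(pathway, accuracy, stratum.age_group, prev)
    assert out.p_tp == pytest.approx(oracle["tp"], abs=1e-12)
    assert out.p_fn == pytest.approx(oracle["fn"], abs=1e-12)
    assert out.p_tn == pytest.approx(oracle["tn"], abs=1e-12)
    assert out.p_fp == pytest.approx(oracle["fp"], abs=1e-12)
    assert out.p_tp + out.p_fn + out.p_tn + out.p_fp == pytest.approx(1.0, abs=1e-12)
    # branch probabilities partition unity given each disease status
    probs = branch_probabilities(pathway, accuracy, stratum.age_group)
    for status in (True, False):
        assert sum(probs[status].values()) == pytest.approx(1.0, abs=1e-12)


def test_sequential_detection_examples(accuracy, pathways, ge50, under50):
    """Spot values: current practice at >=50 and the risk-banded pathway at <50."""
    p1 = evaluate_pathway(pathways[1], accuracy, ge50)
    assert p1.detection_rate == pytest.approx(0.865 * 0.85, abs=1e-12)
    assert p1.referral_rate == pytest.approx(0.0173, abs=5e-5)
    p2 = evaluate_pathway(pathways[2], accuracy, under50)
    assert p2.detection_rate == pytest.approx(0.452 + (0.619 - 0.452) * 0.85, abs=1e-12)


def test_concurrent_referral_example(accuracy, pathways, ge50):
    out = evaluate_pathway(pathways[4], accuracy, ge50)
    expected = 0.0105 * (1 - (1 - 0.831) * 0.15) + 0.9895 * (1 - 0.965 * 0.83)
    assert out.referral_rate == pytest.approx(expected, abs=1e-12)


def test_perfect_tests(pathways):
    accuracy = _FlatAccuracy(
        {
            (TestId.CA125_35, "35 U/mL"): (1.0, 1.0),
            (TestId.OVATOOLS, "1%"): (1.0, 1.0),
            (TestId.OVATOOLS, "3%"): (1.0, 1.0),
            (TestId.AGE_ADJ_CA125, "1%"): (1.0, 1.0),
            (TestId.AGE_ADJ_CA125, "3%"): (1.0, 1.0),
            (TestId.USS, "abnormal"): (1.0, 1.0),
        }
    )
    stratum = _stratum(prev=0.01)
    for pid in range(1, 7):
        out = evaluate_pathway(pathways[pid], accuracy, stratum)
        assert out.detection_rate == pytest.approx(1.0)
        assert out.referral_rate == pytest.approx(0.01)
        assert out.p_fp == 0.0


def test_zero_prevalence_detection_undefined(accuracy, pathways):
    out = evaluate_pathway(pathways[1], accuracy, _stratum(prev=0.0))
    assert out.detection_rate is None


@settings(max_examples=40, deadline=None, derandomize=True)
@given(s_b=prob, sp_b=prob, s_u=prob, sp_u=prob)
def test_concurrent_detects_at_least_sequential(s_b, sp_b, s_u, sp_u):
    """1 - (1-s1)(1-s2) >= s1*s2 for s in [0, 1]."""
    accuracy = _FlatAccuracy(
        {(TestId.CA125_35, "35 U/mL"): (s_b, sp_b), (TestId.USS, "abnormal"): (s_u, sp_u)}
    )
    stratum = _stratum(prev=0.01)
    seq = evaluate_pathway(standard_pathways()[1], accuracy, stratum)
    conc = evaluate_pathway(standard_pathways()[6], accuracy, stratum)
    assert conc.detection_rate >= seq.detection_rate - 1e-12


class TestStageShift:
    def test_incremental_mass_shifted(self, accuracy, pathways, ge50):
        """Late share among incrementally detected cancers scales by the relative risk."""
        ref = evaluate_pathway(pathways[1], accuracy, ge50)
        new = evaluate_pathway(pathways[2], accuracy, ge50)
        shifted = apply_stage_shift(new, ref, StageShiftParams(rr_late=0.836), ge50)
        delta = new.p_tp - ref.p_tp
        # two-state mass-balance oracle
        late_mass = (new.p_tp - delta) * 0.72 + delta * 0.72 * 0.836
        assert shifted.late_stage_prop_detected == pytest.approx(late_mass / new.p_tp, abs=1e-12)
        assert shifted.late_stage_prop_detected < 0.72
        assert shifted.late_stage_prop_missed == 0.72
        # shifted fraction of the incremental late-stage mass moves to early stage
        assert 0.72 * 0.836 == pytest.approx(0.602, abs=5e-4)
        assert 0.72 * (1 - 0.836) == pytest.approx(0.118, abs=5e-4)

    def test_rr_one_is_identity(self, accuracy, pathways, ge50):
        ref = evaluate_pathway(pathways[1], accuracy, ge50)
        new = evaluate_pathway(pathways[2], accuracy, ge50)
        shifted = apply_stage_shift(new, ref, StageShiftParams(rr_late=1.0), ge50)
        assert shifted.late_stage_prop_detected == new.late_stage_prop_detected

    def test_self_comparison_is_identity(self, accuracy, pathways, ge50):
        ref = evaluate_pathway(pathways[1], accuracy, ge50)
        shifted = apply_stage_shift(ref, ref, StageShiftParams(), ge50)
        assert shifted == ref

    def test_no_reverse_shift_when_detection_lower(self, accuracy, pathways, under50):
        """A pathway missing more cancers gets usual-care staging, not a penalty."""
        ref = evaluate_pathway(pathways[1], accuracy, under50)
        new = evaluate_pathway(pathways[2], accuracy, under50)
        assert new.p_tp < ref.p_tp
        shifted = apply_stage_shift(new, ref, StageShiftParams(), under50)
        assert shifted.late_stage_prop_detected == under50.late_stage_prop
        assert shifted.late_stage_prop_missed == under50.late_stage_prop

    def test_mismatched_strata_rejected(self, accuracy, pathways, ge50, under50):
        a = evaluate_pathway(pathways[1], accuracy, ge50)
        b = evaluate_pathway(pathways[1], accuracy, under50)
        with pytest.raises(ValueError):
            apply_stage_shift(a, b, StageShiftParams())

    def test_rr_above_one_capped_with_warning(self, accuracy, pathways, ge50):
        ref = evaluate_pathway(pathways[1], accuracy, ge50)
        new = evaluate_pathway(pathways[2], accuracy, ge50)
        with pytest.warns(UserWarning):
            shifted = apply_stage_shift(new, ref, StageShiftParams(rr_late=1.1), ge50)
        assert shifted.late_stage_prop_detected == ge50.late_stage_prop


@pytest.mark.parametrize(
    "pathway_id, branch, expected",
    [
        (1, Branch.BLOOD_NEG, 59.0),                 # GP + nurse + CA125
        (1, Branch.BLOOD_MOD_USS_NEG, 283.0),        # + telephone + USS
        (1, Branch.BLOOD_MOD_USS_POS, 323.0),        # + referral consultation
        (2, Branch.BLOOD_NEG, 59.0),
        (2, Branch.BLOOD_HIGH, 99.0),                # direct referral consultation
        (6, Branch.BOTH_NEG, 263.0),                 # concurrent: USS up front
        (6, Branch.ANY_POS, 303.0),
    ],
)
def test_branch_costs(pathways, pathway_id, branch, expected):
    assert primary_care_cost(pathways[pathway_id], branch) == expected


def test_branch_inconsistent_with_mode_rejected(pathways):
    with pytest.raises(ValueError):
        primary_care_cost(pathways[1], Branch.BOTH_NEG)
    with pytest.raises(ValueError):
        primary_care_cost(pathways[6], Branch.BLOOD_NEG)
    with pytest.raises(ValueError):
        primary_care_cost(pathways[1], Branch.BLOOD_HIGH)  # no band in pathway 1


def test_expected_cost_doubles_false_negative_branches(accuracy, pathways):
    """Missed cancers repeat the identical primary-care branch once."""
    stratum = _stratum(prev=0.5)  # exaggerate the cancer share
    got = expected_primary_care_cost(pathways[1], accuracy, stratum)
    s_b, sp_b = 0.865, 0.943
    s_u, sp_u = 0.85, 0.83
    cost_oc = (
        (1 - s_b) * 2 * 59.0
        + s_b * (1 - s_u) * 2 * 283.0
        + s_b * s_u * 323.0
    )
    cost_no = sp_b * 59.0 + (1 - sp_b) * sp_u * 283.0 + (1 - sp_b) * (1 - sp_u) * 323.0
    assert got == pytest.approx(0.5 * cost_oc + 0.5 * cost_no, abs=1e-9)


@pytest.mark.parametrize(
    "rate, expected",
    [(0.75, 3094.25), (0.0, 395.0), (1.0, 3994.0)],
)
def test_fp_secondary_cost(rate, expected):
    costs = UnitCosts(benign_surgery_rate=rate)
    assert fp_secondary_cost(costs) == pytest.approx(expected)


def test_pathway_definition_validation():
    with pytest.raises(ValueError):
        PathwayDefinition(7, PathwayMode.SEQUENTIAL, TestId.CA125_35, None, "35 U/mL")
    with pytest.raises(ValueError):
        PathwayDefinition(4, PathwayMode.CONCURRENT, TestId.OVATOOLS, "1%", "3%")
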