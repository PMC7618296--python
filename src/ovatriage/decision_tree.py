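"""Primary-care triage decision tree for the six diagnostic pathways.

Each pathway classifies a woman presenting with possible ovarian-cancer
symptoms into one of four outcome classes — true positive (invasive ovarian
cancer detected and referred), false negative (cancer missed, reassured),
true negative (no cancer, reassured), false positive (no cancer, referred) —
given the test accuracies and the stratum's one-year cancer prevalence.  The
blood test and the ultrasound are treated as conditionally independent given
invasive-cancer status; "no cancer" includes women with other cancers and
benign disease, matching how the accuracy data were tabulated.

Pathway structure:

* Pathway 1 (current practice): CA125 with a 35 U/mL cut, ultrasound if
  raised, referral if the ultrasound is abnormal.
* Pathways 2/3 (sequential, risk-banded): Ovatools risk (or the equivalent
  age-adjusted CA125 threshold); <1% reassure, 1-3% ultrasound, >=3% direct
  urgent referral.
* Pathways 4/5/6 (concurrent): CA125/Ovatools and ultrasound up front,
  referral if either is abnormal (Ovatools >=3%, the age-adjusted equivalent,
  or CA125 >= 35 U/mL respectively).

The module also costs the primary-care journey branch by branch and the
secondary-care workup of referred women without an eventual cancer diagnosis.
A false-negative presentation repeats the identical primary-care branch once
before diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .accuracy import AccuracyTable, AgeGroup, TestId

__all__ = [
    "PathwayMode",
    "Branch",
    "PathwayDefinition",
    "PopulationStratum",
    "DiagnosticOutcome",
    "StageShiftParams",
    "UnitCosts",
    "standard_pathways",
    "evaluate_pathway",
    "apply_stage_shift",
    "primary_care_cost",
    "branch_probabilities",
    "expected_primary_care_cost",
    "fp_secondary_cost",
]


class PathwayMode(str, Enum):
    SEQUENTIAL = "SEQUENTIAL"
    CONCURRENT = "CONCURRENT"


class Branch(str, Enum):
    """Test-result paths through a pathway, used for costing."""

    BLOOD_NEG = "BLOOD_NEG"                  # sequential: below (moderate) threshold
    BLOOD_MOD_USS_NEG = "BLOOD_MOD_USS_NEG"  # sequential: ultrasound arranged, normal
    BLOOD_MOD_USS_POS = "BLOOD_MOD_USS_POS"  # sequential: ultrasound abnormal -> referral
    BLOOD_HIGH = "BLOOD_HIGH"                # sequential banded: direct urgent referral
    BOTH_NEG = "BOTH_NEG"                    # concurrent: both tests normal
    ANY_POS = "ANY_POS"                      # concurrent: either abnormal -> referral


@dataclass(frozen=True)
class PathwayDefinition:
    """Triage logic of one primary-care pathway."""

    id: int
    mode: PathwayMode
    first_test: TestId
    moderate_label: str | None  # band lower bound (sequential risk-banded only)
    high_label: str             # referral threshold (or single CA125 cut)

    def __post_init__(self) -> None:
        if not 1 <= self.id <= 6:
            raise ValueError("pathway id must be 1..6")
        if self.mode is PathwayMode.CONCURRENT and self.moderate_label is not None:
            raise ValueError("concurrent pathways have no moderate band")

    @property
    def banded(self) -> bool:
        return self.mode is PathwayMode.SEQUENTIAL and self.moderate_label is not None


def standard_pathways() -> dict[int, PathwayDefinition]:
    """The six pathways of the evaluation."""
    S, C = PathwayMode.SEQUENTIAL, PathwayMode.CONCURRENT
    return {
        1: PathwayDefinition(1, S, TestId.CA125_35, None, "35 U/mL"),
        2: PathwayDefinition(2, S, TestId.OVATOOLS, "1%", "3%"),
        3: PathwayDefinition(3, S, TestId.AGE_ADJ_CA125, "1%", "3%"),
        4: PathwayDefinition(4, C, TestId.OVATOOLS, None, "3%"),
        5: PathwayDefinition(5, C, TestId.AGE_ADJ_CA125, None, "3%"),
        6: PathwayDefinition(6, C, TestId.CA125_35, None, "35 U/mL"),
    }


@dataclass(frozen=True)
class PopulationStratum:
    """One age stratum of CA125-tested women."""

    age_group: AgeGroup
    n_women: int
    oc_prevalence: float          # invasive ovarian cancer within 1 year
    late_stage_prop: float        # stage III/IV among staged cancers
    other_cancer_prevalences: dict[str, float] = field(default_factory=dict)
    age_weights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.oc_prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if not 0.0 <= self.late_stage_prop <= 1.0:
            raise ValueError("late-stage proportion must lie in [0, 1]")
        total = self.oc_prevalence + sum(self.other_cancer_prevalences.values())
        if total > 1.0:
            raise ValueError("cancer prevalences exceed 1")
        if self.age_weights:
            s = sum(self.age_weights.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError("age weights must sum to 1")

    @property
    def benign_prevalence(self) -> float:
        """No cancer of any modelled type."""
        return 1.0 - self.oc_prevalence - sum(self.other_cancer_prevalences.values())


@dataclass(frozen=True)
class DiagnosticOutcome:
    """Four-class probabilities for one pathway applied to one stratum."""

    pathway_id: int
    stratum: PopulationStratum
    p_tp: float
    p_fn: float
    p_tn: float
    p_fp: float
    late_stage_prop_detected: float
    late_stage_prop_missed: float

    @property
    def detection_rate(self) -> float | None:
        prev = self.stratum.oc_prevalence
        if prev == 0:
            return None
        return self.p_tp / prev

    @property
    def referral_rate(self) -> float:
        return self.p_tp + self.p_fp


@dataclass(frozen=True)
class StageShiftParams:
    """Relative risk of late-stage diagnosis for earlier-detected cancers."""

    rr_late: float = 0.836
    ci: tuple[float, float] = (0.737, 0.950)

    def __post_init__(self) -> None:
        if self.rr_late <= 0:
            raise ValueError("rr_late must be positive")

    def capped(self) -> "StageShiftParams":
        if self.rr_late > 1.0:
            import warnings

            warnings.warn("rr_late > 1 drawn; capping at 1", stacklevel=2)
            return replace(self, rr_late=1.0)
        return self


@dataclass(frozen=True)
class UnitCosts:
    """Unit costs in 2022 GBP."""

    ca125_test: float = 10.0
    nurse_blood: float = 9.0
    uss: float = 204.0
    gp_face_to_face: float = 40.0
    gp_telephone: float = 20.0
    outpatient: float = 181.0
    benign_surgery: float = 3994.0
    benign_surgery_rate: float = 0.75

    def __post_init__(self) -> None:
        for name in (
            "ca125_test", "nurse_blood", "uss", "gp_face_to_face",
            "gp_telephone", "outpatient", "benign_surgery",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.benign_surgery_rate <= 1.0:
            raise ValueError("benign_surgery_rate must lie in [0, 1]")


def _pathway_rates(pathway: PathwayDefinition, accuracy, age_group: AgeGroup):
    """(P(detect|OC), P(refer|no OC)) under conditional independence."""
    sens_u, spec_u = accuracy.lookup(TestId.USS, age_group, "abnormal")
    if pathway.mode is PathwayMode.SEQUENTIAL and not pathway.banded:
        sens_b, spec_b = accuracy.lookup(pathway.first_test, age_group, pathway.high_label)
        detect = sens_b * sens_u
        refer = (1.0 - spec_b) * (1.0 - spec_u)
    elif pathway.banded:
        sens_m, spec_m = accuracy.lookup(pathway.first_test, age_group, pathway.moderate_label)
        sens_h, spec_h = accuracy.lookup(pathway.first_test, age_group, pathway.high_label)
        detect = sens_h + (sens_m - sens_h) * sens_u
        refer = (1.0 - spec_h) + (spec_h - spec_m) * (1.0 - spec_u)
    else:  # concurrent
        sens_b, spec_b = accuracy.lookup(pathway.first_test, age_group, pathway.high_label)
        detect = 1.0 - (1.0 - sens_b) * (1.0 - sens_u)
        refer = 1.0 - spec_b * spec_u
    return detect, refer


def evaluate_pathway(
    pathway: PathwayDefinition,
    accuracy: AccuracyTable,
    stratum: PopulationStratum,
) -> DiagnosticOutcome:
    """Four-class outcome probabilities for a pathway on a stratum.

    Without a stage shift (applied separately against the reference pathway)
    both detected and missed cancers keep the stratum's baseline staging.
    """
    detect, refer = _pathway_rates(pathway, accuracy, stratum.age_group)
    prev = stratum.oc_prevalence
    p_tp = prev * detect
    p_fn = prev * (1.0 - detect)
    p_fp = (1.0 - prev) * refer
    p_tn = (1.0 - prev) * (1.0 - refer)
    return DiagnosticOutcome(
        pathway_id=pathway.id,
        stratum=stratum,
        p_tp=p_tp,
        p_fn=p_fn,
        p_tn=p_tn,
        p_fp=p_fp,
        late_stage_prop_detected=stratum.late_stage_prop,
        late_stage_prop_missed=stratum.late_stage_prop,
    )


def apply_stage_shift(
    outcome_new: DiagnosticOutcome,
    outcome_ref: DiagnosticOutcome,
    shift: StageShiftParams,
    stratum: PopulationStratum | None = None,
) -> DiagnosticOutcome:
    """Shift a fraction of incrementally detected late-stage cancers to early stage.

    Only the detected mass *beyond* the reference (current-practice) pathway
    has its late-stage probability multiplied by ``rr_late``; cancers detected
    under both pathways, and all missed cancers, keep the baseline staging.
    A pathway detecting fewer cancers than the reference gets no reverse
    shift: missed cases revert to usual-care staging.
    """
    stratum = stratum or outcome_new.stratum
    if outcome_new.stratum != outcome_ref.stratum or outcome_new.stratum != stratum:
        raise ValueError("stage shift requires outcomes on the same stratum")
    shift = shift.capped()
    delta = max(0.0, outcome_new.p_tp - outcome_ref.p_tp)
    base_late = stratum.late_stage_prop
    if outcome_new.p_tp > 0 and delta > 0:
        shared = outcome_new.p_tp - delta
        late_detected = (shared * base_late + delta * base_late * shift.rr_late) / outcome_new.p_tp
    else:
        late_detected = base_late
    return replace(
        outcome_new,
        late_stage_prop_detected=late_detected,
        late_stage_prop_missed=base_late,
    )


# --- primary-care costing ---------------------------------------------------

_SEQ_BRANCHES = (Branch.BLOOD_NEG, Branch.BLOOD_MOD_USS_NEG, Branch.BLOOD_MOD_USS_POS)
_BANDED_BRANCHES = _SEQ_BRANCHES + (Branch.BLOOD_HIGH,)
_CONC_BRANCHES = (Branch.BOTH_NEG, Branch.ANY_POS)


def _valid_branches(pathway: PathwayDefinition):
    if pathway.mode is PathwayMode.CONCURRENT:
        return _CONC_BRANCHES
    return _BANDED_BRANCHES if pathway.banded else _SEQ_BRANCHES


def primary_care_cost(
    pathway: PathwayDefinition, branch: Branch, costs: UnitCosts = UnitCosts()
) -> float:
    """Primary-care cost of one test-result branch, in GBP.

    Sequential journeys start with a face-to-face GP consultation, nurse time
    and the CA125 test; if an ultrasound is arranged, a GP telephone follow-up
    and the scan are added, and an abnormal scan adds a further GP
    consultation before referral.  Concurrent journeys order both tests at the
    initial consultation, with one further GP consultation before referral
    when either is abnormal.  Direct urgent referral at high risk likewise
    adds a single further GP consultation.
    """
    branch = Branch(branch)
    if branch not in _valid_branches(pathway):
        raise ValueError(f"branch {branch.value} is not part of pathway {pathway.id}")
    blood = costs.gp_face_to_face + costs.nurse_blood + costs.ca125_test
    if pathway.mode is PathwayMode.CONCURRENT:
        base = blood + costs.uss
        return base if branch is Branch.BOTH_NEG else base + costs.gp_face_to_face
    if branch is Branch.BLOOD_NEG:
        return blood
    if branch is Branch.BLOOD_HIGH:
        return blood + costs.gp_face_to_face
    uss_leg = blood + costs.gp_telephone + costs.uss
    if branch is Branch.BLOOD_MOD_USS_NEG:
        return uss_leg
    return uss_leg + costs.gp_face_to_face  # BLOOD_MOD_USS_POS


def branch_probabilities(
    pathway: PathwayDefinition, accuracy: AccuracyTable, age_group: AgeGroup
) -> dict[bool, dict[Branch, float]]:
    """Branch probabilities conditional on invasive-cancer status.

    Returns ``{True: {branch: P(branch | cancer)}, False: {...| no cancer}}``.
    """
    sens_u, spec_u = accuracy.lookup(TestId.USS, age_group, "abnormal")
    out: dict[bool, dict[Branch, float]] = {}
    if pathway.mode is PathwayMode.CONCURRENT:
        sens_b, spec_b = accuracy.lookup(pathway.first_test, age_group, pathway.high_label)
        out[True] = {
            Branch.BOTH_NEG: (1 - sens_b) * (1 - sens_u),
            Branch.ANY_POS: 1 - (1 - sens_b) * (1 - sens_u),
        }
        out[False] = {
            Branch.BOTH_NEG: spec_b * spec_u,
            Branch.ANY_POS: 1 - spec_b * spec_u,
        }
        return out
    if pathway.banded:
        sens_m, spec_m = accuracy.lookup(pathway.first_test, age_group, pathway.moderate_label)
        sens_h, spec_h = accuracy.lookup(pathway.first_test, age_group, pathway.high_label)
        # P(risk >= moderate | cancer) = sens_m, P(risk >= high | cancer) = sens_h
        out[True] = {
            Branch.BLOOD_NEG: 1 - sens_m,
            Branch.BLOOD_MOD_USS_NEG: (sens_m - sens_h) * (1 - sens_u),
            Branch.BLOOD_MOD_USS_POS: (sens_m - sens_h) * sens_u,
            Branch.BLOOD_HIGH: sens_h,
        }
        out[False] = {
            Branch.BLOOD_NEG: spec_m,
            Branch.BLOOD_MOD_USS_NEG: (spec_h - spec_m) * spec_u,
            Branch.BLOOD_MOD_USS_POS: (spec_h - spec_m) * (1 - spec_u),
            Branch.BLOOD_HIGH: 1 - spec_h,
        }
        return out
    sens_b, spec_b = accuracy.lookup(pathway.first_test, age_group, pathway.high_label)
    out[True] = {
        Branch.BLOOD_NEG: 1 - sens_b,
        Branch.BLOOD_MOD_USS_NEG: sens_b * (1 - sens_u),
        Branch.BLOOD_MOD_USS_POS: sens_b * sens_u,
    }
    out[False] = {
        Branch.BLOOD_NEG: spec_b,
        Branch.BLOOD_MOD_USS_NEG: (1 - spec_b) * spec_u,
        Branch.BLOOD_MOD_USS_POS: (1 - spec_b) * (1 - spec_u),
    }
    return out


_REFERRAL_BRANCHES = {Branch.BLOOD_MOD_USS_POS, Branch.BLOOD_HIGH, Branch.ANY_POS}


def expected_primary_care_cost(
    pathway: PathwayDefinition,
    accuracy: AccuracyTable,
    stratum: PopulationStratum,
    costs: UnitCosts = UnitCosts(),
) -> float:
    """Expected primary-care cost per woman in the stratum, in GBP.

    Women with undetected cancer (false negatives) repeat the identical
    primary-care branch once before diagnosis, so their branch cost is
    incurred twice.
    """
    probs = branch_probabilities(pathway, accuracy, stratum.age_group)
    prev = stratum.oc_prevalence
    cost_oc = 0.0
    for branch, p in probs[True].items():
        c = primary_care_cost(pathway, branch, costs)
        if branch not in _REFERRAL_BRANCHES:
            c *= 2.0  # missed cancer re-enters the same branch once
        cost_oc += p * c
    cost_no = sum(
        p * primary_care_cost(pathway, branch, costs) for branch, p in probs[False].items()
    )
    return prev * cost_oc + (1.0 - prev) * cost_no


def fp_secondary_cost(costs: UnitCosts = UnitCosts()) -> float:
    """Expected secondary-care cost of a referral without a cancer diagnosis.

    A fraction undergoes surgery for benign disease; the rest receive an
    outpatient consultation, a CA125 test and an ultrasound.
    """
    rate = costs.benign_surgery_rate
    non_surgery = costs.outpatient + costs.ca125_test + costs.uss
    return rate * costs.benign_surgery + (1.0 - rate) * non_surgery
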