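"""Five-state lifetime Markov cohort model.

States: no cancer, early-stage cancer, late-stage cancer (entry states) and
two absorbing death states, cancer death and non-cancer death.  Annual cycles
run from the entry age to age 110.  Cancer-death risk in the first years after
diagnosis comes from (stand-in) parametric survival models; beyond the
survival-model horizon, and for all non-cancer deaths, cause-partitioned
national life-table rates at the person's current age apply.  No explicit
early-to-late progression is modelled: the stage-specific death-risk models
subsume progression.

Competing risks within a cycle are combined on the hazard scale: the total
death probability is 1 - exp(-(h_cancer + h_other)) and is allocated to the
two causes in proportion to their hazards, which reduces exactly to the
single-risk form when either hazard is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "State",
    "Stage",
    "CancerType",
    "MarkovSpec",
    "ExponentialSurvival",
    "WeibullSurvival",
    "LifeTable",
    "UtilityModel",
    "CostModel",
    "MarkovParameters",
    "Trajectory",
    "annual_cancer_death_prob",
    "build_transition_row",
    "run_cohort",
    "lifetime_outcomes",
    "surgery_qaly_delta",
]

N_STATES = 5


class State(IntEnum):
    NO_CANCER = 0
    EARLY_CANCER = 1
    LATE_CANCER = 2
    CANCER_DEATH = 3
    NONCANCER_DEATH = 4


LIVE_STATES = (State.NO_CANCER, State.EARLY_CANCER, State.LATE_CANCER)


class Stage(str, Enum):
    EARLY = "EARLY"
    LATE = "LATE"


class CancerType(str, Enum):
    OVARIAN = "OVARIAN"
    LOWER_GI = "LOWER_GI"
    UTERINE = "UTERINE"
    LUNG = "LUNG"
    PANCREATIC = "PANCREATIC"
    OTHER = "OTHER"


@dataclass(frozen=True)
class MarkovSpec:
    """Structural settings of the cohort projection."""

    max_age: int = 110
    survival_model_horizon: int = 8   # years post-diagnosis covered by survival models
    discount_qaly: float = 0.035
    discount_cost: float = 0.035
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.discount_qaly < 0 or self.discount_cost < 0:
            raise ValueError("discount rates must be non-negative")
        if self.survival_model_horizon < 1:
            raise ValueError("survival-model horizon must be at least 1 year")


@dataclass(frozen=True)
class ExponentialSurvival:
    """Constant-hazard survival; pinned exactly by one survival anchor."""

    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("hazard must be non-negative")

    @classmethod
    def from_anchor(cls, t: float, survival: float) -> "ExponentialSurvival":
        if not 0.0 < survival < 1.0:
            raise ValueError(f"anchor survival must lie in (0, 1), got {survival}")
        return cls(rate=-math.log(survival) / t)

    def hazard(self, t: float, age: float | None = None) -> float:
        return self.rate

    def cumulative_hazard(self, t0: float, t1: float, age: float | None = None) -> float:
        return self.rate * (t1 - t0)

    def survival(self, t: float) -> float:
        return math.exp(-self.rate * t)


@dataclass(frozen=True)
class WeibullSurvival:
    """Weibull hazard h(t) = shape/scale * (t/scale)^(shape-1)."""

    shape: float
    scale: float

    def hazard(self, t: float, age: float | None = None) -> float:
        if t <= 0:
            t = 1e-9
        return self.shape / self.scale * (t / self.scale) ** (self.shape - 1.0)

    def cumulative_hazard(self, t0: float, t1: float, age: float | None = None) -> float:
        return (t1 / self.scale) ** self.shape - (t0 / self.scale) ** self.shape

    def survival(self, t: float) -> float:
        return math.exp(-((t / self.scale) ** self.shape))


class LifeTable:
    """Female mortality hazards by integer age, partitioned by cause."""

    def __init__(self, ages: np.ndarray, cancer_rate: np.ndarray, noncancer_rate: np.ndarray):
        ages = np.asarray(ages, dtype=int)
        if np.any(cancer_rate < 0) or np.any(noncancer_rate < 0):
            raise ValueError("mortality rates must be non-negative")
        order = np.argsort(ages)
        self.ages = ages[order]
        self.cancer_rate = np.asarray(cancer_rate, dtype=float)[order]
        self.noncancer_rate = np.asarray(noncancer_rate, dtype=float)[order]

    def _idx(self, age: float) -> int:
        i = int(np.clip(round(age), self.ages[0], self.ages[-1]) - self.ages[0])
        return i

    def cancer_hazard(self, age: float) -> float:
        return float(self.cancer_rate[self._idx(age)])

    def noncancer_hazard(self, age: float) -> float:
        return float(self.noncancer_rate[self._idx(age)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"age": self.ages, "cancer_rate": self.cancer_rate, "noncancer_rate": self.noncancer_rate}
        )


@dataclass(frozen=True)
class UtilityModel:
    """EQ-5D-style utility: age-declining baseline minus state decrements.

    ``decrements`` maps cancer type to (within one year of diagnosis, more
    than one year after diagnosis) utility decrements; late-stage disease
    carries an extra per-cycle decrement.  Benign-surgery effects (a
    disutility in the surgery year, a small annual gain thereafter) are
    layered on the no-cancer trajectory of referred women who undergo surgery.
    """

    base_intercept: float = 0.97
    base_age_slope: float = 0.0035   # utility lost per year of age above the reference
    base_age_ref: float = 18.0
    decrements: dict[CancerType, tuple[float, float]] = field(default_factory=dict)
    late_stage_extra: float = 0.046
    surgery_disutility: float = 0.04
    surgery_disutility_ci: tuple[float, float] = (0.01, 0.06)
    surgery_gain: float = 0.008
    surgery_gain_ci: tuple[float, float] = (-0.005, 0.021)

    def base_utility(self, age: float) -> float:
        u = self.base_intercept - self.base_age_slope * max(0.0, age - self.base_age_ref)
        return min(1.0, max(0.0, u))

    def state_utility(
        self, state: State, age: float, t_since_dx: float, cancer_type: CancerType | None
    ) -> float:
        u = self.base_utility(age)
        if state in (State.EARLY_CANCER, State.LATE_CANCER):
            if cancer_type is None:
                raise ValueError("cancer state utility requires a cancer type")
            recent, later = self.decrements.get(cancer_type, (0.0, 0.0))
            u -= recent if t_since_dx < 1.0 else later
            if state is State.LATE_CANCER:
                u -= self.late_stage_extra
        return min(1.0, u)


@dataclass(frozen=True)
class CostModel:
    """Annual inpatient cost by cancer type, stage and years since diagnosis.

    Step function over years 0, 1, 2, 3 and 4+, plus a constant background
    annual cost for women without a cancer diagnosis.
    """

    curves: dict[tuple[CancerType, Stage], tuple[float, ...]] = field(default_factory=dict)
    background: float = 0.0

    def annual_cost(
        self, state: State, t_since_dx: float, cancer_type: CancerType | None, stage: Stage | None
    ) -> float:
        if state is State.NO_CANCER:
            return self.background
        if state in (State.EARLY_CANCER, State.LATE_CANCER):
            curve = self.curves[(cancer_type, stage)]
            return curve[min(int(t_since_dx), len(curve) - 1)]
        return 0.0


@dataclass(frozen=True)
class MarkovParameters:
    """Everything the cohort projection needs."""

    survival_models: dict[tuple[CancerType, Stage], object]
    life_table: LifeTable
    utility_model: UtilityModel
    cost_model: CostModel
    spec: MarkovSpec = MarkovSpec()


@dataclass
class Trajectory:
    """State occupancy per annual cycle for one entry age."""

    entry_age: int
    occupancy: np.ndarray          # (n_cycles, 5); cycle 0 is the entry year
    cancer_type: CancerType | None

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def ages(self) -> np.ndarray:
        return self.entry_age + np.arange(self.n_cycles)


def annual_cancer_death_prob(
    model,
    t_since_dx: float,
    age: float,
    params: MarkovParameters,
) -> float:
    """Probability of cancer death within the next annual cycle.

    Within the survival-model horizon the survival model's cumulative hazard
    over the cycle applies; beyond it, the life-table cancer mortality at the
    person's current age.
    """
    if t_since_dx < 0:
        raise ValueError("time since diagnosis must be non-negative")
    if t_since_dx < params.spec.survival_model_horizon:
        lam = model.cumulative_hazard(t_since_dx, t_since_dx + 1.0, age)
    else:
        lam = params.life_table.cancer_hazard(age)
    return 1.0 - math.exp(-lam)


def _cause_hazards(
    state: State, age: float, t_since_dx: float, params: MarkovParameters,
    cancer_type: CancerType | None, stage: Stage | None,
) -> tuple[float, float]:
    """(cancer hazard, non-cancer hazard) over the coming cycle."""
    h_nc = params.life_table.noncancer_hazard(age)
    if state is State.NO_CANCER:
        h_c = params.life_table.cancer_hazard(age)
    else:
        if t_since_dx < params.spec.survival_model_horizon:
            model = params.survival_models[(cancer_type, stage)]
            h_c = model.cumulative_hazard(t_since_dx, t_since_dx + 1.0, age)
        else:
            h_c = params.life_table.cancer_hazard(age)
    return h_c, h_nc


def build_transition_row(
    state: State,
    age: float,
    t_since_dx: float,
    params: MarkovParameters,
    cancer_type: CancerType | None = None,
    stage: Stage | None = None,
) -> np.ndarray:
    """One row of the transition matrix for the coming annual cycle.

    Cancer states never return to no-cancer and never switch stage; death
    states are absorbing.  The joint within-cycle death probability is
    allocated to the two causes in proportion to their hazards.
    """
    row = np.zeros(N_STATES)
    if state in (State.CANCER_DEATH, State.NONCANCER_DEATH):
        row[state] = 1.0
        return row
    if state is State.EARLY_CANCER and stage is None:
        stage = Stage.EARLY
    if state is State.LATE_CANCER and stage is None:
        stage = Stage.LATE
    h_c, h_nc = _cause_hazards(state, age, t_since_dx, params, cancer_type, stage)
    total = h_c + h_nc
    p_dead = 1.0 - math.exp(-total)
    if total > 0:
        p_cancer_death = p_dead * h_c / total
        p_other_death = p_dead * h_nc / total
    else:
        p_cancer_death = p_other_death = 0.0
    row[State.CANCER_DEATH] = p_cancer_death
    row[State.NONCANCER_DEATH] = p_other_death
    row[state] = 1.0 - p_cancer_death - p_other_death
    return row


def run_cohort(
    entry_mix: np.ndarray,
    entry_age: int,
    params: MarkovParameters,
    cancer_type: CancerType | None = None,
) -> Trajectory:
    """Project a cohort from its entry age to the maximum age.

    ``entry_mix`` is the occupancy over the five states at entry; cancer-state
    occupants are newly diagnosed (time since diagnosis 0 in cycle 0).  The
    projection is deterministic.
    """
    entry_mix = np.asarray(entry_mix, dtype=float)
    if entry_mix.shape != (N_STATES,):
        raise ValueError("entry mix must have five states")
    if abs(entry_mix.sum() - 1.0) > 1e-9:
        raise ValueError("entry mix must sum to 1")
    if entry_mix[[State.EARLY_CANCER, State.LATE_CANCER]].sum() > 0 and cancer_type is None:
        raise ValueError("cancer entry states require a cancer type")
    n_cycles = params.spec.max_age - int(entry_age) + 1
    if n_cycles < 1:
        raise ValueError("entry age must be below the maximum age")
    occ = np.empty((n_cycles, N_STATES))
    occ[0] = entry_mix
    for t in range(n_cycles - 1):
        age = entry_age + t
        nxt = np.zeros(N_STATES)
        for state in State:
            mass = occ[t, state]
            if mass == 0.0:
                continue
            row = build_transition_row(state, age, float(t), params, cancer_type)
            nxt += mass * row
        occ[t + 1] = nxt
    return Trajectory(entry_age=int(entry_age), occupancy=occ, cancer_type=cancer_type)


def _discount_factors(n: int, rate: float) -> np.ndarray:
    # cycle 0 undiscounted
    return (1.0 + rate) ** -np.arange(n, dtype=float)


def lifetime_outcomes(
    trajectory: Trajectory,
    params: MarkovParameters,
) -> tuple[float, float, float]:
    """Discounted (QALYs, life-years, inpatient costs) over the trajectory.

    Per cycle, live-state occupancy accrues the state utility at the current
    age (and, for cancer states, time since diagnosis) and the state's annual
    cost; streams are discounted at the configured rates with the entry cycle
    undiscounted.
    """
    spec = params.spec
    occ = trajectory.occupancy
    n = trajectory.n_cycles
    ages = trajectory.ages()
    dq = _discount_factors(n, spec.discount_qaly)
    dc = _discount_factors(n, spec.discount_cost)
    util = params.utility_model
    cost = params.cost_model
    ctype = trajectory.cancer_type
    qalys = lys = total_cost = 0.0
    state_stage = {
        State.NO_CANCER: None,
        State.EARLY_CANCER: Stage.EARLY,
        State.LATE_CANCER: Stage.LATE,
    }
    for t in range(n):
        age = float(ages[t])
        live = 0.0
        u_cycle = 0.0
        c_cycle = 0.0
        for state in LIVE_STATES:
            mass = occ[t, state]
            if mass == 0.0:
                continue
            live += mass
            u_cycle += mass * util.state_utility(state, age, float(t), ctype)
            c_cycle += mass * cost.annual_cost(state, float(t), ctype, state_stage[state])
        w = 0.5 if (spec.half_cycle_correction and t == 0) else 1.0
        qalys += w * dq[t] * u_cycle
        lys += w * dq[t] * live
        total_cost += w * dc[t] * c_cycle
    return qalys, lys, total_cost


def surgery_qaly_delta(trajectory: Trajectory, params: MarkovParameters) -> float:
    """Discounted QALY change from benign surgery, per woman operated on.

    The disutility applies in the surgery (entry) year, the annual gain in
    every later year the woman is alive, following her no-cancer survival.
    """
    util = params.utility_model
    alive = trajectory.occupancy[:, list(LIVE_STATES)].sum(axis=1)
    dq = _discount_factors(trajectory.n_cycles, params.spec.discount_qaly)
    delta = -util.surgery_disutility * alive[0] * dq[0]
    if trajectory.n_cycles > 1:
        delta += util.surgery_gain * float(np.sum(alive[1:] * dq[1:]))
    return float(delta)
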