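"""Synthetic stand-ins for the registry-fitted model inputs.

The published evaluation drew its survival, cost and quality-of-life inputs
from fitted regression models on linked UK primary-care, hospital and cancer
registry data, which cannot be redistributed.  This module generates
calibrated synthetic replacements for every such input so the full pipeline
runs with no external data:

* stage-specific cancer survival, exponential by default, pinned exactly to
  published five-year survival anchors (95% for stage I ovarian cancer, 16%
  for stage IV);
* a cause-partitioned female life table (Gompertz-Makeham all-cause mortality
  split into cancer and non-cancer parts by a smooth age-dependent fraction);
* hospital inpatient cost step-curves by cancer type, stage and years since
  diagnosis;
* an age-declining EQ-5D-style utility model with cancer decrements by
  recency of diagnosis;
* the two population strata with the published sizes, one-year cancer
  prevalences and late-stage proportions.

Survival, cost and utility values for non-ovarian cancers are synthetic
placeholders: they set absolute outcome levels but, being pathway-invariant,
cancel out of base-case increments between pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .accuracy import AccuracyTable, AgeGroup, load_default_accuracy
from .decision_tree import PopulationStratum, StageShiftParams, UnitCosts
from .markov import (
    CancerType,
    CostModel,
    ExponentialSurvival,
    LifeTable,
    MarkovParameters,
    MarkovSpec,
    Stage,
    UtilityModel,
)

__all__ = [
    "SyntheticProfile",
    "default_population",
    "synth_survival",
    "synth_life_table",
    "synth_qol_params",
    "synth_cost_models",
    "default_profile",
    "write_profile",
    "read_profile",
]

# Published stratum headers: size, 1-year invasive OC prevalence, late-stage share.
STRATUM_UNDER50 = dict(n_women=112_081, oc_prevalence=0.002, late_stage_prop=0.46)
STRATUM_GE50 = dict(n_women=164_746, oc_prevalence=0.0105, late_stage_prop=0.72)

# Whole-population 1-year prevalence of other cancers among CA125-tested women.
OTHER_CANCER_PREVALENCE = {
    CancerType.LOWER_GI.value: 0.0048,
    CancerType.UTERINE.value: 0.0025,
    CancerType.LUNG.value: 0.0021,
    CancerType.PANCREATIC.value: 0.0016,
    CancerType.OTHER.value: 0.010,
}

AGE_MEAN, AGE_SD = 54.6, 15.8
AGE_MIN, AGE_MAX = 18, 99

# Five-year survival anchors per cancer type and stage.  The ovarian figures
# are the published stage I / stage IV survival rates; the rest are synthetic
# placeholders with the early >= late calibration constraint.
DEFAULT_SURVIVAL_ANCHORS: dict[tuple[CancerType, Stage], tuple[float, float]] = {
    (CancerType.OVARIAN, Stage.EARLY): (5.0, 0.95),
    (CancerType.OVARIAN, Stage.LATE): (5.0, 0.16),
    (CancerType.LOWER_GI, Stage.EARLY): (5.0, 0.65),
    (CancerType.LOWER_GI, Stage.LATE): (5.0, 0.12),
    (CancerType.UTERINE, Stage.EARLY): (5.0, 0.92),
    (CancerType.UTERINE, Stage.LATE): (5.0, 0.25),
    (CancerType.LUNG, Stage.EARLY): (5.0, 0.45),
    (CancerType.LUNG, Stage.LATE): (5.0, 0.04),
    (CancerType.PANCREATIC, Stage.EARLY): (5.0, 0.30),
    (CancerType.PANCREATIC, Stage.LATE): (5.0, 0.02),
    (CancerType.OTHER, Stage.EARLY): (5.0, 0.70),
    (CancerType.OTHER, Stage.LATE): (5.0, 0.20),
}

# Synthetic annual inpatient costs (GBP) by years since diagnosis (0..3, 4+).
DEFAULT_COST_CURVES: dict[tuple[CancerType, Stage], tuple[float, ...]] = {
    (CancerType.OVARIAN, Stage.EARLY): (15_000, 5_000, 3_000, 2_000, 1_200),
    (CancerType.OVARIAN, Stage.LATE): (25_000, 11_000, 6_500, 4_000, 2_500),
    (CancerType.LOWER_GI, Stage.EARLY): (14_000, 4_500, 2_500, 1_800, 1_000),
    (CancerType.LOWER_GI, Stage.LATE): (22_000, 9_000, 5_500, 3_500, 2_000),
    (CancerType.UTERINE, Stage.EARLY): (10_000, 3_000, 1_800, 1_200, 800),
    (CancerType.UTERINE, Stage.LATE): (18_000, 7_000, 4_000, 2_800, 1_700),
    (CancerType.LUNG, Stage.EARLY): (16_000, 6_000, 3_500, 2_500, 1_500),
    (CancerType.LUNG, Stage.LATE): (24_000, 10_000, 6_000, 4_000, 2_400),
    (CancerType.PANCREATIC, Stage.EARLY): (17_000, 6_500, 3_800, 2_600, 1_600),
    (CancerType.PANCREATIC, Stage.LATE): (26_000, 11_500, 7_000, 4_500, 2_800),
    (CancerType.OTHER, Stage.EARLY): (12_000, 4_000, 2_200, 1_500, 900),
    (CancerType.OTHER, Stage.LATE): (20_000, 8_000, 5_000, 3_200, 1_900),
}

# Synthetic utility decrements (within 1 year of diagnosis, later years).
DEFAULT_UTILITY_DECREMENTS: dict[CancerType, tuple[float, float]] = {
    CancerType.OVARIAN: (0.10, 0.040),
    CancerType.LOWER_GI: (0.09, 0.035),
    CancerType.UTERINE: (0.08, 0.030),
    CancerType.LUNG: (0.13, 0.060),
    CancerType.PANCREATIC: (0.14, 0.060),
    CancerType.OTHER: (0.08, 0.030),
}

# Gompertz-Makeham female all-cause mortality mu(age) = A + B exp(C age).
GM_A, GM_B, GM_C = 2.0e-4, 2.5e-5, 0.098


def _age_weights(lower: int, upper: int) -> dict[int, float]:
    """Truncated-normal weights over integer ages in [lower, upper]."""
    a = (AGE_MIN - AGE_MEAN) / AGE_SD
    b = (AGE_MAX - AGE_MEAN) / AGE_SD
    ages = np.arange(lower, upper + 1)
    w = truncnorm.pdf(ages, a, b, loc=AGE_MEAN, scale=AGE_SD)
    w = w / w.sum()
    return {int(age): float(wi) for age, wi in zip(ages, w)}


def default_population(other_cancer_age_gradient: float = 0.5) -> list[PopulationStratum]:
    """The two published strata of CA125-tested women.

    ``other_cancer_age_gradient`` is the under-50 multiplier applied to the
    whole-population other-cancer prevalences; the over-50 multiplier is then
    fixed so that the population-weighted mean reproduces the whole-population
    figures.
    """
    n_u, n_g = STRATUM_UNDER50["n_women"], STRATUM_GE50["n_women"]
    w_u = n_u / (n_u + n_g)
    mult_u = other_cancer_age_gradient
    mult_g = (1.0 - w_u * mult_u) / (1.0 - w_u)
    under50 = PopulationStratum(
        age_group=AgeGroup.UNDER50,
        other_cancer_prevalences={k: v * mult_u for k, v in OTHER_CANCER_PREVALENCE.items()},
        age_weights=_age_weights(AGE_MIN, 49),
        **STRATUM_UNDER50,
    )
    ge50 = PopulationStratum(
        age_group=AgeGroup.GE50,
        other_cancer_prevalences={k: v * mult_g for k, v in OTHER_CANCER_PREVALENCE.items()},
        age_weights=_age_weights(50, AGE_MAX),
        **STRATUM_GE50,
    )
    return [under50, ge50]


def synth_survival(
    anchors: dict[tuple[CancerType, Stage], tuple[float, float]] | None = None,
) -> dict[tuple[CancerType, Stage], ExponentialSurvival]:
    """Exponential survival models solving S(t) = anchor exactly."""
    anchors = dict(DEFAULT_SURVIVAL_ANCHORS if anchors is None else anchors)
    models = {}
    for key, (t, s) in anchors.items():
        models[key] = ExponentialSurvival.from_anchor(t, s)
    for ctype in CancerType:
        early = models.get((ctype, Stage.EARLY))
        late = models.get((ctype, Stage.LATE))
        if early is not None and late is not None and late.rate < early.rate:
            raise ValueError(f"late-stage hazard below early-stage hazard for {ctype.value}")
    return models


def _cancer_fraction(age: np.ndarray) -> np.ndarray:
    """Smooth age-dependent share of all-cause mortality attributed to cancer."""
    return 0.05 + 0.30 * np.exp(-(((age - 62.0) / 25.0) ** 2))


def synth_life_table(max_age: int = 110) -> LifeTable:
    """Deterministic cause-partitioned female life table."""
    ages = np.arange(0, max_age + 1)
    total = GM_A + GM_B * np.exp(GM_C * ages)
    frac = _cancer_fraction(ages.astype(float))
    return LifeTable(ages, cancer_rate=frac * total, noncancer_rate=(1.0 - frac) * total)


def synth_qol_params(late_stage_extra: float = 0.046) -> UtilityModel:
    """Age-declining utility with cancer decrements and surgery effects."""
    return UtilityModel(
        decrements=dict(DEFAULT_UTILITY_DECREMENTS),
        late_stage_extra=late_stage_extra,
    )


def synth_cost_models(background: float = 500.0) -> CostModel:
    """Step-function inpatient cost curves; early-stage never above late at entry."""
    curves = dict(DEFAULT_COST_CURVES)
    for ctype in CancerType:
        if curves[(ctype, Stage.LATE)][0] < curves[(ctype, Stage.EARLY)][0]:
            raise ValueError(f"year-0 late cost below early cost for {ctype.value}")
    return CostModel(curves=curves, background=background)


@dataclass(frozen=True)
class SyntheticProfile:
    """Complete synthetic parametrization of the decision model."""

    strata: list[PopulationStratum]
    accuracy: AccuracyTable
    survival_models: dict[tuple[CancerType, Stage], ExponentialSurvival]
    life_table: LifeTable
    cost_model: CostModel
    utility_model: UtilityModel
    unit_costs: UnitCosts = UnitCosts()
    stage_shift: StageShiftParams = StageShiftParams()
    spec: MarkovSpec = MarkovSpec()
    seed: int = 0

    def markov_parameters(self) -> MarkovParameters:
        return MarkovParameters(
            survival_models=self.survival_models,
            life_table=self.life_table,
            utility_model=self.utility_model,
            cost_model=self.cost_model,
            spec=self.spec,
        )

    def stratum(self, age_group: AgeGroup) -> PopulationStratum:
        for s in self.strata:
            if s.age_group is AgeGroup(age_group):
                return s
        raise KeyError(f"no stratum for age group {age_group}")

    def with_spec(self, **changes) -> "SyntheticProfile":
        return replace(self, spec=replace(self.spec, **changes))


def default_profile(seed: int = 0) -> SyntheticProfile:
    """The base-case synthetic parametrization.

    The base case is fully deterministic; the seed only feeds downstream
    stochastic analyses (probabilistic sensitivity analysis).
    """
    return SyntheticProfile(
        strata=default_population(),
        accuracy=load_default_accuracy(),
        survival_models=synth_survival(),
        life_table=synth_life_table(),
        cost_model=synth_cost_models(),
        utility_model=synth_qol_params(),
        seed=seed,
    )


# --- delimited-file round-trip ---------------------------------------------


def write_profile(profile: SyntheticProfile, out_dir: str | Path) -> dict[str, Path]:
    """Emit the profile as the delimited parameter files the model consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    acc = pd.DataFrame(
        [
            {
                "test_id": r.test_id.value,
                "age_group": r.age_group.value,
                "threshold_label": r.threshold_label,
                "sensitivity": r.sensitivity,
                "sens_ci_low": r.sens_ci[0] if r.sens_ci else np.nan,
                "sens_ci_high": r.sens_ci[1] if r.sens_ci else np.nan,
                "specificity": r.specificity,
                "spec_ci_low": r.spec_ci[0] if r.spec_ci else np.nan,
                "spec_ci_high": r.spec_ci[1] if r.spec_ci else np.nan,
            }
            for r in profile.accuracy.rows()
        ]
    )
    paths["accuracy"] = out / "test_accuracy.csv"
    acc.to_csv(paths["accuracy"], index=False)

    paths["life_table"] = out / "life_table.csv"
    profile.life_table.to_frame().to_csv(paths["life_table"], index=False)

    surv = pd.DataFrame(
        [
            {"cancer_type": c.value, "stage": s.value, "hazard": m.rate, "source": "synthetic"}
            for (c, s), m in profile.survival_models.items()
        ]
    )
    paths["survival"] = out / "survival_models.csv"
    surv.to_csv(paths["survival"], index=False)

    cost_rows = []
    for (c, s), curve in profile.cost_model.curves.items():
        for year, value in enumerate(curve):
            cost_rows.append(
                {"cancer_type": c.value, "stage": s.value, "year_since_dx": year,
                 "annual_cost": value, "source": "synthetic"}
            )
    cost_rows.append(
        {"cancer_type": "NONE", "stage": "NONE", "year_since_dx": 0,
         "annual_cost": profile.cost_model.background, "source": "synthetic"}
    )
    paths["costs"] = out / "cost_curves.csv"
    pd.DataFrame(cost_rows).to_csv(paths["costs"], index=False)

    um = profile.utility_model
    util_rows = [
        {"parameter": "base_intercept", "value": um.base_intercept},
        {"parameter": "base_age_slope", "value": um.base_age_slope},
        {"parameter": "base_age_ref", "value": um.base_age_ref},
        {"parameter": "late_stage_extra", "value": um.late_stage_extra},
        {"parameter": "surgery_disutility", "value": um.surgery_disutility},
        {"parameter": "surgery_gain", "value": um.surgery_gain},
    ]
    for ctype, (recent, later) in um.decrements.items():
        util_rows.append({"parameter": f"decrement_recent_{ctype.value}", "value": recent})
        util_rows.append({"parameter": f"decrement_later_{ctype.value}", "value": later})
    paths["utility"] = out / "utility_model.csv"
    pd.DataFrame(util_rows).to_csv(paths["utility"], index=False)

    strata_rows = []
    for s in profile.strata:
        strata_rows.append(
            {
                "age_group": s.age_group.value,
                "n_women": s.n_women,
                "oc_prevalence": s.oc_prevalence,
                "late_stage_prop": s.late_stage_prop,
                **{f"prev_{k}": v for k, v in s.other_cancer_prevalences.items()},
            }
        )
    paths["strata"] = out / "strata.csv"
    pd.DataFrame(strata_rows).to_csv(paths["strata"], index=False)
    return paths


def read_profile(in_dir: str | Path, seed: int = 0) -> SyntheticProfile:
    """Rebuild a profile from files written by :func:`write_profile`.

    Age weights are regenerated from the documented truncated-normal default
    (they are derived quantities, not fitted inputs).
    """
    d = Path(in_dir)
    accuracy = AccuracyTable.from_csv(d / "test_accuracy.csv")
    lt = pd.read_csv(d / "life_table.csv")
    life_table = LifeTable(
        lt["age"].to_numpy(), lt["cancer_rate"].to_numpy(), lt["noncancer_rate"].to_numpy()
    )
    surv = pd.read_csv(d / "survival_models.csv")
    survival = {
        (CancerType(r.cancer_type), Stage(r.stage)): ExponentialSurvival(rate=float(r.hazard))
        for r in surv.itertuples()
    }
    costs = pd.read_csv(d / "cost_curves.csv")
    curves: dict[tuple[CancerType, Stage], tuple[float, ...]] = {}
    background = 0.0
    for (ctype, stage), grp in costs.groupby(["cancer_type", "stage"]):
        if ctype == "NONE":
            background = float(grp["annual_cost"].iloc[0])
            continue
        grp = grp.sort_values("year_since_dx")
        curves[(CancerType(ctype), Stage(stage))] = tuple(grp["annual_cost"].astype(float))
    util = pd.read_csv(d / "utility_model.csv").set_index("parameter")["value"]
    decrements = {}
    for ctype in CancerType:
        decrements[ctype] = (
            float(util[f"decrement_recent_{ctype.value}"]),
            float(util[f"decrement_later_{ctype.value}"]),
        )
    utility = UtilityModel(
        base_intercept=float(util["base_intercept"]),
        base_age_slope=float(util["base_age_slope"]),
        base_age_ref=float(util["base_age_ref"]),
        decrements=decrements,
        late_stage_extra=float(util["late_stage_extra"]),
        surgery_disutility=float(util["surgery_disutility"]),
        surgery_gain=float(util["surgery_gain"]),
    )
    strata_df = pd.read_csv(d / "strata.csv")
    strata = []
    for r in strata_df.to_dict("records"):
        ag = AgeGroup(r["age_group"])
        bounds = (AGE_MIN, 49) if ag is AgeGroup.UNDER50 else (50, AGE_MAX)
        strata.append(
            PopulationStratum(
                age_group=ag,
                n_women=int(r["n_women"]),
                oc_prevalence=float(r["oc_prevalence"]),
                late_stage_prop=float(r["late_stage_prop"]),
                other_cancer_prevalences={
                    k.removeprefix("prev_"): float(v)
                    for k, v in r.items()
                    if k.startswith("prev_")
                },
                age_weights=_age_weights(*bounds),
            )
        )
    return SyntheticProfile(
        strata=strata,
        accuracy=accuracy,
        survival_models=survival,
        life_table=life_table,
        cost_model=CostModel(curves=curves, background=background),
        utility_model=utility,
        seed=seed,
    )
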