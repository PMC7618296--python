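"""Cost-effectiveness analysis over the six triage pathways.

Combines the decision-tree outcome classes with the lifetime Markov
projections into per-pathway discounted QALYs, life-years and costs per 1000
women, then runs the incremental analysis: pairwise differences against
current practice, the ICER frontier with (extended) dominance pruning,
probabilistic sensitivity analysis, cost-effectiveness acceptability curves,
and the two-way Ovatools risk-threshold sweep.

Because every stochastic parameter of the probabilistic analysis (test
accuracy, the late-stage relative risk, the benign-surgery utility effects)
enters the model through the decision-tree weights or the surgery utility
adjustment — never through the Markov hazards or cost curves — the per-class
Markov outcome library is computed once per stratum and reused across draws;
each draw is still a full model evaluation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .accuracy import AgeGroup, ROCCurve, TestId, ovatools_roc, roc_interpolate, SWEEP_RANGE
from .decision_tree import (
    DiagnosticOutcome,
    PathwayDefinition,
    PathwayMode,
    PopulationStratum,
    StageShiftParams,
    apply_stage_shift,
    evaluate_pathway,
    expected_primary_care_cost,
    fp_secondary_cost,
    standard_pathways,
)
from .markov import (
    CancerType,
    MarkovParameters,
    Stage,
    State,
    LIVE_STATES,
    run_cohort,
    lifetime_outcomes,
    _discount_factors,
)
from .synthetic_data import SyntheticProfile

__all__ = [
    "CEResult",
    "FrontierResult",
    "PSAResult",
    "CEACCurve",
    "OutcomeLibrary",
    "ParameterDistributionError",
    "pathway_ce",
    "evaluate_all_pathways",
    "incremental",
    "icer_frontier",
    "net_benefit",
    "run_psa",
    "ceac",
    "threshold_sweep",
    "VARIANT_PAIRS",
]

# Ovatools pathways and their accuracy-equivalent age-adjusted CA125 twins are
# not compared with each other on the frontier.
VARIANT_PAIRS: tuple[tuple[int, int], ...] = ((2, 3), (4, 5))

# Stage split assumed for non-ovarian cancers (synthetic placeholder; these
# cancers are pathway-invariant in the base case, so the split cancels out of
# all increments).
OTHER_CANCER_LATE_PROP = 0.5


class ParameterDistributionError(ValueError):
    """A confidence interval inconsistent with the parameter's support."""


@dataclass(frozen=True)
class CEResult:
    """Per-pathway discounted outcomes, scaled to 1000 women."""

    pathway_id: int
    qalys_per_1000: float
    lys_per_1000: float
    costs_per_1000: float
    detection_rate: float | None
    referral_rate: float
    cost_breakdown: dict[str, float] = field(default_factory=dict)


@dataclass
class OutcomeLibrary:
    """Age-weighted discounted Markov outcomes per entry class for a stratum.

    ``cancer[(type, stage)]`` and ``no_cancer`` hold (QALY, LY, cost) per
    woman entering that class; ``surgery_year0``/``surgery_annuity`` are the
    discounted survival weights the benign-surgery utility effects multiply.
    """

    stratum: PopulationStratum
    cancer: dict[tuple[CancerType, Stage], tuple[float, float, float]]
    no_cancer: tuple[float, float, float]
    surgery_year0: float
    surgery_annuity: float

    @classmethod
    def build(cls, stratum: PopulationStratum, params: MarkovParameters) -> "OutcomeLibrary":
        weights = stratum.age_weights or {55: 1.0}
        cancer: dict[tuple[CancerType, Stage], np.ndarray] = {
            key: np.zeros(3) for key in params.survival_models
        }
        no_cancer = np.zeros(3)
        surg0 = 0.0
        annuity = 0.0
        entry = {
            Stage.EARLY: np.array([0.0, 1.0, 0.0, 0.0, 0.0]),
            Stage.LATE: np.array([0.0, 0.0, 1.0, 0.0, 0.0]),
        }
        nc_entry = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        for age, w in weights.items():
            for (ctype, stage) in params.survival_models:
                traj = run_cohort(entry[stage], age, params, cancer_type=ctype)
                cancer[(ctype, stage)] += w * np.array(lifetime_outcomes(traj, params))
            traj = run_cohort(nc_entry, age, params, cancer_type=None)
            no_cancer += w * np.array(lifetime_outcomes(traj, params))
            alive = traj.occupancy[:, list(LIVE_STATES)].sum(axis=1)
            dq = _discount_factors(traj.n_cycles, params.spec.discount_qaly)
            surg0 += w * alive[0] * dq[0]
            annuity += w * float(np.sum(alive[1:] * dq[1:]))
        return cls(
            stratum=stratum,
            cancer={k: tuple(v) for k, v in cancer.items()},
            no_cancer=tuple(no_cancer),
            surgery_year0=surg0,
            surgery_annuity=annuity,
        )

    def surgery_qaly_delta(self, disutility: float, gain: float) -> float:
        return -disutility * self.surgery_year0 + gain * self.surgery_annuity


def _staged_outcomes(
    library: OutcomeLibrary, ctype: CancerType, late_prop: float
) -> np.ndarray:
    early = np.array(library.cancer[(ctype, Stage.EARLY)])
    late = np.array(library.cancer[(ctype, Stage.LATE)])
    return (1.0 - late_prop) * early + late_prop * late


def pathway_ce(
    pathway: PathwayDefinition,
    stratum: PopulationStratum,
    profile: SyntheticProfile,
    library: OutcomeLibrary | None = None,
    accuracy=None,
    shift: StageShiftParams | None = None,
    surgery_effects: tuple[float, float] | None = None,
    reference_pathway: PathwayDefinition | None = None,
) -> CEResult:
    """Full cost-effectiveness result for one pathway on one stratum.

    The four decision-tree classes (true positives with post-shift staging,
    false negatives with usual-care staging, other-cancer and benign women)
    are weighted by their probabilities and routed through the Markov model;
    primary-care journey costs, and secondary-care workup costs for referred
    women without a cancer diagnosis, are added on top of inpatient costs.
    """
    accuracy = accuracy if accuracy is not None else profile.accuracy
    shift = shift if shift is not None else profile.stage_shift
    um = profile.utility_model
    surgery_effects = surgery_effects or (um.surgery_disutility, um.surgery_gain)
    if library is None:
        library = OutcomeLibrary.build(stratum, profile.markov_parameters())
    reference_pathway = reference_pathway or standard_pathways()[1]

    outcome = evaluate_pathway(pathway, accuracy, stratum)
    ref = evaluate_pathway(reference_pathway, accuracy, stratum)
    outcome = apply_stage_shift(outcome, ref, shift, stratum)

    # health outcomes and inpatient costs
    oc_detected = _staged_outcomes(library, CancerType.OVARIAN, outcome.late_stage_prop_detected)
    oc_missed = _staged_outcomes(library, CancerType.OVARIAN, outcome.late_stage_prop_missed)
    totals = outcome.p_tp * oc_detected + outcome.p_fn * oc_missed
    for ctype_name, prev in stratum.other_cancer_prevalences.items():
        ctype = CancerType(ctype_name)
        totals = totals + prev * _staged_outcomes(library, ctype, OTHER_CANCER_LATE_PROP)
    benign_prev = stratum.benign_prevalence
    totals = totals + benign_prev * np.array(library.no_cancer)

    # benign-surgery utility effects for referred women without cancer
    refer_given_no_oc = outcome.p_fp / (1.0 - stratum.oc_prevalence)
    benign_referred = benign_prev * refer_given_no_oc
    n_surgery = benign_referred * profile.unit_costs.benign_surgery_rate
    qaly_surgery = n_surgery * library.surgery_qaly_delta(*surgery_effects)

    primary = expected_primary_care_cost(pathway, accuracy, stratum, profile.unit_costs)
    fp_cost = benign_referred * fp_secondary_cost(profile.unit_costs)
    inpatient = totals[2]
    qalys = totals[0] + qaly_surgery
    lys = totals[1]
    cost = inpatient + primary + fp_cost
    return CEResult(
        pathway_id=pathway.id,
        qalys_per_1000=1000.0 * qalys,
        lys_per_1000=1000.0 * lys,
        costs_per_1000=1000.0 * cost,
        detection_rate=outcome.detection_rate,
        referral_rate=outcome.referral_rate,
        cost_breakdown={
            "primary_care": 1000.0 * primary,
            "fp_secondary": 1000.0 * fp_cost,
            "inpatient": 1000.0 * inpatient,
        },
    )


def evaluate_all_pathways(
    stratum: PopulationStratum,
    profile: SyntheticProfile,
    library: OutcomeLibrary | None = None,
    pathway_ids: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
) -> dict[int, CEResult]:
    if library is None:
        library = OutcomeLibrary.build(stratum, profile.markov_parameters())
    defs = standard_pathways()
    return {
        pid: pathway_ce(defs[pid], stratum, profile, library=library) for pid in pathway_ids
    }


def incremental(
    results: dict[int, CEResult], comparator_id: int = 1
) -> dict[int, tuple[float, float]]:
    """(QALY, cost) differences per 1000 women against the comparator."""
    if comparator_id not in results:
        raise KeyError(f"comparator pathway {comparator_id} missing from results")
    base = results[comparator_id]
    return {
        pid: (r.qalys_per_1000 - base.qalys_per_1000, r.costs_per_1000 - base.costs_per_1000)
        for pid, r in results.items()
    }


# --- ICER frontier ----------------------------------------------------------


@dataclass
class FrontierResult:
    """Dominance-pruned ICER ladder over a set of options."""

    order: list[int]                       # option ids by increasing cost
    on_frontier: set[int]
    dominated: set[int]
    extendedly_dominated: set[int]
    icers: dict[int, tuple[int, float]]    # id -> (comparator id, ICER GBP/QALY)
    ties: set[int] = field(default_factory=set)


def _as_points(results) -> list[tuple[int, float, float]]:
    if isinstance(results, dict):
        items = results.items()
        pts = []
        for pid, val in items:
            if isinstance(val, CEResult):
                pts.append((pid, val.qalys_per_1000, val.costs_per_1000))
            else:
                q, c = val
                pts.append((pid, float(q), float(c)))
        return pts
    pts = []
    for val in results:
        if isinstance(val, CEResult):
            pts.append((val.pathway_id, val.qalys_per_1000, val.costs_per_1000))
        else:
            pts.append((int(val[0]), float(val[1]), float(val[2])))
    return pts


def _standard_frontier(points: list[tuple[int, float, float]]) -> FrontierResult:
    order = [pid for pid, _, _ in sorted(points, key=lambda p: (p[2], -p[1], p[0]))]
    q = {pid: qq for pid, qq, _ in points}
    c = {pid: cc for pid, _, cc in points}
    dominated: set[int] = set()
    ties: set[int] = set()
    for pid, qi, ci in points:
        for pjd, qj, cj in points:
            if pid == pjd:
                continue
            if qj == qi and cj == ci:
                if pjd < pid:
                    dominated.add(pid)  # keep the lower pathway id
                    ties.add(pid)
                    ties.add(pjd)
                continue
            if qj >= qi and cj <= ci:
                dominated.add(pid)
    survivors = [pid for pid in order if pid not in dominated]
    ext: set[int] = set()
    # iteratively remove options producing a non-increasing ICER sequence
    while len(survivors) > 2:
        icers = []
        for a, b in zip(survivors, survivors[1:]):
            dq = q[b] - q[a]
            icers.append(math.inf if dq == 0 else (c[b] - c[a]) / dq)
        removed = False
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                ext.add(survivors[k + 1])
                survivors.pop(k + 1)
                removed = True
                break
        if not removed:
            break
    icers_out: dict[int, tuple[int, float]] = {}
    for a, b in zip(survivors, survivors[1:]):
        dq = q[b] - q[a]
        icers_out[b] = (a, math.inf if dq == 0 else (c[b] - c[a]) / dq)
    return FrontierResult(
        order=order,
        on_frontier=set(survivors),
        dominated=dominated,
        extendedly_dominated=ext,
        icers=icers_out,
        ties=ties,
    )


def icer_frontier(results, variant_pairs: tuple[tuple[int, int], ...] | None = None) -> FrontierResult:
    """ICER frontier with strict and extended dominance pruning.

    ``variant_pairs`` lists pairs of options that are parallel variants of one
    another (the Ovatools pathway and its accuracy-equivalent age-adjusted
    twin) and are never compared with each other: each member is assessed on
    the frontier built without its twin, and reported against the shared
    lower neighbour.
    """
    points = _as_points(results)
    if len(points) < 1:
        raise ValueError("at least one option is required")
    ids = {pid for pid, _, _ in points}
    if not variant_pairs:
        return _standard_frontier(points)
    pairs = [(a, b) for a, b in variant_pairs if a in ids and b in ids]
    if not pairs:
        return _standard_frontier(points)
    # one frontier per selection of a single member from each variant pair;
    # an option's flags come from the branches that contain it
    from itertools import product

    branch_results: list[tuple[set[int], FrontierResult]] = []
    for choice in product(*pairs):
        subset = [
            p
            for p in points
            if all(p[0] not in pair or p[0] in choice for pair in pairs)
        ]
        branch_results.append(({p[0] for p in subset}, _standard_frontier(subset)))
    merged = FrontierResult(
        order=[pid for pid, _, _ in sorted(points, key=lambda p: (p[2], -p[1], p[0]))],
        on_frontier=set(),
        dominated=set(),
        extendedly_dominated=set(),
        icers={},
        ties=set(),
    )
    for pid in ids:
        relevant = [fr for sids, fr in branch_results if pid in sids]
        if any(pid in fr.on_frontier for fr in relevant):
            merged.on_frontier.add(pid)
        elif all(pid in fr.dominated for fr in relevant):
            merged.dominated.add(pid)
        elif all(pid in fr.dominated | fr.extendedly_dominated for fr in relevant):
            merged.extendedly_dominated.add(pid)
        if any(pid in fr.ties for fr in relevant):
            merged.ties.add(pid)
        for fr in relevant:
            if pid in fr.icers and pid not in merged.icers:
                merged.icers[pid] = fr.icers[pid]
    return merged


def net_benefit(delta_qaly: float, delta_cost: float, lam: float) -> float:
    """Net monetary benefit at willingness-to-pay ``lam`` (GBP per QALY)."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return lam * delta_qaly - delta_cost


# --- probabilistic sensitivity analysis -------------------------------------


def _beta_params(mean: float, ci: tuple[float, float]) -> tuple[float, float]:
    lo, hi = ci
    if not (0.0 <= lo <= mean <= hi <= 1.0):
        raise ParameterDistributionError(f"CI {ci} inconsistent with [0,1] support at mean {mean}")
    sd = (hi - lo) / (2 * 1.959963984540054)
    if sd == 0:
        raise ParameterDistributionError("zero-width CI")
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ParameterDistributionError(f"CI {ci} too wide for beta at mean {mean}")
    return mean * nu, (1.0 - mean) * nu


def _lognormal_params(mean_ratio: float, ci: tuple[float, float]) -> tuple[float, float]:
    lo, hi = ci
    if not 0 < lo <= mean_ratio <= hi:
        raise ParameterDistributionError(f"CI {ci} inconsistent with ratio {mean_ratio}")
    mu = math.log(mean_ratio)
    sigma = (math.log(hi) - math.log(lo)) / (2 * 1.959963984540054)
    return mu, sigma


class _DrawnAccuracy:
    """Accuracy provider serving per-draw sensitivity/specificity values."""

    def __init__(self, base, overrides: dict[tuple[TestId, AgeGroup, str], tuple[float, float]]):
        self._base = base
        self._overrides = overrides

    def lookup(self, test_id, age_group, label):
        test_id = TestId(test_id)
        age_group = AgeGroup(age_group)
        if test_id is TestId.USS:
            key = (TestId.USS, AgeGroup.ALL, "abnormal")
            if key in self._overrides:
                return self._overrides[key]
        key = (test_id, age_group, label)
        if key in self._overrides:
            return self._overrides[key]
        if test_id is TestId.AGE_ADJ_CA125:
            alt = (TestId.OVATOOLS, age_group, label)
            if alt in self._overrides:
                return self._overrides[alt]
        return self._base.lookup(test_id, age_group, label)


@dataclass
class PSAResult:
    """Per-draw parameter sets and per-pathway (QALY, cost) pairs per 1000."""

    n_draws: int
    seed: int
    stratum: PopulationStratum
    draws: pd.DataFrame
    results: dict[int, np.ndarray]  # id -> (n_draws, 2) array of (QALY, cost)


def run_psa(
    profile: SyntheticProfile,
    stratum: PopulationStratum,
    n: int = 1000,
    seed: int | None = None,
    pathway_ids: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    library: OutcomeLibrary | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis with parametric Monte Carlo draws.

    Sensitivities, specificities and other probabilities are drawn from beta
    distributions matched by method of moments to the published point
    estimates and 95% confidence intervals; the late-stage relative risk from
    a lognormal matched to its interval (draws above 1 are capped with a
    warning); the benign-surgery utility effects from normals.  Parameters
    published without uncertainty are held fixed.
    """
    seed = profile.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if library is None:
        library = OutcomeLibrary.build(stratum, profile.markov_parameters())

    draw_cols: dict[str, np.ndarray] = {}
    acc_draws: dict[tuple[TestId, AgeGroup, str], tuple[np.ndarray, np.ndarray]] = {}
    for row in profile.accuracy.rows():
        key = (row.test_id, row.age_group, row.threshold_label)
        sens = np.full(n, row.sensitivity)
        spec = np.full(n, row.specificity)
        if row.sens_ci is not None:
            a, b = _beta_params(row.sensitivity, row.sens_ci)
            sens = beta_dist.rvs(a, b, size=n, random_state=rng)
        if row.spec_ci is not None:
            a, b = _beta_params(row.specificity, row.spec_ci)
            spec = beta_dist.rvs(a, b, size=n, random_state=rng)
        acc_draws[key] = (sens, spec)
        tag = f"{row.test_id.value}_{row.age_group.value}_{row.threshold_label}"
        draw_cols[f"sens_{tag}"] = sens
        draw_cols[f"spec_{tag}"] = spec

    mu, sigma = _lognormal_params(profile.stage_shift.rr_late, profile.stage_shift.ci)
    rr = rng.lognormal(mu, sigma, size=n)
    draw_cols["rr_late"] = rr

    um = profile.utility_model
    sd_dis = (um.surgery_disutility_ci[1] - um.surgery_disutility_ci[0]) / 3.92
    sd_gain = (um.surgery_gain_ci[1] - um.surgery_gain_ci[0]) / 3.92
    surg_dis = rng.normal(um.surgery_disutility, sd_dis, size=n)
    surg_gain = rng.normal(um.surgery_gain, sd_gain, size=n)
    draw_cols["surgery_disutility"] = surg_dis
    draw_cols["surgery_gain"] = surg_gain

    defs = standard_pathways()
    out = {pid: np.empty((n, 2)) for pid in pathway_ids}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rr_late > 1 capping inside draws
        for i in range(n):
            overrides = {
                key: (float(s[i]), float(p[i])) for key, (s, p) in acc_draws.items()
            }
            accuracy = _DrawnAccuracy(profile.accuracy, overrides)
            shift = StageShiftParams(rr_late=min(float(rr[i]), 1.0))
            for pid in pathway_ids:
                res = pathway_ce(
                    defs[pid],
                    stratum,
                    profile,
                    library=library,
                    accuracy=accuracy,
                    shift=shift,
                    surgery_effects=(float(surg_dis[i]), float(surg_gain[i])),
                )
                out[pid][i, 0] = res.qalys_per_1000
                out[pid][i, 1] = res.costs_per_1000
    return PSAResult(
        n_draws=n, seed=seed, stratum=stratum, draws=pd.DataFrame(draw_cols), results=out
    )


@dataclass
class CEACCurve:
    """Probability each pathway has the highest net benefit, per threshold."""

    lambdas: np.ndarray
    probabilities: pd.DataFrame  # index: lambda, columns: pathway id


def ceac(psa: PSAResult, lambdas) -> CEACCurve:
    """Cost-effectiveness acceptability curves from PSA draws.

    At each willingness-to-pay the probability is the fraction of draws in
    which the pathway attains the maximal net benefit; exact ties share the
    draw equally.
    """
    if psa.n_draws == 0:
        raise ValueError("empty PSA result")
    lambdas = np.asarray(list(lambdas), dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    pids = sorted(psa.results)
    q = np.stack([psa.results[pid][:, 0] for pid in pids], axis=1)  # (n, k)
    c = np.stack([psa.results[pid][:, 1] for pid in pids], axis=1)
    probs = np.zeros((lambdas.size, len(pids)))
    for j, lam in enumerate(lambdas):
        nb = lam * q - c
        best = nb.max(axis=1, keepdims=True)
        winners = np.isclose(nb, best, rtol=0.0, atol=1e-9)
        share = winners / winners.sum(axis=1, keepdims=True)
        probs[j] = share.mean(axis=0)
    return CEACCurve(
        lambdas=lambdas,
        probabilities=pd.DataFrame(probs, index=lambdas, columns=pids),
    )


# --- Ovatools threshold sweep -----------------------------------------------


class _RocAccuracy:
    """Accuracy provider evaluating Ovatools thresholds on the fitted ROC."""

    def __init__(self, base, curve: ROCCurve):
        self._base = base
        self._curve = curve

    def lookup(self, test_id, age_group, label):
        test_id = TestId(test_id)
        if test_id in (TestId.OVATOOLS, TestId.AGE_ADJ_CA125):
            return roc_interpolate(self._curve, float(label))
        return self._base.lookup(test_id, age_group, label)


def threshold_sweep(
    stratum: PopulationStratum,
    profile: SyntheticProfile,
    moderate_grid=None,
    high_grid=None,
    library: OutcomeLibrary | None = None,
) -> pd.DataFrame:
    """ICER of the risk-banded sequential pathway vs current practice over a
    grid of (moderate, high) Ovatools risk thresholds.

    Returns a long-format table with columns ``moderate``, ``high``,
    ``dqaly_per_1000``, ``dcost_per_1000``, ``icer`` and ``flag`` (empty,
    ``dominant`` when the variant gains QALYs and saves cost, ``dominated``
    when it loses QALYs at extra cost, ``extrapolated`` outside the supported
    threshold range).  Only cells with moderate <= high are returned.
    """
    lo, hi = SWEEP_RANGE
    if moderate_grid is None:
        moderate_grid = np.round(np.arange(lo, hi + 1e-12, 0.002), 6)
    if high_grid is None:
        high_grid = np.round(np.arange(0.01, hi + 1e-12, 0.005), 6)
    if library is None:
        library = OutcomeLibrary.build(stratum, profile.markov_parameters())
    curve = ovatools_roc(profile.accuracy, stratum.age_group)
    roc_acc = _RocAccuracy(profile.accuracy, curve)
    defs = standard_pathways()
    base = pathway_ce(defs[1], stratum, profile, library=library)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # extrapolation warnings become flags
        for m in moderate_grid:
            for h in high_grid:
                if m > h:
                    continue
                variant = PathwayDefinition(
                    2, PathwayMode.SEQUENTIAL, TestId.OVATOOLS, repr(float(m)), repr(float(h))
                )
                res = pathway_ce(variant, stratum, profile, library=library, accuracy=roc_acc)
                dq = res.qalys_per_1000 - base.qalys_per_1000
                dc = res.costs_per_1000 - base.costs_per_1000
                icer = dc / dq if dq != 0 else np.nan
                flag = ""
                if dq > 0 and dc < 0:
                    flag = "dominant"
                elif dq < 0 and dc > 0:
                    flag = "dominated"
                if not (lo <= m <= hi and lo <= h <= hi):
                    flag = (flag + ";extrapolated").lstrip(";")
                rows.append(
                    {
                        "moderate": float(m),
                        "high": float(h),
                        "dqaly_per_1000": dq,
                        "dcost_per_1000": dc,
                        "icer": icer,
                        "flag": flag,
                    }
                )
    return pd.DataFrame(rows)
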