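"""Diagnostic test accuracy: lookups and ROC interpolation.

Holds the sensitivity/specificity of the triage tests (CA125 at 35 U/mL,
Ovatools risk thresholds, pelvic ultrasound) by age group, and fits a smooth
binormal ROC curve through the two published Ovatools operating points per age
group so that accuracy can be evaluated at arbitrary risk thresholds for the
threshold-sweep analyses.

The binormal model writes the true-positive rate as a probit-linear function
of the false-positive rate, TPR = Phi(a + b * Phi^-1(FPR)); the mapping from
an Ovatools risk threshold to an operating point is indexed by interpolating
Phi^-1(FPR) linearly against log(risk threshold) through the anchors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

__all__ = [
    "TestId",
    "AgeGroup",
    "TestAccuracy",
    "AccuracyTable",
    "ROCCurve",
    "MissingParameterError",
    "DegenerateAnchorError",
    "load_default_accuracy",
    "build_binormal_roc",
    "roc_interpolate",
]

SWEEP_RANGE = (0.006, 0.04)  # supported Ovatools risk-threshold range


class TestId(str, Enum):
    CA125_35 = "CA125_35"
    OVATOOLS = "OVATOOLS"
    AGE_ADJ_CA125 = "AGE_ADJ_CA125"
    USS = "USS"


class AgeGroup(str, Enum):
    UNDER50 = "UNDER50"
    GE50 = "GE50"
    ALL = "ALL"


class MissingParameterError(KeyError):
    """An accuracy lookup for a (test, age group, threshold) not in the table."""


class DegenerateAnchorError(ValueError):
    """ROC anchors at the boundary of the unit square or with equal FPR."""


@dataclass(frozen=True)
class TestAccuracy:
    """Point accuracy of one test at one threshold for one age group."""

    test_id: TestId
    age_group: AgeGroup
    threshold_label: str
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float] | None = None
    spec_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for point, ci in ((self.sensitivity, self.sens_ci), (self.specificity, self.spec_ci)):
            if ci is not None and not ci[0] <= point <= ci[1]:
                raise ValueError(f"CI {ci} does not bracket point estimate {point}")


class AccuracyTable:
    """Accuracy parameter table with age-group-aware lookups.

    Ultrasound accuracy is stored once for all ages and returned for any
    requested age group.  Age-adjusted CA125 thresholds are, by default,
    accuracy-equivalent to the Ovatools risk threshold they were derived from;
    loading explicit AGE_ADJ_CA125 rows overrides that equivalence.
    """

    def __init__(self, rows: list[TestAccuracy]):
        self._rows: dict[tuple[TestId, AgeGroup, str], TestAccuracy] = {}
        for row in rows:
            self._rows[(row.test_id, row.age_group, row.threshold_label)] = row

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AccuracyTable":
        rows = []
        for rec in df.to_dict("records"):
            def _ci(lo, hi):
                if pd.isna(lo) or pd.isna(hi):
                    return None
                return (float(lo), float(hi))

            rows.append(
                TestAccuracy(
                    test_id=TestId(rec["test_id"]),
                    age_group=AgeGroup(rec["age_group"]),
                    threshold_label=str(rec["threshold_label"]),
                    sensitivity=float(rec["sensitivity"]),
                    specificity=float(rec["specificity"]),
                    sens_ci=_ci(rec.get("sens_ci_low"), rec.get("sens_ci_high")),
                    spec_ci=_ci(rec.get("spec_ci_low"), rec.get("spec_ci_high")),
                )
            )
        return cls(rows)

    @classmethod
    def from_csv(cls, path) -> "AccuracyTable":
        return cls.from_frame(pd.read_csv(path))

    def rows(self) -> list[TestAccuracy]:
        return list(self._rows.values())

    def get(self, test_id: TestId, age_group: AgeGroup, threshold_label: str) -> TestAccuracy:
        test_id = TestId(test_id)
        age_group = AgeGroup(age_group)
        if test_id is TestId.USS:
            # ultrasound accuracy is age-invariant
            key = (test_id, AgeGroup.ALL, threshold_label)
            if key not in self._rows:
                # single USS row regardless of the requested label
                uss = [r for r in self._rows.values() if r.test_id is TestId.USS]
                if uss:
                    return uss[0]
            else:
                return self._rows[key]
        key = (test_id, age_group, threshold_label)
        if key in self._rows:
            return self._rows[key]
        if test_id is TestId.AGE_ADJ_CA125:
            # age-adjusted CA125 thresholds are calibrated to match Ovatools risk
            alt = (TestId.OVATOOLS, age_group, threshold_label)
            if alt in self._rows:
                return self._rows[alt]
        raise MissingParameterError(
            f"no accuracy entry for ({test_id.value}, {age_group.value}, {threshold_label!r})"
        )

    def lookup(self, test_id: TestId, age_group: AgeGroup, threshold_label: str) -> tuple[float, float]:
        acc = self.get(test_id, age_group, threshold_label)
        return acc.sensitivity, acc.specificity


def load_default_accuracy() -> AccuracyTable:
    """Load the bundled published accuracy table."""
    with resources.files("ovatriage.data").joinpath("test_accuracy.csv").open() as fh:
        return AccuracyTable.from_csv(fh)


@dataclass(frozen=True)
class ROCCurve:
    """Binormal ROC through risk-threshold-indexed operating points."""

    age_group: AgeGroup
    anchors: tuple[tuple[float, float, float], ...]  # (risk_threshold, sens, spec)
    a: float
    b: float
    # probit(FPR) interpolated linearly against log(risk threshold)
    _log_risk: np.ndarray = field(repr=False, default=None)
    _probit_fpr: np.ndarray = field(repr=False, default=None)


def build_binormal_roc(
    anchors: list[tuple[float, float, float]], age_group: AgeGroup = AgeGroup.ALL
) -> ROCCurve:
    """Fit a binormal ROC curve through (risk_threshold, sens, spec) anchors.

    With exactly two anchors the slope and intercept solve the two binormal
    equations exactly; with more, they are fit by least squares on the probit
    scale (still exact when the anchors are collinear in probit space).
    """
    if len(anchors) < 2:
        raise ValueError("at least two anchors are required")
    anchors = sorted((float(r), float(se), float(sp)) for r, se, sp in anchors)
    fpr = np.array([1.0 - sp for _, _, sp in anchors])
    tpr = np.array([se for _, se, _ in anchors])
    risk = np.array([r for r, _, _ in anchors])
    if np.any((fpr <= 0) | (fpr >= 1) | (tpr <= 0) | (tpr >= 1)):
        raise DegenerateAnchorError("anchor TPR/FPR must lie strictly inside (0, 1)")
    if len(np.unique(fpr)) < len(fpr):
        raise DegenerateAnchorError("anchors must have distinct false-positive rates")
    if np.any(risk <= 0):
        raise ValueError("risk thresholds must be positive")
    x = ndtri(fpr)
    y = ndtri(tpr)
    b, a = np.polyfit(x, y, 1)
    return ROCCurve(
        age_group=AgeGroup(age_group),
        anchors=tuple(anchors),
        a=float(a),
        b=float(b),
        _log_risk=np.log(risk),
        _probit_fpr=x,
    )


def roc_interpolate(curve: ROCCurve, risk_threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity at an arbitrary Ovatools risk threshold.

    Anchor thresholds return the anchor operating point exactly.  Thresholds
    outside the supported sweep range are extrapolated with a warning.
    """
    if risk_threshold <= 0:
        raise ValueError(f"risk threshold must be positive, got {risk_threshold}")
    lo, hi = SWEEP_RANGE
    if not lo <= risk_threshold <= hi:
        warnings.warn(
            f"risk threshold {risk_threshold} outside supported range [{lo}, {hi}]; extrapolating",
            stacklevel=2,
        )
    for r, se, sp in curve.anchors:
        if math.isclose(risk_threshold, r, rel_tol=1e-12):
            return se, sp
    lx = math.log(risk_threshold)
    # linear inter-/extra-polation of probit(FPR) against log threshold
    z = float(np.interp(lx, curve._log_risk, curve._probit_fpr))
    if lx < curve._log_risk[0]:
        slope = (curve._probit_fpr[1] - curve._probit_fpr[0]) / (
            curve._log_risk[1] - curve._log_risk[0]
        )
        z = curve._probit_fpr[0] + slope * (lx - curve._log_risk[0])
    elif lx > curve._log_risk[-1]:
        slope = (curve._probit_fpr[-1] - curve._probit_fpr[-2]) / (
            curve._log_risk[-1] - curve._log_risk[-2]
        )
        z = curve._probit_fpr[-1] + slope * (lx - curve._log_risk[-1])
    fpr = float(ndtr(z))
    tpr = float(ndtr(curve.a + curve.b * z))
    return tpr, 1.0 - fpr


def ovatools_roc(table: AccuracyTable, age_group: AgeGroup) -> ROCCurve:
    """Binormal curve through the published 1% and 3% Ovatools operating points."""
    anchors = []
    for risk, label in ((0.01, "1%"), (0.03, "3%")):
        acc = table.get(TestId.OVATOOLS, age_group, label)
        anchors.append((risk, acc.sensitivity, acc.specificity))
    return build_binormal_roc(anchors, age_group)
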