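# Methods

## Decision problem and model structure

The package compares six triage pathways for women presenting in primary
care with symptoms of possible ovarian cancer. Each pathway is a rule over
two tests — a blood test (CA125 at 35 U/mL, an Ovatools risk probability, or
an age-adjusted CA125 threshold calibrated to the same risk) and a pelvic
ultrasound — that ends in either reassurance or referral to secondary care.
A cohort decision tree converts test accuracy and one-year cancer prevalence
into the four outcome classes (TP/FN/TN/FP); a five-state Markov cohort
model projects each class over the remaining lifetime; and the economic
layer aggregates discounted QALYs and costs per 1000 women into incremental
comparisons, an ICER frontier, probabilistic sensitivity analysis,
acceptability curves and risk-threshold sweeps.

Two population strata are modelled, split at age 50, with the published
sizes, one-year invasive ovarian-cancer prevalences and late-stage shares:
112,081 women under 50 (prevalence 0.2%, 46% late-stage) and 164,746 women
50 or older (1.05%, 72%). Each stratum carries a truncated-normal integer-age
distribution (mean 54.6, SD 15.8, bounds 18–99, restricted to its side of
50); lifetime outcomes are weighted over entry ages.

## Decision tree

The blood test and ultrasound are conditionally independent given cancer
status. Specificity is defined against "no invasive ovarian cancer", so
women with other cancers or benign disease sit in the negative class, as in
the source accuracy data. Sequential single-cut, sequential banded and
concurrent pathway algebra follows directly from the triage rules; a
brute-force enumeration over all joint (disease, blood band, ultrasound)
atoms backs the implementation in the test suite.

**Stage shift.** Detection gains are converted into health gains by moving a
fraction of incrementally detected cancers from late- to early-stage at
diagnosis: the detected mass exceeding the current-practice pathway has its
late-stage probability multiplied by RR = 0.836 (95% CI 0.737–0.950). All
other cancer mass keeps the stratum's baseline staging, and a pathway that
detects *fewer* cancers than current practice gets no reverse shift — missed
cases simply revert to usual-care staging (they are diagnosed within the
year after repeating the primary-care process once).

**Primary-care costing.** Sequential journeys: face-to-face GP consultation
(£40) + nurse time (£9) + CA125 (£10); if an ultrasound is arranged, a GP
telephone follow-up (£20) and the scan (£204); an abnormal scan adds one
further GP consultation before referral. Concurrent journeys order both
tests at the first consultation, with one further consultation before
referral when either test is abnormal. Direct urgent referral at high risk
is costed with one further GP consultation (£99 total): the source describes
the telephone call only as part of arranging an ultrasound, so the minimal
consistent extension is applied; this choice does not touch any reproduced
quantity. False negatives repeat their identical branch once (double branch
cost) before diagnosis. Referred women with no eventual cancer diagnosis
incur 0.75 × £3,994 (benign surgery) + 0.25 × £395 (outpatient + CA125 +
ultrasound) = £3,094.25 in secondary care. Other-cancer patients follow the
no-cancer branch probabilities in primary care but are not given benign
surgery costs or utility effects (they do receive a cancer diagnosis).

## Markov model

States: no cancer, early-stage cancer, late-stage cancer (entry states) and
cancer death / non-cancer death (absorbing). Annual cycles from entry age to
110. No early↔late transitions: stage-specific death-risk models subsume
progression. Within the first 8 years after diagnosis (15 in scenario),
cancer-death risk comes from the survival model for the person's cancer type
and stage; beyond that, and for non-cancer death always, from the
cause-partitioned life table at current age. Competing risks within a cycle
are combined on the hazard scale — p(death) = 1 − exp(−(h_c + h_nc)),
allocated to causes in proportion to hazards — which reduces exactly to the
single-risk form when one hazard vanishes and matches direct integration of
the two-hazard model (tested at 1e−10).

Per cycle, live occupancy accrues utility (age-declining baseline minus
cancer decrements by recency of diagnosis, minus an extra 0.046 for every
cycle spent in the late-stage state) and costs (step-curves over years 0–4+
since diagnosis; constant background for no-cancer). The late-stage
decrement's duration is not pinned down by the source; applying it while in
state is this package's reading, with 0.06 and 0 supported as scenario
values. Streams are discounted at 3.5%/year (1.5% scenario) with the entry
cycle undiscounted; no half-cycle correction in the base case (a config
switch enables it), since increments between pathways are unaffected to
first order.

Benign-surgery quality-of-life effects — −0.04 in the surgery year, +0.008
in every later year alive — apply to the 75% of referred non-cancer women
undergoing surgery, layered on the no-cancer survival trajectory.

## Synthetic parametrization

The registry-fitted inputs of the original evaluation (flexible parametric
survival, two-part GLM costs, EQ-5D regression) are replaced by synthetic
stand-ins calibrated to published anchors:

* **Survival**: exponential per cancer type × stage, pinned exactly to
  five-year anchors. Ovarian early/late use the published stage I/IV figures
  (95% / 16% → hazards 0.01026 and 0.3665 /yr); other cancers use documented
  placeholder anchors with early ≥ late survival enforced. Weibull shapes
  are accepted through the same interface for richer hazards.
* **Life table**: Gompertz–Makeham female all-cause mortality
  (A = 2×10⁻⁴, B = 2.5×10⁻⁵, C = 0.098), split into cancer/non-cancer
  causes by a smooth age-dependent fraction peaking near age 62; the
  partition conserves the all-cause rate identically.
* **Costs**: step-function inpatient cost curves by type, stage and years
  since diagnosis (late ≥ early at diagnosis year), £500/yr background.
* **Utility**: baseline 0.97 at age 18 declining 0.0035/yr, cancer
  decrements by recency (within vs beyond one year of diagnosis), late-stage
  extra 0.046.

The stand-ins are deterministic: changing the seed alters only PSA draws,
never base-case results. They emulate the *shape* of registry-fitted inputs
(stage-dependent survival, front-loaded costs, age-declining utility), not
their levels — so decision-tree outputs (detection, referral, staging) are
exact reproductions, while QALY/cost magnitudes, and hence absolute ICERs of
the full pipeline, are calibration-dependent. What transfers to real data is
the sign and ordering structure (which pathways gain QALYs, which add cost,
the dominance pattern), not the synthetic magnitudes. Non-ovarian cancers
are pathway-invariant in the base case and cancel out of increments; the
other-cancer stage split (0.5) and all their parameters are labelled
synthetic in emitted files.

## Economic analysis

Incremental QALYs/costs per 1000 women are taken against pathway 1. The
frontier sorts by cost, removes strictly dominated options (ties keep the
lower pathway id and are flagged), then iteratively removes options whose
consecutive ICER sequence is non-increasing until it is strictly increasing
— the standard extended-dominance algorithm, verified against exhaustive
search on all inputs of up to six options. The Ovatools pathways and their
age-adjusted twins (2/3 and 4/5) are never compared with each other: the
frontier is built once per twin selection and each twin is reported against
the shared lower neighbour.

**PSA** (default 1000 draws, seeded): beta distributions for sensitivities
and specificities, matched by method of moments to point estimate and 95%
CI; lognormal for the stage-shift relative risk (draws above 1 capped at 1
with a warning); normal for the two surgery utility deltas. Parameters
published without uncertainty stay fixed. Since none of the drawn parameters
enters the Markov hazards or cost curves, the per-class Markov outcome
library is computed once and reused across draws; each draw is nevertheless
a complete model evaluation. CEACs report, per willingness-to-pay, the
fraction of draws in which each pathway attains the maximal net benefit
λ·ΔQALY − Δcost, ties split equally; the default λ grid is £0–50,000 in
£1,000 steps.

**Threshold sweep.** Accuracy at risk thresholds between the two published
operating points (1% and 3%) is interpolated on a binormal ROC curve,
TPR = Φ(a + b·Φ⁻¹(FPR)), fitted exactly through the two anchors per age
group, with the operating point indexed by linear interpolation of Φ⁻¹(FPR)
against log risk threshold. The source does not state how accuracy varies
between its printed thresholds; the binormal form is this package's choice —
smooth, two-parameter, exactly anchored, and standard in diagnostic-accuracy
modelling — and any user-supplied (threshold, sensitivity, specificity)
table overrides it. The supported sweep range is 0.6–4%; outside it the
curve extrapolates with a warning and a flag. Anchor thresholds snap to the
anchor operating points, so the (1%, 3%) sweep cell equals the base case
bit-for-bit. Cells where the variant gains QALYs while saving cost (or the
reverse) are flagged dominant/dominated instead of carrying a meaningful
ICER.

## Numerical choices and problem sizes

Occupancy is conserved to 1e−10 per cycle; constant-hazard projections match
closed-form exponentials to 1e−8; four-class tree probabilities sum to 1
within 1e−12. The base case evaluates ~13 entry classes × ≤82 entry ages ×
≤93 cycles per stratum, which completes in seconds; the default analyses
(PSA 1000 draws, full sweep grid) each run well under a minute on one core.

## Known limitations

* Absolute QALY/cost levels depend on synthetic stand-ins; only the
  decision-tree layer is an exact reproduction of published inputs.
* Pathways 3 and 5 are modelled as accuracy-equivalent to their risk-model
  twins; their separately derived printed figures (e.g. 60% detection under
  50, 5.8% referral at ≥50) differ in the last digit from the equivalence
  values until an explicit age-adjusted threshold accuracy table is loaded.
* One-time testing: repeat symptomatic presentations beyond the single
  false-negative re-entry are not modelled.
* Other-cancer effects of a pathway (earlier detection of lower-GI, uterine,
  lung, pancreatic cancer) are supported as a scenario mechanism with
  user-supplied parameters, off in the base case.
* The cohort model is expected-value; no individual-level simulation.
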