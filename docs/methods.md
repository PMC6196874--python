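# Methods

This note documents the models, the synthetic-data generator, the
numerical conventions, and the design choices made where the published
description of the PACE-UP economic evaluation leaves the design open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Within-trial (1-year) evaluation

**QALYs.** Trapezoidal area under the EQ-5D utility index over the
measurement times 0, 0.25 and 1 year. With utilities (u0, u3, u12) the
12-month QALY is 0.125·u0 + 0.5·u3 + 0.375·u12. The published per-arm
0–12-month QALY means (0.837 / 0.843 / 0.836) are exactly the trapezoid of
the published per-arm utility means. The published *0–3-month* QALYs
(0.194–0.196) are **not** reproducible as the trapezoid over [0, 0.25]
(which gives ≈0.21); the convention behind those printed figures is not
stated. We do not force agreement: the 3-month QALY here is the [0, 0.25]
trapezoid, and the discrepancy is documented rather than hidden.

**Costs.** Components are set-up (fixed per arm), intervention delivery,
general health service use (GP visits, admissions, A&E — the right-skewed
component), and participant-borne costs. All money is GBP at 2013/14
prices; no discounting within the 1-year horizon. Perspectives:

* `nhs` — set-up + delivery + health service use (base case);
* `nhs_plus_participant` — adds participant costs, with the months-9–12
  participant block multiplied by 3 to represent months 4–12 (participant
  costs were collected only for months 1–3 and 9–12);
* `intervention_only` — set-up + delivery only.

Deterministic sensitivity toggles map the published A–H list: include all
randomised participants (vs accelerometry providers), drop health-service
use, complete-case analysis, serious-adverse-event costing (an alternative
health-service-use column, since the self-report instrument is not
available), participant perspectives, and a pedometer-lifetime scale
factor on the annuitised set-up cost. Each toggle touches only its target
component (regression-tested).

**Missing data.** Fields with ≤5% missingness are filled with the
arm-level observed mean (deterministic). Fields above 5% go through
chained equations (predictive mean matching, `statsmodels` MICE),
conditioning on covariates, arm, and the other outcome variables; EQ-5D is
imputed at index level. M = 5 completed datasets by default; point
estimates are pooled by averaging with a Rubin-style variance combination
(within-imputation variance plus (1 + 1/M) × between-imputation variance).
The published account states neither M nor the pooling rule; these
defaults follow common practice.

**Adjusted arm means.** Cost models use a GLM with log link and Poisson
variance (quasi-likelihood on continuous costs); QALY models use a
logit-link binomial quasi-likelihood — a beta-regression-like model for an
outcome in (0, 1]. QALY values of exactly 1 are shrunk by 1e−6 before
fitting (the boundary is outside the logit's range). Covariates: arm,
age, sex, ethnicity, disease count, plus the baseline outcome for
QALY/activity models. The synthetic covariate set is simpler than the
trial's full list (no practice, marital status, education, employment,
socioeconomic status, smoking or alcohol coding); a model-reduction step
via joint Wald tests is not implemented — the full model is always fitted.
Arm means are *recycled predictions*: every participant is predicted under
each arm assignment and the predictions averaged. Uncertainty comes from
parametric simulation (Krinsky–Robb) of the coefficient vector using the
household-clustered covariance — households are the randomisation unit.

**Bootstrap.** Households are resampled with replacement within arm; each
of the B = 2000 replicates refits the cost and effect models and
recomputes the recycled-prediction incrementals, giving paired (ΔC, ΔE)
draws for the CE plane and the CEAC.

**Psychological one-off utility gain.** "Active" means ≥150 weekly
minutes of MVPA in ≥10-minute bouts at 12 months. The gain is the
recycled-prediction contrast (everyone active vs everyone inactive) from
the 12-month utility model with activity status added, controlling for
baseline utility, demography, disease count and arm. The estimate plugs
directly into the lifetime model's `one_off_utility_gain` parameter.

## Synthetic-trial generator

The generator emulates what the within-trial analysis assumes about the
data: three arms allocated by household, arm-specific distributions for
utilities, activity and costs, and item missingness. Defaults reproduce
the published arm-level summaries (320/arm, ~20% two-person households).

Distribution families (only means and SDs are published; families were
chosen once for support and skew):

* utilities — truncated normal on (0, 1], with the underlying normal
  solved numerically so the truncated mean/SD equal the targets exactly;
  infeasible moment pairs are rejected with a diagnostic. Note the
  published utility means (~0.84–0.85 with SD 0.13–0.15) sit close to the
  feasibility frontier of a [0,1]-truncated normal;
* costs — gamma matched by moments (zero-SD components are constants);
  set-up and postal delivery costs are fixed per arm as published;
* steps and weekly MVPA-bout minutes — lognormal matched by moments, with
  arm-specific follow-up means equal to a common baseline plus the
  published adjusted incrementals.

Correlation uses a Gaussian copula over structured standard-normal scores:
a household intercept (variance share `household_icc`, default 0.05), a
person-level activity factor shared by steps and MVPA (cross-outcome and
over-time correlation `activity_corr`, default 0.7), and a person factor
linking repeated utility measures (`time_corr`, default 0.35). The true
intra-household correlation and household-size mix of the trial are
unreported; these are one-time choices. Monotone marginal transforms
preserve the matched families exactly, so arm means converge to their
targets at SD/√n.

What the generator does **not** emulate: accelerometer epoch-level data
and wear-time rules, EQ-5D domain-level responses (utilities are generated
directly on the index scale, so the 5L→3L crosswalk is out of scope),
covariate effects on outcomes, and any outcome–cost dependence beyond the
shared household intercept. Passing tests therefore demonstrate correct
*method* behaviour under the assumed data-generating process, not
robustness to the full messiness of real trial data.

`apply_missingness` blanks measured fields MCAR at configured rates or MAR
via a logistic model on standardised age, keeping the pre-deletion values
in a truth channel used only by tests.

## Lifetime Markov cohort model

Closed cohort of 100,000 people aged 59, annual cycles to age 88. Nine
states: event-free active, event-free inactive, CHD year-1, CHD post,
stroke year-1, stroke post, T2D, dead (CVD), dead (other). The year-1
tunnel states carry first-event-year treatment costs ("split by initial
event and follow-up"); T2D is a single chronic state; there are no second
events. The precursor model's exact structure is not publicly documented,
so this 9-state reconstruction is a design choice and is flagged as such.

Conventions, chosen once and documented:

* **Activity split.** At the end of year 1 the cohort is active with
  probability `p_active_control × rr_active_by_arm[arm]`, capped at 1
  with a logged warning. Activity status is then fixed; persistence of the
  *effect* is carried entirely by the relative-risk duration rule, because
  the cohort-study RRs already incorporate habit change.
* **Effect duration.** The protective RRs on CHD/stroke/T2D incidence
  apply for cycles 1..D and equal 1 thereafter; D = 10 in the base case,
  1 and 3 in scenarios 1 and 2.
* **Competing risks.** Death first (background all-cause mortality, plus
  any post-event excess attributed to CVD death), then at most one
  incident event conditional on survival, with probabilities equal to the
  (RR-adjusted) annual incidences. Rows are stochastic by construction and
  never renormalised; an implied probability above 1 raises an error
  naming the offending parameter.
* **Accounting.** Occupancy at the start of each annual cycle accrues that
  cycle's state costs and utilities; no half-cycle correction by default
  (a switchable option). Discounting divides cycle t by 1.035^(t−1), so
  the first cycle is undiscounted and a zero rate is an exact identity.
* **Intervention costs.** Model year-1 per-person costs are the
  trial-based adjusted 12-month totals by arm; year 2 adds the annuitised
  intervention cost (£5.03 postal, £4.14 nurse) for people still alive,
  discounted one cycle. Scenario 3 replaces year-1 costs with
  intervention-only costs and removes the psychological one-off gain;
  scenario 4 additionally adds participant-borne costs.
* **One-off utility gain** is a single additive QALY increment in cycle 1
  for everyone active in year 1, regardless of arm.

The shipped parameter file is a **synthetic placeholder**: incidence,
mortality split, excess mortality, state costs and utilities are
plausible order-of-magnitude values for a UK cohort, selected once to
reproduce the published qualitative pattern (postal dominant vs control;
nurse costlier with more QALYs; nurse dominated by postal). Absolute
lifetime costs/QALYs under this file are not estimates of anything.
Baseline mortality uses an abridged life-table-style band structure and is
excluded from the PSA.

## Probabilistic sensitivity analysis

Families by parameter type: beta for probabilities and utilities
(method-of-moments from the point value and an SE), gamma for costs
(coefficient of variation), lognormal for relative risks (log-scale SD,
location set so the mean equals the point value). Defaults — SE 0.05,
CV 0.2, log-SD 0.15 — are placeholders (the original SEs are not
published) and are overridable per parameter; parameters are sampled
independently, as no correlation structure is reported. Age-indexed
incidence profiles are scaled by one mean-1 lognormal multiplier per
condition rather than sampling age bands independently, which preserves
the age gradient. Every prior is validated to centre on its point value
(tolerance 1e−6); draws whose parameter set the engine rejects are
skipped and counted. Default n = 10,000 draws; the test suite and
acceptance script use 200 for speed.

## Numerical conventions and degenerate inputs

* Rounding for reported tables: ICERs to 2 dp, NMB to the nearest
  £million, QALYs to 3 dp, halves away from zero (as printed tables do).
* CEAC tie rule: a draw with NMB exactly 0 counts as *not* cost-effective
  (arbitrary but fixed). Default willingness-to-pay grid £0–£50,000 in
  £1,000 steps; the published figure's axis extent is not stated.
* ICER classification: ΔE = 0 with ΔC = 0 is "equivalent"; ΔE = 0 with
  ΔC ≠ 0 sits on the axis and is resolved by cost alone. ΔC = 0 with
  ΔE > 0 is reported as an ICER of 0.
* The published "£21,162 saved per QALY lost" (postal vs control at 12
  months) corresponds to the unrounded incremental pair; from the rounded
  printed values (−£91, −0.004) the ratio would be £22,750. The package
  stores the consistent unrounded QALY increment (−0.0043).
* Degenerate inputs: all-missing fields are rejected by imputation;
  empty draw sets by the CEAC; bootstrap requires B ≥ 1; singular designs
  in bootstrap refits fall back to pseudo-inverse fits.

## Problem sizes used by the tests and the acceptance script

Chosen as the package's own defaults for routine verification: synthetic
trials of 320/arm for pipeline runs and 100–250/arm for statistical
property tests; B = 2000 bootstrap replicates in the acceptance script and
10–100 in unit tests; 200 seeds for the interval-coverage experiments;
10,000 individuals for the microsimulation cross-check of the cohort
engine; 200 PSA draws in the acceptance script.

## Known limitations

* All lifetime-model epidemiology is placeholder; only qualitative
  patterns and structural properties are meaningful under the shipped
  file. Users with access to calibrated inputs should supply their own
  YAML (schema `pedometer-cea-markov/1`).
* No cancer or adverse-event states; no second events; no post-event
  activity effects; no individual-level heterogeneity in the cohort
  engine (the microsimulation exists only as a validation oracle).
* Recycled-prediction intervals showed mild undercoverage (~92–93% at
  n = 100/arm in the packaged coverage experiment) — typical of
  cluster-robust plus simulation-based intervals at modest cluster counts.
* The synthetic generator cannot represent utility SDs at the published
  mean levels much above ~0.14 (truncated-normal feasibility), and does
  not model covariate-outcome dependence, so confounding-adjustment tests
  construct their own datasets.
* Expected value of (partial) perfect information and >2-arm frontier
  analysis are out of scope.
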