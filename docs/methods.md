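# Methods

This note documents the models, conventions and design choices behind
`ttemu`, in the spirit of a statistical-software methods appendix.  The
empirical numbers quoted are the ones the test suite and the `analysis/`
drivers themselves compute.

## 1. The emulated protocol

The target of emulation is a sequential nested-trial design for an annual
universal health checkup (SHC): at the start of every fiscal year
(April 1), all persons in the claims universe are screened against the
eligibility criteria — age 40–74 in completed years at entry, enrollment
for at least `lookback_days` (365) before entry and still enrolled at
entry, at least one outpatient/hospital record in the lookback window, no
checkup record at any earlier time, no prevalent component disease (a
diagnosis in the exclusion code set **and** a matching drug-class
dispensing, both before entry), and resource use at or below the 99.99th
percentile of the screened population.  Eligible persons form a new trial
with time zero April 1; the SHC arm is the subset with a checkup record in
that fiscal year.  A person can contribute a non-SHC entry in every year
they qualify but at most one SHC entry, because the first checkup removes
them from all later screens.  The primary contrast is intention-to-treat:
non-SHC entrants who attend a checkup later are neither censored nor
reclassified.

Conventions: dates are integer days; intervals are half-open; ages are
completed years computed as ⌊days/365.25⌋; follow-up intervals are
[entry + (k−1)Δ, entry + kΔ) with Δ = 365.25 days (annual) or 365.25/12
(monthly sensitivity design), truncated at 10 years, disenrollment, the
administrative end, or the first qualifying outcome.  An entry censored
mid-interval contributes that interval as a censored period.  Exclusion
history searches the entire observable pre-entry record; the lookback
window governs only the continuity and visit-count criteria.  The
resource-use threshold uses the `higher` quantile method so that screening
an already-screened cohort is a no-op.

Outcomes are claims-defined: a diagnosis code (3-character ICD-10 prefix)
with, where required, a dispensing in the matching ATC class within ±90
days (`conjunction_window_days`, configurable; the source protocol states
the code+drug conjunction without a window).  The composite outcome is the
earliest of the diabetes component (E11/E14 + A10) and the hypertension
component (I10–I13 plus I15 + C02/C03/C07–C09; the printed "E15" is almost
certainly a typo for I15 and both are selectable).  The negative-control
outcome is depression as printed (F32/F34/F35; F35 does not exist in
ICD-10 but matching is by prefix and nothing is coded under it), with no
drug requirement and with prevalent cases excluded at baseline in
negative-control runs.

## 2. Weighting

A single pooled logistic propensity model is fitted across all trials
(fiscal year enters as a categorical covariate) for P(A=1 | L), with L =
age (years, linear), sex, employment, entry fiscal year,
hospitalization-count category (0/1/≥2), visit-count category
(1-2/3-5/6-11/≥12), and one indicator per 3-digit ICD-10 code present in
the pre-entry history, after dropping codes with cohort prevalence below
10⁻⁴ and the component-disease, pregnancy (O*) and perinatal (P*) families.
Constant and collinear columns are pruned (rank-revealing QR); quasi-
separation triggers a ridge-stabilized (10⁻⁶) refit and is flagged.

Stabilized weights use the within-fiscal-year arm fraction as numerator,
so weight means are ≈1 inside every arm-by-year stratum and the year-level
design margins are deliberately preserved (fiscal-year dummies are
therefore *not* expected to balance marginally).  No truncation is applied
by default; `truncate_pct` clips symmetrically at the given percentiles
when set.  Per-protocol analyses censor a non-SHC entry at the **start** of
the interval containing the person's first checkup; the interval itself is
excluded from the outcome risk set (keeping it as a forced event-free
interval measurably dilutes the non-SHC hazard).  The censoring model is a
pooled logistic regression of remaining-in-protocol on the baseline
covariates plus a spline of interval index, fitted on intervals up to and
including the deviation; the stabilized weight of a kept period is the
cumulative product of numerator (intercept+spline) over denominator
probabilities.

## 3. Hazard model and effect measures

The weighted pooled logistic model logit λ(k;a) = β₀ + β_A a + s(k)'γ uses
a restricted cubic spline (Harrell basis) with 4 knots at the 5/35/65/95%
quantiles of the observed interval index (falling back to a linear term if
fewer than three distinct knots exist).  exp(β_A) is reported as the hazard
ratio — the standard odds-as-hazard approximation for rare per-interval
events; the suite verifies agreement with a continuous-time Cox fit
(lifelines) to within 2% at per-interval hazards ≈0.02 and convergence as
intervals shrink.  Options: arm×spline interaction (time-varying HR(k)),
and cumulative checkup sessions as a time-dependent dose covariate
(always 0 in the non-SHC arm).  Standardized cumulative incidence is
1 − Π(1 − λ̂(k;a)) per arm; the risk difference is evaluated at the 10-year
horizon.  Crude estimates refit the same model unweighted (the reference
analysis used a univariable Cox model for the crude HR; the pooled-logistic
analogue is the default here, with `cox_crude_hr` available for
comparison).  Confidence intervals are percentile bootstrap over unique
persons — persons, not entries or periods, because one person's entries
and periods are dependent; replicates reuse frozen design matrices with
multinomial frequency weights, which is algebraically identical to
physically duplicating resampled persons.

The solver for all weighted logistic fits is an in-package IRLS with step
halving and warm starts, cross-checked against statsmodels GLM to 10⁻⁶ in
the test suite; it exists because the bootstrap refits the propensity and
hazard models hundreds of times on ~10⁵–10⁶-row designs.

## 4. The bias audit

The negative-control run repeats the entire pipeline (screening includes
an added exclusion of prevalent depression) and its HR estimates the
residual bias shared with the primary contrast.  The calibrated HR is the
simple ratio primary/negative-control with log-scale independent-variance
CI combination — this reproduces the published 0.86 from 0.90/1.05.  The
E-value uses the common-outcome HR→RR conversion before the E-value
formula because only that route reproduces the published ≈1.456 (the
rare-outcome shortcut gives ≈1.60); `outcome_rare=True` switches to the
shortcut.  A CI crossing 1 yields an infinite E-value bound, serialized as
null.

## 5. The synthetic claims generator

The generator emulates what the emulation assumes, not the full richness
of real claims.  Per person: birth date (age 30–74 at the study start),
sex (65% female), employment (45%), three binary chronic conditions
(allergic rhinitis J30 43%, URI J06 42%, refraction disorders H52 40%)
coded once per enrolled fiscal year, ~27 benign background codes with
prevalences tied mildly to the conditions, a log-normal visit-rate
multiplier, Poisson outpatient visits (3/year) and hospitalizations
(0.06/year), enrollment starting up to 3 years before the study window
with geometric annual disenrollment (0.08) truncated at the
administrative end (fiscal 2022; entries fiscal 2008–2019).

Annual checkup uptake is **exactly logistic in the measured covariates**:
logit p = −3.0 + 2.0·employed − 1.0·female − 0.25·(age−50)/10 +
0.5·J30 + 0.35·J06 + 0.4·H52 + 0.03·(fiscal year − 2008), optionally plus
an unmeasured standard-normal trait (0 by default).  This is a deliberate
design decision: mixtures (latent uptake heterogeneity, a never-taker
mass, unobserved state dependence) make the true assignment probability
non-logistic in L, and measurably leave residual imbalance and bias after
weighting — the generator therefore keeps the propensity model class
correct, and the unmeasured-confounding switches exist for the
negative-control analyses where misspecified adjustment is the point.
These defaults produce baseline imbalances on the scale of the published
cohort (unweighted SMDs: employment ≈0.9, sex ≈0.33, age ≈0.25) and
~38% lifetime participation.

The composite outcome is a yearly Bernoulli hazard on the logit scale:
baseline 0.02/year at the reference covariates, +0.55/decade of age,
−0.10 female, −0.15 employed, +0.3/+0.25/+0.2 for the conditions, plus
log 0.9 from the fiscal year of the first checkup onward (persistent
exposure, matching the ITT contrast).  Onset writes the diagnosis and the
matching dispensing on the same day; diabetes onsets carry both E11 and
E14 so the printed exclusion codes catch prior cases.  The
negative-control (depression) hazard has baseline 0.008/year, its own
covariate effects, an optional unmeasured effect, and never a treatment
term.  Partial-year enrollment scales every annual probability as
1−(1−p)^frac.  Randomness flows from one seed through named sub-streams
(one per purpose and fiscal year), so identical configurations are
byte-identical and person-level draws are stable under unrelated changes.

**The oracle.**  `ground_truth` simulates both potential-outcome
trajectories — checkup from the first eligible year versus never — for
n_mc covariate draws with one shared uniform per person-year (common
random numbers), and fits the common discrete-time odds ratio implied by
the two marginal incidence curves; the Monte-Carlo standard error comes
from 20 batch means.  Under the defaults the oracle marginal HR is 0.906
(conditional 0.90; the small attenuation is odds non-collapsibility).

**What the generator does not emulate**, and what passing tests therefore
do not show about real data: coding breadth and miscoding, visit-driven
diagnosis recording (condition codes are recorded deterministically each
year so history indicators equal the true confounders), measurement error
in checkup values, mortality distinct from disenrollment, calendar-time
outcome trends, and unmeasured confounding of the primary outcome (off by
default).  Real-data propensity models are never exactly correctly
specified; the recovery results here are the best case the design admits.

## 6. Known quantitative limitations

The ITT estimand under crossover is not the always-vs-never oracle
contrast: about 19% of weighted non-SHC person-time under the defaults is
post-first-checkup, which dilutes the adjusted estimand to ≈0.917 against
the oracle's 0.906 (computed exactly by pushing the generator's true
hazards through the weighted score).  This mirrors the real phenomenon —
in the published study 67,811 of 214,554 non-SHC entrants eventually
attended, and their per-protocol HR (0.88) was farther from the null than
the ITT HR (0.90).  The recovery test asks the bootstrap CI (halfwidth
≈0.05 at 50,000 persons) to cover the oracle, which tolerates this
estimand gap.  Per-protocol IPCW under very strong, long-horizon
informative censoring produces heavy cumulative weights (the suite's
censoring checks use a 5-year horizon for that reason).  Finite-sample
IPW bias is visible below ~20,000 persons when weight tails are heavy.

## 7. Scales used by the tests and drivers

Chosen as the package's reference experiment sizes: the recovery and
null-safety experiments use 50,000 persons with 200 bootstrap replicates;
negative-control checks 20,000 persons; the bootstrap-coverage experiment
10 repetitions of 2,000 persons with 60 replicates; the analysis drivers
20,000 persons with 100 replicates; oracle runs 50,000–200,000
counterfactual draws.  Quantiles everywhere (baseline table medians/IQRs,
spline knots) use linear interpolation, except the resource-use threshold
noted above.
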