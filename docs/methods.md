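# Methods

## Setting and decision problem

Patients with a recent NSTEMI (mean age 62) undergo invasive coronary
angiography; the comparison is between disclosing the fractional flow
reserve (FFR) to guide the subsequent management decision and deciding on
visual angiography alone. The decision (medical therapy, PCI or CABG)
drives index-year resource use and the risk of a composite major adverse
cardiovascular event (MACE: death, MI, stroke or revascularisation), which
in turn conditions life expectancy and costs beyond the first year.
Economic outcomes are index-year costs in 2014 GBP and QALYs, from an NHS
payer perspective, over a 1-year (trial) and a lifetime horizon, with costs
and outcomes discounted at 3.5% per year after year 1.

## The decision tree

Each arm's expected index-year cost is

  E[C] = Σ_d P(d) · [ r_d · C(d, MACE) + (1 − r_d) · C(d, no MACE) ] (+ wire cost, FFR arm)

over decisions d ∈ {MT, PCI, CABG}. MACE risks derive from the MT baseline
p₀ by the odds transform: odds = p/(1−p), risk = OR·odds/(1 + OR·odds).
Trial QALYs enter unstructured at the arm level: on generated data (as in
the source analysis) the decision × MACE structure is strongly supported
for costs by partial analysis of deviance but adds nothing for QALYs, so it
is not imposed on them. Beyond year 1 a common tariff applies, conditioned
only on index-year MACE: additional life expectancy of 10.70 (MACE) or 5.96
(no MACE) years, £423/year, and a utility that declines with age with a
−0.05 decrement for MACE. Year t ≥ 2 receives discount weight
(1+r)^−(t−1); the final fractional year contributes pro rata.

Notable point values entered as published: the MACE life expectancy (10.70
years) *exceeds* the no-MACE one (5.96), which is clinically implausible
and looks like a transposition in the source table; the values are kept as
printed, with a `swap_life_expectancy` flag to correct them. The post-year-1
utility schedule is only described qualitatively in the source ("declines
with increasing age"), so the default is a linear decline of 0.003/year
from 0.82 at age 63, fully configurable as an age → utility mapping.

## Statistical models

Costs are fitted with a GLM whose family/link are checked rather than
assumed: the modified Park test regresses log squared residuals on log
fitted values and maps the variance power to a family by a
nearest-integer rule (0 → gaussian, 1 → Poisson-like, 2 → gamma), and a
grouped Hosmer–Lemeshow-type statistic (deciles of fitted values, Pearson
form, df = g − 2) checks calibration. Candidate baseline covariates
(presentation utility, age, sex, smoking, prior PCI, COPD) are screened on
univariable association at p < 0.25, binaries additionally on prevalence
> 10%. MACE is modelled by logistic regression on the treatment decision
plus screened covariates; PCI and CABG odds ratios are exponentiated
coefficients with Wald CIs. Branch costs and the MT MACE baseline are
obtained by marginal (covariate-standardised) prediction: every patient's
predictor of interest is set to the target level, predictions are made on
the response scale and averaged — computed on the pooled two-arm
population by default. Nested models are compared by the deviance
difference scaled by the full model's dispersion against a chi-squared
with df equal to the parameter difference.

Missing 6/12-month EQ-5D responses are imputed by chained equations: each
incomplete column is regressed on arm, baseline covariates, baseline
utility and the other follow-up column; each of m = 20 imputations draws
the residual variance from its scaled inverse-chi-squared posterior and
coefficients from their normal posterior, adds residual noise, and
truncates to the EQ-5D index range [−0.594, 1]. Post-death zeros are
structural, not missing, and are neither modelled nor overwritten.
Estimates are pooled by Rubin's rules (total variance = within +
(1 + 1/m) × between). m is not stated in the source; 20 is a conventional
choice for ~20% missingness. QALYs integrate the utility curve by the
trapezoidal rule over 0/0.5/1.0 years, interpolating linearly to 0 at the
death time — the standard trial-based convention; the source states only
"area under the curve".

## Probabilistic sensitivity analysis

Every uncertain parameter is calibrated by method of moments to its
published mean/SE: gamma for costs, beta for probabilities and utilities
(applied to the magnitude of negative utility changes, sign restored on
sampling), normal (optionally truncated at zero) for life expectancies,
lognormal for odds ratios matched to the printed 95% CI (log-scale SE =
CI log-width / 3.92), and a Dirichlet for the three rival treatment
decisions. The Dirichlet effective sample size is chosen by least squares
over the implied per-category SEs, because no single N reproduces all three
published SEs simultaneously (the published MT and PCI SEs are mutually
inconsistent); an `honour` option matches one chosen category exactly
instead. The default PSA uses 10,000 parameter draws (no count is
published); a bootstrap mode additionally resamples the patient table
within arm and refits every trial-derived parameter per replicate — one
refit plus one parameter draw per replicate in a single loop, not nested.
The ICER is ΔC/ΔE with dominance labels when the signs disagree and an
explicit "undefined" at ΔE = 0; the CEAC reports the fraction of draws
with positive net monetary benefit λ·ΔE − ΔC over a £0–50,000 grid in
£500 steps.

## The synthetic-trial generator

No individual-level data from the source trial are public, so the
generator is the package's data stand-in. It emulates exactly the
structure the analysis assumes — per-arm multinomial decisions, a
patient-level logistic MACE model (covariate effects on the linear
predictor, decision entering as a log-OR shift, intercept solved so the
pooled marginal MT risk equals 9%), a conditional split of MACE into
death/MI/stroke/revascularisation (default 0.1/0.3/0.1/0.5; the source
reports only that event counts were low), uniformly distributed death
times, correlated (exchangeable ρ = 0.5) latent-normal EQ-5D draws clipped
to [−0.594, 1] with the latent means inverted so post-clipping means hit
their targets, completely-at-random missingness at 17%/24% (never at
baseline, never over structural post-death zeros; an optional
covariate-dependent mode exists for stress-testing the imputation), and
resource quantities (Poisson counts, gamma durations, Bernoulli big-ticket
items) whose means are the inverse of the costing step so each category's
expected cost equals its published arm mean. CABG procedure costs follow
the drawn treatment decision at £5041 per operation, which lands within
Monte-Carlo error of the published category means without separate
calibration.

Two published target sets are mutually inconsistent and cannot both be hit:
the arm QALY totals (0.801 standard, 0.82 FFR) versus the trapezoid of the
published arm mean utilities (0.815 / 0.8175) once index-year deaths exist.
The generator treats the QALY totals as primary (they are what the pipeline
reports) and solves a small additive offset on the 6-month mean (FFR arm)
and the 6- and 12-month means (standard arm) so the expected arm QALY hits
its target; the FFR 12-month survivor mean is held at its published 0.83.
The standard arm's follow-up means consequently sit ~0.015 below their
published values — the price of the inconsistency, chosen deliberately.

Arm sizes and covariate prevalences are not published: defaults are 176
patients/arm (pilot scale), age ~ N(62, 11²) truncated to [30, 95], and
prevalences 0.74/0.30/0.12/0.11 for male sex/smoking/prior PCI/COPD — all
invented and configurable. The unit-cost table carries one reconciliation:
the pressure wire is listed at £2700 but the published mean wire cost
(£279 at 1.03 wires/patient) implies an effective £270.87 per wire; the
effective value is the default and the list price ships alongside.

What the generator does *not* emulate: angiographic images or FFR traces
(decisions are drawn directly), EQ-5D descriptive-system responses
(utilities are emitted directly), informative missingness by default,
within-patient correlation between resource use and utilities, and any
covariate effect on costs. Passing tests therefore demonstrate that the
pipeline recovers the parameters of data with this assumed structure —
not that the structure matches any particular real trial.

## Numerical choices

GLMs fit by IRLS to 1e-8 relative tolerance within 100 iterations;
non-convergence and separation raise. Decile grouping uses a stable sort.
The Park test treats squared residuals at or below a relative tolerance of
(1e-10·max|y|)² as exact zeros. Bootstrap CIs are percentile-based with
B = 2000 by default (the interval method is not published). Discounting is
annual with year 1 undiscounted and no mid-year correction (source is
silent; both are configurable). All randomness flows through explicit
`numpy.random.Generator` seeds; identical configuration and seed give
byte-identical tables.

## Problem sizes

Calibration-recovery checks run at 50,000 patients per arm, where
Monte-Carlo standard errors are small enough to resolve the published
increments (−£349 cost, 0.02 QALYs); the narrative analysis scripts run at
the pilot scale of 176/arm, where — as in the source — the event-cost and
length-of-stay categories dominate the uncertainty. The PSA default is
10,000 draws; distribution-moment checks use 2×10⁵–10⁶ draws.

## Known limitations

Exact reproduction of the published adjusted results (branch costs,
per-arm cost and QALY totals, £112/£133 increments, £7516/£4290 ICERs,
64%/59% CEAC values) is not possible from published inputs alone: they depend on the
unpublished individual-level data and on arm-specific regression
predictions that were never printed. The pipeline reproduces the published
*unadjusted* increments under its calibrated generator and the qualitative
model-selection findings; the decision-model point run with bundled inputs
yields near-zero incremental costs rather than the published +£112/+£133,
for exactly this reason. The lifetime model conditions on composite MACE
only, with no per-event differentiation and no recovery of quality of life
after MACE; deaths inside the index year are not modelled separately at the
cohort level (the blended published life expectancies are used).
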