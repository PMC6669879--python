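# Methods

## Scope and model

`ceatk` carries out a trial-based cost–utility analysis from the
perspective of the NHS and personal social services: participant-level
costs and QALYs over a 12-month primary horizon (18 months in
sensitivity analysis), covariate-adjusted incremental means, and
decision-analytic summaries (ICER, cost-effectiveness plane, CEAC).
The statistical model is deliberately the standard one for such
analyses: arm differences from least-squares regressions of each outcome
on treatment allocation plus pre-specified baseline covariates, with all
uncertainty propagated non-parametrically.

## Utilities and QALYs

EQ-5D-3L profiles are scored with an additive-decrement tariff: utility
`1 − c − Σ d(dim, level) − d₃·1{any level 3}`, full health exactly 1.
The packaged default is the UK TTO value set; any coefficient set
satisfying the same structure can be supplied as configuration. QALYs
are the trapezoidal area under the linearly interpolated utility curve,
divided by 12 to convert months to years. The horizon must coincide
with an assessment wave: no extrapolation or carry-forward is applied,
and missing profiles are the imputation stage's responsibility, not the
scorer's. Baseline utility imbalance is handled in the adjustment
regression (baseline utility is a covariate), not inside the QALY
integral itself; this is an interpretation choice, flagged here because
the alternative (regression-free baseline-adjusted QALYs) exists in the
literature.

## Costing

Health and social care use is costed as counts × unit costs from a
user-supplied table (the packaged defaults are illustrative
placeholders, price year 2014–2015). Blank items inside a returned
questionnaire block count as zero use; a wholly absent block is missing
data. Medication spells contribute their category's median daily cost
for every day the spell overlaps the costing window (half-open day
intervals), assuming full adherence.

The therapy programme itself is micro-costed. One attended individual
session costs `hourly employment cost × (1 + r) × duration`, where
`r = 0.91` is the non-direct-to-direct time ratio; unattended individual
sessions cost nothing (the therapist redeploys the time). Group
sessions ran regardless of turnout in closed groups, so each session's
full cost — with two therapists when more than three members were
invited — is allocated equally across everyone invited, attending or
not. Allocation conserves money to the penny; costs are carried at full
precision and rounded only at render time. Productivity losses (absence
and presenteeism hours × national gross wage, employed participants
only) are computed but excluded from every NHS/PSS total; a sensitivity
scenario adds the absenteeism component.

## Missing data

Missing cost, utility and depression-score aggregates are multiply
imputed by chained equations. The default conditional model is
predictive mean matching (type 1, five donors, posterior parameter
draws), which respects the skew and non-negativity of cost data;
Bayesian normal regression and logistic models are available per
variable. Imputation operates at the aggregate level (interval cost
totals, wave utilities, wave scores) with arm, baseline covariates and
the fully observed intervention cost as predictors. The number of
imputations follows the percentage-of-incomplete-cases rule (m =
round(100 × fraction), floor 2, so 30% → 30). Each of the m datasets
runs from an independently spawned sub-seed; observed cells are asserted
unchanged. Point estimates and variances are combined by Rubin's rules
(total variance = within + (1 + 1/m) × between). MICE is implemented
in-package — the contract requires per-dataset seed isolation and an
explicit donor rule — and is cross-checked in the test suite against
statsmodels' independent chained-imputation implementation on MCAR data.

## Uncertainty

Confidence intervals and the CEAC come from a non-parametric bootstrap
nested within the imputations: B resamples of participants (with
replacement, stratified by arm with arm sizes fixed, preserving the
randomisation ratio) of each completed dataset, refitting both
adjustment regressions in every resample so adjustment uncertainty
propagates. The m × B incremental pairs are pooled into a single cloud
(default 30 × 1000 = 30 000) from which percentile intervals, quadrant
shares (half-open convention: NE means ΔE > 0 and ΔC > 0) and
CEAC(λ) = P(λ·ΔE − ΔC > 0) are read off directly. Rubin-pooled point
estimates and standard errors are reported alongside the cloud;
singular resampled designs are redrawn (capped at 100 per dataset).
The ICER is the plain quotient ΔC/ΔE of the pooled point estimates,
labelled by its plane quadrant and left undefined at ΔE = 0.

## Synthetic-trial generator

The generator emulates the study conditions so every stage is testable
without confidential data: 162:88 allocation, waves at 0/7/12/18 months,
and defaults that reproduce the published differences — a 0.032 QALY
difference at 12 months, a −£909 other-care difference, and ≈£5000 mean
intervention delivery cost.

* **Utilities.** Each arm has a target utility per wave; participant
  heterogeneity (SD 0.10) and wave noise (SD 0.22, giving a QALY
  standard error ≈ 0.02 at the trial's size) are added and the result
  snapped to the nearest attainable EQ-5D-3L profile, because the
  pipeline consumes five-digit states. The noiseless targets are
  themselves real profiles chosen so the 12-month trapezoid difference
  is exactly 0.032 (Δu = 0.034 at 7 m and 0.072 at 12 m;
  6·0.034 + 2.5·0.072 = 12·0.032), which makes the zero-noise
  pipeline-exactness test meaningful; other injected QALY differences
  are honoured only up to state-grid rounding. The 18-month profiles
  put the control arm 0.001 ahead, mirroring the small late reversal.
* **Costs.** Service counts are negative-binomial (size 0.15) around
  per-arm means allocated over ten service codes, scaled by a
  participant-level gamma propensity (SD 0.5) that induces
  baseline-to-follow-up cost correlation. These dispersion defaults
  were calibrated once so the ΔC 95% CI half-width at 162:88 is ≈ £900,
  matching the published interval width. The intervention arm uses
  markedly less other talking therapy (the programme discourages it);
  months 12–18 use control rates in both arms, since the published
  cumulative other-care difference barely moves after the primary
  end-point. A `normal` cost family (aggregate Gaussian interval costs)
  exists for coverage simulations where skew is a nuisance; negative
  draws are clipped at zero, a < 0.5% distortion at the default CV.
  Medication spells are identically distributed in both arms, so the
  injected total cost difference is exactly intervention mean + other-care
  difference.
* **Intervention cost.** Attendance follows a per-participant beta
  propensity (mean 22.8/29 individual sessions attended; 80% receive all
  27 group invitations, the rest drop out uniformly, giving ≈ 24.4
  invitations and ≈ 19.3 attendances). The therapist hourly employment
  cost is calibrated — by a large fixed-seed Monte-Carlo expectation of
  the attendance model — so the expected micro-cost equals the configured
  mean; the calibrated parameters travel with the generated dataset.
  With arm sizes not divisible by the group size of 7, the leftover
  mini-group slightly raises realised mean cost (≈ 0.6% at n = 162).
* **Missingness.** One latent draw per participant removes their whole
  follow-up service-use record, with probability constant (MCAR) or
  logistic in baseline severity (MAR), the intercept solved by
  quadrature so the marginal masked fraction equals the target. Block
  loss makes the per-wave masked fraction, the incomplete-at-12-months
  fraction and choose_m's input coincide — the three ways "30%" is used
  in this design. Outcomes are masked jointly with the cost block at a
  configurable rate (default 1: a missed interview loses everything);
  baseline fields and the therapy-record attendance log are never
  masked. Real follow-up loss is more graduated (partial waves,
  increasing over time); the generator trades that texture for exact
  bookkeeping.
* **Seeding.** All draws run through per-participant substreams keyed
  by (seed, arm, within-arm index), so changing one arm's size never
  reshuffles other participants, and fixed seeds give byte-identical
  tables.

What passing tests on these data do *not* show: robustness to
missing-not-at-random loss, to item-level (rather than block-level)
missingness, to cost distributions outside the negative-binomial/gamma
family, or to measurement error in the EQ-5D itself.

## Numerical choices

Bootstrap regressions solve batched normal equations (chunked to bound
memory); the chained-equation fits add a 1e-8 ridge so transiently
collinear predictor sets stay estimable. Nearest-state snapping breaks
ties toward the lower utility and then the lexicographically smallest
profile, so it is deterministic. `choose_m` rounds half-up (12.5% → 13).
Exact zeros on the CE plane follow the half-open quadrant convention.
Percentages in reports round half-up to whole numbers. Sub-seeds are
spawned from numpy `SeedSequence` and reduced below 2³¹.

## Problem sizes in the test suite

The suite exercises the pipeline at the trial's own size (n = 250) for
endpoint behaviour, n = 2000 for parameter-recovery checks under 30%
MAR missingness with m = 30, n = 5000–10 000 for generator moment and
missingness-rate checks, and 200 repetitions of n = 250 for bootstrap
coverage; these sizes give Monte-Carlo error comfortably inside the
3-standard-error acceptance bands while keeping the full suite around
a minute or two.

## Known limitations

The ICER of a single modest-sized trial is a noisy ratio statistic: at
n = 250 the QALY difference's standard error (≈ 0.02) is of the same
order as plausible effects, so single-run ICERs vary widely even though
the CEAC conclusion (probability ≈ 0 at £30 000/QALY for the injected
effects) is stable. Fieller-type ICER intervals, value-of-information
analysis, model-based extrapolation beyond 18 months and
pattern-mixture sensitivity to MNAR are out of scope. The packaged
unit-cost values are placeholders for real national tables, and the
pre-specified clinical covariate list is fully configurable rather than
fixed, since it belongs to the companion clinical analysis.
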