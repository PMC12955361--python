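# Methods

## The kinetic model

The package models hemoglobin glycation at steady state. Intracellular
glucose exposure saturates with plasma glucose through a Michaelis–Menten
transport term, captured by the apparent-glucose composite
X(MG) = 1/MG + 1/K_M with K_M = 472 mg/dL. The glycated fraction satisfies

    A1c = 100 / (1 + 1e5 · X(MG) / AGR),

where the apparent glycation ratio AGR (mL/mg) bundles a person's glycation
rate constant and red-cell lifespan. Inverting at a calibration visit gives
AGR = 1e5·X(MG)/(100/A1c − 1); a later measured A1c is personalized by

    pA1c = 100 / (1 + (AGR/65.1) · (100/A1c − 1)),

with 65.1 mL/mg the standard red-cell-lifespan glycation rate constant
("reference glycator"). Three structural facts pin this algebra and are
enforced by tests: (i) pA1c ≡ A1c exactly at AGR = 65.1; (ii) the reference
curve reproduces the familiar correspondence MG 154 mg/dL ↔ A1c ≈ 7.0%;
(iii) a high glycator (AGR > 65.1) has a measured A1c above the reference
curve for the same MG and is revised downward. The central identity —
pA1c computed from any calibration pair (A1c, AGR(MG, A1c)) equals the
reference curve at MG, independent of A1c — is property-tested to 1e-12
relative.

Assumptions and limits. The model is steady-state: it assumes glucose
stable over roughly the red-cell lifespan, and a person's AGR constant as
long as red-cell physiology is stable. No quantitative stability criterion
is imposed; glucose CV is reported alongside so consumers can judge. The
`estimate_mg` inversion is defined only below the forward model's
finite-glucose asymptote 100/(1 + 1e5/(AGR·K_M)) (≈ 23.5% at the reference
AGR); above it the requested A1c is unreachable at any glucose and a domain
error is raised. AGR units are mL/mg throughout. K_M and the reference
constant are inputs, never estimated from data.

Unit conversions: glucose mmol/L = mg/dL / 18.016; A1c IFCC mmol/mol =
10.929·(NGSP% − 2.15) (the NGSP master equation), with reporting rounded
half-up to one decimal (glucose) and to an integer (IFCC). Note 10.7% NGSP
converts to 93 mmol/mol under the master equation even though 94 is
sometimes quoted for cohort means — such quotes are typically converted
from an unrounded mean; this package always applies the equation to the
value given.

## Study protocol and metrics

The wear protocol is three consecutive blinded sensor wears of 10–14 days
at 15-minute cadence, sensor-reportable range 40–500 mg/dL, with at most
48 h between wears; a protocol is valid only if all three wears span ≥ 10
days and every gap is ≤ 48 h. `days_covered` is the timestamp span — gaps
inside a wear do not invalidate it. Calibration MG pools wears 1–2
(matching the AGR calibration visit at the end of wear 2, laboratory A1c
only); evaluation MG pools all readings through wear 3, overlapping the
calibration window by design — the protocol is reproduced as specified,
not re-optimized.

Consensus metrics are computed with equal weight per reading (equals time
weighting at fixed cadence): mean, population SD (divisor n — pinned so
tests are exact; the difference from the sample SD is negligible at
thousands of readings), CV = 100·SD/mean, and % time <54, <70, 70–180,
>180, >250 mg/dL. Boundary ties, unstated in the consensus standard, are
pinned: 70 and 180 are counted in-range; the < and > bands are strict.
Pooling across wears concatenates readings (reading-weighted), not per-wear
means. Metrics are computed on clamped values, mirroring what the device
reports.

## The synthetic cohort

The generator's defaults are the study conditions: 64 subjects; per-subject
target MG ~ Normal(257, 57) mg/dL truncated to [80, 450]; target CV ~
Normal(44, 10)% truncated to [23, 62]; AGR ~ Normal(65.1, 6) mL/mg
truncated positive (no between-subject AGR spread is reported anywhere, so
the 6 mL/mg SD is this package's modelling choice — roughly 9% relative,
enough to make personalization matter without producing implausible A1c
values); covariate frequencies mirror the reported cohort table (45%
children, 48% female, 13% hemoglobin AS, 10% low G6PD, income
14/25/22/39%).

Each wear's glucose trace is baseline + three components chosen because
they give independent control of mean and CV (no trace model is specified
by the protocol):

* an Ornstein–Uhlenbeck (exact AR(1) discretization) component with mean
  reversion 0.25 h⁻¹ (~4 h autocorrelation time, typical of glycemic
  excursions);
* one diurnal sinusoid, amplitude 10% of the subject's MG, random phase;
* meal pulses at ~3.2/day (Poisson), amplitude uniform on 40–140 mg/dL,
  gamma-like rise-and-decay kernel peaking 1.5 h after onset.

The summed process is affinely rescaled so the realized pre-clamp mean and
CV equal the subject's targets exactly, then clamped to [40, 500] mg/dL.
Clamping shifts the realized (post-clamp) moments slightly for
high-variability subjects; the pre-clamp values are retained on each trace
so tests can verify targeting exactly. A1c at the end of wear k uses the
trailing MG pooled over wears 1..k through the forward model at the
subject's true AGR, times multiplicative lognormal noise with unit mean
(laboratory CV 2%, point-of-care CV 4% — assay imprecision data were not
obtainable for the motivating setting, so both are explicit configuration
knobs; 0 disables noise). Glucose values are kept as floats and A1c at full
precision in the CSVs so that a noise-free run round-trips exactly: the
pipeline's AGR estimates then match the ground truth to < 1e-6 mL/mg, a
frozen test.

What the generator does *not* emulate: sensor error (MARD), dropouts and
compression artifacts, physiological insulin–meal dynamics, within-person
AGR drift, or non-stationary control changes across wears. Passing tests
therefore demonstrate correctness of the estimator pipeline under the
stated statistical structure, not robustness to real-sensor pathology.

Randomness: one master seed; per-subject/per-wear substreams derive from
`SeedSequence([seed, crc32(subject_id), wear_index])`, so any single trace
is reproducible in isolation and cohorts are byte-identical across runs.

## Cohort statistics

* `fit_simple`: OLS with R² = 1 − RSS/TSS and RMSE = √(RSS/n); checked
  against a normal-equations oracle at machine precision.
* `compare_predictors`: straight-line fits of evaluation MG on laboratory
  A1c, POC A1c and pA1c over the identical subject set (plus POC vs lab).
  The pA1c–MG relationship is mildly nonlinear through the kinetic model;
  a linear fit is used for comparability of R²/r/RMSE, as in standard
  practice. The exact noise-free consistency check is instead performed on
  the reference-curve scale (reference-glycator A1c at the evaluation MG
  regressed on pA1c), where the noise-free fit is exact (R² = 1 to 1e-6).
* `spearman`: Pearson correlation of mid-ranks; an all-tied variable
  returns 0 with a warning (documented convention).
* `welch_t`: unequal-variance t with Satterthwaite df (the pooled-variance
  variant is deliberately not offered; Welch is the safer default).
* `stepwise_aic`: bidirectional stepwise from the intercept-plus-primary
  model with AIC = n·ln(RSS/n) + 2(p+1) (p = number of slopes; only AIC
  differences matter, the constant convention is pinned for
  reproducibility). Single best add/drop per step, ties broken by
  candidate order, complete cases only, additions that would exhaust
  residual degrees of freedom or create a rank-deficient design are
  skipped; a rank-deficient full design is an error naming the aliased
  columns. Categorical covariates expand to indicators with a fixed level
  order; Tanner stage is treated as a numeric ordinal.
* `correlation_power`: Fisher-z closed form Φ(√(n−3)·atanh ρ − z_{1−α/2})
  and a Monte-Carlo method (exact t-test on simulated bivariate-normal
  cohorts); the two agree within Monte-Carlo error. As ρ → 0 the
  Monte-Carlo method tends to α while the Fisher-z form tends to α/2 (it
  ignores the lower rejection tail) — inherent to the approximation, and
  immaterial at design-relevant ρ. The design question "power to detect
  ρ = 0.52 at n = 60" is answered by the single-correlation calculation;
  no covariate-adjusted power variant is implemented.

`run_pipeline` stages: ingest → per-subject QC (protocol-invalid subjects
excluded with a logged reason) → metrics → AGR (calibration MG + visit-2
laboratory A1c) → pA1c (visit-3 laboratory A1c) → fits, Spearman CV vs
% < 54, Welch child-vs-adult tests on MG/CV/% < 70, stepwise-AIC models
for MG on laboratory A1c and on pA1c, and the design power. Output is a
JSON-serializable dict; identical inputs give byte-identical JSON.

## Problem sizes in the default test run

The suite exercises: distribution moments at n = 2000 profiles; full trace
pipelines at 5–10 subjects; one 64-subject end-to-end run in the worked
example; the ΔR² superiority property (R²(pA1c) > R²(lab A1c)) over 200
seeded cohorts of 64 subjects at the profile level — realized MG is the
profile target with 3% window-to-window variation, with assay noise on all
A1c values — which isolates the property being tested (between-subject AGR
variance vs assay noise) from trace-level Monte-Carlo noise and keeps the
replicate loop fast. The acceptance script's power target uses 20,000
simulated cohorts of n = 60.

## Known limitations

* Steady-state only; no red-cell age-distribution dynamics, so the model
  cannot represent A1c transients after abrupt control changes.
* The AGR population distribution is a modelling choice; recovery tests
  validate the estimator, not that distribution.
* The linear MG-vs-pA1c comparison understates pA1c's fit quality slightly
  at the extremes of the MG range (curvature of the reference curve).
* Stepwise AIC at small n (tens of subjects) is permissive and will admit
  spurious covariates; its output is descriptive, not confirmatory.
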