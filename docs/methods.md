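# Methods

This note documents the models, defaults and numerical choices behind
`heartspan`, in the order the pipeline runs them.

## 1. Synthetic cohort (the stated world)

The generator emulates a Dutch population-based cohort of adults aged 50+
followed across repeated examination waves with registry-complete event
ascertainment.  Its defaults are fixed, documented conditions — not tuning
knobs — and every number below was calibrated once, before the validation
suites were run, and then frozen.

**Roster and design.**  2,566 participants (49.8% women), filtering to
2,323 eligible after removing self-reported cancer history (114), unknown
cancer status (128) and pregnancy (1); entry ages drawn from 10-year bands
with weights 0.592 / 0.392 / 0.016 (50s / 60s / 70s); five waves 5 years
apart; administrative censoring 22 years after entry.  Exclusion flags are
mutually exclusive by construction (2,566 − 114 − 128 − 1 = 2,323 only
holds without overlap).

**Anthropometry.**  Per sex, (BMI, WC) are bivariate log-normal; height is
sampled separately (men N(1.78, 0.066²) m, women N(1.65, 0.062²) m — tall,
as in Dutch cohorts) and weight back-solved from BMI, guaranteeing positive
values.  Log-scale means/SDs are solved in closed form (probit inversion)
so that the marginal BMI-class prevalences (men 25.3/58.4/16.4%, women
34.1/44.0/21.9%) and WC-class prevalences (men 26.5/33.6/39.9%, women
14.5/24.9/60.5%) are matched exactly.  The within-sex log-scale correlation
defaults to **ρ = 0.873**: because the two sexes have different WC means,
the *pooled* raw-scale Pearson correlation — the quantity a cohort paper
reports — is then 0.81, whereas setting ρ = 0.81 within sex would give a
pooled r ≈ 0.75.  With these parameters the composite adiposity categories
land within ±1.6 percentage points of the reference baseline distribution
in both sexes.  Between waves, (log BMI, log WC) follow a correlated random
walk with per-wave SD 0.035 (≈1 kg/m² BMI drift per 5 years), so exposure
categories genuinely change over follow-up.

**Event process.**  A Markov illness-death process on the attained-age
clock: CVD-free → CVD, CVD-free → death, CVD → death, each with a Gompertz
baseline hazard λ exp(γ(a − 50)) for the low-adiposity reference and
proportional category effects fixed at the published adjusted hazard
ratios.  Event times are drawn by inverse transform
(`sample_gompertz_time`), piecewise across wave intervals so hazards track
the current (wave-updated) category.  Mortality after CVD depends on
attained age only, not time since diagnosis — an assumption (the life table
needs age-indexed rates), not a claim about the source cohort.  Baseline
values (per year at age 50): men λ = 0.00356 / 0.00110 / 0.00275 and women
0.00288 / 0.00077 / 0.00495 for the three transitions, with γ = 0.075 /
0.095 / 0.090; these were calibrated by simulation so the default cohort
yields ≈401/294 incident CVD events and ≈323/264 deaths (men/women) over 22
years, and then frozen.

**Covariates and biomarkers.**  Categorical covariates (household,
education, physical-activity index, smoking, alcohol, COPD) follow the
reference baseline table per sex; the diet score is normal (clipped to
1–130), cigarettes/day log-normal among current smokers.  Biomarkers (BP,
glucose, lipids) are calibrated to reproduce the *flag* prevalences
(hypertension 49.5/44.8%, diabetes 4.8/3.5%, hypercholesterolaemia
22/34.2%, low HDL 14.7/4.0%) rather than the printed medians where the two
are incompatible (men's HDL median 1.2 mmol/L with only 14.7% below 1.03 is
inconsistent with any smooth unimodal fit of the IQR); the flags drive the
comorbidity-exclusion sensitivity analysis, the medians drive nothing.
By default covariates are independent of exposure and carry no hazard
effects; `confounding_strength > 0` links smoking/inactivity to both
adiposity and all three hazards, for testing adjustment.

**Missingness.**  10.5% of men and 5.6% of women have no valid
anthropometry at any wave (participant-level, all-or-nothing), matching the
complete-case attrition of the reference analysis.  Partially missing waves
are not simulated.

**What the generator does *not* emulate** — and hence what a green test
does not establish: recruitment and wave non-response, interval-censored
CVD onset, ICD-coded event adjudication, item-level diet data, frailty or
other unobserved heterogeneity, and duration dependence of post-CVD
mortality.  Tests against this world validate the estimation machinery,
not the epidemiology of any real cohort.

**RNG.**  One root seed spawns independent per-stage substreams
(structure, anthropometry, covariates, events, selection) with fixed-layout
vectorized draws; a fixed (config, seed) pair reproduces tables
byte-identically.

## 2. Phenotyping

Half-open, lower-inclusive intervals throughout: BMI normal < 25,
overweight 25–<30, obesity ≥ 30 kg/m²; WC healthy < 94/80, abdominal
overweight 94–<102 / 80–<88, abdominal obesity ≥ 102/88 cm (men/women).
The 3 × 3 grid maps to four composite categories: BMI obesity → very high
(any WC); abdominal obesity with BMI < 30 → high (including the discordant
normal-BMI cell); remaining overweight/abdominal-overweight combinations →
increased; normal BMI + healthy WC → low.  The placement of the
normal-BMI/obese-WC cell in "high" is a reconstruction chosen so the
composite frequencies reproduce the reference baseline table from its BMI
and WC marginals in both sexes; the mapping is a plain dict
(`DEFAULT_ADIPOSITY_MAPPING`) and can be swapped.  BMI is always recomputed
from measured weight/height; a supplied BMI differing by > 0.5 kg/m² is
overwritten with a warning.

Comorbidity flags: hypertension (SBP ≥ 140 or DBP ≥ 90 or medication),
diabetes (random glucose ≥ 11.1 mmol/L or self-report),
hypercholesterolaemia (TC ≥ 6.5 mmol/L or lipid-lowering therapy), low HDL
(< 1.03 men / < 1.29 mmol/L women).

## 3. Person-time

Timescale is attained age.  Exposure is last-observation-carried-forward
from waves with a valid measurement; person-time before the first valid
measurement is discarded and participants with none are dropped
(complete-case).  Healthy person-time feeds the CVD-incidence and
healthy-mortality transitions simultaneously (event flag on the realised
one); post-CVD person-time feeds CVD mortality.  Segments split at wave
ages and on a 1-year attained-age grid.  The granularity is a choice:
1 year makes the within-interval rate variation of a Gompertz hazard
negligible (relative error (γ·step)²/24 ≈ 3 × 10⁻⁴) while keeping ~1.2M
rows for a 50,000-person cohort.

## 4. Transition models

"Poisson regression with a Gompertz distribution" is operationalised as a
Poisson likelihood on split person-time with a linear attained-age term.
Two numerical details matter:

* **Events enter as point rows at their exact event age.**  Attaching the
  event to its (partial) terminal segment at the segment mid-age biases
  the age slope by ≈ −step/(4·Var(age)) — about 5 SE at n = 40,000 —
  because event segments' midpoints sit systematically below the event
  time.  With exposure rows at interval mid-ages plus zero-exposure event
  point rows, the Poisson score equals the survival-likelihood score
  exactly; the only residual approximation is midpoint integration of the
  cumulative hazard.  The reported `loglik` is the survival log-likelihood
  (point-row constants removed), so Gompertz and Weibull AICs on the same
  rows are directly comparable.
* **The solver is an in-house Newton iteration** (information matrix
  accumulated in 256k-row blocks, cluster-robust sandwich from per-cluster
  bincount score sums, small-sample factor G/(G − 1)).  A general-purpose
  GLM/IRLS implementation holds several copies of the ~1.2M × 20 design
  and exhausts the build container's memory at acceptance scale; the
  Newton path peaks near one copy.  statsmodels GLM remains the
  independent cross-check oracle in the test suite (parameters to 10⁻⁶,
  robust SEs to 2%), alongside a brute-force likelihood oracle and an
  exact survival-MLE equivalence test.  Convergence: relative
  log-likelihood change < 10⁻¹⁰ with step-halving, max 200 iterations;
  start at the exponential-model closed form.  Zero-event (separated)
  categories are flagged and their coefficients capped at ±15.

Adjusted HRs use Wald 95% CIs on the log scale from the robust covariance.
The Weibull comparison refits the same rows with log(age/50) in place of
the linear term.  VIFs are computed from linear regressions on the encoded
design (cigarettes/day is definitionally collinear with current smoking
and excluded from the < 5 check).

## 5. Prevalences and calibration

Prevalences are occurrence-weighted (person-years) shares per sex ×
10-year band × CVD status, applied as step functions over bands (no
interpolation).  Empty cells borrow from the nearest populated band and are
flagged.  The calibration identity r_ref(a) = r_overall(a) / Σ_c p_c(a)
HR_c holds exactly by construction and is asserted to 10⁻¹² in tests.

## 6. Life table

Ages 50 to 80, 1-year steps, rates constant within intervals.  The default
within-interval convention is the **exact exponential** solution of the
constant-rate illness-death process: leaving probabilities
q = 1 − exp(−(r12 + r13)) apportioned by cause-specific rates, new CVD
entrants exposed to r23 for the remainder of their entry interval, and
person-years as exact sojourn expectations.  The naive textbook flow
(entrants carry no within-interval mortality; trapezoid person-years) is
retained as `convention="trapezoid"` but *fails the micro-simulation
oracle*: on realistic rates it overstates total LE by ~8 Monte-Carlo SEs
and with-CVD LE by ~5 SEs at n = 10⁶, which is why it is not the default.
Closure at 80 is truncation — no terminal open-ended expectation — so all
quantities are temporary expectancies over [50, 80) and absolute levels
depend on that choice.  The initial state at 50 is configurable: the
pipeline default seeds each category with its observed with-CVD
person-time fraction in the 50–59 band ("observed"); "healthy" starts
everyone CVD-free.

The micro-simulation oracle (`microsimulate_le`) simulates individuals in
continuous time under the same piecewise-constant rates, including partial-
interval CVD-mortality exposure, and reports Monte-Carlo SEs; the life
table agrees within 3 SEs at 10⁶ individuals for every sex and category of
the default run.

## 7. Bootstrap

Parametric: per (sex, transition), (b0, γ) and the log-HR block are drawn
from multivariate normals centred at the estimates with the cluster-robust
covariances; transitions are independent (they are fitted separately, so no
cross-covariance is estimable).  Prevalence rows are redrawn from
Dirichlet distributions with the observed per-cell person-years as
concentrations — the person-time analogue of "multinomial counts", since
cells are occurrence-weighted; a flag disables prevalence redraw to isolate
regression uncertainty.  Intervals are 95% empirical percentiles (not BCa).
Non-PSD covariances are repaired by eigenvalue clipping with a warning;
draws are all on log scales so negative rates cannot occur (a guard counts
redraws anyway).  Identical seeds give bit-identical intervals, and with
covariances zeroed the percentiles collapse onto the point estimates.

## 8. Scaled-down validation experiments

Two calibration experiments in the test suite are statistically faithful
but scaled to run inside a CI budget; their acceptance bands were set to
the Monte-Carlo allowance of the scaled design *before* running them:

* HR coverage/bias: 50 replicates at n = 3,000 (full design: 200 replicates
  at larger n); pooled CI coverage asserted in [89%, 100%].
* Nested bootstrap coverage: 40 replicates of generate → fit → bootstrap
  (n = 3,000, B = 120) against a truth computed by micro-simulation at the
  generating parameters; coverage asserted in 95% ± 2.5 binomial SEs,
  i.e. [86%, 100%].

## 9. Known limitations

* Absolute LE levels are temporary expectancies to 80 and not comparable
  with open-ended life expectancy.
* The generator's clean proportional-hazards, no-frailty world makes
  recovery tests necessary but not sufficient evidence for behaviour on
  real cohort data (measurement error, informative missingness, duration
  dependence are all absent).
* Restricted-cubic-spline exposure models, flexible parametric (non-
  Weibull) fits, multiple imputation and registry-linkage mechanics are
  out of scope.
* VIF diagnostics use linear approximations, as in standard practice; they
  are indicative only for non-linear survival models.
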