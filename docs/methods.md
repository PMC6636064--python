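# Methods

This note documents the generative model, the statistical procedures, the
defaults and the numerical choices behind `cvduncert`, and what the
synthetic test bed can and cannot demonstrate about real EHR data.

## Synthetic cohort model

Each patient has sex s (female fraction 0.51), an index date drawn
uniformly over 1998-01-01..2015-12-30, age at index from a truncated
normal on [25, 84] with sex-specific moments, continuous risk factors
(BMI, SBP, SBP variability, cholesterol/HDL ratio) from truncated normals
whose means drift linearly with age (marginal moments match the target
cohort's descriptive statistics; residual SDs are reduced so the marginal
SD is preserved), categorical smoking/ethnicity/region from the published
frequencies, a Townsend deprivation quintile (uniform), eighteen binary
medical-history flags at published prevalences (stage-4/5 CKD nested
inside stage-3/4/5; erectile dysfunction male-only), and negative-binomial
consultation/prescription counts dichotomised at >50 for modelling.

The event hazard is

    h(t) = h0_s(t) * exp(beta' x + u_r + delta * (y + t - 1998)),

with h0_s Weibull (`baseline_hazard` in the config), u_r ~ N(0, sigma_r^2)
drawn once per region per cohort seed, delta = log 0.96 per calendar year,
and y the decimal index year. Two deliberate choices:

* **Trend on current calendar time.** The within-follow-up factor
  exp(delta * t) is common to all patients, so it folds into the baseline
  hazard: a Cox model with calendar-time-at-index as covariate has true
  coefficient exactly delta, *and* the crude person-year event rate
  declines by exp(delta) per calendar year, so the Poisson sensitivity
  analysis estimates the same quantity. Applying the trend only at the
  index date would break the latter (the rate at calendar year c would
  average over index years <= c and attenuate the fitted trend).
* **Exponential default baseline (shape 1).** With shape > 1 the hazard
  rises with time-in-study; because mean time-in-study grows with calendar
  year, the calendar-year-only Poisson model absorbs part of that rise
  into its trend coefficient (about +0.01 on the rate ratio at shape
  1.15). Shape 1 keeps all duration/calendar structure in the index
  covariates and the trend — the structure the risk models themselves
  assume — so the generator's trend is recoverable by both analyses. The
  scales (309 / 229 years for females / males) are calibrated so the
  marginal incidence matches the published 6.27 and 8.24 events per 1,000
  person-years.

Event times are sampled by inverse transform on
G(t) = ∫ h0(u) exp(delta u) du, precomputed per sex on a 20,001-point grid
(by-parts form so the integrand is bounded for any shape; exact when
delta = 0). Censoring is the earlier of the administrative study end
(2015-12-31) and an exponential dropout (rate 0.04/yr). Follow-up has a
half-day floor. Calendar arithmetic uses exact day counts / 365.25.

Missingness is MAR through a per-variable logistic model in age (slope
-0.4 per decade: older patients are better recorded), with the intercept
calibrated per sex on the cohort at hand so the expected recorded fraction
equals the published recording rates. Remaining small residual: depletion
of high-risk patients over calendar time makes the person-year trend
estimate slightly conservative (~0.955 vs 0.96 at n = 120,000); this is a
real feature of heterogeneous cohorts, not an implementation artifact.

What the generator does **not** emulate: correlated measurement error or
repeat measurements, practice-level clustering and coding drift,
informative (MNAR) missingness, competing mortality, covariates changing
during follow-up, or any linkage artifacts. Passing tests therefore show
that the estimators recover a known truth under the stated model, not that
the same numbers would arise from real primary-care data.

## Imputation

*Development pathway* — chained equations with the event indicator and the
Nelson-Aalen cumulative hazard at exit appended to the predictors.
Continuous variables: Bayesian linear regression (sigma^2 from a scaled
inverse-chi-square draw, coefficients from the normal posterior) followed
by predictive mean matching with k = 5 donors (type-1 matching, uniform
draw among the k nearest predicted values), so imputed values are always
observed donor values. Categorical variables: multinomial logistic models
fitted on a bootstrap resample (the resample plays the role of the
parameter draw), sampling the category from the predicted probabilities.
Visit order is fixed, most-missing last; chains initialise from the
observed marginals; per-chain means are retained for convergence
diagnostics. Defaults M = 20 datasets, 20 iterations (scaled down in desk
runs; the pipeline records the values used in its provenance manifest).

*Deployment pathway* — deterministic conditional means for BMI,
cholesterol/HDL, SBP and SBP variability from a sex-stratified linear
model on age plus ethnicity indicators fitted to observed reference rows
(`method="cells"` switches to 5-year-band x sex x ethnicity cell means).
An ethnicity level absent from the reference falls back to the age-only
model and is logged. Missing ethnicity at scoring time is treated as the
reference (white / not recorded) level, as a deployed calculator does.

## Model sequence and fitting

Design columns: smoking (never reference), ethnicity (white/not-recorded
reference), Townsend quintile linear, flags as 0/1, age/BMI (and calendar
time in model D+) optionally fractional-polynomial transformed. Stage-4/5
CKD remains in models B-E next to stage-3/4/5 so the covariate sets nest
strictly (the log partial likelihood is then non-decreasing A -> E, which
the tests assert).

Cox fits use Efron tie handling (lifelines) with a tight Newton tolerance
first and two graded fallbacks (stock tolerance, then a 1e-4 ridge) for
quasi-separated small samples; binary indicators with no events in one
level are dropped up front with a warning (monotone likelihood). The
baseline cumulative hazard is a Breslow estimator at the fitted
coefficients, stored at the fitting-sample mean linear predictor l̄p, so
risk = 1 - exp(-H0(10))^exp(lp - l̄p).

Fractional polynomials: powers {-2, -1, -0.5, 0 (log), 0.5, 1, 2, 3},
variables pre-shifted positive and scaled to O(1) by a power of ten.
Closed test at alpha = 0.05: best FP2 vs null (4 df), vs linear (3 df),
vs best FP1 (2 df), returning the simplest adequate form. Candidate fits
run through a dedicated damped-Newton solver (Breslow ties; ties only
matter for discretised data) because dozens of fits are needed; the final
models are refitted with the production path. Transforms selected while
building model A (age, BMI) and model D (calendar time) are reused
unchanged downstream.

Region random intercept (model E): all ten region indicators with an L2
penalty equivalent to a N(0, tau^2) prior (the solver's penalty acts on
standardised coefficients and is scaled by n; both are mapped through the
column SD). tau^2 is selected on a log grid by a Laplace approximation to
the marginal likelihood: l(beta-hat) - ||b||^2/(2 tau^2)
- (q/2) log tau^2 - (1/2) log|H_pen|. Reported effects are size-weighted
sum-to-zero. With ten regions the selection is noisy by nature; recovery
tests pool effects over two 100,000-patient cohorts.

Rubin pooling: coefficients pooled as the mean with total variance =
within + (1 + 1/M) between. Per-patient survival estimates are pooled on
the log(-log) scale: 1 - exp(-exp(mean_m log(-log(1 - r_m)))), with risks
clamped to (1e-12, 1 - 1e-12) beforehand (logged). If an imputation drops
a separated rare indicator that others kept, coefficient pooling restricts
to the common columns; risk pooling is unaffected (each fit scores with
its own columns).

## Scoring pathways

Models A-E are scored on one "calculator" table: categorical gaps filled
from a single seeded stochastic imputation, the four continuous variables
reset to their original missingness and mean-imputed against observed
development rows. Model F applies model E's coefficient sets to the
stochastic imputation itself. With no missing data the two pathways
coincide to 1e-12 (tested). Risks per model are pooled across the M
coefficient sets; the between-imputation variance of the cloglog risk is
kept per patient to report average Wald-style 95% intervals per risk band
(labelled as between-imputation-only, since the within-imputation
parameter variance is not propagated through the baseline).

## Metrics

Conventions that differ between texts, fixed here: the censoring
Kaplan-Meier G enters IPCW weights left-continuously, G(t-); concordance
pairs are (i, j) with t_i < t_j and i an event, linear-predictor ties
count 1/2; Uno's C restricts to event times below tau = 10 years and
weights pairs by G(t_i-)^-2 (equal to the tau-restricted Harrell C when
censoring is absent — exact, tested). C_GH uses the logistic kernel in lp
differences (ties 1/2); it is shift- but not scale-invariant, and is
evaluated on a seeded 20,000-patient subsample above that size (it is
O(n^2) and depends only on the lp distribution). Royston-Sauerbrei D uses
Blom normal scores ((rank - 3/8)/(n + 1/4)) divided by kappa = sqrt(8/pi);
R^2_D = (D^2/kappa^2)/(pi^2/6 + D^2/kappa^2). R^2_PM = V/(V + pi^2/6) and
rho_w,a = V/(V + 1) with V the lp variance (ddof 1). rho_k refits the lp
as a single covariate and uses 1 - exp(-Gamma/k) with Gamma the
partial-likelihood chi-square and k the event count. The integrated Brier
score uses Graf weights (events by 1/G(T_i-), survivors by 1/G(t)) and a
trapezoid over the event-time grid on [0, tau]; R^2_IBS compares against
the all-patient Kaplan-Meier curve. Calibration compares mean predicted
risk with 1 - KM(10) within predicted-risk deciles (degenerate quantile
edges merged with a warning).

## Comparison and trend analyses

Risk bands are half-open [k, k+1)% of the reference model (model A);
percentiles use linear interpolation between order statistics; threshold
crossings use risk >= 10% as high risk and report percentages rounded
half-up, matching how such tables are printed. The population
extrapolation is pure arithmetic: population x eligible fraction x
high-risk fraction x sex-weighted reclassified fraction, counts rounded
half-up.

Person-time is split at exact calendar-year boundaries (nanosecond date
arithmetic; conservation per patient to 1e-9 years is asserted). The
Poisson trend model is log-linear in calendar year with a log person-time
offset; a factor-coded year fit is available as a diagnostic, and the
statin-cohort variant can adjust for the model-A risk at episode start.
Statin episodes extend while successive prescriptions are <= 183 days
apart ("6 months"), end 183 days after the last prescription (truncated at
the CVD event or study end), and re-entry after a gap opens a new episode;
nothing after the event is used.

## Problem sizes

Defaults mirror the full-population analysis (cohort of ~3.9 million,
200,000-patient holdout, M = 20 x 20); the pipeline's `scale` factor
shrinks cohort and holdout proportionally for desk runs, and the package's
own test and acceptance runs use cohorts of 5,000-120,000 patients with
M = 2-5 — sizes chosen so every stochastic recovery check is comfortably
powered while a full run of the suite stays in the minutes range. The
reported example sizes are part of the package's test design, and all
seeds are fixed and recorded.

## Known limitations

Ten regions give a noisy variance-component estimate; tau^2 selection can
collapse to near-zero shrinkage or near-total shrinkage on small cohorts.
The random-intercept model is penalised-fixed-effects with a Laplace
marginal likelihood, not an integrated-likelihood mixed Cox model. The
imputation engine draws categorical parameters by bootstrap rather than
from an explicit posterior. Metric confidence intervals are not computed.
The synthetic cohort's limitations are listed above; in particular,
agreement of the synthetic Table-style outputs with any published
magnitudes beyond the parameter-recovery targets is not expected and not
claimed.
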