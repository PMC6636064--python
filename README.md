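# cvduncert

Uncertainty analysis of individual 10-year cardiovascular-disease (CVD) risk
predictions, exercised end-to-end on synthetic electronic-health-record
cohorts with known ground truth.

## The problem

UK guidelines use a Cox-model risk calculator (the QRISK family) to decide
statin eligibility: treat when the predicted 10-year CVD risk is ≥ 10%.
Population-level performance metrics (Harrell's C, R², Brier scores) are
nearly identical across many defensible model variants, yet the *same
patient* can receive very different risks from them — enough to cross the
treatment threshold. This package quantifies that within-person
variability. It is aimed at biostatisticians and epidemiologists studying
risk-prediction stability, and at anyone needing a fully synthetic but
structurally realistic survival-EHR test bed.

## What it implements

* **`synthetic_cohort`** — a two-sex EHR cohort generator (ages 25–84,
  index dates 1998–2015) with a proportional-hazards event process
  h(t) = h₀(t)·exp(βᵀx + u_region + δ·(calendar year − 1998)), Weibull
  baseline, region intercepts u ~ N(0, σ²), secular trend HR e^δ = 0.96 per
  calendar year, administrative plus dropout censoring, missing-at-random
  under-recording of BMI/SBP/SBP-variability/cholesterol-HDL/smoking/
  ethnicity, and statin prescription histories.
* **`imputation`** — both deployment-relevant pathways: chained-equation
  multiple imputation (predictive mean matching, Nelson–Aalen cumulative
  hazard among the predictors; default M = 20 datasets × 20 iterations) for
  model development, and deterministic mean imputation on age, sex and
  ethnicity as a point-of-care calculator does.
* **`model_fitting`** — the nested Cox sequence per sex: model A
  (QRISK2-style covariates), B (QRISK3 extensions), C (extra literature
  risk factors and utilisation counts), D (+ calendar time at index),
  E (+ region as a ridge-shrunk random intercept), with closed-test
  fractional-polynomial selection and Rubin pooling of coefficients.
* **`risk_scoring`** — 10-year risks 1 − S₀(10)^exp(lp − l̄p), pooled over
  imputations on the log(−log) scale; "model F" re-scores model E on a
  stochastically imputed test table instead of the mean-imputed one.
* **`performance_metrics`** — C_H, C_U (IPCW), C_GH, Royston–Sauerbrei D
  and R²_D, R²_PM, ρ_w,a, ρ_k, integrated Brier score and R²_IBS, and
  Kaplan–Meier calibration by risk decile.
* **`uncertainty`** — 1%-wide risk bands by the reference model, 2.5–97.5
  percentile ranges of comparator risks, 10%-threshold reclassification
  tables, and population extrapolation.
* **`secular_trend`** — exact calendar-year person-time splitting, Poisson
  trend models with log-offset, and statin treatment episodes delimited by
  a 183-day prescription gap.
* **`pipeline` / `cvduncert` CLI** — one-config orchestration
  (`simulate → impute → fit → score → evaluate → compare → trend`) with
  per-stage seeds and a bit-reproducible manifest.

## Worked example

```python
import numpy as np
from cvduncert import (TrueModelSpec, generate_cohort, fit_model_sequence,
                       score_pathways, reclassification_counts)
from cvduncert import model_fitting as mf

spec = TrueModelSpec.default()          # trend HR 0.96/yr, region SD 0.085
cohort = generate_cohort(spec, 30_000, seed=1)
dev, test = cohort.iloc[:24_000], cohort.iloc[24_000:].reset_index(drop=True)

models = {s: fit_model_sequence([dev.reset_index(drop=True)], s)
          for s in ("F", "M")}
fitD = models["F"]["D"].fits[0]
print("calendar-year HR:", float(np.exp(fitD.params["calendar_time"])))

risks = score_pathways(models, test, dev, seed=1)
rc = reclassification_counts(risks[risks.sex == "F"])
print(rc[rc.band == ">=10%"][["band", "n", "down_F", "pct_F"]])
```

Output (seed 1):

```
calendar-year HR: 0.9722
 band   n  down_F  pct_F
>=10% 485      80   16.0
```

The fitted calendar-time hazard ratio recovers the generator's 0.96/year
secular trend to within sampling noise at this desk scale, and 16% of the
female patients classed high-risk (≥ 10%) by the QRISK2-style model A drop
below the treatment threshold when re-scored with the trend- and
region-adjusted model F — the package's central phenomenon: models that
look interchangeable in aggregate disagree for individuals.

A full experiment with all artifacts (metrics, percentile-range and
reclassification tables, calibration, trend sensitivity, report and
manifest) is one command:

```bash
cvduncert run-all --seed 1 --scale 0.005 --out runs/demo
```

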