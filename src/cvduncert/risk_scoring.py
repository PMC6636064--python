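"""Per-patient 10-year risks under the two deployment pathways.

Models A-E are scored on a single mean-imputed test table (what a deployed
calculator sees); "model F" re-scores model E on one stochastically imputed
test table, representing the best estimate of the patient's actual missing
values.  Survival estimates are pooled across the M imputation-specific
coefficient sets with Rubin's rules on the complementary log-log
(log(-log survival)) scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .imputation import (MEAN_IMPUTE_VARS, chained_imputation,
                         mean_impute_by_demographics)
from .model_fitting import CoxFit, FittedRiskModel

log = logging.getLogger(__name__)

__all__ = ["predict_tenyear_risk", "pool_risks_rubin_loglog",
           "score_pathways", "clamp_risks", "model_linear_predictor"]

RISK_EPS = 1e-12


def predict_tenyear_risk(fit: CoxFit, design: pd.DataFrame,
                         horizon: float = 10.0) -> np.ndarray:
    """Risk over ``horizon`` years from one per-imputation Cox fit.

    risk = 1 - S0(horizon) ** exp(lp - lp_center) with S0 the Breslow
    baseline survival stored with the fit (itself referenced to the
    fitting-sample mean linear predictor).
    """
    if fit.baseline.times.size == 0 or horizon > fit.baseline.times.max():
        raise ValueError(
            f"horizon {horizon} beyond the last baseline event time "
            f"({fit.baseline.times.max() if fit.baseline.times.size else 0:.3g}); "
            "cannot extrapolate the baseline hazard")
    h0 = float(fit.baseline(horizon))
    lp = fit.linear_predictor(design)
    return 1.0 - np.exp(-h0 * np.exp(lp - fit.lp_center))


def clamp_risks(r: np.ndarray, eps: float = RISK_EPS) -> np.ndarray:
    """Clamp risks into the open interval (0, 1) before cloglog pooling."""
    r = np.asarray(r, dtype=float)
    n_out = int(((r <= 0) | (r >= 1)).sum())
    if n_out:
        log.info("clamping %d risk value(s) into (%.0e, 1-%.0e)", n_out, eps, eps)
    return np.clip(r, eps, 1.0 - eps)


def pool_risks_rubin_loglog(risks: np.ndarray) -> np.ndarray:
    """Rubin-pool per-imputation risks on the log(-log) survival scale.

    ``risks`` has shape (M, n_patients) with entries in the open (0,1);
    returns 1 - exp(-exp(mean_m log(-log(1 - r_m)))) per patient.
    """
    risks = np.atleast_2d(np.asarray(risks, dtype=float))
    if np.any((risks <= 0) | (risks >= 1)):
        raise ValueError("risks must lie in (0, 1); clamp explicitly first "
                         "(see clamp_risks)")
    eta = np.log(-np.log(1.0 - risks))
    return 1.0 - np.exp(-np.exp(eta.mean(axis=0)))


def _pooled_model_risk(model: FittedRiskModel, table: pd.DataFrame,
                       horizon: float = 10.0, return_eta_var: bool = False):
    design = model.design(table)
    per_m = np.vstack([
        clamp_risks(predict_tenyear_risk(f, design, horizon))
        for f in model.fits])
    pooled = pool_risks_rubin_loglog(per_m)
    if return_eta_var:
        eta = np.log(-np.log(1.0 - per_m))
        M = eta.shape[0]
        var = eta.var(axis=0, ddof=1) * (1.0 + 1.0 / M) if M > 1 \
            else np.zeros(eta.shape[1])
        return pooled, var
    return pooled


def model_linear_predictor(model: FittedRiskModel, table: pd.DataFrame) -> np.ndarray:
    """Linear predictor at the Rubin-pooled coefficients."""
    design = model.design(table)
    beta, _ = model.pooled()
    return design[beta.index].to_numpy(dtype=float) @ beta.to_numpy()


def score_pathways(models_by_sex: dict, test: pd.DataFrame,
                   development: pd.DataFrame, seed: int,
                   horizon: float = 10.0,
                   imputation_kwargs: dict | None = None) -> pd.DataFrame:
    """Score every model under its deployment pathway on the test cohort.

    ``models_by_sex`` maps sex -> {label -> FittedRiskModel} and must
    contain model E for the model-F pathway.  The test table keeps its
    original missingness; categorical gaps are filled from one seeded
    stochastic imputation, the four calculator-imputable continuous
    variables are mean-imputed on age, sex and ethnicity against observed
    development rows (models A-E) or taken from the stochastic imputation
    (model F).  Returns a table with patient_id, sex and risk_A..risk_F in
    [0,1], plus eta_var_* columns (between-imputation variance on the
    cloglog scale) for downstream average-confidence-interval reporting.
    """
    overlap = set(test["patient_id"]) & set(development["patient_id"])
    if overlap:
        raise ValueError(f"test and development cohorts overlap "
                         f"({len(overlap)} patient ids)")
    kw = dict(M=1, iterations=5)
    kw.update(imputation_kwargs or {})
    if test[list(MEAN_IMPUTE_VARS) + ["smoking", "ethnicity"]].isna().any().any():
        stoch = chained_imputation(test, seed=seed, **kw)[0]
    else:
        stoch = test.copy()
    # deployed-calculator table: stochastic categorical fills, original
    # continuous missingness restored, then deterministic mean imputation
    calc = stoch.copy()
    for v in MEAN_IMPUTE_VARS:
        calc[v] = test[v].to_numpy()
    calc = mean_impute_by_demographics(calc, development)

    out = test[["patient_id", "sex"]].copy()
    for label in ("A", "B", "C", "D", "E", "F"):
        out[f"risk_{label}"] = np.nan
        out[f"eta_var_{label}"] = np.nan
    for sex, models in models_by_sex.items():
        mask = (test["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        for label, model in models.items():
            r, v = _pooled_model_risk(model, calc[mask], horizon,
                                      return_eta_var=True)
            out.loc[mask, f"risk_{label}"] = r
            out.loc[mask, f"eta_var_{label}"] = v
        if "E" not in models:
            raise ValueError("model E is required to score the model-F "
                             "pathway; include label 'E' in the fitted set")
        r, v = _pooled_model_risk(models["E"], stoch[mask], horizon,
                                  return_eta_var=True)
        out.loc[mask, "risk_F"] = r
        out.loc[mask, "eta_var_F"] = v
    return out
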