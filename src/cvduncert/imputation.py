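"""Both imputation pathways used when developing and deploying risk models.

Development pathway: multiple imputation by chained equations (MICE) with
predictive mean matching for continuous variables and bootstrap multinomial
logistic draws for categorical ones, with the event indicator and the
Nelson-Aalen cumulative hazard at exit among the predictors.

Deployment pathway: deterministic mean imputation conditional on age, sex
and ethnicity, replicating what a point-of-care risk calculator does when a
patient's BMI, SBP, SBP variability or cholesterol/HDL ratio has never been
recorded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival_utils import nelson_aalen
from .synthetic_cohort import BLANKABLE

log = logging.getLogger(__name__)

__all__ = ["ImputationSet", "nelson_aalen_cumhaz", "chained_imputation",
           "mean_impute_by_demographics", "MEAN_IMPUTE_VARS"]

#: variables a deployed calculator mean-imputes at scoring time
MEAN_IMPUTE_VARS = ("bmi", "chol_hdl", "sbp", "sbp_variability")

_CATEGORICAL = ("smoking", "ethnicity")


@dataclass
class ImputationSet:
    """M completed cohort tables sharing patient ids.

    Tables agree on every originally-observed cell; only originally missing
    cells vary with the imputation index m.  ``chain_means[var]`` has shape
    (M, iterations) and holds the mean of the imputed values of ``var`` after
    each chained-equations sweep, for convergence diagnostics.
    """

    tables: list
    provenance: dict = field(default_factory=dict)
    chain_means: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.tables)

    def __iter__(self):
        return iter(self.tables)

    def __getitem__(self, m):
        return self.tables[m]


def nelson_aalen_cumhaz(times, events):
    """Nelson-Aalen H(t) step function plus per-patient H(t_i).

    Returns ``(H, H_i)`` with H a right-continuous
    :class:`~cvduncert.survival_utils.StepFunction` and ``H_i`` the estimate
    at each patient's own exit time — the auxiliary imputation predictor.
    """
    H = nelson_aalen(times, events)
    return H, H(np.asarray(times, dtype=float))


# ---------------------------------------------------------------------------
# chained-equation multiple imputation
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, predictors, exclude: str) -> np.ndarray:
    """Numeric design matrix (with intercept) from currently-completed data."""
    cols = [np.ones(len(df))]
    for p in predictors:
        if p == exclude:
            continue
        v = df[p]
        if p in _CATEGORICAL or v.dtype == object:
            dummies = pd.get_dummies(v.astype(object), drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy())
        else:
            cols.append(v.to_numpy(dtype=float))
    return np.column_stack(cols)


def _bayes_linear_draw(X, y, rng):
    """Posterior (beta_hat, beta_draw) under the normal linear model."""
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = (resid @ resid) / rng.chisquare(dof)
    cov = sigma2 * np.linalg.inv(XtX)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    beta_draw = beta_hat + L @ rng.standard_normal(p)
    return beta_hat, beta_draw


def _pmm_impute(X_obs, y_obs, X_mis, rng, k=5):
    """Predictive mean matching with k donors (type-1 matching)."""
    beta_hat, beta_draw = _bayes_linear_draw(X_obs, y_obs, rng)
    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_draw
    order = np.argsort(yhat_obs, kind="stable")
    sorted_pred = yhat_obs[order]
    sorted_y = y_obs[order]
    pos = np.searchsorted(sorted_pred, yhat_mis)
    n_obs = sorted_pred.size
    out = np.empty(yhat_mis.size)
    for i, (p0, target) in enumerate(zip(pos, yhat_mis)):
        lo = max(p0 - k, 0)
        hi = min(p0 + k, n_obs)
        window = np.arange(lo, hi)
        dist = np.abs(sorted_pred[window] - target)
        donors = window[np.argsort(dist, kind="stable")[:k]]
        out[i] = sorted_y[donors[rng.integers(0, donors.size)]]
    return out


def _multinomial_impute(X_obs, y_obs, X_mis, rng):
    """Multinomial logistic draw fitted on a bootstrap resample."""
    from sklearn.linear_model import LogisticRegression

    levels, codes = np.unique(y_obs, return_inverse=True)
    if levels.size == 1:
        return np.repeat(levels[0], X_mis.shape[0])
    mu = X_obs.mean(axis=0)
    sd = X_obs.std(axis=0)
    sd[sd == 0] = 1.0
    X_obs = (X_obs - mu) / sd
    X_mis = (X_mis - mu) / sd
    boot = rng.integers(0, len(codes), size=len(codes))
    if np.unique(codes[boot]).size < levels.size:  # keep all levels estimable
        boot = np.arange(len(codes))
    clf = LogisticRegression(max_iter=500, C=1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X_obs[boot], codes[boot])
    prob = clf.predict_proba(X_mis)
    cum = np.cumsum(prob, axis=1)
    u = rng.random(X_mis.shape[0])
    pick = (u[:, None] > cum).sum(axis=1)
    order = {c: i for i, c in enumerate(clf.classes_)}
    lut = np.array([levels[c] for c in clf.classes_], dtype=object)
    return lut[pick]


def chained_imputation(cohort: pd.DataFrame, predictors=None, M: int = 20,
                       iterations: int = 20, seed: int = 0,
                       variables=None, pmm_k: int = 5) -> ImputationSet:
    """Multiple imputation by chained equations.

    Continuous variables are imputed by predictive mean matching (``pmm_k``
    donors) from a Bayesian linear conditional model; categorical variables
    by multinomial logistic models fitted on a bootstrap resample.  The
    event indicator and the Nelson-Aalen cumulative hazard at exit are
    appended to the predictor list, following standard practice for
    imputation in survival models.  Visit order is fixed with the
    most-missing variable last.
    """
    if M < 1 or iterations < 1:
        raise ValueError("M and iterations must be >= 1")
    variables = list(variables) if variables is not None else [
        v for v in BLANKABLE if v in cohort.columns and cohort[v].isna().any()]
    for v in variables:
        if cohort[v].notna().sum() == 0:
            raise ValueError(f"variable {v!r} has no observed values")
    if predictors is None:
        predictors = ["age_at_index", "sex", "townsend", "calendar_time",
                      "bmi", "sbp", "sbp_variability", "chol_hdl",
                      "smoking", "ethnicity", "treated_hypertension",
                      "type2_diabetes"]
    predictors = [p for p in predictors if p in cohort.columns]
    work = cohort.copy()
    work["_event"] = cohort["event"].to_numpy(dtype=float)
    _, work["_na_cumhaz"] = nelson_aalen_cumhaz(cohort["followup_time"],
                                                cohort["event"])
    full_predictors = predictors + ["_event", "_na_cumhaz"]
    # most-missing last
    variables = sorted(variables, key=lambda v: cohort[v].isna().sum())
    miss_masks = {v: cohort[v].isna().to_numpy() for v in variables}

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    tables = []
    chain_means = {v: np.zeros((M, iterations)) for v in variables
                   if v not in _CATEGORICAL}
    for m in range(M):
        dfm = work.copy()
        # initialise missing cells from observed marginals
        for v in variables:
            mask = miss_masks[v]
            obs = dfm.loc[~mask, v].to_numpy()
            dfm.loc[mask, v] = rng.choice(obs, size=int(mask.sum()))
        for it in range(iterations):
            for v in variables:
                mask = miss_masks[v]
                if not mask.any():
                    continue
                X = _design(dfm, full_predictors, exclude=v)
                if v in _CATEGORICAL:
                    imputed = _multinomial_impute(X[~mask], dfm.loc[~mask, v].to_numpy(object),
                                                  X[mask], rng)
                    col = dfm[v].to_numpy(object)
                    col[mask] = imputed
                    dfm[v] = col
                else:
                    y = dfm.loc[~mask, v].to_numpy(dtype=float)
                    dfm.loc[mask, v] = _pmm_impute(X[~mask], y, X[mask], rng,
                                                   k=pmm_k)
                    chain_means[v][m, it] = dfm.loc[mask, v].mean()
        tables.append(dfm.drop(columns=["_event", "_na_cumhaz"]))
    prov = {"M": M, "iterations": iterations, "seed": int(seed),
            "predictors": full_predictors, "variables": variables,
            "pmm_k": pmm_k}
    return ImputationSet(tables, prov, chain_means)


# ---------------------------------------------------------------------------
# demographic mean imputation (deployment pathway)
# ---------------------------------------------------------------------------

def mean_impute_by_demographics(cohort: pd.DataFrame, reference: pd.DataFrame,
                                variables=MEAN_IMPUTE_VARS,
                                method: str = "regression",
                                age_band: float = 5.0) -> pd.DataFrame:
    """Deterministic conditional-mean imputation on age, sex and ethnicity.

    ``method='regression'`` (default) fits, per sex, a least-squares linear
    model of each variable on age and ethnicity indicators using observed
    ``reference`` rows, and fills missing cells in ``cohort`` with fitted
    means.  ``method='cells'`` instead uses cell means over (5-year age band
    x sex x ethnicity) with a fallback to (age band x sex) for unseen cells.
    Ethnicity levels absent from the reference fall back to the age+sex
    model (logged).
    """
    out = cohort.copy()
    for var in variables:
        if var not in out.columns or not out[var].isna().any():
            continue
        if reference[var].notna().sum() == 0:
            raise ValueError(f"reference has no observed values for {var!r}")
        for sex in ("F", "M"):
            mask = (out["sex"] == sex) & out[var].isna()
            if not mask.any():
                continue
            ref = reference[(reference["sex"] == sex) & reference[var].notna()]
            eth_mis = out.loc[mask, "ethnicity"].astype(object).fillna("white")
            if method == "cells":
                bands_ref = (ref["age_at_index"] // age_band).astype(int)
                eth_ref = ref["ethnicity"].astype(object).fillna("white")
                table = ref.groupby([bands_ref, eth_ref])[var].mean()
                by_band = ref.groupby(bands_ref)[var].mean()
                bands_mis = (out.loc[mask, "age_at_index"] // age_band).astype(int)
                vals = np.array([
                    table.get((b, e), by_band.get(b, ref[var].mean()))
                    for b, e in zip(bands_mis, eth_mis)])
                out.loc[mask, var] = vals
                continue
            # regression on age + ethnicity indicators
            levels = sorted(set(ref["ethnicity"].astype(object).fillna("white")))
            unseen = sorted(set(eth_mis) - set(levels))
            if unseen:
                log.info("mean imputation: ethnicity level(s) %s absent from "
                         "reference for %s/%s; falling back to age+sex model",
                         unseen, var, sex)
            X = np.column_stack(
                [np.ones(len(ref)), ref["age_at_index"].to_numpy(dtype=float)]
                + [(ref["ethnicity"].astype(object).fillna("white") == lv)
                   .to_numpy(dtype=float) for lv in levels[1:]])
            beta, *_ = np.linalg.lstsq(X, ref[var].to_numpy(dtype=float),
                                       rcond=None)
            beta_age, *_ = np.linalg.lstsq(
                X[:, :2], ref[var].to_numpy(dtype=float), rcond=None)
            age_mis = out.loc[mask, "age_at_index"].to_numpy(dtype=float)
            Xm = np.column_stack(
                [np.ones(mask.sum()), age_mis]
                + [(eth_mis == lv).to_numpy(dtype=float) for lv in levels[1:]])
            vals = Xm @ beta
            bad = ~np.isin(np.asarray(eth_mis, dtype=object), levels)
            if bad.any():
                vals[bad] = np.column_stack([np.ones(bad.sum()),
                                             age_mis[bad]]) @ beta_age
            out.loc[mask, var] = vals
    return out
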