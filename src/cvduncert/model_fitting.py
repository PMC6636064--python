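"""Nested Cox model sequence A-E: design building, fractional polynomials,
proportional-hazards fitting, region random intercept and Rubin pooling.

Model ladder (per sex, fitted on each completed imputation):

* A - QRISK2-style covariates: age, BMI, cholesterol/HDL, SBP, smoking,
  ethnicity, deprivation, and the classic medical-history flags.
* B - adds the QRISK3 extensions (SBP variability, CKD stage 3-5, atypical
  antipsychotics, corticosteroids, erectile dysfunction, HIV/AIDS,
  migraine, severe mental illness, SLE).
* C - adds literature risk factors (alcohol abuse, anxiety, LVH) and
  heavy-utilisation indicators (>50 consultations / >50 prescriptions in
  the prior year).
* D - adds calendar time at index (secular trend).
* E - adds region as a normally-distributed random intercept, fitted as a
  ridge-penalised set of indicators with the penalty scale chosen by an
  approximate (Laplace) marginal likelihood.

Stage 4/5 CKD stays in models B-E alongside the broader stage 3/4/5 flag so
that each model's covariate set strictly contains the previous one.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines import exceptions as ll_exc
from scipy import stats

from .survival_utils import StepFunction, breslow_baseline

log = logging.getLogger(__name__)

__all__ = [
    "FPTransform", "CoxFit", "FittedRiskModel", "MODEL_LABELS",
    "model_variables", "build_design", "select_fractional_polynomial",
    "fit_cox", "fit_region_random_intercept", "pool_coefficients_rubin",
    "fit_model_sequence",
]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

MODEL_LABELS = ("A", "B", "C", "D", "E")

_FLAGS_A = ("atrial_fibrillation", "ckd45", "family_history_cvd",
            "treated_hypertension", "rheumatoid_arthritis",
            "type1_diabetes", "type2_diabetes")
_FLAGS_B = ("sbp_variability", "atypical_antipsychotic", "corticosteroid",
            "ckd345", "erectile_dysfunction", "hiv_aids", "migraine",
            "severe_mental_illness", "sle")
_FLAGS_C = ("alcohol_abuse", "anxiety", "lvh", "consult_gt50", "rx_gt50")

SMOKING_LEVELS = ("ex", "current")
ETHNICITY_LEVELS = ("indian", "pakistani", "bangladeshi", "other_asian",
                    "black", "chinese", "other")
REGION_LEVELS = ("north_east", "north_west", "yorkshire_humber",
                 "east_midlands", "west_midlands", "east_of_england",
                 "south_west", "south_central", "london", "south_east_coast")


def model_variables(label: str, sex: str) -> list:
    """Raw cohort variables entering a model (region handled separately)."""
    if label not in ("A", "B", "C", "D", "E", "F"):
        raise ValueError(f"unknown model label {label!r}")
    base = ["age_at_index", "bmi", "chol_hdl", "sbp", "smoking", "ethnicity",
            "townsend", *_FLAGS_A]
    if label == "A":
        out = base
    else:
        out = base + list(_FLAGS_B)
        if label in ("C", "D", "E", "F"):
            out = out + list(_FLAGS_C)
        if label in ("D", "E", "F"):
            out = out + ["calendar_time"]
    if sex == "F":
        out = [v for v in out if v != "erectile_dysfunction"]
    return out


@dataclass
class FPTransform:
    """Fractional-polynomial transform of one continuous variable.

    ``powers`` holds 1 or 2 exponents from the standard set (0 denotes log);
    a repeated power (p, p) maps to (x^p, x^p log x).  ``shift`` and
    ``scale`` make the variable positive and O(1) before transformation.
    ``significant`` is False when the closed test found no effect at all.
    """

    variable: str
    powers: tuple = (1.0,)
    shift: float = 0.0
    scale: float = 1.0
    significant: bool = True

    def column_names(self) -> list:
        return [f"{self.variable}__fp{i+1}" for i in range(len(self.powers))]

    def apply(self, x) -> np.ndarray:
        x = (np.asarray(x, dtype=float) + self.shift) / self.scale
        if np.any(x <= 0):
            raise ValueError(
                f"{self.variable}: non-positive values after shift; outside "
                "the valid domain of the fractional polynomial")
        cols = []
        prev = None
        for p in self.powers:
            base = np.log(x) if p == 0.0 else x ** p
            if prev is not None and p == prev:
                base = (np.log(x) if p == 0.0 else x ** p) * np.log(x)
            cols.append(base)
            prev = p
        return np.column_stack(cols)


def default_shift_scale(x) -> tuple:
    x = np.asarray(x, dtype=float)
    lo = np.nanmin(x)
    shift = 0.0 if lo > 0 else float(1.0 - lo)
    med = np.nanmedian(x) + shift
    scale = float(10.0 ** np.floor(np.log10(med))) if med > 0 else 1.0
    return shift, scale


def build_design(df: pd.DataFrame, label: str, sex: str,
                 fp_transforms: dict | None = None,
                 with_region: bool = False) -> pd.DataFrame:
    """Numeric design matrix for one model on one sex's completed rows.

    Missing ethnicity is treated as the reference (white / not recorded), as
    a deployed calculator does.  Region indicators (all 10 levels, for the
    penalised random-intercept fit) are appended when ``with_region``.
    """
    fp_transforms = fp_transforms or {}
    cols = {}
    for var in model_variables(label, sex):
        if var == "smoking":
            sm = df["smoking"].astype(object)
            for lv in SMOKING_LEVELS:
                cols[f"smoking_{lv}"] = (sm == lv).to_numpy(dtype=float)
        elif var == "ethnicity":
            eth = df["ethnicity"].astype(object).fillna("white")
            for lv in ETHNICITY_LEVELS:
                cols[f"ethnicity_{lv}"] = (eth == lv).to_numpy(dtype=float)
        elif var in fp_transforms:
            tr = fp_transforms[var]
            mat = tr.apply(df[var])
            for name, col in zip(tr.column_names(), mat.T):
                cols[name] = col
        else:
            cols[var] = df[var].to_numpy(dtype=float)
    if with_region:
        reg = df["region"].astype(object)
        for lv in REGION_LEVELS:
            cols[f"region_{lv}"] = (reg == lv).to_numpy(dtype=float)
    out = pd.DataFrame(cols, index=df.index)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"design contains missing values in {bad}")
    return out


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """One proportional-hazards fit (per sex, model and imputation)."""

    params: pd.Series
    cov: pd.DataFrame
    baseline: StepFunction       # cumulative hazard at lp == lp_center
    lp_center: float
    loglik: float
    n: int
    events: int

    def linear_predictor(self, design: pd.DataFrame) -> np.ndarray:
        X = design[self.params.index].to_numpy(dtype=float)
        return X @ self.params.to_numpy()


def fit_cox(design: pd.DataFrame, times, events,
            penalizer=None) -> CoxFit:
    """Fit a Cox model with Efron tie handling and a Breslow-type baseline.

    Constant columns are dropped with a warning; separation / non-convergence
    raises ``ValueError`` naming the covariate when lifelines identifies it.
    The baseline cumulative hazard is evaluated at the fitting-sample mean
    linear predictor (stored as ``lp_center``).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.unique(times[events == 1]).size < 2:
        raise ValueError("need >= 2 distinct event times")
    keep = [c for c in design.columns if design[c].nunique() > 1]
    dropped = [c for c in design.columns if c not in keep]
    if dropped:
        log.warning("dropping constant column(s): %s", dropped)
    # monotone-likelihood guard: a binary indicator whose carriers (or
    # non-carriers) have no events drives beta to +/- infinity
    separated = []
    for c in list(keep):
        col = design[c].to_numpy()
        vals = np.unique(col)
        if vals.size == 2 and set(vals) <= {0.0, 1.0}:
            ev1 = events[col == 1].sum()
            ev0 = events[col == 0].sum()
            if ev1 == 0 or ev0 == 0:
                keep.remove(c)
                separated.append(c)
    if separated:
        log.warning("dropping separated indicator column(s) with no events "
                    "in one level: %s", separated)
    X = design[keep].copy()
    df = X.copy()
    df["_T"] = times
    df["_E"] = events
    if isinstance(penalizer, pd.Series):
        penalizer = penalizer[keep].to_numpy()
    # a tight Newton tolerance first (oracle-grade solutions on clean data),
    # then the solver's stock stopping rule, then a whisper of ridge to tame
    # quasi-separated small samples, before giving up
    base_pen = penalizer if penalizer is not None else 0.0
    attempts = [
        (base_pen, {"precision": 1e-12, "r_precision": 1e-15}),
        (base_pen, None),
        (np.maximum(base_pen, 1e-4), None),
    ]
    for pen, fit_options in attempts:
        cph = CoxPHFitter(penalizer=pen)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="_T", event_col="_E",
                        fit_options=fit_options)
            break
        except (ll_exc.ConvergenceError, np.linalg.LinAlgError) as err:
            last_err = err
    else:
        raise ValueError(f"Cox fit failed to converge: {last_err}")
    params = cph.params_.copy()
    lp = X.to_numpy(dtype=float) @ params.to_numpy()
    center = float(lp.mean())
    base = breslow_baseline(lp - center, times, events)
    from .survival_utils import efron_loglik
    return CoxFit(params=params, cov=cph.variance_matrix_.copy(),
                  baseline=base, lp_center=center,
                  loglik=efron_loglik(lp, times, events),
                  n=len(df), events=int(events.sum()))


# ---------------------------------------------------------------------------
# fractional polynomial closed test
# ---------------------------------------------------------------------------

def _breslow_newton(X, times, events, tol=1e-9, max_iter=40):
    """Maximised Cox partial log-likelihood (Breslow ties), Newton-Raphson.

    Compact vectorised solver used only to score the fractional-polynomial
    candidate transforms, where dozens of small fits are needed; the final
    model fits go through :func:`fit_cox`.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    X = np.asarray(X, dtype=float)[order]
    e = events[order]
    t = times[order]
    n, p = X.shape
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    uniq, first, inverse = np.unique(t, return_index=True, return_inverse=True)
    ev = np.flatnonzero(e == 1)
    risk_start = first[inverse[ev]]        # first index of each event's time

    def ll_grad_hess(beta, with_derivs=True):
        lp = Xs @ beta
        z = np.exp(lp - lp.max())
        S0 = np.cumsum(z[::-1])[::-1]
        s0 = S0[risk_start]
        if np.any(s0 <= 0) or not np.all(np.isfinite(s0)):
            return -np.inf, None, None
        ll = float((lp[ev] - lp.max()).sum() - np.log(s0).sum())
        if not with_derivs:
            return ll, None, None
        zx = z[:, None] * Xs
        S1 = np.cumsum(zx[::-1], axis=0)[::-1]
        zxx = zx[:, :, None] * Xs[:, None, :]
        S2 = np.cumsum(zxx[::-1], axis=0)[::-1]
        s1, s2 = S1[risk_start], S2[risk_start]
        mu = s1 / s0[:, None]
        grad = Xs[ev].sum(axis=0) - mu.sum(axis=0)
        hess = -(s2 / s0[:, None, None]
                 - mu[:, :, None] * mu[:, None, :]).sum(axis=0)
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = ll_grad_hess(beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess - 1e-9 * np.eye(p), grad)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"candidate fit singular: {err}") from err
        # damped Newton: halve until the log-likelihood does not decrease
        frac = 1.0
        for _ in range(30):
            cand = beta - frac * step
            ll_new, g_new, h_new = ll_grad_hess(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            frac /= 2.0
        else:
            raise ValueError("candidate fit did not converge (step halving)")
        improved = ll_new - ll
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if abs(improved) < tol * (abs(ll) + 1.0):
            break
    if not np.isfinite(ll):
        raise ValueError("candidate fit did not converge")
    return ll, beta / sd


def _candidate_loglik(xcols, adjust, times, events) -> float:
    parts = []
    if xcols is not None:
        parts.append(np.asarray(xcols, dtype=float))
    if adjust is not None and adjust.shape[1]:
        parts.append(adjust.to_numpy(dtype=float))
    if not parts:
        # null model, Breslow form: sum over events of -log|risk set|
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        order = np.argsort(times, kind="stable")
        t, e = times[order], events[order]
        uniq, first, inverse = np.unique(t, return_index=True,
                                         return_inverse=True)
        ev = np.flatnonzero(e == 1)
        n_at_risk = len(t) - first[inverse[ev]]
        return float(-np.log(n_at_risk).sum())
    X = np.column_stack(parts)
    ll, _ = _breslow_newton(X, times, events)
    return ll


def select_fractional_polynomial(df: pd.DataFrame, variable: str,
                                 times, events,
                                 adjust: pd.DataFrame | None = None,
                                 alpha: float = 0.05) -> FPTransform:
    """Closed-test fractional-polynomial selection for one variable.

    Compares the best 2-term FP against the null (4 df), then against the
    linear term (3 df), then against the best 1-term FP (2 df), by partial
    likelihood deviance chi-square at ``alpha``, returning the simplest
    adequate transform.  Deterministic given the data.
    """
    x = df[variable].to_numpy(dtype=float)
    shift, scale = default_shift_scale(x)

    def tr(powers):
        return FPTransform(variable, tuple(powers), shift, scale)

    ll_null = _candidate_loglik(None, adjust, times, events)
    ll_lin = _candidate_loglik(tr((1.0,)).apply(x), adjust, times, events)

    best1, ll_fp1 = None, -np.inf
    for p in FP_POWERS:
        try:
            ll = _candidate_loglik(tr((p,)).apply(x), adjust, times, events)
        except ValueError as err:
            raise ValueError(f"FP1 power {p} failed: {err}") from err
        if ll > ll_fp1:
            best1, ll_fp1 = (p,), ll
    best2, ll_fp2 = None, -np.inf
    for p, q in itertools.combinations_with_replacement(FP_POWERS, 2):
        try:
            ll = _candidate_loglik(tr((p, q)).apply(x), adjust, times, events)
        except ValueError as err:
            raise ValueError(f"FP2 powers ({p},{q}) failed: {err}") from err
        if ll > ll_fp2:
            best2, ll_fp2 = (p, q), ll

    def pval(ll_big, ll_small, dof):
        dev = max(2.0 * (ll_big - ll_small), 0.0)
        return stats.chi2.sf(dev, dof)

    if pval(ll_fp2, ll_null, 4) >= alpha:
        out = tr((1.0,))
        out.significant = False
        return out
    if pval(ll_fp2, ll_lin, 3) >= alpha:
        return tr((1.0,))
    if pval(ll_fp2, ll_fp1, 2) >= alpha:
        return tr(best1)
    return tr(best2)


# ---------------------------------------------------------------------------
# region random intercept
# ---------------------------------------------------------------------------

def fit_region_random_intercept(design: pd.DataFrame, times, events,
                                tau2_grid=None) -> dict:
    """Ridge-penalised region intercepts with marginal-likelihood tau^2.

    ``design`` must contain the ``region_*`` indicator columns (all levels)
    plus the fixed-effect columns.  The region coefficients get a
    N(0, tau^2) shrinkage penalty; tau^2 is chosen on a grid by a Laplace
    approximation to the marginal likelihood.  Returns the winning
    :class:`CoxFit` plus size-weighted sum-to-zero region effects and tau.
    """
    region_cols = [c for c in design.columns if c.startswith("region_")]
    sizes = design[region_cols].sum(axis=0).to_numpy()
    if (sizes > 0).sum() < 2:
        raise ValueError("need >= 2 regions with patients")
    if tau2_grid is None:
        tau2_grid = np.logspace(-4, -0.5, 8)
    events = np.asarray(events, dtype=int)
    n = len(design)
    # lifelines applies 0.5 * penalizer * n * beta^2 on the standardised
    # scale; map a N(0, tau^2) prior on the raw region coefficient through
    # the column standard deviation.
    col_sd = design.std(axis=0, ddof=0).replace(0.0, 1.0)
    best = None
    from .survival_utils import efron_loglik
    for tau2 in tau2_grid:
        pen = pd.Series(0.0, index=design.columns)
        pen[region_cols] = 1.0 / (tau2 * n * col_sd[region_cols] ** 2)
        fit = fit_cox(design, times, events, penalizer=pen)
        b = fit.params[[c for c in region_cols if c in fit.params.index]]
        q = len(b)
        lp = design[fit.params.index].to_numpy(dtype=float) @ fit.params.to_numpy()
        ll_unpen = efron_loglik(lp, times, events)
        H_pen = np.linalg.inv(fit.cov.to_numpy())
        sign, logdet = np.linalg.slogdet(H_pen)
        lml = (ll_unpen - float((b ** 2).sum()) / (2 * tau2)
               - 0.5 * q * np.log(tau2) - 0.5 * logdet)
        if best is None or lml > best["lml"]:
            best = {"tau2": float(tau2), "fit": fit, "lml": float(lml)}
    fit = best["fit"]
    eff = pd.Series({c.replace("region_", ""): fit.params.get(c, 0.0)
                     for c in region_cols})
    w = sizes / sizes.sum()
    eff = eff - float(np.dot(w, eff.to_numpy()))
    best["region_effects"] = eff
    return best


# ---------------------------------------------------------------------------
# Rubin pooling
# ---------------------------------------------------------------------------

def pool_coefficients_rubin(fits) -> tuple:
    """Rubin's rules over per-imputation fits.

    Returns ``(pooled_beta, total_variance)`` with total variance =
    mean within-imputation variance + (1 + 1/M) x between-imputation
    variance, per coefficient.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to pool")
    index = fits[0].params.index
    for f in fits[1:]:
        if not f.params.index.equals(index):
            raise ValueError("mismatched design columns across imputations")
    M = len(fits)
    betas = np.vstack([f.params.to_numpy() for f in fits])
    within = np.vstack([np.diag(f.cov.to_numpy()) for f in fits]).mean(axis=0)
    pooled = betas.mean(axis=0)
    between = betas.var(axis=0, ddof=1) if M > 1 else np.zeros_like(pooled)
    total = within + (1.0 + 1.0 / M) * between
    return pd.Series(pooled, index=index), pd.Series(total, index=index)


# ---------------------------------------------------------------------------
# fitted model container
# ---------------------------------------------------------------------------

@dataclass
class FittedRiskModel:
    """Per-sex, per-label fitted risk model across M imputations."""

    sex: str
    label: str
    fp_transforms: dict = field(default_factory=dict)
    fits: list = field(default_factory=list)
    region: dict | None = None
    meta: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.fits)

    def pooled(self) -> tuple:
        """Rubin-pooled coefficients.

        Imputation-specific fits can drop a separated rare-indicator column
        on some imputed datasets; pooling is then restricted to the columns
        present in every fit.
        """
        common = self.fits[0].params.index
        for f in self.fits[1:]:
            common = common.intersection(f.params.index)
        if all(f.params.index.equals(common) for f in self.fits):
            return pool_coefficients_rubin(self.fits)
        M = len(self.fits)
        betas = np.vstack([f.params.reindex(common).to_numpy()
                           for f in self.fits])
        within = np.vstack([np.diag(f.cov.reindex(index=common,
                                                  columns=common).to_numpy())
                            for f in self.fits]).mean(axis=0)
        pooled = betas.mean(axis=0)
        between = betas.var(axis=0, ddof=1) if M > 1 else np.zeros_like(pooled)
        return (pd.Series(pooled, index=common),
                pd.Series(within + (1 + 1 / M) * between, index=common))

    def design(self, df: pd.DataFrame) -> pd.DataFrame:
        return build_design(df, self.label, self.sex, self.fp_transforms,
                            with_region=(self.label == "E"))

    # -- serialization (structured text + delimited baseline) -------------
    def save(self, path_prefix) -> None:
        obj = {
            "sex": self.sex, "label": self.label, "meta": self.meta,
            "fp_transforms": {
                v: {"powers": list(t.powers), "shift": t.shift,
                    "scale": t.scale, "significant": t.significant}
                for v, t in self.fp_transforms.items()},
            "region": ({"tau2": self.region["tau2"],
                        "effects": self.region["region_effects"].to_dict()}
                       if self.region else None),
            "fits": [{
                "params": f.params.to_dict(), "lp_center": f.lp_center,
                "loglik": f.loglik, "n": f.n, "events": f.events,
            } for f in self.fits],
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(obj, fh, indent=1)
        rows = []
        for m, f in enumerate(self.fits):
            for t, h in zip(f.baseline.times, f.baseline.values):
                rows.append((m, t, h))
        pd.DataFrame(rows, columns=["m", "time", "cumhaz"]).to_csv(
            f"{path_prefix}_baseline.csv", index=False)


def fit_model_sequence(tables, sex: str, labels=MODEL_LABELS,
                       fp_transforms: dict | None = None,
                       select_fp: bool = False, fp_alpha: float = 0.05,
                       tau2_grid=None) -> dict:
    """Fit the nested sequence on each completed table for one sex.

    ``tables`` is the list of completed imputation tables (development rows
    only).  Fractional polynomials for age and BMI are selected once on the
    first table while building model A, and for calendar time while building
    model D; the chosen transforms are reused for all subsequent models.
    """
    fp_transforms = dict(fp_transforms or {})
    out = {}
    for label in labels:
        first = tables[0][tables[0]["sex"] == sex]
        times0 = first["followup_time"].to_numpy()
        events0 = first["event"].to_numpy()
        if select_fp and label == "A":
            for var in ("age_at_index", "bmi"):
                if var in fp_transforms:
                    continue
                adjust = build_design(first, "A", sex).drop(
                    columns=[var], errors="ignore")
                fp_transforms[var] = select_fractional_polynomial(
                    first, var, times0, events0, adjust, fp_alpha)
        if select_fp and label == "D" and "calendar_time" not in fp_transforms:
            adjust = build_design(first, "D", sex,
                                  {k: v for k, v in fp_transforms.items()
                                   if k != "calendar_time"}).drop(
                columns=["calendar_time"], errors="ignore")
            fp_transforms["calendar_time"] = select_fractional_polynomial(
                first, "calendar_time", times0, events0, adjust, fp_alpha)

        model = FittedRiskModel(sex=sex, label=label,
                                fp_transforms=dict(fp_transforms))
        for tab in tables:
            d = tab[tab["sex"] == sex]
            times = d["followup_time"].to_numpy()
            events = d["event"].to_numpy()
            design = build_design(d, label, sex, fp_transforms,
                                  with_region=(label == "E"))
            if label == "E":
                res = fit_region_random_intercept(design, times, events,
                                                  tau2_grid=tau2_grid)
                model.fits.append(res["fit"])
                model.region = {"tau2": res["tau2"],
                                "region_effects": res["region_effects"]}
            else:
                model.fits.append(fit_cox(design, times, events))
        model.meta = {"n": int(len(tables[0][tables[0]['sex'] == sex])),
                      "events": int(model.fits[0].events),
                      "M": len(tables)}
        out[label] = model
    return out
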