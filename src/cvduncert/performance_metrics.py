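"""Censoring-aware discrimination, explained-variation and accuracy metrics.

The suite mirrors what is routinely reported for 10-year survival risk
models: Harrell's C (C_H), Uno's IPCW C (C_U), Gonen-Heller's concordance
probability (C_GH), Royston-Sauerbrei's D and R^2_D, Kent-O'Quigley
explained variation (R^2_PM, rho_w,a), O'Quigley's explained randomness
(rho_k), the integrated Brier score with Graf censoring weights and its
R^2_IBS, plus Kaplan-Meier calibration by predicted-risk decile.

Conventions, stated because texts differ: the censoring-distribution
Kaplan-Meier G is evaluated left-continuously, G(t-), wherever a patient's
own event time enters an IPCW weight; concordance pairs are (i, j) with
t_i < t_j and patient i an event; ties in the linear predictor count 1/2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .survival_utils import (StepFunction, censoring_survival, efron_loglik,
                             kaplan_meier as _km)
from .model_fitting import fit_cox

__all__ = ["kaplan_meier", "harrell_c", "uno_c", "gonen_heller_c",
           "royston_d", "d_to_r2", "explained_variation", "rho_k",
           "integrated_brier", "calibration_by_risk_group", "metric_suite"]

KAPPA = np.sqrt(8.0 / np.pi)        # scaling of normal scores in D
SIGMA2 = np.pi ** 2 / 6.0           # logistic error variance in R^2 forms


def kaplan_meier(times, events) -> StepFunction:
    """Product-limit survival estimator (right-continuous step function)."""
    return _km(times, events)


# ---------------------------------------------------------------------------
# concordance (shared pair logic, chunked over events)
# ---------------------------------------------------------------------------

def _concordance(lp, times, events, tau=None, ipcw=False, chunk=256):
    lp = np.asarray(lp, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ev_mask = events == 1
    if tau is not None:
        ev_mask = ev_mask & (times < tau)
    ev_idx = np.flatnonzero(ev_mask)
    if ev_idx.size == 0:
        raise ValueError("no usable pairs (no qualifying events)")
    if ipcw:
        G = censoring_survival(times, events)
        g = np.asarray(G.left(times[ev_idx]), dtype=float)
        if np.any(g <= 0):
            raise ValueError("censoring survival is 0 at a contributing "
                             "event time; C inestimable")
        w = 1.0 / g ** 2
    else:
        w = np.ones(ev_idx.size)
    num = 0.0
    den = 0.0
    for s in range(0, ev_idx.size, chunk):
        ii = ev_idx[s:s + chunk]
        later = times[None, :] > times[ii, None]          # usable partners
        n_pairs = later.sum(axis=1)
        conc = ((lp[ii, None] > lp[None, :]) & later).sum(axis=1)
        ties = (np.isclose(lp[ii, None], lp[None, :], rtol=0, atol=0)
                & later).sum(axis=1)
        num += float((w[s:s + chunk] * (conc + 0.5 * ties)).sum())
        den += float((w[s:s + chunk] * n_pairs).sum())
    if den == 0:
        raise ValueError("no usable pairs")
    return num / den


def harrell_c(lp, times, events, tau=None) -> float:
    """Harrell's concordance over usable pairs (earlier time is an event).

    ``tau`` restricts to pairs whose event time is below the horizon — the
    variant that coincides with Uno's C when there is no censoring.
    """
    return _concordance(lp, times, events, tau=tau, ipcw=False)


def uno_c(lp, times, events, tau) -> float:
    """Uno's IPCW concordance restricted to event times below ``tau``.

    Pairs (i, j) with t_i < t_j, t_i < tau and i an event are weighted by
    G(t_i-)^-2 with G the Kaplan-Meier of the censoring distribution.
    """
    if tau is None:
        raise ValueError("uno_c requires a horizon tau")
    return _concordance(lp, times, events, tau=tau, ipcw=True)


def gonen_heller_c(lp, chunk=1024) -> float:
    """Gonen-Heller concordance probability estimate (model-based).

    K = [2 / (n(n-1))] sum_{i<j} 1 / (1 + exp(-|lp_i - lp_j|)), with tied
    linear predictors contributing 1/2.  Depends on the model's linear
    predictor only, not on event or censoring times.
    """
    lp = np.asarray(lp, dtype=float)
    n = lp.size
    if n < 2:
        raise ValueError("need at least 2 patients")
    total = 0.0
    for s in range(0, n, chunk):
        block = lp[s:s + chunk]
        d = np.abs(block[:, None] - lp[None, :])
        kern = 1.0 / (1.0 + np.exp(-d))
        kern[d == 0] = 0.5
        iu = np.arange(s, s + block.size)
        # count each unordered pair once: partner index strictly greater
        mask = np.arange(n)[None, :] > iu[:, None]
        total += float((kern * mask).sum())
    return 2.0 * total / (n * (n - 1))


# ---------------------------------------------------------------------------
# D statistic and explained variation / randomness
# ---------------------------------------------------------------------------

def royston_d(lp, times, events) -> tuple:
    """Royston-Sauerbrei D and R^2_D.

    Ranks the linear predictor, maps ranks to expected standard-normal
    order statistics (Blom constant 3/8), scales by kappa = sqrt(8/pi) and
    refits a one-covariate Cox model on the score; D is the refitted log
    hazard ratio between median-split halves in expectation.
    """
    lp = np.asarray(lp, dtype=float)
    n = lp.size
    if np.unique(lp).size == 1:
        return 0.0, 0.0
    ranks = stats.rankdata(lp, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (n + 0.25)) / KAPPA
    design = pd.DataFrame({"z": z})
    fit = fit_cox(design, times, events)
    D = float(fit.params.iloc[0])
    return D, d_to_r2(D)


def d_to_r2(D: float) -> float:
    """Closed-form R^2_D = (D^2/kappa^2) / (sigma^2 + D^2/kappa^2)."""
    q = D ** 2 / KAPPA ** 2
    return q / (SIGMA2 + q)


def explained_variation(lp) -> tuple:
    """(R^2_PM, rho_w,a) from the variance V of the linear predictor.

    R^2_PM = V / (V + pi^2/6); rho_w,a replaces the logistic error
    variance pi^2/6 by 1.
    """
    lp = np.asarray(lp, dtype=float)
    V = float(lp.var(ddof=1)) if lp.size > 1 else 0.0
    return V / (V + SIGMA2), V / (V + 1.0)


def rho_k(lp, times, events) -> float:
    """O'Quigley et al.'s explained randomness rho^2_k.

    rho^2_k = 1 - exp(-Gamma / k) with Gamma twice the partial-likelihood
    gain of the linear predictor (refitted as a single covariate) over the
    null and k the number of events.
    """
    events = np.asarray(events, dtype=int)
    k = int(events.sum())
    if k < 1:
        raise ValueError("need at least one event")
    lp = np.asarray(lp, dtype=float)
    if np.unique(lp).size == 1:
        return 0.0
    fit = fit_cox(pd.DataFrame({"lp": lp}), times, events)
    beta = float(fit.params.iloc[0])
    gamma = 2.0 * (efron_loglik(beta * lp, times, events)
                   - efron_loglik(np.zeros_like(lp), times, events))
    if gamma < -1e-8:
        raise ValueError("fitted model worse than null; check inputs")
    return 1.0 - np.exp(-max(gamma, 0.0) / k)


# ---------------------------------------------------------------------------
# integrated Brier score
# ---------------------------------------------------------------------------

def integrated_brier(surv_fn, times, events, tau) -> tuple:
    """Integrated Brier score with Graf censoring weights, plus R^2_IBS.

    ``surv_fn(t)`` returns the per-patient predicted survival at time t.
    BS(t) averages S(t)^2 / G(T_i-) over events by t and (1-S(t))^2 / G(t)
    over patients still under observation; IBS integrates BS over [0, tau]
    by the trapezoid rule on the event-time grid.  R^2_IBS compares against
    the overall Kaplan-Meier curve as reference predictor.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    G = censoring_survival(times, events)
    km = _km(times, events)
    grid = np.unique(np.concatenate([[0.0], times[(events == 1) & (times <= tau)],
                                     [tau]]))

    g_at_T = np.asarray(G.left(times), dtype=float)

    def bs(t, surv):
        s = np.asarray(surv, dtype=float)
        had_event = (times <= t) & (events == 1)
        at_risk = times > t
        gt = float(G(t))
        if (had_event.any() and np.any(g_at_T[had_event] <= 0)) or \
           (at_risk.any() and gt <= 0):
            raise ValueError("censoring survival is 0 on the grid; "
                             "IBS inestimable")
        out = np.zeros_like(s)
        out[had_event] = s[had_event] ** 2 / g_at_T[had_event]
        out[at_risk] = (1.0 - s[at_risk]) ** 2 / gt
        return float(out.mean())

    bs_model = np.array([bs(t, surv_fn(t)) for t in grid])
    bs_ref = np.array([bs(t, np.full(times.size, float(km(t)))) for t in grid])
    ibs = float(np.trapezoid(bs_model, grid) / tau)
    ibs_ref = float(np.trapezoid(bs_ref, grid) / tau)
    r2 = 1.0 - ibs / ibs_ref if ibs_ref > 0 else 0.0
    return ibs, r2


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibration_by_risk_group(risks, times, events, groups: int = 10,
                              horizon: float = 10.0) -> pd.DataFrame:
    """Mean predicted risk vs 1 - KM(horizon) within predicted-risk deciles.

    Degenerate quantile boundaries (heavy ties) are merged with a warning;
    group sizes always sum to n.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if risks.size < groups:
        raise ValueError("fewer patients than groups")
    qs = np.quantile(risks, np.linspace(0, 1, groups + 1))
    edges = np.unique(qs)
    if edges.size - 1 < groups:
        import warnings
        warnings.warn("tied risk quantiles; merged into "
                      f"{edges.size - 1} groups", stacklevel=2)
    idx = np.clip(np.searchsorted(edges, risks, side="right") - 1,
                  0, edges.size - 2)
    rows = []
    for g in range(edges.size - 1):
        m = idx == g
        if not m.any():
            continue
        surv = _km(times[m], events[m])
        observed = 1.0 - float(surv(horizon))
        mean_risk = float(risks[m].mean())
        rows.append({"group": g + 1, "n": int(m.sum()),
                     "mean_predicted": mean_risk, "observed": observed,
                     "difference": mean_risk - observed})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# suite
# ---------------------------------------------------------------------------

def metric_suite(lp, risks, surv_fn, times, events, tau: float = 10.0,
                 gh_max_n: int = 20000, seed: int = 0) -> dict:
    """All Table-style metrics for one model on one evaluation sample.

    ``surv_fn`` may be None to skip the Brier-based metrics.  C_GH is
    evaluated on a seeded subsample when n exceeds ``gh_max_n`` (it is
    O(n^2) and depends on the lp distribution only).
    """
    lp = np.asarray(lp, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = lp.size
    out = {"n": n, "events": int(events.sum()),
           "censoring_fraction": float(1.0 - events.mean())}
    out["C_H"] = harrell_c(lp, times, events)
    out["C_U"] = uno_c(lp, times, events, tau)
    if n > gh_max_n:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
        sub = rng.choice(n, gh_max_n, replace=False)
        out["C_GH"] = gonen_heller_c(lp[sub])
    else:
        out["C_GH"] = gonen_heller_c(lp)
    out["D"], out["R2_D"] = royston_d(lp, times, events)
    out["R2_PM"], out["rho_wa"] = explained_variation(lp)
    out["rho_k"] = rho_k(lp, times, events)
    if surv_fn is not None:
        out["IBS"], out["R2_IBS"] = integrated_brier(surv_fn, times, events, tau)
    else:
        out["IBS"] = out["R2_IBS"] = float("nan")
    return out
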