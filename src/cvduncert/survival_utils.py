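"""Shared nonparametric survival estimators (risk-set arithmetic).

Small, fully-vectorised implementations of the Nelson-Aalen and
Kaplan-Meier estimators, the censoring-distribution Kaplan-Meier with
left-continuous evaluation, and the Breslow baseline cumulative hazard of a
fitted Cox model.  These are kept in one place because the imputation,
metric and scoring layers all consume them and the tests check them against
hand risk-set enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StepFunction", "nelson_aalen", "kaplan_meier",
           "censoring_survival", "breslow_baseline", "efron_loglik"]


@dataclass
class StepFunction:
    """Right-continuous step function with jumps at ``times``.

    ``__call__`` evaluates f(t); ``left`` evaluates the left limit f(t-).
    """

    times: np.ndarray      # strictly increasing jump locations
    values: np.ndarray     # value on [times[i], times[i+1])
    initial: float         # value on (-inf, times[0])

    def __call__(self, t):
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate([[self.initial], self.values])
        return vals[idx]

    def left(self, t):
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        vals = np.concatenate([[self.initial], self.values])
        return vals[idx]


def _risk_sets(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be > 0")
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    uniq, first = np.unique(t, return_index=True)
    n = times.size
    # events and totals per unique time
    d = np.add.reduceat(e, first)
    c = np.add.reduceat(np.ones_like(e), first)
    at_risk = n - np.concatenate([[0], np.cumsum(c)[:-1]])
    return uniq, d, at_risk


def nelson_aalen(times, events) -> StepFunction:
    """Nelson-Aalen cumulative hazard H(t) = sum_{s<=t} d_s / n_s."""
    uniq, d, at_risk = _risk_sets(times, events)
    keep = d > 0
    H = np.cumsum(d[keep] / at_risk[keep])
    return StepFunction(uniq[keep], H, 0.0)


def kaplan_meier(times, events) -> StepFunction:
    """Product-limit survival estimator."""
    uniq, d, at_risk = _risk_sets(times, events)
    keep = d > 0
    S = np.cumprod(1.0 - d[keep] / at_risk[keep])
    return StepFunction(uniq[keep], S, 1.0)


def censoring_survival(times, events) -> StepFunction:
    """Kaplan-Meier of the censoring distribution (events reversed).

    Evaluate with ``.left(t)`` for the G(t-) convention used in IPCW
    weighting.
    """
    events = np.asarray(events, dtype=int)
    return kaplan_meier(times, 1 - events)


def breslow_baseline(lp, times, events) -> StepFunction:
    """Breslow cumulative baseline hazard at linear predictor ``lp``.

    H0(t) = sum_{event times t_i <= t} d_i / sum_{j: t_j >= t_i} exp(lp_j).
    The caller is responsible for any centering of ``lp``; predictions are
    then 1 - exp(-H0(t))**exp(lp_new) with lp_new on the same scale.
    """
    lp = np.asarray(lp, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    t, e, z = times[order], events[order], np.exp(lp[order])
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e, first)
    # sum of exp(lp) over the risk set at each unique time (suffix sums)
    denom_all = np.concatenate([np.cumsum(z[::-1])[::-1], [0.0]])
    denom = denom_all[first]
    keep = d > 0
    H0 = np.cumsum(d[keep] / denom[keep])
    return StepFunction(uniq[keep], H0, 0.0)


def efron_loglik(lp, times, events) -> float:
    """Cox partial log-likelihood of a fixed linear predictor, Efron ties."""
    lp = np.asarray(lp, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    t, e, z = times[order], events[order], np.exp(lp[order])
    lp_s = lp[order]
    uniq, first = np.unique(t, return_index=True)
    bounds = np.append(first, t.size)
    suffix = np.concatenate([np.cumsum(z[::-1])[::-1], [0.0]])
    counts = np.diff(bounds)
    if counts.max() == 1:      # no tied times: fully vectorised
        ev = np.flatnonzero(e == 1)
        return float(lp_s[ev].sum() - np.log(suffix[ev]).sum())
    ll = 0.0
    for i in range(uniq.size):
        lo, hi = bounds[i], bounds[i + 1]
        ev = slice(lo, hi)
        mask = e[ev] == 1
        d = int(mask.sum())
        if d == 0:
            continue
        risk_sum = suffix[lo]
        tie_sum = z[ev][mask].sum()
        ll += lp_s[ev][mask].sum()
        j = np.arange(d)
        ll -= np.log(risk_sum - (j / d) * tie_sum).sum()
    return float(ll)
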