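"""Sensitivity analyses for the secular trend in CVD incidence.

Follow-up is segmented into exact person-time per calendar year and a
Poisson model with a log person-time offset estimates the annual rate
ratio; the same machinery runs on a statin-treated cohort built from
prescription records, where exposure episodes end after a 183-day gap
with no prescription (re-entry allowed, censoring at the CVD event).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_cohort import DAYS_PER_YEAR

log = logging.getLogger(__name__)

__all__ = ["split_person_years", "fit_poisson_trend",
           "build_treatment_episodes", "episode_person_years"]

GAP_DAYS = 183


def split_person_years(cohort: pd.DataFrame) -> pd.DataFrame:
    """Segment each patient's follow-up into time at risk per calendar year.

    Splitting is exact: day counts (including fractional days implied by a
    decimal-year follow-up length) divided by 365.25.  The event, if any,
    is assigned to the calendar year containing the exit date; per patient
    the segmented times sum to the total follow-up to floating precision.
    """
    start = cohort["index_date"]
    if not pd.api.types.is_datetime64_any_dtype(start):
        raise ValueError("index_date must be datetime")
    fu_days = cohort["followup_time"].to_numpy(dtype=float) * DAYS_PER_YEAR
    if np.any(fu_days < 0):
        raise ValueError("follow-up end before start")
    start_ns = start.to_numpy().astype("datetime64[ns]").astype(np.int64)
    end_ns = start_ns + (fu_days * 86400e9).astype(np.int64)
    years = np.arange(start.dt.year.min(), pd.to_datetime(end_ns.max()).year + 1)
    pid = cohort["patient_id"].to_numpy()
    event = cohort["event"].to_numpy(dtype=int)
    rows = []
    for y in years:
        y0 = np.int64(pd.Timestamp(f"{y}-01-01").value)
        y1 = np.int64(pd.Timestamp(f"{y + 1}-01-01").value)
        lo = np.maximum(start_ns, y0)
        hi = np.minimum(end_ns, y1)
        dur_ns = hi - lo
        m = dur_ns > 0
        if not m.any():
            continue
        t = dur_ns[m] / 86400e9 / DAYS_PER_YEAR
        ev = (event[m] == 1) & (end_ns[m] > y0) & (end_ns[m] <= y1)
        rows.append(pd.DataFrame({
            "patient_id": pid[m], "calendar_year": y,
            "time_at_risk": t, "event_in_year": ev.astype(int)}))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["patient_id", "calendar_year"],
                           ignore_index=True)


def fit_poisson_trend(rows: pd.DataFrame,
                      adjust_for_baseline_risk: bool = False) -> dict:
    """Annual rate ratio from a log-linear Poisson person-year model.

    Calendar year enters linearly with log(time at risk) as offset;
    optionally adjusts for a per-row ``baseline_risk`` covariate (the
    10-year risk score at inception), whose rate ratio per unit of risk is
    returned alongside.  A factor-coded fit is available as a diagnostic
    via ``factor=True`` columns in the result.
    """
    if rows["event_in_year"].sum() == 0:
        raise ValueError("no events; trend inestimable")
    with_events = rows.loc[rows["event_in_year"] == 1, "calendar_year"]
    if with_events.nunique() < 2:
        raise ValueError("need events in >= 2 distinct calendar years")
    X = pd.DataFrame({"const": 1.0,
                      "calendar_year": rows["calendar_year"].to_numpy(dtype=float)})
    if adjust_for_baseline_risk:
        if "baseline_risk" not in rows.columns:
            raise ValueError("rows lack a baseline_risk column")
        X["baseline_risk"] = rows["baseline_risk"].to_numpy(dtype=float)
    model = sm.GLM(rows["event_in_year"].to_numpy(dtype=float), X,
                   family=sm.families.Poisson(),
                   offset=np.log(rows["time_at_risk"].to_numpy(dtype=float)))
    res = model.fit()
    ci = res.conf_int()
    out = {
        "rate_ratio": float(np.exp(res.params["calendar_year"])),
        "ci": (float(np.exp(ci.loc["calendar_year", 0])),
               float(np.exp(ci.loc["calendar_year", 1]))),
        "coef": res.params.to_dict(),
        "n_rows": int(len(rows)),
        "events": int(rows["event_in_year"].sum()),
    }
    if adjust_for_baseline_risk:
        out["risk_rate_ratio"] = float(np.exp(res.params["baseline_risk"]))
        out["risk_ci"] = (float(np.exp(ci.loc["baseline_risk", 0])),
                          float(np.exp(ci.loc["baseline_risk", 1])))
    return out


def build_treatment_episodes(prescriptions: pd.DataFrame,
                             event_dates: pd.Series,
                             study_end) -> pd.DataFrame:
    """Continuous statin-exposure episodes from prescription records.

    An episode runs while consecutive prescriptions are <= 183 days apart
    and ends 183 days after its last prescription, truncated at the CVD
    event date or the study end; a later prescription after a gap opens a
    new episode (re-entry).  Nothing is followed beyond the event:
    prescriptions after a patient's event are skipped with a warning.
    """
    study_end = pd.Timestamp(study_end)
    gap = pd.Timedelta(days=GAP_DAYS)
    skipped = 0
    rows = []
    for pid, grp in prescriptions.groupby("patient_id", sort=True):
        dates = grp["prescription_date"].sort_values().to_list()
        ev = event_dates.get(pid, pd.NaT)
        ev = pd.Timestamp(ev) if pd.notna(ev) else None
        if ev is not None:
            before = [d for d in dates if d <= ev]
            skipped += len(dates) - len(before)
            dates = before
        if not dates:
            continue
        start = prev = dates[0]
        closed = False
        for d in dates[1:]:
            if closed:
                skipped += 1
                continue
            if (d - prev) > gap:
                rows.append(_close_episode(pid, start, prev, ev, study_end))
                if rows[-1]["end_reason"] == "event":
                    closed = True
                    continue
                start = d
            prev = d
        if not closed:
            rows.append(_close_episode(pid, start, prev, ev, study_end))
    if skipped:
        log.warning("skipped %d prescription(s) after the CVD event", skipped)
    return pd.DataFrame(rows, columns=["patient_id", "episode_start",
                                       "episode_end", "end_reason"])


def _close_episode(pid, start, last_rx, ev, study_end) -> dict:
    end = last_rx + pd.Timedelta(days=GAP_DAYS)
    reason = "gap"
    if ev is not None and ev <= end:
        end, reason = ev, "event"
    if study_end < end:
        end, reason = study_end, "study_end"
    return {"patient_id": pid, "episode_start": start, "episode_end": end,
            "end_reason": reason}


def episode_person_years(episodes: pd.DataFrame) -> pd.DataFrame:
    """Per-calendar-year person-time rows for treatment episodes.

    Episodes are converted to the same (patient, year, time at risk,
    event-in-year) layout as :func:`split_person_years`, with the event
    flagged when the episode ended at the CVD event.
    """
    days = (episodes["episode_end"] - episodes["episode_start"]).dt.days
    tmp = pd.DataFrame({
        "patient_id": episodes["patient_id"],
        "index_date": episodes["episode_start"],
        "followup_time": np.maximum(days, 0.5) / DAYS_PER_YEAR,
        "event": (episodes["end_reason"] == "event").astype(int),
    })
    return split_person_years(tmp)
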