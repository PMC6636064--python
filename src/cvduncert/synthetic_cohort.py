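"""Synthetic EHR-like cohort generator with known ground truth.

Generates two-sex cohorts aged 25-84 with index dates 1998-2015, a
proportional-hazards CVD event process with a multiplicative secular trend
and regional log-hazard intercepts, right censoring (administrative end of
study plus exponential dropout), missing-at-random missingness in the
routinely under-recorded variables, and statin prescription histories.

The generative model
--------------------
For a patient with sex s, covariate vector x, region r and index date at
calendar time y (decimal years), the event hazard at follow-up time t is

    h(t) = h0_s(t) * exp(beta' x + u_r + delta * (y + t - y0))

with h0_s Weibull, u_r ~ N(0, region_sd^2) drawn once per region, delta the
secular-trend log hazard ratio per calendar year, and y0 the study start.
Because the within-follow-up part exp(delta * t) is shared by every patient,
it folds into the baseline hazard; a Cox model with calendar time *at index*
as a covariate therefore has true coefficient delta, and the person-year
event rate also declines by exp(delta) per calendar year.

Event times are sampled by inverse transform on the cumulative hazard
G(t) = integral of h0_s(u) exp(delta * u) du, computed once per sex on a fine
grid (exact when delta = 0).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = [
    "TrueModelSpec",
    "BLANKABLE",
    "FLAG_COLUMNS",
    "COHORT_COLUMNS",
    "generate_cohort",
    "inject_missingness",
    "generate_prescription_histories",
    "linear_predictor",
    "region_effects",
    "true_tenyear_risk",
    "write_table",
    "read_cohort",
]

#: variables that routine records frequently leave unrecorded
BLANKABLE = ("bmi", "sbp", "sbp_variability", "chol_hdl", "smoking", "ethnicity")

_CONTINUOUS = ("bmi", "sbp", "sbp_variability", "chol_hdl")

DAYS_PER_YEAR = 365.25


def _default_config() -> dict:
    ref = importlib.resources.files("cvduncert") / "config" / "default_cohort.yaml"
    return yaml.safe_load(ref.read_text())


@dataclass
class TrueModelSpec:
    """Ground-truth parameters of the synthetic cohort.

    Wraps a nested configuration mapping (see ``config/default_cohort.yaml``)
    holding per-sex Weibull baselines, covariate marginals, log hazard
    ratios, the secular-trend slope, the region-effect SD, censoring,
    missingness and prescription parameters.
    """

    cfg: dict = field(default_factory=_default_config)

    def __post_init__(self) -> None:
        self.validate()

    # -- constructors -----------------------------------------------------
    @classmethod
    def default(cls, **overrides) -> "TrueModelSpec":
        cfg = _default_config()
        cfg.update(overrides)
        return cls(cfg)

    @classmethod
    def from_yaml(cls, path) -> "TrueModelSpec":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.cfg, fh, sort_keys=False)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        c = self.cfg
        for sex in ("F", "M"):
            bh = c["baseline_hazard"][sex]
            if bh["shape"] <= 0 or bh["scale"] <= 0:
                raise ValueError(f"baseline_hazard[{sex}]: shape and scale must be > 0")
        if c["region_effect_sd"] < 0:
            raise ValueError("region_effect_sd must be >= 0")
        if c["dropout_rate"] < 0:
            raise ValueError("dropout_rate must be >= 0")
        if len(c["region"]["levels"]) != 10:
            raise ValueError("region: exactly 10 levels required")
        for var, per_sex in c["missingness"]["recorded"].items():
            for sex, frac in per_sex.items():
                if not (0 < frac <= 1):
                    raise ValueError(
                        f"missingness.recorded[{var}][{sex}] must be in (0, 1]"
                    )
        if not (0 <= c["prescriptions"]["initiation_prob"] <= 1):
            raise ValueError("prescriptions.initiation_prob must be in [0, 1]")
        lo, hi = c["study"]["age_range"]
        if not (0 < lo < hi):
            raise ValueError("study.age_range must be increasing and positive")

    # -- convenience ------------------------------------------------------
    @property
    def trend_loghr(self) -> float:
        return float(self.cfg["trend_loghr"])

    @property
    def region_levels(self) -> list:
        return list(self.cfg["region"]["levels"])

    @property
    def study_years(self) -> float:
        start = pd.Timestamp(self.cfg["study"]["start_date"])
        end = pd.Timestamp(self.cfg["study"]["end_date"])
        return (end - start).days / DAYS_PER_YEAR

    def replace(self, **overrides) -> "TrueModelSpec":
        """Return a copy with top-level config keys replaced."""
        import copy

        cfg = copy.deepcopy(self.cfg)
        cfg.update(overrides)
        return TrueModelSpec(cfg)


FLAG_COLUMNS = (
    "atrial_fibrillation", "atypical_antipsychotic", "ckd345", "ckd45",
    "corticosteroid", "erectile_dysfunction", "family_history_cvd", "hiv_aids",
    "migraine", "rheumatoid_arthritis", "severe_mental_illness", "sle",
    "treated_hypertension", "type1_diabetes", "type2_diabetes",
    "alcohol_abuse", "anxiety", "lvh",
)

COHORT_COLUMNS = (
    ("patient_id", "int64"),
    ("sex", "object"),
    ("age_at_index", "float64"),
    ("index_date", "datetime64[ns]"),
    ("calendar_time", "float64"),
    ("bmi", "float64"),
    ("sbp", "float64"),
    ("sbp_variability", "float64"),
    ("chol_hdl", "float64"),
    ("smoking", "object"),
    ("ethnicity", "object"),
    ("region", "object"),
    ("townsend", "int64"),
    *((f, "int64") for f in FLAG_COLUMNS),
    ("consult_count", "int64"),
    ("rx_count", "int64"),
    ("consult_gt50", "int64"),
    ("rx_gt50", "int64"),
    ("followup_time", "float64"),
    ("event", "int64"),
)


def _empty_cohort() -> pd.DataFrame:
    return pd.DataFrame({name: pd.Series(dtype=dt) for name, dt in COHORT_COLUMNS})


# ---------------------------------------------------------------------------
# linear predictor and ground-truth risks
# ---------------------------------------------------------------------------

def linear_predictor(spec: TrueModelSpec, cohort: pd.DataFrame) -> np.ndarray:
    """True covariate log relative hazard beta'x (trend and region excluded)."""
    lh = spec.cfg["loghr"]
    lp = np.zeros(len(cohort))
    for var, col in (("age", "age_at_index"), ("bmi", "bmi"), ("sbp", "sbp"),
                     ("sbp_variability", "sbp_variability"),
                     ("chol_hdl", "chol_hdl"), ("townsend", "townsend")):
        term = lh[var]
        lp += term["value"] * (cohort[col].to_numpy(dtype=float) - term["center"])
    lp += cohort["smoking"].map(lh["smoking"]).to_numpy(dtype=float)
    lp += cohort["ethnicity"].map(lh["ethnicity"]).to_numpy(dtype=float)
    for flag, beta in lh["flags"].items():
        lp += beta * cohort[flag].to_numpy(dtype=float)
    lp += lh["consult_gt50"] * cohort["consult_gt50"].to_numpy(dtype=float)
    lp += lh["rx_gt50"] * cohort["rx_gt50"].to_numpy(dtype=float)
    return lp


def region_effects(spec: TrueModelSpec, seed: int) -> pd.Series:
    """Region log-hazard intercepts used by ``generate_cohort`` for this seed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    u = rng.normal(0.0, spec.cfg["region_effect_sd"], size=10)
    return pd.Series(u, index=spec.region_levels, name="region_effect")


def _trend_cumhaz_grid(shape: float, scale: float, delta: float,
                       t_max: float = 20.0, n: int = 20001):
    """Grid of G(t) = int_0^t (k/lam)(u/lam)^(k-1) e^(delta u) du.

    Uses integration by parts, G(t) = (t/lam)^k e^(delta t) - delta * T(t)
    with T(t) = int (u/lam)^k e^(delta u) du, whose integrand is bounded at 0
    for every shape > 0 (the direct integrand is not when shape < 1).
    Exact when delta = 0.
    """
    t = np.linspace(0.0, t_max, n)
    base = (t / scale) ** shape
    if delta == 0.0:
        return t, base
    f = base * np.exp(delta * t)
    tail = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) / 2) * (t[1] - t[0])])
    return t, base * np.exp(delta * t) - delta * tail


def true_tenyear_risk(spec: TrueModelSpec, cohort: pd.DataFrame, seed: int,
                      horizon: float = 10.0) -> np.ndarray:
    """Ground-truth risk over ``horizon`` years under the generating model."""
    u = region_effects(spec, seed)
    lp = (linear_predictor(spec, cohort)
          + spec.trend_loghr * cohort["calendar_time"].to_numpy()
          + cohort["region"].map(u).to_numpy(dtype=float))
    out = np.empty(len(cohort))
    for sex in ("F", "M"):
        m = (cohort["sex"] == sex).to_numpy()
        if not m.any():
            continue
        bh = spec.cfg["baseline_hazard"][sex]
        t, g = _trend_cumhaz_grid(bh["shape"], bh["scale"], spec.trend_loghr)
        g10 = np.interp(horizon, t, g)
        out[m] = 1.0 - np.exp(-g10 * np.exp(lp[m]))
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    mean = np.asarray(mean, dtype=float)
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd,
                         size=size if size is not None else mean.shape,
                         random_state=rng)


def generate_cohort(spec: TrueModelSpec, n: int, seed: int) -> pd.DataFrame:
    """Draw a complete cohort of ``n`` patients (no missing values).

    Deterministic given ``(spec, n, seed)``.  Region intercepts are drawn
    once from N(0, region_sd^2) via :func:`region_effects` with the same seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    spec.validate()
    if n == 0:
        return _empty_cohort()

    c = spec.cfg
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    start = pd.Timestamp(c["study"]["start_date"])
    end = pd.Timestamp(c["study"]["end_date"])
    total_days = (end - start).days

    sex = np.where(rng.random(n) < c["sex_fraction_female"], "F", "M")
    lo_age, hi_age = c["study"]["age_range"]

    df = pd.DataFrame({"patient_id": np.arange(n, dtype=np.int64), "sex": sex})
    age = np.empty(n)
    cont = {v: np.empty(n) for v in _CONTINUOUS}
    smoking = np.empty(n, dtype=object)
    ethnicity = np.empty(n, dtype=object)
    region = np.empty(n, dtype=object)
    flags = {f: np.zeros(n, dtype=np.int64) for f in FLAG_COLUMNS}
    counts = {k: np.zeros(n, dtype=np.int64) for k in ("consult_count", "rx_count")}

    for s in ("F", "M"):
        m = sex == s
        k = int(m.sum())
        if k == 0:
            continue
        a = c["continuous"]["age"][s]
        age[m] = _trunc_normal(rng, np.full(k, a["mean"]), a["sd"], lo_age, hi_age)
        for v in _CONTINUOUS:
            p = c["continuous"][v][s]
            slope = p.get("slope_age", 0.0)
            resid_sd = np.sqrt(max(p["sd"] ** 2 - slope ** 2 * a["sd"] ** 2,
                                   (0.3 * p["sd"]) ** 2))
            mu = p["mean"] + slope * (age[m] - a["mean"])
            cont[v][m] = _trunc_normal(rng, mu, resid_sd, p["lo"], p["hi"])
        smoking[m] = rng.choice(c["smoking"]["levels"], size=k, p=np.asarray(
            c["smoking"][s]) / np.sum(c["smoking"][s]))
        ethnicity[m] = rng.choice(c["ethnicity"]["levels"], size=k, p=np.asarray(
            c["ethnicity"][s]) / np.sum(c["ethnicity"][s]))
        region[m] = rng.choice(c["region"]["levels"], size=k, p=np.asarray(
            c["region"][s]) / np.sum(c["region"][s]))
        for f in FLAG_COLUMNS:
            if f == "ckd45":
                continue
            flags[f][m] = (rng.random(k) < c["flags"][f][s]).astype(np.int64)
        # CKD stage 4/5 is a subset of stage 3/4/5
        p45 = c["flags"]["ckd45"][s]
        p345 = max(c["flags"]["ckd345"][s], p45)
        sub = np.zeros(k, dtype=np.int64)
        has345 = flags["ckd345"][m] == 1
        if p345 > 0:
            sub[has345] = (rng.random(int(has345.sum())) < p45 / p345).astype(np.int64)
        flags["ckd45"][m] = sub
        for cname in ("consult_count", "rx_count"):
            par = c["counts"][cname][s]
            r, mean = par["r"], par["mean"]
            counts[cname][m] = rng.negative_binomial(r, r / (r + mean), size=k)

    df["age_at_index"] = age
    offset_days = rng.integers(0, total_days, size=n)
    df["index_date"] = start + pd.to_timedelta(offset_days, unit="D")
    df["calendar_time"] = offset_days / DAYS_PER_YEAR
    for v in _CONTINUOUS:
        df[v] = cont[v]
    df["smoking"] = smoking
    df["ethnicity"] = ethnicity
    df["region"] = region
    df["townsend"] = rng.integers(1, 6, size=n)
    for f in FLAG_COLUMNS:
        df[f] = flags[f]
    df["consult_count"] = counts["consult_count"]
    df["rx_count"] = counts["rx_count"]
    df["consult_gt50"] = (df["consult_count"] > 50).astype(np.int64)
    df["rx_gt50"] = (df["rx_count"] > 50).astype(np.int64)

    # event process
    u_region = region_effects(spec, seed)
    lp = (linear_predictor(spec, df)
          + spec.trend_loghr * df["calendar_time"].to_numpy()
          + df["region"].map(u_region).to_numpy(dtype=float))
    t_event = np.empty(n)
    uu = rng.random(n)
    for s in ("F", "M"):
        m = (sex == s)
        if not m.any():
            continue
        bh = c["baseline_hazard"][s]
        tg, gg = _trend_cumhaz_grid(bh["shape"], bh["scale"], spec.trend_loghr)
        target = -np.log(uu[m]) * np.exp(-lp[m])
        t_event[m] = np.interp(target, gg, tg, right=np.inf)

    admin = (total_days - offset_days) / DAYS_PER_YEAR
    if c["dropout_rate"] > 0:
        dropout = rng.exponential(1.0 / c["dropout_rate"], size=n)
    else:
        dropout = np.full(n, np.inf)
    censor = np.minimum(admin, dropout)
    followup = np.minimum(t_event, censor)
    followup = np.maximum(followup, 0.5 / DAYS_PER_YEAR)  # at least half a day
    df["followup_time"] = followup
    df["event"] = (t_event <= censor).astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def _calibrate_intercept(target_missing: float, slope_term: np.ndarray) -> float:
    """Intercept c with mean(expit(c + slope_term)) == target_missing."""
    if target_missing <= 0:
        return -np.inf

    def f(c):
        return expit(c + slope_term).mean() - target_missing

    return brentq(f, -30.0, 30.0)


def inject_missingness(cohort: pd.DataFrame, spec: TrueModelSpec, seed: int,
                       variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Blank values MAR (logistic on age, by sex) to hit target recorded rates.

    Only the routinely under-recorded variables (``BLANKABLE``) may be
    blanked; the intercept of the logistic missingness model is calibrated on
    the cohort at hand so the expected recorded fraction equals the spec
    target.  Row count and non-blankable columns are preserved exactly.
    """
    variables = tuple(variables) if variables is not None else BLANKABLE
    bad = set(variables) - set(BLANKABLE)
    if bad:
        raise ValueError(f"cannot blank non-blankable column(s): {sorted(bad)}")
    out = cohort.copy()
    if len(out) == 0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    slope = spec.cfg["missingness"]["age_slope_per_decade"]
    age_term = slope * (cohort["age_at_index"].to_numpy() - 45.0) / 10.0
    for var in variables:
        targets = spec.cfg["missingness"]["recorded"][var]
        p_missing = np.zeros(len(out))
        for s in ("F", "M"):
            m = (cohort["sex"] == s).to_numpy()
            if not m.any():
                continue
            t_miss = 1.0 - targets[s]
            icept = _calibrate_intercept(t_miss, age_term[m])
            p_missing[m] = expit(icept + age_term[m]) if np.isfinite(icept) else 0.0
        blank = rng.random(len(out)) < p_missing
        if var in ("smoking", "ethnicity"):
            col = out[var].to_numpy(dtype=object)
            col[blank] = np.nan
            out[var] = col
        else:
            out.loc[blank, var] = np.nan
    return out


def missingness_probability(spec: TrueModelSpec, variable: str, sex: str,
                            age: np.ndarray, cohort: pd.DataFrame) -> np.ndarray:
    """Evaluate the MAR missingness curve used for ``cohort`` (oracle hook)."""
    slope = spec.cfg["missingness"]["age_slope_per_decade"]
    m = (cohort["sex"] == sex).to_numpy()
    age_term_cal = slope * (cohort.loc[m, "age_at_index"].to_numpy() - 45.0) / 10.0
    t_miss = 1.0 - spec.cfg["missingness"]["recorded"][variable][sex]
    icept = _calibrate_intercept(t_miss, age_term_cal)
    return expit(icept + slope * (np.asarray(age, dtype=float) - 45.0) / 10.0)


# ---------------------------------------------------------------------------
# prescriptions
# ---------------------------------------------------------------------------

def generate_prescription_histories(cohort: pd.DataFrame, spec: TrueModelSpec,
                                    seed: int) -> pd.DataFrame:
    """Statin prescription records (patient_id, prescription_date).

    A seeded fraction of patients initiates statins at a uniform date within
    the study window after their index date; successive prescriptions follow
    exponential gap times until the study end.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    p = spec.cfg["prescriptions"]
    end = pd.Timestamp(spec.cfg["study"]["end_date"])
    ids, dates = [], []
    if len(cohort) and p["initiation_prob"] > 0:
        initiate = rng.random(len(cohort)) < p["initiation_prob"]
        idx = cohort.index[initiate]
        for i in idx:
            pid = cohort.at[i, "patient_id"]
            t0 = cohort.at[i, "index_date"]
            span = (end - t0).days
            if span <= 0:
                continue
            first = t0 + pd.Timedelta(days=int(rng.integers(0, span)))
            d = first
            for _ in range(int(p["max_per_patient"])):
                if d > end:
                    break
                ids.append(pid)
                dates.append(d)
                d = d + pd.Timedelta(days=float(rng.exponential(p["gap_mean_days"])))
    return pd.DataFrame({
        "patient_id": pd.Series(ids, dtype="int64"),
        "prescription_date": pd.Series(dates, dtype="datetime64[ns]"),
    })


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    """Write any table as delimited text (ISO dates, empty field = missing)."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["index_date"])
    for f in FLAG_COLUMNS:
        if f in df.columns:
            df[f] = df[f].astype("int64")
    return df


def read_prescriptions(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["prescription_date"])
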