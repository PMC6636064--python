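"""Within-person variation in predicted risk across models.

Patients are stratified into 1%-wide bands of their reference-model
(usually model A) risk; within each band the spread of each comparator
model's risks is summarised by the 2.5th-97.5th percentile range, and the
number crossing the 10% statin treatment threshold is counted, mirroring
how a clinician would experience the disagreement between equally
defensible models.  A simple arithmetic extrapolation scales the observed
reclassification fractions to a national population.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["round_half_up", "stratify_and_percentiles",
           "reclassification_counts", "extrapolate_to_population"]

MODEL_ORDER = ("A", "B", "C", "D", "E", "F")


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal rounding with ties away from zero (printed-table style)."""
    q = 10 ** decimals
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


def _risk_columns(risks: pd.DataFrame, reference: str):
    ref_col = f"risk_{reference}"
    if ref_col not in risks.columns:
        raise ValueError(f"reference column {ref_col!r} missing")
    comps = [c.removeprefix("risk_") for c in risks.columns
             if c.startswith("risk_") and c != ref_col
             and not risks[c].isna().all()]
    comps.sort(key=lambda c: MODEL_ORDER.index(c) if c in MODEL_ORDER else 99)
    return ref_col, comps


def stratify_and_percentiles(risks: pd.DataFrame, reference: str = "A",
                             band_width: float = 1.0, max_band: float = 20.0,
                             percentiles=(2.5, 97.5)) -> pd.DataFrame:
    """Percentile ranges of comparator risks within reference-risk bands.

    Bands are half-open [k, k + band_width) in percent; percentiles use
    linear interpolation of order statistics.  Empty bands are emitted with
    n = 0.  When between-imputation cloglog variances for the reference are
    present (``eta_var_<reference>``), the mean Wald 95% CI of the
    reference risk is reported per band (computed on the log(-log) scale).
    """
    if band_width <= 0:
        raise ValueError("band_width must be > 0")
    ref_col, comps = _risk_columns(risks, reference)
    ref_pct = risks[ref_col].to_numpy(dtype=float) * 100.0
    rows = []
    k = 0.0
    eta_var_col = f"eta_var_{reference}"
    have_ci = eta_var_col in risks.columns and risks[eta_var_col].notna().any()
    while k < max_band:
        m = (ref_pct >= k) & (ref_pct < k + band_width)
        row = {"band": f"{k:g}-{k + band_width:g}%", "band_lo": k,
               "band_hi": k + band_width, "n": int(m.sum())}
        if have_ci and m.any():
            r = np.clip(risks.loc[m, ref_col].to_numpy(dtype=float),
                        1e-12, 1 - 1e-12)
            eta = np.log(-np.log(1.0 - r))
            se = np.sqrt(np.maximum(risks.loc[m, eta_var_col]
                                    .to_numpy(dtype=float), 0.0))
            lo = 1.0 - np.exp(-np.exp(eta - 1.96 * se))
            hi = 1.0 - np.exp(-np.exp(eta + 1.96 * se))
            row["ref_ci_lo"] = float(lo.mean()) * 100.0
            row["ref_ci_hi"] = float(hi.mean()) * 100.0
        for c in comps:
            vals = risks.loc[m, f"risk_{c}"].to_numpy(dtype=float) * 100.0
            if vals.size:
                p_lo, p_hi = np.percentile(vals, percentiles)
            else:
                p_lo = p_hi = np.nan
            row[f"p2_5_{c}"] = p_lo
            row[f"p97_5_{c}"] = p_hi
        rows.append(row)
        k += band_width
    return pd.DataFrame(rows)


def reclassification_counts(risks: pd.DataFrame, reference: str = "A",
                            threshold: float = 10.0,
                            bands=(5, 6, 7, 8, 9, 10, 11, 12, 13, 14)) -> pd.DataFrame:
    """Counts and percentages crossing the treatment threshold per band.

    Up-crossing: reference risk < threshold and comparator >= threshold
    (and conversely for down-crossing); high risk is risk >= threshold.
    Aggregate "<threshold" and ">=threshold" rows cover the whole range.
    Percentages are rounded half-up to integers, as printed tables do.
    """
    if not (0 < threshold < 100):
        raise ValueError("threshold must be in (0, 100) percent")
    ref_col, comps = _risk_columns(risks, reference)
    ref = risks[ref_col].to_numpy(dtype=float) * 100.0
    rows = []

    def tally(mask, name):
        row = {"band": name, "n": int(mask.sum())}
        below = ref[mask] < threshold
        for c in comps:
            comp = risks.loc[mask, f"risk_{c}"].to_numpy(dtype=float) * 100.0
            up = int((below & (comp >= threshold)).sum())
            down = int((~below & (comp < threshold)).sum())
            crossed = up + down
            row[f"up_{c}"] = up
            row[f"down_{c}"] = down
            row[f"pct_{c}"] = (round_half_up(100.0 * crossed / mask.sum())
                               if mask.sum() else 0.0)
        rows.append(row)

    for b in bands:
        tally((ref >= b) & (ref < b + 1), f"{b}-{b + 1}%")
    tally(ref < threshold, f"<{threshold:g}%")
    tally(ref >= threshold, f">={threshold:g}%")
    return pd.DataFrame(rows)


def extrapolate_to_population(population: int, eligible_fraction: float,
                              high_risk_fraction: float,
                              reclassified_fraction_by_sex: dict,
                              sex_weights: dict) -> dict:
    """Scale observed reclassification fractions to a national population.

    eligible = population x eligible_fraction; high risk = eligible x
    high_risk_fraction; reclassified = high risk x the sex-weighted mean of
    the sex-specific reclassified fractions.  Counts are rounded half-up;
    the weights must sum to 1.
    """
    if population < 0:
        raise ValueError("population must be >= 0")
    for name, frac in (("eligible_fraction", eligible_fraction),
                       ("high_risk_fraction", high_risk_fraction),
                       *((f"reclassified[{k}]", v)
                         for k, v in reclassified_fraction_by_sex.items())):
        if not (0 <= frac <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    w = sum(sex_weights.values())
    if abs(w - 1.0) > 1e-9:
        raise ValueError("sex weights must sum to 1")
    if set(sex_weights) != set(reclassified_fraction_by_sex):
        raise ValueError("sex keys of weights and fractions must match")
    eligible = round_half_up(population * eligible_fraction)
    high_risk = round_half_up(eligible * high_risk_fraction)
    frac = sum(sex_weights[s] * reclassified_fraction_by_sex[s]
               for s in sex_weights)
    reclassified = round_half_up(high_risk * frac)
    return {
        "population": int(population),
        "eligible": int(eligible),
        "eligible_pct": round_half_up(100.0 * eligible_fraction),
        "high_risk": int(high_risk),
        "reclassified": int(reclassified),
        "reclassified_pct": round_half_up(100.0 * frac),
    }
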