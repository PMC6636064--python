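"""End-to-end experiment orchestration.

simulate -> impute -> fit A-E per sex -> score A-F -> evaluate -> compare
-> trend sensitivity, from a single configuration, with per-stage seed
streams, delimited-text artifacts and a manifest that makes a rerun
bit-reproducible.

Full-population settings (cohort of several million, 200,000-patient
holdout, M = 20 imputations with 20 iterations) are what the configuration
defaults encode; the ``scale`` factor shrinks the cohort and holdout
proportionally for desk-sized runs while leaving the generating parameters
untouched.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imputation, model_fitting, performance_metrics, risk_scoring
from . import secular_trend, synthetic_cohort, uncertainty

log = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "write_report"]

_STAGE_OFFSETS = {"simulate": 101, "impute": 202, "split": 303, "fit": 404,
                  "score": 505, "evaluate": 606, "trend": 707}


@dataclasses.dataclass
class ExperimentConfig:
    """Configuration of one full experiment run."""

    cohort_n: int = 3_855_660
    holdout_n: int = 200_000
    M: int = 20
    iterations: int = 20
    labels: tuple = ("A", "B", "C", "D", "E")
    band_width: float = 1.0
    threshold: float = 10.0
    tau: float = 10.0
    scale: float = 1.0
    seed: int = 0
    select_fp: bool = False
    calibration_label: str = "B"
    trend_analysis: bool = True
    out_dir: str = "cvduncert_run"

    def stage_seed(self, stage: str) -> int:
        return int((self.seed * 10007 + _STAGE_OFFSETS[stage]) % (2 ** 31))

    @property
    def n_effective(self) -> int:
        return max(int(self.cohort_n * self.scale), 200)

    @property
    def holdout_effective(self) -> int:
        return min(max(int(self.holdout_n * self.scale), 100),
                   self.n_effective // 2)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "labels" in raw:
            raw["labels"] = tuple(raw["labels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["labels"] = list(d["labels"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(config: ExperimentConfig, force: bool = False) -> Path:
    """Run the full pipeline; returns the output directory.

    Re-running with an identical configuration reproduces every artifact
    bit-identically (the manifest records content hashes to check this).
    Refuses to overwrite a previous run unless ``force``.
    """
    out = Path(config.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True "
                              "(or --force) to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    if "E" not in config.labels and config.labels:
        raise ValueError("model F scoring requires model E among the fitted "
                         "labels; add 'E' to labels")

    spec = synthetic_cohort.TrueModelSpec.default()
    n = config.n_effective

    # -- simulate ---------------------------------------------------------
    seed_sim = config.stage_seed("simulate")
    complete = synthetic_cohort.generate_cohort(spec, n, seed_sim)
    cohort = synthetic_cohort.inject_missingness(complete, spec, seed_sim)
    rx = synthetic_cohort.generate_prescription_histories(cohort, spec, seed_sim)
    synthetic_cohort.write_table(cohort, out / "cohort.csv")
    synthetic_cohort.write_table(rx, out / "prescriptions.csv")

    # -- impute -----------------------------------------------------------
    seed_imp = config.stage_seed("impute")
    imps = imputation.chained_imputation(cohort, M=config.M,
                                         iterations=config.iterations,
                                         seed=seed_imp)
    with open(out / "imputation_manifest.json", "w") as fh:
        json.dump(imps.provenance, fh, indent=1)

    # -- split ------------------------------------------------------------
    rng = np.random.default_rng(
        np.random.SeedSequence([config.stage_seed("split")]))
    test_ids = rng.choice(cohort["patient_id"].to_numpy(),
                          size=config.holdout_effective, replace=False)
    test_mask = cohort["patient_id"].isin(test_ids)
    dev_tables = [t[~test_mask].reset_index(drop=True) for t in imps.tables]
    test_raw = cohort[test_mask].reset_index(drop=True)
    development = cohort[~test_mask].reset_index(drop=True)

    # -- fit --------------------------------------------------------------
    models = {}
    for sex in ("F", "M"):
        models[sex] = model_fitting.fit_model_sequence(
            dev_tables, sex, labels=config.labels,
            select_fp=config.select_fp)
        for label, model in models[sex].items():
            model.save(out / f"model_{sex}_{label}")

    # -- score ------------------------------------------------------------
    risks = risk_scoring.score_pathways(
        models, test_raw, development, seed=config.stage_seed("score"),
        horizon=config.tau,
        imputation_kwargs={"iterations": min(config.iterations, 5)})
    synthetic_cohort.write_table(
        risks.assign(**{c: risks[c].round(6)
                        for c in risks.columns if c.startswith("risk_")}),
        out / "risk_matrix.csv")

    # -- evaluate ---------------------------------------------------------
    metric_rows = []
    calib_frames = []
    for sex in ("F", "M"):
        mask = (test_raw["sex"] == sex).to_numpy()
        tt = test_raw.loc[mask, "followup_time"].to_numpy()
        ee = test_raw.loc[mask, "event"].to_numpy()
        # completed test table for linear predictors (calculator pathway)
        for label in (*config.labels, "F"):
            model = models[sex]["E" if label == "F" else label]
            rcol = risks.loc[mask, f"risk_{label}"].to_numpy(dtype=float)
            lp = np.log(-np.log(1.0 - risk_scoring.clamp_risks(rcol)))
            h10 = np.array([float(np.interp(
                config.tau, f.baseline.times, f.baseline.values))
                for f in model.fits]).mean()
            rel = np.exp(lp) / max(h10, 1e-300)

            def surv_fn(t, model=model, rel=rel):
                h0t = np.array([float(f.baseline(t)) for f in model.fits]).mean()
                return np.exp(-h0t * rel)

            ms = performance_metrics.metric_suite(
                lp, rcol, surv_fn, tt, ee, tau=config.tau,
                seed=config.stage_seed("evaluate"))
            ms.update({"sex": sex, "model": label})
            metric_rows.append(ms)
        cal_label = config.calibration_label
        if cal_label in config.labels:
            cal = performance_metrics.calibration_by_risk_group(
                risks.loc[mask, f"risk_{cal_label}"].to_numpy(dtype=float),
                tt, ee, horizon=config.tau)
            cal.insert(0, "sex", sex)
            cal.insert(1, "model", cal_label)
            calib_frames.append(cal)
    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    if calib_frames:
        pd.concat(calib_frames, ignore_index=True).to_csv(
            out / "calibration.csv", index=False)

    # -- compare ----------------------------------------------------------
    strata_frames, reclass_frames = [], []
    for sex in ("F", "M"):
        sub = risks[risks["sex"] == sex]
        st = uncertainty.stratify_and_percentiles(
            sub, reference="A", band_width=config.band_width)
        st.insert(0, "sex", sex)
        strata_frames.append(st)
        rc = uncertainty.reclassification_counts(
            sub, reference="A", threshold=config.threshold)
        rc.insert(0, "sex", sex)
        reclass_frames.append(rc)
    strata = pd.concat(strata_frames, ignore_index=True)
    reclass = pd.concat(reclass_frames, ignore_index=True)
    strata.to_csv(out / "percentile_ranges.csv", index=False)
    reclass.to_csv(out / "reclassification.csv", index=False)

    # -- trend sensitivity ------------------------------------------------
    trend = {}
    if config.trend_analysis:
        py = secular_trend.split_person_years(development)
        trend["development"] = secular_trend.fit_poisson_trend(py)
        ev_dates = development["index_date"] + pd.to_timedelta(
            development["followup_time"] * synthetic_cohort.DAYS_PER_YEAR,
            unit="D")
        ev_dates = ev_dates.where(development["event"] == 1, pd.NaT)
        ev_series = pd.Series(ev_dates.to_numpy(),
                              index=development["patient_id"].to_numpy())
        rx_dev = rx[rx["patient_id"].isin(development["patient_id"])]
        episodes = secular_trend.build_treatment_episodes(
            rx_dev, ev_series, spec.cfg["study"]["end_date"])
        if len(episodes):
            epy = secular_trend.episode_person_years(episodes)
            try:
                trend["statin_users"] = secular_trend.fit_poisson_trend(epy)
            except ValueError as err:
                trend["statin_users"] = {"error": str(err)}
            # adjust for the model-A risk at inception where available
            if "A" in config.labels:
                base_risk = {}
                dev_completed = imputation.mean_impute_by_demographics(
                    imps.tables[0][~test_mask.to_numpy()].reset_index(drop=True),
                    development)
                for sex in ("F", "M"):
                    mm = (dev_completed["sex"] == sex).to_numpy()
                    r = risk_scoring._pooled_model_risk(
                        models[sex]["A"], dev_completed[mm], config.tau)
                    base_risk.update(zip(
                        dev_completed.loc[mm, "patient_id"], r))
                epy["baseline_risk"] = epy["patient_id"].map(base_risk)
                try:
                    trend["statin_users_adjusted"] = \
                        secular_trend.fit_poisson_trend(
                            epy.dropna(subset=["baseline_risk"]),
                            adjust_for_baseline_risk=True)
                except ValueError as err:
                    trend["statin_users_adjusted"] = {"error": str(err)}
        with open(out / "trend.json", "w") as fh:
            json.dump(trend, fh, indent=1)

    write_report(out)

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": {s: config.stage_seed(s) for s in _STAGE_OFFSETS},
        "n_effective": n,
        "holdout_effective": config.holdout_effective,
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir())
                  if p.is_file() and p.name != "manifest.json"},
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def write_report(out_dir) -> Path:
    """Render a human-readable summary from the run's delimited artifacts."""
    out = Path(out_dir)
    lines = ["# Risk-model uncertainty report", ""]
    mpath = out / "metrics.csv"
    if not mpath.exists():
        raise FileNotFoundError(f"missing artifact: {mpath}")
    metrics = pd.read_csv(mpath)
    lines.append("## Performance metrics (10-year horizon)")
    show = ["sex", "model", "C_H", "C_U", "C_GH", "D", "R2_D", "R2_PM",
            "rho_wa", "rho_k", "IBS", "R2_IBS"]
    lines.append(metrics[show].round(3).to_string(index=False))
    lines.append("")
    cpath = out / "calibration.csv"
    if cpath.exists():
        lines.append("## Calibration by risk decile")
        lines.append(pd.read_csv(cpath).round(4).to_string(index=False))
        lines.append("")
    spath = out / "percentile_ranges.csv"
    if spath.exists():
        st = pd.read_csv(spath)
        lines.append("## 2.5th-97.5th percentile ranges by model-A band")
        lines.append(st[st["n"] > 0].round(2).to_string(index=False))
        lines.append("")
    rpath = out / "reclassification.csv"
    if rpath.exists():
        lines.append("## Treatment-threshold (10%) reclassification")
        lines.append(pd.read_csv(rpath).to_string(index=False))
        lines.append("")
    tpath = out / "trend.json"
    if tpath.exists():
        with open(tpath) as fh:
            trend = json.load(fh)
        lines.append("## Secular-trend sensitivity (Poisson rate ratios)")
        for name, res in trend.items():
            if "rate_ratio" in res:
                lo, hi = res["ci"]
                extra = ""
                if "risk_rate_ratio" in res:
                    rlo, rhi = res["risk_ci"]
                    extra = (f"; risk-at-start RR "
                             f"{res['risk_rate_ratio']:.2f} ({rlo:.2f}-{rhi:.2f})")
                lines.append(f"- {name}: RR per calendar year "
                             f"{res['rate_ratio']:.2f} ({lo:.2f}-{hi:.2f})"
                             f"{extra}")
            else:
                lines.append(f"- {name}: {res.get('error', 'n/a')}")
        lines.append("")
    report = out / "report.txt"
    report.write_text("\n".join(lines))
    return report
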