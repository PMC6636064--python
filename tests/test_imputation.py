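"""Imputation pathways: Nelson-Aalen predictor, chained equations,
demographic mean imputation."""

import numpy as np
import pandas as pd
import pytest

from cvduncert import imputation as imp
from cvduncert import synthetic_cohort as sc


class TestNelsonAalen:
    def test_hand_enumeration(self):
        H, Hi = imp.nelson_aalen_cumhaz([1.0, 2.0, 3.0], [1, 0, 1])
        assert H(1.0) == pytest.approx(1 / 3)
        assert H(2.5) == pytest.approx(1 / 3)
        assert H(3.0) == pytest.approx(1 / 3 + 1.0)
        np.testing.assert_allclose(Hi, [1 / 3, 1 / 3, 4 / 3])

    def test_no_events_zero(self):
        H, Hi = imp.nelson_aalen_cumhaz([1.0, 2.0], [0, 0])
        assert H(5.0) == 0.0
        np.testing.assert_array_equal(Hi, [0.0, 0.0])

    def test_single_event(self):
        H, _ = imp.nelson_aalen_cumhaz([5.0], [1])
        assert H(5.0) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            imp.nelson_aalen_cumhaz([], [])

    def test_monotone_right_continuous(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1, 100)
        e = rng.binomial(1, 0.6, 100)
        H, _ = imp.nelson_aalen_cumhaz(t, e)
        grid = np.linspace(0, t.max(), 200)
        vals = H(grid)
        assert (np.diff(vals) >= 0).all()


def _mini_cohort(n, miss_frac, seed, rho=0.8):
    """Bivariate-normal (x fully observed, y partially MCAR) mini cohort."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
    df = pd.DataFrame({
        "patient_id": np.arange(n), "sex": "F", "age_at_index": 50.0,
        "townsend": 3, "calendar_time": 5.0,
        "bmi": 25 + 2 * y, "sbp": 120 + 5 * x,
        "followup_time": rng.exponential(5, n) + 0.01,
        "event": rng.binomial(1, 0.2, n),
    })
    mask = rng.random(n) < miss_frac
    df.loc[mask, "bmi"] = np.nan
    return df, mask


class TestChainedImputation:
    def test_no_missing_returns_identical_tables(self):
        df, _ = _mini_cohort(300, 0.0, 1)
        out = imp.chained_imputation(df, predictors=["sbp"], M=3,
                                     iterations=2, seed=1,
                                     variables=["bmi"])
        for tab in out:
            pd.testing.assert_frame_equal(tab, df)

    def test_defaults_recorded_in_provenance(self):
        df, _ = _mini_cohort(150, 0.2, 2)
        out = imp.chained_imputation(df, predictors=["sbp"], seed=2)
        assert out.provenance["M"] == 20
        assert out.provenance["iterations"] == 20
        assert out.M == 20
        assert "_na_cumhaz" in out.provenance["predictors"]

    def test_zero_observed_variable_rejected(self):
        df, _ = _mini_cohort(100, 0.2, 3)
        df["bmi"] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            imp.chained_imputation(df, predictors=["sbp"], M=2,
                                   iterations=2, seed=3)

    def test_observed_cells_preserved_and_complete(self):
        df, mask = _mini_cohort(500, 0.3, 4)
        out = imp.chained_imputation(df, predictors=["sbp"], M=3,
                                     iterations=3, seed=4)
        for tab in out:
            assert tab["bmi"].notna().all()
            np.testing.assert_array_equal(tab.loc[~mask, "bmi"],
                                          df.loc[~mask, "bmi"])

    def test_pmm_draws_are_observed_donor_values(self):
        df, mask = _mini_cohort(500, 0.3, 5)
        out = imp.chained_imputation(df, predictors=["sbp"], M=2,
                                     iterations=3, seed=5)
        observed = set(df.loc[~mask, "bmi"])
        for tab in out:
            assert set(tab.loc[mask, "bmi"]) <= observed

    def test_rubin_pooled_mean_coverage(self):
        """Rubin 95% CI for the mean of the imputed variable covers the
        truth in >= 90% of seeded repetitions (Monte-Carlo oracle)."""
        true_mean = 25.0
        cover = 0
        reps = 50
        for r in range(reps):
            df, _ = _mini_cohort(800, 0.3, 100 + r)
            out = imp.chained_imputation(df, predictors=["sbp"], M=5,
                                         iterations=4, seed=100 + r)
            means = np.array([t["bmi"].mean() for t in out])
            variances = np.array([t["bmi"].var(ddof=1) / len(t) for t in out])
            qbar = means.mean()
            ubar = variances.mean()
            b = means.var(ddof=1)
            total = ubar + (1 + 1 / 5) * b
            dof = 4 * (1 + ubar / ((1 + 1 / 5) * b)) ** 2
            from scipy import stats
            half = stats.t.ppf(0.975, dof) * np.sqrt(total)
            cover += (qbar - half <= true_mean <= qbar + half)
        assert cover >= 0.9 * reps

    def test_chain_means_stabilise(self):
        df, _ = _mini_cohort(2000, 0.35, 6)
        out = imp.chained_imputation(df, predictors=["sbp"], M=2,
                                     iterations=12, seed=6)
        cm = out.chain_means["bmi"]
        for m in range(cm.shape[0]):
            early = cm[m, :5].std(ddof=1)
            late = cm[m, -5:].std(ddof=1)
            assert late < max(0.5 * early, 0.15)

    def test_categorical_imputation_levels_valid(self, default_spec):
        cohort = sc.generate_cohort(default_spec, 1500, seed=7)
        with_miss = sc.inject_missingness(cohort, default_spec, seed=7)
        out = imp.chained_imputation(with_miss, M=2, iterations=2, seed=7)
        levels = set(default_spec.cfg["smoking"]["levels"])
        for tab in out:
            assert tab["smoking"].notna().all()
            assert set(tab["smoking"]) <= levels
            assert tab["ethnicity"].notna().all()


class TestMeanImputeByDemographics:
    def test_no_missing_identity(self):
        df, _ = _mini_cohort(100, 0.0, 8)
        out = imp.mean_impute_by_demographics(df, df)
        pd.testing.assert_frame_equal(out, df)

    def test_cell_mean_of_two_values(self):
        ref = pd.DataFrame({
            "sex": ["F", "F"], "age_at_index": [45.0, 45.0],
            "ethnicity": ["white", "white"], "bmi": [24.0, 26.0]})
        target = pd.DataFrame({
            "sex": ["F"], "age_at_index": [45.0],
            "ethnicity": ["white"], "bmi": [np.nan]})
        out = imp.mean_impute_by_demographics(target, ref,
                                              variables=("bmi",),
                                              method="cells")
        assert out["bmi"].iloc[0] == pytest.approx(25.0)

    def test_matches_normal_equations_oracle(self, default_spec):
        cohort = sc.generate_cohort(default_spec, 4000, seed=9)
        with_miss = sc.inject_missingness(cohort, default_spec, seed=9)
        out = imp.mean_impute_by_demographics(with_miss, with_miss)
        for sex in ("F", "M"):
            obs = with_miss[(with_miss["sex"] == sex)
                            & with_miss["bmi"].notna()]
            mis = with_miss[(with_miss["sex"] == sex)
                            & with_miss["bmi"].isna()]
            levels = sorted(set(obs["ethnicity"].astype(object)
                                .fillna("white")))
            def dm(d):
                eth = d["ethnicity"].astype(object).fillna("white")
                return np.column_stack(
                    [np.ones(len(d)), d["age_at_index"]]
                    + [(eth == lv).to_numpy(float) for lv in levels[1:]])
            beta = np.linalg.lstsq(dm(obs), obs["bmi"], rcond=None)[0]
            expected = dm(mis) @ beta
            got = out.loc[mis.index, "bmi"].to_numpy()
            seen = mis["ethnicity"].astype(object).fillna("white")\
                .isin(levels).to_numpy()
            np.testing.assert_allclose(got[seen], expected[seen], atol=1e-8)

    def test_unseen_ethnicity_falls_back_to_age_sex(self):
        rng = np.random.default_rng(10)
        ref = pd.DataFrame({
            "sex": "F", "age_at_index": rng.uniform(30, 70, 200),
            "ethnicity": "white", "bmi": rng.normal(26, 3, 200)})
        target = pd.DataFrame({
            "sex": ["F"], "age_at_index": [50.0],
            "ethnicity": ["chinese"], "bmi": [np.nan]})
        out = imp.mean_impute_by_demographics(target, ref, variables=("bmi",))
        beta = np.linalg.lstsq(
            np.column_stack([np.ones(200), ref["age_at_index"]]),
            ref["bmi"], rcond=None)[0]
        assert out["bmi"].iloc[0] == pytest.approx(beta[0] + 50 * beta[1])

    def test_reference_without_observed_values_rejected(self):
        df, _ = _mini_cohort(50, 0.5, 11)
        ref = df.copy()
        ref["bmi"] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            imp.mean_impute_by_demographics(df, ref, variables=("bmi",))
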