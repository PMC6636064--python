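"""Metric suite: hand oracles, brute-force pair enumeration, closed forms,
and cross-checks against an independent library implementation."""

import numpy as np
import pandas as pd
import pytest

from cvduncert import performance_metrics as pm
from cvduncert import synthetic_cohort as sc
from cvduncert.survival_utils import censoring_survival

from conftest import null_spec


def brute_concordance(lp, times, events, tau=None, ipcw=False):
    """Exhaustive pair enumeration oracle."""
    G = censoring_survival(times, events) if ipcw else None
    num = den = 0.0
    n = len(times)
    for i in range(n):
        if events[i] != 1:
            continue
        if tau is not None and times[i] >= tau:
            continue
        w = 1.0 / float(G.left(times[i])) ** 2 if ipcw else 1.0
        for j in range(n):
            if times[j] > times[i]:
                den += w
                if lp[i] > lp[j]:
                    num += w
                elif lp[i] == lp[j]:
                    num += 0.5 * w
    return num / den


class TestKaplanMeier:
    def test_hand_product_limit(self):
        S = pm.kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        assert S(1.0) == pytest.approx(2 / 3)
        assert S(2.9) == pytest.approx(2 / 3)
        assert S(3.0) == pytest.approx(0.0)

    def test_no_events_survival_one(self):
        S = pm.kaplan_meier([1.0, 2.0], [0, 0])
        assert S(10.0) == 1.0

    def test_non_increasing(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 150)
        e = rng.binomial(1, 0.5, 150)
        S = pm.kaplan_meier(t, e)
        vals = S(np.linspace(0, t.max(), 300))
        assert (np.diff(vals) <= 1e-15).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pm.kaplan_meier([], [])


class TestConcordance:
    def test_perfect_ranking_is_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        lp = np.array([4.0, 3.0, 2.0, 1.0])
        assert pm.harrell_c(lp, t, np.ones(4, int)) == 1.0

    def test_constant_lp_is_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert pm.harrell_c(np.zeros(4), t, np.ones(4, int)) == 0.5

    def test_harrell_matches_pair_enumeration(self):
        lp = np.array([0.3, -1.0, 0.3, 2.1, -0.4, 0.9])
        t = np.array([2.0, 1.0, 3.0, 0.5, 2.5, 4.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        assert pm.harrell_c(lp, t, e) == brute_concordance(lp, t, e)

    def test_uno_matches_weighted_pair_sum(self):
        rng = np.random.default_rng(2)
        lp = rng.normal(size=8)
        t = rng.exponential(1, 8)
        e = np.array([1, 0, 1, 1, 0, 1, 0, 1])
        tau = np.quantile(t, 0.9)
        assert pm.uno_c(lp, t, e, tau) == pytest.approx(
            brute_concordance(lp, t, e, tau=tau, ipcw=True), abs=1e-12)

    def test_uno_equals_harrell_without_censoring(self):
        rng = np.random.default_rng(3)
        n = 500
        lp = rng.normal(size=n)
        t = rng.exponential(np.exp(-lp))
        e = np.ones(n, int)
        tau = np.quantile(t, 0.8)
        assert pm.uno_c(lp, t, e, tau) == pm.harrell_c(lp, t, e, tau=tau)

    def test_uno_matches_independent_library(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(4)
        n = 300
        lp = rng.normal(size=n)
        t_ev = rng.exponential(np.exp(-lp))
        c = rng.exponential(1.5, n)
        t = np.minimum(t_ev, c)
        e = (t_ev <= c).astype(int)
        y = np.array([(bool(ei), ti) for ei, ti in zip(e, t)],
                     dtype=[("e", bool), ("t", float)])
        tau = float(np.quantile(t, 0.8))
        ours = pm.uno_c(lp, t, e, tau)
        theirs = sksurv_metrics.concordance_index_ipcw(y, y, lp, tau=tau)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_lp_invariances(self):
        """Rank-based C statistics are invariant to monotone affine
        rescaling of lp; the Gonen-Heller kernel depends on the lp spread
        and is invariant to shifts only."""
        rng = np.random.default_rng(5)
        n = 200
        lp = rng.normal(size=n)
        t = rng.exponential(np.exp(-lp))
        c = rng.exponential(1, n)
        e = (t <= c).astype(int)
        tobs = np.minimum(t, c)
        tau = np.quantile(tobs, 0.8)
        for fn in (lambda l: pm.harrell_c(l, tobs, e),
                   lambda l: pm.uno_c(l, tobs, e, tau)):
            assert fn(2 * lp + 1) == pytest.approx(fn(lp), abs=1e-12)
        assert pm.gonen_heller_c(lp + 1) == pytest.approx(
            pm.gonen_heller_c(lp), abs=1e-12)

    def test_uno_closer_to_truth_under_heavy_censoring(self):
        """IPCW reduces the censoring bias of tau-restricted concordance.

        The reference value is the tau-restricted concordance computed on
        the same sample before censoring is applied.
        """
        wins = 0
        runs = 50
        for r in range(runs):
            rng = np.random.default_rng(600 + r)
            n = 3000
            lp = rng.normal(size=n)
            t_ev = rng.exponential(np.exp(-lp))
            tau = np.quantile(t_ev, 0.7)
            true_c = pm.harrell_c(lp, t_ev, np.ones(n, int), tau=tau)
            c = rng.exponential(np.quantile(t_ev, 0.35), n)
            tobs = np.minimum(t_ev, c)
            e = (t_ev <= c).astype(int)
            cu = pm.uno_c(lp, tobs, e, tau)
            ch = pm.harrell_c(lp, tobs, e, tau=tau)
            wins += abs(cu - true_c) < abs(ch - true_c)
        assert wins >= 0.7 * runs


class TestGonenHeller:
    def test_all_equal_is_half(self):
        assert pm.gonen_heller_c(np.zeros(5)) == pytest.approx(0.5)

    def test_single_pair_hand_value(self):
        assert pm.gonen_heller_c(np.array([0.0, np.log(2.0)])) == \
            pytest.approx(2 / 3)

    def test_matches_direct_double_sum(self):
        rng = np.random.default_rng(6)
        lp = rng.normal(size=40)
        total = 0.0
        for i in range(40):
            for j in range(i + 1, 40):
                d = abs(lp[i] - lp[j])
                total += 0.5 if d == 0 else 1.0 / (1.0 + np.exp(-d))
        expected = 2 * total / (40 * 39)
        assert pm.gonen_heller_c(lp) == pytest.approx(expected, abs=1e-12)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            pm.gonen_heller_c(np.array([1.0]))


class TestRoystonD:
    def test_constant_lp_zero(self):
        t = np.arange(1, 30, dtype=float)
        D, r2 = pm.royston_d(np.zeros(29), t, np.ones(29, int))
        assert D == 0.0 and r2 == 0.0

    @pytest.mark.parametrize("d,expected", [(2.39, 0.58), (2.12, 0.52)])
    def test_closed_form_r2_pairs(self, d, expected):
        assert round(pm.d_to_r2(d), 2) == expected

    def test_standard_normal_lp_gives_kappa(self):
        """For lp ~ N(0,1) under a correctly specified PH model the D
        statistic estimates kappa = sqrt(8/pi)."""
        ds = []
        for r in range(10):
            rng = np.random.default_rng(700 + r)
            n = 5000
            lp = rng.normal(size=n)
            t = rng.exponential(np.exp(-lp))
            c = rng.exponential(np.quantile(t, 0.9), n)
            e = (t <= c).astype(int)
            D, _ = pm.royston_d(lp, np.minimum(t, c), e)
            ds.append(D)
        assert abs(np.mean(ds) - pm.KAPPA) < 0.1 * pm.KAPPA


class TestExplainedVariationAndRandomness:
    def test_zero_variance(self):
        r2, rho = pm.explained_variation(np.zeros(10))
        assert r2 == 0.0 and rho == 0.0

    def test_closed_form_half_points(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200_00)
        x = (x - x.mean()) / x.std(ddof=1)
        r2, _ = pm.explained_variation(x * np.sqrt(np.pi ** 2 / 6))
        assert r2 == pytest.approx(0.5, abs=1e-12)
        _, rho = pm.explained_variation(x)
        assert rho == pytest.approx(0.5, abs=1e-12)

    def test_rho_k_hand_computed_fixture(self):
        """n = 5, no ties: partial likelihoods by explicit risk sets."""
        lp = np.array([1.0, 0.5, 0.0, -0.5, -1.0])
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 0, 1, 0])
        from cvduncert.model_fitting import fit_cox
        beta = float(fit_cox(pd.DataFrame({"lp": lp}), t, e).params.iloc[0])

        def pl(b):
            z = np.exp(b * lp)
            ll = 0.0
            for i in np.flatnonzero(e == 1):
                ll += b * lp[i] - np.log(z[t >= t[i]].sum())
            return ll

        gamma = 2 * (pl(beta) - pl(0.0))
        expected = 1 - np.exp(-gamma / e.sum())
        assert pm.rho_k(lp, t, e) == pytest.approx(expected, abs=1e-8)

    def test_rho_k_null_near_zero_and_monotone_in_effect(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.normal(size=n)
        vals = []
        for effect in (0.0, 0.5, 1.0):
            t = rng.exponential(np.exp(-effect * x))
            e = np.ones(n, int)
            vals.append(pm.rho_k(x, t, e))
        assert vals[0] < 0.01
        assert vals[0] < vals[1] < vals[2]


class TestIntegratedBrier:
    def test_oracle_predictions_zero_ibs(self):
        t = np.array([1.0, 2.0, 3.0, 8.0, 9.0])
        e = np.array([1, 1, 1, 0, 0])
        tau = 5.0

        def surv(s):
            # perfect foresight: events drop to 0 at their event time
            out = np.ones(5)
            out[(e == 1) & (t <= s)] = 0.0
            return out

        ibs, _ = pm.integrated_brier(surv, t, e, tau)
        assert ibs == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_prediction_quarter_after_last_event(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 1, 1])
        grid_val = []

        def surv(s):
            return np.full(3, 0.5)

        ibs, _ = pm.integrated_brier(surv, t, e, tau=4.0)
        # BS(t) = 0.25 for every t (survivors and events weigh the same)
        assert ibs == pytest.approx(0.25, abs=1e-12)

    def test_reference_model_r2_zero(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(2, 300)
        e = rng.binomial(1, 0.7, 300)
        km = pm.kaplan_meier(t, e)

        def surv(s):
            return np.full(300, float(km(s)))

        _, r2 = pm.integrated_brier(surv, t, e, tau=float(np.quantile(t, 0.7)))
        assert r2 == pytest.approx(0.0, abs=1e-12)


class TestCalibration:
    def test_group_sizes_sum_to_n(self):
        rng = np.random.default_rng(10)
        n = 500
        risks = rng.uniform(0, 0.4, n)
        t = rng.exponential(8, n)
        e = rng.binomial(1, 0.4, n)
        cal = pm.calibration_by_risk_group(risks, t, e, groups=10, horizon=5)
        assert cal["n"].sum() == n
        assert cal["group"].is_monotonic_increasing

    def test_single_group_is_overall_comparison(self):
        rng = np.random.default_rng(11)
        n = 300
        risks = rng.uniform(0, 0.4, n)
        t = rng.exponential(8, n)
        e = rng.binomial(1, 0.4, n)
        cal = pm.calibration_by_risk_group(risks, t, e, groups=1, horizon=5)
        assert len(cal) == 1
        km = pm.kaplan_meier(t, e)
        assert cal["observed"].iloc[0] == pytest.approx(1 - float(km(5.0)))
        assert cal["mean_predicted"].iloc[0] == pytest.approx(risks.mean())

    def test_true_risks_are_well_calibrated(self):
        """Feeding the generator's own 10-year risks yields group
        differences below 1% at n = 50,000."""
        spec = null_spec()
        spec.cfg["loghr"]["age"]["value"] = 0.07
        spec.cfg["loghr"]["sbp"]["value"] = 0.01
        df = sc.generate_cohort(spec, 50_000, seed=12)
        true_risk = sc.true_tenyear_risk(spec, df, seed=12)
        cal = pm.calibration_by_risk_group(
            true_risk, df["followup_time"].to_numpy(),
            df["event"].to_numpy(), groups=10, horizon=10.0)
        assert cal["difference"].abs().max() < 0.01
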