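"""Competing-risks estimators: Aalen-Johansen, RMST, cause-specific Cox."""

import numpy as np
import pandas as pd
import pytest

from appersist.errors import ConvergenceError, RankDeficiencyError
from appersist.simulate import SimulationConfig, simulate_episode_table
from appersist.survival import (build_design_matrix, duration_summary, estimate_cif,
                                fit_cox, fit_discontinuation_model,
                                restricted_mean_duration, subgroup_fit)
from appersist.survival import test_interactions as interaction_wald_test
from helpers import cox_loglik_direct, cox_mle_bruteforce, random_toy_survival


class TestAalenJohansen:
    def test_five_subject_hand_example(self):
        """Times 1..5 with statuses (disc, death, disc, censored, disc):
        increments S(t-)*d/n give CIF_disc steps 0.2, 0.2, 0.4, 0.4, 0.8
        (verified against lifelines and R cmprsk)."""
        cif = estimate_cif([1, 2, 3, 4, 5], [1, 2, 1, 0, 1], tau=5)
        np.testing.assert_allclose(cif.cif_disc[1:], [0.2, 0.2, 0.4, 0.4, 0.8], atol=1e-12)
        np.testing.assert_allclose(cif.cif_death[1:], [0.0, 0.2, 0.2, 0.2, 0.2], atol=1e-12)

    def test_reduces_to_one_minus_kaplan_meier_without_competing_events(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(8)
        t = rng.integers(1, 180, 400)
        s = (rng.random(400) < 0.7).astype(int)
        cif = estimate_cif(t, s)
        km = KaplanMeierFitter().fit(t, s)
        km_at = km.survival_function_at_times(cif.grid).to_numpy()
        np.testing.assert_allclose(cif.cif_disc, 1.0 - km_at, atol=1e-12)

    def test_matches_lifelines_on_data_without_cross_cause_ties(self):
        from lifelines import AalenJohansenFitter
        rng = np.random.default_rng(12)
        t = rng.choice(np.arange(1, 170), size=80, replace=False)
        s = rng.choice([0, 1, 2], size=80, p=[0.3, 0.5, 0.2])
        cif = estimate_cif(t, s)
        aj = AalenJohansenFitter(calculate_variance=False).fit(
            pd.Series(t), pd.Series(s), event_of_interest=1)
        theirs = aj.cumulative_density_.iloc[:, 0]
        for day, val in zip(theirs.index.astype(int), theirs.to_numpy()):
            if day >= 1:
                assert cif.cif_disc[day] == pytest.approx(val, abs=1e-10)

    def test_additivity_and_monotonicity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 300))
            t = rng.integers(1, 181, n)
            s = rng.choice([0, 1, 2], size=n)
            cif = estimate_cif(t, s)
            np.testing.assert_allclose(cif.cif_disc + cif.cif_death + cif.surv,
                                       1.0, atol=1e-10)
            assert (np.diff(cif.cif_disc) >= -1e-12).all()
            assert (np.diff(cif.surv) <= 1e-12).all()
            assert cif.cif_disc.min() >= 0 and cif.cif_disc.max() <= 1

    def test_all_censored_gives_zero_incidence(self):
        cif = estimate_cif([180] * 10, [0] * 10)
        assert cif.cif_disc[-1] == 0.0 and cif.surv[-1] == 1.0

    def test_empty_stratum_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_cif([], [])

    def test_variance_tracks_binomial_in_the_simple_case(self):
        # no censoring, no competing risk: CIF(t) is a sample proportion
        rng = np.random.default_rng(21)
        t = rng.integers(1, 150, 500)
        s = np.ones(500, int)
        cif = estimate_cif(t, s, compute_variance=True)
        p = cif.cif_disc[90]
        assert cif.var_disc[90] == pytest.approx(p * (1 - p) / 500, rel=0.05)
        lo, hi = cif.band()
        assert ((lo <= cif.cif_disc) & (cif.cif_disc <= hi)).all()


class TestRestrictedMeanDuration:
    def test_full_survival_gives_tau(self):
        cif = estimate_cif([180] * 5, [0] * 5)
        assert restricted_mean_duration(cif, 180) == 180.0

    def test_everyone_discontinuing_at_day_90_gives_90(self):
        cif = estimate_cif([90] * 8, [1] * 8)
        assert restricted_mean_duration(cif, 180) == pytest.approx(90.0)

    def test_equals_sample_mean_without_censoring_or_competing_deaths(self):
        rng = np.random.default_rng(10)
        t = rng.integers(1, 181, 300)
        cif = estimate_cif(t, np.ones(300, int))
        assert restricted_mean_duration(cif, 180) == pytest.approx(
            np.minimum(t, 180).mean(), abs=1e-9)

    def test_invalid_tau_rejected(self):
        cif = estimate_cif([5], [1], tau=10)
        with pytest.raises(ValueError):
            restricted_mean_duration(cif, 0)
        with pytest.raises(ValueError):
            restricted_mean_duration(cif, 500)

    def test_duration_summary_by_period_and_estimand_variants(self):
        cfg = SimulationConfig(seed=5, n_residents=4000, n_facilities=80)
        tab = simulate_episode_table(cfg)
        on_trt = duration_summary(tab)
        net = duration_summary(tab, estimand="net_of_discontinuation")
        assert set(on_trt.period) == {"pre_partnership", "post_partnership", "post_five_star"}
        merged = on_trt.merge(net, on="period", suffixes=("_on", "_net"))
        # ignoring death as an exit can only lengthen apparent time on drug
        assert (merged.mean_on_treatment_days_net >= merged.mean_on_treatment_days_on).all()
        assert on_trt.mean_on_treatment_days.between(0, 180).all()


class TestCoxFit:
    def test_null_case_two_identical_groups(self):
        rng = np.random.default_rng(42)
        n = 2000
        t = rng.geometric(0.01, n).clip(max=180)
        e = (t < 180).astype(int)
        x = (np.arange(n) % 2).astype(float)
        fit = fit_cox(t, e, x[:, None], ["group"])
        assert abs(fit.coef[0]) < 3 * fit.se[0]
        assert fit.hr[0] == pytest.approx(1.0, abs=0.2)

    def test_six_subject_example_matches_direct_maximization(self):
        times = [2, 5, 8, 11, 15, 21]
        events = [1, 1, 0, 1, 1, 0]
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])[:, None]
        fit = fit_cox(times, events, x, ["z"])
        oracle = cox_mle_bruteforce(times, events, x)
        assert fit.coef[0] == pytest.approx(oracle[0], abs=1e-6)
        assert fit.loglik == pytest.approx(
            cox_loglik_direct(fit.coef, np.array(times), np.array(events), x), abs=1e-9)

    @pytest.mark.parametrize("p", [1, 2])
    def test_matches_bruteforce_on_random_toy_datasets(self, p):
        rng = np.random.default_rng(100 + p)
        for _ in range(10):
            t, e, X = random_toy_survival(rng, int(rng.integers(4, 9)), p)
            try:
                fit = fit_cox(t, e, X, tie_method="breslow")
            except ConvergenceError:
                continue  # separated toy sets are legitimately rejected
            oracle = cox_mle_bruteforce(t, e, X)
            np.testing.assert_allclose(fit.coef, oracle, atol=1e-6)

    def test_wald_quantities_are_consistent(self):
        cfg = SimulationConfig(seed=2, n_residents=3000, n_facilities=50)
        tab = simulate_episode_table(cfg)
        fit = fit_discontinuation_model(tab, ["period", "anxiety", "bipolar"])
        np.testing.assert_allclose(fit.hr, np.exp(fit.coef))
        np.testing.assert_allclose(fit.wald_chi2, (fit.coef / fit.se) ** 2)
        lo, hi = fit.ci()
        np.testing.assert_allclose(lo, np.exp(fit.coef - 1.96 * fit.se))
        np.testing.assert_allclose(hi, np.exp(fit.coef + 1.96 * fit.se))
        assert fit.converged

    def test_covariate_scaling_invariance(self):
        rng = np.random.default_rng(9)
        n = 800
        age = rng.normal(85, 7, n)
        lam = 0.008 * np.exp(0.02 * (age - 85))
        t = np.minimum(rng.geometric(lam), 180)
        e = (t < 180).astype(int)
        fit1 = fit_cox(t, e, age[:, None], ["age"])
        fit2 = fit_cox(t, e, (age / 10.0)[:, None], ["age_decades"])
        assert fit2.coef[0] == pytest.approx(10 * fit1.coef[0], abs=1e-8 * abs(fit2.coef[0]) + 1e-8)
        assert fit2.wald_chi2[0] == pytest.approx(fit1.wald_chi2[0], rel=1e-8)

    def test_breslow_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(17)
        n = 120
        t = rng.choice(np.arange(1, 4000), size=n, replace=False)  # no ties
        e = (rng.random(n) < 0.6).astype(int)
        X = rng.normal(size=(n, 2))
        fit = fit_cox(t, e, X, ["a", "b"])
        df = pd.DataFrame({"t": t, "e": e, "a": X[:, 0], "b": X[:, 1]})
        ll = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(fit.coef, ll.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.se, ll.standard_errors_.to_numpy(), atol=1e-5)

    def test_efron_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(18)
        n = 150
        t = rng.integers(1, 25, n)  # heavy ties
        e = (rng.random(n) < 0.6).astype(int)
        X = rng.normal(size=(n, 2))
        fit = fit_cox(t, e, X, ["a", "b"], tie_method="efron")
        df = pd.DataFrame({"t": t, "e": e, "a": X[:, 0], "b": X[:, 1]})
        ll = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(fit.coef, ll.params_.to_numpy(), atol=1e-5)

    def test_separation_is_flagged(self):
        t = np.arange(1, 21)
        e = np.ones(20, int)
        x = (t <= 10).astype(float)  # perfectly orders event times
        with pytest.raises(ConvergenceError, match="monotone|separation"):
            fit_cox(t, e, x[:, None])

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(4)
        t = rng.integers(1, 100, 50)
        e = np.ones(50, int)
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(RankDeficiencyError):
            fit_cox(t, e, X)

    def test_cluster_robust_se_close_to_naive_under_independence(self):
        cfg = SimulationConfig(seed=6, n_residents=4000, n_facilities=60,
                               second_episode_fraction=0.0)
        tab = simulate_episode_table(cfg)
        naive = fit_discontinuation_model(tab, ["period"])
        robust = fit_discontinuation_model(tab, ["period"], cluster_col="person_id")
        np.testing.assert_allclose(robust.coef, naive.coef)
        np.testing.assert_allclose(robust.se, naive.se, rtol=0.15)


class TestDesignMatrix:
    def test_reference_levels_are_omitted(self):
        cfg = SimulationConfig(seed=13, n_residents=1200, n_facilities=30)
        tab = simulate_episode_table(cfg)
        tab["pct_black_cat"] = "low"
        X, names = build_design_matrix(tab, ["period", "anxiety"])
        assert names == ["period:post_partnership", "period:post_five_star", "anxiety"]
        assert set(np.unique(X)) <= {0.0, 1.0}

    def test_unknown_level_rejected(self):
        df = pd.DataFrame({"period": ["sometime"], "time": [5]})
        with pytest.raises(ValueError, match="unknown levels"):
            build_design_matrix(df, ["period"])


class TestInteractionsAndSubgroups:
    @pytest.fixture(scope="class")
    def table(self):
        cfg = SimulationConfig(seed=23, n_residents=6000, n_facilities=100)
        return simulate_episode_table(cfg)

    def test_constant_characteristic_is_rejected(self, table):
        tab = table.copy()
        tab["ownership"] = "for_profit"
        with pytest.raises(RankDeficiencyError):
            interaction_wald_test(tab, ["period", "anxiety"], "ownership")

    def test_strong_interaction_is_detected(self):
        cfg = SimulationConfig(seed=30, n_residents=12000, n_facilities=150,
                               covariate_effects={},
                               period_interaction={"bipolar": (np.exp(0.5), np.exp(0.5))})
        tab = simulate_episode_table(cfg)
        res = interaction_wald_test(tab, ["period"], "bipolar")
        assert res.joint_p < 0.05
        assert res.joint_df == 2

    def test_null_interaction_p_value_is_not_degenerate(self, table):
        tab = table.copy()
        tab["ownership"] = np.where(tab["nonprofit"] == 1,
                                    "nonprofit_or_government", "for_profit")
        res = interaction_wald_test(tab, ["period", "anxiety", "bipolar"], "ownership")
        assert 0.0 <= res.joint_p <= 1.0
        assert len(res.term_p) == res.joint_df

    def test_subgroup_fits_partition_the_cohort(self, table):
        fits = subgroup_fit(table, "bipolar", ["period", "anxiety", "bipolar"])
        assert fits[True].n + fits[False].n == len(table)
        assert "bipolar" not in fits[True].names

    def test_empty_subgroup_is_an_error(self, table):
        with pytest.raises(ValueError, match="empty"):
            subgroup_fit(table.assign(nobody=0), "nobody", ["period"])

    def test_subgroup_stratum_equals_direct_fit_on_that_stratum(self, table):
        sub = table[table["bipolar"] == 1]
        direct = fit_discontinuation_model(sub, ["period", "anxiety"])
        fits = subgroup_fit(table, "bipolar", ["period", "anxiety", "bipolar"])
        np.testing.assert_allclose(fits[True].coef, direct.coef, atol=1e-10)
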