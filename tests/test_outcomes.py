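"""Survival, stratification, concordance, and exact-test operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.statistics import logrank_test as ll_logrank

from inflamark import pipeline as pl
from inflamark.config import AnalysisConfig
from inflamark.outcomes import (SeparationError, assay_concordance,
                                cox_fit, cumulative_marker_analysis,
                                fisher_2x2, km_estimate, logistic_orr,
                                logrank_statistic, logrank_test,
                                median_dichotomise, survival_mpt)
from inflamark.simulate import SimulationConfig, generate_cohort


class TestKaplanMeier:
    def test_single_death_among_four(self):
        curves = km_estimate([10, 20, 30, 40], [True, False, False, False])
        c = curves["all"]
        assert c.survival[np.searchsorted(c.times, 10)] == pytest.approx(0.75)

    def test_all_censored_stays_at_one(self):
        c = km_estimate([5, 6, 7], [False] * 3)["all"]
        assert np.allclose(c.survival, 1.0)

    def test_hand_product_limit_table(self):
        c = km_estimate([5, 8, 12, 16], [True, True, False, True])["all"]
        surv = dict(zip(c.times, c.survival))
        assert surv[5] == pytest.approx(0.75)
        assert surv[8] == pytest.approx(0.50)
        assert surv[12] == pytest.approx(0.50)
        assert surv[16] == pytest.approx(0.0)

    def test_no_censoring_matches_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50)
        c = km_estimate(t, np.ones(50, bool))["all"]
        for ti, si in zip(c.times, c.survival):
            assert si == pytest.approx((t > ti).mean(), abs=1e-12)


class TestLogrank:
    def test_duplicated_patients_in_both_groups(self):
        t = [3.0, 5.0, 8.0, 9.0]
        e = [True, True, False, True]
        times = np.r_[t, t]
        events = np.r_[e, e]
        group = np.r_[np.zeros(4, bool), np.ones(4, bool)]
        res = logrank_test(times, events, group)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_lifelines_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = 60
            g = rng.random(n) < 0.5
            t = rng.exponential(10 + 5 * g)
            e = rng.random(n) < 0.8
            if not (g.any() and (~g).any() and e.any()):
                continue
            mine = logrank_test(t, e, g)
            ref = ll_logrank(t[g], t[~g], e[g], e[~g])
            assert mine["statistic"] == pytest.approx(
                ref.test_statistic, rel=1e-6)

    def test_no_events_warns_p_one(self):
        with pytest.warns(UserWarning):
            res = logrank_test([1.0, 2.0], [False, False], [True, False])
        assert res["p"] == 1.0

    def test_oe_hazard_ratio_recovery(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            n = 500
            g = np.r_[np.zeros(n, bool), np.ones(n, bool)]
            lam = 0.01 * np.exp(np.log(2.0) * g)
            t = rng.exponential(1 / lam)
            res = logrank_test(t, np.ones(2 * n, bool), g)
            hits += 1.7 <= res["hr"] <= 2.3
        assert hits / 20 >= 0.9


class TestSurvivalMPT:
    def test_single_protein_matches_analytic_logrank(self):
        """Permutation p for one protein agrees with the chi-square log-rank
        p within 0.03 at the study's sample size."""
        rng = np.random.default_rng(3)
        diffs = []
        for seed in range(8):
            sc = generate_cohort(SimulationConfig(rng_seed=900 + seed))
            vals = pl.baseline_by_patient(sc, sc.baseline)[["HGF"]]
            res = survival_mpt(vals, sc.cohort, "OS", n_perm=2000, seed=seed)
            df = sc.cohort.set_index("patient_id")
            flags = median_dichotomise(vals, ["HGF"])["HGF"]
            ana = logrank_test(df.loc[flags.index, "os_time"],
                               df.loc[flags.index, "os_event"],
                               flags.to_numpy())
            diffs.append(abs(res.loc["HGF", "fwer_p"] - ana["p"]))
        assert max(diffs) < 0.03

    def test_injected_hazard_marker_attains_minimum_p(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            sc = generate_cohort(SimulationConfig(rng_seed=950 + seed))
            vals = pl.baseline_by_patient(sc, sc.baseline)[["IL6", "HGF", "MCP2"]]
            res = survival_mpt(vals, sc.cohort, "OS", n_perm=300, seed=seed)
            hits += res["fwer_p"].idxmin() == "IL6"
        assert hits / n_seeds >= 0.8


class TestCox:
    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(4)
        covered = 0
        n_sims = 20
        for _ in range(n_sims):
            t = rng.exponential(10, 400)
            e = np.ones(400, bool)
            x = pd.DataFrame({"x": rng.normal(0, 1, 400)})
            (res,) = cox_fit(t, e, x)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered / n_sims >= 0.85

    def test_two_group_hr_recovery(self):
        rng = np.random.default_rng(5)
        n = 1000
        g = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.01 * np.exp(np.log(2) * g)))
        (res,) = cox_fit(t, np.ones(n, bool), pd.DataFrame({"g": g}))
        se = np.sqrt(4 / n)
        assert abs(np.log(res.hazard_ratio) - np.log(2)) < 3 * se

    def test_time_varying_effect_flagged_by_ph_check(self):
        rng = np.random.default_rng(6)
        hits = 0
        n_seeds = 10
        for _ in range(n_seeds):
            n = 300
            g = (rng.random(n) < 0.5).astype(float)
            # effect reverses over time: early hazard doubled, late halved
            t1 = rng.exponential(1 / (0.02 * np.exp(np.log(3) * g)), n)
            t = np.where(t1 < 40, t1, 40 + rng.exponential(
                1 / (0.02 * np.exp(-np.log(3) * g)), n))
            (res,) = cox_fit(t, np.ones(n, bool), pd.DataFrame({"g": g}))
            hits += res.ph_global_chi2_p <= 0.05
        assert hits / n_seeds >= 0.8

    def test_ph_p_uniform_under_proportional_hazards(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(60):
            n = 150
            x = rng.normal(0, 1, n)
            t = rng.exponential(1 / (0.02 * np.exp(0.3 * x)))
            (res,) = cox_fit(t, np.ones(n, bool), pd.DataFrame({"x": x}))
            ps.append(res.ph_global_chi2_p)
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1.0, 2.0], [True, True], pd.DataFrame({"c": [1.0, 1.0]}))


class TestLogisticORR:
    def test_null_covariate_ci_covers_one(self):
        # percentile-bootstrap coverage approaches nominal with n; at small
        # n (~80) logistic coefficients are heavy-tailed and coverage dips
        rng = np.random.default_rng(8)
        covered = 0
        n_sims = 30
        for s in range(n_sims):
            y = rng.random(250) < 0.5
            x = pd.DataFrame({"x": rng.normal(0, 1, 250)})
            res = logistic_orr(y, x, n_bootstrap=199, seed=s)
            covered += res.loc["x", "ci_low"] <= 1.0 <= res.loc["x", "ci_high"]
        assert covered / n_sims >= 0.85

    def test_recovery_at_reported_effect_scale(self):
        """Mean estimated OR within +-0.1 of truth for log-OR -0.28/unit
        (OR 0.76) at n = 81."""
        rng = np.random.default_rng(9)
        from scipy.special import expit
        ors = []
        for _ in range(60):
            x = rng.normal(2, 1.5, 81)
            y = rng.random(81) < expit(0.6 - 0.28 * x)
            if y.all() or not y.any():
                continue
            res = logistic_orr(y, pd.DataFrame({"x": x}), n_bootstrap=10, seed=0)
            ors.append(res.loc["x", "odds_ratio"])
        assert abs(np.mean(ors) - 0.76) < 0.1

    def test_degenerate_single_bootstrap(self):
        rng = np.random.default_rng(10)
        y = rng.random(40) < 0.5
        x = pd.DataFrame({"x": rng.normal(0, 1, 40)})
        res = logistic_orr(y, x, n_bootstrap=1, seed=1)
        assert res.loc["x", "ci_low"] == pytest.approx(res.loc["x", "ci_high"])

    def test_separation_raises_then_penalised_path_works(self):
        y = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        x = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10) + 5]})
        with pytest.raises(SeparationError):
            logistic_orr(y, x, n_bootstrap=10, seed=0)
        res = logistic_orr(y, x, n_bootstrap=20, seed=0, penalized=True)
        assert res.loc["x", "odds_ratio"] > 1.0


class TestStratification:
    def test_median_split_even_n(self):
        vals = pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0]}, index=list("wxyz"))
        flags = median_dichotomise(vals, ["A"])
        assert list(flags["A"]) == [False, False, True, True]

    def test_value_at_median_not_elevated(self):
        vals = pd.DataFrame({"A": [1.0, 2.0, 3.0]}, index=list("xyz"))
        flags = median_dichotomise(vals, ["A"])
        assert not flags.loc["y", "A"]

    def test_elevated_prevalence_near_half(self, default_cohort):
        absm = pl.baseline_by_patient(default_cohort, default_cohort.absolute_assay)
        flags = median_dichotomise(absm, ["IL6", "HGF", "MCP2"])
        prev = flags.mean()
        assert ((prev - 0.5).abs() < 0.05).all()

    def test_stratum_orr_arithmetic(self):
        # 4 responders of 15 patients in the all-elevated stratum -> 26.7%
        rng = np.random.default_rng(11)
        n = 60
        flags = pd.DataFrame({
            "a": np.r_[np.ones(15, bool), rng.random(45) < 0.5],
            "b": np.r_[np.ones(15, bool), rng.random(45) < 0.5],
            "c": np.r_[np.ones(15, bool), rng.random(45) < 0.5],
        }, index=[f"P{i}" for i in range(n)])
        flags.iloc[15:] &= ~(flags.iloc[15:, 0] & flags.iloc[15:, 1]
                             & flags.iloc[15:, 2]).to_numpy()[:, None]
        y = np.r_[np.zeros(11, bool), np.ones(4, bool),
                  rng.random(45) < 0.6]
        covs = pd.DataFrame({"age": rng.normal(60, 10, n)}, index=flags.index)
        res = cumulative_marker_analysis(flags, y, covs)
        assert res.table.loc[3, "n_patients"] == 15
        assert res.table.loc[3, "orr_pct"] == 26.7

    def test_stratum_sizes_account_for_everyone(self, default_cohort):
        absm = pl.baseline_by_patient(default_cohort, default_cohort.absolute_assay)
        flags = median_dichotomise(absm, ["IL6", "HGF", "MCP2"])
        df = default_cohort.cohort.set_index("patient_id")
        y = df.loc[flags.index, "responder"]
        covs = pd.DataFrame({"age": df.loc[flags.index, "age"]})
        res = cumulative_marker_analysis(flags, y.to_numpy(), covs)
        assert res.table["n_patients"].sum() == len(flags)

    def test_null_additive_or_ci_covers_one(self):
        rng = np.random.default_rng(12)
        covered = 0
        n_sims = 40
        for _ in range(n_sims):
            n = 81
            flags = pd.DataFrame(rng.random((n, 3)) < 0.5,
                                 columns=list("abc"),
                                 index=[f"P{i}" for i in range(n)])
            y = rng.random(n) < 0.5
            covs = pd.DataFrame({"age": rng.normal(60, 10, n)},
                                index=flags.index)
            res = cumulative_marker_analysis(flags, y, covs)
            covered += res.additive_ci[0] <= 1.0 <= res.additive_ci[1]
        assert covered / n_sims >= 0.85

    def test_injected_effects_give_negative_additive_trend(self):
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            sc = generate_cohort(SimulationConfig(rng_seed=600 + seed))
            res = pl.stratify_stage(sc, AnalysisConfig(n_bootstrap=10),
                                    include_marker_models=False)
            hits += res["stratification"].additive_or < 1.0
        assert hits / n_seeds >= 0.9


class TestConcordance:
    def test_monotone_map_gives_perfect_rank_correlation(self):
        rng = np.random.default_rng(13)
        rel = pd.DataFrame({"A": rng.normal(5, 1, 30)},
                           index=[f"P{i}" for i in range(30)])
        absm = 2.0 ** rel
        res = assay_concordance(rel, absm, ["A"])
        assert res.loc["A", "rho"] == pytest.approx(1.0)

    def test_independent_noise_has_low_correlation(self):
        rng = np.random.default_rng(14)
        ok = 0
        for _ in range(20):
            rel = pd.DataFrame({"A": rng.normal(5, 1, 80)},
                               index=[f"P{i}" for i in range(80)])
            absm = pd.DataFrame({"A": rng.normal(5, 1, 80)}, index=rel.index)
            res = assay_concordance(rel, absm, ["A"])
            ok += abs(res.loc["A", "rho"]) < 0.3
        assert ok / 20 >= 0.95

    def test_generator_calibrated_to_target_range(self):
        """Each marker's estimated rho lands in the configured 0.69-0.89
        range in >= 80% of seeds at n = 81."""
        in_range = np.zeros(3)
        n_seeds = 25
        for seed in range(n_seeds):
            sc = generate_cohort(SimulationConfig(rng_seed=500 + seed))
            rel = pl.baseline_by_patient(sc, sc.baseline)
            absm = pl.baseline_by_patient(sc, sc.absolute_assay)
            res = assay_concordance(rel.loc[absm.index], absm,
                                    ["IL6", "HGF", "MCP2"])
            in_range += ((res["rho"] >= 0.69) & (res["rho"] <= 0.89)).to_numpy()
        assert (in_range / n_seeds >= 0.8).all()

    def test_constant_vector_rejected(self):
        rel = pd.DataFrame({"A": np.ones(12)}, index=[f"P{i}" for i in range(12)])
        absm = pd.DataFrame({"A": np.arange(12.0)}, index=rel.index)
        with pytest.raises(ValueError):
            assay_concordance(rel, absm, ["A"])


class TestFisher:
    def test_diagonal_table_enumeration(self):
        # P(table) under hypergeometric: 2/252
        or_, p = fisher_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252)

    def test_identical_rows(self):
        or_, p = fisher_2x2([[4, 6], [4, 6]])
        assert p == pytest.approx(1.0)
        assert or_ == pytest.approx(1.0, abs=0.05)

    def test_zero_margin(self):
        or_, p = fisher_2x2([[0, 0], [3, 4]])
        assert p == 1.0 and np.isnan(or_)

    @settings(max_examples=40, deadline=None)
    @given(st.tuples(*[st.integers(1, 12)] * 4))
    def test_row_swap_inverts_odds_ratio(self, cells):
        a, b, c, d = cells
        or1, p1 = fisher_2x2([[a, b], [c, d]])
        or2, p2 = fisher_2x2([[c, d], [a, b]])
        assert p1 == pytest.approx(p2, rel=1e-9)
        assert or1 == pytest.approx(1 / or2, rel=1e-6)
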