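"""Window assignment, change scores, paired tests, and max-T MPT."""

import numpy as np
import pandas as pd
import pytest

from inflamark.config import AnalysisConfig
from inflamark.longitudinal import (assign_windows, change_scores,
                                    cross_group_change_correlation,
                                    delta_matrix, mean_fold_change, mpt_fwer,
                                    paired_prepost_test)
from inflamark.matrix import ProteinMatrix
from inflamark.simulate import SimulationConfig, generate_cohort
from oracles import exhaustive_signflip_maxt


def _samples(days, patient="P1"):
    return pd.DataFrame({
        "sample_id": [f"{patient}_s{i}" for i in range(len(days))],
        "patient_id": patient,
        "days_from_treatment_start": days,
    })


class TestWindowAssignment:
    def test_midpoint_hits(self):
        out = assign_windows(_samples([-2, 21, 63]))
        assert list(out["window"]) == ["baseline", "early", "late"]

    def test_closest_to_midpoint_kept(self):
        out = assign_windows(_samples([-1, 18, 25]))
        win = out.set_index("days_from_treatment_start")["window"]
        assert win[18] == "early" and win[25] == "unassigned"

    def test_distance_tie_goes_to_earlier_day(self):
        out = assign_windows(_samples([-1, 19, 23]))
        win = out.set_index("days_from_treatment_start")["window"]
        assert win[19] == "early" and win[23] == "unassigned"

    def test_latest_pretreatment_sample_is_baseline(self):
        out = assign_windows(_samples([-30, -3]))
        win = out.set_index("days_from_treatment_start")["window"]
        assert win[-3] == "baseline" and win[-30] == "unassigned"

    def test_boundary_day_35_goes_late(self):
        out = assign_windows(_samples([0, 35]))
        win = out.set_index("days_from_treatment_start")["window"]
        assert win[35] == "late"


def _paired_matrices(base_vals, fu_vals, proteins=("A",)):
    n = len(base_vals)
    patients = [f"P{i}" for i in range(n)]
    lod = pd.Series(-np.inf, index=list(proteins))
    base = ProteinMatrix(pd.DataFrame(
        base_vals, index=[f"{p}_BL" for p in patients], columns=proteins), lod)
    fu = ProteinMatrix(pd.DataFrame(
        fu_vals, index=[f"{p}_FU" for p in patients], columns=proteins), lod.copy())
    samples = pd.DataFrame({
        "sample_id": [f"{p}_BL" for p in patients] + [f"{p}_FU" for p in patients],
        "patient_id": patients * 2,
        "days_from_treatment_start": [0] * n + [21] * n,
    })
    samples = assign_windows(samples)
    return base, fu, samples


class TestChangeScores:
    def test_no_change_gives_zero_delta_unit_fc(self):
        base, fu, samples = _paired_matrices([[1.0], [2.0]], [[1.0], [2.0]])
        tidy = change_scores(base, fu, samples, "early")
        assert np.allclose(tidy["delta"], 0.0)
        assert np.allclose(tidy["fold_change"], 1.0)

    def test_unit_log2_step_doubles(self):
        base, fu, samples = _paired_matrices([[1.0]], [[2.0]])
        tidy = change_scores(base, fu, samples, "early")
        assert tidy.loc[0, "delta"] == pytest.approx(1.0)
        assert tidy.loc[0, "fold_change"] == pytest.approx(2.0)

    def test_mean_fold_change_convention(self):
        # mean delta 0.5161 -> mean FC 1.43 at two decimals
        assert round(mean_fold_change([0.5161] * 5), 2) == 1.43

    def test_no_paired_patients_warns_and_returns_empty(self):
        base, fu, samples = _paired_matrices([[1.0]], [[2.0]])
        with pytest.warns(UserWarning):
            tidy = change_scores(base, fu, samples, "late")
        assert tidy.empty


class TestPairedWilcoxon:
    def test_all_positive_n10_exact(self):
        stat, p = paired_prepost_test(np.arange(1.0, 11.0))
        assert p == pytest.approx(2 / 1024)

    def test_single_nonzero_delta(self):
        _, p = paired_prepost_test([0.7])
        assert p == 1.0

    def test_all_zero_deltas(self):
        stat, p = paired_prepost_test([0.0, 0.0, 0.0])
        assert (stat, p) == (0.0, 1.0)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = [paired_prepost_test(rng.normal(0, 1, 15))[1] for _ in range(200)]
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01


class TestMPT:
    def test_single_protein_fwer_equals_raw(self):
        rng = np.random.default_rng(1)
        deltas = pd.DataFrame({"A": rng.normal(0.5, 1, 12)},
                              index=[f"P{i}" for i in range(12)])
        res = mpt_fwer(deltas, "sign_flip_paired", n_perm=500, seed=2)
        assert res.loc["A", "fwer_p"] == res.loc["A", "raw_p"]

    def test_signflip_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        deltas = pd.DataFrame(rng.normal(0.8, 1, (5, 2)), columns=["A", "B"],
                              index=[f"P{i}" for i in range(5)])
        res = mpt_fwer(deltas, "sign_flip_paired", n_perm=4000, seed=4)
        exact = exhaustive_signflip_maxt(deltas.to_numpy())
        assert np.all(np.abs(res["fwer_p"].to_numpy() - exact) < 0.02)

    def test_duplicated_protein_adds_no_penalty(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.6, 1, 14)
        single = pd.DataFrame({"A": x}, index=[f"P{i}" for i in range(14)])
        doubled = pd.DataFrame({"A": x, "A2": x},
                               index=[f"P{i}" for i in range(14)])
        r1 = mpt_fwer(single, "sign_flip_paired", n_perm=2000, seed=6)
        r2 = mpt_fwer(doubled, "sign_flip_paired", n_perm=2000, seed=6)
        assert r2.loc["A", "fwer_p"] == r2.loc["A2", "fwer_p"]
        assert abs(r2.loc["A", "fwer_p"] - r1.loc["A", "fwer_p"]) < 0.02

    def test_label_permutation_mode_detects_group_shift(self):
        rng = np.random.default_rng(7)
        labels = np.repeat([True, False], 15)
        vals = pd.DataFrame({
            "shifted": rng.normal(0, 1, 30) + labels * 1.5,
            "null": rng.normal(0, 1, 30),
        }, index=[f"P{i}" for i in range(30)])
        res = mpt_fwer(vals, "response_labels", labels=labels,
                       n_perm=1000, seed=8)
        assert res.loc["shifted", "fwer_p"] < 0.05
        assert res.loc["null", "fwer_p"] > 0.1

    def test_treatment_proteins_dominate_panel(self):
        """The two injected on-treatment proteins (FC 1.43, 2.41) attain the
        two smallest FWER p-values in >= 80% of seeds at ~46 pairs."""
        from inflamark import pipeline as pl
        cfg = AnalysisConfig(n_perm_mpt=300)
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            sc = generate_cohort(SimulationConfig(rng_seed=800 + seed))
            baseline, followups, _ = pl.qc_stage(sc, cfg)
            res = pl.longitudinal_stage(sc, baseline, followups, cfg)
            mpt = res["early"]["prepost_mpt"].sort_values("fwer_p")
            top2 = set(mpt.index[:2])
            hits += top2 == {"TNFRSF9", "CXCL9"}
        assert hits / n_seeds >= 0.8


class TestCrossGroupCorrelation:
    def test_identical_vectors(self):
        v = pd.Series(np.arange(12.0))
        rho, _ = cross_group_change_correlation(v, v)
        assert rho == pytest.approx(1.0)

    def test_negated_vectors(self):
        v = pd.Series(np.arange(12.0))
        rho, _ = cross_group_change_correlation(v, -v)
        assert rho == pytest.approx(-1.0)

    def test_hand_formula(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0] * 3)
        b = pd.Series([2.0, 4.0, 5.0, 9.0] * 3)
        rho, _ = cross_group_change_correlation(a, b)
        # direct formula: cov / (sd_a sd_b)
        expected = np.cov(a, b, ddof=0)[0, 1] / (a.std(ddof=0) * b.std(ddof=0))
        assert rho == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cross_group_change_correlation(
                pd.Series(np.ones(12)), pd.Series(np.arange(12.0)))
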