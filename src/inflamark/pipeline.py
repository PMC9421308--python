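"""End-to-end stage runners tying the analysis modules together.

Each function takes a generated (or loaded) cohort bundle and an
:class:`AnalysisConfig` and returns plain tables/dicts, so the CLI, the
test-suite and reproduction scripts all drive the same code paths.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from inflamark import longitudinal as lg
from inflamark import meta as mt
from inflamark import outcomes as oc
from inflamark import predict as pr
from inflamark import qc as qcmod
from inflamark.config import AnalysisConfig
from inflamark.simulate import MARKER_PROTEINS, SyntheticCohort

log = logging.getLogger("inflamark")


def qc_stage(sc: SyntheticCohort, cfg: AnalysisConfig):
    """Panel-wide QC on baseline and follow-ups pooled (one retained set)."""
    pooled = sc.baseline.concat_samples(sc.followups)
    filtered, report = qcmod.run_qc(
        pooled, cfg.lod_max_below_fraction, cfg.outlier_sd_threshold
    )
    base_ids = set(sc.baseline.sample_ids)
    baseline = filtered.select_samples(
        [s for s in filtered.sample_ids if s in base_ids])
    followups = filtered.select_samples(
        [s for s in filtered.sample_ids if s not in base_ids])
    return baseline, followups, report


def baseline_by_patient(sc: SyntheticCohort, baseline_matrix) -> pd.DataFrame:
    mapping = sc.samples.set_index("sample_id")["patient_id"]
    vals = baseline_matrix.values.copy()
    vals.index = vals.index.map(mapping)
    return vals


def meta_stage(sc: SyntheticCohort, baseline_matrix, cfg: AnalysisConfig):
    vals = baseline_by_patient(sc, baseline_matrix)
    return mt.run_meta(vals, sc.cohort, alpha=cfg.alpha)


def prediction_stage(sc: SyntheticCohort, baseline_matrix, cfg: AnalysisConfig,
                     train_centre: str = "UK", test_centre: str = "NL",
                     markers=MARKER_PROTEINS):
    """Full vs null LASSO models trained on one centre, tested on the other,
    plus the correlation-preserving permutation AUC test."""
    vals = baseline_by_patient(sc, baseline_matrix)
    markers = [m for m in markers if m in vals.columns]
    X, y = pr.build_design(sc.cohort, vals, markers)
    centre = sc.cohort.set_index("patient_id")["centre"]
    tr = centre.loc[X.index] == train_centre
    te = centre.loc[X.index] == test_centre
    X_tr, y_tr = X[tr], y[tr]
    X_te, y_te = X[te], y[te]

    full = pr.fit_lasso_loocv(X_tr, y_tr)
    null = pr.fit_lasso_loocv(X_tr.drop(columns=markers), y_tr)
    auc_full = pr.evaluate_auc(full, X_te, y_te, "full", int(tr.sum()))
    auc_null = pr.evaluate_auc(null, X_te.drop(columns=markers), y_te,
                               "null", int(tr.sum()))
    perm = pr.permutation_auc_contribution(
        full, X_te, y_te, markers, n_perm=cfg.n_perm_auc, seed=cfg.rng_seed)
    return {"full": auc_full, "null": auc_null, "perm": perm,
            "full_model": full, "null_model": null}


def longitudinal_stage(sc: SyntheticCohort, baseline_matrix, followup_matrix,
                       cfg: AnalysisConfig):
    """Change scores per window, pre/post MPT, change-vs-response MPT, and
    the responder/non-responder change correlation."""
    samples = lg.assign_windows(sc.samples, cfg)
    resp = sc.cohort.set_index("patient_id")["responder"]
    out = {}
    for i, window in enumerate(("early", "late")):
        tidy = lg.change_scores(baseline_matrix, followup_matrix, samples, window)
        if tidy.empty:
            continue
        deltas = lg.delta_matrix(tidy)
        prepost = lg.mpt_fwer(deltas, "sign_flip_paired",
                              n_perm=cfg.n_perm_mpt, seed=cfg.rng_seed + i)
        labels = resp.reindex(deltas.index).to_numpy(dtype=bool)
        vs_resp = lg.mpt_fwer(deltas, "response_labels", labels=labels,
                              n_perm=cfg.n_perm_mpt, seed=cfg.rng_seed + 10 + i)
        mean_r = deltas[labels].mean(axis=0)
        mean_nr = deltas[~labels].mean(axis=0)
        rho, p = lg.cross_group_change_correlation(mean_r, mean_nr)
        out[window] = {
            "change_scores": tidy, "deltas": deltas, "prepost_mpt": prepost,
            "response_mpt": vs_resp, "cross_group_rho": rho,
            "cross_group_p": p,
            "mean_fold_change": (2.0 ** deltas.mean(axis=0)).rename("mean_fc"),
        }
    return out


def survival_stage(sc: SyntheticCohort, baseline_matrix, cfg: AnalysisConfig,
                   proteins=MARKER_PROTEINS):
    """Median-split KM/log-rank with MPT over the marker proteins, for both
    endpoints, plus the covariate-adjusted Cox model on the absolute assay."""
    vals = baseline_by_patient(sc, baseline_matrix)
    proteins = [p for p in proteins if p in vals.columns]
    res = {}
    for endpoint in ("OS", "PFS"):
        res[endpoint] = oc.survival_mpt(
            vals[proteins], sc.cohort, endpoint,
            n_perm=cfg.n_perm_mpt, seed=cfg.rng_seed)
    df = sc.cohort.set_index("patient_id")
    primary = proteins[0] if proteins else None
    if primary is not None and sc.absolute_assay.n_proteins:
        abs_vals = baseline_by_patient(sc, sc.absolute_assay)
        common = [p for p in abs_vals.index if p in df.index]
        terms = pd.DataFrame({
            primary: abs_vals.loc[common, primary],
            "age": df.loc[common, "age"],
            "sex_male": (df.loc[common, "sex"] == "male").astype(float),
            "bmi": df.loc[common, "bmi"],
            "stage_code": df.loc[common, "stage_code"],
            "ldh_elevated": df.loc[common, "ldh_elevated"].astype(float),
        })
        res["cox"] = oc.cox_fit(df.loc[common, "os_time"],
                                df.loc[common, "os_event"], terms)
    return res


def stratify_stage(sc: SyntheticCohort, cfg: AnalysisConfig,
                   markers=MARKER_PROTEINS, include_marker_models: bool = True):
    """Median-split stratification on the absolute assay: per-marker
    logistic ORs with bootstrap CIs, elevated-count strata, concordance."""
    abs_vals = baseline_by_patient(sc, sc.absolute_assay)
    df = sc.cohort.set_index("patient_id")
    common = [p for p in abs_vals.index if p in df.index]
    abs_vals = abs_vals.loc[common]
    markers = [m for m in markers if m in abs_vals.columns]
    y = df.loc[common, "responder"].to_numpy(dtype=bool)
    covs = pd.DataFrame({
        "age": df.loc[common, "age"],
        "sex_male": (df.loc[common, "sex"] == "male").astype(float),
        "bmi": df.loc[common, "bmi"],
        "stage_code": df.loc[common, "stage_code"],
    })
    flags = oc.median_dichotomise(abs_vals, markers)
    strat = oc.cumulative_marker_analysis(flags, y, covs, seed=cfg.rng_seed)
    per_marker = {}
    if include_marker_models:
        for m in markers:
            terms = covs.assign(**{m: abs_vals[m]})[[m] + list(covs.columns)]
            try:
                per_marker[m] = oc.logistic_orr(
                    y, terms, n_bootstrap=cfg.n_bootstrap, seed=cfg.rng_seed)
            except oc.SeparationError:
                log.info("marker %s separates response; penalised refit", m)
                per_marker[m] = oc.logistic_orr(
                    y, terms, n_bootstrap=cfg.n_bootstrap,
                    seed=cfg.rng_seed, penalized=True)
    rel = baseline_by_patient(sc, sc.baseline)
    conc = oc.assay_concordance(rel.loc[common], abs_vals, markers)
    return {"stratification": strat, "per_marker_or": per_marker,
            "concordance": conc, "flags": flags}
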