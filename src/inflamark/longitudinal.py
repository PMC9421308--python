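"""Longitudinal change-score analysis with multivariate permutation testing.

Follow-up samples are assigned to an early (2-5 week) or late (5-12 week)
window, keeping per patient the sample closest to the window midpoint (3
and 9 weeks).  Change scores are follow-up minus baseline on the log2
scale, so a positive delta is an on-treatment increase and the mean fold
change is 2^(mean delta).  Per-protein significance uses the two-sided
Wilcoxon signed-rank test; family-wise error across the panel is
controlled with a max-T multivariate permutation test whose exchangeable
operation is either whole-vector sign flipping (paired pre/post) or
responder-label permutation (change vs response), both of which preserve
the inter-protein correlation structure.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from inflamark.config import AnalysisConfig
from inflamark.matrix import ProteinMatrix

log = logging.getLogger("inflamark")

WINDOWS = ("baseline", "early", "late", "unassigned")


def assign_windows(samples: pd.DataFrame, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Derive the window column from days relative to treatment start.

    Baseline = latest sample with day <= 0.  Within each follow-up window
    the sample minimising |day - midpoint| is kept (ties go to the earlier
    day); all other samples are marked unassigned.
    """
    cfg = cfg or AnalysisConfig()
    out = samples.copy()
    out["window"] = "unassigned"
    e0, e1 = cfg.early_window_days
    l0, l1 = cfg.late_window_days
    mid_e, mid_l = cfg.window_midpoints_days
    for _, idx in out.groupby("patient_id").groups.items():
        sub = out.loc[idx]
        day = sub["days_from_treatment_start"]
        pre = sub[day <= 0]
        if len(pre):
            best = pre.loc[pre["days_from_treatment_start"].idxmax()]
            # latest pre-treatment sample; ties broken by first occurrence
            out.loc[best.name, "window"] = "baseline"
        for lo, hi, mid, tag in ((e0, e1, mid_e, "early"), (l0, l1, mid_l, "late")):
            cand = sub[(day >= lo) & (day <= hi)]
            if len(cand):
                dist = (cand["days_from_treatment_start"] - mid).abs()
                # minimal distance; tie -> earlier day
                best_idx = cand.assign(_d=dist).sort_values(
                    ["_d", "days_from_treatment_start"]).index[0]
                out.loc[best_idx, "window"] = tag
    return out


def change_scores(baseline: ProteinMatrix, followup: ProteinMatrix,
                  samples: pd.DataFrame, window: str) -> pd.DataFrame:
    """Per-patient change scores (follow-up minus baseline, log2 units).

    ``samples`` must carry the window assignment.  Only patients with both
    a baseline and a sample in the requested window contribute.  Returns a
    tidy table (patient_id, window, protein_id, baseline_value,
    followup_value, delta, fold_change).
    """
    s = samples.set_index("sample_id")
    base_map = {s.loc[sid, "patient_id"]: sid
                for sid in baseline.sample_ids
                if sid in s.index and s.loc[sid, "window"] == "baseline"}
    fu_map = {s.loc[sid, "patient_id"]: sid
              for sid in followup.sample_ids
              if sid in s.index and s.loc[sid, "window"] == window}
    patients = sorted(set(base_map) & set(fu_map))
    if not patients:
        warnings.warn(f"no paired patients for window {window!r}")
        return pd.DataFrame(columns=[
            "patient_id", "window", "protein_id",
            "baseline_value", "followup_value", "delta", "fold_change"])
    b = baseline.values.loc[[base_map[p] for p in patients]]
    f = followup.values.loc[[fu_map[p] for p in patients]]
    b.index = f.index = patients
    common = [p for p in baseline.protein_ids if p in set(followup.protein_ids)]
    delta = f[common] - b[common]
    tidy = delta.stack(future_stack=True).rename("delta").reset_index()
    tidy.columns = ["patient_id", "protein_id", "delta"]
    tidy["window"] = window
    tidy["baseline_value"] = b[common].stack(future_stack=True).to_numpy()
    tidy["followup_value"] = f[common].stack(future_stack=True).to_numpy()
    tidy["fold_change"] = 2.0 ** tidy["delta"]
    return tidy[["patient_id", "window", "protein_id",
                 "baseline_value", "followup_value", "delta", "fold_change"]]


def delta_matrix(tidy: pd.DataFrame) -> pd.DataFrame:
    """Wide patients x proteins delta frame from a tidy change-score table."""
    return tidy.pivot(index="patient_id", columns="protein_id", values="delta")


def mean_fold_change(deltas) -> float:
    """Mean fold change reported as 2^(mean delta)."""
    return float(2.0 ** np.nanmean(np.asarray(deltas, dtype=float)))


def paired_prepost_test(deltas) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on one protein's change scores.

    Zeros are dropped (classic convention); the exact distribution is used
    for n <= 25 and the normal approximation with continuity correction
    above.  All-zero input gives statistic 0, p = 1.
    """
    d = np.asarray(pd.Series(deltas).dropna(), dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                         method=method, correction=True)
    return float(res.statistic), float(res.pvalue)


def _signed_rank_setup(deltas: pd.DataFrame):
    """Per-protein signed ranks (0 where missing/zero) and null SDs."""
    vals = deltas.to_numpy(dtype=float)
    n_pat, n_prot = vals.shape
    signed = np.zeros_like(vals)
    sd = np.empty(n_prot)
    for j in range(n_prot):
        d = vals[:, j]
        ok = np.isfinite(d) & (d != 0)
        n = int(ok.sum())
        if n == 0:
            sd[j] = np.inf
            continue
        r = rankdata(np.abs(d[ok]))
        signed[ok, j] = r * np.sign(d[ok])
        sd[j] = np.sqrt(n * (n + 1) * (2 * n + 1) / 6.0)  # SD of sum of signed ranks
    return signed, sd


def _ranksum_setup(values: pd.DataFrame):
    """Per-protein mid-ranks (0 where missing) and validity mask."""
    vals = values.to_numpy(dtype=float)
    n_pat, n_prot = vals.shape
    ranks = np.zeros_like(vals)
    valid = np.zeros_like(vals, dtype=bool)
    for j in range(n_prot):
        ok = np.isfinite(vals[:, j])
        ranks[ok, j] = rankdata(vals[ok, j])
        valid[:, j] = ok
    return ranks, valid


def mpt_fwer(values: pd.DataFrame, grouping: str, n_perm: int = 5000,
             seed: int = 0, labels=None) -> pd.DataFrame:
    """Max-T multivariate permutation test across a protein panel.

    Parameters
    ----------
    values : DataFrame
        Patients x proteins.  For ``grouping="sign_flip_paired"`` these are
        change scores; for ``grouping="response_labels"`` any per-patient
        values compared between responders and non-responders.
    grouping : str
        Exchangeability operation: ``"sign_flip_paired"`` flips the sign of
        each patient's whole delta vector; ``"response_labels"`` permutes
        the responder labels across patients.  Both keep the protein
        columns intact, so the max statistic adapts to their correlation.
    labels : boolean array, required for ``"response_labels"``.

    Returns
    -------
    DataFrame indexed by protein with the standardised observed statistic,
    its own-permutation raw p, and the max-T FWER-adjusted empirical p,
    all under the add-one convention.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; empirical p will be coarse")
    rng = np.random.default_rng(seed)
    proteins = list(values.columns)
    n_pat = values.shape[0]

    if grouping == "sign_flip_paired":
        signed, sd = _signed_rank_setup(values)
        obs = signed.sum(axis=0) / sd
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n_pat))
        perm_stats = (flips @ signed) / sd
    elif grouping == "response_labels":
        if labels is None:
            raise ValueError("response_labels grouping needs labels")
        lab = np.asarray(labels, dtype=bool)
        ranks, valid = _ranksum_setup(values)
        m = valid.sum(axis=0).astype(float)  # per-protein sample size

        def _stats_for(lab_mat):
            # lab_mat: (B, n_pat) boolean; rank-sum of group-1 per protein
            w = lab_mat.astype(float) @ ranks
            n1 = lab_mat.astype(float) @ valid.astype(float)
            mu = n1 * (m + 1) / 2.0
            var = n1 * (m - n1) * (m + 1) / 12.0
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (w - mu) / np.sqrt(var)
            return np.where(np.isfinite(z), z, 0.0)

        obs = _stats_for(lab[None, :])[0]
        perms = np.stack([rng.permutation(lab) for _ in range(n_perm)])
        perm_stats = _stats_for(perms)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    abs_obs = np.abs(obs)
    abs_perm = np.abs(perm_stats)
    max_perm = abs_perm.max(axis=1)
    raw_p = (1 + (abs_perm >= abs_obs[None, :]).sum(axis=0)) / (n_perm + 1)
    fwer_p = (1 + (max_perm[:, None] >= abs_obs[None, :]).sum(axis=0)) / (n_perm + 1)
    return pd.DataFrame(
        {"statistic": obs, "raw_p": raw_p, "fwer_p": fwer_p, "n_perm": n_perm},
        index=pd.Index(proteins, name="protein_id"),
    )


def cross_group_change_correlation(change_means_resp: pd.Series,
                                   change_means_nonresp: pd.Series) -> tuple[float, float]:
    """Pearson correlation across proteins of mean change scores in
    responders vs non-responders, with its two-sided p-value."""
    a, b = change_means_resp.align(change_means_nonresp, join="inner")
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise ValueError("zero variance in a change-score vector")
    if len(a) < 10:
        warnings.warn(f"only {len(a)} proteins in the correlation")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
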