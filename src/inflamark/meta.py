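"""Two-centre responder/non-responder effects and random-effects meta-analysis.

Per centre, each protein's effect is the mean log2 abundance difference
(non-responders minus responders, so positive = higher in non-responders)
with a Welch (unpooled) standard error.  Centre effects are pooled with a
random-effects model y_i ~ N(mu, se_i^2 + tau^2) whose between-centre
variance tau^2 is estimated by restricted maximum likelihood (Fisher
scoring, floored at zero), with z-based confidence intervals and Cochran's
Q for heterogeneity.  Multiplicity is controlled by dividing alpha by the
effective number of independent tests, estimated from the eigenvalues of
the protein correlation matrix (Li & Ji rule).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from inflamark.matrix import ProteinMatrix

log = logging.getLogger("inflamark")


@dataclass
class CentreEffect:
    protein_id: str
    centre: str
    n_resp: int
    n_nonresp: int
    log2_fc: float
    se: float
    sd_resp: float
    sd_nonresp: float


@dataclass
class MetaResult:
    protein_id: str
    pooled_effect: float
    ci_low: float
    ci_high: float
    p_value: float
    tau2: float
    q_stat: float
    q_df: int
    q_p: float
    centre_weights: list = field(default_factory=list)


@dataclass
class MultiplicityResult:
    n_tests: int
    m_eff: float
    threshold: float
    eigenvalues: np.ndarray


class ConvergenceError(RuntimeError):
    """REML iteration failed to converge; carries the tau^2 trace."""

    def __init__(self, trace):
        super().__init__(f"REML did not converge; tau2 trace: {trace}")
        self.trace = trace


def centre_effects(values_by_patient: pd.DataFrame, cohort: pd.DataFrame,
                   centre: str) -> list[CentreEffect]:
    """Responder/non-responder mean differences for one centre.

    ``values_by_patient``: baseline matrix values indexed by patient id.
    Proteins need >= 2 unmasked values and a positive SD in both groups;
    otherwise the protein is excluded for this centre with a warning.
    """
    sub = cohort[cohort["centre"] == centre]
    resp_ids = [p for p in sub.loc[sub["responder"], "patient_id"]
                if p in values_by_patient.index]
    nonresp_ids = [p for p in sub.loc[~sub["responder"], "patient_id"]
                   if p in values_by_patient.index]
    resp = values_by_patient.loc[resp_ids]
    nonresp = values_by_patient.loc[nonresp_ids]
    out = []
    for pid in values_by_patient.columns:
        r = resp[pid].dropna().to_numpy()
        nr = nonresp[pid].dropna().to_numpy()
        if len(r) < 2 or len(nr) < 2:
            log.warning("protein %s excluded in centre %s: too few values", pid, centre)
            continue
        sd_r, sd_nr = r.std(ddof=1), nr.std(ddof=1)
        if sd_r == 0 and sd_nr == 0:
            log.warning("protein %s excluded in centre %s: zero SD", pid, centre)
            continue
        se = math.sqrt(sd_r**2 / len(r) + sd_nr**2 / len(nr))
        out.append(CentreEffect(
            protein_id=pid, centre=centre, n_resp=len(r), n_nonresp=len(nr),
            log2_fc=float(nr.mean() - r.mean()), se=float(se),
            sd_resp=float(sd_r), sd_nonresp=float(sd_nr),
        ))
    return out


def _restricted_loglik(tau2, y, v):
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return -0.5 * (np.sum(np.log(v + tau2)) + math.log(np.sum(w))
                   + np.sum(w * (y - mu) ** 2))


def reml_meta(y, se, protein_id: str = "", max_iter: int = 100,
              tol: float = 1e-8, alpha: float = 0.05) -> MetaResult:
    """Random-effects pooling of per-centre effects by REML.

    Fisher-scoring iteration on tau^2 with the estimate floored at zero;
    pooled effect is the inverse-variance weighted mean at the converged
    tau^2, with z-based CI and p-value.  Cochran's Q uses fixed-effect
    weights.  Raises :class:`ConvergenceError` with the iteration trace if
    the cap is reached.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(se, dtype=float) ** 2
    if len(y) < 2:
        raise ValueError("need at least two centres")
    if np.any(v <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("effects must be finite with positive SEs")

    # DerSimonian-Laird start
    w_fe = 1.0 / v
    mu_fe = np.sum(w_fe * y) / np.sum(w_fe)
    q = float(np.sum(w_fe * (y - mu_fe) ** 2))
    k = len(y)
    c = np.sum(w_fe) - np.sum(w_fe**2) / np.sum(w_fe)
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0

    trace = [tau2]
    converged = False
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        sw, sw2, sw3 = np.sum(w), np.sum(w**2), np.sum(w**3)
        mu = np.sum(w * y) / sw
        score = -0.5 * (sw - sw2 / sw) + 0.5 * np.sum(w**2 * (y - mu) ** 2)
        info = 0.5 * (sw2 - 2 * sw3 / sw + (sw2 / sw) ** 2)
        step = score / info if info > 0 else 0.0
        new = max(0.0, tau2 + step)
        trace.append(new)
        if abs(new - tau2) < tol:
            tau2 = new
            converged = True
            break
        tau2 = new
    if not converged:
        raise ConvergenceError(trace)

    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    se_pooled = math.sqrt(1.0 / np.sum(w))
    z = stats.norm.ppf(1 - alpha / 2)
    p = float(2 * stats.norm.sf(abs(pooled / se_pooled)))
    return MetaResult(
        protein_id=protein_id, pooled_effect=pooled,
        ci_low=pooled - z * se_pooled, ci_high=pooled + z * se_pooled,
        p_value=p, tau2=float(tau2), q_stat=q, q_df=k - 1,
        q_p=float(stats.chi2.sf(q, k - 1)),
        centre_weights=list(w / np.sum(w)),
    )


def li_meff(corr: pd.DataFrame | np.ndarray, alpha: float = 0.05) -> MultiplicityResult:
    """Effective number of independent tests from correlation eigenvalues.

    M_eff = sum_i [ I(|lambda_i| >= 1) + (|lambda_i| - floor(|lambda_i|)) ],
    the Li & Ji decomposition of each eigenvalue into an integral "whole
    test" part and a fractional part.  The significance threshold is
    alpha / round(M_eff).
    """
    c = pd.DataFrame(corr)
    if not np.all(np.isfinite(c.to_numpy())):
        bad = np.argwhere(~np.isfinite(c.to_numpy()))[0]
        raise ValueError(
            f"non-finite correlation between {c.index[bad[0]]!r} and "
            f"{c.columns[bad[1]]!r}"
        )
    arr = c.to_numpy()
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.abs(np.linalg.eigvalsh(arr))
    meff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    n = arr.shape[0]
    meff = min(max(meff, 1.0), float(n))
    return MultiplicityResult(
        n_tests=n, m_eff=meff,
        threshold=significance_threshold(alpha, meff),
        eigenvalues=lam,
    )


def significance_threshold(alpha: float, m_eff: float) -> float:
    """alpha divided by the effective test count rounded to the nearest
    integer (a threshold like 0.05/42 implies an integer count)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    thr = alpha / round(m_eff)
    log.info("significance threshold: %.3g (alpha=%g, m_eff=%g)", thr, alpha, m_eff)
    return thr


def pairwise_correlation(values_by_patient: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation on pairwise-complete baseline values."""
    return values_by_patient.corr(method="pearson")


def run_meta(values_by_patient: pd.DataFrame, cohort: pd.DataFrame,
             alpha: float = 0.05) -> tuple[pd.DataFrame, MultiplicityResult]:
    """Per-protein two-centre meta-analysis plus multiplicity control.

    Returns a table with one row per protein (per-centre effects, pooled
    estimate, CI, p, tau^2, Q) and the Li M_eff result computed on the
    pairwise-complete correlation of the same baseline values.
    """
    centres = list(dict.fromkeys(cohort["centre"]))
    per_centre = {c: {e.protein_id: e for e in
                      centre_effects(values_by_patient, cohort, c)}
                  for c in centres}
    rows = []
    for pid in values_by_patient.columns:
        effs = [per_centre[c][pid] for c in centres if pid in per_centre[c]]
        if len(effs) < 2:
            log.warning("protein %s skipped in meta-analysis: <2 centres", pid)
            continue
        res = reml_meta([e.log2_fc for e in effs], [e.se for e in effs],
                        protein_id=pid, alpha=alpha)
        row = {
            "protein_id": pid, "pooled_effect": res.pooled_effect,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_value": res.p_value, "tau2": res.tau2,
            "q_stat": res.q_stat, "q_df": res.q_df, "q_p": res.q_p,
        }
        for e in effs:
            row[f"log2_fc_{e.centre}"] = e.log2_fc
            row[f"se_{e.centre}"] = e.se
        rows.append(row)
    table = pd.DataFrame(rows).set_index("protein_id")
    mult = li_meff(pairwise_correlation(values_by_patient), alpha=alpha)
    table["significant"] = table["p_value"] < mult.threshold
    return table, mult
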