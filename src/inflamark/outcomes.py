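"""Survival, stratification, and dual-assay concordance analyses.

Kaplan-Meier curves and log-rank tests on median-dichotomised protein
levels, with a max-T multivariate permutation test (outcome pairs shuffled
across patients, protein matrix fixed) for family-wise control across
proteins; Cox proportional-hazards regression with a global Schoenfeld
chi-square check; covariate-adjusted logistic response models with
percentile-bootstrap confidence intervals; median-split stratification and
the cumulative elevated-marker analysis; and Spearman concordance between
the relative (NPX-like) and absolute (pg/mL) assays.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or

log = logging.getLogger("inflamark")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    group_label: str
    times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    censored_times: np.ndarray


@dataclass
class CoxResult:
    term: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    ph_global_chi2_p: float
    ph_ok: bool


@dataclass
class StratificationResult:
    table: pd.DataFrame           # per-stratum n, responders, ORR%
    fisher_p_extremes: float
    fisher_or_extremes: float
    additive_or: float
    additive_ci: tuple
    additive_p: float


def km_estimate(times, events, groups=None) -> dict[str, SurvivalCurve]:
    """Product-limit survival curves, one per group label."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times <= 0):
        raise ValueError("times must be strictly positive")
    if groups is None:
        groups = np.repeat("all", len(times))
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        km = KaplanMeierFitter()
        km.fit(times[sel], events[sel])
        tab = km.event_table
        out[str(g)] = SurvivalCurve(
            group_label=str(g),
            times=tab.index.to_numpy(dtype=float),
            survival=km.survival_function_["KM_estimate"]
            .reindex(tab.index).to_numpy(),
            n_risk=tab["at_risk"].to_numpy(),
            n_event=tab["observed"].to_numpy(),
            censored_times=np.sort(times[sel & ~events]),
        )
    return out


def logrank_statistic(times, events, group) -> tuple[float, float, float]:
    """Log-rank chi-square for a binary group, plus O/E hazard-ratio pieces.

    Returns (chi2, o_minus_e, variance); the signed z is
    o_minus_e / sqrt(variance).  Vectorised so survival permutation tests
    can call it thousands of times cheaply.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group, dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    n = len(t)
    # risk counts just before each event time
    uniq, first_idx = np.unique(t, return_index=True)
    at_risk_total = n - first_idx
    cum_g = np.concatenate([[0], np.cumsum(g)])
    at_risk_g = g.sum() - cum_g[first_idx]
    d_total = np.add.reduceat(e.astype(int), first_idx)
    d_g = np.add.reduceat((e & g).astype(int), first_idx)
    ev = d_total > 0
    n_t, n1_t = at_risk_total[ev].astype(float), at_risk_g[ev].astype(float)
    d_t, d1_t = d_total[ev].astype(float), d_g[ev].astype(float)
    exp1 = d_t * n1_t / n_t
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / np.maximum(n_t - 1, 1)
    o_minus_e = float(np.sum(d1_t - exp1))
    v = float(np.sum(var))
    chi2 = o_minus_e**2 / v if v > 0 else 0.0
    return chi2, o_minus_e, v


def logrank_test(times, events, group) -> dict:
    """Standard 1-df log-rank test with an O/E hazard-ratio summary."""
    g = np.asarray(group, dtype=bool)
    if g.all() or (~g).all():
        raise ValueError("both groups must be non-empty")
    e = np.asarray(events, dtype=bool)
    if not e.any():
        warnings.warn("no events observed; log-rank p set to 1")
        return {"statistic": 0.0, "p": 1.0, "hr": float("nan"),
                "hr_ci": (float("nan"), float("nan"))}
    chi2, o_minus_e, v = logrank_statistic(times, events, g)
    p = float(stats.chi2.sf(chi2, 1))
    # O/E hazard ratio for display
    d1 = float((e & g).sum())
    d0 = float((e & ~g).sum())
    e1 = d1 - o_minus_e
    if d1 > 0 and d0 > 0 and e1 > 0 and (d1 + d0 - e1) > 0:
        hr = (d1 / e1) / (d0 / (d1 + d0 - e1))
        se = np.sqrt(1 / e1 + 1 / (d1 + d0 - e1))
        ci = (float(hr * np.exp(-1.96 * se)), float(hr * np.exp(1.96 * se)))
    else:
        hr, ci = float("nan"), (float("nan"), float("nan"))
    return {"statistic": float(chi2), "p": p, "hr": float(hr), "hr_ci": ci}


def survival_mpt(values_by_patient: pd.DataFrame, cohort: pd.DataFrame,
                 endpoint: str = "OS", n_perm: int = 5000,
                 seed: int = 0) -> pd.DataFrame:
    """Max-T permutation FWER control for per-protein log-rank tests.

    Each protein is dichotomised at its median (strictly above = high).
    Permutations shuffle the (time, event) pairs across patients jointly,
    leaving the protein matrix fixed, so the inter-protein correlation is
    preserved and the max statistic adapts to it.
    """
    col_t = "os_time" if endpoint.upper() == "OS" else "pfs_time"
    col_e = "os_event" if endpoint.upper() == "OS" else "pfs_event"
    df = cohort.set_index("patient_id")
    patients = [p for p in values_by_patient.index if p in df.index]
    vals = values_by_patient.loc[patients]
    t = df.loc[patients, col_t].to_numpy(dtype=float)
    e = df.loc[patients, col_e].to_numpy(dtype=bool)
    flags = median_dichotomise(vals, vals.columns)

    rng = np.random.default_rng(seed)
    proteins = list(vals.columns)

    def _z_all(tt, ee):
        zs = np.empty(len(proteins))
        for j, pid in enumerate(proteins):
            f = flags[pid].to_numpy()
            ok = np.isfinite(vals[pid].to_numpy(dtype=float))
            chi2, ome, v = logrank_statistic(tt[ok], ee[ok], f[ok])
            zs[j] = ome / np.sqrt(v) if v > 0 else 0.0
        return zs

    obs = _z_all(t, e)
    max_perm = np.empty(n_perm)
    perm_ge = np.zeros(len(proteins))
    for b in range(n_perm):
        perm = rng.permutation(len(t))
        z = np.abs(_z_all(t[perm], e[perm]))
        max_perm[b] = z.max()
        perm_ge += z >= np.abs(obs)
    raw_p = (1 + perm_ge) / (n_perm + 1)
    fwer_p = (1 + (max_perm[:, None] >= np.abs(obs)[None, :]).sum(axis=0)) / (n_perm + 1)
    return pd.DataFrame(
        {"statistic": obs, "raw_p": raw_p, "fwer_p": fwer_p,
         "n_perm": n_perm, "endpoint": endpoint.upper()},
        index=pd.Index(proteins, name="protein_id"),
    )


# ---------------------------------------------------------------------------
# Cox regression with a global proportional-hazards check
# ---------------------------------------------------------------------------

def _global_ph_test(cph: CoxPHFitter, df: pd.DataFrame, time_col: str,
                    event_col: str) -> tuple[float, float]:
    """Global Schoenfeld chi-square (Grambsch-Therneau form, rank time
    transform): correlates unscaled Schoenfeld residuals with transformed
    event times and refers u' [g'g/d * I]^-1 u to chi2(p)."""
    resid = cph.compute_residuals(df, "schoenfeld")
    resid = resid.sort_index()
    event_times = df.loc[resid.index, time_col].to_numpy(dtype=float)
    order = np.argsort(event_times, kind="stable")
    r = resid.to_numpy(dtype=float)[order]
    g = stats.rankdata(event_times[order])
    g = g - g.mean()
    d = r.shape[0]
    u = g @ r
    vcov = cph.variance_matrix_.to_numpy(dtype=float)
    m = (np.sum(g**2) / d) * np.linalg.inv(vcov)
    chi2 = float(u @ np.linalg.solve(m, u))
    p = float(stats.chi2.sf(chi2, r.shape[1]))
    return chi2, p


def cox_fit(times, events, terms: pd.DataFrame, alpha: float = 0.05) -> list[CoxResult]:
    """Cox proportional-hazards fit (Efron ties) with Wald CIs and the
    global Schoenfeld PH check populated on every term's result."""
    terms = pd.DataFrame(terms).astype(float)
    if (terms.std(ddof=0) == 0).any():
        const = terms.columns[(terms.std(ddof=0) == 0)][0]
        raise ValueError(f"constant column {const!r} in the design")
    n_events = int(np.asarray(events, dtype=bool).sum())
    if n_events < 5 * terms.shape[1]:
        warnings.warn(
            f"only {n_events} events for {terms.shape[1]} terms; "
            "estimates may be unstable")
    df = terms.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=bool).astype(int)
    cph = CoxPHFitter(alpha=alpha)
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    chi2, ph_p = _global_ph_test(cph, df, "_time", "_event")
    summ = cph.summary
    out = []
    for term in terms.columns:
        row = summ.loc[term]
        out.append(CoxResult(
            term=term,
            hazard_ratio=float(np.exp(row["coef"])),
            ci_low=float(np.exp(row[f"coef lower {100*(1-alpha):g}%"])),
            ci_high=float(np.exp(row[f"coef upper {100*(1-alpha):g}%"])),
            p=float(row["p"]),
            ph_global_chi2_p=ph_p,
            ph_ok=ph_p > 0.05,
        ))
    return out


# ---------------------------------------------------------------------------
# logistic response models with bootstrap CIs
# ---------------------------------------------------------------------------

class SeparationError(RuntimeError):
    """Logistic likelihood is degenerate (perfect separation)."""


def logistic_orr(response, terms: pd.DataFrame, n_bootstrap: int = 1000,
                 seed: int = 0, penalized: bool = False) -> pd.DataFrame:
    """Covariate-adjusted logistic model of response with percentile
    bootstrap CIs over patient-level resamples.

    Resamples containing a single response class are redrawn (counted and
    logged).  Returns a table per term: OR, p, bootstrap CI bounds.  On
    perfect separation the unpenalised fit raises :class:`SeparationError`
    advising a penalised refit; with ``penalized=True`` a ridge-logistic
    fit is used instead (p-values then come from the bootstrap sign test).
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    terms = pd.DataFrame(terms).astype(float)
    X = sm.add_constant(terms, has_constant="add")

    if penalized:
        from sklearn.linear_model import LogisticRegression

        def fit_params(Xm, ym):
            clf = LogisticRegression(penalty="l2", C=10.0, max_iter=2000)
            clf.fit(Xm, ym)
            return np.concatenate([clf.intercept_, clf.coef_[0]])

        params = fit_params(terms.to_numpy(), y)
        pvals = None
    else:
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        eta = np.abs(fit.predict(X, which="linear"))
        separated = any(issubclass(w.category, PerfectSeparationWarning)
                        for w in caught)
        if separated or np.max(eta) > 15:
            raise SeparationError(
                "apparent separation in logistic fit; retry with penalized=True")
        params = fit.params.to_numpy()
        pvals = fit.pvalues.to_numpy()

    rng = np.random.default_rng(seed)
    n = len(y)
    boots = np.empty((n_bootstrap, X.shape[1]))
    redraws = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_bootstrap):
            while True:
                idx = rng.integers(0, n, n)
                if len(np.unique(y[idx])) == 2:
                    break
                redraws += 1
            if penalized:
                boots[b] = fit_params(terms.to_numpy()[idx], y[idx])
            else:
                bf = sm.GLM(y[idx], X.iloc[idx],
                            family=sm.families.Binomial()).fit()
                boots[b] = bf.params.to_numpy()
    if redraws:
        log.info("redrew %d single-class bootstrap resamples", redraws)

    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    if pvals is None:  # bootstrap two-sided sign p for the penalised path
        frac = np.mean(boots > 0, axis=0)
        pvals = 2 * np.minimum(frac, 1 - frac)
    out = pd.DataFrame({
        "term": X.columns,
        "odds_ratio": np.exp(params),
        "ci_low": np.exp(lo),
        "ci_high": np.exp(hi),
        "p": pvals,
    }).set_index("term")
    return out.drop(index="const")


# ---------------------------------------------------------------------------
# stratification by elevated-marker count
# ---------------------------------------------------------------------------

def median_dichotomise(values_by_patient: pd.DataFrame, protein_ids) -> pd.DataFrame:
    """Elevated = strictly above the per-protein median (ties -> low)."""
    out = {}
    for pid in protein_ids:
        v = values_by_patient[pid].astype(float)
        med = v.median(skipna=True)
        if (v == med).mean() > 0.5:
            warnings.warn(f"degenerate median split for {pid}: >50% ties")
        out[pid] = v > med
    return pd.DataFrame(out, index=values_by_patient.index)


def fisher_2x2(table) -> tuple[float, float]:
    """Fisher's exact test: conditional-MLE odds ratio and two-sided p
    (probability-mass rule).  A zero margin gives p = 1, OR = NaN."""
    tab = np.asarray(table, dtype=int)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    _, p = stats.fisher_exact(tab, alternative="two-sided")
    or_cond = _conditional_or(tab, kind="conditional").statistic
    return float(or_cond), float(p)


def cumulative_marker_analysis(flags: pd.DataFrame, response,
                               covariates: pd.DataFrame,
                               seed: int = 0) -> StratificationResult:
    """Response by number of elevated markers, plus the additive model.

    ``flags``: boolean patients x markers frame.  Produces the per-stratum
    ORR table, the Fisher exact comparison of the 0- vs all-elevated
    strata, and a logistic model of response on the integer elevated count
    adjusted for the covariates (the additive OR per additional marker).
    """
    import statsmodels.api as sm

    counts = flags.sum(axis=1).astype(int)
    y = pd.Series(np.asarray(response, dtype=bool), index=flags.index)
    k = flags.shape[1]
    rows = []
    for c in range(k + 1):
        sel = counts == c
        n = int(sel.sum())
        n_resp = int(y[sel].sum())
        rows.append({
            "n_elevated": c, "n_patients": n, "n_responders": n_resp,
            "orr_pct": round(100.0 * n_resp / n, 1) if n else float("nan"),
        })
    table = pd.DataFrame(rows).set_index("n_elevated")

    lo, hi = counts == 0, counts == k
    if lo.sum() and hi.sum():
        tab = [[int(y[lo].sum()), int(lo.sum() - y[lo].sum())],
               [int(y[hi].sum()), int(hi.sum() - y[hi].sum())]]
        f_or, f_p = fisher_2x2(tab)
    else:
        f_or, f_p = float("nan"), float("nan")

    X = pd.DataFrame(covariates).astype(float).copy()
    X.insert(0, "n_elevated", counts.to_numpy(dtype=float))
    X = sm.add_constant(X, has_constant="add")
    fit = sm.GLM(y.astype(float).to_numpy(), X,
                 family=sm.families.Binomial()).fit()
    beta = float(fit.params["n_elevated"])
    se = float(fit.bse["n_elevated"])
    lo, hi = np.clip([beta - 1.96 * se, beta + 1.96 * se], -700, 700)
    return StratificationResult(
        table=table, fisher_p_extremes=float(f_p), fisher_or_extremes=float(f_or),
        additive_or=float(np.exp(np.clip(beta, -700, 700))),
        additive_ci=(float(np.exp(lo)), float(np.exp(hi))),
        additive_p=float(fit.pvalues["n_elevated"]),
    )


# ---------------------------------------------------------------------------
# dual-assay concordance
# ---------------------------------------------------------------------------

def assay_concordance(relative: pd.DataFrame, absolute: pd.DataFrame,
                      protein_ids) -> pd.DataFrame:
    """Per-protein Spearman rank correlation between paired samples of the
    relative (log2) and absolute (pg/mL) assays, pairwise-complete."""
    rows = []
    for pid in protein_ids:
        a = relative[pid].astype(float)
        b = absolute[pid].astype(float)
        a, b = a.align(b, join="inner")
        ok = a.notna() & b.notna()
        a, b = a[ok], b[ok]
        if len(a) < 10:
            warnings.warn(f"only {len(a)} pairs for {pid}")
        if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
            raise ValueError(f"constant vector for {pid}")
        rho, p = stats.spearmanr(a, b)
        rows.append({"protein_id": pid, "rho": float(rho), "p": float(p),
                     "n_pairs": int(len(a))})
    return pd.DataFrame(rows).set_index("protein_id")
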