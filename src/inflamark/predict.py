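"""Train-on-one-centre LASSO response models and the correlation-preserving
permutation test of marker contribution to discrimination.

Two nested L1-penalised logistic models are trained on one centre — a full
model (marker proteins plus sex, age, BMI and metastatic stage) and a null
model (covariates only) — each with its penalty chosen by leave-one-out
cross-validated binomial deviance, and evaluated by AUC-ROC on the held-out
centre.  The markers' contribution is tested by jointly permuting the rows
of the marker block of the test design matrix (covariates untouched, so
the markers' mutual correlation survives) and recomputing the fixed full
model's AUC, giving an empirical p-value for the observed AUC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

log = logging.getLogger("inflamark")

DEFAULT_COVARIATES = ("sex_male", "age", "bmi", "stage_code")


@dataclass
class LassoModel:
    """Fitted L1-logistic model with its training standardisation."""

    coef: np.ndarray
    intercept: float
    lambda_: float
    feature_names: list
    train_mean: np.ndarray
    train_sd: np.ndarray
    cv_deviance: dict = field(default_factory=dict)

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        Z = self._transform(X)
        return Z @ self.coef + self.intercept

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit
        return expit(self.decision_scores(X))

    def _transform(self, X: pd.DataFrame) -> np.ndarray:
        Z = X.loc[:, self.feature_names].to_numpy(dtype=float)
        # train-mean imputation, then train standardisation
        for j in range(Z.shape[1]):
            nan = np.isnan(Z[:, j])
            if nan.any():
                Z[nan, j] = self.train_mean[j]
        return (Z - self.train_mean) / self.train_sd


@dataclass
class AUCResult:
    model_tag: str
    lambda_selected: float
    auc_test: float
    n_train: int
    n_test: int


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    empirical_p: float
    n_perm: int
    convention_tag: str = "add_one"


def build_design(cohort: pd.DataFrame, values_by_patient: pd.DataFrame,
                 markers, covariates=DEFAULT_COVARIATES):
    """Design matrix (markers + clinical covariates) and binary response.

    Sex enters as an indicator for male, metastatic stage as its ordered
    integer code (1-5).
    """
    df = cohort.set_index("patient_id")
    X = pd.DataFrame(index=df.index)
    for m in markers:
        X[m] = values_by_patient.reindex(df.index)[m]
    for c in covariates:
        if c == "sex_male":
            X[c] = (df["sex"] == "male").astype(float)
        elif c == "stage_code":
            X[c] = df["stage_code"].astype(float)
        else:
            X[c] = df[c].astype(float)
    y = df["responder"].astype(int)
    return X, y


def default_lambda_grid(X: pd.DataFrame, y: pd.Series, n_values: int = 20,
                        ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced grid from the smallest penalty that zeroes every
    coefficient (glmnet-style lambda_max) down to ratio * lambda_max."""
    Z = X.to_numpy(dtype=float)
    mean = np.nanmean(Z, axis=0)
    sd = np.nanstd(Z, axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = np.where(np.isnan(Z), mean, Z)
    Z = (Z - mean) / sd
    yv = y.to_numpy(dtype=float)
    lam_max = np.max(np.abs(Z.T @ (yv - yv.mean()))) / len(yv)
    return np.geomspace(lam_max, lam_max * ratio, n_values)


def _fit_l1(Z: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # glmnet objective (1/n) sum loss + lam * ||w||_1  <=>  C = 1 / (n * lam)
    C = 1.0 / max(len(y) * lam, 1e-12)
    clf = LogisticRegression(
        penalty="l1", C=C, solver="liblinear", intercept_scaling=1000.0,
        max_iter=2000, tol=1e-6,
    )
    clf.fit(Z, y)
    return clf


def fit_lasso_loocv(X: pd.DataFrame, y: pd.Series, lambda_grid=None,
                    loss: str = "deviance") -> LassoModel:
    """L1-logistic fit with the penalty chosen by leave-one-out CV.

    The cross-validation loss is binomial deviance by default
    (``loss="misclass"`` and ``loss="auc"`` are alternatives); ties in the
    CV loss go to the larger penalty.  Predictors are standardised on the
    training set (missing values mean-imputed first); LOOCV is deterministic.
    """
    y = pd.Series(y).astype(int)
    if len(y) < 10:
        raise ValueError("need at least 10 training patients")
    if y.nunique() < 2:
        raise ValueError("training set must contain both classes")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    if len(lambda_grid) == 0:
        raise ValueError("empty lambda grid")

    feature_names = list(X.columns)
    Z_raw = X.to_numpy(dtype=float)
    n = len(y)
    n_imputed = int(np.isnan(Z_raw).sum())
    if n_imputed:
        log.info("mean-imputing %d missing training values", n_imputed)

    def standardise(Zt):
        mean = np.nanmean(Zt, axis=0)
        Zf = np.where(np.isnan(Zt), mean, Zt)
        sd = Zf.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (Zf - mean) / sd, mean, sd

    yv = y.to_numpy()
    eps = 1e-12
    if len(lambda_grid) == 1:  # nothing to select; skip the CV loop
        Zt, mean, sd = standardise(Z_raw)
        clf = _fit_l1(Zt, yv, lambda_grid[0])
        return LassoModel(
            coef=clf.coef_[0].copy(), intercept=float(clf.intercept_[0]),
            lambda_=float(lambda_grid[0]), feature_names=feature_names,
            train_mean=mean, train_sd=sd, cv_deviance={},
        )
    cv_loss = {}
    for lam in lambda_grid:
        losses = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if yv[mask].min() == yv[mask].max():
                losses[i] = np.nan
                continue
            Zt, mean, sd = standardise(Z_raw[mask])
            clf = _fit_l1(Zt, yv[mask], lam)
            zi = Z_raw[i].copy()
            nan = np.isnan(zi)
            zi[nan] = mean[nan]
            zi = (zi - mean) / sd
            p = clf.predict_proba(zi[None, :])[0, list(clf.classes_).index(1)]
            p = min(max(p, eps), 1 - eps)
            if loss == "deviance":
                losses[i] = -2 * (yv[i] * np.log(p) + (1 - yv[i]) * np.log(1 - p))
            elif loss == "misclass":
                losses[i] = float((p >= 0.5) != yv[i])
            else:
                raise ValueError(f"unknown loss {loss!r}")
        cv_loss[float(lam)] = float(np.nanmean(losses))

    best = min(cv_loss, key=lambda l: (cv_loss[l], -l))
    Zt, mean, sd = standardise(Z_raw)
    clf = _fit_l1(Zt, yv, best)
    model = LassoModel(
        coef=clf.coef_[0].copy(), intercept=float(clf.intercept_[0]),
        lambda_=float(best), feature_names=feature_names,
        train_mean=mean, train_sd=sd, cv_deviance=cv_loss,
    )
    log.info("LASSO LOOCV: lambda*=%.4g, %d/%d nonzero coefficients",
             best, int(np.sum(model.coef != 0)), len(model.coef))
    return model


def auc_mann_whitney(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) formulation; ties get half-credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: test set has a single class")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate_auc(model: LassoModel, X_test: pd.DataFrame, y_test,
                 model_tag: str = "full", n_train: int = 0) -> AUCResult:
    y_test = pd.Series(y_test).astype(int)
    auc = auc_mann_whitney(model.decision_scores(X_test), y_test.to_numpy())
    return AUCResult(model_tag=model_tag, lambda_selected=model.lambda_,
                     auc_test=auc, n_train=n_train, n_test=len(y_test))


def permutation_auc_contribution(model: LassoModel, X_test: pd.DataFrame,
                                 y_test, marker_cols, n_perm: int = 1000,
                                 seed: int = 0,
                                 convention: str = "add_one") -> PermutationResult:
    """Correlation-preserving permutation test of the markers' contribution.

    For each permutation the rows of the marker-protein block of the test
    design matrix are permuted jointly (one row permutation applied to all
    markers at once, so their mutual correlation is preserved) while the
    clinical covariates stay in place; the unchanged full model's AUC is
    recomputed on the permuted test set.  The empirical p-value is
    (1 + #{null >= observed}) / (n_perm + 1) under the default add-one
    convention ("strict" uses #{null > observed} / n_perm).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; empirical p will be coarse")
    rng = np.random.default_rng(seed)
    y_arr = pd.Series(y_test).astype(int).to_numpy()
    observed = auc_mann_whitney(model.decision_scores(X_test), y_arr)

    marker_cols = list(marker_cols)
    X_base = X_test.copy()
    marker_vals = X_test.loc[:, marker_cols].to_numpy(dtype=float)
    n = len(X_test)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Xp = X_base.copy()
        Xp.loc[:, marker_cols] = marker_vals[perm]
        null[b] = auc_mann_whitney(model.decision_scores(Xp), y_arr)

    if convention == "add_one":
        p = (1 + np.sum(null >= observed)) / (n_perm + 1)
    elif convention == "strict":
        p = np.sum(null > observed) / n_perm
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return PermutationResult(
        observed_stat=float(observed), null_stats=null,
        empirical_p=float(p), n_perm=n_perm, convention_tag=convention,
    )
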