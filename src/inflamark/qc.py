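"""Panel quality control: LOD filtering, extreme-value masking, PCA check.

Proteins with more than a configurable fraction (default 25%) of values
below the lower detection limit are discarded; for retained proteins,
below-LOD values are masked.  Extreme values beyond k SDs (default 4) of
the protein mean are masked in a single pass — by Chebyshev's inequality
at most 1/k^2 (~6.25% at k=4) of any distribution can be masked, so at
least ~95% of the data survives.  Below-LOD values are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from inflamark.matrix import ProteinMatrix

log = logging.getLogger("inflamark")


@dataclass
class QCReport:
    proteins_in: int = 0
    proteins_dropped_lod: list = field(default_factory=list)
    proteins_dropped_empty: list = field(default_factory=list)
    values_masked_below_lod: int = 0
    values_masked_outlier: int = 0
    proteins_out: int = 0
    pc_variance_explained: list = field(default_factory=list)
    pc_batch_association: dict = field(default_factory=dict)


def filter_lod(m: ProteinMatrix, max_below_fraction: float = 0.25):
    """Drop proteins whose below-LOD fraction strictly exceeds the cutoff;
    mask below-LOD values in retained proteins.

    The fraction is computed over unmasked cells only, so pre-existing
    missingness (assay failure) does not count as below-LOD.  Proteins with
    no unmasked values at all are dropped and reported separately.
    """
    if not 0.0 < max_below_fraction < 1.0:
        raise ValueError("max_below_fraction must be in (0, 1)")
    report = QCReport(proteins_in=m.n_proteins)
    n_obs = m.values.notna().sum(axis=0)
    empty = list(n_obs.index[n_obs == 0])
    if empty:
        log.warning("proteins with zero unmasked values dropped: %s", empty)
        report.proteins_dropped_empty = empty
    below = m.values.lt(m.lod, axis=1)
    frac = below.sum(axis=0) / n_obs.replace(0, np.nan)
    dropped = list(frac.index[(frac > max_below_fraction).fillna(False)])
    report.proteins_dropped_lod = dropped
    keep = [p for p in m.protein_ids if p not in set(dropped) | set(empty)]
    vals = m.values.loc[:, keep].copy()
    below_keep = below.loc[:, keep]
    report.values_masked_below_lod = int(below_keep.sum().sum())
    vals[below_keep] = np.nan
    report.proteins_out = len(keep)
    out = ProteinMatrix(vals, m.lod.loc[keep].copy(), m.scale_tag)
    log.info("LOD filter: %d -> %d proteins, %d values masked",
             report.proteins_in, report.proteins_out,
             report.values_masked_below_lod)
    return out, report


def filter_outliers(m: ProteinMatrix, k_sd: float = 4.0):
    """Mask values further than ``k_sd`` SDs from the protein mean.

    Single pass: means and SDs are computed once from the pre-masking data
    and are not recomputed after masking, preserving the Chebyshev bound on
    the masked fraction.  Proteins with zero SD are left untouched.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    report = QCReport(proteins_in=m.n_proteins, proteins_out=m.n_proteins)
    mean = m.values.mean(axis=0, skipna=True)
    sd = m.values.std(axis=0, ddof=1, skipna=True)
    sd = sd.where(sd > 0)  # zero/undefined SD -> no masking
    outlier = (m.values.sub(mean, axis=1).abs()
               .gt(k_sd * sd, axis=1)).fillna(False)
    vals = m.values.copy()
    vals[outlier] = np.nan
    report.values_masked_outlier = int(outlier.sum().sum())
    log.info("outlier filter (k=%g SD): %d values masked",
             k_sd, report.values_masked_outlier)
    return ProteinMatrix(vals, m.lod.copy(), m.scale_tag), report


def pca_check(m: ProteinMatrix, factors: pd.DataFrame, n_components: int = 5):
    """PCA-based stratification check.

    Proteins are standardised (zero mean, unit variance) with per-protein
    mean imputation used for the decomposition only; the imputed values
    never propagate downstream.  For each factor column (e.g. centre,
    plate) a Kruskal-Wallis p-value of PC1 and PC2 scores across factor
    levels is reported.
    """
    if m.n_samples < 3:
        raise ValueError("PCA check requires at least 3 samples")
    vals = m.values.copy()
    mean = vals.mean(axis=0, skipna=True)
    sd = vals.std(axis=0, ddof=1, skipna=True)
    keep = sd[sd > 0].index
    vals = (vals[keep] - mean[keep]) / sd[keep]
    vals = vals.fillna(0.0)  # mean imputation on the standardised scale
    k = min(n_components, vals.shape[0] - 1, vals.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(vals.to_numpy())
    var_exp = pca.explained_variance_ratio_.tolist()

    assoc = {}
    factors = factors.loc[m.sample_ids]
    for col in factors.columns:
        levels = factors[col]
        assoc[col] = {}
        for pc in range(min(2, k)):
            groups = [scores[(levels == lv).to_numpy(), pc]
                      for lv in levels.unique()]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2:
                assoc[col][f"PC{pc + 1}"] = float("nan")
            else:
                assoc[col][f"PC{pc + 1}"] = float(
                    stats.kruskal(*groups).pvalue
                )
    report = QCReport(
        proteins_in=m.n_proteins, proteins_out=m.n_proteins,
        pc_variance_explained=var_exp, pc_batch_association=assoc,
    )
    return report


def run_qc(m: ProteinMatrix, max_below_fraction: float = 0.25, k_sd: float = 4.0):
    """LOD filter then outlier filter; returns matrix and combined report."""
    m1, rep_lod = filter_lod(m, max_below_fraction)
    m2, rep_out = filter_outliers(m1, k_sd)
    report = QCReport(
        proteins_in=rep_lod.proteins_in,
        proteins_dropped_lod=rep_lod.proteins_dropped_lod,
        proteins_dropped_empty=rep_lod.proteins_dropped_empty,
        values_masked_below_lod=rep_lod.values_masked_below_lod,
        values_masked_outlier=rep_out.values_masked_outlier,
        proteins_out=rep_lod.proteins_out,
    )
    return m2, report
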