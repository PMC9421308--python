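"""Synthetic two-centre ICI cohort generator.

Emulates the data structure of a two-centre advanced-melanoma checkpoint-
inhibitor study: 87 patients (48 + 39), ~53% responders, a 92-protein
inflammation panel on the log2 (NPX-like) scale with block-correlated
proteins and 15 low-detectability proteins, three marker proteins elevated
at baseline in non-responders, response-independent on-treatment increases
in two proteins, survival hazard tied to the primary marker's absolute
level, and a dual absolute-quantification (pg/mL) assay with controllable
rank concordance.  Every injected effect is recorded in a machine-readable
truth record so downstream analyses can be tested for parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from inflamark.matrix import ABSOLUTE_PG_ML, RELATIVE_LOG2, ProteinMatrix

#: Designated marker proteins, elevated at baseline in non-responders.
MARKER_PROTEINS = ("IL6", "HGF", "MCP2")
#: Proteins with a response-independent on-treatment increase.
TREATMENT_PROTEINS = ("TNFRSF9", "CXCL9")

#: Target absolute-scale medians (pg/mL) for the marker proteins.
_ABS_MEDIAN_PG = {"IL6": 1.57, "HGF": 188.98, "MCP2": 50.99}


def default_block_structure(n_proteins: int = 92):
    """Blocks of 6 proteins at within-block correlation 0.6 (remainder in a
    final smaller block).  Chosen so the effective number of independent
    tests among the 77 retained proteins lands near 42."""
    blocks = []
    remaining = n_proteins
    while remaining > 0:
        size = min(6, remaining)
        blocks.append((size, 0.6 if size > 1 else 0.0))
        remaining -= size
    return blocks


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions.

    Effect-size defaults come from the study being emulated: baseline marker
    differences (non-responders minus responders, log2 units) of 0.90, 0.41
    and 0.48; on-treatment fold changes of 1.43 and 2.41; a death-hazard
    ratio of 1.90 per pg/mL of the primary marker; dual-assay Spearman
    concordance in 0.69-0.89.  ``protein_sd`` (within-group SD on the log2
    scale) and ``longitudinal_sd`` (within-patient measurement SD) are free
    parameters of the generator; see docs/methods.md for the rationale
    behind their defaults.
    """

    n_per_centre: tuple = (48, 39)
    centres: tuple = ("UK", "NL")
    orr: float = 0.53
    n_proteins: int = 92
    n_low_detect: int = 15
    block_structure: list | None = None
    marker_effects: dict = field(
        default_factory=lambda: {"IL6": 0.90, "HGF": 0.41, "MCP2": 0.48}
    )
    treatment_effects: dict = field(
        default_factory=lambda: {"TNFRSF9": 1.43, "CXCL9": 2.41}
    )
    protein_sd: float = 0.25
    longitudinal_sd: float = 0.30
    lod_quantile: float = 0.40
    background_lod_quantile: float = 0.01
    followup_retention: tuple = (46 / 87, 35 / 87)
    survival_log_hr_per_unit: float = math.log(1.90)
    log_hr_nonresponder: float = math.log(2.5)
    base_hazard_per_day: float = math.log(2) / 600.0
    progression_hazard_ratio: float = 2.0
    censoring_rate: float = 1 / 1200.0
    admin_censor_days: float = 1095.0
    assay_concordance_rho: tuple = (0.69, 0.89)
    abs_scale_slope: float = 1.2
    n_absolute: int = 81
    covariate_effects: dict = field(
        default_factory=lambda: {
            "sex_male": math.log(0.27),
            "bmi": math.log(0.91),
            "stage": math.log(0.62),
        }
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.orr < 1.0:
            raise ValueError("orr must be in (0, 1)")
        if self.n_low_detect >= self.n_proteins:
            raise ValueError("n_low_detect must be < n_proteins")
        if self.block_structure is None:
            self.block_structure = default_block_structure(self.n_proteins)
        sizes = sum(s for s, _ in self.block_structure)
        if sizes != self.n_proteins:
            raise ValueError(
                f"block sizes sum to {sizes}, expected n_proteins={self.n_proteins}"
            )
        for size, rho in self.block_structure:
            if not -1.0 <= rho <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")
            if size > 1 and rho < -1.0 / (size - 1):
                raise ValueError(
                    f"block of size {size} with correlation {rho} is not "
                    "positive semi-definite"
                )
        lo, hi = self.assay_concordance_rho
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("assay_concordance_rho must be an ordered range in (0,1)")


@dataclass
class SyntheticCohort:
    """Generated cohort: clinical table, assay matrices, and ground truth."""

    cohort: pd.DataFrame
    baseline: ProteinMatrix
    followups: ProteinMatrix
    samples: pd.DataFrame
    absolute_assay: ProteinMatrix
    truth: dict

    def baseline_by_patient(self) -> pd.DataFrame:
        """Baseline values reindexed by patient id."""
        mapping = self.samples.set_index("sample_id")["patient_id"]
        vals = self.baseline.values.copy()
        vals.index = vals.index.map(mapping)
        return vals


def _protein_ids(cfg: SimulationConfig) -> list:
    """Generic ids with the designated proteins placed one per block."""
    ids = [f"P{i + 1:03d}" for i in range(cfg.n_proteins)]
    specials = list(MARKER_PROTEINS) + list(TREATMENT_PROTEINS)
    starts = np.cumsum([0] + [s for s, _ in cfg.block_structure])[:-1]
    for k, name in enumerate(specials):
        if k < len(starts):
            ids[int(starts[k])] = name
        else:  # more specials than blocks: place sequentially
            ids[k] = name
    return ids


def _draw_correlated(rng, n, cfg: SimulationConfig) -> np.ndarray:
    """n x n_proteins standard normals with the configured block correlation."""
    out = np.empty((n, cfg.n_proteins))
    col = 0
    for size, rho in cfg.block_structure:
        if size == 1 or rho == 0.0:
            out[:, col:col + size] = rng.standard_normal((n, size))
        else:
            shared = rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, size))
            if rho < 0:
                # exchangeable negative correlation via centred residuals
                c = np.full((size, size), rho) + (1 - rho) * np.eye(size)
                out[:, col:col + size] = rng.standard_normal((n, size)) @ np.linalg.cholesky(c).T
            else:
                out[:, col:col + size] = (
                    math.sqrt(rho) * shared + math.sqrt(1 - rho) * noise
                )
        col += size
    return out


def _calibrate_intercept(eta: np.ndarray, orr: float) -> float:
    """Logit intercept so the cohort-average response probability is `orr`."""
    def mean_p(c):
        return float(np.mean(expit(c + eta))) - orr
    return brentq(mean_p, -25.0, 25.0)


def generate_cohort(cfg: SimulationConfig | None = None) -> SyntheticCohort:
    """Draw one synthetic cohort; deterministic given ``cfg.rng_seed``."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    n_total = int(sum(cfg.n_per_centre))
    patient_ids = [f"PT{i + 1:03d}" for i in range(n_total)]
    centre = np.repeat(list(cfg.centres), list(cfg.n_per_centre))

    # --- clinical covariates (marginals patterned on the study's Table 1) ---
    sex_male = rng.random(n_total) < 0.655
    age = np.clip(np.round(rng.normal(62, 13, n_total)), 21, 95)
    bmi = np.round(np.exp(rng.normal(math.log(27.5), 0.15, n_total)), 1)
    stage_code = rng.choice(
        np.arange(1, 6), size=n_total, p=[0.057, 0.138, 0.172, 0.368, 0.265]
    )
    ecog = rng.choice([0, 1, 2, 3], size=n_total, p=[0.529, 0.368, 0.080, 0.023])
    ldh = rng.random(n_total) < 0.345
    braf = rng.random(n_total) < 0.465
    treatment = rng.choice(
        ["nivolumab+ipilimumab", "pembrolizumab", "nivolumab", "ipilimumab"],
        size=n_total, p=[0.448, 0.241, 0.300, 0.011],
    )

    # --- response model: covariate log-odds, intercept calibrated to ORR ---
    ce = cfg.covariate_effects
    eta = (
        ce.get("sex_male", 0.0) * sex_male.astype(float)
        + ce.get("bmi", 0.0) * (bmi - np.mean(bmi))
        + ce.get("stage", 0.0) * (stage_code - np.mean(stage_code))
    )
    intercept = _calibrate_intercept(eta, cfg.orr)
    responder = rng.random(n_total) < expit(intercept + eta)

    # --- baseline panel on the log2 scale -----------------------------------
    protein_ids = _protein_ids(cfg)
    for pid in list(cfg.marker_effects) + list(cfg.treatment_effects):
        if pid not in protein_ids:
            raise ValueError(f"effect refers to unknown protein {pid!r}")
    protein_mean = rng.normal(5.0, 1.0, cfg.n_proteins)
    z = _draw_correlated(rng, n_total, cfg)
    baseline_vals = protein_mean + cfg.protein_sd * z
    col_of = {pid: j for j, pid in enumerate(protein_ids)}
    for pid, effect in cfg.marker_effects.items():
        baseline_vals[~responder, col_of[pid]] += effect

    # --- detection limits ---------------------------------------------------
    specials = set(MARKER_PROTEINS) | set(TREATMENT_PROTEINS)
    candidates = [p for p in protein_ids if p not in specials]
    low_detect = candidates[-cfg.n_low_detect:] if cfg.n_low_detect else []
    lod = np.empty(cfg.n_proteins)
    for j, pid in enumerate(protein_ids):
        q = cfg.lod_quantile if pid in low_detect else cfg.background_lod_quantile
        lod[j] = np.quantile(baseline_vals[:, j], q)

    # --- follow-up sampling -------------------------------------------------
    n_early = int(round(cfg.followup_retention[0] * n_total))
    n_late = int(round(cfg.followup_retention[1] * n_total))
    early_pat = rng.choice(n_total, size=n_early, replace=False)
    late_pat = rng.choice(n_total, size=n_late, replace=False)
    treat_shift = np.zeros(cfg.n_proteins)
    for pid, fc in cfg.treatment_effects.items():
        treat_shift[col_of[pid]] = math.log2(fc)

    sample_rows = []
    baseline_day = -rng.integers(0, 7, n_total)
    baseline_sample_ids = []
    for i, pid in enumerate(patient_ids):
        sid = f"{pid}_BL"
        baseline_sample_ids.append(sid)
        sample_rows.append((sid, pid, int(baseline_day[i])))

    def _followup_block(pat_idx, day_lo, day_hi, tag):
        days = rng.integers(day_lo, day_hi + 1, len(pat_idx))
        noise = rng.normal(0.0, cfg.longitudinal_sd, (len(pat_idx), cfg.n_proteins))
        vals = baseline_vals[pat_idx] + treat_shift + noise
        sids = [f"{patient_ids[i]}_{tag}" for i in pat_idx]
        for sid, i, d in zip(sids, pat_idx, days):
            sample_rows.append((sid, patient_ids[i], int(d)))
        return pd.DataFrame(vals, index=sids, columns=protein_ids)

    early_df = _followup_block(early_pat, 14, 34, "FU1")
    late_df = _followup_block(late_pat, 35, 84, "FU2")
    followup_vals = pd.concat([early_df, late_df], axis=0)

    # --- absolute assay (pg/mL) for the marker proteins ---------------------
    rho_target = float(np.mean(cfg.assay_concordance_rho))
    r_latent = 2.0 * math.sin(math.pi * rho_target / 6.0)
    abs_cols, abs_lod, true_pg = {}, {}, {}
    b = cfg.abs_scale_slope
    for pid in MARKER_PROTEINS:
        if pid not in col_of:
            continue
        npx = baseline_vals[:, col_of[pid]]
        a = math.log(_ABS_MEDIAN_PG.get(pid, 10.0)) - b * float(np.median(npx))
        effect = cfg.marker_effects.get(pid, 0.0)
        s_npx = math.sqrt(cfg.protein_sd**2 + cfg.orr * (1 - cfg.orr) * effect**2)
        sigma_e = b * s_npx * math.sqrt(1.0 / r_latent**2 - 1.0)
        obs_ln = a + b * npx + rng.normal(0.0, sigma_e, n_total)
        true_pg[pid] = np.exp(a + b * npx)
        abs_cols[pid] = np.exp(obs_ln)
        abs_lod[pid] = float(np.exp(a + b * np.quantile(npx, 0.001)) / 2.0)
    abs_idx = rng.choice(n_total, size=min(cfg.n_absolute, n_total), replace=False)
    abs_full = pd.DataFrame(abs_cols, index=baseline_sample_ids)
    abs_df = abs_full.iloc[np.sort(abs_idx)]

    # --- survival: hazard log-linear in the primary marker's pg/mL ----------
    primary = MARKER_PROTEINS[0]
    if primary in true_pg:
        pg = true_pg[primary]
        lin = cfg.survival_log_hr_per_unit * (pg - np.median(pg))
    else:
        lin = np.zeros(n_total)
    lam = cfg.base_hazard_per_day * np.exp(
        np.clip(lin, -20, 20) + cfg.log_hr_nonresponder * (~responder)
    )
    t_os = rng.exponential(1.0 / lam)
    t_prog = rng.exponential(1.0 / (cfg.progression_hazard_ratio * lam))
    censor = np.minimum(
        rng.exponential(1.0 / cfg.censoring_rate, n_total), cfg.admin_censor_days
    )
    t_pfs = np.minimum(t_prog, t_os)
    os_time = np.maximum(np.minimum(t_os, censor), 0.5)
    pfs_time = np.maximum(np.minimum(t_pfs, censor), 0.5)
    pfs_time = np.minimum(pfs_time, os_time)

    from inflamark.io import STAGE_LEVELS, validate_cohort

    cohort = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "centre": centre,
            "sex": np.where(sex_male, "male", "female"),
            "age": age,
            "bmi": bmi,
            "metastatic_stage": [STAGE_LEVELS[c - 1] for c in stage_code],
            "ecog": ecog,
            "ldh_elevated": ldh,
            "braf_mutant": braf,
            "treatment": treatment,
            "responder": responder,
            "pfs_time": np.round(pfs_time, 1),
            "pfs_event": t_pfs <= censor,
            "os_time": np.round(os_time, 1),
            "os_event": t_os <= censor,
        }
    )
    cohort = validate_cohort(cohort)

    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "patient_id", "days_from_treatment_start"]
    )
    lod_series = pd.Series(lod, index=protein_ids)
    baseline_m = ProteinMatrix(
        pd.DataFrame(baseline_vals, index=baseline_sample_ids, columns=protein_ids),
        lod_series, RELATIVE_LOG2,
    )
    followup_m = ProteinMatrix(followup_vals, lod_series.copy(), RELATIVE_LOG2)
    absolute_m = ProteinMatrix(
        abs_df, pd.Series(abs_lod), ABSOLUTE_PG_ML
    ) if abs_cols else ProteinMatrix(
        pd.DataFrame(index=baseline_sample_ids), pd.Series(dtype=float), ABSOLUTE_PG_ML
    )

    truth = {
        "rng_seed": int(cfg.rng_seed),
        "n_per_centre": [int(x) for x in cfg.n_per_centre],
        "orr_target": float(cfg.orr),
        "marker_effects_log2": {k: float(v) for k, v in cfg.marker_effects.items()},
        "treatment_effects_fc": {k: float(v) for k, v in cfg.treatment_effects.items()},
        "treatment_effects_log2": {
            k: float(math.log2(v)) for k, v in cfg.treatment_effects.items()
        },
        "low_detect_proteins": list(low_detect),
        "protein_sd": float(cfg.protein_sd),
        "longitudinal_sd": float(cfg.longitudinal_sd),
        "survival_log_hr_per_unit": float(cfg.survival_log_hr_per_unit),
        "survival_hr_per_unit": float(math.exp(cfg.survival_log_hr_per_unit)),
        "assay_concordance_rho": [float(x) for x in cfg.assay_concordance_rho],
        "response_intercept": float(intercept),
        "covariate_effects": {k: float(v) for k, v in cfg.covariate_effects.items()},
    }
    return SyntheticCohort(cohort, baseline_m, followup_m, samples, absolute_m, truth)


def truth_report(sc: SyntheticCohort) -> pd.DataFrame:
    """Tidy table of injected effects for parameter-recovery tests."""
    rows = []
    for pid, eff in sc.truth["marker_effects_log2"].items():
        rows.append(("marker_log2_fc", pid, eff))
    for pid, fc in sc.truth["treatment_effects_fc"].items():
        rows.append(("treatment_fold_change", pid, fc))
    rows.append(("survival_hr_per_unit", MARKER_PROTEINS[0],
                 sc.truth["survival_hr_per_unit"]))
    lo, hi = sc.truth["assay_concordance_rho"]
    rows.append(("assay_concordance_rho_low", "", lo))
    rows.append(("assay_concordance_rho_high", "", hi))
    for pid in sc.truth["low_detect_proteins"]:
        rows.append(("low_detect", pid, float("nan")))
    return pd.DataFrame(rows, columns=["parameter", "protein_id", "value"])
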