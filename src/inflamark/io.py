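"""Readers/writers for the pipeline's tables and cohort descriptives.

All tables are plain delimited text (CSV by default).  Missing values are
empty fields, never sentinel numbers, so a below-LOD value and an assay
failure can never be confused.  Calendar dates never appear: sample timing
is integer days relative to the first treatment dose.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from inflamark.matrix import ProteinMatrix, RELATIVE_LOG2, SCALE_TAGS

log = logging.getLogger("inflamark")

#: Ordered metastatic stage labels (AJCC-like), code 1..5.
STAGE_LEVELS = ("III unresectable", "IV M1a", "IV M1b", "IV M1c", "IV M1d")
STAGE_CODES = {label: i + 1 for i, label in enumerate(STAGE_LEVELS)}

COHORT_COLUMNS = [
    "patient_id", "centre", "sex", "age", "bmi", "metastatic_stage", "ecog",
    "ldh_elevated", "braf_mutant", "treatment", "responder",
    "pfs_time", "pfs_event", "os_time", "os_event",
]

SAMPLE_COLUMNS = ["sample_id", "patient_id", "days_from_treatment_start"]


# ---------------------------------------------------------------------------
# protein matrices
# ---------------------------------------------------------------------------

def read_protein_matrix(path, lod_path, scale_tag=RELATIVE_LOG2, sep=",") -> ProteinMatrix:
    """Read a wide sample-by-protein table plus its LOD map.

    First column of `path` is the sample id; remaining columns are proteins.
    `lod_path` has two columns: protein_id, lod.  Empty cells become masked
    (NaN) values.  Duplicate ids and proteins absent from the LOD file are
    hard errors.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate sample id in {path}: {dup!r}")
    lod_tab = pd.read_csv(lod_path, sep=sep, float_precision="round_trip")
    lod_tab.columns = ["protein_id", "lod"][: len(lod_tab.columns)]
    lod = lod_tab.set_index("protein_id")["lod"]
    lod.index = lod.index.astype(str)
    m = ProteinMatrix(raw, lod, scale_tag)
    log.info("read matrix: %d samples x %d proteins (%s)",
             m.n_samples, m.n_proteins, scale_tag)
    return m


def write_protein_matrix(m: ProteinMatrix, path, lod_path, sep=",") -> None:
    """Write matrix and LOD map; masked cells become empty fields."""
    m.values.to_csv(path, sep=sep, index_label="sample_id")
    m.lod.rename("lod").to_csv(lod_path, sep=sep, index_label="protein_id")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

def _as_bool(s: pd.Series, name: str) -> pd.Series:
    if s.dtype == bool:
        return s
    mapped = s.map({"True": True, "False": False, True: True, False: False,
                    1: True, 0: False, "1": True, "0": False})
    if mapped.isna().any():
        bad = s[mapped.isna()].iloc[0]
        raise ValueError(f"invalid boolean value {bad!r} in column {name}")
    return mapped.astype(bool)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Type-check and validate a cohort table; returns a typed copy."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    out = df.copy()
    out["patient_id"] = out["patient_id"].astype(str)
    if out["patient_id"].duplicated().any():
        dup = out.loc[out["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValueError(f"duplicate patient id: {dup!r}")
    bad_sex = set(out["sex"]) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"unknown sex label: {bad_sex.pop()!r}")
    unknown = set(out["metastatic_stage"]) - set(STAGE_LEVELS)
    if unknown:
        raise ValueError(f"unknown metastatic stage label: {unknown.pop()!r}")
    out["stage_code"] = out["metastatic_stage"].map(STAGE_CODES).astype(int)
    out["ecog"] = out["ecog"].astype(int)
    if not out["ecog"].isin([0, 1, 2, 3]).all():
        raise ValueError("ECOG must be in {0,1,2,3}")
    for col in ("ldh_elevated", "braf_mutant", "responder", "pfs_event", "os_event"):
        out[col] = _as_bool(out[col], col)
    for col in ("age", "bmi", "pfs_time", "os_time"):
        out[col] = out[col].astype(float)
    if (out["pfs_time"] <= 0).any() or (out["os_time"] <= 0).any():
        raise ValueError("survival times must be strictly positive")
    viol = out["pfs_time"] > out["os_time"]
    if viol.any():
        pid = out.loc[viol, "patient_id"].iloc[0]
        raise ValueError(f"pfs_time > os_time for patient {pid!r}")
    return out


def read_cohort(path, sep=",") -> pd.DataFrame:
    """Read and validate the per-patient clinical table."""
    df = pd.read_csv(path, sep=sep)
    cohort = validate_cohort(df)
    log.info("read cohort: %d patients, centres %s",
             len(cohort), dict(cohort["centre"].value_counts()))
    return cohort


def write_cohort(cohort: pd.DataFrame, path, sep=",") -> None:
    cohort[COHORT_COLUMNS].to_csv(path, sep=sep, index=False)


def read_samples(path, sep=",") -> pd.DataFrame:
    """Read per-sample metadata (sample_id, patient_id, day)."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["patient_id"] = df["patient_id"].astype(str)
    df["days_from_treatment_start"] = df["days_from_treatment_start"].astype(int)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    return df


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def overall_response_rate(cohort: pd.DataFrame) -> float:
    """ORR as a percentage rounded to one decimal place."""
    return round(100.0 * cohort["responder"].sum() / len(cohort), 1)


def _median_iqr(x: pd.Series) -> str:
    q1, med, q3 = np.nanpercentile(x.astype(float), [25, 50, 75])
    return f"{med:.1f} [{q1:.1f}-{q3:.1f}]"


def summarise_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary: median/IQR for continuous variables, count and
    percentage (one decimal) for categorical, overall and per centre.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    groups = {"All": cohort}
    for centre, sub in cohort.groupby("centre", observed=True):
        groups[str(centre)] = sub
    rows = []

    def add(variable, level, fmt):
        row = {"variable": variable, "level": level}
        for name, sub in groups.items():
            row[name] = fmt(sub)
        rows.append(row)

    add("n", "", lambda s: f"{len(s)}")
    for var in ("age", "bmi"):
        add(var, "median [IQR]", lambda s, v=var: _median_iqr(s[v]))
    categorical = {
        "sex": lambda s: s["sex"],
        "metastatic_stage": lambda s: s["metastatic_stage"],
        "ecog": lambda s: s["ecog"].astype(str),
        "ldh_elevated": lambda s: s["ldh_elevated"].map({True: "elevated", False: "normal"}),
        "braf_mutant": lambda s: s["braf_mutant"].map({True: "mutant", False: "wild-type"}),
        "treatment": lambda s: s["treatment"],
        "responder": lambda s: s["responder"].map({True: "responder", False: "non-responder"}),
    }
    for var, getter in categorical.items():
        levels = sorted(getter(cohort).unique())
        for level in levels:
            def fmt(s, getter=getter, level=level):
                n = (getter(s) == level).sum()
                pct = 100.0 * n / len(s) if len(s) else 0.0
                return f"{n} ({pct:.1f}%)"
            add(var, str(level), fmt)
    add("ORR", "%", lambda s: f"{overall_response_rate(s):.1f}%")
    return pd.DataFrame(rows)
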