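"""Shared fixtures: a default synthetic cohort and its QC'd matrices."""

import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from inflamark import pipeline as pl
from inflamark.config import AnalysisConfig
from inflamark.simulate import SimulationConfig, generate_cohort

logging.getLogger("inflamark").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message=".*Perfect separation.*")


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SimulationConfig(rng_seed=1))


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig(rng_seed=1)


@pytest.fixture(scope="session")
def qc_matrices(default_cohort, analysis_config):
    baseline, followups, report = pl.qc_stage(default_cohort, analysis_config)
    return baseline, followups, report


def tiny_cohort_frame(n=8, centre="UK", responders=None):
    """Minimal valid cohort table for unit tests."""
    if responders is None:
        responders = [i % 2 == 0 for i in range(n)]
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "centre": centre,
        "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
        "age": 60.0,
        "bmi": 27.0,
        "metastatic_stage": "IV M1c",
        "ecog": 0,
        "ldh_elevated": False,
        "braf_mutant": False,
        "treatment": "nivolumab",
        "responder": responders,
        "pfs_time": 100.0,
        "pfs_event": True,
        "os_time": 200.0,
        "os_event": True,
    })
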