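"""Analysis configuration: QC thresholds, window bounds, permutation counts."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    Attributes
    ----------
    lod_max_below_fraction : float
        Proteins with a strictly greater fraction of values below the LOD
        are discarded (default 0.25, i.e. the ">25% of samples" rule).
    outlier_sd_threshold : float
        Values further than this many SDs from the protein mean are masked
        (default 4; Chebyshev bounds the masked fraction at 1/16).
    early_window_days, late_window_days : tuple[int, int]
        Inclusive day ranges after treatment start for the early (2-5 wk)
        and late (5-12 wk) follow-up windows.
    window_midpoints_days : tuple[int, int]
        Target days (3 and 9 weeks); within a window the sample closest to
        the midpoint is kept.
    n_perm_auc, n_perm_mpt, n_bootstrap : int
        Monte-Carlo sizes for the permutation AUC test, the multivariate
        permutation tests, and bootstrap confidence intervals.
    alpha : float
        Nominal significance level.
    rng_seed : int
        Seed for every stochastic step.
    """

    lod_max_below_fraction: float = 0.25
    outlier_sd_threshold: float = 4.0
    early_window_days: tuple = (14, 34)
    late_window_days: tuple = (35, 84)
    window_midpoints_days: tuple = (21, 63)
    n_perm_auc: int = 1000
    n_perm_mpt: int = 5000
    n_bootstrap: int = 1000
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lod_max_below_fraction < 1.0:
            raise ValueError("lod_max_below_fraction must be in (0, 1)")
        if self.outlier_sd_threshold <= 0:
            raise ValueError("outlier_sd_threshold must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("n_perm_auc", "n_perm_mpt", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        self.early_window_days = tuple(self.early_window_days)
        self.late_window_days = tuple(self.late_window_days)
        self.window_midpoints_days = tuple(self.window_midpoints_days)
        e0, e1 = self.early_window_days
        l0, l1 = self.late_window_days
        if not (e0 <= e1 < l0 <= l1):
            raise ValueError("follow-up windows must be ordered and non-overlapping")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
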