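"""Sample-by-protein abundance matrix with per-protein detection limits.

The central array of the pipeline.  Values are stored in a pandas DataFrame
(rows = samples, columns = proteins); masked cells — assay failures, values
removed by QC — are NaN and are excluded from every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Relative abundance on the log2 scale (NPX-like units).
RELATIVE_LOG2 = "relative_log2"
#: Absolute concentration in pg/mL.
ABSOLUTE_PG_ML = "absolute_pg_ml"

SCALE_TAGS = (RELATIVE_LOG2, ABSOLUTE_PG_ML)


@dataclass
class ProteinMatrix:
    """Samples x proteins abundance values with per-protein LOD.

    Parameters
    ----------
    values : pandas.DataFrame
        Abundance values; index = sample ids, columns = protein ids.
        NaN marks a masked (missing or removed) cell.
    lod : pandas.Series
        Lower detection limit per protein, same units as ``values``;
        index must cover every protein column.
    scale_tag : str
        Either ``"relative_log2"`` or ``"absolute_pg_ml"``; LOD comparisons
        are only meaningful when matrix and LOD share this scale.
    """

    values: pd.DataFrame
    lod: pd.Series
    scale_tag: str = RELATIVE_LOG2

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate protein id: {dup!r}")
        missing = [p for p in self.values.columns if p not in self.lod.index]
        if missing:
            raise ValueError(f"protein missing from LOD table: {missing[0]!r}")
        # keep lod aligned to the column order; normalise axis names
        self.lod = self.lod.loc[self.values.columns].astype(float)
        self.values = self.values.astype(float)
        self.values.index.name = None
        self.values.columns.name = None
        self.lod.name = None
        self.lod.index.name = None

    # -- basic introspection -------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the cell is masked/missing."""
        return self.values.isna()

    # -- manipulation --------------------------------------------------------

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(self.values.copy(), self.lod.copy(), self.scale_tag)

    def select_proteins(self, protein_ids) -> "ProteinMatrix":
        return ProteinMatrix(
            self.values.loc[:, list(protein_ids)].copy(),
            self.lod.loc[list(protein_ids)].copy(),
            self.scale_tag,
        )

    def select_samples(self, sample_ids) -> "ProteinMatrix":
        return ProteinMatrix(
            self.values.loc[list(sample_ids)].copy(), self.lod.copy(), self.scale_tag
        )

    def below_lod_fraction(self) -> pd.Series:
        """Per-protein fraction of unmasked values strictly below the LOD."""
        below = self.values.lt(self.lod, axis=1)
        n_obs = self.values.notna().sum(axis=0)
        frac = below.sum(axis=0) / n_obs.replace(0, np.nan)
        return frac.fillna(0.0)

    def concat_samples(self, other: "ProteinMatrix") -> "ProteinMatrix":
        """Stack another matrix's samples (same proteins, same scale)."""
        if list(other.values.columns) != list(self.values.columns):
            raise ValueError("protein sets differ")
        if other.scale_tag != self.scale_tag:
            raise ValueError("scale tags differ")
        return ProteinMatrix(
            pd.concat([self.values, other.values], axis=0), self.lod.copy(), self.scale_tag
        )
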