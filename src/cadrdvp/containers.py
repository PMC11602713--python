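"""Core in-memory containers for the proteomic pipeline.

The central object is :class:`IntensityMatrix`: a proteins x samples grid of
(log2) protein-group intensities with per-sample metadata. Missing values are
``NaN`` throughout; a ``scale`` flag records whether values are raw, log2, or
z-scored, and a free-form ``meta`` dict carries provenance (applied steps,
parameter conventions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import ValidationError

SCALE_RAW = "raw"
SCALE_LOG2 = "log2"
SCALE_ZSCORE = "zscore"

#: metadata columns required on every sample table
SAMPLE_COLUMNS = ("individual", "cohort", "cell_type", "replicate")

LOG2_RANGE = (0.0, 60.0)  # plausible log2 intensity range for MS data


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity grid with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein/gene-group id with one column per
        sample id. Missing entries are NaN.
    samples
        DataFrame indexed by sample id with columns ``individual``,
        ``cohort``, ``cell_type``, ``replicate`` (and optionally
        ``spatial`` for attached/detached keratinocytes).
    scale
        One of ``raw``, ``log2``, ``zscore``.
    meta
        Provenance: applied processing steps and their parameters.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = SCALE_LOG2
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in (SCALE_RAW, SCALE_LOG2, SCALE_ZSCORE):
            raise ValidationError(f"unknown scale flag {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValidationError(f"sample metadata lacks columns {missing_cols}")
        if set(self.values.columns) != set(self.samples.index):
            extra = set(self.values.columns) - set(self.samples.index)
            absent = set(self.samples.index) - set(self.values.columns)
            raise ValidationError(
                f"sample ids of grid and metadata disagree "
                f"(grid-only: {sorted(extra)[:5]}, meta-only: {sorted(absent)[:5]})"
            )
        if self.scale == SCALE_LOG2:
            finite = self.values.to_numpy(dtype=float)
            finite = finite[np.isfinite(finite)]
            lo, hi = LOG2_RANGE
            if finite.size and (finite.min() <= lo or finite.max() >= hi):
                raise ValidationError(
                    f"log2 intensities outside plausible range {LOG2_RANGE}: "
                    f"[{finite.min():.3g}, {finite.max():.3g}]"
                )

    # -- convenience -------------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def observed_mask(self) -> pd.DataFrame:
        """Boolean grid: True where a value was measured."""
        return self.values.notna()

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_samples(self, sample_ids) -> "IntensityMatrix":
        sample_ids = list(sample_ids)
        return IntensityMatrix(
            values=self.values[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
            scale=self.scale,
            meta=dict(self.meta),
        )

    def subset_cell_type(self, cell_type: str) -> "IntensityMatrix":
        ids = self.samples.index[self.samples["cell_type"] == cell_type]
        if len(ids) == 0:
            raise ValidationError(f"no samples of cell type {cell_type!r}")
        return self.subset_samples(ids)

    def subset_proteins(self, protein_ids) -> "IntensityMatrix":
        protein_ids = list(protein_ids)
        return IntensityMatrix(
            values=self.values.loc[protein_ids].copy(),
            samples=self.samples.copy(),
            scale=self.scale,
            meta=dict(self.meta),
        )

    def with_values(self, values: pd.DataFrame, scale: str | None = None,
                    **meta_updates) -> "IntensityMatrix":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return IntensityMatrix(
            values=values,
            samples=self.samples.loc[list(values.columns)].copy(),
            scale=self.scale if scale is None else scale,
            meta=meta,
        )

    def record_step(self, step: str, **params) -> None:
        # copy-on-write: history lists are shared after with_values/subset
        history = list(self.meta.get("history", []))
        history.append({"step": step, **params})
        self.meta["history"] = history

    def group_sample_ids(self, **selectors) -> pd.Index:
        """Sample ids matching all (column == value) selectors."""
        mask = pd.Series(True, index=self.samples.index)
        for col, val in selectors.items():
            mask &= self.samples[col] == val
        return self.samples.index[mask]
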