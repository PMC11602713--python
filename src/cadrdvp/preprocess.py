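"""Pre-statistics transformations of the intensity matrix.

The processing order mirrors the analysis workflow for cell-type-resolved
DIA data: log2 transform, replicate averaging per individual and cell type,
70%-identification-rate filtering per cell type, downshifted-Gaussian
imputation (only for PCA / clustering style analyses), and per-protein
z-scoring for display and clustering. Hypothesis tests elsewhere in the
package run on non-imputed, available-case data.

Each step is an sklearn-style transformer (``fit``/``transform``,
``get_params``) operating on :class:`~cadrdvp.containers.IntensityMatrix`;
the module-level functions are thin one-shot wrappers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._rng import stream
from .containers import SCALE_LOG2, SCALE_RAW, SCALE_ZSCORE, IntensityMatrix
from .errors import ValidationError

__all__ = [
    "Log2Transformer",
    "ReplicateAverager",
    "IdentificationRateFilter",
    "GaussianImputer",
    "ProteinZScorer",
    "log2_transform",
    "average_replicates",
    "filter_by_identification_rate",
    "impute_gaussian",
    "zscore",
]


class Log2Transformer(TransformerMixin, BaseEstimator):
    """Log2-transform a raw-scale matrix; missing entries stay missing."""

    def fit(self, X: IntensityMatrix, y=None):
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        if X.scale != SCALE_RAW:
            raise ValidationError(f"log2 transform expects raw scale, got {X.scale!r}")
        vals = X.values.to_numpy(dtype=float)
        bad = np.isfinite(vals) & (vals <= 0)
        if bad.any():
            offenders = [
                (X.protein_ids[i], X.sample_ids[j])
                for i, j in zip(*np.nonzero(bad))
            ][:10]
            raise ValidationError(
                f"nonpositive observed intensities cannot be log2-transformed: "
                f"{offenders}")
        out = X.with_values(pd.DataFrame(np.log2(vals), index=X.values.index,
                                         columns=X.values.columns),
                            scale=SCALE_LOG2)
        out.record_step("log2_transform")
        return out


class ReplicateAverager(TransformerMixin, BaseEstimator):
    """Average biological replicates per (individual, cell type).

    The mean is over replicates with an observed value (available-case); a
    protein missing in every replicate stays missing.
    """

    def fit(self, X: IntensityMatrix, y=None):
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        if X.scale != SCALE_LOG2:
            raise ValidationError("replicate averaging expects log2 scale")
        keys = ["individual", "cell_type"]
        if "spatial" in X.samples.columns:
            keys.append("spatial")
        groups = X.samples.groupby(keys, sort=False, dropna=False)
        cols, meta_rows = {}, []
        for key, members in groups.groups.items():
            key = key if isinstance(key, tuple) else (key,)
            sample_id = "_".join(str(k) for k in key)
            cols[sample_id] = X.values[list(members)].mean(axis=1)
            row = dict(zip(keys, key))
            row["cohort"] = X.samples.loc[members[0], "cohort"]
            row["replicate"] = 0
            row["sample_id"] = sample_id
            row["n_replicates"] = len(members)
            meta_rows.append(row)
        values = pd.DataFrame(cols)
        values.index.name = X.values.index.name
        samples = pd.DataFrame(meta_rows).set_index("sample_id")
        out = IntensityMatrix(values=values, samples=samples, scale=X.scale,
                              meta=dict(X.meta))
        out.record_step("average_replicates")
        return out


class IdentificationRateFilter(TransformerMixin, BaseEstimator):
    """Keep proteins identified in >= ``min_rate`` of samples of some cohort.

    The rule is evaluated per cell type independently on the replicate-level
    columns: a protein is retained for a cell type iff its observed fraction
    reaches ``min_rate`` in at least one cohort within that cell type. On a
    joint multi-cell-type matrix, blocks failing the rule are masked to
    missing and rows failing everywhere are dropped; the per-cell-type keep
    table is stored in ``meta['identification_keep']`` and, after ``fit``, in
    the ``keep_`` attribute.
    """

    def __init__(self, min_rate: float = 0.70):
        self.min_rate = min_rate

    def fit(self, X: IntensityMatrix, y=None):
        if not 0 < self.min_rate <= 1:
            raise ValidationError(f"min_rate must be in (0, 1], got {self.min_rate}")
        keep = {}
        observed = X.observed_mask()
        for cell_type in X.samples["cell_type"].unique():
            ct_samples = X.samples[X.samples["cell_type"] == cell_type]
            best_rate = pd.Series(0.0, index=X.protein_ids)
            for cohort, members in ct_samples.groupby("cohort").groups.items():
                if len(members) == 0:
                    raise ValidationError(
                        f"cohort {cohort!r} has no samples in cell type {cell_type!r}")
                rate = observed[list(members)].mean(axis=1)
                best_rate = np.maximum(best_rate, rate)
            keep[cell_type] = best_rate >= self.min_rate
        self.keep_ = pd.DataFrame(keep)
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        keep = self.keep_
        values = X.values.copy()
        for cell_type in keep.columns:
            cols = X.group_sample_ids(cell_type=cell_type)
            failed = keep.index[~keep[cell_type]]
            values.loc[failed, cols] = np.nan
        retained = keep.any(axis=1)
        values = values.loc[retained[retained].index]
        out = X.with_values(values, identification_keep=keep)
        out.record_step("filter_by_identification_rate", min_rate=self.min_rate)
        return out


class GaussianImputer(TransformerMixin, BaseEstimator):
    """Downshifted-Gaussian imputation of left-censored missing values.

    For each sample column with observed mean mu and standard deviation
    sigma (ddof=1), missing entries are drawn i.i.d. from

        Normal(mu - downshift * sigma, (width * sigma)^2),

    the classic Perseus-style treatment of MNAR dropout in DIA data.
    Defaults: width 0.3, downshift 1.8. Only previously missing cells are
    altered. Applied per averaged sample column, i.e. per individual and
    cell type.
    """

    def __init__(self, width: float = 0.3, downshift: float = 1.8,
                 random_state: int = 0):
        self.width = width
        self.downshift = downshift
        self.random_state = random_state

    def fit(self, X: IntensityMatrix, y=None):
        if self.width <= 0:
            raise ValidationError(f"width must be > 0, got {self.width}")
        if self.downshift < 0:
            raise ValidationError(f"downshift must be >= 0, got {self.downshift}")
        n_obs = X.observed_mask().sum(axis=0)
        starved = n_obs[n_obs < 2]
        if len(starved):
            raise ValidationError(
                f"samples with < 2 observed values (sd undefined): "
                f"{list(starved.index)[:5]}")
        self.means_ = X.values.mean(axis=0)
        self.sds_ = X.values.std(axis=0, ddof=1)
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        rng = stream(self.random_state, "gaussian_imputer")
        values = X.values.copy()
        for sample_id in values.columns:
            col = values[sample_id]
            missing = col.isna()
            if not missing.any():
                continue
            mu = self.means_[sample_id] - self.downshift * self.sds_[sample_id]
            sd = self.width * self.sds_[sample_id]
            values.loc[missing, sample_id] = rng.normal(mu, sd, int(missing.sum()))
        out = X.with_values(values, imputation={"width": self.width,
                                                "downshift": self.downshift,
                                                "sd_ddof": 1})
        out.record_step("impute_gaussian", width=self.width,
                        downshift=self.downshift, seed=self.random_state)
        return out


class ProteinZScorer(TransformerMixin, BaseEstimator):
    """Zero-centre and scale each protein row (population sd by default)."""

    def __init__(self, ddof: int = 0):
        self.ddof = ddof

    def fit(self, X: IntensityMatrix, y=None):
        if X.values.isna().any().any():
            raise ValidationError(
                "z-scoring requires a complete matrix; impute first")
        self.means_ = X.values.mean(axis=1)
        self.sds_ = X.values.std(axis=1, ddof=self.ddof)
        flat = self.sds_[self.sds_ == 0]
        if len(flat):
            raise ValidationError(
                f"zero-variance proteins cannot be scaled: {list(flat.index)[:10]}")
        return self

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        values = X.values.sub(self.means_, axis=0).div(self.sds_, axis=0)
        out = X.with_values(values, scale=SCALE_ZSCORE, zscore_ddof=self.ddof)
        out.record_step("zscore", ddof=self.ddof)
        return out


# -- one-shot functional wrappers ------------------------------------------

def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    return Log2Transformer().fit_transform(matrix)


def average_replicates(matrix: IntensityMatrix) -> IntensityMatrix:
    return ReplicateAverager().fit_transform(matrix)


def filter_by_identification_rate(matrix: IntensityMatrix,
                                  min_rate: float = 0.70) -> IntensityMatrix:
    return IdentificationRateFilter(min_rate=min_rate).fit_transform(matrix)


def impute_gaussian(matrix: IntensityMatrix, width: float = 0.3,
                    downshift: float = 1.8, random_state: int = 0
                    ) -> IntensityMatrix:
    return GaussianImputer(width=width, downshift=downshift,
                           random_state=random_state).fit_transform(matrix)


def zscore(matrix: IntensityMatrix, ddof: int = 0) -> IntensityMatrix:
    return ProteinZScorer(ddof=ddof).fit_transform(matrix)
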