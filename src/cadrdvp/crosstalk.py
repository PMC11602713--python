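"""Directional cell-cell interaction scoring across disease conditions.

The procedure works on a joint matrix over two (or more) cell types:

1. keep proteins with fewer than 30% missing values (strict),
2. impute the remainder with chained-equations iterative imputation using a
   nonlinear (random-forest) regressor,
3. gate proteins by a one-way ANOVA over the condition x cell-type groups
   (p < 0.01) plus at least five Tukey-significant pairwise comparisons
   (adjusted p < 0.05),
4. average expression by (condition, cell type),
5. for every directed interaction source -> target matched by gene name and
   every ordered cell-type pair, compute the intensity difference
   Delta = I(source gene, source cell type) - I(target gene, target cell type)
   per condition, and the disease-specificity score
   D = Delta_condition - Delta_reference (reference: healthy).

Positive D flags directional signalling gained in disease; by construction
D of the mirrored direction is exactly -D, and the default keep rule
retains records with D > 0 only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .containers import IntensityMatrix
from .diffexp import anova_tukey
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CrosstalkConfig",
    "CrosstalkImputer",
    "crosstalk_filter",
    "crosstalk_impute",
    "crosstalk_gate",
    "condition_average",
    "score_interactions",
    "run_crosstalk",
]


@dataclass
class CrosstalkConfig:
    """Thresholds of the interaction-screen gating and scoring steps."""

    max_missing_fraction: float = 0.30
    anova_p_cut: float = 0.01
    tukey_alpha: float = 0.05
    min_significant_pairs: int = 5
    imputer_seed: int = 0
    keep_rule: str = "delta_gt_zero"
    reference: str = "healthy"

    def validate(self) -> None:
        for name in ("max_missing_fraction", "anova_p_cut", "tukey_alpha"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.min_significant_pairs < 0:
            raise ValidationError("min_significant_pairs must be >= 0")
        if self.keep_rule not in ("delta_gt_zero", "all"):
            raise ValidationError(f"unknown keep_rule {self.keep_rule!r}")


def crosstalk_filter(matrix: IntensityMatrix,
                     max_missing: float = 0.30) -> IntensityMatrix:
    """Keep proteins with missing fraction strictly below ``max_missing``."""
    frac = matrix.values.isna().mean(axis=1)
    keep = frac < max_missing
    if not keep.any():
        raise ValidationError(
            f"no protein has missing fraction < {max_missing}")
    out = matrix.subset_proteins(keep[keep].index)
    out.record_step("crosstalk_filter", max_missing=max_missing,
                    n_dropped=int((~keep).sum()))
    return out


class CrosstalkImputer(TransformerMixin, BaseEstimator):
    """Chained-equations imputation with a random-forest regressor.

    Each sample column is regressed on the other columns over proteins
    (IterativeImputer round-robin, max 10 rounds, tolerance 1e-3 on mean
    absolute change). Observed cells are never altered, and imputed values
    are clipped to the observed range of their protein row widened by 20%
    of that range. Deterministic given ``random_state``.
    """

    def __init__(self, random_state: int = 0, n_estimators: int = 30,
                 max_iter: int = 10, tol: float = 1e-3, estimator=None):
        self.random_state = random_state
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.tol = tol
        self.estimator = estimator

    def fit_transform(self, X: IntensityMatrix, y=None) -> IntensityMatrix:
        n_obs = X.observed_mask().sum(axis=0)
        starved = n_obs[n_obs < 2]
        if len(starved):
            raise ValidationError(
                f"samples with < 2 observed values: {list(starved.index)[:5]}")
        values = X.values
        if not values.isna().any().any():
            out = X.with_values(values.copy())
            out.record_step("crosstalk_impute", random_state=self.random_state,
                            n_imputed=0)
            return out
        estimator = self.estimator
        if estimator is None:
            estimator = RandomForestRegressor(
                n_estimators=self.n_estimators,
                random_state=self.random_state)
        imputer = IterativeImputer(estimator=estimator, max_iter=self.max_iter,
                                   tol=self.tol, sample_posterior=False,
                                   random_state=self.random_state,
                                   keep_empty_features=True)
        filled = imputer.fit_transform(values.to_numpy(dtype=float))
        filled = pd.DataFrame(filled, index=values.index, columns=values.columns)
        # contract: imputed values stay near the protein's observed range
        row_min = values.min(axis=1)
        row_max = values.max(axis=1)
        margin = 0.2 * (row_max - row_min)
        filled = filled.clip(lower=row_min - margin, upper=row_max + margin,
                             axis=0)
        mask = values.notna()
        filled = filled.where(~mask, values)
        out = X.with_values(filled)
        out.record_step("crosstalk_impute", random_state=self.random_state,
                        n_imputed=int((~mask).to_numpy().sum()))
        return out

    def transform(self, X: IntensityMatrix) -> IntensityMatrix:
        return self.fit_transform(X)

    def fit(self, X: IntensityMatrix, y=None):
        return self


def crosstalk_impute(matrix: IntensityMatrix, seed: int = 0,
                     **kwargs) -> IntensityMatrix:
    return CrosstalkImputer(random_state=seed, **kwargs).fit_transform(matrix)


def crosstalk_gate(matrix: IntensityMatrix, groups=None,
                   config: CrosstalkConfig | None = None) -> pd.Index:
    """Proteins passing the joint ANOVA + Tukey gate.

    Groups default to the condition x cell-type cells of the design. A
    protein is retained iff its one-way ANOVA p is below ``anova_p_cut``
    and at least ``min_significant_pairs`` Tukey-adjusted pairwise
    comparisons fall below ``tukey_alpha``.

    The matrix is expected to be complete (post-imputation), which lets the
    Tukey condition be evaluated against a single studentized-range critical
    value q_crit = ppf(1 - tukey_alpha; k, N - k) instead of per-pair
    p-values; this is exactly equivalent to comparing each adjusted p with
    ``tukey_alpha``. Incomplete matrices fall back to the per-protein
    available-case route.
    """
    config = config or CrosstalkConfig()
    config.validate()
    if groups is None:
        key = matrix.samples["cohort"] + "|" + matrix.samples["cell_type"]
        groups = {lab: list(matrix.samples.index[key == lab])
                  for lab in dict.fromkeys(key)}
    if len(groups) < 2:
        raise ValidationError("crosstalk gate needs >= 2 groups")

    if matrix.values.isna().any().any():
        result = anova_tukey(matrix, groups=groups)
        kept = []
        for protein, row in result.table.iterrows():
            if row["p_value"] >= config.anova_p_cut:
                continue
            n_sig = int(
                (result.tukey[protein]["p_adj"] < config.tukey_alpha).sum())
            if n_sig >= config.min_significant_pairs:
                kept.append(protein)
        return pd.Index(kept, name="protein")

    # vectorized complete-matrix path
    from scipy import stats

    blocks = [matrix.values[list(ids)].to_numpy(dtype=float)
              for ids in groups.values()]
    ns = np.array([b.shape[1] for b in blocks])
    if (ns < 2).any():
        raise ValidationError("every group needs >= 2 samples")
    k = len(blocks)
    total_n = int(ns.sum())
    df_within = total_n - k
    means = np.column_stack([b.mean(axis=1) for b in blocks])
    sse = sum(((b - m[:, None]) ** 2).sum(axis=1)
              for b, m in zip(blocks, means.T))
    grand = sum(b.sum(axis=1) for b in blocks) / total_n
    ssb = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ssb / (k - 1)) / (sse / df_within)
    p_anova = stats.f.sf(f_stat, k - 1, df_within)
    p_anova = np.where(sse == 0, np.where(ssb == 0, 1.0, 0.0), p_anova)

    q_crit = float(stats.studentized_range.ppf(1 - config.tukey_alpha, k,
                                               df_within))
    mse = sse / df_within
    n_sig = np.zeros(len(matrix.values), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
            with np.errstate(divide="ignore", invalid="ignore"):
                q_stat = np.abs(means[:, i] - means[:, j]) / se
            n_sig += np.where(se == 0,
                              means[:, i] != means[:, j], q_stat > q_crit)
    keep = (p_anova < config.anova_p_cut) & \
        (n_sig >= config.min_significant_pairs)
    return pd.Index(matrix.values.index[keep], name="protein")


def condition_average(matrix: IntensityMatrix) -> pd.DataFrame:
    """Mean log2 intensity per protein per (condition, cell type).

    Returns a DataFrame indexed by protein with MultiIndex columns
    (cohort, cell_type).
    """
    key = list(zip(matrix.samples["cohort"], matrix.samples["cell_type"]))
    cols = {}
    for combo in dict.fromkeys(key):
        members = [s for s, k in zip(matrix.samples.index, key) if k == combo]
        cols[combo] = matrix.values[members].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["cohort", "cell_type"])
    return out


def _first_gene(protein_id: str) -> str:
    return protein_id.split(";")[0]


def score_interactions(avg_table: pd.DataFrame, interactions: pd.DataFrame,
                       cell_type_pairs, conditions=None,
                       reference: str = "healthy",
                       keep_rule: str = "delta_gt_zero"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directional interaction deltas per condition and cell-type pair.

    Returns ``(scores, unmatched)``. Each score row carries
    Delta = I(source gene, source ct) - I(target gene, target ct) for its
    condition, and disease_delta D = Delta_condition - Delta_reference.
    ``kept`` marks records passing the keep rule (D > 0). Interactions whose
    genes are absent from the averaged table (for the respective cell type)
    are reported in ``unmatched``.
    """
    all_conditions = list(avg_table.columns.get_level_values("cohort").unique())
    if reference not in all_conditions:
        raise ValidationError(f"reference condition {reference!r} not in table")
    if conditions is None:
        conditions = [c for c in all_conditions if c != reference]
    gene_map: dict[tuple[str, str], float] = {}
    for protein in avg_table.index:
        gene = _first_gene(str(protein))
        if gene != protein:
            logger.debug("protein group %r matched by first gene %r",
                         protein, gene)
        for col in avg_table.columns:
            key = (gene, *col)
            if key in gene_map:
                logger.warning("ambiguous gene %r in %s; keeping first", gene, col)
                continue
            gene_map[key] = float(avg_table.loc[protein, col])

    records, unmatched = [], []
    for _, inter in interactions.iterrows():
        src, tgt = inter["source"], inter["target"]
        for src_ct, tgt_ct in cell_type_pairs:
            needed = [(src, reference, src_ct), (tgt, reference, tgt_ct)]
            for cond in conditions:
                needed += [(src, cond, src_ct), (tgt, cond, tgt_ct)]
            if any(key not in gene_map for key in needed):
                unmatched.append({"source": src, "target": tgt,
                                  "source_cell_type": src_ct,
                                  "target_cell_type": tgt_ct})
                continue
            delta_ref = gene_map[(src, reference, src_ct)] - \
                gene_map[(tgt, reference, tgt_ct)]
            for cond in conditions:
                delta = gene_map[(src, cond, src_ct)] - \
                    gene_map[(tgt, cond, tgt_ct)]
                disease_delta = delta - delta_ref
                records.append({
                    "source_gene": src, "target_gene": tgt,
                    "source_cell_type": src_ct, "target_cell_type": tgt_ct,
                    "condition": cond, "delta": delta,
                    "disease_delta": disease_delta,
                    "kept": bool(disease_delta > 0)
                    if keep_rule == "delta_gt_zero" else True,
                })
    scores = pd.DataFrame(records, columns=[
        "source_gene", "target_gene", "source_cell_type", "target_cell_type",
        "condition", "delta", "disease_delta", "kept"])
    return scores, pd.DataFrame(unmatched, columns=[
        "source", "target", "source_cell_type", "target_cell_type"])


def run_crosstalk(matrix: IntensityMatrix, interactions: pd.DataFrame,
                  cell_type_pairs=None, config: CrosstalkConfig | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter -> impute -> gate -> average -> score, end to end."""
    config = config or CrosstalkConfig()
    config.validate()
    filtered = crosstalk_filter(matrix, config.max_missing_fraction)
    imputed = crosstalk_impute(filtered, seed=config.imputer_seed)
    gated = imputed.subset_proteins(crosstalk_gate(imputed, config=config))
    averaged = condition_average(gated)
    if cell_type_pairs is None:
        cell_types = list(dict.fromkeys(matrix.samples["cell_type"]))
        cell_type_pairs = [(a, b) for a in cell_types for b in cell_types
                           if a != b]
    return score_interactions(averaged, interactions, cell_type_pairs,
                              reference=config.reference,
                              keep_rule=config.keep_rule)
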