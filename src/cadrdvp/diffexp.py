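"""Contrast statistics: t-tests with BH-FDR, ANOVA + Tukey HSD, clustering.

All tests run available-case on non-imputed log2 data. A differentially
expressed protein (DEP) is one with BH q below ``alpha`` and |log2 fold
change| at or beyond ``fc_cut`` (default 1, i.e. twofold). The log2 fold
change is the difference of group means of log2 intensities
(contrast minus reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import IntensityMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "benjamini_hochberg",
    "t_test_dep",
    "call_deps",
    "anova_tukey",
    "HierarchicalClusterer",
    "hierarchical_cluster",
]

MIN_GROUP_N = 2  # variance must be estimable


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_i = min over j with p_j >= p_i of (m * p_j / rank_j), clipped to 1.
    NaN entries are excluded from m and returned as NaN. Ties are resolved
    by a stable sort so the output is deterministic and order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        bad = pv[(pv < 0) | (pv > 1)]
        raise ValidationError(f"p-values outside [0, 1]: {bad[:5]}")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out[valid] = q
    return out


def _group_values(matrix: IntensityMatrix, selector) -> pd.DataFrame:
    """Columns of ``matrix`` selected by cohort label or explicit sample ids."""
    if isinstance(selector, str):
        ids = matrix.group_sample_ids(cohort=selector)
    else:
        ids = pd.Index(selector)
    if len(ids) == 0:
        raise ValidationError(f"empty group {selector!r}")
    return matrix.values[list(ids)]


@dataclass
class DEPResult:
    """Per-protein contrast table plus the thresholds used for calling."""

    table: pd.DataFrame  # log2fc, p_value, q_value, n_a, n_b, call
    contrast: str
    alpha: float = 0.05
    fc_cut: float = 1.0

    @property
    def counts(self) -> dict[str, int]:
        return {direction: int((self.table["call"] == direction).sum())
                for direction in ("up", "down", "ns")}

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["call"] != "ns"]


def t_test_dep(matrix: IntensityMatrix, group_a, group_b, *,
               paired: bool = False, equal_var: bool = True,
               alpha: float = 0.05, fc_cut: float = 1.0,
               contrast: str | None = None) -> DEPResult:
    """Per-protein two-sided t-test of ``group_a`` (contrast) vs ``group_b``.

    Student's pooled-variance test by default (``equal_var=False`` gives
    Welch). Groups are cohort labels or explicit sample-id lists. Proteins
    with fewer than two observations in either group get a missing p and are
    excluded from the BH m. ``paired=True`` matches samples by individual
    and tests the per-individual differences.
    """
    a = _group_values(matrix, group_a)
    b = _group_values(matrix, group_b)

    if paired:
        ind_a = matrix.samples.loc[a.columns, "individual"]
        ind_b = matrix.samples.loc[b.columns, "individual"]
        common = [i for i in ind_a.values if i in set(ind_b.values)]
        if len(common) < MIN_GROUP_N:
            raise ValidationError("paired test needs >= 2 matched individuals")
        a = a[[ind_a.index[ind_a == i][0] for i in common]]
        b = b[[ind_b.index[ind_b == i][0] for i in common]]
        diff = pd.DataFrame(a.to_numpy() - b.to_numpy(), index=a.index)
        n = diff.notna().sum(axis=1)
        mean_d = diff.mean(axis=1)
        sd_d = diff.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean_d / (sd_d / np.sqrt(n))
            p = 2 * stats.t.sf(np.abs(t), n - 1)
        p = pd.Series(np.where((n >= MIN_GROUP_N) & (sd_d > 0), p,
                               np.where(n >= MIN_GROUP_N, 1.0, np.nan)),
                      index=diff.index)
        log2fc = mean_d
        n_a = n_b = n
    else:
        n_a = a.notna().sum(axis=1)
        n_b = b.notna().sum(axis=1)
        mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
        var_a = a.var(axis=1, ddof=1)
        var_b = b.var(axis=1, ddof=1)
        log2fc = mean_a - mean_b
        with np.errstate(divide="ignore", invalid="ignore"):
            if equal_var:
                df = n_a + n_b - 2
                sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
                se = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
            else:
                se = np.sqrt(var_a / n_a + var_b / n_b)
                df = (var_a / n_a + var_b / n_b) ** 2 / (
                    (var_a / n_a) ** 2 / (n_a - 1)
                    + (var_b / n_b) ** 2 / (n_b - 1))
            t = log2fc / se
            p = 2 * stats.t.sf(np.abs(t), df)
        testable = (n_a >= MIN_GROUP_N) & (n_b >= MIN_GROUP_N)
        zero_spread = se == 0
        p = pd.Series(np.where(testable,
                               np.where(zero_spread,
                                        np.where(log2fc == 0, 1.0, 0.0), p),
                               np.nan),
                      index=a.index)

    table = pd.DataFrame({
        "log2fc": log2fc,
        "p_value": p,
        "q_value": benjamini_hochberg(p.to_numpy()),
        "n_a": n_a,
        "n_b": n_b,
    })
    name = contrast or f"{group_a}_vs_{group_b}"
    return call_deps(DEPResult(table=table, contrast=name), alpha=alpha,
                     fc_cut=fc_cut)


def call_deps(result: DEPResult, alpha: float = 0.05,
              fc_cut: float = 1.0) -> DEPResult:
    """Assign up/down/ns calls from q-values and the fold-change cut."""
    table = result.table.copy()
    if "q_value" not in table.columns:
        raise ValidationError("q_value column required; run BH first")
    sig = table["q_value"] < alpha
    call = np.where(sig & (table["log2fc"] >= fc_cut), "up",
                    np.where(sig & (table["log2fc"] <= -fc_cut), "down", "ns"))
    table["call"] = call
    return DEPResult(table=table, contrast=result.contrast, alpha=alpha,
                     fc_cut=fc_cut)


def tukey_pairwise(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Tukey-Kramer HSD adjusted p per group pair via the studentized range.

    For groups i, j with means m_i, m_j and pooled within-group mean square
    MSE on df = N - k:  q = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)),
    p_adj = sf of the studentized range distribution with k groups, df.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([np.mean(g) for g in groups])
    df = int(ns.sum()) - k
    mse = sum(((g - m) ** 2).sum() for g, m in zip(groups, means)) / df
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if mse == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[j]))
                q_stat = np.abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q_stat, k, df))
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "mean_diff": diff, "p_adj": p_adj})
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    table: pd.DataFrame                 # per protein: F, p_value, q_value
    tukey: dict[str, pd.DataFrame]      # protein -> pairwise records
    skipped: dict[str, str]             # protein -> reason

    def significant(self, alpha: float = 0.05) -> pd.Index:
        t = self.table
        return t.index[t["q_value"] < alpha]


def anova_tukey(matrix: IntensityMatrix, groups: dict[str, list] | str = "cohort",
                alpha: float = 0.05, scale: bool = False,
                tukey: bool = True) -> AnovaResult:
    """One-way fixed-effects ANOVA per protein, BH across proteins, Tukey HSD.

    ``groups`` is either a sample-metadata column name whose levels define
    the groups, or an explicit mapping label -> sample ids. Proteins with a
    degenerate group (fewer than two observations) are skipped with a
    logged reason. With ``scale=True`` each protein row is zero-centred and
    unit-scaled first (this leaves F and Tukey p unchanged; only the
    reported mean differences change units). ``tukey=False`` skips the
    (comparatively expensive) pairwise records when only the omnibus test
    is needed.
    """
    if isinstance(groups, str):
        col = groups
        labels = list(dict.fromkeys(matrix.samples[col]))
        groups = {lab: list(matrix.samples.index[matrix.samples[col] == lab])
                  for lab in labels}
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")

    rows, tukey_records, skipped = [], {}, {}
    labels = list(groups)
    for protein, row in matrix.values.iterrows():
        if scale:
            sd = row.std(ddof=0)
            if sd == 0 or np.isnan(sd):
                skipped[protein] = "zero variance"
                continue
            row = (row - row.mean()) / sd
        samples = [row[list(ids)].dropna().to_numpy() for ids in groups.values()]
        if any(len(g) < MIN_GROUP_N for g in samples):
            skipped[protein] = "group with < 2 observations"
            continue
        if all(np.ptp(g) == 0 for g in samples) and \
                np.ptp([g[0] for g in samples]) == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(*samples)
        rows.append({"protein": protein, "F": float(f_stat), "p_value": float(p)})
        if tukey:
            tukey_records[protein] = tukey_pairwise(samples, labels)
    if skipped:
        logger.info("anova_tukey skipped %d proteins: %s", len(skipped),
                    dict(list(skipped.items())[:5]))
    table = pd.DataFrame(rows).set_index("protein") if rows else pd.DataFrame(
        columns=["F", "p_value"])
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    return AnovaResult(table=table, tukey=tukey_records, skipped=skipped)


class HierarchicalClusterer(BaseEstimator):
    """Agglomerative clustering of z-scored protein profiles.

    Euclidean distance with average linkage, cut into ``n_clusters`` flat
    clusters. Labels are canonicalized to order of first appearance so the
    partition is deterministic.
    """

    def __init__(self, n_clusters: int = 3, method: str = "average",
                 metric: str = "euclidean"):
        self.n_clusters = n_clusters
        self.method = method
        self.metric = metric

    def fit(self, X: pd.DataFrame, y=None):
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if self.n_clusters > len(X):
            raise ValidationError(
                f"n_clusters={self.n_clusters} exceeds {len(X)} proteins")
        if np.isnan(X.to_numpy(dtype=float)).any():
            raise ValidationError("clustering input must be complete (imputed)")
        if self.n_clusters == len(X):
            raw = np.arange(1, len(X) + 1)
        else:
            Z = linkage(X.to_numpy(dtype=float), method=self.method,
                        metric=self.metric)
            raw = fcluster(Z, t=self.n_clusters, criterion="maxclust")
        relabel: dict[int, int] = {}
        canonical = np.empty(len(raw), dtype=int)
        for i, lab in enumerate(raw):
            canonical[i] = relabel.setdefault(lab, len(relabel) + 1)
        self.labels_ = pd.Series(canonical, index=X.index, name="cluster")
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(X).labels_


def hierarchical_cluster(zscored: IntensityMatrix | pd.DataFrame,
                         proteins=None, k: int = 3) -> pd.Series:
    """Cluster the given (significant) proteins of a z-scored matrix into k."""
    values = zscored.values if isinstance(zscored, IntensityMatrix) else zscored
    if proteins is not None:
        values = values.loc[list(proteins)]
    return HierarchicalClusterer(n_clusters=k).fit_predict(values)
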