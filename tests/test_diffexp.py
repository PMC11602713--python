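"""Contrast statistics against independent oracles and algebraic identities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cadrdvp.diffexp import (anova_tukey, benjamini_hochberg, call_deps,
                             hierarchical_cluster, t_test_dep, tukey_pairwise,
                             DEPResult)
from cadrdvp.errors import ValidationError
from tests.conftest import build_matrix, two_cohort_meta


def bh_bruteforce(p):
    """Literal definition: q_i = min over p_j >= p_i of m * p_j / rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / rank[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(candidates))
    return q


class TestBenjaminiHochberg:
    def test_single_p_is_its_own_q(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_m2(self):
        assert np.allclose(benjamini_hochberg([0.001, 0.5]), [0.002, 0.5])

    def test_all_ones_stay_ones(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_four_equal_spaced_ps_collapse(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_nan_excluded_from_m(self):
        q = benjamini_hochberg([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], benjamini_hochberg([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=200))
    def test_matches_bruteforce_definition(self, p):
        assert np.allclose(benjamini_hochberg(p), bh_bruteforce(p), atol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(0)
        p = rng.random(500)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(benjamini_hochberg(p), expected, atol=1e-12)


def student_t_oracle(a, b):
    """Textbook pooled-variance two-sample t-test."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


class TestTTestDep:
    def make(self, a_vals, b_vals):
        meta = two_cohort_meta(len(a_vals))
        # interleave: first len(a) healthy then len(b) TEN
        meta = ([(f"h{i}", f"h_ind{i}", "healthy", "keratinocyte", 1)
                 for i in range(len(a_vals))]
                + [(f"t{i}", f"t_ind{i}", "TEN", "keratinocyte", 1)
                   for i in range(len(b_vals))])
        return build_matrix([list(a_vals) + list(b_vals)], sample_meta=meta)

    def test_identical_groups_null(self):
        matrix = self.make([1, 2, 3], [1, 2, 3])
        dep = t_test_dep(matrix, "TEN", "healthy")
        assert dep.table["log2fc"].iloc[0] == 0.0
        assert dep.table["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_oracle(self):
        a, b = [14.0, 15.0, 16.0, 17.0], [10.0, 11.0, 12.0, 13.0]
        matrix = self.make(b, a)  # healthy=b, TEN=a
        dep = t_test_dep(matrix, "TEN", "healthy")
        t_exp, p_exp = student_t_oracle(a, b)
        se = dep.table.iloc[0]
        assert se["log2fc"] == pytest.approx(np.mean(a) - np.mean(b))
        assert se["p_value"] == pytest.approx(p_exp, abs=1e-10)
        # cross-check against scipy as a second, independent route
        assert se["p_value"] == pytest.approx(
            stats.ttest_ind(a, b).pvalue, abs=1e-12)

    def test_welch_option_matches_scipy(self):
        a, b = [10.0, 12.0, 19.0, 11.0], [9.0, 9.5, 10.0]
        matrix = self.make(b, a)
        dep = t_test_dep(matrix, "TEN", "healthy", equal_var=False)
        assert dep.table["p_value"].iloc[0] == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue, abs=1e-12)

    def test_small_groups_untestable_and_excluded_from_bh(self):
        meta = [("h1", "i1", "healthy", "keratinocyte", 1),
                ("h2", "i2", "healthy", "keratinocyte", 1),
                ("t1", "i3", "TEN", "keratinocyte", 1),
                ("t2", "i4", "TEN", "keratinocyte", 1)]
        values = [[10.0, 11.0, 14.0, 15.0],
                  [10.0, np.nan, 14.0, 15.0]]  # one healthy obs only
        dep = t_test_dep(build_matrix(values, sample_meta=meta),
                         "TEN", "healthy")
        assert np.isnan(dep.table["p_value"].iloc[1])
        assert np.isnan(dep.table["q_value"].iloc[1])
        assert dep.table["q_value"].iloc[0] == pytest.approx(
            dep.table["p_value"].iloc[0])  # m=1

    def test_paired_matches_scipy_ttest_rel(self):
        a = [10.0, 12.0, 14.0, 16.0]
        b = [11.0, 11.5, 15.0, 15.5]
        meta = ([(f"h{i}", f"ind{i}", "healthy", "keratinocyte", 1)
                 for i in range(4)]
                + [(f"t{i}", f"ind{i}", "TEN", "keratinocyte", 1)
                   for i in range(4)])
        matrix = build_matrix([b + a], sample_meta=meta)
        dep = t_test_dep(matrix, "TEN", "healthy", paired=True)
        assert dep.table["p_value"].iloc[0] == pytest.approx(
            stats.ttest_rel(a, b).pvalue, abs=1e-12)


class TestCallDeps:
    @pytest.mark.parametrize("q,fc,expected", [
        (0.01, 2.0, "up"),
        (0.01, 0.5, "ns"),    # below the fold cut
        (0.2, 3.0, "ns"),     # not significant
        (0.01, -2.0, "down"),
        (0.01, 1.0, "up"),    # cut is inclusive
    ])
    def test_call_rules(self, q, fc, expected):
        table = pd.DataFrame({"log2fc": [fc], "p_value": [q], "q_value": [q]})
        result = call_deps(DEPResult(table=table, contrast="x"))
        assert result.table["call"].iloc[0] == expected
        assert result.counts[expected] == 1


class TestAnovaTukey:
    def make_three_groups(self, g1, g2, g3):
        meta = []
        for label, vals in (("healthy", g1), ("MPR", g2), ("TEN", g3)):
            for i in range(len(vals)):
                meta.append((f"{label}{i}", f"{label}_i{i}", label,
                             "keratinocyte", 1))
        return build_matrix([list(g1) + list(g2) + list(g3)], sample_meta=meta)

    def test_equal_values_give_f_zero_p_one(self):
        matrix = self.make_three_groups([5, 5], [5, 5], [5, 5])
        res = anova_tukey(matrix, groups="cohort")
        assert res.table["F"].iloc[0] == 0.0
        assert res.table["p_value"].iloc[0] == 1.0

    def test_matches_independent_scipy_implementations(self):
        g1 = [10.1, 10.5, 9.9, 10.3, 10.2]
        g2 = [11.0, 11.4, 10.9, 11.2, 11.1]
        g3 = [12.5, 12.2, 12.8, 12.4, 12.6]
        matrix = self.make_three_groups(g1, g2, g3)
        res = anova_tukey(matrix, groups="cohort")
        f_exp, p_exp = stats.f_oneway(g1, g2, g3)
        assert res.table["F"].iloc[0] == pytest.approx(f_exp, rel=1e-12)
        # Tukey adjusted p against scipy's independent HSD implementation
        hsd = stats.tukey_hsd(g1, g2, g3)
        ours = res.tukey["P1"]
        for _, row in ours.iterrows():
            i = ["healthy", "MPR", "TEN"].index(row["group_a"])
            j = ["healthy", "MPR", "TEN"].index(row["group_b"])
            assert row["p_adj"] == pytest.approx(hsd.pvalue[i, j], abs=1e-8)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(10, 1, 5)
            b = rng.normal(11, 1, 6)
            meta = ([(f"h{i}", f"h{i}", "healthy", "keratinocyte", 1)
                     for i in range(5)]
                    + [(f"t{i}", f"t{i}", "TEN", "keratinocyte", 1)
                       for i in range(6)])
            matrix = build_matrix([np.concatenate([a, b])], sample_meta=meta)
            res = anova_tukey(matrix, groups="cohort")
            dep = t_test_dep(matrix, "TEN", "healthy")
            assert res.table["p_value"].iloc[0] == pytest.approx(
                dep.table["p_value"].iloc[0], abs=1e-10)
            t_stat = stats.ttest_ind(b, a).statistic
            assert res.table["F"].iloc[0] == pytest.approx(t_stat ** 2,
                                                           rel=1e-10)

    def test_degenerate_protein_skipped_with_reason(self):
        matrix = self.make_three_groups([5, 6], [7, 8], [9, 10])
        matrix.values.iloc[0, 0] = np.nan  # healthy group left with 1 obs
        res = anova_tukey(matrix, groups="cohort")
        assert "P1" in res.skipped


class TestHierarchicalCluster:
    def test_separated_blocks_recovered_exactly(self):
        rng = np.random.default_rng(1)
        block1 = rng.normal(0, 0.1, size=(10, 6)) + [1, 1, 1, -1, -1, -1]
        block2 = rng.normal(0, 0.1, size=(10, 6)) + [-1, -1, -1, 1, 1, 1]
        X = pd.DataFrame(np.vstack([block1, block2]),
                         index=[f"P{i}" for i in range(20)])
        labels = hierarchical_cluster(X, k=2)
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_k1_single_cluster_and_k_too_large(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)))
        assert hierarchical_cluster(X, k=1).nunique() == 1
        with pytest.raises(ValidationError):
            hierarchical_cluster(X, k=6)

    def test_row_permutation_gives_identical_partition(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(30, 5)),
                         index=[f"P{i}" for i in range(30)])
        labels = hierarchical_cluster(X, k=3)
        perm = rng.permutation(30)
        labels_perm = hierarchical_cluster(X.iloc[perm], k=3)
        # same partition: co-membership matrices agree
        for idx in X.index:
            for jdx in X.index:
                same_orig = labels[idx] == labels[jdx]
                same_perm = labels_perm[idx] == labels_perm[jdx]
                assert same_orig == same_perm
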