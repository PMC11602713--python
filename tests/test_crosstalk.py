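"""Interaction screen: filter/impute/gate steps and delta-score algebra."""

import numpy as np
import pandas as pd
import pytest

from cadrdvp.containers import IntensityMatrix
from cadrdvp.crosstalk import (CrosstalkConfig, condition_average,
                               crosstalk_filter, crosstalk_gate,
                               crosstalk_impute, score_interactions)
from cadrdvp.errors import ValidationError
from tests.conftest import build_matrix


def joint_meta(n_per_group, cohorts=("healthy", "TEN"),
               cell_types=("keratinocyte", "immune")):
    meta = []
    for cohort in cohorts:
        for ct in cell_types:
            for i in range(1, n_per_group + 1):
                meta.append((f"{cohort}_{ct}_{i}", f"{cohort}_i{i}",
                             cohort, ct, 1))
    return meta


class TestFilter:
    @pytest.mark.parametrize("n_missing,kept", [(0, True), (2, True),
                                                (3, False)])
    def test_strictly_below_thirty_percent(self, n_missing, kept):
        row = [20.0] * 10
        for i in range(n_missing):
            row[i] = np.nan
        anchor = [21.0] * 10  # keeps result non-empty in the dropped case
        meta = [(f"s{i}", f"i{i}", "healthy", "keratinocyte", 1)
                for i in range(1, 11)]
        matrix = build_matrix([row, anchor], sample_meta=meta)
        out = crosstalk_filter(matrix, max_missing=0.30)
        assert ("P1" in out.values.index) == kept


class TestImputer:
    def test_complete_matrix_is_identity(self):
        matrix = build_matrix(np.arange(12.0).reshape(3, 4) + 10,
                              sample_meta=joint_meta(1))
        out = crosstalk_impute(matrix, seed=0)
        assert out.values.equals(matrix.values)

    def test_additive_structure_recovered_from_holes(self):
        rng = np.random.default_rng(7)
        u = rng.normal(20, 2, size=150)          # protein abundances
        v = rng.normal(0, 0.5, size=12)          # sample offsets
        truth = u[:, None] + v[None, :]
        holes = rng.random(truth.shape) < 0.10
        values = np.where(holes, np.nan, truth)
        matrix = build_matrix(values, sample_meta=joint_meta(3))
        out = crosstalk_impute(matrix, seed=1, n_estimators=50)
        rmse = np.sqrt(np.mean((out.values.to_numpy()[holes]
                                - truth[holes]) ** 2))
        assert rmse <= 0.1 * truth.std()
        # observed cells untouched
        assert np.array_equal(out.values.to_numpy()[~holes], truth[~holes])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        values = rng.normal(20, 2, size=(40, 8))
        values[rng.random(values.shape) < 0.15] = np.nan
        matrix = build_matrix(values, sample_meta=joint_meta(2))
        a = crosstalk_impute(matrix, seed=5)
        b = crosstalk_impute(matrix, seed=5)
        assert a.values.equals(b.values)

    def test_imputed_values_stay_near_protein_range(self):
        rng = np.random.default_rng(3)
        values = rng.normal(20, 2, size=(60, 8))
        values[rng.random(values.shape) < 0.2] = np.nan
        matrix = build_matrix(values, sample_meta=joint_meta(2))
        out = crosstalk_impute(matrix, seed=0)
        lo = matrix.values.min(axis=1)
        hi = matrix.values.max(axis=1)
        margin = 0.2 * (hi - lo)
        assert (out.values.ge(lo - margin, axis=0)
                & out.values.le(hi + margin, axis=0)).all().all()


class TestGate:
    def build_gate_matrix(self, k_groups, elevated_groups, n=5, bump=5.0):
        rng = np.random.default_rng(0)
        meta, row = [], []
        for g in range(k_groups):
            cohort = f"cond{g}"
            for i in range(n):
                meta.append((f"g{g}_s{i}", f"g{g}_i{i}", cohort,
                             "keratinocyte", 1))
                base = 20.0 + (bump if g in elevated_groups else 0.0)
                row.append(base + rng.normal(0, 0.5))
        return build_matrix([row], sample_meta=meta)

    def test_one_elevated_group_among_six_passes(self):
        # pairs involving the shifted group: 5 significant of C(6,2)=15
        matrix = self.build_gate_matrix(6, {0})
        kept = crosstalk_gate(matrix, groups={
            c: list(matrix.samples.index[matrix.samples["cohort"] == c])
            for c in matrix.samples["cohort"].unique()})
        assert list(kept) == ["P1"]

    def test_one_elevated_group_among_five_fails_pair_minimum(self):
        # only 4 significant pairs available -> below the minimum of five
        matrix = self.build_gate_matrix(5, {0})
        kept = crosstalk_gate(matrix, groups={
            c: list(matrix.samples.index[matrix.samples["cohort"] == c])
            for c in matrix.samples["cohort"].unique()})
        assert len(kept) == 0

    def test_flat_protein_fails_anova_cut(self):
        matrix = self.build_gate_matrix(6, set())
        kept = crosstalk_gate(matrix)
        assert len(kept) == 0

    def test_fewer_than_two_groups_rejected(self):
        matrix = self.build_gate_matrix(6, {0})
        with pytest.raises(ValidationError):
            crosstalk_gate(matrix, groups={"only": list(matrix.samples.index)})


class TestConditionAverage:
    def test_mean_per_condition_cell_type(self):
        meta = joint_meta(2)
        values = [[8.0, 10.0, 7.0, 9.0, 1.0, 3.0, 2.0, 4.0]]
        avg = condition_average(build_matrix(values, sample_meta=meta))
        assert avg.loc["P1", ("healthy", "keratinocyte")] == 9.0
        assert avg.loc["P1", ("healthy", "immune")] == 8.0
        assert avg.loc["P1", ("TEN", "keratinocyte")] == 2.0


def avg_table(entries):
    """entries: {(protein, cohort, cell_type): value}"""
    prots = sorted({p for p, _, _ in entries})
    cols = sorted({(c, ct) for _, c, ct in entries})
    df = pd.DataFrame(index=prots,
                      columns=pd.MultiIndex.from_tuples(
                          cols, names=["cohort", "cell_type"]), dtype=float)
    for (p, c, ct), v in entries.items():
        df.loc[p, (c, ct)] = v
    return df


class TestScoreInteractions:
    PAIRS = [("keratinocyte", "immune"), ("immune", "keratinocyte")]

    def test_quoted_arithmetic_example(self):
        table = avg_table({
            ("L", "TEN", "keratinocyte"): 12.0,
            ("R", "TEN", "immune"): 9.0,
            ("L", "healthy", "keratinocyte"): 10.0,
            ("R", "healthy", "immune"): 9.0,
            ("L", "TEN", "immune"): 0.0,
            ("R", "TEN", "keratinocyte"): 0.0,
            ("L", "healthy", "immune"): 0.0,
            ("R", "healthy", "keratinocyte"): 0.0,
        })
        inter = pd.DataFrame([{"source": "L", "target": "R"}])
        scores, unmatched = score_interactions(table, inter, self.PAIRS)
        assert unmatched.empty
        row = scores[(scores.source_cell_type == "keratinocyte")].iloc[0]
        assert row["delta"] == 3.0
        assert row["disease_delta"] == 2.0
        assert bool(row["kept"])

    def test_mirrored_direction_is_antisymmetric_and_filtered(self):
        rng = np.random.default_rng(1)
        entries = {}
        for p in ("A", "B"):
            for c in ("healthy", "TEN"):
                for ct in ("keratinocyte", "immune"):
                    entries[(p, c, ct)] = float(rng.normal(20, 2))
        table = avg_table(entries)
        inter = pd.DataFrame([{"source": "A", "target": "B"},
                              {"source": "B", "target": "A"}])
        scores, _ = score_interactions(table, inter, self.PAIRS)
        fwd = scores[(scores.source_gene == "A")
                     & (scores.source_cell_type == "keratinocyte")].iloc[0]
        rev = scores[(scores.source_gene == "B")
                     & (scores.source_cell_type == "immune")].iloc[0]
        assert fwd["disease_delta"] == -rev["disease_delta"]  # exact
        assert bool(fwd["kept"]) != bool(rev["kept"]) or \
            fwd["disease_delta"] == 0.0

    def test_identical_conditions_give_zero_delta_filtered(self):
        entries = {(p, c, ct): 10.0 for p in ("A", "B")
                   for c in ("healthy", "TEN")
                   for ct in ("keratinocyte", "immune")}
        inter = pd.DataFrame([{"source": "A", "target": "B"}])
        scores, _ = score_interactions(avg_table(entries), inter, self.PAIRS)
        assert (scores["disease_delta"] == 0.0).all()
        assert not scores["kept"].any()

    def test_condition_wide_constant_shift_cancels(self):
        rng = np.random.default_rng(2)
        entries = {(p, c, ct): float(rng.normal(20, 2)) for p in ("A", "B")
                   for c in ("healthy", "TEN")
                   for ct in ("keratinocyte", "immune")}
        inter = pd.DataFrame([{"source": "A", "target": "B"}])
        base, _ = score_interactions(avg_table(entries), inter, self.PAIRS)
        shifted = {k: (v + 7.5 if k[1] == "TEN" else v)
                   for k, v in entries.items()}
        after, _ = score_interactions(avg_table(shifted), inter, self.PAIRS)
        # adding c to every entry of one condition shifts Delta by 0
        assert np.allclose(base["disease_delta"], after["disease_delta"])

    def test_missing_reference_condition_rejected(self):
        entries = {("A", "TEN", "keratinocyte"): 1.0,
                   ("B", "TEN", "immune"): 1.0}
        inter = pd.DataFrame([{"source": "A", "target": "B"}])
        with pytest.raises(ValidationError, match="reference"):
            score_interactions(avg_table(entries), inter, self.PAIRS)

    def test_unmatched_interactions_reported(self):
        entries = {(p, c, ct): 10.0 for p in ("A", "B")
                   for c in ("healthy", "TEN")
                   for ct in ("keratinocyte", "immune")}
        inter = pd.DataFrame([{"source": "A", "target": "NOPE"}])
        scores, unmatched = score_interactions(avg_table(entries), inter,
                                               self.PAIRS)
        assert scores.empty
        assert len(unmatched) == 2  # one per ordered cell-type pair

    def test_protein_group_matched_by_first_gene(self):
        entries = {(p, c, ct): 10.0 for p in ("STAT1;STAT1B", "IFNGR1")
                   for c in ("healthy", "TEN")
                   for ct in ("keratinocyte", "immune")}
        table = avg_table(entries)
        inter = pd.DataFrame([{"source": "STAT1", "target": "IFNGR1"}])
        scores, unmatched = score_interactions(table, inter, self.PAIRS)
        assert unmatched.empty
        assert len(scores) == 2
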