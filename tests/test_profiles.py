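"""Normalization, abundance classes and the digital differential-expression test."""

import math

import numpy as np
import pytest

from deepsage.profiles import (
    abundance_class,
    abundance_classes,
    audic_claverie_pvalue,
    audic_claverie_pvalues,
    differential_table,
    fold_and_ratio,
    normalize,
    regulated_set,
    venn_overlap,
)
from oracles import ac_pvalue_exact


class TestNormalize:
    def test_zero_count_stays_zero(self, toy_matrix):
        toy_matrix.counts.loc["STCa-3", "ctl"] = 0
        profile = normalize(toy_matrix)
        assert profile.loc["STCa-3", "ctl"] == 0.0

    def test_hand_computed_value(self, toy_matrix):
        # 37 copies in a library of 57,281 observations
        toy_matrix.counts.loc["STCa-1", "ctl"] = 37
        toy_matrix.counts.loc["STCa-2", "ctl"] = 57_281 - 37
        toy_matrix.counts.loc[["STCa-3", "STCa-4"], "ctl"] = 0
        matrix = toy_matrix.copy()  # resync library totals
        profile = normalize(matrix)
        assert profile.loc["STCa-1", "ctl"] == pytest.approx(37 * 100_000 / 57_281)

    def test_columns_sum_to_100k(self, small_matrix):
        profile = normalize(small_matrix)
        assert np.allclose(profile.sum(axis=0), 100_000.0, atol=1e-6)


class TestAbundanceClasses:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (5.0, "<10"),
            (9.999, "<10"),
            (10.0, "10-100"),
            (100.0, "10-100"),
            (100.5, "100-500"),
            (500.0, "100-500"),
            (501.0, ">500"),
        ],
    )
    def test_boundaries(self, value, expected):
        assert abundance_class(value) == expected

    def test_report_counts_detected_tags(self, toy_matrix):
        profile = normalize(toy_matrix)
        report = abundance_classes(profile, toy_matrix.counts)
        per_lib = report.groupby("library")["n_tags"].sum()
        detected = (toy_matrix.counts > 0).sum(axis=0)
        for lib_id, n in per_lib.items():
            assert n == detected[lib_id]
        assert report.groupby("library")["percent"].sum().round(6).eq(100.0).all()


class TestFoldAndRatio:
    def test_equal_abundance_is_identity(self):
        fold, rln = fold_and_ratio(10, 10, 1000, 1000)
        assert fold == pytest.approx(1.0) and rln == pytest.approx(0.0)

    def test_rln_unity_is_e_fold(self):
        # R(ln) = 1.0 corresponds to the e-fold (~2.7-fold) threshold
        fold, rln = fold_and_ratio(1000, 2718, 100_000, 100_000)
        assert fold == pytest.approx(math.e, rel=1e-3)
        assert rln == pytest.approx(1.0, abs=1e-3)

    def test_pseudocount_applied_only_at_zero(self):
        fold, rln = fold_and_ratio(0, 8, 100_000, 100_000, pseudocount=1)
        assert fold == pytest.approx(9.0)
        assert rln == pytest.approx(math.log(9.0))
        fold2, _ = fold_and_ratio(2, 8, 100_000, 100_000, pseudocount=1)
        assert fold2 == pytest.approx(4.0)  # no pseudocount when both nonzero

    def test_both_zero_without_pseudocount_is_error(self):
        with pytest.raises(ValueError):
            fold_and_ratio(0, 0, 1000, 1000, pseudocount=0)

    def test_exp_rln_equals_fold(self):
        fold, rln = fold_and_ratio(37, 11, 57_281, 86_919)
        assert math.exp(rln) == pytest.approx(fold, rel=1e-9)


class TestAudicClaverie:
    def test_zero_zero_equal_sizes(self):
        assert audic_claverie_pvalue(0, 0, 1000, 1000) == pytest.approx(1.0)

    def test_closed_form_x5_y0(self):
        # P(Y<=0|x=5, r=1) = (1/2)^6, doubled
        assert audic_claverie_pvalue(5, 0, 80_000, 80_000) == pytest.approx(0.03125)

    def test_symmetry_under_library_exchange(self):
        a = audic_claverie_pvalue(12, 3, 80_000, 60_000)
        b = audic_claverie_pvalue(3, 12, 60_000, 80_000)
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("r_num,r_den", [(1, 2), (1, 1), (2, 1)])
    def test_against_exact_rational_oracle_small_grid(self, r_num, r_den):
        n1, n2 = 40_000 * r_den, 40_000 * r_num
        for x in range(0, 13, 3):
            for y in range(0, 13, 2):
                exact = float(ac_pvalue_exact(x, y, n1, n2))
                assert audic_claverie_pvalue(x, y, n1, n2) == pytest.approx(
                    exact, abs=1e-9
                )

    def test_monotone_away_from_conditional_mode(self):
        """The two-sided p never increases as y moves away from its mode."""
        x, n1, n2 = 30, 80_000, 60_000
        ps = [audic_claverie_pvalue(x, y, n1, n2) for y in range(0, 120)]
        mode = int(np.argmax(ps))
        assert all(ps[i] >= ps[i + 1] for i in range(mode, len(ps) - 1))
        assert all(ps[i] <= ps[i + 1] for i in range(mode))

    def test_vectorized_matches_scalar(self):
        x = np.array([0, 5, 12, 100])
        y = np.array([0, 0, 3, 80])
        vec = audic_claverie_pvalues(x, y, 80_000, 60_000)
        for xi, yi, pi in zip(x, y, vec):
            assert pi == pytest.approx(audic_claverie_pvalue(xi, yi, 80_000, 60_000))

    def test_large_counts_are_finite_and_stable(self):
        p = audic_claverie_pvalue(100_000, 100_500, 1_000_000, 1_000_000)
        assert 0.0 < p <= 1.0


class TestDifferentialTable:
    def test_per_tag_recomputation(self, toy_matrix):
        table = differential_table(toy_matrix, "ctl", "str", pseudocount=1)
        n_ctl = toy_matrix.library("ctl").total_tags
        n_str = toy_matrix.library("str").total_tags
        for uid, row in table.iterrows():
            x = toy_matrix.counts.loc[uid, "ctl"]
            y = toy_matrix.counts.loc[uid, "str"]
            fold, rln = fold_and_ratio(x, y, n_ctl, n_str, 1)
            assert row["fold_change"] == pytest.approx(fold)
            assert row["R_ln"] == pytest.approx(rln)
            assert row["p_value"] == pytest.approx(
                audic_claverie_pvalue(x, y, n_ctl, n_str)
            )

    def test_identical_libraries_are_flat_with_p_one(self, toy_matrix):
        toy_matrix.counts["str"] = toy_matrix.counts["ctl"]
        matrix = toy_matrix.copy()
        table = differential_table(matrix, "ctl", "str")
        assert (table["direction"] == "flat").all()
        assert table["p_value"].to_numpy() == pytest.approx(1.0, rel=1e-12)

    def test_same_library_twice_is_error(self, toy_matrix):
        with pytest.raises(ValueError):
            differential_table(toy_matrix, "ctl", "ctl")

    def test_summary_thresholds(self, toy_matrix):
        table = differential_table(toy_matrix, "ctl", "str")
        summary = table.attrs["summary"]
        rln = table["R_ln"].abs()
        for threshold, n in summary.items():
            assert n == int((rln >= threshold).sum())

    def test_spiked_tags_rank_top(self, small_scene, small_matrix):
        """Generator-spiked DE tags dominate the top of the |R_ln| ranking."""
        scene, _, _ = small_scene
        table = differential_table(small_matrix, "root-control", "root-NaCl")
        seq_of = small_matrix.sequences
        true_de = {t for t, r in scene.truth.de_tags.items() if abs(r) >= 1.0}
        top = table.reindex(table["R_ln"].abs().sort_values(ascending=False).index)
        top20_seqs = set(seq_of.loc[top.index[:20]])
        assert len(top20_seqs & true_de) >= 15


class TestVennOverlap:
    def test_two_set_algebra(self):
        report = venn_overlap({"A": {"t1", "t2"}, "B": {"t2", "t3"}})
        assert report.regions[("A", "B")] == 1
        assert report.regions[("A",)] == 1
        assert report.regions[("B",)] == 1
        assert report.union_size() == 3

    def test_three_disjoint_sets(self):
        report = venn_overlap({"A": {"a"}, "B": {"b"}, "C": {"c"}})
        assert report.regions[("A", "B")] == 0
        assert report.regions[("A", "B", "C")] == 0
        assert report.union_size() == 3

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            venn_overlap({})

    def test_designed_overlap_recovered(self):
        rng = np.random.default_rng(5)
        shared = {f"s{i}" for i in range(30)}
        a = shared | {f"a{i}" for i in range(70)}
        b = shared | {f"b{i}" for i in range(70)}
        report = venn_overlap({"A": a, "B": b})
        assert report.regions[("A", "B")] == 30

    def test_regulated_set_threshold_is_inclusive(self, toy_matrix):
        table = differential_table(toy_matrix, "ctl", "str")
        up = regulated_set(table, 3.0, "up")
        assert up == set(table.index[table["fold_change"] >= 3.0])
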