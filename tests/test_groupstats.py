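"""Group comparisons, phospho summaries and ranked-list construction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from baitquant import (
    AnnotationTable,
    PhosphoMatrix,
    phospho_site_max_range,
    protein_phospho_sum,
    ranked_list_builder,
    ttest_site_compare,
    wilcoxon_group_compare,
)

from conftest import make_design


def exact_rank_sum_p(a, b):
    """Full-enumeration oracle: two-sided p of the rank-sum statistic over
    all C(n_a+n_b, n_a) assignments of the pooled tie-free values."""
    pooled = sorted(a) + sorted(b)
    n_a = len(a)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    observed = sum(ranks[v] for v in a)
    mean = n_a * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(pooled, n_a):
        total += 1
        w = sum(ranks[v] for v in combo)
        if abs(w - mean) >= abs(observed - mean) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_two_vs_two_exact(self):
        """{1,2} vs {3,4}: all A below all B, exact two-sided p = 2/6."""
        out = wilcoxon_group_compare({"x": [1, 2], "y": [3, 4]}, [("x", "y")])
        assert out.iloc[0]["method"] == "exact"
        assert out.iloc[0]["p_value"] == pytest.approx(1 / 3)

    def test_identical_groups_approx_path(self):
        out = wilcoxon_group_compare({"x": [1, 2, 3], "y": [1, 2, 3]},
                                     [("x", "y")])
        assert out.iloc[0]["method"] == "asymptotic"  # ties force approx
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (3, 4), (5, 5), (6, 4), (6, 6)])
    def test_exact_path_matches_enumeration(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(5):
            pooled = rng.permutation(
                rng.uniform(0, 100, n_a + n_b)
            )  # tie-free with probability 1
            a, b = pooled[:n_a], pooled[n_a:]
            out = wilcoxon_group_compare({"x": a, "y": b}, [("x", "y")])
            assert out.iloc[0]["method"] == "exact"
            assert out.iloc[0]["p_value"] == pytest.approx(
                exact_rank_sum_p(list(a), list(b)), rel=1e-9
            )

    def test_bonferroni_over_listed_panel(self):
        groups = {"a": [1, 2], "b": [3, 4], "c": [5, 6]}
        out = wilcoxon_group_compare(groups, [("a", "b"), ("a", "c"), ("b", "c")])
        np.testing.assert_allclose(
            out["p_adjusted"], np.minimum(out["p_value"] * 3, 1.0)
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            wilcoxon_group_compare({"a": [], "b": [1]}, [("a", "b")])


class TestSiteTTest:
    def test_closed_form_oracle(self):
        out = ttest_site_compare({"m1": [1, 2, 3], "m2": [4, 5, 6]},
                                 [("m1", "m2")])
        assert abs(out.iloc[0]["t_stat"]) == pytest.approx(3.674, abs=1e-3)
        assert out.iloc[0]["p_value"] == pytest.approx(0.0214, abs=5e-4)

    def test_identical_groups(self):
        out = ttest_site_compare({"m1": [1, 2, 3], "m2": [1, 2, 3]},
                                 [("m1", "m2")])
        assert out.iloc[0]["p_value"] == 1.0

    def test_single_replicate_untested(self):
        out = ttest_site_compare({"m1": [1.0], "m2": [4, 5, 6]}, [("m1", "m2")])
        assert np.isnan(out.iloc[0]["p_value"])
        assert out.iloc[0]["n_a"] == 1


def phospho_fixture(design, rows):
    cols = design.select(fraction="PE")
    df = pd.DataFrame(rows, columns=cols)
    return PhosphoMatrix(df, provenance="protein_normalized")


class TestPhosphoSum:
    def design(self):
        return make_design(conditions=("c1", "c2"), n_replicates=2,
                           tags=("tag",))

    def test_hand_sum(self):
        """Sites with condition means {10, 5} sum to 15 for the protein."""
        design = self.design()
        df = pd.DataFrame(
            {
                "c1.tag.PE.r1": [8.0, 4.0],
                "c1.tag.PE.r2": [12.0, 6.0],
                "c2.tag.PE.r1": [1.0, np.nan],
                "c2.tag.PE.r2": [3.0, np.nan],
            },
            index=["Ndc80-T-54", "Ndc80-S-100"],
        )
        out = protein_phospho_sum(PhosphoMatrix(df), design)
        assert out.loc["Ndc80", "c1"] == pytest.approx(15.0)  # 10 + 5
        assert out.loc["Ndc80", "c2"] == pytest.approx(2.0)   # missing skipped
        assert out.loc["Ndc80", "total"] == pytest.approx(17.0)

    def test_protein_without_sites_ranks_last(self):
        design = self.design()
        df = pd.DataFrame(
            {c: [5.0] for c in design.select(fraction="PE")},
            index=["Ndc80-T-54"],
        )
        out = protein_phospho_sum(PhosphoMatrix(df), design,
                                  proteins=["Ndc80", "Empty"])
        assert out.loc["Empty", "total"] == 0.0
        assert out.loc["Empty", "rank"] == 2

    def test_ranking_matches_sort_oracle(self):
        design = self.design()
        rng = np.random.default_rng(6)
        sites = [f"P{i}-S-{j + 1}" for i in range(5) for j in range(3)]
        df = pd.DataFrame(rng.uniform(1, 100, (15, 4)),
                          columns=design.select(fraction="PE"), index=sites)
        out = protein_phospho_sum(PhosphoMatrix(df), design)
        totals = {}
        for i in range(5):
            block = df.iloc[3 * i: 3 * i + 3]
            c1 = block[["c1.tag.PE.r1", "c1.tag.PE.r2"]].mean(axis=1).sum()
            c2 = block[["c2.tag.PE.r1", "c2.tag.PE.r2"]].mean(axis=1).sum()
            totals[f"P{i}"] = c1 + c2
        expected_order = sorted(totals, key=totals.get, reverse=True)
        assert list(out.index) == expected_order

    def test_additive_over_site_partition(self):
        """Summing the tables of two disjoint site subsets reproduces the
        full table."""
        design = self.design()
        rng = np.random.default_rng(13)
        sites = [f"P{i}-S-{j + 1}" for i in range(3) for j in range(4)]
        vals = np.where(rng.random((12, 4)) < 0.2, np.nan,
                        rng.uniform(1, 50, (12, 4)))
        df = pd.DataFrame(vals, columns=design.select(fraction="PE"),
                          index=sites)
        full = protein_phospho_sum(PhosphoMatrix(df), design)
        half_a = protein_phospho_sum(PhosphoMatrix(df.iloc[::2]), design,
                                     proteins=[f"P{i}" for i in range(3)])
        half_b = protein_phospho_sum(PhosphoMatrix(df.iloc[1::2]), design,
                                     proteins=[f"P{i}" for i in range(3)])
        cols = ["c1", "c2", "total"]
        combined = (half_a[cols] + half_b[cols]).sort_index()
        pd.testing.assert_frame_equal(full[cols].sort_index(), combined,
                                      rtol=1e-12)


class TestSiteMaxRange:
    def design(self):
        return make_design(
            conditions=("c1", "c2", "c3", "c4"), n_replicates=1, tags=("tag",)
        )

    def test_hand_range(self):
        """Condition means (4, 1, 9, 9) give range 8; constant means give 0."""
        design = self.design()
        df = pd.DataFrame(
            [[4.0, 1.0, 9.0, 9.0], [2.0, 2.0, 2.0, 2.0]],
            columns=design.select(fraction="PE"),
            index=["Ndc80-T-54", "Ndc80-S-100"],
        )
        sites, proteins = phospho_site_max_range(PhosphoMatrix(df), design)
        assert sites.loc["Ndc80-T-54", "range"] == pytest.approx(8.0)
        assert sites.loc["Ndc80-S-100", "range"] == 0.0
        assert proteins.loc["Ndc80", "median_range"] == pytest.approx(4.0)

    def test_single_condition_site_excluded(self):
        design = self.design()
        df = pd.DataFrame(
            [[4.0, np.nan, np.nan, np.nan], [1.0, 2.0, 3.0, 4.0]],
            columns=design.select(fraction="PE"),
            index=["Ndc80-T-54", "Ndc80-S-100"],
        )
        sites, proteins = phospho_site_max_range(PhosphoMatrix(df), design)
        assert "Ndc80-T-54" not in sites.index
        assert proteins.attrs["n_excluded_sites"] == 1


class TestRankedLists:
    annotation = AnnotationTable.from_mapping(
        {"Kt1": ("KMN", True), "Kt2": ("CCAN", True)}
    )

    @staticmethod
    def result(order):
        return pd.DataFrame(
            {"log2_fold_change": np.arange(len(order), 0, -1, dtype=float)},
            index=order,
        )

    def test_dedup_union_oracle(self):
        """Top-2 lists [A,B], [B,C], [C,D] combine to [A,B,C,D]."""
        lists = [self.result(["A", "B"]), self.result(["B", "C"]),
                 self.result(["C", "D"])]
        assert ranked_list_builder(lists, self.annotation, top_n=2) == [
            "A", "B", "C", "D",
        ]

    def test_kinetochore_protein_never_emitted(self):
        res = self.result(["Kt1", "A", "Kt2", "B", "C"])
        out = ranked_list_builder([res], self.annotation, top_n=3)
        assert out == ["A", "B", "C"]

    def test_short_list_warns_and_takes_all(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = ranked_list_builder([self.result(["A", "B"])],
                                      self.annotation, top_n=20)
        assert out == ["A", "B"]
        assert "top-20" in caplog.text

    def test_orders_by_descending_fold_change(self):
        res = pd.DataFrame({"log2_fold_change": [0.5, 3.0, -1.0, 2.0]},
                           index=["A", "B", "C", "D"])
        assert ranked_list_builder([res], self.annotation, top_n=3) == [
            "B", "D", "A",
        ]

    @given(st.integers(1, 8))
    def test_length_bound_and_exclusion_property(self, top_n):
        rng = np.random.default_rng(top_n)
        names = [f"X{i}" for i in range(10)] + ["Kt1", "Kt2"]
        lists = []
        for _ in range(3):
            order = list(rng.permutation(names))
            lists.append(self.result(order))
        out = ranked_list_builder(lists, self.annotation, top_n=top_n)
        assert len(out) <= 3 * top_n
        assert "Kt1" not in out and "Kt2" not in out
        assert len(out) == len(set(out))
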