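"""Activity statistic, Fisher/FDR significance, taxonomy collapsing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from sipflow.activity import (
    CountTable,
    activity_heatmap_matrix,
    bh_fdr,
    collapse_rank,
    compute_activity,
    fisher_enrichment_p,
    parse_lineage,
    rank_by_activity,
    relative_abundance,
    significance_tier,
)
from conftest import make_table


def fisher_oracle(a, n1, b, n2):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    k = a + b
    support = range(max(0, k - n2), min(n1, k) + 1)
    pmf = {i: hypergeom.pmf(i, n1 + n2, n1, k) for i in support}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-10)))


def bh_oracle(p):
    """Naive Benjamini-Hochberg step-up."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


class TestRelativeAbundance:
    def test_percentages(self):
        table = make_table({"s": [1, 2, 3, 4]}, list("abcd"))
        ra = relative_abundance(table)
        assert ra["s"].tolist() == pytest.approx([10, 20, 30, 40])

    def test_single_taxon_is_everything(self):
        table = make_table({"s": [7]}, ["a"])
        assert relative_abundance(table)["s"].tolist() == [100.0]

    def test_zero_total_column_rejected(self):
        table = make_table({"s": [1], "empty": [0]}, ["a"])
        with pytest.raises(ValueError, match="empty"):
            relative_abundance(table)

    def test_columns_sum_to_100(self, labeled_dataset):
        ra = relative_abundance(labeled_dataset.labeled_counts)
        np.testing.assert_allclose(ra.sum(axis=0), 100.0, atol=1e-9)


class TestFisher:
    def test_identical_proportions_p_one(self):
        assert fisher_enrichment_p(5, 100, 5, 100) == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        # only the observed table and its mirror are as extreme
        expected = 2 / math.comb(20, 10)
        assert fisher_enrichment_p(10, 10, 0, 10) == pytest.approx(expected, rel=1e-9)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(1, 31, size=2)
            a, b = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            assert fisher_enrichment_p(a, n1, b, n2) == pytest.approx(
                fisher_oracle(a, n1, b, n2), abs=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment_p(-1, 10, 0, 10)
        with pytest.raises(ValueError):
            fisher_enrichment_p(11, 10, 0, 10)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_oracle(self, p):
        q = bh_fdr(p)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        assert (q >= np.asarray(p) - 1e-12).all() and (q <= 1 + 1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])


def paired_tables(rng, n_taxa=12, pools=("medium", "lower")):
    taxa = [f"t{i}" for i in range(n_taxa)]
    lab = make_table(
        {p: rng.integers(0, 500, n_taxa).tolist() for p in pools}, taxa
    )
    ctl = make_table(
        {p: rng.integers(0, 500, n_taxa).tolist() for p in pools}, taxa
    )
    # guarantee positive totals
    lab.counts.iloc[0] += 1
    ctl.counts.iloc[0] += 1
    return lab, ctl


class TestActivity:
    def test_identical_tables_zero_activity(self):
        table = make_table({"medium": [30, 70], "lower": [10, 90]}, ["a", "b"])
        rec = compute_activity(table, table, ["medium", "lower"])
        np.testing.assert_allclose(rec["A"], 0.0, atol=1e-12)
        np.testing.assert_allclose(rec["p"], 1.0)

    def test_printed_formula(self):
        lab = make_table({"lower": [30, 70]}, ["a", "b"])
        ctl = make_table({"lower": [10, 90]}, ["a", "b"])
        rec = compute_activity(lab, ctl, ["lower"]).set_index("taxon")
        assert rec.at["a", "A"] == pytest.approx(20.0)
        assert rec.at["b", "A"] == pytest.approx(-20.0)

    def test_zero_sum_per_pool(self, rng):
        lab, ctl = paired_tables(rng)
        rec = compute_activity(lab, ctl, ["medium", "lower"])
        sums = rec.groupby("pool")["A"].sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)

    def test_antisymmetry_under_table_swap(self, rng):
        lab, ctl = paired_tables(rng)
        fwd = compute_activity(lab, ctl, ["medium"]).set_index("taxon")
        rev = compute_activity(ctl, lab, ["medium"]).set_index("taxon")
        np.testing.assert_allclose(fwd["A"], -rev.loc[fwd.index, "A"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev.loc[fwd.index, "p"], atol=1e-12)

    def test_zero_fill_for_one_sided_taxa(self):
        lab = make_table({"lower": [50, 50]}, ["a", "b"])
        ctl = make_table({"lower": [100]}, ["a"])
        rec = compute_activity(lab, ctl, ["lower"]).set_index("taxon")
        assert rec.at["b", "A"] == pytest.approx(50.0)
        assert rec.at["b", "tNS_control"] == 0

    def test_missing_pool_rejected(self):
        lab = make_table({"lower": [1]}, ["a"])
        with pytest.raises(ValueError, match="medium"):
            compute_activity(lab, lab, ["medium"])

    def test_tier_assignment(self):
        assert significance_tier(0.005) == "p<0.01"
        assert significance_tier(0.03) == "p<0.05"
        assert significance_tier(0.07) == "p<0.1"
        assert significance_tier(0.5) == "ns"


class TestCollapse:
    def lineage_table(self):
        lineages = {
            "o1": "k__Bacteria; p__P; c__C; o__O; f__Lachnospiraceae; g__G1",
            "o2": "k__Bacteria; p__P; c__C; o__O; f__Lachnospiraceae; g__G2",
            "o3": "k__Bacteria; p__P; c__C; o__Clostridiales",
        }
        return make_table({"s1": [10, 20, 5], "s2": [1, 2, 3]}, ["o1", "o2", "o3"], lineages)

    def test_family_sums_and_unclassified_grouping(self):
        fam = collapse_rank(self.lineage_table(), "family")
        assert fam.counts.at["Lachnospiraceae", "s1"] == 30
        assert fam.counts.at["unclassified Clostridiales", "s1"] == 5

    def test_column_totals_preserved(self):
        table = self.lineage_table()
        fam = collapse_rank(table, "family")
        pd.testing.assert_series_equal(fam.sample_totals(), table.sample_totals())

    def test_idempotent(self):
        fam = collapse_rank(self.lineage_table(), "family")
        again = collapse_rank(fam, "family")
        pd.testing.assert_frame_equal(
            fam.counts.sort_index(), again.counts.sort_index()
        )

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            collapse_rank(self.lineage_table(), "tribe")

    def test_parse_plain_and_prefixed_lineages(self):
        assert parse_lineage("Bacteria;Firmicutes")["phylum"] == "Firmicutes"
        assert parse_lineage("k__Bacteria; f__Ruminococcaceae")["family"] == "Ruminococcaceae"


class TestHeatmapAndRanking:
    def test_matrix_matches_records(self, rng):
        lab, ctl = paired_tables(rng)
        rec = compute_activity(lab, ctl, ["medium", "lower"])
        matrix, annot = activity_heatmap_matrix(rec)
        for _, row in rec.iterrows():
            assert matrix.at[row["taxon"], row["pool"]] == pytest.approx(row["A"])
        assert set(np.unique(annot.to_numpy())) <= {"", "+", "*", "**"}

    def test_duplicate_records_rejected(self):
        rec = pd.DataFrame(
            {"taxon": ["a", "a"], "pool": ["lower", "lower"], "A": [1, 2],
             "tier": ["ns", "ns"]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            activity_heatmap_matrix(rec)

    def test_ranking_sorts_by_max_activity_then_name(self):
        rec = pd.DataFrame(
            {
                "taxon": ["b", "b", "a", "c"],
                "pool": ["medium", "lower", "lower", "lower"],
                "A": [5.0, 1.0, 5.0, -2.0],
                "q": [0.01, 0.2, 0.01, 0.9],
            }
        )
        ranked = rank_by_activity(rec)
        assert ranked["taxon"].tolist() == ["a", "b", "c"]


class TestCountTableValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_table({"s": [-1]}, ["a"])

    def test_duplicate_taxa_rejected(self):
        frame = pd.DataFrame({"s": [1, 2]}, index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            CountTable(frame)

    def test_malformed_lineage_rejected(self):
        with pytest.raises(ValueError):
            make_table(
                {"s": [1]}, ["a"],
                {"a": "x;" * 10 + "too;many;ranks"},
            )
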