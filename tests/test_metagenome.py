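"""Copy-number correction, KO-profile prediction and KO enrichment."""

import numpy as np
import pandas as pd
import pytest

from sipflow.metagenome import (
    copy_number_normalize,
    filter_to_labeled_taxa,
    ko_enrichment,
    ko_heatmap_matrix,
    predict_ko_profile,
)
from conftest import make_table


def lineage(i, fam):
    return f"k__Bacteria; p__P; c__C; o__O; f__{fam}; g__G{i}"


@pytest.fixture()
def table():
    taxa = ["o1", "o2", "o3"]
    lineages = {
        "o1": lineage(1, "Lachnospiraceae"),
        "o2": lineage(2, "Lachnospiraceae"),
        "o3": lineage(3, "Enterococcaceae"),
    }
    return make_table({"medium": [10, 20, 30], "lower": [5, 0, 15]}, taxa, lineages)


class TestCopyNumber:
    def test_unit_copy_numbers_identity(self, table):
        out = copy_number_normalize(table, {t: 1.0 for t in table.taxa})
        np.testing.assert_allclose(out.counts, table.counts)

    def test_division(self, table):
        out = copy_number_normalize(table, {"o1": 2.0, "o2": 4.0, "o3": 1.0})
        assert out.counts.at["o1", "medium"] == pytest.approx(5.0)
        assert out.counts.at["o2", "medium"] == pytest.approx(5.0)

    def test_elementwise_oracle(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        counts = rng.integers(0, 100, size=(6, 4))
        cn = rng.uniform(1, 10, size=6)
        table = make_table(
            {f"s{j}": counts[:, j].tolist() for j in range(4)}, taxa
        )
        out = copy_number_normalize(table, dict(zip(taxa, cn)))
        expected = counts / cn[:, None]
        np.testing.assert_allclose(out.counts.to_numpy(), expected, atol=1e-12)

    def test_missing_taxon_needs_default(self, table):
        with pytest.raises(ValueError, match="o3"):
            copy_number_normalize(table, {"o1": 2.0, "o2": 2.0})
        out = copy_number_normalize(table, {"o1": 2.0, "o2": 2.0}, default=4.0)
        assert out.counts.at["o3", "medium"] == pytest.approx(7.5)


class TestLabeledFilter:
    def test_keep_one_family(self, table):
        filtered, removed = filter_to_labeled_taxa(table, ["Lachnospiraceae"])
        assert set(filtered.taxa) == {"o1", "o2"}
        assert removed["taxon"].tolist() == ["o3"]

    def test_totals_conserved(self, table):
        filtered, removed = filter_to_labeled_taxa(table, ["Enterococcaceae"])
        recovered = filtered.sample_totals() + removed.set_index("taxon")[
            ["medium", "lower"]
        ].sum()
        pd.testing.assert_series_equal(recovered, table.sample_totals())

    def test_all_families_identity(self, table):
        filtered, removed = filter_to_labeled_taxa(
            table, ["Lachnospiraceae", "Enterococcaceae"]
        )
        pd.testing.assert_frame_equal(filtered.counts, table.counts)
        assert removed.empty

    def test_filter_removing_everything_rejected(self, table):
        with pytest.raises(ValueError, match="every row"):
            filter_to_labeled_taxa(table, ["Desulfovibrionaceae"])


class TestKoPrediction:
    def test_single_cell_product(self):
        table = make_table({"s": [2]}, ["t"])
        ko_ref = pd.DataFrame({"K00001": [3.0]}, index=["t"])
        profile = predict_ko_profile(table, ko_ref)
        assert profile.at["K00001", "s"] == pytest.approx(6.0)

    def test_zero_reference_zero_profile(self, table):
        ko_ref = pd.DataFrame(0.0, index=list(table.taxa), columns=["K00001", "K00002"])
        profile = predict_ko_profile(table, ko_ref)
        np.testing.assert_allclose(profile, 0.0)

    def test_triple_loop_oracle(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        samples = [f"s{j}" for j in range(4)]
        kos = [f"K{k:05d}" for k in range(6)]
        abundance = pd.DataFrame(rng.uniform(0, 50, (5, 4)), index=taxa, columns=samples)
        ko_ref = pd.DataFrame(rng.uniform(0, 5, (5, 6)), index=taxa, columns=kos)
        profile = predict_ko_profile(abundance, ko_ref)
        for ko in kos:
            for s in samples:
                expected = sum(
                    abundance.at[t, s] * ko_ref.at[t, ko] for t in taxa
                )
                assert profile.at[ko, s] == pytest.approx(expected, abs=1e-12)

    def test_missing_taxa_count_as_zero(self):
        table = make_table({"s": [2, 4]}, ["t", "u"])
        ko_ref = pd.DataFrame({"K00001": [3.0]}, index=["t"])
        profile = predict_ko_profile(table, ko_ref)
        assert profile.at["K00001", "s"] == pytest.approx(6.0)

    def test_disjoint_taxa_rejected(self):
        table = make_table({"s": [2]}, ["t"])
        ko_ref = pd.DataFrame({"K00001": [3.0]}, index=["other"])
        with pytest.raises(ValueError, match="no taxa shared"):
            predict_ko_profile(table, ko_ref)


def profiles(rng, n_ko=8, pools=("medium", "lower")):
    kos = [f"K{k:05d}" for k in range(n_ko)]
    lab = pd.DataFrame(
        rng.uniform(0.1, 20, (n_ko, len(pools))), index=kos, columns=pools
    )
    ctl = pd.DataFrame(
        rng.uniform(0.1, 20, (n_ko, len(pools))), index=kos, columns=pools
    )
    return lab, ctl


class TestKoEnrichment:
    def test_identical_profiles_zero(self, rng):
        lab, _ = profiles(rng)
        enr = ko_enrichment(lab, lab.copy(), ["medium", "lower"])
        np.testing.assert_allclose(enr["enrichment"], 0.0, atol=1e-12)

    def test_share_difference_formula(self):
        lab = pd.DataFrame({"lower": [30.0, 70.0]}, index=["K1", "K2"])
        ctl = pd.DataFrame({"lower": [10.0, 90.0]}, index=["K1", "K2"])
        enr = ko_enrichment(lab, ctl, ["lower"]).set_index("ko")
        assert enr.at["K1", "enrichment"] == pytest.approx(20.0)

    def test_zero_sum_per_pool(self, rng):
        lab, ctl = profiles(rng)
        enr = ko_enrichment(lab, ctl, ["medium", "lower"])
        sums = enr.groupby("pool")["enrichment"].sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)

    def test_sample_scaling_invariance(self, rng):
        lab, ctl = profiles(rng)
        scaled = lab * 7.5
        a = ko_enrichment(lab, ctl, ["medium"])
        b = ko_enrichment(scaled, ctl, ["medium"])
        np.testing.assert_allclose(a["enrichment"], b["enrichment"], atol=1e-9)

    def test_curated_subset_denominator(self, rng):
        lab, ctl = profiles(rng)
        subset = ["K00001", "K00003", "K00005"]
        enr = ko_enrichment(lab, ctl, ["medium"], ko_subset=subset)
        assert set(enr["ko"]) == set(subset)
        np.testing.assert_allclose(enr["enrichment"].sum(), 0.0, atol=1e-9)

    def test_uniform_copy_number_scaling_leaves_enrichment_unchanged(self, rng):
        # doubling all copy numbers scales every abundance by 0.5: share-free
        taxa = [f"t{i}" for i in range(5)]
        counts = {p: rng.integers(1, 100, 5).tolist() for p in ("medium", "lower")}
        lab_tab = make_table(counts, taxa)
        ctl_tab = make_table(
            {p: rng.integers(1, 100, 5).tolist() for p in ("medium", "lower")}, taxa
        )
        ko_ref = pd.DataFrame(
            rng.uniform(0, 3, (5, 4)), index=taxa,
            columns=[f"K{k}" for k in range(4)],
        )
        cn1 = {t: 2.0 for t in taxa}
        cn2 = {t: 4.0 for t in taxa}
        out = []
        for cn in (cn1, cn2):
            lab_p = predict_ko_profile(copy_number_normalize(lab_tab, cn), ko_ref)
            ctl_p = predict_ko_profile(copy_number_normalize(ctl_tab, cn), ko_ref)
            out.append(ko_enrichment(lab_p, ctl_p, ["medium", "lower"]))
        np.testing.assert_allclose(
            out[0]["enrichment"], out[1]["enrichment"], atol=1e-9
        )

    def test_heatmap_matrix_layout(self, rng):
        lab, ctl = profiles(rng)
        enr = ko_enrichment(lab, ctl, ["medium", "lower"])
        matrix = ko_heatmap_matrix(enr)
        assert matrix.shape == (8, 2)
        row = enr.iloc[0]
        assert matrix.at[row["ko"], row["pool"]] == pytest.approx(row["enrichment"])


class TestFilterConservation:
    def test_prediction_after_filter_subtracts_removed_contribution(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        lineages = {
            t: lineage(i, "FamA" if i < 3 else "FamB") for i, t in enumerate(taxa)
        }
        table = make_table(
            {p: rng.integers(0, 50, 6).tolist() for p in ("m", "l")}, taxa, lineages
        )
        table.counts.iloc[0] += 1
        ko_ref = pd.DataFrame(
            rng.uniform(0, 2, (6, 3)), index=taxa, columns=["K1", "K2", "K3"]
        )
        full = predict_ko_profile(table, ko_ref)
        kept, _ = filter_to_labeled_taxa(table, ["FamA"])
        removed_taxa = [t for t in taxa if t not in kept.taxa]
        removed_contrib = ko_ref.loc[removed_taxa].T @ table.counts.loc[removed_taxa]
        part = predict_ko_profile(kept, ko_ref)
        np.testing.assert_allclose(part, full - removed_contrib, atol=1e-9)
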