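"""Phylum composition, family-level core summaries and trajectories."""

import numpy as np
import pandas as pd
import pytest

from coregut import (
    GutRegion,
    TaxonomyTable,
    aggregate_core_families,
    family_trajectories,
    identify_core,
    lineage_label,
    phylum_composition,
)
from coregut import reference
from coregut.taxonomy_summary import FamilyCoreSummary
from conftest import build_table


def make_taxonomy(mapping):
    frame = pd.DataFrame(
        mapping, index=["phylum", "class", "order", "family"]
    ).T
    frame.index.name = "otu_id"
    return TaxonomyTable(frame)


TAX = make_taxonomy(
    {
        "OTU1": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
        "OTU2": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
        "OTU3": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
        "OTU4": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "unclassified"),
        "OTU5": ("TM7", "unclassified", "unclassified", "unclassified"),
    }
)


class TestPhylumComposition:
    def test_single_phylum_is_unity(self):
        table = build_table([[5, 5], [3, 7]], regions=["caecum", "caecum"],
                            animals=["A1", "A2"])
        out = phylum_composition(table, TAX, others_below=0.0)
        assert out.loc["caecum", "Firmicutes"] == pytest.approx(1.0)

    def test_minor_phyla_pooled_into_others(self):
        table = build_table(
            [[60, 0, 39, 0, 1]], regions=["caecum"], animals=["A1"]
        )
        out = phylum_composition(table, TAX, others_below=0.05)
        assert out.loc["caecum", "others"] == pytest.approx(0.01)
        assert "TM7" not in out.columns
        assert out.loc["caecum"].sum() == pytest.approx(1.0)

    def test_rows_sum_to_one_across_regions(self):
        rng = np.random.default_rng(31)
        table = build_table(
            rng.integers(0, 30, size=(4, 5)) + 1,
            regions=["ileum", "ileum", "caecum", "caecum"],
            animals=["A1", "A2", "A1", "A2"],
        )
        out = phylum_composition(table, TAX, others_below=0.2)
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_multinomial_fixture_recovers_weights(self):
        # three phyla at planted weights; pooled depth large
        rng = np.random.default_rng(32)
        weights = np.array([0.46, 0.43, 0.11])
        depth = 32250
        counts = rng.multinomial(depth, np.repeat(weights / 3, 3) / 1)
        # 9 OTUs: 3 per phylum
        tax = make_taxonomy(
            {
                f"OTU{i + 1}": (ph, "unclassified", "unclassified", "unclassified")
                for i, ph in enumerate(
                    ["Firmicutes"] * 3 + ["Bacteroidetes"] * 3 + ["Fibrobacteres"] * 3
                )
            }
        )
        table = build_table(counts[None, :], regions=["caecum"], animals=["A1"])
        out = phylum_composition(table, tax, others_below=0.0)
        for ph, w in zip(["Firmicutes", "Bacteroidetes", "Fibrobacteres"], weights):
            se = np.sqrt(w * (1 - w) / depth)
            assert abs(out.loc["caecum", ph] - w) <= 3 * se


class TestAggregateCoreFamilies:
    @staticmethod
    def _core_result(matrix, theta=0.0):
        table = build_table(
            matrix,
            animals=[f"A{i + 1}" for i in range(len(matrix))],
            regions=["caecum"] * len(matrix),
        )
        return identify_core(
            table, prevalence_fraction=1.0, abundance_threshold=theta
        )

    def test_two_family_group_sums_match_brute_force(self):
        matrix = np.array([[10, 5, 20, 0, 1], [8, 7, 22, 0, 1], [12, 3, 18, 0, 1]])
        res = self._core_result(matrix)
        # OTU4 absent everywhere; core = OTU1,2,3,5
        summary = aggregate_core_families(res, TAX)
        total = matrix.sum()
        lachno = summary.table.set_index("family").loc["Lachnospiraceae"]
        assert lachno["relative_abundance_pct"] == pytest.approx(
            100 * matrix[:, :2].sum() / total
        )
        assert summary.total_core_abundance_pct == pytest.approx(
            100 * res.core_total_abundance
        )

    def test_single_otu_family_equals_otu_abundance(self):
        # OTU3 (Prevotellaceae) is the only member of its family
        matrix = np.array([[30, 0, 10], [30, 0, 10]])
        res = self._core_result(matrix)
        summary = aggregate_core_families(res, TAX)
        prevo = summary.table.set_index("family").loc["Prevotellaceae"]
        assert prevo["otu_ids"] == "OTU3"
        assert prevo["relative_abundance_pct"] == pytest.approx(100 * 20 / 80)

    def test_sd_is_across_animal_dispersion_of_shares(self):
        # Lachnospiraceae share per animal: 10% and 30%
        matrix = np.array([[10, 0, 90], [30, 0, 70]])
        res = self._core_result(matrix)
        summary = aggregate_core_families(res, TAX)
        lachno = summary.table.set_index("family").loc["Lachnospiraceae"]
        shares = 100 * np.array([10 / 100, 30 / 100])
        assert lachno["sd_pct"] == pytest.approx(np.std(shares, ddof=1))

    def test_unknown_core_otu_warns_and_is_unclassified(self):
        matrix = np.array([[5, 5], [5, 5]])
        res = self._core_result(matrix)
        tax = make_taxonomy(
            {"OTU1": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae")}
        )
        with pytest.warns(UserWarning, match="OTU2"):
            summary = aggregate_core_families(res, tax)
        row = summary.table.set_index("otu_ids").loc["OTU2"]
        assert row["phylum"] == "unclassified"

    def test_distinct_unclassified_lineages_kept_separate(self):
        matrix = np.array([[5, 5, 5], [5, 5, 5]])
        tax = make_taxonomy(
            {
                "OTU1": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "unclassified"),
                "OTU2": ("Bacteroidetes", "unclassified", "unclassified", "unclassified"),
                "OTU3": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "unclassified"),
            }
        )
        res = self._core_result(matrix)
        summary = aggregate_core_families(res, tax)
        assert len(summary.table) == 2  # two distinct unclassified lineages

    def test_merging_same_lineage_otus_preserves_family_totals(self):
        matrix = np.array([[10, 6, 4], [8, 5, 5]])
        tax_split = TAX
        res = self._core_result(matrix)
        split = aggregate_core_families(res, tax_split).table
        merged_matrix = np.column_stack([matrix[:, 0] + matrix[:, 1], matrix[:, 2]])
        merged_counts = build_table(
            merged_matrix,
            animals=["A1", "A2"],
            regions=["caecum"] * 2,
        )
        res2 = identify_core(merged_counts, abundance_threshold=0.0)
        merged = aggregate_core_families(res2, make_taxonomy({
            "OTU1": ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae"),
            "OTU2": ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae"),
        })).table
        for family in ("Lachnospiraceae", "Prevotellaceae"):
            assert (
                split.set_index("family").loc[family, "relative_abundance_pct"]
                == pytest.approx(
                    merged.set_index("family").loc[family, "relative_abundance_pct"]
                )
            )


def summaries_from_reference():
    """Build FamilyCoreSummary objects from the published table."""
    out = {}
    for region, group in reference.core_family_table().groupby("region", sort=False):
        tab = group.drop(columns="region").rename(
            columns={"sd": "sd_pct"}
        ).reset_index(drop=True)
        out[GutRegion.parse(region)] = FamilyCoreSummary(
            region=GutRegion.parse(region), table=tab
        )
    return out


class TestFamilyTrajectories:
    def test_projection_matches_summaries(self):
        summaries = summaries_from_reference()
        traj = family_trajectories(summaries)
        caecum = summaries[GutRegion.CAECUM].table
        lachno = traj.query("family == 'Lachnospiraceae' and region == 'caecum'")
        assert lachno["mean_pct"].iloc[0] == pytest.approx(
            caecum.set_index("family").loc["Lachnospiraceae", "relative_abundance_pct"]
        )

    def test_published_prevotellaceae_series(self):
        traj = family_trajectories(summaries_from_reference())
        series = (
            traj.query("family == 'Prevotellaceae'")
            .set_index("region")["mean_pct"]
        )
        assert list(series.index) == [
            "caecum", "RVC", "LVC", "LDC", "RDC", "SC", "faeces",
        ]
        assert list(series.round(2)) == [2.57, 1.77, 2.09, 0.0, 3.55, 2.54, 5.74]

    def test_family_absent_from_all_but_one_region(self):
        region = GutRegion.CAECUM
        table = pd.DataFrame(
            {
                "otu_ids": ["OTU1"],
                "phylum": ["Firmicutes"],
                "class": ["Bacilli"],
                "order": ["Lactobacillales"],
                "family": ["Lactobacillaceae"],
                "relative_abundance_pct": [1.5],
                "sd_pct": [0.1],
            }
        )
        empty = table.iloc[:0]
        summaries = {
            GutRegion.CAECUM: FamilyCoreSummary(GutRegion.CAECUM, table),
            GutRegion.RVC: FamilyCoreSummary(GutRegion.RVC, empty),
        }
        traj = family_trajectories(summaries)
        series = traj.set_index("region")["mean_pct"]
        assert series["caecum"] == 1.5
        assert series["RVC"] == 0.0


class TestLineageLabel:
    def test_labels_distinguish_unclassified_depth(self):
        assert lineage_label(
            ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "unclassified")
        ) == "unclassified Bacteroidales"
        assert lineage_label(
            ("Bacteroidetes", "unclassified", "unclassified", "unclassified")
        ) == "unclassified Bacteroidetes"
        assert lineage_label(("unclassified",) * 4) == "unclassified"
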