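"""Core-community identification, size matrix and abundance profile."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from coregut import (
    CoreParams,
    ValidationError,
    core_abundance_profile,
    core_size_matrix,
    format_core_cell,
    identify_core,
)
from coregut.core_analysis import round_half_up
from conftest import build_table


def region_table(matrix, region="caecum", **kwargs):
    matrix = np.asarray(matrix)
    return build_table(
        matrix,
        animals=[f"A{i + 1}" for i in range(matrix.shape[0])],
        regions=[region] * matrix.shape[0],
        **kwargs,
    )


def oracle_core(matrix, prevalence_fraction, theta, apply_abundance=True):
    """Direct enumeration of the two core predicates."""
    matrix = np.asarray(matrix)
    n_animals, n_otus = matrix.shape
    need = math.ceil(prevalence_fraction * n_animals)
    total = matrix.sum()
    members = []
    for j in range(n_otus):
        present_in = sum(1 for a in range(n_animals) if matrix[a, j] > 0)
        if present_in < need:
            continue
        if apply_abundance and matrix[:, j].sum() / total < theta:
            continue
        members.append(f"OTU{j + 1}")
    return set(members)


class TestIdentifyCore:
    def test_both_predicates_on_toy_table(self):
        # OTU2 misses one animal; OTU3 is 3/123 ~ 2.4% < 5%
        matrix = [
            [10, 10, 1, 40],
            [10, 0, 1, 40],
            [10, 10, 1, 40],
        ]
        res = identify_core(region_table(matrix), abundance_threshold=0.05)
        assert set(res.core_otus) == {"OTU1", "OTU4"}

    def test_vacuous_thresholds_select_every_observed_otu(self):
        matrix = [[5, 0, 1], [0, 3, 1], [9, 0, 2]]
        res = identify_core(
            region_table(matrix),
            prevalence_fraction=1 / 3,
            abundance_threshold=0.0,
        )
        assert set(res.core_otus) == {"OTU1", "OTU2", "OTU3"}
        assert res.n_total_otus == 3

    def test_absence_in_one_animal_excludes_at_full_prevalence(self):
        matrix = [[1000, 10], [1000, 10], [0, 10]]
        res = identify_core(region_table(matrix))
        assert "OTU1" not in res.core_otus
        assert res.core_otus == ["OTU2"]

    def test_mixed_regions_rejected(self):
        table = build_table(
            [[5], [5]], animals=["A1", "A2"], regions=["caecum", "RVC"]
        )
        with pytest.raises(ValidationError):
            identify_core(table)

    def test_zero_depth_sample_rejected(self):
        with pytest.raises(ValidationError):
            identify_core(region_table([[5, 1], [0, 0]]))

    def test_abundance_denominator_is_region_pooled_total(self):
        # OTU1: 4 reads of 4000 = 0.1% exactly -> included at theta=0.001
        matrix = np.zeros((4, 2), dtype=int)
        matrix[:, 0] = 1
        matrix[:, 1] = 999
        res = identify_core(region_table(matrix), abundance_threshold=0.001)
        assert "OTU1" in res.core_otus

    @given(
        arrays(
            np.int64,
            st.tuples(st.integers(2, 6), st.integers(1, 20)),
            elements=st.integers(0, 30),
        ),
        st.floats(0.3, 1.0),
        st.floats(0.0, 0.1),
    )
    def test_matches_enumeration_oracle(self, matrix, prevalence, theta):
        if matrix.sum() == 0 or (matrix.sum(axis=1) == 0).any():
            matrix = matrix + 1
        res = identify_core(
            region_table(matrix),
            prevalence_fraction=prevalence,
            abundance_threshold=theta,
        )
        assert set(res.core_otus) == oracle_core(matrix, prevalence, theta)

    @given(
        arrays(
            np.int64,
            st.tuples(st.integers(2, 5), st.integers(1, 12)),
            elements=st.integers(0, 20),
        )
    )
    def test_monotone_in_thresholds(self, matrix):
        if matrix.sum() == 0 or (matrix.sum(axis=1) == 0).any():
            matrix = matrix + 1
        table = region_table(matrix)
        lo = set(identify_core(table, abundance_threshold=0.001).core_otus)
        hi = set(identify_core(table, abundance_threshold=0.05).core_otus)
        assert hi <= lo
        loose = set(
            identify_core(table, prevalence_fraction=0.5).core_otus
        )
        strict = set(identify_core(table, prevalence_fraction=1.0).core_otus)
        assert strict <= loose

    def test_invariant_to_animal_and_otu_order(self):
        rng = np.random.default_rng(13)
        matrix = rng.integers(0, 20, size=(5, 10)) + 1
        table = region_table(matrix)
        base = set(identify_core(table, abundance_threshold=0.02).core_otus)

        perm_rows = rng.permutation(5)
        perm_cols = rng.permutation(10)
        shuffled = build_table(
            matrix[perm_rows][:, perm_cols],
            animals=[f"A{i + 1}" for i in perm_rows],
            regions=["caecum"] * 5,
            sample_ids=[f"S{i + 1}" for i in perm_rows],
        )
        shuffled_counts = shuffled.counts.copy()
        shuffled_counts.columns = [f"OTU{j + 1}" for j in perm_cols]
        shuffled = shuffled.replace_counts(shuffled_counts)
        assert (
            set(identify_core(shuffled, abundance_threshold=0.02).core_otus)
            == base
        )

    def test_recovers_planted_core_from_simulation(self, sim_rarefied):
        from coregut.synthetic_data import score_core_recovery

        table, _, truth = sim_rarefied
        results = {
            region: identify_core(table.restrict_region(region))
            for region in truth.core
        }
        sens, spec = score_core_recovery(truth, results)
        assert sens == 1.0
        assert spec >= 0.99


class TestFormatting:
    def test_rounding_half_away_from_zero(self):
        assert round_half_up(1.75, 1) == 1.8
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(12.44, 1) == 12.4

    @pytest.mark.parametrize(
        "n_core,n_total,expect",
        [
            (10, 571, "10/571 (1.8%)"),
            (75, 599, "75/599 (12.5%)"),
            (7, 1478, "7/1478 (0.5%)"),
            (0, 50, "0/50 (0.0%)"),
        ],
    )
    def test_rendered_cells(self, n_core, n_total, expect):
        assert format_core_cell(n_core, n_total) == expect

    def test_trim_trailing_zero_option(self):
        assert format_core_cell(52, 1730, trim_trailing_zero=True) == "52/1730 (3%)"
        assert format_core_cell(52, 1730) == "52/1730 (3.0%)"


class TestCoreSizeMatrix:
    def test_counts_and_percentages(self):
        matrix = [[40, 4, 1], [40, 4, 0], [40, 4, 2]]
        table = region_table(matrix)
        out = core_size_matrix({0.97: table}, CoreParams(abundance_threshold=0.02))
        row = out.iloc[0]
        assert (row["n_core"], row["n_total"]) == (2, 3)
        assert row["percentage"] == 66.7
        assert row["rendered"] == "2/3 (66.7%)"

    def test_inconsistent_animal_sets_rejected(self):
        t1 = region_table([[5, 5], [5, 5]])
        t2 = build_table(
            [[5, 5], [5, 5]],
            animals=["A1", "A9"],
            regions=["caecum"] * 2,
        )
        with pytest.raises(ValidationError):
            core_size_matrix({0.90: t1, 0.97: t2})


class TestCoreAbundanceProfile:
    def test_empty_core_is_single_full_remainder(self):
        res = identify_core(
            region_table([[3, 1], [0, 4]]), abundance_threshold=0.9
        )
        prof = core_abundance_profile(res)
        assert len(prof) == 1
        assert prof.iloc[0]["segment"] == "non_core"
        assert prof.iloc[0]["fraction"] == 1.0

    def test_reads_conserved_exactly(self):
        rng = np.random.default_rng(17)
        matrix = rng.integers(0, 50, size=(6, 15)) + 1
        res = identify_core(region_table(matrix), abundance_threshold=0.01)
        prof = core_abundance_profile(res)
        assert int(prof["reads"].sum()) == int(matrix.sum())
        assert prof["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_segments_match_planted_truth_on_noiseless_fixture(self):
        from coregut import SimParams, simulate_study
        from coregut.synthetic_data import RegionCoreSpec
        from coregut.data_model import GutRegion

        params = SimParams(
            n_animals=5,
            regions=(GutRegion.ILEUM,),
            n_otus=60,
            depth_min=20000,
            depth_max=20000,
            core={"ileum": RegionCoreSpec(3, 0.5, 0.1)},
            animal_sigma=0.0,
            patchy_fraction=0.0,
            seed=29,
        )
        table, _, truth = simulate_study(params)
        res = identify_core(table.restrict_region("ileum"))
        prof = core_abundance_profile(res).set_index("segment")
        from conftest import expected_observed_share

        expect = expected_observed_share(truth, "ileum")
        assert set(res.core_otus) == set(truth.core["ileum"])
        for otu in res.core_otus:
            # multinomial se at pooled n=1e5, inflated for safety
            q = float(expect[otu])
            se = np.sqrt(q * (1 - q) / 1e5)
            assert abs(prof.loc[otu, "fraction"] - q) < 4 * se
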