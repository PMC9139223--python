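"""Usage vectors, pairing matrices, clonotypes and the Shannon index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairrep.io import ChainRecord
from pairrep.simulate import DOMINANT_SEGMENTS
from pairrep.stats import (assemble_clonotypes, clonotype_table, diversity,
                           segment_usage, shannon_index, top_clonotypes,
                           vj_pairing)


def chain(cell, locus, v, j, cdr3="AAAA", n=1):
    return ChainRecord(cell, locus, v, j, cdr3, n)


def shannon_oracle(values):
    """Independent direct-summation H' = -sum p ln p (math.fsum based)."""
    total = math.fsum(values)
    return -math.fsum(
        (v / total) * math.log(v / total) for v in values if v > 0
    )


class TestSegmentUsage:
    def test_hand_count_excludes_pseudogene_from_denominator(self, catalog):
        records = [
            chain("c1", "TRA", "TRAV9-2", "TRAJ3", n=2),
            chain("c2", "TRA", "TRAV17", "TRAJ3", n=1),
            chain("c3", "TRA", "TRAV11", "TRAJ3", n=1),  # pseudogene
        ]
        table = segment_usage(records, "TRA", "V", catalog)
        assert table["TRAV9-2"] == pytest.approx(100 * 2 / 3)
        assert table["TRAV17"] == pytest.approx(100 / 3)
        assert "TRAV11" not in table.labels
        assert table.percent.sum() == pytest.approx(100, abs=1e-6)

    def test_single_record_is_100_percent(self, catalog):
        table = segment_usage([chain("c1", "TRB", "TRBV9", "TRBJ2-1")],
                              "TRB", "V", catalog)
        assert table["TRBV9"] == pytest.approx(100)

    def test_zero_count_kept_segments_present_with_zero(self, catalog):
        table = segment_usage([chain("c1", "TRA", "TRAV17", "TRAJ3")],
                              "TRA", "V", catalog)
        assert len(table) == len(catalog.names("TRA", "V", {"functional"}))
        assert table["TRAV9-2"] == 0.0

    def test_min_count_drops_low_expressed_labels(self, catalog):
        records = [chain("c1", "TRA", "TRAV17", "TRAJ3", n=5),
                   chain("c2", "TRA", "TRAV2", "TRAJ3", n=1)]
        table = segment_usage(records, "TRA", "V", catalog, min_count=2)
        assert table.labels == ["TRAV17"]
        assert table["TRAV17"] == pytest.approx(100)

    def test_unknown_segment_kept_as_functional(self, catalog, caplog):
        records = [chain("c1", "TRA", "TRAV99", "TRAJ3")]
        with caplog.at_level("WARNING"):
            table = segment_usage(records, "TRA", "V", catalog)
        assert table["TRAV99"] == pytest.approx(100)
        assert "TRAV99" in caplog.text

    def test_reads_weighting(self, catalog):
        records = [
            ChainRecord("c1", "TRA", "TRAV17", "TRAJ3", "A", 1, read_count=9),
            ChainRecord("c2", "TRA", "TRAV2", "TRAJ3", "C", 1, read_count=1),
        ]
        by_mol = segment_usage(records, "TRA", "V", catalog)
        by_reads = segment_usage(records, "TRA", "V", catalog,
                                 weight_basis="reads")
        assert by_mol["TRAV17"] == pytest.approx(50)
        assert by_reads["TRAV17"] == pytest.approx(90)

    def test_dominant_profile_recovered_as_top5(self, catalog, sim_medium):
        _, records, _ = sim_medium
        table = segment_usage(records, "TRA", "V", catalog)
        order = np.argsort(table.percent)[::-1]
        top5 = {table.labels[i] for i in order[:5]}
        assert top5 == set(DOMINANT_SEGMENTS[("TRA", "V")])

    def test_unknown_locus_rejected(self, catalog):
        with pytest.raises(ValueError):
            segment_usage([], "IGH", "V", catalog)


class TestVjPairing:
    def test_hand_count(self, catalog):
        records = ([chain(f"c{i}", "TRA", "TRAV27", "TRAJ43") for i in range(3)]
                   + [chain("c9", "TRA", "TRAV17", "TRAJ13")])
        matrix = vj_pairing(records, "TRA", catalog)
        frame = matrix.to_frame()
        assert frame.loc["TRAV27", "TRAJ43"] == pytest.approx(75)
        assert frame.loc["TRAV17", "TRAJ13"] == pytest.approx(25)
        assert matrix.percent.sum() == pytest.approx(100)
        assert (matrix.percent > 0).sum() == 2

    def test_one_record_one_hot(self, catalog):
        matrix = vj_pairing([chain("c1", "TRB", "TRBV9", "TRBJ2-1")],
                            "TRB", catalog)
        assert matrix.percent.max() == pytest.approx(100)
        assert (matrix.percent > 0).sum() == 1

    def test_shape_is_recombinant_space(self, catalog):
        matrix = vj_pairing([], "TRB", catalog)
        n_v = len(catalog.names("TRB", "V", {"functional"}))
        n_j = len(catalog.names("TRB", "J", {"functional"}))
        assert matrix.n_recombinants == n_v * n_j
        assert n_j == 13

    def test_marginals_match_usage_on_simulated_data(self, catalog, sim_medium):
        _, records, _ = sim_medium
        for locus in ("TRA", "TRB"):
            matrix = vj_pairing(records, locus, catalog)
            v_usage = segment_usage(records, locus, "V", catalog)
            j_usage = segment_usage(records, locus, "J", catalog)
            np.testing.assert_allclose(matrix.row_sums(), v_usage.percent,
                                       rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(matrix.col_sums(), j_usage.percent,
                                       rtol=1e-9, atol=1e-9)


class TestShannonIndex:
    def test_degenerate_single_species(self):
        assert shannon_index([5]) == 0.0

    def test_uniform_is_log_s(self):
        assert shannon_index([1, 1, 1, 1]) == pytest.approx(math.log(4),
                                                            abs=1e-12)

    def test_direct_evaluation(self):
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.039720770,
                                                                 abs=1e-6)

    @pytest.mark.parametrize("s", [10, 1000, 100_000])
    def test_uniform_log_s_large(self, s):
        assert shannon_index(np.ones(s)) == pytest.approx(math.log(s),
                                                          abs=1e-12)

    def test_zero_entries_skipped(self):
        assert shannon_index([2, 0, 2]) == pytest.approx(math.log(2),
                                                         abs=1e-12)

    @pytest.mark.parametrize("bad", [[], [0, 0], [-1, 2]])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            shannon_index(bad)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1,
                    max_size=50),
           st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=80)
    def test_permutation_and_scale_invariance(self, values, factor):
        h = shannon_index(values)
        assert shannon_index(values[::-1]) == pytest.approx(h, abs=1e-9)
        assert shannon_index([v * factor for v in values]) == pytest.approx(
            h, abs=1e-9)
        assert h == pytest.approx(shannon_oracle(values), abs=1e-9)

    def test_splitting_a_clone_strictly_increases_diversity(self):
        base = [40, 30, 30]
        split = [40, 30, 15, 15]
        assert shannon_index(split) > shannon_index(base)


class TestAssembleClonotypes:
    def test_paired_cell_yields_six_tuple(self):
        records = [
            chain("c1", "TRA", "TRAV27", "TRAJ43", "AGAISNNDMR", 2),
            chain("c1", "TRB", "TRBV9", "TRBJ2-1", "ASSVVGSGTDEQF", 3),
        ]
        clonotypes, unpaired = assemble_clonotypes(records)
        assert unpaired == []
        assert clonotypes[0].key == ("TRAV27", "AGAISNNDMR", "TRAJ43",
                                     "TRBV9", "ASSVVGSGTDEQF", "TRBJ2-1")
        assert clonotypes[0].frequency_percent == pytest.approx(100)

    def test_cell_with_single_locus_is_unpaired(self):
        records = [chain("c1", "TRA", "TRAV2", "TRAJ4", "AVED")]
        clonotypes, unpaired = assemble_clonotypes(records)
        assert clonotypes == [] and unpaired == ["c1"]

    def test_dominant_chain_selected_by_molecule_count(self):
        records = [
            chain("c1", "TRA", "TRAV1-1", "TRAJ4", "AAAA", 5),
            chain("c1", "TRA", "TRAV2", "TRAJ5", "CCCC", 2),
            chain("c1", "TRB", "TRBV9", "TRBJ2-1", "ASSV", 1),
        ]
        clonotypes, _ = assemble_clonotypes(records)
        assert clonotypes[0].tra_v == "TRAV1-1"

    def test_tied_chains_resolved_lexicographically(self):
        records = [
            chain("c1", "TRA", "TRAV2", "TRAJ5", "CCCC", 3),
            chain("c1", "TRA", "TRAV1-1", "TRAJ4", "AAAA", 3),
            chain("c1", "TRB", "TRBV9", "TRBJ2-1", "ASSV", 1),
        ]
        clonotypes, _ = assemble_clonotypes(records)
        assert clonotypes[0].cdr3_a == "AAAA"

    def test_frequencies_over_paired_cells_only(self):
        records = []
        for i in range(3):
            records += [chain(f"p{i}", "TRA", "TRAV2", "TRAJ4", "AVED"),
                        chain(f"p{i}", "TRB", "TRBV9", "TRBJ2-1", "ASSV")]
        records.append(chain("solo", "TRA", "TRAV17", "TRAJ3", "ATDS"))
        clonotypes, unpaired = assemble_clonotypes(records)
        assert unpaired == ["solo"]
        assert clonotypes[0].n_cells == 3
        assert clonotypes[0].frequency_percent == pytest.approx(100)


class TestTopClonotypes:
    def _clonotypes(self, sizes):
        records = []
        cell = 0
        for idx, size in enumerate(sizes):
            for _ in range(size):
                records += [
                    chain(f"c{cell}", "TRA", "TRAV2", "TRAJ4", f"CLONE{idx}"),
                    chain(f"c{cell}", "TRB", "TRBV9", "TRBJ2-1", f"B{idx}"),
                ]
                cell += 1
        clonotypes, _ = assemble_clonotypes(records)
        return clonotypes

    def test_table3_display_convention(self):
        clonotypes = self._clonotypes([10] + [1] * 117)
        top = top_clonotypes(clonotypes, 1)
        assert top[0].n_cells == 10
        assert round(top[0].frequency_percent, 1) == 7.9

    def test_n_larger_than_distinct_returns_all(self):
        clonotypes = self._clonotypes([2, 1])
        assert len(top_clonotypes(clonotypes, 10)) == 2

    def test_ties_deterministic_lexicographic(self):
        clonotypes = self._clonotypes([3, 3])
        top = top_clonotypes(clonotypes, 2)
        assert [c.cdr3_a for c in top] == ["CLONE0", "CLONE1"]

    def test_frequencies_non_increasing_and_bounded(self):
        clonotypes = self._clonotypes([5, 3, 3, 1])
        top = top_clonotypes(clonotypes, 4)
        freqs = [c.frequency_percent for c in top]
        assert all(f <= 100 for f in freqs)
        assert freqs == sorted(freqs, reverse=True)

    def test_report_table_rounds_to_one_decimal(self):
        clonotypes = self._clonotypes([10] + [1] * 117)
        frame = clonotype_table(clonotypes, 1)
        assert frame.loc[0, "frequency_percent"] == 7.9


class TestDiversityEntities:
    def test_clonotype_entity_matches_manual_assembly(self, sim_medium):
        _, records, _ = sim_medium
        clonotypes, _ = assemble_clonotypes(records)
        expected = shannon_index([c.n_cells for c in clonotypes])
        assert diversity(records, entity="clonotype") == pytest.approx(expected)

    def test_per_locus_cdr3_entity(self):
        records = [chain("c1", "TRA", "TRAV2", "TRAJ4", "AAAA", 1),
                   chain("c2", "TRA", "TRAV2", "TRAJ4", "CCCC", 1),
                   chain("c3", "TRB", "TRBV9", "TRBJ2-1", "GGGG", 8)]
        assert diversity(records, "cdr3_aa", locus="TRA") == pytest.approx(
            math.log(2))

    def test_vj_pair_entity(self):
        records = [chain("c1", "TRA", "TRAV2", "TRAJ4"),
                   chain("c2", "TRA", "TRAV2", "TRAJ5")]
        assert diversity(records, "vj_pair", locus="TRA") == pytest.approx(
            math.log(2))

    def test_unknown_entity_rejected(self):
        with pytest.raises(ValueError):
            diversity([], entity="species")
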