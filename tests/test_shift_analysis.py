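"""Shift tables, weighted CSP, reporter classification and correlation
matching."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import allomorph as al
from allomorph.shift_analysis import (
    NITROGEN_WEIGHT,
    ReporterLibrary,
    ShiftRecord,
    ShiftTable,
    classify_closure_state,
    classify_isomer_state,
    classify_proline_isomer,
    correlation_match,
    detect_mgt,
    fisher_z_test,
    read_shift_table,
    weighted_csp,
)

NMRSTAR_FIXTURE = """\
data_synthetic_test
save_assigned_chemical_shifts
   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts
   loop_
      _Atom_chem_shift.ID
      _Atom_chem_shift.Comp_index_ID
      _Atom_chem_shift.Comp_ID
      _Atom_chem_shift.Atom_ID
      _Atom_chem_shift.Val

      1 10 ALA H 8.10
      2 10 ALA N 122.5
      3 10 ALA CB 18.9
      4 11 ILE H 7.55
      5 11 ILE N 119.2
      6 11 ILE CB 38.4
      7 12 SER H 8.42
      8 12 SER N 115.8
      9 12 SER CB 63.1
     10 13 GLY H 8.05
     11 13 GLY N 108.9
     12 13 GLY CB 30.0
     13 14 LYS H 7.91
     14 14 LYS N 120.7
     15 14 LYS CB 32.8
   stop_
save_
"""


def table_from(values, label="tab"):
    """values: dict residue -> (HN, N) or (HN, N, CB)."""
    records = []
    for residue, v in values.items():
        cb = v[2] if len(v) > 2 else None
        records.append(ShiftRecord(residue, "A", v[0], v[1], cb))
    return ShiftTable.from_records(label, records)


class TestIO:
    def test_csv_read(self, tmp_path):
        path = tmp_path / "shifts.csv"
        path.write_text(
            "residue_number,residue_type,delta_HN_ppm,delta_N_ppm\n"
            "5,A,8.30,120.0\n6,G,8.10,108.5\n7,I,7.60,121.2\n")
        table = read_shift_table(path)
        assert len(table) == 3
        assert table.data.loc[6, "delta_HN"] == 8.10

    def test_csv_round_trip(self, tmp_path):
        table = table_from({5: (8.30, 120.0, 35.0), 6: (8.10, 108.5)})
        path = tmp_path / "out.csv"
        table.write_csv(path)
        again = read_shift_table(path)
        pd.testing.assert_frame_equal(table.data, again.data)

    def test_duplicate_residue_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "residue_number,residue_type,delta_HN_ppm,delta_N_ppm\n"
            "5,A,8.30,120.0\n5,A,8.31,120.1\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_shift_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("residue_number,delta_HN_ppm\n5,8.3\n")
        with pytest.raises(ValueError, match="missing"):
            read_shift_table(path)

    def test_nmrstar_backbone_extraction(self, tmp_path):
        path = tmp_path / "shifts.str"
        path.write_text(NMRSTAR_FIXTURE)
        table = read_shift_table(path, format="nmrstar")
        assert len(table) == 5
        assert table.data.loc[11, "delta_HN"] == 7.55
        assert table.data.loc[12, "delta_CB"] == 63.1
        assert table.data.loc[13, "residue_type"] == "G"

    def test_shift_range_soft_validation_warns(self):
        with pytest.warns(UserWarning, match="outside"):
            table_from({5: (3.0, 120.0)})


class TestWeightedCSP:
    def test_identical_tables_all_zero(self):
        t = table_from({1: (8.0, 120.0), 2: (7.5, 115.0)})
        profile = weighted_csp(t, t)
        assert (profile.delta == 0).all()

    def test_proton_only_difference(self):
        x = table_from({1: (9.0, 120.0)}, "X")
        y = table_from({1: (8.0, 120.0)}, "Y")
        assert weighted_csp(x, y).delta.loc[1] == pytest.approx(1.0)

    def test_nitrogen_only_difference_scaled(self):
        x = table_from({1: (8.0, 130.0)}, "X")
        y = table_from({1: (8.0, 120.0)}, "Y")
        assert weighted_csp(x, y).delta.loc[1] == pytest.approx(1.3)

    def test_symmetry_and_offset_invariance(self):
        rng = np.random.default_rng(17)
        residues = range(1, 41)
        x = table_from({i: (rng.uniform(6, 10), rng.uniform(105, 135))
                        for i in residues}, "X")
        y = table_from({i: (rng.uniform(6, 10), rng.uniform(105, 135))
                        for i in residues}, "Y")
        forward = weighted_csp(x, y).delta
        backward = weighted_csp(y, x).delta
        assert np.allclose(forward, backward)
        shifted = ShiftTable("Xs", x.data.assign(
            delta_HN=x.data["delta_HN"] + 0.37,
            delta_N=x.data["delta_N"] + 1.9))
        shifted_y = ShiftTable("Ys", y.data.assign(
            delta_HN=y.data["delta_HN"] + 0.37,
            delta_N=y.data["delta_N"] + 1.9))
        assert np.allclose(weighted_csp(shifted, shifted_y).delta, forward)

    def test_residues_missing_in_either_are_absent(self):
        x = table_from({1: (8.0, 120.0), 2: (7.0, 118.0)}, "X")
        y = table_from({2: (7.0, 118.0), 3: (8.5, 125.0)}, "Y")
        profile = weighted_csp(x, y)
        assert list(profile.delta.index) == [2]

    def test_no_shared_residues_rejected(self):
        x = table_from({1: (8.0, 120.0)}, "X")
        y = table_from({2: (8.0, 120.0)}, "Y")
        with pytest.raises(ValueError, match="shared"):
            weighted_csp(x, y)


class TestIsomerClassification:
    def test_library_points_classify_to_themselves(self, synthetic_library):
        for state in ("cis", "trans"):
            values = {}
            for reporter, residue in (("A143", 143), ("D180", 180)):
                p = synthetic_library.cluster(reporter, state)
                values[residue] = (p["delta_HN"], p["delta_N"])
            label, evidence = classify_isomer_state(table_from(values),
                                                    synthetic_library)
            assert label == state
            assert all(d == 0.0 for _, d in evidence.values())

    def test_noisy_trans_draws_all_recovered(self, synthetic_library):
        rng = np.random.default_rng(23)
        a143 = synthetic_library.cluster("A143", "trans")
        d180 = synthetic_library.cluster("D180", "trans")
        for _ in range(100):
            values = {
                143: (a143["delta_HN"] + rng.normal(0, 0.02),
                      a143["delta_N"] + rng.normal(0, 0.02)),
                180: (d180["delta_HN"] + rng.normal(0, 0.02),
                      d180["delta_N"] + rng.normal(0, 0.02)),
            }
            label, _ = classify_isomer_state(table_from(values),
                                             synthetic_library)
            assert label == "trans"

    def test_disagreeing_reporters_are_ambiguous(self, synthetic_library):
        cis = synthetic_library.cluster("A143", "cis")
        trans = synthetic_library.cluster("D180", "trans")
        values = {143: (cis["delta_HN"], cis["delta_N"]),
                  180: (trans["delta_HN"], trans["delta_N"])}
        label, _ = classify_isomer_state(table_from(values),
                                         synthetic_library)
        assert label == "ambiguous"

    def test_no_reporters_rejected(self, synthetic_library):
        with pytest.raises(ValueError, match="reporter"):
            classify_isomer_state(table_from({5: (8.0, 120.0)}),
                                  synthetic_library)


class TestClosureClassification:
    def test_i84_proton_separates_nac3_variants(self):
        """The published I84 1HN values: ~7.00 ppm NAC III, ~7.17 NAC IIIt."""
        library = ReporterLibrary.bundled()
        nac3, _ = classify_closure_state(
            table_from({84: (7.00, 121.8)}), library)
        nac3t, _ = classify_closure_state(
            table_from({84: (7.17, 121.8)}), library)
        assert nac3 == "NAC_III"
        assert nac3t == "NAC_III_t"

    def test_open_cluster_zero_distance(self, synthetic_library):
        values = {}
        for reporter, residue in (("I84", 84), ("S88", 88)):
            p = synthetic_library.cluster(reporter, "open")
            values[residue] = (p["delta_HN"], p["delta_N"])
        label, evidence = classify_closure_state(table_from(values),
                                                 synthetic_library)
        assert label == "open"
        assert all(d == 0.0 for _, d in evidence.values())

    def test_far_from_all_clusters_is_ambiguous(self, synthetic_library):
        label, _ = classify_closure_state(table_from({84: (9.9, 135.0)}),
                                          synthetic_library)
        assert label == "ambiguous"


class TestProlineAndMgt:
    @pytest.mark.parametrize("cb,expected", [
        (35.0, "cis"), (32.0, "trans"), (33.5, "ambiguous"),
        (35.8, "cis"), (40.0, "ambiguous"),
    ])
    def test_proline_cb_classification(self, cb, expected):
        assert classify_proline_isomer(cb) == expected

    def test_proline_requires_finite_shift(self):
        with pytest.raises(ValueError):
            classify_proline_isomer(float("nan"))

    def test_upfield_displacement_signals_mgt(self):
        reference = table_from({115: (8.8, 122.0)}, "ref")
        bound = table_from({115: (8.8 - 1.6, 122.0)}, "bound")
        label, displacement = detect_mgt(bound, reference)
        assert label == "MgT_bound"
        assert displacement == pytest.approx(1.6)

    def test_identical_tables_are_mgt_free(self):
        t = table_from({115: (8.8, 122.0)})
        label, displacement = detect_mgt(t, t)
        assert label == "MgT_free"
        assert displacement == 0.0

    def test_missing_a115_indeterminate(self):
        t = table_from({5: (8.0, 120.0)})
        label, displacement = detect_mgt(t, t)
        assert label == "indeterminate"
        assert np.isnan(displacement)


class TestCorrelationMatch:
    def make_candidates(self, rng, n=77):
        residues = range(1, n + 1)
        base = {i: (rng.uniform(6.5, 9.5), rng.uniform(105, 132))
                for i in residues}
        query = table_from(base, "query")
        same = table_from({i: (h + rng.normal(0, 0.005),
                               x + rng.normal(0, 0.005))
                           for i, (h, x) in base.items()}, "same_species")
        other = table_from({i: (rng.uniform(6.5, 9.5),
                                rng.uniform(105, 132))
                            for i in residues}, "other_species")
        return query, same, other

    def test_identical_candidate_ranks_first_with_unit_r(self):
        rng = np.random.default_rng(29)
        query, _, other = self.make_candidates(rng)
        twin = ShiftTable("twin", query.data.copy())
        ranked = correlation_match(query, [other, twin])
        assert ranked[0].candidate == "twin"
        assert ranked[0].r_H == pytest.approx(1.0)
        assert ranked[0].r_N == pytest.approx(1.0)
        assert (ranked[0].z, ranked[0].p) == (0.0, 1.0)

    def test_tiny_noise_preserves_ranking(self):
        rng = np.random.default_rng(31)
        query, same, other = self.make_candidates(rng)
        ranked = correlation_match(query, [other, same])
        assert ranked[0].candidate == "same_species"
        assert min(ranked[0].r_H, ranked[0].r_N) > 0.999
        assert ranked[1].p < 0.05  # distinguishable from the near-match

    def test_anticorrelated_candidate_ranks_last(self):
        rng = np.random.default_rng(37)
        query, same, _ = self.make_candidates(rng)
        flipped = ShiftTable("flipped", query.data.assign(
            delta_HN=2 * query.data["delta_HN"].mean()
            - query.data["delta_HN"],
            delta_N=2 * query.data["delta_N"].mean()
            - query.data["delta_N"]))
        ranked = correlation_match(query, [flipped, same])
        assert ranked[-1].candidate == "flipped"
        assert ranked[-1].r_H < 0

    def test_insufficient_overlap_rejected(self):
        query = table_from({1: (8.0, 120.0), 2: (7.9, 119.0),
                            3: (7.8, 118.0)}, "q")
        with pytest.raises(ValueError):
            correlation_match(query, [ShiftTable("c", query.data.copy())],
                              min_shared=4)


class TestFisherZ:
    def test_equal_correlations_give_null(self):
        z, p = fisher_z_test(0.8, 30, 0.8, 50)
        assert z == 0.0
        assert p == 1.0

    def test_matches_hand_computed_closed_form(self):
        z, p = fisher_z_test(0.9, 50, 0.5, 50)
        expected_z = (np.arctanh(0.9) - np.arctanh(0.5)) \
            / np.sqrt(1 / 47 + 1 / 47)
        assert z == pytest.approx(expected_z, abs=1e-12)
        assert p == pytest.approx(2 * norm.sf(abs(expected_z)), abs=1e-15)

    def test_near_perfect_vs_high_correlation_significant(self):
        _, p = fisher_z_test(0.9998, 77, 0.95, 77)
        assert p < 0.05

    def test_p_matches_numerically_integrated_normal_tail(self):
        z, p = fisher_z_test(0.7, 40, 0.4, 60)
        tail, _ = quad(norm.pdf, abs(z), np.inf)
        assert p == pytest.approx(2 * tail, abs=1e-10)

    @pytest.mark.parametrize("args", [
        (1.0, 50, 0.5, 50), (0.5, 3, 0.5, 50), (0.5, 50, -1.0, 50),
    ])
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            fisher_z_test(*args)
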