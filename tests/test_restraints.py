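import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bproline import back_calculate, bin_restraints, calibrate, violations
from bproline.restraints import (
    BIN_EDGES,
    LOWER_BOUND,
    RESTRAINT_COLUMNS,
    RestraintTable,
    proton_sites,
    site_distance,
)
from tests.conftest import two_proton_structure


def make_peaks(rows):
    return pd.DataFrame(rows, columns=["resid_i", "atom_i", "resid_j", "atom_j", "volume"])


def single_restraint(upper, resid_i=1, atom_i="HX", resid_j=2, atom_j="HY"):
    return RestraintTable(
        table=pd.DataFrame(
            [
                {
                    "resid_i": resid_i,
                    "atom_i": atom_i,
                    "resid_j": resid_j,
                    "atom_j": atom_j,
                    "lower": LOWER_BOUND,
                    "upper": upper,
                    "flagged": False,
                }
            ],
            columns=RESTRAINT_COLUMNS,
        )
    )


class TestCalibrate:
    def test_exact_inversion_of_generated_volumes(self, zzz_truth, reference_distance):
        peaks = back_calculate(zzz_truth, c=5.0)
        c = calibrate(peaks, r_ref=reference_distance)
        assert c == pytest.approx(5.0, abs=1e-9)

    def test_median_rule_over_two_reference_peaks(self):
        v = 3.0
        peaks = make_peaks(
            [
                (1, "HA", 1, "HB", v),
                (2, "HA", 2, "HB", 4 * v),
            ]
        )
        assert calibrate(peaks, r_ref=2.3) == pytest.approx(2.5 * v * 2.3**6)

    def test_no_reference_pair_raises(self):
        peaks = make_peaks([(1, "HA", 2, "HD", 1.0)])
        with pytest.raises(ValueError):
            calibrate(peaks)


class TestBinning:
    @pytest.mark.parametrize(
        "distance,expected_upper,flagged",
        [(2.3, 2.5, False), (2.5, 2.5, False), (3.6, 4.5, False),
         (4.4, 4.5, False), (7.0, 5.5, True)],
    )
    def test_bin_edges(self, distance, expected_upper, flagged):
        c = 10.0
        peaks = make_peaks([(1, "HA", 2, "HD", c / distance**6)])
        rt = bin_restraints(peaks, c)
        row = rt.table.iloc[0]
        assert row["upper"] == expected_upper
        assert row["lower"] == LOWER_BOUND
        assert bool(row["flagged"]) is flagged

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6), st.floats(min_value=1.01, max_value=100.0))
    def test_larger_volume_never_larger_bin(self, volume, factor):
        c = 1.0
        peaks = make_peaks(
            [(1, "HA", 2, "HD", volume), (1, "HA", 3, "HD", volume * factor)]
        )
        rt = bin_restraints(peaks, c)
        small, big = rt.table.iloc[0], rt.table.iloc[1]
        assert big["upper"] <= small["upper"]

    def test_duplicate_pairs_collapsed(self):
        peaks = make_peaks([(1, "HA", 2, "HD", 1.0), (2, "HD", 1, "HA", 1.0)])
        rt = bin_restraints(peaks, 1.0)
        assert len(rt) == 1


class TestViolations:
    def test_generating_structure_has_no_violations(self, zzz_truth, zzz_restraints):
        assert violations(zzz_truth, zzz_restraints, 0.0) == []

    def test_boundary_overshoot(self):
        s = two_proton_structure(2.5 + 0.31)
        out = violations(s, single_restraint(2.5), tol=0.3)
        assert len(out) == 1
        (_, excess), = out
        assert excess == pytest.approx(0.01, abs=1e-9)

    def test_close_contact_below_lower_bound(self):
        s = two_proton_structure(1.0)
        out = violations(s, single_restraint(2.5), tol=0.3)
        assert len(out) == 1
        assert out[0][1] == pytest.approx(LOWER_BOUND - 0.3 - 1.0, abs=1e-9)

    def test_missing_atom_names_restraint(self, zzz_truth):
        rt = single_restraint(2.5, atom_i="HZZZ")
        with pytest.raises(KeyError, match="HZZZ"):
            violations(zzz_truth, rt, 0.3)

    def test_decoy_matches_brute_force_oracle(self, zzz_restraints):
        from bproline import ConformerSpec, assemble_oligomer

        decoy = assemble_oligomer(ConformerSpec(4, "ZEZ"))
        reported = {
            tuple(pair): excess for pair, excess in violations(decoy, zzz_restraints, 0.1)
        }
        expected = {}
        for _, row in zzz_restraints.table.iterrows():
            si = (int(row["resid_i"]), str(row["atom_i"]))
            sj = (int(row["resid_j"]), str(row["atom_j"]))
            d = site_distance(decoy, si, sj)
            if d > row["upper"] + 0.1:
                expected[(si, sj)] = d - row["upper"] - 0.1
            elif d < row["lower"] - 0.1:
                expected[(si, sj)] = row["lower"] - 0.1 - d
        assert set(reported) == set(expected)
        for key in expected:
            assert reported[key] == pytest.approx(expected[key], abs=1e-12)
        assert len(expected) > 0  # decoy genuinely violates the ZZZ restraints


class TestBackCalculate:
    def test_volume_of_known_pair(self):
        s = two_proton_structure(2.3)
        table = back_calculate(s, c=1.0)
        assert len(table) == 1
        assert table.iloc[0]["volume"] == pytest.approx(2.3**-6)

    def test_pair_beyond_cutoff_absent(self):
        s = two_proton_structure(6.0)
        assert len(back_calculate(s, c=1.0, cutoff=5.5)) == 0

    def test_full_table_matches_quadratic_oracle(self, template):
        from bproline import build_residue

        s = build_residue(template, "endo", 40.0)
        table = back_calculate(s, c=2.0, cutoff=5.5)
        sites = proton_sites(s)
        from bproline.restraints import site_members

        bd = s.bond_distances()
        expected = {}
        for x in range(len(sites)):
            for y in range(x + 1, len(sites)):
                mi = site_members(s, *sites[x])
                mj = site_members(s, *sites[y])
                if min(bd[i, j] for i in mi for j in mj) < 3:
                    continue  # geminal: fixed by covalent geometry
                d = site_distance(s, sites[x], sites[y])
                if d <= 5.5:
                    expected[(sites[x], sites[y])] = 2.0 * d**-6
        got = {
            ((int(r["resid_i"]), r["atom_i"]), (int(r["resid_j"]), r["atom_j"])): r["volume"]
            for _, r in table.iterrows()
        }
        assert set(got) == set(expected)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], rel=1e-12)

    def test_pseudo_atoms_collapse_equivalent_protons(self, zzz_truth):
        table = back_calculate(zzz_truth, c=1.0)
        names = set(table["atom_i"]) | set(table["atom_j"])
        assert "QT" in names and "QP" in names
        assert not any(n.startswith("HT") for n in names)
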