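import numpy as np
import pytest

from bproline import (
    ClashError,
    ConformerSpec,
    assemble_oligomer,
    build_extended_model,
    build_residue,
    clash_score,
    classify_pucker_geometry,
    measure_omega,
    measure_psi,
    measure_torsion,
    motif_string,
    optimize_psi,
)
from bproline.builder import overlap_energy
from bproline.structure import Atom, Structure
from tests.conftest import two_proton_structure


class TestBuildResidue:
    @pytest.mark.parametrize("pucker", ["endo", "exo"])
    def test_ha_hb_distance_matches_calibration_reference(self, template, pucker):
        s = build_residue(template, pucker, 40.0)
        d = np.linalg.norm(s.position(1, "HA") - s.position(1, "HB"))
        assert 2.2 <= d <= 2.4

    @pytest.mark.parametrize("pucker", ["endo", "exo"])
    @pytest.mark.parametrize("amplitude", [30.0, 40.0, 45.0])
    def test_pucker_round_trip(self, template, pucker, amplitude):
        s = build_residue(template, pucker, amplitude)
        label, disp = classify_pucker_geometry(s, 1)
        assert label == pucker
        assert abs(disp) > 0.1

    def test_bond_lengths_within_tolerance(self, template):
        s = build_residue(template, "endo", 40.0)
        ideal = {}
        for (a, b), L in template.ring_bond_lengths.items():
            ideal[frozenset([a, b])] = L
        for atom in template.atoms:
            if atom.kind in ("sub", "zmat", "ncap", "cterm") and atom.parent:
                ideal[frozenset([atom.parent, atom.name])] = atom.length
        checked = 0
        for i, j in s.bonds:
            key = frozenset([s.atoms[i].name, s.atoms[j].name])
            if key in ideal and ideal[key] > 0:
                assert s.distance(i, j) == pytest.approx(ideal[key], abs=0.02), key
                checked += 1
        assert checked > 30

    def test_exo_brings_beta_delta_substituents_closer(self, template):
        endo = build_residue(template, "endo", 40.0)
        exo = build_residue(template, "exo", 40.0)
        d_endo = np.linalg.norm(endo.position(1, "C") - endo.position(1, "CE"))
        d_exo = np.linalg.norm(exo.position(1, "C") - exo.position(1, "CE"))
        assert d_exo < d_endo

    def test_invalid_inputs_rejected(self, template):
        with pytest.raises(ValueError):
            build_residue(template, "twist", 40.0)
        with pytest.raises(ValueError):
            build_residue(template, "endo", 10.0)
        with pytest.raises(ValueError):
            ConformerSpec(2, "Z", chirality_pattern="AX")


class TestAssemble:
    @pytest.mark.parametrize(
        "n,configs",
        [(2, "Z"), (2, "E"), (4, "ZZZ"), (4, "ZZE"), (5, "ZZEZ"), (5, "ZEZZ")],
    )
    def test_torsion_round_trip(self, n, configs):
        spec = ConformerSpec(n, configs)
        s = assemble_oligomer(spec)
        for link in range(1, n):
            target = 0.0 if configs[link - 1] == "Z" else 180.0
            omega = measure_omega(s, link)
            assert abs((omega - target + 180.0) % 360.0 - 180.0) < 2.0
            assert abs((measure_psi(s, link) - spec.psi[link - 1] + 180.0) % 360.0 - 180.0) < 2.0
        for resid in range(1, n + 1):
            label, _ = classify_pucker_geometry(s, resid)
            assert label == spec.puckers[resid - 1]

    def test_explicit_psi_round_trip(self):
        spec = ConformerSpec(4, "ZZZ", psi=(-77.0, -77.0, -77.0))
        s = assemble_oligomer(spec)
        for link in range(1, 4):
            assert measure_psi(s, link) == pytest.approx(-77.0, abs=2.0)

    def test_dimer_omega_set_equals_measure(self):
        s = assemble_oligomer(ConformerSpec(2, "Z"))
        tau = measure_torsion(s, (1, "CB"), (1, "C"), (2, "N"), (2, "CA"))
        assert tau == pytest.approx(0.0, abs=2.0)

    @pytest.mark.parametrize("pucker", ["endo", "exo"])
    @pytest.mark.parametrize("config", ["Z", "E"])
    def test_diagnostic_contact_inequality(self, config, pucker):
        """Z puts Hβ₁ near Hα₂; E puts it near Hδ₂ — for every ψ rotamer."""
        for psi in np.linspace(-120.0, -40.0, 9):
            s = assemble_oligomer(
                ConformerSpec(2, config, psi=(float(psi),), puckers=pucker)
            )
            d_ha = np.linalg.norm(s.position(1, "HB") - s.position(2, "HA"))
            d_hd = np.linalg.norm(s.position(1, "HB") - s.position(2, "HD"))
            if config == "Z":
                assert d_ha < d_hd
            else:
                assert d_hd < d_ha

    def test_measure_torsion_requires_distinct_atoms(self, zzz_truth):
        with pytest.raises(ValueError):
            measure_torsion(zzz_truth, (1, "CA"), (1, "CA"), (1, "CB"), (1, "CG"))


class TestClashScore:
    def test_distant_atoms_score_zero(self):
        s = two_proton_structure(10.0)
        assert clash_score(s) == (0, 0.0)

    def test_superposed_duplicate_counts_all_pairs(self, zzz_truth):
        s = zzz_truth
        doubled = Structure(
            atoms=[Atom(a.resid, a.name, a.element) for a in s.atoms]
            + [Atom(a.resid + s.n_residues, a.name, a.element) for a in s.atoms],
            coords=np.vstack([s.coords, s.coords]),
            bonds=list(s.bonds)
            + [(i + s.n_atoms, j + s.n_atoms) for i, j in s.bonds],
        )
        from bproline.builder import _eligible_pairs

        count, worst = clash_score(doubled)
        n_eligible = len(_eligible_pairs(doubled)[0])
        # every cross-copy heavy pair coincides exactly; all are eligible hits
        n_heavy = sum(1 for a in s.atoms if a.element != "H")
        assert count >= n_heavy  # at least each atom clashes with its twin
        assert count <= n_eligible
        assert worst > 1.0

    def test_rigid_motion_invariance(self, zzz_truth):
        from bproline.geometry import superpose_transform

        rng = np.random.default_rng(5)
        R, _ = superpose_transform(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
        moved = zzz_truth.transformed(R, np.array([5.0, -3.0, 2.0]))
        assert clash_score(moved) == clash_score(zzz_truth)

    def test_invalid_scale_rejected(self, zzz_truth):
        with pytest.raises(ValueError):
            clash_score(zzz_truth, scale=0.0)


class TestExtendedModels:
    def test_motif_grammar(self):
        assert motif_string(6) == "ZZEZE"
        assert motif_string(8) == "ZZEZEZZ"
        assert motif_string(21) == "ZZEZE" * 4
        for n in (6, 8, 10, 21):
            assert "EE" not in motif_string(n)

    def test_all_z_pentamer_strictly_worse_than_observed_conformers(self):
        _, _, c_allz, w_allz = optimize_psi(ConformerSpec(5, "ZZZZ"), passes=2)
        for cfg in ("ZZEZ", "ZEZZ"):
            _, _, c_obs, w_obs = optimize_psi(ConformerSpec(5, cfg), passes=2)
            assert (c_allz, w_allz) > (c_obs, w_obs)
            assert c_obs == 0

    def test_all_z_extension_raises(self):
        with pytest.raises(ClashError):
            build_extended_model(5, motif_rule="ZZZZ", passes=2)

    def test_octamer_follows_grammar_and_is_clash_free(self):
        s = build_extended_model(8)
        assert s.provenance.endswith("ZZEZEZZ")
        assert clash_score(s) == (0, 0.0)

    def test_extended_chain_grows_monotonically(self):
        lengths = []
        for n in (6, 8, 10):
            s = build_extended_model(n, passes=2)
            lengths.append(
                float(np.linalg.norm(s.position(1, "N") - s.position(n, "C")))
            )
        assert lengths[0] < lengths[1] < lengths[2]
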