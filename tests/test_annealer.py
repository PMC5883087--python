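import numpy as np
import pandas as pd
import pytest

from bproline import (
    ConformerSpec,
    anneal,
    assemble_oligomer,
    back_calculate,
    bin_restraints,
    calibrate,
    clash_score,
    family_stats,
    generate_family,
    kabsch_rmsd,
    select_representative,
    target_energy,
    violations,
)
from bproline.annealer import AnnealSchedule, Ensemble, restraint_class
from bproline.restraints import RESTRAINT_COLUMNS, RestraintTable, site_distance
from bproline.structure import structure_rmsd

FAST = AnnealSchedule(high_T_steps=15, cool_steps=40, minimize_cycles=8,
                      minimize_steps_per_cycle=15, seed=0)


class TestTargetEnergy:
    def test_zero_for_generating_structure(self, zzz_truth, zzz_restraints):
        assert target_energy(zzz_truth, zzz_restraints) == 0.0

    def test_quadratic_at_unit_excess(self):
        from tests.conftest import two_proton_structure

        s = two_proton_structure(3.5)  # 1 Å over a 2.5 Å bound
        rt = RestraintTable(
            table=pd.DataFrame(
                [{"resid_i": 1, "atom_i": "HX", "resid_j": 2, "atom_j": "HY",
                  "lower": 1.8, "upper": 2.5, "flagged": False}],
                columns=RESTRAINT_COLUMNS,
            )
        )
        assert target_energy(s, rt, weights=(1.0, 1.0)) == pytest.approx(1.0, abs=1e-12)

    def test_matches_term_by_term_oracle_on_decoy(self, zzz_restraints):
        from bproline.builder import _eligible_pairs

        decoy = assemble_oligomer(ConformerSpec(4, "ZEZ"))
        w_noe, w_rep = 1.3, 0.7
        got = target_energy(decoy, zzz_restraints, weights=(w_noe, w_rep))
        expected = 0.0
        for _, row in zzz_restraints.table.iterrows():
            d = site_distance(
                decoy,
                (int(row["resid_i"]), str(row["atom_i"])),
                (int(row["resid_j"]), str(row["atom_j"])),
            )
            expected += w_noe * max(0.0, d - row["upper"]) ** 2
            expected += w_noe * max(0.0, row["lower"] - d) ** 2
        ii, jj, rsum = _eligible_pairs(decoy)
        d = np.linalg.norm(decoy.coords[ii] - decoy.coords[jj], axis=1)
        expected += w_rep * float(np.sum(np.maximum(0.0, 0.7 * rsum - d) ** 2))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_negative_weights_rejected(self, zzz_truth, zzz_restraints):
        with pytest.raises(ValueError):
            target_energy(zzz_truth, zzz_restraints, weights=(-1.0, 1.0))


class TestAnneal:
    def test_deterministic_for_fixed_seed(self, zzz_restraints):
        start = ConformerSpec(4, "ZZZ", psi=(-40.0, 40.0, -110.0))
        a = anneal(start, zzz_restraints, FAST)
        b = anneal(start, zzz_restraints, FAST)
        assert np.array_equal(a.structure.coords, b.structure.coords)
        assert a.trace == b.trace
        assert a.energy == b.energy

    def test_empty_restraints_returns_clash_free_model(self):
        start = ConformerSpec(2, "Z", psi=(30.0,))  # clashing rotamer
        res = anneal(start, None, AnnealSchedule(seed=0))
        count, _ = clash_score(res.structure)
        assert count == 0
        assert res.energy == pytest.approx(0.0, abs=1e-9)

    def test_minimization_phase_never_increases_energy(self, zzz_restraints):
        start = ConformerSpec(4, "ZZZ", psi=(-40.0, 40.0, -110.0))
        res = anneal(start, zzz_restraints, FAST)
        minimization = res.trace[3:]  # entries appended once per cycle
        assert all(b <= a + 1e-12 for a, b in zip(minimization, minimization[1:]))

    def test_recovers_generator_from_distorted_start(self, zzz_truth, zzz_restraints):
        start = ConformerSpec(4, "ZZZ", psi=(-30.0, 30.0, -130.0))
        res = anneal(start, zzz_restraints, AnnealSchedule(seed=1))
        assert violations(res.structure, zzz_restraints, 0.3) == []
        assert kabsch_rmsd(res.structure, zzz_truth) < 0.5

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            AnnealSchedule(high_T_steps=0)
        with pytest.raises(ValueError):
            AnnealSchedule(cool_start=0.0, cool_end=1.0)


class TestFamily:
    def test_family_of_one(self, zzz_spec, zzz_restraints):
        fam = generate_family(zzz_spec, zzz_restraints, FAST, n_models=1)
        assert len(fam.models) == 1
        assert fam.violation_counts == [0]

    def test_small_family_all_accepted(self, zzz_spec, zzz_restraints):
        fam = generate_family(zzz_spec, zzz_restraints, FAST, n_models=3, tol=0.3)
        assert len(fam.models) == 3
        for m in fam.models:
            assert violations(m, zzz_restraints, 0.3) == []

    def test_infeasible_restraints_raise_with_report(self, zzz_truth):
        # HA and the ester methyl of the same residue are held apart by the
        # (non-sampled) rigid template geometry, far beyond 2.5 Å
        d0 = site_distance(zzz_truth, (1, "HA"), (1, "QM"))
        assert d0 > 3.5
        rt = RestraintTable(
            table=pd.DataFrame(
                [{"resid_i": 1, "atom_i": "HA", "resid_j": 1, "atom_j": "QM",
                  "lower": 0.0, "upper": 2.5, "flagged": False}],
                columns=RESTRAINT_COLUMNS,
            )
        )
        with pytest.raises(RuntimeError, match="violation"):
            generate_family(
                ConformerSpec(4, "ZZZ"), rt, FAST, n_models=1, retry_factor=2
            )


class TestRepresentative:
    def _family_of(self, psis):
        models = [
            assemble_oligomer(ConformerSpec(4, "ZZZ", psi=p)) for p in psis
        ]
        return Ensemble(
            models=models,
            energies=[0.0] * len(models),
            violation_counts=[0] * len(models),
            accepted=[True] * len(models),
        )

    def test_centroid_model_selected(self):
        fam = self._family_of(
            [(-87.0, 77.0, -77.0), (-77.0, 77.0, -77.0), (-67.0, 77.0, -77.0)]
        )
        assert select_representative(fam) == 1

    def test_matches_brute_force_oracle(self):
        psis = [(-85.0, 70.0, -70.0), (-77.0, 77.0, -77.0),
                (-70.0, 85.0, -90.0), (-90.0, 60.0, -80.0)]
        fam = self._family_of(psis)
        idx = select_representative(fam)
        sums = []
        for i, mi in enumerate(fam.models):
            sums.append(
                sum(structure_rmsd(mi, mj, ("C", "CA", "CB", "N"))
                    for j, mj in enumerate(fam.models) if j != i)
            )
        assert idx == int(np.argmin(sums))

    def test_identical_family_ties_to_first(self):
        fam = self._family_of([(-77.0, 77.0, -77.0)] * 3)
        assert select_representative(fam) == 0

    def test_single_model_rejected(self):
        fam = self._family_of([(-77.0, 77.0, -77.0)])
        with pytest.raises(ValueError):
            select_representative(fam)


class TestFamilyStats:
    def test_identical_models_have_zero_rmsd(self, zzz_restraints):
        models = [assemble_oligomer(ConformerSpec(4, "ZZZ")) for _ in range(3)]
        fam = Ensemble(models=models, energies=[0.0] * 3,
                       violation_counts=[0] * 3, accepted=[True] * 3,
                       restraints=zzz_restraints)
        stats = family_stats(fam)
        assert stats["mean_rmsd_to_representative"] == pytest.approx(0.0, abs=1e-9)
        assert stats["max_violations_per_model"] == 0
        assert stats["n_restraints"] == len(zzz_restraints)
        counted = stats["intraresidue"] + stats["sequential"] + stats["medium-range"]
        assert counted == len(zzz_restraints)

    def test_restraint_distance_classes(self):
        assert restraint_class(2, 2) == "intraresidue"
        assert restraint_class(1, 2) == "sequential"
        assert restraint_class(1, 3) == "medium-range"
        assert restraint_class(3, 1) == "medium-range"
        assert restraint_class(1, 5) == "medium-range"
        assert restraint_class(1, 6) == "long-range"
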