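# bproline

Conformational analysis of alternating β-proline oligopeptides — short chains
of 5-phenylpyrrolidine-2-carboxylate units whose backbone amide runs through
the β-carbon and whose stereocentres alternate between the two mirror forms
of the monomer. These oligomers populate a small set of slowly
interconverting conformers in solution, distinguished by three degrees of
freedom per repeat: the Z/E configuration of each tertiary amide (torsion
ω = Cβⁱ–C′ⁱ–Nⁱ⁺¹–Cαⁱ⁺¹ near 0° or 180°), the Cγ-endo/Cγ-exo pucker of each
pyrrolidine ring, and the backbone rotation ψ = Cαⁱ–Cβⁱ–C′ⁱ–Nⁱ⁺¹.

The package is aimed at NMR spectroscopists and molecular modellers who want
a desk-scale, fully scriptable version of the classic solution-structure
workflow for this family:

* **all-atom model building** from internal coordinates — pseudorotation
  (phase/amplitude) ring construction, chirality-alternating assembly,
  steric clash scoring, and extended-chain models following the
  (ZZ)/(EZE) motif grammar;
* **ROE/NOE restraint handling** — V ∝ r⁻⁶ calibration on the Hα–Hβ
  reference distance (~2.3 Å in both puckers), binning into the four
  distance classes (2.5/3.5/4.5/5.5 Å), violation checks, pseudo-atoms for
  equivalent protons;
* **restrained refinement** by torsion-space simulated annealing into
  20-model families with the lowest-sum-of-pairwise-RMSD representative rule;
* **conformer classification** from observables — Z/E from the diagnostic
  Hβᵢ–Hαᵢ₊₁ (Z) vs Hβᵢ–Hδᵢ₊₁ (E) contacts, ring pucker from vicinal
  ³J coupling patterns via the Karplus relation;
* **thermodynamics** — Boltzmann population analysis
  ΔG_ij = −RT ln(P_j/P_i), Eyring rates, coalescence barriers, and two-site
  Bloch–McConnell exchange line-shape simulation and fitting;
* **shift regression** — affine scaling of computed isotropic shieldings
  onto experimental ¹H/¹³C shifts and conformer discrimination by fit
  quality;
* **synthetic data generators** with serialized ground truth for every
  stage, so the whole pipeline is testable without any experimental input.

## Worked example

```python
from bproline import (
    ConformerSpec, assemble_oligomer, back_calculate, bin_restraints,
    calibrate, classify_bonds, generate_family, select_representative,
    family_stats, boltzmann_dg, PopulationTable,
)
from bproline.annealer import AnnealSchedule

# build the dominant all-Z tetramer and synthesize its ROESY volumes
spec = ConformerSpec(4, "ZZZ")
truth = assemble_oligomer(spec)
peaks = back_calculate(truth, c=100.0)

# calibrate on the Halpha-Hbeta reference peaks and bin into 4 classes
restraints = bin_restraints(peaks, calibrate(peaks))
print(len(restraints))                       # 201

# refine a structure family against the restraints and classify it
family = generate_family(spec, restraints, AnnealSchedule(seed=0), n_models=5)
rep = select_representative(family)
print(classify_bonds(family.models[rep])[0])  # ZZZ
print(family_stats(family)["max_violations_per_model"])  # 0

# printed conformer populations -> relative free energies at 298 K
energies = boltzmann_dg(PopulationTable({"ZZZ": 42, "ZZE": 23}, 298.0))
print(round(energies.energies["ZZE"], 2))    # 0.36
```

The restraint count (201) is what a noiseless 5.5 Å cutoff yields for the
tetramer; `0.36` kcal·mol⁻¹ is the Z→E energy cost implied by the 42%/23%
populations; a refined family is accepted only when every model is free of
restraint violations beyond 0.3 Å.

A command-line interface mirrors the library
(`bproline build | simulate | calibrate | anneal | classify | thermo |
exchange | shifts | report`); `bproline report --config run.yaml` executes
the full volumes → calibrate → bin → anneal → classify → thermo pipeline and
writes PDB ensembles, restraint tables (TSV and CNS dialect) and a manifest
with input hashes.

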