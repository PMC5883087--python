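# Methods

This note records the models, conventions and numerical choices behind
`bproline`, in the spirit of a package reference manual: what is computed,
under which assumptions, and what the synthetic benchmarks do and do not
demonstrate.

## Molecular model

**Residue template.** Each repeat unit is a 5-phenylpyrrolidine-2-carboxylate
monomer: a pyrrolidine ring N–Cα–Cβ–Cγ–Cδ with the phenyl substituent on Cα,
the backbone carbonyl C′/O on Cβ, a methoxycarbonyl ester on Cδ, and named
protons (Hα, Hβ, Hγ2/Hγ3, Hδ). The first residue carries an acetyl cap on
the ring nitrogen; the last carries the tert-butyl ester on its backbone
carbonyl. The template ships as a versioned plain-text table
(`src/bproline/data/beta_proline_template.tsv`) of atoms, elements, bond
lengths, angles and placement rules. The systematic monomer name admits two
Greek-letter mappings; the template follows the convention with phenyl at
the α-position and the ester at the δ-position (see the file header).

Ideal internal coordinates are standard values (C–C 1.53 Å, ring C–N
1.45 Å, amide C′–N 1.35 Å, C=O 1.23 Å, C–H 1.09 Å, sp³ angles 109.5°,
planar amide). Remaining free orientation constants (phenyl ring rotation,
ester and cap orientations, terminal ester torsion) were fixed once by a
grid search that minimises steric overlap across the experimentally
observed conformer set, and are not adjusted thereafter.

**Relative configuration.** The ~2.3 Å Hα–Hβ distance observed in both ring
puckers forces Hα and Hβ onto the same ring face (cis), hence phenyl and C′
cis to each other; the spatial crowding of the β- and δ-substituents in the
Cγ-exo pucker places the ester on that same face. Stereocentre alternation
along the chain is implemented as mirror alternation of the monomer
("A"/"B" pattern); the absolute frame is fixed by the N-terminal residue.

**Ring pucker.** The five endocyclic torsions follow a pseudorotation
pattern τ_j = θ_m·cos(P + 4πj/5) with bond j = 1 being N–Cα. The ring is
built by sequential placement with exact bond lengths; the closure atom is
solved on the two-sphere intersection circle at the point best matching the
torsion pattern. The Cγ envelopes sit at P = 90°/270° (torsion about the
opposite N–Cα bond vanishing); **Cγ-endo** is defined as Cγ displaced to
the same side of the N–Cα–Cβ–Cδ best-fit plane as C′, **Cγ-exo** the
opposite. The default amplitude is θ_m = 40°, typical of proline rings; the
builder accepts 20–50°. The Cγ methylene carries an 8° rocking rotation
about its exocyclic bisector — the distortion that the asymmetric flanking
bonds (N–Cδ vs Cβ–Cγ) impose — without which the two ³J couplings to Hγ2
are numerically degenerate (both dihedrals sit at the Karplus curve
minimum) and the endo/exo coupling signature loses its asymmetry.

**Backbone.** ω targets are 0° (Z) and 180° (E). The default ψ rotamers are
the dominant minima of the Z (−77°) and E (−103°) linkages; because the two
linkage environments of an alternating-chirality chain are enantiomeric,
the default sign alternates with the chirality of the leading residue
(−77°, +77°, −77°, … for an all-Z chain). Uniform-sign defaults produce a
heavily self-intersecting all-Z tetramer; the parity-corrected defaults
build it clash-free.

**Clash scoring** counts heavy-atom pairs at least 4 bonds apart closer
than `scale · (r_i + r_j)` with Bondi radii and default scale 0.7 — chosen
so that the built all-Z tetramer at default torsions is clash-free, while
the all-Z pentamer cannot be made clash-free by any per-linkage ψ
assignment (grid search), reproducing the steric argument for mandatory E
bonds in chains longer than four. Extended chains follow the grammar of ZZ
fragments interleaved with EZE motifs (blocks ZZ, EZE, ZZ, … truncated to
n−1 linkages), with per-linkage ψ optimised by cyclic coordinate descent
over a 15° grid.

## Restraints

Cross-peak volumes obey V = c·r⁻⁶. Calibration takes the median of
V·r_ref⁶ over the intra-residue Hα–Hβ reference peaks (r_ref = 2.3 Å); the
median is robust to a single mis-integrated reference peak. Distances
d = (c/V)^{1/6} are binned into upper bounds {2.5, 3.5, 4.5, 5.5 Å}
(smallest bound ≥ d; beyond 5.5 Å clamped and flagged). The lower bound is
1.8 Å (van der Waals contact) for single-proton pairs and 0 for pseudo-atom
groups, whose r⁻⁶-summed effective distance legitimately undercuts atomic
contact. Equivalent protons (phenyl ring, methyls, tert-butyl) are treated
as pseudo-atoms (QP/QM/QC/QT) with effective distance (Σ r⁻⁶)^{−1/6}.
Back-calculation omits proton pairs fewer than three bonds apart: geminal
separations are fixed by covalent geometry and carry no conformational
information.

## Refinement

The annealer works in torsion space: ψ per linkage, a bounded ω
perturbation (±15° about the declared Z/E target — Z/E interconversion is
never sampled, matching the per-conformer treatment of slowly exchanging
species), and pseudorotation phase/amplitude per ring (amplitude clamped to
25–48°). The target is E = w_NOE·Σ max(0, d−upper)² + w_NOE·Σ max(0,
lower−d)² + w_rep·Σ overlap², zero exactly when all restraints and contacts
are satisfied.

The schedule is Metropolis sampling at a high control temperature (default
80 sweeps at T = 2, one proposal per degree of freedom per sweep, proposal
σ = 20° for torsions and 3° for amplitude, scaled by √(T/T₀) during
cooling), linear cooling 1 → 0 over 200 sweeps, then 20 cycles × 30 steps
of greedy coordinate descent (energy non-increasing by construction, step
halved when a cycle stalls). These counts are the package's desk-scale
defaults — they recover a synthetic tetramer generator to ~0.16 Å backbone
RMSD with zero violations, and a 20-model family completes in a few minutes
on one CPU — and are fully configurable through `AnnealSchedule` for users
who want longer schedules. Families are grown with consecutive seeds until
the requested number of models passes the acceptance rule (no violation
beyond 0.3 Å), with a retry cap of 10× the family size; everything is
bit-reproducible given the seed. The representative is the model with the
lowest sum of pairwise backbone RMSDs (C′, Cα, Cβ, N) to the rest of the
family, ties toward the lowest index.

## Classification

Z/E: linkage i is Z when Hβᵢ is closer to Hαᵢ₊₁ than to Hδᵢ₊₁ (distances
from a structure, or the larger diagnostic volume from a peak table; a peak
counts as present above 5% of the strongest single-proton cross peak —
pseudo-atom volumes aggregate many pairs and sit on a different scale). A
linkage with neither diagnostic is reported undetermined. The assignment is
invariant to rigid motion and to global mirroring (which flips chirality,
not Z/E).

Pucker: the five H–C–C–H ring dihedrals are mapped through the Karplus
relation J = A·cos²θ + B·cosθ + C with default (A, B, C) =
(9.5, −1.6, 1.8) Hz, and the resulting set is assigned to the nearer of the
two reference coupling patterns (endo: all couplings similar; exo: strongly
split couplings involving Hγ2/Hγ3 with ³J(Hβ,Hγ2) smallest) by
least-squares distance; fits closer than a 1 Hz margin return "ambiguous".
Only orderings and patterns are meaningful at this level of theory — the
reference values themselves derive from quantum-chemical calculation, which
this package does not perform.

## Thermodynamics and exchange

Populations map to relative free energies through ΔG_j = −RT ln(P_j/P_max)
with R = 1.98720425×10⁻³ kcal·mol⁻¹·K⁻¹; the dominant state defines zero.
Ratios are scale-free, so population tables that sum to less than 100% (minor
unlisted conformers) need no renormalisation; the inverse map normalises to
100%. Note that printed integer percentages do not always reproduce printed
energies to 2 decimals — e.g. 16% and 4% against a 42% reference give 0.57
and 1.39 kcal·mol⁻¹ where rounded published tables may print 0.56 and 1.30,
presumably from unrounded populations; this package always reports the value
implied by the percentages it is given.

Rates use the Eyring equation k = (k_B T/h)·e^{−ΔG‡/RT} with transmission
coefficient 1; at coalescence of two equal lines k_c = πΔν/√2, giving the
barrier by Eyring inversion at the coalescence temperature. Line shapes are
the two-site Bloch–McConnell absorption solution for unequal populations
under detailed balance, with the intrinsic linewidth (FWHM) entering as
R₂ = π·lw; the integrated intensity is rate-independent. Exchange fitting
estimates one rate per temperature by bounded least squares on log₁₀k, and
the activation energy by a one-parameter Eyring fit across all profiles,
with an uncertainty from the curvature of the residual surface. The fit
assumes a single averaged resonance per exchanging site, known frequency
separation and populations.

## Shift regression

Experimental shifts are regressed on computed isotropic shieldings
(δ = a·σ + b, OLS per nucleus, ¹H and ¹³C never pooled); R² is the squared
Pearson correlation and per-atom residuals are reported largest-first. A
slope far outside −1 warns but does not fail, since the regression
direction is a convention. Conformer discrimination ranks candidates by R²
then RMS residual; atoms whose predicted shifts spread across candidates by
more than 1 ppm (¹H) or 2 ppm (¹³C) are flagged as configuration-diagnostic
— the Hδ proton (downfield on Z→E) and Cβ carbon (upfield) are the expected
markers.

## Synthetic data

Every generator is seeded and serialises its ground truth as JSON. ROE
volumes get multiplicative log-normal noise of a given coefficient of
variation (volumes are positive; integration error scales with peak size);
population tables are multinomial draws from Boltzmann weights; exchange
profiles add Gaussian noise relative to the profile maximum; shift tables
perturb an exact affine map with Gaussian noise in ppm and inject the Hδ
(+1.5 ppm) / Cβ (−2.5 ppm) markers at every linkage whose configuration
differs from the generating conformer. Default problem sizes mirror the
scale of the real study (tetramer/pentamer conformers, tens of restraints
per residue pair class, 298–408 K in 10 K steps, ~25 ¹H rows per shift
table).

What the closed loop shows: that each analysis stage inverts its generator
at realistic noise (calibration recovered exactly at zero noise; <15%
mis-binned restraint classes at 20% volume noise; barriers within
0.3 kcal·mol⁻¹ at 1% line-shape noise; slopes within two standard errors at
0.1 ppm shift noise). What it does not show: robustness to spectral overlap
between conformer cross-peaks, spin diffusion, assignment errors, or
temperature-dependent populations — real-data effects the generators do not
emulate. Input volume tables are assumed to be per-conformer (resolved
multiplets); overlapping-conformer volumes are out of scope.

## Known limitations

* Energies are restraint + soft-sphere only; no force field, no solvent,
  no quantum-chemical computation of any kind (couplings and shieldings are
  consumed, never computed).
* Ester, cap and phenyl torsions are fixed template constants, not sampled
  degrees of freedom; the Cγ-exo monomer retains a small β/δ-substituent
  contact at the default clash scale, consistent with the crowding that
  restricts rotation in that pucker.
* The Hγ2/Hγ3 prochirality convention is fixed by the template; data using
  the opposite convention must be swapped on input.
* The distance-based Z/E classifier presumes the alternating-chirality
  scaffold geometry; it is not a general amide-isomer classifier.
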