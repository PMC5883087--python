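"""All-atom construction of alternating β-proline oligopeptides.

Residues are built from internal coordinates: the pyrrolidine ring from a
pseudorotation (phase/amplitude) model, exocyclic substituents from the
shipped template, and residues are chained through the amide linkage with
prescribed backbone torsions ψ (Cαⁱ–Cβⁱ–C′ⁱ–Nⁱ⁺¹) and ω
(Cβⁱ–C′ⁱ–Nⁱ⁺¹–Cαⁱ⁺¹, ≈0° for a Z and ≈180° for an E peptide bond).

The Cγ-endo pucker is defined as the envelope that displaces Cγ to the same
side of the N–Cα–Cβ–Cδ plane as the backbone carbonyl carbon C′; Cγ-exo is
the opposite envelope. The convention is self-consistent between builder and
classifier and is invariant under mirroring (which flips chirality labels,
not pucker labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import templates as T
from .geometry import (
    bond_angle,
    dihedral,
    fit_plane,
    place_atom,
    point_plane_distance,
    superpose_transform,
    wrap_angle,
)
from .structure import Atom, Structure, structure_rmsd

__all__ = [
    "ConformerSpec",
    "ClashError",
    "build_residue",
    "assemble_oligomer",
    "assemble_from_params",
    "measure_torsion",
    "measure_psi",
    "measure_omega",
    "classify_pucker_geometry",
    "clash_score",
    "kabsch_rmsd",
    "build_extended_model",
    "motif_string",
    "optimize_psi",
]

PUCKER_STATES = ("endo", "exo")
_HALF_SUB_ANGLE = np.radians(109.47 / 2.0)


class ClashError(ValueError):
    """Raised when no sterically feasible torsion assignment exists."""


# ---------------------------------------------------------------------------
# conformer specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConformerSpec:
    """Declarative state of an oligomer conformer.

    ``bond_configs`` is the Z/E string over the n−1 amide linkages; ``psi``
    the backbone rotations per linkage (defaults to the dominant rotamer of
    each configuration: −77° for Z, −103° for E); ``puckers`` one state per
    ring; ``chirality_pattern`` alternates the two mirror classes of the
    monomer ("A"/"B", default strict alternation starting from the
    N-terminal residue).
    """

    n_residues: int
    bond_configs: str = ""
    psi: tuple[float, ...] | None = None
    puckers: tuple[str, ...] | str = "endo"
    pucker_amplitude: float = 40.0
    chirality_pattern: str | None = None

    def __post_init__(self):
        n = self.n_residues
        if n < 1:
            raise ValueError("need at least one residue")
        if len(self.bond_configs) != n - 1:
            raise ValueError(f"bond_configs must have length {n - 1}")
        if any(c not in "ZE" for c in self.bond_configs):
            raise ValueError("bond_configs characters must be 'Z' or 'E'")
        if self.chirality_pattern is None:
            object.__setattr__(
                self, "chirality_pattern", "".join("AB"[i % 2] for i in range(n))
            )
        if self.psi is None:
            # the two linkage environments of an alternating chain are
            # enantiomeric, so the preferred rotamer changes sign with the
            # chirality of the leading residue
            object.__setattr__(
                self,
                "psi",
                tuple(
                    T.DEFAULT_PSI[c] * (1.0 if self.chirality_pattern[i] == "A" else -1.0)
                    for i, c in enumerate(self.bond_configs)
                ),
            )
        else:
            object.__setattr__(self, "psi", tuple(float(p) for p in self.psi))
        if len(self.psi) != n - 1:
            raise ValueError(f"psi must have length {n - 1}")
        if any(not (-180.0 < p <= 180.0) for p in self.psi):
            raise ValueError("psi values must lie in (-180, 180]")
        if isinstance(self.puckers, str):
            object.__setattr__(self, "puckers", (self.puckers,) * n)
        else:
            object.__setattr__(self, "puckers", tuple(self.puckers))
        if len(self.puckers) != n:
            raise ValueError(f"puckers must have length {n}")
        if any(p not in PUCKER_STATES for p in self.puckers):
            raise ValueError(f"puckers must be in {PUCKER_STATES}")
        if not self.pucker_amplitude > 0:
            raise ValueError("pucker amplitude must be positive")
        if len(self.chirality_pattern) != n or any(
            c not in "AB" for c in self.chirality_pattern
        ):
            raise ValueError("chirality_pattern must be a string over {A, B} of length n")

    def with_psi(self, psi) -> "ConformerSpec":
        return ConformerSpec(
            self.n_residues,
            self.bond_configs,
            tuple(psi),
            self.puckers,
            self.pucker_amplitude,
            self.chirality_pattern,
        )


# ---------------------------------------------------------------------------
# ring construction (pseudorotation)
# ---------------------------------------------------------------------------


def _dihedral_many(p0, p1, p2, p3):
    """Vectorised torsion over leading axes; inputs broadcastable (..., 3)."""
    p0, p1, p2, p3 = np.broadcast_arrays(
        np.asarray(p0, float), np.asarray(p1, float), np.asarray(p2, float), np.asarray(p3, float)
    )
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def ring_torsion_targets(phase: float, amplitude: float) -> np.ndarray:
    """Endocyclic torsion pattern τ_j = θ_m·cos(P + 4πj/5), j over the bonds
    N–Cα, Cα–Cβ, Cβ–Cγ, Cγ–Cδ, Cδ–N. The Cγ envelopes sit at P = 90°/270°,
    where the torsion about the opposite bond N–Cα vanishes."""
    j = np.arange(5)
    return amplitude * np.cos(np.radians(phase) + 0.8 * np.pi * j)


_RING_CACHE: dict[tuple, np.ndarray] = {}


def build_ring(phase: float, amplitude: float) -> np.ndarray:
    """Coordinates (5, 3) of the ring atoms N, CA, CB, CG, CD.

    Bond lengths are exact by construction (the closing pair Cγ–Cδ / Cδ–N is
    solved as a two-sphere intersection); the endocyclic torsions follow the
    pseudorotation pattern as closely as ring closure permits.
    """
    key = (round(phase, 4), round(amplitude, 4))
    cached = _RING_CACHE.get(key)
    if cached is not None:
        return cached.copy()

    L = T.default_template().ring_bond_lengths
    l_na, l_ab, l_bg, l_gd, l_dn = (
        L[("N", "CA")],
        L[("CA", "CB")],
        L[("CB", "CG")],
        L[("CG", "CD")],
        L[("CD", "N")],
    )
    tau = ring_torsion_targets(phase, amplitude)
    a = np.radians(T.RING_ANGLE)

    N = np.zeros(3)
    CA = np.array([l_na, 0.0, 0.0])
    CB = CA + l_ab * np.array([-np.cos(a), np.sin(a), 0.0])
    CG = place_atom(CB, CA, N, l_bg, T.RING_ANGLE, tau[1])

    # close the ring: CD lies on the circle |CD-CG| = l_gd, |CD-N| = l_dn
    axis = N - CG
    D = np.linalg.norm(axis)
    u = axis / D
    along = (l_gd**2 - l_dn**2 + D**2) / (2.0 * D)
    rho_sq = l_gd**2 - along**2
    if rho_sq <= 0:
        raise ValueError("ring closure infeasible for the requested geometry")
    rho = np.sqrt(rho_sq)
    center = CG + along * u
    e1 = np.cross(u, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(u, np.array([0.0, 1.0, 0.0]))
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    def closure_error(t):
        cd = center + rho * (np.cos(t)[:, None] * e1 + np.sin(t)[:, None] * e2)
        r3 = _dihedral_many(CA, CB, CG, cd) - tau[2]
        r4 = _dihedral_many(CB, CG, cd, N) - tau[3]
        r5 = _dihedral_many(CG, cd, N, CA) - tau[4]
        r1 = _dihedral_many(cd, N, CA, CB) - tau[0]
        res = np.stack([wrap_angle(r) for r in (r1, r3, r4, r5)])
        return np.sum(res**2, axis=0)

    t_grid = np.linspace(0.0, 2.0 * np.pi, 181)
    err = closure_error(t_grid)
    k = int(np.argmin(err))
    # parabolic refinement around the best grid point
    tm, t0, tp = t_grid[k - 1], t_grid[k], t_grid[(k + 1) % len(t_grid)]
    em, e0, ep = (
        closure_error(np.array([tm]))[0],
        err[k],
        closure_error(np.array([tp]))[0],
    )
    denom = em - 2 * e0 + ep
    t_best = t0 if abs(denom) < 1e-12 else t0 + 0.5 * (em - ep) / denom * (t_grid[1] - t_grid[0])
    CD = center + rho * (np.cos(t_best) * e1 + np.sin(t_best) * e2)

    ring = np.vstack([N, CA, CB, CG, CD])
    _RING_CACHE[key] = ring.copy()
    if len(_RING_CACHE) > 4096:
        _RING_CACHE.clear()
    return ring


# ---------------------------------------------------------------------------
# residue construction
# ---------------------------------------------------------------------------


def _sub_position(host, prev, nxt, side, length, rock: float = 0.0):
    """Exocyclic substituent on a ring atom, symmetric about the ring tangent.

    ``rock`` rotates the substituent pair coherently about the exocyclic
    bisector (degrees) — the CH₂ rocking that the asymmetric N/C flanking
    bonds impose on the Cγ methylene.
    """
    u1 = prev - host
    u1 /= np.linalg.norm(u1)
    u2 = nxt - host
    u2 /= np.linalg.norm(u2)
    b = -(u1 + u2)
    b /= np.linalg.norm(b)
    v = np.cross(u1, u2)
    v /= np.linalg.norm(v)
    if rock:
        w = np.cross(b, v)
        rho = np.radians(rock)
        v = np.cos(rho) * v + np.sin(rho) * w
    direction = np.cos(_HALF_SUB_ANGLE) * b + side * np.sin(_HALF_SUB_ANGLE) * v
    return host + length * direction


_META_CACHE: dict[int, tuple] = {}
_RES_CACHE: dict[tuple, np.ndarray] = {}


def _tpl_meta(template: T.ResidueTemplate):
    """Row layout of the residue base block (ring + sub + zmat atoms)."""
    key = id(template)
    cached = _META_CACHE.get(key)
    if cached is not None:
        return cached
    base = [a.name for a in template.atoms if a.kind in ("ring", "sub", "zmat")]
    row = {n: i for i, n in enumerate(base)}
    subs = [
        (row[a.name], T.RING_ATOMS.index(a.parent), a.side, a.length, a.torsion)
        for a in template.atoms_of_kind("sub")
    ]
    zmats = [
        (row[a.name], row[a.parent], row[a.ref1], row[a.ref2], a.length, a.angle, a.torsion)
        for a in template.atoms_of_kind("zmat")
    ]
    meta = (tuple(base), row, tuple(subs), tuple(zmats))
    _META_CACHE[key] = meta
    return meta


def _residue_coords(
    template: T.ResidueTemplate, phase: float, amplitude: float, mirror: bool
) -> np.ndarray:
    """Residue base-block coordinates in a local frame (cached; treat as
    read-only). ``mirror`` selects the enantiomeric monomer."""
    key = (round(phase, 4), round(amplitude, 4), mirror, id(template))
    cached = _RES_CACHE.get(key)
    if cached is not None:
        return cached

    base, row, subs, zmats = _tpl_meta(template)
    ring = build_ring(phase, amplitude)
    arr = np.empty((len(base), 3))
    arr[:5] = ring
    for r, ring_i, side, length, rock in subs:
        prev = ring[(ring_i - 1) % 5]
        nxt = ring[(ring_i + 1) % 5]
        arr[r] = _sub_position(ring[ring_i], prev, nxt, side, length, rock)
    for r, rp, r1, r2, length, angle, torsion in zmats:
        arr[r] = place_atom(arr[rp], arr[r1], arr[r2], length, angle, torsion)
    if mirror:
        arr = arr * np.array([1.0, 1.0, -1.0])
    arr.setflags(write=False)
    _RES_CACHE[key] = arr
    if len(_RES_CACHE) > 2048:
        _RES_CACHE.clear()
    return arr


def residue_local(
    template: T.ResidueTemplate, phase: float, amplitude: float, mirror: bool
) -> dict[str, np.ndarray]:
    """Dict view (atom name → coordinates) of a locally built residue."""
    base, _, _, _ = _tpl_meta(template)
    arr = _residue_coords(template, phase, amplitude, mirror)
    return {n: arr[i].copy() for i, n in enumerate(base)}


def _ring_label(pos: dict[str, np.ndarray]) -> tuple[str, float]:
    """Pucker label from residue coordinates; displacement signed so that
    the C′ side of the N–Cα–Cβ–Cδ plane is positive (endo > 0)."""
    plane_pts = np.vstack([pos[n] for n in ("N", "CA", "CB", "CD")])
    centroid, normal = fit_plane(plane_pts)
    d_c = point_plane_distance(pos["C"], centroid, normal)
    if d_c < 0:
        normal = -normal
    disp = point_plane_distance(pos["CG"], centroid, normal)
    if abs(disp) <= 0.05:
        return "planar", disp
    return ("endo" if disp > 0 else "exo"), disp


_PHASE_RULE: dict[str, float] = {}


def phase_for_pucker(pucker: str) -> float:
    """Pseudorotation phase (90° or 270°) realising the requested Cγ pucker.

    The Cγ envelopes sit where the torsion about the opposite N–Cα bond
    vanishes, i.e. at cos(P) = 0.
    """
    if pucker not in PUCKER_STATES:
        raise ValueError(f"unknown pucker label {pucker!r}; expected one of {PUCKER_STATES}")
    if not _PHASE_RULE:
        tpl = T.default_template()
        for phase in (90.0, 270.0):
            label, _ = _ring_label(residue_local(tpl, phase, 40.0, mirror=False))
            _PHASE_RULE[label] = phase
    return _PHASE_RULE[pucker]


# ---------------------------------------------------------------------------
# oligomer assembly
# ---------------------------------------------------------------------------

#: per-residue atom output order: template order, then the carbonyl oxygen;
#: caps are appended to the first / last residue.


def assemble_from_params(
    n_residues: int,
    omegas,
    psis,
    phases,
    amplitudes,
    chirality: str,
    template: T.ResidueTemplate | None = None,
    psi_term: float | None = None,
    provenance: str = "",
    check_overlap: bool = True,
) -> Structure:
    """Assemble an oligomer from raw per-linkage/per-ring parameters.

    ``omegas``/``psis`` have length n−1; ``phases``/``amplitudes`` length n;
    ``chirality`` is the A/B mirror pattern. This is the fast core used both
    by :func:`assemble_oligomer` and by the torsion-space annealer.
    """
    tpl = template or T.default_template()
    n = n_residues
    base, row, _, _ = _tpl_meta(tpl)
    blocks = [
        _residue_coords(tpl, phases[i], amplitudes[i], mirror=(chirality[i] == "B"))
        for i in range(n)
    ]
    r_c, r_cb, r_ca, r_n, r_cd = row["C"], row["CB"], row["CA"], row["N"], row["CD"]

    placed: list[np.ndarray] = [blocks[0]]
    oxygens: list[np.ndarray] = []
    for i in range(n - 1):
        cur = placed[i]
        nxt = blocks[i + 1]
        c, cb, ca = cur[r_c], cur[r_cb], cur[r_ca]
        n_anchor = place_atom(c, cb, ca, T.AMIDE_C_N, T.ANGLE_CB_C_N, psis[i])
        oxygens.append(place_atom(c, cb, ca, T.CARBONYL_C_O, T.ANGLE_CB_C_O, psis[i] + 180.0))
        # local geometry of the incoming ring at its nitrogen
        ln, lca, lcd = nxt[r_n], nxt[r_ca], nxt[r_cd]
        d_nca = np.linalg.norm(lca - ln)
        d_ncd = np.linalg.norm(lcd - ln)
        theta_ring = bond_angle(lca, ln, lcd)
        ca_anchor = place_atom(n_anchor, c, cb, d_nca, T.ANGLE_C_N_CA, omegas[i])
        # planar tertiary amide nitrogen: Cδ lies opposite Cα across the C-N axis
        ang_cd = 360.0 - T.ANGLE_C_N_CA - theta_ring
        cd_anchor = place_atom(n_anchor, c, cb, d_ncd, ang_cd, omegas[i] + 180.0)
        R, t = superpose_transform(
            np.vstack([ln, lca, lcd]), np.vstack([n_anchor, ca_anchor, cd_anchor])
        )
        placed.append(nxt @ R.T + t)

    # last residue: carbonyl oxygen and C-terminal tert-butyl ester. Fixed
    # torsion constants describe the canonical monomer and change sign on
    # the mirrored one (cap atoms are placed after any mirroring).
    last = {name: placed[-1][i] for i, name in enumerate(base)}
    sign_last = 1.0 if chirality[n - 1] == "A" else -1.0
    if psi_term is None:
        psi_term = sign_last * T.TERMINAL_PSI
    c, cb, ca = last["C"], last["CB"], last["CA"]
    oxygens.append(place_atom(c, cb, ca, T.CARBONYL_C_O, T.ANGLE_CB_C_O, psi_term + 180.0))
    for atom in tpl.atoms_of_kind("cterm"):
        if atom.name == "OT":
            last["OT"] = place_atom(c, cb, ca, atom.length, atom.angle, psi_term)
        else:
            last[atom.name] = place_atom(
                last[atom.parent], last[atom.ref1], last[atom.ref2],
                atom.length, atom.angle, sign_last * atom.torsion,
            )

    # first residue: N-terminal acyl cap, in the amide plane of the ring N
    first = {name: placed[0][i] for i, name in enumerate(base)}
    sign_first = 1.0 if chirality[0] == "A" else -1.0
    cap_atoms = tpl.atoms_of_kind("ncap")
    if cap_atoms:
        npos, capos, cdpos = first["N"], first["CA"], first["CD"]
        u1 = capos - npos
        u1 /= np.linalg.norm(u1)
        u2 = cdpos - npos
        u2 /= np.linalg.norm(u2)
        b = -(u1 + u2)
        first["CCAP"] = npos + cap_atoms[0].length * b / np.linalg.norm(b)
        for atom in cap_atoms[1:]:
            first[atom.name] = place_atom(
                first[atom.parent], first[atom.ref1], first[atom.ref2],
                atom.length, atom.angle, sign_first * atom.torsion,
            )

    atoms, bonds = _oligomer_topology(tpl, n)
    ncap_names = [a.name for a in tpl.atoms_of_kind("ncap")]
    cterm_names = [a.name for a in tpl.atoms_of_kind("cterm")]
    parts: list[np.ndarray] = []
    for resid0 in range(n):
        resid = resid0 + 1
        block = placed[resid0]
        extra = [oxygens[resid0]]
        if resid == 1:
            extra += [first[nm] for nm in ncap_names]
        if resid == n:
            extra += [last[nm] for nm in cterm_names]
        parts.append(block)
        parts.append(np.vstack(extra))
    s = Structure(
        atoms=list(atoms),
        coords=np.vstack(parts),
        bonds=list(bonds),
        provenance=provenance,
    )
    if check_overlap:
        _flag_overlaps(s)
    return s


_TOPO_CACHE: dict[tuple, tuple] = {}


def _oligomer_topology(tpl: T.ResidueTemplate, n: int):
    """Atom records and bond index pairs for an n-residue chain (cached)."""
    key = (id(tpl), n)
    cached = _TOPO_CACHE.get(key)
    if cached is not None:
        return cached
    base = [a.name for a in tpl.atoms if a.kind in ("ring", "sub", "zmat")]
    elements = {a.name: a.element for a in tpl.atoms}
    elements["O"] = "O"
    atoms: list[Atom] = []
    index: dict[tuple[int, str], int] = {}
    for resid in range(1, n + 1):
        order = list(base) + ["O"]
        if resid == 1:
            order += [a.name for a in tpl.atoms_of_kind("ncap")]
        if resid == n:
            order += [a.name for a in tpl.atoms_of_kind("cterm")]
        for name in order:
            index[(resid, name)] = len(atoms)
            atoms.append(Atom(resid, name, elements[name]))
    bonds: list[tuple[int, int]] = []
    for resid in range(1, n + 1):
        for a1, a2 in tpl.bonds:
            if (resid, a1) in index and (resid, a2) in index:
                bonds.append((index[(resid, a1)], index[(resid, a2)]))
        bonds.append((index[(resid, "C")], index[(resid, "O")]))
    for i in range(n - 1):
        bonds.append((index[(i + 1, "C")], index[(i + 2, "N")]))
    result = (tuple(atoms), tuple(sorted(set(tuple(sorted(b)) for b in bonds))))
    _TOPO_CACHE[key] = result
    return result


def _flag_overlaps(s: Structure, threshold: float = 0.5) -> None:
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(s.coords))
    np.fill_diagonal(d, np.inf)
    for i, j in s.bonds:
        d[i, j] = d[j, i] = np.inf
    ii, jj = np.where(np.triu(d < threshold))
    for i, j in zip(ii, jj):
        a, b = s.atoms[i], s.atoms[j]
        s.flags.append(
            f"atom overlap {d[i, j]:.2f} Å: {a.resid}:{a.name} / {b.resid}:{b.name}"
        )


def assemble_oligomer(
    spec: ConformerSpec, template: T.ResidueTemplate | None = None
) -> Structure:
    """Build the all-atom model declared by ``spec``.

    Placement overlaps below 0.5 Å are reported through ``Structure.flags``
    (the model is still returned).
    """
    tpl = template or T.default_template()
    omegas = [T.OMEGA_TARGET[c] for c in spec.bond_configs]
    phases = [phase_for_pucker(p) for p in spec.puckers]
    amps = [spec.pucker_amplitude] * spec.n_residues
    return assemble_from_params(
        spec.n_residues,
        omegas,
        spec.psi,
        phases,
        amps,
        spec.chirality_pattern,
        template=tpl,
        provenance=f"built:{spec.bond_configs or 'monomer'}",
    )


def build_residue(
    template: T.ResidueTemplate | None = None,
    pucker: str = "endo",
    amplitude: float = 40.0,
) -> Structure:
    """Build a single capped 5-phenylpyrrolidine-2-carboxylate residue."""
    if pucker not in PUCKER_STATES:
        raise ValueError(f"unknown pucker label {pucker!r}; expected one of {PUCKER_STATES}")
    if not (20.0 < amplitude < 50.0):
        raise ValueError("pucker amplitude must lie in (20°, 50°)")
    spec = ConformerSpec(1, "", puckers=pucker, pucker_amplitude=amplitude)
    return assemble_oligomer(spec, template=template)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------


def measure_torsion(s: Structure, a1, a2, a3, a4) -> float:
    """Torsion over four (resid, name) atom references, degrees (IUPAC)."""
    refs = (a1, a2, a3, a4)
    if len(set(refs)) != 4:
        raise ValueError("torsion requires four distinct atoms")
    pts = [s.position(*r) for r in refs]
    return dihedral(*pts)


def measure_psi(s: Structure, linkage: int) -> float:
    """ψ of linkage i (1-based): torsion Cαⁱ–Cβⁱ–C′ⁱ–Nⁱ⁺¹."""
    return measure_torsion(
        s, (linkage, "CA"), (linkage, "CB"), (linkage, "C"), (linkage + 1, "N")
    )


def measure_omega(s: Structure, linkage: int) -> float:
    """ω of linkage i (1-based): torsion Cβⁱ–C′ⁱ–Nⁱ⁺¹–Cαⁱ⁺¹."""
    return measure_torsion(
        s, (linkage, "CB"), (linkage, "C"), (linkage + 1, "N"), (linkage + 1, "CA")
    )


def classify_pucker_geometry(s: Structure, residue: int) -> tuple[str, float]:
    """Pucker state of a residue plus the signed Cγ out-of-plane displacement.

    Displacement is measured from the N–Cα–Cβ–Cδ best-fit plane, positive on
    the side of the backbone carbonyl carbon. |displacement| ≤ 0.05 Å returns
    the "planar" diagnostic instead of a state label.
    """
    pos = {n: s.position(residue, n) for n in ("N", "CA", "CB", "CG", "CD", "C")}
    return _ring_label(pos)


# ---------------------------------------------------------------------------
# steric clash scoring
# ---------------------------------------------------------------------------

_PAIR_CACHE: dict = {}


def _eligible_pairs(s: Structure):
    """Heavy-atom pairs separated by ≥ 4 bonds, with van der Waals radius sums."""
    key = (
        len(s.atoms),
        hash(tuple(s.bonds)),
        hash(tuple(a.element for a in s.atoms)),
    )
    cached = _PAIR_CACHE.get(key)
    if cached is not None:
        return cached
    heavy = np.array([i for i, a in enumerate(s.atoms) if a.element != "H"])
    bd = s.bond_distances()
    ii, jj = [], []
    for x in range(len(heavy)):
        for y in range(x + 1, len(heavy)):
            i, j = heavy[x], heavy[y]
            if bd[i, j] >= 4:
                ii.append(i)
                jj.append(j)
    ii = np.array(ii, dtype=int)
    jj = np.array(jj, dtype=int)
    radii = np.array([T.BONDI_RADII[a.element] for a in s.atoms])
    rsum = radii[ii] + radii[jj]
    result = (ii, jj, rsum)
    _PAIR_CACHE[key] = result
    if len(_PAIR_CACHE) > 64:
        _PAIR_CACHE.clear()
    return result


def clash_score(s: Structure, scale: float = 0.7) -> tuple[int, float]:
    """Count heavy-atom pairs (≥ 4 bonds apart) closer than
    ``scale · (r_vdw_i + r_vdw_j)``; also return the worst overlap in Å."""
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must lie in (0, 1]")
    ii, jj, rsum = _eligible_pairs(s)
    if len(ii) == 0:
        return 0, 0.0
    d = np.linalg.norm(s.coords[ii] - s.coords[jj], axis=1)
    overlap = scale * rsum - d
    clashing = overlap > 0
    worst = float(overlap.max()) if clashing.any() else 0.0
    return int(np.count_nonzero(clashing)), worst


def overlap_energy(s: Structure, scale: float = 0.7) -> float:
    """Soft-sphere repulsion: Σ overlap² over eligible heavy-atom pairs."""
    ii, jj, rsum = _eligible_pairs(s)
    if len(ii) == 0:
        return 0.0
    d = np.linalg.norm(s.coords[ii] - s.coords[jj], axis=1)
    overlap = np.maximum(0.0, scale * rsum - d)
    return float(np.sum(overlap**2))


def kabsch_rmsd(a: Structure, b: Structure, selection=T.BACKBONE_ATOMS) -> float:
    """Least-squares superposition RMSD over the named atoms (Å)."""
    return structure_rmsd(a, b, selection)


# ---------------------------------------------------------------------------
# extended models: the ZZ / EZE motif grammar
# ---------------------------------------------------------------------------


def motif_string(n_residues: int) -> str:
    """Z/E string for an extended chain: ZZ fragments interleaved with EZE
    motifs (blocks ZZ, EZE, ZZ, … truncated to the n−1 linkages)."""
    blocks = ["ZZ", "EZE"]
    out = ""
    k = 0
    while len(out) < n_residues - 1:
        out += blocks[k % 2]
        k += 1
    return out[: n_residues - 1]


def optimize_psi(
    spec: ConformerSpec,
    grid=None,
    passes: int = 3,
    scale: float = 0.7,
) -> tuple[Structure, ConformerSpec, int, float]:
    """Greedy per-linkage ψ optimisation of the soft-sphere clash energy.

    Cycles over linkages, testing each grid value while the others are held
    fixed; returns (structure, optimised spec, clash count, worst overlap).
    """
    if grid is None:
        grid = np.arange(-165.0, 181.0, 15.0)
    psi = list(spec.psi)
    best_spec = spec.with_psi(psi)

    def energy_of(p):
        sp = spec.with_psi(p)
        s = assemble_oligomer(sp)
        return overlap_energy(s, scale), s, sp

    best_e, best_s, best_spec = energy_of(psi)
    for _ in range(passes):
        improved = False
        for link in range(spec.n_residues - 1):
            for val in grid:
                trial = list(best_spec.psi)
                trial[link] = float(val)
                e, s, sp = energy_of(trial)
                if e < best_e - 1e-12:
                    best_e, best_s, best_spec = e, s, sp
                    improved = True
        if not improved:
            break
    count, worst = clash_score(best_s, scale)
    return best_s, best_spec, count, worst


def build_extended_model(
    n_residues: int,
    motif_rule: str = "ZZ/EZE",
    scale: float = 0.7,
    grid=None,
    passes: int = 3,
) -> Structure:
    """Build a long chain following the motif grammar (or an explicit Z/E
    string) with per-linkage ψ optimised to remove steric clashes.

    Raises :class:`ClashError` when no clash-free ψ assignment is found.
    """
    if n_residues < 2:
        raise ValueError("need at least two residues")
    if motif_rule == "ZZ/EZE":
        configs = motif_string(n_residues)
    else:
        configs = motif_rule
        if len(configs) != n_residues - 1 or any(c not in "ZE" for c in configs):
            raise ValueError("explicit motif rule must be a Z/E string of length n-1")
    spec = ConformerSpec(n_residues, configs)
    s, sp, count, worst = optimize_psi(spec, grid=grid, passes=passes, scale=scale)
    if count > 0:
        ii, jj, rsum = _eligible_pairs(s)
        d = np.linalg.norm(s.coords[ii] - s.coords[jj], axis=1)
        overlap = scale * rsum - d
        k = int(np.argmax(overlap))
        a, b = s.atoms[ii[k]], s.atoms[jj[k]]
        raise ClashError(
            f"no clash-free ψ assignment for {configs}: worst offender "
            f"{a.resid}:{a.name} / {b.resid}:{b.name} overlap {overlap[k]:.2f} Å "
            f"({count} clashing pairs)"
        )
    s.provenance = f"extended:{configs}"
    return s
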