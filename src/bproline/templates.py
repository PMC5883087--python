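"""Residue template for the 5-phenylpyrrolidine-2-carboxylate unit.

The template is shipped as a versioned plain-text table
(``data/beta_proline_template.tsv``) listing every atom with its element and
internal-coordinate placement rule. The five ring atoms (N, CA, CB, CG, CD)
are built from a pseudorotation model; exocyclic substituents on ring carbons
are placed symmetrically about the local ring tangent with a chirality sign;
all remaining atoms are ordinary Z-matrix entries.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import networkx as nx

RING_ATOMS = ("N", "CA", "CB", "CG", "CD")

#: Bondi van der Waals radii (Å) for the elements that occur in the template.
BONDI_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52}

#: Equivalent-proton groups collapsed to pseudo-atoms with an r⁻⁶-summed
#: effective distance (methyls rotate fast; phenyl flips average the ring).
PSEUDO_GROUPS = {
    "QP": ("HP2", "HP3", "HP4", "HP5", "HP6"),  # phenyl ring protons
    "QM": ("HM1", "HM2", "HM3"),                # ester O-methyl
    "QC": ("HC1", "HC2", "HC3"),                # N-terminal acetyl methyl
    "QT": tuple(f"HT{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)),  # tert-butyl
}

#: Backbone atoms used for family RMSD statistics.
BACKBONE_ATOMS = ("C", "CA", "CB", "N")

#: Default backbone rotation ψ (Cα–Cβ–C′–N, degrees) for each amide
#: configuration; the dominant rotamer of the Z linkage sits near −77° and of
#: the E linkage near −103°.
DEFAULT_PSI = {"Z": -77.0, "E": -103.0}

#: Amide torsion ω (Cβⁱ–C′ⁱ–Nⁱ⁺¹–Cαⁱ⁺¹) targets.
OMEGA_TARGET = {"Z": 0.0, "E": 180.0}

# Inter-residue / carbonyl ideal internal coordinates (Å, degrees).
AMIDE_C_N = 1.35
CARBONYL_C_O = 1.23
ANGLE_CB_C_N = 114.0
ANGLE_CB_C_O = 121.0
ANGLE_C_N_CA = 121.0
#: Torsion about Cβ–C′ used to orient the last residue's ester oxygen.
TERMINAL_PSI = 150.0

#: Target endocyclic bond angle used when closing the pyrrolidine ring.
RING_ANGLE = 104.0


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    element: str
    kind: str  # ring | sub | zmat | ncap | cterm
    parent: str | None = None
    ref1: str | None = None
    ref2: str | None = None
    side: int = 0
    length: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0


@dataclass(frozen=True)
class ResidueTemplate:
    """Parsed template: atom records, bond list and ring bond lengths."""

    atoms: tuple[TemplateAtom, ...]
    bonds: tuple[tuple[str, str], ...] = field(default=())
    version: str = "1.0"

    def __post_init__(self):
        object.__setattr__(self, "_by_name", {a.name: a for a in self.atoms})
        self.validate()

    def __getitem__(self, name: str) -> TemplateAtom:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def ring_bond_lengths(self) -> dict[tuple[str, str], float]:
        # each ring atom stores the bond length to the previous atom in the
        # cycle; N stores the closing CD-N bond
        lengths = {}
        for i in range(1, 5):
            lengths[(RING_ATOMS[i - 1], RING_ATOMS[i])] = self._by_name[RING_ATOMS[i]].length
        lengths[("CD", "N")] = self._by_name["N"].length
        return lengths

    def atoms_of_kind(self, *kinds: str) -> list[TemplateAtom]:
        return [a for a in self.atoms if a.kind in kinds]

    def validate(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError("duplicate atom names in template")
        g = nx.Graph(self.bonds)
        if set(g.nodes) != set(names):
            missing = set(names) - set(g.nodes)
            raise ValueError(f"atoms without bonds in template: {sorted(missing)}")
        if not nx.is_connected(g):
            raise ValueError("template bond graph is not connected")
        ring_cycle = [tuple(sorted((RING_ATOMS[i - 1], RING_ATOMS[i]))) for i in range(5)]
        for b in ring_cycle:
            if not g.has_edge(*b):
                raise ValueError(f"ring bond {b} missing; ring must be the 5-cycle N-CA-CB-CG-CD")
        for a in self.atoms:
            if a.element == "H":
                (heavy,) = list(g.neighbors(a.name))
                if self._by_name[heavy].element == "H":
                    raise ValueError(f"proton {a.name} not bonded to a heavy atom")


def _parse_row(row: dict[str, str]) -> TemplateAtom:
    def opt(key):
        v = row[key]
        return None if v == "." else v

    def num(key, default=0.0):
        v = row[key]
        return default if v == "." else float(v)

    return TemplateAtom(
        name=row["atom"],
        element=row["element"],
        kind=row["kind"],
        parent=opt("parent"),
        ref1=opt("ref1"),
        ref2=opt("ref2"),
        side=int(num("side", 0)),
        length=num("length"),
        angle=num("angle"),
        torsion=num("torsion"),
    )


def load_template() -> ResidueTemplate:
    """Load the shipped β-proline residue template."""
    text = (
        importlib.resources.files("bproline")
        .joinpath("data/beta_proline_template.tsv")
        .read_text()
    )
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    atoms = [_parse_row(dict(zip(header, ln.split("\t")))) for ln in lines[1:]]

    version = "1.0"
    for ln in text.splitlines():
        if "version" in ln and ln.startswith("#"):
            version = ln.rsplit("version", 1)[1].strip()
            break

    bonds: list[tuple[str, str]] = []
    for i in range(5):
        bonds.append((RING_ATOMS[i - 1], RING_ATOMS[i]))
    for a in atoms:
        if a.kind == "ring":
            continue
        if a.parent is not None:
            bonds.append((a.parent, a.name))
    bonds.append(("CP6", "CP1"))  # phenyl ring closure
    return ResidueTemplate(atoms=tuple(atoms), bonds=tuple(bonds), version=version)


_TEMPLATE_CACHE: ResidueTemplate | None = None


def default_template() -> ResidueTemplate:
    global _TEMPLATE_CACHE
    if _TEMPLATE_CACHE is None:
        _TEMPLATE_CACHE = load_template()
    return _TEMPLATE_CACHE
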