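"""Ordered all-atom record with residue indexing and a bond graph."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .geometry import kabsch_rmsd as _kabsch_rmsd


@dataclass(frozen=True)
class Atom:
    resid: int  # 1-based residue index
    name: str
    element: str


@dataclass
class Structure:
    """All-atom model: ordered atom records, coordinates (Å) and bonds.

    ``bonds`` holds index pairs into ``atoms``. ``flags`` carries non-fatal
    diagnostics raised during construction (e.g. placement overlaps).
    """

    atoms: list[Atom]
    coords: np.ndarray
    bonds: list[tuple[int, int]]
    provenance: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self._index: dict[tuple[int, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.resid, a.name)
            if key in self._index:
                raise ValueError(f"duplicate atom {a.name} in residue {a.resid}")
            self._index[key] = i
        self._graph: nx.Graph | None = None

    # -- lookup ---------------------------------------------------------
    def index(self, resid: int, name: str) -> int:
        try:
            return self._index[(resid, name)]
        except KeyError:
            raise KeyError(f"no atom {name!r} in residue {resid}") from None

    def has_atom(self, resid: int, name: str) -> bool:
        return (resid, name) in self._index

    def position(self, resid: int, name: str) -> np.ndarray:
        return self.coords[self.index(resid, name)]

    @property
    def n_residues(self) -> int:
        return max(a.resid for a in self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_atoms(self, resid: int) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.resid == resid]

    def select(self, names, resids=None) -> list[int]:
        """Indices of atoms whose name is in ``names`` (ordered by residue,
        then by the order of ``names``), optionally limited to ``resids``."""
        names = tuple(names)
        out = []
        for resid in range(1, self.n_residues + 1):
            if resids is not None and resid not in resids:
                continue
            for nm in names:
                if self.has_atom(resid, nm):
                    out.append(self.index(resid, nm))
        return out

    # -- graph ----------------------------------------------------------
    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(range(len(self.atoms)))
            g.add_edges_from(self.bonds)
            self._graph = g
        return self._graph

    def bond_distances(self) -> np.ndarray:
        """Bond-count (graph) distance matrix; unreachable pairs are inf."""
        n = len(self.atoms)
        dist = np.full((n, n), np.inf)
        for src, lengths in nx.all_pairs_shortest_path_length(self.graph()):
            for dst, d in lengths.items():
                dist[src, dst] = d
        return dist

    # -- convenience ----------------------------------------------------
    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Structure":
        return replace(self, coords=self.coords @ R.T + t, flags=list(self.flags))

    def copy(self) -> "Structure":
        return Structure(
            atoms=list(self.atoms),
            coords=self.coords.copy(),
            bonds=list(self.bonds),
            provenance=self.provenance,
            flags=list(self.flags),
        )

    def validate_bonds(self, lo: float = 0.7, hi: float = 1.9) -> None:
        """Check bonded heavy-atom distances fall in [lo, hi] Å."""
        for i, j in self.bonds:
            if self.atoms[i].element == "H" or self.atoms[j].element == "H":
                continue
            d = self.distance(i, j)
            if not (lo <= d <= hi):
                raise ValueError(
                    f"bond {self.atoms[i]}-{self.atoms[j]} length {d:.2f} Å outside [{lo}, {hi}]"
                )


def structure_rmsd(a: Structure, b: Structure, selection) -> float:
    """Kabsch RMSD between two structures over atoms named in ``selection``.

    Selections are matched per residue in identical order; both structures
    must contain the same selected atoms.
    """
    ia = a.select(selection)
    ib = b.select(selection)
    if len(ia) != len(ib):
        raise ValueError("selected atom counts differ between structures")
    if len(ia) < 3:
        raise ValueError("need at least 3 selected atoms")
    return _kabsch_rmsd(a.coords[ia], b.coords[ib])
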