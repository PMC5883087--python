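"""File formats: PDB models/ensembles, restraint tables (TSV and CNS
dialect), population/energy tables and shielding/shift tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .restraints import LOWER_BOUND, RESTRAINT_COLUMNS, RestraintTable
from .structure import Atom, Structure
from .thermo import EnergyTable, PopulationTable

__all__ = [
    "write_pdb",
    "read_pdb",
    "write_restraints_tsv",
    "read_restraints_tsv",
    "write_cns_restraints",
    "write_population_tsv",
    "read_population_tsv",
    "write_energy_tsv",
    "write_shift_tsv",
    "read_shift_tsv",
    "write_manifest",
]

RESIDUE_NAME = "BPR"


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def _to_gemmi(models: list[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "bproline"
    for m_idx, s in enumerate(models, start=1):
        model = gemmi.Model(m_idx)
        chain = gemmi.Chain("A")
        for resid in range(1, s.n_residues + 1):
            res = gemmi.Residue()
            res.name = RESIDUE_NAME
            res.seqid = gemmi.SeqId(resid, " ")
            for i in s.residue_atoms(resid):
                a = s.atoms[i]
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                x, y, z = s.coords[i]
                atom.pos = gemmi.Position(x, y, z)
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(models: Structure | list[Structure], path) -> None:
    """Write one model, or an ensemble as MODEL/ENDMDL blocks (chain A,
    residues numbered from 1)."""
    if isinstance(models, Structure):
        models = [models]
    st = _to_gemmi(models)
    doc = st.make_pdb_string()
    # strip the date-bearing header line so identical runs give identical files
    lines = [ln for ln in doc.splitlines() if not ln.startswith(("HEADER", "TITLE "))]
    Path(path).write_text("\n".join(lines) + "\n")


def _infer_bonds(atoms: list[Atom], coords: np.ndarray) -> list[tuple[int, int]]:
    """Distance-based bond inference: heavy pairs < 1.9 Å bond; each proton
    bonds to its nearest heavy atom."""
    bonds = []
    heavy = [i for i, a in enumerate(atoms) if a.element != "H"]
    for x in range(len(heavy)):
        for y in range(x + 1, len(heavy)):
            i, j = heavy[x], heavy[y]
            d = np.linalg.norm(coords[i] - coords[j])
            if d < 1.9:
                bonds.append((i, j))
    for i, a in enumerate(atoms):
        if a.element != "H":
            continue
        d = np.linalg.norm(coords[heavy] - coords[i], axis=1)
        bonds.append(tuple(sorted((i, heavy[int(np.argmin(d))]))))
    return sorted(set(tuple(sorted(b)) for b in bonds))


def read_pdb(path) -> list[Structure]:
    """Read a PDB file back into Structures (one per MODEL). Bonds are
    re-inferred from distances."""
    st = gemmi.read_structure(str(path))
    out = []
    for model in st:
        atoms: list[Atom] = []
        coords = []
        for chain in model:
            for res in chain:
                for atom in res:
                    atoms.append(Atom(res.seqid.num, atom.name, atom.element.name))
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        coords = np.asarray(coords)
        out.append(
            Structure(
                atoms=atoms,
                coords=coords,
                bonds=_infer_bonds(atoms, coords),
                provenance=f"read:{path}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# restraints
# ---------------------------------------------------------------------------


def write_restraints_tsv(rt: RestraintTable, path) -> None:
    df = rt.table.copy()
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# calibration\t{rt.calibration!r}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_restraints_tsv(path) -> RestraintTable:
    calibration = np.nan
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# calibration"):
            calibration = float(first.split("\t")[1])
            table = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            table = pd.read_csv(fh, sep="\t")
    if "flagged" not in table.columns:
        table["flagged"] = False
    if "lower" not in table.columns:
        table["lower"] = LOWER_BOUND
    return RestraintTable(table=table[RESTRAINT_COLUMNS], calibration=calibration)


def write_cns_restraints(rt: RestraintTable, path) -> None:
    """CNS-style NOE table: assign (resid i and name a)(resid j and name b)
    d dminus dplus with bounds [d − dminus, d + dplus]."""
    lines = []
    for _, row in rt.table.iterrows():
        d = 0.5 * (row["lower"] + row["upper"])
        dminus = d - row["lower"]
        dplus = row["upper"] - d
        lines.append(
            f"assign (resid {int(row['resid_i'])} and name {row['atom_i']}) "
            f"(resid {int(row['resid_j'])} and name {row['atom_j']}) "
            f"{d:.2f} {dminus:.2f} {dplus:.2f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_population_tsv(p: PopulationTable, path) -> None:
    df = pd.DataFrame(
        {"conformer": list(p.populations), "population_percent": list(p.populations.values())}
    )
    with open(path, "w") as fh:
        fh.write(f"# temperature_K\t{p.temperature}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_population_tsv(path) -> PopulationTable:
    temperature = 298.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# temperature_K"):
            temperature = float(first.split("\t")[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    return PopulationTable(
        populations=dict(zip(df["conformer"], df["population_percent"])),
        temperature=temperature,
    )


def write_energy_tsv(e: EnergyTable, path) -> None:
    df = pd.DataFrame(
        {
            "conformer": list(e.energies),
            "dG_kcal_per_mol": [f"{v:.2f}" for v in e.energies.values()],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# temperature_K\t{e.temperature}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_shift_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_shift_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def write_manifest(path, inputs: dict, outputs: dict, config: dict) -> None:
    """Run manifest: configuration echo plus SHA-256 of inputs/outputs."""

    def digest(p):
        h = hashlib.sha256()
        h.update(Path(p).read_bytes())
        return h.hexdigest()

    manifest = {
        "config": config,
        "inputs": {k: {"path": str(v), "sha256": digest(v)} for k, v in inputs.items()},
        "outputs": {k: {"path": str(v), "sha256": digest(v)} for k, v in outputs.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
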