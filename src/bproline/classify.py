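"""Conformer classification from NMR observables.

Z/E amide configurations are read from the characteristic short contacts:
a Z linkage puts Hβᵢ close to Hαᵢ₊₁, an E linkage puts Hβᵢ close to Hδᵢ₊₁.
Ring puckers are read from the pattern of vicinal ³J couplings: the Cγ-exo
state shows strongly split couplings involving Hγ2/Hγ3 (with ³J(Hβ,Hγ2)
near zero) while Cγ-endo couplings are all of similar size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .builder import measure_torsion
from .restraints import site_distance
from .structure import Structure

__all__ = [
    "CouplingSet",
    "KARPLUS_DEFAULT",
    "PUCKER_PATTERNS",
    "classify_bonds",
    "karplus_j",
    "predict_ring_couplings",
    "classify_pucker_from_j",
]

#: Default Karplus coefficients (A, B, C) in Hz for ³J(H,H) across H–C–C–H.
KARPLUS_DEFAULT = (9.5, -1.6, 1.8)

#: Reference vicinal-coupling patterns (Hz) for the two ring puckers, in the
#: order J(Hα,Hβ), J(Hβ,Hγ2), J(Hβ,Hγ3), J(Hδ,Hγ2), J(Hδ,Hγ3).
PUCKER_PATTERNS = {
    "endo": (8.7, 11.6, 6.1, 9.7, 6.9),
    "exo": (9.6, 0.5, 9.0, 0.7, 10.0),
}

#: A diagnostic cross-peak counts as "present" above this fraction of the
#: strongest peak in its table.
PRESENCE_THRESHOLD = 0.05


@dataclass(frozen=True)
class CouplingSet:
    """Vicinal ring couplings in Hz."""

    j_ab: float   # ³J(Hα,Hβ)
    j_bg2: float  # ³J(Hβ,Hγ2)
    j_bg3: float  # ³J(Hβ,Hγ3)
    j_dg2: float  # ³J(Hδ,Hγ2)
    j_dg3: float  # ³J(Hδ,Hγ3)

    def as_array(self) -> np.ndarray:
        return np.array([self.j_ab, self.j_bg2, self.j_bg3, self.j_dg2, self.j_dg3])

    def __post_init__(self):
        if any(j < 0 or j > 15.0 for j in self.as_array()):
            raise ValueError("vicinal couplings must lie in [0, 15] Hz")


# ---------------------------------------------------------------------------
# Z/E classification
# ---------------------------------------------------------------------------


def _classify_from_structure(s: Structure):
    labels = []
    margins = []
    for link in range(1, s.n_residues):
        d_za = site_distance(s, (link, "HB"), (link + 1, "HA"))
        d_ed = site_distance(s, (link, "HB"), (link + 1, "HD"))
        labels.append("Z" if d_za < d_ed else "E")
        margins.append(abs(d_za - d_ed))
    return "".join(labels), margins


def _classify_from_peaks(peaks: pd.DataFrame):
    if "volume" in peaks.columns:
        # pseudo-atom (group) volumes aggregate many proton pairs and sit on
        # a different scale; the presence threshold is referenced to the
        # strongest single-proton cross peak
        from .templates import PSEUDO_GROUPS

        single = peaks[
            ~peaks["atom_i"].isin(PSEUDO_GROUPS) & ~peaks["atom_j"].isin(PSEUDO_GROUPS)
        ]
        strongest = float((single if len(single) else peaks)["volume"].max())
        threshold = PRESENCE_THRESHOLD * strongest
        score_col, prefer_large = "volume", True
    elif "distance" in peaks.columns:
        score_col, prefer_large = "distance", False
        threshold = None
    else:
        raise ValueError("peak table needs a 'volume' or 'distance' column")

    n_res = int(max(peaks["resid_i"].max(), peaks["resid_j"].max()))

    def lookup(ri, ai, rj, aj):
        m = peaks[
            ((peaks["resid_i"] == ri) & (peaks["atom_i"] == ai)
             & (peaks["resid_j"] == rj) & (peaks["atom_j"] == aj))
            | ((peaks["resid_i"] == rj) & (peaks["atom_i"] == aj)
               & (peaks["resid_j"] == ri) & (peaks["atom_j"] == ai))
        ]
        if len(m) == 0:
            return None
        v = float(m[score_col].iloc[0])
        if threshold is not None and v < threshold:
            return None
        return v

    labels, margins = [], []
    for link in range(1, n_res):
        v_z = lookup(link, "HB", link + 1, "HA")
        v_e = lookup(link, "HB", link + 1, "HD")
        if v_z is None and v_e is None:
            labels.append("U")
            margins.append(0.0)
            continue
        if v_e is None:
            labels.append("Z")
            margins.append(v_z)
        elif v_z is None:
            labels.append("E")
            margins.append(v_e)
        else:
            if prefer_large:
                labels.append("Z" if v_z > v_e else "E")
            else:
                labels.append("Z" if v_z < v_e else "E")
            margins.append(abs(v_z - v_e))
    return "".join(labels), margins


def classify_bonds(source) -> tuple[str, list[float]]:
    """Assign the Z/E string of an oligomer from short-contact data.

    ``source`` is either a :class:`Structure` (distances are measured
    directly) or a peak/contact table with columns resid_i, atom_i, resid_j,
    atom_j and either ``volume`` (larger diagnostic volume wins) or
    ``distance`` (shorter wins). A linkage with neither diagnostic pair is
    labelled "U" (undetermined). Returns the label string and a per-linkage
    discrimination margin.
    """
    if isinstance(source, Structure):
        return _classify_from_structure(source)
    return _classify_from_peaks(source)


# ---------------------------------------------------------------------------
# Karplus couplings and pucker classification
# ---------------------------------------------------------------------------


def karplus_j(theta: float, coefficients=KARPLUS_DEFAULT) -> float:
    """Karplus relation J(θ) = A·cos²θ + B·cosθ + C (θ in degrees)."""
    theta = float(theta)
    if not np.isfinite(theta):
        raise ValueError("dihedral angle must be finite")
    a, b, c = coefficients
    ct = np.cos(np.radians(theta))
    return float(a * ct * ct + b * ct + c)


_RING_J_DIHEDRALS = (
    ("HA", "CA", "CB", "HB"),
    ("HB", "CB", "CG", "HG2"),
    ("HB", "CB", "CG", "HG3"),
    ("HD", "CD", "CG", "HG2"),
    ("HD", "CD", "CG", "HG3"),
)


def predict_ring_couplings(
    s: Structure, residue: int, coefficients=KARPLUS_DEFAULT
) -> CouplingSet:
    """Apply the Karplus relation to the five H–C–C–H ring dihedrals of one
    residue."""
    js = []
    for a1, a2, a3, a4 in _RING_J_DIHEDRALS:
        for nm in (a1, a2, a3, a4):
            if not s.has_atom(residue, nm):
                raise KeyError(f"residue {residue} missing proton/carbon {nm}")
        theta = measure_torsion(s, (residue, a1), (residue, a2), (residue, a3), (residue, a4))
        js.append(np.clip(karplus_j(theta, coefficients), 0.0, 15.0))
    return CouplingSet(*js)


def classify_pucker_from_j(j: CouplingSet) -> tuple[str, float]:
    """Nearest-pattern pucker assignment by least-squares distance to the
    endo/exo reference coupling patterns.

    Returns the closer state and the score margin between the two fits;
    margins below 1 Hz give the label "ambiguous".
    """
    obs = j.as_array()
    dists = {
        state: float(np.sum((obs - np.array(pattern)) ** 2))
        for state, pattern in PUCKER_PATTERNS.items()
    }
    ranked = sorted(dists, key=dists.get)
    margin = float(np.sqrt(dists[ranked[1]]) - np.sqrt(dists[ranked[0]]))
    if margin < 1.0:
        return "ambiguous", margin
    return ranked[0], margin
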