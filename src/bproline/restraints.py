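"""ROE/NOE peak volumes → binned distance restraints, and violation checks.

Cross-peak volumes follow V ≈ c·r⁻⁶. Calibration uses the intra-ring Hα–Hβ
pairs, whose separation is essentially pucker-independent (~2.3 Å), and the
derived distances are clustered into four classes with upper bounds 2.5,
3.5, 4.5 and 5.5 Å. Equivalent protons (methyls, phenyl ring, tert-butyl)
are treated as pseudo-atoms with an r⁻⁶-summed effective distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import Structure
from .templates import PSEUDO_GROUPS

__all__ = [
    "BIN_EDGES",
    "LOWER_BOUND",
    "REFERENCE_DISTANCE",
    "RestraintTable",
    "proton_sites",
    "site_members",
    "site_distance",
    "calibrate",
    "bin_restraints",
    "violations",
    "back_calculate",
]

#: Upper-bound classes for binned distance restraints (Å).
BIN_EDGES = (2.5, 3.5, 4.5, 5.5)

#: Van der Waals contact lower bound applied to every restraint (Å).
LOWER_BOUND = 1.8

#: Reference Hα–Hβ distance used for volume calibration (Å).
REFERENCE_DISTANCE = 2.3

PEAK_COLUMNS = ["resid_i", "atom_i", "resid_j", "atom_j", "volume"]
RESTRAINT_COLUMNS = ["resid_i", "atom_i", "resid_j", "atom_j", "lower", "upper", "flagged"]

_MEMBER_TO_GROUP = {m: g for g, members in PSEUDO_GROUPS.items() for m in members}


@dataclass
class RestraintTable:
    """Distance restraints: one row per unordered proton-pair with a lower
    bound, a binned upper bound and an out-of-range flag."""

    table: pd.DataFrame
    calibration: float = np.nan

    def __post_init__(self):
        missing = [c for c in RESTRAINT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"restraint table missing columns {missing}")
        t = self.table
        if (t["lower"] >= t["upper"]).any():
            raise ValueError("restraint lower bound must be below the upper bound")
        if not t["upper"].isin(BIN_EDGES).all():
            raise ValueError(f"upper bounds must be one of {BIN_EDGES}")
        keys = t.apply(_pair_key, axis=1)
        if keys.duplicated().any():
            raise ValueError("duplicate unordered proton pairs in restraint table")

    def __len__(self):
        return len(self.table)


def _pair_key(row) -> tuple:
    a = (int(row["resid_i"]), str(row["atom_i"]))
    b = (int(row["resid_j"]), str(row["atom_j"]))
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# proton sites and effective distances
# ---------------------------------------------------------------------------


def proton_sites(s: Structure) -> list[tuple[int, str]]:
    """Observable proton sites: individual protons plus pseudo-atoms for the
    equivalent-proton groups present in each residue."""
    sites: list[tuple[int, str]] = []
    seen_groups: set[tuple[int, str]] = set()
    for a in s.atoms:
        if a.element != "H":
            continue
        group = _MEMBER_TO_GROUP.get(a.name)
        if group is None:
            sites.append((a.resid, a.name))
        else:
            key = (a.resid, group)
            if key not in seen_groups:
                seen_groups.add(key)
                sites.append(key)
    return sites


def site_members(s: Structure, resid: int, name: str) -> list[int]:
    """Atom indices making up a site (a proton, or a pseudo-atom group)."""
    if name in PSEUDO_GROUPS:
        idx = [s.index(resid, m) for m in PSEUDO_GROUPS[name] if s.has_atom(resid, m)]
        if not idx:
            raise KeyError(f"pseudo-atom {name} has no members in residue {resid}")
        return idx
    return [s.index(resid, name)]


def site_distance(s: Structure, site_i: tuple[int, str], site_j: tuple[int, str]) -> float:
    """Effective distance between two sites: (Σ r⁻⁶)^(−1/6) over member pairs."""
    ii = site_members(s, *site_i)
    jj = site_members(s, *site_j)
    d = np.linalg.norm(s.coords[ii][:, None, :] - s.coords[jj][None, :, :], axis=-1)
    return float(np.sum(d**-6.0) ** (-1.0 / 6.0))


# ---------------------------------------------------------------------------
# calibration and binning
# ---------------------------------------------------------------------------


def _is_reference(row, reference_pairs) -> bool:
    if reference_pairs is not None:
        return _pair_key(row) in reference_pairs
    return (
        row["resid_i"] == row["resid_j"]
        and {row["atom_i"], row["atom_j"]} == {"HA", "HB"}
    )


def calibrate(
    peaks: pd.DataFrame,
    reference_pairs=None,
    r_ref: float = REFERENCE_DISTANCE,
) -> float:
    """Calibration constant c from reference cross-peaks.

    ``c`` is the median of V·r_ref⁶ over the reference pairs (default: the
    intra-residue Hα–Hβ peaks). The median is preferred over the mean for
    robustness against a single mis-integrated reference peak.
    """
    if r_ref <= 0:
        raise ValueError("reference distance must be positive")
    if reference_pairs is not None:
        reference_pairs = {tuple(sorted(p)) for p in reference_pairs}
    mask = peaks.apply(lambda r: _is_reference(r, reference_pairs), axis=1)
    ref = peaks.loc[mask] if len(peaks) else peaks
    if len(ref) == 0:
        raise ValueError("no reference pair found in the peak table")
    c = float(np.median(ref["volume"].to_numpy() * r_ref**6))
    if c <= 0:
        raise ValueError("non-positive calibration constant")
    return c


def bin_restraints(peaks: pd.DataFrame, c: float) -> RestraintTable:
    """Convert volumes to distances d = (c/V)^(1/6) and cluster into the four
    upper-bound classes. Distances beyond the last class are clamped to its
    5.5 Å bound and flagged."""
    if c <= 0:
        raise ValueError("calibration constant must be positive")
    if (peaks["volume"] <= 0).any():
        raise ValueError("peak volumes must be positive")
    rows = []
    seen = set()
    for _, row in peaks.iterrows():
        key = _pair_key(row)
        if key in seen:
            continue
        seen.add(key)
        d = (c / float(row["volume"])) ** (1.0 / 6.0)
        upper = next((b for b in BIN_EDGES if d <= b), BIN_EDGES[-1])
        # an r⁻⁶-summed pseudo-atom distance may legitimately undercut the
        # van der Waals contact floor, so group restraints carry no floor
        pseudo = row["atom_i"] in PSEUDO_GROUPS or row["atom_j"] in PSEUDO_GROUPS
        rows.append(
            {
                "resid_i": int(row["resid_i"]),
                "atom_i": str(row["atom_i"]),
                "resid_j": int(row["resid_j"]),
                "atom_j": str(row["atom_j"]),
                "lower": 0.0 if pseudo else LOWER_BOUND,
                "upper": float(upper),
                "flagged": bool(d > BIN_EDGES[-1]),
            }
        )
    table = pd.DataFrame(rows, columns=RESTRAINT_COLUMNS)
    return RestraintTable(table=table, calibration=c)


# ---------------------------------------------------------------------------
# structure checks
# ---------------------------------------------------------------------------


def violations(
    s: Structure, t: RestraintTable, tol: float = 0.3
) -> list[tuple[tuple, float]]:
    """Restraint violations beyond ``tol``: pairs with d > upper + tol or
    d < lower − tol, with the overshoot in Å."""
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    out = []
    for _, row in t.table.iterrows():
        si = (int(row["resid_i"]), str(row["atom_i"]))
        sj = (int(row["resid_j"]), str(row["atom_j"]))
        try:
            d = site_distance(s, si, sj)
        except KeyError as exc:
            raise KeyError(f"restraint {si}-{sj}: {exc}") from None
        if d > row["upper"] + tol:
            out.append(((si, sj), d - (row["upper"] + tol)))
        elif d < row["lower"] - tol:
            out.append(((si, sj), (row["lower"] - tol) - d))
    return out


def back_calculate(s: Structure, c: float = 1.0, cutoff: float = 5.5) -> pd.DataFrame:
    """Predicted peak-volume table: one row per proton-site pair with an
    effective distance ≤ cutoff, V = c·d⁻⁶.

    Geminal pairs (protons fewer than three bonds apart, fixed at ~1.76 Å by
    covalent geometry) are omitted: their cross-peaks carry no conformational
    information and sit below the van der Waals restraint floor.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sites = proton_sites(s)
    bd = s.bond_distances()
    rows = []
    for x in range(len(sites)):
        for y in range(x + 1, len(sites)):
            ii = site_members(s, *sites[x])
            jj = site_members(s, *sites[y])
            if min(bd[i, j] for i in ii for j in jj) < 3:
                continue
            d = site_distance(s, sites[x], sites[y])
            if d <= cutoff:
                (ri, ai), (rj, aj) = sites[x], sites[y]
                rows.append(
                    {
                        "resid_i": ri,
                        "atom_i": ai,
                        "resid_j": rj,
                        "atom_j": aj,
                        "volume": c * d**-6.0,
                    }
                )
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)
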