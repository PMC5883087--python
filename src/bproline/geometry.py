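"""Low-level vector geometry: torsions, angles, internal-coordinate placement,
plane fits and Kabsch superposition.

All coordinates are in Å, all angles in degrees unless noted. Torsions follow
the IUPAC sign convention (cis = 0°, values in (−180°, 180°]).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "bond_angle",
    "place_atom",
    "fit_plane",
    "point_plane_distance",
    "kabsch_rotation",
    "kabsch_rmsd",
    "superpose_transform",
    "wrap_angle",
]


def wrap_angle(a: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees into (−180, 180]."""
    w = np.mod(np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0
    w = np.where(w == -180.0, 180.0, w)
    if np.ndim(a) == 0:
        return float(w)
    return w


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0–p1–p2–p3 in degrees, IUPAC convention.

    Satisfies dihedral(a, b, c, d) == dihedral(d, c, b, a). Raises
    ``ValueError`` if either inner triple is collinear (torsion undefined).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise ValueError("central atoms coincide; torsion undefined")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise ValueError("collinear atom triple; torsion undefined")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def bond_angle(p0, p1, p2) -> float:
    """Angle p0–p1–p2 at vertex p1, in degrees [0, 180]."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    u = p0 - p1
    v = p2 - p1
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(c, b, a, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom ``d`` bonded to ``c`` from internal coordinates.

    ``|d−c| = bond``, angle d–c–b = ``angle`` and torsion a–b–c–d =
    ``torsion`` (degrees). This is the standard natural-extension
    (self-normalising frame) construction used by Z-matrix builders.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc = bc / np.sqrt(bc @ bc)
    ab = b - a
    n = _cross3(ab, bc)
    nn = np.sqrt(n @ n)
    if nn < 1e-10:
        raise ValueError("reference atoms collinear; torsion frame undefined")
    n = n / nn
    m = _cross3(n, bc)
    x = -bond * np.cos(ang)
    y = bond * np.sin(ang) * np.cos(tor)
    z = bond * np.sin(ang) * np.sin(tor)
    return c + x * bc + y * m + z * n


def _cross3(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    # explicit 3-vector cross product; avoids np.cross dispatch overhead
    return np.array(
        [
            u[1] * v[2] - u[2] * v[1],
            u[2] * v[0] - u[0] * v[2],
            u[0] * v[1] - u[1] * v[0],
        ]
    )


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through ``points`` → (centroid, unit normal).

    The normal direction follows the smallest principal axis of the point
    cloud; its sign is arbitrary but deterministic.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]


def point_plane_distance(point, centroid, normal) -> float:
    """Signed distance of ``point`` from the plane (centroid, normal)."""
    return float(np.dot(np.asarray(point, dtype=float) - centroid, normal))


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation mapping centred ``P`` onto centred ``Q``."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD between coordinate sets after optimal superposition.

    ``P`` and ``Q`` are (n, 3) arrays with matched rows, n ≥ 3.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    R = kabsch_rotation(Pc, Qc)
    diff = (R @ Pc.T).T - Qc
    return float(np.sqrt((diff * diff).sum() / P.shape[0]))


def superpose_transform(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) minimising ‖R·P + t − Q‖; apply as ``x @ R.T + t``."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    R = kabsch_rotation(P - pc, Q - qc)
    t = qc - R @ pc
    return R, t
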