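"""Linear scaling of computed isotropic shieldings onto chemical shifts.

Computed isotropic shieldings σ map onto experimental shifts δ through an
affine relation δ = a·σ + b with a near −1 (diamagnetic convention); the
quality of the fit (R², RMS residual) discriminates candidate conformers.
¹H and ¹³C data are always fitted separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScalingFit",
    "fit_scaling",
    "predict_shifts",
    "discriminate_conformers",
    "DIAGNOSTIC_THRESHOLDS",
]

SHIFT_COLUMNS = ["atom", "nucleus", "sigma", "delta"]

#: |Δδ| thresholds (ppm) above which an atom is flagged as diagnostic of the
#: peptide-bond configuration (the Hδ proton moves 1–2 ppm downfield and the
#: Cβ carbon 2–3 ppm upfield on a Z→E change).
DIAGNOSTIC_THRESHOLDS = {"1H": 1.0, "13C": 2.0}


@dataclass(frozen=True)
class ScalingFit:
    nucleus: str
    slope: float
    intercept: float
    r_squared: float
    residuals: pd.DataFrame  # per-atom residuals, largest magnitude first
    n: int

    def rms_residual(self) -> float:
        return float(np.sqrt(np.mean(self.residuals["residual"] ** 2)))


def _select_nucleus(table: pd.DataFrame, nucleus: str) -> pd.DataFrame:
    missing = [c for c in SHIFT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"shielding/shift table missing columns {missing}")
    sub = table[table["nucleus"] == nucleus]
    if len(sub) < 3:
        raise ValueError(f"need at least 3 rows for nucleus {nucleus!r}, got {len(sub)}")
    return sub


def fit_scaling(table: pd.DataFrame, nucleus: str) -> ScalingFit:
    """Ordinary least squares of δ_exp on σ_iso for one nucleus.

    Returns slope, intercept, R² (squared Pearson correlation) and per-atom
    residuals sorted largest-first. A slope far from −1 is suspicious for
    scaled-shielding data and triggers a warning, not an error.
    """
    sub = _select_nucleus(table, nucleus)
    sigma = sub["sigma"].to_numpy(dtype=float)
    delta = sub["delta"].to_numpy(dtype=float)
    if np.ptp(sigma) < 1e-12:
        raise ValueError("degenerate shielding values: no variance to fit")
    res = stats.linregress(sigma, delta)
    if not (-1.5 < res.slope < -0.5):
        warnings.warn(
            f"scaling slope {res.slope:.2f} is far from the expected −1",
            stacklevel=2,
        )
    fitted = res.slope * sigma + res.intercept
    residuals = pd.DataFrame(
        {
            "atom": sub["atom"].to_numpy(),
            "residual": delta - fitted,
        }
    )
    residuals = residuals.iloc[np.argsort(-np.abs(residuals["residual"]))].reset_index(
        drop=True
    )
    return ScalingFit(
        nucleus=nucleus,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        residuals=residuals,
        n=len(sub),
    )


def predict_shifts(sigma, slope: float, intercept: float) -> np.ndarray:
    """Predicted shifts δ̂ = slope·σ + intercept."""
    return slope * np.asarray(sigma, dtype=float) + intercept


def discriminate_conformers(
    tables: dict[str, pd.DataFrame], nucleus: str
) -> tuple[pd.DataFrame, list[str]]:
    """Rank candidate conformers by how well their computed shieldings map
    onto the (shared) experimental shifts.

    ``tables`` maps conformer label → shielding/shift table; all candidates
    must cover the same atoms. Candidates are ranked by R² (descending) and
    RMS residual (ascending). Atoms whose predicted shifts spread across
    candidates by more than the nucleus threshold (1 ppm for ¹H, 2 ppm for
    ¹³C) are returned as configuration-diagnostic.
    """
    if len(tables) < 2:
        raise ValueError("need at least two candidate conformers")
    fits: dict[str, ScalingFit] = {}
    atom_sets = {}
    for label, table in tables.items():
        sub = _select_nucleus(table, nucleus)
        atom_sets[label] = list(sub["atom"])
        fits[label] = fit_scaling(table, nucleus)
    ref_atoms = atom_sets[next(iter(atom_sets))]
    for label, atoms in atom_sets.items():
        if sorted(atoms) != sorted(ref_atoms):
            unmatched = sorted(set(atoms) ^ set(ref_atoms))
            raise ValueError(f"candidate {label!r} has unmatched atoms: {unmatched}")

    ranking = pd.DataFrame(
        {
            "conformer": list(fits),
            "r_squared": [fits[c].r_squared for c in fits],
            "rms_residual": [fits[c].rms_residual() for c in fits],
        }
    )
    ranking = ranking.sort_values(
        ["r_squared", "rms_residual"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranking["tied_with_best"] = np.isclose(
        ranking["r_squared"], ranking["r_squared"].iloc[0], atol=1e-12
    ) & np.isclose(ranking["rms_residual"], ranking["rms_residual"].iloc[0], atol=1e-12)

    # per-atom spread of predicted shifts across candidates
    preds = {}
    for label, table in tables.items():
        sub = _select_nucleus(table, nucleus).set_index("atom")
        fit = fits[label]
        preds[label] = pd.Series(
            predict_shifts(sub["sigma"], fit.slope, fit.intercept), index=sub.index
        ).reindex(ref_atoms)
    pred_frame = pd.DataFrame(preds)
    spread = pred_frame.max(axis=1) - pred_frame.min(axis=1)
    threshold = DIAGNOSTIC_THRESHOLDS.get(nucleus, 1.0)
    diagnostic = sorted(spread[spread > threshold].index.tolist())
    return ranking, diagnostic
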