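"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is deterministic under a fixed seed and returns (or writes)
a :class:`GroundTruth` record next to its data, so downstream recovery can
be scored without any external measurement:

* ROE peak-volume tables follow V = c·r⁻⁶ for proton pairs below 5.5 Å with
  multiplicative log-normal noise (volumes are positive and integration
  errors grow with peak size).
* Conformer population tables are finite multinomial draws from Boltzmann
  weights.
* Variable-temperature ¹H line shapes follow the two-site exchange model
  with Eyring rates.
* Shielding/shift tables follow a noisy affine map with the Z/E marker
  offsets on the Hδ and Cβ resonances.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .builder import ConformerSpec, assemble_oligomer
from .restraints import back_calculate
from .thermo import EnergyTable, ExchangeModel, PopulationTable, R_KCAL, eyring_rate, simulate_lineshape

__all__ = [
    "GroundTruth",
    "make_roesy_table",
    "make_population_counts",
    "make_exchange_profiles",
    "make_shift_tables",
]


@dataclass(frozen=True)
class GroundTruth:
    """Serializable record of what a synthetic dataset was generated from."""

    kind: str
    seed: int
    payload: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"kind": self.kind, "seed": self.seed, **self.payload},
            indent=2,
            sort_keys=True,
            default=_jsonable,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def _spec_payload(spec: ConformerSpec) -> dict:
    return {
        "n_residues": spec.n_residues,
        "bond_configs": spec.bond_configs,
        "psi": list(spec.psi),
        "puckers": list(spec.puckers),
        "pucker_amplitude": spec.pucker_amplitude,
        "chirality_pattern": spec.chirality_pattern,
    }


# ---------------------------------------------------------------------------
# ROE volumes
# ---------------------------------------------------------------------------


def make_roesy_table(
    spec: ConformerSpec,
    c: float = 100.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    cutoff: float = 5.5,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulated ROESY peak-volume table for one conformer.

    Volumes are back-calculated from the built model (V = c·d⁻⁶, pairs with
    effective distance ≤ cutoff, Hα–Hβ reference peaks included) and
    multiplied by log-normal noise with coefficient of variation
    ``noise_cv``.
    """
    if noise_cv < 0:
        raise ValueError("noise coefficient of variation must be non-negative")
    s = assemble_oligomer(spec)
    peaks = back_calculate(s, c=c, cutoff=cutoff)
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + noise_cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(peaks))
        peaks = peaks.assign(volume=peaks["volume"] * factors)
    truth = GroundTruth(
        kind="roesy_volumes",
        seed=seed,
        payload={
            "spec": _spec_payload(spec),
            "calibration": c,
            "noise_cv": noise_cv,
            "cutoff": cutoff,
            "n_peaks": len(peaks),
        },
    )
    return peaks, truth


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


def make_population_counts(
    true_dg: EnergyTable,
    temperature: float | None = None,
    n_observations: int = 1000,
    seed: int = 0,
) -> tuple[PopulationTable, GroundTruth]:
    """Finite-sampling population table: a multinomial draw of
    ``n_observations`` conformer sightings from Boltzmann weights."""
    if n_observations < 1:
        raise ValueError("need at least one observation")
    temp = true_dg.temperature if temperature is None else temperature
    rt = R_KCAL * temp
    labels = list(true_dg.energies)
    w = np.array([np.exp(-true_dg.energies[k] / rt) for k in labels])
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_observations, w)
    populations = {
        k: 100.0 * n / n_observations for k, n in zip(labels, counts) if n > 0
    }
    table = PopulationTable(populations=populations, temperature=temp)
    truth = GroundTruth(
        kind="population_counts",
        seed=seed,
        payload={
            "true_dg": dict(true_dg.energies),
            "temperature": temp,
            "n_observations": n_observations,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# exchange line shapes
# ---------------------------------------------------------------------------


def make_exchange_profiles(
    dg_act: float = 20.6,
    delta_nu: float = 20.0,
    temperatures=tuple(range(298, 409, 10)),
    noise: float = 0.01,
    seed: int = 0,
    p_a: float = 0.5,
    linewidth: float = 2.0,
    n_points: int = 600,
    span_factor: float = 6.0,
) -> tuple[dict[float, tuple[np.ndarray, np.ndarray]], GroundTruth]:
    """Variable-temperature two-site ¹H line shapes for a barrier ``dg_act``.

    The rate at each temperature follows the Eyring equation; ``noise`` is
    the additive Gaussian amplitude relative to the profile maximum.
    """
    if noise < 0:
        raise ValueError("noise amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    half_span = span_factor * delta_nu / 2.0
    freq = np.linspace(-half_span, half_span, n_points)
    profiles = {}
    for temp in temperatures:
        k = eyring_rate(dg_act, temp)
        model = ExchangeModel(-delta_nu / 2.0, delta_nu / 2.0, p_a, k, linewidth, temp)
        y = simulate_lineshape(model, freq)
        if noise > 0:
            y = y + rng.normal(0.0, noise * y.max(), size=y.shape)
        profiles[float(temp)] = (freq, y)
    truth = GroundTruth(
        kind="exchange_profiles",
        seed=seed,
        payload={
            "dg_act": dg_act,
            "delta_nu": delta_nu,
            "temperatures": list(map(float, temperatures)),
            "noise": noise,
            "p_a": p_a,
            "linewidth": linewidth,
        },
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# shielding/shift tables
# ---------------------------------------------------------------------------

#: Z→E marker offsets (ppm, applied to the experimental-scale shift): the
#: Hδ proton of the residue following the bond moves downfield, the Cβ of
#: the residue carrying the carbonyl moves upfield.
ZE_MARKER_OFFSETS = {"HD": 1.5, "CB": -2.5}

_PROTON_ATOMS = ("HA", "HB", "HG2", "HG3", "HD", "HM")
_CARBON_ATOMS = ("CA", "CB", "CG", "CD", "CE", "CP1")
_SHIFT_RANGES = {"1H": (0.5, 9.5), "13C": (10.0, 175.0)}
_DEFAULT_INTERCEPTS = {"1H": 31.0, "13C": 185.0}


def make_shift_tables(
    conformers=("ZZZ", "ZZE"),
    n_residues: int = 4,
    slope: float = -1.0,
    intercepts: dict[str, float] | None = None,
    noise: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Shielding/shift tables for candidate Z/E conformers of one oligomer.

    The first conformer is the generating ("true") one: experimental shifts
    are its affine-mapped shieldings plus Gaussian noise of ``noise`` ppm.
    Candidate shieldings differ by the Hδ/Cβ marker offsets at every linkage
    whose configuration differs from the true conformer, plus a small
    conformational perturbation elsewhere.
    """
    if len(conformers) < 1:
        raise ValueError("need at least one conformer label")
    if any(len(cfg) != n_residues - 1 or set(cfg) - set("ZE") for cfg in conformers):
        raise ValueError("conformer labels must be Z/E strings of length n_residues-1")
    intercepts = dict(_DEFAULT_INTERCEPTS if intercepts is None else intercepts)
    rng = np.random.default_rng(seed)
    true_cfg = conformers[0]

    atoms, nuclei = [], []
    for resid in range(1, n_residues + 1):
        for a in _PROTON_ATOMS:
            atoms.append(f"{a}{resid}")
            nuclei.append("1H")
        for a in _CARBON_ATOMS:
            atoms.append(f"{a}{resid}")
            nuclei.append("13C")

    base_delta = np.array(
        [rng.uniform(*_SHIFT_RANGES[nuc]) for nuc in nuclei]
    )
    exp_delta = base_delta + rng.normal(0.0, noise, size=len(atoms))

    def candidate_delta(cfg: str) -> np.ndarray:
        delta = base_delta.copy()
        for link, (c_true, c_cand) in enumerate(zip(true_cfg, cfg), start=1):
            if c_true == c_cand:
                continue
            sign = 1.0 if (c_true == "Z" and c_cand == "E") else -1.0
            for atom_prefix, offset in ZE_MARKER_OFFSETS.items():
                resid = link + 1 if atom_prefix.startswith("H") else link
                name = f"{atom_prefix}{resid}"
                if name in atoms:
                    delta[atoms.index(name)] += sign * offset
        if cfg != true_cfg:
            delta = delta + rng.normal(0.0, noise / 2.0, size=len(atoms))
        return delta

    tables = {}
    for cfg in conformers:
        delta_cand = candidate_delta(cfg)
        sigma = (delta_cand - np.array([intercepts[n] for n in nuclei])) / slope
        tables[cfg] = pd.DataFrame(
            {
                "atom": atoms,
                "nucleus": nuclei,
                "sigma": sigma,
                "delta": exp_delta,
                "conformer": cfg,
            }
        )
    truth = GroundTruth(
        kind="shift_tables",
        seed=seed,
        payload={
            "conformers": list(conformers),
            "true_conformer": true_cfg,
            "slope": slope,
            "intercepts": intercepts,
            "noise": noise,
            "marker_offsets": ZE_MARKER_OFFSETS,
        },
    )
    return tables, truth
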