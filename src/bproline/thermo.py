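"""Conformer thermodynamics and two-site chemical exchange.

Populations map to relative free energies through ΔG_j = −RT·ln(P_j/P_max);
exchange rates map to activation free energies through the Eyring equation
(transmission coefficient 1); slow↔fast exchange line shapes follow the
Bloch–McConnell solution for two sites with unequal populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "R_KCAL",
    "PopulationTable",
    "EnergyTable",
    "ExchangeModel",
    "boltzmann_dg",
    "populations_from_dg",
    "eyring_rate",
    "coalescence_rate",
    "coalescence_dg",
    "simulate_lineshape",
    "fit_exchange",
    "ExchangeFit",
]

#: Gas constant in kcal·mol⁻¹·K⁻¹ (CODATA).
R_KCAL = 1.98720425e-3
#: Boltzmann constant (J·K⁻¹) and Planck constant (J·s), CODATA exact values.
K_B = 1.380649e-23
H_PLANCK = 6.62607015e-34


@dataclass(frozen=True)
class PopulationTable:
    """Conformer populations in percent at a given temperature.

    Percentages may sum to less than 100 (minor unlisted conformers)."""

    populations: dict[str, float]
    temperature: float = 298.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not self.populations:
            raise ValueError("empty population table")
        if any(p <= 0 for p in self.populations.values()):
            raise ValueError("populations must be positive percentages")
        if sum(self.populations.values()) > 100.0 + 1e-9:
            raise ValueError("populations must sum to at most 100%")

    @property
    def dominant(self) -> str:
        return max(self.populations, key=self.populations.get)


@dataclass(frozen=True)
class EnergyTable:
    """Free energies of formation (kcal·mol⁻¹) relative to the dominant
    conformer, which sits at ΔG = 0."""

    energies: dict[str, float]
    temperature: float = 298.0

    def __post_init__(self):
        if min(self.energies.values()) < -1e-9:
            raise ValueError("relative energies must be non-negative")

    def rounded(self, decimals: int = 2) -> dict[str, float]:
        return {k: round(v, decimals) for k, v in self.energies.items()}


@dataclass(frozen=True)
class ExchangeModel:
    """Two-site exchange parameters: site frequencies (Hz), population of
    site A, forward rate k (A→B, s⁻¹), intrinsic linewidth (Hz FWHM)."""

    nu_a: float
    nu_b: float
    p_a: float
    k: float
    linewidth: float = 2.0
    temperature: float = 298.0

    def __post_init__(self):
        if not (0.0 < self.p_a < 1.0):
            raise ValueError("p_a must lie strictly between 0 and 1")
        if self.k < 0:
            raise ValueError("rate must be non-negative")
        if self.nu_a == self.nu_b:
            raise ValueError("site frequencies must differ")
        if self.linewidth <= 0:
            raise ValueError("intrinsic linewidth must be positive")


# ---------------------------------------------------------------------------
# populations ↔ free energies
# ---------------------------------------------------------------------------


def boltzmann_dg(p: PopulationTable) -> EnergyTable:
    """Relative free energies ΔG_j = −RT·ln(P_j/P_max) from populations.

    Ratios are scale-free, so under-complete population tables need no
    renormalisation here.
    """
    ref = p.populations[p.dominant]
    rt = R_KCAL * p.temperature
    energies = {
        label: -rt * np.log(pop / ref) for label, pop in p.populations.items()
    }
    return EnergyTable(energies=energies, temperature=p.temperature)


def populations_from_dg(e: EnergyTable, temperature: float | None = None) -> PopulationTable:
    """Boltzmann populations (percent, normalised to 100) from relative free
    energies; inverse of :func:`boltzmann_dg` up to normalisation."""
    temp = e.temperature if temperature is None else temperature
    if temp <= 0:
        raise ValueError("temperature must be positive")
    rt = R_KCAL * temp
    weights = {k: np.exp(-v / rt) for k, v in e.energies.items()}
    z = sum(weights.values())
    return PopulationTable(
        populations={k: 100.0 * w / z for k, w in weights.items()}, temperature=temp
    )


# ---------------------------------------------------------------------------
# rates and barriers
# ---------------------------------------------------------------------------


def eyring_rate(dg_act: float, temperature: float) -> float:
    """Eyring rate k = (k_B·T/h)·exp(−ΔG‡/RT), s⁻¹ (κ = 1)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return K_B * temperature / H_PLANCK * np.exp(-dg_act / (R_KCAL * temperature))


def eyring_dg(k: float, temperature: float) -> float:
    """Activation free energy (kcal·mol⁻¹) from a rate: inverse Eyring."""
    if k <= 0 or temperature <= 0:
        raise ValueError("rate and temperature must be positive")
    return -R_KCAL * temperature * np.log(k * H_PLANCK / (K_B * temperature))


def coalescence_rate(delta_nu: float) -> float:
    """Exchange rate at coalescence of two equal lines: k_c = π·Δν/√2."""
    if delta_nu <= 0:
        raise ValueError("frequency separation must be positive")
    return np.pi * delta_nu / np.sqrt(2.0)


def coalescence_dg(delta_nu: float, t_c: float) -> float:
    """Barrier from the coalescence temperature: Eyring inversion of
    k_c = π·Δν/√2 at T_c."""
    return eyring_dg(coalescence_rate(delta_nu), t_c)


# ---------------------------------------------------------------------------
# line shapes
# ---------------------------------------------------------------------------


def simulate_lineshape(m: ExchangeModel, freq: np.ndarray) -> np.ndarray:
    """Two-site exchange absorption profile on a frequency grid (Hz).

    Bloch–McConnell solution for unequal populations under detailed balance
    (k_AB·p_A = k_BA·p_B with k = k_AB the A→B rate). The returned intensity
    is non-negative and its integral over a grid spanning both lines is
    independent of the rate.
    """
    freq = np.asarray(freq, dtype=float)
    if freq.min() > min(m.nu_a, m.nu_b) or freq.max() < max(m.nu_a, m.nu_b):
        raise ValueError("frequency grid must span both site frequencies")
    p_a, p_b = m.p_a, 1.0 - m.p_a
    k_ab = m.k
    k_ba = k_ab * p_a / p_b
    r2 = np.pi * m.linewidth  # FWHM → decay rate
    # dM/dt = (iΩ − R − K)·M ; S(ν) = Re Σ [(i·2πν·I − L)⁻¹ · M0]
    omega_a = 2.0j * np.pi * m.nu_a
    omega_b = 2.0j * np.pi * m.nu_b
    iw = 2.0j * np.pi * freq
    a11 = iw - (omega_a - r2 - k_ab)
    a22 = iw - (omega_b - r2 - k_ba)
    a12 = -k_ba
    a21 = -k_ab
    det = a11 * a22 - a12 * a21
    # (A⁻¹ M0) summed over rows, M0 = (p_a, p_b)
    x = (a22 * p_a - a12 * p_b) / det
    y = (-a21 * p_a + a11 * p_b) / det
    profile = np.real(x + y)
    return np.maximum(profile, 0.0)


@dataclass
class ExchangeFit:
    rates: dict[float, float]
    dg_act: float
    dg_uncertainty: float
    residual_norm: float


def _fit_single_rate(model_args, freq, profile) -> float:
    """Least-squares rate for one profile (amplitude-free comparison)."""
    nu_a, nu_b, p_a, lw, temp = model_args

    def cost(log10_k):
        sim = simulate_lineshape(
            ExchangeModel(nu_a, nu_b, p_a, 10.0**log10_k, lw, temp), freq
        )
        return float(np.sum((sim - profile) ** 2))

    res = minimize_scalar(cost, bounds=(-6.0, 8.0), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"rate fit did not converge (residual {res.fun:.3g})")
    return 10.0**res.x


def fit_exchange(
    profiles: dict[float, tuple[np.ndarray, np.ndarray]],
    delta_nu: float,
    p_a: float = 0.5,
    linewidth: float = 2.0,
    nu_center: float = 0.0,
) -> ExchangeFit:
    """Fit exchange rates per temperature and a global activation energy.

    ``profiles`` maps temperature (K) to (frequency grid, intensity). Site
    frequencies are ``nu_center ± delta_nu/2``. Per-temperature rates come
    from independent least-squares fits; ΔG‡ from a one-parameter Eyring fit
    across all profiles, with its uncertainty from the fit curvature.
    """
    if len(profiles) < 3:
        raise ValueError("need profiles at three or more temperatures")
    if delta_nu <= 0:
        raise ValueError("frequency separation must be positive")
    nu_a = nu_center - delta_nu / 2.0
    nu_b = nu_center + delta_nu / 2.0

    rates = {}
    for temp, (freq, profile) in profiles.items():
        rates[temp] = _fit_single_rate((nu_a, nu_b, p_a, linewidth, temp), freq, profile)

    def total_cost(dg):
        c = 0.0
        for temp, (freq, profile) in profiles.items():
            k = eyring_rate(dg, temp)
            sim = simulate_lineshape(ExchangeModel(nu_a, nu_b, p_a, k, linewidth, temp), freq)
            c += float(np.sum((sim - profile) ** 2))
        return c

    res = minimize_scalar(total_cost, bounds=(5.0, 40.0), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"Eyring fit did not converge (residual {res.fun:.3g})")
    dg = float(res.x)

    # curvature-based uncertainty: σ² ≈ 2·s²/ f''(ΔG‡)
    h = 0.02
    f0, fm, fp = total_cost(dg), total_cost(dg - h), total_cost(dg + h)
    curv = (fm - 2 * f0 + fp) / h**2
    n_pts = sum(len(f) for f, _ in profiles.values())
    s2 = f0 / max(n_pts - 1, 1)
    sigma = float(np.sqrt(2.0 * s2 / curv)) if curv > 0 else float("nan")
    return ExchangeFit(rates=rates, dg_act=dg, dg_uncertainty=sigma,
                       residual_norm=float(np.sqrt(f0)))
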