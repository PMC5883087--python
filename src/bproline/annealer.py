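"""Restrained refinement by torsion-space simulated annealing.

The degrees of freedom are the backbone rotations ψ per linkage, a bounded
perturbation of each amide torsion ω about its Z/E target (±15°; Z/E
interconversion is never sampled, each conformer is refined separately), and
the pseudorotation phase and amplitude of each pyrrolidine ring. The target
function is a flat-bottom quadratic on the restraint bounds plus a
soft-sphere repulsion. A Metropolis phase at a high control temperature is
followed by linear cooling and a greedy coordinate-descent minimisation, so
the final phase never increases the energy. Everything is deterministic
given the schedule seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import templates as T
from .builder import ConformerSpec, assemble_from_params, phase_for_pucker
from .restraints import RestraintTable, site_members, violations
from .structure import Structure, structure_rmsd

__all__ = [
    "AnnealSchedule",
    "AnnealResult",
    "Ensemble",
    "target_energy",
    "anneal",
    "generate_family",
    "select_representative",
    "family_stats",
]

OMEGA_WINDOW = 15.0  # max |ω − target| sampled, degrees
AMPLITUDE_RANGE = (25.0, 48.0)
CLASH_SCALE = 0.7


@dataclass(frozen=True)
class AnnealSchedule:
    """Annealing control parameters.

    Counts are Metropolis sweeps (one proposal per degree of freedom);
    temperatures are in energy units of the target function (Å²-scaled).
    """

    high_T_steps: int = 80
    high_T: float = 2.0
    cool_start: float = 1.0
    cool_end: float = 0.0
    cool_steps: int = 200
    minimize_cycles: int = 20
    minimize_steps_per_cycle: int = 30
    seed: int = 0

    def __post_init__(self):
        if min(self.high_T_steps, self.cool_steps, self.minimize_cycles,
               self.minimize_steps_per_cycle) <= 0:
            raise ValueError("all schedule counts must be positive")
        if not (self.cool_start > self.cool_end >= 0):
            raise ValueError("need cool_start > cool_end >= 0")


@dataclass
class AnnealResult:
    structure: Structure
    energy: float
    params: dict
    n_evaluations: int
    accept_rate: float
    trace: tuple[float, ...]


@dataclass
class Ensemble:
    """Refined structure family plus per-model bookkeeping."""

    models: list[Structure]
    energies: list[float]
    violation_counts: list[int]
    accepted: list[bool]
    n_rejected: int = 0
    restraints: RestraintTable | None = None
    representative: int | None = None

    def __post_init__(self):
        if not self.models:
            raise ValueError("empty ensemble")
        n0 = self.models[0].n_atoms
        if any(m.n_atoms != n0 for m in self.models):
            raise ValueError("ensemble models must share atom ordering")


# ---------------------------------------------------------------------------
# target function
# ---------------------------------------------------------------------------


def _compile_restraints(s: Structure, t: RestraintTable):
    """Pre-resolve restraint rows into atom-index arrays.

    Single-proton pairs are stacked for vectorised evaluation; pseudo-atom
    (group) restraints keep their member lists for the r⁻⁶ sum.
    """
    si, sj, slo, sup = [], [], [], []
    mi, mj, mseg, mlo, mup = [], [], [0], [], []
    for _, row in t.table.iterrows():
        ii = site_members(s, int(row["resid_i"]), str(row["atom_i"]))
        jj = site_members(s, int(row["resid_j"]), str(row["atom_j"]))
        lo, up = float(row["lower"]), float(row["upper"])
        if len(ii) == 1 and len(jj) == 1:
            si.append(ii[0])
            sj.append(jj[0])
            slo.append(lo)
            sup.append(up)
        else:
            # flatten all member pairs; segment boundaries for the r⁻⁶ sums
            for a in ii:
                for b in jj:
                    mi.append(a)
                    mj.append(b)
            mseg.append(len(mi))
            mlo.append(lo)
            mup.append(up)
    return (
        np.array(si, dtype=int),
        np.array(sj, dtype=int),
        np.array(slo),
        np.array(sup),
        np.array(mi, dtype=int),
        np.array(mj, dtype=int),
        np.array(mseg[:-1], dtype=int),
        np.array(mlo),
        np.array(mup),
    )


def _restraint_energy(coords: np.ndarray, compiled) -> float:
    si, sj, slo, sup, mi, mj, mseg, mlo, mup = compiled
    e = 0.0
    if len(si):
        diff = coords[si] - coords[sj]
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        e += float(np.sum(np.maximum(0.0, d - sup) ** 2))
        e += float(np.sum(np.maximum(0.0, slo - d) ** 2))
    if len(mi):
        diff = coords[mi] - coords[mj]
        d6 = np.einsum("ij,ij->i", diff, diff) ** -3.0
        sums = np.add.reduceat(d6, mseg)
        deff = sums ** (-1.0 / 6.0)
        e += float(np.sum(np.maximum(0.0, deff - mup) ** 2))
        e += float(np.sum(np.maximum(0.0, mlo - deff) ** 2))
    return e


def target_energy(
    s: Structure,
    t: RestraintTable | None,
    weights: tuple[float, float] = (1.0, 1.0),
    clash_scale: float = CLASH_SCALE,
) -> float:
    """Flat-bottom restraint penalty plus soft-sphere repulsion.

    E = w_noe·Σ max(0, d−upper)² + w_noe·Σ max(0, lower−d)² + w_rep·Σ overlap².
    Zero iff no bound is violated and no van der Waals overlap remains.
    """
    from .builder import overlap_energy

    w_noe, w_rep = weights
    if w_noe < 0 or w_rep < 0:
        raise ValueError("weights must be non-negative")
    e = w_rep * overlap_energy(s, clash_scale)
    if t is not None and len(t):
        e += w_noe * _restraint_energy(s.coords, _compile_restraints(s, t))
    return float(e)


# ---------------------------------------------------------------------------
# annealing
# ---------------------------------------------------------------------------


class _State:
    """Mutable torsion-space state with fast rebuild."""

    def __init__(self, spec: ConformerSpec):
        n = spec.n_residues
        self.n = n
        self.chirality = spec.chirality_pattern
        self.omega_targets = np.array([T.OMEGA_TARGET[c] for c in spec.bond_configs])
        self.psi = np.array(spec.psi, dtype=float)
        self.omega_dev = np.zeros(n - 1)
        self.phase = np.array([phase_for_pucker(p) for p in spec.puckers], dtype=float)
        self.amplitude = np.full(n, float(spec.pucker_amplitude))
        # DOF vector layout: [psi | omega_dev | phase | amplitude]
        self.n_dof = 2 * (n - 1) + 2 * n

    def build(self) -> Structure:
        return assemble_from_params(
            self.n,
            self.omega_targets + self.omega_dev,
            self.psi,
            self.phase,
            self.amplitude,
            self.chirality,
            check_overlap=False,
        )

    def get(self, k: int) -> float:
        n = self.n
        if k < n - 1:
            return self.psi[k]
        if k < 2 * (n - 1):
            return self.omega_dev[k - (n - 1)]
        if k < 2 * (n - 1) + n:
            return self.phase[k - 2 * (n - 1)]
        return self.amplitude[k - 2 * (n - 1) - n]

    def set(self, k: int, v: float) -> None:
        n = self.n
        if k < n - 1:
            self.psi[k] = (v + 180.0) % 360.0 - 180.0
        elif k < 2 * (n - 1):
            self.omega_dev[k - (n - 1)] = np.clip(v, -OMEGA_WINDOW, OMEGA_WINDOW)
        elif k < 2 * (n - 1) + n:
            self.phase[k - 2 * (n - 1)] = v % 360.0
        else:
            self.amplitude[k - 2 * (n - 1) - n] = np.clip(v, *AMPLITUDE_RANGE)

    def sigma(self, k: int, scale: float) -> float:
        n = self.n
        if k < 2 * (n - 1):
            return 20.0 * scale  # ψ and ω proposals
        if k < 2 * (n - 1) + n:
            return 20.0 * scale  # pucker phase
        return 3.0 * scale  # pucker amplitude

    def params(self) -> dict:
        return {
            "psi": self.psi.tolist(),
            "omega": (self.omega_targets + self.omega_dev).tolist(),
            "phase": self.phase.tolist(),
            "amplitude": self.amplitude.tolist(),
        }


def anneal(
    spec0: ConformerSpec,
    t: RestraintTable | None,
    sched: AnnealSchedule,
    weights: tuple[float, float] = (1.0, 1.0),
) -> AnnealResult:
    """Refine one model against the restraints by simulated annealing.

    Returns the refined structure together with its target energy, the final
    torsion parameters and a short energy trace. Identical inputs and seed
    give bit-identical results.
    """
    rng = np.random.default_rng(sched.seed)
    state = _State(spec0)
    s = state.build()
    compiled = _compile_restraints(s, t) if (t is not None and len(t)) else None
    w_noe, w_rep = weights

    from .builder import overlap_energy

    def energy_of(structure: Structure) -> float:
        e = w_rep * overlap_energy(structure, CLASH_SCALE)
        if compiled is not None:
            e += w_noe * _restraint_energy(structure.coords, compiled)
        if not np.isfinite(e):
            raise FloatingPointError("non-finite target energy during annealing")
        return float(e)

    e = energy_of(s)
    n_eval = 1
    n_accept = 0
    n_prop = 0
    trace = [e]

    temps = [(sched.high_T, sched.high_T_steps)]
    cool = np.linspace(sched.cool_start, sched.cool_end, sched.cool_steps)

    def sweep(temp: float, scale: float):
        nonlocal s, e, n_eval, n_accept, n_prop
        for k in rng.permutation(state.n_dof):
            old = state.get(k)
            state.set(k, old + rng.normal(0.0, state.sigma(k, scale)))
            trial = state.build()
            e_new = energy_of(trial)
            n_eval += 1
            n_prop += 1
            accept = e_new <= e or (temp > 0 and rng.random() < np.exp((e - e_new) / temp))
            if accept:
                s, e = trial, e_new
                n_accept += 1
            else:
                state.set(k, old)

    for temp, steps in temps:
        for _ in range(steps):
            sweep(temp, 1.0)
        trace.append(e)
    t0 = sched.cool_start if sched.cool_start > 0 else 1.0
    for temp in cool:
        sweep(temp, max(np.sqrt(temp / t0), 0.05))
    trace.append(e)

    # greedy coordinate descent: energy can only decrease
    step = 1.0
    for _cycle in range(sched.minimize_cycles):
        improved = False
        for _ in range(sched.minimize_steps_per_cycle):
            k = int(rng.integers(state.n_dof))
            old = state.get(k)
            best_local = e
            best_val = old
            for delta in (-step, step):
                state.set(k, old + delta)
                trial = state.build()
                e_new = energy_of(trial)
                n_eval += 1
                if e_new < best_local:
                    best_local, best_val = e_new, state.get(k)
            state.set(k, best_val)
            if best_local < e:
                s = state.build()
                e = best_local
                improved = True
        trace.append(e)
        if not improved:
            step *= 0.5
            if step < 0.05:
                break

    s.provenance = f"annealed seed={sched.seed}"
    return AnnealResult(
        structure=s,
        energy=e,
        params=state.params(),
        n_evaluations=n_eval,
        accept_rate=n_accept / max(n_prop, 1),
        trace=tuple(trace),
    )


# ---------------------------------------------------------------------------
# families
# ---------------------------------------------------------------------------


def generate_family(
    spec0: ConformerSpec,
    t: RestraintTable,
    sched: AnnealSchedule,
    n_models: int = 20,
    tol: float = 0.3,
    retry_factor: int = 10,
) -> Ensemble:
    """Run the annealer with consecutive seeds until ``n_models`` models with
    no restraint violation beyond ``tol`` are accepted.

    Raises ``RuntimeError`` with the best-achieved violation count when the
    acceptance criterion is unreachable within ``retry_factor`` × n_models
    attempts.
    """
    if n_models < 1:
        raise ValueError("need at least one model")
    models, energies, counts, accepted = [], [], [], []
    n_rejected = 0
    best_failed = None
    attempt = 0
    cap = retry_factor * n_models
    while sum(accepted) < n_models and attempt < cap:
        res = anneal(spec0, t, replace(sched, seed=sched.seed + attempt))
        v = violations(res.structure, t, tol)
        ok = len(v) == 0
        if ok:
            models.append(res.structure)
            energies.append(res.energy)
            counts.append(0)
            accepted.append(True)
        else:
            n_rejected += 1
            if best_failed is None or len(v) < best_failed[0]:
                best_failed = (len(v), max(x for _, x in v))
        attempt += 1
    if sum(accepted) < n_models:
        nviol, worst = best_failed if best_failed else (0, 0.0)
        raise RuntimeError(
            f"annealing produced only {sum(accepted)}/{n_models} accepted models "
            f"in {attempt} attempts; best rejected model had {nviol} violations "
            f"(worst excess {worst:.2f} Å) — restraints may be unsatisfiable"
        )
    return Ensemble(
        models=models,
        energies=energies,
        violation_counts=counts,
        accepted=accepted,
        n_rejected=n_rejected,
        restraints=t,
    )


def select_representative(e: Ensemble, selection=T.BACKBONE_ATOMS) -> int:
    """Index of the model with the lowest sum of pairwise RMSDs to the rest
    of the family (ties broken toward the lowest index)."""
    if len(e.models) < 2:
        raise ValueError("need at least two models to pick a representative")
    n = len(e.models)
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd[i, j] = rmsd[j, i] = structure_rmsd(e.models[i], e.models[j], selection)
    sums = rmsd.sum(axis=1)
    idx = int(np.argmin(sums))  # argmin returns the first (lowest) index on ties
    e.representative = idx
    return idx


def restraint_class(resid_i: int, resid_j: int) -> str:
    """Intraresidue (i = j), sequential (|i−j| = 1) or medium-range
    (1 < |i−j| ≤ 4) restraint class."""
    gap = abs(resid_i - resid_j)
    if gap == 0:
        return "intraresidue"
    if gap == 1:
        return "sequential"
    if gap <= 4:
        return "medium-range"
    return "long-range"


def family_stats(
    e: Ensemble, selection=T.BACKBONE_ATOMS, tol: float = 0.3
) -> dict:
    """Ensemble statistics: restraint counts by class, violations beyond
    ``tol`` per model, and mean RMSD to the representative over the backbone
    atoms C′, Cα, Cβ, N."""
    rep = e.representative
    if rep is None:
        rep = select_representative(e, selection) if len(e.models) > 1 else 0
    stats: dict = {"n_models": len(e.models), "representative": rep}
    if e.restraints is not None:
        t = e.restraints.table
        classes = [
            restraint_class(int(r["resid_i"]), int(r["resid_j"]))
            for _, r in t.iterrows()
        ]
        stats["n_restraints"] = len(t)
        for cls in ("intraresidue", "sequential", "medium-range"):
            stats[cls] = sum(1 for c in classes if c == cls)
        stats["max_violations_per_model"] = max(
            len(violations(m, e.restraints, tol)) for m in e.models
        )
    others = [i for i in range(len(e.models)) if i != rep]
    if others:
        stats["mean_rmsd_to_representative"] = float(
            np.mean([structure_rmsd(e.models[i], e.models[rep], selection) for i in others])
        )
    else:
        stats["mean_rmsd_to_representative"] = 0.0
    return stats
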