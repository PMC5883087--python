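"""End-to-end pipeline: volumes → calibration → binning → annealing →
family statistics → representative → classification → thermodynamics."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .annealer import AnnealSchedule, family_stats, generate_family, select_representative
from .builder import ConformerSpec
from .classify import classify_bonds, classify_pucker_from_j, predict_ring_couplings
from .fileio import (
    read_restraints_tsv,
    write_cns_restraints,
    write_energy_tsv,
    write_manifest,
    write_pdb,
    write_population_tsv,
    write_restraints_tsv,
)
from .restraints import bin_restraints, calibrate
from .synthetic import make_roesy_table
from .thermo import PopulationTable, boltzmann_dg

logger = logging.getLogger("bproline")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Pipeline configuration. Every defaulted field is echoed to the run
    log so a run can be reproduced from its log alone."""

    # conformer under study
    n_residues: int = 4
    bond_configs: str = "ZZZ"
    puckers: str = "endo"
    pucker_amplitude: float = 40.0
    # input volumes: path to a peak TSV, or None to simulate
    volumes_path: str | None = None
    calibration: float = 100.0
    noise_cv: float = 0.0
    # restraint handling
    tolerance: float = 0.3
    # refinement
    n_models: int = 20
    high_T_steps: int = 80
    cool_steps: int = 200
    # thermodynamics (optional population table: label -> percent)
    populations: dict | None = None
    temperature: float = 298.0
    # bookkeeping
    seed: int = 0
    out_dir: str = "bproline_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config``.

    Returns a result bundle (paths and in-memory results). Raises
    :class:`PipelineError` naming the failing stage; partial outputs are
    left in place.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for key, value in asdict(config).items():
        logger.info("config %s = %r", key, value)

    out = Path(config.out_dir)
    if config.volumes_path is not None and not Path(config.volumes_path).exists():
        raise PipelineError(f"stage inputs: volume table {config.volumes_path!r} does not exist")
    out.mkdir(parents=True, exist_ok=True)

    spec = ConformerSpec(
        config.n_residues,
        config.bond_configs,
        puckers=config.puckers,
        pucker_amplitude=config.pucker_amplitude,
    )
    bundle: dict = {"config": asdict(config)}
    inputs: dict = {}
    outputs: dict = {}

    # --- stage: volumes ------------------------------------------------
    try:
        if config.volumes_path is None:
            peaks, truth = make_roesy_table(
                spec, c=config.calibration, noise_cv=config.noise_cv, seed=config.seed
            )
            truth.to_json(out / "volumes_ground_truth.json")
            outputs["volumes_ground_truth"] = out / "volumes_ground_truth.json"
            peaks_path = out / "volumes.tsv"
            peaks.to_csv(peaks_path, sep="\t", index=False)
            outputs["volumes"] = peaks_path
        else:
            import pandas as pd

            peaks = pd.read_csv(config.volumes_path, sep="\t")
            inputs["volumes"] = Path(config.volumes_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage volumes: {exc}") from exc

    # --- stage: calibrate + bin ----------------------------------------
    try:
        c = calibrate(peaks)
        restraints = bin_restraints(peaks, c)
        write_restraints_tsv(restraints, out / "restraints.tsv")
        write_cns_restraints(restraints, out / "restraints.cns")
        outputs["restraints"] = out / "restraints.tsv"
        outputs["restraints_cns"] = out / "restraints.cns"
        bundle["calibration"] = c
        bundle["n_restraints"] = len(restraints)
        logger.info("calibration c = %.4g, %d restraints", c, len(restraints))
    except Exception as exc:
        raise PipelineError(f"stage calibrate: {exc}") from exc

    # --- stage: anneal + family ----------------------------------------
    try:
        sched = AnnealSchedule(
            high_T_steps=config.high_T_steps,
            cool_steps=config.cool_steps,
            seed=config.seed,
        )
        family = generate_family(
            spec, restraints, sched, n_models=config.n_models, tol=config.tolerance
        )
        rep = select_representative(family)
        stats = family_stats(family, tol=config.tolerance)
        write_pdb(family.models, out / "family.pdb")
        write_pdb(family.models[rep], out / "representative.pdb")
        outputs["family"] = out / "family.pdb"
        outputs["representative"] = out / "representative.pdb"
        bundle["family_stats"] = stats
        bundle["representative_index"] = rep
        logger.info("family: %s", stats)
    except Exception as exc:
        raise PipelineError(f"stage anneal: {exc}") from exc

    # --- stage: classify ------------------------------------------------
    try:
        model = family.models[rep]
        bonds, margins = classify_bonds(model)
        puckers = []
        for resid in range(1, model.n_residues + 1):
            state, _ = classify_pucker_from_j(predict_ring_couplings(model, resid))
            puckers.append(state)
        bundle["classification"] = {
            "bonds": bonds,
            "margins": margins,
            "puckers": puckers,
        }
        (out / "classification.txt").write_text(
            f"bonds\t{bonds}\npuckers\t{','.join(puckers)}\n"
        )
        outputs["classification"] = out / "classification.txt"
        logger.info("classified bonds=%s puckers=%s", bonds, puckers)
    except Exception as exc:
        raise PipelineError(f"stage classify: {exc}") from exc

    # --- stage: thermo ---------------------------------------------------
    if config.populations:
        try:
            pop = PopulationTable(
                populations=dict(config.populations), temperature=config.temperature
            )
            energies = boltzmann_dg(pop)
            write_population_tsv(pop, out / "populations.tsv")
            write_energy_tsv(energies, out / "energies.tsv")
            outputs["populations"] = out / "populations.tsv"
            outputs["energies"] = out / "energies.tsv"
            bundle["energies"] = energies.rounded()
        except Exception as exc:
            raise PipelineError(f"stage thermo: {exc}") from exc

    write_manifest(out / "manifest.json", inputs, outputs, asdict(config))
    bundle["out_dir"] = str(out)
    bundle["outputs"] = {k: str(v) for k, v in outputs.items()}
    return bundle
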