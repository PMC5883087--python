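import numpy as np
import pytest

from bproline import (
    ConformerSpec,
    assemble_oligomer,
    back_calculate,
    bin_restraints,
    build_residue,
    calibrate,
    default_template,
)
from bproline.structure import Atom, Structure


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def zzz_spec():
    return ConformerSpec(4, "ZZZ")


@pytest.fixture(scope="session")
def zzz_truth(zzz_spec):
    return assemble_oligomer(zzz_spec)


@pytest.fixture(scope="session")
def reference_distance(zzz_truth):
    """Exact Hα–Hβ distance of the built ring, used so that synthetic
    calibration is free of reference-distance bias."""
    return float(
        np.linalg.norm(zzz_truth.position(1, "HA") - zzz_truth.position(1, "HB"))
    )


@pytest.fixture(scope="session")
def zzz_peaks(zzz_truth):
    return back_calculate(zzz_truth, c=5.0)


@pytest.fixture(scope="session")
def zzz_restraints(zzz_peaks, reference_distance):
    c = calibrate(zzz_peaks, r_ref=reference_distance)
    return bin_restraints(zzz_peaks, c)


def two_proton_structure(distance: float) -> Structure:
    """Minimal two-proton structure at an exact separation (test helper)."""
    return Structure(
        atoms=[Atom(1, "HX", "H"), Atom(2, "HY", "H")],
        coords=np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
        bonds=[],
    )
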