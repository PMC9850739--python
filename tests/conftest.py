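import numpy as np
import pytest

from pesscan import synth
from pesscan.model import (
    CalculationRecord,
    PESScan,
    ScanCoordinate,
    ScanPointRecord,
)


def make_diatomic_scan(
    values,
    energies=None,
    kind="distance",
    iri="https://example.org/pes/PotentialEnergySurfaceScan/test",
    recorded=None,
    source_order=False,
):
    """Minimal two-atom distance scan with geometry consistent with the
    recorded values (unless ``recorded`` overrides them)."""
    values = list(values)
    if energies is None:
        energies = [-155.0 - 0.01 * i for i in range(len(values))]
    recorded = list(recorded) if recorded is not None else values
    points = []
    for i, (r, rec, e) in enumerate(zip(values, recorded, energies)):
        calc = CalculationRecord(
            iri=f"{iri}/calculation/{i}",
            program="Gaussian 16:  ES64L-G16RevC.01",
            method="b3lyp",
            basis_set="6-31g",
            charge=0,
            spin_multiplicity=1,
            scf_energy=e,
            scf_energy_text=f"{e:.7f}",
            geometry=(("C", 0.0, 0.0, 0.0), ("C", 0.0, 0.0, float(r))),
            job_kind="rigid",
        )
        points.append(
            ScanPointRecord(
                order_index=i,
                coordinate_value=float(rec),
                unit="angstrom",
                input_atom_ids=(1, 2),
                calculation=calc,
                source_order=i if source_order else None,
            )
        )
    coord = ScanCoordinate("distance", ("https://example.org/species/x/atom/1",
                                        "https://example.org/species/x/atom/2"))
    return PESScan(iri=iri, on_species=("https://example.org/species/x",),
                   coordinate=coord, points=tuple(points))


@pytest.fixture(scope="session")
def ethanol_scan():
    return synth.make_ethanol_like_fixture()


@pytest.fixture(scope="session")
def ethanol_species():
    return synth.ethanol_like_species()


@pytest.fixture()
def two_state_const():
    """Noiseless harmonic/harmonic system with constant coupling A=25."""
    return synth.make_two_state_system(synth.default_two_state_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
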