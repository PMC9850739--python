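"""Deterministic synthetic fixtures: two-state systems with known coupling,
dialect-conformant pseudo-logs, and an ethanol-like worked-example scan.

Everything here is a pure function of (spec, seed).  The two-state
generator is the forward model of the calibration problem: it builds the
reference profile *exactly* as the EVB ground state of two shifted
classical state curves plus an optional seeded noise term, and returns the
embedded ground truth so recovery can be tested.  The ethanol-like fixture
mimics the shape of a carbon–carbon bond-dissociation scan (first point at
1.51 Å, Morse-like energies) but is synthetic throughout: it is not derived
from any deposited quantum-chemistry data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .ffeval import HarmonicBond, MorseBond
from .fitting import CouplingModel, EnergyProfile, EVBInput, evb_ground
from .model import (
    _SYMBOL_TO_Z,
    CalculationRecord,
    PESScan,
    ScanCoordinate,
    ScanPointRecord,
    SpeciesRef,
    AtomRef,
    measure_distance,
)

__all__ = [
    "TwoStateSpec",
    "TwoStateTruth",
    "make_two_state_system",
    "make_fixture_log",
    "make_single_point_logs",
    "ethanol_like_species",
    "make_ethanol_like_fixture",
    "write_fixture_tree",
]

StateCurve = Union[HarmonicBond, MorseBond]


def _state_energy(curve: StateCurve, r: np.ndarray) -> np.ndarray:
    """Diatomic state energy as a function of the scan coordinate."""
    if isinstance(curve, HarmonicBond):
        return 0.5 * curve.k * (r - curve.r0) ** 2
    if isinstance(curve, MorseBond):
        return curve.De * (1.0 - np.exp(-curve.a * (r - curve.re))) ** 2
    raise TypeError(f"unsupported state curve {type(curve).__name__}")


@dataclass(frozen=True)
class TwoStateSpec:
    """Forward-model specification for a synthetic two-state system."""

    grid: tuple[float, ...]
    state1: StateCurve
    state2: StateCurve
    coupling: CouplingModel
    s1: float = 0.0
    s2: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.grid, dtype=float)
        if r.size < 2 or np.any(np.diff(r) <= 0):
            raise ValueError("grid must be strictly increasing with >= 2 points")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass(frozen=True)
class TwoStateTruth:
    """The ground truth embedded in a generated system."""

    coupling: CouplingModel
    s1: float
    s2: float


def make_two_state_system(spec: TwoStateSpec) -> tuple[EVBInput, TwoStateTruth]:
    """Generate (E1, E2, Eref) with Eref = EVB ground state of the shifted
    states plus seeded zero-mean Gaussian noise.  Identical spec (including
    seed) gives bit-identical output."""
    r = np.asarray(spec.grid, dtype=float)
    e1 = _state_energy(spec.state1, r)
    e2 = _state_energy(spec.state2, r)
    eref = evb_ground(e1 + spec.s1, e2 + spec.s2, spec.coupling(r))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        eref = eref + rng.normal(0.0, spec.noise_sigma, size=r.size)
    data = EVBInput(
        e1=EnergyProfile.from_arrays(r, e1),
        e2=EnergyProfile.from_arrays(r, e2),
        eref=EnergyProfile.from_arrays(r, eref),
    )
    return data, TwoStateTruth(spec.coupling, spec.s1, spec.s2)


# ---------------------------------------------------------------------------
# pseudo-log emission (the documented dialect)

_ORIENT_HEADER = """\
                         Input orientation:
 ---------------------------------------------------------------------
 Center     Atomic      Atomic             Coordinates (Angstroms)
 Number     Number       Type             X           Y           Z
 ---------------------------------------------------------------------
"""
_ORIENT_FOOTER = " ---------------------------------------------------------------------\n"

_KIND_LETTER = {"distance": "B", "angle": "A", "dihedral": "D"}


def _orientation_block(geometry) -> str:
    rows = [_ORIENT_HEADER]
    for i, (el, x, y, z) in enumerate(geometry, start=1):
        z_num = _SYMBOL_TO_Z[el]
        rows.append(f"    {i:3d}       {z_num:4d}           0     "
                    f"{x:12.6f}{y:12.6f}{z:12.6f}\n")
    rows.append(_ORIENT_FOOTER)
    return "".join(rows)


def _scf_line(calc: CalculationRecord) -> str:
    label = calc.method.upper() if calc.method != "unknown" else "B3LYP"
    return (f" SCF Done:  E(R{label}) =  {calc.energy_text}     "
            f"A.U. after   11 cycles\n")


def _header(scan: PESScan, kind: str) -> str:
    calc = scan.points[0].calculation
    route_extra = " opt=modredundant" if kind == "relaxed" else ""
    method = calc.method if calc.method != "unknown" else "b3lyp"
    basis = calc.basis_set if calc.basis_set != "unknown" else "6-31g"
    head = (
        " Entering Gaussian System\n"
        f" Gaussian 16:  ES64L-G16RevC.01\n"
        f" #{route_extra} {method}/{basis}\n"
        "\n"
        f" Charge =  {calc.charge} Multiplicity = {calc.spin_multiplicity}\n"
    )
    if kind in ("relaxed", "rigid"):
        letter = _KIND_LETTER[scan.coordinate.kind]
        ids = " ".join(str(i) for i in scan.points[0].input_atom_ids)
        values = scan.coordinate_values()
        n_steps = len(values) - 1
        step = float(np.mean(np.diff(values))) if n_steps else 0.0
        head += (
            " The following ModRedundant input section has been read:\n"
            f" {letter} {ids} S {n_steps} {step:.6f}\n"
        )
    return head


def make_fixture_log(scan: PESScan, kind: str = "relaxed", opt_cycles: int = 2) -> str:
    """Emit one dialect-conformant log embedding the scan exactly.

    ``relaxed`` logs carry ``opt_cycles`` SCF/geometry cycles per point (the
    last one exact, earlier ones perturbed surrogates of unconverged
    intermediates) closed by an ``Optimization completed.`` marker; ``rigid``
    logs carry one bare SCF per point and no markers.  Parsing plus assembly
    reproduces the scan's energies to full printed precision and geometries
    exactly (fixture geometries are 6-decimal quantized).
    """
    if kind not in ("relaxed", "rigid"):
        raise ValueError("kind must be 'relaxed' or 'rigid'")
    parts = [_header(scan, kind)]
    for p in scan.points:
        calc = p.calculation
        if kind == "relaxed":
            for cycle in range(max(opt_cycles - 1, 0)):
                wobble = tuple(
                    (el, round(x + 0.011, 6), round(y - 0.007, 6), z)
                    for el, x, y, z in calc.geometry
                )
                parts.append(_orientation_block(wobble))
                fake = CalculationRecord(
                    iri=calc.iri, program=calc.program, method=calc.method,
                    basis_set=calc.basis_set, charge=calc.charge,
                    spin_multiplicity=calc.spin_multiplicity,
                    scf_energy=calc.scf_energy + 0.0123,
                    scf_energy_text=f"{calc.scf_energy + 0.0123:.7f}",
                    geometry=calc.geometry, job_kind=calc.job_kind,
                )
                parts.append(_scf_line(fake))
            parts.append(_orientation_block(calc.geometry))
            parts.append(_scf_line(calc))
            parts.append(" Optimization completed.\n    -- Stationary point found.\n")
        else:
            parts.append(_orientation_block(calc.geometry))
            parts.append(_scf_line(calc))
    parts.append(" Normal termination of Gaussian 16.\n")
    return "".join(parts)


def make_single_point_logs(scan: PESScan) -> list[str]:
    """One single-point log per scan point (no scan header, no markers)."""
    out = []
    for p in scan.points:
        calc = p.calculation
        text = (
            " Entering Gaussian System\n"
            " Gaussian 16:  ES64L-G16RevC.01\n"
            f" # {calc.method}/{calc.basis_set}\n"
            "\n"
            f" Charge =  {calc.charge} Multiplicity = {calc.spin_multiplicity}\n"
            + _orientation_block(calc.geometry)
            + _scf_line(calc)
            + " Normal termination of Gaussian 16.\n"
        )
        out.append(text)
    return out


# ---------------------------------------------------------------------------
# ethanol-like worked example

_ETHANOL_INCHI = "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3"
_SPECIES_IRI = "https://example.org/species/ethanol-synthetic"


def _q6(x: float) -> float:
    """Quantize to the float nearest the 6-decimal print of x."""
    return float(f"{x:.6f}")


def _ethanol_geometry(r_cc: float) -> tuple[tuple[str, float, float, float], ...]:
    """A 9-atom CH3–CH2OH-like cluster with the two carbons on the z axis.

    The methyl fragment sits on atom 1, the CH2OH fragment rides rigidly on
    atom 2, so stretching r_cc emulates a relaxed dissociation scan.  All
    coordinates are 6-decimal quantized.
    """
    s, c = 0.942809, 0.333333  # tetrahedral direction components
    ch, co, oh = 1.09, 1.43, 0.96
    atoms: list[tuple[str, float, float, float]] = []
    atoms.append(("C", 0.0, 0.0, 0.0))
    atoms.append(("C", 0.0, 0.0, r_cc))
    # O on C2, pointing away from C1
    atoms.append(("O", co * s, 0.0, r_cc + co * c))
    # methyl hydrogens on C1 (pointing away from C2)
    for phi_deg in (0.0, 120.0, 240.0):
        phi = np.radians(phi_deg)
        atoms.append(("H", ch * s * np.cos(phi), ch * s * np.sin(phi), -ch * c))
    # two hydrogens on C2
    for phi_deg in (140.0, 220.0):
        phi = np.radians(phi_deg)
        atoms.append(("H", ch * s * np.cos(phi), ch * s * np.sin(phi), r_cc + ch * c))
    # hydroxyl hydrogen
    atoms.append(("H", co * s + oh * 0.5, oh * 0.7, r_cc + co * c + 0.2))
    return tuple((el, _q6(x), _q6(y), _q6(z)) for el, x, y, z in atoms)


def ethanol_like_species() -> SpeciesRef:
    """Synthetic ethanol-like species reference (geometry at r_CC = 1.51 Å)."""
    geom = _ethanol_geometry(1.51)
    atoms = tuple(
        AtomRef(iri=f"{_SPECIES_IRI}/atom/{i}", element=el, index=i, position=(x, y, z))
        for i, (el, x, y, z) in enumerate(geom, start=1)
    )
    return SpeciesRef(
        iri=_SPECIES_IRI,
        inchi=_ETHANOL_INCHI,
        label="ethanol (synthetic fixture)",
        atoms=atoms,
        smiles="CCO",
    )


def make_ethanol_like_fixture(
    n_points: int = 13,
    start: float = 1.51,
    step: float = 0.3,
    scan_iri: str = "https://example.org/pes/PotentialEnergySurfaceScan/ethanol-cc",
) -> PESScan:
    """A synthetic C–C bond-dissociation scan: first point at 1.51 Å,
    Morse-like SCF energies, recorded coordinate values measured exactly
    from the constructed geometries."""
    species = ethanol_like_species()
    de, a, re_ = 360.0, 1.8, 1.526  # kJ/mol, 1/Å, Å — a plausible C–C well
    e_inf = -154.0  # Hartree pedestal for the dissociated fragments
    points = []
    for i in range(n_points):
        r = start + i * step
        geom = _ethanol_geometry(r)
        value = measure_distance(geom[0][1:4], geom[1][1:4])
        morse = de * (1.0 - np.exp(-a * (value - re_))) ** 2
        text = f"{e_inf + (morse - de) / 2625.499639479826:.7f}"
        calc = CalculationRecord(
            iri=f"{scan_iri}/calculation/{i}",
            program="Gaussian 16:  ES64L-G16RevC.01",
            method="ub3lyp",
            basis_set="cc-pvqz",
            charge=0,
            spin_multiplicity=1,
            scf_energy=float(text),
            scf_energy_text=text,
            geometry=geom,
            job_kind="relaxed",
        )
        points.append(
            ScanPointRecord(
                order_index=i,
                coordinate_value=value,
                unit="angstrom",
                input_atom_ids=(1, 2),
                calculation=calc,
                source_order=i,
            )
        )
    coordinate = ScanCoordinate(
        "distance", (f"{_SPECIES_IRI}/atom/1", f"{_SPECIES_IRI}/atom/2")
    )
    return PESScan(
        iri=scan_iri,
        on_species=(_SPECIES_IRI,),
        coordinate=coordinate,
        points=tuple(points),
    )


# ---------------------------------------------------------------------------
# fixture tree


def default_two_state_spec(seed: int = 0, noise_sigma: float = 0.0) -> TwoStateSpec:
    """The canonical harmonic/harmonic constant-coupling test system."""
    grid = tuple(np.linspace(1.2, 4.0, 40))
    return TwoStateSpec(
        grid=grid,
        state1=HarmonicBond(1, 2, k=900.0, r0=1.5),
        state2=HarmonicBond(1, 2, k=350.0, r0=3.0),
        coupling=CouplingModel("constant", 25.0),
        s1=0.0,
        s2=40.0,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def write_fixture_tree(outdir, seed: int = 0) -> dict:
    """Write every fixture the test surface needs; returns the manifest.

    Deterministic in (outdir-content, seed): identical calls give
    bit-identical trees.  The manifest lists every emitted file with its
    SHA-256 digest and the generating seed/spec.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import kg  # local import: kg pulls in rdflib

    files: dict[str, str] = {}

    scan = make_ethanol_like_fixture()
    species = ethanol_like_species()

    (outdir / "relaxed.log").write_text(make_fixture_log(scan, "relaxed"))
    (outdir / "rigid.log").write_text(make_fixture_log(scan, "rigid"))
    for i, text in enumerate(make_single_point_logs(scan)):
        (outdir / f"sp_{i:03d}.log").write_text(text)
    kg.save_graph(kg.to_graph(scan, species=[species]), outdir / "ethanol_scan.ttl")

    spec = default_two_state_spec(seed=seed)
    data, truth = make_two_state_system(spec)
    rows = ["coordinate,E1,E2,Eref"]
    for r, e1, e2, er in zip(data.r, data.e1.e, data.e2.e, data.eref.e):
        rows.append(f"{float(r)!r},{float(e1)!r},{float(e2)!r},{float(er)!r}")
    (outdir / "twostate.csv").write_text("\n".join(rows) + "\n")
    (outdir / "twostate_truth.json").write_text(json.dumps({
        "coupling": {"kind": truth.coupling.kind, "A": truth.coupling.A},
        "s1": truth.s1, "s2": truth.s2, "seed": seed,
    }, indent=2) + "\n")

    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {"seed": seed, "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
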