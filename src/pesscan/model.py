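"""In-memory domain model for one-dimensional potential-energy-surface scans.

A scan samples the electronic energy of a molecular system along one internal
coordinate (a bond distance, plane angle, or dihedral).  Each sampled point
carries a surrogate of the quantum-chemistry calculation that produced it
(converged SCF energy in Hartree, Cartesian geometry in Å, level of theory),
and a scan may carry any number of fitting records describing analytic models
(Morse potentials, EVB couplings, ...) parametrized against it.

Canonical units: Å for distances, degrees for angles, Hartree for stored SCF
energies; all force-field fitting downstream happens in kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "HARTREE_TO_KJ_PER_MOL",
    "AtomRef",
    "SpeciesRef",
    "ScanCoordinate",
    "CalculationRecord",
    "ScanPointRecord",
    "FittingRecord",
    "PESScan",
    "Violation",
    "DegenerateGeometryError",
    "hartree_to_kjmol",
    "measure_distance",
    "measure_angle",
    "measure_dihedral",
    "measure_coordinate",
    "validate_scan",
]

#: Molar Hartree energy, kJ/mol per Hartree.  Pinned bit-exactly here and
#: nowhere else; every conversion in the package routes through it.
HARTREE_TO_KJ_PER_MOL = 2625.499639479826

# Element symbols indexed by atomic number (1-based; index 0 unused).
ELEMENTS = (
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn",
)
_ELEMENT_SET = frozenset(ELEMENTS[1:])
_SYMBOL_TO_Z = {sym: z for z, sym in enumerate(ELEMENTS) if z}


class DegenerateGeometryError(ValueError):
    """Raised when an internal coordinate is undefined for the given points
    (zero-length angle arm, collinear dihedral trio)."""


@dataclass(frozen=True)
class AtomRef:
    """One atom of a species reference geometry.

    ``index`` is the 1-based position in the species geometry, matching the
    numbering used in quantum-chemistry input files.
    """

    iri: str
    element: str
    index: int
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.element not in _ELEMENT_SET:
            raise ValueError(f"unknown element symbol: {self.element!r}")
        if self.index < 1:
            raise ValueError("atom index must be >= 1 (1-based)")


@dataclass(frozen=True)
class SpeciesRef:
    """A chemical species with a unique IRI, InChI, and reference geometry."""

    iri: str
    inchi: str
    label: str
    atoms: tuple[AtomRef, ...]
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.inchi.startswith("InChI="):
            raise ValueError("InChI string must begin with 'InChI='")
        if not self.atoms:
            raise ValueError("species must carry at least one atom")
        iris = [a.iri for a in self.atoms]
        if len(set(iris)) != len(iris):
            raise ValueError("atom IRIs must be unique within a species")
        if sorted(a.index for a in self.atoms) != list(range(1, len(self.atoms) + 1)):
            raise ValueError("atom indices must be contiguous 1..N")

    def atom_by_index(self, index: int) -> AtomRef:
        for a in self.atoms:
            if a.index == index:
                return a
        raise KeyError(f"no atom with index {index}")


COORDINATE_ARITY = {"distance": 2, "angle": 3, "dihedral": 4}
COORDINATE_UNIT = {"distance": "angstrom", "angle": "degree", "dihedral": "degree"}


@dataclass(frozen=True)
class ScanCoordinate:
    """The varied internal coordinate of a 1D scan.

    ``scan_atoms`` are the IRIs of the defining atoms, in order: 2 for a
    distance, 3 for a plane angle (vertex second), 4 for a dihedral.
    """

    kind: str
    scan_atoms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in COORDINATE_ARITY:
            raise ValueError(f"unknown coordinate kind: {self.kind!r}")
        if len(self.scan_atoms) != COORDINATE_ARITY[self.kind]:
            raise ValueError(
                f"{self.kind} coordinate needs {COORDINATE_ARITY[self.kind]} atoms,"
                f" got {len(self.scan_atoms)}"
            )

    @property
    def arity(self) -> int:
        return COORDINATE_ARITY[self.kind]

    @property
    def unit(self) -> str:
        return COORDINATE_UNIT[self.kind]


@dataclass(frozen=True)
class CalculationRecord:
    """Surrogate of one quantum-chemistry calculation backing a scan point.

    ``scf_energy`` is the final converged self-consistent-field energy in
    Hartree.  ``scf_energy_text`` preserves the energy exactly as printed in
    the source log so round trips through serialization are bit-exact; when
    absent it is derived from the float with shortest round-trip formatting.
    """

    iri: str
    program: str
    method: str
    basis_set: str
    charge: int
    spin_multiplicity: int
    scf_energy: float
    geometry: tuple[tuple[str, float, float, float], ...]
    job_kind: str
    scf_energy_text: Optional[str] = None

    def __post_init__(self) -> None:
        if self.spin_multiplicity < 1:
            raise ValueError("spin multiplicity must be >= 1")
        if not self.geometry:
            raise ValueError("geometry must be non-empty")
        if self.job_kind not in ("relaxed", "rigid", "single_point"):
            raise ValueError(f"unknown job kind: {self.job_kind!r}")
        if not math.isfinite(self.scf_energy):
            raise ValueError("SCF energy must be finite")

    @property
    def energy_text(self) -> str:
        return self.scf_energy_text if self.scf_energy_text is not None else repr(self.scf_energy)

    def positions(self) -> np.ndarray:
        return np.array([[x, y, z] for _e, x, y, z in self.geometry], dtype=float)


@dataclass(frozen=True)
class ScanPointRecord:
    """One sampled point of the scan: coordinate value + its calculation."""

    order_index: int
    coordinate_value: float
    unit: str
    input_atom_ids: tuple[int, ...]
    calculation: CalculationRecord
    #: position of this point in the source file(s), before sorting; None for
    #: points constructed directly in memory.
    source_order: Optional[int] = None

    def __post_init__(self) -> None:
        if any(i < 1 for i in self.input_atom_ids):
            raise ValueError("input atom ids are 1-based and must be >= 1")


@dataclass(frozen=True)
class FittingRecord:
    """An analytic model fitted to a scan: method name, provenance, parameters.

    ``parameters`` is an ordered list of (name, value, unit) triples, e.g.
    (De, 350.0, kJ/mol), (re, 1.53, angstrom), (a, 1.9, 1/angstrom) for a
    Morse potential.
    """

    method_name: str
    method_source: str
    parameters: tuple[tuple[str, float, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _v, _u in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique within a record")

    def get(self, name: str) -> float:
        for n, v, _u in self.parameters:
            if n == name:
                return v
        raise KeyError(name)


@dataclass(frozen=True)
class PESScan:
    """A 1D potential-energy-surface scan.

    Species are referenced by IRI; points are stored sorted ascending by
    coordinate value with distinct values (duplicate merging is the
    assembler's job, see :mod:`pesscan.gaussian_io`).
    """

    iri: str
    on_species: tuple[str, ...]
    coordinate: ScanCoordinate
    points: tuple[ScanPointRecord, ...]
    fragments: tuple[str, ...] = ()
    fittings: tuple[FittingRecord, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.on_species:
            raise ValueError("scan must reference at least one species")
        if len(self.points) < 2:
            raise ValueError("scan needs at least two points")

    def coordinate_values(self) -> np.ndarray:
        return np.array([p.coordinate_value for p in self.points], dtype=float)

    def scf_energies(self) -> np.ndarray:
        """SCF energies in Hartree, point order."""
        return np.array([p.calculation.scf_energy for p in self.points], dtype=float)


# ---------------------------------------------------------------------------
# unit conversion and internal-coordinate measurement


def hartree_to_kjmol(e):
    """Convert an energy from Hartree to kJ/mol (elementwise on arrays)."""
    arr = np.asarray(e, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("energy must be finite")
    out = arr * HARTREE_TO_KJ_PER_MOL
    return float(out) if np.isscalar(e) or arr.ndim == 0 else out


def _vec(p) -> np.ndarray:
    return np.asarray(p, dtype=float)


def measure_distance(p1, p2) -> float:
    """Euclidean distance between two points, Å."""
    return float(np.linalg.norm(_vec(p1) - _vec(p2)))


def measure_angle(p1, p2, p3) -> float:
    """Plane angle at vertex ``p2`` in degrees, in [0, 180]."""
    u = _vec(p1) - _vec(p2)
    v = _vec(p3) - _vec(p2)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("angle arm has zero length")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, range (−180, 180].

    IUPAC sign convention: looking along p2→p3, a clockwise rotation of the
    far bond relative to the near bond is positive.  Computed as
    atan2((n1×n2)·b̂2, n1·n2) with b_i the bond vectors and n_i the plane
    normals.
    """
    b1 = _vec(p2) - _vec(p1)
    b2 = _vec(p3) - _vec(p2)
    b3 = _vec(p4) - _vec(p3)
    if np.linalg.norm(b2) == 0.0:
        raise DegenerateGeometryError("central dihedral bond has zero length")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        raise DegenerateGeometryError("collinear atoms leave the dihedral undefined")
    b2_hat = b2 / np.linalg.norm(b2)
    ang = math.degrees(math.atan2(np.dot(np.cross(n1, n2), b2_hat), np.dot(n1, n2)))
    if ang <= -180.0:
        ang += 360.0
    return ang


_MEASURES = {"distance": measure_distance, "angle": measure_angle, "dihedral": measure_dihedral}


def measure_coordinate(kind: str, points: Sequence) -> float:
    """Dispatch to the distance/angle/dihedral measurement for ``kind``."""
    return _MEASURES[kind](*points)


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    """One validation failure: the offending point (or None for scan-level
    problems) and a human-readable reason."""

    point_index: Optional[int]
    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = "scan" if self.point_index is None else f"point {self.point_index}"
        return f"[{where}] {self.reason}"


def validate_scan(
    scan: PESScan,
    tol_dist: float = 1e-3,
    tol_ang: float = 0.1,
    species: Optional[Iterable[SpeciesRef]] = None,
) -> list[Violation]:
    """Check a scan's semantic invariants; return a list of violations.

    Checks: (i) points sorted ascending with distinct coordinate values,
    (ii) each recorded coordinate value agrees with the value re-measured
    from the point's geometry through ``input_atom_ids`` within ``tol_dist``
    Å / ``tol_ang`` degrees, (iii) species InChI strings (when species are
    supplied) carry the mandatory prefix, (iv) input-atom-id lists match the
    coordinate arity.  Unresolvable atom indices are reported as violations,
    never raised.
    """
    out: list[Violation] = []
    arity = scan.coordinate.arity
    tol = tol_dist if scan.coordinate.kind == "distance" else tol_ang

    values = [p.coordinate_value for p in scan.points]
    for i in range(1, len(values)):
        if values[i] <= values[i - 1]:
            out.append(
                Violation(i, f"coordinate values not strictly increasing "
                             f"({values[i - 1]!r} then {values[i]!r})")
            )

    for i, p in enumerate(scan.points):
        if len(p.input_atom_ids) != arity:
            out.append(Violation(i, f"input_atom_ids has {len(p.input_atom_ids)} "
                                    f"entries; {scan.coordinate.kind} needs {arity}"))
            continue
        geom = p.calculation.geometry
        if any(idx > len(geom) for idx in p.input_atom_ids):
            out.append(Violation(i, "input atom id outside the point geometry"))
            continue
        pts = [geom[idx - 1][1:4] for idx in p.input_atom_ids]
        try:
            measured = measure_coordinate(scan.coordinate.kind, pts)
        except DegenerateGeometryError as exc:
            out.append(Violation(i, f"degenerate geometry: {exc}"))
            continue
        if abs(measured - p.coordinate_value) > tol:
            out.append(
                Violation(i, f"recorded coordinate {p.coordinate_value:g} differs "
                             f"from measured {measured:g} by more than {tol:g}")
            )

    if species is not None:
        for sp in species:
            if not sp.inchi.startswith("InChI="):  # defensive: SpeciesRef enforces it
                out.append(Violation(None, f"species {sp.iri} has malformed InChI"))
    return out
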