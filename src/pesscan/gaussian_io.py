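"""Parser for quantum-chemistry scan output logs and PES-scan assembly.

The parser understands a minimal, documented text dialect replicating the
anchor strings of Gaussian 09/16 output:

* an orientation block (``Input orientation:`` or ``Standard orientation:``
  followed by the dashed Center/Atomic-Number/Coordinates table),
* ``SCF Done:  E(...) =  <energy>     A.U. ...`` lines,
* ``Optimization completed.`` / ``Optimization stopped.`` markers for
  relaxed scans,
* an optional ModRedundant-style scan declaration such as
  ``B 1 2 S 10 0.200000`` (bond between input atoms 1 and 2, 10 steps of
  0.2 Å), ``A i j k S n step`` for angles, ``D i j k l S n step`` for
  dihedrals.

Real Gaussian logs that use these anchors parse as well, but only the
documented dialect is guaranteed.  Relaxed scans yield one step per
optimization marker (last SCF energy and last preceding geometry block,
preferring *Input orientation* for its stable atom order); rigid scans and
single points yield one step per SCF line.  Energies are kept as the exact
printed decimal text so round trips are bit-exact.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    ELEMENTS,
    CalculationRecord,
    PESScan,
    ScanCoordinate,
    ScanPointRecord,
    SpeciesRef,
    measure_coordinate,
)

__all__ = [
    "RawStep",
    "ScanSpec",
    "ParsedLog",
    "DialectError",
    "EmptyLogError",
    "MappingError",
    "AssemblyError",
    "parse_log",
    "read_log",
    "detect_scan_type",
    "extract_scan_spec",
    "assemble_scan",
]


class DialectError(ValueError):
    """The text violates the documented log dialect; carries a byte offset."""

    def __init__(self, message: str, offset: Optional[int] = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at byte offset {offset})"
        super().__init__(message)


class EmptyLogError(DialectError):
    """No SCF energy found: the log holds no usable calculation."""


class MappingError(KeyError):
    """The input-index → species-atom map does not cover a required atom."""


class AssemblyError(ValueError):
    """No converged steps were available to assemble a scan from."""


@dataclass(frozen=True)
class RawStep:
    """One extracted scan step: geometry (Å), SCF energy (Hartree), and
    whether the step converged.  ``source`` records file/byte provenance."""

    geometry: tuple[tuple[str, float, float, float], ...]
    scf_energy: float
    scf_energy_text: str
    converged: bool
    source: str


@dataclass(frozen=True)
class ScanSpec:
    """A declared scan: coordinate kind, 1-based input atom ids, step grid."""

    atom_ids: tuple[int, ...]
    kind: str
    n_steps: int
    step_size: float


@dataclass(frozen=True)
class ParsedLog:
    """Full parse of one log: steps plus route/header metadata."""

    steps: tuple[RawStep, ...]
    job_kind: str
    scan_spec: Optional[ScanSpec]
    program: str = "unknown"
    method: str = "unknown"
    basis_set: str = "unknown"
    charge: int = 0
    spin_multiplicity: int = 1


_SCF_RE = re.compile(r"SCF Done:\s+E\([^)]*\)\s*=\s*(-?\d+\.\d+)")
_ORIENT_RE = re.compile(r"(Input|Standard) orientation:")
_OPT_DONE_RE = re.compile(r"Optimization (completed|stopped)\.")
_SCAN_LINE_RE = re.compile(
    r"^\s*([BAD])((?:\s+\d+){2,4})\s+S\s+(\d+)\s+([-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)\s*$",
    re.MULTILINE,
)
_CHARGE_RE = re.compile(r"Charge\s*=\s*(-?\d+)\s+Multiplicity\s*=\s*(\d+)")
_ROUTE_RE = re.compile(r"^\s*#\s*(.+)$", re.MULTILINE)
_PROGRAM_RE = re.compile(r"(Gaussian\s+\d+[^,\n]*)")

_KIND_BY_LETTER = {"B": "distance", "A": "angle", "D": "dihedral"}
_ARITY_BY_LETTER = {"B": 2, "A": 3, "D": 4}


def _parse_orientation(lines: Sequence[str], start: int):
    """Parse one orientation table starting at the header line index."""
    i = start + 1
    dashes = 0
    geom: list[tuple[str, float, float, float]] = []
    while i < len(lines):
        line = lines[i]
        if set(line.strip()) == {"-"} and line.strip():
            dashes += 1
            if dashes == 3:
                break
            i += 1
            continue
        if dashes == 2:
            parts = line.split()
            if len(parts) < 6:
                raise DialectError("malformed orientation row", None)
            z = int(parts[1])
            if not 1 <= z < len(ELEMENTS):
                raise DialectError(f"atomic number {z} out of range", None)
            geom.append((ELEMENTS[z], float(parts[-3]), float(parts[-2]), float(parts[-1])))
        i += 1
    if not geom:
        raise DialectError("empty orientation block", None)
    return tuple(geom), i


def parse_log(text: str, source: str = "<string>") -> list[RawStep]:
    """Extract the scan steps of one log.

    Relaxed scans (optimization markers present) yield one step per marker;
    otherwise every ``SCF Done:`` line is a step.  Unconverged optimizations
    (``Optimization stopped.``) are flagged ``converged=False``, never
    dropped.  Raises :class:`EmptyLogError` when no SCF line exists and
    :class:`DialectError` when an energy has no preceding geometry.
    """
    lines = text.splitlines()
    offsets: list[int] = []
    pos = 0
    for line in lines:
        offsets.append(pos)
        pos += len(line) + 1

    # (line_no, energy_text, geometry) per SCF line; geometry = last block
    # before it, preferring Input orientation when the log has any.
    has_input_orient = any(
        m and m.group(1) == "Input" for m in (_ORIENT_RE.search(l) for l in lines)
    )
    scf_entries: list[tuple[int, str, tuple]] = []
    markers: list[tuple[int, bool]] = []  # (line_no, converged)
    last_geom: Optional[tuple] = None
    i = 0
    while i < len(lines):
        line = lines[i]
        m = _ORIENT_RE.search(line)
        if m:
            which = m.group(1)
            geom, i = _parse_orientation(lines, i)
            if which == "Input" or not has_input_orient:
                last_geom = geom
            i += 1
            continue
        m = _SCF_RE.search(line)
        if m:
            if last_geom is None:
                raise DialectError("SCF energy with no preceding geometry block",
                                   offsets[i])
            scf_entries.append((i, m.group(1), last_geom))
            i += 1
            continue
        m = _OPT_DONE_RE.search(line)
        if m:
            markers.append((i, m.group(1) == "completed"))
            i += 1
            continue
        i += 1

    if not scf_entries:
        raise EmptyLogError("no 'SCF Done:' line found in log", 0)

    steps: list[RawStep] = []
    if markers:
        prev_marker = -1
        for line_no, converged in markers:
            cands = [e for e in scf_entries if prev_marker < e[0] < line_no]
            if not cands:
                raise DialectError("optimization marker with no SCF energy",
                                   offsets[line_no])
            scf_line, etext, geom = cands[-1]
            steps.append(RawStep(geom, float(etext), etext, converged,
                                 f"{source}:+{offsets[scf_line]}"))
            prev_marker = line_no
    else:
        for line_no, etext, geom in scf_entries:
            steps.append(RawStep(geom, float(etext), etext, True,
                                 f"{source}:+{offsets[line_no]}"))
    return steps


def extract_scan_spec(text: str) -> Optional[ScanSpec]:
    """Read the ModRedundant-style scan declaration, if any.

    Returns None when no declaration is present; raises
    :class:`DialectError` when a declaration line is malformed (wrong atom
    count for its coordinate letter).
    """
    m = _SCAN_LINE_RE.search(text)
    if m is None:
        # a line that starts like a declaration but fails the grammar
        for bad in re.finditer(r"^\s*([BAD])\s+\d+.*\bS\b.*$", text, re.MULTILINE):
            if not _SCAN_LINE_RE.match(bad.group(0)):
                raise DialectError("malformed scan declaration: " + bad.group(0).strip())
        return None
    letter = m.group(1)
    atom_ids = tuple(int(t) for t in m.group(2).split())
    if len(atom_ids) != _ARITY_BY_LETTER[letter]:
        raise DialectError(
            f"scan declaration '{m.group(0).strip()}' names {len(atom_ids)} atoms;"
            f" '{letter}' requires {_ARITY_BY_LETTER[letter]}"
        )
    return ScanSpec(atom_ids, _KIND_BY_LETTER[letter], int(m.group(3)), float(m.group(4)))


def detect_scan_type(text: str) -> str:
    """Classify a log as ``relaxed``, ``rigid``, or ``single_point``."""
    if _OPT_DONE_RE.search(text):
        return "relaxed"
    if _SCAN_LINE_RE.search(text):
        return "rigid"
    return "single_point"


def read_log(text: str, source: str = "<string>") -> ParsedLog:
    """Parse steps plus route/header metadata into one :class:`ParsedLog`."""
    steps = parse_log(text, source=source)
    kind = detect_scan_type(text)
    spec = extract_scan_spec(text)
    program, method, basis = "unknown", "unknown", "unknown"
    m = _PROGRAM_RE.search(text)
    if m:
        program = m.group(1).strip()
    m = _ROUTE_RE.search(text)
    if m:
        for token in m.group(1).split():
            if "/" in token and not token.startswith("/"):
                method, basis = token.split("/", 1)
                break
    charge, mult = 0, 1
    m = _CHARGE_RE.search(text)
    if m:
        charge, mult = int(m.group(1)), int(m.group(2))
    return ParsedLog(tuple(steps), kind, spec, program, method, basis, charge, mult)


# ---------------------------------------------------------------------------
# assembly


def _mint_scan_iri(species: SpeciesRef, coordinate: ScanCoordinate, values) -> str:
    h = hashlib.sha1()
    h.update(species.iri.encode())
    h.update(coordinate.kind.encode())
    h.update(",".join(f"{v:.9f}" for v in values).encode())
    return f"https://example.org/pes/PotentialEnergySurfaceScan/{h.hexdigest()[:12]}"


def assemble_scan(
    logs: Sequence[ParsedLog],
    species: SpeciesRef,
    coordinate: ScanCoordinate,
    atom_map: dict[int, str],
    scan_iri: Optional[str] = None,
    fragments: Sequence[str] = (),
    merge_tol: float = 1e-6,
) -> PESScan:
    """Assemble one PESScan from one or many parsed logs.

    ``atom_map`` maps 1-based input-file atom indices to species atom IRIs
    and must cover all of the coordinate's scan atoms.  Coordinate values
    are recomputed from each step's geometry (the scan declaration, when
    present, is only a cross-check).  Points are merged across logs, sorted
    ascending; values closer than ``merge_tol`` collapse to the point with
    the lowest SCF energy.  Unconverged steps are excluded.
    """
    inverse = {iri: idx for idx, iri in atom_map.items()}
    try:
        input_atom_ids = tuple(inverse[iri] for iri in coordinate.scan_atoms)
    except KeyError as exc:
        raise MappingError(f"atom map does not cover scan atom {exc.args[0]!r}") from exc
    n_atoms = len(species.atoms)
    if any(idx > n_atoms or idx < 1 for idx in input_atom_ids):
        raise MappingError("atom map points outside the species geometry")

    entries = []  # (value, step, parsed)
    source_order = 0
    for parsed in logs:
        for step in parsed.steps:
            if not step.converged:
                continue
            pts = [step.geometry[idx - 1][1:4] for idx in input_atom_ids]
            value = measure_coordinate(coordinate.kind, pts)
            entries.append((value, step, parsed, source_order))
            source_order += 1
    if not entries:
        raise AssemblyError("no converged steps to assemble a scan from")

    entries.sort(key=lambda e: (e[0], e[1].scf_energy))
    merged = []
    for entry in entries:
        if merged and abs(entry[0] - merged[-1][0]) < merge_tol:
            if entry[1].scf_energy < merged[-1][1].scf_energy:
                merged[-1] = entry
            continue
        merged.append(entry)

    if scan_iri is None:
        scan_iri = _mint_scan_iri(species, coordinate, [e[0] for e in merged])

    points = []
    for i, (value, step, parsed, order) in enumerate(merged):
        calc = CalculationRecord(
            iri=f"{scan_iri}/calculation/{i}",
            program=parsed.program,
            method=parsed.method,
            basis_set=parsed.basis_set,
            charge=parsed.charge,
            spin_multiplicity=parsed.spin_multiplicity,
            scf_energy=step.scf_energy,
            scf_energy_text=step.scf_energy_text,
            geometry=step.geometry,
            job_kind=parsed.job_kind if parsed.job_kind != "single_point" else "single_point",
        )
        points.append(
            ScanPointRecord(
                order_index=i,
                coordinate_value=value,
                unit=coordinate.unit,
                input_atom_ids=input_atom_ids,
                calculation=calc,
                source_order=order,
            )
        )

    return PESScan(
        iri=scan_iri,
        on_species=(species.iri,),
        fragments=tuple(fragments),
        coordinate=coordinate,
        points=tuple(points),
    )
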