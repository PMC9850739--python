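"""RDF knowledge-graph mapping for PES scans.

Scans are serialized under a compact vocabulary mirroring the published
class/property names for PES-scan semantics (PotentialEnergySurfaceScan,
ScanCoordinate and its distance/angle/dihedral subclasses, ScanPoint,
ScanCoordinateValue, onSpecies/hasFragment/hasScanAtom/...), with minimal
species and calculation surrogates standing in for the upstream species and
computational-chemistry vocabularies.  Quantities follow the value+unit
pattern: a quantity node carries one numeric ``hasValue`` literal and one
``hasUnit`` object link to a unit IRI (Ångström, Degree, Hartree).

The exact upstream term IRIs for calculation internals (SCF energy,
geometry) are not fixed by the published vocabulary; defaults are declared
in :class:`VocabularyMap` and are configurable rather than authoritative.

Mapping table (triples emitted by :func:`to_graph`, per scan):

====================================  =======================================
count                                 triples
====================================  =======================================
1                                     scan ``rdf:type`` PotentialEnergySurfaceScan
n_species / n_fragments               ``onSpecies`` / ``hasFragment`` links
2                                     ``hasScanCoordinate`` + coordinate type
n_scan_atoms                          ``hasScanAtom`` links
20 per point (+1 if source order)     point link/type; coordinate-value node
                                      (type, value, unit) + link; input atom
                                      ids; calculation link/type; SCF-energy
                                      node (type, value, unit) + link;
                                      geometry, program, method, basis,
                                      charge, spin multiplicity, job kind
3 + 4·n_params per fitting record     ``hasFitting`` grouping link; method,
                                      source; per parameter one
                                      ``hasFittingParameters`` link plus
                                      name/value/unit literals
====================================  =======================================

Total = 3 + n_species + n_fragments + n_scan_atoms + 20·n_points
      + n_points_with_source_order + Σ_fittings (3 + 4·n_params).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Iterable, Optional

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.compare import isomorphic, to_isomorphic
from rdflib.namespace import XSD

from .model import (
    CalculationRecord,
    FittingRecord,
    PESScan,
    ScanCoordinate,
    ScanPointRecord,
    SpeciesRef,
)

__all__ = [
    "VocabularyMap",
    "DEFAULT_VOCAB",
    "MappingError",
    "IncompletenessError",
    "AmbiguityError",
    "NotFoundError",
    "to_graph",
    "from_graph",
    "find_scans_by_inchi",
    "point_energies",
    "attach_fitting",
    "save_graph",
    "load_graph",
    "graphs_isomorphic",
    "SCANS_BY_INCHI_SPARQL",
    "POINT_ENERGIES_SPARQL",
]


class MappingError(KeyError):
    """A vocabulary term needed by the mapping is missing or duplicated."""


class IncompletenessError(ValueError):
    """A scan subgraph lacks mandatory triples; lists the absent terms."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__("incomplete scan subgraph; missing: " + ", ".join(self.missing))


class AmbiguityError(ValueError):
    """More than one node fills a slot the model constrains to one."""


class NotFoundError(KeyError):
    """The requested scan IRI is absent from the graph."""


_COORD_CLASS = {
    "distance": "DistanceCoordinate",
    "angle": "AngleCoordinate",
    "dihedral": "DihedralAngleCoordinate",
}
_UNIT_TERM = {"angstrom": "Angstrom", "degree": "Degree", "hartree": "Hartree"}


@dataclass(frozen=True)
class VocabularyMap:
    """Namespace prefixes and term names used by the RDF mapping.

    Every term used by the mapping resolves to exactly one absolute IRI;
    the reverse map is checked to be bijective at construction.
    """

    scan_ns: str = "https://example.org/ontology/pesscan#"
    species_ns: str = "https://example.org/ontology/species#"
    calc_ns: str = "https://example.org/ontology/compchem#"
    quantity_ns: str = "https://example.org/ontology/quantity#"
    unit_ns: str = "https://example.org/ontology/unit#"
    #: (term name, full IRI) overrides, e.g. to point SCF-energy terms at a
    #: real upstream computational-chemistry vocabulary
    overrides: tuple[tuple[str, str], ...] = ()

    _SCAN_TERMS = (
        "PotentialEnergySurfaceScan", "ScanCoordinate", "DistanceCoordinate",
        "AngleCoordinate", "DihedralAngleCoordinate", "ScanPoint",
        "ScanCoordinateValue", "onSpecies", "hasFragment", "hasScanCoordinate",
        "hasScanAtom", "hasScanPoint", "hasScanCoordinateValue",
        "hasCalculation", "hasInputAtomIDs", "hasFitting", "hasFittingMethod",
        "hasFittingMethodSource", "hasFittingParameters", "parameterName",
        "parameterUnit", "sourceOrder",
    )
    _SPECIES_TERMS = ("Species", "Atom", "inChI", "hasAtom", "element", "atomIndex")
    _CALC_TERMS = (
        "GaussianCalculation", "ScfEnergy", "hasSCFEnergy", "hasGeometry",
        "program", "method", "basisSet", "charge", "spinMultiplicity", "jobKind",
    )
    _QUANTITY_TERMS = ("hasValue", "hasUnit")
    _UNIT_TERMS = ("Angstrom", "Degree", "Hartree")

    def __post_init__(self) -> None:
        iris = [str(self.term(t)) for t in self._all_terms()]
        if len(set(iris)) != len(iris):
            raise MappingError("vocabulary term IRIs are not unique (mapping must be bijective)")

    def _all_terms(self):
        return (self._SCAN_TERMS + self._SPECIES_TERMS + self._CALC_TERMS
                + self._QUANTITY_TERMS + self._UNIT_TERMS)

    def term(self, name: str) -> URIRef:
        for t, iri in self.overrides:
            if t == name:
                return URIRef(iri)
        if name in self._SCAN_TERMS:
            return URIRef(self.scan_ns + name)
        if name in self._SPECIES_TERMS:
            return URIRef(self.species_ns + name)
        if name in self._CALC_TERMS:
            return URIRef(self.calc_ns + name)
        if name in self._QUANTITY_TERMS:
            return URIRef(self.quantity_ns + name)
        if name in self._UNIT_TERMS:
            return URIRef(self.unit_ns + name)
        raise MappingError(f"vocabulary has no term {name!r}")

    def unit_iri(self, unit: str) -> URIRef:
        try:
            return self.term(_UNIT_TERM[unit])
        except KeyError as exc:
            raise MappingError(f"no unit IRI for {unit!r}") from exc

    def unit_name(self, iri: URIRef) -> str:
        for name, term in _UNIT_TERM.items():
            if self.term(term) == iri:
                return name
        raise MappingError(f"unknown unit IRI {iri}")

    def bind(self, g: Graph) -> None:
        g.bind("pes", Namespace(self.scan_ns))
        g.bind("spc", Namespace(self.species_ns))
        g.bind("occ", Namespace(self.calc_ns))
        g.bind("qty", Namespace(self.quantity_ns))
        g.bind("unit", Namespace(self.unit_ns))


DEFAULT_VOCAB = VocabularyMap()


_PLAIN_DECIMAL_RE = re.compile(r"^[+-]?\d+(\.\d+)?$")


def _plain_decimal(x: float) -> str:
    """Shortest round-trip decimal text, exponent-free (valid xsd:decimal)."""
    return format(Decimal(repr(float(x))), "f")


def _num(x: float) -> Literal:
    """Numeric literal whose lexical form survives Turtle bit-exactly."""
    return Literal(_plain_decimal(x), datatype=XSD.decimal)


def _text_num(text: str) -> Literal:
    """Preserve an as-printed decimal (e.g. an SCF energy) exactly."""
    if not _PLAIN_DECIMAL_RE.match(text):
        text = _plain_decimal(float(text))
    return Literal(text, datatype=XSD.decimal)


def _geometry_text(geometry) -> str:
    return "\n".join(f"{el} {repr(x)} {repr(y)} {repr(z)}" for el, x, y, z in geometry)


def _parse_geometry_text(text: str):
    rows = []
    for line in text.splitlines():
        el, x, y, z = line.split()
        rows.append((el, float(x), float(y), float(z)))
    return tuple(rows)


def _fitting_node_iri(scan_iri: str, rec: FittingRecord) -> URIRef:
    h = hashlib.sha1()
    h.update(rec.method_name.encode())
    h.update(rec.method_source.encode())
    for n, v, u in rec.parameters:
        h.update(f"{n}={repr(float(v))}[{u}]".encode())
    return URIRef(f"{scan_iri}/fitting/{h.hexdigest()[:12]}")


def _add_fitting(g: Graph, scan: URIRef, rec: FittingRecord, vocab: VocabularyMap) -> None:
    node = _fitting_node_iri(str(scan), rec)
    g.add((scan, vocab.term("hasFitting"), node))
    g.add((node, vocab.term("hasFittingMethod"), Literal(rec.method_name)))
    g.add((node, vocab.term("hasFittingMethodSource"), Literal(rec.method_source)))
    for pos, (name, value, unit) in enumerate(rec.parameters):
        # position encoded in the IRI so the record's parameter order survives
        p = URIRef(f"{node}/parameter/{pos:02d}/{name}")
        g.add((node, vocab.term("hasFittingParameters"), p))
        g.add((p, vocab.term("parameterName"), Literal(name)))
        g.add((p, vocab.term("hasValue"), _num(value)))
        g.add((p, vocab.term("parameterUnit"), Literal(unit)))


def to_graph(
    scan: PESScan,
    vocab: VocabularyMap = DEFAULT_VOCAB,
    species: Iterable[SpeciesRef] = (),
) -> Graph:
    """Serialize one scan (and optional species descriptions) to triples.

    The triple count follows the documented mapping table in the module
    docstring.  ``species`` objects, when given, additionally emit species
    nodes with type/InChI/label and minimal atom descriptions so that
    InChI-based queries work.
    """
    g = Graph()
    vocab.bind(g)
    s = URIRef(scan.iri)
    g.add((s, RDF.type, vocab.term("PotentialEnergySurfaceScan")))
    for sp_iri in scan.on_species:
        g.add((s, vocab.term("onSpecies"), URIRef(sp_iri)))
    for fr_iri in scan.fragments:
        g.add((s, vocab.term("hasFragment"), URIRef(fr_iri)))

    coord = URIRef(f"{scan.iri}/coordinate")
    g.add((s, vocab.term("hasScanCoordinate"), coord))
    g.add((coord, RDF.type, vocab.term(_COORD_CLASS[scan.coordinate.kind])))
    for atom_iri in scan.coordinate.scan_atoms:
        g.add((coord, vocab.term("hasScanAtom"), URIRef(atom_iri)))

    for p in scan.points:
        pt = URIRef(f"{scan.iri}/point/{p.order_index}")
        g.add((s, vocab.term("hasScanPoint"), pt))
        g.add((pt, RDF.type, vocab.term("ScanPoint")))
        scv = URIRef(f"{pt}/value")
        g.add((pt, vocab.term("hasScanCoordinateValue"), scv))
        g.add((scv, RDF.type, vocab.term("ScanCoordinateValue")))
        g.add((scv, vocab.term("hasValue"), _num(p.coordinate_value)))
        g.add((scv, vocab.term("hasUnit"), vocab.unit_iri(p.unit)))
        g.add((pt, vocab.term("hasInputAtomIDs"),
               Literal(",".join(str(i) for i in p.input_atom_ids))))
        if p.source_order is not None:
            g.add((pt, vocab.term("sourceOrder"), Literal(int(p.source_order))))
        c = p.calculation
        calc = URIRef(c.iri)
        g.add((pt, vocab.term("hasCalculation"), calc))
        g.add((calc, RDF.type, vocab.term("GaussianCalculation")))
        en = URIRef(f"{c.iri}/scfEnergy")
        g.add((calc, vocab.term("hasSCFEnergy"), en))
        g.add((en, RDF.type, vocab.term("ScfEnergy")))
        g.add((en, vocab.term("hasValue"), _text_num(c.energy_text)))
        g.add((en, vocab.term("hasUnit"), vocab.unit_iri("hartree")))
        g.add((calc, vocab.term("hasGeometry"), Literal(_geometry_text(c.geometry))))
        g.add((calc, vocab.term("program"), Literal(c.program)))
        g.add((calc, vocab.term("method"), Literal(c.method)))
        g.add((calc, vocab.term("basisSet"), Literal(c.basis_set)))
        g.add((calc, vocab.term("charge"), Literal(int(c.charge))))
        g.add((calc, vocab.term("spinMultiplicity"), Literal(int(c.spin_multiplicity))))
        g.add((calc, vocab.term("jobKind"), Literal(c.job_kind)))

    for rec in scan.fittings:
        _add_fitting(g, s, rec, vocab)

    for sp in species:
        node = URIRef(sp.iri)
        g.add((node, RDF.type, vocab.term("Species")))
        g.add((node, vocab.term("inChI"), Literal(sp.inchi)))
        g.add((node, RDFS.label, Literal(sp.label)))
        for a in sp.atoms:
            an = URIRef(a.iri)
            g.add((node, vocab.term("hasAtom"), an))
            g.add((an, RDF.type, vocab.term("Atom")))
            g.add((an, vocab.term("element"), Literal(a.element)))
            g.add((an, vocab.term("atomIndex"), Literal(int(a.index))))
    return g


def _one(g: Graph, s, p, what: str, missing: list, allow_absent: bool = False):
    objs = list(g.objects(s, p))
    if not objs:
        if not allow_absent:
            missing.append(what)
        return None
    if len(objs) > 1:
        raise AmbiguityError(f"more than one {what} for {s}")
    return objs[0]


def from_graph(g: Graph, scan_iri: str, vocab: VocabularyMap = DEFAULT_VOCAB) -> PESScan:
    """Rebuild a :class:`PESScan` from its subgraph (inverse of to_graph).

    Raises :class:`IncompletenessError` listing absent mandatory terms, and
    :class:`AmbiguityError` when e.g. two coordinate nodes target one scan.
    """
    s = URIRef(scan_iri)
    missing: list[str] = []
    if (s, RDF.type, vocab.term("PotentialEnergySurfaceScan")) not in g:
        raise IncompletenessError(["PotentialEnergySurfaceScan type assertion"])

    on_species = tuple(sorted(str(o) for o in g.objects(s, vocab.term("onSpecies"))))
    fragments = tuple(sorted(str(o) for o in g.objects(s, vocab.term("hasFragment"))))
    if not on_species:
        missing.append("onSpecies")

    coord_nodes = list(g.objects(s, vocab.term("hasScanCoordinate")))
    if not coord_nodes:
        missing.append("hasScanCoordinate")
        raise IncompletenessError(missing)
    if len(coord_nodes) > 1:
        raise AmbiguityError(f"scan {scan_iri} has {len(coord_nodes)} coordinate nodes; "
                             "a 1D scan is linked to exactly one")
    coord_node = coord_nodes[0]
    kind = None
    for k, cls in _COORD_CLASS.items():
        if (coord_node, RDF.type, vocab.term(cls)) in g:
            kind = k
    if kind is None:
        missing.append("coordinate kind (DistanceCoordinate/AngleCoordinate/"
                       "DihedralAngleCoordinate type)")
        raise IncompletenessError(missing)
    scan_atoms = tuple(sorted(str(o) for o in g.objects(coord_node, vocab.term("hasScanAtom"))))
    coordinate = ScanCoordinate(kind, scan_atoms)

    points = []
    for pt in g.objects(s, vocab.term("hasScanPoint")):
        pmissing: list[str] = []
        scv = _one(g, pt, vocab.term("hasScanCoordinateValue"),
                   f"hasScanCoordinateValue on {pt}", pmissing)
        ids_lit = _one(g, pt, vocab.term("hasInputAtomIDs"),
                       f"hasInputAtomIDs on {pt}", pmissing)
        calc_node = _one(g, pt, vocab.term("hasCalculation"),
                         f"hasCalculation on {pt}", pmissing)
        if pmissing:
            raise IncompletenessError(pmissing)
        value = float(_one(g, scv, vocab.term("hasValue"), f"value on {scv}", pmissing))
        unit = vocab.unit_name(_one(g, scv, vocab.term("hasUnit"), f"unit on {scv}", pmissing))
        src_order = _one(g, pt, vocab.term("sourceOrder"), "sourceOrder", pmissing,
                         allow_absent=True)

        cmissing: list[str] = []
        en = _one(g, calc_node, vocab.term("hasSCFEnergy"),
                  f"hasSCFEnergy on {calc_node}", cmissing)
        geom_lit = _one(g, calc_node, vocab.term("hasGeometry"),
                        f"hasGeometry on {calc_node}", cmissing)
        if cmissing:
            raise IncompletenessError(cmissing)
        e_lit = _one(g, en, vocab.term("hasValue"), f"value on {en}", cmissing)
        if cmissing:
            raise IncompletenessError(cmissing)

        def _lit(term: str, default=None):
            o = _one(g, calc_node, vocab.term(term), term, [], allow_absent=True)
            return default if o is None else o.toPython()

        calc = CalculationRecord(
            iri=str(calc_node),
            program=str(_lit("program", "unknown")),
            method=str(_lit("method", "unknown")),
            basis_set=str(_lit("basisSet", "unknown")),
            charge=int(_lit("charge", 0)),
            spin_multiplicity=int(_lit("spinMultiplicity", 1)),
            scf_energy=float(e_lit),
            scf_energy_text=str(e_lit),
            geometry=_parse_geometry_text(str(geom_lit)),
            job_kind=str(_lit("jobKind", "single_point")),
        )
        points.append(
            ScanPointRecord(
                order_index=0,  # reassigned after sorting
                coordinate_value=value,
                unit=unit,
                input_atom_ids=tuple(int(t) for t in str(ids_lit).split(",")),
                calculation=calc,
                source_order=None if src_order is None else int(src_order),
            )
        )
    if len(points) < 2:
        missing.append("hasScanPoint (at least two points)")
    if missing:
        raise IncompletenessError(missing)
    points.sort(key=lambda p: p.coordinate_value)
    points = [ScanPointRecord(i, p.coordinate_value, p.unit, p.input_atom_ids,
                              p.calculation, p.source_order)
              for i, p in enumerate(points)]

    fittings = []
    for node in sorted(g.objects(s, vocab.term("hasFitting")), key=str):
        method = _one(g, node, vocab.term("hasFittingMethod"), "hasFittingMethod", missing)
        source = _one(g, node, vocab.term("hasFittingMethodSource"),
                      "hasFittingMethodSource", missing)
        params = []
        for p in sorted(g.objects(node, vocab.term("hasFittingParameters")), key=str):
            name = str(_one(g, p, vocab.term("parameterName"), "parameterName", missing))
            value = float(_one(g, p, vocab.term("hasValue"), "parameter value", missing))
            unit = str(_one(g, p, vocab.term("parameterUnit"), "parameterUnit", missing))
            params.append((name, value, unit))
        fittings.append(FittingRecord(str(method), str(source), tuple(params)))
    if missing:
        raise IncompletenessError(missing)

    return PESScan(
        iri=scan_iri,
        on_species=on_species,
        fragments=fragments,
        coordinate=coordinate,
        points=tuple(points),
        fittings=tuple(fittings),
    )


# ---------------------------------------------------------------------------
# the two canonical query patterns

#: Find scans performed on a species, going through the species InChI.
SCANS_BY_INCHI_SPARQL = """
SELECT DISTINCT ?scan WHERE {{
  ?species a <{spc}Species> ;
           <{spc}inChI> ?inchi .
  ?scan a <{pes}PotentialEnergySurfaceScan> ;
        <{pes}onSpecies> ?species .
}}
ORDER BY ?scan
"""

#: Retrieve the electronic energy at each point of one scan.
POINT_ENERGIES_SPARQL = """
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>
SELECT ?value ?unit ?energy WHERE {{
  ?scan <{pes}hasScanPoint> ?point .
  ?point <{pes}hasScanCoordinateValue> ?scv ;
         <{pes}hasCalculation> ?calc .
  ?scv <{qty}hasValue> ?value ;
       <{qty}hasUnit> ?unit .
  ?calc <{occ}hasSCFEnergy> ?en .
  ?en <{qty}hasValue> ?energy .
}}
ORDER BY xsd:decimal(?value)
"""


def find_scans_by_inchi(g: Graph, inchi: str, vocab: VocabularyMap = DEFAULT_VOCAB) -> list[str]:
    """All scan IRIs performed on a species with the given InChI (exact text
    match), sorted lexicographically.  Empty list when nothing matches."""
    scans: set[str] = set()
    for sp in g.subjects(vocab.term("inChI"), Literal(inchi)):
        for scan in g.subjects(vocab.term("onSpecies"), sp):
            if (scan, RDF.type, vocab.term("PotentialEnergySurfaceScan")) in g:
                scans.add(str(scan))
    return sorted(scans)


def point_energies(
    g: Graph, scan_iri: str, vocab: VocabularyMap = DEFAULT_VOCAB
) -> list[tuple[float, str, float]]:
    """Per-point (coordinate value, unit, SCF energy in Hartree), ascending
    by coordinate value.  The energy floats are exactly the stored literals."""
    s = URIRef(scan_iri)
    pts = list(g.objects(s, vocab.term("hasScanPoint")))
    if not pts:
        raise IncompletenessError([f"hasScanPoint for {scan_iri}"])
    rows = []
    for pt in pts:
        missing: list[str] = []
        scv = _one(g, pt, vocab.term("hasScanCoordinateValue"),
                   f"hasScanCoordinateValue on {pt}", missing)
        calc = _one(g, pt, vocab.term("hasCalculation"), f"hasCalculation on {pt}", missing)
        if missing:
            raise IncompletenessError(missing)
        value = float(_one(g, scv, vocab.term("hasValue"), "value", missing))
        unit = vocab.unit_name(_one(g, scv, vocab.term("hasUnit"), "unit", missing))
        en = _one(g, calc, vocab.term("hasSCFEnergy"), f"hasSCFEnergy on {calc}", missing)
        if missing:
            raise IncompletenessError(missing)
        energy = float(_one(g, en, vocab.term("hasValue"), "energy value", missing))
        if missing:
            raise IncompletenessError(missing)
        rows.append((value, unit, energy))
    rows.sort(key=lambda r: r[0])
    return rows


def attach_fitting(
    g: Graph, scan_iri: str, rec: FittingRecord, vocab: VocabularyMap = DEFAULT_VOCAB
) -> Graph:
    """Add one fitting record to an existing scan; idempotent for identical
    records (the fitting node IRI is a content hash, and RDF graphs are
    triple sets)."""
    s = URIRef(scan_iri)
    if (s, RDF.type, vocab.term("PotentialEnergySurfaceScan")) not in g:
        raise NotFoundError(f"no PotentialEnergySurfaceScan {scan_iri} in graph")
    _add_fitting(g, s, rec, vocab)
    return g


# ---------------------------------------------------------------------------
# serialization helpers


def save_graph(g: Graph, path, fmt: str = "turtle") -> None:
    Graph.serialize(g, destination=str(path), format=fmt)


def load_graph(path, fmt: Optional[str] = None) -> Graph:
    g = Graph()
    g.parse(str(path), format=fmt or "turtle")
    return g


def graphs_isomorphic(g1: Graph, g2: Graph) -> bool:
    """Blank-node-safe graph comparison."""
    return isomorphic(g1, g2)
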