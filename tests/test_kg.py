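"""RDF mapping: triple counts, round trips, and the two query patterns."""

import itertools
from dataclasses import replace

import pytest
from rdflib import Graph, RDF

from pesscan import kg
from pesscan.kg import (
    DEFAULT_VOCAB,
    AmbiguityError,
    IncompletenessError,
    NotFoundError,
    VocabularyMap,
)
from pesscan.model import FittingRecord
from pesscan import synth

from conftest import make_diatomic_scan

MORSE_REC = FittingRecord(
    "MorsePotential", "textbook",
    (("De", 350.0, "kJ/mol"), ("re", 1.53, "angstrom"), ("a", 1.9, "1/angstrom")),
)


class TestToGraph:
    def test_minimal_scan_triple_count_matches_mapping_table(self):
        # hand count: 1 type + 1 onSpecies + 2 coordinate (link+type)
        # + 2 hasScanAtom + 2 points × 20 = 46
        scan = make_diatomic_scan([1.5, 1.6])
        assert len(kg.to_graph(scan)) == 46

    def test_triple_count_affine_in_points(self):
        n2 = len(kg.to_graph(make_diatomic_scan([1.5, 1.6])))
        n3 = len(kg.to_graph(make_diatomic_scan([1.5, 1.6, 1.7])))
        n4 = len(kg.to_graph(make_diatomic_scan([1.5, 1.6, 1.7, 1.8])))
        assert n3 - n2 == n4 - n3 == 20

    def test_morse_fitting_triples(self):
        scan = replace(make_diatomic_scan([1.5, 1.6]), fittings=(MORSE_REC,))
        g = kg.to_graph(scan)
        v = DEFAULT_VOCAB
        assert len(list(g.subject_objects(v.term("hasFittingMethod")))) == 1
        assert len(list(g.subject_objects(v.term("hasFittingMethodSource")))) == 1
        param_nodes = list(g.objects(None, v.term("hasFittingParameters")))
        assert len(param_nodes) == 3
        value_triples = [o for p in param_nodes for o in g.objects(p, v.term("hasValue"))]
        assert len(value_triples) == 3

    def test_no_fittings_no_fitting_triples(self):
        g = kg.to_graph(make_diatomic_scan([1.5, 1.6]))
        assert list(g.subject_objects(DEFAULT_VOCAB.term("hasFitting"))) == []

    def test_unknown_vocabulary_term_is_mapping_error(self):
        with pytest.raises(kg.MappingError):
            DEFAULT_VOCAB.term("hasNonexistentTerm")

    def test_override_collision_is_mapping_error(self):
        # forcing two terms onto one IRI breaks the bijective term map
        with pytest.raises(kg.MappingError):
            VocabularyMap(overrides=(
                ("hasValue", "https://example.org/clash#v"),
                ("hasUnit", "https://example.org/clash#v"),
            ))


class TestRoundTrip:
    def test_in_memory_round_trip(self, ethanol_scan, ethanol_species):
        g = kg.to_graph(ethanol_scan, species=[ethanol_species])
        assert kg.from_graph(g, ethanol_scan.iri) == ethanol_scan

    def test_turtle_round_trip_isomorphic_and_lossless(
        self, tmp_path, ethanol_scan, ethanol_species
    ):
        g = kg.to_graph(ethanol_scan, species=[ethanol_species])
        path = tmp_path / "scan.ttl"
        kg.save_graph(g, path)
        g2 = kg.load_graph(path)
        assert kg.graphs_isomorphic(g, g2)
        assert kg.from_graph(g2, ethanol_scan.iri) == ethanol_scan

    def test_round_trip_preserves_energy_text_exactly(self):
        scan = make_diatomic_scan([1.5, 1.6], energies=[-155.0790990, -155.1])
        back = kg.from_graph(kg.to_graph(scan), scan.iri)
        assert back.points[0].calculation.scf_energy_text == "-155.0790990"

    def test_missing_coordinate_is_incompleteness_error(self):
        scan = make_diatomic_scan([1.5, 1.6])
        g = kg.to_graph(scan)
        coord = next(g.objects(None, DEFAULT_VOCAB.term("hasScanCoordinate")))
        g.remove((None, DEFAULT_VOCAB.term("hasScanCoordinate"), coord))
        with pytest.raises(IncompletenessError) as err:
            kg.from_graph(g, scan.iri)
        assert "hasScanCoordinate" in str(err.value)

    def test_two_coordinate_nodes_is_ambiguity_error(self):
        from rdflib import URIRef

        scan = make_diatomic_scan([1.5, 1.6])
        g = kg.to_graph(scan)
        g.add((URIRef(scan.iri), DEFAULT_VOCAB.term("hasScanCoordinate"),
               URIRef(scan.iri + "/coordinate2")))
        with pytest.raises(AmbiguityError):
            kg.from_graph(g, scan.iri)


class TestQueries:
    def test_by_inchi_single_match(self, ethanol_scan, ethanol_species):
        g = kg.to_graph(ethanol_scan, species=[ethanol_species])
        assert kg.find_scans_by_inchi(g, ethanol_species.inchi) == [ethanol_scan.iri]

    def test_by_inchi_no_match(self, ethanol_scan, ethanol_species):
        g = kg.to_graph(ethanol_scan, species=[ethanol_species])
        assert kg.find_scans_by_inchi(g, "InChI=1S/CO2/c2-1-3") == []

    def test_two_scans_same_species_sorted(self, ethanol_species):
        a = make_diatomic_scan([1.5, 1.6], iri="https://example.org/pes/scan/b")
        b = make_diatomic_scan([1.5, 1.7], iri="https://example.org/pes/scan/a")
        g = Graph()
        for scan in (a, b):
            scan = replace(scan, on_species=(ethanol_species.iri,))
            g += kg.to_graph(scan, species=[ethanol_species])
        assert kg.find_scans_by_inchi(g, ethanol_species.inchi) == [
            "https://example.org/pes/scan/a", "https://example.org/pes/scan/b"]

    def test_query_matches_brute_force_over_models(self):
        # exhaustive: up to 3 species × scans distributed among them
        from pesscan.model import AtomRef, SpeciesRef

        species = []
        for m in range(3):
            iri = f"https://example.org/species/s{m}"
            species.append(SpeciesRef(
                iri=iri, inchi=f"InChI=1S/X{m}", label=f"s{m}",
                atoms=(AtomRef(f"{iri}/atom/1", "C", 1, (0.0, 0.0, 0.0)),
                       AtomRef(f"{iri}/atom/2", "C", 2, (0.0, 0.0, 1.5)))))
        scans = []
        for k, sp in enumerate(itertools.islice(itertools.cycle(species), 5)):
            scan = replace(
                make_diatomic_scan([1.5, 1.6], iri=f"https://example.org/pes/scan/{k}"),
                on_species=(sp.iri,))
            scans.append((scan, sp))
        g = Graph()
        for scan, sp in scans:
            g += kg.to_graph(scan, species=[sp])
        for sp in species:
            expected = sorted(s.iri for s, owner in scans if owner.iri == sp.iri)
            assert kg.find_scans_by_inchi(g, sp.inchi) == expected

    def test_point_energies_match_fixture(self, ethanol_scan, ethanol_species):
        g = kg.to_graph(ethanol_scan, species=[ethanol_species])
        rows = kg.point_energies(g, ethanol_scan.iri)
        assert len(rows) == len(ethanol_scan.points)
        assert rows[0][0] == 1.51
        assert rows[0][1] == "angstrom"
        assert [r[2] for r in rows] == [p.calculation.scf_energy
                                        for p in ethanol_scan.points]

    def test_point_energies_first_value_ordering(self):
        scan = make_diatomic_scan([1.51, 1.71])
        rows = kg.point_energies(kg.to_graph(scan), scan.iri)
        assert rows[0][0] == 1.51

    def test_point_energies_on_empty_graph(self):
        with pytest.raises(IncompletenessError):
            kg.point_energies(Graph(), "https://example.org/pes/none")

    def test_point_without_calculation_is_incompleteness_error(self):
        scan = make_diatomic_scan([1.5, 1.6])
        g = kg.to_graph(scan)
        g.remove((None, DEFAULT_VOCAB.term("hasCalculation"), None))
        with pytest.raises(IncompletenessError):
            kg.point_energies(g, scan.iri)


class TestAttachFitting:
    def test_attach_adds_parameter_value_triples(self):
        scan = make_diatomic_scan([1.5, 1.6])
        g = kg.to_graph(scan)
        n0 = len(g)
        rec = FittingRecord("EVB-2state-constant", "src",
                            (("A", 25.0, "kJ/mol"), ("s1", 0.0, "kJ/mol"),
                             ("s2", 40.0, "kJ/mol")))
        kg.attach_fitting(g, scan.iri, rec)
        # 3 grouping/method/source + 3 params × 4 triples
        assert len(g) - n0 == 15
        params = list(g.objects(None, DEFAULT_VOCAB.term("hasFittingParameters")))
        assert len(params) == 3

    def test_attach_is_idempotent(self):
        scan = make_diatomic_scan([1.5, 1.6])
        g = kg.to_graph(scan)
        rec = MORSE_REC
        kg.attach_fitting(g, scan.iri, rec)
        n1 = len(g)
        kg.attach_fitting(g, scan.iri, rec)
        assert len(g) == n1

    def test_attach_to_absent_scan_is_not_found(self):
        g = kg.to_graph(make_diatomic_scan([1.5, 1.6]))
        with pytest.raises(NotFoundError):
            kg.attach_fitting(g, "https://example.org/pes/none", MORSE_REC)

    def test_attached_record_survives_reload(self, tmp_path):
        scan = make_diatomic_scan([1.5, 1.6])
        g = kg.to_graph(scan)
        kg.attach_fitting(g, scan.iri, MORSE_REC)
        path = tmp_path / "g.ttl"
        kg.save_graph(g, path)
        back = kg.from_graph(kg.load_graph(path), scan.iri)
        assert back.fittings == (MORSE_REC,)
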