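"""PPEO-style RDF: triple emission, constraint checks, serialization."""

import pytest
from rdflib.namespace import XSD

from miappe.ppeo_rdf import (
    PPEO,
    RdfError,
    TripleSet,
    check_rdf_constraints,
    from_rdf,
    read_rdf,
    to_rdf,
    write_rdf,
)
from miappe.model import canonical
from miappe.validate import validate
from miappe import synth

BASE = "https://example.org/data/"


class TestTripleEmission:
    def test_unit_links_to_its_biological_material(self, minimal_dataset):
        triples = to_rdf(minimal_dataset, BASE).triples
        subject = BASE + "observation_unit/OU1"
        target = BASE + "biological_material/BM1"
        assert any(str(s) == subject and p == PPEO.hasBiologicalMaterial
                   and str(o) == target for s, p, o in triples)

    def test_collection_timestamp_is_datetime_typed(self, glasshouse):
        triples = to_rdf(glasshouse, BASE).triples
        literals = [o for s, p, o in triples if p == PPEO.collectionDate]
        assert literals and all(
            lit.datatype == XSD.dateTime for lit in literals)

    def test_one_study_one_has_study_triple(self, minimal_dataset):
        triples = to_rdf(minimal_dataset, BASE).triples
        assert sum(1 for _, p, _o in triples if p == PPEO.hasStudy) == 1

    def test_relative_base_iri_is_rejected(self, minimal_dataset):
        with pytest.raises(RdfError, match="absolute"):
            to_rdf(minimal_dataset, "not-absolute")

    def test_minimal_dataset_triple_count_matches_enumeration(
            self, minimal_dataset):
        # independent oracle: count the emitted statements by enumerating
        # the minimal dataset's populated fields and links by hand
        expected = sum([
            6,   # investigation: type + id/title/license/version + hasStudy
            7,   # study: type + id/title/start/end/hierarchy + hasLocation
            3,   # location node: type + country + site name
            5,   # data file: link via hasDataFile + type + 3 fields
            5,   # material: via hasBiologicalMaterial + type + id + organism
                 #   label + accession
            5,   # unit: via hasObservationUnit + type + id + level + link
                 #   to material
            5,   # sample: via hasSample + type + id + date + unit link
            4,   # variable: via hasObservedVariable + type + id + name
            3, 3, 3,  # trait / method / scale: link + type + name each
        ])
        assert len(to_rdf(minimal_dataset, BASE).triples) == expected


class TestConstraints:
    def test_investigation_without_study_is_violated(self, field_network):
        mutated = synth.mutate(field_network, "CARD-INV-STUDY", seed=0)
        violations = check_rdf_constraints(to_rdf(mutated, BASE))
        assert [v.restriction for v in violations] == [
            "investigation-min-1-study"]

    def test_valid_dataset_has_no_violations(self, field_network):
        assert check_rdf_constraints(to_rdf(field_network, BASE)) == []

    def test_sample_with_two_unit_links_is_violated(self, minimal_dataset):
        ts = to_rdf(minimal_dataset, BASE)
        from rdflib import URIRef
        extra = (URIRef(BASE + "sample/SA1"), PPEO.hasObservationUnit,
                 URIRef(BASE + "observation_unit/OU2"))
        mutated = TripleSet(triples=ts.triples | {extra},
                            base_iri=ts.base_iri)
        violations = check_rdf_constraints(mutated)
        assert [v.restriction for v in violations] == [
            "sample-exactly-1-observation-unit"]

    @pytest.mark.parametrize("rule_id", ["CARD-INV-STUDY", "CARD-STU-LOC",
                                         "CARD-SAM-OU"])
    def test_agreement_with_checklist_validator(self, field_network,
                                                rule_id):
        # the graph check and the checklist validator must agree on
        # cardinality verdicts, for valid and defective datasets alike
        for dataset in (field_network,
                        synth.mutate(field_network, rule_id, seed=0)):
            card_errors = any(
                i.rule_id in {"CARD-INV-STUDY", "CARD-STU-LOC",
                              "CARD-SAM-OU"}
                for i in validate(dataset).issues)
            violations = check_rdf_constraints(to_rdf(dataset, BASE))
            assert bool(violations) == card_errors


class TestSerialization:
    def test_turtle_is_byte_identical_across_runs(self, glasshouse,
                                                  tmp_path):
        ts = to_rdf(glasshouse, BASE)
        p1, p2 = tmp_path / "a.ttl", tmp_path / "b.ttl"
        write_rdf(ts, "turtle", p1)
        write_rdf(ts, "turtle", p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_turtle_and_jsonld_parse_to_equal_triples(self, glasshouse,
                                                      tmp_path):
        ts = to_rdf(glasshouse, BASE)
        write_rdf(ts, "turtle", tmp_path / "d.ttl")
        write_rdf(ts, "json-ld", tmp_path / "d.jsonld")
        assert read_rdf(tmp_path / "d.ttl").triples == ts.triples
        assert read_rdf(tmp_path / "d.jsonld").triples == ts.triples

    def test_unknown_format_tag(self, minimal_dataset, tmp_path):
        ts = to_rdf(minimal_dataset, BASE)
        with pytest.raises(RdfError, match="unknown RDF format"):
            write_rdf(ts, "n-quads-ish", tmp_path / "x")

    @pytest.mark.parametrize("scenario", synth.SCENARIOS)
    def test_graph_round_trip(self, scenario, tmp_path):
        dataset = synth.generate(scenario, seed=2)
        ts = to_rdf(dataset, BASE)
        path = tmp_path / f"{scenario}.ttl"
        write_rdf(ts, "turtle", path)
        recovered = from_rdf(read_rdf(path))
        assert canonical(recovered) == canonical(dataset)
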