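"""Object-graph construction, indexing, reference walking and ancestry."""

import copy

import pytest
from hypothesis import given, settings, strategies as st

from miappe.iso8601 import is_iso8601, parse_iso8601
from miappe.model import (
    ContractViolationError,
    DuplicateIdError,
    ObservationUnit,
    Sample,
    build_dataset,
    canonical,
    observation_unit_ancestry,
    resolve_references,
)
from miappe import synth

from conftest import make_minimal_investigation


class TestBuildDataset:
    def test_minimal_graph_is_indexed_and_closed(self, minimal_dataset):
        d = minimal_dataset
        assert d.record("study", "S1").title == "Single plot trial"
        assert d.record("observation_unit", "OU1").level == "plot"
        assert d.record("sample", "SA1").observation_unit_id == "OU1"
        assert d.record("biological_material", "BM1") is not None
        assert resolve_references(d) == []

    def test_duplicate_observation_unit_id_is_an_error(self):
        inv = make_minimal_investigation()
        inv.studies[0].observation_units.append(
            ObservationUnit(id="OU1", level="study"))
        with pytest.raises(DuplicateIdError, match="OU1"):
            build_dataset(inv)

    def test_shared_identical_records_are_not_duplicates(self, field_network):
        # a network shares its material list across studies; the same id
        # with identical content is one shared record, not a collision
        studies = field_network.investigation.studies
        shared = studies[0].biological_materials[0].id
        assert any(bm.id == shared
                   for bm in studies[1].biological_materials)

    def test_construction_does_not_mutate_input_and_is_idempotent(self):
        inv = make_minimal_investigation()
        before = copy.deepcopy(inv)
        d1 = build_dataset(inv)
        d2 = build_dataset(inv)
        assert inv == before
        assert canonical(d1) == canonical(d2)


class TestResolveReferences:
    def test_dangling_sample_reference_is_reported(self):
        inv = make_minimal_investigation()
        inv.studies[0].samples.append(
            Sample(id="s1", observation_unit_id="OU9",
                   collection_date="2020-06-01"))
        refs = resolve_references(build_dataset(inv))
        assert len(refs) == 1
        r = refs[0]
        assert (r.section, r.source_id, r.field, r.target_id) == (
            "Sample", "s1", "observation_unit_id", "OU9")

    @pytest.mark.parametrize("scenario", synth.SCENARIOS)
    def test_generated_graphs_are_closed(self, scenario):
        for seed in range(25):
            assert resolve_references(synth.generate(scenario, seed=seed)) \
                == []


class TestAncestry:
    def test_plot_under_three_level_hierarchy(self, field_network):
        unit = sorted(u for u in field_network.records("observation_unit")
                      if u.endswith("-P1"))[0]
        assert observation_unit_ancestry(field_network, unit) == [
            "study", "genotype", "plot"]

    def test_study_level_unit_has_single_element_path(self, field_network):
        unit = sorted(u for u in field_network.records("observation_unit")
                      if u.endswith("-station"))[0]
        assert observation_unit_ancestry(field_network, unit) == ["study"]

    def test_undeclared_level_is_a_contract_violation(self):
        inv = make_minimal_investigation()
        inv.studies[0].observation_units[0].level = "pot"
        d = build_dataset(inv)
        with pytest.raises(ContractViolationError, match="pot"):
            observation_unit_ancestry(d, "OU1")


class TestCanonical:
    def test_record_order_does_not_matter(self, glasshouse):
        inv = copy.deepcopy(glasshouse.investigation)
        study = inv.studies[0]
        study.observation_units.reverse()
        study.biological_materials.reverse()
        study.samples.reverse()
        assert canonical(build_dataset(inv)) == canonical(glasshouse)

    def test_hierarchy_order_does_matter(self, glasshouse):
        inv = copy.deepcopy(glasshouse.investigation)
        inv.studies[0].observation_unit_level_hierarchy.reverse()
        assert canonical(build_dataset(inv)) != canonical(glasshouse)


class TestIso8601:
    @pytest.mark.parametrize("text,valid", [
        ("2017", True),
        ("2017-06", True),
        ("2017-06-30", True),
        ("2017-06-31", False),      # impossible calendar date
        ("2017-13", False),
        ("2017-06-15T10:30:00", True),
        ("2017-06-15T10:30:00Z", True),
        ("2017-06-15T10:30:00+02:00", True),
        ("15/06/2017", False),
        ("June 2017", False),
        ("", False),
    ])
    def test_reduced_precision_parsing(self, text, valid):
        assert is_iso8601(text) is valid

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.dates())
    def test_any_calendar_date_parses_and_orders(self, d):
        parsed = parse_iso8601(d.isoformat())
        assert parsed is not None
        assert (parsed.year, parsed.month, parsed.day) == (
            d.year, d.month, d.day)
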