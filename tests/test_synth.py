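"""Scenario generator: archetype semantics, determinism, mutation harness."""

import json

import pytest

from miappe.model import canonical
from miappe.validate import validate
from miappe import synth


class TestScenarios:
    def test_field_network_one_study_per_location(self):
        dataset = synth.generate("field_network", seed=42,
                                 params={"locations": 3, "years": 2})
        inv = dataset.investigation
        assert len(inv.studies) == 3
        # material and variable lists are shared across the network
        ids0 = {bm.id for bm in inv.studies[0].biological_materials}
        for study in inv.studies[1:]:
            assert {bm.id for bm in study.biological_materials} == ids0
        for study in inv.studies:
            assert study.observation_unit_level_hierarchy == [
                "study", "genotype", "plot"]
            assert any(u.level == "study" for u in study.observation_units)

    def test_forest_trees_identified_by_coordinates_alone(self):
        dataset = synth.generate("forest_geo", seed=1, params={"trees": 10})
        materials = list(dataset.records("biological_material").values())
        assert len(materials) == 10
        for bm in materials:
            assert bm.geo is not None
            assert bm.geo.latitude is not None
            assert bm.material_source is None

    def test_factorial_factor_values_are_crossed_over_units(self):
        dataset = synth.generate("glasshouse_factorial", seed=2)
        study = dataset.investigation.studies[0]
        factor = study.factors[0]
        assert factor.type == "drought"
        assert set(factor.values) == {"rainfed", "irrigated"}
        seen = {u.factor_values.get("drought")
                for u in study.observation_units if u.factor_values}
        assert seen == {"rainfed", "irrigated"}

    def test_time_series_uses_thermal_time_and_repeated_events(self):
        dataset = synth.generate("time_series", seed=3)
        study = dataset.investigation.studies[0]
        assert study.observed_variables[0].time_scale == \
            "growing degree days"
        keys = {(e.type.label, e.description) for e in study.events}
        assert len(keys) == 1            # one repeated event series
        assert len(study.events) >= 2    # several dated occurrences
        assert len({e.date for e in study.events}) == len(study.events)

    def test_sensor_unit_contains_no_plant_yet_validates(self):
        dataset = synth.generate("sensor_only", seed=4)
        units = dataset.records("observation_unit").values()
        assert any(u.biological_material_id is None for u in units)
        assert validate(dataset).error_count == 0

    def test_crossing_population_traces_parents_via_material_source(self):
        dataset = synth.generate("crossing_population", seed=5,
                                 params={"progeny": 6})
        materials = list(dataset.records("biological_material").values())
        assert len(materials) == 6
        assert len({bm.id for bm in materials}) == 6
        sources = {bm.material_source.id for bm in materials}
        assert len(sources) == 1  # all progeny share the cross

    def test_unknown_scenario(self):
        with pytest.raises(synth.UnknownScenarioError):
            synth.generate("orbital_greenhouse", seed=0)


class TestDeterminism:
    @pytest.mark.parametrize("scenario", synth.SCENARIOS)
    def test_same_spec_same_output(self, scenario):
        a = synth.generate(synth.ScenarioSpec(scenario=scenario, seed=9))
        b = synth.generate(synth.ScenarioSpec(scenario=scenario, seed=9))
        assert json.dumps(canonical(a), sort_keys=True) == \
            json.dumps(canonical(b), sort_keys=True)

    def test_different_seeds_differ(self):
        a = synth.generate("field_network", seed=1)
        b = synth.generate("field_network", seed=2)
        assert canonical(a) != canonical(b)


class TestMutate:
    def test_unknown_rule_is_an_error(self, field_network):
        with pytest.raises(synth.UnknownRuleError):
            synth.mutate(field_network, "RULE-THAT-DOES-NOT-EXIST")

    def test_not_mutable_when_structure_absent(self):
        dataset = synth.generate("forest_geo", seed=0)  # has no events
        with pytest.raises(synth.RuleNotMutableError):
            synth.mutate(dataset, "REQ-EV-DATE")

    def test_mutation_leaves_the_original_untouched(self, field_network):
        before = canonical(field_network)
        synth.mutate(field_network, "CARD-INV-STUDY", seed=0)
        assert canonical(field_network) == before

    def test_geo_mutation_produces_out_of_range_latitude(self,
                                                         field_network):
        mutated = synth.mutate(field_network, "FMT-GEO", seed=0)
        geo = mutated.investigation.studies[0].location.geo
        assert geo.latitude == 91.0


class TestDataFiles:
    def test_linked_observation_files_are_materialized(self, field_network,
                                                       tmp_path):
        written = synth.write_data_files(field_network, tmp_path, seed=0)
        links = {df.link for s in field_network.investigation.studies
                 for df in s.data_files}
        assert {p.name for p in written} == links
        header = written[0].read_text().splitlines()[0]
        assert header.split("\t") == ["observation_unit_id", "variable_id",
                                      "time", "value"]
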