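"""Checklist validation: rule registry, per-rule behaviour, determinism."""

import pytest

from miappe.model import DataFile, Sample, build_dataset
from miappe.validate import ERROR, WARNING, check_value_formats, \
    rule_registry, validate
from miappe import synth

from conftest import make_minimal_investigation


class TestRuleRegistry:
    def test_rule_ids_are_unique(self):
        ids = [r.rule_id for r in rule_registry()]
        assert len(ids) == len(set(ids))

    def test_severities_are_binary(self):
        assert {r.severity for r in rule_registry()} == {ERROR, WARNING}

    def test_investigation_study_cardinality_is_an_error_rule(self):
        rules = {r.rule_id: r for r in rule_registry()}
        assert rules["CARD-INV-STUDY"].severity == ERROR
        assert rules["CARD-STU-OU"].severity == WARNING

    def test_every_emitted_rule_is_registered(self, field_network):
        registered = {r.rule_id for r in rule_registry()}
        for rule_id in registered:
            report = validate(synth.mutate(field_network, rule_id, seed=0))
            assert {i.rule_id for i in report.issues} <= registered


class TestCardinalityAndRequirements:
    def test_zero_studies_fails_with_cardinality_error(self):
        inv = make_minimal_investigation()
        inv.studies = []
        report = validate(build_dataset(inv))
        assert report.verdict == "FAIL"
        assert [i.rule_id for i in report.issues
                if i.severity == ERROR] == ["CARD-INV-STUDY"]

    def test_zero_observation_units_warns_but_passes(self):
        inv = make_minimal_investigation()
        study = inv.studies[0]
        study.observation_units = []
        study.samples = []
        report = validate(build_dataset(inv))
        assert report.has_rule("CARD-STU-OU")
        assert report.verdict == "PASS"

    def test_sample_without_observation_unit_is_an_error(self):
        inv = make_minimal_investigation()
        inv.studies[0].samples.append(
            Sample(id="SA2", collection_date="2020-06-01"))
        report = validate(build_dataset(inv))
        assert report.has_rule("CARD-SAM-OU")
        assert report.verdict == "FAIL"

    def test_material_without_organism_is_an_error(self):
        inv = make_minimal_investigation()
        inv.studies[0].biological_materials[0].organism = None
        report = validate(build_dataset(inv))
        assert report.has_rule("REQ-BM-ORGANISM")

    def test_data_file_without_version_is_an_error(self):
        inv = make_minimal_investigation()
        inv.studies[0].data_files.append(
            DataFile(link="x.tsv", description="no version here"))
        report = validate(build_dataset(inv))
        assert report.has_rule("REQ-DF-VERSION")

    def test_missing_location_is_an_error(self):
        inv = make_minimal_investigation()
        inv.studies[0].location = None
        report = validate(build_dataset(inv))
        assert report.has_rule("CARD-STU-LOC")


class TestValueFormats:
    def test_impossible_calendar_date_is_flagged(self):
        inv = make_minimal_investigation()
        inv.studies[0].samples[0].collection_date = "2017-06-31"
        issues = check_value_formats(build_dataset(inv))
        assert any(i.rule_id == "FMT-DATE" for i in issues)

    def test_latitude_out_of_range_is_flagged(self, field_network):
        mutated = synth.mutate(field_network, "FMT-GEO", seed=0)
        issues = check_value_formats(mutated)
        assert any(i.rule_id == "FMT-GEO" for i in issues)

    def test_undeclared_factor_value_is_flagged(self):
        # drought declares rainfed / irrigated; "flooded" is not a modality
        inv = synth.generate("glasshouse_factorial", seed=0).investigation
        import copy
        inv = copy.deepcopy(inv)
        unit = next(u for u in inv.studies[0].observation_units
                    if u.factor_values)
        unit.factor_values["drought"] = "flooded"
        issues = check_value_formats(build_dataset(inv))
        assert any(i.rule_id == "FMT-FACTORVALUE" for i in issues)

    def test_wrong_checklist_version_is_flagged(self):
        inv = make_minimal_investigation()
        inv.miappe_version = "1.0"
        issues = check_value_formats(build_dataset(inv))
        assert any(i.rule_id == "FMT-MIAPPE-VERSION" for i in issues)


class TestGeneratedDatasetsAreClean:
    @pytest.mark.parametrize("scenario", synth.SCENARIOS)
    def test_zero_errors_across_seeds(self, scenario):
        for seed in range(10):
            report = validate(synth.generate(scenario, seed=seed))
            assert report.error_count == 0, report.to_tsv()


class TestMutationProperty:
    @pytest.mark.parametrize("rule_id",
                             [r.rule_id for r in rule_registry()])
    def test_each_defect_triggers_exactly_its_rule(self, field_network,
                                                   rule_id):
        baseline = {i.rule_id for i in validate(field_network).issues
                    if i.severity == ERROR}
        report = validate(synth.mutate(field_network, rule_id, seed=0))
        assert report.has_rule(rule_id)
        new_errors = {i.rule_id for i in report.issues
                      if i.severity == ERROR} - baseline
        assert new_errors <= {rule_id}


class TestReportShape:
    def test_report_is_deterministic_and_sorted(self, field_network):
        mutated = synth.mutate(field_network, "REQ-DF-VERSION", seed=0)
        r1, r2 = validate(mutated), validate(mutated)
        assert r1.to_tsv() == r2.to_tsv()
        assert r1.to_json() == r2.to_json()
        keys = [i.sort_key() for i in r1.issues]
        assert keys == sorted(keys)

    def test_counts_match_issue_tallies(self, field_network):
        mutated = synth.mutate(field_network, "WARN-SAM-DATE-RANGE", seed=0)
        report = validate(mutated)
        assert report.error_count == sum(
            1 for i in report.issues if i.severity == ERROR)
        assert report.warning_count == sum(
            1 for i in report.issues if i.severity == WARNING)
        assert report.verdict == "PASS"
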