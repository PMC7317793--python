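"""BrAPI mapping: field carry, additionalInfo routing, round-trips."""

import pytest

from miappe.brapi import (
    BrapiDocumentSet,
    DanglingReferenceError,
    MODEL_FIELD_ROUTING,
    from_brapi,
    read_brapi,
    to_brapi,
    write_brapi,
)
from miappe.model import canonical
from miappe import synth

from conftest import model_field_census


class TestMapping:
    def test_investigation_becomes_trial(self, minimal_dataset):
        docs = to_brapi(minimal_dataset)
        trial = docs.collection("trials")[0]
        assert trial["trialDbId"] == "doi:10.5072/minimal"
        assert trial["trialName"] == "Minimal experiment"
        assert trial["studies"] == [{"studyDbId": "S1",
                                     "studyName": "Single plot trial"}]

    def test_one_material_one_germplasm(self, minimal_dataset):
        docs = to_brapi(minimal_dataset)
        germplasm = docs.collection("germplasm")
        assert len(germplasm) == 1
        assert germplasm[0]["germplasmDbId"] == "BM1"

    def test_environment_parameters_go_to_additional_info(self,
                                                          field_network):
        docs = to_brapi(field_network)
        study = docs.collection("studies")[0]
        env = study["additionalInfo"]["miappe:environment"]
        assert len(env) == 2
        assert {e["parameter"] for e in env} == {"sowing density",
                                                 "rooting medium"}

    def test_three_level_factor_yields_three_treatments(self,
                                                        field_network):
        docs = to_brapi(field_network)
        study = docs.collection("studies")[0]
        treatments = study["treatments"]
        assert len(treatments) == 3
        assert {t["modality"] for t in treatments} == {
            "high nitrogen input", "low nitrogen input",
            "no nitrogen inputs"}

    def test_dbids_equal_miappe_ids(self, glasshouse):
        docs = to_brapi(glasshouse)
        model_units = set(glasshouse.records("observation_unit"))
        brapi_units = {d["observationUnitDbId"]
                       for d in docs.collection("observationunits")}
        assert brapi_units == model_units


class TestRoundTrip:
    @pytest.mark.parametrize("scenario", synth.SCENARIOS)
    def test_in_memory_identity(self, scenario):
        for seed in range(5):
            dataset = synth.generate(scenario, seed=seed)
            assert canonical(from_brapi(to_brapi(dataset))) == \
                canonical(dataset)

    def test_disk_identity(self, glasshouse, tmp_path):
        write_brapi(to_brapi(glasshouse), tmp_path)
        assert canonical(from_brapi(read_brapi(tmp_path))) == \
            canonical(glasshouse)

    def test_dangling_observation_unit_reference(self, glasshouse):
        docs = to_brapi(glasshouse)
        docs.collection("samples")[0]["observationUnitDbId"] = "NO-SUCH"
        with pytest.raises(DanglingReferenceError, match="NO-SUCH"):
            from_brapi(docs)


class TestCannedFixture:
    """A hand-authored BrAPI payload; the expectation is built manually."""

    def _docs(self):
        docs = BrapiDocumentSet()
        docs.collection("trials").append({
            "trialDbId": "T1", "trialName": "Canned trial",
            "studies": [{"studyDbId": "ST1", "studyName": "Canned study"}],
            "additionalInfo": {"miappe:miappe_version": "1.1",
                               "miappe:license": "CC BY 4.0"},
        })
        docs.collection("studies").append({
            "studyDbId": "ST1", "studyName": "Canned study",
            "trialDbId": "T1", "startDate": "2019",
            "locationName": "Nowhere field",
            "location": {"countryName": "Italy", "name": "Nowhere field"},
            "additionalInfo": {
                "miappe:biological_material_ids": ["G1"],
                "miappe:observation_variable_ids": ["V1"],
            },
        })
        docs.collection("germplasm").append({
            "germplasmDbId": "G1", "genus": "Solanum",
            "commonCropName": "Solanum lycopersicum",
        })
        docs.collection("observationunits").append({
            "observationUnitDbId": "U1", "observationLevel": "plant",
            "germplasmDbId": "G1", "studyDbId": "ST1",
        })
        docs.collection("variables").append({
            "observationVariableDbId": "V1",
            "observationVariableName": "Fruit weight",
            "trait": {"traitName": "Fruit weight"},
            "method": {"methodName": "Balance"},
            "scale": {"scaleName": "g"},
        })
        return docs

    def test_expected_dataset(self):
        dataset = from_brapi(self._docs())
        inv = dataset.investigation
        assert inv.id == "T1"
        assert inv.miappe_version == "1.1"
        study = inv.studies[0]
        assert study.start_date == "2019"
        assert study.location.country == "Italy"
        assert [bm.id for bm in study.biological_materials] == ["G1"]
        assert study.biological_materials[0].organism.label == \
            "Solanum lycopersicum"
        assert [u.id for u in study.observation_units] == ["U1"]
        assert study.observation_units[0].biological_material_id == "G1"
        var = study.observed_variables[0]
        assert (var.trait.name, var.method.name, var.scale.name) == (
            "Fruit weight", "Balance", "g")


class TestCompleteness:
    def test_every_model_field_is_routed(self):
        census = model_field_census()
        for sheet, paths in census.items():
            routing = MODEL_FIELD_ROUTING[sheet]
            missing = paths - set(routing)
            assert not missing, f"{sheet}: unrouted fields {missing}"
            assert set(routing.values()) <= {"named", "additionalInfo"}
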