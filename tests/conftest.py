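"""Shared fixtures: a hand-built minimal dataset, generated scenario
datasets, and a census of model fields derived from the dataclasses."""

from __future__ import annotations

import dataclasses

import pytest

from miappe.model import (
    BiologicalMaterial,
    DataFile,
    ExperimentalDesign,
    ExperimentalFactor,
    GeoPoint,
    GrowthFacility,
    Investigation,
    MaterialSource,
    MethodRef,
    ObservationUnit,
    ObservedVariable,
    OntologyRef,
    Person,
    Sample,
    ScaleRef,
    Study,
    StudyLocation,
    TraitRef,
    build_dataset,
)
from miappe import synth


def make_minimal_investigation() -> Investigation:
    """One study, one unit, one sample, one material, one variable."""
    return Investigation(
        id="doi:10.5072/minimal",
        title="Minimal experiment",
        license="CC BY 4.0",
        miappe_version="1.1",
        studies=[Study(
            id="S1",
            title="Single plot trial",
            start_date="2020-04-01",
            end_date="2020-09-30",
            location=StudyLocation(country="France", site_name="Site A"),
            observation_unit_level_hierarchy=["study", "plot"],
            data_files=[DataFile(link="obs.tsv", description="observations",
                                 version="1.0")],
            biological_materials=[BiologicalMaterial(
                id="BM1",
                organism=OntologyRef(label="Zea mays",
                                     accession="NCBITaxon:4577"))],
            observation_units=[ObservationUnit(
                id="OU1", level="plot", biological_material_id="BM1")],
            samples=[Sample(id="SA1", observation_unit_id="OU1",
                            collection_date="2020-06-15")],
            observed_variables=[ObservedVariable(
                id="V1", name="Plant height",
                trait=TraitRef(name="Plant height"),
                method=MethodRef(name="Ruler"),
                scale=ScaleRef(name="cm"))],
        )],
    )


@pytest.fixture
def minimal_dataset():
    return build_dataset(make_minimal_investigation())


@pytest.fixture
def field_network():
    return synth.generate("field_network", seed=42)


@pytest.fixture
def glasshouse():
    return synth.generate("glasshouse_factorial", seed=42)


# ---------------------------------------------------------------------------
# Model field census: leaf field paths per checklist section, derived from
# the dataclasses themselves so the serializer coverage tests cannot drift.

_VALUE_TYPES = {
    "OntologyRef": OntologyRef,
    "GeoPoint": GeoPoint,
    "MaterialSource": MaterialSource,
    "StudyLocation": StudyLocation,
    "ExperimentalDesign": ExperimentalDesign,
    "GrowthFacility": GrowthFacility,
    "TraitRef": TraitRef,
    "MethodRef": MethodRef,
    "ScaleRef": ScaleRef,
}

# (section sheet name, dataclass, record-list fields that are sections of
# their own and therefore not leaf fields of this record)
_SECTION_TYPES = [
    ("Investigation", Investigation, {"persons", "studies"}),
    ("Study", Study, {"data_files", "biological_materials", "environments",
                      "factors", "events", "observation_units", "samples",
                      "observed_variables", "persons"}),
    ("Person", Person, set()),
    ("Data file", DataFile, set()),
    ("Biological material", BiologicalMaterial, set()),
    ("Environment", __import__("miappe.model", fromlist=[
        "EnvironmentParameter"]).EnvironmentParameter, set()),
    ("Experimental factor", ExperimentalFactor, set()),
    ("Event", __import__("miappe.model", fromlist=["Event"]).Event, set()),
    ("Observation unit", ObservationUnit, set()),
    ("Sample", Sample, set()),
    ("Observed variable", ObservedVariable, set()),
]


def _leaf_paths(dc_type, exclude=frozenset()) -> set[str]:
    out: set[str] = set()
    for f in dataclasses.fields(dc_type):
        if f.name in exclude or f.name.startswith("_"):
            continue
        annotation = str(f.type)
        sub = next((t for name, t in _VALUE_TYPES.items()
                    if name in annotation), None)
        if sub is not None:
            out |= {f"{f.name}.{p}" for p in _leaf_paths(sub)}
        else:
            out.add(f.name)
    return out


def model_field_census() -> dict[str, set[str]]:
    """Every leaf model field path, grouped by checklist section."""
    return {sheet: _leaf_paths(dc, exclude)
            for sheet, dc, exclude in _SECTION_TYPES}
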