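"""BrAPI v1.3-shaped JSON document sets.

A dataset maps onto eight document collections (trial, study, contact,
germplasm, observation unit, sample, variable, data link), exchanged as one
JSON array file per collection in a directory — no HTTP layer. DbIds equal
MIAPPE identifiers verbatim, which is what makes the mapping reversible.

MIAPPE sections absent from BrAPI 1.3 (environment, event) and fields
without an official key travel under ``additionalInfo`` with keys prefixed
``miappe:``; every model field is either mapped to a named BrAPI key or
carried that way, never dropped. The scalar key-level mapping is shipped as
configuration tables (``TRIAL_FIELDS`` etc.) so it can be realigned when
the official field mapping evolves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from miappe.model import (
    BiologicalMaterial,
    Dataset,
    DataFile,
    EnvironmentParameter,
    Event,
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
from miappe.validate import validate

COLLECTIONS = ("trials", "studies", "contacts", "germplasm",
               "observationunits", "samples", "variables", "datalinks")


class BrapiError(ValueError):
    pass


class DanglingReferenceError(BrapiError):
    pass


@dataclass
class BrapiDocumentSet:
    documents: dict[str, list[dict]] = field(default_factory=lambda: {
        name: [] for name in COLLECTIONS})

    def collection(self, name: str) -> list[dict]:
        return self.documents.setdefault(name, [])


# Scalar field mapping tables: (model attribute, BrAPI key).
TRIAL_FIELDS = [
    ("id", "trialDbId"),
    ("title", "trialName"),
]
STUDY_FIELDS = [
    ("id", "studyDbId"),
    ("title", "studyName"),
    ("description", "studyDescription"),
    ("start_date", "startDate"),
    ("end_date", "endDate"),
]
CONTACT_FIELDS = [
    ("name", "name"),
    ("email", "email"),
    ("orcid", "orcid"),
    ("affiliation", "instituteName"),
    ("role", "type"),
]
GERMPLASM_FIELDS = [
    ("id", "germplasmDbId"),
    ("genus", "genus"),
    ("species", "species"),
    ("infraspecific_name", "subtaxa"),
]
OBSERVATIONUNIT_FIELDS = [
    ("id", "observationUnitDbId"),
    ("level", "observationLevel"),
    ("biological_material_id", "germplasmDbId"),
]
SAMPLE_FIELDS = [
    ("id", "sampleDbId"),
    ("observation_unit_id", "observationUnitDbId"),
    ("collection_date", "sampleTimestamp"),
    ("external_id", "externalSampleDbId"),
]
DATALINK_FIELDS = [
    ("link", "url"),
    ("description", "description"),
    ("version", "version"),
]


# Routing of every model field: "named" = an official BrAPI key holds it,
# "additionalInfo" = carried under a miappe:-prefixed additionalInfo key.
# The completeness test asserts this partition covers the model registry.
MODEL_FIELD_ROUTING: dict[str, dict[str, str]] = {
    "Investigation": {
        "id": "named", "title": "named", "description": "additionalInfo",
        "submission_date": "additionalInfo",
        "public_release_date": "additionalInfo",
        "license": "additionalInfo", "miappe_version": "additionalInfo",
        "publications": "additionalInfo",
    },
    "Study": {
        "id": "named", "title": "named", "description": "named",
        "start_date": "named", "end_date": "named",
        "contact_institution": "additionalInfo",
        "location.country": "named", "location.site_name": "named",
        "location.geo.latitude": "named", "location.geo.longitude": "named",
        "location.geo.altitude": "named",
        "location.geo.coordinates_uncertainty": "named",
        "experimental_design.description": "additionalInfo",
        "experimental_design.type.label": "additionalInfo",
        "experimental_design.type.accession": "additionalInfo",
        "experimental_design.map": "additionalInfo",
        "growth_facility.description": "additionalInfo",
        "growth_facility.type.label": "additionalInfo",
        "growth_facility.type.accession": "additionalInfo",
        "cultural_practices": "additionalInfo",
        "observation_unit_level_hierarchy": "additionalInfo",
    },
    "Person": {
        "name": "named", "email": "named", "orcid": "named",
        "affiliation": "named", "role": "named",
    },
    "Data file": {
        "link": "named", "description": "named", "version": "named",
    },
    "Biological material": {
        "id": "named", "organism.label": "named",
        "organism.accession": "named", "genus": "named", "species": "named",
        "infraspecific_name": "named", "geo.latitude": "named",
        "geo.longitude": "named", "geo.altitude": "named",
        "geo.coordinates_uncertainty": "named",
        "preprocessing": "additionalInfo",
        "material_source.id": "additionalInfo",
        "material_source.doi": "additionalInfo",
        "material_source.geo.latitude": "additionalInfo",
        "material_source.geo.longitude": "additionalInfo",
        "material_source.geo.altitude": "additionalInfo",
        "material_source.geo.coordinates_uncertainty": "additionalInfo",
        "material_source.description": "additionalInfo",
    },
    "Environment": {"parameter": "additionalInfo",
                    "value": "additionalInfo"},
    "Experimental factor": {
        "type": "named", "values": "named",
        "description": "additionalInfo", "accession": "additionalInfo",
    },
    "Event": {
        "type.label": "additionalInfo", "type.accession": "additionalInfo",
        "description": "additionalInfo", "date": "additionalInfo",
        "affected_units": "additionalInfo",
    },
    "Observation unit": {
        "id": "named", "level": "named",
        "biological_material_id": "named", "external_ref": "named",
        "spatial_distribution": "additionalInfo", "factor_values": "named",
    },
    "Sample": {
        "id": "named", "observation_unit_id": "named",
        "collection_date": "named", "external_id": "named",
        "description": "additionalInfo",
        "plant_anatomical_entity.label": "named",
        "plant_anatomical_entity.accession": "named",
        "plant_structure_development_stage.label": "named",
        "plant_structure_development_stage.accession": "named",
    },
    "Observed variable": {
        "id": "named", "name": "named", "trait.name": "named",
        "trait.accession": "named", "method.name": "named",
        "method.accession": "named", "method.description": "named",
        "method.reference": "named", "scale.name": "named",
        "scale.accession": "named", "time_scale": "additionalInfo",
    },
}


def _put(doc: dict, key: str, value) -> None:
    if value is not None:
        doc[key] = value


def _add_info(doc: dict, key: str, value) -> None:
    if value is None or value == [] or value == {}:
        return
    doc.setdefault("additionalInfo", {})[f"miappe:{key}"] = value


def _info(doc: dict, key: str):
    return (doc.get("additionalInfo") or {}).get(f"miappe:{key}")


def _geo_dict(geo: GeoPoint | None) -> dict | None:
    if geo is None:
        return None
    out = {}
    _put(out, "latitude", geo.latitude)
    _put(out, "longitude", geo.longitude)
    _put(out, "altitude", geo.altitude)
    _put(out, "coordinateUncertainty", geo.coordinates_uncertainty)
    return out or None


def _geo_from(d: dict | None) -> GeoPoint | None:
    if not d:
        return None
    geo = GeoPoint(latitude=d.get("latitude"), longitude=d.get("longitude"),
                   altitude=d.get("altitude"),
                   coordinates_uncertainty=d.get("coordinateUncertainty"))
    return None if geo.is_empty() else geo


def _ref_dict(ref: OntologyRef | None) -> dict | None:
    if ref is None:
        return None
    out = {}
    _put(out, "label", ref.label)
    _put(out, "accession", ref.accession)
    return out or None


def _ref_from(d: dict | None) -> OntologyRef | None:
    if not d:
        return None
    ref = OntologyRef(label=d.get("label"), accession=d.get("accession"))
    return None if ref.is_empty() else ref


def _contact_doc(person: Person, owner_key: str, owner_id: str,
                 index: int) -> dict:
    doc = {"contactDbId": f"{owner_id}#contact/{index}"}
    for attr, key in CONTACT_FIELDS:
        _put(doc, key, getattr(person, attr))
    doc[owner_key] = owner_id
    return doc


def to_brapi(dataset: Dataset) -> BrapiDocumentSet:
    """Map a validated dataset onto BrAPI v1.3-shaped documents."""
    report = validate(dataset)
    if report.error_count:
        raise BrapiError(
            f"dataset has {report.error_count} validation error(s); refusing "
            "to export")
    inv = dataset.investigation
    docs = BrapiDocumentSet()

    trial = {}
    for attr, key in TRIAL_FIELDS:
        _put(trial, key, getattr(inv, attr))
    trial["studies"] = [
        {"studyDbId": s.id, "studyName": s.title} for s in inv.studies
    ]
    _add_info(trial, "description", inv.description)
    _add_info(trial, "submission_date", inv.submission_date)
    _add_info(trial, "public_release_date", inv.public_release_date)
    _add_info(trial, "license", inv.license)
    _add_info(trial, "miappe_version", inv.miappe_version)
    _add_info(trial, "publications", inv.publications)
    docs.collection("trials").append(trial)

    for i, person in enumerate(inv.persons):
        docs.collection("contacts").append(
            _contact_doc(person, "trialDbId", inv.id, i))

    seen_germplasm: set[str] = set()
    seen_variables: set[str] = set()
    for study in inv.studies:
        docs.collection("studies").append(_study_doc(study, inv.id))
        for i, person in enumerate(study.persons):
            docs.collection("contacts").append(
                _contact_doc(person, "studyDbId", study.id, i))
        for i, df in enumerate(study.data_files):
            doc = {"dataLinkDbId": f"{study.id}#datalink/{i}",
                   "studyDbId": study.id}
            for attr, key in DATALINK_FIELDS:
                _put(doc, key, getattr(df, attr))
            docs.collection("datalinks").append(doc)
        for bm in study.biological_materials:
            if bm.id in seen_germplasm:
                continue
            seen_germplasm.add(bm.id)
            docs.collection("germplasm").append(_germplasm_doc(bm))
        for ou in study.observation_units:
            docs.collection("observationunits").append(
                _observationunit_doc(ou, study.id))
        for sample in study.samples:
            docs.collection("samples").append(_sample_doc(sample, study.id))
        for var in study.observed_variables:
            if var.id in seen_variables:
                continue
            seen_variables.add(var.id)
            docs.collection("variables").append(_variable_doc(var))
    return docs


def _study_doc(study: Study, trial_id: str) -> dict:
    doc = {}
    for attr, key in STUDY_FIELDS:
        _put(doc, key, getattr(study, attr))
    doc["trialDbId"] = trial_id
    loc = study.location
    if loc is not None:
        _put(doc, "locationName", loc.site_name)
        location = {}
        _put(location, "countryName", loc.country)
        _put(location, "name", loc.site_name)
        if loc.geo is not None:
            _put(location, "latitude", loc.geo.latitude)
            _put(location, "longitude", loc.geo.longitude)
            _put(location, "altitude", loc.geo.altitude)
            _put(location, "coordinateUncertainty",
                 loc.geo.coordinates_uncertainty)
        if location:
            doc["location"] = location
    _add_info(doc, "contact_institution", study.contact_institution)
    if study.experimental_design is not None:
        design = {}
        _put(design, "description", study.experimental_design.description)
        _put(design, "type", _ref_dict(study.experimental_design.type))
        _put(design, "map", study.experimental_design.map)
        _add_info(doc, "experimental_design", design)
    if study.growth_facility is not None:
        facility = {}
        _put(facility, "description", study.growth_facility.description)
        _put(facility, "type", _ref_dict(study.growth_facility.type))
        _add_info(doc, "growth_facility", facility)
    _add_info(doc, "cultural_practices", study.cultural_practices)
    _add_info(doc, "observation_unit_level_hierarchy",
              study.observation_unit_level_hierarchy)
    # sections absent from BrAPI 1.3 travel under additionalInfo
    _add_info(doc, "environment", [
        {"parameter": e.parameter, "value": e.value}
        for e in study.environments
    ])
    _add_info(doc, "event", [
        {"type": _ref_dict(e.type), "description": e.description,
         "date": e.date, "observationUnitDbIds": e.affected_units}
        for e in study.events
    ])
    treatments = []
    factor_meta = []
    for factor in study.factors:
        for value in factor.values:
            treatments.append({"factor": factor.type, "modality": value})
        meta = {"factor": factor.type}
        _put(meta, "description", factor.description)
        _put(meta, "accession", factor.accession)
        factor_meta.append(meta)
    if treatments:
        doc["treatments"] = treatments
    _add_info(doc, "factors", factor_meta)
    # germplasm and variables are global collections in BrAPI; the study's
    # membership lists keep the per-study attachment reversible
    _add_info(doc, "biological_material_ids",
              [bm.id for bm in study.biological_materials])
    _add_info(doc, "observation_variable_ids",
              [v.id for v in study.observed_variables])
    return doc


def _germplasm_doc(bm: BiologicalMaterial) -> dict:
    doc = {}
    for attr, key in GERMPLASM_FIELDS:
        _put(doc, key, getattr(bm, attr))
    if bm.organism is not None:
        _put(doc, "commonCropName", bm.organism.label)
        if bm.organism.accession is not None:
            doc["taxonIds"] = [{"sourceName": "organism",
                                "taxonId": bm.organism.accession}]
    _put(doc, "germplasmOrigin", _geo_dict(bm.geo))
    _add_info(doc, "preprocessing", bm.preprocessing)
    ms = bm.material_source
    if ms is not None:
        source = {}
        _put(source, "id", ms.id)
        _put(source, "doi", ms.doi)
        _put(source, "geo", _geo_dict(ms.geo))
        _put(source, "description", ms.description)
        _add_info(doc, "material_source", source)
    return doc


def _observationunit_doc(ou: ObservationUnit, study_id: str) -> dict:
    doc = {}
    for attr, key in OBSERVATIONUNIT_FIELDS:
        _put(doc, key, getattr(ou, attr))
    doc["studyDbId"] = study_id
    if ou.external_ref is not None:
        doc["observationUnitXref"] = [{"source": "external",
                                       "id": ou.external_ref}]
    if ou.factor_values:
        doc["treatments"] = [
            {"factor": k, "modality": v}
            for k, v in sorted(ou.factor_values.items())
        ]
    _add_info(doc, "spatial_distribution", [
        {"key": k, "value": v} for k, v in ou.spatial_distribution
    ])
    return doc


def _sample_doc(sample: Sample, study_id: str) -> dict:
    doc = {}
    for attr, key in SAMPLE_FIELDS:
        _put(doc, key, getattr(sample, attr))
    doc["studyDbId"] = study_id
    _put(doc, "plantAnatomicalEntity",
         _ref_dict(sample.plant_anatomical_entity))
    _put(doc, "plantStructureDevelopmentStage",
         _ref_dict(sample.plant_structure_development_stage))
    _add_info(doc, "description", sample.description)
    return doc


def _variable_doc(var: ObservedVariable) -> dict:
    doc = {"observationVariableDbId": var.id,
           "observationVariableName": var.name}
    trait = {}
    _put(trait, "traitName", var.trait.name)
    _put(trait, "traitDbId", var.trait.accession)
    doc["trait"] = trait
    method = {}
    _put(method, "methodName", var.method.name)
    _put(method, "methodDbId", var.method.accession)
    _put(method, "description", var.method.description)
    _put(method, "reference", var.method.reference)
    doc["method"] = method
    scale = {}
    _put(scale, "scaleName", var.scale.name)
    _put(scale, "scaleDbId", var.scale.accession)
    doc["scale"] = scale
    _add_info(doc, "time_scale", var.time_scale)
    return doc


# ---------------------------------------------------------------------------
# Inverse mapping

def from_brapi(docs: BrapiDocumentSet) -> Dataset:
    """Rebuild a dataset from a BrAPI document set.

    Raises :class:`DanglingReferenceError` when a document references a
    DbId absent from the set (e.g. a sample pointing at a missing
    observation unit).
    """
    trials = docs.collection("trials")
    if not trials:
        raise BrapiError("document set has no trial document")
    trial = trials[0]
    inv = Investigation(
        id=trial.get("trialDbId"),
        title=trial.get("trialName"),
        description=_info(trial, "description"),
        submission_date=_info(trial, "submission_date"),
        public_release_date=_info(trial, "public_release_date"),
        license=_info(trial, "license"),
        miappe_version=_info(trial, "miappe_version"),
        publications=_info(trial, "publications") or [],
    )

    def person_from(doc: dict) -> Person:
        kwargs = {attr: doc.get(key) for attr, key in CONTACT_FIELDS}
        return Person(**kwargs)

    contacts = docs.collection("contacts")
    inv.persons = [person_from(c) for c in contacts
                   if c.get("trialDbId") == inv.id]

    germplasm_by_id = {g.get("germplasmDbId"): g
                       for g in docs.collection("germplasm")}
    variables_by_id = {v.get("observationVariableDbId"): v
                       for v in docs.collection("variables")}
    known_units = {ou.get("observationUnitDbId")
                   for ou in docs.collection("observationunits")}

    studies_by_id: dict[str, Study] = {}
    for sdoc in docs.collection("studies"):
        study = _study_from(sdoc)
        study.persons = [person_from(c) for c in contacts
                         if c.get("studyDbId") == study.id]
        studies_by_id[study.id] = study
        inv.studies.append(study)

    for sdoc in docs.collection("studies"):
        study = studies_by_id[sdoc.get("studyDbId")]
        for gid in _info(sdoc, "biological_material_ids") or []:
            gdoc = germplasm_by_id.get(gid)
            if gdoc is None:
                raise DanglingReferenceError(
                    f"study {study.id!r} references unknown germplasm "
                    f"{gid!r}")
            study.biological_materials.append(_germplasm_from(gdoc))

    for doc in docs.collection("datalinks"):
        study = _owning(studies_by_id, doc, "data link")
        kwargs = {attr: doc.get(key) for attr, key in DATALINK_FIELDS}
        study.data_files.append(DataFile(**kwargs))

    for doc in docs.collection("observationunits"):
        study = _owning(studies_by_id, doc, "observation unit")
        gid = doc.get("germplasmDbId")
        if gid is not None:
            if gid not in germplasm_by_id:
                raise DanglingReferenceError(
                    f"observation unit {doc.get('observationUnitDbId')!r} "
                    f"references unknown germplasm {gid!r}")
            bm = _germplasm_from(germplasm_by_id[gid])
            if all(existing.id != gid
                   for existing in study.biological_materials):
                study.biological_materials.append(bm)
        xref = doc.get("observationUnitXref") or []
        study.observation_units.append(ObservationUnit(
            id=doc.get("observationUnitDbId"),
            level=doc.get("observationLevel"),
            biological_material_id=gid,
            external_ref=xref[0]["id"] if xref else None,
            spatial_distribution=[
                (p["key"], p["value"])
                for p in _info(doc, "spatial_distribution") or []
            ],
            factor_values={
                t["factor"]: t["modality"]
                for t in doc.get("treatments", [])
            },
        ))

    for doc in docs.collection("samples"):
        study = _owning(studies_by_id, doc, "sample")
        ou_id = doc.get("observationUnitDbId")
        if ou_id is not None and ou_id not in known_units:
            raise DanglingReferenceError(
                f"sample {doc.get('sampleDbId')!r} references unknown "
                f"observation unit {ou_id!r}")
        kwargs = {attr: doc.get(key) for attr, key in SAMPLE_FIELDS}
        study.samples.append(Sample(
            **kwargs,
            description=_info(doc, "description"),
            plant_anatomical_entity=_ref_from(
                doc.get("plantAnatomicalEntity")),
            plant_structure_development_stage=_ref_from(
                doc.get("plantStructureDevelopmentStage")),
        ))

    # variables are attached to every study that declares them; BrAPI keeps
    # them global, so studies record their variable ids under additionalInfo
    for sdoc in docs.collection("studies"):
        study = studies_by_id[sdoc.get("studyDbId")]
        for vid in _info(sdoc, "observation_variable_ids") or []:
            vdoc = variables_by_id.get(vid)
            if vdoc is None:
                raise DanglingReferenceError(
                    f"study {study.id!r} references unknown variable "
                    f"{vid!r}")
            study.observed_variables.append(_variable_from(vdoc))

    return build_dataset(inv, provenance={"format": "brapi"})


def _owning(studies_by_id: dict[str, Study], doc: dict, what: str) -> Study:
    sid = doc.get("studyDbId")
    study = studies_by_id.get(sid)
    if study is None:
        raise DanglingReferenceError(
            f"{what} references unknown study {sid!r}")
    return study


def _study_from(doc: dict) -> Study:
    kwargs = {attr: doc.get(key) for attr, key in STUDY_FIELDS}
    location_doc = doc.get("location") or {}
    geo = GeoPoint(latitude=location_doc.get("latitude"),
                   longitude=location_doc.get("longitude"),
                   altitude=location_doc.get("altitude"),
                   coordinates_uncertainty=location_doc.get(
                       "coordinateUncertainty"))
    design_doc = _info(doc, "experimental_design") or {}
    facility_doc = _info(doc, "growth_facility") or {}
    factor_meta = {m["factor"]: m for m in _info(doc, "factors") or []}
    factor_values: dict[str, list[str]] = {}
    for t in doc.get("treatments", []):
        factor_values.setdefault(t["factor"], []).append(t["modality"])
    factors = [
        ExperimentalFactor(
            type=ftype, values=values,
            description=factor_meta.get(ftype, {}).get("description"),
            accession=factor_meta.get(ftype, {}).get("accession"),
        )
        for ftype, values in factor_values.items()
    ]
    return Study(
        **kwargs,
        contact_institution=_info(doc, "contact_institution"),
        location=StudyLocation(
            country=location_doc.get("countryName"),
            site_name=location_doc.get("name") or doc.get("locationName"),
            geo=None if geo.is_empty() else geo,
        ),
        experimental_design=ExperimentalDesign(
            description=design_doc.get("description"),
            type=_ref_from(design_doc.get("type")),
            map=design_doc.get("map"),
        ),
        growth_facility=GrowthFacility(
            description=facility_doc.get("description"),
            type=_ref_from(facility_doc.get("type")),
        ),
        cultural_practices=_info(doc, "cultural_practices"),
        observation_unit_level_hierarchy=_info(
            doc, "observation_unit_level_hierarchy") or [],
        environments=[
            EnvironmentParameter(parameter=e.get("parameter"),
                                 value=e.get("value"))
            for e in _info(doc, "environment") or []
        ],
        factors=factors,
        events=[
            Event(type=_ref_from(e.get("type")),
                  description=e.get("description"), date=e.get("date"),
                  affected_units=e.get("observationUnitDbIds") or [])
            for e in _info(doc, "event") or []
        ],
    )


def _germplasm_from(doc: dict) -> BiologicalMaterial:
    kwargs = {attr: doc.get(key) for attr, key in GERMPLASM_FIELDS}
    taxon_ids = doc.get("taxonIds") or []
    organism = OntologyRef(
        label=doc.get("commonCropName"),
        accession=taxon_ids[0]["taxonId"] if taxon_ids else None,
    )
    source_doc = _info(doc, "material_source")
    source = None
    if source_doc:
        source = MaterialSource(
            id=source_doc.get("id"), doi=source_doc.get("doi"),
            geo=_geo_from(source_doc.get("geo")),
            description=source_doc.get("description"),
        )
    return BiologicalMaterial(
        **kwargs,
        organism=None if organism.is_empty() else organism,
        geo=_geo_from(doc.get("germplasmOrigin")),
        preprocessing=_info(doc, "preprocessing"),
        material_source=source,
    )


def _variable_from(doc: dict) -> ObservedVariable:
    trait = doc.get("trait") or {}
    method = doc.get("method") or {}
    scale = doc.get("scale") or {}
    return ObservedVariable(
        id=doc.get("observationVariableDbId"),
        name=doc.get("observationVariableName"),
        trait=TraitRef(name=trait.get("traitName"),
                       accession=trait.get("traitDbId")),
        method=MethodRef(name=method.get("methodName"),
                         accession=method.get("methodDbId"),
                         description=method.get("description"),
                         reference=method.get("reference")),
        scale=ScaleRef(name=scale.get("scaleName"),
                       accession=scale.get("scaleDbId")),
        time_scale=_info(doc, "time_scale"),
    )


# ---------------------------------------------------------------------------
# Disk I/O: one JSON array per collection, stable key order.

def write_brapi(docs: BrapiDocumentSet, root_dir: str | Path) -> list[Path]:
    root = Path(root_dir)
    root.mkdir(parents=True, exist_ok=True)
    written = []
    for name in COLLECTIONS:
        path = root / f"{name}.json"
        path.write_text(
            json.dumps(docs.collection(name), indent=2, ensure_ascii=False,
                       sort_keys=True) + "\n",
            encoding="utf-8")
        written.append(path)
    return written


def read_brapi(root_dir: str | Path) -> BrapiDocumentSet:
    root = Path(root_dir)
    docs = BrapiDocumentSet()
    found = False
    for name in COLLECTIONS:
        path = root / f"{name}.json"
        if path.is_file():
            found = True
            docs.documents[name] = json.loads(
                path.read_text(encoding="utf-8"))
    if not found:
        raise BrapiError(f"no BrAPI collection files under {root}")
    return docs
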