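"""RDF serialization following the PPEO scheme.

Each checklist section is a class, each field a data property, each link an
object property; the trait / method / scale components of an observed
variable are instances of their own classes grouped under the variable.
Predicate and class IRIs use camel-cased labels ("has biological material"
-> ``hasBiologicalMaterial``) under a single toolkit namespace; a prefix
remap is possible later because nothing outside this module hard-codes the
IRIs.

Instance IRIs are minted deterministically as
``<base_iri><section-slug>/<percent-encoded id>``; records without a native
identifier (persons, environment parameters, factors, events, data files)
get zero-padded positional ids under their owner, which keeps serialization
stable and reversible.

Cardinality restrictions of the data model (an investigation has at least
one study; a sample derives from exactly one observation unit; a study has
exactly one location node) are re-checked closed-world on the instance
graph by :func:`check_rdf_constraints` — open-world OWL reasoning cannot
flag a *missing* study, a direct graph check can.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from urllib.parse import quote, unquote

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF, XSD

from miappe.iso8601 import parse_iso8601
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

VOCAB_IRI = "https://w3id.org/miappe-toolkit/ppeo#"
PPEO = Namespace(VOCAB_IRI)

JSONLD_CONTEXT = {
    "ppeo": VOCAB_IRI,
    "xsd": str(XSD),
}


class RdfError(ValueError):
    pass


@dataclass
class TripleSet:
    """An RDF instantiation of a dataset: plain triples plus the base IRI
    under which instance IRIs were minted."""

    triples: frozenset[tuple]
    base_iri: str

    def graph(self) -> Graph:
        g = Graph()
        g.bind("ppeo", PPEO)
        g.bind("xsd", XSD)
        for t in sorted(self.triples):
            g.add(t)
        return g


def _iri(base: str, slug: str, identifier: str) -> URIRef:
    return URIRef(base + slug + "/" + quote(identifier, safe=""))


def _date_literal(value: str) -> Literal:
    parsed = parse_iso8601(value)
    if parsed is None:
        return Literal(value)
    if "T" in value or " " in value:
        return Literal(value, datatype=XSD.dateTime)
    if len(value) == 10:
        return Literal(value, datatype=XSD.date)
    return Literal(value)  # reduced precision kept verbatim


def _decimal(value: float) -> Literal:
    return Literal(str(value), datatype=XSD.decimal)


class _Emitter:
    def __init__(self, base_iri: str):
        self.base = base_iri
        self.triples: set[tuple] = set()

    def type(self, subject: URIRef, cls: URIRef) -> None:
        self.triples.add((subject, RDF.type, cls))

    def lit(self, subject: URIRef, predicate: URIRef, value,
            literal_factory=Literal) -> None:
        if value is not None:
            self.triples.add((subject, predicate, literal_factory(value)))

    def obj(self, subject: URIRef, predicate: URIRef,
            target: URIRef) -> None:
        self.triples.add((subject, predicate, target))

    def geo(self, subject: URIRef, geo: GeoPoint | None) -> None:
        if geo is None:
            return
        self.lit(subject, PPEO.latitude, geo.latitude, _decimal)
        self.lit(subject, PPEO.longitude, geo.longitude, _decimal)
        self.lit(subject, PPEO.altitude, geo.altitude, _decimal)
        self.lit(subject, PPEO.coordinatesUncertainty,
                 geo.coordinates_uncertainty, _decimal)

    def person(self, owner_iri_id: str, person: Person, i: int) -> URIRef:
        node = _iri(self.base, "person", f"{owner_iri_id}/{i:04d}")
        self.type(node, PPEO.Person)
        self.lit(node, PPEO.name, person.name)
        self.lit(node, PPEO.email, person.email)
        self.lit(node, PPEO.personId, person.orcid)
        self.lit(node, PPEO.affiliation, person.affiliation)
        self.lit(node, PPEO.role, person.role)
        return node


def to_rdf(dataset: Dataset, base_iri: str) -> TripleSet:
    """Express a dataset as PPEO-style triples under *base_iri*."""
    if "://" not in base_iri:
        raise RdfError(f"base IRI must be absolute, got {base_iri!r}")
    if not base_iri.endswith(("/", "#")):
        base_iri += "/"
    e = _Emitter(base_iri)
    inv = dataset.investigation
    inv_id = inv.id or "investigation"
    inv_node = _iri(base_iri, "investigation", inv_id)
    e.type(inv_node, PPEO.Investigation)
    e.lit(inv_node, PPEO.identifier, inv.id)
    e.lit(inv_node, PPEO.title, inv.title)
    e.lit(inv_node, PPEO.description, inv.description)
    e.lit(inv_node, PPEO.submissionDate, inv.submission_date, _date_literal)
    e.lit(inv_node, PPEO.publicReleaseDate, inv.public_release_date,
          _date_literal)
    e.lit(inv_node, PPEO.license, inv.license)
    e.lit(inv_node, PPEO.miappeVersion, inv.miappe_version)
    for pub in inv.publications:
        e.lit(inv_node, PPEO.publication, pub)
    for i, person in enumerate(inv.persons):
        e.obj(inv_node, PPEO.hasPerson, e.person(inv_id, person, i))
    for study in inv.studies:
        e.obj(inv_node, PPEO.hasStudy, _study_triples(e, study))
    return TripleSet(triples=frozenset(e.triples), base_iri=base_iri)


def _study_triples(e: _Emitter, study: Study) -> URIRef:
    sid = study.id or "study"
    node = _iri(e.base, "study", sid)
    e.type(node, PPEO.Study)
    e.lit(node, PPEO.identifier, study.id)
    e.lit(node, PPEO.title, study.title)
    e.lit(node, PPEO.description, study.description)
    e.lit(node, PPEO.startDate, study.start_date, _date_literal)
    e.lit(node, PPEO.endDate, study.end_date, _date_literal)
    e.lit(node, PPEO.contactInstitution, study.contact_institution)
    e.lit(node, PPEO.culturalPractices, study.cultural_practices)
    if study.observation_unit_level_hierarchy:
        e.lit(node, PPEO.observationUnitLevelHierarchy,
              " > ".join(study.observation_unit_level_hierarchy))
    if study.location is not None:
        loc = _iri(e.base, "location", sid)
        e.type(loc, PPEO.Location)
        e.obj(node, PPEO.hasLocation, loc)
        e.lit(loc, PPEO.country, study.location.country)
        e.lit(loc, PPEO.siteName, study.location.site_name)
        e.geo(loc, study.location.geo)
    if study.experimental_design is not None:
        d = study.experimental_design
        e.lit(node, PPEO.experimentalDesignDescription, d.description)
        if d.type is not None:
            e.lit(node, PPEO.experimentalDesignType, d.type.label)
            e.lit(node, PPEO.experimentalDesignTypeAccession,
                  d.type.accession)
        e.lit(node, PPEO.experimentalDesignMap, d.map)
    if study.growth_facility is not None:
        f = study.growth_facility
        e.lit(node, PPEO.growthFacilityDescription, f.description)
        if f.type is not None:
            e.lit(node, PPEO.growthFacilityType, f.type.label)
            e.lit(node, PPEO.growthFacilityTypeAccession, f.type.accession)
    for i, person in enumerate(study.persons):
        e.obj(node, PPEO.hasPerson, e.person(sid, person, i))
    for i, df in enumerate(study.data_files):
        dfn = _iri(e.base, "data_file", f"{sid}/{i:04d}")
        e.type(dfn, PPEO.DataFile)
        e.obj(node, PPEO.hasDataFile, dfn)
        e.lit(dfn, PPEO.link, df.link)
        e.lit(dfn, PPEO.description, df.description)
        e.lit(dfn, PPEO.version, df.version)
    for i, env in enumerate(study.environments):
        envn = _iri(e.base, "environment", f"{sid}/{i:04d}")
        e.type(envn, PPEO.EnvironmentParameter)
        e.obj(node, PPEO.hasEnvironmentParameter, envn)
        e.lit(envn, PPEO.parameter, env.parameter)
        e.lit(envn, PPEO.value, env.value)
    for i, factor in enumerate(study.factors):
        fn = _iri(e.base, "experimental_factor", f"{sid}/{i:04d}")
        e.type(fn, PPEO.ExperimentalFactor)
        e.obj(node, PPEO.hasExperimentalFactor, fn)
        e.lit(fn, PPEO.factorType, factor.type)
        e.lit(fn, PPEO.factorTypeAccession, factor.accession)
        e.lit(fn, PPEO.description, factor.description)
        for value in factor.values:
            e.lit(fn, PPEO.factorValue, value)
    for i, event in enumerate(study.events):
        evn = _iri(e.base, "event", f"{sid}/{i:04d}")
        e.type(evn, PPEO.Event)
        e.obj(node, PPEO.hasEvent, evn)
        if event.type is not None:
            e.lit(evn, PPEO.eventType, event.type.label)
            e.lit(evn, PPEO.eventTypeAccession, event.type.accession)
        e.lit(evn, PPEO.description, event.description)
        e.lit(evn, PPEO.date, event.date, _date_literal)
        for target in event.affected_units:
            e.obj(evn, PPEO.affectsObservationUnit,
                  _iri(e.base, "observation_unit", target))
    for bm in study.biological_materials:
        e.obj(node, PPEO.hasBiologicalMaterial, _material_triples(e, bm))
    for ou in study.observation_units:
        e.obj(node, PPEO.hasObservationUnit, _unit_triples(e, ou))
    for sample in study.samples:
        e.obj(node, PPEO.hasSample, _sample_triples(e, sample))
    for var in study.observed_variables:
        e.obj(node, PPEO.hasObservedVariable, _variable_triples(e, var))
    return node


def _material_triples(e: _Emitter, bm: BiologicalMaterial) -> URIRef:
    bid = bm.id or "material"
    node = _iri(e.base, "biological_material", bid)
    e.type(node, PPEO.BiologicalMaterial)
    e.lit(node, PPEO.identifier, bm.id)
    if bm.organism is not None:
        e.lit(node, PPEO.organism, bm.organism.label)
        e.lit(node, PPEO.organismAccession, bm.organism.accession)
    e.lit(node, PPEO.genus, bm.genus)
    e.lit(node, PPEO.species, bm.species)
    e.lit(node, PPEO.infraspecificName, bm.infraspecific_name)
    e.geo(node, bm.geo)
    e.lit(node, PPEO.preprocessing, bm.preprocessing)
    if bm.material_source is not None:
        ms = bm.material_source
        msn = _iri(e.base, "material_source", ms.id or f"{bid}/source")
        e.type(msn, PPEO.MaterialSource)
        e.obj(node, PPEO.hasMaterialSource, msn)
        e.lit(msn, PPEO.identifier, ms.id)
        e.lit(msn, PPEO.doi, ms.doi)
        e.geo(msn, ms.geo)
        e.lit(msn, PPEO.description, ms.description)
    return node


def _unit_triples(e: _Emitter, ou: ObservationUnit) -> URIRef:
    node = _iri(e.base, "observation_unit", ou.id or "unit")
    e.type(node, PPEO.ObservationUnit)
    e.lit(node, PPEO.identifier, ou.id)
    e.lit(node, PPEO.observationLevel, ou.level)
    e.lit(node, PPEO.externalReference, ou.external_ref)
    if ou.biological_material_id is not None:
        e.obj(node, PPEO.hasBiologicalMaterial,
              _iri(e.base, "biological_material", ou.biological_material_id))
    for key, value in ou.spatial_distribution:
        e.lit(node, PPEO.spatialDistribution, f"{key}: {value}")
    for ftype, fvalue in sorted(ou.factor_values.items()):
        e.lit(node, PPEO.factorValue, f"{ftype}: {fvalue}")
    return node


def _sample_triples(e: _Emitter, sample: Sample) -> URIRef:
    node = _iri(e.base, "sample", sample.id or "sample")
    e.type(node, PPEO.Sample)
    e.lit(node, PPEO.identifier, sample.id)
    e.lit(node, PPEO.description, sample.description)
    if sample.plant_anatomical_entity is not None:
        e.lit(node, PPEO.plantAnatomicalEntity,
              sample.plant_anatomical_entity.label)
        e.lit(node, PPEO.plantAnatomicalEntityAccession,
              sample.plant_anatomical_entity.accession)
    if sample.plant_structure_development_stage is not None:
        e.lit(node, PPEO.plantStructureDevelopmentStage,
              sample.plant_structure_development_stage.label)
        e.lit(node, PPEO.plantStructureDevelopmentStageAccession,
              sample.plant_structure_development_stage.accession)
    e.lit(node, PPEO.collectionDate, sample.collection_date, _date_literal)
    e.lit(node, PPEO.externalId, sample.external_id)
    if sample.observation_unit_id is not None:
        e.obj(node, PPEO.hasObservationUnit,
              _iri(e.base, "observation_unit", sample.observation_unit_id))
    return node


def _variable_triples(e: _Emitter, var: ObservedVariable) -> URIRef:
    vid = var.id or "variable"
    node = _iri(e.base, "observed_variable", vid)
    e.type(node, PPEO.ObservedVariable)
    e.lit(node, PPEO.identifier, var.id)
    e.lit(node, PPEO.variableName, var.name)
    e.lit(node, PPEO.timeScale, var.time_scale)
    trait = _iri(e.base, "trait", vid)
    e.type(trait, PPEO.Trait)
    e.obj(node, PPEO.hasTrait, trait)
    e.lit(trait, PPEO.name, var.trait.name)
    e.lit(trait, PPEO.termAccession, var.trait.accession)
    method = _iri(e.base, "method", vid)
    e.type(method, PPEO.Method)
    e.obj(node, PPEO.hasMethod, method)
    e.lit(method, PPEO.name, var.method.name)
    e.lit(method, PPEO.termAccession, var.method.accession)
    e.lit(method, PPEO.description, var.method.description)
    e.lit(method, PPEO.reference, var.method.reference)
    scale = _iri(e.base, "scale", vid)
    e.type(scale, PPEO.Scale)
    e.obj(node, PPEO.hasScale, scale)
    e.lit(scale, PPEO.name, var.scale.name)
    e.lit(scale, PPEO.termAccession, var.scale.accession)
    return node


# ---------------------------------------------------------------------------
# Constraint checking

@dataclass(frozen=True)
class ConstraintViolation:
    instance: str
    restriction: str
    message: str


def check_rdf_constraints(triples: TripleSet) -> list[ConstraintViolation]:
    """Closed-world re-check of the model's cardinality restrictions.

    Verifies on the instance graph that every investigation has at least
    one study, every sample exactly one observation unit, and every study
    exactly one location node; returns one violation per (instance,
    restriction).
    """
    by_type: dict[URIRef, set] = {}
    counts: dict[tuple, int] = {}
    for s, p, o in triples.triples:
        if p == RDF.type:
            by_type.setdefault(o, set()).add(s)
        counts[(s, p)] = counts.get((s, p), 0) + 1

    out = []
    for inv in sorted(by_type.get(PPEO.Investigation, ())):
        n = counts.get((inv, PPEO.hasStudy), 0)
        if n < 1:
            out.append(ConstraintViolation(
                str(inv), "investigation-min-1-study",
                "investigation must have at least one study"))
    for study in sorted(by_type.get(PPEO.Study, ())):
        n = counts.get((study, PPEO.hasLocation), 0)
        if n != 1:
            out.append(ConstraintViolation(
                str(study), "study-exactly-1-location",
                f"study has {n} location nodes, exactly 1 required"))
    for sample in sorted(by_type.get(PPEO.Sample, ())):
        n = counts.get((sample, PPEO.hasObservationUnit), 0)
        if n != 1:
            out.append(ConstraintViolation(
                str(sample), "sample-exactly-1-observation-unit",
                f"sample derives from {n} observation units, exactly 1 "
                "required"))
    return out


# ---------------------------------------------------------------------------
# Serialization

def write_rdf(triples: TripleSet, fmt: str, path: str | Path) -> Path:
    """Serialize deterministically as Turtle or JSON-LD.

    Subjects are inserted in sorted order, so the same triple set always
    produces byte-identical Turtle.
    """
    path = Path(path)
    g = triples.graph()
    if fmt == "turtle":
        data = g.serialize(format="turtle")
    elif fmt == "json-ld":
        data = g.serialize(format="json-ld", context=dict(JSONLD_CONTEXT),
                           sort_keys=True)
    else:
        raise RdfError(f"unknown RDF format {fmt!r}; use turtle or json-ld")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(data, encoding="utf-8")
    return path


def read_rdf(path: str | Path, fmt: str | None = None) -> TripleSet:
    """Parse a Turtle / JSON-LD file back into a :class:`TripleSet`."""
    path = Path(path)
    if fmt is None:
        fmt = {"ttl": "turtle", "turtle": "turtle", "jsonld": "json-ld",
               "json-ld": "json-ld"}.get(path.suffix.lstrip(".").lower())
    g = Graph()
    g.parse(path, format=fmt)
    triples = frozenset(g)
    base = None
    for s, p, o in triples:
        if p == RDF.type and o == PPEO.Investigation:
            text = str(s)
            cut = text.find("investigation/")
            if cut > 0:
                base = text[:cut]
            break
    if base is None:
        raise RdfError("no typed investigation instance found in graph")
    return TripleSet(triples=triples, base_iri=base)


# ---------------------------------------------------------------------------
# Inverse mapping (graph -> Dataset)

def _index(triples: frozenset) -> tuple[dict, dict]:
    by_type: dict[URIRef, list] = {}
    props: dict[URIRef, dict[URIRef, list]] = {}
    for s, p, o in triples:
        if p == RDF.type:
            by_type.setdefault(o, []).append(s)
        else:
            props.setdefault(s, {}).setdefault(p, []).append(o)
    for subjects in by_type.values():
        subjects.sort()
    return by_type, props


def _one(props: dict, node: URIRef, predicate: URIRef) -> str | None:
    values = props.get(node, {}).get(predicate)
    if not values:
        return None
    return str(values[0])


def _many(props: dict, node: URIRef, predicate: URIRef) -> list:
    return sorted(props.get(node, {}).get(predicate, []))


def _maybe_float(value: str | None) -> float | None:
    return float(value) if value is not None else None


def _geo_from(props: dict, node: URIRef) -> GeoPoint | None:
    geo = GeoPoint(
        latitude=_maybe_float(_one(props, node, PPEO.latitude)),
        longitude=_maybe_float(_one(props, node, PPEO.longitude)),
        altitude=_maybe_float(_one(props, node, PPEO.altitude)),
        coordinates_uncertainty=_maybe_float(
            _one(props, node, PPEO.coordinatesUncertainty)),
    )
    return None if geo.is_empty() else geo


def _person_from(props: dict, node: URIRef) -> Person:
    return Person(
        name=_one(props, node, PPEO.name),
        email=_one(props, node, PPEO.email),
        orcid=_one(props, node, PPEO.personId),
        affiliation=_one(props, node, PPEO.affiliation),
        role=_one(props, node, PPEO.role),
    )


def _tail_id(node: URIRef, slug: str) -> str:
    text = str(node)
    marker = slug + "/"
    cut = text.find(marker)
    return unquote(text[cut + len(marker):]) if cut >= 0 else text


def from_rdf(triples: TripleSet) -> Dataset:
    """Rebuild a :class:`Dataset` from PPEO-style triples.

    The inverse of :func:`to_rdf`; record order within lists follows the
    minted positional ids, so a write/read cycle preserves the graph up to
    ordering of unordered collections.
    """
    by_type, props = _index(triples.triples)
    inv_nodes = by_type.get(PPEO.Investigation, [])
    if not inv_nodes:
        raise RdfError("graph has no investigation instance")
    inv_node = inv_nodes[0]
    inv = Investigation(
        id=_one(props, inv_node, PPEO.identifier),
        title=_one(props, inv_node, PPEO.title),
        description=_one(props, inv_node, PPEO.description),
        submission_date=_one(props, inv_node, PPEO.submissionDate),
        public_release_date=_one(props, inv_node, PPEO.publicReleaseDate),
        license=_one(props, inv_node, PPEO.license),
        miappe_version=_one(props, inv_node, PPEO.miappeVersion),
        publications=[str(v) for v in
                      _many(props, inv_node, PPEO.publication)],
        persons=[_person_from(props, n)
                 for n in _many(props, inv_node, PPEO.hasPerson)],
    )
    for study_node in _many(props, inv_node, PPEO.hasStudy):
        inv.studies.append(_study_from(by_type, props, study_node))
    return build_dataset(inv, provenance={"format": "rdf",
                                          "base_iri": triples.base_iri})


def _study_from(by_type: dict, props: dict, node: URIRef) -> Study:
    location = None
    loc_nodes = _many(props, node, PPEO.hasLocation)
    if loc_nodes:
        loc = loc_nodes[0]
        location = StudyLocation(
            country=_one(props, loc, PPEO.country),
            site_name=_one(props, loc, PPEO.siteName),
            geo=_geo_from(props, loc),
        )
    hierarchy = _one(props, node, PPEO.observationUnitLevelHierarchy) or ""
    study = Study(
        id=_one(props, node, PPEO.identifier),
        title=_one(props, node, PPEO.title),
        description=_one(props, node, PPEO.description),
        start_date=_one(props, node, PPEO.startDate),
        end_date=_one(props, node, PPEO.endDate),
        contact_institution=_one(props, node, PPEO.contactInstitution),
        cultural_practices=_one(props, node, PPEO.culturalPractices),
        location=location,
        experimental_design=ExperimentalDesign(
            description=_one(props, node,
                             PPEO.experimentalDesignDescription),
            type=OntologyRef(
                label=_one(props, node, PPEO.experimentalDesignType),
                accession=_one(props, node,
                               PPEO.experimentalDesignTypeAccession)),
            map=_one(props, node, PPEO.experimentalDesignMap),
        ),
        growth_facility=GrowthFacility(
            description=_one(props, node, PPEO.growthFacilityDescription),
            type=OntologyRef(
                label=_one(props, node, PPEO.growthFacilityType),
                accession=_one(props, node,
                               PPEO.growthFacilityTypeAccession)),
        ),
        observation_unit_level_hierarchy=[
            part.strip() for part in hierarchy.split(">") if part.strip()],
        persons=[_person_from(props, n)
                 for n in _many(props, node, PPEO.hasPerson)],
    )
    for dfn in _many(props, node, PPEO.hasDataFile):
        study.data_files.append(DataFile(
            link=_one(props, dfn, PPEO.link),
            description=_one(props, dfn, PPEO.description),
            version=_one(props, dfn, PPEO.version)))
    for envn in _many(props, node, PPEO.hasEnvironmentParameter):
        study.environments.append(EnvironmentParameter(
            parameter=_one(props, envn, PPEO.parameter),
            value=_one(props, envn, PPEO.value)))
    for fn in _many(props, node, PPEO.hasExperimentalFactor):
        study.factors.append(ExperimentalFactor(
            type=_one(props, fn, PPEO.factorType),
            accession=_one(props, fn, PPEO.factorTypeAccession),
            description=_one(props, fn, PPEO.description),
            values=[str(v) for v in _many(props, fn, PPEO.factorValue)]))
    for evn in _many(props, node, PPEO.hasEvent):
        study.events.append(Event(
            type=OntologyRef(
                label=_one(props, evn, PPEO.eventType),
                accession=_one(props, evn, PPEO.eventTypeAccession)),
            description=_one(props, evn, PPEO.description),
            date=_one(props, evn, PPEO.date),
            affected_units=[
                _tail_id(t, "observation_unit")
                for t in _many(props, evn, PPEO.affectsObservationUnit)]))
    for bmn in _many(props, node, PPEO.hasBiologicalMaterial):
        study.biological_materials.append(_material_from(props, bmn))
    for oun in _many(props, node, PPEO.hasObservationUnit):
        study.observation_units.append(_unit_from(props, oun))
    for sn in _many(props, node, PPEO.hasSample):
        study.samples.append(_sample_from(props, sn))
    for vn in _many(props, node, PPEO.hasObservedVariable):
        study.observed_variables.append(_variable_from(props, vn))
    return study


def _material_from(props: dict, node: URIRef) -> BiologicalMaterial:
    source = None
    ms_nodes = _many(props, node, PPEO.hasMaterialSource)
    if ms_nodes:
        msn = ms_nodes[0]
        source = MaterialSource(
            id=_one(props, msn, PPEO.identifier),
            doi=_one(props, msn, PPEO.doi),
            geo=_geo_from(props, msn),
            description=_one(props, msn, PPEO.description))
    return BiologicalMaterial(
        id=_one(props, node, PPEO.identifier),
        organism=OntologyRef(
            label=_one(props, node, PPEO.organism),
            accession=_one(props, node, PPEO.organismAccession)),
        genus=_one(props, node, PPEO.genus),
        species=_one(props, node, PPEO.species),
        infraspecific_name=_one(props, node, PPEO.infraspecificName),
        geo=_geo_from(props, node),
        preprocessing=_one(props, node, PPEO.preprocessing),
        material_source=source,
    )


def _split_pair(text: str) -> tuple[str, str]:
    key, _, value = text.partition(":")
    return key.strip(), value.strip()


def _unit_from(props: dict, node: URIRef) -> ObservationUnit:
    bm_nodes = _many(props, node, PPEO.hasBiologicalMaterial)
    return ObservationUnit(
        id=_one(props, node, PPEO.identifier),
        level=_one(props, node, PPEO.observationLevel),
        biological_material_id=(
            _tail_id(bm_nodes[0], "biological_material")
            if bm_nodes else None),
        external_ref=_one(props, node, PPEO.externalReference),
        spatial_distribution=[
            _split_pair(str(v))
            for v in _many(props, node, PPEO.spatialDistribution)],
        factor_values=dict(
            _split_pair(str(v))
            for v in _many(props, node, PPEO.factorValue)),
    )


def _sample_from(props: dict, node: URIRef) -> Sample:
    ou_nodes = _many(props, node, PPEO.hasObservationUnit)
    anat = OntologyRef(
        label=_one(props, node, PPEO.plantAnatomicalEntity),
        accession=_one(props, node, PPEO.plantAnatomicalEntityAccession))
    stage = OntologyRef(
        label=_one(props, node, PPEO.plantStructureDevelopmentStage),
        accession=_one(props, node,
                       PPEO.plantStructureDevelopmentStageAccession))
    return Sample(
        id=_one(props, node, PPEO.identifier),
        observation_unit_id=(
            _tail_id(ou_nodes[0], "observation_unit") if ou_nodes else None),
        description=_one(props, node, PPEO.description),
        plant_anatomical_entity=anat,
        plant_structure_development_stage=stage,
        collection_date=_one(props, node, PPEO.collectionDate),
        external_id=_one(props, node, PPEO.externalId),
    )


def _variable_from(props: dict, node: URIRef) -> ObservedVariable:
    def component(predicate: URIRef):
        nodes = _many(props, node, predicate)
        return nodes[0] if nodes else None

    tn, mn, sn = (component(PPEO.hasTrait), component(PPEO.hasMethod),
                  component(PPEO.hasScale))
    return ObservedVariable(
        id=_one(props, node, PPEO.identifier),
        name=_one(props, node, PPEO.variableName),
        trait=TraitRef(
            name=_one(props, tn, PPEO.name) if tn else None,
            accession=_one(props, tn, PPEO.termAccession) if tn else None),
        method=MethodRef(
            name=_one(props, mn, PPEO.name) if mn else None,
            accession=_one(props, mn, PPEO.termAccession) if mn else None,
            description=_one(props, mn, PPEO.description) if mn else None,
            reference=_one(props, mn, PPEO.reference) if mn else None),
        scale=ScaleRef(
            name=_one(props, sn, PPEO.name) if sn else None,
            accession=_one(props, sn, PPEO.termAccession) if sn else None),
        time_scale=_one(props, node, PPEO.timeScale),
    )
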