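"""The MIAPPE 1.1 object graph.

One type per checklist section plus the shared value types (ontology
references, geolocations, the trait/method/scale trio). Construction is
deliberately permissive: records hold whatever was read, empty strings are
normalized to ``None`` (absent), and checklist conformance is judged by
:mod:`miappe.validate`, never at construction time. The only construction
error is a duplicate identifier within a section type, because the
by-identifier index that every serialization relies on would be ambiguous.

Identifier uniqueness is dataset-global per section type. Records that are
genuinely shared between studies (a field network shares its biological
material and observed-variable lists across locations) may appear in several
per-study lists as long as every occurrence is identical; differing records
under one identifier are a construction error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Iterator


class DuplicateIdError(ValueError):
    """Two distinct records of one section type share an identifier."""


class ContractViolationError(ValueError):
    """An operation precondition was broken (e.g. undeclared level)."""


def _clean(value: Any) -> Any:
    """Normalize empty / whitespace-only strings to None (absent)."""
    if isinstance(value, str):
        value = value.strip()
        return value if value else None
    return value


@dataclass
class OntologyRef:
    """A human label with an optional term reference (CURIE or IRI)."""

    label: str | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        self.label = _clean(self.label)
        self.accession = _clean(self.accession)

    def is_empty(self) -> bool:
        return self.label is None and self.accession is None


@dataclass
class GeoPoint:
    """WGS84 decimal-degree coordinates; signs encode hemisphere.

    The four fields mirror the checklist's geolocation block (latitude,
    longitude, altitude in metres, coordinates uncertainty in metres), used
    identically on studies, biological materials and material sources.
    """

    latitude: float | None = None
    longitude: float | None = None
    altitude: float | None = None
    coordinates_uncertainty: float | None = None

    def is_empty(self) -> bool:
        return all(
            v is None
            for v in (
                self.latitude,
                self.longitude,
                self.altitude,
                self.coordinates_uncertainty,
            )
        )


@dataclass
class Person:
    name: str | None = None
    role: str | None = None
    email: str | None = None
    orcid: str | None = None
    affiliation: str | None = None

    def __post_init__(self) -> None:
        for f in ("name", "role", "email", "orcid", "affiliation"):
            setattr(self, f, _clean(getattr(self, f)))


@dataclass
class DataFile:
    """A reference to an observation data file; never parsed, only linked."""

    link: str | None = None
    description: str | None = None
    version: str | None = None

    def __post_init__(self) -> None:
        self.link = _clean(self.link)
        self.description = _clean(self.description)
        self.version = _clean(self.version)


@dataclass
class MaterialSource:
    """Provenance of a biological material before the experiment."""

    id: str | None = None
    doi: str | None = None
    geo: GeoPoint | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        self.id = _clean(self.id)
        self.doi = _clean(self.doi)
        self.description = _clean(self.description)
        if self.geo is not None and self.geo.is_empty():
            self.geo = None

    def is_empty(self) -> bool:
        return (
            self.id is None
            and self.doi is None
            and self.geo is None
            and self.description is None
        )


@dataclass
class BiologicalMaterial:
    """Plant material used in a study.

    Identification is two-level: within the experiment (``id`` + taxon) and
    before it (``material_source``). Forest trees may instead be identified
    purely by coordinates (``geo``) with no material source at all.
    """

    id: str | None = None
    organism: OntologyRef | None = None
    genus: str | None = None
    species: str | None = None
    infraspecific_name: str | None = None
    geo: GeoPoint | None = None
    preprocessing: str | None = None
    material_source: MaterialSource | None = None

    def __post_init__(self) -> None:
        for f in ("id", "genus", "species", "infraspecific_name", "preprocessing"):
            setattr(self, f, _clean(getattr(self, f)))
        if self.organism is not None and self.organism.is_empty():
            self.organism = None
        if self.geo is not None and self.geo.is_empty():
            self.geo = None
        if self.material_source is not None and self.material_source.is_empty():
            self.material_source = None


@dataclass
class EnvironmentParameter:
    """A condition held constant study-wide, as a parameter/value pair."""

    parameter: str | None = None
    value: str | None = None

    def __post_init__(self) -> None:
        self.parameter = _clean(self.parameter)
        self.value = _clean(self.value)


@dataclass
class ExperimentalFactor:
    """A deliberately varied condition with a declared set of values."""

    type: str | None = None
    values: list[str] = field(default_factory=list)
    description: str | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        self.type = _clean(self.type)
        self.description = _clean(self.description)
        self.accession = _clean(self.accession)
        self.values = [v for v in (_clean(v) for v in self.values) if v is not None]


@dataclass
class Event:
    """A dated occurrence affecting the whole study or specific units.

    A repeated event (e.g. fertiliser added weekly) is a series of records
    sharing type and description and differing only in date. An empty
    ``affected_units`` list means the whole study.
    """

    type: OntologyRef | None = None
    date: str | None = None
    description: str | None = None
    affected_units: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.date = _clean(self.date)
        self.description = _clean(self.description)
        if self.type is not None and self.type.is_empty():
            self.type = None
        self.affected_units = [
            u for u in (_clean(u) for u in self.affected_units) if u is not None
        ]


@dataclass
class ObservationUnit:
    """The object observations are made on; may contain no plant at all."""

    id: str | None = None
    level: str | None = None
    biological_material_id: str | None = None
    external_ref: str | None = None
    spatial_distribution: list[tuple[str, str]] = field(default_factory=list)
    factor_values: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in ("id", "level", "biological_material_id", "external_ref"):
            setattr(self, f, _clean(getattr(self, f)))
        self.spatial_distribution = [tuple(p) for p in self.spatial_distribution]


@dataclass
class Sample:
    """Sub-plant material physically collected from one observation unit."""

    id: str | None = None
    observation_unit_id: str | None = None
    collection_date: str | None = None
    description: str | None = None
    plant_anatomical_entity: OntologyRef | None = None
    plant_structure_development_stage: OntologyRef | None = None
    external_id: str | None = None

    def __post_init__(self) -> None:
        for f in ("id", "observation_unit_id", "collection_date", "description",
                  "external_id"):
            setattr(self, f, _clean(getattr(self, f)))
        if (self.plant_anatomical_entity is not None
                and self.plant_anatomical_entity.is_empty()):
            self.plant_anatomical_entity = None
        if (self.plant_structure_development_stage is not None
                and self.plant_structure_development_stage.is_empty()):
            self.plant_structure_development_stage = None


@dataclass
class TraitRef:
    name: str | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        self.name = _clean(self.name)
        self.accession = _clean(self.accession)


@dataclass
class MethodRef:
    name: str | None = None
    accession: str | None = None
    description: str | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        for f in ("name", "accession", "description", "reference"):
            setattr(self, f, _clean(getattr(self, f)))


@dataclass
class ScaleRef:
    name: str | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        self.name = _clean(self.name)
        self.accession = _clean(self.accession)


@dataclass
class ObservedVariable:
    """A variable following the Crop Ontology trait/method/scale trio.

    ``time_scale`` names the unit of time used to timestamp observations of
    this variable (date-time, julian days, growing degree days, ...).
    """

    id: str | None = None
    name: str | None = None
    trait: TraitRef = field(default_factory=TraitRef)
    method: MethodRef = field(default_factory=MethodRef)
    scale: ScaleRef = field(default_factory=ScaleRef)
    time_scale: str | None = None

    def __post_init__(self) -> None:
        self.id = _clean(self.id)
        self.name = _clean(self.name)
        self.time_scale = _clean(self.time_scale)


@dataclass
class StudyLocation:
    """The single location of a study (free-text and/or coordinates)."""

    country: str | None = None
    site_name: str | None = None
    geo: GeoPoint | None = None

    def __post_init__(self) -> None:
        self.country = _clean(self.country)
        self.site_name = _clean(self.site_name)
        if self.geo is not None and self.geo.is_empty():
            self.geo = None

    def is_empty(self) -> bool:
        return self.country is None and self.site_name is None and self.geo is None


@dataclass
class ExperimentalDesign:
    description: str | None = None
    type: OntologyRef | None = None
    map: str | None = None

    def __post_init__(self) -> None:
        self.description = _clean(self.description)
        self.map = _clean(self.map)
        if self.type is not None and self.type.is_empty():
            self.type = None

    def is_empty(self) -> bool:
        return self.description is None and self.type is None and self.map is None


@dataclass
class GrowthFacility:
    description: str | None = None
    type: OntologyRef | None = None

    def __post_init__(self) -> None:
        self.description = _clean(self.description)
        if self.type is not None and self.type.is_empty():
            self.type = None

    def is_empty(self) -> bool:
        return self.description is None and self.type is None


@dataclass
class Study:
    """One experiment: a single location, a duration and its section lists."""

    id: str | None = None
    title: str | None = None
    description: str | None = None
    start_date: str | None = None
    end_date: str | None = None
    contact_institution: str | None = None
    location: StudyLocation | None = None
    experimental_design: ExperimentalDesign | None = None
    growth_facility: GrowthFacility | None = None
    cultural_practices: str | None = None
    observation_unit_level_hierarchy: list[str] = field(default_factory=list)
    data_files: list[DataFile] = field(default_factory=list)
    biological_materials: list[BiologicalMaterial] = field(default_factory=list)
    environments: list[EnvironmentParameter] = field(default_factory=list)
    factors: list[ExperimentalFactor] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    observation_units: list[ObservationUnit] = field(default_factory=list)
    samples: list[Sample] = field(default_factory=list)
    observed_variables: list[ObservedVariable] = field(default_factory=list)
    persons: list[Person] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in ("id", "title", "description", "start_date", "end_date",
                  "contact_institution", "cultural_practices"):
            setattr(self, f, _clean(getattr(self, f)))
        if self.location is not None and self.location.is_empty():
            self.location = None
        if self.experimental_design is not None and self.experimental_design.is_empty():
            self.experimental_design = None
        if self.growth_facility is not None and self.growth_facility.is_empty():
            self.growth_facility = None
        self.observation_unit_level_hierarchy = [
            v for v in (_clean(v) for v in self.observation_unit_level_hierarchy)
            if v is not None
        ]


@dataclass
class Investigation:
    """The entry point of a MIAPPE dataset; owns one or more studies."""

    id: str | None = None
    title: str | None = None
    description: str | None = None
    submission_date: str | None = None
    public_release_date: str | None = None
    license: str | None = None
    miappe_version: str | None = "1.1"
    publications: list[str] = field(default_factory=list)
    persons: list[Person] = field(default_factory=list)
    studies: list[Study] = field(default_factory=list)

    def __post_init__(self) -> None:
        for f in ("id", "title", "description", "submission_date",
                  "public_release_date", "license", "miappe_version"):
            setattr(self, f, _clean(getattr(self, f)))
        self.publications = [
            p for p in (_clean(p) for p in self.publications) if p is not None
        ]


# section tag -> (human section name, study attribute holding the records)
_ID_SECTIONS = {
    "study": "Study",
    "biological_material": "Biological material",
    "observation_unit": "Observation unit",
    "sample": "Sample",
    "observed_variable": "Observed variable",
}


@dataclass
class UnresolvedReference:
    """A dangling cross-reference found while walking the graph."""

    section: str
    source_id: str
    field: str
    target_id: str


@dataclass
class Dataset:
    """The root object graph: an investigation plus by-identifier indexes.

    ``provenance`` optionally records the source format and any fields that
    a reader preserved but the model does not represent (a side-map keyed by
    record identifier); it is excluded from canonical comparison.
    """

    investigation: Investigation
    provenance: dict[str, Any] | None = None
    _index: dict[str, dict[str, Any]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def record(self, section: str, record_id: str) -> Any:
        """Look up a record by section tag and identifier."""
        return self._index.get(section, {}).get(record_id)

    def records(self, section: str) -> dict[str, Any]:
        return dict(self._index.get(section, {}))

    def owning_study(self, section: str, record_id: str) -> Study | None:
        """The first study whose section list contains the given record."""
        attr = {
            "biological_material": "biological_materials",
            "observation_unit": "observation_units",
            "sample": "samples",
            "observed_variable": "observed_variables",
        }.get(section)
        if attr is None:
            return None
        for study in self.investigation.studies:
            for rec in getattr(study, attr):
                if rec.id == record_id:
                    return study
        return None


def _iter_section_records(
    investigation: Investigation,
) -> Iterator[tuple[str, Any]]:
    for study in investigation.studies:
        yield "study", study
        for bm in study.biological_materials:
            yield "biological_material", bm
        for ou in study.observation_units:
            yield "observation_unit", ou
        for sample in study.samples:
            yield "sample", sample
        for var in study.observed_variables:
            yield "observed_variable", var


def build_dataset(
    investigation: Investigation, provenance: dict[str, Any] | None = None
) -> Dataset:
    """Index an investigation into a :class:`Dataset`.

    Builds the id->record index for every identifier-bearing section type.
    Checklist rules are *not* evaluated here (that is ``validate``'s job);
    the single structural requirement is identifier uniqueness: two records
    of the same section type under one id must be identical (a shared
    record), otherwise a :class:`DuplicateIdError` names both.
    """
    index: dict[str, dict[str, Any]] = {sec: {} for sec in _ID_SECTIONS}
    for section, rec in _iter_section_records(investigation):
        if rec.id is None:
            continue
        existing = index[section].get(rec.id)
        if existing is None:
            index[section][rec.id] = rec
        elif existing != rec:
            raise DuplicateIdError(
                f"duplicate {_ID_SECTIONS[section]} id {rec.id!r}: "
                f"{existing!r} vs {rec!r}"
            )
    return Dataset(investigation=investigation, provenance=provenance, _index=index)


def resolve_references(dataset: Dataset) -> list[UnresolvedReference]:
    """Report every dangling cross-reference in the graph.

    Walks sample -> observation unit, observation unit -> biological
    material and event -> observation unit links; returns an empty list iff
    the graph is closed.
    """
    out: list[UnresolvedReference] = []
    ous = dataset._index.get("observation_unit", {})
    bms = dataset._index.get("biological_material", {})
    for study in dataset.investigation.studies:
        for ou in study.observation_units:
            if ou.biological_material_id is not None and (
                ou.biological_material_id not in bms
            ):
                out.append(UnresolvedReference(
                    "Observation unit", ou.id or "-",
                    "biological_material_id", ou.biological_material_id,
                ))
        for sample in study.samples:
            if sample.observation_unit_id is not None and (
                sample.observation_unit_id not in ous
            ):
                out.append(UnresolvedReference(
                    "Sample", sample.id or "-",
                    "observation_unit_id", sample.observation_unit_id,
                ))
        for event in study.events:
            for target in event.affected_units:
                if target not in ous:
                    out.append(UnresolvedReference(
                        "Event",
                        (event.type.label if event.type else None) or "-",
                        "affected_units", target,
                    ))
    return out


def observation_unit_ancestry(dataset: Dataset, ou_id: str) -> list[str]:
    """Position of a unit's level within its study's level hierarchy.

    Returns the hierarchy prefix ending at the unit's level, root first
    (e.g. level "plot" under "study" > "genotype" > "plot" gives
    ``["study", "genotype", "plot"]``).
    """
    ou = dataset.record("observation_unit", ou_id)
    if ou is None:
        raise ContractViolationError(f"unknown observation unit {ou_id!r}")
    study = dataset.owning_study("observation_unit", ou_id)
    if study is None or not study.observation_unit_level_hierarchy:
        raise ContractViolationError(
            f"observation unit {ou_id!r} has no owning study with a declared "
            "level hierarchy"
        )
    hierarchy = study.observation_unit_level_hierarchy
    if ou.level not in hierarchy:
        raise ContractViolationError(
            f"level {ou.level!r} of unit {ou_id!r} is not in the declared "
            f"hierarchy {hierarchy!r}"
        )
    return hierarchy[: hierarchy.index(ou.level) + 1]


def _canon(value: Any) -> Any:
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {
            f.name: _canon(getattr(value, f.name))
            for f in dataclasses.fields(value)
            if not f.name.startswith("_")
        }
    if isinstance(value, dict):
        return {k: _canon(value[k]) for k in sorted(value)}
    if isinstance(value, tuple):
        return [_canon(v) for v in value]
    if isinstance(value, list):
        return [_canon(v) for v in value]
    return value


_SORT_KEYS = {
    "studies": lambda r: r.get("id") or "",
    "persons": lambda r: (r.get("name") or "", r.get("role") or ""),
    "publications": lambda r: r,
    "data_files": lambda r: r.get("link") or "",
    "biological_materials": lambda r: r.get("id") or "",
    "environments": lambda r: r.get("parameter") or "",
    "factors": lambda r: r.get("type") or "",
    "events": lambda r: ((r.get("type") or {}).get("label") or "",
                         r.get("date") or "",
                         r.get("description") or ""),
    "observation_units": lambda r: r.get("id") or "",
    "samples": lambda r: r.get("id") or "",
    "observed_variables": lambda r: r.get("id") or "",
    "affected_units": lambda r: r,
    "values": lambda r: r,
    "spatial_distribution": lambda r: tuple(r),
}


def _sort_lists(node: Any, key_name: str | None = None) -> Any:
    if isinstance(node, dict):
        return {k: _sort_lists(v, k) for k, v in node.items()}
    if isinstance(node, list):
        items = [_sort_lists(v, None) for v in node]
        sorter = _SORT_KEYS.get(key_name or "")
        if sorter is not None:
            items.sort(key=sorter)
        return items
    return node


def canonical(dataset: Dataset) -> dict[str, Any]:
    """A canonical nested-dict form of a dataset for order-insensitive
    comparison.

    Record lists are sorted by their natural identifying key; ordered
    structures (the observation-unit level hierarchy, spatial-distribution
    pairs) keep their order. Provenance and indexes are dropped. Two
    datasets are the same graph iff their canonical forms are equal.
    """
    return _sort_lists(_canon(dataset.investigation))
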