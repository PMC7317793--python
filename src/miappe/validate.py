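"""Checklist validation.

Every requirement the standard states with MUST becomes an ERROR rule and
every SHOULD a WARNING rule; fields the checklist leaves unqualified get no
rule at all. Each rule has a stable identifier so reports are comparable
across versions, and the report ordering is total (section, record, rule),
making a report byte-identical across runs on the same dataset.

Ontology-term checks are syntactic only (CURIE / absolute-IRI shape); no
network resolution is attempted.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from miappe.iso8601 import is_iso8601, parse_iso8601
from miappe.model import Dataset, OntologyRef, Study

ERROR = "ERROR"
WARNING = "WARNING"

_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*:[A-Za-z0-9_.-]+$")
_IRI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*://\S+$")


def is_term_reference(text: str) -> bool:
    """Whether *text* is shaped like a CURIE (``PREFIX:ID``) or an
    absolute IRI."""
    return bool(_CURIE_RE.match(text) or _IRI_RE.match(text))


@dataclass(frozen=True)
class Rule:
    rule_id: str
    severity: str
    description: str
    anchor: str  # the checklist statement the rule enforces


_RULES: list[Rule] = [
    Rule("CARD-INV-STUDY", ERROR,
         "An investigation must have one or more studies.",
         "investigation cardinality"),
    Rule("REQ-INV-ID", ERROR,
         "The investigation must carry a non-empty unique identifier.",
         "investigation identifier"),
    Rule("FMT-MIAPPE-VERSION", ERROR,
         'The MIAPPE version field must equal "1.1".',
         "investigation MIAPPE version"),
    Rule("CARD-STU-LOC", ERROR,
         "A study must define exactly one location.",
         "study location"),
    Rule("REQ-STU-ID", ERROR,
         "A study must carry a non-empty unique identifier.",
         "study identifier"),
    Rule("FMT-STU-DATES", ERROR,
         "Study end date must not precede its start date.",
         "study duration"),
    Rule("CARD-STU-OU", WARNING,
         "A study should have one or more observation units.",
         "study / observation unit cardinality"),
    Rule("REQ-PER-NAME", ERROR,
         "A person must have a name.", "person"),
    Rule("REQ-PER-ROLE", ERROR,
         "A person must have a role.", "person role"),
    Rule("REQ-DF-LINK", ERROR,
         "A data file must carry a link (filename or URL).", "data file"),
    Rule("REQ-DF-DESC", ERROR,
         "A description must be provided for each data file.",
         "data file description"),
    Rule("REQ-DF-VERSION", ERROR,
         "A version must be provided for each data file.",
         "data file version"),
    Rule("REQ-BM-ID", ERROR,
         "Plant material must be identified through a biological material ID.",
         "biological material ID"),
    Rule("REQ-BM-ORGANISM", ERROR,
         "Biological material must be identified through the organism field.",
         "biological material organism"),
    Rule("REQ-ENV-FIELDS", ERROR,
         "An environment parameter needs both a parameter name and a value.",
         "environment"),
    Rule("UNIQ-ENV-PARAM", ERROR,
         "Environment parameter names must be unique within a study.",
         "environment uniqueness"),
    Rule("REQ-FAC-TYPE", ERROR,
         "An experimental factor must have a type.", "experimental factor"),
    Rule("REQ-FAC-VALUES", ERROR,
         "An experimental factor needs a non-empty list of pairwise-distinct "
         "values.", "experimental factor values"),
    Rule("REQ-EV-TYPE", ERROR,
         "An event must have a type.", "event type"),
    Rule("REQ-EV-DATE", ERROR,
         "An event must have a date.", "event date"),
    Rule("REQ-OU-LEVEL", ERROR,
         "An observation unit's level must be one of the study's declared "
         "hierarchy levels.", "observation unit level"),
    Rule("REF-OU-BM", ERROR,
         "An observation unit's biological material reference must resolve.",
         "observation unit / biological material link"),
    Rule("REF-EV-OU", ERROR,
         "Every observation unit affected by an event must resolve.",
         "event / observation unit link"),
    Rule("CARD-SAM-OU", ERROR,
         "A sample must be derived from a single observation unit.",
         "sample / observation unit cardinality"),
    Rule("REF-SAM-OU", ERROR,
         "A sample's observation unit reference must resolve.",
         "sample / observation unit link"),
    Rule("REQ-SAM-DATE", ERROR,
         "A sample must carry a collection date.", "sample collection date"),
    Rule("WARN-SAM-DATE-RANGE", WARNING,
         "Sample collection date should fall within the study date range.",
         "sample collection date vs study duration"),
    Rule("REQ-VAR-COMPONENTS", ERROR,
         "An observed variable must decompose into named trait, method and "
         "scale, and carry an ID and a name.", "observed variable trio"),
    Rule("FMT-DATE", ERROR,
         "Dates must be valid ISO 8601 values.", "ISO 8601 recommendation"),
    Rule("FMT-GEO", ERROR,
         "Coordinates must be valid WGS84 decimal degrees (latitude within "
         "[-90, 90], longitude within [-180, 180], uncertainty >= 0 and only "
         "with latitude+longitude).", "geolocation fields"),
    Rule("FMT-CURIE", ERROR,
         "Term references must be CURIEs (PREFIX:ID) or absolute IRIs.",
         "controlled vocabulary references"),
    Rule("FMT-FACTORVALUE", ERROR,
         "An observation unit's factor values must name a declared factor and "
         "use one of its declared values.", "experimental factor values"),
]

_RULES_BY_ID = {r.rule_id: r for r in _RULES}


def rule_registry() -> list[Rule]:
    """The full shipped rule table (stable ids, severities, descriptions)."""
    return list(_RULES)


@dataclass(frozen=True)
class Issue:
    severity: str
    rule_id: str
    section: str
    record_id: str
    field: str
    message: str

    def sort_key(self) -> tuple[str, str, str, str]:
        return (self.section, self.record_id, self.rule_id, self.field)


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def error_count(self) -> int:
        return sum(1 for i in self.issues if i.severity == ERROR)

    @property
    def warning_count(self) -> int:
        return sum(1 for i in self.issues if i.severity == WARNING)

    @property
    def verdict(self) -> str:
        return "PASS" if self.error_count == 0 else "FAIL"

    def has_rule(self, rule_id: str) -> bool:
        return any(i.rule_id == rule_id for i in self.issues)

    def to_tsv(self) -> str:
        lines = ["severity\trule_id\tsection\trecord_id\tfield\tmessage"]
        for i in self.issues:
            lines.append("\t".join(
                [i.severity, i.rule_id, i.section, i.record_id, i.field,
                 i.message]))
        lines.append(f"# errors={self.error_count} warnings="
                     f"{self.warning_count} verdict={self.verdict}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        doc = {
            "verdict": self.verdict,
            "error_count": self.error_count,
            "warning_count": self.warning_count,
            "issues": [
                {
                    "severity": i.severity,
                    "rule_id": i.rule_id,
                    "section": i.section,
                    "record_id": i.record_id,
                    "field": i.field,
                    "message": i.message,
                }
                for i in self.issues
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=False) + "\n"


class _Collector:
    def __init__(self) -> None:
        self.issues: list[Issue] = []

    def add(self, rule_id: str, section: str, record_id: str | None,
            fieldname: str | None, message: str) -> None:
        rule = _RULES_BY_ID[rule_id]
        self.issues.append(Issue(
            severity=rule.severity,
            rule_id=rule_id,
            section=section,
            record_id=record_id or "-",
            field=fieldname or "-",
            message=message,
        ))

    def report(self) -> ValidationReport:
        seen = set()
        unique = []
        for issue in sorted(self.issues, key=Issue.sort_key):
            key = (issue.rule_id, issue.section, issue.record_id, issue.field)
            if key not in seen:
                seen.add(key)
                unique.append(issue)
        return ValidationReport(issues=unique)


def _check_geo(c: _Collector, geo, section: str, record_id: str | None) -> None:
    if geo is None:
        return
    if geo.latitude is not None and not (-90.0 <= geo.latitude <= 90.0):
        c.add("FMT-GEO", section, record_id, "latitude",
              f"latitude {geo.latitude} outside [-90, 90]")
    if geo.longitude is not None and not (-180.0 <= geo.longitude <= 180.0):
        c.add("FMT-GEO", section, record_id, "longitude",
              f"longitude {geo.longitude} outside [-180, 180]")
    if geo.coordinates_uncertainty is not None:
        if geo.coordinates_uncertainty < 0:
            c.add("FMT-GEO", section, record_id, "coordinates_uncertainty",
                  "coordinates uncertainty is negative")
        if geo.latitude is None or geo.longitude is None:
            c.add("FMT-GEO", section, record_id, "coordinates_uncertainty",
                  "coordinates uncertainty given without latitude+longitude")


def _check_term(c: _Collector, ref: OntologyRef | None, section: str,
                record_id: str | None, fieldname: str) -> None:
    if ref is None or ref.accession is None:
        return
    if not is_term_reference(ref.accession):
        c.add("FMT-CURIE", section, record_id, fieldname,
              f"{ref.accession!r} is neither a CURIE nor an absolute IRI")


def _check_date(c: _Collector, value: str | None, section: str,
                record_id: str | None, fieldname: str) -> None:
    if value is not None and not is_iso8601(value):
        c.add("FMT-DATE", section, record_id, fieldname,
              f"{value!r} is not a valid ISO 8601 date")


def _validate_study(c: _Collector, dataset: Dataset, study: Study) -> None:
    sid = study.id
    if sid is None:
        c.add("REQ-STU-ID", "Study", None, "id", "study lacks an identifier")
    if study.location is None:
        c.add("CARD-STU-LOC", "Study", sid, "location",
              "study defines no location (exactly one is required)")
    else:
        _check_geo(c, study.location.geo, "Study", sid)
    if not study.observation_units:
        c.add("CARD-STU-OU", "Study", sid, "observation_units",
              "study has no observation units")
    _check_date(c, study.start_date, "Study", sid, "start_date")
    _check_date(c, study.end_date, "Study", sid, "end_date")
    start = parse_iso8601(study.start_date) if study.start_date else None
    end = parse_iso8601(study.end_date) if study.end_date else None
    if start is not None and end is not None and end < start:
        c.add("FMT-STU-DATES", "Study", sid, "end_date",
              f"end date {study.end_date!r} precedes start date "
              f"{study.start_date!r}")
    if study.experimental_design is not None:
        _check_term(c, study.experimental_design.type, "Study", sid,
                    "experimental_design.type")
    if study.growth_facility is not None:
        _check_term(c, study.growth_facility.type, "Study", sid,
                    "growth_facility.type")

    for person in study.persons:
        _validate_person(c, person, "Study")

    for df in study.data_files:
        rid = df.link
        if df.link is None:
            c.add("REQ-DF-LINK", "Data file", rid, "link",
                  "data file lacks a link")
        if df.description is None:
            c.add("REQ-DF-DESC", "Data file", rid, "description",
                  "data file lacks a description")
        if df.version is None:
            c.add("REQ-DF-VERSION", "Data file", rid, "version",
                  "data file lacks a version")

    for bm in study.biological_materials:
        rid = bm.id
        if bm.id is None:
            c.add("REQ-BM-ID", "Biological material", rid, "id",
                  "biological material lacks an ID")
        if bm.organism is None:
            c.add("REQ-BM-ORGANISM", "Biological material", rid, "organism",
                  "biological material lacks an organism")
        _check_term(c, bm.organism, "Biological material", rid, "organism")
        _check_geo(c, bm.geo, "Biological material", rid)
        if bm.material_source is not None:
            _check_geo(c, bm.material_source.geo, "Biological material", rid)

    seen_params: dict[str, int] = {}
    for env in study.environments:
        rid = env.parameter
        if env.parameter is None or env.value is None:
            c.add("REQ-ENV-FIELDS", "Environment", rid, "parameter/value",
                  "environment parameter needs both a name and a value")
        if env.parameter is not None:
            seen_params[env.parameter] = seen_params.get(env.parameter, 0) + 1
    for name, count in seen_params.items():
        if count > 1:
            c.add("UNIQ-ENV-PARAM", "Environment", name, "parameter",
                  f"environment parameter {name!r} declared {count} times")

    declared: dict[str, list[str]] = {}
    for factor in study.factors:
        rid = factor.type
        if factor.type is None:
            c.add("REQ-FAC-TYPE", "Experimental factor", rid, "type",
                  "experimental factor lacks a type")
        if not factor.values or len(set(factor.values)) != len(factor.values):
            c.add("REQ-FAC-VALUES", "Experimental factor", rid, "values",
                  "factor values must be non-empty and pairwise distinct")
        if factor.accession is not None and not is_term_reference(
                factor.accession):
            c.add("FMT-CURIE", "Experimental factor", rid, "accession",
                  f"{factor.accession!r} is neither a CURIE nor an IRI")
        if factor.type is not None:
            declared[factor.type] = factor.values

    for event in study.events:
        rid = (event.type.label if event.type else None) or event.date
        if event.type is None:
            c.add("REQ-EV-TYPE", "Event", rid, "type", "event lacks a type")
        _check_term(c, event.type, "Event", rid, "type")
        if event.date is None:
            c.add("REQ-EV-DATE", "Event", rid, "date", "event lacks a date")
        _check_date(c, event.date, "Event", rid, "date")
        for target in event.affected_units:
            if dataset.record("observation_unit", target) is None:
                c.add("REF-EV-OU", "Event", rid, "affected_units",
                      f"affected observation unit {target!r} does not resolve")

    hierarchy = study.observation_unit_level_hierarchy
    for ou in study.observation_units:
        rid = ou.id
        if hierarchy and (ou.level is None or ou.level not in hierarchy):
            c.add("REQ-OU-LEVEL", "Observation unit", rid, "level",
                  f"level {ou.level!r} is not in the declared hierarchy "
                  f"{hierarchy!r}")
        if ou.biological_material_id is not None and dataset.record(
                "biological_material", ou.biological_material_id) is None:
            c.add("REF-OU-BM", "Observation unit", rid,
                  "biological_material_id",
                  f"biological material {ou.biological_material_id!r} does "
                  "not resolve")
        for ftype, fvalue in ou.factor_values.items():
            if ftype not in declared:
                c.add("FMT-FACTORVALUE", "Observation unit", rid,
                      "factor_values",
                      f"factor {ftype!r} is not declared in the study")
            elif fvalue not in declared[ftype]:
                c.add("FMT-FACTORVALUE", "Observation unit", rid,
                      "factor_values",
                      f"value {fvalue!r} is not among the declared values of "
                      f"factor {ftype!r}")

    for sample in study.samples:
        rid = sample.id
        if sample.observation_unit_id is None:
            c.add("CARD-SAM-OU", "Sample", rid, "observation_unit_id",
                  "sample is not derived from an observation unit")
        elif dataset.record("observation_unit",
                            sample.observation_unit_id) is None:
            c.add("REF-SAM-OU", "Sample", rid, "observation_unit_id",
                  f"observation unit {sample.observation_unit_id!r} does not "
                  "resolve")
        if sample.collection_date is None:
            c.add("REQ-SAM-DATE", "Sample", rid, "collection_date",
                  "sample lacks a collection date")
        _check_date(c, sample.collection_date, "Sample", rid,
                    "collection_date")
        _check_term(c, sample.plant_anatomical_entity, "Sample", rid,
                    "plant_anatomical_entity")
        _check_term(c, sample.plant_structure_development_stage, "Sample",
                    rid, "plant_structure_development_stage")
        coll = parse_iso8601(sample.collection_date) if sample.collection_date else None
        if coll is not None:
            if (start is not None and coll < start) or (
                    end is not None and coll > end):
                c.add("WARN-SAM-DATE-RANGE", "Sample", rid, "collection_date",
                      f"collection date {sample.collection_date!r} falls "
                      f"outside the study range "
                      f"[{study.start_date}, {study.end_date}]")

    for var in study.observed_variables:
        rid = var.id
        missing = [
            name for name, value in (
                ("id", var.id), ("name", var.name),
                ("trait.name", var.trait.name),
                ("method.name", var.method.name),
                ("scale.name", var.scale.name),
            ) if value is None
        ]
        if missing:
            c.add("REQ-VAR-COMPONENTS", "Observed variable", rid,
                  ",".join(missing),
                  "observed variable must decompose into named trait, method "
                  f"and scale (missing: {', '.join(missing)})")
        for fieldname, acc in (
            ("trait.accession", var.trait.accession),
            ("method.accession", var.method.accession),
            ("scale.accession", var.scale.accession),
        ):
            if acc is not None and not is_term_reference(acc):
                c.add("FMT-CURIE", "Observed variable", rid, fieldname,
                      f"{acc!r} is neither a CURIE nor an absolute IRI")


def _validate_person(c: _Collector, person, section: str) -> None:
    rid = person.name or person.email
    if person.name is None:
        c.add("REQ-PER-NAME", "Person", rid, "name", "person lacks a name")
    if person.role is None:
        c.add("REQ-PER-ROLE", "Person", rid, "role", "person lacks a role")


def check_value_formats(dataset: Dataset) -> list[Issue]:
    """Value-format checks only: ISO 8601 dates, coordinate ranges, CURIE /
    IRI shape, the MIAPPE version literal and factor-value membership."""
    full = validate(dataset)
    fmt = {"FMT-DATE", "FMT-GEO", "FMT-CURIE", "FMT-FACTORVALUE",
           "FMT-MIAPPE-VERSION", "FMT-STU-DATES"}
    return [i for i in full.issues if i.rule_id in fmt]


def validate(dataset: Dataset) -> ValidationReport:
    """Evaluate a dataset against the checklist rule registry.

    Always returns a report: one issue per violated (rule, record) pair,
    ERROR for MUST-level rules, WARNING for SHOULD-level ones, sorted by
    (section, record id, rule id). Verdict is PASS iff no ERRORs.
    """
    c = _Collector()
    inv = dataset.investigation
    if inv.id is None:
        c.add("REQ-INV-ID", "Investigation", None, "id",
              "investigation lacks a unique identifier")
    if inv.miappe_version != "1.1":
        c.add("FMT-MIAPPE-VERSION", "Investigation", inv.id, "miappe_version",
              f"MIAPPE version is {inv.miappe_version!r}, expected '1.1'")
    if not inv.studies:
        c.add("CARD-INV-STUDY", "Investigation", inv.id, "studies",
              "investigation has no studies (one or more required)")
    _check_date(c, inv.submission_date, "Investigation", inv.id,
                "submission_date")
    _check_date(c, inv.public_release_date, "Investigation", inv.id,
                "public_release_date")
    for person in inv.persons:
        _validate_person(c, person, "Investigation")
    for study in inv.studies:
        _validate_study(c, dataset, study)
    return c.report()
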