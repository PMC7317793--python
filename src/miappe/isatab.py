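"""MIAPPE-flavoured ISA-Tab archives.

The archive is a directory of UTF-8, Unix-newline, tab-delimited files:

``i_investigation.txt``
    Investigation, publications and contacts, plus one STUDY block group per
    study (study metadata, data-file comments, STUDY FACTORS, STUDY ASSAYS,
    STUDY PROTOCOLS, STUDY CONTACTS).
``s_<study>.txt``
    The study table: ISA Source = biological material, ISA Sample =
    observation unit, with Characteristics / Comment / Factor Value columns.
``a_<study>_<n>.txt``
    One assay per data file; rows run Sample Name -> (Sampling) -> Extract
    Name = MIAPPE sample -> Raw Data File, or directly Sample Name -> data
    file where the study has no samples.
``tdf_<study>.txt``
    The trait definition file listing observed variables as
    trait / method / scale rows.
``ev_<study>.txt``
    The events file (present only when the study has events).

Protocol conventions: a "Growth" protocol carries the cultural practices and
the environment parameters (names as protocol parameters, values in a
comment row); a "Phenotyping" protocol marks the observation process; a
"Sampling" protocol appears whenever samples are derived; each event type
gets a protocol of type "Event" with its occurrences in the events file.

MIAPPE-only fields travel as ``Comment[MIAPPE: <field name>]`` rows and
columns, which makes the reverse mapping unambiguous. Cells may not contain
tabs, newlines or the ``;`` list separator: such values are rejected on
write rather than quoted, because quoting conventions vary too much in the
wild to round-trip reliably.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from miappe.fields import check_cell, join_list, split_list
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

INVESTIGATION_FILE = "i_investigation.txt"


class IsaTabError(ValueError):
    pass


class IsaTabWriteError(IsaTabError):
    pass


class IsaTabParseError(IsaTabError):
    def __init__(self, message: str, filename: str = "?", line: int = 0):
        super().__init__(f"{filename}:{line}: {message}")
        self.filename = filename
        self.line = line


@dataclass
class IsaTabArchive:
    """Manifest of a written or read archive."""

    root_dir: Path
    investigation_file: str = INVESTIGATION_FILE
    study_files: list[str] = field(default_factory=list)
    assay_files: list[str] = field(default_factory=list)
    trait_definition_files: list[str] = field(default_factory=list)
    events_files: list[str] = field(default_factory=list)

    def all_files(self) -> list[str]:
        return ([self.investigation_file] + self.study_files
                + self.assay_files + self.trait_definition_files
                + self.events_files)


def _slug(identifier: str, taken: set[str]) -> str:
    base = re.sub(r"[^A-Za-z0-9._-]+", "-", identifier).strip("-")[:60] or "x"
    slug, n = base, 1
    while slug in taken:
        n += 1
        slug = f"{base}-{n}"
    taken.add(slug)
    return slug


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return str(value)  # shortest repr; round-trips exactly
    return check_cell(str(value), "ISA-Tab cell")


def _fmt_lines(rows: list[list[str]]) -> str:
    return "\n".join("\t".join(row) for row in rows) + "\n"


class _Block:
    """A columnar investigation-file block: rows of label + value list."""

    def __init__(self, header: str):
        self.header = header
        self.rows: list[tuple[str, list[str]]] = []

    def add(self, label: str, *values) -> None:
        self.rows.append((label, [_cell(v) for v in values]))

    def add_list(self, label: str, values: list) -> None:
        self.rows.append((label, [_cell(v) for v in values]))

    def emit(self) -> list[list[str]]:
        out = [[self.header]]
        for label, values in self.rows:
            out.append([label] + values)
        return out


def _person_rows(block: _Block, prefix: str, persons: list[Person]) -> None:
    block.add_list(f"{prefix} Person Name", [p.name for p in persons])
    block.add_list(f"{prefix} Person Email", [p.email for p in persons])
    block.add_list(f"{prefix} Person ID", [p.orcid for p in persons])
    block.add_list(f"{prefix} Person Affiliation",
                   [p.affiliation for p in persons])
    block.add_list(f"{prefix} Person Roles", [p.role for p in persons])


_STUDY_COMMENTS: list[tuple[str, str]] = [
    # (Comment key, attribute path on Study)
    ("Start date of study", "start_date"),
    ("End date of study", "end_date"),
    ("Contact institution", "contact_institution"),
    ("Geographic location (country)", "location.country"),
    ("Experimental site name", "location.site_name"),
    ("Geographic location (latitude)", "location.geo.latitude"),
    ("Geographic location (longitude)", "location.geo.longitude"),
    ("Geographic location (altitude)", "location.geo.altitude"),
    ("Geographic location (coordinates uncertainty)",
     "location.geo.coordinates_uncertainty"),
    ("Description of the experimental design",
     "experimental_design.description"),
    ("Type of experimental design", "experimental_design.type.label"),
    ("Type of experimental design accession",
     "experimental_design.type.accession"),
    ("Map of experimental design", "experimental_design.map"),
    ("Description of growth facility", "growth_facility.description"),
    ("Type of growth facility", "growth_facility.type.label"),
    ("Type of growth facility accession", "growth_facility.type.accession"),
]

_BM_COLUMNS: list[tuple[str, str]] = [
    ("Characteristics[Organism]", "organism.label"),
    ("Characteristics[Organism accession]", "organism.accession"),
    ("Characteristics[Genus]", "genus"),
    ("Characteristics[Species]", "species"),
    ("Characteristics[Infraspecific name]", "infraspecific_name"),
    ("Characteristics[Biological material latitude]", "geo.latitude"),
    ("Characteristics[Biological material longitude]", "geo.longitude"),
    ("Characteristics[Biological material altitude]", "geo.altitude"),
    ("Characteristics[Biological material coordinates uncertainty]",
     "geo.coordinates_uncertainty"),
    ("Characteristics[Biological material preprocessing]", "preprocessing"),
    ("Characteristics[Material source ID]", "material_source.id"),
    ("Characteristics[Material source DOI]", "material_source.doi"),
    ("Characteristics[Material source latitude]",
     "material_source.geo.latitude"),
    ("Characteristics[Material source longitude]",
     "material_source.geo.longitude"),
    ("Characteristics[Material source altitude]",
     "material_source.geo.altitude"),
    ("Characteristics[Material source coordinates uncertainty]",
     "material_source.geo.coordinates_uncertainty"),
    ("Characteristics[Material source description]",
     "material_source.description"),
]

_TDF_COLUMNS = [
    "Variable ID", "Variable name", "Trait", "Trait accession", "Method",
    "Method accession", "Method description", "Method reference", "Scale",
    "Scale accession", "Time scale",
]

_EVENTS_COLUMNS = [
    "Event type", "Event accession", "Description", "Date",
    "Affected observation units",
]


def covered_model_paths() -> dict[str, set[str]]:
    """Which model fields the writer serializes, per section.

    The tables drive most of it (study comments, source characteristics,
    trait-definition columns); fields handled directly in writer code are
    listed explicitly. The completeness test compares this against the
    model field registry, so a field added to the model without a column
    here fails the suite.
    """
    covered = {
        "Investigation": {"id", "title", "description", "submission_date",
                          "public_release_date", "license", "miappe_version",
                          "publications"},
        "Study": {"id", "title", "description", "cultural_practices",
                  "observation_unit_level_hierarchy"}
        | {path for _, path in _STUDY_COMMENTS},
        "Person": {"name", "email", "orcid", "affiliation", "role"},
        "Data file": {"link", "description", "version"},
        "Biological material": {"id"} | {path for _, path in _BM_COLUMNS},
        "Environment": {"parameter", "value"},
        "Experimental factor": {"type", "accession", "description",
                                "values"},
        "Event": {"type.label", "type.accession", "description", "date",
                  "affected_units"},
        "Observation unit": {"id", "level", "biological_material_id",
                             "external_ref", "spatial_distribution",
                             "factor_values"},
        "Sample": {"id", "observation_unit_id", "description",
                   "plant_anatomical_entity.label",
                   "plant_anatomical_entity.accession",
                   "plant_structure_development_stage.label",
                   "plant_structure_development_stage.accession",
                   "collection_date", "external_id"},
        "Observed variable": {"id", "name", "trait.name", "trait.accession",
                              "method.name", "method.accession",
                              "method.description", "method.reference",
                              "scale.name", "scale.accession", "time_scale"},
    }
    return covered


def _get_path(obj, path: str):
    for part in path.split("."):
        if obj is None:
            return None
        obj = getattr(obj, part)
    return obj


def write_isatab(dataset: Dataset, root_dir: str | Path) -> IsaTabArchive:
    """Serialize a validated dataset as an ISA-Tab archive.

    Refuses datasets that do not pass checklist validation with zero
    errors, and studies whose samples could not be anchored (a study with
    samples needs at least one data file, because samples are expressed in
    assay files and every assay references exactly one data file).
    """
    report = validate(dataset)
    if report.error_count:
        raise IsaTabWriteError(
            f"dataset has {report.error_count} validation error(s); refusing "
            "to write (run validate for details)")
    root = Path(root_dir)
    root.mkdir(parents=True, exist_ok=True)
    archive = IsaTabArchive(root_dir=root)
    taken: set[str] = set()
    inv = dataset.investigation

    blocks: list[_Block] = []
    b = _Block("INVESTIGATION")
    b.add("Investigation Identifier", inv.id)
    b.add("Investigation Title", inv.title)
    b.add("Investigation Description", inv.description)
    b.add("Investigation Submission Date", inv.submission_date)
    b.add("Investigation Public Release Date", inv.public_release_date)
    b.add("Comment[MIAPPE: License]", inv.license)
    b.add("Comment[MIAPPE: MIAPPE version]", inv.miappe_version)
    blocks.append(b)

    b = _Block("INVESTIGATION PUBLICATIONS")
    b.add_list("Investigation Publication DOI", inv.publications)
    blocks.append(b)

    b = _Block("INVESTIGATION CONTACTS")
    _person_rows(b, "Investigation", inv.persons)
    blocks.append(b)

    for study in inv.studies:
        slug = _slug(study.id or "study", taken)
        s_file = f"s_{slug}.txt"
        tdf_file = f"tdf_{slug}.txt"
        ev_file = f"ev_{slug}.txt" if study.events else None
        if study.samples and not study.data_files:
            raise IsaTabWriteError(
                f"study {study.id!r} has samples but no data files; samples "
                "are serialized in assay files, each anchored to one data "
                "file")

        b = _Block("STUDY")
        b.add("Study Identifier", study.id)
        b.add("Study Title", study.title)
        b.add("Study Description", study.description)
        b.add("Study File Name", s_file)
        for key, path in _STUDY_COMMENTS:
            b.add(f"Comment[MIAPPE: {key}]", _get_path(study, path))
        b.add("Comment[MIAPPE: Observation unit level hierarchy]",
              " > ".join(study.observation_unit_level_hierarchy) or None)
        b.add("Comment[MIAPPE: Trait definition file]", tdf_file)
        b.add("Comment[MIAPPE: Events file]", ev_file)
        b.add_list("Comment[MIAPPE: Data file link]",
                   [df.link for df in study.data_files])
        b.add_list("Comment[MIAPPE: Data file description]",
                   [df.description for df in study.data_files])
        b.add_list("Comment[MIAPPE: Data file version]",
                   [df.version for df in study.data_files])
        blocks.append(b)

        b = _Block("STUDY FACTORS")
        b.add_list("Study Factor Name", [f.type for f in study.factors])
        b.add_list("Study Factor Type Term Accession Number",
                   [f.accession for f in study.factors])
        b.add_list("Comment[MIAPPE: Factor description]",
                   [f.description for f in study.factors])
        b.add_list("Comment[MIAPPE: Factor values]",
                   [join_list(f.values, "factor values")
                    for f in study.factors])
        blocks.append(b)

        assay_files = []
        for n, df in enumerate(study.data_files, start=1):
            assay_files.append(f"a_{slug}_{n}.txt")
        b = _Block("STUDY ASSAYS")
        b.add_list("Study Assay File Name", assay_files)
        b.add_list("Study Assay Measurement Type",
                   ["phenotyping"] * len(assay_files))
        blocks.append(b)

        names = ["Growth", "Phenotyping"]
        types = ["Growth", "Phenotyping"]
        descriptions = [study.cultural_practices, None]
        parameters = [join_list([e.parameter for e in study.environments],
                                "environment parameters"), None]
        param_values = [join_list([e.value for e in study.environments],
                                  "environment values"), None]
        accessions = [None, None]
        if study.samples:
            names.append("Sampling")
            types.append("Sampling")
            descriptions.append(None)
            parameters.append(None)
            param_values.append(None)
            accessions.append(None)
        seen_ev: set[str] = set()
        for event in study.events:
            label = event.type.label if event.type else None
            if label is None or label in seen_ev:
                continue
            seen_ev.add(label)
            names.append(label)
            types.append("Event")
            descriptions.append(event.description)
            parameters.append(None)
            param_values.append(None)
            accessions.append(event.type.accession if event.type else None)
        b = _Block("STUDY PROTOCOLS")
        b.add_list("Study Protocol Name", names)
        b.add_list("Study Protocol Type", types)
        b.add_list("Study Protocol Description", descriptions)
        b.add_list("Study Protocol Parameters Name", parameters)
        b.add_list("Comment[MIAPPE: Protocol parameter values]", param_values)
        b.add_list("Comment[MIAPPE: Protocol term accession]", accessions)
        blocks.append(b)

        b = _Block("STUDY CONTACTS")
        _person_rows(b, "Study", study.persons)
        blocks.append(b)

        _write_study_table(root / s_file, study)
        archive.study_files.append(s_file)
        _write_tdf(root / tdf_file, study)
        archive.trait_definition_files.append(tdf_file)
        if ev_file:
            _write_events(root / ev_file, study)
            archive.events_files.append(ev_file)
        for a_file, df in zip(assay_files, study.data_files):
            _write_assay(root / a_file, study, df)
            archive.assay_files.append(a_file)

    rows: list[list[str]] = []
    for block in blocks:
        rows.extend(block.emit())
    (root / INVESTIGATION_FILE).write_text(_fmt_lines(rows), encoding="utf-8",
                                           newline="\n")
    return archive


def _write_study_table(path: Path, study: Study) -> None:
    factor_types = [f.type for f in study.factors if f.type]
    header = (["Source Name"] + [c for c, _ in _BM_COLUMNS]
              + ["Protocol REF", "Sample Name",
                 "Comment[MIAPPE: Observation unit level]",
                 "Comment[MIAPPE: External ID]",
                 "Comment[MIAPPE: Spatial distribution]"]
              + [f"Factor Value[{t}]" for t in factor_types])
    rows = [header]
    bms = {bm.id: bm for bm in study.biological_materials}
    referenced: set[str] = set()

    def bm_cells(bm: BiologicalMaterial | None) -> list[str]:
        if bm is None:
            return [""] * len(_BM_COLUMNS)
        return [_cell(_get_path(bm, p)) for _, p in _BM_COLUMNS]

    for ou in study.observation_units:
        bm = bms.get(ou.biological_material_id)
        if bm is not None:
            referenced.add(bm.id)
        spatial = join_list(
            [f"{k}: {v}" for k, v in ou.spatial_distribution],
            "spatial distribution")
        row = ([_cell(ou.biological_material_id)] + bm_cells(bm)
               + ["Growth", _cell(ou.id), _cell(ou.level),
                  _cell(ou.external_ref), spatial]
               + [_cell(ou.factor_values.get(t)) for t in factor_types])
        rows.append(row)
    for bm in study.biological_materials:
        if bm.id not in referenced:
            rows.append([_cell(bm.id)] + bm_cells(bm)
                        + ["Growth", "", "", "", ""]
                        + [""] * len(factor_types))
    path.write_text(_fmt_lines(rows), encoding="utf-8", newline="\n")


def _write_tdf(path: Path, study: Study) -> None:
    rows = [list(_TDF_COLUMNS)]
    for var in study.observed_variables:
        rows.append([_cell(v) for v in [
            var.id, var.name, var.trait.name, var.trait.accession,
            var.method.name, var.method.accession, var.method.description,
            var.method.reference, var.scale.name, var.scale.accession,
            var.time_scale,
        ]])
    path.write_text(_fmt_lines(rows), encoding="utf-8", newline="\n")


def _write_events(path: Path, study: Study) -> None:
    rows = [list(_EVENTS_COLUMNS)]
    for event in study.events:
        rows.append([
            _cell(event.type.label if event.type else None),
            _cell(event.type.accession if event.type else None),
            _cell(event.description),
            _cell(event.date),
            join_list(event.affected_units, "affected units"),
        ])
    path.write_text(_fmt_lines(rows), encoding="utf-8", newline="\n")


def _write_assay(path: Path, study: Study, df: DataFile) -> None:
    if study.samples:
        header = ["Sample Name", "Protocol REF", "Extract Name",
                  "Comment[MIAPPE: Sample description]",
                  "Comment[MIAPPE: Plant anatomical entity]",
                  "Comment[MIAPPE: Plant anatomical entity accession]",
                  "Comment[MIAPPE: Plant structure development stage]",
                  "Comment[MIAPPE: Plant structure development stage "
                  "accession]",
                  "Comment[MIAPPE: Collection date]",
                  "Comment[MIAPPE: External ID]",
                  "Protocol REF", "Raw Data File"]
        rows = [header]
        for s in study.samples:
            rows.append([
                _cell(s.observation_unit_id), "Sampling", _cell(s.id),
                _cell(s.description),
                _cell(s.plant_anatomical_entity.label
                      if s.plant_anatomical_entity else None),
                _cell(s.plant_anatomical_entity.accession
                      if s.plant_anatomical_entity else None),
                _cell(s.plant_structure_development_stage.label
                      if s.plant_structure_development_stage else None),
                _cell(s.plant_structure_development_stage.accession
                      if s.plant_structure_development_stage else None),
                _cell(s.collection_date), _cell(s.external_id),
                "Phenotyping", _cell(df.link),
            ])
    else:
        rows = [["Sample Name", "Protocol REF", "Raw Data File"]]
        for ou in study.observation_units:
            rows.append([_cell(ou.id), "Phenotyping", _cell(df.link)])
    path.write_text(_fmt_lines(rows), encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# Reading

def _read_table(path: Path) -> list[list[str]]:
    if not path.is_file():
        raise IsaTabParseError("referenced file is missing", path.name, 0)
    lines = path.read_text(encoding="utf-8").splitlines()
    return [line.split("\t") for line in lines]


_BLOCK_HEADERS = {
    "ONTOLOGY SOURCE REFERENCE", "INVESTIGATION",
    "INVESTIGATION PUBLICATIONS", "INVESTIGATION CONTACTS", "STUDY",
    "STUDY DESIGN DESCRIPTORS", "STUDY PUBLICATIONS", "STUDY FACTORS",
    "STUDY ASSAYS", "STUDY PROTOCOLS", "STUDY CONTACTS",
}


class _BlockView:
    def __init__(self) -> None:
        self.rows: dict[str, list[str]] = {}

    def value(self, label: str) -> str | None:
        values = self.rows.get(label)
        if not values:
            return None
        return values[0] or None

    def values(self, label: str) -> list[str]:
        return self.rows.get(label, [])


def _parse_investigation_file(path: Path) -> tuple[_BlockView, _BlockView,
                                                   _BlockView,
                                                   list[dict[str, _BlockView]]]:
    table = _read_table(path)
    inv_blocks: dict[str, _BlockView] = {}
    studies: list[dict[str, _BlockView]] = []
    current: _BlockView | None = None
    context: dict[str, _BlockView] | None = None
    for lineno, row in enumerate(table, start=1):
        label = row[0].strip()
        if not label and all(not c for c in row):
            continue
        if label in _BLOCK_HEADERS:
            current = _BlockView()
            if label == "STUDY":
                context = {"STUDY": current}
                studies.append(context)
            elif label.startswith("STUDY "):
                if context is None:
                    raise IsaTabParseError(
                        f"{label} block before any STUDY block", path.name,
                        lineno)
                context[label] = current
            else:
                inv_blocks[label] = current
            continue
        if current is None:
            raise IsaTabParseError("row outside any block", path.name, lineno)
        values = [c.strip() for c in row[1:]]
        while values and not values[-1]:
            values.pop()
        current.rows[label] = values
    for name in ("INVESTIGATION",):
        if name not in inv_blocks:
            raise IsaTabParseError(f"missing {name} block", path.name, 0)
    return (inv_blocks.get("INVESTIGATION", _BlockView()),
            inv_blocks.get("INVESTIGATION PUBLICATIONS", _BlockView()),
            inv_blocks.get("INVESTIGATION CONTACTS", _BlockView()),
            studies)


def _read_persons(block: _BlockView, prefix: str) -> list[Person]:
    names = block.values(f"{prefix} Person Name")
    emails = block.values(f"{prefix} Person Email")
    ids = block.values(f"{prefix} Person ID")
    affils = block.values(f"{prefix} Person Affiliation")
    roles = block.values(f"{prefix} Person Roles")
    count = max([len(names), len(emails), len(ids), len(affils), len(roles)],
                default=0)

    def at(values: list[str], i: int) -> str | None:
        return values[i] if i < len(values) and values[i] else None

    return [
        Person(name=at(names, i), email=at(emails, i), orcid=at(ids, i),
               affiliation=at(affils, i), role=at(roles, i))
        for i in range(count)
    ]


def _maybe_geo(getter) -> GeoPoint | None:
    def as_float(v):
        return float(v) if v not in (None, "") else None

    geo = GeoPoint(
        latitude=as_float(getter("latitude")),
        longitude=as_float(getter("longitude")),
        altitude=as_float(getter("altitude")),
        coordinates_uncertainty=as_float(getter("coordinates uncertainty")),
    )
    return None if geo.is_empty() else geo


def read_isatab(root_dir: str | Path) -> Dataset:
    """Parse an ISA-Tab archive back into a :class:`Dataset`.

    Inverts :func:`write_isatab`. Unknown ``Comment[...]`` rows in the
    investigation file are preserved in the dataset's provenance side-map.
    """
    root = Path(root_dir)
    inv_path = root / INVESTIGATION_FILE
    if not inv_path.is_file():
        raise IsaTabParseError("no investigation file in directory",
                               str(root), 0)
    inv_b, pub_b, contacts_b, study_blocks = _parse_investigation_file(
        inv_path)

    known = {
        "Comment[MIAPPE: License]", "Comment[MIAPPE: MIAPPE version]",
    }
    extras = {
        label: values
        for label, values in inv_b.rows.items()
        if label.startswith("Comment[") and label not in known
    }

    investigation = Investigation(
        id=inv_b.value("Investigation Identifier"),
        title=inv_b.value("Investigation Title"),
        description=inv_b.value("Investigation Description"),
        submission_date=inv_b.value("Investigation Submission Date"),
        public_release_date=inv_b.value("Investigation Public Release Date"),
        license=inv_b.value("Comment[MIAPPE: License]"),
        miappe_version=inv_b.value("Comment[MIAPPE: MIAPPE version]"),
        publications=[p for p in pub_b.values("Investigation Publication DOI")
                      if p],
        persons=_read_persons(contacts_b, "Investigation"),
    )

    for context in study_blocks:
        investigation.studies.append(_read_study(root, context))

    provenance = {"format": "isatab", "root_dir": str(root)}
    if extras:
        provenance["extras"] = extras
    return build_dataset(investigation, provenance=provenance)


def _read_study(root: Path, context: dict[str, _BlockView]) -> Study:
    sb = context["STUDY"]

    def com(key: str) -> str | None:
        return sb.value(f"Comment[MIAPPE: {key}]")

    location = StudyLocation(
        country=com("Geographic location (country)"),
        site_name=com("Experimental site name"),
        geo=_maybe_geo(lambda part: com(f"Geographic location ({part})")),
    )
    design = ExperimentalDesign(
        description=com("Description of the experimental design"),
        type=OntologyRef(label=com("Type of experimental design"),
                         accession=com("Type of experimental design "
                                       "accession")),
        map=com("Map of experimental design"),
    )
    facility = GrowthFacility(
        description=com("Description of growth facility"),
        type=OntologyRef(label=com("Type of growth facility"),
                         accession=com("Type of growth facility accession")),
    )
    hierarchy = [part.strip() for part in
                 (com("Observation unit level hierarchy") or "").split(">")
                 if part.strip()]

    links = sb.values("Comment[MIAPPE: Data file link]")
    descs = sb.values("Comment[MIAPPE: Data file description]")
    versions = sb.values("Comment[MIAPPE: Data file version]")
    data_files = [
        DataFile(link=links[i] if i < len(links) else None,
                 description=descs[i] if i < len(descs) else None,
                 version=versions[i] if i < len(versions) else None)
        for i in range(max(len(links), len(descs), len(versions)))
    ]

    fb = context.get("STUDY FACTORS", _BlockView())
    names = fb.values("Study Factor Name")
    accs = fb.values("Study Factor Type Term Accession Number")
    fdescs = fb.values("Comment[MIAPPE: Factor description]")
    fvalues = fb.values("Comment[MIAPPE: Factor values]")

    def at(values: list[str], i: int) -> str | None:
        return values[i] if i < len(values) and values[i] else None

    factors = [
        ExperimentalFactor(
            type=at(names, i), accession=at(accs, i),
            description=at(fdescs, i),
            values=split_list(at(fvalues, i)),
        )
        for i in range(len(names))
    ]

    pb = context.get("STUDY PROTOCOLS", _BlockView())
    pnames = pb.values("Study Protocol Name")
    ptypes = pb.values("Study Protocol Type")
    pdescs = pb.values("Study Protocol Description")
    pparams = pb.values("Study Protocol Parameters Name")
    pvalues = pb.values("Comment[MIAPPE: Protocol parameter values]")
    cultural = None
    environments: list[EnvironmentParameter] = []
    for i, ptype in enumerate(ptypes):
        if ptype == "Growth":
            cultural = at(pdescs, i)
            env_names = split_list(at(pparams, i))
            env_values = split_list(at(pvalues, i))
            environments = [
                EnvironmentParameter(
                    parameter=name,
                    value=env_values[j] if j < len(env_values) else None)
                for j, name in enumerate(env_names)
            ]

    study = Study(
        id=sb.value("Study Identifier"),
        title=sb.value("Study Title"),
        description=sb.value("Study Description"),
        start_date=com("Start date of study"),
        end_date=com("End date of study"),
        contact_institution=com("Contact institution"),
        location=location,
        experimental_design=design,
        growth_facility=facility,
        cultural_practices=cultural,
        observation_unit_level_hierarchy=hierarchy,
        data_files=data_files,
        environments=environments,
        factors=factors,
        persons=_read_persons(context.get("STUDY CONTACTS", _BlockView()),
                              "Study"),
    )

    s_file = sb.value("Study File Name")
    if s_file:
        _read_study_table(root / s_file, study)
    tdf_file = com("Trait definition file")
    if tdf_file:
        _read_tdf(root / tdf_file, study)
    ev_file = com("Events file")
    if ev_file:
        _read_events(root / ev_file, study)

    ab = context.get("STUDY ASSAYS", _BlockView())
    for a_file in ab.values("Study Assay File Name"):
        if a_file:
            _read_assay(root / a_file, study)
    return study


def _read_study_table(path: Path, study: Study) -> None:
    table = _read_table(path)
    if not table:
        raise IsaTabParseError("empty study table", path.name, 1)
    header = table[0]
    idx = {name: i for i, name in enumerate(header)}
    if "Sample Name" not in idx or "Source Name" not in idx:
        raise IsaTabParseError(
            "study table lacks Source Name / Sample Name columns",
            path.name, 1)
    factor_cols = [(name[len("Factor Value["):-1], i)
                   for i, name in enumerate(header)
                   if name.startswith("Factor Value[") and name.endswith("]")]

    def get(row: list[str], col: str) -> str | None:
        i = idx.get(col)
        if i is None or i >= len(row):
            return None
        return row[i].strip() or None

    seen_bm: dict[str, BiologicalMaterial] = {}
    for lineno, row in enumerate(table[1:], start=2):
        if all(not c.strip() for c in row):
            continue
        source = get(row, "Source Name")
        if source and source not in seen_bm:
            def bm_get(column: str) -> str | None:
                return get(row, column)

            def geo_for(prefix: str) -> GeoPoint | None:
                return _maybe_geo(lambda part: bm_get(
                    f"Characteristics[{prefix} {part}]"))

            bm = BiologicalMaterial(
                id=source,
                organism=OntologyRef(
                    label=bm_get("Characteristics[Organism]"),
                    accession=bm_get("Characteristics[Organism accession]")),
                genus=bm_get("Characteristics[Genus]"),
                species=bm_get("Characteristics[Species]"),
                infraspecific_name=bm_get(
                    "Characteristics[Infraspecific name]"),
                geo=geo_for("Biological material"),
                preprocessing=bm_get(
                    "Characteristics[Biological material preprocessing]"),
                material_source=MaterialSource(
                    id=bm_get("Characteristics[Material source ID]"),
                    doi=bm_get("Characteristics[Material source DOI]"),
                    geo=geo_for("Material source"),
                    description=bm_get(
                        "Characteristics[Material source description]")),
            )
            seen_bm[source] = bm
            study.biological_materials.append(bm)
        ou_id = get(row, "Sample Name")
        if ou_id:
            spatial = [
                (part.partition(":")[0].strip(),
                 part.partition(":")[2].strip())
                for part in split_list(
                    get(row, "Comment[MIAPPE: Spatial distribution]"))
            ]
            factor_values = {}
            for ftype, i in factor_cols:
                if i < len(row) and row[i].strip():
                    factor_values[ftype] = row[i].strip()
            study.observation_units.append(ObservationUnit(
                id=ou_id,
                level=get(row, "Comment[MIAPPE: Observation unit level]"),
                biological_material_id=source,
                external_ref=get(row, "Comment[MIAPPE: External ID]"),
                spatial_distribution=spatial,
                factor_values=factor_values,
            ))


def _read_tdf(path: Path, study: Study) -> None:
    table = _read_table(path)
    if not table or table[0] != _TDF_COLUMNS:
        raise IsaTabParseError(
            "trait definition file header mismatch", path.name, 1)
    for row in table[1:]:
        row = row + [""] * (len(_TDF_COLUMNS) - len(row))
        if all(not c.strip() for c in row):
            continue
        study.observed_variables.append(ObservedVariable(
            id=row[0], name=row[1],
            trait=TraitRef(name=row[2], accession=row[3]),
            method=MethodRef(name=row[4], accession=row[5],
                             description=row[6], reference=row[7]),
            scale=ScaleRef(name=row[8], accession=row[9]),
            time_scale=row[10],
        ))


def _read_events(path: Path, study: Study) -> None:
    table = _read_table(path)
    if not table or table[0] != _EVENTS_COLUMNS:
        raise IsaTabParseError("events file header mismatch", path.name, 1)
    for row in table[1:]:
        row = row + [""] * (len(_EVENTS_COLUMNS) - len(row))
        if all(not c.strip() for c in row):
            continue
        study.events.append(Event(
            type=OntologyRef(label=row[0].strip() or None,
                             accession=row[1].strip() or None),
            description=row[2].strip() or None,
            date=row[3].strip() or None,
            affected_units=split_list(row[4]),
        ))


def _read_assay(path: Path, study: Study) -> None:
    table = _read_table(path)
    if not table:
        raise IsaTabParseError("empty assay file", path.name, 1)
    header = table[0]
    if "Extract Name" not in header:
        return  # no samples expressed in this assay
    idx = {name: i for i, name in enumerate(header)}
    seen = {s.id for s in study.samples}

    def get(row: list[str], col: str) -> str | None:
        i = idx.get(col)
        if i is None or i >= len(row):
            return None
        return row[i].strip() or None

    for row in table[1:]:
        if all(not c.strip() for c in row):
            continue
        sample_id = get(row, "Extract Name")
        if sample_id is None or sample_id in seen:
            continue
        seen.add(sample_id)
        study.samples.append(Sample(
            id=sample_id,
            observation_unit_id=get(row, "Sample Name"),
            description=get(row, "Comment[MIAPPE: Sample description]"),
            plant_anatomical_entity=OntologyRef(
                label=get(row, "Comment[MIAPPE: Plant anatomical entity]"),
                accession=get(row, "Comment[MIAPPE: Plant anatomical entity "
                                   "accession]")),
            plant_structure_development_stage=OntologyRef(
                label=get(row, "Comment[MIAPPE: Plant structure development "
                               "stage]"),
                accession=get(row, "Comment[MIAPPE: Plant structure "
                                   "development stage accession]")),
            collection_date=get(row, "Comment[MIAPPE: Collection date]"),
            external_id=get(row, "Comment[MIAPPE: External ID]"),
        ))
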