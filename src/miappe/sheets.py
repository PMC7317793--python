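"""The multi-worksheet spreadsheet template.

One worksheet per checklist section, a header row of human-readable field
names (row 1), one record per data row. Cross-sheet references use id
columns ("Study unique ID", "Observation unit ID", ...); records shared by
several studies (a network's biological materials and variables) list their
study ids joined with ``"; "`` in one row.

Two carriers share the layout: an XLSX workbook (the biologist-facing form,
written with openpyxl) and a directory of TSV files, one per sheet with the
same headers. The headers come from the model's field registry
(:mod:`miappe.fields`), so the template cannot silently drop a model field.
"""

from __future__ import annotations

from pathlib import Path

import openpyxl

from miappe.fields import (
    SHEET_FIELDS,
    SHEET_ORDER,
    check_cell,
    join_hierarchy,
    join_list,
    join_pairs,
    sheet_headers,
    split_hierarchy,
    split_list,
    split_pairs,
)
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

_MANDATORY_SHEETS = ("Investigation", "Study")


class SheetsError(ValueError):
    pass


class MissingSheetError(SheetsError):
    pass


class HeaderMismatchError(SheetsError):
    pass


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return str(value)
    return check_cell(str(value), "worksheet cell")


def _tsv_name(sheet: str) -> str:
    return sheet.lower().replace(" ", "_") + ".tsv"


# ---------------------------------------------------------------------------
# Row construction (write side)

def _geo_cells(geo: GeoPoint | None) -> list[str]:
    if geo is None:
        return ["", "", "", ""]
    return [_cell(geo.latitude), _cell(geo.longitude), _cell(geo.altitude),
            _cell(geo.coordinates_uncertainty)]


def _rows_for(dataset: Dataset) -> dict[str, list[list[str]]]:
    inv = dataset.investigation
    rows: dict[str, list[list[str]]] = {name: [] for name in SHEET_ORDER}

    rows["Investigation"].append([
        _cell(inv.id), _cell(inv.title), _cell(inv.description),
        _cell(inv.submission_date), _cell(inv.public_release_date),
        _cell(inv.license), _cell(inv.miappe_version),
        join_list(inv.publications, "publications"),
    ])
    for person in inv.persons:
        rows["Person"].append([
            _cell(person.name), _cell(person.email), _cell(person.orcid),
            _cell(person.affiliation), _cell(person.role), "",
        ])

    # records shared across studies collapse into one row with joined ids
    bm_studies: dict[str, tuple[BiologicalMaterial, list[str]]] = {}
    var_studies: dict[str, tuple[ObservedVariable, list[str]]] = {}

    for study in inv.studies:
        loc = study.location or StudyLocation()
        design = study.experimental_design or ExperimentalDesign()
        facility = study.growth_facility or GrowthFacility()
        design_type = design.type or OntologyRef()
        facility_type = facility.type or OntologyRef()
        rows["Study"].append([
            _cell(study.id), _cell(study.title), _cell(study.description),
            _cell(study.start_date), _cell(study.end_date),
            _cell(study.contact_institution), _cell(loc.country),
            _cell(loc.site_name), *_geo_cells(loc.geo),
            _cell(design.description), _cell(design_type.label),
            _cell(design_type.accession), _cell(design.map),
            _cell(facility.description), _cell(facility_type.label),
            _cell(facility_type.accession), _cell(study.cultural_practices),
            join_hierarchy(study.observation_unit_level_hierarchy,
                           "hierarchy"),
        ])
        for person in study.persons:
            rows["Person"].append([
                _cell(person.name), _cell(person.email), _cell(person.orcid),
                _cell(person.affiliation), _cell(person.role),
                _cell(study.id),
            ])
        for df in study.data_files:
            rows["Data file"].append([
                _cell(study.id), _cell(df.link), _cell(df.description),
                _cell(df.version),
            ])
        for bm in study.biological_materials:
            entry = bm_studies.setdefault(bm.id, (bm, []))
            entry[1].append(study.id)
        for env in study.environments:
            rows["Environment"].append([
                _cell(study.id), _cell(env.parameter), _cell(env.value),
            ])
        for factor in study.factors:
            rows["Experimental factor"].append([
                _cell(study.id), _cell(factor.type), _cell(factor.accession),
                _cell(factor.description),
                join_list(factor.values, "factor values"),
            ])
        for event in study.events:
            etype = event.type or OntologyRef()
            rows["Event"].append([
                _cell(study.id), _cell(etype.label), _cell(etype.accession),
                _cell(event.description), _cell(event.date),
                join_list(event.affected_units, "affected units"),
            ])
        for ou in study.observation_units:
            rows["Observation unit"].append([
                _cell(ou.id), _cell(study.id), _cell(ou.level),
                _cell(ou.biological_material_id), _cell(ou.external_ref),
                join_pairs(ou.spatial_distribution, "spatial distribution"),
                join_pairs(sorted(ou.factor_values.items()),
                           "factor values"),
            ])
        for sample in study.samples:
            anat = sample.plant_anatomical_entity or OntologyRef()
            stage = sample.plant_structure_development_stage or OntologyRef()
            rows["Sample"].append([
                _cell(sample.id), _cell(sample.observation_unit_id),
                _cell(sample.description), _cell(anat.label),
                _cell(anat.accession), _cell(stage.label),
                _cell(stage.accession), _cell(sample.collection_date),
                _cell(sample.external_id),
            ])
        for var in study.observed_variables:
            entry = var_studies.setdefault(var.id, (var, []))
            entry[1].append(study.id)

    for bm, study_ids in bm_studies.values():
        source = bm.material_source or MaterialSource()
        organism = bm.organism or OntologyRef()
        rows["Biological material"].append([
            _cell(bm.id), join_list(study_ids, "study ids"),
            _cell(organism.label), _cell(organism.accession),
            _cell(bm.genus), _cell(bm.species),
            _cell(bm.infraspecific_name), *_geo_cells(bm.geo),
            _cell(bm.preprocessing), _cell(source.id), _cell(source.doi),
            *_geo_cells(source.geo), _cell(source.description),
        ])
    for var, study_ids in var_studies.values():
        rows["Observed variable"].append([
            _cell(var.id), join_list(study_ids, "study ids"),
            _cell(var.name), _cell(var.trait.name),
            _cell(var.trait.accession), _cell(var.method.name),
            _cell(var.method.accession), _cell(var.method.description),
            _cell(var.method.reference), _cell(var.scale.name),
            _cell(var.scale.accession), _cell(var.time_scale),
        ])
    return rows


def write_workbook(dataset: Dataset, path: str | Path) -> Path:
    """Write a dataset as the spreadsheet template.

    A ``.xlsx`` path produces a workbook with the eleven section
    worksheets; any other path is treated as a directory and receives one
    TSV per sheet with identical headers and rows.
    """
    path = Path(path)
    rows = _rows_for(dataset)
    if path.suffix.lower() == ".xlsx":
        wb = openpyxl.Workbook()
        wb.remove(wb.active)
        for sheet in SHEET_ORDER:
            ws = wb.create_sheet(title=sheet)
            ws.append(sheet_headers(sheet))
            for row in rows[sheet]:
                ws.append(row)
        path.parent.mkdir(parents=True, exist_ok=True)
        wb.save(path)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for sheet in SHEET_ORDER:
            lines = ["\t".join(sheet_headers(sheet))]
            lines.extend("\t".join(row) for row in rows[sheet])
            (path / _tsv_name(sheet)).write_text(
                "\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Read side

def _load_grids(path: Path) -> dict[str, list[list[str]]]:
    grids: dict[str, list[list[str]]] = {}
    if path.is_file() and path.suffix.lower() == ".xlsx":
        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        for ws in wb.worksheets:
            grid = []
            for row in ws.iter_rows(values_only=True):
                grid.append(["" if v is None else str(v) for v in row])
            grids[ws.title] = grid
        wb.close()
    elif path.is_dir():
        for sheet in SHEET_ORDER:
            fp = path / _tsv_name(sheet)
            if fp.is_file():
                lines = fp.read_text(encoding="utf-8").splitlines()
                grids[sheet] = [line.split("\t") for line in lines]
    else:
        raise SheetsError(f"{path} is neither a workbook nor a directory")
    return grids


class _Sheet:
    def __init__(self, sheet: str, grid: list[list[str]]):
        headers = sheet_headers(sheet)
        if not grid or [h.strip() for h in grid[0][:len(headers)]] != headers:
            got = grid[0] if grid else []
            for i, header in enumerate(headers):
                if i >= len(got) or got[i].strip() != header:
                    raise HeaderMismatchError(
                        f"sheet {sheet!r}: expected column {i + 1} to be "
                        f"{header!r}")
        self.headers = headers
        self.extra_headers = [h for h in (grid[0][len(headers):] if grid
                                          else []) if h.strip()]
        self.rows = []
        for row in grid[1:]:
            if all(not str(c).strip() for c in row):
                continue
            padded = [str(c).strip() for c in row]
            padded += [""] * (len(headers) - len(padded))
            self.rows.append(padded)

    def get(self, row: list[str], header: str) -> str | None:
        value = row[self.headers.index(header)]
        return value if value else None


def _geo_from_row(sheet: _Sheet, row: list[str],
                  headers: tuple[str, str, str, str]) -> GeoPoint | None:
    def fl(header: str) -> float | None:
        v = sheet.get(row, header)
        return float(v) if v is not None else None

    geo = GeoPoint(latitude=fl(headers[0]), longitude=fl(headers[1]),
                   altitude=fl(headers[2]), coordinates_uncertainty=fl(
                       headers[3]))
    return None if geo.is_empty() else geo


def read_workbook(path: str | Path) -> Dataset:
    """Read the spreadsheet template back into a :class:`Dataset`.

    Unknown worksheets are ignored; unknown extra columns are recorded in
    the provenance side-map. A missing Investigation or Study sheet, or a
    header row that does not match the shipped template, is an error.
    """
    path = Path(path)
    grids = _load_grids(path)
    for sheet in _MANDATORY_SHEETS:
        if sheet not in grids:
            raise MissingSheetError(f"mandatory sheet {sheet!r} is missing")
    sheets = {name: _Sheet(name, grids[name])
              for name in SHEET_ORDER if name in grids}

    s = sheets["Investigation"]
    if not s.rows:
        raise SheetsError("Investigation sheet has no data row")
    row = s.rows[0]
    inv = Investigation(
        id=s.get(row, "Investigation unique ID"),
        title=s.get(row, "Investigation title"),
        description=s.get(row, "Investigation description"),
        submission_date=s.get(row, "Submission date"),
        public_release_date=s.get(row, "Public release date"),
        license=s.get(row, "License"),
        miappe_version=s.get(row, "MIAPPE version"),
        publications=split_list(s.get(row, "Associated publication")),
    )

    studies: dict[str, Study] = {}
    s = sheets["Study"]
    for row in s.rows:
        study = Study(
            id=s.get(row, "Study unique ID"),
            title=s.get(row, "Study title"),
            description=s.get(row, "Study description"),
            start_date=s.get(row, "Start date of study"),
            end_date=s.get(row, "End date of study"),
            contact_institution=s.get(row, "Contact institution"),
            location=StudyLocation(
                country=s.get(row, "Geographic location (country)"),
                site_name=s.get(row, "Experimental site name"),
                geo=_geo_from_row(s, row, (
                    "Geographic location (latitude)",
                    "Geographic location (longitude)",
                    "Geographic location (altitude)",
                    "Geographic location (coordinates uncertainty)")),
            ),
            experimental_design=ExperimentalDesign(
                description=s.get(
                    row, "Description of the experimental design"),
                type=OntologyRef(
                    label=s.get(row, "Type of experimental design"),
                    accession=s.get(
                        row, "Type of experimental design accession")),
                map=s.get(row, "Map of experimental design"),
            ),
            growth_facility=GrowthFacility(
                description=s.get(row, "Description of growth facility"),
                type=OntologyRef(
                    label=s.get(row, "Type of growth facility"),
                    accession=s.get(row,
                                    "Type of growth facility accession")),
            ),
            cultural_practices=s.get(row, "Cultural practices"),
            observation_unit_level_hierarchy=split_hierarchy(
                s.get(row, "Observation unit level hierarchy")),
        )
        studies[study.id] = study
        inv.studies.append(study)

    def owning(row_study_id: str | None, what: str) -> Study:
        study = studies.get(row_study_id)
        if study is None:
            raise SheetsError(
                f"{what} references unknown study {row_study_id!r}")
        return study

    if "Person" in sheets:
        s = sheets["Person"]
        for row in s.rows:
            person = Person(
                name=s.get(row, "Person name"),
                email=s.get(row, "Person email"),
                orcid=s.get(row, "Person ID"),
                affiliation=s.get(row, "Person affiliation"),
                role=s.get(row, "Person role"),
            )
            sid = s.get(row, "Study unique ID")
            if sid is None:
                inv.persons.append(person)
            else:
                owning(sid, "person").persons.append(person)

    if "Data file" in sheets:
        s = sheets["Data file"]
        for row in s.rows:
            owning(s.get(row, "Study unique ID"), "data file") \
                .data_files.append(DataFile(
                    link=s.get(row, "Data file link"),
                    description=s.get(row, "Data file description"),
                    version=s.get(row, "Data file version")))

    if "Biological material" in sheets:
        s = sheets["Biological material"]
        for row in s.rows:
            bm = BiologicalMaterial(
                id=s.get(row, "Biological material ID"),
                organism=OntologyRef(
                    label=s.get(row, "Organism"),
                    accession=s.get(row, "Organism accession")),
                genus=s.get(row, "Genus"),
                species=s.get(row, "Species"),
                infraspecific_name=s.get(row, "Infraspecific name"),
                geo=_geo_from_row(s, row, (
                    "Biological material latitude",
                    "Biological material longitude",
                    "Biological material altitude",
                    "Biological material coordinates uncertainty")),
                preprocessing=s.get(row, "Biological material preprocessing"),
                material_source=MaterialSource(
                    id=s.get(row, "Material source ID"),
                    doi=s.get(row, "Material source DOI"),
                    geo=_geo_from_row(s, row, (
                        "Material source latitude",
                        "Material source longitude",
                        "Material source altitude",
                        "Material source coordinates uncertainty")),
                    description=s.get(row, "Material source description")),
            )
            for sid in split_list(s.get(row, "Study unique ID")):
                owning(sid, "biological material") \
                    .biological_materials.append(bm)

    if "Environment" in sheets:
        s = sheets["Environment"]
        for row in s.rows:
            owning(s.get(row, "Study unique ID"), "environment parameter") \
                .environments.append(EnvironmentParameter(
                    parameter=s.get(row, "Environment parameter"),
                    value=s.get(row, "Environment parameter value")))

    if "Experimental factor" in sheets:
        s = sheets["Experimental factor"]
        for row in s.rows:
            owning(s.get(row, "Study unique ID"), "experimental factor") \
                .factors.append(ExperimentalFactor(
                    type=s.get(row, "Experimental factor type"),
                    accession=s.get(row, "Experimental factor accession"),
                    description=s.get(
                        row, "Experimental factor description"),
                    values=split_list(
                        s.get(row, "Experimental factor values"))))

    if "Event" in sheets:
        s = sheets["Event"]
        for row in s.rows:
            owning(s.get(row, "Study unique ID"), "event") \
                .events.append(Event(
                    type=OntologyRef(
                        label=s.get(row, "Event type"),
                        accession=s.get(row, "Event accession")),
                    description=s.get(row, "Event description"),
                    date=s.get(row, "Event date"),
                    affected_units=split_list(
                        s.get(row, "Affected observation units"))))

    if "Observation unit" in sheets:
        s = sheets["Observation unit"]
        for row in s.rows:
            owning(s.get(row, "Study unique ID"), "observation unit") \
                .observation_units.append(ObservationUnit(
                    id=s.get(row, "Observation unit ID"),
                    level=s.get(row, "Observation unit level"),
                    biological_material_id=s.get(
                        row, "Biological material ID"),
                    external_ref=s.get(row, "External ID"),
                    spatial_distribution=split_pairs(
                        s.get(row, "Spatial distribution")),
                    factor_values=dict(split_pairs(
                        s.get(row, "Factor values")))))

    sample_rows = []
    if "Sample" in sheets:
        s = sheets["Sample"]
        for row in s.rows:
            sample_rows.append(Sample(
                id=s.get(row, "Sample ID"),
                observation_unit_id=s.get(row, "Observation unit ID"),
                description=s.get(row, "Sample description"),
                plant_anatomical_entity=OntologyRef(
                    label=s.get(row, "Plant anatomical entity"),
                    accession=s.get(row,
                                    "Plant anatomical entity accession")),
                plant_structure_development_stage=OntologyRef(
                    label=s.get(row, "Plant structure development stage"),
                    accession=s.get(
                        row,
                        "Plant structure development stage accession")),
                collection_date=s.get(row, "Collection date"),
                external_id=s.get(row, "External ID")))

    # samples attach to the study owning their observation unit
    unit_owner: dict[str, Study] = {}
    for study in inv.studies:
        for ou in study.observation_units:
            unit_owner[ou.id] = study
    for sample in sample_rows:
        study = unit_owner.get(sample.observation_unit_id)
        if study is None:
            study = inv.studies[0] if inv.studies else None
            if study is None:
                raise SheetsError("sample present but no study to attach to")
        study.samples.append(sample)

    if "Observed variable" in sheets:
        s = sheets["Observed variable"]
        for row in s.rows:
            var = ObservedVariable(
                id=s.get(row, "Variable ID"),
                name=s.get(row, "Variable name"),
                trait=TraitRef(name=s.get(row, "Trait"),
                               accession=s.get(row, "Trait accession")),
                method=MethodRef(name=s.get(row, "Method"),
                                 accession=s.get(row, "Method accession"),
                                 description=s.get(row, "Method description"),
                                 reference=s.get(row, "Method reference")),
                scale=ScaleRef(name=s.get(row, "Scale"),
                               accession=s.get(row, "Scale accession")),
                time_scale=s.get(row, "Time scale"),
            )
            for sid in split_list(s.get(row, "Study unique ID")):
                owning(sid, "observed variable") \
                    .observed_variables.append(var)

    extras = {name: sheet.extra_headers
              for name, sheet in sheets.items() if sheet.extra_headers}
    provenance = {"format": "xlsx" if path.suffix.lower() == ".xlsx"
                  else "tsv-sheets", "path": str(path)}
    if extras:
        provenance["extra_columns"] = extras
    return build_dataset(inv, provenance=provenance)
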