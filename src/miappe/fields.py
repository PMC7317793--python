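"""Field registry: the single source of truth for human-readable headers.

Maps every model field to the checklist-style column name used by the
spreadsheet template and (prefixed) by ISA-Tab comment keys. The sheet
writers/readers and the completeness tests are all driven by this table, so
a field added to the model without a header here fails the suite.

List-valued cells are joined with ``"; "``; values containing ``";"`` are
rejected on write to keep the encoding reversible. Spatial-distribution and
factor-value pairs are encoded as ``"key: value"`` entries.
"""

from __future__ import annotations

LIST_SEP = "; "
PAIR_SEP = ": "
HIERARCHY_SEP = " > "

# The eleven section worksheets, in checklist order.
SHEET_ORDER = [
    "Investigation",
    "Study",
    "Person",
    "Data file",
    "Biological material",
    "Environment",
    "Experimental factor",
    "Event",
    "Observation unit",
    "Sample",
    "Observed variable",
]

# sheet name -> list of (model field path, column header)
SHEET_FIELDS: dict[str, list[tuple[str, str]]] = {
    "Investigation": [
        ("id", "Investigation unique ID"),
        ("title", "Investigation title"),
        ("description", "Investigation description"),
        ("submission_date", "Submission date"),
        ("public_release_date", "Public release date"),
        ("license", "License"),
        ("miappe_version", "MIAPPE version"),
        ("publications", "Associated publication"),
    ],
    "Study": [
        ("id", "Study unique ID"),
        ("title", "Study title"),
        ("description", "Study description"),
        ("start_date", "Start date of study"),
        ("end_date", "End date of study"),
        ("contact_institution", "Contact institution"),
        ("location.country", "Geographic location (country)"),
        ("location.site_name", "Experimental site name"),
        ("location.geo.latitude", "Geographic location (latitude)"),
        ("location.geo.longitude", "Geographic location (longitude)"),
        ("location.geo.altitude", "Geographic location (altitude)"),
        ("location.geo.coordinates_uncertainty",
         "Geographic location (coordinates uncertainty)"),
        ("experimental_design.description",
         "Description of the experimental design"),
        ("experimental_design.type.label", "Type of experimental design"),
        ("experimental_design.type.accession",
         "Type of experimental design accession"),
        ("experimental_design.map", "Map of experimental design"),
        ("growth_facility.description", "Description of growth facility"),
        ("growth_facility.type.label", "Type of growth facility"),
        ("growth_facility.type.accession", "Type of growth facility accession"),
        ("cultural_practices", "Cultural practices"),
        ("observation_unit_level_hierarchy",
         "Observation unit level hierarchy"),
    ],
    "Person": [
        ("name", "Person name"),
        ("email", "Person email"),
        ("orcid", "Person ID"),
        ("affiliation", "Person affiliation"),
        ("role", "Person role"),
        ("", "Study unique ID"),  # empty = investigation-level contact
    ],
    "Data file": [
        ("", "Study unique ID"),
        ("link", "Data file link"),
        ("description", "Data file description"),
        ("version", "Data file version"),
    ],
    "Biological material": [
        ("id", "Biological material ID"),
        ("", "Study unique ID"),
        ("organism.label", "Organism"),
        ("organism.accession", "Organism accession"),
        ("genus", "Genus"),
        ("species", "Species"),
        ("infraspecific_name", "Infraspecific name"),
        ("geo.latitude", "Biological material latitude"),
        ("geo.longitude", "Biological material longitude"),
        ("geo.altitude", "Biological material altitude"),
        ("geo.coordinates_uncertainty",
         "Biological material coordinates uncertainty"),
        ("preprocessing", "Biological material preprocessing"),
        ("material_source.id", "Material source ID"),
        ("material_source.doi", "Material source DOI"),
        ("material_source.geo.latitude", "Material source latitude"),
        ("material_source.geo.longitude", "Material source longitude"),
        ("material_source.geo.altitude", "Material source altitude"),
        ("material_source.geo.coordinates_uncertainty",
         "Material source coordinates uncertainty"),
        ("material_source.description", "Material source description"),
    ],
    "Environment": [
        ("", "Study unique ID"),
        ("parameter", "Environment parameter"),
        ("value", "Environment parameter value"),
    ],
    "Experimental factor": [
        ("", "Study unique ID"),
        ("type", "Experimental factor type"),
        ("accession", "Experimental factor accession"),
        ("description", "Experimental factor description"),
        ("values", "Experimental factor values"),
    ],
    "Event": [
        ("", "Study unique ID"),
        ("type.label", "Event type"),
        ("type.accession", "Event accession"),
        ("description", "Event description"),
        ("date", "Event date"),
        ("affected_units", "Affected observation units"),
    ],
    "Observation unit": [
        ("id", "Observation unit ID"),
        ("", "Study unique ID"),
        ("level", "Observation unit level"),
        ("biological_material_id", "Biological material ID"),
        ("external_ref", "External ID"),
        ("spatial_distribution", "Spatial distribution"),
        ("factor_values", "Factor values"),
    ],
    "Sample": [
        ("id", "Sample ID"),
        ("observation_unit_id", "Observation unit ID"),
        ("description", "Sample description"),
        ("plant_anatomical_entity.label", "Plant anatomical entity"),
        ("plant_anatomical_entity.accession",
         "Plant anatomical entity accession"),
        ("plant_structure_development_stage.label",
         "Plant structure development stage"),
        ("plant_structure_development_stage.accession",
         "Plant structure development stage accession"),
        ("collection_date", "Collection date"),
        ("external_id", "External ID"),
    ],
    "Observed variable": [
        ("id", "Variable ID"),
        ("", "Study unique ID"),
        ("name", "Variable name"),
        ("trait.name", "Trait"),
        ("trait.accession", "Trait accession"),
        ("method.name", "Method"),
        ("method.accession", "Method accession"),
        ("method.description", "Method description"),
        ("method.reference", "Method reference"),
        ("scale.name", "Scale"),
        ("scale.accession", "Scale accession"),
        ("time_scale", "Time scale"),
    ],
}


def sheet_headers(sheet: str) -> list[str]:
    """Header row (row 1) for a section worksheet."""
    return [header for _, header in SHEET_FIELDS[sheet]]


class CellEncodingError(ValueError):
    """A value cannot be encoded reversibly in a cell."""


def check_cell(value: str, where: str) -> str:
    """Reject values that would break the cell encoding (tabs, newlines)."""
    if "\t" in value or "\n" in value or "\r" in value:
        raise CellEncodingError(f"tab/newline in value {value!r} ({where})")
    return value


def check_list_item(value: str, where: str) -> str:
    """List components additionally may not contain the ``;`` separator."""
    check_cell(value, where)
    if ";" in value:
        raise CellEncodingError(
            f"';' in value {value!r} ({where}); the list separator is "
            "reserved")
    return value


def join_list(values: list[str], where: str) -> str:
    return LIST_SEP.join(check_list_item(v, where) for v in values)


def split_list(cell: str | None) -> list[str]:
    if not cell:
        return []
    return [part.strip() for part in cell.split(";") if part.strip()]


def join_pairs(pairs: list[tuple[str, str]], where: str) -> str:
    return LIST_SEP.join(
        check_list_item(k, where) + PAIR_SEP + check_list_item(v, where)
        for k, v in pairs
    )


def split_pairs(cell: str | None) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    for part in split_list(cell):
        key, sep, value = part.partition(":")
        out.append((key.strip(), value.strip() if sep else ""))
    return out


def join_hierarchy(levels: list[str], where: str) -> str:
    for level in levels:
        check_list_item(level, where)
        if ">" in level:
            raise CellEncodingError(
                f"'>' in level name {level!r} ({where}); the hierarchy "
                "separator is reserved")
    return HIERARCHY_SEP.join(levels)


def split_hierarchy(cell: str | None) -> list[str]:
    if not cell:
        return []
    return [part.strip() for part in cell.split(">") if part.strip()]
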