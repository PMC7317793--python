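"""Format tags, auto-detection and uniform read/write dispatch.

The closed set of format tags: ``isatab`` (directory with an
``i_investigation.txt``), ``brapi`` (directory of collection JSON files),
``xlsx`` (workbook), ``tsv-sheets`` (directory of per-sheet TSVs),
``turtle`` and ``jsonld`` (RDF files).
"""

from __future__ import annotations

from pathlib import Path

from miappe import brapi, isatab, ppeo_rdf, sheets
from miappe.model import Dataset

FORMAT_TAGS = ("isatab", "brapi", "xlsx", "tsv-sheets", "turtle", "jsonld")

DEFAULT_BASE_IRI = "https://example.org/miappe/"


class FormatError(ValueError):
    pass


def detect_format(path: str | Path) -> str:
    """Map a path onto a format tag by its shape."""
    path = Path(path)
    if path.is_dir():
        if (path / isatab.INVESTIGATION_FILE).is_file():
            return "isatab"
        if (path / "trials.json").is_file():
            return "brapi"
        if (path / "investigation.tsv").is_file():
            return "tsv-sheets"
        raise FormatError(
            f"cannot detect a dataset format in directory {path}")
    suffix = path.suffix.lower()
    if suffix == ".xlsx":
        return "xlsx"
    if suffix == ".ttl":
        return "turtle"
    if suffix == ".jsonld":
        return "jsonld"
    raise FormatError(f"cannot detect a dataset format for {path}")


def read_dataset(path: str | Path, fmt: str | None = None) -> Dataset:
    fmt = fmt or detect_format(path)
    if fmt == "isatab":
        return isatab.read_isatab(path)
    if fmt == "brapi":
        return brapi.from_brapi(brapi.read_brapi(path))
    if fmt in ("xlsx", "tsv-sheets"):
        return sheets.read_workbook(path)
    if fmt in ("turtle", "jsonld"):
        return ppeo_rdf.from_rdf(ppeo_rdf.read_rdf(path))
    raise FormatError(f"unknown format tag {fmt!r}; known: "
                      f"{', '.join(FORMAT_TAGS)}")


def write_dataset(dataset: Dataset, path: str | Path, fmt: str,
                  base_iri: str = DEFAULT_BASE_IRI) -> None:
    if fmt == "isatab":
        isatab.write_isatab(dataset, path)
    elif fmt == "brapi":
        brapi.write_brapi(brapi.to_brapi(dataset), path)
    elif fmt in ("xlsx", "tsv-sheets"):
        sheets.write_workbook(dataset, path)
    elif fmt in ("turtle", "jsonld"):
        rdf_fmt = "turtle" if fmt == "turtle" else "json-ld"
        ppeo_rdf.write_rdf(ppeo_rdf.to_rdf(dataset, base_iri), rdf_fmt, path)
    else:
        raise FormatError(f"unknown format tag {fmt!r}; known: "
                          f"{', '.join(FORMAT_TAGS)}")
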