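"""Spreadsheet template: layout, headers, round-trips, hand fixtures."""

import random

import openpyxl
import pytest

from miappe.fields import SHEET_FIELDS, SHEET_ORDER, sheet_headers
from miappe.model import ObservationUnit, build_dataset, canonical
from miappe.sheets import (
    HeaderMismatchError,
    MissingSheetError,
    read_workbook,
    write_workbook,
)
from miappe import synth

from conftest import make_minimal_investigation, model_field_census


class TestLayout:
    def test_workbook_has_exactly_the_eleven_section_sheets(
            self, minimal_dataset, tmp_path):
        path = tmp_path / "d.xlsx"
        write_workbook(minimal_dataset, path)
        wb = openpyxl.load_workbook(path)
        assert wb.sheetnames == SHEET_ORDER
        assert len(wb.sheetnames) == 11

    def test_one_row_per_observation_unit(self, tmp_path):
        inv = make_minimal_investigation()
        inv.studies[0].observation_units.extend([
            ObservationUnit(id="OU2", level="plot"),
            ObservationUnit(id="OU3", level="study"),
        ])
        path = tmp_path / "d.xlsx"
        write_workbook(build_dataset(inv), path)
        ws = openpyxl.load_workbook(path)["Observation unit"]
        assert ws.max_row - 1 == 3

    def test_header_rows_match_the_registry(self, minimal_dataset,
                                            tmp_path):
        path = tmp_path / "d.xlsx"
        write_workbook(minimal_dataset, path)
        wb = openpyxl.load_workbook(path)
        for sheet in SHEET_ORDER:
            got = [c.value for c in wb[sheet][1]]
            assert got == sheet_headers(sheet)

    def test_registry_covers_every_model_field(self):
        census = model_field_census()
        for sheet, paths in census.items():
            mapped = {p for p, _ in SHEET_FIELDS[sheet] if p}
            missing = paths - mapped
            assert not missing, f"{sheet}: headerless fields {missing}"


class TestRoundTrip:
    @pytest.mark.parametrize("scenario", synth.SCENARIOS)
    @pytest.mark.parametrize("kind", ["xlsx", "tsv"])
    def test_identity(self, scenario, kind, tmp_path):
        dataset = synth.generate(scenario, seed=4)
        path = tmp_path / ("d.xlsx" if kind == "xlsx" else "sheets")
        write_workbook(dataset, path)
        assert canonical(read_workbook(path)) == canonical(dataset)

    def test_reordered_data_rows_read_to_the_same_graph(self, glasshouse,
                                                        tmp_path):
        path = tmp_path / "sheets"
        write_workbook(glasshouse, path)
        rng = random.Random(0)
        for tsv in path.glob("*.tsv"):
            lines = tsv.read_text().splitlines()
            body = lines[1:]
            rng.shuffle(body)
            tsv.write_text("\n".join([lines[0]] + body) + "\n")
        assert canonical(read_workbook(path)) == canonical(glasshouse)


class TestErrors:
    def test_missing_study_sheet(self, minimal_dataset, tmp_path):
        path = tmp_path / "sheets"
        write_workbook(minimal_dataset, path)
        (path / "study.tsv").unlink()
        with pytest.raises(MissingSheetError, match="Study"):
            read_workbook(path)

    def test_header_mismatch_names_sheet_and_column(self, minimal_dataset,
                                                    tmp_path):
        path = tmp_path / "sheets"
        write_workbook(minimal_dataset, path)
        tsv = path / "environment.tsv"
        lines = tsv.read_text().splitlines()
        lines[0] = lines[0].replace("Environment parameter value",
                                    "Param value")
        tsv.write_text("\n".join(lines) + "\n")
        with pytest.raises(HeaderMismatchError,
                           match="Environment parameter value"):
            read_workbook(path)


class TestHandAuthoredWorkbook:
    """A two-record TSV fixture authored by hand; expectation built
    manually."""

    def test_expected_dataset(self, tmp_path):
        path = tmp_path / "sheets"
        path.mkdir()
        (path / "investigation.tsv").write_text(
            "\t".join(sheet_headers("Investigation")) + "\n"
            "INV-W\tWorkbook inv\t\t\t\tCC0\t1.1\t\n")
        (path / "study.tsv").write_text(
            "\t".join(sheet_headers("Study")) + "\n"
            + "\t".join(["STW", "Wb study", "", "2021", "2022", "",
                         "Portugal", "", "", "", "", "", "", "", "", "",
                         "", "", "", "", "study > plant"]) + "\n")
        (path / "observation_unit.tsv").write_text(
            "\t".join(sheet_headers("Observation unit")) + "\n"
            "U-A\tSTW\tplant\t\t\t\t\n"
            "U-B\tSTW\tplant\t\t\t\t\n")
        dataset = read_workbook(path)
        inv = dataset.investigation
        assert inv.id == "INV-W"
        assert inv.miappe_version == "1.1"
        study = inv.studies[0]
        assert study.location.country == "Portugal"
        assert study.observation_unit_level_hierarchy == ["study", "plant"]
        assert sorted(u.id for u in study.observation_units) == ["U-A",
                                                                 "U-B"]
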