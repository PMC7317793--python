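"""ISA-Tab archive writer/reader: conventions, round-trips, completeness."""

import pytest

from miappe.isatab import (
    IsaTabParseError,
    IsaTabWriteError,
    covered_model_paths,
    read_isatab,
    write_isatab,
)
from miappe.model import (
    BiologicalMaterial,
    ObservationUnit,
    OntologyRef,
    build_dataset,
    canonical,
)
from miappe import synth

from conftest import make_minimal_investigation, model_field_census


def _block(lines, header):
    """Rows of one investigation-file block, as label -> values."""
    rows, active = {}, False
    for line in lines:
        cells = line.split("\t")
        if cells[0] in {"INVESTIGATION", "INVESTIGATION PUBLICATIONS",
                        "INVESTIGATION CONTACTS", "STUDY", "STUDY FACTORS",
                        "STUDY ASSAYS", "STUDY PROTOCOLS", "STUDY CONTACTS"}:
            active = cells[0] == header
            continue
        if active:
            rows.setdefault(cells[0], []).append([c for c in cells[1:] if c])
    return rows


class TestWriterConventions:
    def test_environment_parameters_live_on_the_growth_protocol(
            self, field_network, tmp_path):
        write_isatab(field_network, tmp_path)
        lines = (tmp_path / "i_investigation.txt").read_text().splitlines()
        protocols = _block(lines, "STUDY PROTOCOLS")
        names = protocols["Study Protocol Name"][0]
        types = protocols["Study Protocol Type"][0]
        growth = types.index("Growth")
        assert names[growth] == "Growth"
        params = protocols["Study Protocol Parameters Name"][0][growth]
        assert len(params.split("; ")) == 2  # the two study parameters

    def test_one_assay_file_per_data_file(self, field_network, tmp_path):
        archive = write_isatab(field_network, tmp_path)
        n_data_files = sum(len(s.data_files)
                           for s in field_network.investigation.studies)
        assert len(archive.assay_files) == n_data_files
        for a_file in archive.assay_files:
            rows = (tmp_path / a_file).read_text().splitlines()
            header = rows[0].split("\t")
            col = header.index("Raw Data File")
            links = {row.split("\t")[col] for row in rows[1:]}
            assert len(links) == 1  # each assay references exactly one file

    def test_event_type_protocols_and_events_file_rows(self, field_network,
                                                       tmp_path):
        archive = write_isatab(field_network, tmp_path)
        study = field_network.investigation.studies[0]
        lines = (tmp_path / "i_investigation.txt").read_text().splitlines()
        protocols = _block(lines, "STUDY PROTOCOLS")
        event_protocols = [
            t for t in protocols["Study Protocol Type"][0] if t == "Event"]
        n_types = len({e.type.label for e in study.events})
        assert len(event_protocols) == n_types  # one protocol per type
        ev_rows = (tmp_path / archive.events_files[0]) \
            .read_text().splitlines()
        assert len(ev_rows) - 1 == len(study.events)  # one row per instance

    def test_without_samples_assays_link_units_directly(self, tmp_path):
        dataset = synth.generate("forest_geo", seed=1)
        archive = write_isatab(dataset, tmp_path)
        header = (tmp_path / archive.assay_files[0]) \
            .read_text().splitlines()[0]
        assert "Extract Name" not in header
        assert header.split("\t")[0] == "Sample Name"

    def test_invalid_dataset_is_refused(self):
        inv = make_minimal_investigation()
        inv.studies = []
        with pytest.raises(IsaTabWriteError, match="validation error"):
            write_isatab(build_dataset(inv), "/tmp/never-written")

    def test_tab_in_value_is_rejected_not_quoted(self, tmp_path):
        inv = make_minimal_investigation()
        inv.title = "has\ttab"
        with pytest.raises(Exception, match="tab"):
            write_isatab(build_dataset(inv), tmp_path)


class TestRoundTrip:
    @pytest.mark.parametrize("scenario", synth.SCENARIOS)
    def test_read_write_identity(self, scenario, tmp_path):
        for seed in range(5):
            dataset = synth.generate(scenario, seed=seed)
            root = tmp_path / f"{scenario}-{seed}"
            write_isatab(dataset, root)
            assert canonical(read_isatab(root)) == canonical(dataset)

    def test_missing_referenced_events_file_is_an_error(self, field_network,
                                                        tmp_path):
        archive = write_isatab(field_network, tmp_path)
        (tmp_path / archive.events_files[0]).unlink()
        with pytest.raises(IsaTabParseError,
                           match=archive.events_files[0]):
            read_isatab(tmp_path)

    def test_directory_without_investigation_file(self, tmp_path):
        with pytest.raises(IsaTabParseError, match="investigation"):
            read_isatab(tmp_path)


class TestHandWrittenArchive:
    """A minimal archive authored by hand; the expected dataset is built
    manually, independent of the writer."""

    def _write(self, root):
        (root / "i_investigation.txt").write_text(
            "INVESTIGATION\n"
            "Investigation Identifier\tINV-H\n"
            "Investigation Title\tHand archive\n"
            "Comment[MIAPPE: License]\tCC0\n"
            "Comment[MIAPPE: MIAPPE version]\t1.1\n"
            "INVESTIGATION PUBLICATIONS\n"
            "INVESTIGATION CONTACTS\n"
            "STUDY\n"
            "Study Identifier\tSH1\n"
            "Study Title\tHand study\n"
            "Study File Name\ts_SH1.txt\n"
            "Comment[MIAPPE: Geographic location (country)]\tSpain\n"
            "Comment[MIAPPE: Observation unit level hierarchy]\t"
            "study > plot\n"
            "Comment[MIAPPE: Data file link]\traw.tsv\n"
            "Comment[MIAPPE: Data file description]\traw data\n"
            "Comment[MIAPPE: Data file version]\t1\n"
            "STUDY FACTORS\n"
            "STUDY ASSAYS\n"
            "Study Assay File Name\ta_SH1_1.txt\n"
            "STUDY PROTOCOLS\n"
            "Study Protocol Name\tGrowth\tPhenotyping\n"
            "Study Protocol Type\tGrowth\tPhenotyping\n"
            "STUDY CONTACTS\n")
        (root / "s_SH1.txt").write_text(
            "Source Name\tCharacteristics[Organism]\tSample Name\t"
            "Comment[MIAPPE: Observation unit level]\n"
            "BMH\tVitis vinifera\tOUH\tplot\n")
        (root / "a_SH1_1.txt").write_text(
            "Sample Name\tProtocol REF\tRaw Data File\n"
            "OUH\tPhenotyping\traw.tsv\n")

    def test_reads_to_expected_dataset(self, tmp_path):
        self._write(tmp_path)
        dataset = read_isatab(tmp_path)
        inv = dataset.investigation
        assert inv.id == "INV-H"
        assert inv.license == "CC0"
        study = inv.studies[0]
        assert study.location.country == "Spain"
        assert study.observation_unit_level_hierarchy == ["study", "plot"]
        assert [bm.id for bm in study.biological_materials] == ["BMH"]
        assert study.biological_materials[0].organism == OntologyRef(
            label="Vitis vinifera")
        assert [ou.id for ou in study.observation_units] == ["OUH"]
        unit = study.observation_units[0]
        assert unit.level == "plot"
        assert unit.biological_material_id == "BMH"
        assert study.data_files[0].link == "raw.tsv"


class TestCompleteness:
    def test_every_model_field_has_a_column(self):
        census = model_field_census()
        covered = covered_model_paths()
        for sheet, paths in census.items():
            missing = paths - covered[sheet]
            assert not missing, f"{sheet}: unmapped fields {missing}"
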