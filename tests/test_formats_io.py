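"""Workbook readers/writers and the sample store."""

import pytest
from openpyxl import Workbook

from forenstr import fixtures as fx
from forenstr.formats_io import (
    ConsistencyError,
    FrequencyTable,
    ImportOutcome,
    LocusGenotype,
    PersonMetadata,
    ReportFormatError,
    SampleRecord,
    SampleStore,
    SequenceAllele,
    import_sample,
    read_alignment_export,
    read_core_loci,
    read_frequency_tables,
    read_motif_specs,
    read_personal_data,
    read_sample_report,
    write_alignment_export,
)
from forenstr.repeat_motif import Orientation, align_cohort


# ---------------------------------------------------------------------------
# sample detail reports


def _tpox_report(tmp_path, rows, genotype=("8", "11")):
    wb = Workbook()
    ws = wb.create_sheet("Autosomal STRs")
    wb.remove(wb["Sheet"])
    ws.append(["Sample ID", "S001"])
    ws.append([])
    ws.append(["Locus", "Allele 1", "Allele 2"])
    ws.append(["TPOX", *genotype])
    ws.append([])
    ws.append(["Locus", "Allele", "Typed Allele", "Reads", "Sequence"])
    for r in rows:
        ws.append(r)
    path = tmp_path / "report.xlsx"
    wb.save(path)
    return path


def test_typed_rows_drive_the_genotype(tmp_path):
    path = _tpox_report(
        tmp_path,
        [
            ["TPOX", "8", "Yes", 400, "AATG" * 8],
            ["TPOX", "11", "Yes", 350, "AATG" * 11],
            ["TPOX", "9", "No", 20, "AATG" * 9],
        ],
    )
    rec = read_sample_report(path)
    assert rec.sample_id == "S001"
    assert rec.genotypes["TPOX"].alleles == ("8", "11")
    assert rec.typed_labels("TPOX") == ["8", "11"]
    assert sum(1 for sa in rec.sequence_alleles if not sa.typed) == 1


def test_contradicting_typed_rows_raise_naming_the_locus(tmp_path):
    path = _tpox_report(
        tmp_path,
        [
            ["TPOX", "8", "Yes", 400, "AATG" * 8],
            ["TPOX", "9", "Yes", 350, "AATG" * 9],
        ],
    )
    with pytest.raises(ConsistencyError, match="TPOX"):
        read_sample_report(path)


def test_report_without_str_sheets_rejected(tmp_path):
    wb = Workbook()
    wb.active.title = "Settings"
    path = tmp_path / "empty.xlsx"
    wb.save(path)
    with pytest.raises(ReportFormatError, match="empty.xlsx"):
        read_sample_report(path)


def test_figure_and_unknown_sheets_are_ignored(tmp_path):
    path = _tpox_report(tmp_path, [["TPOX", "8", "Yes", 100, "AATG" * 8],
                                   ["TPOX", "11", "Yes", 90, "AATG" * 11]])
    from openpyxl import load_workbook

    wb = load_workbook(path)
    wb.create_sheet("Autosomal STR Figure").append(["junk"])
    wb.create_sheet("Settings").append(["junk"])
    wb.save(path)
    rec = read_sample_report(path)
    assert set(rec.genotypes) == {"TPOX"}


def test_mock_report_round_trip(small_cohort, tmp_path):
    _, records, _ = small_cohort
    for record in records[:3]:
        path = tmp_path / f"{record.sample_id}.xlsx"
        fx.write_mock_report(record, path)
        back = read_sample_report(path)
        assert back.sample_id == record.sample_id
        assert back.year == record.year
        assert back.genotypes == record.genotypes
        assert sorted(back.sequence_alleles, key=lambda s: (s.locus, s.allele_label, s.sequence)) == sorted(
            record.sequence_alleles, key=lambda s: (s.locus, s.allele_label, s.sequence)
        )
        assert sorted(back.isnps, key=lambda s: s.locus) == sorted(record.isnps, key=lambda s: s.locus)


def test_flanked_sequences_survive_parsing_unmodified(small_cohort, tmp_path):
    _, records, _ = small_cohort
    record = next(r for r in records if "D1S1656" in r.genotypes)
    path = tmp_path / "flank.xlsx"
    fx.write_mock_report(record, path)
    back = read_sample_report(path)
    seqs = [sa.sequence for sa in back.sequence_alleles if sa.locus == "D1S1656" and sa.typed]
    assert all(s.startswith("CACA") and s.endswith("TGACACA") for s in seqs)


# ---------------------------------------------------------------------------
# personal data


def test_personal_data_blank_cells_become_absent(tmp_path):
    wb = Workbook()
    ws = wb.active
    ws.append(["Sample ID", "Province", "Region", "Country", "Race"])
    ws.append(["S001", "Bangkok", "Central", "Thailand", "Thai"])
    ws.append(["S002", "", "North", "Thailand", ""])
    ws.append(["S002", "Phuket", "South", "Thailand", "Thai"])
    path = tmp_path / "people.xlsx"
    wb.save(path)
    people = read_personal_data(path)
    assert people[0] == PersonMetadata("S001", "Bangkok", "Central", "Thailand", "Thai")
    assert people[1].province is None and people[1].race is None
    assert len(people) == 3  # duplicates preserved; de-duplication is import's job


def test_personal_data_requires_sample_id_column(tmp_path):
    wb = Workbook()
    wb.active.append(["Province", "Country"])
    path = tmp_path / "bad.xlsx"
    wb.save(path)
    with pytest.raises(ReportFormatError):
        read_personal_data(path)


# ---------------------------------------------------------------------------
# motif specs


def test_motif_spec_round_trip(tmp_path, motif_specs):
    path = tmp_path / "motifs.xlsx"
    fx.write_motif_specs(motif_specs, path)
    back = read_motif_specs(path)
    assert back == motif_specs


def test_motif_spec_rows(tmp_path):
    wb = Workbook()
    ws = wb.active
    ws.append(["Locus", "Repeat Motif", "Allele", "Orientation"])
    ws.append(["CSF1PO", "[ATCT]n", "Default", "Reverse"])
    ws.append(["D2S441", "[TCTA]n TCT", "10.3", "Forward"])
    path = tmp_path / "m.xlsx"
    wb.save(path)
    specs = read_motif_specs(path)
    assert specs[0].locus == "CSF1PO" and specs[0].orientation is Orientation.REVERSE
    assert specs[0].allele_scope == "Default"
    assert specs[1].allele_scope == "10.3"


@pytest.mark.parametrize(
    "row, message",
    [
        (["CSF1PO", "[ATCT", "Default", "Forward"], "bad motif"),
        (["CSF1PO", "[ATCT]n", "Default", "sideways"], "orientation"),
    ],
)
def test_motif_spec_errors(tmp_path, row, message):
    wb = Workbook()
    ws = wb.active
    ws.append(["Locus", "Repeat Motif", "Allele", "Orientation"])
    ws.append(row)
    path = tmp_path / "m.xlsx"
    wb.save(path)
    with pytest.raises(ReportFormatError, match=message):
        read_motif_specs(path)


# ---------------------------------------------------------------------------
# frequency tables


def _one_country_workbook(tmp_path, freq=0.5):
    wb = Workbook()
    ws = wb.active
    ws.append(["TPOX"])
    ws.append(["Allele", "Frequency"])
    ws.append(["8", freq])
    ws.append(["11", 0.5])
    path = tmp_path / "freq.xlsx"
    wb.save(path)
    return path


def test_one_country_layout(tmp_path):
    table = read_frequency_tables(_one_country_workbook(tmp_path), "XX")
    assert table.freq("XX", "TPOX", "8") == 0.5
    assert table.freq("XX", "TPOX", "11") == 0.5


def test_frequency_out_of_range_rejected(tmp_path):
    path = _one_country_workbook(tmp_path, freq=1.2)
    with pytest.raises(ReportFormatError, match="TPOX"):
        read_frequency_tables(path, "XX")


def test_layouts_agree_on_the_same_logical_table(tmp_path):
    table = FrequencyTable()
    for allele, p in [("8", 0.4), ("9", 0.35), ("11", 0.25)]:
        table.set("Thailand", "TPOX", allele, p)
    for allele, p in [("14", 0.6), ("15", 0.4)]:
        table.set("Thailand", "D1S1656", allele, p)
    all_path = tmp_path / "all.xlsx"
    one_path = tmp_path / "one.xlsx"
    fx.write_frequency_tables(table, all_path)
    fx.write_frequency_tables(table, one_path, country="Thailand")
    via_all = read_frequency_tables(all_path, "all")
    via_one = read_frequency_tables(one_path, "Thailand")
    assert via_all.data == via_one.data == table.data


def test_all_countries_layout_covers_every_country(tmp_path):
    table = FrequencyTable()
    for country in ("Norway", "Thailand"):
        table.set(country, "TPOX", "8", 0.5)
        table.set(country, "TPOX", "11", 0.5)
        table.set(country, "FGA", "22", 1.0)
    path = tmp_path / "all.xlsx"
    fx.write_frequency_tables(table, path)
    back = read_frequency_tables(path, "all")
    assert back.countries() == ["Norway", "Thailand"]
    for c in back.countries():
        assert back.loci(c) == ["FGA", "TPOX"]


def test_truncated_table_warns_but_loads(tmp_path):
    wb = Workbook()
    ws = wb.active
    ws.append(["TPOX"])
    ws.append(["Allele", "Frequency"])
    ws.append(["8", 0.9])
    ws.append(["11", 0.4])
    path = tmp_path / "over.xlsx"
    wb.save(path)
    with pytest.warns(UserWarning, match="sum"):
        table = read_frequency_tables(path, "XX")
    assert table.freq("XX", "TPOX", "11") == 0.4


# ---------------------------------------------------------------------------
# core loci


def test_core_loci_defaults_and_country_rows(tmp_path):
    path = tmp_path / "core.xlsx"
    fx.write_core_loci(
        ["FGA", "TH01", "TPOX", "vWA"], {"ABC": ["FGA", "TPOX", "TPOX"]}, path
    )
    core = read_core_loci(path)
    assert core.defaults == {"FGA", "TH01", "TPOX", "vWA"}
    assert core.by_country == {"ABC": {"FGA", "TPOX"}}  # duplicate row collapsed


def test_empty_core_loci_file_rejected(tmp_path):
    wb = Workbook()
    wb.active.append(["Locus", "Country"])
    path = tmp_path / "core.xlsx"
    wb.save(path)
    with pytest.raises(ReportFormatError):
        read_core_loci(path)


# ---------------------------------------------------------------------------
# alignment export


def test_alignment_export_round_trip(small_cohort, motif_specs, tmp_path):
    _, records, _ = small_cohort
    rows = align_cohort(records[:5], motif_specs).rows
    path = tmp_path / "export.xlsx"
    write_alignment_export(rows, path)
    back = read_alignment_export(path)
    assert back == [(r.sample_id, r.year, r.allele, r.rendered, r.sequence) for r in rows]
    with pytest.raises(ValueError):
        write_alignment_export([], tmp_path / "empty.xlsx")


# ---------------------------------------------------------------------------
# sample store / import


def _record(sid, allele="8"):
    rec = SampleRecord(sample_id=sid)
    rec.genotypes["TPOX"] = LocusGenotype("TPOX", (allele, allele))
    return rec


def test_import_cancel_keeps_first_version(tmp_path):
    store = SampleStore(tmp_path / "store")
    assert import_sample(store, _record("S001", "8")).status == "imported"
    outcome = import_sample(store, _record("S001", "9"), on_duplicate="cancel")
    assert outcome == ImportOutcome("S001", "conflict")
    assert store.get("S001").genotypes["TPOX"].alleles == ("8", "8")


def test_import_overwrite_replaces(tmp_path):
    store = SampleStore(tmp_path / "store")
    import_sample(store, _record("S001", "8"))
    outcome = import_sample(store, _record("S001", "9"), on_duplicate="overwrite")
    assert outcome.status == "overwritten"
    assert store.get("S001").genotypes["TPOX"].alleles == ("9", "9")


def test_store_persists_and_reloads(tmp_path, small_cohort):
    _, records, people = small_cohort
    root = tmp_path / "store"
    store = SampleStore(root)
    for rec in records[:4]:
        import_sample(store, rec)
    store.add_metadata(people[:4])
    reloaded = SampleStore(root)
    assert len(reloaded) == 4
    assert reloaded.get(records[0].sample_id).genotypes == records[0].genotypes
    assert reloaded.metadata[people[0].sample_id] == people[0]


def test_import_distinct_ids_coexist():
    store = SampleStore()
    import_sample(store, _record("S001"))
    import_sample(store, _record("S002"))
    assert len(store) == 2
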