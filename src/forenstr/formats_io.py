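"""Workbook I/O for sequencing-based STR sample reports and reference tables.

Everything the toolkit reads or writes is an XLSX workbook, mirroring how
forensic laboratories exchange this data:

* **sample detail reports** — one workbook per donor with sheets
  ``Autosomal STRs`` / ``Y STRs`` / ``X STRs`` (each holding a length-based
  genotype table and a sequence-based allele table) and optionally ``iSNPs``;
  per-chromosome "Figure" sheets and the run "Settings" sheet are ignored;
* **personal metadata** (sample ID, Province, Region, Country, Race);
* **reference repeat-motif patterns** (locus, bracketed pattern, allele
  scope, orientation);
* **length-based allele-frequency tables**, in an all-countries layout
  (stacked per-locus tables whose columns are countries) or a one-country
  layout (a single frequency column, the country supplied by the caller);
* **core-loci panels** (locus, country) defining profile-search requirements;
* the five-column **pattern-alignment export**.

Tables inside a sheet are located by scanning for their header rows rather
than by fixed cell addresses, and the header labels are configurable, so the
readers tolerate layout drift across report versions.
"""

from __future__ import annotations

import json
import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from openpyxl import Workbook, load_workbook

from .repeat_motif import (
    MotifParseError,
    MotifSpec,
    Orientation,
    parse_bracket_notation,
)

__all__ = [
    "ReportFormatError",
    "ConsistencyError",
    "SequenceAllele",
    "LocusGenotype",
    "ISNPGenotype",
    "SampleRecord",
    "PersonMetadata",
    "KitDefinition",
    "CoreLoci",
    "FrequencyTable",
    "SampleStore",
    "ImportOutcome",
    "STR_SHEETS",
    "read_sample_report",
    "read_personal_data",
    "read_motif_specs",
    "read_frequency_tables",
    "read_core_loci",
    "write_alignment_export",
    "read_alignment_export",
    "import_sample",
]

_DNA_RE = re.compile(r"^[ACGT]+$")
_ALLELE_RE = re.compile(r"^[0-9]+(\.[0-9])?$")

STR_SHEETS: dict[str, str] = {
    "Autosomal STRs": "autosomal",
    "Y STRs": "Y",
    "X STRs": "X",
}


class ReportFormatError(ValueError):
    """A workbook does not have the shape the reader expects."""


class ConsistencyError(ValueError):
    """Parsed report content contradicts itself (typed alleles vs genotypes)."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class SequenceAllele:
    """One row of a sequence-based allele table."""

    locus: str
    allele_label: str
    sequence: str
    read_count: int
    typed: bool

    def __post_init__(self) -> None:
        if not _ALLELE_RE.match(self.allele_label):
            raise ValueError(f"bad allele label {self.allele_label!r} at {self.locus}")
        if self.read_count < 0:
            raise ValueError(f"negative read count at {self.locus}")
        if self.typed and not self.sequence:
            raise ValueError(f"typed allele with empty sequence at {self.locus}")
        if self.sequence and not _DNA_RE.match(self.sequence):
            raise ValueError(f"non-ACGT sequence at {self.locus}: {self.sequence!r}")


def _allele_num(label: str) -> float:
    return float(label)


@dataclass(frozen=True)
class LocusGenotype:
    """A length-based genotype: one (haploid) or two (diploid) allele labels.

    Diploid alleles are stored in non-decreasing numeric order so unordered
    comparisons are just equality.
    """

    locus: str
    alleles: tuple[str, ...]
    chromosome_class: str = "autosomal"  # autosomal | X | Y

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError(f"genotype at {self.locus} must have 1 or 2 alleles")
        for a in self.alleles:
            if not _ALLELE_RE.match(a):
                raise ValueError(f"bad allele label {a!r} at {self.locus}")
        ordered = tuple(sorted(self.alleles, key=_allele_num))
        object.__setattr__(self, "alleles", ordered)

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    @property
    def heterozygous(self) -> bool:
        return self.ploidy == 2 and self.alleles[0] != self.alleles[1]


@dataclass(frozen=True)
class ISNPGenotype:
    """An identity-informative SNP call with per-allele read coverage."""

    locus: str
    alleles: tuple[str, ...]
    coverage: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError(f"iSNP {self.locus} must carry 1 or 2 alleles")
        for a in self.alleles:
            if a not in "ACGT" or len(a) != 1:
                raise ValueError(f"bad SNP allele {a!r} at {self.locus}")
        if any(v < 0 for v in self.coverage.values()):
            raise ValueError(f"negative coverage at {self.locus}")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))
        object.__setattr__(self, "coverage", dict(self.coverage))

    @property
    def genotype_label(self) -> str:
        return "".join(self.alleles) if len(self.alleles) == 2 else self.alleles[0] * 2


@dataclass
class SampleRecord:
    """One donor's parsed report: genotypes, sequence alleles and iSNPs."""

    sample_id: str
    genotypes: dict[str, LocusGenotype] = field(default_factory=dict)
    sequence_alleles: list[SequenceAllele] = field(default_factory=list)
    isnps: list[ISNPGenotype] = field(default_factory=list)
    year: Optional[int] = None

    def typed_labels(self, locus: str) -> list[str]:
        """Sorted multiset of typed sequence-allele labels at a locus."""
        return sorted(
            (sa.allele_label for sa in self.sequence_alleles if sa.locus == locus and sa.typed),
            key=_allele_num,
        )

    def check_typed_allele_law(self) -> None:
        """Genotypes must equal the multiset of typed sequence alleles per locus."""
        loci_with_rows = {sa.locus for sa in self.sequence_alleles}
        for locus, gt in self.genotypes.items():
            if locus not in loci_with_rows:
                continue
            typed = self.typed_labels(locus)
            if typed != list(gt.alleles):
                raise ConsistencyError(
                    f"locus {locus}: typed sequence alleles {typed} contradict "
                    f"length-based genotype {list(gt.alleles)}"
                )

    # JSON round-trip used by SampleStore ------------------------------------
    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "year": self.year,
            "genotypes": [
                {"locus": g.locus, "alleles": list(g.alleles), "chromosome_class": g.chromosome_class}
                for g in self.genotypes.values()
            ],
            "sequence_alleles": [
                {
                    "locus": sa.locus,
                    "allele_label": sa.allele_label,
                    "sequence": sa.sequence,
                    "read_count": sa.read_count,
                    "typed": sa.typed,
                }
                for sa in self.sequence_alleles
            ],
            "isnps": [
                {"locus": s.locus, "alleles": list(s.alleles), "coverage": dict(s.coverage)}
                for s in self.isnps
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SampleRecord":
        rec = cls(sample_id=d["sample_id"], year=d.get("year"))
        for g in d.get("genotypes", []):
            rec.genotypes[g["locus"]] = LocusGenotype(
                g["locus"], tuple(g["alleles"]), g.get("chromosome_class", "autosomal")
            )
        rec.sequence_alleles = [SequenceAllele(**sa) for sa in d.get("sequence_alleles", [])]
        rec.isnps = [
            ISNPGenotype(s["locus"], tuple(s["alleles"]), s.get("coverage", {}))
            for s in d.get("isnps", [])
        ]
        return rec


@dataclass(frozen=True)
class PersonMetadata:
    sample_id: str
    province: Optional[str] = None
    region: Optional[str] = None
    country: Optional[str] = None
    race: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


@dataclass(frozen=True)
class KitDefinition:
    """A named typing panel and the loci it covers."""

    kit_name: str
    loci: frozenset[str]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("a kit must define at least one locus")
        object.__setattr__(self, "loci", frozenset(self.loci))


@dataclass
class CoreLoci:
    """Per-country core-locus panels plus the default panel.

    A country's *displayed* panel is the defaults unioned with its own loci;
    only the country's own loci are marked required in a profile search.
    """

    defaults: set[str]
    by_country: dict[str, set[str]]

    def panels(self) -> list[str]:
        return sorted(self.by_country)


@dataclass
class FrequencyTable:
    """country -> locus -> allele label -> length-based allele frequency."""

    data: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)

    def countries(self) -> list[str]:
        return sorted(self.data)

    def loci(self, country: str) -> list[str]:
        return sorted(self.data.get(country, {}))

    def freq(self, country: str, locus: str, allele: str) -> Optional[float]:
        return self.data.get(country, {}).get(locus, {}).get(allele)

    def set(self, country: str, locus: str, allele: str, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError(
                f"frequency out of [0,1] at {country}/{locus}/{allele}: {value}"
            )
        self.data.setdefault(country, {}).setdefault(locus, {})[allele] = value


# ---------------------------------------------------------------------------
# Low-level sheet helpers


def _rows(ws) -> list[list]:
    return [list(r) for r in ws.iter_rows(values_only=True)]


def _norm(cell) -> str:
    return str(cell).strip() if cell is not None else ""


def _find_header(rows: list[list], required: Sequence[str], start: int = 0) -> Optional[int]:
    """Index of the first row at/after ``start`` containing every required label."""
    req = [r.lower() for r in required]
    for idx in range(start, len(rows)):
        labels = [_norm(c).lower() for c in rows[idx]]
        if all(r in labels for r in req):
            return idx
    return None


def _col(rows: list[list], header_idx: int, label: str) -> Optional[int]:
    labels = [_norm(c).lower() for c in rows[header_idx]]
    try:
        return labels.index(label.lower())
    except ValueError:
        return None


def _cell_str(row: list, col: Optional[int]) -> str:
    if col is None or col >= len(row):
        return ""
    return _norm(row[col])


def _fmt_allele(value) -> str:
    """Normalize a workbook cell to an allele label string (8, 10.3, ...)."""
    if value is None:
        return ""
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value).strip()


# ---------------------------------------------------------------------------
# Sample detail report


def read_sample_report(
    workbook_path,
    *,
    sample_id: Optional[str] = None,
    genotype_labels: Sequence[str] = ("Allele 1", "Allele 2"),
    validate: bool = True,
) -> SampleRecord:
    """Parse a sample detail report workbook into a :class:`SampleRecord`.

    At least one of the three STR sheets must be present.  Each STR sheet
    holds a length-based genotype table (``Locus`` + allele columns; diploid
    genotypes may also appear comma-joined in a single ``Genotype`` column)
    and a sequence-based allele table (``Locus``/``Allele``/``Typed Allele``/
    ``Reads``/``Sequence``); only rows whose Typed Allele cell is "Yes"
    contribute to genotypes.  When ``validate`` is true the typed-allele law
    is enforced and violations raise :class:`ConsistencyError`.
    """
    path = Path(workbook_path)
    wb = load_workbook(path, data_only=True, read_only=True)
    present = [name for name in STR_SHEETS if name in wb.sheetnames]
    if not present:
        raise ReportFormatError(
            f"{path.name}: none of the STR sheets {sorted(STR_SHEETS)} found"
        )

    record = SampleRecord(sample_id=sample_id or path.stem)
    for sheet_name in present:
        chrom = STR_SHEETS[sheet_name]
        rows = _rows(wb[sheet_name])
        _parse_header_cells(rows, record)
        _parse_genotype_table(rows, record, chrom, genotype_labels)
        _parse_sequence_table(rows, record)

    if "iSNPs" in wb.sheetnames:
        _parse_isnp_sheet(_rows(wb["iSNPs"]), record)
    wb.close()

    if validate:
        record.check_typed_allele_law()
    return record


def _parse_header_cells(rows: list[list], record: SampleRecord) -> None:
    for row in rows[:10]:
        for j, cell in enumerate(row):
            label = _norm(cell).lower()
            if label == "sample id" and j + 1 < len(row) and _norm(row[j + 1]):
                record.sample_id = _norm(row[j + 1])
            elif label == "sample year" and j + 1 < len(row) and _norm(row[j + 1]):
                try:
                    record.year = int(float(_norm(row[j + 1])))
                except ValueError:
                    pass


def _parse_genotype_table(
    rows: list[list], record: SampleRecord, chrom: str, genotype_labels: Sequence[str]
) -> None:
    hdr = _find_header(rows, ["Locus", genotype_labels[0]])
    single_col = False
    if hdr is None:
        hdr = _find_header(rows, ["Locus", "Genotype"])
        single_col = True
    if hdr is None:
        raise ReportFormatError(f"no length-based genotype table found ({chrom} sheet)")
    locus_c = _col(rows, hdr, "Locus")
    if single_col:
        geno_c = _col(rows, hdr, "Genotype")
        allele_cols = []
    else:
        allele_cols = [c for lbl in genotype_labels if (c := _col(rows, hdr, lbl)) is not None]
    for row in rows[hdr + 1 :]:
        locus = _cell_str(row, locus_c)
        if not locus:
            break  # blank row ends the table
        if single_col:
            raw = _cell_str(row, geno_c)
            labels = [s.strip() for s in raw.split(",") if s.strip()]
        else:
            labels = [
                _fmt_allele(row[c]) for c in allele_cols if c < len(row) and _norm(row[c])
            ]
        if not labels:
            continue  # untyped locus
        record.genotypes[locus] = LocusGenotype(locus, tuple(labels), chrom)


def _parse_sequence_table(rows: list[list], record: SampleRecord) -> None:
    hdr = _find_header(rows, ["Typed Allele", "Reads"])
    if hdr is None:
        return  # reports may omit sequence detail for a chromosome
    locus_c = _col(rows, hdr, "Locus")
    allele_c = _col(rows, hdr, "Allele")
    typed_c = _col(rows, hdr, "Typed Allele")
    reads_c = _col(rows, hdr, "Reads")
    seq_c = _col(rows, hdr, "Sequence")
    for row in rows[hdr + 1 :]:
        locus = _cell_str(row, locus_c)
        if not locus:
            break
        sequence = _cell_str(row, seq_c).upper()
        if sequence and not _DNA_RE.match(sequence):
            raise ReportFormatError(f"non-ACGT sequence at locus {locus}: {sequence!r}")
        record.sequence_alleles.append(
            SequenceAllele(
                locus=locus,
                allele_label=_fmt_allele(row[allele_c] if allele_c is not None else None),
                sequence=sequence,
                read_count=int(float(_cell_str(row, reads_c) or 0)),
                typed=_cell_str(row, typed_c).lower() == "yes",
            )
        )


def _parse_isnp_sheet(rows: list[list], record: SampleRecord) -> None:
    geno_hdr = _find_header(rows, ["Locus", "Genotype"])
    if geno_hdr is None:
        return
    locus_c = _col(rows, geno_hdr, "Locus")
    geno_c = _col(rows, geno_hdr, "Genotype")
    calls: dict[str, tuple[str, ...]] = {}
    for row in rows[geno_hdr + 1 :]:
        locus = _cell_str(row, locus_c)
        if not locus:
            break
        geno = _cell_str(row, geno_c).upper().replace("/", "")
        if geno:
            calls[locus] = tuple(geno)
    cov_hdr = _find_header(rows, ["Locus", "Allele", "Reads"], start=(geno_hdr + 1))
    coverage: dict[str, dict[str, int]] = {}
    if cov_hdr is not None:
        locus_c = _col(rows, cov_hdr, "Locus")
        allele_c = _col(rows, cov_hdr, "Allele")
        reads_c = _col(rows, cov_hdr, "Reads")
        for row in rows[cov_hdr + 1 :]:
            locus = _cell_str(row, locus_c)
            if not locus:
                break
            coverage.setdefault(locus, {})[_cell_str(row, allele_c).upper()] = int(
                float(_cell_str(row, reads_c) or 0)
            )
    for locus, alleles in calls.items():
        record.isnps.append(ISNPGenotype(locus, alleles, coverage.get(locus, {})))


# ---------------------------------------------------------------------------
# Personal metadata


def read_personal_data(workbook_path) -> list[PersonMetadata]:
    """Read a personal-metadata workbook: one row per person, blank cells absent.

    Duplicate sample IDs are returned as-is; de-duplication policy belongs to
    the import step.
    """
    rows = _first_sheet_rows(workbook_path)
    hdr = _find_header(rows, ["Sample ID"])
    if hdr is None:
        raise ReportFormatError(f"{Path(workbook_path).name}: no 'Sample ID' column found")
    cols = {
        name: _col(rows, hdr, name)
        for name in ("Sample ID", "Province", "Region", "Country", "Race")
    }
    people = []
    for row in rows[hdr + 1 :]:
        sid = _cell_str(row, cols["Sample ID"])
        if not sid:
            continue
        people.append(
            PersonMetadata(
                sample_id=sid,
                province=_cell_str(row, cols["Province"]) or None,
                region=_cell_str(row, cols["Region"]) or None,
                country=_cell_str(row, cols["Country"]) or None,
                race=_cell_str(row, cols["Race"]) or None,
            )
        )
    return people


def _first_sheet_rows(workbook_path) -> list[list]:
    wb = load_workbook(workbook_path, data_only=True, read_only=True)
    rows = _rows(wb[wb.sheetnames[0]])
    wb.close()
    return rows


# ---------------------------------------------------------------------------
# Reference repeat-motif specifications


def read_motif_specs(workbook_path) -> list[MotifSpec]:
    """Read a reference repeat-motif workbook into :class:`MotifSpec` rows.

    Expected columns: locus, the bracketed repeat-motif pattern (forward
    strand), the allele scope ("Default" or a specific label), and the
    orientation (forward/reverse, case-insensitive).
    """
    rows = _first_sheet_rows(workbook_path)
    hdr = _find_header(rows, ["Locus", "Repeat Motif", "Allele", "Orientation"])
    if hdr is None:
        raise ReportFormatError(
            f"{Path(workbook_path).name}: motif spec header "
            "(Locus/Repeat Motif/Allele/Orientation) not found"
        )
    locus_c = _col(rows, hdr, "Locus")
    motif_c = _col(rows, hdr, "Repeat Motif")
    allele_c = _col(rows, hdr, "Allele")
    orient_c = _col(rows, hdr, "Orientation")
    specs = []
    for i, row in enumerate(rows[hdr + 1 :], start=hdr + 2):
        locus = _cell_str(row, locus_c)
        if not locus:
            continue
        pattern = _cell_str(row, motif_c)
        try:
            blocks = parse_bracket_notation(pattern)
        except MotifParseError as exc:
            raise ReportFormatError(f"row {i}: bad motif pattern {pattern!r}: {exc}") from exc
        orient_raw = _cell_str(row, orient_c).lower()
        if orient_raw not in ("forward", "reverse"):
            raise ReportFormatError(
                f"row {i}: orientation must be forward or reverse, got {orient_raw!r}"
            )
        specs.append(
            MotifSpec(
                locus=locus,
                blocks=tuple(blocks),
                allele_scope=_fmt_allele(row[allele_c] if allele_c is not None else None) or "Default",
                orientation=Orientation(orient_raw),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Allele-frequency tables


def read_frequency_tables(
    workbook_path, country_or_all: str = "all", *, sum_tolerance: float = 0.01
) -> FrequencyTable:
    """Read length-based allele frequencies.

    ``country_or_all="all"`` expects the stacked all-countries layout: each
    locus table starts with a row holding only the locus name, followed by a
    header row ``Allele | <country> | <country> ...``.  Any other value names
    the country for the one-country layout, whose header is
    ``Allele | Frequency``.

    A locus/country column summing to more than ``1 + sum_tolerance`` earns a
    warning entry (sources are sometimes truncated); frequencies outside
    [0, 1] are hard errors.
    """
    import warnings

    rows = _first_sheet_rows(workbook_path)
    table = FrequencyTable()
    all_countries = country_or_all.lower() == "all"

    i = 0
    while i < len(rows):
        non_empty = [(_norm(c)) for c in rows[i] if _norm(c)]
        if len(non_empty) != 1:
            i += 1
            continue
        locus = non_empty[0]
        if i + 1 >= len(rows):
            break
        header = [_norm(c) for c in rows[i + 1]]
        if not header or header[0].lower() != "allele":
            i += 1
            continue
        if all_countries:
            countries = [(j, c) for j, c in enumerate(header[1:], start=1) if c]
        else:
            freq_c = next((j for j, c in enumerate(header) if c.lower() == "frequency"), None)
            if freq_c is None:
                raise ReportFormatError(
                    f"locus {locus}: one-country layout needs a Frequency column"
                )
            countries = [(freq_c, country_or_all)]
        i += 2
        while i < len(rows):
            allele = _fmt_allele(rows[i][0] if rows[i] else None)
            if not allele:
                break
            for j, country in countries:
                raw = rows[i][j] if j < len(rows[i]) else None
                if raw is None or _norm(raw) == "":
                    continue
                value = float(raw)
                if not 0.0 <= value <= 1.0:
                    raise ReportFormatError(
                        f"frequency out of [0,1] at {locus}/{allele} for {country}: {value}"
                    )
                table.set(country, locus, allele, value)
            i += 1

    for country in table.countries():
        for locus in table.loci(country):
            total = sum(table.data[country][locus].values())
            if total > 1.0 + sum_tolerance:
                warnings.warn(
                    f"frequencies at {country}/{locus} sum to {total:.4f} > 1",
                    stacklevel=2,
                )
    if not table.data:
        raise ReportFormatError(f"{Path(workbook_path).name}: no locus tables found")
    return table


# ---------------------------------------------------------------------------
# Core loci


DEFAULT_PANEL = "Default"


def read_core_loci(workbook_path) -> CoreLoci:
    """Read a two-column (Locus, Country) core-loci workbook.

    Rows whose country is "Default" define the default panel shown for every
    country; duplicate rows collapse.
    """
    rows = _first_sheet_rows(workbook_path)
    hdr = _find_header(rows, ["Locus", "Country"])
    if hdr is None:
        raise ReportFormatError(
            f"{Path(workbook_path).name}: core loci file needs Locus and Country columns"
        )
    locus_c = _col(rows, hdr, "Locus")
    country_c = _col(rows, hdr, "Country")
    defaults: set[str] = set()
    by_country: dict[str, set[str]] = {}
    seen_any = False
    for row in rows[hdr + 1 :]:
        locus = _cell_str(row, locus_c)
        country = _cell_str(row, country_c)
        if not locus or not country:
            continue
        seen_any = True
        if country == DEFAULT_PANEL:
            defaults.add(locus)
        else:
            by_country.setdefault(country, set()).add(locus)
    if not seen_any:
        raise ReportFormatError(f"{Path(workbook_path).name}: core loci file is empty")
    return CoreLoci(defaults=defaults, by_country=by_country)


# ---------------------------------------------------------------------------
# Alignment export

EXPORT_COLUMNS = ("Sample ID", "Sample Year", "Allele", "Repeat Structure", "Sequence")


def write_alignment_export(results: Sequence, workbook_path) -> None:
    """Write alignment rows as the five-column export workbook.

    ``results`` are :class:`~forenstr.repeat_motif.AlignmentRow` objects (or
    anything exposing sample_id/year/allele/rendered/sequence).
    """
    if not results:
        raise ValueError("nothing to export")
    wb = Workbook()
    ws = wb.active
    ws.title = "Pattern Alignment"
    ws.append(list(EXPORT_COLUMNS))
    for row in results:
        ws.append(
            [
                row.sample_id,
                row.year if row.year is not None else "",
                row.allele,
                row.rendered,
                row.sequence,
            ]
        )
    wb.save(workbook_path)


def read_alignment_export(workbook_path) -> list[tuple]:
    """Read back an alignment export as a list of 5-tuples (round-trip check)."""
    rows = _first_sheet_rows(workbook_path)
    hdr = _find_header(rows, list(EXPORT_COLUMNS))
    if hdr is None:
        raise ReportFormatError(f"{Path(workbook_path).name}: not an alignment export")
    cols = [_col(rows, hdr, c) for c in EXPORT_COLUMNS]
    out = []
    for row in rows[hdr + 1 :]:
        if not _cell_str(row, cols[0]):
            break
        year = _cell_str(row, cols[1])
        out.append(
            (
                _cell_str(row, cols[0]),
                int(float(year)) if year else None,
                _fmt_allele(row[cols[2]]),
                _cell_str(row, cols[3]),
                _cell_str(row, cols[4]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Sample store


@dataclass(frozen=True)
class ImportOutcome:
    sample_id: str
    status: str  # imported | overwritten | conflict


class SampleStore:
    """A desk-scale sample repository: a directory of JSON records + an index.

    With ``root=None`` the store is purely in-memory; with a directory it
    persists each record as ``<sample_id>.json`` and keeps ``index.json``
    listing the stored IDs, replacing files atomically.
    """

    def __init__(self, root: Optional[os.PathLike] = None):
        self.root = Path(root) if root is not None else None
        self._records: dict[str, SampleRecord] = {}
        self.metadata: dict[str, PersonMetadata] = {}
        if self.root is not None:
            self.root.mkdir(parents=True, exist_ok=True)
            self._load()

    def _load(self) -> None:
        index = self.root / "index.json"
        if not index.exists():
            return
        payload = json.loads(index.read_text())
        for sid in payload.get("samples", []):
            rec_path = self.root / f"{sid}.json"
            if rec_path.exists():
                self._records[sid] = SampleRecord.from_dict(json.loads(rec_path.read_text()))
        for m in payload.get("metadata", []):
            self.metadata[m["sample_id"]] = PersonMetadata(**m)

    def _persist_record(self, record: SampleRecord) -> None:
        if self.root is None:
            return
        self._atomic_write(self.root / f"{record.sample_id}.json", json.dumps(record.to_dict()))
        self._write_index()

    def _write_index(self) -> None:
        payload = {
            "samples": sorted(self._records),
            "metadata": [
                {
                    "sample_id": m.sample_id,
                    "province": m.province,
                    "region": m.region,
                    "country": m.country,
                    "race": m.race,
                }
                for m in self.metadata.values()
            ],
        }
        self._atomic_write(self.root / "index.json", json.dumps(payload, indent=1))

    @staticmethod
    def _atomic_write(path: Path, text: str) -> None:
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._records

    def get(self, sample_id: str) -> Optional[SampleRecord]:
        return self._records.get(sample_id)

    def samples(self) -> list[SampleRecord]:
        return [self._records[sid] for sid in sorted(self._records)]

    def add_metadata(self, people: Iterable[PersonMetadata]) -> None:
        for p in people:
            self.metadata[p.sample_id] = p
        if self.root is not None:
            self._write_index()


def import_sample(
    store: SampleStore, record: SampleRecord, on_duplicate: str = "cancel"
) -> ImportOutcome:
    """Import a record; duplicates either cancel (store unchanged) or overwrite."""
    if on_duplicate not in ("cancel", "overwrite"):
        raise ValueError("on_duplicate must be 'cancel' or 'overwrite'")
    if record.sample_id in store:
        if on_duplicate == "cancel":
            return ImportOutcome(record.sample_id, "conflict")
        store._records[record.sample_id] = record
        store._persist_record(record)
        return ImportOutcome(record.sample_id, "overwritten")
    store._records[record.sample_id] = record
    store._persist_record(record)
    return ImportOutcome(record.sample_id, "imported")
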