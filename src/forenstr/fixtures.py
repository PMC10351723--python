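"""Seeded synthetic cohorts and mock sample-detail-report workbooks.

Every other module is testable offline against data produced here.  The
generator emulates what a sequencing-based STR panel reports for a cohort of
donors:

* per-locus length-based genotypes drawn from a stated allele-frequency
  vector — diploid loci pair alleles under Hardy-Weinberg (independent
  draws), with an optional inbreeding coefficient ``f`` that inflates
  homozygosity for power checks of the statistics;
* sequence-based alleles synthesized by expanding the locus motif to the
  allele's repeat count (fractional microvariants append that many leading
  motif bases), wrapped in optional flanking bases, reverse-complemented for
  reverse-orientation loci, with one typed row per genotype allele;
* iSNP genotypes with per-allele read coverage;
* personal metadata drawn from a province/region/country/race vocabulary.

The default spec mirrors a 125-donor demonstration cohort over a small
panel spanning autosomal, Y (haploid) and X (mixed-ploidy) loci.  Sex is
drawn per donor: males carry haploid X and Y genotypes, females diploid X
and no Y, so X loci come out mixed-ploidy at the cohort level.

``swap_anonymize`` reproduces the mock-data construction used for such
showcases: within each locus, genotypes are permuted across samples, each
genotype's sequence-based rows travelling with it, so every per-locus allele
and genotype multiset — hence every per-locus statistic — is unchanged while
no output row set belongs to a real donor.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from openpyxl import Workbook

from .formats_io import (
    FrequencyTable,
    ISNPGenotype,
    LocusGenotype,
    PersonMetadata,
    SampleRecord,
    SequenceAllele,
)
from .popstats import allele_frequencies
from .repeat_motif import MotifBlock, MotifSpec, Orientation, reverse_complement

__all__ = [
    "LocusSpec",
    "SNPSpec",
    "GeoVocabulary",
    "CohortSpec",
    "default_cohort_spec",
    "expand_allele",
    "generate_cohort",
    "swap_anonymize",
    "write_mock_report",
    "write_personal_data",
    "write_motif_specs",
    "write_frequency_tables",
    "write_core_loci",
    "cohort_frequency_table",
]


@dataclass(frozen=True)
class LocusSpec:
    """How one STR locus is simulated."""

    name: str
    chromosome_class: str  # autosomal | X | Y
    motif: str
    alleles: tuple[str, ...]
    freqs: tuple[float, ...]
    orientation: Orientation = Orientation.FORWARD
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.freqs):
            raise ValueError(f"{self.name}: alleles and freqs differ in length")
        total = sum(self.freqs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: allele frequencies sum to {total}, not 1")

    def motif_spec(self) -> MotifSpec:
        """The matching reference pattern (forward strand, as authored)."""
        blocks = []
        if self.flank5:
            blocks.append(MotifBlock(self.flank5, 1))
        blocks.append(MotifBlock(self.motif, "n"))
        if self.flank3:
            blocks.append(MotifBlock(self.flank3, 1))
        return MotifSpec(
            locus=self.name,
            blocks=tuple(blocks),
            allele_scope="Default",
            orientation=self.orientation,
        )


@dataclass(frozen=True)
class SNPSpec:
    name: str
    ref: str
    alt: str
    alt_freq: float


@dataclass(frozen=True)
class GeoVocabulary:
    country: str
    provinces: tuple[tuple[str, str], ...]  # (province, region)
    races: tuple[str, ...]


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort; the seed fixes all randomness."""

    n_samples: int = 125
    loci: Sequence[LocusSpec] = ()
    snps: Sequence[SNPSpec] = ()
    geo: Optional[GeoVocabulary] = None
    seed: int = 0
    inbreeding_f: float = 0.0
    untyped_extra_rate: float = 0.1  # chance of an extra untyped (stutter-like) row per locus
    indel_rate: float = 0.0  # chance a synthesized sequence carries one short insertion
    start_year: int = 2018


def default_cohort_spec(seed: int = 0, n_samples: int = 125) -> CohortSpec:
    """The default study conditions: 125 donors, six STR loci, three iSNPs."""
    loci = (
        LocusSpec(
            "TPOX", "autosomal", "AATG",
            alleles=("6", "7", "8", "9", "10", "11", "12"),
            freqs=(0.02, 0.03, 0.45, 0.12, 0.06, 0.27, 0.05),
        ),
        LocusSpec(
            "CSF1PO", "autosomal", "ATCT",
            alleles=("9", "10", "11", "12", "13"),
            freqs=(0.05, 0.25, 0.30, 0.32, 0.08),
            orientation=Orientation.REVERSE,
        ),
        LocusSpec(
            "D2S441", "autosomal", "TCTA",
            alleles=("10", "10.3", "11", "11.3", "12", "14"),
            freqs=(0.30, 0.06, 0.34, 0.04, 0.16, 0.10),
        ),
        LocusSpec(
            "D1S1656", "autosomal", "TAGA",
            alleles=("12", "13", "14", "15", "16", "17.3"),
            freqs=(0.10, 0.15, 0.25, 0.27, 0.15, 0.08),
            flank5="CACA",
            flank3="TGACACA",
        ),
        LocusSpec(
            "DYS391", "Y", "TCTA",
            alleles=("9", "10", "11", "12"),
            freqs=(0.05, 0.48, 0.40, 0.07),
        ),
        LocusSpec(
            "DXS10074", "X", "AAGA",
            alleles=("14", "15", "16", "17", "18"),
            freqs=(0.12, 0.28, 0.30, 0.22, 0.08),
        ),
    )
    snps = (
        SNPSpec("rs1357617", "A", "T", 0.35),
        SNPSpec("rs2046361", "A", "T", 0.48),
        SNPSpec("rs876724", "C", "T", 0.22),
    )
    geo = GeoVocabulary(
        country="Thailand",
        provinces=(
            ("Bangkok", "Central"),
            ("Chiang Mai", "North"),
            ("Khon Kaen", "Northeast"),
            ("Phuket", "South"),
        ),
        races=("Thai",),
    )
    return CohortSpec(n_samples=n_samples, loci=loci, snps=snps, geo=geo, seed=seed)


def expand_allele(locus: LocusSpec, label: str, rng: Optional[np.random.Generator] = None,
                  indel_rate: float = 0.0) -> str:
    """Synthesize the reported sequence for one allele of a locus.

    The integer part of the label becomes that many motif copies; a
    fractional digit appends that many leading motif bases (the microvariant
    partial repeat).  Flanks wrap the repeat tract, and reverse-orientation
    loci report the reverse complement of the whole thing.  With probability
    ``indel_rate`` one insertion of 1..(motif length - 1) random bases lands
    between two repeat copies.
    """
    if "." in label:
        whole_s, frac_s = label.split(".", 1)
        whole, frac = int(whole_s), int(frac_s)
    else:
        whole, frac = int(label), 0
    core = locus.motif * whole + locus.motif[:frac]
    if rng is not None and indel_rate > 0 and whole >= 2 and rng.random() < indel_rate:
        ins_len = int(rng.integers(1, len(locus.motif)))
        ins = "".join(rng.choice(list("ACGT"), size=ins_len))
        boundary = int(rng.integers(1, whole)) * len(locus.motif)
        core = core[:boundary] + ins + core[boundary:]
    seq = locus.flank5 + core + locus.flank3
    if locus.orientation is Orientation.REVERSE:
        seq = reverse_complement(seq)
    return seq


def _draw_allele(rng: np.random.Generator, locus: LocusSpec) -> str:
    return str(rng.choice(list(locus.alleles), p=list(locus.freqs)))


def generate_cohort(spec: CohortSpec) -> tuple[list[SampleRecord], list[PersonMetadata]]:
    """Generate a seeded cohort of sample records with personal metadata."""
    rng = np.random.default_rng(spec.seed)
    records: list[SampleRecord] = []
    people: list[PersonMetadata] = []
    for i in range(spec.n_samples):
        sid = f"S{i + 1:04d}"
        male = bool(rng.random() < 0.5)
        rec = SampleRecord(sample_id=sid, year=int(spec.start_year + rng.integers(0, 5)))
        for locus in spec.loci:
            if locus.chromosome_class == "Y":
                if not male:
                    continue
                labels = (_draw_allele(rng, locus),)
            elif locus.chromosome_class == "X" and male:
                labels = (_draw_allele(rng, locus),)
            else:
                a = _draw_allele(rng, locus)
                if spec.inbreeding_f > 0 and rng.random() < spec.inbreeding_f:
                    b = a
                else:
                    b = _draw_allele(rng, locus)
                labels = (a, b)
            gt = LocusGenotype(locus.name, labels, locus.chromosome_class)
            rec.genotypes[locus.name] = gt
            for label in gt.alleles:
                rec.sequence_alleles.append(
                    SequenceAllele(
                        locus=locus.name,
                        allele_label=label,
                        sequence=expand_allele(locus, label, rng, spec.indel_rate),
                        read_count=int(rng.integers(150, 1200)),
                        typed=True,
                    )
                )
            if rng.random() < spec.untyped_extra_rate:
                stutter = locus.alleles[int(rng.integers(0, len(locus.alleles)))]
                rec.sequence_alleles.append(
                    SequenceAllele(
                        locus=locus.name,
                        allele_label=stutter,
                        sequence=expand_allele(locus, stutter),
                        read_count=int(rng.integers(5, 60)),
                        typed=False,
                    )
                )
        for snp in spec.snps:
            pair = tuple(
                snp.alt if rng.random() < snp.alt_freq else snp.ref for _ in range(2)
            )
            coverage = {a: int(rng.integers(40, 400)) for a in set(pair)}
            rec.isnps.append(ISNPGenotype(snp.name, pair, coverage))
        records.append(rec)
        if spec.geo is not None:
            province, region = spec.geo.provinces[int(rng.integers(0, len(spec.geo.provinces)))]
            people.append(
                PersonMetadata(
                    sample_id=sid,
                    province=province,
                    region=region,
                    country=spec.geo.country,
                    race=str(rng.choice(list(spec.geo.races))),
                )
            )
    return records, people


def swap_anonymize(cohort: Sequence[SampleRecord], seed: int) -> list[SampleRecord]:
    """Permute genotypes within each locus across samples; rows travel along.

    Per locus, the genotypes of the samples carrying that locus are shuffled
    among those same samples, and each genotype's sequence-based allele rows
    (typed and untyped) move with it.  Per-locus genotype multisets — and so
    every per-locus statistic — are invariant.
    """
    if len(cohort) < 2:
        raise ValueError("need at least two samples to swap")
    rng = np.random.default_rng(seed)
    out = [
        SampleRecord(sample_id=s.sample_id, year=s.year, isnps=list(s.isnps))
        for s in cohort
    ]
    loci = sorted({locus for s in cohort for locus in s.genotypes})
    for locus in loci:
        carriers = [i for i, s in enumerate(cohort) if locus in s.genotypes]
        perm = rng.permutation(len(carriers))
        for dst_pos, src_pos in enumerate(perm):
            src = cohort[carriers[src_pos]]
            dst = out[carriers[dst_pos]]
            dst.genotypes[locus] = src.genotypes[locus]
            dst.sequence_alleles.extend(
                sa for sa in src.sequence_alleles if sa.locus == locus
            )
    return out


# ---------------------------------------------------------------------------
# Workbook writers (the inverse of the formats_io readers)


def write_mock_report(record: SampleRecord, workbook_path) -> None:
    """Write a record as a sample-detail-report workbook the reader accepts."""
    wb = Workbook()
    wb.remove(wb.active)
    sheet_for_class = {"autosomal": "Autosomal STRs", "Y": "Y STRs", "X": "X STRs"}
    for chrom, sheet_name in sheet_for_class.items():
        genos = [g for g in record.genotypes.values() if g.chromosome_class == chrom]
        seqs = [
            sa
            for sa in record.sequence_alleles
            if record.genotypes.get(sa.locus) is not None
            and record.genotypes[sa.locus].chromosome_class == chrom
        ]
        if not genos:
            continue
        ws = wb.create_sheet(sheet_name)
        ws.append(["Sample ID", record.sample_id])
        ws.append(["Sample Year", record.year if record.year is not None else ""])
        ws.append([])
        ws.append(["Locus", "Allele 1", "Allele 2"])
        for g in sorted(genos, key=lambda g: g.locus):
            row = [g.locus, g.alleles[0], g.alleles[1] if g.ploidy == 2 else ""]
            ws.append(row)
        ws.append([])
        ws.append(["Locus", "Allele", "Typed Allele", "Reads", "Sequence"])
        for sa in sorted(seqs, key=lambda s: (s.locus, float(s.allele_label), not s.typed)):
            ws.append(
                [sa.locus, sa.allele_label, "Yes" if sa.typed else "No", sa.read_count, sa.sequence]
            )
    if record.isnps:
        ws = wb.create_sheet("iSNPs")
        ws.append(["Locus", "Genotype"])
        for snp in sorted(record.isnps, key=lambda s: s.locus):
            ws.append([snp.locus, snp.genotype_label])
        ws.append([])
        ws.append(["Locus", "Allele", "Reads"])
        for snp in sorted(record.isnps, key=lambda s: s.locus):
            for allele, reads in sorted(snp.coverage.items()):
                ws.append([snp.locus, allele, reads])
    if not wb.sheetnames:
        raise ValueError(f"record {record.sample_id} has no STR genotypes to write")
    wb.save(workbook_path)


def write_personal_data(people: Sequence[PersonMetadata], workbook_path) -> None:
    wb = Workbook()
    ws = wb.active
    ws.title = "Personal Data"
    ws.append(["Sample ID", "Province", "Region", "Country", "Race"])
    for p in people:
        ws.append([p.sample_id, p.province or "", p.region or "", p.country or "", p.race or ""])
    wb.save(workbook_path)


def write_motif_specs(specs: Sequence[MotifSpec], workbook_path) -> None:
    wb = Workbook()
    ws = wb.active
    ws.title = "Repeat Motifs"
    ws.append(["Locus", "Repeat Motif", "Allele", "Orientation"])
    for spec in specs:
        parts = []
        for b in spec.blocks:
            if b.count_spec == "n":
                parts.append(f"[{b.motif}]n")
            elif b.count_spec == 1:
                parts.append(b.motif)
            else:
                parts.append(f"[{b.motif}]{b.count_spec}")
        ws.append([spec.locus, " ".join(parts), spec.allele_scope, spec.orientation.value.capitalize()])
    wb.save(workbook_path)


def write_frequency_tables(
    table: FrequencyTable, workbook_path, country: Optional[str] = None
) -> None:
    """Write a frequency workbook: all-countries layout, or one-country when named."""
    wb = Workbook()
    ws = wb.active
    ws.title = "Allele Frequencies"
    if country is not None:
        loci = table.loci(country)
        for locus in loci:
            ws.append([locus])
            ws.append(["Allele", "Frequency"])
            for allele in sorted(table.data[country][locus], key=float):
                ws.append([allele, table.data[country][locus][allele]])
            ws.append([])
    else:
        countries = table.countries()
        loci = sorted({l for c in countries for l in table.loci(c)})
        for locus in loci:
            ws.append([locus])
            ws.append(["Allele"] + countries)
            alleles = sorted(
                {a for c in countries for a in table.data.get(c, {}).get(locus, {})},
                key=float,
            )
            for allele in alleles:
                row = [allele]
                for c in countries:
                    v = table.freq(c, locus, allele)
                    row.append(v if v is not None else "")
                ws.append(row)
            ws.append([])
    wb.save(workbook_path)


def write_core_loci(defaults: Sequence[str], by_country: dict[str, Sequence[str]], workbook_path) -> None:
    wb = Workbook()
    ws = wb.active
    ws.title = "Core Loci"
    ws.append(["Locus", "Country"])
    for locus in defaults:
        ws.append([locus, "Default"])
    for country in sorted(by_country):
        for locus in by_country[country]:
            ws.append([locus, country])
    wb.save(workbook_path)


def cohort_frequency_table(
    samples: Sequence[SampleRecord], country: str, loci: Optional[Sequence[str]] = None
) -> FrequencyTable:
    """Length-based allele frequencies of a cohort, as a one-country table."""
    table = FrequencyTable()
    wanted = loci if loci is not None else sorted({l for s in samples for l in s.genotypes})
    for locus in wanted:
        freqset = allele_frequencies(samples, locus)
        for allele, p in freqset.freqs.items():
            table.set(country, locus, allele, p)
    return table
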