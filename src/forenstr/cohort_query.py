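"""Genotype-containment search over stored samples, with role-shaped output.

The overview search takes a set of (locus, genotype) criteria and returns the
samples that carry *every* queried genotype exactly (unordered allele
comparison); samples lacking a queried locus simply fail to match.  Output is
shaped by the caller's role: public users see only the match count, while
laboratory users and administrators additionally get sample IDs and counts
grouped by country and province.  A query may be restricted to a typing kit,
in which case every queried locus must belong to the kit's panel.

Also here: tabular geographic aggregation of a locus's alleles by province
(with region-level sample counts) and per-SNP genotype-class proportions.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .formats_io import KitDefinition, PersonMetadata, SampleRecord, SampleStore, read_sample_report

__all__ = [
    "Role",
    "SearchCriteria",
    "SearchResult",
    "GeoAggregate",
    "overview_search",
    "search_by_report",
    "geo_aggregate",
    "isnp_summary",
]

PUBLIC = "public"
LABORATORY = "laboratory"
ADMINISTRATOR = "administrator"
Role = str


@dataclass(frozen=True)
class SearchCriteria:
    """Loci and genotypes a matching sample must contain."""

    genotypes: Mapping[str, tuple[str, ...]]
    kit: Optional[KitDefinition] = None

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValueError("search criteria must name at least one locus")
        norm = {
            locus: tuple(sorted(alleles, key=float))
            for locus, alleles in self.genotypes.items()
        }
        object.__setattr__(self, "genotypes", norm)
        if self.kit is not None:
            foreign = sorted(set(norm) - self.kit.loci)
            if foreign:
                raise ValueError(
                    f"loci not in kit {self.kit.kit_name}: {', '.join(foreign)}"
                )


@dataclass
class SearchResult:
    match_count: int
    sample_ids: Optional[list[str]] = None
    by_country: Optional[dict[str, int]] = None
    by_province: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        if self.sample_ids is not None:
            assert self.match_count == len(self.sample_ids)


def _matches(sample: SampleRecord, criteria: SearchCriteria) -> bool:
    for locus, alleles in criteria.genotypes.items():
        gt = sample.genotypes.get(locus)
        if gt is None or gt.alleles != alleles:
            return False
    return True


def overview_search(
    store: SampleStore, criteria: SearchCriteria, role: Role = PUBLIC
) -> SearchResult:
    """Find samples containing every queried (locus, genotype) pair.

    Public callers get the count only; laboratory/administrator callers also
    get sorted sample IDs and per-country / per-province grouped counts
    (samples without metadata fall under ``"(unknown)"``).
    """
    matched = [s for s in store.samples() if _matches(s, criteria)]
    if role == PUBLIC:
        return SearchResult(match_count=len(matched))
    by_country: Counter[str] = Counter()
    by_province: Counter[str] = Counter()
    for s in matched:
        meta = store.metadata.get(s.sample_id)
        by_country[(meta.country if meta and meta.country else "(unknown)")] += 1
        by_province[(meta.province if meta and meta.province else "(unknown)")] += 1
    return SearchResult(
        match_count=len(matched),
        sample_ids=sorted(s.sample_id for s in matched),
        by_country=dict(by_country),
        by_province=dict(by_province),
    )


def search_by_report(
    store: SampleStore, report_path, role: Role = PUBLIC
) -> SearchResult:
    """Overview search whose criteria are every genotype in a sample report."""
    record = read_sample_report(report_path)
    criteria = SearchCriteria(
        genotypes={locus: gt.alleles for locus, gt in record.genotypes.items()}
    )
    return overview_search(store, criteria, role)


@dataclass
class GeoAggregate:
    """Tabular geographic aggregation for one locus."""

    locus: str
    allele_counts_by_province: dict[str, dict[str, int]] = field(default_factory=dict)
    samples_by_province: dict[str, int] = field(default_factory=dict)
    samples_by_region: dict[str, int] = field(default_factory=dict)
    unlocated: int = 0

    @property
    def located(self) -> int:
        return sum(self.samples_by_province.values())


def geo_aggregate(
    store: SampleStore,
    locus: str,
    metadata: Optional[Mapping[str, PersonMetadata]] = None,
) -> GeoAggregate:
    """Count a locus's length-based alleles per province, and samples per region.

    Counts cover samples that have both metadata (a province) and a genotype
    at the locus; samples missing either a province or the locus genotype are
    tallied as unlocated.
    """
    meta = store.metadata if metadata is None else metadata
    agg = GeoAggregate(locus=locus)
    allele_counts: dict[str, Counter[str]] = defaultdict(Counter)
    for sample in store.samples():
        m = meta.get(sample.sample_id)
        gt = sample.genotypes.get(locus)
        if m is None or not m.province or gt is None:
            agg.unlocated += 1
            continue
        allele_counts[m.province].update(gt.alleles)
        agg.samples_by_province[m.province] = agg.samples_by_province.get(m.province, 0) + 1
        region = m.region or "(unknown)"
        agg.samples_by_region[region] = agg.samples_by_region.get(region, 0) + 1
    agg.allele_counts_by_province = {p: dict(c) for p, c in allele_counts.items()}
    return agg


def isnp_summary(
    store: SampleStore, locus_filter: Optional[Iterable[str]] = None
) -> dict[str, dict[str, float]]:
    """Per SNP locus: genotype class -> proportion over non-missing calls."""
    wanted = set(locus_filter) if locus_filter is not None else None
    counts: dict[str, Counter[str]] = defaultdict(Counter)
    for sample in store.samples():
        for snp in sample.isnps:
            if wanted is not None and snp.locus not in wanted:
                continue
            counts[snp.locus][snp.genotype_label] += 1
    out: dict[str, dict[str, float]] = {}
    for locus, classes in sorted(counts.items()):
        total = sum(classes.values())
        out[locus] = {g: c / total for g, c in sorted(classes.items())}
    return out
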