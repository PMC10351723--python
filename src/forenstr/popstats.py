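"""Forensic population statistics per STR locus.

For every locus the toolkit reports length-based allele frequencies and the
standard forensic parameter set, split by ploidy:

haploid observations (Y loci, hemizygous X):
    PM  = sum of squared observed haplotype-class frequencies
    PD  = 1 - PM
    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2          (Botstein)

diploid observations:
    Hobs = observed heterozygote proportion
    Hexp = (2N / (2N - 1)) (1 - sum p_i^2)                  (unbiased)
    PM   = sum of squared observed genotype-class frequencies
    PD   = 1 - PM
    PIC  = Botstein, as above
    PE   = h^2 (1 - 2 h H^2), h = Hobs, H = 1 - Hobs        (Fisher)

PM is a *match probability*: it is computed from the observed genotype (or
haplotype) class proportions, not from expected Hardy-Weinberg frequencies.
Loci mixing haploid and diploid genotypes (X-chromosome loci in a mixed-sex
cohort) get both statistic sets, each computed on its own genotype subset,
never pooled.  Values are stored at full precision; display rounding is five
decimal places.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .formats_io import LocusGenotype, SampleRecord

__all__ = [
    "AlleleFrequencySet",
    "LocusStats",
    "allele_frequencies",
    "classify_ploidy",
    "stats_haploid",
    "stats_diploid",
    "locus_statistics",
    "cohort_statistics",
    "write_stats_table",
    "HAPLOID_ONLY",
    "DIPLOID_ONLY",
    "MIXED",
]

HAPLOID_ONLY = "haploid_only"
DIPLOID_ONLY = "diploid_only"
MIXED = "mixed"

DISPLAY_DECIMALS = 5


@dataclass
class AlleleFrequencySet:
    """Observed allele counts and relative frequencies at one locus."""

    locus: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_alleles(self) -> int:
        return sum(self.counts.values())

    @property
    def freqs(self) -> dict[str, float]:
        n = self.n_alleles
        if n == 0:
            return {}
        # sorted by allele so downstream float sums are order-independent
        return {a: self.counts[a] / n for a in sorted(self.counts, key=float)}

    def __bool__(self) -> bool:
        return self.n_alleles > 0


@dataclass
class LocusStats:
    locus: str
    ploidy_case: str
    n_samples: int
    pm: float
    pd: float
    pic: float
    hobs: Optional[float] = None
    hexp: Optional[float] = None
    pe: Optional[float] = None

    def rounded(self) -> dict[str, Optional[float]]:
        """Display form: five decimal places, as validation tables print them."""
        out = {}
        for name in ("hobs", "hexp", "pm", "pic", "pd", "pe"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, DISPLAY_DECIMALS)
        return out


def _genotypes_at(samples: Iterable[SampleRecord], locus: str) -> list[LocusGenotype]:
    return [s.genotypes[locus] for s in samples if locus in s.genotypes]


def allele_frequencies(
    samples: Iterable[SampleRecord], locus: str, ploidy_filter: Optional[int] = None
) -> AlleleFrequencySet:
    """Count allele occurrences at a locus: 2 per diploid genotype, 1 per haploid.

    ``ploidy_filter`` restricts to genotypes of that arity (1 or 2); loci with
    no matching data yield an empty (falsy) set rather than an error.
    """
    counts: Counter[str] = Counter()
    for gt in _genotypes_at(samples, locus):
        if ploidy_filter is not None and gt.ploidy != ploidy_filter:
            continue
        counts.update(gt.alleles)
    return AlleleFrequencySet(locus=locus, counts=dict(counts))


def classify_ploidy(samples: Iterable[SampleRecord], locus: str) -> str:
    """haploid_only / diploid_only / mixed, by the genotype arities observed."""
    arities = {gt.ploidy for gt in _genotypes_at(samples, locus)}
    if not arities:
        raise ValueError(f"locus {locus} not observed in any sample")
    if arities == {1}:
        return HAPLOID_ONLY
    if arities == {2}:
        return DIPLOID_ONLY
    return MIXED


def _pic(freqs: Sequence[float]) -> float:
    """Botstein polymorphic information content."""
    sum_sq = sum(p * p for p in freqs)
    cross = 0.0
    for i, p in enumerate(freqs):
        for q in freqs[i + 1 :]:
            cross += 2.0 * p * p * q * q
    return 1.0 - sum_sq - cross


def stats_haploid(
    freqset: AlleleFrequencySet, haplotype_counts: Counter[str]
) -> LocusStats:
    """Haploid statistic set: PM over haplotype classes, PD, and PIC."""
    n = sum(haplotype_counts.values())
    if n < 1:
        raise ValueError(f"no haploid observations at {freqset.locus}")
    pm = sum((haplotype_counts[k] / n) ** 2 for k in sorted(haplotype_counts))
    freqs = list(freqset.freqs.values())
    return LocusStats(
        locus=freqset.locus,
        ploidy_case=HAPLOID_ONLY,
        n_samples=n,
        pm=pm,
        pd=1.0 - pm,
        pic=_pic(freqs),
    )


def stats_diploid(
    freqset: AlleleFrequencySet, genotype_counts: Counter[tuple[str, str]]
) -> Optional[LocusStats]:
    """Diploid statistic set: Hobs, unbiased Hexp, PM, PD, PIC and PE.

    Returns None (insufficient data: Hexp undefined) with fewer than two
    genotypes.
    """
    n = sum(genotype_counts.values())
    if n < 2:
        return None
    het = sum(c for (a, b), c in genotype_counts.items() if a != b)
    hobs = het / n
    freqs = list(freqset.freqs.values())
    sum_sq = sum(p * p for p in freqs)
    two_n = 2 * n
    hexp = (two_n / (two_n - 1)) * (1.0 - sum_sq)
    pm = sum((genotype_counts[k] / n) ** 2 for k in sorted(genotype_counts))
    h = hobs
    homo = 1.0 - hobs
    pe = h * h * (1.0 - 2.0 * h * homo * homo)
    return LocusStats(
        locus=freqset.locus,
        ploidy_case=DIPLOID_ONLY,
        n_samples=n,
        pm=pm,
        pd=1.0 - pm,
        pic=_pic(freqs),
        hobs=hobs,
        hexp=hexp,
        pe=pe,
    )


def locus_statistics(samples: Sequence[SampleRecord], locus: str) -> list[LocusStats]:
    """All statistic sets a locus supports: one for pure cases, two when mixed.

    Mixed-ploidy loci are evaluated on the haploid and diploid genotype
    subsets separately (the toggle view), never pooled.
    """
    case = classify_ploidy(samples, locus)
    out: list[LocusStats] = []
    if case in (HAPLOID_ONLY, MIXED):
        hap_counts: Counter[str] = Counter(
            gt.alleles[0] for gt in _genotypes_at(samples, locus) if gt.ploidy == 1
        )
        freqset = allele_frequencies(samples, locus, ploidy_filter=1)
        st = stats_haploid(freqset, hap_counts)
        st.ploidy_case = case if case == HAPLOID_ONLY else MIXED
        out.append(st)
    if case in (DIPLOID_ONLY, MIXED):
        geno_counts: Counter[tuple[str, str]] = Counter(
            gt.alleles for gt in _genotypes_at(samples, locus) if gt.ploidy == 2
        )
        freqset = allele_frequencies(samples, locus, ploidy_filter=2)
        st = stats_diploid(freqset, geno_counts)
        if st is not None:
            st.ploidy_case = case if case == DIPLOID_ONLY else MIXED
            out.append(st)
    return out


def cohort_statistics(samples: Sequence[SampleRecord]) -> list[LocusStats]:
    """Statistics for every locus observed anywhere in the cohort."""
    loci = sorted({locus for s in samples for locus in s.genotypes})
    out: list[LocusStats] = []
    for locus in loci:
        out.extend(locus_statistics(samples, locus))
    return out


_COLUMNS = ("Locus", "Ploidy", "N", "Hobs", "Hexp", "PM", "PIC", "PD", "PE")


def write_stats_table(stats: Sequence[LocusStats], path) -> None:
    """One row per statistic set, CSV or XLSX by file extension, 5-dp display."""
    rows = []
    for st in stats:
        r = st.rounded()
        subset = "haploid" if st.hobs is None else "diploid"
        ploidy = st.ploidy_case if st.ploidy_case != MIXED else f"mixed ({subset})"
        rows.append(
            [st.locus, ploidy, st.n_samples, r["hobs"], r["hexp"], r["pm"], r["pic"], r["pd"], r["pe"]]
        )
    path = str(path)
    if path.endswith(".xlsx"):
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "Statistics"
        ws.append(list(_COLUMNS))
        for row in rows:
            ws.append(row)
        wb.save(path)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_COLUMNS)
            writer.writerows(rows)
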