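"""Profile-frequency search: rank reference populations by profile commonness.

Given a multi-locus autosomal genotype profile and per-country length-based
allele-frequency tables, each locus genotype gets an expected population
frequency:

    homozygote   F(x) = p^2 + p (1 - p) theta
    heterozygote F(x) = 2 p q

where ``theta`` is the population-subdivision correction applied only to
homozygotes (at theta = 0 the homozygote formula is the plain Hardy-Weinberg
p^2).  A country's score is the product of reciprocal genotype frequencies
over the queried loci; countries are ranked ascending — the lowest score
marks the population where the profile is most common.

Queries are validated against a core-loci panel: the selected panel's own
loci are required, and the default panel is always displayed alongside.
Query alleles absent from a country's table are, by default, substituted
with a small floor frequency and flagged in the output (silent exclusion
would bias rankings invisibly); a strict mode excludes such countries
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .formats_io import CoreLoci, FrequencyTable, LocusGenotype

__all__ = [
    "DEFAULT_THETA",
    "DEFAULT_MIN_FREQ",
    "ProfileQuery",
    "LocusFrequency",
    "CountryRanking",
    "RequiredLocus",
    "genotype_frequency",
    "rank_countries",
    "required_loci",
]

DEFAULT_THETA = 0.0
DEFAULT_MIN_FREQ = 0.001


class MissingFrequency(Exception):
    """A query allele has no frequency in a country's table (strict mode)."""


@dataclass(frozen=True)
class ProfileQuery:
    """The queried profile: locus -> two allele labels (possibly equal)."""

    genotypes: Mapping[str, tuple[str, str]]
    panel: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValueError("a profile query needs at least one locus")
        norm = {}
        for locus, alleles in self.genotypes.items():
            if len(alleles) != 2:
                raise ValueError(
                    f"{locus}: profile search covers autosomal diploid genotypes; "
                    f"got {len(alleles)} allele(s)"
                )
            norm[locus] = tuple(sorted(alleles, key=float))
        object.__setattr__(self, "genotypes", norm)

    def validate_against(self, required: Sequence["RequiredLocus"]) -> None:
        missing = [r.locus for r in required if r.required and r.locus not in self.genotypes]
        if missing:
            raise ValueError(f"missing required loci: {', '.join(sorted(missing))}")


def genotype_frequency(
    genotype: tuple[str, str],
    locus_freqs: Mapping[str, float],
    theta: float = DEFAULT_THETA,
    *,
    min_freq: Optional[float] = DEFAULT_MIN_FREQ,
) -> tuple[float, bool]:
    """Expected population frequency of one locus genotype.

    Returns ``(F(x), substituted)`` where ``substituted`` is True when any
    allele's frequency was missing and the floor ``min_freq`` stood in for
    it.  With ``min_freq=None`` (strict mode) a missing allele raises
    :class:`MissingFrequency` instead.
    """
    if not 0.0 <= theta < 1.0:
        raise ValueError(f"theta must be in [0, 1), got {theta}")
    a, b = genotype
    substituted = False

    def freq_of(allele: str) -> float:
        nonlocal substituted
        p = locus_freqs.get(allele)
        if p is None or p <= 0.0:
            if min_freq is None:
                raise MissingFrequency(allele)
            substituted = True
            return min_freq
        return p

    p = freq_of(a)
    if a == b:
        fx = p * p + p * (1.0 - p) * theta
    else:
        q = freq_of(b)
        fx = 2.0 * p * q
    return fx, substituted


@dataclass(frozen=True)
class LocusFrequency:
    locus: str
    genotype: tuple[str, str]
    frequency: float
    substituted: bool


@dataclass
class CountryRanking:
    country: str
    score: float  # product of reciprocal genotype frequencies; lower = more common
    rank: int = 0
    per_locus: list[LocusFrequency] = field(default_factory=list)

    @property
    def substituted_loci(self) -> list[str]:
        return [lf.locus for lf in self.per_locus if lf.substituted]


def rank_countries(
    query: ProfileQuery,
    freq_table: FrequencyTable,
    theta: float = DEFAULT_THETA,
    *,
    min_freq: Optional[float] = DEFAULT_MIN_FREQ,
) -> tuple[list[CountryRanking], list[str]]:
    """Score and rank every country in the table against the queried profile.

    Returns ``(rankings, excluded)``: rankings sorted ascending by score
    (ties broken by country name), ranks 1..K; ``excluded`` lists countries
    dropped in strict mode for missing frequencies, or with no usable loci.
    """
    if not freq_table.data:
        raise ValueError("frequency table is empty")
    rankings: list[CountryRanking] = []
    excluded: list[str] = []
    for country in freq_table.countries():
        per_locus: list[LocusFrequency] = []
        score = 1.0
        usable = 0
        try:
            for locus, genotype in sorted(query.genotypes.items()):
                locus_freqs = freq_table.data[country].get(locus, {})
                fx, substituted = genotype_frequency(
                    genotype, locus_freqs, theta, min_freq=min_freq
                )
                per_locus.append(LocusFrequency(locus, genotype, fx, substituted))
                score *= 1.0 / fx
                usable += 1
        except MissingFrequency:
            excluded.append(country)
            continue
        if usable == 0:
            excluded.append(country)
            continue
        rankings.append(CountryRanking(country=country, score=score, per_locus=per_locus))
    rankings.sort(key=lambda r: (r.score, r.country))
    for i, r in enumerate(rankings, start=1):
        r.rank = i
    return rankings, excluded


@dataclass(frozen=True)
class RequiredLocus:
    locus: str
    required: bool


def required_loci(
    core: CoreLoci, selected_panel: Optional[str] = None
) -> list[RequiredLocus]:
    """The loci a profile search displays for a panel, with required flags.

    The display set is the default panel unioned with the selected country's
    own loci; only the country's own loci are required.  ``selected_panel``
    of None (or "Default") means the default panel alone, nothing required.
    """
    if selected_panel in (None, "Default"):
        return [RequiredLocus(l, False) for l in sorted(core.defaults)]
    if selected_panel not in core.by_country:
        raise ValueError(
            f"unknown core-loci panel {selected_panel!r}; "
            f"available: {', '.join(core.panels()) or '(none)'}"
        )
    own = core.by_country[selected_panel]
    display = sorted(core.defaults | own)
    return [RequiredLocus(l, l in own) for l in display]
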