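"""Repeat-motif grammar, orientation handling, and sequence decomposition.

Sequence-based STR alleles are reported as raw nucleotide strings.  To make
them comparable across samples they are decomposed against a reference
repeat-motif pattern written in bracketed nomenclature, e.g. ``[TCTA]n [TCTG]n``
for a compound locus: each bracketed group is a motif block repeated a
variable (``n``) or fixed number of times, and bare sequence runs between
groups are literal blocks.  Reference patterns are always given on the
forward strand; a per-locus orientation flag says whether the sequences in
the sample reports are reversed, in which case the pattern is
reverse-complemented (and its block order flipped) before alignment.

The decomposition itself is a small dynamic program that explains a sequence
as an ordered series of exact motif copies, with three kinds of deviations:

* insertions of fewer bases than the motif length, between adjacent copies;
* deletions of fewer bases than the motif length, i.e. an interrupted copy
  missing a contiguous chunk of the motif;
* a trailing partial copy (a proper prefix of the motif) at a block's 3' end,
  which is how fractional "microvariant" alleles such as 10.3 arise.

Unmatched sequence at either end, up to a configurable flank budget, is kept
as literal flanking segments: some loci (D1S1656, D5S818, ...) carry flanking
region bases in their reported sequences.

The objective is lexicographic: first maximise the bases assigned to exact
motif copies, then minimise inserted-plus-deleted bases, then minimise
literal (flank/partial) bases; remaining ties are broken leftmost so renders
are stable.  Indels of length greater than or equal to the motif length are
never reported — a sequence that cannot be explained without one yields an
alignment-failure outcome carrying the best partial explanation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio.Seq import Seq

__all__ = [
    "Orientation",
    "MotifBlock",
    "MotifSpec",
    "RepeatRun",
    "Literal",
    "Insertion",
    "Deletion",
    "RepeatStructure",
    "MotifParseError",
    "parse_bracket_notation",
    "reverse_complement",
    "orient_spec",
    "select_spec",
    "decompose",
    "render",
    "parse_render",
    "check_allele_consistency",
    "align_cohort",
    "AlignmentRow",
    "CohortAlignment",
]

_DNA_RE = re.compile(r"^[ACGT]+$")

VARIABLE = "n"


class MotifParseError(ValueError):
    """Raised when bracketed motif notation cannot be parsed."""


class Orientation(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string."""
    if sequence == "":
        return ""
    if not _DNA_RE.match(sequence):
        raise ValueError(f"non-DNA character in sequence: {sequence!r}")
    return str(Seq(sequence).reverse_complement())


@dataclass(frozen=True)
class MotifBlock:
    """One block of a repeat pattern: a motif and how often it repeats.

    ``count_spec`` is either the string ``"n"`` (variable repeat count) or a
    fixed non-negative integer; bare sequence runs in bracket notation become
    fixed blocks of count 1.
    """

    motif: str
    count_spec: Union[str, int]

    def __post_init__(self) -> None:
        if not self.motif or not _DNA_RE.match(self.motif):
            raise ValueError(f"motif must be non-empty A/C/G/T, got {self.motif!r}")
        if self.count_spec != VARIABLE:
            if not isinstance(self.count_spec, int) or self.count_spec < 0:
                raise ValueError(f"fixed count must be a non-negative int, got {self.count_spec!r}")

    @property
    def variable(self) -> bool:
        return self.count_spec == VARIABLE


@dataclass(frozen=True)
class MotifSpec:
    """A locus's reference repeat pattern.

    ``allele_scope`` is ``"Default"`` when the pattern applies to every allele
    of the locus, or a specific allele label (e.g. ``"10.3"``) when an
    administrator has registered a microvariant-specific pattern.  Reference
    patterns are authored on the forward strand; ``orientation`` records the
    strand of the sample sequences this locus reports.
    """

    locus: str
    blocks: tuple[MotifBlock, ...]
    allele_scope: str = "Default"
    orientation: Orientation = Orientation.FORWARD

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("MotifSpec needs at least one block")
        object.__setattr__(self, "blocks", tuple(self.blocks))


_TOKEN_RE = re.compile(r"\[(?P<motif>[^\[\]]*)\](?P<count>n|\d+)|(?P<bare>[^\[\]\s]+)|(?P<ws>\s+)")


def parse_bracket_notation(text: str) -> list[MotifBlock]:
    """Parse bracketed repeat notation into an ordered list of motif blocks.

    ``"[ATCT]n"`` yields one variable block; ``"[ATCT]3"`` a fixed block of
    count 3; bare runs between groups (``"AC[ATCT]n"``) become fixed literal
    blocks of count 1.  Whitespace between groups is ignored.
    """
    if not text or not text.strip():
        raise MotifParseError("empty motif pattern")
    blocks: list[MotifBlock] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or ("[" in text[pos] and m.lastgroup == "bare"):
            raise MotifParseError(f"cannot parse motif pattern at position {pos}: {text[pos:]!r}")
        if m.lastgroup == "ws":
            pos = m.end()
            continue
        if m.lastgroup == "bare":
            bare = m.group("bare").upper()
            if "]" in bare or "[" in bare:
                raise MotifParseError(f"unbalanced bracket at position {pos} in {text!r}")
            if not _DNA_RE.match(bare):
                raise MotifParseError(f"non-DNA characters at position {pos}: {bare!r}")
            blocks.append(MotifBlock(bare, 1))
        else:
            motif = m.group("motif").upper()
            if not motif:
                raise MotifParseError(f"empty motif in brackets at position {pos}")
            if not _DNA_RE.match(motif):
                raise MotifParseError(f"non-DNA characters in motif at position {pos}: {motif!r}")
            count = m.group("count")
            blocks.append(MotifBlock(motif, VARIABLE if count == "n" else int(count)))
        pos = m.end()
    if not blocks:
        raise MotifParseError(f"no motif blocks in {text!r}")
    return blocks


def orient_spec(spec: MotifSpec) -> MotifSpec:
    """Return the spec effective against sequences as they appear in reports.

    Forward-orientation specs are returned unchanged.  Reverse orientation
    means the sample sequences are on the opposite strand from the reference
    pattern, so the block order is reversed and each motif reverse-complemented;
    the returned spec is marked forward (it is already effective).
    """
    if spec.orientation is Orientation.FORWARD:
        return spec
    blocks = tuple(
        MotifBlock(reverse_complement(b.motif), b.count_spec) for b in reversed(spec.blocks)
    )
    return replace(spec, blocks=blocks, orientation=Orientation.FORWARD)


def select_spec(
    specs: Iterable[MotifSpec], locus: str, allele_label: str
) -> Optional[MotifSpec]:
    """Pick the pattern for a (locus, allele): exact allele scope wins over Default.

    Returns None when the locus has no registered pattern at all, so callers
    can skip the locus rather than fail.
    """
    default = None
    for spec in specs:
        if spec.locus != locus:
            continue
        if spec.allele_scope == allele_label:
            return spec
        if spec.allele_scope == "Default":
            default = spec
    return default


# ---------------------------------------------------------------------------
# Repeat structures


@dataclass(frozen=True)
class RepeatRun:
    """``count`` consecutive exact copies of ``motif``."""

    motif: str
    count: int

    @property
    def bases(self) -> str:
        return self.motif * self.count


@dataclass(frozen=True)
class Literal:
    """A literal segment: 5'/3' flank, trailing partial repeat, or unexplained bases."""

    text: str
    role: str = "flank"  # flank | partial | mismatch

    @property
    def bases(self) -> str:
        return self.text


@dataclass(frozen=True)
class Insertion:
    """Extra bases between two motif copies; length < motif length."""

    text: str
    position: int  # offset of the inserted bases in the input sequence

    @property
    def bases(self) -> str:
        return self.text


@dataclass(frozen=True)
class Deletion:
    """An interrupted motif copy missing contiguous bases; length < motif length.

    ``observed`` is what the copy actually contributed to the sequence
    (the motif with ``text`` excised), starting at ``position``.
    """

    text: str
    position: int
    observed: str
    motif: str

    @property
    def bases(self) -> str:
        return self.observed


Segment = Union[RepeatRun, Literal, Insertion, Deletion]


@dataclass(frozen=True)
class RepeatStructure:
    """A decomposed sequence: ordered segments whose bases reconstruct the input."""

    segments: tuple[Segment, ...]
    sequence: str
    exact_bases: int
    indel_bases: int
    mismatch_bases: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def ok(self) -> bool:
        """True when the whole sequence was explained by the pattern grammar."""
        return self.mismatch_bases == 0

    @property
    def rendered(self) -> str:
        return render(self)

    @property
    def indels(self) -> list[Union[Insertion, Deletion]]:
        return [s for s in self.segments if isinstance(s, (Insertion, Deletion))]

    def reconstruct(self) -> str:
        return "".join(s.bases for s in self.segments)

    def repeat_count(self, motif: Optional[str] = None) -> int:
        """Total full copies (exact runs plus interrupted copies are *not* counted)."""
        return sum(
            s.count for s in self.segments
            if isinstance(s, RepeatRun) and (motif is None or s.motif == motif)
        )

    def reverse_complement(self) -> "RepeatStructure":
        """The same decomposition viewed on the opposite strand."""
        n = len(self.sequence)
        out: list[Segment] = []
        for seg in reversed(self.segments):
            if isinstance(seg, RepeatRun):
                out.append(RepeatRun(reverse_complement(seg.motif), seg.count))
            elif isinstance(seg, Literal):
                out.append(Literal(reverse_complement(seg.text), seg.role))
            elif isinstance(seg, Insertion):
                pos = n - (seg.position + len(seg.text))
                out.append(Insertion(reverse_complement(seg.text), pos))
            else:
                pos = n - (seg.position + len(seg.observed))
                out.append(
                    Deletion(
                        reverse_complement(seg.text),
                        pos,
                        reverse_complement(seg.observed),
                        reverse_complement(seg.motif),
                    )
                )
        return RepeatStructure(
            tuple(out),
            reverse_complement(self.sequence),
            self.exact_bases,
            self.indel_bases,
            self.mismatch_bases,
        )


def render(structure: RepeatStructure) -> str:
    """Canonical text form: ``[ATCT]3``, literals verbatim, ``+BASES``/``-BASES`` indels."""
    parts: list[str] = []
    for seg in structure.segments:
        if isinstance(seg, RepeatRun):
            parts.append(f"[{seg.motif}]{seg.count}")
        elif isinstance(seg, Literal):
            parts.append(seg.text)
        elif isinstance(seg, Insertion):
            parts.append(f"+{seg.text}")
        else:
            parts.append(f"-{seg.text}")
    return " ".join(parts)


_RENDER_TOKEN = re.compile(r"\[(?P<motif>[ACGT]+)\](?P<count>\d+)|\+(?P<ins>[ACGT]+)|-(?P<dele>[ACGT]+)|(?P<lit>[ACGT]+)")


def parse_render(text: str) -> list[tuple[str, str, int]]:
    """Parse a rendered structure back into (kind, bases, count) tokens.

    Kinds are ``repeat``, ``literal``, ``insertion``, ``deletion``; used to
    verify that rendering is invertible at the token level.
    """
    tokens: list[tuple[str, str, int]] = []
    for part in text.split():
        m = _RENDER_TOKEN.fullmatch(part)
        if m is None:
            raise ValueError(f"unparseable rendered token: {part!r}")
        if m.group("motif"):
            tokens.append(("repeat", m.group("motif"), int(m.group("count"))))
        elif m.group("ins"):
            tokens.append(("insertion", m.group("ins"), 1))
        elif m.group("dele"):
            tokens.append(("deletion", m.group("dele"), 1))
        else:
            tokens.append(("literal", m.group("lit"), 1))
    return tokens


# ---------------------------------------------------------------------------
# Decomposition dynamic program

# Internal atomic events carried through the DP before coalescing:
#   ("flank5"/"flank3"/"mismatch"/"partial", bases, pos)
#   ("copy", motif, pos)
#   ("del", motif, pos, observed, deleted)
#   ("ins", bases, pos)

_START, _MID, _INS = 0, 1, 2  # phase within a block


def decompose(
    sequence: str,
    spec: MotifSpec,
    *,
    flank_budget: int = 20,
) -> RepeatStructure:
    """Decompose ``sequence`` against an already-oriented ``spec``.

    Returns a :class:`RepeatStructure`; check ``.ok`` — when the sequence
    cannot be explained under the pattern with sub-motif-length indels, the
    returned structure carries the best partial explanation with its
    unexplained bases as ``mismatch`` literals.
    """
    if not sequence:
        raise ValueError("cannot decompose an empty sequence")
    sequence = sequence.upper()
    if not _DNA_RE.match(sequence):
        raise ValueError(f"non-DNA character in sequence: {sequence!r}")
    s = sequence
    n = len(s)
    blocks = spec.blocks
    nb = len(blocks)

    # Cost tuples: (-exact, mismatch, indel, literal) — lexicographic minimum,
    # i.e. maximise exact-repeat bases, then minimise unexplained bases, then
    # indel bases, then literal (flank/partial) bases.
    INF = (float("inf"),) * 4

    def add(a, b):
        return tuple(x + y for x, y in zip(a, b))

    @lru_cache(maxsize=None)
    def best(i: int, b: int, phase: int):
        """Best (cost, events) explaining s[i:] with blocks[b:]; phase is
        position within block b.  Events are returned as a tuple (so they
        memoise cheaply); transition order fixes the leftmost tie-break."""
        if b == nb:
            if phase == _INS:
                return INF, ()
            rest = n - i
            if rest == 0:
                return (0, 0, 0, 0), ()
            flank = min(rest, flank_budget)
            mism = rest - flank
            events = []
            if flank:
                events.append(("flank3", s[i : i + flank], i))
            if mism:
                events.append(("mismatch", s[i + flank :], i + flank))
            return (0, mism, 0, flank), tuple(events)

        blk = blocks[b]
        L = len(blk.motif)
        cand_cost, cand_ev = INF, ()

        def consider(cost, ev):
            nonlocal cand_cost, cand_ev
            if cost < cand_cost:
                cand_cost, cand_ev = cost, ev

        if not blk.variable:
            if phase == _START:
                k = blk.count_spec
                expansion = blk.motif * k
                if s.startswith(expansion, i):
                    sub_cost, sub_ev = best(i + len(expansion), b + 1, _START)
                    ev = tuple(("copy", blk.motif, i + j * L) for j in range(k)) + sub_ev
                    consider(add(sub_cost, (-k * L, 0, 0, 0)), ev)
                # fixed block may also be skipped only if its count is 0
                if k == 0:
                    consider(*best(i, b + 1, _START))
            return cand_cost, cand_ev

        # Variable block.  Candidate order fixes the leftmost tie-break:
        # exact copies in the current block are considered before anything
        # that pushes bases rightward (skips, flanks, later blocks).
        # exact copy
        if s.startswith(blk.motif, i):
            sub_cost, sub_ev = best(i + L, b, _MID)
            consider(add(sub_cost, (-L, 0, 0, 0)), (("copy", blk.motif, i),) + sub_ev)
        # interrupted copy: motif with a contiguous chunk deleted
        for dstart in range(L):
            for dlen in range(1, L - dstart + 1):
                if dlen >= L:
                    break
                observed = blk.motif[:dstart] + blk.motif[dstart + dlen :]
                if observed and s.startswith(observed, i):
                    deleted = blk.motif[dstart : dstart + dlen]
                    sub_cost, sub_ev = best(i + len(observed), b, _MID)
                    consider(
                        add(sub_cost, (0, 0, dlen, 0)),
                        (("del", blk.motif, i, observed, deleted),) + sub_ev,
                    )

        if phase == _MID:
            # trailing partial copy (proper prefix) closes the block: microvariant
            for p in range(L - 1, 0, -1):
                if s.startswith(blk.motif[:p], i):
                    sub_cost, sub_ev = best(i + p, b + 1, _START)
                    consider(add(sub_cost, (0, 0, 0, p)), (("partial", s[i : i + p], i),) + sub_ev)
            # block ends cleanly
            consider(*best(i, b + 1, _START))
            # insertion between copies (must be followed by another event)
            for il in range(1, L):
                if i + il <= n:
                    sub_cost, sub_ev = best(i + il, b, _INS)
                    consider(add(sub_cost, (0, 0, il, 0)), (("ins", s[i : i + il], i),) + sub_ev)
            # unexplained bases mid-block (escape hatch; makes failures informative)
            for ml in range(L, n - i + 1):
                sub_cost, sub_ev = best(i + ml, b, _INS)
                consider(add(sub_cost, (0, ml, 0, 0)), (("mismatch", s[i : i + ml], i),) + sub_ev)

        if phase == _START:
            # zero copies: move to next block
            consider(*best(i, b + 1, _START))
            # leading 5' flank only before the first block
            if b == 0 and i == 0 and n > 0:
                for f in range(1, min(flank_budget, n) + 1):
                    sub_cost, sub_ev = best(f, 0, _START)
                    consider(add(sub_cost, (0, 0, 0, f)), (("flank5", s[:f], 0),) + sub_ev)
                # beyond-budget leading bases are mismatches
                for f in range(flank_budget + 1, n + 1):
                    sub_cost, sub_ev = best(f, 0, _START)
                    ev = (("flank5", s[:flank_budget], 0), ("mismatch", s[flank_budget:f], flank_budget)) + sub_ev
                    consider(add(sub_cost, (0, f - flank_budget, 0, flank_budget)), ev)

        return cand_cost, cand_ev

    cost, events = best(0, 0, _START)
    best.cache_clear()
    if cost == INF:
        # nothing matched at all: whole sequence is flank+mismatch
        flank = min(n, flank_budget)
        events = [("flank5", s[:flank], 0)]
        if flank < n:
            events.append(("mismatch", s[flank:], flank))
        cost = (0, n - flank, 0, flank)
        events = tuple(events)

    return _coalesce(events, s, cost)


def _coalesce(events, s: str, cost) -> RepeatStructure:
    """Collapse atomic DP events into display segments (runs of exact copies merge)."""
    segments: list[Segment] = []
    run_motif: Optional[str] = None
    run_count = 0

    def flush():
        nonlocal run_motif, run_count
        if run_motif is not None:
            segments.append(RepeatRun(run_motif, run_count))
            run_motif, run_count = None, 0

    for ev in events:
        kind = ev[0]
        if kind == "copy":
            motif = ev[1]
            if run_motif == motif:
                run_count += 1
            else:
                flush()
                run_motif, run_count = motif, 1
        elif kind == "del":
            flush()
            _, motif, pos, observed, deleted = ev
            segments.append(Deletion(deleted, pos, observed, motif))
        elif kind == "ins":
            flush()
            segments.append(Insertion(ev[1], ev[2]))
        elif kind == "partial":
            flush()
            segments.append(Literal(ev[1], "partial"))
        elif kind == "mismatch":
            flush()
            segments.append(Literal(ev[1], "mismatch"))
        else:  # flank5 / flank3
            flush()
            segments.append(Literal(ev[1], "flank"))
    flush()

    neg_exact, mism, indel, _lit = cost
    return RepeatStructure(
        tuple(segments),
        s,
        exact_bases=-neg_exact,
        indel_bases=indel,
        mismatch_bases=int(mism),
    )


def check_allele_consistency(
    structure: RepeatStructure, allele_label: str, motif: str
) -> bool:
    """Check a single-variable-block decomposition against its allele label.

    The integer part of the label should equal the number of full motif
    copies and the fractional digit the length of the trailing partial
    segment (e.g. ``.2`` means two extra bases).  Returns True when
    consistent; callers flag (not reject) mismatches.
    """
    if "." in allele_label:
        whole_s, frac_s = allele_label.split(".", 1)
        whole, frac = int(whole_s), int(frac_s)
    else:
        whole, frac = int(allele_label), 0
    copies = structure.repeat_count(motif)
    partial = sum(
        len(seg.text) for seg in structure.segments
        if isinstance(seg, Literal) and seg.role == "partial"
    )
    return copies == whole and partial == frac


# ---------------------------------------------------------------------------
# Cohort alignment


@dataclass(frozen=True)
class AlignmentRow:
    locus: str
    allele: str
    sample_id: str
    year: Optional[int]
    sequence: str
    read_count: int
    structure: RepeatStructure

    @property
    def rendered(self) -> str:
        return render(self.structure)


@dataclass
class CohortAlignment:
    """Per-(locus, allele) alignment tables over a cohort of samples."""

    rows: list[AlignmentRow] = field(default_factory=list)
    skipped_loci: list[str] = field(default_factory=list)
    failures: list[AlignmentRow] = field(default_factory=list)

    def table(self, locus: str, allele: str) -> list[AlignmentRow]:
        return [r for r in self.rows if r.locus == locus and r.allele == allele]

    def forward_view(self, specs: Sequence[MotifSpec]) -> "CohortAlignment":
        """Display every row on the forward strand.

        Rows whose locus pattern is reverse-oriented have their sequence and
        structure reverse-complemented; forward loci are shown unchanged.
        The row set itself is unchanged.
        """
        rev_loci = {sp.locus for sp in specs if sp.orientation is Orientation.REVERSE}

        def flip(row: AlignmentRow) -> AlignmentRow:
            if row.locus not in rev_loci:
                return row
            return replace(
                row,
                sequence=reverse_complement(row.sequence),
                structure=row.structure.reverse_complement(),
            )

        return CohortAlignment(
            rows=[flip(r) for r in self.rows],
            skipped_loci=list(self.skipped_loci),
            failures=[flip(r) for r in self.failures],
        )


def align_cohort(
    samples: Iterable,
    specs: Sequence[MotifSpec],
    *,
    flank_budget: int = 20,
) -> CohortAlignment:
    """Decompose every typed sequence-based allele in a cohort.

    For each typed allele with a selectable pattern, one row is produced;
    loci with no pattern are collected in ``skipped_loci`` and rows whose
    sequence the pattern cannot explain go to ``failures``.  Output order is
    deterministic: (locus, allele, sample_id).
    """
    result = CohortAlignment()
    skipped: set[str] = set()
    for sample in samples:
        for sa in sample.sequence_alleles:
            if not sa.typed:
                continue
            spec = select_spec(specs, sa.locus, sa.allele_label)
            if spec is None:
                skipped.add(sa.locus)
                continue
            structure = decompose(sa.sequence, orient_spec(spec), flank_budget=flank_budget)
            row = AlignmentRow(
                locus=sa.locus,
                allele=sa.allele_label,
                sample_id=sample.sample_id,
                year=sample.year,
                sequence=sa.sequence,
                read_count=sa.read_count,
                structure=structure,
            )
            (result.rows if structure.ok else result.failures).append(row)
    result.rows.sort(key=lambda r: (r.locus, _allele_sort_key(r.allele), r.sample_id))
    result.failures.sort(key=lambda r: (r.locus, _allele_sort_key(r.allele), r.sample_id))
    result.skipped_loci = sorted(skipped)
    return result


def _allele_sort_key(label: str) -> tuple[float, str]:
    try:
        return (float(label), label)
    except ValueError:
        return (float("inf"), label)
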