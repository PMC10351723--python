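"""Motif grammar, orientation, and decomposition behaviour."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forenstr.repeat_motif import (
    Deletion,
    Insertion,
    Literal,
    MotifBlock,
    MotifParseError,
    MotifSpec,
    Orientation,
    RepeatRun,
    align_cohort,
    check_allele_consistency,
    decompose,
    orient_spec,
    parse_bracket_notation,
    parse_render,
    render,
    reverse_complement,
    select_spec,
)

from oracle import oracle_matches

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


# ---------------------------------------------------------------------------
# bracket notation


@pytest.mark.parametrize(
    "text, expected",
    [
        ("[ATCT]n", [("ATCT", "n")]),
        ("[TCTA]n [TCTG]n", [("TCTA", "n"), ("TCTG", "n")]),
        ("AC[ATCT]n", [("AC", 1), ("ATCT", "n")]),
        ("[TAGA]3", [("TAGA", 3)]),
        ("[TCTA]n TCA [TCTG]2", [("TCTA", "n"), ("TCA", 1), ("TCTG", 2)]),
    ],
)
def test_parse_bracket_notation(text, expected):
    blocks = parse_bracket_notation(text)
    assert [(b.motif, b.count_spec) for b in blocks] == expected


@pytest.mark.parametrize("bad", ["", "  ", "[ATCT", "ATCT]n", "[]n", "[AXCT]n", "[ATCT]n QQ"])
def test_parse_bracket_notation_rejects(bad):
    with pytest.raises(MotifParseError):
        parse_bracket_notation(bad)


def test_parse_matches_recursive_oracle_on_random_patterns():
    """Token-level agreement with a direct regex-free split on 20 random patterns."""
    rng = random.Random(5)
    for _ in range(20):
        blocks = []
        text = ""
        for _ in range(rng.randint(1, 4)):
            motif = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 5)))
            kind = rng.choice(["n", "fixed", "bare"])
            if kind == "n":
                blocks.append((motif, "n"))
                text += f"[{motif}]n "
            elif kind == "fixed":
                k = rng.randint(0, 5)
                blocks.append((motif, k))
                text += f"[{motif}]{k} "
            else:
                blocks.append((motif, 1))
                text += f"{motif} "
        parsed = parse_bracket_notation(text)
        assert [(b.motif, b.count_spec) for b in parsed] == blocks


# ---------------------------------------------------------------------------
# reverse complement and orientation


def test_reverse_complement_examples():
    assert reverse_complement("ATCT") == "AGAT"
    assert reverse_complement("") == ""
    with pytest.raises(ValueError):
        reverse_complement("ATXN")


@settings(max_examples=200, derandomize=True)
@given(dna)
def test_reverse_complement_is_an_involution(s):
    assert reverse_complement(reverse_complement(s)) == s


def test_orient_spec_reverse_flips_blocks_and_complements():
    spec = MotifSpec("CSF1PO", parse_bracket_notation("[ATCT]n"), orientation=Orientation.REVERSE)
    eff = orient_spec(spec)
    assert [b.motif for b in eff.blocks] == ["AGAT"]
    assert eff.orientation is Orientation.FORWARD

    compound = MotifSpec(
        "X", parse_bracket_notation("[TCTA]n [TCTG]n"), orientation=Orientation.REVERSE
    )
    assert [b.motif for b in orient_spec(compound).blocks] == ["CAGA", "TAGA"]


def test_orient_spec_forward_is_identity(motif_specs):
    fwd = [s for s in motif_specs if s.orientation is Orientation.FORWARD][0]
    assert orient_spec(fwd) is fwd


# ---------------------------------------------------------------------------
# spec selection


def test_select_spec_prefers_allele_scope_over_default():
    default = MotifSpec("D2S441", parse_bracket_notation("[TCTA]n"))
    micro = MotifSpec("D2S441", parse_bracket_notation("[TCTA]n TCT"), allele_scope="10.3")
    specs = [default, micro]
    assert select_spec(specs, "D2S441", "10.3") is micro
    assert select_spec(specs, "D2S441", "10") is default
    assert select_spec(specs, "FGA", "22") is None


# ---------------------------------------------------------------------------
# decomposition


SINGLE = MotifSpec("L", (MotifBlock("ATCT", "n"),))


@pytest.mark.parametrize(
    "seq, rendered, exact, indel",
    [
        ("ATCTATCTATCT", "[ATCT]3", 12, 0),
        ("ATCTATCTAATCT", "[ATCT]2 +A [ATCT]1", 12, 1),
        ("ATCTATCTAT", "[ATCT]2 AT", 8, 0),
        ("ATCT", "[ATCT]1", 4, 0),
    ],
)
def test_decompose_single_block(seq, rendered, exact, indel):
    st = decompose(seq, SINGLE)
    assert st.ok
    assert render(st) == rendered
    assert (st.exact_bases, st.indel_bases) == (exact, indel)
    assert st.reconstruct() == seq


def test_decompose_compound_blocks():
    spec = MotifSpec("L2", parse_bracket_notation("[TCTA]n [TCTG]n"))
    st = decompose("TCTATCTATCTGTCTG", spec)
    assert st.ok and render(st) == "[TCTA]2 [TCTG]2"


def test_decompose_keeps_flanks_as_literals():
    st = decompose("GGGATCTATCTATCTCCA", SINGLE)
    assert st.ok
    roles = [s.role for s in st.segments if isinstance(s, Literal)]
    assert roles == ["flank", "flank"]
    assert st.repeat_count("ATCT") == 3


def test_decompose_reports_deletion_shorter_than_motif():
    st = decompose("ATCTATATCT", SINGLE)  # middle copy missing two bases
    assert st.ok and st.indel_bases == 2
    assert any(isinstance(s, Deletion) for s in st.segments)
    assert st.reconstruct() == "ATCTATATCT"


def test_decompose_flags_overlong_gap_as_failure():
    seq = "ATCTATCT" + "G" * 25 + "ATCTATCT"
    st = decompose(seq, SINGLE)
    assert not st.ok
    assert st.mismatch_bases == 25
    assert st.exact_bases == 16  # best partial explanation keeps the repeats
    assert st.reconstruct() == seq


def test_decompose_empty_sequence_rejected():
    with pytest.raises(ValueError):
        decompose("", SINGLE)


def test_decompose_agrees_with_bruteforce_oracle_exhaustively():
    """Every binary sequence up to length 8 against a two-letter motif."""
    import itertools

    spec = MotifSpec("L", (MotifBlock("AT", "n"),))
    for length in range(1, 9):
        for tup in itertools.product("AT", repeat=length):
            s = "".join(tup)
            st = decompose(s, spec)
            assert st.reconstruct() == s
            assert oracle_matches(s, "AT", st), s


def test_indel_lengths_always_below_motif_length():
    rng = random.Random(9)
    spec = MotifSpec("L", (MotifBlock("TCTA", "n"),))
    for _ in range(50):
        core = "TCTA" * rng.randint(3, 8)
        cut = rng.randrange(4, len(core) - 4)
        seq = core[:cut] + "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 3))) + core[cut:]
        st = decompose(seq, spec)
        for indel in st.indels:
            assert len(indel.text) < 4
        assert st.reconstruct() == seq


def test_check_allele_consistency():
    st = decompose("TCTA" * 10 + "TCT", MotifSpec("D2S441", (MotifBlock("TCTA", "n"),)))
    assert check_allele_consistency(st, "10.3", "TCTA")
    assert not check_allele_consistency(st, "10", "TCTA")
    assert not check_allele_consistency(st, "11.3", "TCTA")


# ---------------------------------------------------------------------------
# rendering


def test_render_round_trips_through_parser():
    st = decompose("ATCTATCTAATCT", SINGLE)
    tokens = parse_render(render(st))
    assert tokens == [("repeat", "ATCT", 2), ("insertion", "A", 1), ("repeat", "ATCT", 1)]


def test_render_is_deterministic_for_equal_structures():
    a = decompose("ATCTATCTAATCT", SINGLE)
    b = decompose("ATCTATCTAATCT", SINGLE)
    assert a == b and render(a) == render(b)


def test_structure_reverse_complement_is_involution():
    st = decompose("GGATCTATCTAATCTAT", SINGLE)
    rc = st.reverse_complement()
    assert rc.reconstruct() == reverse_complement(st.sequence)
    assert rc.reverse_complement() == st


# ---------------------------------------------------------------------------
# cohort alignment


def test_align_cohort_rows_and_determinism(small_cohort, motif_specs):
    _, records, _ = small_cohort
    result = align_cohort(records, motif_specs)
    typed = sum(1 for r in records for sa in r.sequence_alleles if sa.typed)
    assert len(result.rows) + len(result.failures) == typed
    assert not result.failures
    keys = [(r.locus, float(r.allele), r.sample_id) for r in result.rows]
    assert keys == sorted(keys)
    again = align_cohort(records, motif_specs)
    assert [(r.sample_id, r.rendered) for r in again.rows] == [
        (r.sample_id, r.rendered) for r in result.rows
    ]


def test_align_cohort_skips_loci_without_specs(small_cohort, motif_specs):
    _, records, _ = small_cohort
    partial = [s for s in motif_specs if s.locus != "TPOX"]
    result = align_cohort(records, partial)
    assert result.skipped_loci == ["TPOX"]
    assert all(r.locus != "TPOX" for r in result.rows)


def test_forward_view_is_a_display_involution(small_cohort, motif_specs):
    """Toggling the strand view reverse-complements reverse-locus sequences only."""
    _, records, _ = small_cohort
    result = align_cohort(records, motif_specs)
    flipped = result.forward_view(motif_specs)
    assert len(flipped.rows) == len(result.rows)
    rev_loci = {s.locus for s in motif_specs if s.orientation is Orientation.REVERSE}
    for before, after in zip(result.rows, flipped.rows):
        if before.locus in rev_loci:
            assert after.sequence == reverse_complement(before.sequence)
            assert after.structure.reverse_complement() == before.structure
        else:
            assert after == before


def test_alignment_invariant_under_orientation_flip(small_cohort):
    """Flipping a spec's orientation together with reverse-complementing every
    input sequence leaves the decomposition equivalent up to display."""
    spec_fwd = MotifSpec("T", (MotifBlock("AATG", "n"),), orientation=Orientation.FORWARD)
    spec_rev = MotifSpec("T", (MotifBlock("AATG", "n"),), orientation=Orientation.REVERSE)
    seq = "AATG" * 5 + "AA"
    st_fwd = decompose(seq, orient_spec(spec_fwd))
    st_rev = decompose(reverse_complement(seq), orient_spec(spec_rev))
    flipped_back = st_rev.reverse_complement()
    assert flipped_back.reconstruct() == seq
    assert render(flipped_back) == render(st_fwd)
    assert (st_rev.exact_bases, st_rev.indel_bases) == (st_fwd.exact_bases, st_fwd.indel_bases)
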