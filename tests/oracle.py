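"""Independent brute-force oracles used by the test suite.

The segmentation oracle re-states the decomposition grammar from scratch as
a set-valued recursion: for a single variable motif block it enumerates the
cost of *every* admissible segmentation of a sequence (flanks at the ends,
exact copies, interrupted copies missing a contiguous sub-motif chunk,
insertions shorter than the motif between copies, unexplained runs of at
least motif length between copies, an optional trailing partial prefix) and
returns the lexicographic optimum.  It shares no code with the dynamic
program it checks.

Cost tuples are (-exact_bases, mismatch_bases, indel_bases, literal_bases),
compared lexicographically; smaller is better.
"""

from __future__ import annotations

from functools import lru_cache


def oracle_best_cost(seq: str, motif: str, budget: int = 20) -> tuple:
    """Optimal decomposition cost of ``seq`` against ``[motif]n``."""
    n = len(seq)
    L = len(motif)

    # every way one copy event can appear in the sequence: (consumed, exact, indel)
    events: list[tuple[str, int, int]] = [(motif, L, 0)]
    seen = {motif}
    for dstart in range(L):
        for dlen in range(1, L):
            if dstart + dlen > L:
                break
            observed = motif[:dstart] + motif[dstart + dlen :]
            if observed and observed not in seen:
                seen.add(observed)
                events.append((observed, 0, dlen))
            elif observed in seen and observed != motif:
                pass  # same observed text, same cost class already listed
    partials = [motif[:p] for p in range(1, L)]

    best = None
    for f5 in range(n + 1):
        lead_lit = min(f5, budget)
        lead_mis = f5 - lead_lit
        for f3 in range(n - f5 + 1):
            tail_lit = min(f3, budget)
            tail_mis = f3 - tail_lit
            end = n - f3
            if f5 == end:
                body = {(0, 0, 0, 0)}
            else:
                body = body_costs_window(seq[f5:end], motif, events, partials)
            for e, d, l, m in body:
                cost = (-e, m + lead_mis + tail_mis, d, l + lead_lit + tail_lit)
                if best is None or cost < best:
                    best = cost
    return best


def body_costs_window(window: str, motif: str, events, partials) -> set:
    """Costs of explaining the *entire* window as repeat-body events."""
    n = len(window)
    L = len(motif)

    @lru_cache(maxsize=None)
    def rec(i: int, after_gap: bool) -> frozenset:
        out = set()
        if i == n:
            if not after_gap:
                out.add((0, 0, 0, 0))
            return frozenset(out)
        if not after_gap:
            for p in partials:
                if i + len(p) == n and window.startswith(p, i):
                    out.add((0, 0, len(p), 0))
        for text, exact, indel in events:
            if window.startswith(text, i):
                for e, d, l, m in rec(i + len(text), False):
                    out.add((e + exact, d + indel, l, m))
                j = i + len(text)
                for g in range(1, n - j + 1):
                    for e, d, l, m in rec(j + g, True):
                        if g < L:
                            out.add((e + exact, d + indel + g, l, m))
                        else:
                            out.add((e + exact, d + indel, l, m + g))
        return frozenset(out)

    result = set(rec(0, False))
    rec.cache_clear()
    return result


def oracle_matches(seq: str, motif: str, structure, budget: int = 20) -> bool:
    """Does a decomposition achieve the oracle optimum for this sequence?"""
    best = oracle_best_cost(seq, motif, budget)
    if best is None:
        return False
    literal = sum(
        len(s.text)
        for s in structure.segments
        if type(s).__name__ == "Literal" and s.role in ("flank", "partial")
    )
    got = (-structure.exact_bases, structure.mismatch_bases, structure.indel_bases, literal)
    return got == best
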