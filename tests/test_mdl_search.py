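"""MDL search: cost accounting, chunk preservation, and equivalence with
an independent brute-force enumerator at small lengths."""

import itertools

import pytest

from seqlot.lot_language import (
    CHANGE,
    STAY,
    Concat,
    Primitive,
    Repeat,
    evaluate,
    flip_sequence,
    iter_spans,
    to_string,
)
from seqlot.mdl_search import (
    CostSchedule,
    SearchLimits,
    chunk_preserving_candidates,
    description_length,
    lot_complexity,
    run_lengths,
    spans_preserve_chunks,
)

DEFAULT = CostSchedule()


@pytest.mark.parametrize(
    "expr, expected",
    [
        (Concat(tuple(Primitive(STAY) for _ in range(4))), 4.0),
        (Repeat(Primitive(STAY), 4), 3.0),  # primitive + operator + 1 digit
        (Repeat(Primitive(STAY), 16, CHANGE), 5.0),  # + 2 digits + variation
    ],
)
def test_description_length_defaults(expr, expected):
    assert description_length(expr, DEFAULT) == expected


def test_repetition_count_cost_is_digit_count():
    # the digit count, not a rounded logarithm: n = 10 costs 2 digits
    c10 = description_length(Repeat(Primitive(STAY), 10), DEFAULT)
    c9 = description_length(Repeat(Primitive(STAY), 9), DEFAULT)
    assert c10 - c9 == 1.0


class TestChunkPreservingCandidates:
    def test_aaaa_includes_flat_and_compressed_descriptions(self):
        cands = {to_string(e) for e in chunk_preserving_candidates("AAAA")}
        assert "[+0,+0,+0,+0]" in cands
        assert "[+0]^4" in cands

    def test_abba_never_splits_the_inner_run(self):
        seen = 0
        for expr in chunk_preserving_candidates("ABBA"):
            seen += 1
            assert evaluate(expr, "A") == "ABBA"
            assert spans_preserve_chunks(expr, "ABBA")
            for start, end in iter_spans(expr):
                # boundary position 2 splits the BB run: only spans living
                # entirely inside that run may touch it ([AB][BA] forbidden)
                if 2 in (start, end):
                    assert start >= 1 and end <= 3
        assert seen > 0

    def test_ab_candidate_set_is_exactly_enumerable(self):
        cands = {to_string(e) for e in chunk_preserving_candidates("AB")}
        assert cands == {"[+0,b]", "[+0]^2<b>"}


# ---------------------------------------------------------------------------
# Independent brute-force oracle: plain recursive enumeration guided only by
# the target items, chunk preservation checked from its definition on every
# complete candidate, minimum taken over full description lengths.  No
# memoization, no dynamic programming, no cost pruning.
# ---------------------------------------------------------------------------


def _oracle_exprs(seq, i, j, state):
    if j - i == 1:
        yield Primitive(STAY if seq[i] == state else CHANGE)
        return
    length = j - i
    # repetitions (any unit length dividing the span, any variation)
    for n in range(2, length + 1):
        if length % n:
            continue
        unit = length // n
        for variation in (None, STAY, CHANGE):
            for body in _oracle_exprs(seq, i, i + unit, state):
                expr = Repeat(body, n, variation)
                if evaluate(expr, state) == seq[i:j]:
                    yield expr
    # flat concatenations: first piece (non-concat) + remainder
    for p in range(i + 1, j):
        for head in _oracle_exprs(seq, i, p, state):
            if isinstance(head, Concat):
                continue
            for tail in _oracle_exprs(seq, p, j, seq[p - 1]):
                children = (
                    tail.children if isinstance(tail, Concat) else (tail,)
                )
                yield Concat((head,) + children)


def oracle_complexity(seq, schedule=DEFAULT):
    best = None
    for start in ("A", "B"):
        for expr in _oracle_exprs(seq, 0, len(seq), start):
            if not spans_preserve_chunks(expr, seq):
                continue
            cost = description_length(expr, schedule)
            if best is None or cost < best:
                best = cost
    return best


@pytest.mark.parametrize("length", range(1, 9))
def test_search_matches_brute_force_at_all_small_lengths(length):
    for bits in itertools.product("AB", repeat=length - 1):
        seq = "A" + "".join(bits)
        assert lot_complexity(seq).complexity == oracle_complexity(seq), seq


def test_alternate_minimum_is_single_group_with_15_alternations():
    result = lot_complexity("AB" * 8)
    assert isinstance(result.argmin_expr, Repeat)  # one top-level group
    items = evaluate(result.argmin_expr, result.start)
    alternations = sum(1 for a, b in zip(items, items[1:]) if a != b)
    assert alternations == 15


def test_repeat_is_strictly_simplest_roster_sequence(roster):
    repeat = next(r for r in roster if r.name == "Repeat")
    for record in roster:
        if record.name != "Repeat":
            assert record.complexity > repeat.complexity


def test_roster_complexity_hierarchy(roster):
    values = [r.complexity for r in roster]
    assert values == sorted(values)
    assert values[-1] > max(values[:-1])  # Complex strictly maximal


def test_complexity_invariant_under_item_relabeling():
    for seq in ("AABBABABAABBABAB", "AAABBBAABB", "ABBA"):
        assert (
            lot_complexity(seq).complexity
            == lot_complexity(flip_sequence(seq)).complexity
        )


def test_compression_never_beats_trivial_description():
    import numpy as np

    rng = np.random.default_rng(11)
    for _ in range(25):
        seq = "".join(rng.choice(["A", "B"], size=16))
        # trivial primitive-by-primitive description, start = first item
        ops = [STAY] + [
            STAY if b == a else CHANGE for a, b in zip(seq, seq[1:])
        ]
        trivial = Concat(tuple(Primitive(op) for op in ops))
        assert evaluate(trivial, seq[0]) == seq
        cost = description_length(trivial, DEFAULT)
        assert lot_complexity(seq, DEFAULT).complexity <= cost


def test_argmin_reproduces_input_and_counts_candidates(roster):
    for record in roster:
        res = record.lot_result
        assert evaluate(res.argmin_expr, res.start) == record.items
        assert res.n_candidates > 0


def test_depth_cap_restricts_nesting():
    # depth 1 admits one composite level: [+0]^4 but not nested repeats
    assert lot_complexity("AAAA", limits=SearchLimits(max_depth=1)).complexity == 3.0
    shallow = lot_complexity("AABB" * 4, limits=SearchLimits(max_depth=1))
    deep = lot_complexity("AABB" * 4, limits=SearchLimits(max_depth=4))
    assert shallow.complexity > deep.complexity


def test_run_lengths():
    assert run_lengths("AABBBA") == [2, 3, 1]
    assert run_lengths("A") == [1]
    assert run_lengths("") == []
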