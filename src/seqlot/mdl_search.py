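"""Minimum-description-length search over chunk-preserving expressions.

The complexity of a binary sequence is the cost of the cheapest expression
that generates it, where cost is a weighted sum of per-construct charges
(a cost schedule).  The search space is restricted to *chunk-preserving*
expressions: no grouping boundary (Concat child edge or repetition edge)
may fall strictly inside a maximal run of identical items while straddling
material from outside that run — e.g. ABBA parses as [A][BB][A], never as
[AB][BA].  Spans lying entirely inside one run are allowed, which is what
licenses ``[+0]^4`` for AAAA.

The search run-length encodes the input, then runs a memoized dynamic
program over subsequence spans and incoming machine states, proposing
primitives, concatenation splits at admissible boundaries, and repetition
factorizations (with the three variation modes) whose repetition pattern
is compatible with the observed items.  Both start states are tried and
the cheaper version is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

from .lot_language import (
    CHANGE,
    STAY,
    Concat,
    LotExpr,
    Primitive,
    Repeat,
    evaluate,
    flip_sequence,
    iter_spans,
    n_nodes,
    to_string,
)

__all__ = [
    "CostSchedule",
    "SearchLimits",
    "MdlResult",
    "description_length",
    "run_lengths",
    "chunk_preserving_candidates",
    "lot_complexity",
]


def digit_cost(n: int) -> float:
    """Default cost of encoding a repetition count: its number of decimal
    digits, floor(log10 n) + 1."""
    return float(len(str(n)))


@dataclass(frozen=True)
class CostSchedule:
    """Per-construct description-length charges.

    The default schedule charges 1 for *stay* and 2 for *change*, 1 for the
    repetition operator, the decimal digit count of n for the repetition
    count, 1 for a non-trivial variation, and nothing for concatenation.
    Under it the shortest encodings of the two simplest 16-item sequences
    are ``[+0]^16`` (cost 4) and ``[+0]^16<b>`` (cost 5), and complexity
    grows along the experimental sequence hierarchy.
    """

    instruction_cost: Dict[str, float] = field(
        default_factory=lambda: {STAY: 1.0, CHANGE: 2.0}
    )
    repetition_operator_cost: float = 1.0
    repetition_cost: Callable[[int], float] = digit_cost
    variation_cost: Dict[Optional[str], float] = field(
        default_factory=lambda: {None: 0.0, STAY: 1.0, CHANGE: 1.0}
    )
    concat_cost: float = 0.0

    def __post_init__(self):
        if any(v < 0 for v in self.instruction_cost.values()):
            raise ValueError("instruction costs must be nonnegative")
        if any(v < 0 for v in self.variation_cost.values()):
            raise ValueError("variation costs must be nonnegative")
        if self.repetition_operator_cost < 0 or self.concat_cost < 0:
            raise ValueError("costs must be nonnegative")


@dataclass(frozen=True)
class SearchLimits:
    """Caps on the enumerated grammar.

    ``max_depth`` bounds the nesting of composite (Concat/Repeat) nodes.
    ``max_concat_children`` bounds Concat arity; ``None`` leaves it
    unbounded so the primitive-by-primitive fallback always exists.
    """

    max_depth: int = 4
    max_concat_children: Optional[int] = None


@dataclass(frozen=True)
class MdlResult:
    complexity: float
    argmin_expr: LotExpr
    n_candidates: int
    start: str

    @property
    def notation(self) -> str:
        return to_string(self.argmin_expr)


def description_length(expr: LotExpr, schedule: CostSchedule = CostSchedule()) -> float:
    """Cost of an expression: each primitive token is charged once (not per
    executed repetition), each Repeat adds operator + count + variation
    charges, each Concat node adds the concatenation charge."""
    if isinstance(expr, Primitive):
        return schedule.instruction_cost[expr.op]
    if isinstance(expr, Concat):
        return schedule.concat_cost + sum(
            description_length(c, schedule) for c in expr.children
        )
    return (
        description_length(expr.body, schedule)
        + schedule.repetition_operator_cost
        + schedule.repetition_cost(expr.n)
        + schedule.variation_cost[expr.variation]
    )


def run_lengths(seq: str) -> list:
    """Maximal-run decomposition: lengths of consecutive identical items."""
    if not seq:
        return []
    lengths = [1]
    for prev, cur in zip(seq, seq[1:]):
        if cur == prev:
            lengths[-1] += 1
        else:
            lengths.append(1)
    return lengths


def _run_geometry(seq: str) -> Tuple[set, list]:
    """Run boundaries (positions 0..N) and per-position run ids."""
    boundaries = {0, len(seq)}
    run_id = [0] * len(seq)
    rid = 0
    for i in range(1, len(seq)):
        if seq[i] != seq[i - 1]:
            boundaries.add(i)
            rid += 1
        run_id[i] = rid
    return boundaries, run_id


def spans_preserve_chunks(expr: LotExpr, seq: str) -> bool:
    """Definitional check: every grouping span of ``expr`` either lies
    entirely within one maximal run of ``seq`` or has both edges on run
    boundaries."""
    boundaries, run_id = _run_geometry(seq)
    for start, end in iter_spans(expr):
        if start in boundaries and end in boundaries:
            continue
        if run_id[start] == run_id[end - 1]:
            continue
        return False
    return True


class _Search:
    """Memoized minimum-cost search over (span, incoming state)."""

    def __init__(self, seq: str, schedule: CostSchedule, limits: SearchLimits):
        self.seq = seq
        self.schedule = schedule
        self.limits = limits
        self.boundaries, self.run_id = _run_geometry(seq)
        self.memo: Dict[Tuple[int, int, str, int], Optional[tuple]] = {}
        self.n_candidates = 0

    def valid_span(self, i: int, j: int) -> bool:
        if i in self.boundaries and j in self.boundaries:
            return True
        return self.run_id[i] == self.run_id[j - 1]

    def key(self, expr: LotExpr) -> tuple:
        # (cost, node count, notation): deterministic preference order.
        return (
            description_length(expr, self.schedule),
            n_nodes(expr),
            to_string(expr),
        )

    def best(self, i: int, j: int, state: str, depth: int) -> Optional[tuple]:
        """Cheapest (key, expr) generating seq[i:j] from ``state`` with
        composite nesting depth left ``depth``; None if impossible."""
        memo_key = (i, j, state, depth)
        if memo_key in self.memo:
            return self.memo[memo_key]
        self.memo[memo_key] = None  # guard (no cycles occur, spans shrink)
        result = None

        if j - i == 1:
            op = STAY if self.seq[i] == state else CHANGE
            expr = Primitive(op)
            result = (self.key(expr), expr)
            self.n_candidates += 1
        elif depth > 0:
            for cand in self._concat_candidates(i, j, state, depth):
                self.n_candidates += 1
                if result is None or cand[0] < result[0]:
                    result = cand
            for cand in self._repeat_candidates(i, j, state, depth):
                self.n_candidates += 1
                if result is None or cand[0] < result[0]:
                    result = cand

        self.memo[memo_key] = result
        return result

    def _concat_candidates(self, i, j, state, depth):
        """Minimal Concat over admissible split chains, via a prefix DP.

        dp[p] holds the best (key-sum proxy) chain of >= 1 pieces covering
        seq[i:p]; a Concat needs >= 2 pieces, enforced at readout.
        """
        limit = self.limits.max_concat_children
        # dp entries: position -> (cost, nodes, notations, parts, n_parts, end_state)
        dp: Dict[int, tuple] = {
            i: (self.schedule.concat_cost, 1, (), (), 0, state)
        }
        for p in range(i + 1, j + 1):
            best_entry = None
            for q in range(i, p):
                if q == i and p == j:
                    continue  # a single full-span piece is not a Concat
                if q not in dp:
                    continue
                if not self.valid_span(q, p):
                    continue
                prev = dp[q]
                if limit is not None and prev[4] >= limit:
                    continue
                piece = self.best(q, p, prev[5], depth - 1)
                if piece is None:
                    continue
                (pc, pn, ps), pexpr = piece
                entry = (
                    prev[0] + pc,
                    prev[1] + pn,
                    prev[2] + (ps,),
                    prev[3] + (pexpr,),
                    prev[4] + 1,
                    self.seq[p - 1],
                )
                if best_entry is None or (entry[0], entry[1], entry[2]) < (
                    best_entry[0],
                    best_entry[1],
                    best_entry[2],
                ):
                    best_entry = entry
            if best_entry is not None and (p < j or best_entry[4] >= 2):
                dp[p] = best_entry
        if j in dp:
            entry = dp[j]
            expr = Concat(entry[3])
            yield (self.key(expr), expr)

    def _repeat_candidates(self, i, j, state, depth):
        length = j - i
        seq = self.seq
        within_one_run = self.run_id[i] == self.run_id[j - 1]
        for n in range(2, length + 1):
            if length % n:
                continue
            unit = length // n
            cuts = [i + k * unit for k in range(1, n)]
            # Chunk preservation of repetition edges, checked for every
            # repetition (content of each repetition is equal or flipped,
            # so interior runs align; only edge cuts can split runs).
            if not within_one_run and not all(c in self.boundaries for c in cuts):
                continue
            first = seq[i : i + unit]
            for variation in (None, STAY, CHANGE):
                if not self._pattern_matches(i, unit, n, state, variation):
                    continue
                body = self.best(i, i + unit, state, depth - 1)
                if body is None:
                    continue
                expr = Repeat(body[1], n, variation)
                yield (self.key(expr), expr)

    def _pattern_matches(self, i, unit, n, state, variation) -> bool:
        """Would one body, executed n times under ``variation`` from
        ``state``, reproduce seq[i : i + n*unit]?  Decided from the item
        pattern alone: a body's output is its op-string applied to the
        incoming state, so equal op-strings are equivalent to the stated
        item relations."""
        seq = self.seq
        first = seq[i : i + unit]
        if variation is None:
            # Continuous execution: repetition k must realize the same
            # op-string from the state left by repetition k-1.
            ops0 = self._ops(first, state)
            prev_end = first[-1]
            for k in range(1, n):
                rep = seq[i + k * unit : i + (k + 1) * unit]
                if self._ops(rep, prev_end) != ops0:
                    return False
                prev_end = rep[-1]
            return True
        if variation == STAY:
            # Every repetition restarts from the same state: identical items.
            return all(
                seq[i + k * unit : i + (k + 1) * unit] == first for k in range(1, n)
            )
        # CHANGE: start states alternate, so items alternate with the flip.
        flipped = flip_sequence(first)
        for k in range(1, n):
            want = first if k % 2 == 0 else flipped
            if seq[i + k * unit : i + (k + 1) * unit] != want:
                return False
        return True

    @staticmethod
    def _ops(chunk: str, state: str) -> tuple:
        ops = []
        for item in chunk:
            ops.append(STAY if item == state else CHANGE)
            state = item
        return tuple(ops)


def chunk_preserving_candidates(
    seq: str,
    limits: SearchLimits = SearchLimits(),
    start: Optional[str] = None,
):
    """Exhaustively enumerate chunk-preserving expressions for ``seq`` (up
    to the configured depth cap), for one start state (default: the state
    matching a *stay* first emission).

    This is a plain recursive enumeration used for inspection and as a
    generator of the candidate stream; the optimizing search in
    :func:`lot_complexity` shares its admissibility rules but prunes with
    a dynamic program.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    if start is None:
        start = seq[0]
    yield from _enumerate(seq, seq, 0, start, limits.max_depth, limits)


def _enumerate(full_seq, sub, offset, state, depth, limits):
    boundaries, run_id = _run_geometry(full_seq)

    def valid_span(a, b):
        if a in boundaries and b in boundaries:
            return True
        return run_id[a] == run_id[b - 1]

    def rec(i, j, state, depth):
        if j - i == 1:
            op = STAY if full_seq[i] == state else CHANGE
            yield Primitive(op)
            return
        if depth <= 0:
            return
        # Concats: all ordered splits into >=2 admissible pieces.
        yield from _concat_rec(i, j, state, depth)
        # Repeats.
        length = j - i
        within_one_run = run_id[i] == run_id[j - 1]
        for n in range(2, length + 1):
            if length % n:
                continue
            unit = length // n
            cuts = [i + k * unit for k in range(1, n)]
            if not within_one_run and not all(c in boundaries for c in cuts):
                continue
            for variation in (None, STAY, CHANGE):
                for body in rec(i, i + unit, state, depth - 1):
                    expr = Repeat(body, n, variation)
                    if evaluate(expr, state) == full_seq[i:j]:
                        yield expr

    def _concat_rec(i, j, state, depth, n_parts=0):
        limit = limits.max_concat_children
        for p in range(i + 1, j):
            if not valid_span(i, p):
                continue
            for head in rec(i, p, state, depth - 1):
                tail_state = full_seq[p - 1]
                # tail: either a single final piece or further splits
                if valid_span(p, j):
                    for last in rec(p, j, tail_state, depth - 1):
                        if limit is None or n_parts + 2 <= limit:
                            yield _merge(head, last)
                for tail in _concat_rec(p, j, tail_state, depth, n_parts + 1):
                    if limit is None or n_parts + len(tail.children) + 1 <= limit:
                        yield Concat((head,) + tail.children)

    def _merge(head, last):
        return Concat((head, last))

    yield from rec(offset, offset + len(sub), state, depth)


def lot_complexity(
    seq: str,
    schedule: CostSchedule = CostSchedule(),
    limits: SearchLimits = SearchLimits(),
) -> MdlResult:
    """Complexity of ``seq``: the cheapest chunk-preserving expression.

    Both start states are tried (mirror-image "versions"); ties between
    equal-cost minima break by fewer AST nodes, then by notation string.
    """
    if not seq or any(ch not in "AB" for ch in seq):
        raise ValueError("sequence must be a non-empty string over {A, B}")
    best = None
    best_start = None
    total_candidates = 0
    for start in ("A", "B"):
        search = _Search(seq, schedule, limits)
        res = search.best(0, len(seq), start, limits.max_depth)
        total_candidates += search.n_candidates
        if res is not None and (best is None or res[0] < best[0]):
            best = res
            best_start = start
    if best is None:  # unreachable: primitive concat always exists at depth>=1
        raise RuntimeError("no candidate expression found")
    (cost, _, _), expr = best
    assert evaluate(expr, best_start) == seq
    return MdlResult(
        complexity=cost,
        argmin_expr=expr,
        n_candidates=total_candidates,
        start=best_start,
    )
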