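"""Formal language for binary sequences.

Sequences over the two-item alphabet ``{A, B}`` are described by small
programs built from two primitive instructions — *stay* (written ``+0``),
which re-emits the current item, and *change* (written ``b``), which flips
it — combined by concatenation and by repetition with an optional
*variation* applied to the starting item of each successive repetition.
Execution is sequential, Turing-machine style: every instruction acts
relative to the current state, so one program denotes two mirror-image
sequences depending on the start state (the two experimental "versions").

The module provides the expression types, a deterministic evaluator, a
textual notation with parser/printer round-trip, and the segmentation
("bracketing") profile implied by an expression's grouping structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Union

__all__ = [
    "STAY",
    "CHANGE",
    "Primitive",
    "Concat",
    "Repeat",
    "LotExpr",
    "InvalidExpressionError",
    "ParseError",
    "flip_item",
    "flip_sequence",
    "validate",
    "emitted_length",
    "evaluate",
    "to_string",
    "parse",
    "bracket_prediction",
    "iter_spans",
    "n_nodes",
]

STAY = "+0"
CHANGE = "b"

_ITEMS = ("A", "B")
_FLIP = {"A": "B", "B": "A"}


class InvalidExpressionError(ValueError):
    """Raised for structurally ill-formed expressions."""


class ParseError(ValueError):
    """Raised when a notation string cannot be parsed; carries a position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Primitive:
    """A single instruction: ``+0`` (stay) or ``b`` (change)."""

    op: str

    def __post_init__(self):
        if self.op not in (STAY, CHANGE):
            raise InvalidExpressionError(f"unknown primitive op {self.op!r}")


@dataclass(frozen=True)
class Concat:
    """Sequential composition of two or more sub-expressions."""

    children: tuple

    def __post_init__(self):
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 2:
            raise InvalidExpressionError("Concat requires at least 2 children")


@dataclass(frozen=True)
class Repeat:
    """Execute ``body`` ``n`` times (n >= 2).

    ``variation`` controls the start state of repetitions 2..n:

    - ``None``: continue from the current state (plain repetition);
    - ``"+0"``: restart from the previous repetition's start state;
    - ``"b"``: restart from the flip of the previous repetition's start.
    """

    body: "LotExpr"
    n: int
    variation: Union[str, None] = None

    def __post_init__(self):
        if not isinstance(self.n, int) or self.n < 2:
            raise InvalidExpressionError(f"Repeat.n must be an integer >= 2, got {self.n!r}")
        if self.variation not in (None, STAY, CHANGE):
            raise InvalidExpressionError(f"unknown variation {self.variation!r}")


LotExpr = Union[Primitive, Concat, Repeat]


def flip_item(item: str) -> str:
    """Exchange A and B."""
    return _FLIP[item]


def flip_sequence(seq: str) -> str:
    """Item-wise A<->B exchange (the other sequence "version")."""
    return seq.translate(str.maketrans("AB", "BA"))


def validate(expr: LotExpr) -> None:
    """Recursively check well-formedness (dataclass constructors already do
    most of it; this rejects foreign objects in the tree)."""
    if isinstance(expr, Primitive):
        return
    if isinstance(expr, Concat):
        for child in expr.children:
            validate(child)
        return
    if isinstance(expr, Repeat):
        validate(expr.body)
        return
    raise InvalidExpressionError(f"not a LotExpr node: {expr!r}")


def emitted_length(expr: LotExpr) -> int:
    if isinstance(expr, Primitive):
        return 1
    if isinstance(expr, Concat):
        return sum(emitted_length(c) for c in expr.children)
    if isinstance(expr, Repeat):
        return expr.n * emitted_length(expr.body)
    raise InvalidExpressionError(f"not a LotExpr node: {expr!r}")


def n_nodes(expr: LotExpr) -> int:
    """Number of AST nodes (used for deterministic tie-breaking)."""
    if isinstance(expr, Primitive):
        return 1
    if isinstance(expr, Concat):
        return 1 + sum(n_nodes(c) for c in expr.children)
    return 1 + n_nodes(expr.body)


def _run(expr: LotExpr, state: str, out: list) -> str:
    """Execute ``expr`` from ``state``; append items to ``out``; return the
    new current state (the last emitted item)."""
    if isinstance(expr, Primitive):
        item = state if expr.op == STAY else _FLIP[state]
        out.append(item)
        return item
    if isinstance(expr, Concat):
        for child in expr.children:
            state = _run(child, state, out)
        return state
    # Repeat
    rep_start = state
    state = _run(expr.body, state, out)
    for _ in range(expr.n - 1):
        if expr.variation == STAY:
            state = rep_start
        elif expr.variation == CHANGE:
            state = _FLIP[rep_start]
        rep_start = state
        state = _run(expr.body, state, out)
    return state


def evaluate(expr: LotExpr, start: str) -> str:
    """Deterministically expand ``expr`` into its item string.

    ``start`` is the state from which the first instruction executes: a
    leading *stay* emits it unchanged, a leading *change* emits its flip.
    """
    if start not in _ITEMS:
        raise ValueError(f"start state must be 'A' or 'B', got {start!r}")
    validate(expr)
    out: list = []
    _run(expr, start, out)
    return "".join(out)


# ---------------------------------------------------------------------------
# Textual notation
#
#   expr     := primitive | group
#   group    := "[" expr ("," expr)* "]" repeat?
#   repeat   := "^" integer variation?
#   variation:= "<" primitive ">"
#   primitive:= "+0" | "b"
#
# A bracketed single expression must carry "^n" (it is a Repeat); bracketed
# comma lists without "^n" are Concats.  "to_string" emits the body of a
# Concat-bodied Repeat without doubled brackets, e.g. "[+0,b]^3".
# ---------------------------------------------------------------------------


def to_string(expr: LotExpr) -> str:
    """Serialize to the bracket/caret notation; round-trips with parse."""
    validate(expr)
    if isinstance(expr, Primitive):
        return expr.op
    if isinstance(expr, Concat):
        return "[" + ",".join(to_string(c) for c in expr.children) + "]"
    body = expr.body
    if isinstance(body, Concat):
        inner = ",".join(to_string(c) for c in body.children)
    else:
        inner = to_string(body)
    var = f"<{expr.variation}>" if expr.variation is not None else ""
    return f"[{inner}]^{expr.n}{var}"


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, message: str) -> ParseError:
        return ParseError(message, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, ch: str) -> None:
        if self.peek() != ch:
            raise self.error(f"expected {ch!r}, found {self.peek()!r}")
        self.pos += 1

    def parse_primitive(self) -> Primitive:
        if self.text.startswith(STAY, self.pos):
            self.pos += len(STAY)
            return Primitive(STAY)
        if self.text.startswith(CHANGE, self.pos):
            self.pos += len(CHANGE)
            return Primitive(CHANGE)
        raise self.error("expected primitive '+0' or 'b'")

    def parse_expr(self) -> LotExpr:
        if self.peek() == "[":
            return self.parse_group()
        return self.parse_primitive()

    def parse_group(self) -> LotExpr:
        self.expect("[")
        parts = [self.parse_expr()]
        while self.peek() == ",":
            self.pos += 1
            parts.append(self.parse_expr())
        self.expect("]")
        if self.peek() == "^":
            self.pos += 1
            digits_start = self.pos
            while self.peek().isdigit():
                self.pos += 1
            if self.pos == digits_start:
                raise self.error("expected repetition count after '^'")
            n = int(self.text[digits_start : self.pos])
            variation = None
            if self.peek() == "<":
                self.pos += 1
                variation = self.parse_primitive().op
                self.expect(">")
            body = parts[0] if len(parts) == 1 else Concat(tuple(parts))
            try:
                return Repeat(body, n, variation)
            except InvalidExpressionError as exc:
                raise self.error(str(exc)) from exc
        if len(parts) == 1:
            raise self.error("bracketed single expression requires '^n'")
        return Concat(tuple(parts))


def parse(text: str) -> LotExpr:
    """Parse the bracket/caret notation (e.g. ``"[+0]^16<b>"``)."""
    parser = _Parser(text)
    expr = parser.parse_expr()
    if parser.pos != len(text):
        raise parser.error("trailing characters after expression")
    return expr


# ---------------------------------------------------------------------------
# Bracketing prediction
# ---------------------------------------------------------------------------


def iter_spans(expr: LotExpr, offset: int = 0) -> Iterator[tuple]:
    """Yield the (start, end) item spans of every grouping unit in ``expr``:
    each Concat child and each individual repetition of a Repeat, at every
    nesting level, in absolute item coordinates starting at ``offset``.
    """
    if isinstance(expr, Primitive):
        return
    if isinstance(expr, Concat):
        pos = offset
        for child in expr.children:
            length = emitted_length(child)
            yield (pos, pos + length)
            yield from iter_spans(child, pos)
            pos += length
        return
    body_len = emitted_length(expr.body)
    pos = offset
    for _ in range(expr.n):
        yield (pos, pos + body_len)
        yield from iter_spans(expr.body, pos)
        pos += body_len


def bracket_prediction(expr: LotExpr, n_items: int) -> list:
    """Predicted segmentation profile: bracket counts at the ``n_items + 1``
    inter-item intervals (interval i sits before item i+1; interval 0 and
    interval N flank the sequence).

    The whole expression contributes one opening and one closing bracket;
    every grouping span of length >= 2 (Concat child, Repeat repetition)
    contributes one opening bracket at its start interval and one closing
    bracket at its end interval, accumulated across nesting levels.
    Single-item spans mark no group of their own, so e.g. ``[+0]^16<b>``
    predicts brackets only at the two ends — one group of 16 items.
    """
    if emitted_length(expr) != n_items:
        raise ValueError(
            f"expression emits {emitted_length(expr)} items, expected {n_items}"
        )
    counts = [0] * (n_items + 1)
    counts[0] += 1
    counts[n_items] += 1
    for start, end in iter_spans(expr):
        if end - start >= 2:
            counts[start] += 1
            counts[end] += 1
    return counts
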