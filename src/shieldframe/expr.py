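"""Tidy-expression DSL: parse, validate, serialize.

Client calls carry selectors, predicates and clause lists as text in a
``tidy_expr`` argument.  The grammar is a closed-world subset of the R
expression surface used in tidy-style calls: identifiers, literals,
calls, infix comparisons and arithmetic, ``&``/``|`` logic, ``~``
formulas (used by ``case_when`` clauses and ``rename`` pairs), ``:``
name ranges, and comma-separated lists.  ``a$b`` is accepted and
resolved to a plain column reference, since every expression is
evaluated against a single named frame.

There is deliberately no escape into the host language: ``%op%``
operators, ``function``/``\\`` definitions and anything outside the
grammar fail at parse time, and every function call inside an
expression must later pass the privacy profile's allowlist
(:func:`validate_expression`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Union

__all__ = [
    "ExprNode", "Identifier", "NumberLit", "StringLit", "BoolLit",
    "MissingLit", "Call", "Binary", "Unary", "Formula", "NamedArg",
    "ExprList", "ExprParseError", "ValidationReport",
    "parse_tidy_expr", "serialize_expression", "validate_expression",
    "validate_source", "walk",
]

BINARY_OPS = {"&", "|", "<", "<=", ">", ">=", "==", "!=", "+", "-", "*", "/", "^", ":"}
UNARY_OPS = {"!", "-"}


@dataclass(frozen=True)
class Identifier:
    name: str


@dataclass(frozen=True)
class NumberLit:
    value: float | int


@dataclass(frozen=True)
class StringLit:
    value: str


@dataclass(frozen=True)
class BoolLit:
    value: bool


@dataclass(frozen=True)
class MissingLit:
    pass


@dataclass(frozen=True)
class Call:
    fn_name: str
    args: tuple = ()


@dataclass(frozen=True)
class Binary:
    op: str
    lhs: "ExprNode"
    rhs: "ExprNode"

    def __post_init__(self):
        if self.op not in BINARY_OPS:
            raise ValueError(f"unknown binary operator {self.op!r}")


@dataclass(frozen=True)
class Unary:
    op: str
    operand: "ExprNode"

    def __post_init__(self):
        if self.op not in UNARY_OPS:
            raise ValueError(f"unknown unary operator {self.op!r}")


@dataclass(frozen=True)
class Formula:
    lhs: "ExprNode"
    rhs: "ExprNode"


@dataclass(frozen=True)
class NamedArg:
    name: str
    value: "ExprNode"


@dataclass(frozen=True)
class ExprList:
    items: tuple = ()


ExprNode = Union[Identifier, NumberLit, StringLit, BoolLit, MissingLit,
                 Call, Binary, Unary, Formula, NamedArg, ExprList]


class ExprParseError(Exception):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"""
    (?P<ws>\s+)
  | (?P<number>(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?)
  | (?P<ident>[A-Za-z._][A-Za-z0-9._]*)
  | (?P<string>"(?:[^"\\]|\\.)*"|'(?:[^'\\]|\\.)*'|“[^“”]*”|‘[^‘’]*’)
  | (?P<op><=|>=|==|!=|[&|<>+\-*/^!~$:,()=])
""", re.VERBOSE)

_RESERVED = {"function"}  # no host-language function definitions


@dataclass
class _Token:
    kind: str
    text: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i = 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if not m:
            if text[i] == "%":
                raise ExprParseError("%...% operators are not supported", i)
            raise ExprParseError(f"unexpected character {text[i]!r}", i)
        kind = m.lastgroup
        if kind != "ws":
            tokens.append(_Token(kind, m.group(), i))
        i = m.end()
    tokens.append(_Token("eof", "", len(text)))
    return tokens


def _unquote(tok: str) -> str:
    if tok[0] in "“‘":
        return tok[1:-1]
    body = tok[1:-1]
    return re.sub(r"\\(.)", r"\1", body)


class _Parser:
    """Recursive descent with conventional R-like precedence."""

    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def next(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_op(self, op: str) -> _Token:
        tok = self.peek()
        if tok.kind != "op" or tok.text != op:
            raise ExprParseError(f"expected {op!r}, found {tok.text or 'end of input'!r}", tok.pos)
        return self.next()

    def at_op(self, *ops: str) -> bool:
        tok = self.peek()
        return tok.kind == "op" and tok.text in ops

    # entry -----------------------------------------------------------------
    def parse_top(self) -> ExprNode:
        items = [self.parse_item()]
        while self.at_op(","):
            self.next()
            items.append(self.parse_item())
        tok = self.peek()
        if tok.kind != "eof":
            raise ExprParseError(f"unexpected trailing input {tok.text!r}", tok.pos)
        if len(items) == 1:
            node = items[0]
            if isinstance(node, Call) and node.fn_name == "list":
                return ExprList(node.args)
            return node
        return ExprList(tuple(items))

    def parse_item(self) -> ExprNode:
        # possible named argument: IDENT '=' (but not '==')
        tok = self.peek()
        if (tok.kind == "ident"
                and self.tokens[self.i + 1].kind == "op"
                and self.tokens[self.i + 1].text == "="):
            self.next()
            self.next()
            return NamedArg(tok.text, self.parse_formula())
        return self.parse_formula()

    # precedence ladder -----------------------------------------------------
    def parse_formula(self) -> ExprNode:
        lhs = self.parse_or()
        if self.at_op("~"):
            self.next()
            rhs = self.parse_or()
            return Formula(lhs, rhs)
        return lhs

    def parse_or(self) -> ExprNode:
        node = self.parse_and()
        while self.at_op("|"):
            self.next()
            node = Binary("|", node, self.parse_and())
        return node

    def parse_and(self) -> ExprNode:
        node = self.parse_not()
        while self.at_op("&"):
            self.next()
            node = Binary("&", node, self.parse_not())
        return node

    def parse_not(self) -> ExprNode:
        if self.at_op("!"):
            self.next()
            return Unary("!", self.parse_not())
        return self.parse_comparison()

    def parse_comparison(self) -> ExprNode:
        node = self.parse_range()
        if self.at_op("<", "<=", ">", ">=", "==", "!="):
            op = self.next().text
            node = Binary(op, node, self.parse_range())
        return node

    def parse_range(self) -> ExprNode:
        node = self.parse_additive()
        if self.at_op(":"):
            self.next()
            node = Binary(":", node, self.parse_additive())
        return node

    def parse_additive(self) -> ExprNode:
        node = self.parse_term()
        while self.at_op("+", "-"):
            op = self.next().text
            node = Binary(op, node, self.parse_term())
        return node

    def parse_term(self) -> ExprNode:
        node = self.parse_unary()
        while self.at_op("*", "/"):
            op = self.next().text
            node = Binary(op, node, self.parse_unary())
        return node

    def parse_unary(self) -> ExprNode:
        if self.at_op("-"):
            self.next()
            return Unary("-", self.parse_unary())
        return self.parse_power()

    def parse_power(self) -> ExprNode:
        node = self.parse_postfix()
        if self.at_op("^"):
            self.next()
            return Binary("^", node, self.parse_unary())  # right-assoc
        return node

    def parse_postfix(self) -> ExprNode:
        node = self.parse_atom()
        while self.at_op("$"):
            pos = self.next().pos
            tok = self.peek()
            if tok.kind != "ident":
                raise ExprParseError("expected column name after '$'", pos)
            self.next()
            # the frame context is fixed per call, so a$b is just column b
            node = Identifier(tok.text)
        return node

    def parse_atom(self) -> ExprNode:
        tok = self.peek()
        if tok.kind == "number":
            self.next()
            text = tok.text
            value = float(text) if ("." in text or "e" in text or "E" in text) else int(text)
            return NumberLit(value)
        if tok.kind == "string":
            self.next()
            return StringLit(_unquote(tok.text))
        if tok.kind == "ident":
            if tok.text in _RESERVED:
                raise ExprParseError("function definitions are not allowed", tok.pos)
            self.next()
            if tok.text in ("TRUE", "FALSE"):
                return BoolLit(tok.text == "TRUE")
            if tok.text in ("NA", "NA_real_", "NA_integer_", "NA_character_"):
                return MissingLit()
            if self.at_op("("):
                return self.parse_call(tok.text)
            return Identifier(tok.text)
        if tok.kind == "op" and tok.text == "(":
            self.next()
            node = self.parse_formula()
            self.expect_op(")")
            return node
        raise ExprParseError(
            f"unexpected {tok.text!r}" if tok.text else "unexpected end of input", tok.pos)

    def parse_call(self, fn_name: str) -> Call:
        self.expect_op("(")
        args: list[ExprNode] = []
        if not self.at_op(")"):
            args.append(self.parse_item())
            while self.at_op(","):
                self.next()
                args.append(self.parse_item())
        self.expect_op(")")
        return Call(fn_name, tuple(args))


def parse_tidy_expr(text: str) -> ExprNode:
    """Parse a tidy expression string into an AST.

    A top-level ``list(...)`` wrapper or bare comma-separated sequence
    becomes an :class:`ExprList`; anything else parses to a single node.
    Raises :class:`ExprParseError` (with position) on malformed input.
    """
    if not text or not text.strip():
        raise ExprParseError("empty expression", 0)
    return _Parser(text).parse_top()


# ---------------------------------------------------------------------------
# Serializer
# ---------------------------------------------------------------------------

def _ser(node: ExprNode) -> str:
    if isinstance(node, Identifier):
        return node.name
    if isinstance(node, NumberLit):
        v = node.value
        if isinstance(v, int) or (isinstance(v, float) and v.is_integer()):
            return str(int(v))
        return repr(float(v))
    if isinstance(node, StringLit):
        return '"' + node.value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(node, BoolLit):
        return "TRUE" if node.value else "FALSE"
    if isinstance(node, MissingLit):
        return "NA"
    if isinstance(node, Call):
        return f"{node.fn_name}({', '.join(_ser(a) for a in node.args)})"
    if isinstance(node, Binary):
        return f"{_wrap(node.lhs)} {node.op} {_wrap(node.rhs)}"
    if isinstance(node, Unary):
        return f"{node.op}{_wrap(node.operand)}"
    if isinstance(node, Formula):
        return f"{_wrap(node.lhs)} ~ {_wrap(node.rhs)}"
    if isinstance(node, NamedArg):
        return f"{node.name} = {_ser(node.value)}"
    if isinstance(node, ExprList):
        return f"list({', '.join(_ser(i) for i in node.items)})"
    raise TypeError(f"not an ExprNode: {node!r}")


def _wrap(node: ExprNode) -> str:
    # compound children are always parenthesized: structure survives
    # re-parsing regardless of relative precedence
    if isinstance(node, (Binary, Unary, Formula)):
        return f"({_ser(node)})"
    return _ser(node)


def serialize_expression(node: ExprNode) -> str:
    """Render an AST back to text such that re-parsing is the identity."""
    return _ser(node)


# ---------------------------------------------------------------------------
# Validation against a privacy profile
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, code: str, detail: str) -> None:
        self.violations.append((code, detail))


def walk(node: ExprNode):
    """Yield every node in the tree, depth-first, parent first."""
    yield node
    if isinstance(node, Call):
        for a in node.args:
            yield from walk(a)
    elif isinstance(node, Binary):
        yield from walk(node.lhs)
        yield from walk(node.rhs)
    elif isinstance(node, Unary):
        yield from walk(node.operand)
    elif isinstance(node, Formula):
        yield from walk(node.lhs)
        yield from walk(node.rhs)
    elif isinstance(node, NamedArg):
        yield from walk(node.value)
    elif isinstance(node, ExprList):
        for item in node.items:
            yield from walk(item)


def validate_expression(node: ExprNode, profile) -> ValidationReport:
    """Check an AST against a profile's function allowlist and name-length cap.

    Violations are data, not exceptions: callers decide whether to block.
    The check visits every node, so a forbidden call at any depth is
    reported; names are checked per identifier and per function name.
    """
    report = ValidationReport()
    permitted = set(profile.permitted_functions)
    max_len = profile.max_name_length
    for sub in walk(node):
        if isinstance(sub, Call):
            if sub.fn_name not in permitted:
                report.add("FORBIDDEN_FUNCTION",
                           f"function {sub.fn_name!r} is not in the permitted list")
            if len(sub.fn_name) > max_len:
                report.add("NAME_TOO_LONG",
                           f"function name of length {len(sub.fn_name)} exceeds {max_len}")
        elif isinstance(sub, Identifier):
            if len(sub.name) > max_len:
                report.add("NAME_TOO_LONG",
                           f"identifier of length {len(sub.name)} exceeds {max_len}")
        elif isinstance(sub, NamedArg):
            if len(sub.name) > max_len:
                report.add("NAME_TOO_LONG",
                           f"argument name of length {len(sub.name)} exceeds {max_len}")
    return report


def validate_source(text: str, profile) -> ValidationReport:
    """Parse then validate; parse failures become PARSE_ERROR violations."""
    try:
        node = parse_tidy_expr(text)
    except ExprParseError as exc:
        report = ValidationReport()
        report.add("PARSE_ERROR", str(exc))
        return report
    return validate_expression(node, profile)
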