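"""Boolean attribute-filter language for live graph refinement.

Expressions combine comparisons over node or edge attributes with ``and``,
``or``, ``not`` and parentheses, e.g.::

    snp_distance <= 10
    region == 'Tierralta' and not resistance == 'XDR-TB'
    probability >= 0.5 or (snp_distance < 5 and region != 'Other')

Grammar (EBNF)::

    expr        = or_expr ;
    or_expr     = and_expr , { "or" , and_expr } ;
    and_expr    = not_expr , { "and" , not_expr } ;
    not_expr    = "not" , not_expr | atom ;
    atom        = "(" , expr , ")" | comparison ;
    comparison  = NAME , OP , literal ;
    OP          = "==" | "!=" | "<" | "<=" | ">" | ">=" ;
    literal     = NUMBER | STRING ;      (* STRING in single or double quotes *)

Precedence is ``not`` > ``and`` > ``or``; parentheses override. Keywords are
case-insensitive; attribute names are case-sensitive. Ordering operators
(``<``, ``<=``, ``>``, ``>=``) accept only numeric literals — applying one
to a quoted string is rejected at parse time.

Evaluation is total: by default a comparison on an attribute absent from the
map is false (heterogeneously annotated graphs must not abort a filter);
strict mode turns that into an error. Equality unifies integer and float
numerically; a string never equals a number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Union

from .errors import FilterSyntaxError, FilterTypeError, MissingAttributeError

Literal = Union[str, int, float]

_ORDERING_OPS = frozenset({"<", "<=", ">", ">="})
_ALL_OPS = frozenset({"==", "!=", "<", "<=", ">", ">="})

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<op>==|!=|<=|>=|<|>)
  | (?P<lparen>\()
  | (?P<rparen>\))
  | (?P<number>-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
  | (?P<string>'[^']*'|"[^"]*")
  | (?P<name>[A-Za-z_][A-Za-z0-9_.\-]*)
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class Token:
    kind: str  # op | lparen | rparen | number | string | name | and | or | not | end
    text: str
    position: int


def _tokenize(text: str) -> list[Token]:
    tokens: list[Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise FilterSyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        value = m.group()
        if kind != "ws":
            if kind == "name" and value.lower() in ("and", "or", "not"):
                kind = value.lower()
            tokens.append(Token(kind, value, pos))
        pos = m.end()
    tokens.append(Token("end", "", len(text)))
    return tokens


# ---------------------------------------------------------------------------
# expression tree


class FilterExpression:
    """Base class of parsed filter-expression nodes."""

    def evaluate(self, attributes: Mapping[str, Literal], strict: bool = False) -> bool:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:
        return self.to_string()


@dataclass(frozen=True)
class Comparison(FilterExpression):
    attribute: str
    op: str
    literal: Literal

    def evaluate(self, attributes: Mapping[str, Literal], strict: bool = False) -> bool:
        if self.attribute not in attributes:
            if strict:
                raise MissingAttributeError(
                    f"attribute {self.attribute!r} absent from the attribute map"
                )
            return False
        value = attributes[self.attribute]
        lit = self.literal
        value_is_num = isinstance(value, (int, float)) and not isinstance(value, bool)
        lit_is_num = isinstance(lit, (int, float)) and not isinstance(lit, bool)
        if self.op in _ORDERING_OPS:
            # the parser guarantees a numeric literal; a string attribute
            # value is simply incomparable → false
            if not value_is_num:
                return False
            if self.op == "<":
                return value < lit
            if self.op == "<=":
                return value <= lit
            if self.op == ">":
                return value > lit
            return value >= lit
        # equality: ints and floats compare numerically; string vs number
        # is never equal
        if value_is_num != lit_is_num:
            equal = False
        else:
            equal = value == lit
        return equal if self.op == "==" else not equal

    def to_string(self) -> str:
        if isinstance(self.literal, str):
            lit = "'" + self.literal + "'"
        else:
            lit = repr(self.literal)
        return f"{self.attribute} {self.op} {lit}"


@dataclass(frozen=True)
class Not(FilterExpression):
    operand: FilterExpression

    def evaluate(self, attributes: Mapping[str, Literal], strict: bool = False) -> bool:
        return not self.operand.evaluate(attributes, strict=strict)

    def to_string(self) -> str:
        return f"not ({self.operand.to_string()})"


@dataclass(frozen=True)
class And(FilterExpression):
    left: FilterExpression
    right: FilterExpression

    def evaluate(self, attributes: Mapping[str, Literal], strict: bool = False) -> bool:
        # no short-circuit in strict mode semantics: both sides are total anyway
        left = self.left.evaluate(attributes, strict=strict)
        right = self.right.evaluate(attributes, strict=strict)
        return left and right

    def to_string(self) -> str:
        return f"({self.left.to_string()}) and ({self.right.to_string()})"


@dataclass(frozen=True)
class Or(FilterExpression):
    left: FilterExpression
    right: FilterExpression

    def evaluate(self, attributes: Mapping[str, Literal], strict: bool = False) -> bool:
        left = self.left.evaluate(attributes, strict=strict)
        right = self.right.evaluate(attributes, strict=strict)
        return left or right

    def to_string(self) -> str:
        return f"({self.left.to_string()}) or ({self.right.to_string()})"


# ---------------------------------------------------------------------------
# recursive-descent parser


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.index = 0

    @property
    def current(self) -> Token:
        return self.tokens[self.index]

    def advance(self) -> Token:
        token = self.current
        self.index += 1
        return token

    def expect(self, kind: str) -> Token:
        if self.current.kind != kind:
            raise FilterSyntaxError(
                f"expected {kind}, found {self.current.text or 'end of input'!r}",
                self.current.position,
            )
        return self.advance()

    def parse(self) -> FilterExpression:
        expr = self.parse_or()
        if self.current.kind != "end":
            raise FilterSyntaxError(
                f"unexpected trailing input {self.current.text!r}", self.current.position
            )
        return expr

    def parse_or(self) -> FilterExpression:
        left = self.parse_and()
        while self.current.kind == "or":
            self.advance()
            left = Or(left, self.parse_and())
        return left

    def parse_and(self) -> FilterExpression:
        left = self.parse_not()
        while self.current.kind == "and":
            self.advance()
            left = And(left, self.parse_not())
        return left

    def parse_not(self) -> FilterExpression:
        if self.current.kind == "not":
            self.advance()
            return Not(self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> FilterExpression:
        if self.current.kind == "lparen":
            self.advance()
            expr = self.parse_or()
            self.expect("rparen")
            return expr
        return self.parse_comparison()

    def parse_comparison(self) -> Comparison:
        name_token = self.current
        if name_token.kind != "name":
            raise FilterSyntaxError(
                f"expected an attribute name, found {name_token.text or 'end of input'!r}",
                name_token.position,
            )
        self.advance()
        op_token = self.current
        if op_token.kind != "op":
            raise FilterSyntaxError(
                f"expected a comparison operator, found {op_token.text or 'end of input'!r}",
                op_token.position,
            )
        self.advance()
        lit_token = self.current
        if lit_token.kind == "number":
            text = lit_token.text
            literal: Literal = (
                int(text) if re.fullmatch(r"-?\d+", text) else float(text)
            )
        elif lit_token.kind == "string":
            if op_token.text in _ORDERING_OPS:
                raise FilterTypeError(
                    f"ordering operator {op_token.text!r} cannot apply to a string literal",
                    lit_token.position,
                )
            literal = lit_token.text[1:-1]
        else:
            raise FilterSyntaxError(
                f"expected a number or quoted string, found {lit_token.text or 'end of input'!r}",
                lit_token.position,
            )
        self.advance()
        return Comparison(name_token.text, op_token.text, literal)


def parse(text: str) -> FilterExpression:
    """Parse a filter expression string into an expression tree.

    Syntax errors raise :class:`FilterSyntaxError` with the character
    position; an ordering operator applied to a quoted string raises
    :class:`FilterTypeError` at parse time.
    """
    return _Parser(text).parse()


def evaluate(
    expr: FilterExpression, attributes: Mapping[str, Literal], strict: bool = False
) -> bool:
    """Evaluate an expression tree against an attribute map.

    By default a comparison whose attribute is missing is false; with
    ``strict=True`` it raises :class:`MissingAttributeError` naming the
    attribute. The result is always a plain bool.
    """
    return expr.evaluate(attributes, strict=strict)
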