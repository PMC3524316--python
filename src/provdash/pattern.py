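"""Boolean query patterns and their text DSL.

A pattern is an ordered list of equality conditions on facet classes joined
by binary AND/OR connectives, e.g.::

    "Cell Line"='Embryonic stem' AND Organism='Homo Sapiens'

Mixed chains carry no operator precedence: evaluation folds strictly left to
right, ``((c1 op1 c2) op2 c3) ...``. Class names consisting of a single bare
word may appear unquoted; names with spaces are double-quoted. Values are
always single-quoted, with backslash escaping for ``'`` and ``\\``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

CONNECTIVES = ("AND", "OR")

_BARE_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_\-]*")


class PatternError(ValueError):
    pass


class DSLParseError(PatternError):
    """Syntax error in the pattern DSL; carries the 0-based text position."""

    def __init__(self, message: str, text: str, position: int):
        self.position = position
        self.text = text
        super().__init__(f"{message} (at position {position})")

    def annotated(self) -> str:
        """The offending text with a caret under the error position."""
        return f"{self.text}\n{' ' * self.position}^"


@dataclass(frozen=True)
class Condition:
    """One equality test; ``value`` is None while a slot is pending a value."""

    class_name: str
    value: str | None
    operator: str = "="

    def __post_init__(self):
        if self.operator != "=":
            raise PatternError(f"unsupported operator {self.operator!r} (only '=')")


@dataclass(frozen=True)
class QueryPattern:
    conditions: tuple[Condition, ...] = ()
    connectives: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "connectives", tuple(c.upper() for c in self.connectives))
        n = len(self.conditions)
        want = max(n - 1, 0)
        if len(self.connectives) != want:
            raise PatternError(
                f"{n} condition(s) require {want} connective(s), got {len(self.connectives)}"
            )
        for c in self.connectives:
            if c not in CONNECTIVES:
                raise PatternError(f"unknown connective {c!r}")

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def is_complete(self) -> bool:
        return all(c.value is not None for c in self.conditions)

    def prefix(self, n: int) -> "QueryPattern":
        """The pattern restricted to its first ``n`` conditions."""
        n = max(0, min(n, len(self.conditions)))
        return QueryPattern(self.conditions[:n], self.connectives[: max(n - 1, 0)])

    def replace_value(self, index: int, value: str | None) -> "QueryPattern":
        conds = list(self.conditions)
        conds[index] = Condition(conds[index].class_name, value)
        return QueryPattern(tuple(conds), self.connectives)


def _quote_value(v: str) -> str:
    return "'" + v.replace("\\", "\\\\").replace("'", "\\'") + "'"


def _quote_class(name: str) -> str:
    if _BARE_RE.fullmatch(name) and name.upper() not in CONNECTIVES:
        return name
    return '"' + name.replace("\\", "\\\\").replace('"', '\\"') + '"'


def render_pattern(p: QueryPattern) -> str:
    """Serialize a complete pattern to DSL text (inverse of parse_pattern)."""
    parts: list[str] = []
    for i, c in enumerate(p.conditions):
        if c.value is None:
            raise PatternError(f"condition {i} on {c.class_name!r} has no value")
        if i:
            parts.append(p.connectives[i - 1])
        parts.append(f"{_quote_class(c.class_name)}={_quote_value(c.value)}")
    return " ".join(parts)


def _scan_quoted(text: str, i: int, quote: str) -> tuple[str, int]:
    assert text[i] == quote
    out, j = [], i + 1
    while j < len(text):
        ch = text[j]
        if ch == "\\":
            if j + 1 >= len(text):
                raise DSLParseError("dangling escape", text, j)
            out.append(text[j + 1])
            j += 2
        elif ch == quote:
            return "".join(out), j + 1
        else:
            out.append(ch)
            j += 1
    raise DSLParseError(f"unterminated {quote} quote", text, i)


def parse_pattern(text: str) -> QueryPattern:
    """Parse DSL text into a QueryPattern (no ontology validation here)."""
    conditions: list[Condition] = []
    connectives: list[str] = []
    i, n = 0, len(text)

    def skip_ws(i: int) -> int:
        while i < n and text[i].isspace():
            i += 1
        return i

    i = skip_ws(i)
    while i < n:
        if conditions:
            m = _BARE_RE.match(text, i)
            if not m or m.group().upper() not in CONNECTIVES:
                raise DSLParseError("expected connective AND or OR", text, i)
            connectives.append(m.group().upper())
            i = skip_ws(m.end())
            if i >= n:
                raise DSLParseError("pattern ends after connective", text, i)
        if text[i] == '"':
            cls, i = _scan_quoted(text, i, '"')
        else:
            m = _BARE_RE.match(text, i)
            if not m:
                raise DSLParseError("expected a class name", text, i)
            cls = m.group()
            if cls.upper() in CONNECTIVES:
                raise DSLParseError("expected a class name, found connective", text, i)
            i = m.end()
        i = skip_ws(i)
        if i >= n or text[i] != "=":
            raise DSLParseError("expected '=' after class name", text, i)
        i = skip_ws(i + 1)
        if i >= n or text[i] != "'":
            raise DSLParseError("expected single-quoted value", text, i)
        val, i = _scan_quoted(text, i, "'")
        conditions.append(Condition(cls, val))
        i = skip_ws(i)
    return QueryPattern(tuple(conditions), tuple(connectives))
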