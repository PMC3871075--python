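"""Minimal independent DOT grammar checker used as a test oracle.

Implements a tokenizer and recursive-descent parser for the DOT digraph
subset (node statements, chained edge statements, attribute statements,
quoted and bare identifiers).  Deliberately shares no code with the
package's DOT writer so it can serve as an independent syntactic oracle.
"""

from __future__ import annotations

import re

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+|//[^\n]*|\#[^\n]*|/\*.*?\*/)
  | (?P<quoted>"(?:[^"\\]|\\.)*")
  | (?P<arrow>->|--)
  | (?P<sym>[{}\[\];=,])
  | (?P<bare>[A-Za-z0-9_.\-]+)
    """,
    re.VERBOSE | re.DOTALL,
)


class DotSyntaxError(ValueError):
    pass


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise DotSyntaxError(f"unexpected character {text[pos]!r} at offset {pos}")
        pos = m.end()
        if m.lastgroup != "ws":
            tokens.append(m.group())
    return tokens


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise DotSyntaxError("unexpected end of input")
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        tok = self.next()
        if tok != value:
            raise DotSyntaxError(f"expected {value!r}, got {tok!r}")

    def is_id(self, tok: str | None) -> bool:
        if tok is None or tok in "{}[];=," or tok in ("->", "--"):
            return False
        return True

    def parse_id(self) -> str:
        tok = self.next()
        if not self.is_id(tok):
            raise DotSyntaxError(f"expected identifier, got {tok!r}")
        return tok

    def parse(self) -> None:
        kw = self.next()
        if kw not in ("digraph", "graph", "strict"):
            raise DotSyntaxError(f"expected graph keyword, got {kw!r}")
        if kw == "strict":
            kw = self.next()
        if self.peek() != "{":
            self.parse_id()  # optional graph name
        self.expect("{")
        self.parse_stmt_list()
        self.expect("}")
        if self.peek() is not None:
            raise DotSyntaxError(f"trailing tokens after graph: {self.peek()!r}")

    def parse_stmt_list(self) -> None:
        while self.peek() not in (None, "}"):
            self.parse_stmt()
            while self.peek() == ";":
                self.next()

    def parse_stmt(self) -> None:
        first = self.parse_id()
        tok = self.peek()
        if tok == "=":  # graph-level attribute: ID = ID
            self.next()
            self.parse_id()
            return
        if first in ("graph", "node", "edge") and tok == "[":
            self.parse_attr_list()
            return
        while self.peek() in ("->", "--"):
            self.next()
            self.parse_id()
        if self.peek() == "[":
            self.parse_attr_list()

    def parse_attr_list(self) -> None:
        self.expect("[")
        while self.peek() != "]":
            self.parse_id()
            self.expect("=")
            self.parse_id()
            if self.peek() == ",":
                self.next()
        self.expect("]")


def check_dot(text: str) -> None:
    """Raise :class:`DotSyntaxError` unless *text* is a valid DOT graph."""
    _Parser(_tokenize(text)).parse()
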