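"""Mini grammar for guideline conditions.

BPMN 2.0 leaves conditions as opaque strings, which is the main source of
post-editing in generated guideline code.  This module accepts a small
boolean grammar so that emitters can tell *formalized* conditions (which
they may negate, combine, and prove mutually exclusive) from free text
(copied verbatim and flagged for post-editing)::

    expr   := term ("or" term)*
    term   := factor ("and" factor)*
    factor := "not" factor | "(" expr ")" | atom
    atom   := IDENT "=" STRING        -- data comparison, e.g. condition="yes"
            | "completed" "(" IDENT ")" -- task-state predicate
            | IDENT                    -- free boolean

ASTs are plain tuples: ``("or", [..])``, ``("and", [..])``, ``("not", x)``,
``("cmp", ident, literal)``, ``("done", task)``, ``("var", ident)``.
"""

from __future__ import annotations

import re
from typing import Optional

_TOKEN = re.compile(
    r"""\s*(?:
        (?P<str>"[^"]*"|'[^']*')
      | (?P<op>[()=])
      | (?P<word>[A-Za-z_][A-Za-z0-9_.]*)
    )""",
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "completed"}


class ConditionSyntaxError(ValueError):
    """The string is not in the mini grammar (i.e. not formalized)."""


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ConditionSyntaxError(f"unexpected character at {pos}: {text[pos:]!r}")
            break
        pos = m.end()
        tokens.append(m.group("str") or m.group("op") or m.group("word"))
    return tokens


class _Parser:
    def __init__(self, tokens: list[str]) -> None:
        self.tokens = tokens
        self.i = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self, expected: Optional[str] = None) -> str:
        tok = self.peek()
        if tok is None or (expected is not None and tok != expected):
            raise ConditionSyntaxError(f"expected {expected or 'a token'}, got {tok!r}")
        self.i += 1
        return tok

    def expr(self):
        parts = [self.term()]
        while self.peek() == "or":
            self.take()
            parts.append(self.term())
        return parts[0] if len(parts) == 1 else ("or", parts)

    def term(self):
        parts = [self.factor()]
        while self.peek() == "and":
            self.take()
            parts.append(self.factor())
        return parts[0] if len(parts) == 1 else ("and", parts)

    def factor(self):
        tok = self.peek()
        if tok == "not":
            self.take()
            return ("not", self.factor())
        if tok == "(":
            self.take()
            inner = self.expr()
            self.take(")")
            return inner
        return self.atom()

    def atom(self):
        tok = self.take()
        if tok in _KEYWORDS and tok != "completed":
            raise ConditionSyntaxError(f"keyword {tok!r} cannot start an atom")
        if tok == "completed":
            self.take("(")
            name = self.take()
            self.take(")")
            return ("done", name)
        if self.peek() == "=":
            self.take()
            lit = self.take()
            if not (lit[:1] in "\"'" and lit[-1:] in "\"'"):
                raise ConditionSyntaxError(f"comparison literal must be quoted, got {lit!r}")
            return ("cmp", tok, lit[1:-1])
        return ("var", tok)


def parse(text: str):
    """Parse ``text`` into an AST; raise :class:`ConditionSyntaxError` if not formalized."""
    tokens = _tokenize(text)
    if not tokens:
        raise ConditionSyntaxError("empty condition")
    parser = _Parser(tokens)
    ast = parser.expr()
    if parser.peek() is not None:
        raise ConditionSyntaxError(f"trailing tokens: {parser.tokens[parser.i:]!r}")
    return ast


def try_parse(text: str):
    try:
        return parse(text)
    except ConditionSyntaxError:
        return None


def is_formalized(text: str) -> bool:
    return try_parse(text) is not None


def unparse(ast) -> str:
    """Canonical textual form (single spaces, double-quoted literals)."""
    kind = ast[0]
    if kind == "var":
        return ast[1]
    if kind == "done":
        return f"completed({ast[1]})"
    if kind == "cmp":
        return f'{ast[1]}="{ast[2]}"'
    if kind == "not":
        return f"not ({unparse(ast[1])})"
    if kind in ("and", "or"):
        return f" {kind} ".join(f"({unparse(p)})" for p in ast[1])
    raise ValueError(f"bad AST node {ast!r}")


def negate(text: str) -> str:
    """Textual negation; ``not (not x)`` collapses to ``x``."""
    ast = parse(text)
    if ast[0] == "not":
        return unparse(ast[1])
    return f"not ({unparse(ast)})"


def negated_disjunction(texts: list[str]) -> str:
    """The 'otherwise' condition for a default branch: none of ``texts`` holds."""
    if not texts:
        raise ValueError("need at least one sibling condition")
    if len(texts) == 1:
        return negate(texts[0])
    joined = " or ".join(f"({unparse(parse(t))})" for t in texts)
    return f"not ({joined})"


def mutually_exclusive(a: str, b: str) -> bool:
    """Syntactic proof of mutual exclusion (conservative: False means 'unproven').

    Two cases are recognized: comparisons of the same identifier against
    different literals, and one condition being the literal negation of the
    other.
    """
    ast_a, ast_b = try_parse(a), try_parse(b)
    if ast_a is None or ast_b is None:
        return False
    if ast_a[0] == "cmp" and ast_b[0] == "cmp" and ast_a[1] == ast_b[1] and ast_a[2] != ast_b[2]:
        return True
    if ast_a == ("not", ast_b) or ast_b == ("not", ast_a):
        return True
    # negated disjunction covering the other side, e.g. b == not (a or ...)
    for outer, inner in ((ast_a, ast_b), (ast_b, ast_a)):
        if outer[0] == "not":
            body = outer[1]
            parts = body[1] if body[0] == "or" else [body]
            if inner in parts:
                return True
    return False


def completed_references(ast) -> set[str]:
    """Task names referenced by ``completed(...)`` predicates anywhere in the AST."""
    kind = ast[0]
    if kind == "done":
        return {ast[1]}
    if kind == "not":
        return completed_references(ast[1])
    if kind in ("and", "or"):
        out: set[str] = set()
        for part in ast[1]:
            out |= completed_references(part)
        return out
    return set()


def free_atoms(ast) -> set[str]:
    """Identifiers of free boolean / comparison atoms (everything but ``completed``)."""
    kind = ast[0]
    if kind in ("var", "cmp"):
        return {ast[1]}
    if kind == "not":
        return free_atoms(ast[1])
    if kind in ("and", "or"):
        out: set[str] = set()
        for part in ast[1]:
            out |= free_atoms(part)
        return out
    return set()
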