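"""Parser for the supported SPARQL subset.

Grammar: optional ``PREFIX`` declarations, ``SELECT`` with a variable list
or ``*``, and a ``WHERE`` block of dot/semicolon-separated triple patterns,
each optionally followed by ``FILTER regex(?var, "pattern")`` clauses (the
bare ``filter(?var, "pattern")`` spelling is accepted too).  Typographic
quotes are accepted around filter patterns and literals.  The prefixes
``rdf:``, ``rdfs:`` and ``go:`` are built in; any other prefix must be
declared.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import QueryValidationError, SparqlSyntaxError

# a term is ("var", name) or ("const", lexical string)
Term = tuple[str, str]

BUILTIN_PREFIXES = {
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "go": "http://www.geneontology.org/go#",
}
RDF_TYPE = BUILTIN_PREFIXES["rdf"] + "type"


@dataclass(frozen=True)
class TriplePattern:
    s: Term
    p: Term
    o: Term

    @property
    def terms(self) -> tuple[Term, Term, Term]:
        return (self.s, self.p, self.o)

    def variables(self) -> list[str]:
        """Variable names in S, P, O order, without duplicates."""
        out: list[str] = []
        for kind, value in self.terms:
            if kind == "var" and value not in out:
                out.append(value)
        return out


@dataclass(frozen=True)
class RegexFilter:
    var: str
    pattern: str
    pattern_index: int  # triple pattern the clause was attached to


@dataclass
class QuerySpec:
    select: list[str] | None  # None = SELECT *
    patterns: list[TriplePattern]
    filters: list[RegexFilter] = field(default_factory=list)

    def variables(self) -> list[str]:
        out: list[str] = []
        for pat in self.patterns:
            for v in pat.variables():
                if v not in out:
                    out.append(v)
        return out

    def projected(self) -> list[str]:
        if self.select is None:
            return sorted(self.variables())
        return self.select


_QUOTES_OPEN = "\"“”"
_QUOTES_CLOSE = "\"“”"

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<var>\?[A-Za-z_][A-Za-z0-9_]*)
  | (?P<iri><[^<>\s]*>)
  | (?P<string>["“”](?:[^"“”\\]|\\.)*["“”])
  | (?P<pname>[A-Za-z_][A-Za-z0-9_.-]*:[A-Za-z0-9_.-]+)
  | (?P<word>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<punct>[{}().;,*:])
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class _Token:
    kind: str
    value: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise SparqlSyntaxError(
                f"unexpected character {text[pos]!r} at offset {pos}"
            )
        kind = m.lastgroup or ""
        if kind != "ws":
            tokens.append(_Token(kind, m.group(), pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0
        self.prefixes = dict(BUILTIN_PREFIXES)

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise SparqlSyntaxError("query ended unexpectedly")
        self.i += 1
        return tok

    def expect_word(self, word: str) -> None:
        tok = self.take()
        if tok.kind != "word" or tok.value.upper() != word:
            raise SparqlSyntaxError(
                f"expected {word} at offset {tok.pos}, found {tok.value!r}"
            )

    def expect_punct(self, ch: str) -> None:
        tok = self.take()
        if tok.kind != "punct" or tok.value != ch:
            raise SparqlSyntaxError(
                f"expected {ch!r} at offset {tok.pos}, found {tok.value!r}"
            )

    def at_word(self, *words: str) -> bool:
        tok = self.peek()
        return tok is not None and tok.kind == "word" and tok.value.upper() in words

    def at_punct(self, ch: str) -> bool:
        tok = self.peek()
        return tok is not None and tok.kind == "punct" and tok.value == ch

    # -- grammar ----------------------------------------------------------

    def parse(self) -> QuerySpec:
        while self.at_word("PREFIX"):
            self.take()
            tok = self.take()
            if tok.kind != "word":
                raise SparqlSyntaxError(f"bad prefix name at offset {tok.pos}")
            name = tok.value
            colon = self.take()
            if not (colon.kind == "punct" and colon.value == ":"):
                raise SparqlSyntaxError(
                    f"expected ':' after prefix name at offset {colon.pos}"
                )
            iri = self.take()
            if iri.kind != "iri":
                raise SparqlSyntaxError(f"expected <iri> at offset {iri.pos}")
            self.prefixes[name] = iri.value[1:-1]
        self.expect_word("SELECT")
        select: list[str] | None
        if self.at_punct("*"):
            self.take()
            select = None
        else:
            select = []
            while True:
                tok = self.peek()
                if tok is not None and tok.kind == "var":
                    select.append(self.take().value[1:])
                else:
                    break
            if not select:
                raise SparqlSyntaxError("SELECT needs variables or *")
        self.expect_word("WHERE")
        self.expect_punct("{")
        patterns: list[TriplePattern] = []
        filters: list[RegexFilter] = []
        while True:
            while self.at_punct(".") or self.at_punct(";"):
                self.take()
            if self.at_punct("}"):
                self.take()
                break
            if self.at_word("FILTER"):
                if not patterns:
                    raise SparqlSyntaxError("FILTER before any triple pattern")
                filters.append(self._parse_filter(len(patterns) - 1))
                continue
            patterns.append(self._parse_pattern())
        if self.peek() is not None:
            tok = self.peek()
            raise SparqlSyntaxError(
                f"trailing input at offset {tok.pos}: {tok.value!r}"
            )
        spec = QuerySpec(select=select, patterns=patterns, filters=filters)
        _validate(spec)
        return spec

    def _parse_filter(self, pattern_index: int) -> RegexFilter:
        self.expect_word("FILTER")
        if self.at_word("REGEX"):
            self.take()
        self.expect_punct("(")
        var_tok = self.take()
        if var_tok.kind != "var":
            raise SparqlSyntaxError(
                f"FILTER needs a ?variable at offset {var_tok.pos}"
            )
        self.expect_punct(",")
        pat_tok = self.take()
        if pat_tok.kind != "string":
            raise SparqlSyntaxError(
                f"FILTER needs a quoted pattern at offset {pat_tok.pos}"
            )
        self.expect_punct(")")
        return RegexFilter(
            var=var_tok.value[1:],
            pattern=_unquote(pat_tok.value),
            pattern_index=pattern_index,
        )

    def _parse_pattern(self) -> TriplePattern:
        s = self._parse_term(position="subject")
        p = self._parse_term(position="predicate")
        o = self._parse_term(position="object")
        return TriplePattern(s, p, o)

    def _parse_term(self, position: str) -> Term:
        tok = self.take()
        if tok.kind == "var":
            return ("var", tok.value[1:])
        if tok.kind == "iri":
            return ("const", tok.value[1:-1])
        if tok.kind == "string":
            return ("const", _unquote(tok.value))
        if tok.kind == "pname":
            prefix, local = tok.value.split(":", 1)
            if prefix not in self.prefixes:
                raise SparqlSyntaxError(
                    f"unknown prefix {prefix!r} at offset {tok.pos}"
                )
            return ("const", self.prefixes[prefix] + local)
        if tok.kind == "word" and tok.value == "a" and position == "predicate":
            return ("const", RDF_TYPE)
        raise SparqlSyntaxError(
            f"cannot read a {position} term at offset {tok.pos}: {tok.value!r}"
        )


def _unquote(token_text: str) -> str:
    return token_text[1:-1]


def _validate(spec: QuerySpec) -> None:
    if not spec.patterns:
        raise QueryValidationError("WHERE block has no triple patterns")
    all_vars = set(spec.variables())
    for f in spec.filters:
        if f.var not in all_vars:
            raise QueryValidationError(
                f"filter variable ?{f.var} is not bound by any pattern"
            )
    if spec.select:
        for v in spec.select:
            if v not in all_vars:
                raise QueryValidationError(f"selected variable ?{v} is unbound")
    # connectivity of the pattern graph through shared variables
    n = len(spec.patterns)
    if n > 1:
        reached = {0}
        frontier = [0]
        var_sets = [set(p.variables()) for p in spec.patterns]
        while frontier:
            i = frontier.pop()
            for j in range(n):
                if j not in reached and var_sets[i] & var_sets[j]:
                    reached.add(j)
                    frontier.append(j)
        if len(reached) != n:
            raise QueryValidationError(
                "triple patterns are not connected through shared variables"
            )


def parse_sparql(text: str) -> QuerySpec:
    """Parse query text into a validated :class:`QuerySpec`."""
    return _Parser(text).parse()
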