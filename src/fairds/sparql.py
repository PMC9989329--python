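"""A small SPARQL engine for querying metadata graphs.

Projects exported to Turtle are usually loaded into a real triple store;
for desk-scale use this module evaluates queries directly against a
:class:`~fairds.rdf.MetadataGraph`. Supported subset of SPARQL 1.1:

* ``PREFIX`` declarations
* ``SELECT`` with a variable list, ``*``, ``DISTINCT`` and the single
  aggregate form ``SELECT (COUNT(?v) AS ?alias)``
* ``ASK``
* a basic graph pattern: triple patterns joined by ``.``, with the ``a``
  keyword, IRIs, prefixed names, string literals (with ``^^datatype``)
  and booleans
* ``FILTER(?var = <term>)`` equality filters

Blank nodes, OPTIONAL, UNION, property paths and ORDER/GROUP BY are not
supported; a :class:`~fairds.errors.QueryError` is raised for anything
outside the subset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import QueryError
from .rdf import IRI, Literal, MetadataGraph, RDF_TYPE, Term, XSD_BOOLEAN

__all__ = ["SPARQLResult", "evaluate"]


@dataclass
class SPARQLResult:
    """Rows for SELECT (list of var->term dicts) or a boolean for ASK."""

    variables: list[str] = field(default_factory=list)
    rows: list[dict[str, Term]] = field(default_factory=list)
    boolean: bool | None = None

    def column(self, var: str) -> list[Term]:
        return [row.get(var) for row in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


_TOKEN = re.compile(
    r"""
    \s+
  | \#[^\n]*
  | (?P<iri><[^<>\s]*>)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<var>\?[A-Za-z_][A-Za-z0-9_]*)
  | (?P<dtype>\^\^)
  | (?P<word>[A-Za-z][A-Za-z0-9_-]*)
  | (?P<pnamesep>:)
  | (?P<punct>[{}().;,=*])
    """,
    re.VERBOSE,
)


def _tokenize(query: str) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(query):
        m = _TOKEN.match(query, pos)
        if m is None:
            raise QueryError(f"cannot tokenize query at {query[pos:pos+30]!r}")
        pos = m.end()
        for kind in ("iri", "string", "var", "dtype", "word", "pnamesep", "punct"):
            if m.group(kind):
                tokens.append((kind, m.group(kind)))
                break
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]]):
        self.tokens = tokens
        self.i = 0
        self.prefixes: dict[str, str] = {}

    def peek(self) -> tuple[str, str]:
        if self.i >= len(self.tokens):
            return ("eof", "")
        return self.tokens[self.i]

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        self.i += 1
        return tok

    def expect(self, kind: str, value: str | None = None) -> str:
        k, v = self.next()
        if k != kind or (value is not None and v.upper() != value.upper()):
            raise QueryError(f"expected {value or kind}, got {v!r}")
        return v

    def word_is(self, value: str) -> bool:
        k, v = self.peek()
        return k == "word" and v.upper() == value.upper()

    # -- terms -----------------------------------------------------------
    def parse_term(self, allow_var: bool = True):
        kind, value = self.next()
        if kind == "var":
            if not allow_var:
                raise QueryError("variable not allowed here")
            return value
        if kind == "iri":
            return IRI(value[1:-1])
        if kind == "string":
            raw = value[1:-1].replace('\\"', '"').replace("\\\\", "\\")
            if self.peek() == ("dtype", "^^"):
                self.next()
                dt = self.parse_term(allow_var=False)
                if not isinstance(dt, IRI):
                    raise QueryError("datatype must be an IRI")
                return Literal(raw, datatype=dt)
            return Literal(raw)
        if kind == "word":
            if value == "a":
                return RDF_TYPE
            if value in ("true", "false"):
                return Literal(value, datatype=XSD_BOOLEAN)
            # prefixed name: word ':' word?
            if self.peek()[0] == "pnamesep":
                self.next()
                local = ""
                if self.peek()[0] == "word":
                    local = self.next()[1]
                if value not in self.prefixes:
                    raise QueryError(f"undeclared prefix {value!r}")
                return IRI(self.prefixes[value] + local)
        if kind == "pnamesep":  # default prefix ':local'
            local = ""
            if self.peek()[0] == "word":
                local = self.next()[1]
            if "" not in self.prefixes:
                raise QueryError("undeclared default prefix")
            return IRI(self.prefixes[""] + local)
        raise QueryError(f"unexpected token {value!r} in graph pattern")


def _match_pattern(graph: MetadataGraph, pattern, binding: dict):
    """Yield extended bindings for one triple pattern."""
    def resolve(term):
        if isinstance(term, str) and term.startswith("?"):
            return binding.get(term)
        return term

    s, p, o = (resolve(t) for t in pattern)
    for ts, tp, to in graph.triples(
            s if isinstance(s, IRI) else None,
            p if isinstance(p, IRI) else None,
            o if isinstance(o, (IRI, Literal)) else None):
        new = dict(binding)
        ok = True
        for want, got in zip(pattern, (ts, tp, to)):
            if isinstance(want, str) and want.startswith("?"):
                if want in new and new[want] != got:
                    ok = False
                    break
                new[want] = got
        if ok:
            yield new


def evaluate(graph: MetadataGraph, query: str) -> SPARQLResult:
    """Parse and evaluate a query against ``graph``."""
    parser = _Parser(_tokenize(query))

    while parser.word_is("PREFIX"):
        parser.next()
        k, v = parser.next()
        prefix = ""
        if k == "word":
            prefix = v
            parser.expect("pnamesep")
        elif k != "pnamesep":
            raise QueryError("malformed PREFIX declaration")
        iri = parser.next()
        if iri[0] != "iri":
            raise QueryError("PREFIX requires an IRI")
        parser.prefixes[prefix] = iri[1][1:-1]

    form_kind, form = parser.next()
    if form_kind != "word" or form.upper() not in ("SELECT", "ASK"):
        raise QueryError(f"only SELECT and ASK are supported, got {form!r}")
    is_ask = form.upper() == "ASK"

    distinct = False
    select_vars: list[str] = []
    aggregate: tuple[str, str] | None = None  # (counted var or '*', alias)
    if not is_ask:
        if parser.word_is("DISTINCT"):
            parser.next()
            distinct = True
        while True:
            kind, value = parser.peek()
            if kind == "var":
                select_vars.append(parser.next()[1])
            elif (kind, value) == ("punct", "*"):
                parser.next()
                select_vars = ["*"]
            elif (kind, value) == ("punct", "("):
                parser.next()
                parser.expect("word", "COUNT")
                parser.expect("punct", "(")
                k, v = parser.next()
                if (k, v) == ("punct", "*"):
                    counted = "*"
                elif k == "var":
                    counted = v
                else:
                    raise QueryError("COUNT takes a variable or *")
                parser.expect("punct", ")")
                parser.expect("word", "AS")
                alias = parser.expect("var")
                parser.expect("punct", ")")
                aggregate = (counted, alias)
            else:
                break
        if not select_vars and aggregate is None:
            raise QueryError("SELECT clause names no variables")

    if parser.word_is("WHERE"):
        parser.next()
    parser.expect("punct", "{")

    patterns: list[tuple] = []
    filters: list[tuple[str, Term]] = []
    while parser.peek() != ("punct", "}"):
        if parser.word_is("FILTER"):
            parser.next()
            parser.expect("punct", "(")
            var = parser.expect("var")
            parser.expect("punct", "=")
            value = parser.parse_term(allow_var=False)
            parser.expect("punct", ")")
            filters.append((var, value))
            if parser.peek() == ("punct", "."):
                parser.next()
            continue
        s = parser.parse_term()
        p = parser.parse_term()
        o = parser.parse_term()
        patterns.append((s, p, o))
        while parser.peek() == ("punct", ";"):
            parser.next()
            if parser.peek() == ("punct", "}"):
                break
            p = parser.parse_term()
            o = parser.parse_term()
            patterns.append((s, p, o))
        if parser.peek() == ("punct", "."):
            parser.next()
    parser.expect("punct", "}")

    bindings: list[dict] = [{}]
    for pattern in patterns:
        bindings = [new for b in bindings for new in _match_pattern(graph, pattern, b)]
        if not bindings:
            break
    for var, value in filters:
        bindings = [b for b in bindings if b.get(var) == value]

    if is_ask:
        return SPARQLResult(boolean=bool(bindings))

    if aggregate is not None:
        counted, alias = aggregate
        if counted == "*":
            n = len(bindings)
        else:
            n = sum(1 for b in bindings if counted in b)
        return SPARQLResult(
            variables=[alias.lstrip("?")],
            rows=[{alias.lstrip("?"): Literal(
                str(n), datatype=IRI("http://www.w3.org/2001/XMLSchema#integer"))}])

    if select_vars == ["*"]:
        names = sorted({v.lstrip("?") for b in bindings for v in b})
    else:
        names = [v.lstrip("?") for v in select_vars]
    rows = [{name: b.get("?" + name) for name in names} for b in bindings]
    if distinct:
        unique, seen = [], set()
        for row in rows:
            key = tuple(sorted(row.items()))
            if key not in seen:
                seen.add(key)
                unique.append(row)
        rows = unique
    return SPARQLResult(variables=names, rows=rows)
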