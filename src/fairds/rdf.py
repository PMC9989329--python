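"""RDF export of validated project metadata.

A validated project is converted into a knowledge graph: one typed node
per investigation, study, observation unit, sample and assay; parent
links as containment/derivation predicates; one triple per recorded
attribute. The graph serializes to Turtle so it can be loaded into any
triple store and queried cross-project.

Vocabulary bindings (one editable table, :data:`TYPE_BINDINGS` /
namespace constants below): people via FOAF, investigation/study/sample
and assay classes via JERM, the observation-unit class via PPEO,
derivation links via PROV, titles and descriptions via Schema.org and
checklist attributes under a MIxS-rooted namespace. The two inserted
hierarchy levels are linked to the classic ISA material classes with
``owl:equivalentClass``.

No RDF library is assumed: :class:`MetadataGraph` is a plain triple set
with its own Turtle writer and a reader covering the subset of Turtle
this package (and simple OWL ontologies) use — prefixed names, IRIs,
string literals with escapes, datatypes, language tags, ``a``, and
``;``/``,`` continuation.
"""

from __future__ import annotations

import re
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ConfigurationError, FairdsError
from .isa import (
    EQUIVALENCE_MAP,
    IDENTIFIER_FIELDS,
    PARENT_FIELDS,
    Level,
    ProjectMetadata,
)
from .library import PackageLibrary, ValueKind

__all__ = [
    "IRI",
    "Literal",
    "MetadataGraph",
    "export_rdf",
    "merge_graphs",
    "find_samples_where",
    "run_sparql",
    "parse_turtle",
    "DEFAULT_BASE_IRI",
]


class IRI(str):
    """An IRI reference (a distinct type so literals never compare equal)."""

    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{str(self)}>"


@dataclass(frozen=True)
class Literal:
    """An RDF literal: lexical form plus optional datatype or language."""

    value: str
    datatype: IRI | None = None
    lang: str | None = None


Term = IRI | Literal
Triple = tuple[IRI, IRI, Term]

# -- namespaces -------------------------------------------------------------

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
OWL_NS = "http://www.w3.org/2002/07/owl#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"
FOAF_NS = "http://xmlns.com/foaf/0.1/"
JERM_NS = "http://jermontology.org/ontology/JERMOntology#"
PPEO_NS = "http://purl.org/ppeo/PPEO.owl#"
PROV_NS = "http://www.w3.org/ns/prov#"
SCHEMA_NS = "http://schema.org/"
MIXS_NS = "https://w3id.org/mixs/"
ISA_NS = "http://purl.org/isaterms/"

RDF_TYPE = IRI(RDF_NS + "type")
RDFS_LABEL = IRI(RDFS_NS + "label")
OWL_EQUIVALENT_CLASS = IRI(OWL_NS + "equivalentClass")
XSD_BOOLEAN = IRI(XSD_NS + "boolean")
XSD_DATE = IRI(XSD_NS + "date")

DEFAULT_BASE_IRI = "http://fairbydesign.nl/data"

STANDARD_PREFIXES: dict[str, str] = {
    "rdf": RDF_NS,
    "rdfs": RDFS_NS,
    "owl": OWL_NS,
    "xsd": XSD_NS,
    "foaf": FOAF_NS,
    "jerm": JERM_NS,
    "ppeo": PPEO_NS,
    "prov": PROV_NS,
    "schema": SCHEMA_NS,
    "mixs": MIXS_NS,
    "isa": ISA_NS,
}

#: level -> RDF class of the level's entities
TYPE_BINDINGS: dict[Level, IRI] = {
    Level.INVESTIGATION: IRI(JERM_NS + "Investigation"),
    Level.STUDY: IRI(JERM_NS + "Study"),
    Level.OBSERVATION_UNIT: IRI(PPEO_NS + "observation_unit"),
    Level.SAMPLE: IRI(JERM_NS + "Sample"),
    Level.ASSAY: IRI(JERM_NS + "Assay"),
}

#: classic-ISA material classes for the equivalence links
ISA_CLASS_BINDINGS: dict[str, IRI] = {
    "source material": IRI(ISA_NS + "source_material"),
    "sample material": IRI(ISA_NS + "sample_material"),
}

#: child level -> predicate linking a record to its parent
PARENT_PREDICATES: dict[Level, IRI] = {
    Level.STUDY: IRI(SCHEMA_NS + "isPartOf"),
    Level.OBSERVATION_UNIT: IRI(SCHEMA_NS + "isPartOf"),
    Level.SAMPLE: IRI(PROV_NS + "wasDerivedFrom"),
    Level.ASSAY: IRI(PROV_NS + "wasDerivedFrom"),
}

SCHEMA_NAME = IRI(SCHEMA_NS + "name")
SCHEMA_DESCRIPTION = IRI(SCHEMA_NS + "description")
SCHEMA_IDENTIFIER = IRI(SCHEMA_NS + "identifier")
SCHEMA_CONTACT = IRI(SCHEMA_NS + "contactPoint")
FOAF_PERSON = IRI(FOAF_NS + "Person")
FOAF_NAME = IRI(FOAF_NS + "name")
FOAF_MBOX = IRI(FOAF_NS + "mbox")


class MetadataGraph:
    """A set of RDF triples with a namespace table."""

    def __init__(self, triples: Iterable[Triple] = (),
                 namespaces: dict[str, str] | None = None):
        self._triples: set[Triple] = set(triples)
        self.namespaces: dict[str, str] = dict(STANDARD_PREFIXES)
        if namespaces:
            self.namespaces.update(namespaces)

    # -- set-like surface ------------------------------------------------
    def add(self, s: IRI, p: IRI, o: Term) -> None:
        self._triples.add((s, p, o))

    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self._triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triples

    def __eq__(self, other) -> bool:
        return isinstance(other, MetadataGraph) and self._triples == other._triples

    def triples(self, s: IRI | None = None, p: IRI | None = None,
                o: Term | None = None) -> Iterator[Triple]:
        for ts, tp, to in self._triples:
            if (s is None or ts == s) and (p is None or tp == p) \
                    and (o is None or to == o):
                yield ts, tp, to

    def subjects_of_type(self, rdf_class: IRI) -> list[IRI]:
        return sorted({s for s, _, o in self.triples(p=RDF_TYPE, o=rdf_class)})

    def value(self, s: IRI, p: IRI) -> Term | None:
        for _, _, o in self.triples(s=s, p=p):
            return o
        return None

    # -- serialization ---------------------------------------------------
    def serialize(self, path: str | Path | None = None) -> str:
        """Serialize to Turtle; deterministic (sorted subjects/predicates)."""
        used = {ns: prefix for prefix, ns in self.namespaces.items()}
        lines = [
            f"@prefix {prefix}: <{ns}> ."
            for prefix, ns in sorted(self.namespaces.items())
        ]
        lines.append("")
        by_subject: dict[IRI, dict[IRI, list[Term]]] = {}
        for s, p, o in self._triples:
            by_subject.setdefault(s, {}).setdefault(p, []).append(o)
        for s in sorted(by_subject):
            preds = by_subject[s]
            pred_keys = sorted(preds, key=lambda p: (p != RDF_TYPE, p))
            chunks = []
            for p in pred_keys:
                objects = ", ".join(self._format_term(o)
                                    for o in sorted(preds[p], key=_term_sort_key))
                pname = "a" if p == RDF_TYPE else self._format_term(p)
                chunks.append(f"    {pname} {objects}")
            lines.append(self._format_term(s) + "\n" + " ;\n".join(chunks) + " .")
            lines.append("")
        text = "\n".join(lines)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    _LOCAL_RE = re.compile(r"[A-Za-z][A-Za-z0-9_-]*\Z")

    def _format_term(self, term: Term) -> str:
        if isinstance(term, Literal):
            body = '"%s"' % _escape(term.value)
            if term.lang:
                return f"{body}@{term.lang}"
            if term.datatype:
                return f"{body}^^{self._format_term(term.datatype)}"
            return body
        for prefix, ns in sorted(self.namespaces.items()):
            if term.startswith(ns):
                local = term[len(ns):]
                if self._LOCAL_RE.fullmatch(local):
                    return f"{prefix}:{local}"
        return f"<{term}>"


def _term_sort_key(term: Term):
    if isinstance(term, Literal):
        return (1, term.value, term.datatype or "", term.lang or "")
    return (0, str(term), "", "")


def _escape(value: str) -> str:
    return (value.replace("\\", "\\\\").replace('"', '\\"')
            .replace("\n", "\\n").replace("\r", "\\r").replace("\t", "\\t"))


# ---------------------------------------------------------------------------
# Turtle parsing (subset)


class TurtleParseError(FairdsError):
    pass


_TOKEN_RE = re.compile(
    r"""
    \s+
  | \#[^\n]*
  | (?P<iri><[^<>"{}|^`\\\s]*>)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<dtype>\^\^)
  | (?P<keyword>@prefix|@base|a\b|true\b|false\b)
  | (?P<lang>@[A-Za-z][A-Za-z0-9-]*)
  | (?P<pname>[A-Za-z_][A-Za-z0-9_.-]*)?:(?P<plocal>[A-Za-z0-9_][A-Za-z0-9_.-]*)?
  | (?P<number>[+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)
  | (?P<punct>[.;,\[\]()])
    """,
    re.VERBOSE,
)

_ESCAPES = {"n": "\n", "r": "\r", "t": "\t", '"': '"', "\\": "\\",
            "b": "\b", "f": "\f", "'": "'"}


def _unescape(raw: str) -> str:
    out, i = [], 0
    while i < len(raw):
        ch = raw[i]
        if ch == "\\":
            nxt = raw[i + 1]
            if nxt == "u":
                out.append(chr(int(raw[i + 2:i + 6], 16)))
                i += 6
                continue
            if nxt == "U":
                out.append(chr(int(raw[i + 2:i + 10], 16)))
                i += 10
                continue
            out.append(_ESCAPES.get(nxt, nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise TurtleParseError(
                f"cannot tokenize Turtle at offset {pos}: {text[pos:pos+30]!r}")
        pos = m.end()
        if m.group("iri"):
            tokens.append(("iri", m.group("iri")[1:-1]))
        elif m.group("string"):
            tokens.append(("string", _unescape(m.group("string")[1:-1])))
        elif m.group("dtype"):
            tokens.append(("dtype", "^^"))
        elif m.group("lang"):
            tokens.append(("lang", m.group("lang")[1:]))
        elif m.group("keyword"):
            tokens.append(("keyword", m.group("keyword")))
        elif m.group("number"):
            tokens.append(("number", m.group("number")))
        elif m.group("punct"):
            tokens.append(("punct", m.group("punct")))
        elif m.group("pname") is not None or m.group("plocal") is not None \
                or ":" in text[m.start():m.end()]:
            tokens.append(("pname",
                           f"{m.group('pname') or ''}:{m.group('plocal') or ''}"))
    return tokens


def parse_turtle(text: str) -> MetadataGraph:
    """Parse the Turtle subset emitted by this package.

    Supports ``@prefix``, IRIs, prefixed names, string literals with
    escapes, ``^^`` datatypes, language tags, the ``a`` keyword, numeric
    and boolean shorthand, and ``;`` / ``,`` continuation. Blank nodes
    and collections are not supported.
    """
    tokens = _tokenize(text)
    prefixes: dict[str, str] = {}
    graph = MetadataGraph()
    i = 0

    def term(j: int) -> tuple[Term, int]:
        kind, value = tokens[j]
        if kind == "iri":
            return IRI(value), j + 1
        if kind == "pname":
            prefix, _, local = value.partition(":")
            if prefix not in prefixes:
                raise TurtleParseError(f"undeclared prefix {prefix!r}")
            return IRI(prefixes[prefix] + local), j + 1
        if kind == "string":
            if j + 1 < len(tokens) and tokens[j + 1][0] == "lang":
                return Literal(value, lang=tokens[j + 1][1]), j + 2
            if j + 1 < len(tokens) and tokens[j + 1][0] == "dtype":
                dtype, k = term(j + 2)
                if not isinstance(dtype, IRI):
                    raise TurtleParseError("datatype must be an IRI")
                return Literal(value, datatype=dtype), k
            return Literal(value), j + 1
        if kind == "number":
            dt = XSD_NS + ("decimal" if "." in value else "integer")
            if "e" in value.lower():
                dt = XSD_NS + "double"
            return Literal(value, datatype=IRI(dt)), j + 1
        if kind == "keyword" and value in ("true", "false"):
            return Literal(value, datatype=XSD_BOOLEAN), j + 1
        raise TurtleParseError(f"unexpected token {tokens[j]!r}")

    while i < len(tokens):
        kind, value = tokens[i]
        if kind == "keyword" and value == "@prefix":
            pkind, pvalue = tokens[i + 1]
            if pkind != "pname":
                raise TurtleParseError("malformed @prefix")
            ikind, ivalue = tokens[i + 2]
            if ikind != "iri":
                raise TurtleParseError("malformed @prefix IRI")
            prefixes[pvalue.rstrip(":").partition(":")[0]] = ivalue
            if tokens[i + 3] != ("punct", "."):
                raise TurtleParseError("@prefix not terminated by '.'")
            i += 4
            continue
        subject, i = term(i)
        if not isinstance(subject, IRI):
            raise TurtleParseError("subject must be an IRI")
        while True:
            if tokens[i] == ("keyword", "a"):
                predicate: IRI = RDF_TYPE
                i += 1
            else:
                p, i = term(i)
                if not isinstance(p, IRI):
                    raise TurtleParseError("predicate must be an IRI")
                predicate = p
            while True:
                obj, i = term(i)
                graph.add(subject, predicate, obj)
                if i < len(tokens) and tokens[i] == ("punct", ","):
                    i += 1
                    continue
                break
            if i < len(tokens) and tokens[i] == ("punct", ";"):
                i += 1
                if i < len(tokens) and tokens[i] == ("punct", "."):
                    i += 1
                    break
                continue
            if i < len(tokens) and tokens[i] == ("punct", "."):
                i += 1
                break
            raise TurtleParseError("statement not terminated")
    graph.namespaces.update(prefixes)
    return graph


# ---------------------------------------------------------------------------
# export


def slugify(header: str) -> str:
    """Header -> predicate local name: lowercase, non-alphanumerics -> '_'."""
    slug = re.sub(r"[^a-z0-9]+", "_", header.strip().lower()).strip("_")
    return slug or "field"


def entity_iri(base: str, level: Level, identifier: str) -> IRI:
    return IRI(f"{base}/{level.value}/{urllib.parse.quote(identifier, safe='')}")


def _attribute_predicate(name: str, base: str, user_defined: bool) -> IRI:
    if user_defined:
        return IRI(f"{base}/ns/{slugify(name)}")
    return IRI(MIXS_NS + name)


_IRI_RE = re.compile(r"[a-z][a-z0-9+.-]*://\S+\Z", re.IGNORECASE)


def export_rdf(
    project: ProjectMetadata,
    library: PackageLibrary,
    base_iri: str = DEFAULT_BASE_IRI,
    path: str | Path | None = None,
) -> MetadataGraph:
    """Convert a project into an RDF graph (optionally writing Turtle).

    One typed node per record; parent links per
    :data:`PARENT_PREDICATES`; one triple per attribute name/value pair.
    Library attributes become predicates in the MIxS-rooted checklist
    namespace, user-defined columns in the project-local namespace.
    Booleans and dates get XSD datatypes when the library declares the
    kind; everything else is a plain string literal.
    """
    if not _IRI_RE.match(base_iri) or base_iri.endswith("/"):
        raise ConfigurationError(
            f"base IRI must be an absolute IRI without trailing slash: {base_iri!r}")
    attr_kinds = {name: spec.value_kind for name, spec in library.attribute_index().items()}
    graph = MetadataGraph(namespaces={"this": base_iri + "/ns/"})

    # class-level equivalence to the classic ISA material classes
    for level, classic in EQUIVALENCE_MAP:
        graph.add(TYPE_BINDINGS[level], OWL_EQUIVALENT_CLASS,
                  ISA_CLASS_BINDINGS[classic])
        graph.add(ISA_CLASS_BINDINGS[classic], RDFS_LABEL, Literal(classic))

    for level, rec in project.iter_records():
        node = entity_iri(base_iri, level, rec.identifier)
        graph.add(node, RDF_TYPE, TYPE_BINDINGS[level])
        graph.add(node, SCHEMA_IDENTIFIER, Literal(rec.identifier))
        title = getattr(rec, "title", "")
        if title:
            graph.add(node, SCHEMA_NAME, Literal(title))
        description = getattr(rec, "description", "")
        if description:
            graph.add(node, SCHEMA_DESCRIPTION, Literal(description))
        parent_field = PARENT_FIELDS.get(level)
        parent_level = {
            Level.STUDY: Level.INVESTIGATION,
            Level.OBSERVATION_UNIT: Level.STUDY,
            Level.SAMPLE: Level.OBSERVATION_UNIT,
            Level.ASSAY: Level.SAMPLE,
        }.get(level)
        for name, value in rec.attributes.items():
            if not value:
                continue
            if name == IDENTIFIER_FIELDS[level]:
                continue  # already emitted as schema:identifier
            if name == parent_field and parent_level is not None:
                graph.add(node, PARENT_PREDICATES[level],
                          entity_iri(base_iri, parent_level, value))
                continue
            info = rec.cell_info.get(name)
            user_defined = bool(info and info.user_defined)
            predicate = _attribute_predicate(name, base_iri, user_defined)
            kind = None if user_defined else attr_kinds.get(name)
            if kind is ValueKind.BOOLEAN and value in ("true", "false"):
                obj: Term = Literal(value, datatype=XSD_BOOLEAN)
            elif kind is ValueKind.DATE and re.fullmatch(r"\d{4}-\d{2}-\d{2}", value):
                obj = Literal(value, datatype=XSD_DATE)
            else:
                obj = Literal(value)
            graph.add(node, predicate, obj)

    inv = project.investigation
    inv_node = entity_iri(base_iri, Level.INVESTIGATION, inv.identifier)
    for contact in inv.contacts:
        person = IRI(f"{base_iri}/person/"
                     + urllib.parse.quote(slugify(contact.name or contact.email), safe=""))
        graph.add(inv_node, SCHEMA_CONTACT, person)
        graph.add(person, RDF_TYPE, FOAF_PERSON)
        if contact.name:
            graph.add(person, FOAF_NAME, Literal(contact.name))
        if contact.email:
            graph.add(person, FOAF_MBOX, IRI("mailto:" + contact.email))
        if contact.orcid:
            graph.add(person, SCHEMA_IDENTIFIER,
                      IRI("https://orcid.org/" + contact.orcid))

    if path is not None:
        graph.serialize(path)
    return graph


def merge_graphs(graphs: Iterable[MetadataGraph]) -> MetadataGraph:
    """Set-union of the input graphs (associative, commutative, idempotent)."""
    merged = MetadataGraph()
    for graph in graphs:
        merged._triples |= graph._triples
        merged.namespaces.update(graph.namespaces)
    return merged


def find_samples_where(graph: MetadataGraph, attribute: str, value: str) -> list[str]:
    """Identifiers of all sample nodes whose ``attribute`` literal matches.

    ``attribute`` may be a library attribute token, a user-defined column
    header, or a full predicate IRI. Matching is on the literal's lexical
    form; results are sorted lexicographically.
    """
    if _IRI_RE.match(attribute):
        predicates = [IRI(attribute)]
    else:
        predicates = [IRI(MIXS_NS + attribute)]
        slug = slugify(attribute)
        predicates += [IRI(f"{ns}{slug}") for prefix, ns in graph.namespaces.items()
                       if ns.endswith("/ns/")]
    sample_nodes = set(graph.subjects_of_type(TYPE_BINDINGS[Level.SAMPLE]))
    hits = set()
    for predicate in predicates:
        for s, _, o in graph.triples(p=predicate):
            if s in sample_nodes and isinstance(o, Literal) and o.value == value:
                ident = graph.value(s, SCHEMA_IDENTIFIER)
                hits.add(ident.value if isinstance(ident, Literal) else str(s))
    return sorted(hits)


def run_sparql(graph: MetadataGraph, query: str):
    """Evaluate a SPARQL SELECT/ASK query (restricted engine).

    See :mod:`fairds.sparql` for the supported subset.
    """
    from .sparql import evaluate

    return evaluate(graph, query)
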