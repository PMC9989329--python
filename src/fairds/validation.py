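"""Validation of recorded metadata values.

Every cell of a filled workbook is checked against its attribute's
contract: presence for mandatory attributes, the anchored syntax regex
for restricted values, the strict ``true``/``false`` rule for booleans,
ISO 8601 for dates, and membership of the ontology's ``rdfs:label`` set
for ontology terms. On top of the per-cell rules the validator flags
spreadsheet auto-correction artifacts (e.g. a numeric value silently
turned into a calendar date), identifier mismatches between the ISA
levels, and columns unknown to the library (a warning — user-defined
columns are legitimate and end up as predicates in the RDF export).

All applicable rules fire for every cell, so a single pass produces a
complete, cell-addressed report. Values are stripped of surrounding
whitespace before validation. Label matching for ontology terms is
exact after trimming and case folding; no fuzzy matching and no synonym
properties, only ``rdfs:label``.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import ConfigurationError, OntologyError
from .isa import IDENTIFIER_FIELDS, Level, ProjectMetadata
from .library import (
    AttributeSpec,
    PackageLibrary,
    Requirement,
    ValueKind,
    effective_attributes,
)

__all__ = [
    "ValidationIssue",
    "ValidationReport",
    "OntologyIndex",
    "load_ontology",
    "validate_value",
    "detect_autocorrection",
    "validate_links",
    "validate_project",
    "format_valid",
]

ERROR_RULES = frozenset({
    "missing_mandatory", "regex_mismatch", "bad_boolean", "bad_date",
    "ontology_unknown", "duplicate_identifier", "unknown_parent",
})
WARNING_RULES = frozenset({"autocorrect_suspect", "unknown_header", "orphan_record"})


@dataclass(frozen=True)
class ValidationIssue:
    """One problem at one cell (or record, for link rules)."""

    sheet: str
    row: int
    attribute: str
    value: str
    rule: str
    severity: str  # error | warning
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def counts(self) -> dict[str, int]:
        return {"error": len(self.errors), "warning": len(self.warnings)}

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "is_valid": self.is_valid,
            "counts": self.counts,
            "issues": [dataclasses.asdict(i) for i in self.issues],
        }

    def __str__(self) -> str:
        if not self.issues:
            return "valid: no issues"
        width = max(len(i.sheet) for i in self.issues)
        lines = [f"{'sheet'.ljust(width)}  row  severity  rule                "
                 f"attribute"]
        for i in self.issues:
            lines.append(f"{i.sheet.ljust(width)}  {str(i.row).rjust(3)}  "
                         f"{i.severity:<8}  {i.rule:<18}  {i.attribute}: "
                         f"{i.message}")
        return "\n".join(lines)


def _issue(rule: str, attribute: str, value: str, message: str,
           sheet: str = "", row: int = 0) -> ValidationIssue:
    severity = "error" if rule in ERROR_RULES else "warning"
    return ValidationIssue(sheet, row, attribute, value, rule, severity, message)


# ---------------------------------------------------------------------------
# ontology indices


@dataclass
class OntologyIndex:
    """The ``rdfs:label`` vocabulary of one ontology document."""

    source: str
    label_to_iri: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def normalize(label: str) -> str:
        return label.strip().casefold()

    @property
    def labels(self) -> set[str]:
        return set(self.label_to_iri)

    def __contains__(self, label: str) -> bool:
        return self.normalize(label) in self.label_to_iri

    def term_iri(self, label: str) -> str | None:
        return self.label_to_iri.get(self.normalize(label))

    def __len__(self) -> int:
        return len(self.label_to_iri)


_RDF_ABOUT = "{http://www.w3.org/1999/02/22-rdf-syntax-ns#}about"
_RDF_ID = "{http://www.w3.org/1999/02/22-rdf-syntax-ns#}ID"
_RDFS_LABEL_TAG = "{http://www.w3.org/2000/01/rdf-schema#}label"


def _labels_from_rdfxml(text: str) -> dict[str, str]:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise OntologyError(f"cannot parse RDF/XML ontology: {exc}") from exc
    labels: dict[str, str] = {}
    for element in root.iter():
        subject = element.get(_RDF_ABOUT) or element.get(_RDF_ID)
        if subject is None:
            continue
        for child in element:
            if child.tag == _RDFS_LABEL_TAG and child.text:
                labels[OntologyIndex.normalize(child.text)] = subject
    return labels


def _labels_from_turtle(text: str) -> dict[str, str]:
    from .rdf import RDFS_LABEL, Literal, parse_turtle

    graph = parse_turtle(text)
    return {
        OntologyIndex.normalize(o.value): str(s)
        for s, p, o in graph.triples(p=RDFS_LABEL)
        if isinstance(o, Literal)
    }


def load_ontology(source: str | Path, cache_dir: str | Path | None = None,
                  offline: bool = False) -> OntologyIndex:
    """Build an :class:`OntologyIndex` from an OWL/RDF document.

    ``source`` may be a local file path or an ``http(s)`` IRI. Remote
    documents are cached on disk (keyed by the IRI) so that repeated
    validation runs never re-download; with ``offline=True`` a cache
    miss is an error instead of a retrieval. RDF/XML and Turtle are
    accepted, distinguished by sniffing the document head.
    """
    source = str(source)
    text: str | None = None
    if source.startswith(("http://", "https://")):
        cache_file = None
        if cache_dir is not None:
            key = hashlib.sha256(source.encode()).hexdigest()[:24]
            cache_file = Path(cache_dir) / f"{key}.rdf"
            if cache_file.exists():
                text = cache_file.read_text(encoding="utf-8")
        if text is None:
            if offline:
                raise OntologyError(
                    f"ontology {source!r} is not cached and offline mode is set")
            import requests

            try:
                response = requests.get(source, timeout=60)
                response.raise_for_status()
            except Exception as exc:
                raise OntologyError(
                    f"cannot retrieve ontology {source!r}: {exc}") from exc
            text = response.text
            if cache_file is not None:
                cache_file.parent.mkdir(parents=True, exist_ok=True)
                cache_file.write_text(text, encoding="utf-8")
    else:
        path = Path(source.removeprefix("file://"))
        if not path.exists():
            raise OntologyError(f"ontology file not found: {path}")
        text = path.read_text(encoding="utf-8")

    head = text.lstrip()[:512]
    if head.startswith("<?xml") or "<rdf:RDF" in head or head.startswith("<rdf"):
        labels = _labels_from_rdfxml(text)
    else:
        labels = _labels_from_turtle(text)
    return OntologyIndex(source=source, label_to_iri=labels)


# ---------------------------------------------------------------------------
# per-value rules

_DATE_RE = re.compile(
    r"\d{4}-(0[1-9]|1[0-2])-(0[1-9]|[12][0-9]|3[01])"
    r"(T\d{2}:\d{2}(:\d{2})?(Z|[+-]\d{2}:\d{2})?)?\Z")
_NUMERIC_RE = re.compile(r"[+-]?(\d+(\.\d*)?|\.\d+)([Ee][+-]?\d+)?\Z")


def _check_date(part: str) -> bool:
    if not _DATE_RE.match(part):
        return False
    try:
        datetime.date.fromisoformat(part[:10])
    except ValueError:
        return False
    return True


def validate_value(
    value: str,
    spec: AttributeSpec,
    ontologies: Mapping[str, OntologyIndex] | None = None,
) -> list[ValidationIssue]:
    """Check one recorded value against its attribute contract.

    Returns an empty list iff the value conforms. An ``ontology_term``
    attribute whose ontology index was not supplied raises
    :class:`~fairds.errors.ConfigurationError` (a configuration problem,
    not a finding about the data).
    """
    value = (value or "").strip()
    if value == "":
        if spec.requirement is Requirement.MANDATORY:
            return [_issue("missing_mandatory", spec.name, value,
                           f"mandatory attribute {spec.name!r} has no value")]
        return []
    parts = [p.strip() for p in value.split(";")] if spec.multivalued else [value]
    issues: list[ValidationIssue] = []
    for part in parts:
        if spec.value_kind is ValueKind.BOOLEAN:
            if part not in ("true", "false"):
                issues.append(_issue(
                    "bad_boolean", spec.name, part,
                    f"{part!r} is not a boolean; use exactly 'true' or 'false'"))
        elif spec.value_kind is ValueKind.DATE:
            if not _check_date(part):
                issues.append(_issue(
                    "bad_date", spec.name, part,
                    f"{part!r} is not an ISO 8601 date (YYYY-MM-DD)"))
        elif spec.value_kind is ValueKind.ONTOLOGY_TERM:
            if ontologies is None or spec.ontology_iri not in ontologies:
                raise ConfigurationError(
                    f"attribute {spec.name!r} requires the ontology index for "
                    f"{spec.ontology_iri!r}, which was not supplied")
            index = ontologies[spec.ontology_iri]
            if part not in index:
                issues.append(_issue(
                    "ontology_unknown", spec.name, part,
                    f"{part!r} is not an rdfs:label in {spec.ontology_iri}"))
        elif spec.syntax_regex is not None:
            if spec.compiled_regex().fullmatch(part) is None:
                issues.append(_issue(
                    "regex_mismatch", spec.name, part,
                    f"{part!r} does not match the pattern "
                    f"{spec.syntax_regex!r}"))
        elif spec.value_kind is ValueKind.NUMERIC:
            if _NUMERIC_RE.match(part) is None:
                issues.append(_issue(
                    "regex_mismatch", spec.name, part,
                    f"{part!r} is not a number"))
    return issues


_EXCEL_EPOCH_MIN, _EXCEL_EPOCH_MAX = 1, 2958465  # 1900-01-01 .. 9999-12-31


def detect_autocorrection(cell: tuple[str, str], spec: AttributeSpec,
                          raw: object = None) -> ValidationIssue | None:
    """Spot spreadsheet auto-conversion artifacts.

    ``cell`` is ``(display string, native type)`` with native types as
    recorded by the parser (``s`` text, ``n`` numeric, ``d`` date,
    ``b`` boolean). Warned cases: a date-typed cell backing a non-date
    attribute (the classic "3-6 became March 6th"), a numeric cell whose
    display string no longer equals the stored value under a text
    attribute, and a date attribute backed by a bare numeric cell that
    reads as a spreadsheet date serial.
    """
    display, native = cell
    if display == "":
        return None
    text_like = spec.value_kind in (
        ValueKind.TEXT, ValueKind.RESTRICTED_TEXT, ValueKind.ONTOLOGY_TERM,
        ValueKind.BOOLEAN,
    )
    if native == "d" and spec.value_kind is not ValueKind.DATE:
        return _issue(
            "autocorrect_suspect", spec.name, display,
            f"cell is date-typed but {spec.name!r} is not a date attribute; "
            f"the spreadsheet may have auto-converted the entry")
    if native == "n" and text_like and raw is not None and display != str(raw):
        return _issue(
            "autocorrect_suspect", spec.name, display,
            f"numeric cell displays {display!r} but stores {raw!r}")
    if native == "n" and spec.value_kind is ValueKind.DATE:
        try:
            serial = int(float(display))
        except ValueError:
            return None
        if _EXCEL_EPOCH_MIN <= serial <= _EXCEL_EPOCH_MAX:
            return _issue(
                "autocorrect_suspect", spec.name, display,
                f"{display!r} reads as a spreadsheet date serial; "
                f"record dates as YYYY-MM-DD text")
    return None


# ---------------------------------------------------------------------------
# cross-level link rules


def validate_links(project: ProjectMetadata, strict: bool = False) -> list[ValidationIssue]:
    """Identifier consistency between the five ISA levels.

    One ``unknown_parent`` error per record whose parent identifier does
    not exist, one ``duplicate_identifier`` error per repeated
    identifier (occurrences after the first), and, in strict mode, one
    ``orphan_record`` warning per study or observation unit without
    descendants.
    """
    issues: list[ValidationIssue] = []
    from .isa import PARENT_FIELDS

    for problem in project.integrity_issues():
        if problem.kind == "unknown_parent":
            attr = PARENT_FIELDS[problem.level]
        else:
            attr = IDENTIFIER_FIELDS[problem.level]
        issues.append(ValidationIssue(
            problem.sheet or problem.level.value, problem.row or 0,
            attr, problem.identifier, problem.kind, "error", problem.message))
    if strict:
        from .isa import children_of

        for level in (Level.STUDY, Level.OBSERVATION_UNIT):
            seen = set()
            for rec in project.records(level):
                if rec.identifier in seen:
                    continue
                seen.add(rec.identifier)
                if not children_of(project, level, rec.identifier):
                    issues.append(_issue(
                        "orphan_record", IDENTIFIER_FIELDS[level], rec.identifier,
                        f"{level.value} {rec.identifier!r} has no descendants",
                        sheet=rec.sheet or level.value, row=rec.row or 0))
    return issues


# ---------------------------------------------------------------------------
# whole-project validation


def _record_specs(library: PackageLibrary, level: Level, package_id: str) -> list[AttributeSpec]:
    if level in (Level.SAMPLE, Level.ASSAY) and package_id \
            and library.has_package(package_id):
        pkg = library.package(package_id)
        return effective_attributes(library, package_id, pkg.optional_names)
    return library.core_for(level)


def validate_project(
    source: ProjectMetadata | str | Path,
    library: PackageLibrary,
    ontologies: Mapping[str, OntologyIndex] | None = None,
    strict: bool = False,
    check_ontology: bool = True,
) -> ValidationReport:
    """Validate a workbook (by path) or an already-parsed project.

    Aggregates :func:`validate_value` and :func:`detect_autocorrection`
    over every cell, :func:`validate_links` once, plus ``unknown_header``
    warnings for user-defined columns. Issue order is deterministic:
    sorted by sheet, row, then attribute. With ``check_ontology=False``
    ontology-term membership is skipped (useful when no index is
    configured); everything else still runs.
    """
    if not isinstance(source, ProjectMetadata):
        from .template import parse_workbook

        source, _ = parse_workbook(source, library)
    project = source

    issues: list[ValidationIssue] = []
    seen_user_columns: set[tuple[str, str]] = set()
    for level, rec in project.iter_records():
        sheet = rec.sheet or level.value
        row = rec.row or 0
        specs = _record_specs(library, level, getattr(rec, "package_id", ""))
        for spec in specs:
            if spec.value_kind is ValueKind.ONTOLOGY_TERM and not check_ontology:
                continue
            if spec.name not in rec.attributes and not spec.mandatory:
                continue  # optional column not present on this sheet
            value = rec.attributes.get(spec.name, "")
            for issue in validate_value(value, spec, ontologies):
                issues.append(dataclasses.replace(issue, sheet=sheet, row=row))
            info = rec.cell_info.get(spec.name)
            if info is not None:
                suspect = detect_autocorrection(
                    (value, info.native_type), spec, raw=info.raw)
                if suspect is not None:
                    issues.append(dataclasses.replace(suspect, sheet=sheet, row=row))
        for name, info in rec.cell_info.items():
            if info.user_defined and (sheet, name) not in seen_user_columns:
                seen_user_columns.add((sheet, name))
                issues.append(_issue(
                    "unknown_header", name, "",
                    f"column {name!r} is not defined by the library; kept as a "
                    f"user-defined attribute (not validated)",
                    sheet=sheet, row=1))
    issues.extend(validate_links(project, strict=strict))
    issues.sort(key=lambda i: (i.sheet, i.row, i.attribute, i.rule))
    return ValidationReport(issues=issues)


def format_valid(library: PackageLibrary, package_id: str,
                 record: Mapping[str, str]) -> bool:
    """Verdict of the format rules alone (requirement + syntax patterns).

    This is exactly the rule subset mirrored by the exported JSON
    Schema: mandatory presence and regex/boolean/date/numeric patterns.
    Ontology membership and link rules are out of scope here.
    """
    pkg = library.package(package_id)
    specs = effective_attributes(library, package_id, pkg.optional_names)
    for spec in specs:
        value = record.get(spec.name, "")
        if spec.value_kind is ValueKind.ONTOLOGY_TERM:
            # membership needs an index; the format contract is presence only
            if spec.mandatory and not value.strip():
                return False
            continue
        if validate_value(value, spec):
            return False
    return True
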