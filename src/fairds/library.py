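"""Minimal-information checklist library.

A *package* is one minimal-information checklist (a MIxS standard such as
MIMS or a sample checklist from the European Nucleotide Archive): an
ordered set of attributes, each with a requirement level and a syntax
rule. The *library* is the catalogue of all packages plus the core
attributes that apply to every sheet of a given hierarchy level
regardless of the chosen checklist.

The library lives in an ordinary two-sheet XLSX workbook so that
researchers can add or amend checklists with any spreadsheet editor:

* sheet ``packages`` — columns ``id``, ``title``, ``source``, ``level``
* sheet ``attributes`` — columns ``package_id`` (the literal token
  ``core`` for shared attributes), ``level`` (core rows only), ``name``,
  ``label``, ``requirement``, ``value_kind``, ``regex``, ``ontology_iri``,
  ``units``, ``example``, ``definition``, ``multivalued``

Syntax patterns follow the ENA checklist convention: they are treated as
fully anchored (an implicit ``^...$``) and evaluated with Python's
standard :mod:`re` engine.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from openpyxl import load_workbook

from .errors import LibraryFormatError, PackageLookupError, SelectionError

__all__ = [
    "Level",
    "Requirement",
    "ValueKind",
    "Source",
    "AttributeSpec",
    "Package",
    "PackageLibrary",
    "LibraryIssue",
    "load_library",
    "list_packages",
    "effective_attributes",
    "export_json_schema",
    "lint_library",
]

_NAME_RE = re.compile(r"[a-z][a-z0-9_]*\Z")


class Level(str, enum.Enum):
    """The five layers of the extended ISA hierarchy, top to bottom."""

    INVESTIGATION = "investigation"
    STUDY = "study"
    OBSERVATION_UNIT = "observation_unit"
    SAMPLE = "sample"
    ASSAY = "assay"

    @classmethod
    def ordered(cls) -> tuple["Level", ...]:
        return (
            cls.INVESTIGATION,
            cls.STUDY,
            cls.OBSERVATION_UNIT,
            cls.SAMPLE,
            cls.ASSAY,
        )


class Requirement(str, enum.Enum):
    MANDATORY = "mandatory"
    OPTIONAL = "optional"


class ValueKind(str, enum.Enum):
    TEXT = "text"
    BOOLEAN = "boolean"
    NUMERIC = "numeric"
    DATE = "date"
    RESTRICTED_TEXT = "restricted_text"
    ONTOLOGY_TERM = "ontology_term"


class Source(str, enum.Enum):
    MIXS = "MIxS"
    ENA = "ENA"
    USER = "user"


@dataclass
class AttributeSpec:
    """One checklist attribute and its validation contract.

    ``name`` is the machine token used as the workbook column header and,
    later, as the local name of the RDF predicate minted for the
    attribute. ``syntax_regex`` (when present) is anchored implicitly.
    """

    name: str
    label: str
    definition: str = ""
    requirement: Requirement = Requirement.OPTIONAL
    value_kind: ValueKind = ValueKind.TEXT
    syntax_regex: str | None = None
    ontology_iri: str | None = None
    units_hint: str | None = None
    example_value: str | None = None
    level: Level = Level.SAMPLE
    multivalued: bool = False

    @property
    def mandatory(self) -> bool:
        return self.requirement is Requirement.MANDATORY

    def compiled_regex(self) -> re.Pattern | None:
        """The compiled pattern (apply with ``fullmatch``: anchored)."""
        if self.syntax_regex is None:
            return None
        return re.compile(self.syntax_regex)


@dataclass
class Package:
    """A minimal-information checklist: ordered package-specific attributes."""

    id: str
    title: str
    source: Source
    level: Level
    attributes: list[AttributeSpec] = field(default_factory=list)

    def attribute(self, name: str) -> AttributeSpec | None:
        for spec in self.attributes:
            if spec.name == name:
                return spec
        return None

    @property
    def optional_names(self) -> list[str]:
        return [a.name for a in self.attributes if not a.mandatory]


@dataclass
class PackageLibrary:
    """The catalogue of checklists plus per-level core attributes."""

    packages: list[Package] = field(default_factory=list)
    core_attributes: dict[Level, list[AttributeSpec]] = field(default_factory=dict)
    source_path: str | None = None
    version_tag: str = ""
    # rows that failed to parse under permissive loading; surfaced by lint
    _load_issues: list["LibraryIssue"] = field(default_factory=list, repr=False)

    def package(self, package_id: str) -> Package:
        for pkg in self.packages:
            if pkg.id == package_id:
                return pkg
        raise PackageLookupError(f"unknown package id: {package_id!r}")

    def has_package(self, package_id: str) -> bool:
        return any(p.id == package_id for p in self.packages)

    def core_for(self, level: Level) -> list[AttributeSpec]:
        return list(self.core_attributes.get(level, []))

    def attribute_index(self) -> dict[str, AttributeSpec]:
        """name -> spec over core and all packages (first definition wins)."""
        index: dict[str, AttributeSpec] = {}
        for specs in self.core_attributes.values():
            for spec in specs:
                index.setdefault(spec.name, spec)
        for pkg in self.packages:
            for spec in pkg.attributes:
                index.setdefault(spec.name, spec)
        return index


@dataclass(frozen=True)
class LibraryIssue:
    """One problem found by :func:`lint_library`."""

    kind: str  # duplicate_name | bad_regex | missing_ontology_iri |
    #            missing_regex | unknown_level | unknown_token | bad_name
    package_id: str
    attribute: str
    message: str


# ---------------------------------------------------------------------------
# loading

_PACKAGE_COLUMNS = ("id", "title", "source", "level")
_ATTRIBUTE_COLUMNS = (
    "package_id",
    "level",
    "name",
    "label",
    "requirement",
    "value_kind",
    "regex",
    "ontology_iri",
    "units",
    "example",
    "definition",
    "multivalued",
)


def _sheet_rows(ws) -> tuple[dict[str, int], list[tuple[int, tuple]]]:
    rows = list(ws.iter_rows(values_only=True))
    if not rows:
        return {}, []
    header = {str(h).strip(): i for i, h in enumerate(rows[0]) if h is not None}
    data = [(r + 2, row) for r, row in enumerate(rows[1:])]
    return header, data


def _cell(row: tuple, header: Mapping[str, int], column: str) -> str:
    idx = header.get(column)
    if idx is None or idx >= len(row) or row[idx] is None:
        return ""
    return str(row[idx]).strip()


def load_library(path: str | Path, *, strict: bool = True) -> PackageLibrary:
    """Load a package library from its two-sheet XLSX workbook.

    With ``strict=True`` (default) malformed rows raise
    :class:`LibraryFormatError` naming the sheet and row. With
    ``strict=False`` malformed rows are skipped and recorded so that
    :func:`lint_library` can report them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    wb = load_workbook(path, read_only=True, data_only=True)
    try:
        for sheet in ("packages", "attributes"):
            if sheet not in wb.sheetnames:
                raise LibraryFormatError(f"library workbook lacks sheet {sheet!r}")
        issues: list[LibraryIssue] = []

        def problem(sheet: str, rownum: int, kind: str, pkg: str, attr: str, msg: str):
            if strict:
                raise LibraryFormatError(f"sheet {sheet!r} row {rownum}: {msg}")
            issues.append(LibraryIssue(kind, pkg, attr, f"{sheet} row {rownum}: {msg}"))

        pkg_header, pkg_rows = _sheet_rows(wb["packages"])
        for col in _PACKAGE_COLUMNS:
            if col not in pkg_header:
                raise LibraryFormatError(f"sheet 'packages' lacks column {col!r}")
        attr_header, attr_rows = _sheet_rows(wb["attributes"])
        for col in ("package_id", "name", "requirement", "value_kind"):
            if col not in attr_header:
                raise LibraryFormatError(f"sheet 'attributes' lacks column {col!r}")

        library = PackageLibrary(source_path=str(path))
        by_id: dict[str, Package] = {}
        for rownum, row in pkg_rows:
            pid = _cell(row, pkg_header, "id")
            if not pid:
                continue
            if pid in by_id:
                problem("packages", rownum, "duplicate_name", pid, "",
                        f"duplicate package id {pid!r}")
                continue
            try:
                source = Source(_cell(row, pkg_header, "source"))
            except ValueError:
                problem("packages", rownum, "unknown_token", pid, "",
                        f"unknown source token {_cell(row, pkg_header, 'source')!r}")
                continue
            level_token = _cell(row, pkg_header, "level")
            try:
                level = Level(level_token)
            except ValueError:
                problem("packages", rownum, "unknown_level", pid, "",
                        f"unknown level token {level_token!r}")
                continue
            if level not in (Level.SAMPLE, Level.ASSAY):
                problem("packages", rownum, "unknown_level", pid, "",
                        f"package level must be sample or assay, got {level.value!r}")
                continue
            pkg = Package(pid, _cell(row, pkg_header, "title") or pid, source, level)
            by_id[pid] = pkg
            library.packages.append(pkg)

        n_attr_rows = 0
        for rownum, row in attr_rows:
            name = _cell(row, attr_header, "name")
            pid = _cell(row, attr_header, "package_id")
            if not name and not pid:
                continue
            n_attr_rows += 1
            if not _NAME_RE.fullmatch(name):
                problem("attributes", rownum, "bad_name", pid, name,
                        f"attribute name {name!r} is not a lowercase_underscore token")
                continue
            try:
                requirement = Requirement(_cell(row, attr_header, "requirement"))
            except ValueError:
                problem("attributes", rownum, "unknown_token", pid, name,
                        f"unknown requirement token "
                        f"{_cell(row, attr_header, 'requirement')!r}")
                continue
            try:
                kind = ValueKind(_cell(row, attr_header, "value_kind"))
            except ValueError:
                problem("attributes", rownum, "unknown_token", pid, name,
                        f"unknown value_kind token "
                        f"{_cell(row, attr_header, 'value_kind')!r}")
                continue
            regex = _cell(row, attr_header, "regex") or None
            if regex is not None:
                try:
                    re.compile(regex)
                except re.error as exc:
                    problem("attributes", rownum, "bad_regex", pid, name,
                            f"regex does not compile: {exc}")
                    continue
            spec = AttributeSpec(
                name=name,
                label=_cell(row, attr_header, "label") or name.replace("_", " "),
                definition=_cell(row, attr_header, "definition"),
                requirement=requirement,
                value_kind=kind,
                syntax_regex=regex,
                ontology_iri=_cell(row, attr_header, "ontology_iri") or None,
                units_hint=_cell(row, attr_header, "units") or None,
                example_value=_cell(row, attr_header, "example") or None,
                multivalued=_cell(row, attr_header, "multivalued").lower()
                in ("true", "1", "yes"),
            )
            if pid == "core":
                level_token = _cell(row, attr_header, "level")
                try:
                    spec.level = Level(level_token)
                except ValueError:
                    problem("attributes", rownum, "unknown_level", pid, name,
                            f"unknown core level token {level_token!r}")
                    continue
                library.core_attributes.setdefault(spec.level, []).append(spec)
            else:
                pkg = by_id.get(pid)
                if pkg is None:
                    problem("attributes", rownum, "unknown_token", pid, name,
                            f"attribute row references unknown package {pid!r}")
                    continue
                spec.level = pkg.level
                pkg.attributes.append(spec)

        if n_attr_rows == 0:
            raise LibraryFormatError(
                "sheet 'attributes' contains no attribute rows")

        library._load_issues = issues
        if strict:
            dup_issues = [i for i in lint_library(library) if i.kind == "duplicate_name"]
            if dup_issues:
                raise LibraryFormatError(dup_issues[0].message)
        return library
    finally:
        wb.close()


# ---------------------------------------------------------------------------
# queries


def list_packages(
    library: PackageLibrary,
    source: Source | str | None = None,
    level: Level | str | None = None,
) -> list[Package]:
    """Stable-ordered subset of packages matching all supplied filters."""
    result = list(library.packages)
    if source is not None:
        source = Source(source)
        result = [p for p in result if p.source is source]
    if level is not None:
        level = Level(level)
        result = [p for p in result if p.level is level]
    return result


def effective_attributes(
    library: PackageLibrary,
    package_id: str,
    selected_optional: Iterable[str] = (),
) -> list[AttributeSpec]:
    """The column set for one package sheet.

    Order: core attributes for the package's level, then the package's
    mandatory attributes, then the selected optional attributes (in
    package order). Requirement flags are retained.
    """
    pkg = library.package(package_id)
    selected = set(selected_optional)
    valid_optional = set(pkg.optional_names)
    unknown = selected - valid_optional
    if unknown:
        raise SelectionError(
            f"unknown optional attribute(s) {sorted(unknown)} for package "
            f"{package_id!r}; valid options: {sorted(valid_optional)}"
        )
    result = library.core_for(pkg.level)
    result += [a for a in pkg.attributes if a.mandatory]
    result += [a for a in pkg.attributes if not a.mandatory and a.name in selected]
    return result


# ---------------------------------------------------------------------------
# JSON Schema export

# Validation applied by kind when no explicit regex is given. The boolean
# rule is strict: exactly "true" or "false".
KIND_PATTERNS: dict[ValueKind, str] = {
    ValueKind.BOOLEAN: r"(true|false)",
    ValueKind.NUMERIC: r"[+-]?(\d+(\.\d*)?|\.\d+)([Ee][+-]?\d+)?",
    ValueKind.DATE: r"\d{4}-(0[1-9]|1[0-2])-(0[1-9]|[12][0-9]|3[01])"
                    r"(T\d{2}:\d{2}(:\d{2})?(Z|[+-]\d{2}:\d{2})?)?",
}


def _value_pattern(spec: AttributeSpec) -> str | None:
    if spec.syntax_regex is not None and spec.value_kind in (
        ValueKind.RESTRICTED_TEXT,
        ValueKind.TEXT,
        ValueKind.NUMERIC,
    ):
        return spec.syntax_regex
    return KIND_PATTERNS.get(spec.value_kind)


def export_json_schema(
    library: PackageLibrary,
    package_id: str,
    selected_optional: Iterable[str] | None = None,
) -> dict:
    """Export one package as a draft-07 JSON Schema document.

    The schema mirrors the internal regex + requirement rules: one string
    property per effective attribute, ``pattern`` from the (anchored)
    syntax rule, ``required`` listing the mandatory attribute names.
    Suitable for JSON-Schema-based validators such as the ELIXIR
    Biovalidator.
    """
    pkg = library.package(package_id)
    if selected_optional is None:
        selected_optional = pkg.optional_names
    specs = effective_attributes(library, package_id, selected_optional)
    properties: dict[str, dict] = {}
    required: list[str] = []
    for spec in specs:
        prop: dict = {"type": "string"}
        if spec.definition:
            prop["description"] = spec.definition
        pattern = _value_pattern(spec)
        if pattern is not None:
            if spec.multivalued:
                # the workbook convention: multiple values separated by ';'
                pattern = f"(?:{pattern})(?:\\s*;\\s*(?:{pattern}))*"
            if spec.mandatory:
                prop["pattern"] = f"^(?:{pattern})$"
            else:
                # optional attributes may legitimately be left empty
                prop["pattern"] = f"^(?:(?:{pattern}))?$"
        if spec.mandatory:
            prop["minLength"] = 1
            required.append(spec.name)
        if spec.example_value:
            prop["examples"] = [spec.example_value]
        properties[spec.name] = prop
    schema = {
        "$schema": "http://json-schema.org/draft-07/schema#",
        "$id": f"https://w3id.org/fairds/schema/{pkg.id}.json",
        "title": pkg.title,
        "description": f"Checklist {pkg.id} ({pkg.source.value}, "
                       f"{pkg.level.value} level)",
        "type": "object",
        "properties": properties,
        "required": required,
    }
    return schema


def write_json_schema(library: PackageLibrary, package_id: str, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(export_json_schema(library, package_id), indent=2) + "\n",
                    encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# lint


def lint_library(library: PackageLibrary) -> list[LibraryIssue]:
    """Report invariant violations; an empty list means the library is sound.

    Linting never raises: it exists so that a hand-edited library can be
    checked before use.
    """
    issues: list[LibraryIssue] = list(library._load_issues)
    for level, specs in library.core_attributes.items():
        issues += _lint_specs("core", specs, seen=set())
    for pkg in library.packages:
        seen = {s.name for s in library.core_for(pkg.level)}
        issues += _lint_specs(pkg.id, pkg.attributes, seen=seen)
    return issues


def _lint_specs(owner: str, specs: Sequence[AttributeSpec], seen: set[str]) -> list[LibraryIssue]:
    issues = []
    for spec in specs:
        if not _NAME_RE.fullmatch(spec.name):
            issues.append(LibraryIssue(
                "bad_name", owner, spec.name,
                f"{owner}: attribute name {spec.name!r} is not a valid token"))
        if spec.name in seen:
            issues.append(LibraryIssue(
                "duplicate_name", owner, spec.name,
                f"{owner}: duplicate attribute name {spec.name!r}"))
        seen.add(spec.name)
        if spec.syntax_regex is not None:
            try:
                re.compile(spec.syntax_regex)
            except re.error as exc:
                issues.append(LibraryIssue(
                    "bad_regex", owner, spec.name,
                    f"{owner}: regex for {spec.name!r} does not compile: {exc}"))
        if spec.value_kind is ValueKind.ONTOLOGY_TERM and not spec.ontology_iri:
            issues.append(LibraryIssue(
                "missing_ontology_iri", owner, spec.name,
                f"{owner}: ontology_term attribute {spec.name!r} lacks an IRI"))
        if spec.value_kind is ValueKind.RESTRICTED_TEXT and not spec.syntax_regex:
            issues.append(LibraryIssue(
                "missing_regex", owner, spec.name,
                f"{owner}: restricted_text attribute {spec.name!r} lacks a regex"))
    return issues
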