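"""The extended five-level ISA hierarchy.

Classic ISA describes an experiment in three levels: Investigation,
Study, Assay. Minimal-information checklists, however, centre on the
*sampling environment*, so two levels are inserted between Study and
Assay:

* **Observation unit** — the entity under study from which samples are
  taken (the term comes from MIAPPE's ISA-Tab profile); equivalent to
  classic ISA "source material".
* **Sample** — the biological material taken from an observation unit
  (the term comes from the Just Enough Results Model, JERM); equivalent
  to classic ISA "sample material".

Each record stores its attributes as a plain ``name -> string`` map plus
per-cell bookkeeping (native spreadsheet type, user-defined flag, sheet
and row of origin) used by the validator and the RDF exporter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .errors import RecordLookupError, StructuralError
from .library import Level

__all__ = [
    "Contact",
    "Investigation",
    "Study",
    "ObservationUnit",
    "Sample",
    "Assay",
    "ProjectMetadata",
    "CellInfo",
    "IntegrityIssue",
    "EQUIVALENCE_MAP",
    "IDENTIFIER_FIELDS",
    "PARENT_FIELDS",
    "build_project",
    "children_of",
    "flatten",
]

#: Equivalence between the two inserted levels and the classic ISA
#: material classes (emitted as class-level links in the RDF export).
EQUIVALENCE_MAP: tuple[tuple[Level, str], ...] = (
    (Level.OBSERVATION_UNIT, "source material"),
    (Level.SAMPLE, "sample material"),
)

#: The identifier attribute of each level.
IDENTIFIER_FIELDS: dict[Level, str] = {
    Level.INVESTIGATION: "investigation_identifier",
    Level.STUDY: "study_identifier",
    Level.OBSERVATION_UNIT: "observation_unit_identifier",
    Level.SAMPLE: "sample_identifier",
    Level.ASSAY: "assay_identifier",
}

#: The parent-identifier attribute of each non-root level.
PARENT_FIELDS: dict[Level, str] = {
    Level.STUDY: "investigation_identifier",
    Level.OBSERVATION_UNIT: "study_identifier",
    Level.SAMPLE: "observation_unit_identifier",
    Level.ASSAY: "sample_identifier",
}

_CHILD_LEVEL: dict[Level, Level] = {
    Level.INVESTIGATION: Level.STUDY,
    Level.STUDY: Level.OBSERVATION_UNIT,
    Level.OBSERVATION_UNIT: Level.SAMPLE,
    Level.SAMPLE: Level.ASSAY,
}


@dataclass
class CellInfo:
    """Provenance of one cell: native spreadsheet type and origin."""

    native_type: str = "s"  # openpyxl data types: s, n, d, b
    user_defined: bool = False
    raw: object = None  # underlying value before display-string conversion


@dataclass
class Contact:
    name: str
    email: str = ""
    orcid: str = ""


@dataclass
class _Record:
    identifier: str
    attributes: dict[str, str] = field(default_factory=dict)
    cell_info: dict[str, CellInfo] = field(default_factory=dict)
    sheet: str | None = None
    row: int | None = None

    def user_defined_attributes(self) -> dict[str, str]:
        return {
            k: v
            for k, v in self.attributes.items()
            if self.cell_info.get(k, CellInfo()).user_defined
        }


@dataclass
class Investigation(_Record):
    title: str = ""
    description: str = ""
    contacts: list[Contact] = field(default_factory=list)

    @property
    def user_fields(self) -> dict[str, str]:
        return self.user_defined_attributes()


@dataclass
class Study(_Record):
    title: str = ""
    description: str = ""
    investigation_id: str = ""


@dataclass
class ObservationUnit(_Record):
    study_id: str = ""


@dataclass
class Sample(_Record):
    observation_unit_id: str = ""
    package_id: str = ""


@dataclass
class Assay(_Record):
    sample_id: str = ""
    package_id: str = ""

    @property
    def data_files(self) -> list[str]:
        raw = self.attributes.get("file_name", "")
        return [p.strip() for p in raw.split(";") if p.strip()]


@dataclass(frozen=True)
class IntegrityIssue:
    """A buffered referential-integrity problem (never raised)."""

    kind: str  # unknown_parent | duplicate_identifier
    level: Level
    identifier: str
    sheet: str | None
    row: int | None
    message: str


@dataclass
class ProjectMetadata:
    """One project: the full five-level hierarchy plus an issue buffer."""

    investigation: Investigation
    studies: list[Study] = field(default_factory=list)
    observation_units: list[ObservationUnit] = field(default_factory=list)
    samples: list[Sample] = field(default_factory=list)
    assays: list[Assay] = field(default_factory=list)

    def records(self, level: Level) -> list:
        return {
            Level.INVESTIGATION: [self.investigation],
            Level.STUDY: self.studies,
            Level.OBSERVATION_UNIT: self.observation_units,
            Level.SAMPLE: self.samples,
            Level.ASSAY: self.assays,
        }[level]

    @property
    def source_packages(self) -> set[str]:
        return {r.package_id for r in [*self.samples, *self.assays] if r.package_id}

    def identifiers(self, level: Level) -> list[str]:
        return [r.identifier for r in self.records(level)]

    def iter_records(self) -> Iterator[tuple[Level, _Record]]:
        for level in Level.ordered():
            for rec in self.records(level):
                yield level, rec

    # -- referential integrity -------------------------------------------
    def integrity_issues(self) -> list[IntegrityIssue]:
        """Duplicate identifiers and dangling parent references.

        Violations are reported, never raised; the validation module
        turns them into cell-addressed issues.
        """
        issues: list[IntegrityIssue] = []
        parents: dict[Level, set[str]] = {}
        for level in Level.ordered():
            seen: set[str] = set()
            for rec in self.records(level):
                if rec.identifier in seen:
                    issues.append(IntegrityIssue(
                        "duplicate_identifier", level, rec.identifier,
                        rec.sheet, rec.row,
                        f"duplicate {level.value} identifier {rec.identifier!r}"))
                seen.add(rec.identifier)
            parents[level] = seen
        parent_of = {
            Level.STUDY: Level.INVESTIGATION,
            Level.OBSERVATION_UNIT: Level.STUDY,
            Level.SAMPLE: Level.OBSERVATION_UNIT,
            Level.ASSAY: Level.SAMPLE,
        }
        for level, parent_level in parent_of.items():
            for rec in self.records(level):
                pid = rec.attributes.get(PARENT_FIELDS[level], "")
                if pid not in parents[parent_level]:
                    issues.append(IntegrityIssue(
                        "unknown_parent", level, rec.identifier,
                        rec.sheet, rec.row,
                        f"{level.value} {rec.identifier!r} references unknown "
                        f"{parent_level.value} {pid!r}"))
        return issues


# ---------------------------------------------------------------------------
# construction


def _split_multi(value: str) -> list[str]:
    return [v.strip() for v in value.split(";")] if value else []


def _make_investigation(row: dict[str, str]) -> Investigation:
    names = _split_multi(row.get("contact_name", ""))
    emails = _split_multi(row.get("contact_email", ""))
    orcids = _split_multi(row.get("contact_orcid", ""))
    contacts = [
        Contact(
            name=names[i] if i < len(names) else "",
            email=emails[i] if i < len(emails) else "",
            orcid=orcids[i] if i < len(orcids) else "",
        )
        for i in range(max(len(names), len(emails), len(orcids)))
    ]
    return Investigation(
        identifier=row.get("investigation_identifier", ""),
        attributes=dict(row),
        title=row.get("investigation_title", ""),
        description=row.get("investigation_description", ""),
        contacts=contacts,
    )


def build_project(
    investigation_rows: list[dict[str, str]],
    study_rows: list[dict[str, str]] = (),
    observation_unit_rows: list[dict[str, str]] = (),
    sample_rows: list[dict[str, str]] = (),
    assay_rows: list[dict[str, str]] = (),
    *,
    sample_packages: dict[int, str] | str | None = None,
    assay_packages: dict[int, str] | str | None = None,
) -> ProjectMetadata:
    """Assemble a :class:`ProjectMetadata` from per-level attribute rows.

    Row order is preserved at every level. Referential-integrity
    violations are buffered on the project (see
    :meth:`ProjectMetadata.integrity_issues`), not raised; a missing
    identifier column is a :class:`~fairds.errors.StructuralError`.

    ``sample_packages`` / ``assay_packages`` assign the checklist used by
    each row: either one package id for all rows or a map of row index to
    package id.
    """
    def ident(level: Level, rows) -> None:
        key = IDENTIFIER_FIELDS[level]
        for row in rows:
            if key not in row:
                raise StructuralError(
                    f"{level.value} rows lack the identifier column {key!r}")

    if not investigation_rows:
        raise StructuralError("at least one investigation row is required")
    for level, rows in (
        (Level.INVESTIGATION, investigation_rows),
        (Level.STUDY, study_rows),
        (Level.OBSERVATION_UNIT, observation_unit_rows),
        (Level.SAMPLE, sample_rows),
        (Level.ASSAY, assay_rows),
    ):
        ident(level, rows)

    def pkg_for(packages, i: int) -> str:
        if packages is None:
            return ""
        if isinstance(packages, str):
            return packages
        return packages.get(i, "")

    project = ProjectMetadata(investigation=_make_investigation(investigation_rows[0]))
    for row in study_rows:
        project.studies.append(Study(
            identifier=row["study_identifier"], attributes=dict(row),
            title=row.get("study_title", ""),
            description=row.get("study_description", ""),
            investigation_id=row.get("investigation_identifier", "")))
    for row in observation_unit_rows:
        project.observation_units.append(ObservationUnit(
            identifier=row["observation_unit_identifier"], attributes=dict(row),
            study_id=row.get("study_identifier", "")))
    for i, row in enumerate(sample_rows):
        project.samples.append(Sample(
            identifier=row["sample_identifier"], attributes=dict(row),
            observation_unit_id=row.get("observation_unit_identifier", ""),
            package_id=pkg_for(sample_packages, i)))
    for i, row in enumerate(assay_rows):
        project.assays.append(Assay(
            identifier=row["assay_identifier"], attributes=dict(row),
            sample_id=row.get("sample_identifier", ""),
            package_id=pkg_for(assay_packages, i)))
    return project


def children_of(project: ProjectMetadata, level: Level | str, identifier: str) -> list:
    """Records at the next level whose parent field equals ``identifier``."""
    level = Level(level)
    if identifier not in project.identifiers(level):
        raise RecordLookupError(
            f"no {level.value} record with identifier {identifier!r}")
    child_level = _CHILD_LEVEL.get(level)
    if child_level is None:
        return []
    parent_key = PARENT_FIELDS[child_level]
    return [
        rec for rec in project.records(child_level)
        if rec.attributes.get(parent_key, "") == identifier
    ]


def flatten(project: ProjectMetadata) -> dict[Level, list[dict[str, str]]]:
    """Rows per level, inverse of :func:`build_project` on well-formed input."""
    return {
        level: [dict(rec.attributes) for rec in project.records(level)]
        for level in Level.ordered()
    }
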