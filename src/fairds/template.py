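"""Metadata template workbooks.

The form-generation half of the workflow: from one or more selected
checklists, build a multi-sheet XLSX workbook whose header row carries
machine-actionable attribute names (with the attribute definition
attached as a cell note), hand it to the data producers to fill, and
parse the filled workbook back into a :class:`~fairds.isa.ProjectMetadata`.

Workbook layout
---------------
* fixed sheets ``Investigation``, ``Study`` and ``ObservationUnit``;
* one ``Sample - <package id>`` sheet per selected sample checklist and
  one ``Assay - <package id>`` sheet per selected assay checklist;
* a hidden ``_meta`` sheet recording the library version and the
  selected packages (ignored when absent).

Headers, not column positions, are authoritative on parse: users may
reorder columns and add their own columns, which are preserved verbatim
and flagged as user-defined. All template columns are formatted as text
to discourage spreadsheet auto-conversion; the parser still records each
cell's native type so the validator can flag auto-correction artifacts.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

from openpyxl import Workbook, load_workbook
from openpyxl.comments import Comment
from openpyxl.styles import Font, PatternFill

from .errors import PackageLookupError, SelectionError, StructuralError
from .isa import CellInfo, Level, ProjectMetadata, build_project
from .library import AttributeSpec, PackageLibrary, effective_attributes

__all__ = [
    "TemplateSpec",
    "SheetModel",
    "WorkbookModel",
    "generate_template",
    "parse_workbook",
    "write_project",
    "FIXED_SHEETS",
]

FIXED_SHEETS = ("Investigation", "Study", "ObservationUnit")
_LEVEL_SHEETS = {
    "Investigation": Level.INVESTIGATION,
    "Study": Level.STUDY,
    "ObservationUnit": Level.OBSERVATION_UNIT,
}
_SAMPLE_PREFIX = "Sample - "
_ASSAY_PREFIX = "Assay - "
_META_SHEET = "_meta"

_MANDATORY_FILL = PatternFill("solid", start_color="FFE8F0E0")
_MANDATORY_FONT = Font(bold=True)


@dataclass
class TemplateSpec:
    """What to put in a template: packages, optional picks, prefill."""

    library: PackageLibrary
    packages: list[str]
    optional: dict[str, list[str]] = field(default_factory=dict)
    investigation_prefill: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.packages:
            raise SelectionError("select at least one package")
        for pid in self.packages:
            if not self.library.has_package(pid):
                raise SelectionError(f"unknown package id: {pid!r}")
        for pid, names in self.optional.items():
            if pid not in self.packages:
                raise SelectionError(
                    f"optional selection for unselected package {pid!r}")
            effective_attributes(self.library, pid, names)  # raises on bad names


@dataclass
class SheetModel:
    """One sheet: headers with instruction notes plus string rows."""

    name: str
    level: Level
    headers: list[str]
    notes: dict[str, str] = field(default_factory=dict)
    mandatory: set[str] = field(default_factory=set)
    rows: list[dict[str, str]] = field(default_factory=list)
    package_id: str | None = None


@dataclass
class WorkbookModel:
    """An in-memory workbook; ``_meta`` bookkeeping is not a sheet here."""

    sheets: list[SheetModel]
    library_version: str = ""
    packages: list[str] = field(default_factory=list)

    def sheet(self, name: str) -> SheetModel:
        for sheet in self.sheets:
            if sheet.name == name:
                return sheet
        raise KeyError(name)

    def save(self, path: str | Path) -> Path:
        """Write the workbook as XLSX (deterministic output)."""
        path = Path(path)
        wb = Workbook()
        stamp = datetime.datetime(2026, 1, 1)
        wb.properties.created = stamp
        wb.properties.modified = stamp
        wb.properties.creator = "fairds"
        wb.remove(wb.active)
        for model in self.sheets:
            ws = wb.create_sheet(model.name)
            for col, header in enumerate(model.headers, start=1):
                cell = ws.cell(row=1, column=col, value=header)
                note = model.notes.get(header, "")
                if note:
                    cell.comment = Comment(note, "fairds")
                if header in model.mandatory:
                    cell.font = _MANDATORY_FONT
                    cell.fill = _MANDATORY_FILL
                # text format to discourage spreadsheet auto-conversion
                for data_row in range(2, len(model.rows) + 2):
                    ws.cell(row=data_row, column=col).number_format = "@"
            for r, row in enumerate(model.rows, start=2):
                for col, header in enumerate(model.headers, start=1):
                    value = row.get(header, "")
                    if value != "":
                        ws.cell(row=r, column=col, value=value)
        meta = wb.create_sheet(_META_SHEET)
        meta.sheet_state = "hidden"
        meta.append(["library_version", self.library_version])
        meta.append(["packages", ",".join(self.packages)])
        wb.save(path)
        return path


def _spec_note(spec: AttributeSpec) -> str:
    parts = [spec.definition or spec.label]
    parts.append(f"[{spec.requirement.value}, {spec.value_kind.value}]")
    if spec.syntax_regex:
        parts.append(f"Syntax: {spec.syntax_regex}")
    if spec.units_hint:
        parts.append(f"Units: {spec.units_hint}")
    if spec.example_value:
        parts.append(f"Example: {spec.example_value}")
    return "\n".join(parts)


def _make_sheet(name: str, level: Level, specs: list[AttributeSpec],
                package_id: str | None = None) -> SheetModel:
    return SheetModel(
        name=name,
        level=level,
        headers=[s.name for s in specs],
        notes={s.name: _spec_note(s) for s in specs},
        mandatory={s.name for s in specs if s.mandatory},
        package_id=package_id,
    )


def generate_template(spec: TemplateSpec, path: str | Path | None = None) -> WorkbookModel:
    """Build a template workbook for the selected checklists.

    Fixed sheets (Investigation, Study, ObservationUnit) carry the
    per-level core attributes; each selected package adds one
    ``Sample - <id>`` or ``Assay - <id>`` sheet with the package's
    effective attributes. Mandatory headers are flagged in bold on a
    tinted background.
    """
    spec.validate()
    lib = spec.library
    sheets = [
        _make_sheet(name, level, lib.core_for(level))
        for name, level in _LEVEL_SHEETS.items()
    ]
    if spec.investigation_prefill:
        sheets[0].rows.append({
            k: v for k, v in spec.investigation_prefill.items()
            if k in sheets[0].headers
        })
    for pid in spec.packages:
        pkg = lib.package(pid)
        specs = effective_attributes(lib, pid, spec.optional.get(pid, []))
        prefix = _SAMPLE_PREFIX if pkg.level is Level.SAMPLE else _ASSAY_PREFIX
        sheets.append(_make_sheet(prefix + pid, pkg.level, specs, package_id=pid))
    model = WorkbookModel(sheets=sheets, packages=list(spec.packages),
                          library_version=lib.version_tag)
    if path is not None:
        model.save(path)
    return model


# ---------------------------------------------------------------------------
# parsing


def _display(cell) -> tuple[str, str, object]:
    """Cell -> (display string, native type, raw value)."""
    value = cell.value
    if value is None:
        return "", "s", None
    if cell.is_date:
        if isinstance(value, datetime.datetime) and (
                value.hour, value.minute, value.second) == (0, 0, 0):
            return value.date().isoformat(), "d", value
        return value.isoformat(), "d", value
    if isinstance(value, bool):
        return ("true" if value else "false"), "b", value
    if isinstance(value, float) and value.is_integer():
        return str(int(value)), "n", value
    if isinstance(value, (int, float)):
        return str(value), "n", value
    return str(value), "s", value


def _normalize_header(header: str) -> str:
    return header.strip().lower().replace(" ", "_")


def _read_sheet(ws, known: dict[str, AttributeSpec], notes: list[str]):
    """Read one sheet into (rows, infos, rownums, headers, user_headers)."""
    it = ws.iter_rows()
    try:
        header_cells = next(it)
    except StopIteration:
        return [], [], [], [], []
    headers: list[str] = []
    canonical: list[str] = []
    user_headers: list[str] = []
    for cell in header_cells:
        if cell.value is None:
            headers.append("")
            canonical.append("")
            continue
        raw = str(cell.value).strip()
        token = _normalize_header(raw)
        if token in known:
            headers.append(raw)
            canonical.append(token)
        else:
            headers.append(raw)
            canonical.append(raw)  # user columns keep their verbatim header
            user_headers.append(raw)
    rows, infos, rownums = [], [], []
    for row_cells in it:
        row: dict[str, str] = {}
        info: dict[str, CellInfo] = {}
        non_empty = False
        for cell, name in zip(row_cells, canonical):
            if not name:
                continue
            display, native, raw_value = _display(cell)
            row[name] = display
            info[name] = CellInfo(native_type=native,
                                  user_defined=name in user_headers,
                                  raw=raw_value)
            if display != "":
                non_empty = True
        if not non_empty:
            notes.append(f"sheet {ws.title!r} row {row_cells[0].row}: "
                         f"empty row skipped")
            continue
        rows.append(row)
        infos.append(info)
        rownums.append(row_cells[0].row)
    return rows, infos, rownums, canonical, user_headers


def parse_workbook(path: str | Path,
                   library: PackageLibrary) -> tuple[ProjectMetadata, list[str]]:
    """Parse a filled template workbook into project metadata.

    Returns the project plus a list of parse notes (skipped empty rows,
    unrecognised sheets). Referential-integrity problems are buffered on
    the project, not raised. A missing fixed sheet raises
    :class:`~fairds.errors.StructuralError` naming the sheet.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    wb = load_workbook(path, data_only=True)
    try:
        notes: list[str] = []
        for name in FIXED_SHEETS:
            if name not in wb.sheetnames:
                raise StructuralError(f"workbook is missing sheet {name!r}")
        index = library.attribute_index()

        level_rows: dict[Level, list[dict[str, str]]] = {lv: [] for lv in Level}
        level_infos: dict[Level, list[dict[str, CellInfo]]] = {lv: [] for lv in Level}
        level_meta: dict[Level, list[tuple[str, int]]] = {lv: [] for lv in Level}
        sample_packages: dict[int, str] = {}
        assay_packages: dict[int, str] = {}

        for ws in wb.worksheets:
            title = ws.title
            if title.startswith("_"):
                continue
            if title in _LEVEL_SHEETS:
                level = _LEVEL_SHEETS[title]
                package_id = None
            elif title.startswith(_SAMPLE_PREFIX):
                level = Level.SAMPLE
                package_id = title[len(_SAMPLE_PREFIX):].strip()
            elif title.startswith(_ASSAY_PREFIX):
                level = Level.ASSAY
                package_id = title[len(_ASSAY_PREFIX):].strip()
            else:
                notes.append(f"sheet {title!r} does not follow the template "
                             f"layout; ignored")
                continue
            rows, infos, rownums, _, _ = _read_sheet(ws, index, notes)
            for row, info, rownum in zip(rows, infos, rownums):
                i = len(level_rows[level])
                if level is Level.SAMPLE and package_id:
                    sample_packages[i] = package_id
                if level is Level.ASSAY and package_id:
                    assay_packages[i] = package_id
                level_rows[level].append(row)
                level_infos[level].append(info)
                level_meta[level].append((title, rownum))

        if not level_rows[Level.INVESTIGATION]:
            raise StructuralError("Investigation sheet has no data row")

        project = build_project(
            level_rows[Level.INVESTIGATION],
            level_rows[Level.STUDY],
            level_rows[Level.OBSERVATION_UNIT],
            level_rows[Level.SAMPLE],
            level_rows[Level.ASSAY],
            sample_packages=sample_packages,
            assay_packages=assay_packages,
        )
        for level in Level.ordered():
            for rec, info, (sheet, rownum) in zip(
                    project.records(level), level_infos[level], level_meta[level]):
                rec.cell_info = info
                rec.sheet = sheet
                rec.row = rownum
        return project, notes
    finally:
        wb.close()


# ---------------------------------------------------------------------------
# writing a project back out


def write_project(project: ProjectMetadata, library: PackageLibrary,
                  path: str | Path) -> Path:
    """Regenerate a filled workbook from project metadata.

    ``parse_workbook(write_project(p))`` reproduces ``p``: values and
    user-defined columns are written verbatim. Raises
    :class:`~fairds.errors.PackageLookupError` when the project uses a
    package the library does not define.
    """
    for pid in sorted(project.source_packages):
        if not library.has_package(pid):
            raise PackageLookupError(
                f"project uses package {pid!r} which is absent from the library")

    sheets: list[SheetModel] = []
    for name, level in _LEVEL_SHEETS.items():
        sheet = _make_sheet(name, level, library.core_for(level))
        for rec in project.records(level):
            _append_record(sheet, rec)
        sheets.append(sheet)

    for level, prefix in ((Level.SAMPLE, _SAMPLE_PREFIX),
                          (Level.ASSAY, _ASSAY_PREFIX)):
        by_package: dict[str, list] = {}
        for rec in project.records(level):
            by_package.setdefault(rec.package_id, []).append(rec)
        for pid in sorted(by_package):
            records = by_package[pid]
            if pid:
                pkg = library.package(pid)
                present = {n for rec in records for n in rec.attributes}
                selected = [n for n in pkg.optional_names if n in present]
                specs = effective_attributes(library, pid, selected)
            else:
                specs = library.core_for(level)
            sheet = _make_sheet(prefix + pid if pid else
                                ("Sample - unassigned" if level is Level.SAMPLE
                                 else "Assay - unassigned"),
                                level, specs, package_id=pid or None)
            for rec in records:
                _append_record(sheet, rec)
            sheets.append(sheet)
        if not by_package and level is Level.SAMPLE:
            pass  # no sample sheet needed for an investigation-only project

    model = WorkbookModel(sheets=sheets,
                          packages=sorted(p for p in project.source_packages),
                          library_version=library.version_tag)
    return model.save(path)


def _append_record(sheet: SheetModel, rec) -> None:
    for name in rec.attributes:
        if name not in sheet.headers:
            sheet.headers.append(name)  # user-defined or unselected column
    sheet.rows.append(dict(rec.attributes))
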