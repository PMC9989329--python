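"""Bundled data: the package library and the ENA structural rule set.

The canonical source of the bundled checklist library is a pair of TSV
files (diff-friendly, reviewable in version control). The spreadsheet
form researchers edit — the two-sheet XLSX workbook that
:func:`fairds.library.load_library` reads — is materialised from the
TSVs on demand by :func:`build_package_library_xlsx`.
"""

from __future__ import annotations

import csv
import datetime
import json
import tempfile
from importlib import resources
from pathlib import Path

from openpyxl import Workbook

__all__ = [
    "build_package_library_xlsx",
    "default_library_path",
    "load_default_library",
    "LIBRARY_VERSION",
]

LIBRARY_VERSION = "2026.1"

_CACHED: Path | None = None


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files(__package__).joinpath(name).read_text(encoding="utf-8")
    return [row for row in csv.reader(text.splitlines(), delimiter="\t")]


def _fixed_properties(wb: Workbook) -> None:
    # pinned so repeated builds are byte-identical
    stamp = datetime.datetime(2026, 1, 1)
    wb.properties.created = stamp
    wb.properties.modified = stamp
    wb.properties.creator = "fairds"


def build_package_library_xlsx(dest: str | Path) -> Path:
    """Write the bundled library as a two-sheet XLSX workbook at ``dest``."""
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    wb = Workbook()
    _fixed_properties(wb)
    ws = wb.active
    ws.title = "packages"
    for row in _read_tsv("packages.tsv"):
        ws.append(row)
    ws2 = wb.create_sheet("attributes")
    for row in _read_tsv("attributes.tsv"):
        ws2.append(row)
    wb.save(dest)
    return dest


def default_library_path() -> Path:
    """Path to a materialised copy of the bundled library workbook.

    Built once per process into a temporary directory; callers that want
    the workbook at a specific location use
    :func:`build_package_library_xlsx` directly.
    """
    global _CACHED
    if _CACHED is None or not _CACHED.exists():
        tmpdir = Path(tempfile.mkdtemp(prefix="fairds_library_"))
        _CACHED = build_package_library_xlsx(tmpdir / "package_library.xlsx")
    return _CACHED


def load_default_library():
    """Load the bundled package library (40 checklists)."""
    from ..library import load_library

    lib = load_library(default_library_path())
    lib.version_tag = LIBRARY_VERSION
    return lib


def sra_rules() -> dict:
    """The distilled structural rule set for ENA SRA XML documents."""
    text = resources.files(__package__).joinpath("sra_rules.json").read_text("utf-8")
    return json.loads(text)
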