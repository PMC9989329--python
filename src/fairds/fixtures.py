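"""Deterministic demo data so every stage runs without downloads.

The generator stands in for a real field campaign: a freshwater
monitoring project recorded with the ``mixs_water`` sample checklist and
the ``ena_short_read_assay`` assay checklist. It produces

* a toy Environment-Ontology-like vocabulary (12 labelled terms, in
  Turtle) for ontology-term validation,
* a demo subset of the package library (core attributes plus the two
  packages used) as an editable two-sheet workbook,
* a filled project workbook that validates cleanly, plus tiny FASTQ
  files for the assays so checksummed ENA run blocks can be built,
* optionally a menu of injected errors with a manifest of the exact
  issues the validator must report (sheet, row, attribute, rule).

Everything is driven by one integer seed; two runs with the same
configuration produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from openpyxl import Workbook

from .library import Level
from .template import TemplateSpec, generate_template

__all__ = ["FixtureConfig", "FixtureSet", "generate_fixtures", "TOY_ONTOLOGY_TERMS"]

SAMPLE_PACKAGE = "mixs_water"
ASSAY_PACKAGE = "ena_short_read_assay"
OPTIONAL_SELECTION = {
    SAMPLE_PACKAGE: ["depth", "temperature", "oxygenic"],
    ASSAY_PACKAGE: ["insert_size"],
}

#: the toy ontology: (local id, label); exactly 12 labelled terms
TOY_ONTOLOGY_TERMS: tuple[tuple[str, str], ...] = (
    ("ENVO_00000020", "freshwater lake"),
    ("ENVO_00000447", "marine biome"),
    ("ENVO_00001998", "soil"),
    ("ENVO_00002001", "sea water"),
    ("ENVO_00002007", "sediment"),
    ("ENVO_00002259", "activated sludge"),
    ("ENVO_00002979", "compost"),
    ("ENVO_00005801", "rhizosphere"),
    ("ENVO_00005774", "peat soil"),
    ("ENVO_01000177", "grassland biome"),
    ("ENVO_01000253", "freshwater river biome"),
    ("ENVO_01001059", "bioreactor"),
)

_BROAD = ["marine biome", "grassland biome", "freshwater river biome"]
_LOCAL = ["freshwater lake", "sea water", "rhizosphere", "sediment"]
_MEDIUM = ["sea water", "soil", "sediment", "compost", "activated sludge",
           "peat soil"]

#: injection rule -> (sheet kind, attribute, replacement value)
_INJECTIONS = {
    "missing_mandatory": ("sample", "collection_date", ""),
    "bad_boolean": ("sample", "oxygenic", "yes"),
    "bad_date": ("sample", "collection_date", "12/04/2026"),
    "regex_mismatch": ("sample", "depth", "very deep"),
    "ontology_unknown": ("sample", "env_medium", "lunar regolith"),
    "unknown_parent": ("sample", "observation_unit_identifier", "OU_missing"),
    "duplicate_identifier": ("sample", "sample_identifier", None),
}


@dataclass
class FixtureConfig:
    """Shape of the generated project and the error-injection menu."""

    seed: int = 42
    studies: int = 1
    units_per_study: int = 2
    samples_per_unit: int = 2
    assays_per_sample: int = 1
    injections: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, count in (("studies", self.studies),
                            ("units_per_study", self.units_per_study),
                            ("samples_per_unit", self.samples_per_unit),
                            ("assays_per_sample", self.assays_per_sample)):
            if count < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.injections) - set(_INJECTIONS)
        if unknown:
            raise ValueError(f"unknown injection rule(s): {sorted(unknown)}")


@dataclass
class FixtureSet:
    """Paths and oracle data produced by :func:`generate_fixtures`."""

    workbook: Path
    ontology: Path
    library_subset: Path
    data_dir: Path
    manifest: Path
    expected_issues: list[dict]
    counts: dict[str, int]


def _toy_ontology_text() -> str:
    lines = [
        "@prefix obo: <http://purl.obolibrary.org/obo/> .",
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "",
    ]
    for local, label in TOY_ONTOLOGY_TERMS:
        lines.append(f'obo:{local}\n    a owl:Class ;\n    rdfs:label "{label}" .')
        lines.append("")
    return "\n".join(lines)


def _write_library_subset(path: Path, packages: list[str]) -> None:
    """A two-sheet library workbook restricted to the given packages."""
    pkg_rows = csv.reader(
        resources.files("fairds.data").joinpath("packages.tsv")
        .read_text("utf-8").splitlines(), delimiter="\t")
    attr_rows = csv.reader(
        resources.files("fairds.data").joinpath("attributes.tsv")
        .read_text("utf-8").splitlines(), delimiter="\t")
    wb = Workbook()
    import datetime

    wb.properties.created = datetime.datetime(2026, 1, 1)
    wb.properties.modified = datetime.datetime(2026, 1, 1)
    wb.properties.creator = "fairds"
    ws = wb.active
    ws.title = "packages"
    keep = set(packages) | {"core"}
    for i, row in enumerate(pkg_rows):
        if i == 0 or row[0] in keep:
            ws.append(row)
    ws2 = wb.create_sheet("attributes")
    for i, row in enumerate(attr_rows):
        if i == 0 or row[0] in keep:
            ws2.append(row)
    wb.save(path)


def _fastq_text(rng: random.Random, read_id: str, n_reads: int = 3) -> str:
    lines = []
    for i in range(n_reads):
        seq = "".join(rng.choice("ACGT") for _ in range(60))
        qual = "".join(rng.choice("FGHI") for _ in range(60))
        lines += [f"@{read_id}.{i + 1}", seq, "+", qual]
    return "\n".join(lines) + "\n"


def generate_fixtures(config: FixtureConfig, outdir: str | Path) -> FixtureSet:
    """Write the demo fixture set into ``outdir``; see the module docstring.

    With an empty injection menu the workbook validates with zero
    errors; with injections the returned manifest lists the exact
    error-severity issues ``validate_project`` must report.
    """
    from .data import load_default_library

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)
    library = load_default_library()

    ontology_path = outdir / "toy_envo.ttl"
    ontology_path.write_text(_toy_ontology_text(), encoding="utf-8")
    library_path = outdir / "demo_library.xlsx"
    _write_library_subset(library_path, [SAMPLE_PACKAGE, ASSAY_PACKAGE])

    spec = TemplateSpec(
        library=library,
        packages=[SAMPLE_PACKAGE, ASSAY_PACKAGE],
        optional=dict(OPTIONAL_SELECTION),
    )
    model = generate_template(spec)

    inv_id = "INV_demo"
    model.sheet("Investigation").rows.append({
        "investigation_identifier": inv_id,
        "investigation_title": "Freshwater microbial monitoring demo",
        "investigation_description":
            "Synthetic demonstration project generated by fairds.fixtures.",
        "contact_name": "A. Researcher;B. Datamanager",
        "contact_email": "a.researcher@example.org;b.datamanager@example.org",
        "contact_orcid": "0000-0002-1825-0097",
    })
    study_sheet = model.sheet("Study")
    unit_sheet = model.sheet("ObservationUnit")
    sample_sheet = model.sheet(f"Sample - {SAMPLE_PACKAGE}")
    assay_sheet = model.sheet(f"Assay - {ASSAY_PACKAGE}")

    data_dir = outdir / "data"
    data_dir.mkdir(exist_ok=True)
    n_samples = 0
    n_assays = 0
    for s in range(1, config.studies + 1):
        sid = f"S{s}"
        study_sheet.rows.append({
            "study_identifier": sid,
            "investigation_identifier": inv_id,
            "study_title": f"Lake survey {s}",
            "study_description": f"Seasonal sampling campaign {s} of the demo "
                                 f"lake system.",
        })
        for u in range(1, config.units_per_study + 1):
            uid = f"{sid}_OU{u}"
            unit_sheet.rows.append({
                "observation_unit_identifier": uid,
                "study_identifier": sid,
                "observation_unit_description":
                    f"Sampling station {u} of study {sid}",
            })
            for k in range(1, config.samples_per_unit + 1):
                n_samples += 1
                sample_id = f"SA{n_samples}"
                month = rng.randint(3, 9)
                day = rng.randint(1, 28)
                sample_sheet.rows.append({
                    "sample_identifier": sample_id,
                    "observation_unit_identifier": uid,
                    "sample_description": f"Replicate {k} at station {uid}",
                    "collection_date": f"2026-{month:02d}-{day:02d}",
                    "tax_id": "449393",
                    "scientific_name": "freshwater metagenome",
                    "geographic_location": "Netherlands: Veluwe",
                    "env_broad_scale": rng.choice(_BROAD),
                    "env_local_scale": rng.choice(_LOCAL),
                    "env_medium": rng.choice(_MEDIUM),
                    "sample_volume_or_weight_for_dna_extraction":
                        f"{rng.randint(1, 9)}.{rng.randint(0, 9)} mg",
                    "depth": f"{rng.randint(0, 40)} m",
                    "temperature": f"{rng.randint(4, 25)} C",
                    "oxygenic": rng.choice(["true", "false"]),
                })
                for a in range(1, config.assays_per_sample + 1):
                    n_assays += 1
                    assay_id = f"A{n_assays}"
                    files = [f"{assay_id}_R1.fastq", f"{assay_id}_R2.fastq"]
                    for fname in files:
                        (data_dir / fname).write_text(
                            _fastq_text(rng, f"{assay_id}_{fname[-8]}"),
                            encoding="utf-8")
                    assay_sheet.rows.append({
                        "assay_identifier": assay_id,
                        "sample_identifier": sample_id,
                        "platform": "ILLUMINA",
                        "instrument_model": "Illumina NovaSeq 6000",
                        "library_strategy": "WGS",
                        "library_source": "METAGENOMIC",
                        "library_selection": "RANDOM",
                        "library_layout": "PAIRED",
                        "file_name": ";".join(files),
                        "insert_size": str(rng.randint(250, 500)),
                    })

    expected = _apply_injections(config, model, sample_sheet, assay_sheet)

    workbook_path = outdir / "demo_project.xlsx"
    model.save(workbook_path)
    manifest_path = outdir / "expected_issues.json"
    manifest_path.write_text(json.dumps(expected, indent=2) + "\n",
                             encoding="utf-8")
    return FixtureSet(
        workbook=workbook_path,
        ontology=ontology_path,
        library_subset=library_path,
        data_dir=data_dir,
        manifest=manifest_path,
        expected_issues=expected,
        counts={
            "studies": config.studies,
            "observation_units": config.studies * config.units_per_study,
            "samples": n_samples,
            "assays": n_assays,
        },
    )


def _apply_injections(config: FixtureConfig, model, sample_sheet,
                      assay_sheet) -> list[dict]:
    """Perturb filled rows so each injection yields exactly one error."""
    expected: list[dict] = []
    target = 0
    n_rows = len(sample_sheet.rows)
    for rule in sorted(config.injections):
        count = config.injections[rule]
        for _ in range(count):
            if target >= n_rows:
                raise ValueError(
                    "not enough sample rows to place all injections; "
                    "increase the per-level counts")
            sheet_kind, attribute, replacement = _INJECTIONS[rule]
            row = sample_sheet.rows[target]
            if rule == "duplicate_identifier":
                if target == 0:
                    target += 1
                    row = sample_sheet.rows[target]
                original = row["sample_identifier"]
                duplicate_of = sample_sheet.rows[0]["sample_identifier"]
                row["sample_identifier"] = duplicate_of
                for assay_row in assay_sheet.rows:
                    if assay_row["sample_identifier"] == original:
                        assay_row["sample_identifier"] = duplicate_of
                value = duplicate_of
            else:
                row[attribute] = replacement
                value = replacement
            expected.append({
                "sheet": sample_sheet.name,
                "row": target + 2,  # header is row 1
                "attribute": attribute,
                "rule": rule,
                "value": value,
            })
            target += 1
    expected.sort(key=lambda e: (e["sheet"], e["row"], e["attribute"], e["rule"]))
    return expected
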