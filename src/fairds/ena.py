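"""ENA submission sets.

Converts validated project metadata into the five SRA-schema XML
documents the European Nucleotide Archive accepts (study, sample,
experiment, run, submission). The ENA data model has no observation-unit
level, so each observation unit's attributes are folded into the
attribute list of its descendant samples (on a name collision the
sample's own value wins and a warning is recorded). Aliases are minted
deterministically as ``<investigation id>_<record id>`` so re-building a
submission never shuffles references.

``validate_submission`` checks each document against a distilled
structural rule set (required elements and attributes, the SRA
controlled vocabularies for platform and library descriptors, checksum
syntax) plus the cross-document reference graph. The rule set is a
synthetic stand-in for the SRA XSDs, which cannot be validated offline
without an XML Schema engine; it covers the constraints this package
can produce or violate.
"""

from __future__ import annotations

import hashlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .data import sra_rules
from .errors import ConversionError
from .isa import Level, ProjectMetadata
from .library import PackageLibrary

__all__ = [
    "EnaOptions",
    "EnaSubmissionSet",
    "SchemaViolation",
    "build_submission",
    "compute_file_checksums",
    "validate_submission",
]

DOCUMENT_NAMES = ("study", "sample", "experiment", "run", "submission")

#: sample attributes lifted into dedicated SAMPLE_NAME / TITLE elements
_SAMPLE_STRUCTURAL = {"tax_id", "scientific_name"}
_MANDATORY_ASSAY_ATTRS = (
    "platform", "library_strategy", "library_source", "library_selection",
    "file_name",
)


@dataclass
class EnaOptions:
    checklist: str = "ERC000011"
    center_name: str = ""
    hold_date: str | None = None  # YYYY-MM-DD; omitted -> no HOLD action


@dataclass(frozen=True)
class SchemaViolation:
    document: str
    element: str
    kind: str  # missing_element | missing_attribute | bad_enum | bad_value |
    #            dangling_reference
    message: str


@dataclass
class EnaSubmissionSet:
    """The five XML documents plus the alias map for one project."""

    study_xml: ET.Element
    sample_xml: ET.Element
    experiment_xml: ET.Element
    run_xml: ET.Element
    submission_xml: ET.Element
    aliases: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def documents(self) -> dict[str, ET.Element]:
        return {
            "study": self.study_xml,
            "sample": self.sample_xml,
            "experiment": self.experiment_xml,
            "run": self.run_xml,
            "submission": self.submission_xml,
        }

    def to_strings(self) -> dict[str, str]:
        return {name: _to_string(root) for name, root in self.documents().items()}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, text in self.to_strings().items():
            path = outdir / f"{name}.xml"
            path.write_text(text, encoding="utf-8")
            paths[name] = path
        return paths


def _to_string(root: ET.Element) -> str:
    clone = ET.ElementTree(root)
    ET.indent(clone, space="  ")
    return ET.tostring(clone.getroot(), encoding="unicode",
                       xml_declaration=True) + "\n"


def _sub(parent: ET.Element, tag: str, text: str | None = None,
         **attrs: str) -> ET.Element:
    element = ET.SubElement(parent, tag, dict(attrs))
    if text is not None:
        element.text = text
    return element


def compute_file_checksums(paths: list[str | Path]) -> dict[str, str]:
    """MD5 hex digests of data files, keyed by the given path string.

    Missing files are reported together in a single ``FileNotFoundError``
    rather than silently skipped.
    """
    missing = [str(p) for p in paths if not Path(p).is_file()]
    if missing:
        raise FileNotFoundError(
            "data file(s) not found: " + ", ".join(sorted(missing)))
    digests: dict[str, str] = {}
    for path in paths:
        h = hashlib.md5()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        digests[str(path)] = h.hexdigest()
    return digests


def build_submission(
    project: ProjectMetadata,
    library: PackageLibrary,
    options: EnaOptions | None = None,
    data_dir: str | Path | None = None,
) -> EnaSubmissionSet:
    """Convert a validated project into an ENA submission set.

    ``data_dir`` is where the assays' data files live (for MD5 checksum
    blocks in the run document); file names in assay records are resolved
    relative to it. Missing mandatory sequencing attributes and missing
    data files raise :class:`~fairds.errors.ConversionError`.
    """
    options = options or EnaOptions()
    inv = project.investigation.identifier or "project"
    warnings: list[str] = []

    def alias(identifier: str) -> str:
        return f"{inv}_{identifier}"

    aliases: dict[str, str] = {}
    for level in (Level.STUDY, Level.SAMPLE, Level.ASSAY):
        for rec in project.records(level):
            a = alias(rec.identifier)
            if a in aliases.values():
                raise ConversionError(f"duplicate minted alias {a!r}")
            aliases[f"{level.value}:{rec.identifier}"] = a

    units = {u.identifier: u for u in project.observation_units}
    samples = {s.identifier: s for s in project.samples}

    center = {"center_name": options.center_name} if options.center_name else {}

    # -- study ------------------------------------------------------------
    study_set = ET.Element("STUDY_SET")
    for study in project.studies:
        study_el = _sub(study_set, "STUDY",
                        alias=aliases[f"study:{study.identifier}"], **center)
        descriptor = _sub(study_el, "DESCRIPTOR")
        _sub(descriptor, "STUDY_TITLE", study.title or study.identifier)
        _sub(descriptor, "STUDY_TYPE", existing_study_type="Other")
        abstract = study.description or project.investigation.description
        _sub(descriptor, "STUDY_ABSTRACT", abstract)

    # -- sample -----------------------------------------------------------
    sample_set = ET.Element("SAMPLE_SET")
    for sample in project.samples:
        sample_el = _sub(sample_set, "SAMPLE",
                         alias=aliases[f"sample:{sample.identifier}"], **center)
        _sub(sample_el, "TITLE",
             sample.attributes.get("sample_description") or sample.identifier)
        name_el = _sub(sample_el, "SAMPLE_NAME")
        tax_id = sample.attributes.get("tax_id", "")
        if tax_id:
            _sub(name_el, "TAXON_ID", tax_id)
        scientific = sample.attributes.get("scientific_name", "")
        if scientific:
            _sub(name_el, "SCIENTIFIC_NAME", scientific)

        merged: dict[str, str] = {}
        unit = units.get(sample.observation_unit_id)
        if unit is not None:
            for name, value in unit.attributes.items():
                if value:
                    merged[name] = value
        for name, value in sample.attributes.items():
            if not value:
                continue
            if name in merged and merged[name] != value:
                warnings.append(
                    f"sample {sample.identifier!r}: attribute {name!r} set on "
                    f"both the sample and its observation unit; sample value "
                    f"wins")
            merged[name] = value
        attrs_el = _sub(sample_el, "SAMPLE_ATTRIBUTES")
        for name in merged:
            attr_el = _sub(attrs_el, "SAMPLE_ATTRIBUTE")
            _sub(attr_el, "TAG", name)
            _sub(attr_el, "VALUE", merged[name])
        checklist_el = _sub(attrs_el, "SAMPLE_ATTRIBUTE")
        _sub(checklist_el, "TAG", "ENA-CHECKLIST")
        _sub(checklist_el, "VALUE", options.checklist)

    # -- experiment and run ----------------------------------------------
    experiment_set = ET.Element("EXPERIMENT_SET")
    run_set = ET.Element("RUN_SET")
    for assay in project.assays:
        for attr in _MANDATORY_ASSAY_ATTRS:
            if not assay.attributes.get(attr, "").strip():
                raise ConversionError(
                    f"assay {assay.identifier!r} lacks the mandatory "
                    f"sequencing attribute {attr!r}")
        sample = samples.get(assay.sample_id)
        if sample is None:
            raise ConversionError(
                f"assay {assay.identifier!r} references unknown sample "
                f"{assay.sample_id!r}")
        unit = units.get(sample.observation_unit_id)
        study_id = unit.study_id if unit is not None else ""
        study_key = f"study:{study_id}"
        if study_key not in aliases:
            raise ConversionError(
                f"assay {assay.identifier!r} cannot be linked to a study "
                f"(sample {sample.identifier!r} -> observation unit "
                f"{sample.observation_unit_id!r} -> study {study_id!r})")

        exp_el = _sub(experiment_set, "EXPERIMENT",
                      alias=aliases[f"assay:{assay.identifier}"], **center)
        _sub(exp_el, "TITLE", f"Sequencing of sample {sample.identifier}")
        _sub(exp_el, "STUDY_REF", refname=aliases[study_key])
        design = _sub(exp_el, "DESIGN")
        _sub(design, "DESIGN_DESCRIPTION",
             assay.attributes.get("assay_description", ""))
        _sub(design, "SAMPLE_DESCRIPTOR",
             refname=aliases[f"sample:{sample.identifier}"])
        lib_el = _sub(design, "LIBRARY_DESCRIPTOR")
        _sub(lib_el, "LIBRARY_NAME", assay.identifier)
        _sub(lib_el, "LIBRARY_STRATEGY", assay.attributes["library_strategy"])
        _sub(lib_el, "LIBRARY_SOURCE", assay.attributes["library_source"])
        _sub(lib_el, "LIBRARY_SELECTION", assay.attributes["library_selection"])
        layout_el = _sub(lib_el, "LIBRARY_LAYOUT")
        layout = assay.attributes.get("library_layout", "").strip().upper()
        if not layout:
            layout = "PAIRED" if len(assay.data_files) == 2 else "SINGLE"
        _sub(layout_el, layout if layout in ("SINGLE", "PAIRED") else "SINGLE")
        platform_el = _sub(exp_el, "PLATFORM")
        model_el = _sub(platform_el, assay.attributes["platform"].strip())
        _sub(model_el, "INSTRUMENT_MODEL",
             assay.attributes.get("instrument_model", "").strip()
             or "unspecified")

        if assay.data_files:
            resolved = [
                (name, Path(data_dir) / name if data_dir is not None
                 else Path(name))
                for name in assay.data_files
            ]
            try:
                checksums = compute_file_checksums([p for _, p in resolved])
            except FileNotFoundError as exc:
                raise ConversionError(
                    f"assay {assay.identifier!r}: {exc}") from exc
            run_el = _sub(run_set, "RUN",
                          alias=aliases[f"assay:{assay.identifier}"] + "_run",
                          **center)
            _sub(run_el, "EXPERIMENT_REF",
                 refname=aliases[f"assay:{assay.identifier}"])
            files_el = _sub(_sub(run_el, "DATA_BLOCK"), "FILES")
            for name, resolved_path in resolved:
                filetype = "fastq" if ".f" in name else "other"
                _sub(files_el, "FILE", filename=name, filetype=filetype,
                     checksum_method="MD5",
                     checksum=checksums[str(resolved_path)])

    # -- submission -------------------------------------------------------
    submission_el = ET.Element("SUBMISSION", {"alias": f"{inv}_submission",
                                              **center})
    actions_el = _sub(submission_el, "ACTIONS")
    for name in ("study", "sample", "experiment", "run"):
        action_el = _sub(actions_el, "ACTION")
        _sub(action_el, "ADD", source=f"{name}.xml", schema=name)
    if options.hold_date:
        action_el = _sub(actions_el, "ACTION")
        _sub(action_el, "HOLD", HoldUntilDate=options.hold_date)

    return EnaSubmissionSet(
        study_xml=study_set,
        sample_xml=sample_set,
        experiment_xml=experiment_set,
        run_xml=run_set,
        submission_xml=submission_el,
        aliases=aliases,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# structural validation


def _check_required(doc: str, record: ET.Element, rules: dict,
                    violations: list[SchemaViolation]) -> None:
    for path in rules.get("required_paths", ()):
        if record.find(path) is None:
            violations.append(SchemaViolation(
                doc, f"{record.tag}/{path}", "missing_element",
                f"{record.tag} {record.get('alias', '?')!r} lacks required "
                f"element {path}"))
    for attr in rules.get("required_attrs", ()):
        if not record.get(attr):
            violations.append(SchemaViolation(
                doc, record.tag, "missing_attribute",
                f"{record.tag} lacks required attribute {attr!r}"))
    for enum in rules.get("enums", ()):
        for el in ([record] if enum["path"] == "." else record.findall(enum["path"])):
            if "attr" in enum:
                value = el.get(enum["attr"], "")
            elif enum.get("child_tag"):
                children = [c.tag for c in el]
                value = children[0] if children else ""
            else:
                value = (el.text or "").strip()
            if "values" in enum and value not in enum["values"]:
                violations.append(SchemaViolation(
                    doc, f"{record.tag}/{enum['path']}", "bad_enum",
                    f"{value!r} is not one of the allowed values for "
                    f"{enum['path']}"))
            if "pattern" in enum:
                import re as _re

                if not _re.fullmatch(enum["pattern"], value):
                    violations.append(SchemaViolation(
                        doc, f"{record.tag}/{enum['path']}", "bad_value",
                        f"{value!r} does not match {enum['pattern']!r}"))


def validate_submission(subset: EnaSubmissionSet) -> list[SchemaViolation]:
    """Structural and cross-reference validation of a submission set.

    Violations are returned as data, never raised; an empty list means
    the set is submission-ready as far as this package can check.
    """
    rules = sra_rules()
    violations: list[SchemaViolation] = []
    for doc, root in subset.documents().items():
        doc_rules = rules[doc]
        if root.tag != doc_rules["root"]:
            violations.append(SchemaViolation(
                doc, root.tag, "missing_element",
                f"root element must be {doc_rules['root']!r}"))
            continue
        records = [root] if doc_rules["record"] == doc_rules["root"] \
            else root.findall(doc_rules["record"])
        for record in records:
            _check_required(doc, record, doc_rules, violations)

    study_aliases = {el.get("alias") for el in subset.study_xml.findall("STUDY")}
    sample_aliases = {el.get("alias") for el in subset.sample_xml.findall("SAMPLE")}
    experiment_aliases = {
        el.get("alias") for el in subset.experiment_xml.findall("EXPERIMENT")}
    for exp in subset.experiment_xml.findall("EXPERIMENT"):
        ref = exp.find("STUDY_REF")
        if ref is not None and ref.get("refname") not in study_aliases:
            violations.append(SchemaViolation(
                "experiment", "EXPERIMENT/STUDY_REF", "dangling_reference",
                f"experiment {exp.get('alias')!r} references unknown study "
                f"{ref.get('refname')!r}"))
        ref = exp.find("DESIGN/SAMPLE_DESCRIPTOR")
        if ref is not None and ref.get("refname") not in sample_aliases:
            violations.append(SchemaViolation(
                "experiment", "EXPERIMENT/DESIGN/SAMPLE_DESCRIPTOR",
                "dangling_reference",
                f"experiment {exp.get('alias')!r} references unknown sample "
                f"{ref.get('refname')!r}"))
    for run in subset.run_xml.findall("RUN"):
        ref = run.find("EXPERIMENT_REF")
        if ref is not None and ref.get("refname") not in experiment_aliases:
            violations.append(SchemaViolation(
                "run", "RUN/EXPERIMENT_REF", "dangling_reference",
                f"run {run.get('alias')!r} references unknown experiment "
                f"{ref.get('refname')!r}"))
    return violations
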