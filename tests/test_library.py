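"""Checklist library: loading, selection, JSON Schema export, linting."""

import re

import jsonschema
import pytest
from openpyxl import Workbook

from fairds import (
    AttributeSpec,
    Level,
    Package,
    PackageLibrary,
    Requirement,
    Source,
    ValueKind,
    effective_attributes,
    export_json_schema,
    lint_library,
    list_packages,
    load_library,
)
from fairds.errors import (
    LibraryFormatError,
    PackageLookupError,
    SelectionError,
)

SAMPLE_VOLUME = "sample_volume_or_weight_for_dna_extraction"
SAMPLE_VOLUME_REGEX = (
    "(0|((0.)|([1-9][0-9]*.?))[0-9]*)([Ee][+-]?[0-9]+)? (g|mL|mg|ng)"
)


class TestLoadLibrary:
    def test_bundled_counts(self, library):
        assert len(library.packages) == 40
        assert len(list_packages(library, source=Source.MIXS)) == 23
        assert len(list_packages(library, source=Source.ENA)) == 17

    def test_no_filters_returns_all(self, library):
        assert list_packages(library) == library.packages
        assert len(list_packages(library)) == 40

    def test_user_filter_empty_on_pristine_library(self, library):
        assert list_packages(library, source="user") == []

    def test_level_filter(self, library):
        for pkg in list_packages(library, level=Level.ASSAY):
            assert pkg.level is Level.ASSAY

    def test_deterministic_load(self, library_path):
        first = load_library(library_path)
        second = load_library(library_path)
        assert [p.id for p in first.packages] == [p.id for p in second.packages]
        assert first.core_attributes == second.core_attributes
        assert [p.attributes for p in first.packages] == \
            [p.attributes for p in second.packages]

    def test_attribute_order_preserved(self, library):
        pkg = library.package("mixs_water")
        names = [a.name for a in pkg.attributes]
        assert names.index("depth") < names.index("oxygenic")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_library(tmp_path / "nope.xlsx")

    def test_empty_attribute_sheet_is_format_error(self, tmp_path):
        wb = Workbook()
        ws = wb.active
        ws.title = "packages"
        ws.append(["id", "title", "source", "level"])
        ws.append(["p1", "P one", "ENA", "sample"])
        ws2 = wb.create_sheet("attributes")
        ws2.append(["package_id", "level", "name", "label", "requirement",
                    "value_kind", "regex", "ontology_iri", "units", "example",
                    "definition", "multivalued"])
        path = tmp_path / "empty.xlsx"
        wb.save(path)
        with pytest.raises(LibraryFormatError):
            load_library(path)

    def test_malformed_rows_name_sheet_and_row(self, tmp_path):
        wb = Workbook()
        ws = wb.active
        ws.title = "packages"
        ws.append(["id", "title", "source", "level"])
        ws.append(["p1", "P one", "ENA", "sample"])
        ws2 = wb.create_sheet("attributes")
        ws2.append(["package_id", "level", "name", "label", "requirement",
                    "value_kind", "regex", "ontology_iri", "units", "example",
                    "definition", "multivalued"])
        ws2.append(["p1", "", "x", "X", "sometimes", "text", "", "", "", "",
                    "", ""])
        path = tmp_path / "bad.xlsx"
        wb.save(path)
        with pytest.raises(LibraryFormatError, match="row 2"):
            load_library(path)


class TestEffectiveAttributes:
    def test_empty_selection_is_core_plus_mandatory(self, library):
        for pkg in library.packages:
            specs = effective_attributes(library, pkg.id, set())
            core = library.core_for(pkg.level)
            assert specs[: len(core)] == core
            assert all(s.mandatory for s in specs[len(core):])

    def test_selection_is_superset_with_same_mandatory(self, library):
        for pkg in library.packages:
            base = effective_attributes(library, pkg.id, set())
            full = effective_attributes(library, pkg.id, pkg.optional_names)
            assert set(s.name for s in base) <= set(s.name for s in full)
            assert [s for s in base if s.mandatory] == \
                [s for s in full if s.mandatory]

    def test_sample_volume_regex_verbatim(self, library):
        specs = effective_attributes(library, "mixs_water", {SAMPLE_VOLUME})
        spec = next(s for s in specs if s.name == SAMPLE_VOLUME)
        assert spec.syntax_regex == SAMPLE_VOLUME_REGEX

    def test_unknown_package(self, library):
        with pytest.raises(PackageLookupError):
            effective_attributes(library, "no_such_package", set())

    def test_unknown_optional_lists_valid_options(self, library):
        with pytest.raises(SelectionError, match="depth"):
            effective_attributes(library, "mixs_water", {"nonexistent_attr"})

    def test_requirement_flags_retained(self, library):
        specs = effective_attributes(library, "mixs_water", {"depth"})
        by_name = {s.name: s for s in specs}
        assert by_name["env_medium"].requirement is Requirement.MANDATORY
        assert by_name["depth"].requirement is Requirement.OPTIONAL


class TestJsonSchemaExport:
    def test_required_matches_mandatory_count(self, library):
        for pkg in library.packages:
            schema = export_json_schema(library, pkg.id)
            mandatory = [s.name for s in
                         effective_attributes(library, pkg.id, set())
                         if s.mandatory]
            assert schema["required"] == mandatory
            jsonschema.Draft7Validator.check_schema(schema)

    def test_pattern_carries_library_regex(self, library):
        schema = export_json_schema(library, "mixs_water")
        pattern = schema["properties"][SAMPLE_VOLUME]["pattern"]
        assert SAMPLE_VOLUME_REGEX in pattern

    def test_blank_mandatory_invalid_under_both_engines(self, library):
        from fairds.validation import format_valid

        schema = export_json_schema(library, "ena_default_sample")
        validator = jsonschema.Draft7Validator(schema)
        record = {name: "x" for name in schema["required"]}
        record["tax_id"] = "9606"
        record["collection_date"] = "2026-01-01"
        record["sample_identifier"] = "S1"
        record["observation_unit_identifier"] = "OU1"
        assert validator.is_valid(record)
        assert format_valid(library, "ena_default_sample", record)
        record["scientific_name"] = ""
        assert not validator.is_valid(record)
        assert not format_valid(library, "ena_default_sample", record)

    def test_unknown_package(self, library):
        with pytest.raises(PackageLookupError):
            export_json_schema(library, "no_such_package")


class TestLint:
    def test_pristine_library_is_clean(self, library):
        assert lint_library(library) == []

    def _library_with(self, attributes):
        pkg = Package("p1", "P one", Source.USER, Level.SAMPLE,
                      attributes=attributes)
        return PackageLibrary(packages=[pkg])

    def test_duplicate_name(self):
        lib = self._library_with([
            AttributeSpec(name="dup", label="d"),
            AttributeSpec(name="dup", label="d2"),
        ])
        issues = lint_library(lib)
        assert [i.kind for i in issues] == ["duplicate_name"]

    def test_bad_regex_names_attribute(self):
        lib = self._library_with([
            AttributeSpec(name="broken", label="b",
                          value_kind=ValueKind.RESTRICTED_TEXT,
                          syntax_regex="([a-"),
        ])
        # the oracle: the pattern must really be rejected by the regex engine
        with pytest.raises(re.error):
            re.compile("([a-")
        issues = lint_library(lib)
        assert len(issues) == 1
        assert issues[0].kind == "bad_regex"
        assert issues[0].attribute == "broken"

    def test_ontology_term_without_iri(self):
        lib = self._library_with([
            AttributeSpec(name="env", label="env",
                          value_kind=ValueKind.ONTOLOGY_TERM),
        ])
        assert [i.kind for i in lint_library(lib)] == ["missing_ontology_iri"]

    def test_lint_never_raises_on_permissive_load(self, tmp_path):
        wb = Workbook()
        ws = wb.active
        ws.title = "packages"
        ws.append(["id", "title", "source", "level"])
        ws.append(["p1", "P one", "ENA", "kingdom"])  # unknown level token
        ws2 = wb.create_sheet("attributes")
        ws2.append(["package_id", "level", "name", "label", "requirement",
                    "value_kind", "regex", "ontology_iri", "units", "example",
                    "definition", "multivalued"])
        ws2.append(["core", "sample", "ok_attr", "OK", "mandatory", "text",
                    "", "", "", "", "", ""])
        path = tmp_path / "weird.xlsx"
        wb.save(path)
        lib = load_library(path, strict=False)
        kinds = {i.kind for i in lint_library(lib)}
        assert "unknown_level" in kinds
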