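"""Value rules, ontology validation, auto-correction and link checks."""

import copy
import random

import jsonschema
import pytest

from fairds import (
    AttributeSpec,
    Requirement,
    ValueKind,
    detect_autocorrection,
    export_json_schema,
    load_ontology,
    validate_links,
    validate_project,
    validate_value,
)
from fairds.errors import ConfigurationError
from fairds.library import effective_attributes
from fairds.validation import format_valid
from tests.conftest import ENVO_IRI

SAMPLE_VOLUME_SPEC = AttributeSpec(
    name="sample_volume_or_weight_for_dna_extraction",
    label="Sample volume or weight for DNA extraction",
    requirement=Requirement.OPTIONAL,
    value_kind=ValueKind.RESTRICTED_TEXT,
    syntax_regex="(0|((0.)|([1-9][0-9]*.?))[0-9]*)([Ee][+-]?[0-9]+)? (g|mL|mg|ng)",
)
BOOL_SPEC = AttributeSpec(name="oxygenic", label="Oxygenic",
                          value_kind=ValueKind.BOOLEAN)
DATE_SPEC = AttributeSpec(name="collection_date", label="Collection date",
                          value_kind=ValueKind.DATE)


class TestValidateValue:
    @pytest.mark.parametrize("value,ok", [
        ("3.5 mg", True),
        ("0.5 g", True),
        ("1E+2 mL", True),
        ("3.5 kg", False),   # kg is not an allowed unit token
        ("mg", False),
        ("-1 g", False),
    ])
    def test_sample_volume_regex(self, value, ok):
        issues = validate_value(value, SAMPLE_VOLUME_SPEC)
        assert (issues == []) is ok
        if not ok:
            assert issues[0].rule == "regex_mismatch"

    @pytest.mark.parametrize("value,rules", [
        ("true", []), ("false", []),
        ("yes", ["bad_boolean"]), ("True", ["bad_boolean"]),
        ("", []),  # optional and empty: fine
    ])
    def test_boolean_accepts_exactly_true_false(self, value, rules):
        assert [i.rule for i in validate_value(value, BOOL_SPEC)] == rules

    @pytest.mark.parametrize("value,ok", [
        ("2026-03-06", True), ("2026-03-06T10:30", True),
        ("06/03/2026", False), ("2026-13-01", False), ("yesterday", False),
    ])
    def test_date_rule_is_iso8601(self, value, ok):
        issues = validate_value(value, DATE_SPEC)
        assert (issues == []) is ok

    def test_empty_mandatory_is_missing_mandatory(self):
        spec = copy.replace(BOOL_SPEC, requirement=Requirement.MANDATORY) \
            if hasattr(copy, "replace") else AttributeSpec(
                name="oxygenic", label="Oxygenic",
                value_kind=ValueKind.BOOLEAN,
                requirement=Requirement.MANDATORY)
        issues = validate_value("   ", spec)
        assert [i.rule for i in issues] == ["missing_mandatory"]

    def test_multivalued_validates_each_part(self):
        spec = AttributeSpec(name="contact_email", label="e",
                             value_kind=ValueKind.RESTRICTED_TEXT,
                             syntax_regex=r"[^@\s;]+@[^@\s;]+\.[^@\s;]+",
                             multivalued=True)
        assert validate_value("a@b.org;c@d.org", spec) == []
        assert len(validate_value("a@b.org;not-an-email", spec)) == 1

    def test_ontology_membership(self, ontologies):
        spec = AttributeSpec(name="env_medium", label="m",
                             value_kind=ValueKind.ONTOLOGY_TERM,
                             ontology_iri=ENVO_IRI)
        assert validate_value("soil", spec, ontologies) == []
        assert validate_value("SOIL  ", spec, ontologies) == []  # normalized
        issues = validate_value("lunar regolith", spec, ontologies)
        assert [i.rule for i in issues] == ["ontology_unknown"]

    def test_missing_ontology_index_is_configuration_error(self):
        spec = AttributeSpec(name="env_medium", label="m",
                             value_kind=ValueKind.ONTOLOGY_TERM,
                             ontology_iri="http://example.org/none.owl")
        with pytest.raises(ConfigurationError):
            validate_value("soil", spec, {})


class TestLoadOntology:
    def test_fixture_has_twelve_labels(self, ontologies):
        assert len(ontologies[ENVO_IRI]) == 12

    def test_rdfxml_document_and_double_label(self, tmp_path):
        doc = """<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
         xmlns:owl="http://www.w3.org/2002/07/owl#">
  <owl:Class rdf:about="http://example.org/T1">
    <rdfs:label>soil</rdfs:label>
    <rdfs:label>dirt</rdfs:label>
  </owl:Class>
</rdf:RDF>"""
        path = tmp_path / "mini.owl"
        path.write_text(doc)
        index = load_ontology(path)
        assert index.term_iri("soil") == "http://example.org/T1"
        assert index.term_iri("dirt") == "http://example.org/T1"

    def test_offline_cache_miss_is_error(self, tmp_path):
        from fairds.errors import OntologyError

        with pytest.raises(OntologyError):
            load_ontology("http://example.org/envo.owl", cache_dir=tmp_path,
                          offline=True)

    def test_cache_hit_needs_no_network(self, tmp_path, fixture_set):
        import hashlib

        iri = "http://example.org/envo.owl"
        key = hashlib.sha256(iri.encode()).hexdigest()[:24]
        (tmp_path / f"{key}.rdf").write_text(
            fixture_set.ontology.read_text(), encoding="utf-8")
        index = load_ontology(iri, cache_dir=tmp_path, offline=True)
        assert len(index) == 12


class TestAutocorrection:
    TEXT_SPEC = AttributeSpec(name="free", label="f", value_kind=ValueKind.TEXT)

    def test_date_typed_cell_under_text_spec(self):
        issue = detect_autocorrection(("2023-03-06", "d"), self.TEXT_SPEC)
        assert issue is not None and issue.rule == "autocorrect_suspect"
        assert issue.severity == "warning"

    def test_text_cell_is_fine(self):
        assert detect_autocorrection(("3-6", "s"), self.TEXT_SPEC) is None

    def test_numeric_cell_under_numeric_spec_is_fine(self):
        spec = AttributeSpec(name="ph", label="pH",
                             value_kind=ValueKind.NUMERIC)
        assert detect_autocorrection(("6.8", "n"), spec) is None

    def test_date_serial_under_date_spec(self):
        issue = detect_autocorrection(("44991", "n"), DATE_SPEC)
        assert issue is not None and issue.rule == "autocorrect_suspect"


class TestValidateLinks:
    def test_consistent_project_is_clean(self, project):
        assert validate_links(project) == []

    def test_unknown_parent_and_duplicate(self, project):
        broken = copy.deepcopy(project)
        broken.samples[0].attributes["observation_unit_identifier"] = "OU9"
        broken.samples[2].identifier = broken.samples[1].identifier
        issues = validate_links(broken)
        rules = sorted(i.rule for i in issues)
        # renaming sample 3 also dangles its assay's parent reference
        assert rules == ["duplicate_identifier", "unknown_parent",
                         "unknown_parent"]

    def test_orphans_only_in_strict_mode(self, library):
        from fairds import build_project

        project = build_project(
            [{"investigation_identifier": "I", "investigation_title": "t",
              "investigation_description": "d"}],
            [{"study_identifier": "S1", "investigation_identifier": "I"}])
        assert validate_links(project) == []
        strict = validate_links(project, strict=True)
        assert [i.rule for i in strict] == ["orphan_record"]
        assert strict[0].severity == "warning"


class TestValidateProject:
    def test_clean_fixture_is_valid(self, project, library, ontologies):
        report = validate_project(project, library, ontologies)
        assert report.is_valid
        assert report.counts == {"error": 0, "warning": 0}

    def test_two_perturbations_two_errors(self, project, library, ontologies):
        broken = copy.deepcopy(project)
        broken.samples[0].attributes["collection_date"] = ""
        broken.samples[1].attributes["oxygenic"] = "yes"
        report = validate_project(broken, library, ontologies)
        assert sorted(i.rule for i in report.errors) == \
            ["bad_boolean", "missing_mandatory"]

    def test_adding_conforming_row_never_increases_errors(
            self, project, library, ontologies):
        base = validate_project(project, library, ontologies)
        grown = copy.deepcopy(project)
        import dataclasses

        extra = copy.deepcopy(grown.samples[0])
        extra.identifier = "SA_extra"
        extra.attributes["sample_identifier"] = "SA_extra"
        grown.samples.append(extra)
        report = validate_project(grown, library, ontologies)
        assert len(report.errors) <= len(base.errors)

    def test_report_order_deterministic(self, project, library, ontologies):
        first = validate_project(project, library, ontologies)
        second = validate_project(copy.deepcopy(project), library, ontologies)
        assert first.to_dict() == second.to_dict()

    def test_headers_only_levels_yield_orphans_in_strict(self, library,
                                                         ontologies):
        from fairds import build_project

        project = build_project(
            [{"investigation_identifier": "I", "investigation_title": "t",
              "investigation_description": "d"}],
            [{"study_identifier": "S1", "investigation_identifier": "I",
              "study_title": "t", "study_description": "d"}])
        report = validate_project(project, library, ontologies, strict=True)
        assert report.is_valid
        assert any(i.rule == "orphan_record" for i in report.warnings)


class TestJsonSchemaEquivalence:
    """Internal format verdicts equal an independent JSON Schema engine's.

    Randomized records are validated by the package's own rules and by
    the jsonschema library running on the exported draft-07 schema; the
    verdicts must agree on every case.
    """

    PACKAGES = ("mixs_water", "mixs_soil", "ena_default_sample",
                "ena_short_read_assay", "mimarks_survey")

    @staticmethod
    def _random_value(rng, spec):
        choice = rng.random()
        if choice < 0.35 and spec.example_value:
            return spec.example_value
        if choice < 0.45:
            return ""
        if choice < 0.55:
            return rng.choice(["true", "false", "yes", "TRUE"])
        if choice < 0.65:
            return rng.choice(["2026-01-31", "31/01/2026", "2026-1-1"])
        if choice < 0.75:
            return str(rng.randint(0, 1000))
        if choice < 0.85:
            return f"{rng.randint(0, 99)}.{rng.randint(0, 9)} " + \
                rng.choice(["g", "mg", "kg", "m", "C"])
        return "".join(rng.choice("abcdefgh -_.") for _ in range(rng.randint(1, 12)))

    def test_verdict_equivalence_on_randomized_records(self, library):
        rng = random.Random(20260918)
        total_cells = 0
        for package_id in self.PACKAGES:
            schema = export_json_schema(library, package_id)
            validator = jsonschema.Draft7Validator(schema)
            pkg = library.package(package_id)
            specs = effective_attributes(library, package_id,
                                         pkg.optional_names)
            for _ in range(180):
                record = {s.name: self._random_value(rng, s).strip()
                          for s in specs if rng.random() > 0.1}
                internal = format_valid(library, package_id, record)
                external = validator.is_valid(record)
                assert internal == external, (package_id, record)
                total_cells += len(record)
        assert total_cells >= 10_000
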