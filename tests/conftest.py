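import pytest

from fairds import FixtureConfig, generate_fixtures, load_library, parse_workbook
from fairds.data import build_package_library_xlsx
from fairds.validation import load_ontology

ENVO_IRI = "http://purl.obolibrary.org/obo/envo.owl"


@pytest.fixture(scope="session")
def library_path(tmp_path_factory):
    dest = tmp_path_factory.mktemp("library") / "package_library.xlsx"
    return build_package_library_xlsx(dest)


@pytest.fixture(scope="session")
def library(library_path):
    return load_library(library_path)


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures")
    return generate_fixtures(FixtureConfig(seed=42), outdir)


@pytest.fixture(scope="session")
def project(fixture_set, library):
    project, notes = parse_workbook(fixture_set.workbook, library)
    assert notes == []
    return project


@pytest.fixture(scope="session")
def ontologies(fixture_set):
    return {ENVO_IRI: load_ontology(fixture_set.ontology)}
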