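"""RDF export: Turtle round trips, merging, queries, SPARQL equivalence."""

import copy
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fairds import (
    build_project,
    export_rdf,
    find_samples_where,
    merge_graphs,
    parse_turtle,
    run_sparql,
)
from fairds.errors import ConfigurationError, QueryError
from fairds.isa import Level
from fairds.rdf import (
    IRI,
    JERM_NS,
    Literal,
    MetadataGraph,
    OWL_EQUIVALENT_CLASS,
    PPEO_NS,
    RDF_TYPE,
    TYPE_BINDINGS,
)


def _tiny_project(tag="P", n_units=2, n_samples=4, oxygenic=None):
    inv = [{"investigation_identifier": f"INV{tag}",
            "investigation_title": "t", "investigation_description": "d"}]
    studies = [{"study_identifier": f"{tag}S1",
                "investigation_identifier": f"INV{tag}",
                "study_title": "st", "study_description": "sd"}]
    units = [{"observation_unit_identifier": f"{tag}OU{i+1}",
              "study_identifier": f"{tag}S1"} for i in range(n_units)]
    samples = []
    for i in range(n_samples):
        row = {"sample_identifier": f"{tag}SA{i+1}",
               "observation_unit_identifier": f"{tag}OU{i % n_units + 1}"}
        if oxygenic is not None:
            row["oxygenic"] = oxygenic[i]
        samples.append(row)
    assays = [{"assay_identifier": f"{tag}A{i+1}",
               "sample_identifier": f"{tag}SA{i+1}"} for i in range(n_samples)]
    return build_project(inv, studies, units, samples, assays,
                         sample_packages="mixs_water",
                         assay_packages="ena_short_read_assay")


class TestExport:
    def test_one_typed_node_per_record(self, project, library):
        graph = export_rdf(project, library)
        for level in Level.ordered():
            nodes = graph.subjects_of_type(TYPE_BINDINGS[level])
            assert len(nodes) == len(project.records(level))

    def test_equivalence_links_present(self, project, library):
        graph = export_rdf(project, library)
        ou_class = IRI(PPEO_NS + "observation_unit")
        sample_class = IRI(JERM_NS + "Sample")
        equivalents = {s: o for s, p, o in graph.triples(p=OWL_EQUIVALENT_CLASS)}
        assert str(equivalents[ou_class]).endswith("source_material")
        assert str(equivalents[sample_class]).endswith("sample_material")

    def test_user_column_becomes_local_predicate(self, project, library):
        augmented = copy.deepcopy(project)
        sample = augmented.samples[0]
        sample.attributes["Electron acceptor condition"] = "nitrate"
        from fairds.isa import CellInfo

        sample.cell_info["Electron acceptor condition"] = CellInfo(
            user_defined=True)
        graph = export_rdf(augmented, library)
        hits = [(s, p, o) for s, p, o in graph
                if isinstance(o, Literal) and o.value == "nitrate"]
        assert len(hits) == 1
        assert str(hits[0][1]).endswith("/ns/electron_acceptor_condition")

    def test_every_value_reachable_as_one_literal(self, project, library):
        graph = export_rdf(project, library)
        sample = project.samples[0]
        from fairds.rdf import DEFAULT_BASE_IRI, entity_iri

        node = entity_iri(DEFAULT_BASE_IRI, Level.SAMPLE, sample.identifier)
        literals = [o.value for _, _, o in graph.triples(s=node)
                    if isinstance(o, Literal)]
        value = sample.attributes["env_medium"]
        assert literals.count(value) == 1

    def test_investigation_only_project_round_trips(self, library):
        project = build_project([
            {"investigation_identifier": "I1", "investigation_title": "t",
             "investigation_description": "d"}])
        graph = export_rdf(project, library)
        typed = [s for s, p, o in graph.triples(p=RDF_TYPE)
                 if o in TYPE_BINDINGS.values()]
        assert len(typed) == 1
        assert parse_turtle(graph.serialize()) == graph

    def test_determinism(self, project, library):
        a = export_rdf(project, library).serialize()
        b = export_rdf(copy.deepcopy(project), library).serialize()
        assert a == b

    def test_bad_base_iri(self, project, library):
        with pytest.raises(ConfigurationError):
            export_rdf(project, library, base_iri="not an iri")


class TestSerializationRoundTrip:
    def test_fixture_graph(self, project, library):
        graph = export_rdf(project, library)
        assert parse_turtle(graph.serialize()) == graph

    @pytest.mark.parametrize("value", [
        'quotes "inside"', "back\\slash", "tab\there", "new\nline",
        "unicode: éß世", "trailing space ",
    ])
    def test_literal_escaping(self, value):
        graph = MetadataGraph()
        graph.add(IRI("http://x.org/s"), IRI("http://x.org/p"), Literal(value))
        back = parse_turtle(graph.serialize())
        assert back == graph

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet=st.characters(blacklist_categories=("Cs",)),
                   min_size=0, max_size=40))
    def test_literal_round_trip_property(self, value):
        """Any unicode literal survives serialize -> parse unchanged."""
        graph = MetadataGraph()
        graph.add(IRI("http://x.org/s"), IRI("http://x.org/p"), Literal(value))
        assert parse_turtle(graph.serialize()) == graph


class TestMerge:
    def test_disjoint_union_counts_add(self, library):
        g1 = export_rdf(_tiny_project("A"), library)
        g2 = export_rdf(_tiny_project("B"), library)
        shared = {t for t in g1} & {t for t in g2}  # vocabulary triples
        merged = merge_graphs([g1, g2])
        assert len(merged) == len(g1) + len(g2) - len(shared)

    def test_idempotent_commutative_associative(self, library):
        g1 = export_rdf(_tiny_project("A"), library)
        g2 = export_rdf(_tiny_project("B"), library)
        g3 = export_rdf(_tiny_project("C"), library)
        assert merge_graphs([g1, g1]) == g1
        assert merge_graphs([g1, g2]) == merge_graphs([g2, g1])
        assert merge_graphs([merge_graphs([g1, g2]), g3]) == \
            merge_graphs([g1, merge_graphs([g2, g3])])

    def test_cross_project_query_spans_both(self, library):
        g1 = export_rdf(_tiny_project("A", oxygenic=["true"] * 4), library)
        g2 = export_rdf(_tiny_project("B", oxygenic=["true"] * 4), library)
        merged = merge_graphs([g1, g2])
        hits = find_samples_where(merged, "oxygenic", "true")
        assert hits == sorted(find_samples_where(g1, "oxygenic", "true")
                              + find_samples_where(g2, "oxygenic", "true"))


class TestFindSamplesWhere:
    def test_known_attribute(self, library):
        project = _tiny_project(oxygenic=["true", "false", "true", "false"])
        graph = export_rdf(project, library)
        assert find_samples_where(graph, "oxygenic", "true") == ["PSA1", "PSA3"]

    def test_no_match_is_empty(self, library):
        graph = export_rdf(_tiny_project(), library)
        assert find_samples_where(graph, "oxygenic", "true") == []


class TestSparql:
    def test_count_samples(self, project, library):
        graph = export_rdf(project, library)
        result = run_sparql(graph, """
            PREFIX jerm: <http://jermontology.org/ontology/JERMOntology#>
            SELECT (COUNT(?s) AS ?n) WHERE { ?s a jerm:Sample }
        """)
        assert result.rows[0]["n"].value == str(len(project.samples))

    def test_ask_known_triple(self, project, library):
        graph = export_rdf(project, library)
        result = run_sparql(graph, """
            PREFIX ppeo: <http://purl.org/ppeo/PPEO.owl#>
            PREFIX owl: <http://www.w3.org/2002/07/owl#>
            ASK { ppeo:observation_unit owl:equivalentClass ?c }
        """)
        assert result.boolean is True

    def test_malformed_query(self, project, library):
        graph = export_rdf(project, library)
        with pytest.raises(QueryError):
            run_sparql(graph, "CONSTRUCT { ?s ?p ?o } WHERE { ?s ?p ?o }")

    def test_find_samples_where_equals_sparql_on_random_fixtures(self, library):
        """Dual-route check: direct triple scan vs the query engine."""
        rng = random.Random(1234)
        query = """
            PREFIX jerm: <http://jermontology.org/ontology/JERMOntology#>
            PREFIX mixs: <https://w3id.org/mixs/>
            PREFIX schema: <http://schema.org/>
            SELECT ?id WHERE {
                ?s a jerm:Sample .
                ?s mixs:oxygenic "%s"^^<http://www.w3.org/2001/XMLSchema#boolean> .
                ?s schema:identifier ?id .
            }
        """
        for trial in range(100):
            n = rng.randint(1, 6)
            flags = [rng.choice(["true", "false"]) for _ in range(n)]
            project = _tiny_project(tag=f"T{trial}", n_units=1, n_samples=n,
                                    oxygenic=flags)
            graph = export_rdf(project, library)
            wanted = rng.choice(["true", "false"])
            direct = find_samples_where(graph, "oxygenic", wanted)
            via_sparql = sorted(row["id"].value
                                for row in run_sparql(graph, query % wanted).rows)
            brute = sorted(s.identifier for s in project.samples
                           if s.attributes.get("oxygenic") == wanted)
            assert direct == via_sparql == brute
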