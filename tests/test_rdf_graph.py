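import re

import numpy as np
import pytest

from rolhs.errors import (
    ArgumentFailure,
    LookupFailure,
    MalformedFileError,
    MappingFailure,
)
from rolhs.rdf_graph import (
    RDF_TYPE,
    ClassMap,
    Literal,
    MappingSpec,
    PropertyBridge,
    Triple,
    TripleStore,
    compile_mapping,
    export_graph,
    parse_sparql,
    parse_turtle,
    parse_turtle_text,
    patient_subgraph,
    query,
    serialize_turtle,
)
from rolhs.resources import default_mapping_spec, fixture_ontology
from rolhs.synthetic_cohort import CohortTables

from conftest import make_ontology, random_store

EX = "http://example.org/"
NCIT = "http://purl.obolibrary.org/obo/NCIT_"
ROO = "http://www.cancerdata.org/roo/"


# ---------------------------------------------------------------------------
# hand-enumerable three-patient fixture

def three_patient_tables():
    return CohortTables(tables={
        "demographics": [
            {"Patient ID Number": "P1", "Sex": "Male"},
            {"Patient ID Number": "P2", "Sex": "Female"},
            {"Patient ID Number": "P3", "Sex": "Male"},
        ],
        "staging": [
            {"Patient ID Number": "P1", "T Stage": "T1"},
            {"Patient ID Number": "P2", "T Stage": "T1a"},
            {"Patient ID Number": "P3", "T Stage": "T2"},
        ],
    })


def three_patient_spec():
    return MappingSpec(
        base="http://rolhs.example.org",
        class_maps=[
            ClassMap("patient", "demographics", "Patient ID Number",
                     uri_template="patient/{Patient ID Number}",
                     type_code="NCIT:C16960"),
            ClassMap("sex_class", "demographics", "Patient ID Number",
                     value_lookup={"column": "Sex",
                                   "map": {"Male": "NCIT:C20197",
                                           "Female": "NCIT:C16576"}}),
            ClassMap("t_stage", "staging", "Patient ID Number",
                     value_lookup={"column": "T Stage",
                                   "map": {"T1": "NCIT:C48720",
                                           "T1a": "NCIT:C48721",
                                           "T2": "NCIT:C48724"}}),
        ],
        property_bridges=[
            PropertyBridge("patient", "roo:hasSex", {"ref": "sex_class"}),
            PropertyBridge("patient", "roo:hasTStage", {"ref": "t_stage"}),
        ],
    )


def pat(pid):
    return f"http://rolhs.example.org/patient/{pid}"


class TestCompileMapping:
    def test_t1_row_produces_t_stage_triple(self, ont):
        store = compile_mapping(three_patient_spec(), three_patient_tables(), ont)
        assert Triple(pat("P1"), ROO + "hasTStage", NCIT + "C48720") in store

    def test_empty_tables_empty_store(self, ont):
        tables = CohortTables(tables={"demographics": [], "staging": []})
        store = compile_mapping(three_patient_spec(), tables, ont)
        assert len(store) == 0

    def test_exact_triple_set_hand_enumerated(self, ont):
        store = compile_mapping(three_patient_spec(), three_patient_tables(), ont)
        expected = set()
        sexes = {"P1": "C20197", "P2": "C16576", "P3": "C20197"}
        stages = {"P1": "C48720", "P2": "C48721", "P3": "C48724"}
        for pid in ("P1", "P2", "P3"):
            expected.add(Triple(pat(pid), RDF_TYPE, NCIT + "C16960"))
            expected.add(Triple(pat(pid), ROO + "hasSex", NCIT + sexes[pid]))
            expected.add(Triple(pat(pid), ROO + "hasTStage", NCIT + stages[pid]))
        assert store.triples() == expected
        assert len(store) == 9  # 3 patients x (1 type + 2 attribute links)

    def test_blank_cell_produces_no_triple(self, ont):
        tables = three_patient_tables()
        tables["staging"][0]["T Stage"] = ""
        store = compile_mapping(three_patient_spec(), tables, ont)
        assert not store.match(pat("P1"), ROO + "hasTStage", None)

    def test_unknown_lookup_value_skipped_and_logged(self, ont):
        tables = three_patient_tables()
        tables["staging"][0]["T Stage"] = "T9"
        store = compile_mapping(three_patient_spec(), tables, ont)
        assert not store.match(pat("P1"), ROO + "hasTStage", None)
        assert ("staging", "T Stage", "T9") in store.mapping_log.skipped

    def test_unresolvable_code_in_lookup_is_mapping_failure(self, ont):
        spec = three_patient_spec()
        spec.class_maps[2].value_lookup["map"]["T1"] = "NCIT:C00000"
        with pytest.raises(MappingFailure) as err:
            compile_mapping(spec, three_patient_tables(), ont)
        assert "T Stage" in str(err.value) and "T1" in str(err.value)

    def test_store_size_equals_cell_count_oracle(self, ont, cohort):
        store = compile_mapping(default_mapping_spec(), cohort, ont)
        log = store.mapping_log
        # every mapped element is one triple; plus template-map type triples
        n_template_types = (
            len(cohort["demographics"]) + len(cohort["treatment_course"]))
        # bridges referencing class maps add one triple per joined pair
        assert len(store) >= log.n_mapped_elements
        assert log.n_mapped_elements == log.n_source_elements
        assert len(store.by_predicate[RDF_TYPE]) >= n_template_types

    def test_every_uri_resolves_through_prefixes_or_base(self, store):
        bases = tuple(store.prefixes.values()) + ("http://rolhs.example.org/",)
        for t in store:
            assert t.subject.startswith(bases)
            assert t.predicate.startswith(bases)
            if isinstance(t.object, str):
                assert t.object.startswith(bases)

    def test_duplicate_triples_deduplicated(self):
        store = TripleStore()
        t = Triple(EX + "s", EX + "p", Literal("x"))
        store.add(t)
        store.add(t)
        assert len(store) == 1


class TestLiteralsAndTriples:
    def test_bad_integer_literal(self):
        with pytest.raises(ArgumentFailure):
            Literal("twelve", "integer")

    def test_bad_date_literal(self):
        with pytest.raises(ArgumentFailure):
            Literal("20200101", "date")

    def test_unknown_datatype(self):
        with pytest.raises(ArgumentFailure):
            Literal("x", "boolean")

    def test_relative_uri_rejected(self):
        with pytest.raises(ArgumentFailure):
            Triple("not-a-uri", EX + "p", EX + "o")


class TestTurtle:
    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_identity(self, seed):
        store = random_store(np.random.default_rng(seed))
        text = serialize_turtle(store)
        assert parse_turtle_text(text).triples() == store.triples()

    def test_empty_store_serializes_prefixes_only(self):
        text = serialize_turtle(TripleStore(prefixes={"ex": EX}))
        lines = [ln for ln in text.splitlines() if ln.strip()]
        assert all(ln.startswith("@prefix") for ln in lines)

    def test_statement_count_independent_line_oracle(self, store, tmp_path):
        path = tmp_path / "g.ttl"
        serialize_turtle(store, path)
        # one triple per non-prefix statement line; independent textual count
        lines = path.read_text().splitlines()
        statements = [ln for ln in lines
                      if ln.endswith(" .") and not ln.startswith("@prefix")]
        assert len(statements) == len(store)

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.ttl"
        path.write_text("@prefix ex: <http://example.org/> .\nex:a ex:b .\n")
        with pytest.raises(MalformedFileError) as err:
            parse_turtle(path)
        assert err.value.line == 2

    def test_undeclared_prefix_fails(self):
        with pytest.raises(MalformedFileError):
            parse_turtle_text("foo:a foo:b foo:c .")

    def test_serialization_is_deterministic(self, store):
        assert serialize_turtle(store) == serialize_turtle(store)

    def test_escaped_quotes_round_trip(self):
        store = TripleStore(prefixes={"ex": EX})
        store.add(Triple(EX + "s", EX + "p", Literal('say "hi" \\ there')))
        assert parse_turtle_text(serialize_turtle(store)).triples() == store.triples()

    def test_file_round_trip(self, store, tmp_path):
        path = tmp_path / "cohort.ttl"
        serialize_turtle(store, path)
        assert parse_turtle(path).triples() == store.triples()


class TestQuery:
    def test_constant_pattern_ask_semantics(self, ont):
        st = compile_mapping(three_patient_spec(), three_patient_tables(), ont)
        hit = query(st, [(pat("P1"), ROO + "hasTStage", NCIT + "C48720")])
        miss = query(st, [(pat("P1"), ROO + "hasTStage", NCIT + "C48724")])
        assert hit == [{}]
        assert miss == []

    def test_t1_filter_matches_relational_oracle(self, ont):
        tables = three_patient_tables()
        st = compile_mapping(three_patient_spec(), tables, ont)
        bindings = query(st, [("?p", ROO + "hasTStage", NCIT + "C48720")])
        expected = {pat(r["Patient ID Number"])
                    for r in tables["staging"] if r["T Stage"] == "T1"}
        assert {b["?p"] for b in bindings} == expected

    def test_join_equals_intersection_of_single_patterns(self, store):
        p1 = ("?p", ROO + "hasSex", NCIT + "C20197")
        p2 = ("?p", ROO + "hasSmokingStatus", NCIT + "C67147")
        joined = {b["?p"] for b in query(store, [p1, p2])}
        only1 = {b["?p"] for b in query(store, [p1])}
        only2 = {b["?p"] for b in query(store, [p2])}
        assert joined == only1 & only2

    def test_bruteforce_bgp_oracle(self):
        rng = np.random.default_rng(3)
        st = random_store(rng, 40)
        triples = sorted(st.triples(), key=lambda t: (t.subject, t.predicate))
        patterns = [("?s", triples[0].predicate, "?o"),
                    ("?s", triples[1].predicate, "?o2")]
        got = query(st, patterns)
        brute = set()
        for t1 in st.triples():
            for t2 in st.triples():
                if (t1.predicate == triples[0].predicate
                        and t2.predicate == triples[1].predicate
                        and t1.subject == t2.subject):
                    brute.add((t1.subject, t1.object, t2.object))
        assert {(b["?s"], b["?o"], b["?o2"]) for b in got} == brute

    def test_duplicate_bindings_eliminated(self):
        st = TripleStore()
        st.add(Triple(EX + "s", EX + "p1", EX + "a"))
        st.add(Triple(EX + "s", EX + "p2", EX + "b"))
        bindings = query(st, [("?s", "?p", "?o")], project=["?s"])
        assert bindings == [{"?s": EX + "s"}]

    def test_unknown_projection_rejected(self, store):
        with pytest.raises(ArgumentFailure):
            query(store, [("?s", "?p", "?o")], project=["?zzz"])

    def test_sparql_text_form(self, ont):
        st = compile_mapping(three_patient_spec(), three_patient_tables(), ont)
        q = """PREFIX roo: <http://www.cancerdata.org/roo/>
               PREFIX NCIT: <http://purl.obolibrary.org/obo/NCIT_>
               SELECT ?p WHERE { ?p roo:hasTStage NCIT:C48720 }"""
        patterns, project = parse_sparql(q)
        assert project == ["?p"]
        assert {b["?p"] for b in query(st, patterns, project)} == {pat("P1")}


class TestSubgraphAndExport:
    @pytest.fixture
    def chain_store(self):
        st = TripleStore(prefixes={"ex": EX})
        st.add(Triple(EX + "a", EX + "p", EX + "b"))
        st.add(Triple(EX + "b", EX + "p", EX + "c"))
        st.add(Triple(EX + "c", EX + "p", EX + "d"))
        return st

    def test_depth_zero_empty(self, chain_store):
        assert len(patient_subgraph(chain_store, EX + "a", 0)) == 0

    def test_depth_one_is_outgoing_triples(self, chain_store):
        sub = patient_subgraph(chain_store, EX + "a", 1)
        assert sub.triples() == {Triple(EX + "a", EX + "p", EX + "b")}

    def test_depth_two_first_two_hops(self, chain_store):
        sub = patient_subgraph(chain_store, EX + "a", 2)
        assert sub.triples() == {
            Triple(EX + "a", EX + "p", EX + "b"),
            Triple(EX + "b", EX + "p", EX + "c"),
        }

    def test_unknown_patient_fails(self, chain_store):
        with pytest.raises(LookupFailure):
            patient_subgraph(chain_store, EX + "zzz", 1)

    def test_empty_store_exports_empty_graph(self, tmp_path):
        path = export_graph(TripleStore(), tmp_path / "g.dot", "dot")
        body = path.read_text()
        assert "->" not in body

    def test_dot_counts_match_store(self, store, tmp_path, ont):
        first = sorted(s for s in store.subjects() if "/patient/" in s)[0]
        sub = patient_subgraph(store, first, 3)
        path = export_graph(sub, tmp_path / "p.dot", "dot", ont)
        body = path.read_text()
        assert body.count("->") == len(sub)
        n_nodes = len(re.findall(r'^\s+n\d+ \[', body, flags=re.M))
        assert n_nodes == len(sub.terms())

    def test_graphml_counts_match_store(self, store, tmp_path, ont):
        first = sorted(s for s in store.subjects() if "/patient/" in s)[0]
        sub = patient_subgraph(store, first, 2)
        path = export_graph(sub, tmp_path / "p.graphml", "graphml", ont)
        body = path.read_text()
        assert body.count("<edge ") == len(sub)
        assert body.count("<node ") == len(sub.terms())

    def test_prostate_patient_graph_has_diagnosis_edges(self, ont, cohort, store):
        prostate = [r["Patient ID Number"] for r in cohort["diagnosis"]
                    if r["Diagnosis Group"] == "Prostate Cancer"]
        uri = f"http://rolhs.example.org/patient/{prostate[0]}"
        sub = patient_subgraph(store, uri, 3)
        dx = f"http://rolhs.example.org/diagnosis/{prostate[0]}"
        assert sub.match(dx, ROO + "hasTStage", None)
        assert sub.match(dx, ROO + "hasToxicity", None)

    def test_unknown_format_rejected(self, store, tmp_path):
        with pytest.raises(ArgumentFailure):
            export_graph(store, tmp_path / "x", "svg")


def test_graphml_parses_with_networkx(store, tmp_path, ont):
    networkx = pytest.importorskip("networkx")
    first = sorted(s for s in store.subjects() if "/patient/" in s)[0]
    sub = patient_subgraph(store, first, 2)
    path = export_graph(sub, tmp_path / "p.graphml", "graphml", ont)
    g = networkx.read_graphml(path)
    assert g.number_of_edges() == len(sub)


def test_numeric_post_filter_on_bindings(store):
    from rolhs.rdf_graph import filter_bindings
    bindings = query(store, [("?c", ROO + "hasPrescriptionDose", "?dose")])
    assert bindings
    high = filter_bindings(bindings, "?dose", lower=7000)
    assert high
    assert all(float(b["?dose"].value) >= 7000 for b in high)
    assert len(high) < len(bindings)
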