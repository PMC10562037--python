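import numpy as np
import pytest

from rolhs.ontology import Ontology, OntologyClass, ontology_from_dict
from rolhs.rdf_graph import Literal, Triple, TripleStore, compile_mapping
from rolhs.resources import default_mapping_spec, fixture_ontology
from rolhs.synthetic_cohort import generate_cohort

PFX = {"NCIT": "http://purl.obolibrary.org/obo/NCIT_",
       "EX": "http://example.org/ex_"}


def make_ontology(classes, prefixes=PFX):
    """classes: list of (code, label, parents[, synonyms]) tuples."""
    return ontology_from_dict({
        "prefixes": prefixes,
        "classes": [
            {"code": c[0], "label": c[1], "parents": list(c[2]),
             "synonyms": list(c[3]) if len(c) > 3 else []}
            for c in classes
        ],
    })


@pytest.fixture(scope="session")
def ont():
    return fixture_ontology()


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(60, seed=42)


@pytest.fixture(scope="session")
def store(ont, cohort):
    return compile_mapping(default_mapping_spec(), cohort, ont)


@pytest.fixture
def chain_ontology():
    # A -> B -> C (A is the root; arrows point parent -> child)
    return make_ontology([
        ("EX:A", "Alpha", []),
        ("EX:B", "Beta", ["EX:A"]),
        ("EX:C", "Gamma", ["EX:B"]),
    ])


@pytest.fixture
def diamond_ontology():
    # D has parents B and C, both under A
    return make_ontology([
        ("EX:A", "Top", []),
        ("EX:B", "LeftMid", ["EX:A"]),
        ("EX:C", "RightMid", ["EX:A"]),
        ("EX:D", "Bottom", ["EX:B", "EX:C"]),
    ])


def random_dag_ontology(rng: np.random.Generator, n_classes: int) -> Ontology:
    """Random DAG: parents drawn only from earlier codes (acyclic by order)."""
    classes = []
    for i in range(n_classes):
        n_parents = int(rng.integers(0, min(i, 3) + 1))
        parents = sorted(
            f"EX:N{j}" for j in rng.choice(i, size=n_parents, replace=False)
        ) if i else []
        classes.append((f"EX:N{i}", f"node {i}", parents))
    return make_ontology(classes)


def random_store(rng: np.random.Generator, n_triples: int = 30) -> TripleStore:
    subjects = [f"http://example.org/s{i}" for i in range(6)]
    predicates = [f"http://example.org/p{i}" for i in range(4)]
    objects = (
        subjects
        + [Literal(str(i), "integer") for i in range(5)]
        + [Literal(f"text {i}") for i in range(3)]
        + [Literal("2021-05-01", "date"), Literal("3.25", "decimal")]
    )
    store = TripleStore(prefixes={"ex": "http://example.org/"})
    for _ in range(n_triples):
        store.add(Triple(
            subjects[rng.integers(len(subjects))],
            predicates[rng.integers(len(predicates))],
            objects[rng.integers(len(objects))],
        ))
    return store
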