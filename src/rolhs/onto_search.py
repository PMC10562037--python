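"""Ontology-expanded keyword search over the compiled knowledge graph.

A q-term is resolved to ontology classes by exact label match (and synonym
match when enabled), the expansion is widened with up to ``child_levels``
levels of descendants and, optionally, ``parent_levels`` of ancestors, and
patients whose subgraph references any expanded class are returned with
provenance.  Multiple q-terms combine conjunctively by default (cohort
definition style); ``any_term=True`` switches to union.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from rolhs.errors import ArgumentFailure
from rolhs.ontology import Ontology, find_classes, leveled_expansion
from rolhs.rdf_graph import RDF_TYPE, Literal, TripleStore, patient_subgraph

__all__ = ["SearchOptions", "ExpandedClass", "PatientHit", "SearchResult",
           "expand_terms", "search"]

MAX_LEVELS = 10
_PROVENANCE_RANK = {"exact": 0, "synonym": 1, "child": 2, "parent": 3}


@dataclass(frozen=True)
class SearchOptions:
    include_synonyms: bool = True
    child_levels: int = 0
    include_parents: bool = False
    parent_levels: int = 1
    any_term: bool = False          # OR across q-terms instead of AND
    subgraph_depth: int = 3         # forward hops scanned per patient

    def __post_init__(self):
        for levels in (self.child_levels, self.parent_levels):
            if not 0 <= levels <= MAX_LEVELS:
                raise ArgumentFailure(f"levels must be in [0, {MAX_LEVELS}]")


@dataclass(frozen=True)
class ExpandedClass:
    code: str
    label: str
    provenance: str     # exact | synonym | child | parent
    hop: int            # 0 for seed matches


@dataclass(frozen=True)
class PatientHit:
    patient_uri: str
    matched_code: str
    attributes: tuple[tuple[str, str], ...]  # (predicate CURIE, literal value)


@dataclass
class SearchResult:
    expanded_classes: list[ExpandedClass]
    patient_hits: list[PatientHit]

    def patient_uris(self) -> list[str]:
        seen = []
        for hit in self.patient_hits:
            if hit.patient_uri not in seen:
                seen.append(hit.patient_uri)
        return seen

    def to_json(self, path: str | Path) -> Path:
        doc = {
            "expanded_classes": [c.__dict__ for c in self.expanded_classes],
            "patient_hits": [
                {"patient_uri": h.patient_uri, "matched_code": h.matched_code,
                 "attributes": [list(a) for a in h.attributes]}
                for h in self.patient_hits
            ],
        }
        path = Path(path)
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
        return path


def _expand_one(ont: Ontology, q_term: str, opts: SearchOptions) -> list[ExpandedClass]:
    best: dict[str, ExpandedClass] = {}

    def offer(code: str, label: str, provenance: str, hop: int) -> None:
        incumbent = best.get(code)
        candidate = ExpandedClass(code, label, provenance, hop)
        if incumbent is None or (hop, _PROVENANCE_RANK[provenance]) < (
                incumbent.hop, _PROVENANCE_RANK[incumbent.provenance]):
            best[code] = candidate

    seeds = find_classes(ont, q_term, include_synonyms=opts.include_synonyms)
    for cls, provenance in seeds.items():
        offer(cls.code, cls.label, provenance, 0)
        for code, hop in leveled_expansion(ont, cls.code, opts.child_levels,
                                           "children").items():
            offer(code, ont.get(code).label, "child", hop)
        if opts.include_parents:
            for code, hop in leveled_expansion(ont, cls.code, opts.parent_levels,
                                               "parents").items():
                offer(code, ont.get(code).label, "parent", hop)
    return sorted(best.values(), key=lambda c: (c.hop, _PROVENANCE_RANK[c.provenance],
                                                c.code))


def expand_terms(
    ont: Ontology, q_terms: list[str], opts: SearchOptions = SearchOptions()
) -> list[ExpandedClass]:
    """Union over q-terms of seed matches plus leveled child/parent expansion,
    deduplicated keeping the smallest hop distance."""
    if not q_terms:
        raise ArgumentFailure("at least one q-term is required")
    best: dict[str, ExpandedClass] = {}
    for q_term in q_terms:
        for cand in _expand_one(ont, q_term, opts):
            incumbent = best.get(cand.code)
            if incumbent is None or (cand.hop, _PROVENANCE_RANK[cand.provenance]) < (
                    incumbent.hop, _PROVENANCE_RANK[incumbent.provenance]):
                best[cand.code] = cand
    return sorted(best.values(), key=lambda c: (c.hop, _PROVENANCE_RANK[c.provenance],
                                                c.code))


def _patient_uris(store: TripleStore) -> list[str]:
    """Subjects typed as patient-like roots: any subject never appearing as an
    object of a non-type triple — falls back to URI shape when ambiguous."""
    patients = sorted(
        s for s in store.subjects() if "/patient/" in s
    )
    return patients


def _matches_in_subgraph(
    sub: TripleStore, class_uris: dict[str, str], store: TripleStore
) -> dict[str, list[tuple[str, str]]]:
    """matched class code -> clinical attributes (outgoing literals of the
    matched attribute node, or of the triple's subject for direct class links)."""
    hits: dict[str, list[tuple[str, str]]] = {}
    for t in sub:
        obj = t.object
        if not isinstance(obj, str):
            continue
        code = class_uris.get(obj)
        if code is None:
            continue
        # attributes: literal triples of the node that carries the class
        node = t.subject if t.predicate == RDF_TYPE else obj
        attrs = [
            (store.curie(lit.predicate), lit.object.value)
            for lit in sorted(store.by_subject.get(node, set()),
                              key=lambda x: (x.predicate, str(x.object)))
            if isinstance(lit.object, Literal)
        ]
        hits.setdefault(code, []).extend(a for a in attrs if a not in hits.get(code, []))
        hits.setdefault(code, [])
    return hits


def search(
    store: TripleStore,
    ont: Ontology,
    q_terms: list[str],
    opts: SearchOptions = SearchOptions(),
) -> SearchResult:
    """Expand q-terms and return matching patients with provenance.

    A patient matches a term iff some triple in its forward subgraph points
    at an expanded class URI (object position or type triple of an attribute
    node).  Terms combine conjunctively unless ``opts.any_term``.
    """
    per_term_expansions = [
        _expand_one(ont, q_term, opts) for q_term in q_terms
    ]
    expanded = expand_terms(ont, q_terms, opts) if q_terms else []
    patients = _patient_uris(store)

    hits: list[PatientHit] = []
    for patient in patients:
        sub = patient_subgraph(store, patient, opts.subgraph_depth)
        term_hits = []
        for expansion in per_term_expansions:
            class_uris = {ont.uri_of(c.code): c.code for c in expansion}
            term_hits.append(_matches_in_subgraph(sub, class_uris, store))
        matched = (
            any(term_hits) if opts.any_term else all(term_hits)
        ) if term_hits else False
        if not matched:
            continue
        merged: dict[str, list[tuple[str, str]]] = {}
        for th in term_hits:
            for code, attrs in th.items():
                bucket = merged.setdefault(code, [])
                bucket.extend(a for a in attrs if a not in bucket)
        for code in sorted(merged):
            hits.append(PatientHit(patient, code, tuple(merged[code])))
    return SearchResult(expanded_classes=expanded, patient_hits=hits)
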