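"""Relational-to-RDF mapping, an in-memory triple store, Turtle I/O, basic
graph pattern queries and DOT/GraphML export.

The mapping-spec dialect is a JSON mirror of the D2RQ ClassMap /
PropertyBridge / refersToClassMap triad:

* a *class map* turns table rows into subject nodes — either instance nodes
  built from a URI template (optionally typed via ``type_code`` or a
  ``type_lookup`` column), or ontology class nodes selected by a
  ``value_lookup`` column (the node *is* the coded concept);
* a *property bridge* attaches, for each row of the subject map, either a
  reference to another class map's node (joined on row for same-table maps,
  on the key column otherwise) or a typed literal taken from a column.

Blank cells never produce triples; data values missing from a lookup map are
skipped and logged, never invented.  Dates arrive as YYYYMMDD and are stored
as ISO-8601 ``xsd:date`` literals.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union
from xml.sax.saxutils import escape as _xml_escape

from rolhs.errors import (
    ArgumentFailure,
    LookupFailure,
    MalformedFileError,
    MappingFailure,
)
from rolhs.ontology import Ontology
from rolhs.synthetic_cohort import CohortTables

__all__ = [
    "RDF_TYPE",
    "XSD",
    "Literal",
    "Triple",
    "TripleStore",
    "MappingSpec",
    "MappingLog",
    "compile_mapping",
    "serialize_turtle",
    "parse_turtle",
    "parse_turtle_text",
    "query",
    "parse_sparql",
    "patient_subgraph",
    "export_graph",
]

RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
XSD = "http://www.w3.org/2001/XMLSchema#"

_DATATYPES = {"string", "integer", "decimal", "date"}
_XSD_OF = {
    "string": XSD + "string",
    "integer": XSD + "integer",
    "decimal": XSD + "decimal",
    "date": XSD + "date",
}
_TYPE_OF_XSD = {v: k for k, v in _XSD_OF.items()}


@dataclass(frozen=True, order=True)
class Literal:
    """A typed RDF literal."""

    value: str
    datatype: str = "string"

    def __post_init__(self):
        if self.datatype not in _DATATYPES:
            raise ArgumentFailure(f"unknown literal datatype {self.datatype!r}")
        if self.datatype == "integer" and not re.match(r"^[+-]?\d+$", self.value):
            raise ArgumentFailure(f"{self.value!r} is not an integer literal")
        if self.datatype == "decimal":
            try:
                float(self.value)
            except ValueError:
                raise ArgumentFailure(f"{self.value!r} is not a decimal literal") from None
        if self.datatype == "date" and not re.match(r"^\d{4}-\d{2}-\d{2}$", self.value):
            raise ArgumentFailure(f"{self.value!r} is not an ISO date literal")


Term = Union[str, Literal]  # subjects/predicates are URI strings


@dataclass(frozen=True)
class Triple:
    subject: str
    predicate: str
    object: Term

    def __post_init__(self):
        for uri in (self.subject, self.predicate):
            if not isinstance(uri, str) or "://" not in uri:
                raise ArgumentFailure(f"not an absolute URI: {uri!r}")
        if isinstance(self.object, str) and "://" not in self.object:
            raise ArgumentFailure(f"object URI not absolute: {self.object!r}")


def _term_key(term: Term) -> tuple:
    if isinstance(term, Literal):
        return (1, term.datatype, term.value)
    return (0, term)


def _triple_key(t: Triple) -> tuple:
    return (t.subject, t.predicate, _term_key(t.object))


class TripleStore:
    """Set of triples with subject-, predicate- and object-major indexes."""

    def __init__(self, triples: Iterable[Triple] = (), prefixes: dict[str, str] | None = None):
        self._triples: set[Triple] = set()
        self.by_subject: dict[str, set[Triple]] = {}
        self.by_predicate: dict[str, set[Triple]] = {}
        self.by_object: dict[Term, set[Triple]] = {}
        self.prefixes: dict[str, str] = dict(prefixes or {})
        self.prefixes.setdefault("rdf", "http://www.w3.org/1999/02/22-rdf-syntax-ns#")
        self.prefixes.setdefault("xsd", XSD)
        for t in triples:
            self.add(t)

    def add(self, triple: Triple) -> None:
        if triple in self._triples:
            return  # RDF set semantics: silently deduplicate
        self._triples.add(triple)
        self.by_subject.setdefault(triple.subject, set()).add(triple)
        self.by_predicate.setdefault(triple.predicate, set()).add(triple)
        self.by_object.setdefault(triple.object, set()).add(triple)

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triples

    def __iter__(self) -> Iterator[Triple]:
        return iter(sorted(self._triples, key=_triple_key))

    def triples(self) -> set[Triple]:
        return set(self._triples)

    def subjects(self) -> set[str]:
        return set(self.by_subject)

    def terms(self) -> set[Term]:
        out: set[Term] = set()
        for t in self._triples:
            out.add(t.subject)
            out.add(t.object)
        return out

    def match(self, s: str | None = None, p: str | None = None,
              o: Term | None = None) -> set[Triple]:
        """All triples matching the given constants (None = wildcard)."""
        candidates: set[Triple] | None = None
        for constant, index in ((s, self.by_subject), (p, self.by_predicate),
                                (o, self.by_object)):
            if constant is None:
                continue
            bucket = index.get(constant, set())
            candidates = bucket if candidates is None else candidates & bucket
        return set(self._triples) if candidates is None else set(candidates)

    def curie(self, uri: str) -> str:
        """Compact a URI through the prefix table when possible."""
        best: tuple[str, str] | None = None
        for prefix, base in self.prefixes.items():
            if uri.startswith(base) and (best is None or len(base) > len(best[1])):
                best = (prefix, base)
        if best is None:
            return uri
        return f"{best[0]}:{uri[len(best[1]):]}"


# ---------------------------------------------------------------------------
# mapping spec

@dataclass
class ClassMap:
    name: str
    table: str
    key: str
    uri_template: str | None = None
    type_code: str | None = None
    type_lookup: dict | None = None     # {"column": ..., "map": {value: code}}
    value_lookup: dict | None = None    # node IS the looked-up ontology class


@dataclass
class PropertyBridge:
    subject_map: str
    predicate: str
    object: dict                        # {"ref": name} | {"column":..,"datatype":..}


@dataclass
class MappingSpec:
    base: str
    class_maps: list[ClassMap]
    property_bridges: list[PropertyBridge]

    @classmethod
    def from_dict(cls, doc: dict) -> "MappingSpec":
        return cls(
            base=doc["base"],
            class_maps=[ClassMap(**cm) for cm in doc["class_maps"]],
            property_bridges=[PropertyBridge(**pb) for pb in doc["property_bridges"]],
        )

    @classmethod
    def load(cls, path: str | Path) -> "MappingSpec":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def dump(self, path: str | Path) -> Path:
        doc = {
            "base": self.base,
            "class_maps": [
                {k: v for k, v in cm.__dict__.items() if v is not None}
                for cm in self.class_maps
            ],
            "property_bridges": [dict(pb.__dict__) for pb in self.property_bridges],
        }
        path = Path(path)
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
        return path


@dataclass
class MappingLog:
    """Bookkeeping for the mapping-completeness metric."""

    n_source_elements: int = 0
    n_mapped_elements: int = 0
    skipped: list[tuple[str, str, str]] = field(default_factory=list)  # table, column, value


def _validate_spec(spec: MappingSpec, tables: CohortTables, ont: Ontology) -> None:
    names = [cm.name for cm in spec.class_maps]
    if len(names) != len(set(names)):
        raise MappingFailure("class map names must be unique")
    by_name = {cm.name: cm for cm in spec.class_maps}
    for cm in spec.class_maps:
        if cm.table not in tables.tables:
            raise MappingFailure(f"class map {cm.name!r}: unknown table {cm.table!r}")
        if cm.uri_template is None and cm.value_lookup is None:
            raise MappingFailure(f"class map {cm.name!r}: needs uri_template or value_lookup")
        for lookup, what in ((cm.type_lookup, "type_lookup"),
                             (cm.value_lookup, "value_lookup")):
            if lookup:
                for value, code in lookup["map"].items():
                    if code not in ont:
                        raise MappingFailure(
                            f"class map {cm.name!r} {what}: ({cm.table!r}, "
                            f"{lookup['column']!r}, {value!r}) maps to unresolvable "
                            f"class code {code!r}"
                        )
        if cm.type_code is not None and cm.type_code not in ont:
            raise MappingFailure(
                f"class map {cm.name!r}: unresolvable type code {cm.type_code!r}")
    for pb in spec.property_bridges:
        if pb.subject_map not in by_name:
            raise MappingFailure(f"bridge references unknown class map {pb.subject_map!r}")
        if "ref" in pb.object and pb.object["ref"] not in by_name:
            raise MappingFailure(f"bridge references unknown class map {pb.object['ref']!r}")
        prefix = pb.predicate.partition(":")[0]
        if prefix not in ont.prefix_table:
            raise MappingFailure(f"predicate {pb.predicate!r}: unknown prefix {prefix!r}")


def _convert_literal(value: str, datatype: str) -> Literal | None:
    if datatype == "date":
        if re.match(r"^\d{8}$", value):
            return Literal(f"{value[:4]}-{value[4:6]}-{value[6:]}", "date")
        if re.match(r"^\d{4}-\d{2}-\d{2}$", value):
            return Literal(value, "date")
        return None
    try:
        return Literal(value, datatype)
    except ArgumentFailure:
        return None


def _class_map_instances(
    cm: ClassMap, tables: CohortTables, ont: Ontology, spec: MappingSpec,
    log: MappingLog,
) -> list[tuple[int, str | None, dict]]:
    """(row index, subject URI or None, row) for each row of the map's table."""
    out = []
    for i, row in enumerate(tables[cm.table]):
        if row.get(cm.key, "").strip() == "":
            out.append((i, None, row))
            continue
        if cm.value_lookup is not None:
            column = cm.value_lookup["column"]
            value = row.get(column, "")
            log.n_source_elements += bool(value != "")
            if value == "":
                out.append((i, None, row))
            elif value in cm.value_lookup["map"]:
                log.n_mapped_elements += 1
                out.append((i, ont.uri_of(cm.value_lookup["map"][value]), row))
            else:
                log.skipped.append((cm.table, column, value))
                out.append((i, None, row))
            continue
        fields = re.findall(r"\{([^}]+)\}", cm.uri_template)
        if any(row.get(f, "").strip() == "" for f in fields):
            out.append((i, None, row))
            continue
        local = cm.uri_template
        for f in fields:
            local = local.replace("{%s}" % f, _uri_safe(row[f]))
        out.append((i, spec.base.rstrip("/") + "/" + local, row))
    return out


def _uri_safe(value: str) -> str:
    return re.sub(r"[^A-Za-z0-9._~-]", "_", value)


def compile_mapping(
    spec: MappingSpec, tables: CohortTables, ont: Ontology
) -> TripleStore:
    """Compile cleaned tables into a triple store under the mapping spec.

    The returned store carries a ``mapping_log`` attribute with element
    counts for the mapping-completeness metric and the list of skipped
    (table, column, value) lookups.
    """
    _validate_spec(spec, tables, ont)
    prefixes = dict(ont.prefix_table)
    store = TripleStore(prefixes=prefixes)
    log = MappingLog()
    by_name = {cm.name: cm for cm in spec.class_maps}
    instances = {
        cm.name: _class_map_instances(cm, tables, ont, spec, log)
        for cm in spec.class_maps
    }

    # type triples
    for cm in spec.class_maps:
        for _, subject, row in instances[cm.name]:
            if subject is None:
                continue
            if cm.type_code is not None:
                store.add(Triple(subject, RDF_TYPE, ont.uri_of(cm.type_code)))
            elif cm.type_lookup is not None:
                column = cm.type_lookup["column"]
                value = row.get(column, "")
                log.n_source_elements += bool(value != "")
                if value == "":
                    continue
                code = cm.type_lookup["map"].get(value)
                if code is None:
                    log.skipped.append((cm.table, column, value))
                    continue
                log.n_mapped_elements += 1
                store.add(Triple(subject, RDF_TYPE, ont.uri_of(code)))

    # property bridges
    from rolhs.ontology import expand_curie

    pred_prefixes = dict(ont.prefix_table)
    for pb in spec.property_bridges:
        scm = by_name[pb.subject_map]
        predicate = expand_curie(pb.predicate, pred_prefixes)
        subject_rows = instances[scm.name]
        if "ref" in pb.object:
            ocm = by_name[pb.object["ref"]]
            object_rows = instances[ocm.name]
            if ocm.table == scm.table:
                # same table: row-level join
                obj_by_row = {i: s for i, s, _ in object_rows if s is not None}
                for i, subject, _row in subject_rows:
                    if subject is None:
                        continue
                    obj = obj_by_row.get(i)
                    if obj is not None:
                        store.add(Triple(subject, predicate, obj))
            else:
                obj_by_key: dict[str, list[str]] = {}
                for _, s, row in object_rows:
                    if s is not None:
                        obj_by_key.setdefault(row.get(ocm.key, ""), []).append(s)
                for _, subject, row in subject_rows:
                    if subject is None:
                        continue
                    for obj in obj_by_key.get(row.get(scm.key, ""), []):
                        store.add(Triple(subject, predicate, obj))
        else:
            column = pb.object["column"]
            datatype = pb.object.get("datatype", "string")
            for _, subject, row in subject_rows:
                if subject is None:
                    continue
                value = row.get(column, "")
                log.n_source_elements += bool(value != "")
                if value == "":
                    continue
                literal = _convert_literal(value, datatype)
                if literal is None:
                    log.skipped.append((scm.table, column, value))
                    continue
                log.n_mapped_elements += 1
                store.add(Triple(subject, predicate, literal))

    store.mapping_log = log  # type: ignore[attr-defined]
    return store


# ---------------------------------------------------------------------------
# Turtle serialization / parsing

_PN_LOCAL = re.compile(r"^[A-Za-z_][A-Za-z0-9._-]*$")


def _turtle_term(term: Term, prefixes: dict[str, str]) -> str:
    if isinstance(term, Literal):
        escaped = term.value.replace("\\", "\\\\").replace('"', '\\"')
        if term.datatype == "string":
            return f'"{escaped}"'
        return f'"{escaped}"^^xsd:{term.datatype if term.datatype != "date" else "date"}'
    best = None
    for prefix, base in prefixes.items():
        if term.startswith(base):
            local = term[len(base):]
            if _PN_LOCAL.match(local) and (best is None or len(base) > best[2]):
                best = (prefix, local, len(base))
    if best is not None:
        return f"{best[0]}:{best[1]}"
    return f"<{term}>"


def serialize_turtle(store: TripleStore, path: str | Path | None = None) -> str:
    """Deterministic Turtle: sorted prefixes, one sorted triple per line."""
    lines = [
        f"@prefix {prefix}: <{base}> ."
        for prefix, base in sorted(store.prefixes.items())
    ]
    lines.append("")
    for t in store:  # iteration is sorted
        s = _turtle_term(t.subject, store.prefixes)
        p = ("a" if t.predicate == RDF_TYPE
             else _turtle_term(t.predicate, store.prefixes))
        o = _turtle_term(t.object, store.prefixes)
        lines.append(f"{s} {p} {o} .")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


_TOKEN_RE = re.compile(
    r"""(?P<comment>\#[^\n]*)
      | (?P<iri><[^<>"{}|^`\\\s]*>)
      | (?P<literal>"(?:[^"\\]|\\.)*")
      | (?P<dtype>\^\^)
      | (?P<prefix_decl>@prefix)
      | (?P<a_kw>\ba\b)
      | (?P<pname>[A-Za-z_][\w.-]*:[A-Za-z0-9_][\w.-]*|[A-Za-z_][\w.-]*:)
      | (?P<number>[+-]?\d+(?:\.\d+)?)
      | (?P<dot>\.)
      | (?P<ws>\s+)
    """,
    re.VERBOSE,
)


def parse_turtle(path: str | Path) -> TripleStore:
    """Parse the Turtle subset this package emits (plus comments)."""
    return parse_turtle_text(Path(path).read_text(encoding="utf-8"))


def parse_turtle_text(text: str) -> TripleStore:
    tokens: list[tuple[str, str, int]] = []
    pos, line = 0, 1
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise MalformedFileError(f"unexpected character {text[pos]!r}", line=line)
        kind = m.lastgroup
        value = m.group()
        if kind not in ("ws", "comment"):
            tokens.append((kind, value, line))
        line += value.count("\n")
        pos = m.end()

    prefixes: dict[str, str] = {}
    triples: list[Triple] = []
    i = 0

    def expand(pname: str, at_line: int) -> str:
        prefix, _, local = pname.partition(":")
        if prefix not in prefixes:
            raise MalformedFileError(f"undeclared prefix {prefix!r}", line=at_line)
        return prefixes[prefix] + local

    def read_term(allow_literal: bool) -> Term:
        nonlocal i
        kind, value, at_line = tokens[i]
        if kind == "iri":
            i += 1
            return value[1:-1]
        if kind == "pname":
            i += 1
            return expand(value, at_line)
        if kind == "a_kw":
            i += 1
            return RDF_TYPE
        if kind == "literal" and allow_literal:
            raw = value[1:-1].replace('\\"', '"').replace("\\\\", "\\")
            i += 1
            datatype = "string"
            if i < len(tokens) and tokens[i][0] == "dtype":
                i += 1
                dkind, dvalue, dline = tokens[i]
                if dkind == "iri":
                    dt_uri = dvalue[1:-1]
                elif dkind == "pname":
                    dt_uri = expand(dvalue, dline)
                else:
                    raise MalformedFileError("expected datatype IRI after ^^", line=dline)
                i += 1
                datatype = _TYPE_OF_XSD.get(dt_uri, "string")
            return Literal(raw, datatype)
        if kind == "number" and allow_literal:
            i += 1
            datatype = "decimal" if "." in value else "integer"
            return Literal(value, datatype)
        raise MalformedFileError(f"unexpected token {value!r}", line=at_line)

    while i < len(tokens):
        kind, value, at_line = tokens[i]
        if kind == "prefix_decl":
            try:
                _, pname, _ = tokens[i + 1]
                _, iri, _ = tokens[i + 2]
                dot_kind = tokens[i + 3][0]
            except IndexError:
                raise MalformedFileError("truncated @prefix declaration", line=at_line)
            if tokens[i + 1][0] != "pname" or tokens[i + 2][0] != "iri" or dot_kind != "dot":
                raise MalformedFileError("malformed @prefix declaration", line=at_line)
            prefixes[pname.rstrip(":")] = iri[1:-1]
            i += 4
            continue
        subject = read_term(allow_literal=False)
        predicate = read_term(allow_literal=False)
        obj = read_term(allow_literal=True)
        if i >= len(tokens) or tokens[i][0] != "dot":
            raise MalformedFileError("expected '.' after triple", line=at_line)
        i += 1
        if not isinstance(subject, str) or not isinstance(predicate, str):
            raise MalformedFileError("subject/predicate must be IRIs", line=at_line)
        triples.append(Triple(subject, predicate, obj))

    return TripleStore(triples, prefixes=prefixes)


# ---------------------------------------------------------------------------
# basic graph pattern queries

Pattern = tuple[object, object, object]  # each a Term or a "?var" string


def _is_var(term: object) -> bool:
    return isinstance(term, str) and term.startswith("?")


def query(
    store: TripleStore,
    patterns: list[Pattern],
    project: list[str] | None = None,
) -> list[dict[str, Term]]:
    """Exact BGP join semantics; duplicate bindings eliminated, sorted output.

    A binding is returned iff substituting it into every pattern yields a
    triple present in the store.  ``project`` restricts the variables kept
    (default: all).  An all-constant query returns ``[{}]`` when the triple
    exists (ask semantics) and ``[]`` otherwise.
    """
    if project is not None:
        pattern_vars = {t for pat in patterns for t in pat if _is_var(t)}
        unknown = set(project) - pattern_vars
        if unknown:
            raise ArgumentFailure(f"projected variables not in any pattern: {sorted(unknown)}")

    solutions: list[dict[str, Term]] = [{}]
    for pattern in patterns:
        next_solutions: list[dict[str, Term]] = []
        for binding in solutions:
            s, p, o = (binding.get(t, None) if _is_var(t) else t for t in pattern)
            for triple in store.match(
                s if not _is_var(pattern[0]) or pattern[0] in binding else None,
                p if not _is_var(pattern[1]) or pattern[1] in binding else None,
                o if not _is_var(pattern[2]) or pattern[2] in binding else None,
            ):
                new = dict(binding)
                ok = True
                for slot, value in zip(pattern, (triple.subject, triple.predicate,
                                                 triple.object)):
                    if _is_var(slot):
                        if slot in new and new[slot] != value:
                            ok = False
                            break
                        new[slot] = value
                if ok:
                    next_solutions.append(new)
        solutions = next_solutions
        if not solutions:
            break

    if project is not None:
        solutions = [{v: b[v] for v in project if v in b} for b in solutions]
    unique: dict[tuple, dict[str, Term]] = {}
    for b in solutions:
        key = tuple(sorted((k, _term_key(v)) for k, v in b.items()))
        unique.setdefault(key, b)
    return [unique[k] for k in sorted(unique)]


_SPARQL_RE = re.compile(
    r"^\s*(?:(?P<prefixes>(?:PREFIX\s+[\w-]*:\s*<[^>]*>\s*)+))?"
    r"SELECT\s+(?P<proj>(?:\?\w+\s*)+|\*)\s*WHERE\s*\{(?P<body>.*)\}\s*$",
    re.IGNORECASE | re.DOTALL,
)


def parse_sparql(
    text: str, prefixes: dict[str, str] | None = None
) -> tuple[list[Pattern], list[str] | None]:
    """Parse a minimal BGP-only SPARQL SELECT into (patterns, projection)."""
    m = _SPARQL_RE.match(text)
    if m is None:
        raise MalformedFileError("not a recognizable BGP-only SELECT query")
    table = dict(prefixes or {})
    for pm in re.finditer(r"PREFIX\s+([\w-]*):\s*<([^>]*)>", m.group("prefixes") or "",
                          re.IGNORECASE):
        table[pm.group(1)] = pm.group(2)
    proj_text = m.group("proj").strip()
    project = None if proj_text == "*" else re.findall(r"\?\w+", proj_text)

    def term(token: str) -> object:
        if token.startswith("?"):
            return token
        if token.startswith("<") and token.endswith(">"):
            return token[1:-1]
        if token == "a":
            return RDF_TYPE
        if token.startswith('"'):
            return Literal(token[1:-1])
        if re.match(r"^[+-]?\d+$", token):
            return Literal(token, "integer")
        prefix, sep, local = token.partition(":")
        if sep and prefix in table:
            return table[prefix] + local
        raise MalformedFileError(f"cannot resolve term {token!r}")

    patterns: list[Pattern] = []
    for stmt in m.group("body").split("."):
        tokens = stmt.split()
        if not tokens:
            continue
        if len(tokens) != 3:
            raise MalformedFileError(f"pattern must have 3 terms: {stmt.strip()!r}")
        patterns.append(tuple(term(t) for t in tokens))  # type: ignore[arg-type]
    if not patterns:
        raise MalformedFileError("query has no triple patterns")
    return patterns, project


def filter_bindings(
    bindings: list[dict[str, Term]], var: str, lower: float | None = None,
    upper: float | None = None,
) -> list[dict[str, Term]]:
    """Numeric post-filter on query bindings (extension beyond strict BGP)."""
    out = []
    for b in bindings:
        value = b.get(var)
        if not isinstance(value, Literal):
            continue
        try:
            x = float(value.value)
        except ValueError:
            continue
        if (lower is None or x >= lower) and (upper is None or x <= upper):
            out.append(b)
    return out


# ---------------------------------------------------------------------------
# subgraphs and export

def patient_subgraph(store: TripleStore, patient_uri: str, max_depth: int) -> TripleStore:
    """Triples reachable by at most ``max_depth`` forward hops from a patient."""
    if patient_uri not in store.by_subject:
        raise LookupFailure(f"{patient_uri!r} is not a subject in the store")
    sub = TripleStore(prefixes=store.prefixes)
    frontier = {patient_uri}
    visited: set[str] = set()
    for _ in range(max_depth):
        next_frontier: set[str] = set()
        for node in frontier:
            if node in visited:
                continue
            visited.add(node)
            for t in store.by_subject.get(node, ()):
                sub.add(t)
                if isinstance(t.object, str) and t.object not in visited:
                    next_frontier.add(t.object)
        frontier = next_frontier
        if not frontier:
            break
    return sub


def _node_label(term: Term, store: TripleStore, ont: Ontology | None) -> str:
    if isinstance(term, Literal):
        return term.value
    curie = store.curie(term)
    if ont is not None and curie in ont:
        return ont.get(curie).label
    return curie if curie != term else term.rsplit("/", 1)[-1]


def export_graph(
    store: TripleStore,
    path: str | Path,
    fmt: str = "dot",
    ont: Ontology | None = None,
) -> Path:
    """Write the store as a DOT or GraphML file; one node per distinct term,
    one edge per triple, ontology labels where resolvable."""
    if fmt not in ("dot", "graphml"):
        raise ArgumentFailure(f"unknown export format {fmt!r}")
    terms = sorted(store.terms(), key=_term_key)
    node_id = {term: f"n{i}" for i, term in enumerate(terms)}
    edges = [
        (node_id[t.subject], node_id[t.object], store.curie(t.predicate))
        for t in store
    ]
    path = Path(path)
    if fmt == "dot":
        lines = ["digraph rolhs {"]
        for term in terms:
            label = _node_label(term, store, ont).replace('"', '\\"')
            shape = "box" if isinstance(term, Literal) else "ellipse"
            lines.append(f'  {node_id[term]} [label="{label}", shape={shape}];')
        for s, o, p in edges:
            lines.append(f'  {s} -> {o} [label="{p}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        lines = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
            '<key id="label" for="node" attr.name="label" attr.type="string"/>',
            '<key id="predicate" for="edge" attr.name="predicate" attr.type="string"/>',
            '<graph id="G" edgedefault="directed">',
        ]
        for term in terms:
            label = _xml_escape(_node_label(term, store, ont))
            lines.append(f'<node id="{node_id[term]}"><data key="label">{label}</data></node>')
        for s, o, p in edges:
            lines.append(
                f'<edge source="{s}" target="{o}">'
                f'<data key="predicate">{_xml_escape(p)}</data></edge>'
            )
        lines += ["</graph>", "</graphml>"]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
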