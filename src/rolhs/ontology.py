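"""Coded concept hierarchy (NCIT/ROO-style) with synonym-aware term matching.

The on-disk dialect is a small JSON document::

    {
      "prefixes": {"NCIT": "http://purl.obolibrary.org/obo/NCIT_", ...},
      "classes": [
        {"code": "NCIT:C48720", "label": "T1 Stage",
         "synonyms": ["T1"], "definition": "...", "parents": ["NCIT:C48719"]}
      ]
    }

Codes are CURIEs (``prefix:local``) expanded to absolute URIs through the
prefix table.  The parent relation must form a DAG; multiple parents are
allowed.  A converter from Bioportal-style JSON is a documented extension
point, not implemented here.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from rolhs.errors import ArgumentFailure, IntegrityError, LookupFailure, MalformedFileError

__all__ = [
    "OntologyClass",
    "Ontology",
    "load_ontology",
    "expand_curie",
    "find_classes",
    "descendants",
    "ancestors",
]


def _norm_term(term: str) -> str:
    """Case-fold and collapse internal whitespace for exact term matching."""
    return " ".join(term.split()).casefold()


def expand_curie(code: str, prefix_table: dict[str, str]) -> str:
    """Expand ``prefix:local`` to an absolute URI via the prefix table."""
    prefix, sep, local = code.partition(":")
    if not sep or not prefix or not local:
        raise ArgumentFailure(f"not a CURIE: {code!r}")
    try:
        return prefix_table[prefix] + local
    except KeyError:
        raise LookupFailure(f"unknown CURIE prefix {prefix!r} in {code!r}") from None


@dataclass(frozen=True)
class OntologyClass:
    """A coded concept: CURIE, preferred label, synonyms and parent links."""

    code: str
    uri: str
    label: str
    synonyms: frozenset[str] = frozenset()
    definition: str | None = None
    parents: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.code:
            raise IntegrityError("class code must be non-empty")
        if not self.label:
            raise IntegrityError(f"class {self.code}: label must be non-empty")
        if self.code in self.parents:
            raise IntegrityError(f"class {self.code} lists itself as parent", {self.code})

    def matches(self, q_term: str, include_synonyms: bool) -> str | None:
        """Return ``'exact'``/``'synonym'`` provenance for a match, else None."""
        q = _norm_term(q_term)
        if _norm_term(self.label) == q:
            return "exact"
        if include_synonyms and any(_norm_term(s) == q for s in self.synonyms):
            return "synonym"
        return None


@dataclass
class Ontology:
    """A validated DAG of :class:`OntologyClass` with derived child index."""

    classes: dict[str, OntologyClass]
    prefix_table: dict[str, str]
    child_index: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()
        self.child_index = {code: set() for code in self.classes}
        for cls in self.classes.values():
            for parent in cls.parents:
                self.child_index[parent].add(cls.code)

    def _validate(self) -> None:
        dangling = {
            parent
            for cls in self.classes.values()
            for parent in cls.parents
            if parent not in self.classes
        }
        if dangling:
            raise IntegrityError(
                f"dangling parent codes: {sorted(dangling)}", dangling
            )
        cycle = self._find_cycle()
        if cycle:
            raise IntegrityError(
                f"parent relation contains a cycle: {sorted(cycle)}", cycle
            )

    def _find_cycle(self) -> set[str]:
        # Kahn's algorithm over the parent relation; leftover nodes lie on cycles.
        indegree = {code: len(cls.parents) for code, cls in self.classes.items()}
        children: dict[str, list[str]] = {code: [] for code in self.classes}
        for code, cls in self.classes.items():
            for parent in cls.parents:
                children[parent].append(code)
        queue = deque(code for code, d in indegree.items() if d == 0)
        seen = 0
        while queue:
            node = queue.popleft()
            seen += 1
            for child in children[node]:
                indegree[child] -= 1
                if indegree[child] == 0:
                    queue.append(child)
        if seen == len(self.classes):
            return set()
        return {code for code, d in indegree.items() if d > 0}

    def __contains__(self, code: str) -> bool:
        return code in self.classes

    def __len__(self) -> int:
        return len(self.classes)

    def get(self, code: str) -> OntologyClass:
        try:
            return self.classes[code]
        except KeyError:
            raise LookupFailure(f"unknown ontology code {code!r}") from None

    def uri_of(self, code: str) -> str:
        return self.get(code).uri

    def code_of_uri(self, uri: str) -> str | None:
        """Reverse URI->CURIE through the prefix table; None when unmapped."""
        best = None
        for prefix, base in self.prefix_table.items():
            if uri.startswith(base) and (best is None or len(base) > len(best[1])):
                best = (prefix, base)
        if best is None:
            return None
        return f"{best[0]}:{uri[len(best[1]):]}"  # CURIE even for non-classes

    def roots(self) -> set[str]:
        return {code for code, cls in self.classes.items() if not cls.parents}


def load_ontology(path: str | Path) -> Ontology:
    """Load and validate an ontology file in the JSON dialect."""
    path = Path(path)
    if not path.exists():
        raise MalformedFileError(f"no such file: {path}")
    text = path.read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MalformedFileError(f"invalid JSON in {path}: {exc.msg}", line=exc.lineno) from exc
    return ontology_from_dict(doc)


def ontology_from_dict(doc: dict) -> Ontology:
    """Build an :class:`Ontology` from an already-parsed JSON document."""
    if not isinstance(doc, dict) or "classes" not in doc:
        raise MalformedFileError("ontology document must be an object with a 'classes' list")
    prefixes = dict(doc.get("prefixes", {}))
    classes: dict[str, OntologyClass] = {}
    for i, raw in enumerate(doc["classes"]):
        code = raw.get("code", "")
        if not code:
            raise MalformedFileError(f"class #{i}: missing code")
        if code in classes:
            raise IntegrityError(f"duplicate class code {code!r}", {code})
        classes[code] = OntologyClass(
            code=code,
            uri=expand_curie(code, prefixes),
            label=raw.get("label", ""),
            synonyms=frozenset(raw.get("synonyms", ())),
            definition=raw.get("definition"),
            parents=frozenset(raw.get("parents", ())),
        )
    return Ontology(classes=classes, prefix_table=prefixes)


def ontology_to_dict(ont: Ontology) -> dict:
    """Inverse of :func:`ontology_from_dict` (stable ordering for diffs)."""
    return {
        "prefixes": dict(sorted(ont.prefix_table.items())),
        "classes": [
            {
                "code": cls.code,
                "label": cls.label,
                "synonyms": sorted(cls.synonyms),
                "definition": cls.definition,
                "parents": sorted(cls.parents),
            }
            for code, cls in sorted(ont.classes.items())
        ],
    }


def find_classes(
    ont: Ontology, q_term: str, include_synonyms: bool = True
) -> dict[OntologyClass, str]:
    """Classes whose label (or synonym, when enabled) equals ``q_term``.

    Matching is case-insensitive and whitespace-normalized exact-string; no
    stemming or fuzzy matching.  Returns a mapping class -> provenance
    (``'exact'`` or ``'synonym'``); empty when nothing matches.
    """
    if not q_term or not q_term.strip():
        raise ArgumentFailure("q_term must be non-empty")
    hits: dict[OntologyClass, str] = {}
    for cls in ont.classes.values():
        provenance = cls.matches(q_term, include_synonyms)
        if provenance:
            hits[cls] = provenance
    return hits


def _leveled_closure(
    start: str, step: "dict[str, set[str]] | None", neighbours, levels: int
) -> set[str]:
    if levels < 0:
        raise ArgumentFailure("levels must be non-negative")
    frontier = {start}
    seen: set[str] = set()
    for _ in range(levels):
        frontier = set().union(*(neighbours(c) for c in frontier)) - seen - {start}
        if not frontier:
            break
        seen |= frontier
    return seen


def descendants(ont: Ontology, code: str, levels: int = 1) -> set[str]:
    """Codes reachable by 1..levels child steps; excludes ``code`` itself."""
    ont.get(code)
    return _leveled_closure(code, None, lambda c: ont.child_index[c], levels)


def ancestors(ont: Ontology, code: str, levels: int = 1) -> set[str]:
    """Codes reachable by 1..levels parent steps; excludes ``code`` itself."""
    ont.get(code)
    return _leveled_closure(code, None, lambda c: set(ont.get(c).parents), levels)


def leveled_expansion(
    ont: Ontology, code: str, levels: int, direction: str
) -> dict[str, int]:
    """Like descendants/ancestors but keeping the minimal hop distance."""
    if direction not in ("children", "parents"):
        raise ArgumentFailure(f"unknown direction {direction!r}")
    neighbours = (
        (lambda c: ont.child_index[c])
        if direction == "children"
        else (lambda c: set(ont.get(c).parents))
    )
    ont.get(code)
    hops: dict[str, int] = {}
    frontier = {code}
    for hop in range(1, levels + 1):
        frontier = set().union(*(neighbours(c) for c in frontier)) if frontier else set()
        frontier -= set(hops)
        frontier.discard(code)
        for c in frontier:
            hops[c] = hop
        if not frontier:
            break
    return hops
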