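"""Graph-walk corpora, embedding models, similarity metrics and 5-group
cluster evaluation for patient records in the knowledge graph.

Walks are breadth-first traversals of each patient's individual subgraph
with seeded random shuffling of every node's neighbour order ("breadth-first
search random walks"): the breadth-first frontier is kept, the randomness
lives in the neighbour permutation, and walks truncate at ``max_walk_length``
tokens.  A pure uniform random-walk mode is selectable via ``strategy``.

Tokens are class CURIEs for URI nodes and predicate-qualified normalized
literal tokens for categorical literals; date and decimal literals are
excluded (the similarity analysis is categorical-only).
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from rolhs import _embed
from rolhs.errors import ArgumentFailure, LookupFailure, UndefinedMetricFailure
from rolhs.ontology import Ontology
from rolhs.rdf_graph import Literal, TripleStore

__all__ = [
    "WalkCorpus",
    "EmbeddingParams",
    "EmbeddingModel",
    "PatientVector",
    "ClusterEvalReport",
    "build_walk_corpus",
    "ontology_corpus",
    "train_embedding",
    "patient_vector",
    "similarity",
    "rank_similar",
    "evaluate_clusters",
]

MODEL_KINDS = ("word2vec", "doc2vec", "glove", "fasttext")


def _token_of(term, store: TripleStore, predicate: str | None = None) -> str | None:
    """Map a graph node to a corpus token; None when excluded."""
    if isinstance(term, Literal):
        if term.datatype in ("date", "decimal"):
            return None  # categorical-only corpus
        pred = store.curie(predicate) if predicate else ""
        return f"{pred}={term.value.strip().lower().replace(' ', '_')}"
    curie = store.curie(term)
    if curie != term and "/" not in curie.partition(":")[2]:
        return curie
    # entity URI without a prefix: path after the authority, '/' -> ':'
    tail = term.split("://", 1)[-1]
    tail = tail.split("/", 1)[1] if "/" in tail else tail
    return tail.replace("/", ":")


@dataclass
class WalkCorpus:
    """Sentences with per-sentence patient provenance and a fixed vocabulary."""

    sentences: list[list[str]]
    patients: list[str | None]              # provenance: sentence -> patient URI
    empty_patients: set[str] = field(default_factory=set)

    @property
    def vocabulary(self) -> set[str]:
        return {t for s in self.sentences for t in s}

    def sentences_of(self, patient_uri: str) -> list[list[str]]:
        return [s for s, p in zip(self.sentences, self.patients) if p == patient_uri]

    def tokens_of(self, patient_uri: str) -> list[str]:
        seen: list[str] = []
        for sentence in self.sentences_of(patient_uri):
            for token in sentence:
                if token not in seen:
                    seen.append(token)
        return seen

    def extended(self, extra_sentences: list[list[str]]) -> "WalkCorpus":
        return WalkCorpus(
            sentences=self.sentences + extra_sentences,
            patients=self.patients + [None] * len(extra_sentences),
            empty_patients=set(self.empty_patients),
        )

    def write_text(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            "\n".join(" ".join(s) for s in self.sentences) + "\n", encoding="utf-8")
        return path


def _walk(
    store: TripleStore, start: str, max_len: int, rng: np.random.Generator,
    strategy: str,
) -> list[str]:
    tokens: list[str] = []
    start_token = _token_of(start, store)
    if start_token:
        tokens.append(start_token)
    if strategy == "bfs":
        visited = {start}
        queue: deque[str] = deque([start])
        while queue and len(tokens) < max_len:
            node = queue.popleft()
            out = sorted(store.by_subject.get(node, ()), key=lambda t: (
                t.predicate, str(t.object)))
            rng.shuffle(out)
            for t in out:
                if len(tokens) >= max_len:
                    break
                token = _token_of(t.object, store, t.predicate)
                obj_is_uri = isinstance(t.object, str)
                if obj_is_uri and t.object in visited:
                    continue
                if token is not None:
                    tokens.append(token)
                if obj_is_uri:
                    visited.add(t.object)
                    queue.append(t.object)
        return tokens
    # uniform random walk: step to a random outgoing edge, restart at leaves
    node = start
    while len(tokens) < max_len:
        out = sorted(store.by_subject.get(node, ()), key=lambda t: (
            t.predicate, str(t.object)))
        if not out:
            break
        t = out[rng.integers(0, len(out))]
        token = _token_of(t.object, store, t.predicate)
        if token is not None:
            tokens.append(token)
        node = t.object if isinstance(t.object, str) else start
    return tokens


def build_walk_corpus(
    store: TripleStore,
    patients: list[str],
    walks_per_patient: int = 10,
    max_walk_length: int = 20,
    seed: int = 0,
    strategy: str = "bfs",
) -> WalkCorpus:
    """n seeded walks per patient over its individual knowledge graph."""
    if strategy not in ("bfs", "uniform"):
        raise ArgumentFailure(f"unknown walk strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    sentences: list[list[str]] = []
    provenance: list[str | None] = []
    empty: set[str] = set()
    for patient in patients:
        if patient not in store.by_subject:
            empty.add(patient)
            token = _token_of(patient, store)
            for _ in range(walks_per_patient):
                sentences.append([token])
                provenance.append(patient)
            continue
        for _ in range(walks_per_patient):
            sentence = _walk(store, patient, max_walk_length, rng, strategy)
            if sentence:
                sentences.append(sentence)
                provenance.append(patient)
    return WalkCorpus(sentences=sentences, patients=provenance, empty_patients=empty)


def ontology_corpus(ont: Ontology) -> list[list[str]]:
    """One sentence per class: code, parent codes, normalized label/synonyms.

    Stand-in for the large public-terminology scrape the similarity models
    would ideally be trained on; concatenated with the walk corpus.
    """
    sentences = []
    for code in sorted(ont.classes):
        cls = ont.get(code)
        tokens = [code, *sorted(cls.parents)]
        tokens.append(cls.label.strip().lower().replace(" ", "_"))
        tokens.extend(s.strip().lower().replace(" ", "_") for s in sorted(cls.synonyms))
        sentences.append(tokens)
    return sentences


@dataclass(frozen=True)
class EmbeddingParams:
    dimension: int = 100
    window: int = 5
    epochs: int = 100       # training iterations over the corpus
    negative: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.dimension < 2:
            raise ArgumentFailure("dimension must be >= 2")
        if self.epochs < 1:
            raise ArgumentFailure("epochs must be >= 1")


@dataclass
class EmbeddingModel:
    kind: str
    dimension: int
    vectors: dict[str, np.ndarray]                  # token -> vector
    doc_vectors: dict[str, np.ndarray] = field(default_factory=dict)
    params: EmbeddingParams | None = None

    def write_word2vec_text(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vectors)} {self.dimension}\n")
            for token in sorted(self.vectors):
                values = " ".join(f"{x:.6f}" for x in self.vectors[token])
                fh.write(f"{token} {values}\n")
        return path


@dataclass(frozen=True)
class PatientVector:
    patient_uri: str
    vector: np.ndarray
    kind: str
    empty_corpus: bool = False

    def __post_init__(self):
        if not np.all(np.isfinite(self.vector)):
            raise ArgumentFailure(f"non-finite patient vector for {self.patient_uri}")


def train_embedding(
    corpus: WalkCorpus, kind: str, params: EmbeddingParams = EmbeddingParams()
) -> EmbeddingModel:
    """Train one of the four embedding kinds on the corpus (seeded)."""
    if kind not in MODEL_KINDS:
        raise ArgumentFailure(f"unknown embedding kind {kind!r}; valid: {MODEL_KINDS}")
    if not corpus.sentences:
        raise ArgumentFailure("corpus must be non-empty")
    rng = np.random.default_rng(params.seed)
    vocab = _embed.build_vocab(corpus.sentences)
    noise = vocab.noise_distribution()

    if kind == "glove":
        table = _embed.train_glove(
            corpus.sentences, vocab, params.dimension, params.epochs,
            params.window, rng)
    elif kind == "doc2vec":
        patients = sorted({p for p in corpus.patients if p is not None})
        doc_tokens = []
        doc_names = []
        for patient in patients:
            toks = np.concatenate([
                vocab.encode(s) for s in corpus.sentences_of(patient)
            ]) if corpus.sentences_of(patient) else np.empty(0, dtype=np.int64)
            doc_tokens.append(toks)
            doc_names.append(patient)
        # background sentences train the shared output layer via extra docs
        background = [s for s, p in zip(corpus.sentences, corpus.patients)
                      if p is None]
        for s in background:
            doc_tokens.append(vocab.encode(s))
            doc_names.append(None)
        table_docs = _embed.train_pvdbow(
            doc_tokens, len(vocab), noise, params.dimension, params.epochs,
            params.negative, params.learning_rate, rng)
        doc_vectors = {
            name: table_docs[i] for i, name in enumerate(doc_names)
            if name is not None
        }
        # token vectors: PV-DBOW has no input word table; expose doc table only
        return EmbeddingModel(kind, params.dimension, vectors={},
                              doc_vectors=doc_vectors, params=params)
    else:
        pairs = _embed.skipgram_pairs(corpus.sentences, vocab, params.window, rng)
        if kind == "word2vec":
            table = _embed.train_sgns(
                pairs, len(vocab), noise, params.dimension, params.epochs,
                params.negative, params.learning_rate, rng)
        else:  # fasttext
            table = _embed.train_fasttext(
                pairs, vocab, noise, params.dimension, params.epochs,
                params.negative, params.learning_rate, rng)
    vectors = {token: table[i] for i, token in enumerate(vocab.tokens)}
    return EmbeddingModel(kind, params.dimension, vectors=vectors, params=params)


def patient_vector(
    model: EmbeddingModel, corpus: WalkCorpus, patient_uri: str
) -> PatientVector:
    """doc2vec: the trained document vector; word kinds: unweighted mean of
    the patient's distinct token vectors."""
    if model.kind == "doc2vec":
        if patient_uri not in model.doc_vectors:
            raise LookupFailure(f"{patient_uri!r} has no document vector")
        return PatientVector(patient_uri, model.doc_vectors[patient_uri],
                             model.kind,
                             empty_corpus=patient_uri in corpus.empty_patients)
    tokens = corpus.tokens_of(patient_uri)
    if not tokens:
        raise LookupFailure(f"{patient_uri!r} not present in corpus")
    known = [t for t in tokens if t in model.vectors]
    if not known:
        return PatientVector(patient_uri, np.zeros(model.dimension), model.kind,
                             empty_corpus=True)
    vec = np.mean([model.vectors[t] for t in known], axis=0)
    return PatientVector(patient_uri, vec, model.kind,
                         empty_corpus=patient_uri in corpus.empty_patients)


# ---------------------------------------------------------------------------
# metrics

def similarity(u: np.ndarray, v: np.ndarray, metric: str, p: float = 3.0) -> float:
    """cosine similarity or euclidean/manhattan/minkowski distance."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ArgumentFailure(f"dimension mismatch: {u.shape} vs {v.shape}")
    if metric == "cosine":
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            raise UndefinedMetricFailure("cosine similarity undefined for zero vectors")
        return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "manhattan":
        return float(np.abs(u - v).sum())
    if metric == "minkowski":
        if p < 1:
            raise ArgumentFailure("minkowski order must be >= 1")
        return float((np.abs(u - v) ** p).sum() ** (1.0 / p))
    raise ArgumentFailure(f"unknown metric {metric!r}")


def rank_similar(
    vectors: list[PatientVector], query: str, metric: str = "cosine",
    k: int = 10, p: float = 3.0,
) -> list[tuple[str, float]]:
    """Top-k neighbours of the query patient; query excluded, ties by ID."""
    if k <= 0:
        raise ArgumentFailure("k must be positive")
    by_uri = {pv.patient_uri: pv for pv in vectors}
    if query not in by_uri:
        raise LookupFailure(f"query patient {query!r} not among vectors")
    q = by_uri[query].vector
    scored = []
    for pv in vectors:
        if pv.patient_uri == query:
            continue
        scored.append((pv.patient_uri, similarity(q, pv.vector, metric, p)))
    reverse = metric == "cosine"
    scored.sort(key=lambda x: ((-x[1] if reverse else x[1]), x[0]))
    return scored[:k]


@dataclass
class ClusterEvalReport:
    """Within-group cosine coherence plus global distance dispersion."""

    kind: str
    intra_cosine: float                       # mean over same-group pairs
    inter_cosine: float                       # mean over cross-group pairs
    all_pairs_cosine: float
    mean_distances: dict[str, float]          # euclidean/manhattan/minkowski
    cluster_counts: dict[str, int]
    per_cluster_cosine: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=1), encoding="utf-8")
        return path

    def to_tsv_row(self) -> str:
        d = self.mean_distances
        return "\t".join([
            self.kind, f"{self.intra_cosine:.3f}",
            f"{d.get('euclidean', float('nan')):.3f}",
            f"{d.get('manhattan', float('nan')):.3f}",
            f"{d.get('minkowski', float('nan')):.3f}",
        ])


def evaluate_clusters(
    vectors: list[PatientVector],
    labels: dict[str, str],
    metrics: tuple[str, ...] = ("euclidean", "manhattan", "minkowski"),
    p: float = 3.0,
) -> ClusterEvalReport:
    """Mean pairwise cosine within diagnosis groups and mean pairwise
    distances over all distinct pairs; singleton groups excluded with warning."""
    usable = [pv for pv in vectors if pv.patient_uri in labels]
    groups: dict[str, list[PatientVector]] = {}
    for pv in usable:
        groups.setdefault(labels[pv.patient_uri], []).append(pv)
    for name in [g for g, members in groups.items() if len(members) < 2]:
        warnings.warn(f"cluster {name!r} has fewer than 2 patients; excluded")
        del groups[name]
    if not groups:
        raise ArgumentFailure("no group with >= 2 labelled patients")

    mat = np.stack([pv.vector for pv in usable])
    uris = [pv.patient_uri for pv in usable]
    norms = np.linalg.norm(mat, axis=1)
    if (norms == 0).any():
        raise UndefinedMetricFailure("zero patient vector in cluster evaluation")
    unit = mat / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    n = len(usable)
    iu = np.triu_indices(n, k=1)
    same = np.array([[labels[a] == labels[b] for b in uris] for a in uris])

    intra = float(cos[iu][same[iu]].mean())
    inter_mask = ~same[iu]
    inter = float(cos[iu][inter_mask].mean()) if inter_mask.any() else float("nan")
    all_pairs = float(cos[iu].mean())

    per_cluster = {}
    for name, members in sorted(groups.items()):
        idx = [uris.index(pv.patient_uri) for pv in members]
        block = cos[np.ix_(idx, idx)]
        biu = np.triu_indices(len(idx), k=1)
        per_cluster[name] = float(block[biu].mean())

    from scipy.spatial.distance import pdist

    mean_distances = {}
    for metric in metrics:
        if metric == "euclidean":
            condensed = pdist(mat, metric="euclidean")
        elif metric == "manhattan":
            condensed = pdist(mat, metric="cityblock")
        elif metric == "minkowski":
            condensed = pdist(mat, metric="minkowski", p=p)
        else:
            raise ArgumentFailure(f"unknown distance metric {metric!r}")
        mean_distances[metric] = float(condensed.mean())

    return ClusterEvalReport(
        kind=usable[0].kind if usable else "",
        intra_cosine=intra,
        inter_cosine=inter,
        all_pairs_cosine=all_pairs,
        mean_distances=mean_distances,
        cluster_counts={g: len(m) for g, m in sorted(groups.items())},
        per_cluster_cosine=per_cluster,
    )
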