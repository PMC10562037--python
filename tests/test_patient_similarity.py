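import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rolhs.errors import ArgumentFailure, LookupFailure, UndefinedMetricFailure
from rolhs.patient_similarity import (
    EmbeddingModel,
    EmbeddingParams,
    PatientVector,
    WalkCorpus,
    build_walk_corpus,
    evaluate_clusters,
    ontology_corpus,
    patient_vector,
    rank_similar,
    similarity,
    train_embedding,
)
from rolhs.rdf_graph import Literal, Triple, TripleStore

EX = "http://example.org/"


def star_store(n_attrs=4):
    st_ = TripleStore()  # no ex: prefix -> tokens fall back to path style
    for i in range(n_attrs):
        st_.add(Triple(EX + "patient/P1", EX + f"p{i}", EX + f"attr{i}"))
    return st_


SMALL_PARAMS = EmbeddingParams(dimension=8, epochs=5, seed=0)


class TestWalkCorpus:
    def test_star_graph_sentence_is_patient_plus_permutation(self):
        store = star_store()
        corpus = build_walk_corpus(store, [EX + "patient/P1"],
                                   walks_per_patient=1, max_walk_length=5, seed=3)
        assert len(corpus.sentences) == 1
        sentence = corpus.sentences[0]
        assert sentence[0] == "patient:P1"
        # token SET is always the full star, order is a seeded permutation
        assert sorted(sentence[1:]) == [f"attr{i}" for i in range(4)]

    def test_all_24_permutations_reachable(self):
        store = star_store()
        seen = set()
        for seed in range(200):
            corpus = build_walk_corpus(store, [EX + "patient/P1"], 1, 5, seed)
            seen.add(tuple(corpus.sentences[0][1:]))
        assert seen == set(itertools.permutations(
            [f"attr{i}" for i in range(4)]))

    def test_truncation_at_max_length(self):
        store = star_store(10)
        corpus = build_walk_corpus(store, [EX + "patient/P1"], 1, 5, seed=0)
        assert len(corpus.sentences[0]) == 5

    def test_zero_walks_empty_corpus(self):
        corpus = build_walk_corpus(star_store(), [EX + "patient/P1"], 0, 5, 0)
        assert corpus.sentences == []

    def test_determinism(self, store):
        patients = sorted(s for s in store.subjects() if "/patient/" in s)[:10]
        a = build_walk_corpus(store, patients, 3, 12, seed=5)
        b = build_walk_corpus(store, patients, 3, 12, seed=5)
        assert a.sentences == b.sentences
        assert a.patients == b.patients

    def test_every_patient_contributes_sentences(self, store):
        patients = sorted(s for s in store.subjects() if "/patient/" in s)
        corpus = build_walk_corpus(store, patients, 2, 10, seed=1)
        assert {p for p in corpus.patients} == set(patients)
        assert all(corpus.sentences_of(p) for p in patients)

    def test_empty_subgraph_patient_flagged_with_id_sentence(self):
        store = star_store()
        ghost = EX + "patient/P9"
        corpus = build_walk_corpus(store, [ghost], 2, 5, seed=0)
        assert ghost in corpus.empty_patients
        assert corpus.sentences_of(ghost) == [["patient:P9"], ["patient:P9"]]

    def test_date_and_decimal_literals_excluded(self):
        store = TripleStore(prefixes={"ex": EX})
        store.add(Triple(EX + "patient/P1", EX + "p", Literal("2020-01-01", "date")))
        store.add(Triple(EX + "patient/P1", EX + "q", Literal("1.5", "decimal")))
        store.add(Triple(EX + "patient/P1", EX + "r", Literal("2", "integer")))
        corpus = build_walk_corpus(store, [EX + "patient/P1"], 1, 10, 0)
        assert corpus.sentences[0] == ["patient:P1", "ex:r=2"]

    def test_uniform_strategy_runs(self):
        corpus = build_walk_corpus(star_store(), [EX + "patient/P1"], 2, 6, 0,
                                   strategy="uniform")
        assert corpus.sentences

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ArgumentFailure):
            build_walk_corpus(star_store(), [], 1, 5, 0, strategy="dfs")


def contrived_corpus():
    """A and B always co-occur; C only ever co-occurs with D."""
    sentences = ([["A", "B"]] * 40) + ([["C", "D"]] * 40)
    return WalkCorpus(sentences=sentences, patients=[None] * len(sentences))


class TestTrainEmbedding:
    @pytest.mark.parametrize("kind", ["word2vec", "glove", "fasttext"])
    def test_cooccurring_tokens_more_similar(self, kind):
        model = train_embedding(
            contrived_corpus(), kind,
            EmbeddingParams(dimension=8, epochs=60, seed=1))
        sim_ab = similarity(model.vectors["A"], model.vectors["B"], "cosine")
        sim_ac = similarity(model.vectors["A"], model.vectors["C"], "cosine")
        assert sim_ab > sim_ac

    def test_single_sentence_vocabulary(self):
        corpus = WalkCorpus(sentences=[["x", "y", "z"]], patients=[None])
        model = train_embedding(corpus, "word2vec", SMALL_PARAMS)
        assert set(model.vectors) == {"x", "y", "z"}

    @pytest.mark.parametrize("kind", ["word2vec", "doc2vec", "glove", "fasttext"])
    def test_seeded_training_is_deterministic(self, kind):
        corpus = WalkCorpus(
            sentences=[["a", "b", "c"], ["b", "c", "d"], ["a", "d"]] * 4,
            patients=["P1", "P2", None] * 4)
        m1 = train_embedding(corpus, kind, SMALL_PARAMS)
        m2 = train_embedding(corpus, kind, SMALL_PARAMS)
        for token in m1.vectors:
            assert np.array_equal(m1.vectors[token], m2.vectors[token])
        for doc in m1.doc_vectors:
            assert np.array_equal(m1.doc_vectors[doc], m2.doc_vectors[doc])

    @pytest.mark.parametrize("kind", ["word2vec", "doc2vec", "glove", "fasttext"])
    def test_vectors_finite_with_dimension(self, kind):
        corpus = WalkCorpus(
            sentences=[["a", "b"], ["b", "c"]], patients=["P1", "P2"])
        model = train_embedding(corpus, kind, SMALL_PARAMS)
        table = model.doc_vectors if kind == "doc2vec" else model.vectors
        assert table
        for vec in table.values():
            assert vec.shape == (8,)
            assert np.all(np.isfinite(vec))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ArgumentFailure):
            train_embedding(contrived_corpus(), "bert", SMALL_PARAMS)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ArgumentFailure):
            train_embedding(WalkCorpus([], []), "word2vec", SMALL_PARAMS)

    def test_dimension_lower_bound(self):
        with pytest.raises(ArgumentFailure):
            EmbeddingParams(dimension=1)

    def test_epochs_default_is_100(self):
        assert EmbeddingParams().epochs == 100


class TestPatientVector:
    def make_model(self, table):
        d = len(next(iter(table.values())))
        return EmbeddingModel("word2vec", d,
                              {k: np.asarray(v, float) for k, v in table.items()})

    def test_single_token_patient_gets_token_vector(self):
        model = self.make_model({"t": [1.0, 2.0]})
        corpus = WalkCorpus([["t"]], ["P1"])
        assert np.array_equal(patient_vector(model, corpus, "P1").vector, [1, 2])

    def test_two_tokens_mean(self):
        model = self.make_model({"a": [2.0, 0.0], "b": [0.0, 4.0]})
        corpus = WalkCorpus([["a", "b"]], ["P1"])
        assert np.array_equal(patient_vector(model, corpus, "P1").vector, [1, 2])

    def test_distinct_tokens_only(self):
        model = self.make_model({"a": [3.0], "b": [9.0]})
        corpus = WalkCorpus([["a", "a", "a", "b"]], ["P1"])
        assert patient_vector(model, corpus, "P1").vector[0] == 6.0

    def test_mean_matches_independent_summation(self, store):
        patients = sorted(s for s in store.subjects() if "/patient/" in s)[:5]
        corpus = build_walk_corpus(store, patients, 2, 10, seed=2)
        model = train_embedding(corpus, "word2vec", SMALL_PARAMS)
        for p in patients:
            tokens = corpus.tokens_of(p)
            manual = sum(model.vectors[t] for t in tokens) / len(tokens)
            assert np.allclose(patient_vector(model, corpus, p).vector, manual)

    def test_aggregation_linearity(self):
        model = self.make_model({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        corpus = WalkCorpus([["a", "b"]], ["P1"])
        base = patient_vector(model, corpus, "P1").vector
        scaled_model = self.make_model({"a": [3.0, 6.0], "b": [9.0, 12.0]})
        scaled = patient_vector(scaled_model, corpus, "P1").vector
        assert np.allclose(scaled, 3.0 * base)

    def test_unknown_patient_fails(self):
        model = self.make_model({"a": [1.0]})
        with pytest.raises(LookupFailure):
            patient_vector(model, WalkCorpus([["a"]], ["P1"]), "P2")

    def test_doc2vec_returns_document_vector(self):
        corpus = WalkCorpus([["a", "b"], ["b", "c"]], ["P1", "P2"])
        model = train_embedding(corpus, "doc2vec", SMALL_PARAMS)
        pv = patient_vector(model, corpus, "P1")
        assert np.array_equal(pv.vector, model.doc_vectors["P1"])


class TestSimilarityMetric:
    def test_cosine_self_similarity_is_one(self):
        v = np.array([1.0, -2.0, 3.0])
        assert similarity(v, v, "cosine") == pytest.approx(1.0)

    def test_closed_forms(self):
        a, b = np.zeros(2), np.ones(2)
        assert similarity(a, b, "manhattan") == pytest.approx(2.0)
        assert similarity(a, b, "euclidean") == pytest.approx(math.sqrt(2))

    def test_minkowski_family_identities(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            u, v = rng.normal(size=8), rng.normal(size=8)
            assert similarity(u, v, "minkowski", p=2) == pytest.approx(
                similarity(u, v, "euclidean"), abs=1e-12)
            assert similarity(u, v, "minkowski", p=1) == pytest.approx(
                similarity(u, v, "manhattan"), abs=1e-12)

    def test_matches_scipy(self):
        from scipy.spatial import distance

        rng = np.random.default_rng(1)
        u, v = rng.normal(size=16), rng.normal(size=16)
        assert similarity(u, v, "cosine") == pytest.approx(
            1 - distance.cosine(u, v))
        assert similarity(u, v, "euclidean") == pytest.approx(
            distance.euclidean(u, v))
        assert similarity(u, v, "manhattan") == pytest.approx(
            distance.cityblock(u, v))
        assert similarity(u, v, "minkowski", 3) == pytest.approx(
            distance.minkowski(u, v, 3))

    def test_zero_vector_cosine_undefined(self):
        with pytest.raises(UndefinedMetricFailure):
            similarity(np.zeros(3), np.ones(3), "cosine")

    def test_dimension_mismatch(self):
        with pytest.raises(ArgumentFailure):
            similarity(np.ones(2), np.ones(3), "euclidean")

    def test_unknown_metric(self):
        with pytest.raises(ArgumentFailure):
            similarity(np.ones(2), np.ones(2), "hamming")

    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=4),
           st.lists(st.floats(-10, 10), min_size=4, max_size=4),
           st.lists(st.floats(-10, 10), min_size=4, max_size=4))
    @settings(max_examples=60, deadline=None)
    def test_metric_axioms(self, a, b, c):
        u, v, w = np.array(a), np.array(b), np.array(c)
        for metric in ("euclidean", "manhattan", "minkowski"):
            duv = similarity(u, v, metric)
            assert duv >= 0
            assert duv == pytest.approx(similarity(v, u, metric), rel=1e-9)
            assert similarity(u, w, metric) <= duv + similarity(v, w, metric) + 1e-9


class TestRankSimilar:
    def make_vectors(self, table):
        return [PatientVector(uri, np.asarray(vec, float), "word2vec")
                for uri, vec in table.items()]

    def test_duplicate_vector_ranks_first(self):
        vectors = self.make_vectors({
            "P1": [1.0, 0.0], "P2": [1.0, 0.0], "P3": [0.0, 1.0]})
        top = rank_similar(vectors, "P1", "cosine", k=2)
        assert top[0][0] == "P2"

    def test_query_excluded(self):
        vectors = self.make_vectors({"P1": [1, 0], "P2": [0, 1]})
        assert all(uri != "P1" for uri, _ in rank_similar(vectors, "P1", "cosine", 5))

    def test_k_caps_and_full_ordering(self):
        rng = np.random.default_rng(4)
        vectors = self.make_vectors(
            {f"P{i}": rng.normal(size=3) for i in range(6)})
        full = rank_similar(vectors, "P0", "euclidean", k=10)
        assert len(full) == 5
        # brute force over all pairwise computations
        brute = sorted(
            ((pv.patient_uri,
              float(np.linalg.norm(pv.vector - vectors[0].vector)))
             for pv in vectors[1:]),
            key=lambda x: (x[1], x[0]))
        assert [u for u, _ in full] == [u for u, _ in brute]

    def test_ties_broken_by_patient_id(self):
        vectors = self.make_vectors({"P1": [1, 0], "P3": [1, 0], "P2": [1, 0]})
        assert [u for u, _ in rank_similar(vectors, "P1", "cosine", 5)] == \
            ["P2", "P3"]

    def test_bad_k(self):
        vectors = self.make_vectors({"P1": [1, 0], "P2": [0, 1]})
        with pytest.raises(ArgumentFailure):
            rank_similar(vectors, "P1", "cosine", k=0)

    def test_unknown_query(self):
        vectors = self.make_vectors({"P1": [1, 0]})
        with pytest.raises(LookupFailure):
            rank_similar(vectors, "P9", "cosine", 1)


class TestEvaluateClusters:
    def make_vectors(self, table):
        return [PatientVector(uri, np.asarray(vec, float), "word2vec")
                for uri, vec in table.items()]

    def test_identical_vectors(self):
        vectors = self.make_vectors({f"P{i}": [1.0, 1.0] for i in range(6)})
        labels = {f"P{i}": f"G{i % 2}" for i in range(6)}
        report = evaluate_clusters(vectors, labels)
        assert report.intra_cosine == pytest.approx(1.0)
        assert all(v == pytest.approx(0.0)
                   for v in report.mean_distances.values())

    def test_orthogonal_groups(self):
        vectors = self.make_vectors({
            "P1": [1, 0], "P2": [1, 0], "P3": [0, 1], "P4": [0, 1]})
        labels = {"P1": "A", "P2": "A", "P3": "B", "P4": "B"}
        report = evaluate_clusters(vectors, labels)
        assert report.intra_cosine == pytest.approx(1.0)
        assert report.inter_cosine == pytest.approx(0.0)

    def test_against_brute_force_pairwise_loops(self):
        rng = np.random.default_rng(6)
        table = {f"P{i}": rng.normal(size=4) for i in range(12)}
        labels = {f"P{i}": f"G{i % 3}" for i in range(12)}
        report = evaluate_clusters(self.make_vectors(table), labels, p=3.0)

        def cos(u, v):
            return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))

        uris = list(table)
        intra, inter, alld = [], [], {"euclidean": [], "manhattan": [],
                                      "minkowski": []}
        for i in range(len(uris)):
            for j in range(i + 1, len(uris)):
                u, v = table[uris[i]], table[uris[j]]
                c = cos(u, v)
                (intra if labels[uris[i]] == labels[uris[j]] else inter).append(c)
                alld["euclidean"].append(float(np.linalg.norm(u - v)))
                alld["manhattan"].append(float(np.abs(u - v).sum()))
                alld["minkowski"].append(float((np.abs(u - v) ** 3).sum() ** (1 / 3)))
        assert report.intra_cosine == pytest.approx(np.mean(intra))
        assert report.inter_cosine == pytest.approx(np.mean(inter))
        for metric, values in alld.items():
            assert report.mean_distances[metric] == pytest.approx(np.mean(values))

    def test_singleton_group_excluded_with_warning(self):
        vectors = self.make_vectors({"P1": [1, 0], "P2": [1, 1], "P3": [0, 1]})
        labels = {"P1": "A", "P2": "A", "P3": "B"}
        with pytest.warns(UserWarning, match="fewer than 2"):
            report = evaluate_clusters(vectors, labels)
        assert set(report.cluster_counts) == {"A"}

    def test_cluster_counts(self):
        vectors = self.make_vectors({f"P{i}": [1.0, float(i)] for i in range(10)})
        labels = {f"P{i}": f"G{i % 2}" for i in range(10)}
        report = evaluate_clusters(vectors, labels)
        assert report.cluster_counts == {"G0": 5, "G1": 5}


def test_ontology_corpus_covers_all_classes(ont):
    sentences = ontology_corpus(ont)
    assert len(sentences) == len(ont)
    codes = {s[0] for s in sentences}
    assert codes == set(ont.classes)
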