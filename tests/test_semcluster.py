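"""Abstract embeddings, department profiles, clustering, within-cluster ranks."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from rtindex import semcluster, synth

TOPICS = synth._DEFAULT_TOPICS  # three disjoint vocabularies


def topic_docs(n_per_topic=30, words=30, seed=0):
    rng = np.random.default_rng(seed)
    docs, labels = [], []
    for k, vocab in enumerate(TOPICS):
        for _ in range(n_per_topic):
            docs.append(" ".join(rng.choice(vocab, words)))
            labels.append(k)
    return docs, labels


@pytest.fixture(scope="module")
def topic_model():
    docs, labels = topic_docs()
    model = semcluster.train_embeddings(docs, sample_fraction=1.0, dim=20, seed=0)
    return model, docs, labels


class TestTrainEmbeddings:
    def test_full_sample_covers_vocabulary(self, topic_model):
        model, docs, _ = topic_model
        tokens = {t for d in docs for t in semcluster.tokenize(d)}
        assert tokens <= set(model.vocab)

    def test_seeded_sampling_deterministic(self):
        docs, _ = topic_docs()
        m1 = semcluster.train_embeddings(docs, sample_fraction=0.5, dim=10, seed=42)
        m2 = semcluster.train_embeddings(docs, sample_fraction=0.5, dim=10, seed=42)
        assert m1.vocab == m2.vocab
        assert np.array_equal(m1.vectors, m2.vectors)

    def test_requested_dimension_honored(self):
        docs, _ = topic_docs(n_per_topic=5)
        model = semcluster.train_embeddings(docs, sample_fraction=1.0, dim=10, seed=0)
        vec = semcluster.embed_abstract(model, docs[0])
        assert vec.vector.shape == (10,)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            semcluster.train_embeddings([], seed=0)

    def test_vectors_unit_norm(self, topic_model):
        model, _, _ = topic_model
        norms = np.linalg.norm(model.vectors, axis=1)
        nonzero = norms > 0
        assert np.allclose(norms[nonzero], 1.0, atol=1e-6)


class TestEmbedAbstract:
    def test_single_token_gives_that_vector(self, topic_model):
        model, _, _ = topic_model
        token = sorted(model.vocab)[0]
        av = semcluster.embed_abstract(model, token)
        assert np.allclose(av.vector, model.vector(token), atol=1e-9)

    def test_token_order_irrelevant(self, topic_model):
        model, docs, _ = topic_model
        words = semcluster.tokenize(docs[0])
        a = semcluster.embed_abstract(model, " ".join(words))
        b = semcluster.embed_abstract(model, " ".join(reversed(words)))
        assert np.allclose(a.vector, b.vector, atol=1e-12)

    def test_orthogonal_planted_model_cosine_zero(self):
        # explicit fixture model with orthogonal word vectors per topic
        vocab = {"alpha": 0, "beta": 1}
        vectors = np.eye(2)
        model = semcluster.WordEmbeddingModel(vocab, vectors, dim=2, seed=0)
        a = semcluster.embed_abstract(model, "alpha alpha alpha")
        b = semcluster.embed_abstract(model, "beta beta")
        assert float(a.vector @ b.vector) == pytest.approx(0.0, abs=1e-12)

    def test_unembeddable_text_flagged(self):
        model = semcluster.WordEmbeddingModel({"alpha": 0}, np.eye(1, 2), dim=2, seed=0)
        av = semcluster.embed_abstract(model, "zzzzqqqq wwww")
        assert not av.embeddable
        assert not np.any(av.vector)

    def test_embedded_vectors_unit_norm(self, topic_model):
        model, docs, _ = topic_model
        for d in docs[:10]:
            av = semcluster.embed_abstract(model, d)
            assert np.linalg.norm(av.vector) == pytest.approx(1.0, abs=1e-6)

    def test_within_topic_similarity_exceeds_across(self, topic_model):
        model, docs, labels = topic_model
        X = np.array([semcluster.embed_abstract(model, d).vector for d in docs])
        within, across = [], []
        for i, j in itertools.combinations(range(0, len(docs), 3), 2):
            (within if labels[i] == labels[j] else across).append(float(X[i] @ X[j]))
        assert np.mean(within) > np.mean(across) + 0.3


def profiles_from_topics(model, docs, labels, rti_by_topic=(2.0, 5.0, 8.0)):
    return [
        semcluster.DepartmentProfile(
            department=f"dept-{i}", institution_id=f"I{i}", n_papers=300,
            mean_vector=semcluster.embed_abstract(model, d).vector,
            rti=rti_by_topic[lab],
        )
        for i, (d, lab) in enumerate(zip(docs, labels))
    ]


class TestClusterDepartments:
    def test_planted_topics_recovered(self, topic_model):
        model, docs, labels = topic_model
        profiles = profiles_from_topics(model, docs, labels)
        pred, coords = semcluster.cluster_departments(profiles, k=3, perplexity=7, seed=0)
        assert adjusted_rand_score(labels, pred) == 1.0
        assert coords.shape == (len(profiles), 2)

    def test_requested_cluster_count(self, topic_model):
        model, docs, labels = topic_model
        profiles = profiles_from_topics(model, docs, labels)[:40]
        pred, _ = semcluster.cluster_departments(profiles, k=10, perplexity=5, seed=0)
        assert len(set(pred)) == 10

    def test_alternative_spellings_cluster_together(self, topic_model):
        model, docs, labels = topic_model
        profiles = profiles_from_topics(model, docs, labels)
        # same department text, alternative spelling of the name
        twin = semcluster.DepartmentProfile(
            "dept-0 & variant", "I0", 300, profiles[0].mean_vector.copy(), profiles[0].rti
        )
        pred, _ = semcluster.cluster_departments(profiles + [twin], k=3, perplexity=7, seed=0)
        assert pred[-1] == pred[0]

    def test_fewer_profiles_than_k_rejected(self, topic_model):
        model, docs, labels = topic_model
        profiles = profiles_from_topics(model, docs, labels)[:4]
        with pytest.raises(ValueError, match="at least k"):
            semcluster.cluster_departments(profiles, k=10)

    def test_deterministic_given_seed(self, topic_model):
        model, docs, labels = topic_model
        profiles = profiles_from_topics(model, docs, labels)
        a, ca = semcluster.cluster_departments(profiles, k=3, seed=9)
        b, cb = semcluster.cluster_departments(profiles, k=3, seed=9)
        assert np.array_equal(a, b) and np.allclose(ca, cb)


class TestRankWithinClusters:
    def test_descending_rti_order(self):
        profiles = [
            semcluster.DepartmentProfile("a", "I", 10, np.zeros(2), 2.0),
            semcluster.DepartmentProfile("b", "I", 10, np.zeros(2), 5.0),
            semcluster.DepartmentProfile("c", "I", 10, np.zeros(2), 4.0),
        ]
        out = semcluster.rank_within_clusters(profiles, [0, 0, 0])
        assert list(out["rti"]) == [5.0, 4.0, 2.0]
        assert list(out["rank_in_cluster"]) == [1, 2, 3]

    def test_singleton_cluster_rank_one(self):
        profiles = [semcluster.DepartmentProfile("solo", "I", 10, np.zeros(2), 3.0)]
        out = semcluster.rank_within_clusters(profiles, [7])
        assert out.iloc[0]["rank_in_cluster"] == 1

    def test_rti_tie_broken_by_paper_count(self):
        profiles = [
            semcluster.DepartmentProfile("small", "I", 10, np.zeros(2), 4.0),
            semcluster.DepartmentProfile("large", "I", 99, np.zeros(2), 4.0),
        ]
        out = semcluster.rank_within_clusters(profiles, [0, 0])
        assert list(out["department"]) == ["large", "small"]


class TestBuildProfiles:
    def test_min_papers_cut_and_na_exclusion(self):
        vocab = {"alpha": 0, "beta": 1}
        model = semcluster.WordEmbeddingModel(vocab, np.eye(2), dim=2, seed=0)
        vectors = {
            f"p{i}": semcluster.embed_abstract(model, "alpha", f"p{i}") for i in range(12)
        }
        departments = {f"p{i}": ("Dept A", "I1") for i in range(12)}
        scores = {f"p{i}": (0.0 if i == 0 else 4.0) for i in range(12)}
        profiles = semcluster.build_profiles(vectors, departments, scores, min_papers=10)
        assert len(profiles) == 1
        assert profiles[0].n_papers == 12
        assert profiles[0].rti == pytest.approx(4.0)  # the score-0 paper is excluded
        # below the cut: nothing emitted
        assert semcluster.build_profiles(vectors, departments, scores, min_papers=12) == []
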