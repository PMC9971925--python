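"""Cosine search, query classification and variant dispatch."""

import numpy as np
import pytest

from casq.embedding_core import EmbeddingList, PathEmbeddingParams, build_list, cosine_similarity
from casq.errors import ConfigurationError, ValidationError
from casq.evaluation import QueryEntitySet, ap_at_k
from casq.query_pipeline import QueryEmbeddingParams, query_embedding
from casq.retrieval import (
    ListChoice,
    NearestCentroidQueryClassifier,
    RankedResult,
    classify_query,
    generate_qc_labels,
    retrieve,
    search,
)


def random_list(rng, n, dim=8):
    el = EmbeddingList(name="L", w_p=0.0)
    for i in range(n):
        el.upsert(f"e{i:03d}", rng.normal(size=dim))
    return el


def brute_force_ranking(e_q, elist, k):
    """Full-sort oracle: score every entry, sort by (-score, id), cut at k."""
    scored = [(eid, cosine_similarity(e_q, elist.embedding_of(eid))) for eid in elist.entity_ids]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [eid for eid, _ in scored[:k]]


class TestSearch:
    def test_full_ranking_is_permutation(self):
        rng = np.random.default_rng(0)
        el = random_list(rng, 7)
        result = search(rng.normal(size=8), el, k=100)
        assert sorted(result.entity_ids()) == sorted(el.entity_ids)

    def test_exact_match_ranks_first(self):
        rng = np.random.default_rng(1)
        el = random_list(rng, 10)
        target = el.embedding_of("e004")
        result = search(target, el, k=3)
        assert result.entries[0][0] == "e004"
        assert result.entries[0][1] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        el = random_list(rng, 50)
        for _ in range(20):
            e_q = rng.normal(size=8)
            k = int(rng.integers(1, 60))
            assert search(e_q, el, k).entity_ids() == brute_force_ranking(e_q, el, k)

    def test_tie_break_by_entity_id(self):
        el = EmbeddingList(name="L", w_p=0.0)
        el.upsert("zz", np.array([1.0, 0.0]))
        el.upsert("aa", np.array([2.0, 0.0]))  # same cosine direction
        result = search(np.array([1.0, 0.0]), el, k=2)
        assert result.entity_ids() == ["aa", "zz"]

    def test_scores_non_increasing(self):
        rng = np.random.default_rng(3)
        el = random_list(rng, 30)
        scores = [s for _, s in search(rng.normal(size=8), el, k=30).entries]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_invalid_inputs(self):
        rng = np.random.default_rng(4)
        el = random_list(rng, 3)
        with pytest.raises(ValidationError):
            search(np.ones(8), el, k=0)
        with pytest.raises(ValidationError):
            search(np.ones(5), el, k=1)
        with pytest.raises(ValidationError):
            search(np.zeros(8), el, k=1)


class TestClassifier:
    def test_nearest_centroid_recovers_separable_labels(self, encoder):
        # predicate-phrase queries vs plain class-name queries are linearly
        # separable under the trigram encoder
        plain = [f"concentration of metabolite {w}" for w in ("alpha", "beta", "gamma", "delta", "epsilon")]
        pred = [f"is property of is part of {w}" for w in ("alpha", "beta", "gamma", "delta", "epsilon")]
        train = [(q, ListChoice("L1")) for q in plain[:3]] + [(q, ListChoice("L2")) for q in pred[:3]]
        clf = NearestCentroidQueryClassifier(encoder).fit(train)
        held_out = [(q, "L1") for q in plain[3:]] + [(q, "L2") for q in pred[3:]]
        agreement = sum(clf.predict(q).label == lab for q, lab in held_out) / len(held_out)
        assert agreement >= 0.9

    def test_identical_training_query_gets_its_label(self, encoder):
        clf = NearestCentroidQueryClassifier(encoder).fit(
            [("alpha flux", ListChoice("L1")), ("is part of beta", ListChoice("L2"))]
        )
        assert clf.predict("alpha flux").label == "L1"
        assert clf.predict("is part of beta").label == "L2"

    def test_untrained_falls_back_to_l1(self, encoder, caplog):
        clf = NearestCentroidQueryClassifier(encoder)
        with caplog.at_level("WARNING"):
            assert classify_query("anything", clf) == ListChoice("L1")
        assert "defaulting to L1" in caplog.text

    def test_no_classifier_falls_back_to_l1(self):
        assert classify_query("anything", None) == ListChoice("L1")


class TestGenerateQcLabels:
    def test_labels_match_hand_argmax(self, example_lexicon, encoder):
        # six queries over a two-entity corpus; APs hand-computed from the
        # explicit rankings below
        from casq.fixtures import load_example_corpus

        corpus = load_example_corpus()
        l1 = build_list(corpus, example_lexicon, encoder, PathEmbeddingParams(0.0), "L1")
        l2 = build_list(corpus, example_lexicon, encoder, PathEmbeddingParams(0.22), "L2")
        queries = [
            "concentration of triose phosphate in the astrocyte",
            "is property of glyceraldehyde 3-phosphate",
            "adenosine triphosphate in the neuron",
            "is version of concentration",
            "astrocyte",
            "neuron atp",
        ]
        gapg, damp = corpus[0].entity_id, corpus[1].entity_id
        relevant = [gapg, gapg, damp, damp, gapg, damp]
        pairs = [
            QueryEntitySet(f"q{i}", q, frozenset([r])) for i, (q, r) in enumerate(zip(queries, relevant))
        ]
        params = QueryEmbeddingParams(method="mixed")
        labels = generate_qc_labels(pairs, l1, l2, example_lexicon, encoder, params)
        assert len(labels) == 6
        # independent argmax via explicit searches
        from casq.query_pipeline import class_embedding_matrix

        class_embs = class_embedding_matrix(example_lexicon, encoder, l1.class_ids)
        for (query, choice), pair in zip(labels, pairs):
            e_q = query_embedding(query, params, example_lexicon, encoder, class_embeddings=class_embs)
            ap1 = ap_at_k(search(e_q, l1, 10), pair.relevant_entity_ids, 10)
            ap2 = ap_at_k(search(e_q, l2, 10), pair.relevant_entity_ids, 10)
            expected = "L2" if ap2 > ap1 else "L1"
            assert choice.label == expected

    def test_query_without_indexed_relevant_is_excluded(self, example_corpus, example_lexicon, encoder, caplog):
        l1 = build_list(example_corpus, example_lexicon, encoder, PathEmbeddingParams(0.0), "L1")
        l2 = build_list(example_corpus, example_lexicon, encoder, PathEmbeddingParams(0.22), "L2")
        pairs = [QueryEntitySet("q0", "astrocyte", frozenset(["m#ghost"]))]
        with caplog.at_level("WARNING"):
            assert generate_qc_labels(pairs, l1, l2, example_lexicon, encoder) == []
        assert "excluded" in caplog.text


class TestRetrieve:
    @pytest.fixture()
    def indexes(self, example_corpus, example_lexicon, encoder):
        return {
            "L1": build_list(example_corpus, example_lexicon, encoder, PathEmbeddingParams(0.0), "L1"),
            "L2": build_list(example_corpus, example_lexicon, encoder, PathEmbeddingParams(0.22), "L2"),
        }

    def test_macro_equals_direct_search(self, indexes, example_lexicon, encoder):
        q = "concentration of triose phosphate in the astrocyte"
        out = retrieve(q, indexes, example_lexicon, encoder, variant="macro", k=10)
        expected = search(encoder.encode(q), indexes["L1"], 10)
        assert out.entries == expected.entries

    def test_mixed_wp_uses_l2_and_full_query_embedding(self, indexes, example_lexicon, encoder):
        from casq.query_pipeline import class_embedding_matrix

        q = "is property of triose phosphate in the astrocyte"
        out = retrieve(q, indexes, example_lexicon, encoder, variant="mixedWP", k=10)
        params = QueryEmbeddingParams(method="mixed", m_e=1.9, use_auxiliary_phrases=True, w_p=0.22)
        class_embs = class_embedding_matrix(example_lexicon, encoder, indexes["L2"].class_ids)
        e_q = query_embedding(q, params, example_lexicon, encoder, class_embeddings=class_embs)
        assert out.entries == search(e_q, indexes["L2"], 10).entries

    def test_mixed_cl_routed_to_l2_equals_mixed_wp(self, indexes, example_lexicon, encoder):
        class AlwaysL2:
            trained = True

            def predict(self, query):
                return ListChoice("L2")

        q = "is property of triose phosphate"
        routed = retrieve(q, indexes, example_lexicon, encoder, variant="mixedCl", classifier=AlwaysL2())
        direct = retrieve(q, indexes, example_lexicon, encoder, variant="mixedWP")
        assert routed.entries == direct.entries

    def test_missing_index_is_configuration_error(self, indexes, example_lexicon, encoder):
        with pytest.raises(ConfigurationError):
            retrieve("astrocyte", {"L1": indexes["L1"]}, example_lexicon, encoder, variant="macroWP")

    def test_unknown_variant(self, indexes, example_lexicon, encoder):
        with pytest.raises(ConfigurationError):
            retrieve("astrocyte", indexes, example_lexicon, encoder, variant="nano")

    def test_end_to_end_determinism(self, indexes, example_lexicon, encoder):
        q = "concentration of adenosine triphosphate in the neuron"
        a = retrieve(q, indexes, example_lexicon, encoder, variant="mixed")
        b = retrieve(q, indexes, example_lexicon, encoder, variant="mixed")
        assert a.entries == b.entries


def test_ranked_result_container():
    r = RankedResult(entries=[("a", 0.9), ("b", 0.5)], query_id="q1")
    assert len(r) == 2 and r.entity_ids() == ["a", "b"]
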