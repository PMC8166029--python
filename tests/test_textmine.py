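"""Segmentation, frequencies, skip-gram training and association ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zjscreen import textmine
from zjscreen.textmine import (
    EmbeddingModel,
    PhraseDictionary,
    SkipGramParams,
    bidirectional_validate,
    cosine,
    embed_2d,
    frequencies,
    rank_associations,
    segment,
    sgns_pair_loss_grad,
    top_k,
    train_skipgram,
)


class TestSegment:
    def test_longest_match_wins(self):
        d = PhraseDictionary({"AB": "formula", "B": "disease"})
        assert segment("ABB", d) == ["AB", "B"]

    def test_empty_dictionary_falls_back_to_characters(self):
        assert segment("xyz", PhraseDictionary({})) == ["x", "y", "z"]

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        text=st.text(alphabet="abcd", max_size=40),
        phrases=st.sets(st.text(alphabet="abcd", min_size=1, max_size=4), max_size=8),
    )
    def test_segmentation_is_lossless(self, text, phrases):
        d = PhraseDictionary({p: "other" for p in phrases})
        assert "".join(segment(text, d)) == text

    def test_category_validation(self):
        with pytest.raises(ValueError, match="category"):
            PhraseDictionary({"x": "nonsense"})
        with pytest.raises(ValueError, match="empty"):
            PhraseDictionary({"": "other"})


class TestFrequencies:
    def test_category_filter(self):
        d = PhraseDictionary({"A": "disease", "B": "formula"})
        docs = [["A", "A", "B"]]
        assert frequencies(docs, d, "disease") == {"A": 2}
        assert frequencies(docs, d, "all") == {"A": 2, "B": 1}

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            frequencies([["A"]], PhraseDictionary({"A": "other"}), "bogus")

    def test_counts_equal_brute_force_tally(self, default_corpus):
        d = PhraseDictionary(default_corpus.dictionary)
        table = frequencies(default_corpus.documents, d, "formula")
        for tok, count in table.items():
            brute = sum(t == tok for doc in default_corpus.documents for t in doc)
            assert count == brute

    def test_top_k_ordering(self):
        table = {"b": 3, "a": 3, "c": 9}
        assert top_k(table, 2) == [("c", 9), ("a", 3)]


class TestSkipGramGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        # 5-token setting: one center, one context, three negatives
        rng = np.random.default_rng(0)
        center = rng.normal(size=8)
        context = rng.normal(size=8)
        negatives = rng.normal(size=(3, 8))
        loss, g_c, g_ctx, g_neg = sgns_pair_loss_grad(center, context, negatives)

        eps = 1e-6

        def fd(setter):
            out = np.zeros_like(center)
            for i in range(len(center)):
                lp = setter(i, +eps)
                lm = setter(i, -eps)
                out[i] = (lp - lm) / (2 * eps)
            return out

        def perturb_center(i, e):
            c = center.copy()
            c[i] += e
            return sgns_pair_loss_grad(c, context, negatives)[0]

        def perturb_context(i, e):
            c = context.copy()
            c[i] += e
            return sgns_pair_loss_grad(center, c, negatives)[0]

        assert np.allclose(fd(perturb_center), g_c, rtol=1e-5, atol=1e-8)
        assert np.allclose(fd(perturb_context), g_ctx, rtol=1e-5, atol=1e-8)
        for j in range(3):
            def perturb_neg(i, e, j=j):
                n = negatives.copy()
                n[j, i] += e
                return sgns_pair_loss_grad(center, context, n)[0]

            assert np.allclose(fd(perturb_neg), g_neg[j], rtol=1e-5, atol=1e-8)


class TestSkipGramTraining:
    def test_deterministic_for_fixed_seed(self, default_corpus):
        p = SkipGramParams(seed=0, dim=20, epochs=1)
        a = train_skipgram(default_corpus, p)
        b = train_skipgram(default_corpus, p)
        assert np.array_equal(a.input_vectors, b.input_vectors)
        assert np.array_equal(a.output_vectors, b.output_vectors)

    def test_loss_decreases_from_first_epoch(self, trained_model):
        losses = trained_model.epoch_losses
        assert all(np.isfinite(losses))
        assert losses[-1] < losses[0]

    def test_planted_pair_beats_random_fillers(self, default_corpus, trained_model):
        # the formula's own topic fillers are genuinely close to it, so the
        # contract is against the average background token, not the maximum
        f, s = default_corpus.planted_pairs[0]
        planted = cosine(trained_model.vector(f), trained_model.vector(s))
        filler_cos = [
            cosine(trained_model.vector(f), trained_model.vector(t))
            for t, cat in default_corpus.dictionary.items()
            if cat == "other" and t in trained_model
        ]
        assert planted > np.mean(filler_cos)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_skipgram([], SkipGramParams())
        with pytest.raises(ValueError, match="min_count"):
            train_skipgram([["a", "b"]], SkipGramParams(min_count=5))

    def test_min_count_filters_vocabulary(self):
        docs = [["a", "a", "a", "b"]] * 5
        m = train_skipgram(docs, SkipGramParams(dim=4, min_count=10, epochs=1))
        assert m.vocabulary == ["a"]

    def test_model_roundtrip(self, trained_model, tmp_path):
        trained_model.save(tmp_path / "v.tsv", tmp_path / "m.json")
        loaded = EmbeddingModel.load(tmp_path / "v.tsv", tmp_path / "m.json")
        assert loaded.vocabulary == trained_model.vocabulary
        assert np.array_equal(loaded.input_vectors, trained_model.input_vectors)


class TestCosine:
    def test_self_similarity_is_one(self, rng):
        for _ in range(5):
            x = rng.normal(size=7)
            assert cosine(x, x) == pytest.approx(1.0)

    def test_orthogonal_and_diagonal(self):
        assert cosine((1, 0), (0, 1)) == pytest.approx(0.0)
        assert cosine((1, 1), (1, 0)) == pytest.approx(np.sqrt(2) / 2)

    def test_symmetric_and_scale_invariant(self, rng):
        u, v = rng.normal(size=6), rng.normal(size=6)
        assert cosine(u, v) == pytest.approx(cosine(v, u))
        assert cosine(3.7 * u, 0.2 * v) == pytest.approx(cosine(u, v))

    def test_zero_norm_raises(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine(np.zeros(3), np.ones(3))


class TestRanking:
    def _toy_model(self):
        vocab = ["alpha", "beta", "gamma", "query"]
        vecs = np.array(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.2]]
        )
        return EmbeddingModel(vocabulary=vocab, input_vectors=vecs,
                              output_vectors=np.zeros_like(vecs))

    def test_identical_vectors_tie_break_lexicographically(self):
        m = self._toy_model()
        ranked = rank_associations(m, ["query"], ["beta", "alpha", "gamma"])
        assert [r.candidate for r in ranked] == ["alpha", "beta", "gamma"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_k_larger_than_candidate_set_returns_all(self):
        m = self._toy_model()
        ranked = rank_associations(m, ["query"], ["alpha", "gamma"], k=10)
        assert len(ranked) == 2

    def test_scores_non_increasing_with_rank(self, trained_model, default_corpus):
        s = default_corpus.planted_pairs[0][1]
        ranked = rank_associations(trained_model, [s], sorted(default_corpus.formulae))
        scores = [r.score for r in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_out_of_vocabulary_error_lists_tokens(self):
        m = self._toy_model()
        with pytest.raises(KeyError, match="nope"):
            rank_associations(m, ["query"], ["alpha", "nope"])

    def test_planted_formula_is_rank_one(self, trained_model, default_corpus):
        f, s = default_corpus.planted_pairs[0]
        ranked = rank_associations(trained_model, [s], sorted(default_corpus.formulae), k=1)
        assert ranked[0].candidate == f


class TestBidirectional:
    def test_single_candidate_each_gives_full_consistency(self):
        vocab = ["f", "s"]
        vecs = np.array([[1.0, 0.1], [1.0, 0.0]])
        m = EmbeddingModel(vocabulary=vocab, input_vectors=vecs,
                           output_vectors=np.zeros_like(vecs))
        table, consistency = bidirectional_validate(m, ["f"], ["s"], k=1)
        assert consistency == 1.0

    def test_empty_pair_set_reports_missing(self):
        vocab = ["f", "s"]
        vecs = np.eye(2)
        m = EmbeddingModel(vocabulary=vocab, input_vectors=vecs,
                           output_vectors=np.zeros_like(vecs))
        table, consistency = bidirectional_validate(m, [], ["s"], k=3)
        assert consistency is None
        assert len(table) == 0

    def test_planted_corpus_consistency(self, trained_model, default_corpus):
        s = default_corpus.planted_pairs[0][1]
        _, consistency = bidirectional_validate(
            trained_model, sorted(default_corpus.formulae), [s], k=3
        )
        assert consistency >= 0.8


class TestEmbed2d:
    def _cluster_model(self, rng):
        # two tight clusters far apart in 10 dimensions
        a = rng.normal(0.0, 0.5, size=(20, 10))
        b = rng.normal(0.0, 0.5, size=(20, 10)) + 30.0
        vecs = np.vstack([a, b])
        vocab = [f"t{i}" for i in range(40)]
        return EmbeddingModel(vocabulary=vocab, input_vectors=vecs,
                              output_vectors=np.zeros_like(vecs))

    def test_separated_clusters_stay_separated(self, rng):
        from sklearn.metrics import silhouette_score

        m = self._cluster_model(rng)
        coords = embed_2d(m, perplexity=10, seed=0)
        assert coords.shape == (40, 2)
        labels = [0] * 20 + [1] * 20
        assert silhouette_score(coords, labels) > 0.5

    def test_reproducible_layout(self, rng):
        m = self._cluster_model(rng)
        a = embed_2d(m, perplexity=5, seed=3)
        b = embed_2d(m, perplexity=5, seed=3)
        assert np.array_equal(a, b)

    def test_perplexity_validation(self, rng):
        m = self._cluster_model(rng)
        with pytest.raises(ValueError, match="perplexity"):
            embed_2d(m, perplexity=40, seed=0)

    def test_too_small_vocabulary_rejected(self):
        vecs = np.eye(3)
        m = EmbeddingModel(vocabulary=["a", "b", "c"], input_vectors=vecs,
                           output_vectors=np.zeros_like(vecs))
        with pytest.raises(ValueError, match="at least 5"):
            embed_2d(m)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            ({"dim": 0}, "dim"),
            ({"window": 0}, "window"),
            ({"negative": 0}, "negative"),
            ({"start_lr": 0.001, "end_lr": 0.01}, "start_lr"),
        ],
    )
    def test_invalid_hyperparameters(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            SkipGramParams(**kwargs).validate()
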