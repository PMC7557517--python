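"""Tokenizer, vocabulary filters, TF-IDF / n-gram / embedding features.

The TF-IDF and bigram constructions are checked against brute-force
oracles that recompute the weights from the definition."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from injloc import (FeatureMatrix, GloveModel, TfidfWeighter, add_ngrams,
                    build_vocabulary, embedding_matrix, ngram_matrix,
                    tfidf_matrix, tokenize)
from injloc.text import Vocabulary


# ---------------------------------------------------------------- oracles

def brute_force_tfidf(corpus, vocab_terms, normalize=True):
    """Direct implementation of tf·ln(N/df) with L2 row normalization."""
    N = len(corpus)
    df = {t: sum(t in doc for doc in corpus) for t in vocab_terms}
    rows = []
    for doc in corpus:
        counts = Counter(doc)
        row = [counts[t] * (math.log(N / df[t]) if df[t] else 0.0)
               for t in vocab_terms]
        norm = math.sqrt(sum(v * v for v in row))
        if normalize and norm > 0:
            row = [v / norm for v in row]
        rows.append(row)
    return np.array(rows)


def brute_force_bigram_counts(doc):
    return Counter((doc[i], doc[i + 1]) for i in range(len(doc) - 1))


# -------------------------------------------------------------- tokenizer

class TestTokenize:
    def test_hand_trace(self):
        assert tokenize("24YOM SHOT IN LEG ON STREET") == \
            ["<NUM>YOM", "SHOT", "IN", "LEG", "ON", "STREET"]

    def test_punctuation_stripped_and_uppercased(self):
        assert tokenize("shot, self-inflicted.") == ["SHOT", "SELF", "INFLICTED"]

    def test_digit_runs_collapse_to_one_placeholder(self):
        assert tokenize("AGE 123 45") == ["AGE", "<NUM>", "<NUM>"]

    def test_empty_after_strip_raises(self):
        with pytest.raises(ValueError):
            tokenize("   ")

    def test_deterministic(self):
        s = "24YOM GSW L LEG ACCIDENTLY"
        assert tokenize(s) == tokenize(s)


# ------------------------------------------------------------- vocabulary

class TestVocabulary:
    def test_count_and_doc_fraction_filters(self):
        # term B: 12 docs of 100 -> passes 1% doc filter and count 10
        corpus_a = [["A", "B"] if i < 12 else ["A"] for i in range(100)]
        corpus_b = [["A", "B"] for _ in range(20)]
        vocab = build_vocabulary(corpus_a, corpus_b, "shared", min_count=10,
                                 min_doc_fraction=0.01)
        assert "B" in vocab.terms

    def test_nine_occurrences_omitted_at_min_count_ten(self):
        corpus_a = [["RARE", "A"] for _ in range(9)] + [["A"]] * 91
        corpus_b = [["RARE", "A"] for _ in range(50)]
        vocab = build_vocabulary(corpus_a, corpus_b, "all", min_count=10)
        # RARE appears 9 times in corpus_a (omitted there) but 50 in corpus_b
        assert "RARE" in vocab.terms  # union keeps the corpus_b survivor
        shared = build_vocabulary(corpus_a, corpus_b, "shared", min_count=10)
        assert "RARE" not in shared.terms

    def test_shared_subset_of_all_on_fixture(self):
        corpus_a = [["A", "B", "C"]] * 15
        corpus_b = [["B", "C", "D"]] * 15
        shared = build_vocabulary(corpus_a, corpus_b, "shared", min_count=5)
        allv = build_vocabulary(corpus_a, corpus_b, "all", min_count=5)
        assert set(shared.terms) <= set(allv.terms)
        assert set(shared.terms) == {"B", "C"}
        assert set(allv.terms) == {"A", "B", "C", "D"}

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.lists(st.sampled_from("ABCDEF"), min_size=1, max_size=6),
                    min_size=1, max_size=20),
           st.lists(st.lists(st.sampled_from("ABCDEF"), min_size=1, max_size=6),
                    min_size=1, max_size=20),
           st.integers(min_value=1, max_value=5))
    def test_shared_subset_of_all_property(self, ca, cb, mc):
        shared = build_vocabulary(ca, cb, "shared", min_count=mc)
        allv = build_vocabulary(ca, cb, "all", min_count=mc)
        assert set(shared.terms) <= set(allv.terms)

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError):
            Vocabulary(("A", "A"), "all", 1, 0.0)


# ----------------------------------------------------------------- tf-idf

class TestTfidf:
    def test_everywhere_term_has_zero_idf(self, toy_corpus):
        vocab = Vocabulary(("A", "B", "C"), "all", 1, 0.0)
        fm = tfidf_matrix(toy_corpus, vocab, normalize=False)
        col_a = np.asarray(fm.values.todense())[:, 0]
        assert np.allclose(col_a, 0.0)  # A in all 3 docs: idf = ln(3/3) = 0

    def test_hand_computed_weight(self, toy_corpus):
        vocab = Vocabulary(("A", "B", "C"), "all", 1, 0.0)
        fm = tfidf_matrix(toy_corpus, vocab, normalize=False)
        dense = np.asarray(fm.values.todense())
        assert dense[2, 1] == pytest.approx(2 * math.log(3 / 2), abs=1e-12)

    def test_matches_brute_force_oracle(self, toy_corpus):
        vocab = Vocabulary(("A", "B", "C"), "all", 1, 0.0)
        fm = tfidf_matrix(toy_corpus, vocab)
        np.testing.assert_allclose(np.asarray(fm.values.todense()),
                                   brute_force_tfidf(toy_corpus, vocab.terms),
                                   atol=1e-10)

    def test_rows_unit_norm_unless_zero(self, toy_corpus):
        vocab = Vocabulary(("B", "C"), "all", 1, 0.0)
        corpus = toy_corpus + [["A"]]  # doc with only OOV token
        fm = tfidf_matrix(corpus, vocab, fit_corpus=toy_corpus)
        norms = np.sqrt(np.asarray(fm.values.multiply(fm.values).sum(axis=1))
                        ).ravel()
        for nrm in norms:
            assert nrm == pytest.approx(1.0, abs=1e-12) or nrm == 0.0

    def test_frequent_word_downweighted_vs_rare_at_equal_tf(self):
        corpus = [["SHOT", "CLEANING"]] + [["SHOT"]] * 9
        vocab = Vocabulary(("CLEANING", "SHOT"), "all", 1, 0.0)
        fm = tfidf_matrix(corpus, vocab, normalize=False)
        dense = np.asarray(fm.values.todense())
        assert dense[0, 0] > dense[0, 1]  # CLEANING outweighs ubiquitous SHOT

    def test_frozen_df_applied_to_new_documents(self, toy_corpus):
        vocab = Vocabulary(("A", "B", "C"), "all", 1, 0.0)
        w = TfidfWeighter(vocab, normalize=False).fit(toy_corpus)
        fm = w.transform([["B", "B", "B"]])
        dense = np.asarray(fm.values.todense())
        assert dense[0, 1] == pytest.approx(3 * math.log(3 / 2), abs=1e-12)

    def test_unseen_in_vocab_term_gets_ln_n_idf(self, toy_corpus):
        vocab = Vocabulary(("A", "B", "Z"), "all", 1, 0.0)
        w = TfidfWeighter(vocab, normalize=False).fit(toy_corpus)
        fm = w.transform([["Z"]])
        dense = np.asarray(fm.values.todense())
        assert dense[0, 2] == pytest.approx(math.log(3), abs=1e-12)

    def test_row_order_follows_input_order(self, toy_corpus):
        vocab = Vocabulary(("A", "B", "C"), "all", 1, 0.0)
        fm = tfidf_matrix(toy_corpus, vocab)
        rev = tfidf_matrix(toy_corpus[::-1], vocab, fit_corpus=toy_corpus)
        np.testing.assert_allclose(np.asarray(fm.values.todense())[::-1],
                                   np.asarray(rev.values.todense()), atol=1e-12)


# ---------------------------------------------------------------- n-grams

class TestNgrams:
    def test_adjacent_bigrams_present(self):
        corpus = [["A", "B", "C"]] * 3
        expanded = [add_ngrams(d) for d in corpus]
        vocab = build_vocabulary(expanded, expanded, "shared", min_count=1)
        fm = ngram_matrix(corpus, vocab)
        assert "A_B" in fm.feature_names and "B_C" in fm.feature_names

    def test_unigram_range_reduces_to_tfidf(self, toy_corpus):
        vocab = Vocabulary(("A", "B", "C"), "all", 1, 0.0)
        fm1 = ngram_matrix(toy_corpus, vocab, n_range=(1, 1))
        fm2 = tfidf_matrix(toy_corpus, vocab)
        assert fm1.feature_names == fm2.feature_names
        np.testing.assert_allclose(np.asarray(fm1.values.todense()),
                                   np.asarray(fm2.values.todense()), atol=1e-12)

    def test_bigram_counts_match_sliding_window_oracle(self):
        rng = np.random.default_rng(0)
        corpus = [[rng.choice(["A", "B", "C", "D"]) for _ in range(8)]
                  for _ in range(10)]
        expanded = [add_ngrams(doc) for doc in corpus]
        vocab = build_vocabulary(expanded, expanded, "all", min_count=1)
        fm = ngram_matrix(corpus, vocab, fit_corpus=corpus)
        # undo the idf/norm: recompute raw counts with the oracle instead
        dense_counts = np.zeros((10, len(vocab)))
        idx = vocab.index
        for r, doc in enumerate(corpus):
            for (a, b), c in brute_force_bigram_counts(doc).items():
                dense_counts[r, idx[f"{a}_{b}"]] = c
        raw = tfidf_matrix(expanded, vocab, normalize=False)
        N = len(corpus)
        df = np.asarray([sum(t in d for d in expanded) for t in vocab.terms],
                        float)
        expected = dense_counts * np.log(N / df)[None, :]
        got = np.asarray(raw.values.todense())
        bigram_cols = [i for i, t in enumerate(vocab.terms) if "_" in t]
        np.testing.assert_allclose(got[:, bigram_cols],
                                   expected[:, bigram_cols], atol=1e-10)


# -------------------------------------------------------------- embeddings

@pytest.fixture(scope="module")
def glove():
    rng = np.random.default_rng(1)
    # PAIRED always co-occurs with BUDDY; LONER never meets them
    corpus = []
    for _ in range(300):
        if rng.random() < 0.5:
            corpus.append(["PAIRED", "BUDDY", "FILL", "STUFF"])
        else:
            corpus.append(["LONER", "FILL", "STUFF", "MORE"])
    vocab = Vocabulary(tuple(sorted({t for d in corpus for t in d})),
                       "all", 1, 0.0)
    model = GloveModel(vocab, dim=12, epochs=30, seed=7).fit(corpus)
    return model, corpus


class TestEmbeddings:

    def test_single_token_doc_equals_word_vector(self, glove):
        model, _ = glove
        fm = model.transform([["PAIRED"]])
        np.testing.assert_allclose(fm.values[0], model.word_vector("PAIRED"))

    def test_identical_multisets_identical_rows(self, glove):
        model, _ = glove
        fm = model.transform([["FILL", "STUFF", "FILL"],
                              ["STUFF", "FILL", "FILL"]])
        np.testing.assert_allclose(fm.values[0], fm.values[1])

    def test_cooccurring_tokens_more_similar_than_strangers(self, glove):
        model, _ = glove
        def cos(a, b):
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        paired = cos(model.word_vector("PAIRED"), model.word_vector("BUDDY"))
        stranger = cos(model.word_vector("PAIRED"), model.word_vector("LONER"))
        assert paired > stranger

    def test_deterministic_given_seed(self, glove):
        model, corpus = glove
        again = GloveModel(model.vocab, dim=12, epochs=30, seed=7).fit(corpus)
        np.testing.assert_allclose(model.vectors_, again.vectors_)

    def test_zero_vector_for_all_oov_doc(self, glove):
        model, _ = glove
        fm = model.transform([["NOTINVOCAB"]])
        np.testing.assert_allclose(fm.values[0], 0.0)


def test_feature_matrix_invariants():
    with pytest.raises(ValueError, match="non-finite"):
        FeatureMatrix(np.array([[np.nan]]), ("a",), ("r",), "tfidf")
    with pytest.raises(ValueError, match="duplicate"):
        FeatureMatrix(np.zeros((1, 2)), ("a", "a"), ("r",), "tfidf")
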