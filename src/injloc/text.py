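"""Narrative tokenization, vocabulary filtering, and predictor construction.

Three predictor families are built from coder narratives:

* TF-IDF — term frequency times ln(N/df) inverse document frequency, with
  document frequencies frozen from the fitting corpus and rows
  L2-normalized.  No smoothing: a term in every fitting document gets idf
  exactly 0.
* n-grams — unigrams plus adjacent bigrams, passed through the same
  frequency filters and TF-IDF weighting.
* word embeddings — dense vectors trained on the corpus's own token
  co-occurrence by the GloVe weighted least-squares objective, with each
  document represented as the unweighted mean of its in-vocabulary token
  vectors.

Vocabularies come in two scopes: "all" (union of terms surviving the
frequency filters in the missing-location and nonmissing-location corpora)
and "shared" (intersection).  Shared-scope features guarantee the model's
columns exist in both domains, which is the robustness-to-selection device
the downstream classifier relies on.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

NUM_TOKEN = "<NUM>"
_DIGIT_RUN = re.compile(r"[0-9]+")
_TOKEN = re.compile(r"[A-Z\x00]+")


def tokenize(narrative: str) -> list[str]:
    """Uppercase, collapse digit runs to a placeholder, strip punctuation.

    ``"24YOM SHOT IN LEG"`` → ``["<NUM>YOM", "SHOT", "IN", "LEG"]``.
    Alphabetic runs are kept in order; digits never enter the vocabulary
    (so patient ages cannot leak as features).
    """
    if not narrative or not narrative.strip():
        raise ValueError("narrative is empty after whitespace strip")
    s = _DIGIT_RUN.sub("\x00", narrative.upper())
    return [t.replace("\x00", NUM_TOKEN) for t in _TOKEN.findall(s)]


def add_ngrams(tokens: list[str], n_range: tuple[int, int] = (1, 2)) -> list[str]:
    """Expand a token sequence with its contiguous n-grams (joined by '_')."""
    lo, hi = n_range
    out: list[str] = []
    for n in range(lo, hi + 1):
        if n == 1:
            out.extend(tokens)
        else:
            out.extend("_".join(tokens[i:i + n]) for i in range(len(tokens) - n + 1))
    return out


@dataclass(frozen=True)
class Vocabulary:
    """Ordered, filtered token inventory.

    ``scope="all"`` is the union of both corpora's surviving terms,
    ``scope="shared"`` the intersection; a term survives in a corpus iff
    its total count ≥ ``min_count`` AND its document fraction ≥
    ``min_doc_fraction``.  Terms are sorted for determinism.
    """

    terms: tuple[str, ...]
    scope: str
    min_count: int
    min_doc_fraction: float
    source_sizes: tuple[int, int] = (0, 0)  # (missing-corpus, nonmissing-corpus)

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in vocabulary")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}


def _surviving_terms(corpus: list[list[str]], min_count: int,
                     min_doc_fraction: float) -> set[str]:
    totals: Counter = Counter()
    doc_freq: Counter = Counter()
    for doc in corpus:
        totals.update(doc)
        doc_freq.update(set(doc))
    n_docs = len(corpus)
    return {
        t for t in totals
        if totals[t] >= min_count and doc_freq[t] / n_docs >= min_doc_fraction
    }


def build_vocabulary(missing_corpus: list[list[str]],
                     nonmissing_corpus: list[list[str]],
                     scope: str = "shared",
                     min_count: int = 10,
                     min_doc_fraction: float = 0.0) -> Vocabulary:
    """Build a filtered vocabulary from the two location-status corpora."""
    if not missing_corpus or not nonmissing_corpus:
        raise ValueError("both corpora must be non-empty")
    if scope not in ("shared", "all"):
        raise ValueError(f"scope must be 'shared' or 'all', got {scope!r}")
    surv_m = _surviving_terms(missing_corpus, min_count, min_doc_fraction)
    surv_nm = _surviving_terms(nonmissing_corpus, min_count, min_doc_fraction)
    terms = surv_m & surv_nm if scope == "shared" else surv_m | surv_nm
    return Vocabulary(tuple(sorted(terms)), scope, min_count, min_doc_fraction,
                      source_sizes=(len(surv_m), len(surv_nm)))


@dataclass
class FeatureMatrix:
    """records × features numeric matrix with named columns."""

    values: sp.csr_matrix | np.ndarray
    feature_names: tuple[str, ...]
    record_ids: tuple[str, ...]
    construction: str  # tfidf | ngram | embedding

    def __post_init__(self):
        if self.values.shape != (len(self.record_ids), len(self.feature_names)):
            raise ValueError("shape does not match names/ids")
        data = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(data)):
            raise ValueError("non-finite feature values")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _count_matrix(corpus: list[list[str]], vocab: Vocabulary) -> sp.csr_matrix:
    index = vocab.index
    indptr, indices, data = [0], [], []
    for doc in corpus:
        counts = Counter(index[t] for t in doc if t in index)
        indices.extend(counts.keys())
        data.extend(counts.values())
        indptr.append(len(indices))
    return sp.csr_matrix((np.asarray(data, float), indices, indptr),
                         shape=(len(corpus), len(vocab)))


class TfidfWeighter:
    """TF-IDF transform with document frequencies frozen at fit time.

    entry(d, t) = tf(t, d) · ln(N / df(t)); rows L2-normalized afterwards
    (all-zero rows stay zero).  An in-vocabulary term never seen in the
    fitting corpus is given idf ln(N/1) and logged.
    """

    def __init__(self, vocab: Vocabulary, normalize: bool = True,
                 smooth_idf: bool = False):
        self.vocab = vocab
        self.normalize = normalize
        self.smooth_idf = smooth_idf
        self.df_: np.ndarray | None = None
        self.n_docs_: int | None = None

    def fit(self, corpus: list[list[str]]) -> "TfidfWeighter":
        counts = _count_matrix(corpus, self.vocab)
        self.df_ = np.asarray((counts > 0).sum(axis=0)).ravel().astype(float)
        self.n_docs_ = len(corpus)
        return self

    def transform(self, corpus: list[list[str]],
                  record_ids: list[str] | None = None) -> FeatureMatrix:
        if self.df_ is None:
            raise RuntimeError("fit before transform")
        counts = _count_matrix(corpus, self.vocab)
        df = self.df_.copy()
        unseen = df == 0
        if unseen.any():
            logger.info("%d in-vocab terms unseen in fitting corpus; df treated as 1",
                        int(unseen.sum()))
            df[unseen] = 1.0
        if self.smooth_idf:
            idf = np.log((1.0 + self.n_docs_) / (1.0 + df)) + 1.0
        else:
            idf = np.log(self.n_docs_ / df)
        mat = counts.multiply(idf[np.newaxis, :]).tocsr()
        if self.normalize:
            norms = np.sqrt(np.asarray(mat.multiply(mat).sum(axis=1)).ravel())
            norms[norms == 0] = 1.0
            mat = sp.diags(1.0 / norms) @ mat
        ids = tuple(record_ids) if record_ids is not None else tuple(
            str(i) for i in range(len(corpus)))
        return FeatureMatrix(mat.tocsr(), tuple(self.vocab.terms), ids, "tfidf")


def tfidf_matrix(corpus: list[list[str]], vocab: Vocabulary,
                 fit_corpus: list[list[str]] | None = None,
                 record_ids: list[str] | None = None,
                 normalize: bool = True) -> FeatureMatrix:
    """One-shot TF-IDF: fit document frequencies (on ``fit_corpus`` if
    given, else on ``corpus`` itself) and transform ``corpus``."""
    w = TfidfWeighter(vocab, normalize=normalize).fit(fit_corpus or corpus)
    return w.transform(corpus, record_ids)


def ngram_matrix(corpus: list[list[str]], vocab: Vocabulary,
                 n_range: tuple[int, int] = (1, 2),
                 fit_corpus: list[list[str]] | None = None,
                 record_ids: list[str] | None = None) -> FeatureMatrix:
    """TF-IDF over unigram+bigram features.

    ``vocab`` must have been built from n-gram-expanded corpora (use
    :func:`add_ngrams`); the same frequency filters and TF-IDF weighting
    apply as for plain words.
    """
    expanded = [add_ngrams(doc, n_range) for doc in corpus]
    fit_expanded = ([add_ngrams(doc, n_range) for doc in fit_corpus]
                    if fit_corpus is not None else expanded)
    fm = tfidf_matrix(expanded, vocab, fit_corpus=fit_expanded,
                      record_ids=record_ids)
    return FeatureMatrix(fm.values, fm.feature_names, fm.record_ids, "ngram")


# --------------------------------------------------------------------------
# GloVe: weighted least-squares factorization of the log co-occurrence
# matrix, trained full-batch with AdaGrad.  Window 5 symmetric with 1/d
# distance weighting; f(x) = min(1, (x/x_max)^alpha).
# --------------------------------------------------------------------------

class GloveModel:
    def __init__(self, vocab: Vocabulary, dim: int = 50, window: int = 5,
                 epochs: int = 15, x_max: float = 10.0, alpha: float = 0.75,
                 learning_rate: float = 0.05, seed: int = 0):
        self.vocab = vocab
        self.dim = dim
        self.window = window
        self.epochs = epochs
        self.x_max = x_max
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.seed = seed
        self.vectors_: np.ndarray | None = None

    def _cooccurrence(self, corpus: list[list[str]]):
        index = self.vocab.index
        cooc: dict[tuple[int, int], float] = {}
        for doc in corpus:
            ids = [index[t] for t in doc if t in index]
            for a in range(len(ids)):
                for b in range(a + 1, min(a + 1 + self.window, len(ids))):
                    w = 1.0 / (b - a)
                    i, j = ids[a], ids[b]
                    cooc[(i, j)] = cooc.get((i, j), 0.0) + w
                    cooc[(j, i)] = cooc.get((j, i), 0.0) + w
        return cooc

    def fit(self, corpus: list[list[str]]) -> "GloveModel":
        if len(corpus) < 1:
            raise ValueError("empty corpus")
        cooc = self._cooccurrence(corpus)
        V, d = len(self.vocab), self.dim
        if not cooc:
            self.vectors_ = np.zeros((V, d))
            return self
        keys = sorted(cooc)
        rows = np.fromiter((k[0] for k in keys), int, len(keys))
        cols = np.fromiter((k[1] for k in keys), int, len(keys))
        X = np.fromiter((cooc[k] for k in keys), float, len(keys))
        fX = np.minimum(1.0, (X / self.x_max) ** self.alpha)
        logX = np.log(X)

        rng = np.random.default_rng(self.seed)
        W = (rng.random((V, d)) - 0.5) / d
        Wc = (rng.random((V, d)) - 0.5) / d
        b = np.zeros(V)
        bc = np.zeros(V)
        gW = np.ones((V, d)); gWc = np.ones((V, d))
        gb = np.ones(V); gbc = np.ones(V)
        lr = self.learning_rate
        for _ in range(self.epochs):
            diff = (W[rows] * Wc[cols]).sum(axis=1) + b[rows] + bc[cols] - logX
            fdiff = fX * diff
            grad_w = fdiff[:, None] * Wc[cols]
            grad_wc = fdiff[:, None] * W[rows]
            dW = np.zeros_like(W); dWc = np.zeros_like(Wc)
            db = np.zeros_like(b); dbc = np.zeros_like(bc)
            np.add.at(dW, rows, grad_w)
            np.add.at(dWc, cols, grad_wc)
            np.add.at(db, rows, fdiff)
            np.add.at(dbc, cols, fdiff)
            W -= lr * dW / np.sqrt(gW)
            Wc -= lr * dWc / np.sqrt(gWc)
            b -= lr * db / np.sqrt(gb)
            bc -= lr * dbc / np.sqrt(gbc)
            gW += dW ** 2; gWc += dWc ** 2
            gb += db ** 2; gbc += dbc ** 2
        self.vectors_ = W + Wc  # standard GloVe sum of the two factors
        return self

    def word_vector(self, term: str) -> np.ndarray:
        return self.vectors_[self.vocab.index[term]]

    def transform(self, corpus: list[list[str]],
                  record_ids: list[str] | None = None) -> FeatureMatrix:
        if self.vectors_ is None:
            raise RuntimeError("fit before transform")
        index = self.vocab.index
        out = np.zeros((len(corpus), self.dim))
        n_empty = 0
        for r, doc in enumerate(corpus):
            ids = [index[t] for t in doc if t in index]
            if ids:
                out[r] = self.vectors_[ids].mean(axis=0)
            else:
                n_empty += 1
        if n_empty:
            logger.info("%d documents had no in-vocab tokens (zero vectors)", n_empty)
        names = tuple(f"emb_{k}" for k in range(self.dim))
        ids_ = tuple(record_ids) if record_ids is not None else tuple(
            str(i) for i in range(len(corpus)))
        return FeatureMatrix(out, names, ids_, "embedding")


def embedding_matrix(corpus: list[list[str]], vocab: Vocabulary,
                     dim: int = 50, seed: int = 0,
                     fit_corpus: list[list[str]] | None = None,
                     record_ids: list[str] | None = None,
                     **glove_kwargs) -> FeatureMatrix:
    """Train GloVe on ``fit_corpus`` (default: ``corpus``) and return mean
    word-vector document representations of ``corpus``."""
    model = GloveModel(vocab, dim=dim, seed=seed, **glove_kwargs)
    model.fit(fit_corpus or corpus)
    return model.transform(corpus, record_ids)


def save_word_vectors(model: GloveModel, path) -> None:
    """Plain-text word-vector format: token then dim floats per line."""
    with open(path, "w") as fh:
        for term in model.vocab.terms:
            vec = " ".join(f"{v:.6f}" for v in model.word_vector(term))
            fh.write(f"{term} {vec}\n")
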