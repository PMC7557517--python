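"""Selection diagnostics: are the missing-location and nonmissing-location
narratives drawn from the same language?

Two corpus-level checks — Spearman correlation of ranked word frequencies
over the top-k terms, and the count of top-k terms unique to one corpus —
quantify how far the missing-location text drifts from the labeled text
(severe drift would undermine a classifier trained only on labeled
records).  A third, model-level view extracts the words with the largest
fitted coefficients per location class from the sparse multinomial model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harness import FittedModel
from .text import Vocabulary


@dataclass
class RankedFrequencyList:
    """In-vocabulary terms ordered by descending corpus frequency; ties
    break lexicographically so the ranking is deterministic."""

    terms: tuple[str, ...]
    frequencies: tuple[int, ...]
    corpus_label: str = ""

    def __post_init__(self):
        freqs = np.asarray(self.frequencies)
        if len(freqs) > 1 and (np.diff(freqs) > 0).any():
            raise ValueError("frequencies must be non-increasing")

    def rank_of(self) -> dict[str, int]:
        """1-based rank per term."""
        return {t: i + 1 for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)


def rank_word_frequencies(corpus: list[list[str]], vocab: Vocabulary,
                          corpus_label: str = "") -> RankedFrequencyList:
    """Rank in-vocabulary terms by total count, descending."""
    terms_set = set(vocab.terms)
    counts: Counter = Counter()
    for doc in corpus:
        counts.update(t for t in doc if t in terms_set)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedFrequencyList(tuple(t for t, _ in ordered),
                               tuple(c for _, c in ordered), corpus_label)


def spearman_rank_correlation(list_a: RankedFrequencyList,
                              list_b: RankedFrequencyList,
                              top_k: int = 200,
                              unshared: str = "append",
                              ) -> tuple[float, float]:
    """Spearman rho (and two-tailed p, t-approximation) between the ranks
    of list_a's top-k terms in the two corpora.

    Terms absent from list_b get rank ``len(list_b) + 1`` when
    ``unshared="append"`` (default) or are dropped when
    ``unshared="drop"``.
    """
    k = min(top_k, len(list_a))
    top = list_a.terms[:k]
    ranks_b_map = list_b.rank_of()
    ranks_a, ranks_b = [], []
    for i, t in enumerate(top):
        if t in ranks_b_map:
            ranks_b.append(ranks_b_map[t])
        elif unshared == "append":
            ranks_b.append(len(list_b) + 1)
        else:
            continue
        ranks_a.append(i + 1)
    if len(ranks_a) < 2:
        raise ValueError("fewer than 2 comparable terms")
    rho, p = stats.spearmanr(ranks_a, ranks_b)
    return float(rho), float(p)


def top_word_overlap(list_a: RankedFrequencyList, list_b: RankedFrequencyList,
                     k: int) -> int:
    """Number of list_a's top-k terms absent from list_b's top-k."""
    if len(list_a) < k or len(list_b) < k:
        raise ValueError(f"both lists must have at least k={k} terms")
    return len(set(list_a.terms[:k]) - set(list_b.terms[:k]))


def influential_words(model: FittedModel, location_class: str,
                      top_n: int = 10) -> pd.DataFrame:
    """Top-n words by |fitted coefficient| for one location class.

    Requires a sparse multinomial model over named word features (TF-IDF
    or n-grams); zero coefficients are never padded in.
    """
    coefs = model.linear_coefficients().loc[location_class]
    nz = coefs[coefs != 0.0]
    order = nz.abs().sort_values(ascending=False, kind="stable")
    top = order.index[:top_n]
    return pd.DataFrame({"term": top, "coefficient": nz.loc[top].to_numpy()})


def diagnostics_summary(list_missing: RankedFrequencyList,
                        list_nonmissing: RankedFrequencyList,
                        top_k: int = 200) -> dict:
    """Bundle the corpus-drift diagnostics into one dict."""
    k = min(top_k, len(list_missing), len(list_nonmissing))
    rho, p = spearman_rank_correlation(list_missing, list_nonmissing, k)
    return {
        "top_k": k,
        "spearman_rho": rho,
        "spearman_p": p,
        "unique_to_missing": top_word_overlap(list_missing, list_nonmissing, k),
        "unique_to_nonmissing": top_word_overlap(list_nonmissing, list_missing, k),
    }
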