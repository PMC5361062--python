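"""Small TF-IDF helpers shared by the language-distance analyses.

The analyses fix a specific convention — raw term counts, inverse document
frequency ``idf(w) = ln(N / df(w))`` with no smoothing (documents never have
zero df for observed words), and L2 normalization before cosine — so these
helpers implement exactly that on scipy sparse matrices.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp


def bigrams(tokens: Sequence[str]) -> list[str]:
    """Adjacent token pairs joined with a space; empty for < 2 tokens."""
    return [f"{a} {b}" for a, b in zip(tokens, tokens[1:])]


def ngram_terms(tokens: Sequence[str], n: int) -> list[str]:
    if n == 1:
        return list(tokens)
    if n == 2:
        return bigrams(tokens)
    raise ValueError("only unigrams and bigrams are supported")


def ln_idf(docs: Iterable[Iterable[str]]) -> dict[str, float]:
    """idf(w) = ln(N / df(w)) over the given documents (no smoothing)."""
    df: Counter = Counter()
    n_docs = 0
    for doc in docs:
        n_docs += 1
        df.update(set(doc))
    if n_docs == 0:
        raise ValueError("idf requires a nonempty document collection")
    return {w: math.log(n_docs / c) for w, c in df.items()}


def count_matrix(
    docs: Sequence[Sequence[str]],
    vocab: dict[str, int] | None = None,
) -> tuple[sp.csr_matrix, dict[str, int]]:
    """Sparse document-term raw-count matrix; builds the vocab if not given."""
    if vocab is None:
        vocab = {}
        for doc in docs:
            for t in doc:
                if t not in vocab:
                    vocab[t] = len(vocab)
    rows, cols, vals = [], [], []
    for i, doc in enumerate(docs):
        c = Counter(t for t in doc if t in vocab)
        for t, v in c.items():
            rows.append(i)
            cols.append(vocab[t])
            vals.append(v)
    mat = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(docs), len(vocab)), dtype=float
    )
    return mat, vocab


def l2_normalize(mat: sp.csr_matrix) -> sp.csr_matrix:
    norms = np.sqrt(mat.multiply(mat).sum(axis=1)).A1
    norms[norms == 0.0] = 1.0
    return sp.diags(1.0 / norms) @ mat


def tfidf_matrix(
    docs: Sequence[Sequence[str]],
    n: int = 1,
    idf_offset: float = 1.0,
) -> tuple[sp.csr_matrix, dict[str, int]]:
    """L2-normalized TF-IDF rows over the docs' own n-gram collection.

    idf is ``ln(N/df) + idf_offset``; the default offset of 1 keeps terms
    shared by every document (idf 0) from vanishing, so two identical
    documents are at cosine distance 0 rather than degenerating to zero
    vectors.
    """
    terms = [ngram_terms(d, n) for d in docs]
    counts, vocab = count_matrix(terms)
    idf = ln_idf(terms)
    idf_vec = np.zeros(len(vocab))
    for w, i in vocab.items():
        idf_vec[i] = idf[w] + idf_offset
    return l2_normalize(counts @ sp.diags(idf_vec)), vocab


def cosine_similarity_rows(mat: sp.csr_matrix) -> np.ndarray:
    """Dense pairwise cosine similarity of already-normalized rows."""
    return np.asarray((mat @ mat.T).todense())


def cosine(u: dict[str, float], v: dict[str, float]) -> float:
    """Cosine similarity of two sparse dict vectors (0 if either is empty)."""
    nu = math.sqrt(sum(x * x for x in u.values()))
    nv = math.sqrt(sum(x * x for x in v.values()))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    dot = sum(x * v[w] for w, x in u.items() if w in v)
    return dot / (nu * nv)
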