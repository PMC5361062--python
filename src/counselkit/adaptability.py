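"""Counselor adaptability: language divergence across outcomes over time.

For each counselor group (more vs less successful), each conversation is cut
into five even message chunks and a TF-IDF vector of the counselor tokens in
each (outcome, chunk) cell is built — raw counts weighted so every counselor
contributes equally (each conversation scaled by 1 / that counselor's
conversation count in the cell), multiplied by global inverse *conversation*
frequencies, and L2 normalized.  The adaptability curve is the cosine
distance between the positive and negative vectors per chunk; a counselor
group that senses when a conversation goes badly and reacts shows a distance
that grows with conversation time.

Confidence intervals come from a member bootstrap: counselors are resampled
with replacement and the whole statistic recomputed.  A permuted-outcome null
(outcome labels shuffled across the group's conversations) gives the
distances expected with no outcome-dependent language at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .corpus import (COUNSELOR, NEGATIVE, POSITIVE, Conversation,
                     CounselorSplit, chunk_messages)
from .vectorize import ln_idf


def global_idf(convs: list[Conversation]) -> dict[str, float]:
    """idf(w) = ln(N / df(w)) with conversations as documents."""
    if not convs:
        raise ValueError("idf requires a nonempty corpus")
    return ln_idf([{t for m in c.messages for t in m.tokens} for c in convs])


@dataclass
class GroupChunkVector:
    """TF-IDF vector of one (group, outcome, chunk) cell."""

    group: str
    outcome: str
    chunk: int
    weights: dict[str, float]
    empty: bool

    def norm(self) -> float:
        return math.sqrt(sum(v * v for v in self.weights.values()))


@dataclass
class AdaptabilityCurve:
    group: str
    distances: list[float]
    ci: list[tuple[float, float]]


def _corpus_vocab(convs: list[Conversation]) -> dict[str, int]:
    vocab: dict[str, int] = {}
    for c in convs:
        for m in c.messages:
            for t in m.tokens:
                if t not in vocab:
                    vocab[t] = len(vocab)
    return vocab


def _idf_vector(idf: dict[str, float], vocab: dict[str, int]) -> np.ndarray:
    v = np.zeros(len(vocab))
    for w, i in vocab.items():
        v[i] = idf.get(w, 0.0)
    return v


class _GroupCounts:
    """Per-conversation, per-chunk token counts for one counselor group.

    Counting happens once; cell vectors for any outcome labeling, counselor
    bootstrap multiplicity, or permuted labels are then pure array work.
    """

    def __init__(
        self,
        convs: list[Conversation],
        members: list[str],
        n_chunks: int,
        role: str,
        vocab: dict[str, int],
    ):
        self.members = members
        self.n_chunks = n_chunks
        c_index = {c: i for i, c in enumerate(members)}
        group_convs = [
            c for c in convs if c.labeled and c.counselor_id in c_index
        ]
        self.conv_ids = [c.conv_id for c in group_convs]
        self.counselor_of = np.array(
            [c_index[c.counselor_id] for c in group_convs], dtype=np.intp
        )
        self.labels = np.array(
            [c.outcome == POSITIVE for c in group_convs], dtype=bool
        )
        n_convs, n_v = len(group_convs), len(vocab)
        self.counts = np.zeros((n_convs, n_chunks, n_v))
        for i, conv in enumerate(group_convs):
            for ch, msgs in enumerate(chunk_messages(conv, n_chunks)):
                row = self.counts[i, ch]
                for m in msgs:
                    if m.role == role:
                        for t in m.tokens:
                            row[vocab[t]] += 1

    def counselor_cell_matrix(
        self, chunk: int, positive: bool, labels: np.ndarray | None = None
    ) -> np.ndarray:
        """(counselor, vocab) matrix of counselor-equalized counts for a cell."""
        labels = self.labels if labels is None else labels
        sel = np.flatnonzero(labels == positive)
        n_c = len(self.members)
        mat = np.zeros((n_c, self.counts.shape[2]))
        np.add.at(mat, self.counselor_of[sel], self.counts[sel, chunk])
        n_convs = np.bincount(self.counselor_of[sel], minlength=n_c).astype(float)
        n_convs[n_convs == 0.0] = 1.0
        return mat / n_convs[:, None]

    @staticmethod
    def normalize(v: np.ndarray, idf_vec: np.ndarray) -> np.ndarray:
        v = v * idf_vec
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    def distances(
        self,
        idf_vec: np.ndarray,
        labels: np.ndarray | None = None,
        multiplicity: np.ndarray | None = None,
        strict: bool = True,
    ) -> list[float]:
        out = []
        for ch in range(self.n_chunks):
            vecs = {}
            for positive in (True, False):
                m = self.counselor_cell_matrix(ch, positive, labels)
                v = m.sum(axis=0) if multiplicity is None else multiplicity @ m
                vecs[positive] = self.normalize(v, idf_vec)
            if not vecs[True].any() or not vecs[False].any():
                if strict:
                    which = "positive" if not vecs[True].any() else "negative"
                    raise ValueError(
                        f"empty language vector in cell (chunk={ch}, outcome={which})"
                    )
                out.append(float("nan"))
                continue
            out.append(float(1.0 - vecs[True] @ vecs[False]))
        return out


def _prepare(
    convs: list[Conversation],
    split: CounselorSplit,
    group: str,
    n_chunks: int,
    role: str,
    idf: dict[str, float] | None,
) -> tuple[_GroupCounts, np.ndarray]:
    if idf is None:
        idf = global_idf(convs)
    vocab = _corpus_vocab(convs)
    counts = _GroupCounts(
        convs, sorted(split.group_members(group)), n_chunks, role, vocab
    )
    idf_vec = _idf_vector(idf, vocab)
    counts._vocab = vocab  # kept for dict-vector export
    return counts, idf_vec


def group_chunk_vector(
    convs: list[Conversation],
    split: CounselorSplit,
    group: str,
    outcome: str,
    chunk: int,
    n_chunks: int = 5,
    idf: dict[str, float] | None = None,
    role: str = COUNSELOR,
) -> GroupChunkVector:
    """TF-IDF vector of one (group, outcome, chunk) cell as a word→weight map."""
    counts, idf_vec = _prepare(convs, split, group, n_chunks, role, idf)
    mat = counts.counselor_cell_matrix(chunk, outcome == POSITIVE)
    vec = counts.normalize(mat.sum(axis=0), idf_vec)
    weights = {w: float(vec[i]) for w, i in counts._vocab.items() if vec[i] != 0.0}
    return GroupChunkVector(
        group=group, outcome=outcome, chunk=chunk,
        weights=weights, empty=not weights,
    )


def adaptability_curve(
    convs: list[Conversation],
    split: CounselorSplit,
    group: str,
    n_chunks: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
    role: str = COUNSELOR,
    idf: dict[str, float] | None = None,
) -> AdaptabilityCurve:
    """Per-chunk cosine distance between positive and negative language.

    Bootstrap CIs resample the group's counselors with replacement
    (percentile 95% interval over ``n_boot`` resamples).
    """
    counts, idf_vec = _prepare(convs, split, group, n_chunks, role, idf)
    point = counts.distances(idf_vec)
    rng = np.random.default_rng(seed)
    n_c = len(counts.members)
    boots = np.empty((n_boot, n_chunks))
    for b in range(n_boot):
        idx = rng.integers(0, n_c, size=n_c)
        mult = np.bincount(idx, minlength=n_c).astype(float)
        boots[b] = counts.distances(idf_vec, multiplicity=mult, strict=False)
    lo = np.nanpercentile(boots, 2.5, axis=0)
    hi = np.nanpercentile(boots, 97.5, axis=0)
    return AdaptabilityCurve(
        group=group,
        distances=point,
        ci=[(float(a), float(b)) for a, b in zip(lo, hi)],
    )


def adaptability_null(
    convs: list[Conversation],
    split: CounselorSplit,
    group: str,
    n_chunks: int = 5,
    n_perm: int = 200,
    seed: int = 0,
    role: str = COUNSELOR,
    idf: dict[str, float] | None = None,
) -> list[tuple[float, float]]:
    """Per-chunk 95% interval of distances with outcome labels permuted.

    Outcomes are shuffled across the group's labeled conversations (keeping
    overall positive/negative counts), breaking any outcome-language link
    while preserving corpus composition.
    """
    counts, idf_vec = _prepare(convs, split, group, n_chunks, role, idf)
    if counts.labels.size == 0:
        raise ValueError(f"no labeled conversations for group {group}")
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_chunks))
    for p in range(n_perm):
        labels = rng.permutation(counts.labels)
        null[p] = counts.distances(idf_vec, labels=labels, strict=False)
    lo = np.nanpercentile(null, 2.5, axis=0)
    hi = np.nanpercentile(null, 97.5, axis=0)
    return [(float(a), float(b)) for a, b in zip(lo, hi)]
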