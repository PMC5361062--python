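"""Ambiguity analyses: situation setters, setter clustering, response classes.

Ambiguity is measured as the shortness of the texter's *situation setter* —
the first long texter message, where the texter first explains why they are
texting in.  The analyses here cover: how setter length relates to the
conversation outcome, how much counselors write back relative to the setter,
nearest-neighbor clustering of near-identical setters in bigram TF-IDF space
(so counselor reactions to nearly identical situations can be compared),
pattern-based classification of counselor responses (check questions,
suicide checks, thanks, hedges, surprise), and a templatedness count — the
number of near-duplicate counselor responses, whose inverse proxies
creativity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus import COUNSELOR, POSITIVE, TEXTER, Conversation
from .lexicons import RESPONSE_PATTERNS, compile_patterns
from .vectorize import cosine_similarity_rows, tfidf_matrix


@dataclass
class SituationSetter:
    """The first long texter message of a conversation."""

    conv_id: str
    message_index: int
    n_tokens: int
    tokens: list[str]
    text: str


def find_situation_setter(
    conv: Conversation, min_tokens: int = 10
) -> Optional[SituationSetter]:
    """Earliest texter message with at least ``min_tokens`` tokens."""
    if min_tokens < 1:
        raise ValueError("min_tokens must be >= 1")
    for m in conv.messages:
        if m.role == TEXTER and m.n_tokens >= min_tokens:
            return SituationSetter(
                conv_id=conv.conv_id, message_index=m.index,
                n_tokens=m.n_tokens, tokens=list(m.tokens), text=m.text,
            )
    return None


@dataclass
class BinnedFractions:
    """Per-bin positive-outcome fraction with a normal-approximation CI."""

    bin_edges: list[float]
    fraction_positive: list[float]  # NaN where the bin is empty
    ci: list[tuple[float, float]]
    counts: list[int]

    @property
    def empty_bins(self) -> list[int]:
        return [i for i, n in enumerate(self.counts) if n == 0]


def ambiguity_outcome_table(
    convs: Sequence[Conversation],
    setter_len_bins: Sequence[float],
    min_tokens: int = 10,
) -> BinnedFractions:
    """Fraction of positive conversations per situation-setter-length bin."""
    edges = list(setter_len_bins)
    n_bins = len(edges) - 1
    pos = np.zeros(n_bins)
    tot = np.zeros(n_bins)
    for conv in convs:
        if not conv.labeled:
            continue
        setter = find_situation_setter(conv, min_tokens)
        if setter is None:
            continue
        b = np.searchsorted(edges, setter.n_tokens, side="right") - 1
        if 0 <= b < n_bins:
            tot[b] += 1
            pos[b] += conv.outcome == POSITIVE
    frac, ci = [], []
    for b in range(n_bins):
        if tot[b] == 0:
            frac.append(float("nan"))
            ci.append((float("nan"), float("nan")))
            continue
        p = pos[b] / tot[b]
        se = float(np.sqrt(p * (1 - p) / tot[b]))
        frac.append(float(p))
        ci.append((max(0.0, p - 1.96 * se), min(1.0, p + 1.96 * se)))
    return BinnedFractions(bin_edges=edges, fraction_positive=frac, ci=ci,
                           counts=[int(n) for n in tot])


def counselor_texter_length_ratio(
    convs: Sequence[Conversation],
    setter_len_bins: Sequence[float],
    min_tokens: int = 10,
) -> tuple[list[float], list[int]]:
    """Per setter-length bin: mean (counselor reply length / setter length).

    The reply is the first counselor message after the setter; a flat line at
    1 would mean counselors write exactly as much as the texter.
    """
    edges = list(setter_len_bins)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    tot = np.zeros(n_bins)
    for conv in convs:
        setter = find_situation_setter(conv, min_tokens)
        if setter is None:
            continue
        reply = next(
            (m for m in conv.messages[setter.message_index + 1:] if m.role == COUNSELOR),
            None,
        )
        if reply is None:
            continue
        b = np.searchsorted(edges, setter.n_tokens, side="right") - 1
        if 0 <= b < n_bins:
            sums[b] += reply.n_tokens / setter.n_tokens
            tot[b] += 1
    ratios = [float(sums[b] / tot[b]) if tot[b] else float("nan") for b in range(n_bins)]
    return ratios, [int(n) for n in tot]


@dataclass
class SetterCluster:
    """A dense neighborhood of near-identical situation setters."""

    center: int            # index of one center whose neighborhood seeded it
    members: list[int]     # setter indices, sorted


def cluster_setters(
    setters: Sequence[SituationSetter],
    distance_threshold: float = 0.4,
    min_neighbors: int = 10,
) -> list[SetterCluster]:
    """Dense clusters of setters in bigram TF-IDF space.

    A setter's neighbors are the other setters within the cosine-distance
    threshold; setters with at least ``min_neighbors`` neighbors are centers,
    and centers with overlapping neighborhoods merge (union of members).
    Construction is order-invariant: centers and members are index-sorted.
    """
    if not 0.0 <= distance_threshold <= 1.0:
        raise ValueError("distance_threshold must lie in [0, 1]")
    n = len(setters)
    if n < min_neighbors + 1:
        raise ValueError(
            f"need at least min_neighbors+1={min_neighbors + 1} setters, got {n}"
        )
    mat, _ = tfidf_matrix([s.tokens for s in setters], n=2)
    sim = cosine_similarity_rows(mat)
    dist = 1.0 - sim
    np.fill_diagonal(dist, np.inf)
    neighbor_sets = [set(np.flatnonzero(dist[i] <= distance_threshold)) for i in range(n)]
    centers = sorted(i for i in range(n) if len(neighbor_sets[i]) >= min_neighbors)

    # merge centers whose neighborhoods (incl. themselves) intersect
    parent = list(range(len(centers)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    hoods = [neighbor_sets[c] | {c} for c in centers]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if hoods[i] & hoods[j]:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(centers)):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for g in sorted(groups.values(), key=lambda idxs: centers[idxs[0]]):
        members: set[int] = set()
        for i in g:
            members |= hoods[i]
        clusters.append(SetterCluster(center=centers[g[0]], members=sorted(members)))
    return clusters


@dataclass
class ResponseClassification:
    """Pattern classes plus length/similarity features of a setter exchange."""

    check_question: bool
    suicide_check: bool
    thanks: bool
    hedge: bool
    surprise: bool
    counselor_len: int
    texter_len: int
    sim_counselor_setter: float
    sim_texter_setter: float

    def flags(self) -> dict[str, bool]:
        return {c: getattr(self, c) for c in
                ("check_question", "suicide_check", "thanks", "hedge", "surprise")}


def classify_response(
    setter: SituationSetter,
    counselor_reply: Optional[str],
    next_texter_reply: Optional[str],
    patterns: dict[str, list[str]] | None = None,
    ngram: int = 2,
) -> ResponseClassification:
    """Classify a counselor reply by regex pattern sets and similarity.

    Similarities are cosine in the same bigram TF-IDF space used for setter
    matching (unigram space with ``ngram=1``); an empty reply yields all-false
    flags and similarity 0.
    """
    from .corpus import tokenize

    compiled = compile_patterns(patterns if patterns is not None else RESPONSE_PATTERNS)
    reply = counselor_reply or ""
    flags = {
        name: any(p.search(reply) for p in pats)
        for name, pats in compiled.items()
    }
    c_tokens = tokenize(reply)
    t_tokens = tokenize(next_texter_reply or "")
    docs = [setter.tokens, c_tokens, t_tokens]
    mat, _ = tfidf_matrix(docs, n=ngram)
    sim = cosine_similarity_rows(mat)
    return ResponseClassification(
        check_question=flags.get("check_question", False),
        suicide_check=flags.get("suicide_check", False),
        thanks=flags.get("thanks", False),
        hedge=flags.get("hedge", False),
        surprise=flags.get("surprise", False),
        counselor_len=len(c_tokens),
        texter_len=len(t_tokens),
        sim_counselor_setter=float(max(0.0, sim[0, 1])) if c_tokens else 0.0,
        sim_texter_setter=float(max(0.0, sim[0, 2])) if t_tokens else 0.0,
    )


def setter_response_table(
    convs: Sequence[Conversation],
    split,
    distance_threshold: float = 0.4,
    min_neighbors: int = 10,
    min_tokens: int = 10,
    patterns: dict[str, list[str]] | None = None,
):
    """Group comparison of counselor reactions to near-identical setters.

    Situation setters from both counselor groups are clustered; within each
    cluster containing both groups, per-group means of each response measure
    are computed, and groups are compared by a Wilcoxon signed-rank test over
    the per-cluster paired means.  Returns a pandas DataFrame with one row
    per measure (mean per group, p-value, number of paired clusters).
    """
    import pandas as pd
    from scipy import stats

    entries = []  # (group, conv, setter)
    for conv in convs:
        g = split.group_of(conv.counselor_id)
        if g is None:
            continue
        s = find_situation_setter(conv, min_tokens)
        if s is not None:
            entries.append((g, conv, s))
    if not entries:
        raise ValueError("no situation setters found for either group")
    setters = [e[2] for e in entries]
    clusters = cluster_setters(setters, distance_threshold, min_neighbors)

    def measures(group: str, conv: Conversation, setter: SituationSetter) -> dict[str, float]:
        reply = next((m for m in conv.messages[setter.message_index + 1:]
                      if m.role == COUNSELOR), None)
        nxt = None
        if reply is not None:
            nxt = next((m for m in conv.messages[reply.index + 1:]
                        if m.role == TEXTER), None)
        cls = classify_response(setter, reply.text if reply else None,
                                nxt.text if nxt else None, patterns)
        out = {
            "pct_successful": 100.0 * (conv.outcome == POSITIVE) if conv.labeled else float("nan"),
            "n_messages": float(len(conv)),
            "setter_len": float(setter.n_tokens),
            "c_response_len": float(cls.counselor_len),
            "t_response_len": float(cls.texter_len),
            "pct_cos_sim_c": 100.0 * cls.sim_counselor_setter,
            "pct_cos_sim_t": 100.0 * cls.sim_texter_setter,
        }
        for name, flag in cls.flags().items():
            out[f"pct_{name}"] = 100.0 * flag
        return out

    rows = []
    for ci, cluster in enumerate(clusters):
        per_group: dict[str, list[dict]] = {"more_successful": [], "less_successful": []}
        for idx in cluster.members:
            g, conv, setter = entries[idx]
            per_group[g].append(measures(g, conv, setter))
        if not per_group["more_successful"] or not per_group["less_successful"]:
            continue
        for g, ms in per_group.items():
            mean = {k: float(np.nanmean([m[k] for m in ms])) for k in ms[0]}
            mean.update(cluster=ci, group=g)
            rows.append(mean)
    if not rows:
        raise ValueError("no setter cluster contains both counselor groups")
    df = pd.DataFrame(rows)
    keys = [c for c in df.columns if c not in ("cluster", "group")]
    out_rows = []
    wide = df.pivot(index="cluster", columns="group")
    for k in keys:
        a = wide[(k, "more_successful")].to_numpy(dtype=float)
        b = wide[(k, "less_successful")].to_numpy(dtype=float)
        mask = ~(np.isnan(a) | np.isnan(b))
        a, b = a[mask], b[mask]
        if len(a) and np.any(a != b):
            p = float(stats.wilcoxon(a, b).pvalue)
        else:
            p = float("nan")
        out_rows.append({
            "measure": k,
            "more_successful": float(np.mean(a)) if len(a) else float("nan"),
            "less_successful": float(np.mean(b)) if len(b) else float("nan"),
            "p_value": p,
            "n_clusters": int(len(a)),
        })
    return pd.DataFrame(out_rows)


def templatedness(
    counselor_replies: Sequence[Sequence[str]],
    distance_threshold: float = 0.4,
) -> list[int]:
    """Per reply: how many other replies sit within the cosine-distance
    threshold in bigram TF-IDF space.  High counts mean templated responses;
    low counts mean creative ones."""
    if len(counselor_replies) < 2:
        raise ValueError("templatedness needs at least two replies")
    mat, _ = tfidf_matrix(list(counselor_replies), n=2)
    dist = 1.0 - cosine_similarity_rows(mat)
    np.fill_diagonal(dist, np.inf)
    return [int((row <= distance_threshold).sum()) for row in dist]
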