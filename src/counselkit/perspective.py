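"""Perspective-change trajectories of texter language over conversation time.

Three within-conversation measures, each a ratio of category word counts in
texter messages, computed per conversation fifth and outcome group:

* temporal orientation — past, present and future word fractions of the
  tense-category total (a shift from past toward future accompanies
  successful conversations);
* self focus — first-person-singular pronouns over first-singular plus
  third-person pronouns (depressed texters self-focus more; considering
  others accompanies improvement);
* sentiment — positive-emotion words over positive plus negative
  (texters start below 0.5 and drift upward).

Counts are pooled over the conversations of each outcome group, so the
measures are invariant to permuting messages within a chunk.  Confidence
intervals bootstrap over conversations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import NEGATIVE, POSITIVE, TEXTER, Conversation, chunk_messages
from .lexicons import PERSPECTIVE_CATEGORIES, build_matchers


@dataclass
class Trajectory:
    """One measure's per-chunk values for both outcome groups."""

    measure: str
    values: dict[str, list[float]]               # outcome -> per-chunk value
    ci: dict[str, list[tuple[float, float]]]
    flagged_chunks: dict[str, list[int]]         # chunks with zero denominator


def _category_counts(
    convs: Sequence[Conversation],
    categories: Sequence[str],
    lexicons: dict[str, list[str]],
    n_chunks: int,
    role: str,
) -> dict[str, np.ndarray]:
    """Per conversation: (n_chunks, n_categories) token hit counts."""
    matchers = build_matchers({c: lexicons[c] for c in categories})
    out = {}
    for conv in convs:
        counts = np.zeros((n_chunks, len(categories)))
        for ch, msgs in enumerate(chunk_messages(conv, n_chunks)):
            for m in msgs:
                if m.role != role:
                    continue
                for j, c in enumerate(categories):
                    counts[ch, j] += matchers[c].count(m.tokens)
        out[conv.conv_id] = counts
    return out


def _ratio_trajectory(
    convs: Sequence[Conversation],
    categories: Sequence[str],
    numerator: Sequence[int],
    lexicons: dict[str, list[str]],
    n_chunks: int,
    role: str,
    measure: str,
    n_boot: int,
    seed: int,
) -> dict[str, Trajectory]:
    """Pooled count ratios per chunk/outcome, one trajectory per numerator
    category (self-focus and sentiment use a single numerator)."""
    by_outcome = {
        POSITIVE: [c for c in convs if c.outcome == POSITIVE],
        NEGATIVE: [c for c in convs if c.outcome == NEGATIVE],
    }
    counts = _category_counts(convs, categories, lexicons, n_chunks, role)
    rng = np.random.default_rng(seed)

    trajectories: dict[str, Trajectory] = {}
    for num_j in numerator:
        name = f"{measure}:{categories[num_j]}" if len(numerator) > 1 else measure
        values: dict[str, list[float]] = {}
        cis: dict[str, list[tuple[float, float]]] = {}
        flagged: dict[str, list[int]] = {}
        for outcome, group in by_outcome.items():
            arr = np.array([counts[c.conv_id] for c in group])  # (n, chunks, cats)
            if arr.size == 0:
                values[outcome] = [float("nan")] * n_chunks
                cis[outcome] = [(float("nan"), float("nan"))] * n_chunks
                flagged[outcome] = list(range(n_chunks))
                continue
            tot = arr.sum(axis=0)                              # (chunks, cats)
            den = tot.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = tot[:, num_j] / den
            values[outcome] = [float(v) for v in vals]
            flagged[outcome] = [ch for ch in range(n_chunks) if den[ch] == 0]
            boots = np.empty((n_boot, n_chunks))
            n = arr.shape[0]
            for b in range(n_boot):
                idx = rng.integers(0, n, size=n)
                t = arr[idx].sum(axis=0)
                d = t.sum(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    boots[b] = t[:, num_j] / d
            lo = np.nanpercentile(boots, 2.5, axis=0)
            hi = np.nanpercentile(boots, 97.5, axis=0)
            cis[outcome] = [(float(a), float(b_)) for a, b_ in zip(lo, hi)]
        trajectories[name] = Trajectory(
            measure=name, values=values, ci=cis, flagged_chunks=flagged,
        )
    return trajectories


def temporal_orientation(
    convs: Sequence[Conversation],
    lexicons: dict[str, list[str]] | None = None,
    n_chunks: int = 5,
    role: str = TEXTER,
    n_boot: int = 200,
    seed: int = 0,
) -> dict[str, Trajectory]:
    """Past/present/future fractions of tense-category words per chunk."""
    lex = lexicons if lexicons is not None else PERSPECTIVE_CATEGORIES
    cats = ["past", "present", "future"]
    labeled = [c for c in convs if c.labeled]
    return _ratio_trajectory(labeled, cats, [0, 1, 2], lex, n_chunks, role,
                             "temporal", n_boot, seed)


def self_focus(
    convs: Sequence[Conversation],
    lexicons: dict[str, list[str]] | None = None,
    n_chunks: int = 5,
    role: str = TEXTER,
    n_boot: int = 200,
    seed: int = 0,
) -> Trajectory:
    """First-person-singular share of first-singular + third-person pronouns."""
    lex = lexicons if lexicons is not None else PERSPECTIVE_CATEGORIES
    labeled = [c for c in convs if c.labeled]
    out = _ratio_trajectory(labeled, ["first_singular", "third_person"], [0],
                            lex, n_chunks, role, "self_focus", n_boot, seed)
    return out["self_focus"]


def sentiment_ratio(
    convs: Sequence[Conversation],
    lexicons: dict[str, list[str]] | None = None,
    n_chunks: int = 5,
    role: str = TEXTER,
    n_boot: int = 200,
    seed: int = 0,
) -> Trajectory:
    """Positive-emotion share of positive + negative emotion words."""
    lex = lexicons if lexicons is not None else PERSPECTIVE_CATEGORIES
    labeled = [c for c in convs if c.labeled]
    out = _ratio_trajectory(labeled, ["pos_emo", "neg_emo"], [0],
                            lex, n_chunks, role, "sentiment", n_boot, seed)
    return out["sentiment"]
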