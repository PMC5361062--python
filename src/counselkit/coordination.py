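"""Linguistic coordination (accommodation) between conversation partners.

For a replier *b* in group B responding to initiators in group A, the
coordination on marker *m* is the increase in *b*'s probability of
exhibiting *m* (using at least one word of the marker's category) when the
utterance just replied to exhibited it:

    C^m(b, A) = P(exhibit in reply | initial exhibited) - P(exhibit in reply)

estimated by counting over all of *b*'s exchanges.  Markers where the
initiator never exhibits leave C^m undefined and are excluded from *b*'s
macro-average C(b, A); the group value C(B, A) is the unweighted mean over
repliers with enough exchanges.  Participants holding more power in a
conversation coordinate less.

The same statistic applied with perspective-category lexicons (future words,
third-person pronouns, positive emotion...) as markers measures whether a
texter picks up a concept right after the counselor introduces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .corpus import COUNSELOR, TEXTER, Conversation
from .lexicons import STYLISTIC_MARKERS, WordMatcher, build_matchers


@dataclass
class Exchange:
    """An adjacent (initial utterance by A, reply by B) message pair."""

    conv_id: str
    speaker_b: str                    # replier identity (counselor id or conv id)
    initial_index: int
    exhibits_u1: dict[str, bool]      # marker -> initial utterance exhibits it
    exhibits_u2: dict[str, bool]      # marker -> reply exhibits it


def extract_exchanges(
    convs: Sequence[Conversation],
    b_role: str = TEXTER,
    a_role: str = COUNSELOR,
    markers: dict[str, list[str]] | None = None,
) -> list[Exchange]:
    """Every adjacent (a_role message, b_role message) pair in the corpus.

    A reply pairs only with the immediately preceding other-role message;
    consecutive same-role messages are not concatenated, so after a run of
    a_role messages only the last one forms an exchange.
    """
    matchers = build_matchers(markers if markers is not None else STYLISTIC_MARKERS)
    out = []
    for conv in convs:
        speaker_b = conv.counselor_id if b_role == COUNSELOR else conv.conv_id
        for u1, u2 in zip(conv.messages, conv.messages[1:]):
            if u1.role == a_role and u2.role == b_role:
                out.append(Exchange(
                    conv_id=conv.conv_id,
                    speaker_b=speaker_b,
                    initial_index=u1.index,
                    exhibits_u1={m: f.any(u1.tokens) for m, f in matchers.items()},
                    exhibits_u2={m: f.any(u2.tokens) for m, f in matchers.items()},
                ))
    return out


def coordination_per_marker(
    exchanges: Sequence[Exchange], marker: str
) -> Optional[float]:
    """C^m over a set of exchanges; None when the initiator never exhibits."""
    if not exchanges:
        raise ValueError("coordination needs at least one exchange")
    n = len(exchanges)
    n_u1 = sum(e.exhibits_u1[marker] for e in exchanges)
    if n_u1 == 0:
        return None
    n_u2 = sum(e.exhibits_u2[marker] for e in exchanges)
    n_both = sum(e.exhibits_u1[marker] and e.exhibits_u2[marker] for e in exchanges)
    return n_both / n_u1 - n_u2 / n


@dataclass
class CoordinationResult:
    """Per-speaker and group coordination values with supporting counts."""

    per_speaker_marker: dict[str, dict[str, Optional[float]]]
    per_speaker: dict[str, float]     # macro-average over defined markers
    group_value: float                # unweighted mean over included speakers
    excluded_speakers: list[str] = field(default_factory=list)
    n_exchanges: dict[str, int] = field(default_factory=dict)


def aggregate(
    exchanges: Sequence[Exchange],
    markers: Sequence[str],
    min_exchanges: int = 10,
) -> CoordinationResult:
    """Speaker macro-averages and the group mean coordination.

    Speakers with fewer than ``min_exchanges`` exchanges or no defined marker
    are excluded from the group value (listed in ``excluded_speakers``).
    """
    by_speaker: dict[str, list[Exchange]] = {}
    for e in exchanges:
        by_speaker.setdefault(e.speaker_b, []).append(e)
    per_sm: dict[str, dict[str, Optional[float]]] = {}
    per_s: dict[str, float] = {}
    excluded = []
    for sp in sorted(by_speaker):
        exs = by_speaker[sp]
        vals = {m: coordination_per_marker(exs, m) for m in markers}
        per_sm[sp] = vals
        defined = [v for v in vals.values() if v is not None]
        if len(exs) < min_exchanges or not defined:
            excluded.append(sp)
            continue
        per_s[sp] = float(np.mean(defined))
    if not per_s:
        raise ValueError("no speaker has enough exchanges and defined markers")
    return CoordinationResult(
        per_speaker_marker=per_sm,
        per_speaker=per_s,
        group_value=float(np.mean(list(per_s.values()))),
        excluded_speakers=excluded,
        n_exchanges={sp: len(v) for sp, v in by_speaker.items()},
    )


def coordination_null_interval(
    exchanges: Sequence[Exchange],
    markers: Sequence[str],
    n_perm: int = 200,
    seed: int = 0,
    min_exchanges: int = 10,
) -> tuple[float, float]:
    """95% interval of the group coordination with replies decoupled.

    Reply exhibit maps are permuted across exchanges (within each speaker),
    preserving every marginal rate while destroying the pairing with the
    initial utterance.
    """
    rng = np.random.default_rng(seed)
    by_speaker: dict[str, list[Exchange]] = {}
    for e in exchanges:
        by_speaker.setdefault(e.speaker_b, []).append(e)
    vals = []
    for _ in range(n_perm):
        permuted: list[Exchange] = []
        for sp, exs in sorted(by_speaker.items()):
            perm = rng.permutation(len(exs))
            for e, j in zip(exs, perm):
                permuted.append(Exchange(
                    conv_id=e.conv_id, speaker_b=e.speaker_b,
                    initial_index=e.initial_index,
                    exhibits_u1=e.exhibits_u1,
                    exhibits_u2=exs[j].exhibits_u2,
                ))
        vals.append(aggregate(permuted, markers, min_exchanges).group_value)
    return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


@dataclass
class CategoryCoordination:
    category: str
    group_value: float
    per_speaker: dict[str, float]
    p_value: float                   # signed-rank test of per-speaker C vs 0
    n_speakers: int


def category_coordination(
    convs: Sequence[Conversation],
    category_lexicons: dict[str, list[str]],
    b_role: str = TEXTER,
    a_role: str = COUNSELOR,
    min_exchanges: int = 10,
) -> dict[str, CategoryCoordination]:
    """Coordination per perspective category, texter replying by default.

    Each category is treated as a single marker; per-speaker values are
    tested against zero with a Wilcoxon signed-rank test.
    """
    exchanges = extract_exchanges(convs, b_role, a_role, markers=category_lexicons)
    out = {}
    for cat in sorted(category_lexicons):
        by_speaker: dict[str, list[Exchange]] = {}
        for e in exchanges:
            by_speaker.setdefault(e.speaker_b, []).append(e)
        per_s = {}
        for sp, exs in sorted(by_speaker.items()):
            if len(exs) < min_exchanges:
                continue
            v = coordination_per_marker(exs, cat)
            if v is not None:
                per_s[sp] = v
        if not per_s:
            out[cat] = CategoryCoordination(cat, float("nan"), {}, float("nan"), 0)
            continue
        vals = np.array(list(per_s.values()))
        if len(vals) >= 5 and np.any(vals != 0.0):
            p = float(stats.wilcoxon(vals).pvalue)
        else:
            p = float("nan")
        out[cat] = CategoryCoordination(
            category=cat, group_value=float(vals.mean()),
            per_speaker=per_s, p_value=p, n_speakers=len(vals),
        )
    return out
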