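"""Conversation data model, tokenization, corpus I/O, and the counselor split.

A corpus is a list of two-party conversations between a ``counselor`` (the
trained responder) and a ``texter`` (the person in crisis).  Conversations
optionally carry a binary outcome label derived from the texter's
post-conversation survey (``positive`` = felt better, ``negative`` = felt the
same or worse) and a free-form issue tag.

Corpus files are UTF-8 JSON Lines, one conversation per line::

    {"conv_id": "c1", "counselor_id": "A", "outcome": "positive",
     "issue": "stress", "messages": [{"role": "counselor", "text": "Hi!"}, ...]}

``outcome`` and ``issue`` may be omitted or null for unlabeled conversations.
"""

from __future__ import annotations

import json
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

COUNSELOR = "counselor"
TEXTER = "texter"
ROLES = (COUNSELOR, TEXTER)

POSITIVE = "positive"
NEGATIVE = "negative"
OUTCOMES = (POSITIVE, NEGATIVE)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens: split on non-alphanumerics, keep digit tokens.

    Deterministic and punctuation-free; an empty string yields an empty list.
    """
    return _TOKEN_RE.findall(text.lower())


class CorpusFormatError(ValueError):
    """A corpus record violates the documented JSONL schema."""


@dataclass
class Message:
    """One utterance: speaker role, raw text, tokens, position in conversation."""

    role: str
    text: str
    index: int
    tokens: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CorpusFormatError(f"unknown role {self.role!r}")
        if not self.tokens and self.text:
            self.tokens = tokenize(self.text)

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


@dataclass
class Conversation:
    """An ordered message sequence with counselor id and optional outcome label."""

    conv_id: str
    counselor_id: str
    messages: list[Message]
    outcome: Optional[str] = None
    issue: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.messages:
            raise CorpusFormatError(f"conversation {self.conv_id} has no messages")
        if self.outcome is not None and self.outcome not in OUTCOMES:
            raise CorpusFormatError(
                f"conversation {self.conv_id}: unknown outcome {self.outcome!r}"
            )
        for i, m in enumerate(self.messages):
            if m.index != i:
                raise CorpusFormatError(
                    f"conversation {self.conv_id}: message index {m.index} at position {i}"
                )

    @property
    def labeled(self) -> bool:
        return self.outcome is not None

    def __len__(self) -> int:
        return len(self.messages)

    def role_messages(self, role: str) -> list[Message]:
        return [m for m in self.messages if m.role == role]


def _conv_to_record(conv: Conversation) -> dict:
    rec: dict = {
        "conv_id": conv.conv_id,
        "counselor_id": conv.counselor_id,
        "messages": [{"role": m.role, "text": m.text} for m in conv.messages],
    }
    if conv.outcome is not None:
        rec["outcome"] = conv.outcome
    if conv.issue is not None:
        rec["issue"] = conv.issue
    return rec


def _record_to_conv(rec: dict, lineno: int) -> Conversation:
    try:
        messages = [
            Message(role=m["role"], text=m["text"], index=i)
            for i, m in enumerate(rec["messages"])
        ]
        return Conversation(
            conv_id=str(rec["conv_id"]),
            counselor_id=str(rec["counselor_id"]),
            messages=messages,
            outcome=rec.get("outcome"),
            issue=rec.get("issue"),
        )
    except (KeyError, TypeError, CorpusFormatError) as exc:
        raise CorpusFormatError(f"line {lineno}: {exc}") from exc


def read_corpus(path: str | Path) -> list[Conversation]:
    """Parse a JSONL corpus file; errors name the offending line number."""
    convs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
            convs.append(_record_to_conv(rec, lineno))
    return convs


def write_corpus(convs: Iterable[Conversation], path: str | Path) -> None:
    """Write conversations as sorted-key JSONL; round-trips losslessly."""
    with open(path, "w", encoding="utf-8") as fh:
        for conv in convs:
            fh.write(json.dumps(_conv_to_record(conv), sort_keys=True))
            fh.write("\n")


@dataclass
class CounselorSplit:
    """Most- vs least-successful counselors by labeled-conversation success rate."""

    more_successful: set[str]
    less_successful: set[str]
    success_rate: dict[str, float]

    def group_of(self, counselor_id: str) -> Optional[str]:
        if counselor_id in self.more_successful:
            return "more_successful"
        if counselor_id in self.less_successful:
            return "less_successful"
        return None

    def group_members(self, group: str) -> set[str]:
        if group == "more_successful":
            return self.more_successful
        if group == "less_successful":
            return self.less_successful
        raise ValueError(f"unknown group {group!r}")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "more_successful": sorted(self.more_successful),
                    "less_successful": sorted(self.less_successful),
                    "success_rate": dict(sorted(self.success_rate.items())),
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "CounselorSplit":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            more_successful=set(d["more_successful"]),
            less_successful=set(d["less_successful"]),
            success_rate=d["success_rate"],
        )


def split_counselors(
    convs: Sequence[Conversation],
    min_labeled: int = 15,
    min_messages: int = 30,
    top_n: int = 40,
    bottom_n: int = 40,
) -> CounselorSplit:
    """Rank counselors by success rate and take the two extremes.

    A counselor is eligible when they have strictly more than ``min_labeled``
    labeled conversations of at least ``min_messages`` messages each; the
    success rate is the positive fraction of those qualifying conversations.
    Ranking ties break by qualifying-conversation count, then id.
    """
    qualifying: dict[str, list[Conversation]] = defaultdict(list)
    for conv in convs:
        if conv.labeled and len(conv) >= min_messages:
            qualifying[conv.counselor_id].append(conv)

    rates: dict[str, float] = {}
    counts: dict[str, int] = {}
    for cid, cl in qualifying.items():
        if len(cl) > min_labeled:
            rates[cid] = sum(1 for c in cl if c.outcome == POSITIVE) / len(cl)
            counts[cid] = len(cl)

    if len(rates) < top_n + bottom_n:
        raise ValueError(
            f"only {len(rates)} eligible counselors; need {top_n + bottom_n} "
            f"(top_n={top_n}, bottom_n={bottom_n})"
        )

    ranked = sorted(rates, key=lambda c: (-rates[c], -counts[c], c))
    return CounselorSplit(
        more_successful=set(ranked[:top_n]),
        less_successful=set(ranked[-bottom_n:]),
        success_rate=rates,
    )


def chunk_sizes(n: int, n_chunks: int) -> list[int]:
    """Contiguous partition sizes differing by at most one, larger first."""
    base, rem = divmod(n, n_chunks)
    return [base + 1 if i < rem else base for i in range(n_chunks)]


def chunk_messages(
    conv: Conversation,
    n_chunks: int = 5,
    role_filter: Optional[str] = None,
) -> list[list[Message]]:
    """Partition (optionally role-filtered) messages into contiguous chunks.

    Chunk sizes differ by at most one, with earlier chunks taking the larger
    size; fewer messages than chunks leaves trailing empty chunks.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    msgs = conv.messages if role_filter is None else conv.role_messages(role_filter)
    sizes = chunk_sizes(len(msgs), n_chunks)
    chunks, pos = [], 0
    for s in sizes:
        chunks.append(msgs[pos : pos + s])
        pos += s
    return chunks


def chunk_index_of(i: int, n: int, n_chunks: int = 5) -> int:
    """Chunk index of message position ``i`` in a conversation of ``n`` messages."""
    sizes = chunk_sizes(n, n_chunks)
    pos = 0
    for c, s in enumerate(sizes):
        pos += s
        if i < pos:
            return c
    return n_chunks - 1
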