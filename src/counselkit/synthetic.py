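"""Synthetic counseling-conversation corpora with planted, recoverable structure.

The generator emulates the structural properties the analyses target, each
controlled by an explicit parameter and echoed in a :class:`GroundTruth`
object so recovery tests have an oracle:

* alternating counselor/texter messages, counselor first;
* a left-to-right latent stage process (stage never decreases, starts at 1)
  with per-stage advance probabilities, emitting each message as a bag of
  words mixing stage-and-role keywords with shared background vocabulary;
* counselor quality: each counselor has a probability that a conversation
  ends with a positive outcome;
* outcome-dependent lexical drift in counselor language that grows linearly
  with conversation time (the signal the adaptability measure recovers);
* marker coordination: a message exhibits marker *m* (one marker word is
  appended) with probability ``base + delta`` if the previous message
  exhibited *m*, else ``base``;
* role-asymmetric negative-binomial message lengths, with the first texter
  message (the situation setter) drawn longer, and longer still in positive
  conversations;
* perspective-category token rates in texter messages that follow planted
  linear-in-time schedules with outcome-dependent shifts;
* counselor behavior injection (hedges, check-question phrases) at
  outcome-dependent rates, giving the outcome classifier a planted signal.

Everything is sampled from a single seeded generator stream: the same
(config, seed) yields a byte-identical corpus.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .corpus import (COUNSELOR, NEGATIVE, POSITIVE, TEXTER, Conversation,
                     Message, chunk_index_of)
from .lexicons import PERSPECTIVE_CATEGORIES, STYLISTIC_MARKERS


def _default_keywords(prefix: str, n_stages: int, per_stage: int) -> list[list[str]]:
    # purely alphanumeric so the default tokenizer keeps each word intact
    return [
        [f"kw{prefix}{s + 1}w{i:02d}" for i in range(per_stage)]
        for s in range(n_stages)
    ]


def _clean_words(words: list[str]) -> list[str]:
    return [w.rstrip("*") for w in words]


@dataclass
class GeneratorConfig:
    """All planted parameters of the synthetic corpus.

    Defaults describe the standard study conditions: 20 counselors (half with
    quality 0.8, half 0.5) at 40 labeled conversations each, conversations of
    40-60 alternating messages, five ordered stages with keyword weight 0.8,
    outcome drift strength 4.0, and eight stylistic markers at base exhibit
    probability 0.2 with coordination increment 0.1.
    """

    n_counselors: int = 20
    conversations_per_counselor: int = 40
    n_stages: int = 5
    min_messages: int = 40
    max_messages: int = 60
    label_fraction: float = 1.0

    # vocabulary and stage emissions
    counselor_keywords: list[list[str]] = field(default_factory=lambda: _default_keywords("c", 5, 10))
    texter_keywords: list[list[str]] = field(default_factory=lambda: _default_keywords("t", 5, 10))
    background_words: list[str] = field(default_factory=lambda: [f"bg{i:03d}" for i in range(200)])
    background_zipf: float = 1.05  # rank-frequency exponent of the background block
    pos_drift_words: list[str] = field(default_factory=lambda: [f"driftpos{i}" for i in range(20)])
    neg_drift_words: list[str] = field(default_factory=lambda: [f"driftneg{i}" for i in range(20)])
    drift_word_mass: float = 0.3  # share of the background block held by drift lexicons
    keyword_weight: float = 0.8
    stage_advance_prob: list[float] = field(default_factory=lambda: [0.15, 0.15, 0.15, 0.15, 0.0])
    advance_prob_overrides: dict[str, list[float]] = field(default_factory=dict)

    # outcomes and drift
    counselor_quality: Optional[list[float]] = None  # default: half 0.8, half 0.5
    drift_strength: float = 4.0

    # marker coordination
    markers: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in STYLISTIC_MARKERS.items()})
    base_marker_prob: float | dict[str, float] = 0.2
    coordination_delta: float | dict[str, float] = 0.1

    # message lengths: per-role negative binomial (n, p); mean = n (1-p) / p
    counselor_length: tuple[float, float] = (8.0, 1.0 / 3.0)
    texter_length: tuple[float, float] = (4.0, 4.0 / 14.0)
    setter_length: tuple[float, float] = (8.0, 8.0 / 28.0)
    setter_length_effect: float = 4.0

    # perspective-category token rates in texter messages:
    # rate = base + slope * t + positive_shift [positive only], t in [0, 1]
    category_rates: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "past": {"base": 0.05, "slope": -0.03, "positive_shift": 0.0},
        "present": {"base": 0.04, "slope": 0.0, "positive_shift": 0.0},
        "future": {"base": 0.01, "slope": 0.03, "positive_shift": 0.01},
        "first_singular": {"base": 0.04, "slope": -0.01, "positive_shift": -0.005},
        "third_person": {"base": 0.015, "slope": 0.005, "positive_shift": 0.01},
        "pos_emo": {"base": 0.015, "slope": 0.025, "positive_shift": 0.015},
        "neg_emo": {"base": 0.05, "slope": -0.02, "positive_shift": -0.015},
    })
    category_words: dict[str, list[str]] = field(default_factory=lambda: {k: _clean_words(v) for k, v in PERSPECTIVE_CATEGORIES.items()})

    # counselor behavior injection: probability of inserting the phrase
    behavior_rates: dict[str, dict] = field(default_factory=lambda: {
        "hedge": {"base": 0.30, "positive_shift": 0.12, "words": ["maybe"]},
        "check_question": {"base": 0.08, "positive_shift": 0.06, "words": ["sounds", "like"]},
    })

    seed: int = 0

    # ------------------------------------------------------------------

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.counselor_keywords) != self.n_stages or len(self.texter_keywords) != self.n_stages:
            raise ValueError("keyword lists must have one entry per stage")
        for lists in (self.counselor_keywords, self.texter_keywords):
            flat = [w for ws in lists for w in ws]
            if len(set(flat)) != len(flat):
                raise ValueError("stage keyword lists must be disjoint within a role")
        if not 0.0 <= self.keyword_weight <= 1.0:
            raise ValueError("keyword_weight must be in [0, 1]")
        if len(self.stage_advance_prob) != self.n_stages:
            raise ValueError("stage_advance_prob needs one value per stage")
        for p in self.stage_advance_prob:
            if not 0.0 <= p <= 1.0:
                raise ValueError("advance probabilities must be in [0, 1]")
        if self.stage_advance_prob[-1] != 0.0:
            raise ValueError("last stage must not advance (probability 0)")
        for q in self.quality_by_counselor().values():
            if not 0.0 <= q <= 1.0:
                raise ValueError("counselor quality must be in [0, 1]")
        for m in self.markers:
            for p in (self.marker_base(m), self.marker_base(m) + self.marker_delta(m)):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"marker {m}: exhibit probability outside [0, 1]")
        total = sum(r["base"] + abs(r.get("slope", 0.0)) + abs(r.get("positive_shift", 0.0))
                    for r in self.category_rates.values())
        if total > 1.0:
            raise ValueError("category replacement rates may sum past 1")
        if not 0.0 <= self.label_fraction <= 1.0:
            raise ValueError("label_fraction must be in [0, 1]")

    # --- parameter accessors ------------------------------------------

    def counselor_ids(self) -> list[str]:
        return [f"c{i:03d}" for i in range(self.n_counselors)]

    def quality_by_counselor(self) -> dict[str, float]:
        ids = self.counselor_ids()
        if self.counselor_quality is None:
            half = self.n_counselors // 2
            qs = [0.8 if i < half else 0.5 for i in range(self.n_counselors)]
        else:
            if len(self.counselor_quality) != self.n_counselors:
                raise ValueError("counselor_quality must have one entry per counselor")
            qs = list(self.counselor_quality)
        return dict(zip(ids, qs))

    def marker_base(self, m: str) -> float:
        if isinstance(self.base_marker_prob, dict):
            return self.base_marker_prob.get(m, 0.0)
        return float(self.base_marker_prob)

    def marker_delta(self, m: str) -> float:
        if isinstance(self.coordination_delta, dict):
            return self.coordination_delta.get(m, 0.0)
        return float(self.coordination_delta)

    def advance_probs_for(self, counselor_id: str) -> list[float]:
        return list(self.advance_prob_overrides.get(counselor_id, self.stage_advance_prob))

    # --- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["counselor_length"] = list(d["counselor_length"])
        d["texter_length"] = list(d["texter_length"])
        d["setter_length"] = list(d["setter_length"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for k in ("counselor_length", "texter_length", "setter_length"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def expected_coordination(base: float, delta: float) -> float:
    """Stationary coordination value implied by the planted exhibit chain.

    A message exhibits the marker with probability ``base + delta`` when its
    predecessor did and ``base`` otherwise, so the stationary exhibit rate is
    ``p* = base / (1 - delta)`` and the coordination statistic
    ``P(exhibit | partner exhibited) - P(exhibit)`` converges to
    ``(base + delta) - p* = delta (1 - base - delta) / (1 - delta)``.
    """
    return delta * (1.0 - base - delta) / (1.0 - delta)


@dataclass
class GroundTruth:
    """Planted values aligned one-to-one with the emitted corpus."""

    stages: dict[str, list[int]]                 # conv_id -> 1-based stage per message
    outcomes: dict[str, str]                     # conv_id -> true outcome (even if unlabeled)
    qualities: dict[str, float]                  # counselor_id -> planted quality
    marker_exhibits: dict[str, list[list[str]]]  # conv_id -> per message, exhibited markers
    behaviors: dict[str, list[list[str]]]        # conv_id -> per message, injected behaviors
    config: dict                                 # full generator configuration echo

    def keyword_stage_map(self) -> dict[tuple[str, str], int]:
        """Planted (role, keyword) → 1-based stage for stage-recovery checks."""
        cfg = GeneratorConfig.from_dict(self.config)
        out: dict[tuple[str, str], int] = {}
        for s, words in enumerate(cfg.counselor_keywords, start=1):
            for w in words:
                out[(COUNSELOR, w)] = s
        for s, words in enumerate(cfg.texter_keywords, start=1):
            for w in words:
                out[(TEXTER, w)] = s
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def export_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    gt.to_json(path)


# ---------------------------------------------------------------------------


def _emission_probs(cfg: GeneratorConfig) -> tuple[list[str], dict]:
    """Full token list plus index ranges for keywords/background/drift words."""
    vocab: list[str] = []
    index: dict[str, int] = {}

    def add(words: list[str]) -> np.ndarray:
        idx = []
        for w in words:
            if w not in index:
                index[w] = len(vocab)
                vocab.append(w)
            idx.append(index[w])
        return np.array(idx, dtype=np.intp)

    layout = {
        "counselor_kw": [add(ws) for ws in cfg.counselor_keywords],
        "texter_kw": [add(ws) for ws in cfg.texter_keywords],
        "background": add(cfg.background_words),
        "pos_drift": add(cfg.pos_drift_words),
        "neg_drift": add(cfg.neg_drift_words),
    }
    return vocab, layout


def _message_dist(cfg: GeneratorConfig, layout: dict, n_vocab: int, role: str,
                  stage: int, outcome: str, t: float) -> np.ndarray:
    """Token distribution for one (role, stage, outcome, time) combination."""
    p = np.zeros(n_vocab)
    kw = layout["counselor_kw" if role == COUNSELOR else "texter_kw"][stage]
    if len(kw):
        p[kw] += cfg.keyword_weight / len(kw)
    # background block: Zipfian ordinary words plus mid-frequency drift lexicons
    bg = np.zeros(n_vocab)
    ranks = np.arange(1, len(layout["background"]) + 1, dtype=float)
    zipf = ranks ** -cfg.background_zipf
    n_drift = len(layout["pos_drift"]) + len(layout["neg_drift"])
    drift_mass = cfg.drift_word_mass if n_drift else 0.0
    bg[layout["background"]] = (1.0 - drift_mass) * zipf / zipf.sum()
    if n_drift:
        bg[layout["pos_drift"]] = drift_mass / n_drift
        bg[layout["neg_drift"]] = drift_mass / n_drift
    if role == COUNSELOR and cfg.drift_strength > 0.0:
        # symmetric tilt: each outcome shifts toward its own lexicon and away
        # from the other's, increasingly with conversation time
        toward = layout["pos_drift"] if outcome == POSITIVE else layout["neg_drift"]
        away = layout["neg_drift"] if outcome == POSITIVE else layout["pos_drift"]
        bg[toward] *= 1.0 + cfg.drift_strength * t
        bg[away] /= 1.0 + cfg.drift_strength * t
        bg /= bg.sum()
    p += (1.0 - cfg.keyword_weight) * bg
    total = p.sum()
    if total <= 0.0:
        raise ValueError("empty emission distribution; check vocabulary config")
    return p / total


def generate_corpus(cfg: GeneratorConfig) -> tuple[list[Conversation], GroundTruth]:
    """Sample a corpus and its aligned ground truth from the planted model."""
    rng = np.random.default_rng(cfg.seed)
    vocab, layout = _emission_probs(cfg)
    n_vocab = len(vocab)
    vocab_arr = np.array(vocab, dtype=object)
    qualities = self_q = cfg.quality_by_counselor()

    # cache emission distributions per (role, stage, outcome, chunk)
    n_time = 5
    dist_cache: dict[tuple, np.ndarray] = {}

    def dist_for(role: str, stage: int, outcome: str, chunk: int) -> np.ndarray:
        key = (role, stage, outcome, chunk)
        if key not in dist_cache:
            t = chunk / (n_time - 1)
            dist_cache[key] = _message_dist(cfg, layout, n_vocab, role, stage, outcome, t)
        return dist_cache[key]

    marker_names = sorted(cfg.markers)
    marker_words = {m: np.array(cfg.markers[m], dtype=object) for m in marker_names}
    cat_names = sorted(cfg.category_rates)
    behavior_names = sorted(cfg.behavior_rates)

    convs: list[Conversation] = []
    stages_gt: dict[str, list[int]] = {}
    outcomes_gt: dict[str, str] = {}
    exhibits_gt: dict[str, list[list[str]]] = {}
    behaviors_gt: dict[str, list[list[str]]] = {}

    counselors = cfg.counselor_ids()
    n_total = cfg.n_counselors * cfg.conversations_per_counselor
    for ci in range(n_total):
        counselor_id = counselors[ci % cfg.n_counselors]
        conv_id = f"conv{ci:05d}"
        outcome = POSITIVE if rng.random() < self_q[counselor_id] else NEGATIVE
        labeled = rng.random() < cfg.label_fraction
        n_msgs = int(rng.integers(cfg.min_messages, cfg.max_messages + 1))
        advance = cfg.advance_probs_for(counselor_id)

        stage = 0
        stage_seq: list[int] = []
        prev_exhibit = {m: False for m in marker_names}
        msg_exhibits: list[list[str]] = []
        msg_behaviors: list[list[str]] = []
        messages: list[Message] = []
        seen_texter = False

        for i in range(n_msgs):
            role = COUNSELOR if i % 2 == 0 else TEXTER
            chunk = chunk_index_of(i, n_msgs, n_time)
            t = chunk / (n_time - 1)
            stage_seq.append(stage + 1)

            # message length
            if role == TEXTER and not seen_texter:
                r, pr = cfg.setter_length
                L = int(rng.negative_binomial(r, pr))
                if outcome == POSITIVE and cfg.setter_length_effect > 0:
                    L += int(rng.poisson(cfg.setter_length_effect))
                seen_texter = True
            else:
                r, pr = cfg.counselor_length if role == COUNSELOR else cfg.texter_length
                L = int(rng.negative_binomial(r, pr))
            L = max(1, L)

            p = dist_for(role, stage, outcome, chunk)
            idx = rng.choice(n_vocab, size=L, p=p)
            tokens = list(vocab_arr[idx])

            # perspective-category replacement (texter messages)
            if role == TEXTER and cat_names:
                rates = []
                for c in cat_names:
                    r_ = cfg.category_rates[c]
                    rate = r_["base"] + r_.get("slope", 0.0) * t
                    if outcome == POSITIVE:
                        rate += r_.get("positive_shift", 0.0)
                    rates.append(min(max(rate, 0.0), 1.0))
                rates = np.array(rates)
                if rates.sum() > 0:
                    probs = np.concatenate([rates, [max(0.0, 1.0 - rates.sum())]])
                    probs /= probs.sum()
                    assign = rng.choice(len(cat_names) + 1, size=L, p=probs)
                    for j in range(L):
                        if assign[j] < len(cat_names):
                            words = cfg.category_words[cat_names[assign[j]]]
                            tokens[j] = words[int(rng.integers(len(words)))]

            # counselor behavior injection
            inj: list[str] = []
            if role == COUNSELOR:
                for b in behavior_names:
                    rate = cfg.behavior_rates[b]
                    pb = rate["base"] + (rate.get("positive_shift", 0.0) if outcome == POSITIVE else 0.0)
                    if rng.random() < pb:
                        tokens.extend(rate["words"])
                        inj.append(b)
            msg_behaviors.append(inj)

            # marker coordination injection
            ex: list[str] = []
            for m in marker_names:
                pm = cfg.marker_base(m) + (cfg.marker_delta(m) if prev_exhibit[m] else 0.0)
                if rng.random() < pm:
                    tokens.append(str(marker_words[m][int(rng.integers(len(marker_words[m])))]))
                    ex.append(m)
            prev_exhibit = {m: (m in ex) for m in marker_names}
            msg_exhibits.append(ex)

            messages.append(Message(role=role, text=" ".join(tokens), index=i))

            if rng.random() < advance[stage]:
                stage = min(stage + 1, cfg.n_stages - 1)

        convs.append(Conversation(
            conv_id=conv_id,
            counselor_id=counselor_id,
            messages=messages,
            outcome=outcome if labeled else None,
            issue=None,
        ))
        stages_gt[conv_id] = stage_seq
        outcomes_gt[conv_id] = outcome
        exhibits_gt[conv_id] = msg_exhibits
        behaviors_gt[conv_id] = msg_behaviors

    gt = GroundTruth(
        stages=stages_gt,
        outcomes=outcomes_gt,
        qualities=dict(qualities),
        marker_exhibits=exhibits_gt,
        behaviors=behaviors_gt,
        config=cfg.to_dict(),
    )
    return convs, gt
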