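"""Coordination measure: exchanges, per-marker values, aggregation, nulls."""

import numpy as np
import pytest

from counselkit.coordination import (Exchange, aggregate, category_coordination,
                                     coordination_null_interval,
                                     coordination_per_marker, extract_exchanges)
from counselkit.corpus import Conversation, Message


def _conv(roles_texts, conv_id="x", counselor="c"):
    msgs = [Message(role=r, text=t, index=i) for i, (r, t) in enumerate(roles_texts)]
    return Conversation(conv_id, counselor, msgs)


def _exchange(u1, u2, marker="m", speaker="s"):
    return Exchange(conv_id="x", speaker_b=speaker, initial_index=0,
                    exhibits_u1={marker: bool(u1)}, exhibits_u2={marker: bool(u2)})


class TestExtractExchanges:
    def test_alternating_conversation_counts(self):
        conv = _conv([("counselor", "the plan"), ("texter", "ok"),
                      ("counselor", "a thought"), ("texter", "sure"),
                      ("counselor", "an idea"), ("texter", "yes")])
        ex = extract_exchanges([conv], b_role="texter", a_role="counselor")
        assert len(ex) == 3
        assert [e.initial_index for e in ex] == [0, 2, 4]

    def test_consecutive_same_role_pairs_with_last_only(self):
        conv = _conv([("counselor", "first the message"),
                      ("counselor", "second an update"),
                      ("texter", "reply")])
        ex = extract_exchanges([conv], b_role="texter", a_role="counselor")
        assert len(ex) == 1
        assert ex[0].initial_index == 1

    def test_exhibit_flags_from_lexicon(self):
        conv = _conv([("counselor", "the plan"), ("texter", "a reply")])
        ex = extract_exchanges([conv], markers={"article": ["a", "an", "the"]})
        assert ex[0].exhibits_u1["article"] and ex[0].exhibits_u2["article"]

    def test_exchange_count_matches_generator(self, small_corpus):
        _, convs, _ = small_corpus
        # alternating counselor-first conversations: texter replies = floor(n/2)
        ex = extract_exchanges(convs)
        assert len(ex) == sum(len(c) // 2 for c in convs)


class TestPerMarker:
    def test_independence_fixture_zero(self):
        exs = [_exchange(*p) for p in [(1, 1), (1, 0), (0, 1), (0, 0)]]
        assert coordination_per_marker(exs, "m") == pytest.approx(0.0)

    def test_saturated_reply_zero(self):
        exs = [_exchange(u1, 1) for u1 in (1, 1, 0, 0)]
        assert coordination_per_marker(exs, "m") == pytest.approx(0.0)

    def test_hand_counted_five_exchange_fixture(self):
        exs = [_exchange(*p) for p in [(1, 1), (1, 1), (1, 0), (0, 0), (0, 1)]]
        assert coordination_per_marker(exs, "m") == pytest.approx(2 / 3 - 3 / 5)

    def test_undefined_when_initiator_never_exhibits(self):
        exs = [_exchange(0, 1), _exchange(0, 0)]
        assert coordination_per_marker(exs, "m") is None

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        pairs = [(int(rng.random() < 0.4), int(rng.random() < 0.5)) for _ in range(50)]
        exs = [_exchange(*p) for p in pairs]
        v1 = coordination_per_marker(exs, "m")
        rng.shuffle(exs)
        assert coordination_per_marker(exs, "m") == pytest.approx(v1)


class TestAggregate:
    def _two_marker_exchanges(self, speaker="s"):
        out = []
        for u1a, u2a, u1b, u2b in [(1, 1, 1, 1), (1, 1, 1, 0), (1, 0, 1, 1),
                                   (0, 0, 1, 1), (0, 1, 0, 0), (1, 1, 0, 0),
                                   (1, 0, 1, 1), (0, 0, 0, 0), (1, 1, 1, 1),
                                   (0, 1, 1, 0)]:
            out.append(Exchange("x", speaker, 0,
                                {"a": bool(u1a), "b": bool(u1b)},
                                {"a": bool(u2a), "b": bool(u2b)}))
        return out

    def test_single_marker_equals_per_marker(self):
        exs = [_exchange(*p) for p in [(1, 1), (1, 1), (1, 0), (0, 0), (0, 1)]] * 2
        res = aggregate(exs, ["m"], min_exchanges=10)
        assert res.per_speaker["s"] == pytest.approx(coordination_per_marker(exs, "m"))
        assert res.group_value == pytest.approx(res.per_speaker["s"])

    def test_macro_average_arithmetic(self):
        exs = self._two_marker_exchanges()
        res = aggregate(exs, ["a", "b"], min_exchanges=10)
        ca = coordination_per_marker(exs, "a")
        cb = coordination_per_marker(exs, "b")
        assert res.per_speaker["s"] == pytest.approx((ca + cb) / 2)

    def test_group_value_bounded_by_speakers(self):
        exs = self._two_marker_exchanges("s1") + [
            _exchange(*p, speaker="s2") for p in
            [(1, 1)] * 4 + [(1, 0)] * 2 + [(0, 0)] * 3 + [(0, 1)]]
        for e in exs:
            e.exhibits_u1.setdefault("a", e.exhibits_u1.get("m", False))
            e.exhibits_u2.setdefault("a", e.exhibits_u2.get("m", False))
        res = aggregate(exs, ["a"], min_exchanges=10)
        vals = list(res.per_speaker.values())
        assert min(vals) <= res.group_value <= max(vals)

    def test_speakers_below_minimum_excluded(self):
        exs = self._two_marker_exchanges("big") + [_exchange(1, 1, speaker="tiny")]
        for e in exs:
            e.exhibits_u1.setdefault("a", True)
            e.exhibits_u2.setdefault("a", True)
            e.exhibits_u1.setdefault("b", False)
            e.exhibits_u2.setdefault("b", False)
        res = aggregate(exs, ["a"], min_exchanges=10)
        assert "tiny" in res.excluded_speakers
        assert "tiny" not in res.per_speaker


class TestNullBehavior:
    def test_independent_speakers_center_on_zero(self):
        # 1000 simulated speakers with independent exhibit draws
        rng = np.random.default_rng(7)
        values = []
        for s in range(1000):
            exs = [_exchange(int(rng.random() < 0.3), int(rng.random() < 0.3),
                             speaker=f"s{s}") for _ in range(40)]
            v = coordination_per_marker(exs, "m")
            if v is not None:
                values.append(v)
        se = np.std(values) / np.sqrt(len(values))
        assert abs(np.mean(values)) < 2 * se + 1e-3

    def test_null_interval_covers_independent_data(self):
        rng = np.random.default_rng(9)
        exs = [_exchange(int(rng.random() < 0.3), int(rng.random() < 0.3),
                         speaker=f"s{i % 20}") for i in range(2000)]
        res = aggregate(exs, ["m"], min_exchanges=10)
        lo, hi = coordination_null_interval(exs, ["m"], n_perm=100, seed=0)
        assert lo <= res.group_value <= hi


class TestCategoryCoordination:
    def test_planted_future_only_effect(self):
        from counselkit.lexicons import PERSPECTIVE_CATEGORIES
        from counselkit.synthetic import GeneratorConfig, generate_corpus

        cats = {k: [w.rstrip("*") for w in v] for k, v in PERSPECTIVE_CATEGORIES.items()}
        sig = 0
        others_sig = 0
        seeds = 5
        for s in range(seeds):
            cfg = GeneratorConfig(
                seed=60 + s, n_counselors=6, conversations_per_counselor=12,
                markers=cats, base_marker_prob=0.2,
                coordination_delta={"future": 0.15},
                category_rates={}, behavior_rates={}, drift_strength=0.0,
            )
            convs, _ = generate_corpus(cfg)
            res = category_coordination(convs, cats)
            sig += res["future"].p_value < 0.01
            others_sig += sum(res[c].p_value < 0.01 for c in cats if c != "future"
                              and not np.isnan(res[c].p_value))
        assert sig >= 4
        # false positives across 6 null categories x 5 seeds stay rare
        assert others_sig <= 3

    def test_single_exchange_corpus_does_not_crash(self):
        conv = _conv([("counselor", "will see"), ("texter", "i will")])
        res = category_coordination([conv], {"future": ["will"]}, min_exchanges=1)
        assert res["future"].n_speakers in (0, 1)
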