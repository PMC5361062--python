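"""Situation setters, setter clustering, response classes, templatedness."""

import numpy as np
import pytest

from counselkit.ambiguity import (SituationSetter, ambiguity_outcome_table,
                                  classify_response, cluster_setters,
                                  counselor_texter_length_ratio,
                                  find_situation_setter, templatedness)
from counselkit.corpus import Conversation, Message, tokenize
from counselkit.vectorize import cosine_similarity_rows, tfidf_matrix


def _conv(conv_id, texts_roles, outcome=None, counselor="c"):
    msgs = [Message(role=r, text=t, index=i) for i, (r, t) in enumerate(texts_roles)]
    return Conversation(conv_id, counselor, msgs, outcome=outcome)


def _setter(i, text):
    toks = tokenize(text)
    return SituationSetter(conv_id=f"s{i}", message_index=1,
                           n_tokens=len(toks), tokens=toks, text=text)


class TestFindSituationSetter:
    def test_first_long_texter_message(self):
        conv = _conv("a", [
            ("counselor", "hi"),
            ("texter", "short one two"),                       # 3 tokens
            ("counselor", "tell me more"),
            ("texter", " ".join(f"w{i}" for i in range(14))),  # 14 tokens
            ("texter", " ".join(f"v{i}" for i in range(20))),
        ])
        s = find_situation_setter(conv, min_tokens=10)
        assert s.message_index == 3 and s.n_tokens == 14

    def test_none_when_all_short(self):
        conv = _conv("a", [("counselor", "hi"), ("texter", "ok then")])
        assert find_situation_setter(conv, min_tokens=10) is None

    def test_counselor_messages_ignored(self):
        conv = _conv("a", [
            ("counselor", " ".join(f"c{i}" for i in range(30))),
            ("texter", " ".join(f"t{i}" for i in range(12))),
        ])
        assert find_situation_setter(conv, 10).message_index == 1


class TestAmbiguityOutcomeTable:
    def _convs(self, lengths_outcomes):
        out = []
        for i, (L, oc) in enumerate(lengths_outcomes):
            out.append(_conv(f"c{i}", [
                ("counselor", "hello"),
                ("texter", " ".join(f"w{j}" for j in range(L))),
            ], outcome=oc))
        return out

    def test_all_positive_every_bin_one(self):
        convs = self._convs([(12, "positive"), (25, "positive"), (35, "positive")])
        t = ambiguity_outcome_table(convs, [10, 20, 30, 40])
        assert t.fraction_positive == [1.0, 1.0, 1.0]

    def test_single_bin_marginal_rate(self):
        convs = self._convs([(12, "positive"), (14, "negative"),
                             (16, "positive"), (18, "positive")])
        t = ambiguity_outcome_table(convs, [10, 100])
        assert t.fraction_positive[0] == pytest.approx(0.75)

    def test_empty_bin_flagged(self):
        convs = self._convs([(12, "positive")])
        t = ambiguity_outcome_table(convs, [10, 20, 30])
        assert t.empty_bins == [1]
        assert np.isnan(t.fraction_positive[1])

    def test_planted_length_outcome_link_increases(self):
        from counselkit.synthetic import GeneratorConfig, generate_corpus
        from scipy.stats import spearmanr

        cfg = GeneratorConfig(seed=17, n_counselors=8, conversations_per_counselor=80,
                              setter_length_effect=8.0)
        convs, _ = generate_corpus(cfg)
        t = ambiguity_outcome_table(convs, [1, 15, 22, 29, 200], min_tokens=1)
        rho = spearmanr(range(4), t.fraction_positive).statistic
        assert rho > 0.7


class TestLengthRatio:
    def test_identity_when_reply_equals_setter(self):
        convs = [_conv(f"c{i}", [
            ("counselor", "hi"),
            ("texter", " ".join(f"w{j}" for j in range(L))),
            ("counselor", " ".join(f"r{j}" for j in range(L))),
        ]) for i, L in enumerate((12, 18, 25))]
        ratios, counts = counselor_texter_length_ratio(convs, [10, 20, 30])
        assert ratios[0] == pytest.approx(1.0) and ratios[1] == pytest.approx(1.0)

    def test_fixture_ratio(self):
        convs = [_conv("a", [
            ("counselor", "hi"),
            ("texter", " ".join(f"w{j}" for j in range(10))),
            ("counselor", " ".join(f"r{j}" for j in range(15))),
        ])]
        ratios, _ = counselor_texter_length_ratio(convs, [5, 20])
        assert ratios[0] == pytest.approx(1.5)

    def test_constant_reply_gives_inverse_shape(self):
        convs = [_conv(f"c{i}", [
            ("counselor", "hi"),
            ("texter", " ".join(f"w{j}" for j in range(L))),
            ("counselor", " ".join(f"r{j}" for j in range(20))),
        ]) for i, L in enumerate((10, 20, 40))]
        ratios, _ = counselor_texter_length_ratio(convs, [9, 11, 19, 21, 39, 41])
        observed = [ratios[0], ratios[2], ratios[4]]
        assert observed == pytest.approx([2.0, 1.0, 0.5])


class TestClusterSetters:
    def test_identical_setters_one_cluster(self):
        setters = [_setter(i, "my partner left me and i feel alone") for i in range(12)]
        clusters = cluster_setters(setters, 0.4, min_neighbors=10)
        assert len(clusters) == 1
        assert clusters[0].members == list(range(12))

    def test_disjoint_singletons_excluded(self):
        base = [_setter(i, "my partner left me and i feel alone") for i in range(12)]
        noise = [_setter(100 + i, f"unique{i} words{i} only{i} here{i}") for i in range(5)]
        clusters = cluster_setters(base + noise, 0.4, min_neighbors=10)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 12

    def test_two_template_recovery_vs_brute_force(self):
        rng = np.random.default_rng(0)
        t1 = "i lost my job today and i do not know what to do next".split()
        t2 = "my exams are coming up and i cannot stop panicking about them".split()
        setters = []
        truth = []
        for i in range(30):
            base = list(t1 if i % 2 == 0 else t2)
            truth.append(i % 2)
            j = int(rng.integers(len(base)))
            base[j] = f"perturb{i}"
            setters.append(_setter(i, " ".join(base)))
        # brute-force oracle: explicit pairwise distance matrix
        mat, _ = tfidf_matrix([s.tokens for s in setters], n=2)
        dist = 1.0 - cosine_similarity_rows(mat)
        threshold = 0.8
        neighbor_counts = [(dist[i] <= threshold).sum() - 1 for i in range(30)]
        assert min(neighbor_counts) >= 10  # fixture is genuinely dense
        clusters = cluster_setters(setters, threshold, min_neighbors=10)
        assert len(clusters) == 2
        recovered = [sorted(c.members) for c in clusters]
        expected = [sorted(i for i in range(30) if truth[i] == g) for g in (0, 1)]
        assert sorted(recovered) == sorted(expected)

    def test_order_invariance(self):
        setters = [_setter(i, "my partner left me and i feel alone") for i in range(12)] \
            + [_setter(50 + i, "school is too much pressure for me right now") for i in range(12)]
        c1 = cluster_setters(setters, 0.4, 10)
        perm = list(reversed(setters))
        c2 = cluster_setters(perm, 0.4, 10)
        sets1 = sorted(tuple(sorted(setters[i].conv_id for i in c.members)) for c in c1)
        sets2 = sorted(tuple(sorted(perm[i].conv_id for i in c.members)) for c in c2)
        assert sets1 == sets2

    def test_bad_threshold_rejected(self):
        setters = [_setter(i, "same text here okay") for i in range(12)]
        with pytest.raises(ValueError):
            cluster_setters(setters, 1.4, 10)


class TestClassifyResponse:
    SETTER = None

    @pytest.fixture(autouse=True)
    def _setter_fixture(self):
        self.SETTER = _setter(0, "i have been feeling really down since my breakup")

    @pytest.mark.parametrize("reply,expected", [
        ("that sounds like a really hard situation", "check_question"),
        ("do you ever feel like you want to die", "suicide_check"),
        ("i appreciate you reaching out", "thanks"),
        ("maybe we can think this through", "hedge"),
        ("oh, this sounds really awful", "surprise"),
    ])
    def test_exemplars_trigger_exactly_their_class(self, reply, expected):
        cls = classify_response(self.SETTER, reply, None)
        flags = cls.flags()
        assert flags[expected] is True
        assert all(not v for k, v in flags.items() if k != expected)

    def test_empty_reply_all_false(self):
        cls = classify_response(self.SETTER, None, None)
        assert not any(cls.flags().values())
        assert cls.sim_counselor_setter == 0.0

    def test_identical_reply_similarity_one(self):
        cls = classify_response(self.SETTER, self.SETTER.text, None)
        assert cls.sim_counselor_setter == pytest.approx(1.0)

    def test_classification_pure_function_of_text(self):
        reply = "Maybe   we can think,  this THROUGH"
        a = classify_response(self.SETTER, reply, None)
        b = classify_response(self.SETTER, " ".join(tokenize(reply)), None)
        assert a.flags() == b.flags()


class TestTemplatedness:
    def test_all_identical(self):
        replies = [tokenize("let us think about what might help") for _ in range(10)]
        assert templatedness(replies, 0.4) == [9] * 10

    def test_all_disjoint(self):
        replies = [tokenize(f"alpha{i} beta{i} gamma{i} delta{i}") for i in range(6)]
        assert templatedness(replies, 0.4) == [0] * 6

    def test_two_template_counts(self):
        a = tokenize("have you thought about talking to someone you trust")
        b = tokenize("what usually helps you calm down when things get hard")
        replies = [a] * 7 + [b] * 3
        counts = templatedness(replies, 0.4)
        assert counts == [6] * 7 + [2] * 3

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        words = [f"w{i}" for i in range(12)]
        replies = [list(rng.choice(words, size=6)) for _ in range(15)]
        counts = templatedness(replies, 0.7)
        mat, _ = tfidf_matrix(replies, n=2)
        dist = 1.0 - cosine_similarity_rows(mat)
        np.fill_diagonal(dist, np.inf)
        inn = dist <= 0.7
        assert np.array_equal(inn, inn.T)
        assert counts == [int(r.sum()) for r in inn]

    def test_needs_two_replies(self):
        with pytest.raises(ValueError):
            templatedness([tokenize("only one")], 0.4)
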