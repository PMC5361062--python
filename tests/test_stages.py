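"""Ordered-stage HMM: vocabulary, EM, forward-backward, Viterbi, durations."""

import numpy as np
import pytest

from counselkit.corpus import Conversation, Message, split_counselors
from counselkit.stages import (ROLE_INDEX, UNK, StageHMM, Vocabulary,
                               brute_force_loglik, brute_force_viterbi,
                               build_vocab, encode_conversation, fit_em,
                               forward_backward, init_model, stage_durations,
                               viterbi_decode)


def _conv(texts, conv_id="x", counselor="c", outcome=None):
    msgs = [Message(role="counselor" if i % 2 == 0 else "texter", text=t, index=i)
            for i, t in enumerate(texts)]
    return Conversation(conv_id, counselor, msgs, outcome=outcome)


def _random_model(S, V, rng, max_advance=0.9):
    index = {f"w{i}": i for i in range(V - 1)}
    index[UNK] = V - 1
    vocab = Vocabulary(index=index, coverage=1.0,
                       word_counts={w: 50 for w in index if w != UNK})
    e = rng.random((S, 2, V)) + 0.05
    e /= e.sum(axis=2, keepdims=True)
    a = rng.random((S, 2)) * max_advance
    a[-1] = 0.0
    return StageHMM(n_stages=S, vocab=vocab, emission=e, advance_prob=a,
                    role_unigram=np.full((2, V), 1.0 / V))


def _random_conv(rng, words, n):
    texts = [" ".join(rng.choice(words, size=int(rng.integers(1, 6))))
             for _ in range(n)]
    return _conv(texts)


class TestBuildVocab:
    def test_strictly_more_than_min_count(self):
        texts = [" ".join(["often"] * 21 + ["exactly"] * 20 + ["rare"])]
        vocab = build_vocab([_conv(texts)], min_count=20)
        assert "often" in vocab.index
        assert "exactly" not in vocab.index
        assert "rare" not in vocab.index
        assert vocab.coverage == pytest.approx(21 / 42)

    def test_min_count_zero_keeps_everything(self, small_corpus):
        _, convs, _ = small_corpus
        vocab = build_vocab(convs[:5], min_count=0)
        assert vocab.coverage == pytest.approx(1.0)

    def test_known_frequency_fixture(self):
        # corpus frequencies: a=4, b=3, c=3; strict > 3 keeps only a
        convs = [_conv(["a a a b", "b c"]), _conv(["a b", "c c"])]
        vocab = build_vocab(convs, min_count=3)
        assert set(vocab.index) - {UNK} == {"a"}

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocab([])


class TestInitModel:
    def test_zero_perturbation_identical_unigram(self, small_corpus):
        _, convs, _ = small_corpus
        m = init_model(convs[:10], n_stages=3, perturbation=0.0)
        for s in range(3):
            assert np.allclose(m.emission[s], m.role_unigram)
        assert np.allclose(m.emission.sum(axis=2), 1.0)
        assert np.all(m.advance_prob[:-1] == 0.5)
        assert np.all(m.advance_prob[-1] == 0.0)

    def test_same_seed_identical(self, small_corpus):
        _, convs, _ = small_corpus
        a = init_model(convs[:10], seed=3)
        b = init_model(convs[:10], seed=3)
        assert np.array_equal(a.emission, b.emission)


class TestForwardBackward:
    def test_single_message_all_mass_on_stage_one(self):
        rng = np.random.default_rng(0)
        m = _random_model(3, 6, rng)
        post = forward_backward(m, _conv(["w0 w1"]))
        assert np.allclose(post.gamma[0], [1.0, 0.0, 0.0])

    def test_identical_emissions_match_markov_occupancy(self):
        rng = np.random.default_rng(1)
        m = _random_model(3, 6, rng)
        m.emission[:] = m.emission[0]  # emission-free limit
        conv = _random_conv(rng, ["w0", "w1", "w2"], 7)
        post = forward_backward(m, conv)
        roles, _ = encode_conversation(conv, m.vocab)
        occ = np.zeros((7, 3))
        occ[0, 0] = 1.0
        for i in range(1, 7):
            r = roles[i - 1]
            for s in range(3):
                occ[i, s] += occ[i - 1, s] * (1 - m.advance_prob[s, r])
                if s > 0:
                    occ[i, s] += occ[i - 1, s - 1] * m.advance_prob[s - 1, r]
        assert np.allclose(post.gamma, occ, atol=1e-12)

    def test_hand_set_toy_matches_brute_force(self):
        rng = np.random.default_rng(2)
        m = _random_model(2, 5, rng)
        m.advance_prob[0] = [0.3, 0.6]
        conv = _random_conv(rng, ["w0", "w1", "w2", "w3"], 6)
        post = forward_backward(m, conv)
        assert post.log_likelihood == pytest.approx(
            brute_force_loglik(m, conv), rel=1e-9)

    def test_posteriors_are_consistent(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            S = int(rng.integers(2, 5))
            m = _random_model(S, 7, rng)
            conv = _random_conv(rng, [f"w{i}" for i in range(6)],
                                int(rng.integers(2, 9)))
            post = forward_backward(m, conv)
            assert np.allclose(post.gamma.sum(axis=1), 1.0, atol=1e-10)
            # transition posteriors marginalize to the stage posteriors
            assert np.allclose(post.xi_stay + post.xi_advance,
                               post.gamma[:-1], atol=1e-10)
            incoming = post.xi_stay.copy()
            incoming[:, 1:] += post.xi_advance[:, :-1]
            assert np.allclose(incoming, post.gamma[1:], atol=1e-10)

    def test_monotone_constraint_zero_mass_on_jumps(self):
        rng = np.random.default_rng(4)
        m = _random_model(4, 6, rng)
        conv = _random_conv(rng, ["w0", "w1"], 3)
        post = forward_backward(m, conv)
        # after i messages at most stage i is reachable
        assert post.gamma[0, 1:].max() == 0.0
        assert post.gamma[1, 2:].max() == 0.0


class TestFitEM:
    def test_trace_non_decreasing(self, small_corpus):
        _, convs, _ = small_corpus
        m = init_model(convs[:30], n_stages=3, seed=1)
        m = fit_em(m, convs[:30], max_iter=15, tol=1e-9)
        tr = m.log_likelihood_trace
        assert len(tr) > 1
        assert all(b >= a - 1e-6 for a, b in zip(tr, tr[1:]))
        assert np.allclose(m.emission.sum(axis=2), 1.0, atol=1e-10)

    def test_one_stage_converges_to_role_unigram_in_one_step(self, small_corpus):
        _, convs, _ = small_corpus
        sub = convs[:20]
        m = init_model(sub, n_stages=1, perturbation=0.05, seed=2, smoothing=0.0)
        m = fit_em(m, sub, max_iter=1)
        assert np.allclose(m.emission[0], m.role_unigram, atol=1e-12)


class TestViterbi:
    def test_single_message_path(self):
        rng = np.random.default_rng(5)
        m = _random_model(3, 6, rng)
        assert viterbi_decode(m, _conv(["w0"])).stages == [1]

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            S = int(rng.integers(1, 4))
            m = _random_model(S, int(rng.integers(3, 9)), rng)
            words = [w for w in m.vocab.index if w != UNK]
            conv = _random_conv(rng, words, int(rng.integers(1, 9)))
            assert viterbi_decode(m, conv).stages == brute_force_viterbi(m, conv).stages

    def test_decoded_paths_satisfy_invariants(self, small_corpus, fitted_stage_model):
        _, convs, _ = small_corpus
        m = fitted_stage_model
        for conv in convs[:20]:
            path = viterbi_decode(m, conv)
            s = path.stages
            assert s[0] == 1
            assert all(0 <= b - a <= 1 for a, b in zip(s, s[1:]))
            assert sum(path.durations) == len(conv)

    def test_planted_stage_recovery(self, staged_corpus, fitted_stage_model):
        _, convs, gt = staged_corpus
        correct = total = 0
        for c in convs[:50]:
            p = viterbi_decode(fitted_stage_model, c).stages
            correct += sum(a == b for a, b in zip(p, gt.stages[c.conv_id]))
            total += len(p)
        assert correct / total >= 0.9


class TestStageDurations:
    def test_durations_and_equal_weighting(self, staged_corpus, fitted_stage_model):
        _, convs, _ = staged_corpus
        split = split_counselors(convs, top_n=5, bottom_n=5)
        base = stage_durations(convs, fitted_stage_model, split, seed=0, n_boot=10)
        # duplicating all negative conversations must not move group means
        dup = list(convs)
        for c in convs:
            if c.outcome == "negative":
                dup.append(Conversation(c.conv_id + "d", c.counselor_id,
                                        c.messages, outcome=c.outcome))
        doubled = stage_durations(dup, fitted_stage_model, split, seed=0, n_boot=10)
        for key in base:
            assert base[key][0] == pytest.approx(doubled[key][0], abs=1e-9)

    def test_no_qualifying_conversations_raises(self, staged_corpus, fitted_stage_model):
        _, convs, _ = staged_corpus
        split = split_counselors(convs, top_n=5, bottom_n=5)
        with pytest.raises(ValueError, match="qualifying"):
            stage_durations(convs, fitted_stage_model, split,
                            min_len=1000, max_len=2000)

    def test_planted_advance_gap_recovered(self):
        from counselkit.stages import fit_stage_model
        from counselkit.synthetic import GeneratorConfig, generate_corpus

        hits = 0
        for seed in range(3):
            slow = {f"c{i:03d}": [0.15, 0.05, 0.15, 0.15, 0.0] for i in range(3, 6)}
            cfg = GeneratorConfig(seed=30 + seed, n_counselors=6,
                                  conversations_per_counselor=25,
                                  advance_prob_overrides=slow)
            convs, gt = generate_corpus(cfg)
            split = split_counselors(convs, top_n=3, bottom_n=3)
            model = fit_stage_model(convs[:100], n_stages=5, seed=0)
            dur = stage_durations(convs, model, split, seed=0, n_boot=10)
            # low-quality counselors (the bottom group) dwell longer in stage 2
            gap = dur[("less_successful", 2)][0] - dur[("more_successful", 2)][0]
            hits += gap > 0
        assert hits >= 2
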