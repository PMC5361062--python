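"""Ordered-stage conversation model: a message-level HMM with left-to-right
stage structure and role-split states.

Each hidden state is a conversation stage (introductions → problem
introduction → exploration → problem solving → wrap-up, with five stages by
default).  A conversation starts in stage 1 and may only stay or advance to
the next stage after each message, so the model learns a dialogue structure
shared by all conversations rather than free topics.  Counselor and texter
messages are emitted by distinct per-stage unigram distributions (the
speaker role is observed, only the stage is latent), and a message's
emission probability is the product of its tokens' probabilities (bag of
words).  The stage-advance probability is per (stage, role): a transition
opportunity follows every message.

Training is expectation maximization with the forward-backward algorithm;
decoding is Viterbi under the monotone-path constraint.  Exhaustive
enumeration over all monotone stage sequences is provided as an oracle for
small conversations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import (COUNSELOR, NEGATIVE, POSITIVE, TEXTER, Conversation,
                     CounselorSplit)

ROLE_INDEX = {COUNSELOR: 0, TEXTER: 1}
UNK = "<unk>"


@dataclass
class Vocabulary:
    """Kept words plus an unknown token folding everything rarer."""

    index: dict[str, int]          # word -> id; UNK has the last id
    coverage: float                # fraction of corpus tokens kept verbatim
    word_counts: dict[str, int]    # corpus frequency of kept words

    @property
    def unk_id(self) -> int:
        return self.index[UNK]

    @property
    def size(self) -> int:
        return len(self.index)

    def encode(self, tokens: Sequence[str]) -> list[int]:
        unk = self.unk_id
        return [self.index.get(t, unk) for t in tokens]

    def words(self) -> list[str]:
        out = [""] * self.size
        for w, i in self.index.items():
            out[i] = w
        return out


def build_vocab(convs: Sequence[Conversation], min_count: int = 20) -> Vocabulary:
    """Keep words occurring strictly more than ``min_count`` times; fold the
    rest into an unknown token."""
    if not convs:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: dict[str, int] = {}
    total = 0
    for c in convs:
        for m in c.messages:
            for t in m.tokens:
                counts[t] = counts.get(t, 0) + 1
                total += 1
    kept = sorted(w for w, n in counts.items() if n > min_count)
    index = {w: i for i, w in enumerate(kept)}
    index[UNK] = len(kept)
    kept_tokens = sum(counts[w] for w in kept)
    coverage = kept_tokens / total if total else 0.0
    return Vocabulary(index=index, coverage=coverage,
                      word_counts={w: counts[w] for w in kept})


@dataclass
class StagePath:
    """Decoded stage assignment of one conversation (1-based stages)."""

    stages: list[int]
    n_stages: int

    @property
    def durations(self) -> list[int]:
        out = [0] * self.n_stages
        for s in self.stages:
            out[s - 1] += 1
        return out


@dataclass
class StageHMM:
    """Left-to-right stage HMM over messages with role-split emissions."""

    n_stages: int
    vocab: Vocabulary
    emission: np.ndarray            # (n_stages, 2 roles, V) probabilities
    advance_prob: np.ndarray        # (n_stages, 2 roles); last stage all 0
    role_unigram: np.ndarray        # (2, V) corpus unigram per role
    log_likelihood_trace: list[float] = field(default_factory=list)
    smoothing: float = 1e-6         # uniform-mixture weight in each M step

    def __post_init__(self) -> None:
        if not np.allclose(self.emission.sum(axis=2), 1.0, atol=1e-10):
            raise ValueError("emission rows must sum to 1")
        if np.any(self.advance_prob < 0) or np.any(self.advance_prob > 1):
            raise ValueError("advance probabilities must lie in [0, 1]")
        if np.any(self.advance_prob[-1] != 0.0):
            raise ValueError("the last stage cannot advance")

    # --- serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({
                "n_stages": self.n_stages,
                "vocab": {"index": self.vocab.index,
                          "coverage": self.vocab.coverage,
                          "word_counts": self.vocab.word_counts},
                "emission": self.emission.tolist(),
                "advance_prob": self.advance_prob.tolist(),
                "role_unigram": self.role_unigram.tolist(),
                "log_likelihood_trace": self.log_likelihood_trace,
                "smoothing": self.smoothing,
            }, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "StageHMM":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            n_stages=d["n_stages"],
            vocab=Vocabulary(index=d["vocab"]["index"],
                             coverage=d["vocab"]["coverage"],
                             word_counts=d["vocab"]["word_counts"]),
            emission=np.array(d["emission"]),
            advance_prob=np.array(d["advance_prob"]),
            role_unigram=np.array(d["role_unigram"]),
            log_likelihood_trace=list(d["log_likelihood_trace"]),
            smoothing=d["smoothing"],
        )


def _role_unigram(convs: Sequence[Conversation], vocab: Vocabulary) -> np.ndarray:
    counts = np.zeros((2, vocab.size))
    for c in convs:
        for m in c.messages:
            r = ROLE_INDEX[m.role]
            for i in vocab.encode(m.tokens):
                counts[r, i] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0.0] = 1.0
    return counts / totals


def init_model(
    convs: Sequence[Conversation],
    n_stages: int = 5,
    perturbation: float = 1e-2,
    seed: int = 0,
    vocab: Optional[Vocabulary] = None,
    min_count: int = 20,
    smoothing: float = 1e-6,
) -> StageHMM:
    """Stated initialization: per-role corpus unigram emissions for every
    stage and uniform (0.5) advance probabilities.

    That initialization is an EM fixed point (all stages identical), so a
    small seeded multiplicative perturbation breaks the symmetry.
    """
    if vocab is None:
        vocab = build_vocab(convs, min_count=min_count)
    unigram = _role_unigram(convs, vocab)
    rng = np.random.default_rng(seed)
    emission = np.empty((n_stages, 2, vocab.size))
    for s in range(n_stages):
        for r in range(2):
            e = unigram[r] * (1.0 + perturbation * rng.uniform(-1.0, 1.0, vocab.size))
            e = np.clip(e, 1e-300, None)
            emission[s, r] = e / e.sum()
    advance = np.full((n_stages, 2), 0.5)
    advance[-1] = 0.0
    return StageHMM(
        n_stages=n_stages, vocab=vocab, emission=emission,
        advance_prob=advance, role_unigram=unigram, smoothing=smoothing,
    )


# --- encoding --------------------------------------------------------------


def encode_conversation(conv: Conversation, vocab: Vocabulary) -> tuple[np.ndarray, sp.csr_matrix]:
    """(roles, token-count matrix) of one conversation against the vocab."""
    roles = np.array([ROLE_INDEX[m.role] for m in conv.messages], dtype=np.intp)
    rows, cols, vals = [], [], []
    for i, m in enumerate(conv.messages):
        counts: dict[int, int] = {}
        for t in vocab.encode(m.tokens):
            counts[t] = counts.get(t, 0) + 1
        for t, v in counts.items():
            rows.append(i)
            cols.append(t)
            vals.append(v)
    mat = sp.csr_matrix((vals, (rows, cols)),
                        shape=(len(conv.messages), vocab.size), dtype=float)
    return roles, mat


def _message_logprobs(model: StageHMM, roles: np.ndarray, counts: sp.csr_matrix) -> np.ndarray:
    """(n_messages, n_stages) bag-of-words log emission probabilities."""
    log_e = np.log(model.emission)  # (S, 2, V)
    out = np.empty((len(roles), model.n_stages))
    for r in range(2):
        rows = np.flatnonzero(roles == r)
        if rows.size:
            out[rows] = counts[rows] @ log_e[:, r, :].T
    return out


# --- forward-backward ------------------------------------------------------


@dataclass
class Posteriors:
    log_likelihood: float
    gamma: np.ndarray        # (n_messages, n_stages) stage posteriors
    xi_stay: np.ndarray      # (n_messages-1, n_stages) P(stage s at i and i+1)
    xi_advance: np.ndarray   # (n_messages-1, n_stages) P(s at i, s+1 at i+1)


def _log_advance(model: StageHMM) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore"):
        la = np.log(model.advance_prob)        # (S, 2)
        ls = np.log1p(-model.advance_prob)
    return la, ls


def forward_backward(
    model: StageHMM,
    conv: Conversation | tuple[np.ndarray, sp.csr_matrix],
) -> Posteriors:
    """Exact posteriors under the monotone-stage constraint.

    Raises if the conversation has probability zero under every stage path
    (prevented in practice by emission smoothing).
    """
    roles, counts = (
        encode_conversation(conv, model.vocab)
        if isinstance(conv, Conversation) else conv
    )
    n, S = len(roles), model.n_stages
    logB = _message_logprobs(model, roles, counts)
    log_a, log_stay = _log_advance(model)

    alpha = np.full((n, S), -np.inf)
    alpha[0, 0] = logB[0, 0]
    for i in range(1, n):
        r = roles[i - 1]
        stay = alpha[i - 1] + log_stay[:, r]
        adv = np.full(S, -np.inf)
        adv[1:] = alpha[i - 1, :-1] + log_a[:-1, r]
        alpha[i] = np.logaddexp(stay, adv) + logB[i]
    ll = float(_logsumexp(alpha[-1]))
    if not math.isfinite(ll):
        raise ValueError("conversation has zero probability under the model")

    beta = np.zeros((n, S))
    for i in range(n - 2, -1, -1):
        r = roles[i]
        nxt = logB[i + 1] + beta[i + 1]
        stay = log_stay[:, r] + nxt
        adv = np.full(S, -np.inf)
        adv[:-1] = log_a[:-1, r] + nxt[1:]
        beta[i] = np.logaddexp(stay, adv)

    gamma = np.exp(alpha + beta - ll)
    xi_stay = np.empty((n - 1, S))
    xi_adv = np.empty((n - 1, S))
    for i in range(n - 1):
        r = roles[i]
        nxt = logB[i + 1] + beta[i + 1]
        xi_stay[i] = np.exp(alpha[i] + log_stay[:, r] + nxt - ll)
        adv = np.full(S, -np.inf)
        adv[:-1] = alpha[i, :-1] + log_a[:-1, r] + nxt[1:]
        xi_adv[i] = np.exp(adv - ll)
    return Posteriors(log_likelihood=ll, gamma=gamma,
                      xi_stay=xi_stay, xi_advance=xi_adv)


def _logsumexp(v: np.ndarray) -> float:
    m = np.max(v)
    if not math.isfinite(m):
        return float(m)
    return float(m + math.log(np.exp(v - m).sum()))


# --- EM --------------------------------------------------------------------


def fit_em(
    model: StageHMM,
    convs: Sequence[Conversation],
    max_iter: int = 100,
    tol: float = 1e-4,
) -> StageHMM:
    """Expectation maximization until the relative log-likelihood change
    drops below ``tol``; the per-iteration trace is recorded on the model."""
    encoded = [encode_conversation(c, model.vocab) for c in convs]
    S, V = model.n_stages, model.vocab.size
    prev_ll = None
    for it in range(max_iter):
        exp_counts = np.zeros((S, 2, V))
        adv_num = np.zeros((S, 2))
        adv_den = np.zeros((S, 2))
        total_ll = 0.0
        for roles, counts in encoded:
            post = forward_backward(model, (roles, counts))
            total_ll += post.log_likelihood
            for r in range(2):
                rows = np.flatnonzero(roles == r)
                if rows.size:
                    exp_counts[:, r, :] += post.gamma[rows].T @ counts[rows]
            for r in range(2):
                rows = np.flatnonzero(roles[:-1] == r)
                if rows.size:
                    adv_num[:, r] += post.xi_advance[rows].sum(axis=0)
                    adv_den[:, r] += (post.xi_advance[rows] + post.xi_stay[rows]).sum(axis=0)
        if not math.isfinite(total_ll):
            raise ValueError(f"non-finite corpus log likelihood at EM iteration {it}")
        model.log_likelihood_trace.append(total_ll)

        # M step: emissions with a uniform-mixture smoothing floor
        row_tot = exp_counts.sum(axis=2, keepdims=True)
        uniform = np.full((S, 2, V), 1.0 / V)
        nonzero = row_tot[:, :, 0] > 0
        new_e = uniform.copy()
        with np.errstate(invalid="ignore"):
            mle = np.where(row_tot > 0, exp_counts / np.where(row_tot > 0, row_tot, 1.0), 0.0)
        new_e[nonzero] = (1.0 - model.smoothing) * mle[nonzero] + model.smoothing / V
        model.emission = new_e

        new_a = np.zeros((S, 2))
        mask = adv_den > 0
        new_a[mask] = adv_num[mask] / adv_den[mask]
        new_a[-1] = 0.0
        model.advance_prob = np.clip(new_a, 0.0, 1.0)

        if prev_ll is not None:
            rel = abs(total_ll - prev_ll) / max(abs(prev_ll), 1.0)
            if rel < tol:
                break
        prev_ll = total_ll
    return model


def fit_stage_model(
    convs: Sequence[Conversation],
    n_stages: int = 5,
    min_count: int = 20,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    advance_inits: Sequence[float] | None = None,
    perturbation: float = 1e-2,
    n_seed_restarts: int = 3,
) -> StageHMM:
    """Fit the stage model with restarts, selected by corpus log likelihood.

    The symmetric initialization (identical per-role unigram emissions,
    advance probability 0.5 everywhere) sits in a poor basin for strongly
    staged corpora: EM collapses one stage and merges late ones, and which
    basin a run reaches also depends on the symmetry-breaking perturbation
    draw.  Restarting over a coarse geometric grid of initial advance
    probabilities crossed with a few perturbation seeds, and keeping the fit
    with the best final corpus log likelihood, finds the dominant basin
    without reference to any ground truth.
    """
    if advance_inits is None:
        advance_inits = np.geomspace(0.05, 0.5, 5)
    vocab = build_vocab(convs, min_count=min_count)
    best: Optional[StageHMM] = None
    for s in range(n_seed_restarts):
        for a0 in advance_inits:
            model = init_model(convs, n_stages=n_stages, perturbation=perturbation,
                               seed=seed + s, vocab=vocab)
            model.advance_prob[:-1] = a0
            model = fit_em(model, convs, max_iter=max_iter, tol=tol)
            if best is None or model.log_likelihood_trace[-1] > best.log_likelihood_trace[-1]:
                best = model
    assert best is not None
    return best


# --- decoding --------------------------------------------------------------


def viterbi_decode(
    model: StageHMM,
    conv: Conversation | tuple[np.ndarray, sp.csr_matrix],
) -> StagePath:
    """Most probable monotone stage path; ties break toward staying in the
    current stage (advances happen as late as possible)."""
    roles, counts = (
        encode_conversation(conv, model.vocab)
        if isinstance(conv, Conversation) else conv
    )
    n, S = len(roles), model.n_stages
    logB = _message_logprobs(model, roles, counts)
    log_a, log_stay = _log_advance(model)

    # best achievable suffix score from message i in stage s
    V = np.empty((n, S))
    V[n - 1] = logB[n - 1]
    for i in range(n - 2, -1, -1):
        r = roles[i]
        stay = log_stay[:, r] + V[i + 1]
        adv = np.full(S, -np.inf)
        adv[:-1] = log_a[:-1, r] + V[i + 1, 1:]
        V[i] = logB[i] + np.maximum(stay, adv)

    # walk forward from the forced start, staying whenever staying is optimal
    path = [0]
    s = 0
    for i in range(n - 1):
        r = roles[i]
        stay = log_stay[s, r] + V[i + 1, s]
        adv = log_a[s, r] + V[i + 1, s + 1] if s + 1 < S else -np.inf
        if adv > stay:
            s += 1
        path.append(s)
    return StagePath(stages=[s + 1 for s in path], n_stages=S)


# --- brute-force oracles ---------------------------------------------------


def _monotone_paths(n: int, n_stages: int):
    """All stage paths of length n: start at 0, steps of 0 or +1, in
    lexicographic order."""
    path = [0] * n

    def rec(i: int):
        if i == n:
            yield tuple(path)
            return
        prev = path[i - 1]
        for s in (prev, prev + 1) if prev + 1 < n_stages else (prev,):
            path[i] = s
            yield from rec(i + 1)

    if n == 0:
        return
    yield from rec(1)


def brute_force_loglik(model: StageHMM, conv: Conversation) -> float:
    """Total likelihood by explicit summation over all monotone stage paths."""
    roles, counts = encode_conversation(conv, model.vocab)
    logB = _message_logprobs(model, roles, counts)
    log_a, log_stay = _log_advance(model)
    terms = []
    for path in _monotone_paths(len(roles), model.n_stages):
        if path[0] != 0:
            continue
        lp = 0.0
        for i, s in enumerate(path):
            lp += logB[i, s]
            if i + 1 < len(path):
                r = roles[i]
                lp += log_a[s, r] if path[i + 1] == s + 1 else log_stay[s, r]
        terms.append(lp)
    return _logsumexp(np.array(terms))


def brute_force_viterbi(model: StageHMM, conv: Conversation) -> StagePath:
    """Argmax over all monotone paths; first (lexicographically smallest)
    maximizer wins, matching the decoder's stay-on-ties rule."""
    roles, counts = encode_conversation(conv, model.vocab)
    logB = _message_logprobs(model, roles, counts)
    log_a, log_stay = _log_advance(model)
    best, best_lp = None, -np.inf
    for path in _monotone_paths(len(roles), model.n_stages):
        lp = 0.0
        for i, s in enumerate(path):
            lp += logB[i, s]
            if i + 1 < len(path):
                r = roles[i]
                lp += log_a[s, r] if path[i + 1] == s + 1 else log_stay[s, r]
        if lp > best_lp:
            best, best_lp = path, lp
    assert best is not None
    return StagePath(stages=[s + 1 for s in best], n_stages=model.n_stages)


# --- analytics -------------------------------------------------------------


def stage_durations(
    convs: Sequence[Conversation],
    model: StageHMM,
    split: CounselorSplit,
    min_len: int = 40,
    max_len: int = 60,
    n_boot: int = 200,
    seed: int = 0,
) -> dict[tuple[str, int], tuple[float, float, float]]:
    """Mean Viterbi stage durations per counselor group.

    Only labeled conversations of ``min_len``–``max_len`` messages enter
    (length control); positive and negative conversations get equal weight
    within a group.  Returns (group, 1-based stage) → (mean, ci_lo, ci_hi)
    with a bootstrap over counselors.
    """
    rows = []  # (group, counselor, outcome, durations)
    for c in convs:
        if not c.labeled or not (min_len <= len(c) <= max_len):
            continue
        g = split.group_of(c.counselor_id)
        if g is None:
            continue
        path = viterbi_decode(model, c)
        rows.append((g, c.counselor_id, c.outcome, np.array(path.durations, dtype=float)))
    if not rows:
        raise ValueError("no qualifying conversations for stage-duration analysis")

    def group_mean(entries) -> np.ndarray:
        by_outcome = {POSITIVE: [], NEGATIVE: []}
        for _, _, oc, dur in entries:
            by_outcome[oc].append(dur)
        means = [np.mean(v, axis=0) for v in by_outcome.values() if v]
        return np.mean(means, axis=0)

    rng = np.random.default_rng(seed)
    out: dict[tuple[str, int], tuple[float, float, float]] = {}
    for g in ("more_successful", "less_successful"):
        entries = [r for r in rows if r[0] == g]
        if not entries:
            raise ValueError(f"no qualifying conversations for group {g}")
        point = group_mean(entries)
        counselors = sorted({r[1] for r in entries})
        by_c = {c: [r for r in entries if r[1] == c] for c in counselors}
        boots = np.empty((n_boot, model.n_stages))
        for b in range(n_boot):
            sample = rng.choice(counselors, size=len(counselors), replace=True)
            picked = [r for c in sample for r in by_c[c]]
            if not any(r[2] == POSITIVE for r in picked) or not any(r[2] == NEGATIVE for r in picked):
                boots[b] = np.nan
                continue
            boots[b] = group_mean(picked)
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
        for s in range(model.n_stages):
            out[(g, s + 1)] = (float(point[s]), float(lo[s]), float(hi[s]))
    return out


def top_words(
    model: StageHMM,
    per_stage: int = 5,
    min_freq: int = 0,
) -> dict[tuple[int, str], list[str]]:
    """Words with the greatest emission-likelihood increase per stage.

    Ranked by the ratio of the stage emission probability to the corpus
    unigram probability for the word's role, restricted to words above a
    corpus-frequency floor; the unknown token is excluded.
    """
    words = model.vocab.words()
    out: dict[tuple[int, str], list[str]] = {}
    for s in range(model.n_stages):
        for role, r in ROLE_INDEX.items():
            ratios = []
            for i, w in enumerate(words):
                if w == UNK or model.vocab.word_counts.get(w, 0) < min_freq:
                    continue
                base = model.role_unigram[r, i]
                if base <= 0:
                    continue
                ratios.append((model.emission[s, r, i] / base, w))
            ratios.sort(key=lambda t: (-t[0], t[1]))
            out[(s + 1, role)] = [w for _, w in ratios[:per_stage]]
    return out
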