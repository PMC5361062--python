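"""Predicting the conversation outcome from a message prefix.

A logistic-regression classifier over features computed on the first *x*% of
a conversation's messages: counselor hedge and check-question rates, mean
similarity of counselor messages to the preceding texter message, per-stage
Viterbi durations under the stage model, mean per-message sentiment and
message length, stage-conjunction features (each base feature averaged
within each decoded stage), and optionally counselor unigram/bigram counts.
Training is penalized batch gradient descent (L1 when n-gram features are
present, L2 otherwise); evaluation is stratified 10-fold cross-validation
with the area under the ROC curve computed by the rank statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .corpus import COUNSELOR, NEGATIVE, POSITIVE, TEXTER, Conversation
from .lexicons import (PERSPECTIVE_CATEGORIES, RESPONSE_PATTERNS,
                       WordMatcher, compile_patterns)
from .stages import StageHMM, viterbi_decode
from .vectorize import ngram_terms

# ---------------------------------------------------------------------------
# dataset assembly


def balance_dataset(
    convs: Sequence[Conversation],
    min_messages: int = 30,
    seed: int = 0,
) -> list[Conversation]:
    """Equal-size positive/negative sets of long-enough conversations.

    Keeps labeled conversations strictly longer than ``min_messages`` and
    randomly subsamples the larger outcome class (seeded, order-preserving).
    """
    eligible = [c for c in convs if c.labeled and len(c) > min_messages]
    pos = [c for c in eligible if c.outcome == POSITIVE]
    neg = [c for c in eligible if c.outcome == NEGATIVE]
    if not pos or not neg:
        raise ValueError("both outcome classes must be present to balance")
    rng = np.random.default_rng(seed)
    n = min(len(pos), len(neg))
    if len(pos) > n:
        keep = set(rng.choice(len(pos), size=n, replace=False))
        pos = [c for i, c in enumerate(pos) if i in keep]
    if len(neg) > n:
        keep = set(rng.choice(len(neg), size=n, replace=False))
        neg = [c for i, c in enumerate(neg) if i in keep]
    order = {c.conv_id: i for i, c in enumerate(convs)}
    return sorted(pos + neg, key=lambda c: order[c.conv_id])


def lexicon_sentiment(tokens: Sequence[str]) -> float:
    """Default sentiment scorer: (positive - negative hits) / message length."""
    pos = _SENT_POS.count(list(tokens))
    neg = _SENT_NEG.count(list(tokens))
    return (pos - neg) / max(1, len(tokens))


_SENT_POS = WordMatcher(PERSPECTIVE_CATEGORIES["pos_emo"])
_SENT_NEG = WordMatcher(PERSPECTIVE_CATEGORIES["neg_emo"])

BASE_FEATURES = ("hedge", "check_question", "similarity", "sentiment", "length")


@dataclass
class FeatureVector:
    conv_id: str
    label: int                       # 1 positive, 0 negative
    features: dict[str, float]


def _token_cosine(a: Sequence[str], b: Sequence[str]) -> float:
    if not a or not b:
        return 0.0
    from collections import Counter

    ca, cb = Counter(a), Counter(b)
    dot = sum(v * cb.get(w, 0) for w, v in ca.items())
    na = np.sqrt(sum(v * v for v in ca.values()))
    nb = np.sqrt(sum(v * v for v in cb.values()))
    return float(dot / (na * nb))


def _prefix(conv: Conversation, x_percent: float) -> list:
    if x_percent <= 0:
        raise ValueError("x_percent must be positive")
    k = max(1, int(np.floor(len(conv) * x_percent / 100.0)))
    return conv.messages[:k]


def extract_features(
    conv: Conversation,
    x_percent: float,
    model: Optional[StageHMM] = None,
    patterns: dict[str, list[str]] | None = None,
    sentiment: Callable[[Sequence[str]], float] = lexicon_sentiment,
    use_ngrams: bool = False,
    ngram_vocab: Optional[dict[str, int]] = None,
    texter_features: bool = False,
) -> FeatureVector:
    """Features of the first ``x_percent`` of messages.

    Counselor-message features by default; ``texter_features`` adds the same
    aggregates over texter messages.  Stage durations and conjunctions need a
    fitted stage model; absent stages contribute zeros.  N-gram counts need a
    prebuilt term→column vocabulary (see :func:`build_ngram_vocab`).
    """
    msgs = _prefix(conv, x_percent)
    compiled = compile_patterns(patterns if patterns is not None else RESPONSE_PATTERNS)

    def base_values(role: str) -> list[dict[str, float]]:
        rows = []
        prev_other: list[str] = []
        other = TEXTER if role == COUNSELOR else COUNSELOR
        last_other: list[str] = []
        for m in msgs:
            if m.role == other:
                last_other = m.tokens
            elif m.role == role:
                rows.append({
                    "hedge": float(any(p.search(m.text) for p in compiled["hedge"])),
                    "check_question": float(any(p.search(m.text) for p in compiled["check_question"])),
                    "similarity": _token_cosine(m.tokens, last_other),
                    "sentiment": sentiment(m.tokens),
                    "length": float(m.n_tokens),
                })
        return rows

    feats: dict[str, float] = {}
    c_rows = base_values(COUNSELOR)
    if not c_rows:
        raise ValueError(f"conversation {conv.conv_id}: empty counselor prefix")
    for f in BASE_FEATURES:
        feats[f] = float(np.mean([r[f] for r in c_rows]))

    if model is not None:
        sub = Conversation(conv.conv_id, conv.counselor_id, msgs,
                           outcome=conv.outcome, issue=conv.issue)
        path = viterbi_decode(model, sub)
        for s, d in enumerate(path.durations, start=1):
            feats[f"stage_dur_{s}"] = float(d)
        # conjunction features: base-feature mean within each decoded stage
        stage_of = {m.index: st for m, st in zip(msgs, path.stages)}
        c_idx = [m.index for m in msgs if m.role == COUNSELOR]
        for s in range(1, model.n_stages + 1):
            rows = [r for i, r in zip(c_idx, c_rows) if stage_of[i] == s]
            for f in BASE_FEATURES:
                feats[f"conj_s{s}_{f}"] = (
                    float(np.mean([r[f] for r in rows])) if rows else 0.0
                )

    if texter_features:
        t_rows = base_values(TEXTER)
        for f in BASE_FEATURES:
            feats[f"texter_{f}"] = float(np.mean([r[f] for r in t_rows])) if t_rows else 0.0

    if use_ngrams:
        if ngram_vocab is None:
            raise ValueError("use_ngrams requires a prebuilt ngram vocabulary")
        counts = np.zeros(len(ngram_vocab))
        for m in msgs:
            if m.role != COUNSELOR:
                continue
            for n in (1, 2):
                for term in ngram_terms(m.tokens, n):
                    j = ngram_vocab.get(term)
                    if j is not None:
                        counts[j] += 1
        for term, j in ngram_vocab.items():
            feats[f"ng:{term}"] = float(counts[j])

    return FeatureVector(
        conv_id=conv.conv_id,
        label=int(conv.outcome == POSITIVE),
        features=feats,
    )


def build_ngram_vocab(
    convs: Sequence[Conversation],
    x_percent: float,
    min_freq: int = 5,
    role: str = COUNSELOR,
) -> dict[str, int]:
    """Counselor unigram+bigram terms above a corpus-frequency floor."""
    counts: dict[str, int] = {}
    for conv in convs:
        for m in _prefix(conv, x_percent):
            if m.role != role:
                continue
            for n in (1, 2):
                for term in ngram_terms(m.tokens, n):
                    counts[term] = counts.get(term, 0) + 1
    kept = sorted(t for t, c in counts.items() if c > min_freq)
    return {t: i for i, t in enumerate(kept)}


def features_frame(
    convs: Sequence[Conversation],
    x_percent: float,
    model: Optional[StageHMM] = None,
    use_ngrams: bool = False,
    texter_features: bool = False,
    ngram_min_freq: int = 5,
    **kwargs,
) -> pd.DataFrame:
    """Feature matrix for a conversation list (one row per conversation,
    ``label`` column last)."""
    vocab = (build_ngram_vocab(convs, x_percent, ngram_min_freq)
             if use_ngrams else None)
    rows = []
    for c in convs:
        fv = extract_features(c, x_percent, model=model, use_ngrams=use_ngrams,
                              ngram_vocab=vocab, texter_features=texter_features,
                              **kwargs)
        row = dict(fv.features)
        row["conv_id"] = fv.conv_id
        row["label"] = fv.label
        rows.append(row)
    df = pd.DataFrame(rows).set_index("conv_id")
    return df.fillna(0.0)


# ---------------------------------------------------------------------------
# penalized logistic regression by batch (proximal) gradient descent


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    penalty: str = "l2",
    lam: float = 1.0,
    learning_rate: Optional[float] = None,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Penalized logistic regression weights by batch gradient descent.

    Minimizes mean log loss plus ``lam/(2n) ||w||_2^2`` (L2) or
    ``lam/n ||w||_1`` (L1, via the proximal soft-threshold step); the
    intercept (last weight) is never penalized.  ``X`` should be
    standardized.  The default step size is the inverse Lipschitz constant
    of the smooth part; convergence is declared when the step displacement
    drops below ``tol``.
    """
    if penalty not in ("l1", "l2"):
        raise ValueError("penalty must be 'l1' or 'l2'")
    n, d = X.shape
    Xb = np.hstack([X, np.ones((n, 1))])
    w = np.zeros(d + 1)
    if learning_rate is None:
        s = np.linalg.norm(Xb, 2)
        lip = s * s / (4.0 * n) + (lam / n if penalty == "l2" else 0.0)
        learning_rate = 1.0 / lip
    yv = y.astype(float)
    reg = lam / n
    # FISTA acceleration
    z, t_acc = w.copy(), 1.0
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(Xb @ z)))
        grad = Xb.T @ (p - yv) / n
        if penalty == "l2":
            grad[:-1] += reg * z[:-1]
            w_new = z - learning_rate * grad
        else:
            step = z - learning_rate * grad
            w_new = step.copy()
            w_new[:-1] = np.sign(step[:-1]) * np.maximum(
                np.abs(step[:-1]) - learning_rate * reg, 0.0
            )
        if not np.all(np.isfinite(w_new)):
            raise ValueError("non-finite weights during gradient descent")
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_acc * t_acc)) / 2.0
        z = w_new + ((t_acc - 1.0) / t_next) * (w_new - w)
        done = np.max(np.abs(w_new - w)) < tol
        w, t_acc = w_new, t_next
        if done:
            break
    return w


def predict_proba(w: np.ndarray, X: np.ndarray) -> np.ndarray:
    Xb = np.hstack([X, np.ones((X.shape[0], 1))])
    return 1.0 / (1.0 + np.exp(-(Xb @ w)))


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) statistic with midranks for ties."""
    from scipy.stats import rankdata

    y = np.asarray(y_true).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    r = rankdata(scores)
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    feature_set: str
    x_percent: float
    fold_auc: list[float]
    fold_accuracy: list[float]
    oof_scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0.0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    penalty: str = "l2",
    lam: float = 1.0,
    feature_set: str = "",
    x_percent: float = 100.0,
    max_iter: int = 2000,
) -> CVResult:
    """Stratified k-fold CV; features standardized on each train split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs, accs = [], []
    oof = np.zeros(len(y))
    for tr, te in skf.split(X, y):
        if len(np.unique(y[te])) < 2:
            raise ValueError("a fold contains a single class")
        if X.shape[1] == 0:
            scores = np.full(len(te), y[tr].mean())
        else:
            Xtr, Xte = _standardize(X[tr], X[te])
            w = fit_logistic(Xtr, y[tr], penalty=penalty, lam=lam, max_iter=max_iter)
            scores = predict_proba(w, Xte)
        oof[te] = scores
        aucs.append(rank_auc(y[te], scores))
        accs.append(float(np.mean((scores >= 0.5).astype(int) == y[te])))
    return CVResult(feature_set=feature_set, x_percent=x_percent,
                    fold_auc=aucs, fold_accuracy=accs,
                    oof_scores=oof, labels=y.copy())


def paired_bootstrap_pvalue(
    labels: np.ndarray,
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """One-sided paired bootstrap p-value that model B beats model A in AUC.

    Resamples conversations with replacement and counts how often B's AUC
    fails to exceed A's.
    """
    rng = np.random.default_rng(seed)
    n = len(labels)
    worse = 0
    used = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = labels[idx]
        if yb.sum() == 0 or yb.sum() == n:
            continue
        used += 1
        if rank_auc(yb, scores_b[idx]) <= rank_auc(yb, scores_a[idx]):
            worse += 1
    return (worse + 1) / (used + 1)


DEFAULT_LADDER: list[tuple[str, list[str]]] = [
    ("none", []),
    ("+hedges", ["hedge"]),
    ("+check_questions", ["check_question"]),
    ("+similarity", ["similarity"]),
    ("+stage_durations", ["stage_dur_*"]),
    ("+sentiment", ["sentiment"]),
    ("+message_length", ["length"]),
    ("+stage_conjunctions", ["conj_*"]),
    ("+ngrams", ["ng:*"]),
]


def _select_columns(df: pd.DataFrame, specs: Sequence[str]) -> list[str]:
    cols = []
    for sel in specs:
        if sel.endswith("*"):
            cols.extend(c for c in df.columns if c.startswith(sel[:-1]))
        elif sel in df.columns:
            cols.append(sel)
    return cols


def feature_ladder(
    convs: Sequence[Conversation],
    x_percent: float,
    model: Optional[StageHMM] = None,
    feature_sets: Sequence[tuple[str, list[str]]] | None = None,
    k: int = 10,
    seed: int = 0,
    lam: float = 1.0,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Nested models evaluated in order, with paired-bootstrap significance
    between consecutive models.

    L1 regularization is used once n-gram features enter, L2 otherwise.
    Returns a DataFrame with feature set, mean AUC, delta, and p-value.
    """
    ladder = list(feature_sets if feature_sets is not None else DEFAULT_LADDER)
    needs_ngrams = any(any(s.startswith("ng:") for s in specs) for _, specs in ladder)
    df = features_frame(convs, x_percent, model=model, use_ngrams=needs_ngrams)
    y = df["label"].to_numpy()
    rows = []
    cum_specs: list[str] = []
    prev: Optional[CVResult] = None
    for name, specs in ladder:
        cum_specs.extend(specs)
        cols = _select_columns(df, cum_specs)
        penalty = "l1" if any(c.startswith("ng:") for c in cols) else "l2"
        res = cross_validate(df[cols].to_numpy() if cols else np.empty((len(y), 0)),
                             y, k=k, seed=seed, penalty=penalty, lam=lam,
                             feature_set=name, x_percent=x_percent)
        if prev is not None:
            p = paired_bootstrap_pvalue(y, prev.oof_scores, res.oof_scores,
                                        n_boot=n_boot, seed=seed)
            delta = res.mean_auc - prev.mean_auc
        else:
            p, delta = float("nan"), float("nan")
        rows.append({"feature_set": name, "n_features": len(cols),
                     "penalty": penalty, "auc": res.mean_auc,
                     "accuracy": res.mean_accuracy, "delta_auc": delta,
                     "p_value": p})
        prev = res
    return pd.DataFrame(rows)
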