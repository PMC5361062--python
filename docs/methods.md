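# Methods

This note documents the models behind each `counselkit` analysis, the
parameters that matter, what the synthetic-corpus generator does and does
not emulate, and the numerical and design choices that were genuinely open.

## Conversation data model

A conversation is an ordered list of messages, each with a role
(`counselor` or `texter`), raw text, and a deterministic token list
(lowercased, split on non-alphanumerics, digit tokens kept). Outcomes are
binary: the texter's post-conversation report of feeling *better* maps to
`positive`; *same* or *worse* map to `negative`. Conversations without a
survey response are unlabeled and excluded from outcome-conditioned
analyses but still contribute to global statistics such as inverse
conversation frequencies.

Counselor quality is defined at the counselor level: among counselors with
strictly more than `min_labeled` (default 15) labeled conversations of at
least `min_messages` (default 30) messages, the success rate is the
positive fraction of those qualifying conversations. Ranking ties break by
qualifying-conversation count and then id so the split is deterministic.

## Adaptability

Time is operationalized as five even message chunks (earlier chunks take
the extra message when the count is not divisible). For each (group,
outcome, chunk) cell the counselor-token count vector of every conversation
is scaled by one over its counselor's conversation count in that cell —
so each counselor contributes equal mass regardless of caseload — summed,
multiplied by global `idf(w) = ln(N/df(w))` (documents = conversations, no
smoothing; observed words always have df ≥ 1), and L2 normalized. The
curve is `1 − cos` between the positive and negative cell vectors per
chunk.

Uncertainty: a member bootstrap resamples the group's counselors with
replacement (default 1000 resamples, percentile 95% interval). The
permuted-outcome null shuffles outcome labels across the group's labeled
conversations, preserving class counts; with no outcome-language link the
observed distances fall inside the null's 95% band. Chunk boundaries are
defined over all messages; only counselor tokens populate the vectors
(a texter-language variant is available via the `role` argument).

## Ambiguity and situation setters

The situation setter is the earliest texter message with at least
`min_tokens` (default 10) tokens; the threshold is a free parameter since
"long" has no canonical value. Setter matching uses bigram TF-IDF vectors
fit on the setter collection itself. In these self-fit spaces idf is
`ln(N/df) + 1`: the +1 keeps terms shared by every document from vanishing,
so identical documents sit at cosine distance 0 (with pure `ln(N/df)` two
identical setters would have zero vectors and undefined similarity). The
adaptability module keeps pure `ln(N/df)` because its vectors are compared
across cells under one global weighting.

Clustering: a setter's neighbors are the other setters within cosine
distance `distance_threshold` (default 0.4, a free parameter); setters
with at least `min_neighbors` (default 10) neighbors seed clusters, and
seeds with overlapping neighborhoods merge by union. Construction is
index-sorted and therefore order-invariant.

Response classes are regular-expression pattern sets (shipped defaults,
YAML-overridable): check-question stems ("sounds like", "it seems", "i
hear"), suicide checks ("want to die", "kill myself", ...), thanks
("thank", "appreciat", "courage", "brave"), hedges ("maybe", "perhaps",
"kind of", ...), and surprise (a leading interjection "oh"/"wow" or an
exclamatory adjective "awful"/"terrible"). Templatedness counts, for each
counselor reply, the other replies within the cosine threshold in the same
bigram space; symmetric by construction.

The group comparison over matched setters pairs group means within each
cluster containing both groups and applies a Wilcoxon signed-rank test
across clusters. (A one-sample location test against zero or a paired
comparison calls for the signed-rank test; the Mann-Whitney U test is used
where two independent groups of speakers are compared.)

## The ordered-stage conversation model

States are (stage, role) pairs with the role observed, so only the stage
(default 5) is latent. Stage 1 is the forced start; after every message the
stage either stays or advances by one with probability
`advance_prob[stage, role]`; the last stage never advances. A message is a
bag of words: its emission log-probability is the sum of per-token log
probabilities under its (stage, role) unigram distribution. The vocabulary
keeps words occurring strictly more than `min_count` (default 20) times and
folds the rest into an unknown token.

Forward-backward and Viterbi run in log space over the two-predecessor
lattice. Viterbi tie-breaks toward staying: the decoder walks forward
through best-suffix values and advances only when advancing is strictly
better, which yields the lexicographically smallest optimal path and
matches the enumeration oracle's first-maximizer rule.

EM re-estimates emissions from expected token counts with a uniform-mixture
smoothing floor (`(1−ε)·MLE + ε/V`, ε = 1e-6) to guarantee finite
likelihoods, and advance probabilities from expected transition counts.
Convergence is declared when the relative corpus log-likelihood change
falls below `tol`; the per-iteration trace is stored and is non-decreasing
up to floating-point noise.

**Initialization.** The symmetric initialization — every stage emitting the
per-role corpus unigram and advance probability 0.5 — is an EM fixed point,
so `init_model` applies a small seeded multiplicative perturbation (scale
1e-2). On strongly staged corpora that basin is still poor: EM reliably
collapses one stage (advance probability → 1) and merges late stages,
costing ~40 points of decoding accuracy, and which basin a run reaches also
depends on the perturbation draw. `fit_stage_model` therefore restarts EM
from a coarse geometric grid of initial advance probabilities (0.05 … 0.5,
five points) crossed with three perturbation seeds and keeps the fit with
the best final corpus log likelihood. Selection uses likelihood only; on
planted corpora the
likelihood gap between basins is large (≈ 3% of the total) and the chosen
fit decodes at ≈ 0.999 message accuracy. `fit_stage_model` passes
`tol = 1e-6`; the looser 1e-4 stops before stage differentiation completes
at corpus scale.

Stage-duration comparisons control for length by keeping conversations of
40–60 messages, weight positive and negative conversations equally within a
group (the two outcome-class means are averaged), and bootstrap over
counselors. "Top words" per stage are ranked by the ratio of stage emission
probability to the role's corpus unigram probability above an optional
frequency floor; conversations are not forced to reach the last stage.

## Coordination

`C^m(b, A)` is estimated by pure counting over b's exchanges — adjacent
(initiator message, reply) pairs of opposite roles; after a run of
same-role messages only the last one pairs (no concatenation). Markers with
no exhibiting initiator are undefined and excluded from the speaker
macro-average; speakers need `min_exchanges` (default 10) exchanges to
enter the group mean. The permutation null shuffles reply exhibit maps
within each speaker, preserving all marginal rates while destroying the
pairing.

For a planted exhibit chain (reply exhibits with probability `base + δ`
after an exhibiting message, `base` otherwise) the stationary exhibit rate
is `base/(1−δ)` and the expected statistic is `δ(1−base−δ)/(1−δ)` —
the analytic oracle used by the recovery checks. Per-speaker category
coordination values are tested against zero with a Wilcoxon signed-rank
test.

## Perspective trajectories

Each measure is a ratio of pooled category token counts over texter
messages per conversation fifth and outcome group: tense fractions use the
past+present+future union as denominator, self-focus uses first-singular
plus third-person pronouns, sentiment uses positive plus negative emotion
words. Category-internal denominators (not all tokens) are used because the
measures are about the *relative* orientation; pooling counts makes the
measures invariant to message order within a chunk. Word lists are open
approximations of the standard psycholinguistic categories (the licensed
dictionaries are not redistributable) with `stem*` wildcard support;
confidence intervals bootstrap over conversations.

## Outcome prediction

The dataset is balanced by subsampling the larger outcome class among
labeled conversations strictly longer than 30 messages. The prefix is the
first `floor(n·x/100)` messages (at least one). Per-message base features
over counselor messages — hedge flag, check-question flag, token-cosine
similarity to the last texter message, lexicon sentiment
`(pos−neg)/length`, token count — are averaged over the prefix;
stage-duration features come from the Viterbi path of the prefix (absent
stages contribute zero), and conjunction features average each base feature
within each decoded stage. N-gram features are counselor unigram+bigram
counts above corpus frequency 5. The n-gram vocabulary is built on the full
balanced dataset before cross-validation — a deliberate simplification
(term selection, not label information, crosses folds).

The classifier is logistic regression fit by accelerated batch proximal
gradient descent: mean log loss plus `λ/(2n)·||w||²` (L2) or `λ/n·||w||₁`
(L1 via soft-thresholding), intercept unpenalized, default step size the
inverse Lipschitz constant, λ = 1 by default. The objective matches the
reference implementation's with `C = 1/λ`, and fitted weights agree with it
to < 1e-3 on test fixtures. Features are standardized per fold on the
training split. Evaluation is stratified 10-fold cross-validation; AUC is
the rank (Mann-Whitney) statistic with midranks for ties, identical to the
trapezoidal ROC integral. The feature ladder adds feature groups in a fixed
order, switches to L1 when n-grams enter, and compares consecutive models
with a one-sided paired bootstrap over held-out scores. The sentiment
feature is a per-message mean (not a conversation total), and the sentiment
scorer is pluggable.

## The synthetic-corpus generator

The generator is the package's test bed: every analysis has a knob that
plants exactly the effect it measures, and `GroundTruth` echoes all planted
values.

* **Structure.** Roles alternate strictly, counselor first; message counts
  are uniform on 40–60. Stages follow the left-to-right chain with
  per-stage advance probability 0.15, matching typical stage dwell times of
  ~7 messages. Message lengths are negative binomial per role (counselor
  mean 16, texter mean 10; the first texter message — the setter — mean 20,
  plus a Poisson extra with mean `setter_length_effect` = 4 in positive
  conversations).
* **Emissions.** Each token comes from a mixture: weight `keyword_weight`
  (default 0.8) on the message's (stage, role) keyword list (10 disjoint
  synthetic words per stage and role) and the rest on a shared background
  block. The background is Zipfian (exponent 1.05 over 200 words) with two
  20-word outcome-drift lexicons holding `drift_word_mass` = 0.3 of the
  block. A uniform background would put every background word in every
  conversation, driving idf to zero and erasing any planted signal from
  TF-IDF vectors; the Zipfian shape with mid-frequency drift words mimics
  how real signal-bearing vocabulary behaves.
* **Drift.** In counselor messages the background tilts multiplicatively
  toward the conversation's own outcome lexicon and away from the other's
  by `1 + drift_strength·t` (t = chunk/4, `drift_strength` = 4), so the
  planted positive/negative divergence is zero at the start and grows
  linearly — the monotone ground truth the adaptability curve recovers.
  The default strength was chosen so the divergence is clearly visible
  above counselor-equalized sampling noise at a 12-counselor,
  40-conversation corpus, echoing how clearly the effect separates in real
  data.
* **Quality and outcomes.** Half the counselors have positive-outcome
  probability 0.8, half 0.5; outcomes are Bernoulli draws, so the split
  recovery test has a planted answer.
* **Coordination.** Each message exhibits each marker with probability
  `base + δ·[previous message exhibited]` (defaults 0.2 and 0.1; one marker
  word is appended per exhibit). Marker lexicons default to the shipped
  stylistic lists and are disjoint from the synthetic stage/background
  vocabulary.
* **Perspective.** Texter tokens are replaced by perspective-category words
  via one multinomial draw per token with per-category rates
  `base + slope·t + positive_shift·[positive]` (small defaults, see
  `GeneratorConfig`), giving the trajectories linear planted schedules and
  outcome gaps.
* **Behaviors.** Counselor messages insert hedge words and check-question
  phrases at outcome-dependent rates, planting the classifier's signal.

One `numpy` generator stream drives all sampling, so a (config, seed) pair
yields a byte-identical corpus.

**What the generator does not emulate.** Surface text is bags of synthetic
tokens, not natural language: there is no syntax, no discourse coherence,
no topic mixture within a stage, no correlation between measures beyond
what is planted, and the lexicon overlaps of real language (a word that is
both a future marker and a positive-emotion word) occur only where the
shipped word lists overlap. Passing recovery tests shows the estimators
recover the effects they target at realistic sizes and noise levels — not
that the effects exist, or have these magnitudes, in real counseling
corpora. Analyses that depend on real phrasing (setter clustering of
genuinely similar crises, regex response classes) are validated on
hand-built text fixtures instead.

## Problem sizes and numerical choices

Study corpora are desk-scale: 200 conversations (10 counselors × 20) for
stage recovery and prediction, 12 × 60 for adaptability drift recovery,
~100 conversations (≥ 2000 exchanges per marker) for coordination recovery.
Bootstraps default to 1000 resamples in library calls and use smaller
counts (10–200) inside recovery loops where only the point estimate
matters. All log-domain computations use `log`/`log1p` with explicit
`-inf` handling; emission floors guarantee finite likelihoods; degenerate
inputs (empty chunks, undefined markers, missing stages, single-class
folds) are flagged or raised rather than silently imputed, as documented
per function.

## Known limitations

* The EM restart grid assumes the corpus genuinely has left-to-right stage
  structure; on unstructured corpora all restarts converge to near-identical
  likelihoods and the "stages" are arbitrary.
* The n-gram vocabulary's frequency filter sees the full balanced dataset
  (see above); with planted drift words this makes the n-gram ladder step
  look stronger than a strictly fold-pure pipeline would.
* Pattern-based response classes are precision-oriented string matches; no
  attempt is made to handle negation or sarcasm.
* The setter-response group table needs clusters containing both counselor
  groups; on synthetic corpora (random token bags) such clusters are rare
  and the pipeline emits an empty table rather than failing.
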