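"""Shipped word lists and pattern sets, and helpers to match them.

Psycholinguistic dictionaries of the LIWC family are licensed, so the package
ships open word lists that approximate the categories the analyses need:

* eight stylistic coordination markers (articles, auxiliary verbs,
  conjunctions, high-frequency adverbs, indefinite pronouns, personal
  pronouns, prepositions, quantifiers);
* perspective categories (past/present/future orientation, first-person
  singular vs third-person pronouns, positive/negative emotion);
* regular-expression pattern sets for classifying counselor responses
  (check questions, suicide checks, thanks, hedges, surprise).

Every list is overridable from a YAML file mapping category name to a list of
entries.  Word-list entries may end in ``*`` to match any suffix
(``appreciat*`` matches ``appreciate``, ``appreciated`` ...), mirroring how
stem-based category dictionaries are written.
"""

from __future__ import annotations

import re
from pathlib import Path

import yaml

# --- stylistic coordination markers -----------------------------------------

STYLISTIC_MARKERS: dict[str, list[str]] = {
    "article": ["a", "an", "the"],
    "aux_verb": ["am", "are", "be", "been", "can", "could", "did", "do",
                 "does", "had", "has", "have", "is", "was", "were", "will",
                 "would"],
    "conjunction": ["and", "because", "but", "or", "so", "while"],
    "adverb": ["also", "just", "really", "too", "very"],
    "indefinite_pronoun": ["anybody", "anyone", "anything", "everybody",
                           "everyone", "everything", "nobody", "nothing",
                           "somebody", "someone", "something"],
    "personal_pronoun": ["i", "you", "he", "she", "we", "they", "me", "him",
                         "her", "us", "them"],
    "preposition": ["about", "at", "for", "from", "in", "of", "on", "to",
                    "with"],
    "quantifier": ["all", "any", "few", "many", "more", "much", "some"],
}

# --- perspective categories --------------------------------------------------

PERSPECTIVE_CATEGORIES: dict[str, list[str]] = {
    "past": ["ago", "before", "did", "earlier", "happened", "had", "was",
             "were", "yesterday"],
    "present": ["am", "are", "is", "now", "today", "currently", "right"],
    "future": ["will", "going", "gonna", "tomorrow", "soon", "later",
               "future", "hope", "plan*"],
    "first_singular": ["i", "me", "my", "mine", "myself"],
    "third_person": ["he", "she", "him", "her", "his", "hers", "they",
                     "them", "their", "theirs"],
    "pos_emo": ["good", "better", "great", "happy", "glad", "love", "nice",
                "thank*", "appreciat*", "hope", "calm", "relief"],
    "neg_emo": ["bad", "worse", "sad", "hurt*", "afraid", "scared", "alone",
                "angry", "hate", "awful", "terrible", "cry*", "pain*"],
}

# --- counselor response pattern sets -----------------------------------------
# Regular expressions, case-insensitive, applied to the raw reply text.
# ``surprise`` requires a leading interjection or an exclamatory adjective.

RESPONSE_PATTERNS: dict[str, list[str]] = {
    "check_question": [r"\bsounds? like\b", r"\bit seems\b", r"\bi hear\b",
                       r"\bif i understand\b"],
    "suicide_check": [r"\bsuicid", r"\bkill (?:yourself|myself)\b",
                      r"\bwant(?:ed)? to die\b", r"\bend (?:my|your) life\b",
                      r"\bhurt (?:yourself|myself)\b"],
    "thanks": [r"\bthank", r"\bappreciat", r"\bcourage\b", r"\bbrave\b",
               r"\bglad you reached out\b"],
    "hedge": [r"\bmaybe\b", r"\bperhaps\b", r"\bfairly\b", r"\bkind of\b",
              r"\bsort of\b", r"\ba little\b", r"\bpossibly\b",
              r"\bsomewhat\b"],
    "surprise": [r"^\s*(?:oh|wow|whoa)\b", r"\bawful\b", r"\bterrible\b",
                 r"\bhorrible\b"],
}

RESPONSE_CLASSES = tuple(RESPONSE_PATTERNS)


def load_lexicon(path: str | Path) -> dict[str, list[str]]:
    """Load a category → entry-list mapping from YAML."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of category to list")
    out = {}
    for name, entries in data.items():
        if not isinstance(entries, list) or not entries:
            raise ValueError(f"{path}: category {name!r} must be a nonempty list")
        out[str(name)] = [str(e) for e in entries]
    return out


def save_lexicon(lexicon: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(lexicon, fh, sort_keys=True)


class WordMatcher:
    """Token-level matcher for a word list with ``stem*`` wildcard support."""

    def __init__(self, words: list[str]):
        self.exact: set[str] = set()
        self.prefixes: list[str] = []
        for w in words:
            w = w.lower()
            if w.endswith("*"):
                self.prefixes.append(w[:-1])
            else:
                self.exact.add(w)

    def __call__(self, token: str) -> bool:
        if token in self.exact:
            return True
        return any(token.startswith(p) for p in self.prefixes)

    def count(self, tokens: list[str]) -> int:
        return sum(1 for t in tokens if self(t))

    def any(self, tokens: list[str]) -> bool:
        return any(self(t) for t in tokens)


def build_matchers(lexicon: dict[str, list[str]]) -> dict[str, WordMatcher]:
    return {name: WordMatcher(words) for name, words in lexicon.items()}


def compile_patterns(patterns: dict[str, list[str]]) -> dict[str, list[re.Pattern]]:
    return {
        name: [re.compile(p, re.IGNORECASE) for p in pats]
        for name, pats in patterns.items()
    }
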