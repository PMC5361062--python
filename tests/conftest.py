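"""Shared fixtures: synthetic corpora and a fitted stage model.

Expensive artifacts (corpus generation, EM fits) are session-scoped so the
whole suite pays for them once.
"""

from __future__ import annotations

import pytest

from counselkit.corpus import split_counselors
from counselkit.stages import fit_stage_model
from counselkit.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """~120 conversations under default study conditions."""
    cfg = GeneratorConfig(seed=11, n_counselors=8, conversations_per_counselor=16)
    convs, gt = generate_corpus(cfg)
    return cfg, convs, gt


@pytest.fixture(scope="session")
def small_split(small_corpus):
    _, convs, _ = small_corpus
    return split_counselors(convs, top_n=4, bottom_n=4)


@pytest.fixture(scope="session")
def staged_corpus():
    """200 conversations, 5 stages, keyword weight 0.8, fixed seed."""
    cfg = GeneratorConfig(seed=42, n_counselors=10, conversations_per_counselor=20)
    convs, gt = generate_corpus(cfg)
    return cfg, convs, gt


@pytest.fixture(scope="session")
def fitted_stage_model(staged_corpus):
    """EM fit (restarts, likelihood-selected) on the staged corpus."""
    _, convs, _ = staged_corpus
    return fit_stage_model(convs, n_stages=5, seed=0)
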