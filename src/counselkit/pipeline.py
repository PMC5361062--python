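"""End-to-end analysis pipeline: corpus → split → all analyses → report bundle.

Runs the whole study on a corpus (read from disk or generated synthetically),
writing one CSV per analysis plus JSON artifacts, optional figures, and a
manifest with the seed, configuration echo, and SHA-256 hash of every output.
All randomness flows from the single configured seed, so rerunning with the
same configuration produces byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import adaptability as adapt
from . import ambiguity as ambig
from . import coordination as coord
from . import perspective as persp
from . import prediction as pred
from . import stages as stg
from .corpus import (COUNSELOR, TEXTER, Conversation, CounselorSplit,
                     read_corpus, split_counselors, write_corpus)
from .lexicons import PERSPECTIVE_CATEGORIES, STYLISTIC_MARKERS
from .synthetic import GeneratorConfig, generate_corpus

log = logging.getLogger("counselkit.pipeline")

_CSV_KW = dict(index=False, float_format="%.10g", lineterminator="\n")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; unknown keys are rejected on load."""

    out_dir: str = "counselkit_run"
    seed: int = 0
    corpus_path: Optional[str] = None          # read instead of generating
    generator: dict = field(default_factory=dict)   # GeneratorConfig overrides
    split: dict = field(default_factory=dict)       # split_counselors kwargs
    n_chunks: int = 5
    adaptability_bootstrap: int = 200
    setter_min_tokens: int = 10
    setter_bins: list[float] = field(default_factory=lambda: [0, 10, 15, 20, 25, 30, 40, 1000])
    cluster_threshold: float = 0.4
    cluster_min_neighbors: int = 10
    n_stages: int = 5
    vocab_min_count: int = 20
    stage_fit_sample: Optional[int] = 200      # conversations used to fit the HMM
    duration_min_len: int = 40
    duration_max_len: int = 60
    coordination_min_exchanges: int = 10
    prediction_x: list[float] = field(default_factory=lambda: [20, 40, 60, 80, 100])
    prediction_folds: int = 10
    ladder_x: float = 80.0
    ladder_bootstrap: int = 500
    include_ngrams: bool = True
    plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, **_CSV_KW)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage and return the manifest (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage_times: dict[str, float] = {}

    def tick(name: str, t0: float) -> None:
        stage_times[name] = round(time.time() - t0, 2)
        log.info("stage %s finished in %.2fs", name, stage_times[name])

    # --- corpus -----------------------------------------------------------
    t0 = time.time()
    if config.corpus_path:
        if not Path(config.corpus_path).exists():
            raise FileNotFoundError(f"corpus path {config.corpus_path} does not exist")
        convs = read_corpus(config.corpus_path)
        gt = None
    else:
        gen_cfg = GeneratorConfig.from_dict({**config.generator, "seed": config.seed})
        convs, gt = generate_corpus(gen_cfg)
        write_corpus(convs, out / "corpus.jsonl")
        gt.to_json(out / "ground_truth.json")
    log.info("corpus: %d conversations (seed %d)", len(convs), config.seed)
    tick("corpus", t0)

    # --- counselor split --------------------------------------------------
    t0 = time.time()
    split_kw = dict(config.split)
    if "top_n" not in split_kw or "bottom_n" not in split_kw:
        counselors = {c.counselor_id for c in convs if c.labeled}
        half = max(1, len(counselors) // 2)
        split_kw.setdefault("top_n", half)
        split_kw.setdefault("bottom_n", len(counselors) - half)
    split = split_counselors(convs, **split_kw)
    split.to_json(out / "split.json")
    tick("split", t0)

    # --- adaptability -----------------------------------------------------
    t0 = time.time()
    idf = adapt.global_idf(convs)
    rows = []
    for group in ("more_successful", "less_successful"):
        curve = adapt.adaptability_curve(
            convs, split, group, n_chunks=config.n_chunks,
            n_boot=config.adaptability_bootstrap, seed=config.seed, idf=idf,
        )
        for ch, (d, (lo, hi)) in enumerate(zip(curve.distances, curve.ci)):
            rows.append({"group": group, "chunk": ch, "distance": d,
                         "ci_lo": lo, "ci_hi": hi})
    adapt_df = pd.DataFrame(rows)
    _write_csv(adapt_df, out / "adaptability.csv")
    tick("adaptability", t0)

    # --- ambiguity --------------------------------------------------------
    t0 = time.time()
    table = ambig.ambiguity_outcome_table(convs, config.setter_bins,
                                          config.setter_min_tokens)
    _write_csv(pd.DataFrame({
        "bin_lo": table.bin_edges[:-1], "bin_hi": table.bin_edges[1:],
        "fraction_positive": table.fraction_positive,
        "ci_lo": [c[0] for c in table.ci], "ci_hi": [c[1] for c in table.ci],
        "n": table.counts,
    }), out / "ambiguity_outcome.csv")
    ratios, counts = ambig.counselor_texter_length_ratio(
        convs, config.setter_bins, config.setter_min_tokens)
    _write_csv(pd.DataFrame({
        "bin_lo": table.bin_edges[:-1], "bin_hi": table.bin_edges[1:],
        "length_ratio": ratios, "n": counts,
    }), out / "length_ratio.csv")
    try:
        t3 = ambig.setter_response_table(
            convs, split, config.cluster_threshold,
            config.cluster_min_neighbors, config.setter_min_tokens)
    except ValueError as exc:
        log.warning("setter-response table unavailable: %s", exc)
        t3 = pd.DataFrame(columns=["measure", "more_successful",
                                   "less_successful", "p_value", "n_clusters"])
    _write_csv(t3, out / "setter_responses.csv")

    # templatedness of counselor replies to the situation setter, per group
    reply_rows = []
    for conv in convs:
        g = split.group_of(conv.counselor_id)
        if g is None:
            continue
        s = ambig.find_situation_setter(conv, config.setter_min_tokens)
        if s is None:
            continue
        reply = next((m for m in conv.messages[s.message_index + 1:]
                      if m.role == COUNSELOR), None)
        if reply is not None and reply.tokens:
            reply_rows.append((g, reply.tokens))
    if len(reply_rows) >= 2:
        counts_t = ambig.templatedness([r[1] for r in reply_rows],
                                       config.cluster_threshold)
        tmpl = pd.DataFrame({"group": [r[0] for r in reply_rows],
                             "neighbors": counts_t})
        tmpl = tmpl.groupby("group", as_index=False)["neighbors"].mean()
    else:
        tmpl = pd.DataFrame(columns=["group", "neighbors"])
    _write_csv(tmpl, out / "templatedness.csv")
    tick("ambiguity", t0)

    # --- stage model ------------------------------------------------------
    t0 = time.time()
    fit_convs = convs[: config.stage_fit_sample] if config.stage_fit_sample else convs
    model = stg.fit_stage_model(fit_convs, n_stages=config.n_stages,
                                min_count=config.vocab_min_count,
                                seed=config.seed)
    model.to_json(out / "stage_model.json")
    durations = stg.stage_durations(convs, model, split,
                                    min_len=config.duration_min_len,
                                    max_len=config.duration_max_len,
                                    seed=config.seed)
    _write_csv(pd.DataFrame([
        {"group": g, "stage": s, "mean_duration": v[0],
         "ci_lo": v[1], "ci_hi": v[2]}
        for (g, s), v in sorted(durations.items())
    ]), out / "stage_durations.csv")
    tw = stg.top_words(model, per_stage=5)
    _write_csv(pd.DataFrame([
        {"stage": s, "role": role, "rank": i + 1, "word": w}
        for (s, role), words in sorted(tw.items())
        for i, w in enumerate(words)
    ]), out / "stage_top_words.csv")
    tick("stages", t0)

    # --- coordination -----------------------------------------------------
    t0 = time.time()
    rows = []
    for b_role, a_role, name in ((TEXTER, COUNSELOR, "texter_to_counselor"),
                                 (COUNSELOR, TEXTER, "counselor_to_texter")):
        ex = coord.extract_exchanges(convs, b_role, a_role)
        res = coord.aggregate(ex, sorted(STYLISTIC_MARKERS),
                              config.coordination_min_exchanges)
        rows.append({"direction": name, "group": "all",
                     "coordination": res.group_value,
                     "n_speakers": len(res.per_speaker)})
        if b_role == COUNSELOR:
            for g in ("more_successful", "less_successful"):
                members = split.group_members(g)
                sub = [e for e in ex if e.speaker_b in members]
                if sub:
                    r = coord.aggregate(sub, sorted(STYLISTIC_MARKERS),
                                        config.coordination_min_exchanges)
                    rows.append({"direction": name, "group": g,
                                 "coordination": r.group_value,
                                 "n_speakers": len(r.per_speaker)})
    _write_csv(pd.DataFrame(rows), out / "coordination.csv")
    cat = coord.category_coordination(convs, PERSPECTIVE_CATEGORIES,
                                      min_exchanges=config.coordination_min_exchanges)
    _write_csv(pd.DataFrame([
        {"category": c.category, "coordination": c.group_value,
         "p_value": c.p_value, "n_speakers": c.n_speakers}
        for c in cat.values()
    ]), out / "category_coordination.csv")
    tick("coordination", t0)

    # --- perspective ------------------------------------------------------
    t0 = time.time()
    trajs = dict(persp.temporal_orientation(convs, n_chunks=config.n_chunks,
                                            seed=config.seed))
    trajs["self_focus"] = persp.self_focus(convs, n_chunks=config.n_chunks,
                                           seed=config.seed)
    trajs["sentiment"] = persp.sentiment_ratio(convs, n_chunks=config.n_chunks,
                                               seed=config.seed)
    rows = []
    for name, tr in trajs.items():
        for outcome, vals in tr.values.items():
            for ch, v in enumerate(vals):
                lo, hi = tr.ci[outcome][ch]
                rows.append({"measure": name, "outcome": outcome, "chunk": ch,
                             "value": v, "ci_lo": lo, "ci_hi": hi})
    persp_df = pd.DataFrame(rows)
    _write_csv(persp_df, out / "perspective.csv")
    tick("perspective", t0)

    # --- prediction -------------------------------------------------------
    t0 = time.time()
    balanced = pred.balance_dataset(convs, seed=config.seed)
    rows = []
    for x in config.prediction_x:
        df = pred.features_frame(balanced, x, model=model)
        y = df["label"].to_numpy()
        res = pred.cross_validate(df.drop(columns=["label"]).to_numpy(), y,
                                  k=config.prediction_folds, seed=config.seed,
                                  x_percent=x)
        rows.append({"x_percent": x, "auc": res.mean_auc,
                     "accuracy": res.mean_accuracy})
    auc_df = pd.DataFrame(rows)
    _write_csv(auc_df, out / "auc_by_x.csv")
    ladder = pred.DEFAULT_LADDER
    if not config.include_ngrams:
        ladder = [step for step in ladder if step[0] != "+ngrams"]
    ladder_df = pred.feature_ladder(balanced, config.ladder_x, model=model,
                                    feature_sets=ladder,
                                    k=config.prediction_folds,
                                    seed=config.seed,
                                    n_boot=config.ladder_bootstrap)
    _write_csv(ladder_df, out / "feature_ladder.csv")
    tick("prediction", t0)

    # --- figures ----------------------------------------------------------
    if config.plots:
        t0 = time.time()
        _plots(out, adapt_df, persp_df, auc_df)
        tick("plots", t0)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_conversations": len(convs),
        "stage_seconds": stage_times,
        "total_seconds": round(time.time() - t_start, 2),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".csv", ".json", ".jsonl") and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _plots(out: Path, adapt_df: pd.DataFrame, persp_df: pd.DataFrame,
           auc_df: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for group, sub in adapt_df.groupby("group"):
        lo = (sub["distance"] - sub["ci_lo"]).clip(lower=0)
        hi = (sub["ci_hi"] - sub["distance"]).clip(lower=0)
        ax.errorbar(sub["chunk"], sub["distance"], yerr=[lo, hi],
                    marker="o", capsize=3, label=group)
    ax.set_xlabel("conversation fifth")
    ax.set_ylabel("cosine distance (positive vs negative)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "fig_adaptability.png", dpi=120)
    plt.close(fig)

    measures = persp_df["measure"].unique()
    fig, axes = plt.subplots(1, len(measures), figsize=(3.2 * len(measures), 3.2),
                             squeeze=False)
    for ax, meas in zip(axes[0], measures):
        sub = persp_df[persp_df["measure"] == meas]
        for outcome, ss in sub.groupby("outcome"):
            ax.plot(ss["chunk"], ss["value"], marker="o", label=outcome)
        ax.set_title(meas)
        ax.set_xlabel("fifth")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(out / "fig_perspective.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(auc_df["x_percent"], auc_df["auc"], marker="o")
    ax.set_xlabel("% of conversation seen")
    ax.set_ylabel("mean 10-fold AUC")
    fig.tight_layout()
    fig.savefig(out / "fig_auc_by_x.png", dpi=120)
    plt.close(fig)
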