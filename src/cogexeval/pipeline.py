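"""End-to-end orchestration: generate -> extract -> review -> adjudicate ->
evaluate -> agree -> report.

A single :class:`PipelineConfig` fully determines a run: the corpus, the
extractor engines (rule-based or simulated with an error model), the review
design (number of reviewers, per-reviewer cap, double-review count, reviewer
noise) and per-stage seeds. Re-running the same config reproduces
byte-identical artifacts.

The primary extractor's responses are what reviewers judge and correct (the
adjudicated corrections become the ground truth used to evaluate *every*
extractor) — mirroring a review design in which one model's answers seed the
annotation and other models are scored against the corrected truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import agreement_report
from .corpus import (
    CorpusBundle, CorpusConfig, generate_corpus, gold_to_extraction,
    write_corpus,
)
from .extractors import (
    ErrorModelConfig, preset_error_config, regex_extract, run_error_model,
)
from .metrics import (
    ErrorTaxonomy, MetricsReport, classify_errors, evaluate_run,
)
from .notes import (
    ConfigError, NoteExtraction, PreprocessConfig, extraction_to_obj,
    write_extractions_jsonl,
)
from .review import (
    QUESTIONS, ReviewRecord, UnadjudicatableError, adjudicate, assign_notes,
    detect_disagreement, simulate_reviewer, write_reviews_jsonl,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractorSpec", "ReviewDesign", "PipelineConfig", "RunManifest",
    "PipelineResult", "demo_config", "run_pipeline", "render_report",
    "THIRD_REVIEWER_ID",
]

THIRD_REVIEWER_ID = "rev-third"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ExtractorSpec:
    """One extractor run: the rule-based engine or a simulated error model."""

    name: str
    engine: str  # "regex" | "simulate"
    error_config: ErrorModelConfig | None = None

    def __post_init__(self) -> None:
        if self.engine not in ("regex", "simulate"):
            raise ConfigError(f"unknown engine {self.engine!r}")
        if self.engine == "simulate" and self.error_config is None:
            raise ConfigError("simulate engine requires an error_config")

    def to_dict(self) -> dict:
        return {"name": self.name, "engine": self.engine,
                "error_config": (self.error_config.to_dict()
                                 if self.error_config else None)}


@dataclass
class ReviewDesign:
    n_reviewers: int = 6
    cap: int = 80
    n_double: int = 120
    noise_q: float = 0.05
    tuple_noise: float | None = None

    def __post_init__(self) -> None:
        if self.n_reviewers < 1:
            raise ConfigError("n_reviewers must be >= 1")
        if not (0.0 <= self.noise_q <= 0.5):
            raise ConfigError("noise_q must be in [0, 0.5]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineConfig:
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    extractors: list[ExtractorSpec] = field(default_factory=list)
    review: ReviewDesign = field(default_factory=ReviewDesign)
    primary_extractor: str | None = None  # defaults to the first spec
    seed_review: int = 0
    seed_adjudication: int = 0

    def __post_init__(self) -> None:
        if not self.extractors:
            raise ConfigError("at least one extractor spec is required")
        names = [s.name for s in self.extractors]
        if len(set(names)) != len(names):
            raise ConfigError("extractor names must be unique")
        if self.primary_extractor is None:
            self.primary_extractor = names[0]
        elif self.primary_extractor not in names:
            raise ConfigError(
                f"primary extractor {self.primary_extractor!r} not among "
                f"{names}")

    def to_dict(self) -> dict:
        return {
            "corpus": self.corpus.to_dict(),
            "preprocess": dataclasses.asdict(self.preprocess),
            "extractors": [s.to_dict() for s in self.extractors],
            "review": self.review.to_dict(),
            "primary_extractor": self.primary_extractor,
            "seed_review": self.seed_review,
            "seed_adjudication": self.seed_adjudication,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        specs = []
        for s in obj.get("extractors", []):
            err = s.get("error_config")
            specs.append(ExtractorSpec(
                name=s["name"], engine=s["engine"],
                error_config=ErrorModelConfig(**err) if err else None))
        return cls(
            corpus=CorpusConfig.from_dict(obj["corpus"]),
            preprocess=PreprocessConfig(**obj.get("preprocess", {})),
            extractors=specs,
            review=ReviewDesign(**obj.get("review", {})),
            primary_extractor=obj.get("primary_extractor"),
            seed_review=obj.get("seed_review", 0),
            seed_adjudication=obj.get("seed_adjudication", 0),
        )


def demo_config(seed: int = 0, n_notes: int = 300,
                noise_q: float = 0.05) -> PipelineConfig:
    """The standard demonstration run: a 300-note corpus, two simulated
    extractors calibrated to the published error profiles, six reviewers.

    Per-stage seeds are derived deterministically from the master seed.
    """
    ss = np.random.SeedSequence(seed)
    s_corpus, s_chatgpt, s_llama, s_review, s_adj = [
        int(x % (2 ** 31)) for x in ss.generate_state(5)]
    return PipelineConfig(
        corpus=CorpusConfig(n_notes=n_notes, seed=s_corpus),
        extractors=[
            ExtractorSpec(name="chatgpt-like", engine="simulate",
                          error_config=preset_error_config(
                              "chatgpt-like", seed=s_chatgpt)),
            ExtractorSpec(name="llama2-like", engine="simulate",
                          error_config=preset_error_config(
                              "llama2-like", seed=s_llama)),
        ],
        review=ReviewDesign(
            n_reviewers=6,
            n_double=max(2, int(round(n_notes * 0.4))),
            # cap scaled like the 50-note cap of a 722-note / 21-reviewer
            # design: total demand over reviewers, with ~15% slack
            cap=max(2, -(-int((n_notes + round(n_notes * 0.4)) * 1.15) // 6)),
            noise_q=noise_q),
        seed_review=s_review,
        seed_adjudication=s_adj,
    )


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config: dict
    counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)

    def check_consistency(self) -> None:
        c = self.counts
        for name, parse_failed in c.get("parse_failed", {}).items():
            evaluated = c.get("evaluated", {}).get(name)
            if evaluated != c["generated"] - parse_failed:
                raise AssertionError(
                    f"{name}: evaluated {evaluated} != generated "
                    f"{c['generated']} - parse_failed {parse_failed}")

    def to_dict(self) -> dict:
        return {"config": self.config, "counts": self.counts,
                "stage_seconds": self.stage_seconds}


@dataclass
class PipelineResult:
    manifest: RunManifest
    bundle: CorpusBundle
    predictions: dict[str, list[NoteExtraction]]
    truth: dict[str, NoteExtraction]
    reviews: list[ReviewRecord]
    metrics: dict[str, dict[str, MetricsReport]]
    taxonomy: dict[str, ErrorTaxonomy]
    agreement: dict
    table4: pd.DataFrame


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _extract_stage(config: PipelineConfig, bundle: CorpusBundle
                   ) -> dict[str, list[NoteExtraction]]:
    preds: dict[str, list[NoteExtraction]] = {}
    for spec in config.extractors:
        if spec.engine == "regex":
            preds[spec.name] = [regex_extract(n.plain_text, n.note_id)
                                for n in bundle.notes]
        else:
            preds[spec.name] = run_error_model(bundle, spec.error_config)
    return preds


def _review_stage(config: PipelineConfig, bundle: CorpusBundle,
                  primary: list[NoteExtraction]
                  ) -> tuple[list[ReviewRecord], dict[str, NoteExtraction],
                             dict]:
    design = config.review
    note_ids = [n.note_id for n in bundle.notes]
    reviewer_ids = [f"rev-{i:02d}" for i in range(design.n_reviewers)]
    plan = assign_notes(note_ids, reviewer_ids, design.n_double, design.cap,
                        seed=config.seed_review)
    rng = np.random.default_rng(config.seed_review + 1)
    gold_by_note = {g.note_id: g for g in bundle.gold}
    pred_by_note = {p.note_id: p for p in primary}
    reviews: list[ReviewRecord] = []
    by_note: dict[str, list[ReviewRecord]] = {}
    for note_id in note_ids:
        for reviewer in plan.assignments[note_id]:
            rec = simulate_reviewer(gold_by_note[note_id],
                                    pred_by_note[note_id],
                                    design.noise_q, rng,
                                    reviewer_id=reviewer,
                                    tuple_noise=design.tuple_noise)
            reviews.append(rec)
            by_note.setdefault(note_id, []).append(rec)
    # third review + adjudication for double notes; singles stand as-is
    adj_rng = np.random.default_rng(config.seed_adjudication)
    truth: dict[str, NoteExtraction] = {}
    n_disagreements = 0
    n_unadjudicatable = 0
    for note_id in note_ids:
        group = by_note[note_id]
        if len(group) == 1:
            truth[note_id] = group[0].corrected
            continue
        a, b = group
        disagree, _ = detect_disagreement(a, b)
        c = None
        if disagree:
            n_disagreements += 1
            c = simulate_reviewer(gold_by_note[note_id], pred_by_note[note_id],
                                  design.noise_q, adj_rng,
                                  reviewer_id=THIRD_REVIEWER_ID,
                                  tuple_noise=design.tuple_noise)
            reviews.append(c)
        try:
            truth[note_id] = adjudicate(a, b, c, adj_rng).final
        except UnadjudicatableError as exc:
            logger.warning("%s", exc)
            n_unadjudicatable += 1
    stats = {"assigned": len(note_ids), "double_reviewed": len(plan.double_set),
             "disagreements": n_disagreements,
             "adjudicated": len(truth),
             "unadjudicatable": n_unadjudicatable}
    return reviews, truth, stats


def _taxonomy_stage(bundle: CorpusBundle,
                    preds: dict[str, list[NoteExtraction]]
                    ) -> dict[str, ErrorTaxonomy]:
    gold_by_note = {g.note_id: g for g in bundle.gold}
    out: dict[str, ErrorTaxonomy] = {}
    for name, extractions in preds.items():
        total = ErrorTaxonomy()
        for p in extractions:
            if not p.parse_ok:
                continue
            total = total + classify_errors(p, gold_by_note[p.note_id])
        out[name] = total
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_ROW_ORDER = (
    ("n_truth_empty", "Total notes without any {t} (in ground truth)", 0),
    ("n_pred_empty", "Total notes without any {t} (in model results)", 0),
    ("n_correct_empty", "Total correctly predicted empty {t}", 0),
    ("tnr", "{t} True Negative Rate (%)", 1),
    ("fnr", "{t} False Negative Rate (%)", 1),
    ("n_eval_subset",
     "Notes with non-empty response used for Precision/Recall ({t})", 0),
    ("n_instances_pred", "Total {t} instances predicted", 0),
    ("macro_precision", "{t} Macro Precision (%)", 1),
    ("macro_precision_sd", "{t} Macro Precision sd (%)", 1),
    ("macro_recall", "{t} Macro Recall (%)", 1),
    ("macro_recall_sd", "{t} Macro Recall sd (%)", 1),
    ("micro_precision", "{t} Micro Precision (%)", 1),
    ("micro_recall", "{t} Micro Recall (%)", 1),
    ("n_error_notes", "Total notes with any error {t} result", 0),
    ("accuracy", "Overall accuracy of {t} (%)", 1),
)


def render_report(metrics: dict[str, dict[str, MetricsReport]],
                  agreement: dict | None = None,
                  taxonomy: dict[str, ErrorTaxonomy] | None = None,
                  reviews: list[ReviewRecord] | None = None
                  ) -> tuple[pd.DataFrame, str]:
    """Render the aggregate-metrics table (one column per extractor run)
    plus a text report with the agreement block and error taxonomy.

    Percentages are rounded to one decimal in the rendered table; the raw
    fractions stay available in the MetricsReport objects.
    """
    runs = list(metrics)
    rows, labels = [], []
    n_parsed = {name: metrics[name]["MMSE"].n_parsed for name in runs}
    labels.append("Notes with parsed JSON")
    rows.append([n_parsed[name] for name in runs])
    for test in ("MMSE", "CDR"):
        for attr, fmt, ndigits in _ROW_ORDER:
            labels.append(fmt.format(t=test))
            row = []
            for name in runs:
                value = getattr(metrics[name][test], attr)
                if value is None or (isinstance(value, float)
                                     and not np.isfinite(value)):
                    row.append("NA")
                elif ndigits:
                    row.append(round(float(value), ndigits))
                else:
                    row.append(int(value))
            rows.append(row)
    table = pd.DataFrame(rows, index=labels, columns=runs)
    table.index.name = "quantity"

    lines = ["= Aggregate metrics =", table.to_string(), ""]
    if reviews:
        lines.append("= Mean reviewer answers to the binary questions (%) =")
        for i, q in enumerate(QUESTIONS):
            vals = [100.0 * r.flags()[i] for r in reviews]
            lines.append(f"  {q}: {np.mean(vals):.1f} (sd {np.std(vals):.1f})")
        lines.append("")
    if agreement is not None:
        lines.append("= Inter-rater agreement (Fleiss' kappa, %) =")
        for block in ("binary_questions", "tuples_2way", "tuples_3way"):
            for key, cellv in agreement.get(block, {}).items():
                v = cellv.get("kappa_pct")
                shown = "undefined" if v is None else f"{v:.1f}"
                lines.append(f"  {block}/{key}: {shown} "
                             f"(n={cellv.get('n_items', 0)})")
        lines.append("")
    if taxonomy:
        lines.append("= Error taxonomy (tuple counts) =")
        for name, tax in taxonomy.items():
            lines.append(f"  {name}: hallucination={tax.hallucination} "
                         f"wrong_test={tax.wrong_test} "
                         f"wrong_date={tax.wrong_date} missed={tax.missed}")
        lines.append("")
    return table, "\n".join(lines)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Execute all stages in order and write every artifact under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    timings = manifest.stage_seconds

    t0 = time.perf_counter()
    bundle = generate_corpus(config.corpus)
    write_corpus(bundle, out / "corpus")
    manifest.counts["generated"] = len(bundle.notes)
    timings["generate"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    preds = _extract_stage(config, bundle)
    manifest.counts["parse_failed"] = {}
    for name, extractions in preds.items():
        write_extractions_jsonl(out / f"preds_{name}.jsonl", extractions)
        manifest.counts["parse_failed"][name] = sum(
            not e.parse_ok for e in extractions)
    timings["extract"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    primary = preds[config.primary_extractor]
    reviews, truth, review_stats = _review_stage(config, bundle, primary)
    write_reviews_jsonl(out / "reviews.jsonl", reviews)
    with open(out / "truth.jsonl", "w", encoding="utf-8") as fh:
        for note_id in sorted(truth):
            fh.write(json.dumps(extraction_to_obj(truth[note_id])) + "\n")
    manifest.counts.update(review_stats)
    timings["review"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    metrics: dict[str, dict[str, MetricsReport]] = {}
    manifest.counts["evaluated"] = {}
    for name, extractions in preds.items():
        per_test, n_fail = evaluate_run(extractions, truth)
        metrics[name] = per_test
        manifest.counts["evaluated"][name] = len(extractions) - n_fail
        with open(out / f"metrics_{name}.json", "w", encoding="utf-8") as fh:
            json.dump({t: r.to_dict() for t, r in per_test.items()}, fh,
                      indent=2, sort_keys=True)
    taxonomy = _taxonomy_stage(bundle, preds)
    with open(out / "taxonomy.json", "w", encoding="utf-8") as fh:
        json.dump({k: v.to_dict() for k, v in taxonomy.items()}, fh,
                  indent=2, sort_keys=True)
    timings["evaluate"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    from collections import Counter
    first_reviews = [r for r in reviews if r.reviewer_id != THIRD_REVIEWER_ID]
    review_counts = Counter(r.note_id for r in first_reviews)
    double_reviews = [r for r in first_reviews
                      if review_counts[r.note_id] == 2]
    machine = {p.note_id: p for p in primary if p.parse_ok}
    agree = agreement_report(double_reviews, machine)
    with open(out / "agreement.json", "w", encoding="utf-8") as fh:
        json.dump(agree, fh, indent=2, sort_keys=True)
    timings["agree"] = round(time.perf_counter() - t0, 3)

    table4, text = render_report(metrics, agree, taxonomy, reviews)
    table4.to_csv(out / "table4.csv")
    (out / "report.txt").write_text(text, encoding="utf-8")
    manifest.check_consistency()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
    return PipelineResult(manifest=manifest, bundle=bundle, predictions=preds,
                          truth=truth, reviews=reviews, metrics=metrics,
                          taxonomy=taxonomy, agreement=agree, table4=table4)
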