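"""Seeded synthetic clinical-note corpora with gold-standard annotations.

Real dementia-clinic notes cannot be shared, so every downstream stage of the
harness (extraction, review, metrics, agreement) is exercised on synthetic
corpora that emulate the statistical structure of such notes: most notes
mention an MMSE (Mini-Mental State Examination, integer out of 30), a minority
mention a CDR (Clinical Dementia Rating, levels 0/0.5/1/2/3), some mention a
MoCA (Montreal Cognitive Assessment) as a distractor test, mentions come in
heterogeneous free-text dialects with dates written many ways, some mentions
are undated, and notes may carry several instances of the same test.

The generator is deterministic: identical (config, seed) reproduce an
identical corpus byte for byte.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .notes import (
    ConfigError,
    ExtractionTuple,
    NoteExtraction,
    NoteRecord,
    PreprocessConfig,
    CDR_LEVELS,
    DATE_DIALECTS,
    RESPONSE_SCHEMA_VERSION,
    preprocess_note,
    render_date,
    tuple_from_obj,
    validate_tuple,
)
from .notes import _tuple_to_obj  # shared serialization helper

__all__ = [
    "CorpusConfig", "GoldAnnotation", "CorpusBundle", "TemplateError",
    "generate_corpus", "render_mention", "gold_to_extraction",
    "template_ids", "write_corpus", "read_gold_jsonl", "write_gold_jsonl",
]


class TemplateError(ValueError):
    """Unknown template id or template incompatible with the tuple."""


# ---------------------------------------------------------------------------
# Mention templates
# ---------------------------------------------------------------------------
# Each template is (sentence format, dated, slash). `slash` templates render
# the score as "s/30" and set denominator 30 in gold; they exist only for the
# 30-point tests. Keyword synonyms (abbreviation vs full test name) are
# separate template ids so round-trip checks can enumerate the whole set.

def _thirty_point_templates(kw: str, kw_long: str) -> dict:
    return {
        "slash_dated": (kw + " {score}/30 on {date}.", True, True),
        "slash_undated": (kw + " {score}/30.", False, True),
        "score_first_dated": (kw + " score of {score} on {date}.", True, False),
        "score_first_undated": (kw + " score of {score}.", False, False),
        "date_first_dated": ("On {date}, " + kw + " was {score}.", True, False),
        "prose_dated": (kw_long + " score of {score} was documented on {date}.",
                        True, False),
        "prose_undated": (kw_long + " score of {score}.", False, False),
        "bare_dated": (kw + ": {score} ({date}).", True, False),
        "bare_undated": (kw + ": {score}.", False, False),
    }


TEMPLATES: dict[str, dict[str, tuple[str, bool, bool]]] = {
    "MMSE": _thirty_point_templates("MMSE", "Mini-Mental State Examination"),
    "MoCA": _thirty_point_templates("MoCA", "Montreal Cognitive Assessment"),
    "CDR": {
        "score_first_dated": ("CDR {score} on {date}.", True, False),
        "score_first_undated": ("CDR of {score}.", False, False),
        "date_first_dated": ("On {date}, CDR was {score}.", True, False),
        "prose_dated": ("Clinical Dementia Rating of {score} was assigned "
                        "on {date}.", True, False),
        "prose_undated": ("Clinical Dementia Rating of {score}.", False, False),
        "bare_dated": ("CDR: {score} ({date}).", True, False),
        "bare_undated": ("CDR: {score}.", False, False),
    },
}


def template_ids(test: str, dated: bool | None = None) -> list[str]:
    """Template ids shipped for a test, optionally filtered by datedness."""
    try:
        items = TEMPLATES[test]
    except KeyError:
        raise TemplateError(f"no templates for test {test!r}") from None
    return [tid for tid, (_, d, _s) in items.items()
            if dated is None or d == dated]


def _fmt_score(score: float) -> str:
    return str(int(score)) if score == int(score) else f"{score:g}"


def render_mention(tuple_: ExtractionTuple, template_id: str,
                   dialect: str = "iso", rng=None) -> str:
    """Render one gold tuple as a free-text mention sentence.

    Deterministic given (tuple, template_id, dialect); ``rng`` is accepted for
    interface symmetry with the stochastic generator but unused. Partial
    (month-year) gold dates must use the ``month_year`` dialect.
    """
    try:
        fmt, dated, _slash = TEMPLATES[tuple_.test][template_id]
    except KeyError:
        raise TemplateError(
            f"unknown template {template_id!r} for test {tuple_.test!r}") from None
    if dated != (tuple_.date is not None):
        raise TemplateError(
            f"template {template_id!r} datedness does not fit the tuple")
    if tuple_.date_partial and dialect != "month_year":
        raise TemplateError("partial dates must render in the month_year dialect")
    if dialect == "month_year" and tuple_.date is not None and not tuple_.date_partial:
        raise TemplateError("month_year dialect requires a partial gold date")
    date_txt = render_date(tuple_.date, dialect) if tuple_.date is not None else ""
    return fmt.format(score=_fmt_score(tuple_.score), date=date_txt)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: sampling weights over date dialects used when rendering dated mentions
DEFAULT_DATE_WEIGHTS = {
    "iso": 1.0, "mdy_dash": 1.0, "mdy_slash": 1.0,
    "month_name": 1.0, "month_year": 0.5,
}

_FILLER_VOCAB = (
    "patient denies reports stable followup medication review history chronic "
    "daily sleep appetite exam normal alert oriented mood memory family "
    "caregiver home plan continue discussed visit clinic no acute distress "
    "gait steady labs ordered diet exercise fatigue mild moderate unchanged "
    "tolerating well improved cognition concerns"
).split()


@dataclass
class CorpusConfig:
    """Knobs of the synthetic corpus.

    Prevalence defaults (89.1% of notes with an MMSE mention, 14.3% with a
    CDR) match the documentation rates observed in dementia-clinic note
    corpora this harness emulates. Filler length defaults to 150-600 words to
    keep runs fast; ``realistic_length`` scales filler to the ~8,400-word mean
    (sd ~3,800) typical of full EHR notes.
    """

    n_notes: int = 300
    mmse_prevalence: float = 0.891
    cdr_prevalence: float = 0.143
    moca_distractor_rate: float = 0.30
    instances_mean: float = 1.5          # truncated-geometric mean, given presence
    max_instances: int = 4
    date_format_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_DATE_WEIGHTS))
    undated_rate: float = 0.15
    filler_words_min: int = 150
    filler_words_max: int = 600
    realistic_length: bool = False
    vital_distractor_rate: float = 0.40  # "BP 120/80"-style numeric noise
    visit_date_rate: float = 0.50        # non-exam date sentences
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mmse_prevalence", "cdr_prevalence", "moca_distractor_rate",
                     "undated_rate", "vital_distractor_rate", "visit_date_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_notes < 0:
            raise ConfigError("n_notes must be >= 0")
        if self.instances_mean < 1.0:
            raise ConfigError("instances_mean must be >= 1 (support is k >= 1)")
        if self.max_instances < 1:
            raise ConfigError("max_instances must be >= 1")
        if not self.date_format_weights:
            raise ConfigError("date_format_weights must be non-empty")
        bad = set(self.date_format_weights) - set(DATE_DIALECTS)
        if bad:
            raise ConfigError(f"unknown date dialects in weights: {sorted(bad)}")
        if any(w < 0 for w in self.date_format_weights.values()):
            raise ConfigError("date_format_weights must be nonnegative")
        if not any(w > 0 for w in self.date_format_weights.values()):
            raise ConfigError("at least one date_format weight must be positive")
        if not (0 < self.filler_words_min <= self.filler_words_max):
            raise ConfigError("need 0 < filler_words_min <= filler_words_max")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, obj: dict) -> "CorpusConfig":
        return cls(**obj)


@dataclass
class GoldAnnotation:
    """Ground-truth tuples for one note, covering MMSE, CDR and MoCA.

    MoCA tuples are gold *context* only: they create wrong-test opportunities
    and are never expected in an MMSE/CDR answer.
    """

    note_id: str
    tuples: list[ExtractionTuple] = field(default_factory=list)
    spans: list[str] | None = None

    def by_test(self, test: str) -> list[ExtractionTuple]:
        return [t for t in self.tuples if t.test == test]


@dataclass
class CorpusBundle:
    notes: list[NoteRecord]
    gold: list[GoldAnnotation]
    manifest: dict


def gold_to_extraction(gold: GoldAnnotation) -> NoteExtraction:
    """The ideal extractor answer implied by a gold annotation (MoCA dropped)."""
    return NoteExtraction(note_id=gold.note_id,
                          mmse=list(gold.by_test("MMSE")),
                          cdr=list(gold.by_test("CDR")))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_EPOCH = _dt.date(2010, 1, 12)
_HORIZON = _dt.date(2023, 5, 24)


def _draw_instances(rng, config: CorpusConfig) -> int:
    p = 1.0 / config.instances_mean
    return int(min(rng.geometric(p), config.max_instances))


def _draw_score(rng, test: str) -> float:
    if test == "CDR":
        return float(rng.choice(CDR_LEVELS, p=[0.25, 0.30, 0.20, 0.15, 0.10]))
    return float(rng.integers(0, 31))


def _draw_mention(rng, config: CorpusConfig, test: str,
                  encounter: _dt.date) -> tuple[ExtractionTuple, str, str]:
    """Draw one gold tuple plus the (template, dialect) that will render it."""
    score = _draw_score(rng, test)
    dated = rng.random() >= config.undated_rate
    date = None
    partial = False
    dialect = "iso"
    if dated:
        date = encounter - _dt.timedelta(days=int(rng.integers(0, 1096)))
        names = sorted(config.date_format_weights)
        weights = np.array([config.date_format_weights[n] for n in names], float)
        dialect = str(names[rng.choice(len(names), p=weights / weights.sum())])
        if dialect == "month_year":
            date = date.replace(day=1)
            partial = True
    tid = str(rng.choice(template_ids(test, dated=dated)))
    fmt, _d, slash = TEMPLATES[test][tid]
    denom = 30.0 if slash else None
    t = ExtractionTuple(test=test, score=score, denominator=denom,
                        date=date, date_partial=partial)
    validate_tuple(t)
    return t, tid, dialect


def _filler_sentences(rng, config: CorpusConfig) -> list[str]:
    if config.realistic_length:
        n_words = int(max(config.filler_words_min,
                          rng.normal(8428.2, 3822.3)))
    else:
        n_words = int(rng.integers(config.filler_words_min,
                                   config.filler_words_max + 1))
    words = [str(w) for w in rng.choice(_FILLER_VOCAB, size=n_words)]
    sentences, i = [], 0
    while i < n_words:
        k = int(rng.integers(8, 15))
        chunk = words[i:i + k]
        sentences.append(chunk[0].capitalize() + " " + " ".join(chunk[1:]) + "."
                         if len(chunk) > 1 else chunk[0].capitalize() + ".")
        i += k
    return sentences


def _distractor_sentences(rng, config: CorpusConfig,
                          encounter: _dt.date) -> list[str]:
    out = []
    if rng.random() < config.vital_distractor_rate:
        sys_bp = int(rng.integers(100, 180))
        dia_bp = int(rng.integers(60, 100))
        hr = int(rng.integers(55, 110))
        out.append(f"Vital signs: BP {sys_bp}/{dia_bp}, HR {hr}.")
    if rng.random() < config.visit_date_rate:
        d = encounter - _dt.timedelta(days=int(rng.integers(0, 700)))
        out.append(f"Patient seen in clinic on {render_date(d, 'mdy_slash')}.")
    return out


def generate_corpus(config: CorpusConfig) -> CorpusBundle:
    """Generate a corpus of ``config.n_notes`` annotated synthetic notes.

    Per-note presence of MMSE, CDR and MoCA mentions are independent
    Bernoulli draws at the configured prevalences; given presence, the number
    of instances follows a truncated geometric. Every mention is rendered by
    exactly one (template, date-dialect) pair and the gold annotation lists
    the true tuples, so normalization applied to the rendered tokens recovers
    the gold values exactly.
    """
    rng = np.random.default_rng(config.seed)
    notes: list[NoteRecord] = []
    gold: list[GoldAnnotation] = []
    pp = PreprocessConfig()
    for i in range(config.n_notes):
        note_id = f"note-{i:05d}"
        encounter = _EPOCH + _dt.timedelta(
            days=int(rng.integers(0, (_HORIZON - _EPOCH).days + 1)))
        tuples: list[ExtractionTuple] = []
        spans: list[str] = []
        mention_sentences: list[str] = []
        for test, prev in (("MMSE", config.mmse_prevalence),
                           ("CDR", config.cdr_prevalence),
                           ("MoCA", config.moca_distractor_rate)):
            if rng.random() >= prev:
                continue
            for _ in range(_draw_instances(rng, config)):
                t, tid, dialect = _draw_mention(rng, config, test, encounter)
                sentence = render_mention(t, tid, dialect)
                tuples.append(ExtractionTuple(
                    test=t.test, score=t.score, denominator=t.denominator,
                    date=t.date, date_partial=t.date_partial, raw_span=sentence))
                spans.append(sentence)
                mention_sentences.append(sentence)
        sentences = _filler_sentences(rng, config)
        sentences += _distractor_sentences(rng, config, encounter)
        # splice mention sentences at random positions
        for s in mention_sentences:
            pos = int(rng.integers(0, len(sentences) + 1))
            sentences.insert(pos, s)
        raw_text = " ".join(sentences)
        plain = preprocess_note(raw_text, encounter, pp)
        notes.append(NoteRecord(note_id=note_id, encounter_date=encounter,
                                raw_text=raw_text, plain_text=plain))
        gold.append(GoldAnnotation(note_id=note_id, tuples=tuples, spans=spans))
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_notes": config.n_notes,
        "response_schema_version": RESPONSE_SCHEMA_VERSION,
    }
    return CorpusBundle(notes=notes, gold=gold, manifest=manifest)


# ---------------------------------------------------------------------------
# Persistence (plain text + JSONL, all UTF-8)
# ---------------------------------------------------------------------------

def write_gold_jsonl(path, gold: list[GoldAnnotation]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in gold:
            fh.write(json.dumps({
                "note_id": g.note_id,
                "tuples": [_tuple_to_obj(t) for t in g.tuples],
                "spans": g.spans,
            }) + "\n")


def read_gold_jsonl(path) -> list[GoldAnnotation]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                out.append(GoldAnnotation(
                    note_id=obj["note_id"],
                    tuples=[tuple_from_obj(o) for o in obj["tuples"]],
                    spans=obj.get("spans")))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad gold record: {exc}")
    return out


def write_corpus(bundle: CorpusBundle, out_dir) -> None:
    """Write one plain-text file per note plus gold JSONL and a manifest."""
    from pathlib import Path

    out = Path(out_dir)
    notes_dir = out / "notes"
    notes_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for note in bundle.notes:
        (notes_dir / f"{note.note_id}.txt").write_text(note.raw_text,
                                                       encoding="utf-8")
        index.append({"note_id": note.note_id,
                      "encounter_date": note.encounter_date.isoformat()})
    write_gold_jsonl(out / "gold.jsonl", bundle.gold)
    manifest = dict(bundle.manifest)
    manifest["notes"] = index
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                       encoding="utf-8")


def read_corpus(corpus_dir) -> CorpusBundle:
    from pathlib import Path

    out = Path(corpus_dir)
    manifest = json.loads((out / "manifest.json").read_text(encoding="utf-8"))
    pp = PreprocessConfig()
    notes = []
    for entry in manifest["notes"]:
        raw = (out / "notes" / f"{entry['note_id']}.txt").read_text(
            encoding="utf-8")
        enc = _dt.date.fromisoformat(entry["encounter_date"])
        notes.append(NoteRecord(note_id=entry["note_id"], encounter_date=enc,
                                raw_text=raw,
                                plain_text=preprocess_note(raw, enc, pp)))
    gold = read_gold_jsonl(out / "gold.jsonl")
    return CorpusBundle(notes=notes, gold=gold, manifest=manifest)
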