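"""Extractors standing in for the LLMs under evaluation.

Two engines ship:

* :func:`regex_extract` — a deterministic rule-based baseline (keyword plus
  nearest score/date inside the sentence) so the whole pipeline runs
  end-to-end with no model at all.
* :func:`simulate_extraction` — a seeded error-model simulator that starts
  from the gold annotation and injects the four empirically observed failure
  modes of LLM extractors: total hallucination, reporting another test's
  score, missing a score, and reporting the right score with the wrong date.

A thin adapter contract (:class:`ExtractorAdapter`) is provided for plugging
in a real external model; failures there are recorded values (the note is
excluded from evaluation), never crashes. No network code ships enabled.
"""

from __future__ import annotations

import abc
import datetime as _dt
import logging
import re
from dataclasses import dataclass, asdict

import numpy as np

from .corpus import CorpusBundle, CorpusConfig, GoldAnnotation
from .notes import (
    CDR_LEVELS,
    ConfigError,
    ExtractionTuple,
    NoteExtraction,
    NoteRecord,
    ScoreError,
    normalize_date,
    parse_extraction_json,
    validate_tuple,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorModelConfig", "ExposureCounts", "ExtractorAdapter", "AdapterRun",
    "regex_scan", "regex_extract", "simulate_extraction", "run_error_model",
    "calibrate_error_config", "preset_error_config", "PRESET_NAMES",
    "apply_adapter",
]


# ---------------------------------------------------------------------------
# Regex baseline
# ---------------------------------------------------------------------------

_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")

_KEYWORD_RE = re.compile(
    r"\b(Mini-Mental State Examination|Montreal Cognitive Assessment|"
    r"Clinical Dementia Rating|MMSE|MoCA|CDR)\b", re.IGNORECASE)

_KEYWORD_TEST = {
    "mini-mental state examination": "MMSE",
    "mmse": "MMSE",
    "montreal cognitive assessment": "MoCA",
    "moca": "MoCA",
    "clinical dementia rating": "CDR",
    "cdr": "CDR",
}

# search-form date patterns, most specific first
_DATE_PATTERNS = (
    re.compile(r"\b\d{4}-\d{1,2}-\d{1,2}\b"),
    re.compile(r"\b\d{1,2}-\d{1,2}-\d{4}\b"),
    re.compile(r"\b\d{1,2}/\d{1,2}/\d{2,4}\b"),
    re.compile(r"\b[A-Za-z]+\.?\s+\d{1,2},\s+\d{4}\b"),
    re.compile(r"\b[A-Za-z]+\.?\s+\d{4}\b"),
)

_SLASH30_RE = re.compile(r"\b(\d{1,2})\s*/\s*30\b")
_BARE_INT_RE = re.compile(r"\b(\d{1,2})\b")
_CDR_RE = re.compile(r"\b([0-3](?:\.5)?)(?!\.?\d)")  # "0.5" before its "0"

#: characters of post-keyword context searched for the score token
_SCORE_WINDOW = 60


def _date_candidates(sentence: str):
    """Spans of parseable date tokens in a sentence, longest-span first.

    A date immediately followed by ':' is the encounter-date prefix that
    preprocessing prepends to the note; it is not an exam date and is skipped.
    """
    taken: list[tuple[int, int, object, bool]] = []
    for pat in _DATE_PATTERNS:
        for m in pat.finditer(sentence):
            if any(m.start() < e and s < m.end() for s, e, *_ in taken):
                continue
            if sentence[m.end():m.end() + 1] == ":":
                continue
            try:
                date, partial = normalize_date(m.group(0))
            except ValueError:
                continue
            if date is not None:
                taken.append((m.start(), m.end(), date, partial))
    return sorted(taken)


def _inside(pos_a: int, pos_b: int, spans) -> bool:
    return any(pos_a < e and s < pos_b for s, e, *_ in spans)


def _find_score(test: str, window: str, offset: int, date_spans):
    """First valid score token for `test` in the post-keyword window."""
    if test in ("MMSE", "MoCA"):
        m = _SLASH30_RE.search(window)
        if m and not _inside(offset + m.start(), offset + m.end(), date_spans):
            return float(m.group(1)), 30.0
        for m in _BARE_INT_RE.finditer(window):
            if _inside(offset + m.start(), offset + m.end(), date_spans):
                continue
            v = float(m.group(1))
            if 0 <= v <= 30:
                return v, None
        return None
    for m in _CDR_RE.finditer(window):
        if _inside(offset + m.start(), offset + m.end(), date_spans):
            continue
        v = float(m.group(1))
        if v in CDR_LEVELS:
            return v, None
    return None


def regex_scan(plain_text: str) -> list[ExtractionTuple]:
    """Scan preprocessed text for test-score mentions of all three tests.

    Deterministic. Per keyword occurrence: the first valid score token within
    a bounded window after the keyword, and the nearest parseable date within
    the same sentence (else no date). Numbers inside date tokens are never
    read as scores.
    """
    found: list[ExtractionTuple] = []
    for sentence in _SENTENCE_SPLIT.split(plain_text):
        date_spans = _date_candidates(sentence)
        for kw in _KEYWORD_RE.finditer(sentence):
            test = _KEYWORD_TEST[kw.group(1).lower()]
            window = sentence[kw.end():kw.end() + _SCORE_WINDOW]
            hit = _find_score(test, window, kw.end(), date_spans)
            if hit is None:
                continue
            score, denom = hit
            date, partial = None, False
            if date_spans:
                def dist(span):
                    s, e, *_ = span
                    return 0 if s < kw.end() and kw.start() < e else \
                        min(abs(s - kw.end()), abs(kw.start() - e))
                s, e, date, partial = min(date_spans, key=dist)
            t = ExtractionTuple(test=test, score=score, denominator=denom,
                                date=date, date_partial=partial,
                                raw_span=sentence)
            try:
                validate_tuple(t)
            except ScoreError:
                continue
            found.append(t)
    return found


def regex_extract(plain_text: str, note_id: str = "") -> NoteExtraction:
    """Rule-based baseline extraction: MMSE and CDR tuples from plain text.

    MoCA mentions are recognized and deliberately excluded — the baseline
    never reports a MoCA score under MMSE or CDR.
    """
    tuples = regex_scan(plain_text)
    return NoteExtraction(
        note_id=note_id,
        mmse=[t for t in tuples if t.test == "MMSE"],
        cdr=[t for t in tuples if t.test == "CDR"])


# ---------------------------------------------------------------------------
# Error-model simulator
# ---------------------------------------------------------------------------

@dataclass
class ErrorModelConfig:
    """Per-tuple and per-note error probabilities of a simulated extractor.

    The per-tuple outcomes (miss, wrong test, wrong date, faithful) are
    mutually exclusive — one draw per gold tuple — while hallucination is an
    additive per-note event and parse failure a per-note veto.
    """

    p_hallucinate: float = 0.0
    p_wrong_test: float = 0.0
    p_miss: float = 0.0
    p_wrong_date: float = 0.0
    p_parse_fail: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_hallucinate", "p_wrong_test", "p_miss",
                     "p_wrong_date", "p_parse_fail"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.p_miss + self.p_wrong_test + self.p_wrong_date > 1.0 + 1e-12:
            raise ConfigError(
                "p_miss + p_wrong_test + p_wrong_date must not exceed 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _shift_date(base: _dt.date, rng) -> _dt.date:
    """A guaranteed-different date: uniform nonzero offset of 30-400 days."""
    sign = -1 if rng.random() < 0.5 else 1
    return base + _dt.timedelta(days=sign * int(rng.integers(30, 401)))


def _substitute_distractor(orig: ExtractionTuple, gold: GoldAnnotation, rng):
    """Report another test's score under `orig.test`, if validly possible."""
    candidates = []
    for d in gold.tuples:
        if d.test == orig.test:
            continue
        sub = ExtractionTuple(test=orig.test, score=d.score,
                              date=d.date, date_partial=d.date_partial)
        try:
            validate_tuple(sub)
        except ScoreError:
            continue
        candidates.append(sub)
    if not candidates:
        return None
    return candidates[int(rng.integers(len(candidates)))]


def _hallucinated_tuple(gold: GoldAnnotation, note: NoteRecord, rng):
    """Fabricate a tuple unsupported by any gold value in the note."""
    seen = {float(t.score) for t in gold.tuples}
    test = "MMSE" if rng.random() < 0.5 else "CDR"
    if test == "CDR":
        free = [v for v in CDR_LEVELS if v not in seen]
        if not free:
            test = "MMSE"
    if test == "CDR":
        score = float(free[int(rng.integers(len(free)))])
    else:
        score = float(rng.integers(0, 31))
        while score in seen:
            score = float(rng.integers(0, 31))
    date = note.encounter_date - _dt.timedelta(days=int(rng.integers(0, 1096)))
    return ExtractionTuple(test=test, score=score, date=date)


def simulate_extraction(gold: GoldAnnotation, note: NoteRecord,
                        config: ErrorModelConfig, rng) -> NoteExtraction:
    """Simulate one extractor response for a note from its gold annotation.

    Per gold MMSE/CDR tuple one outcome is drawn: faithful, missed, wrong
    test (a distractor tuple's score reported under this test), or wrong date
    (score kept, date perturbed). Per note, a fabricated tuple may be
    injected (hallucination) and the whole response may fail to parse.
    Fully reproducible given the rng state.
    """
    if gold.note_id != note.note_id:
        raise ValueError("gold annotation does not belong to this note")
    if rng.random() < config.p_parse_fail:
        return NoteExtraction(note_id=note.note_id, parse_ok=False,
                              failure_reason="simulated parse failure")
    out: dict[str, list[ExtractionTuple]] = {"MMSE": [], "CDR": []}
    cut1 = config.p_miss
    cut2 = cut1 + config.p_wrong_test
    cut3 = cut2 + config.p_wrong_date
    for t in gold.tuples:
        if t.test not in out:
            continue
        u = rng.random()
        if u < cut1:
            continue  # missed
        if u < cut2:
            sub = _substitute_distractor(t, gold, rng)
            if sub is None:
                logger.debug("note %s: no usable distractor, falling back to "
                             "faithful", note.note_id)
                out[t.test].append(t)
            else:
                out[t.test].append(sub)
            continue
        if u < cut3:
            base = t.date if t.date is not None else note.encounter_date
            out[t.test].append(ExtractionTuple(
                test=t.test, score=t.score, denominator=t.denominator,
                date=_shift_date(base, rng)))
            continue
        out[t.test].append(t)
    if rng.random() < config.p_hallucinate:
        h = _hallucinated_tuple(gold, note, rng)
        out[h.test].append(h)
    return NoteExtraction(note_id=note.note_id,
                          mmse=out["MMSE"], cdr=out["CDR"])


def run_error_model(bundle: CorpusBundle,
                    config: ErrorModelConfig) -> list[NoteExtraction]:
    """Apply the error model to a whole corpus, seeded from the config."""
    rng = np.random.default_rng(config.seed)
    return [simulate_extraction(g, n, config, rng)
            for g, n in zip(bundle.gold, bundle.notes)]


# ---------------------------------------------------------------------------
# Calibration and presets
# ---------------------------------------------------------------------------

@dataclass
class ExposureCounts:
    """Denominators a calibration converts error counts over.

    ``n_gold_tuples`` exposes the per-tuple modes (miss, wrong test, wrong
    date); ``n_notes`` exposes the per-note modes (hallucination, parse
    failure).
    """

    n_gold_tuples: int
    n_notes: int
    n_parse_fail: int = 0

    def __post_init__(self) -> None:
        if self.n_gold_tuples < 0 or self.n_notes < 0 or self.n_parse_fail < 0:
            raise ConfigError("exposure counts must be nonnegative")


def calibrate_error_config(error_counts, exposures: ExposureCounts,
                           seed: int = 0) -> ErrorModelConfig:
    """Convert observed error-mode counts over exposures into probabilities.

    ``error_counts`` is an :class:`~cogexeval.metrics.ErrorTaxonomy` (or any
    object with hallucination/wrong_test/wrong_date/missed counts).
    """
    tuple_counts = (error_counts.missed, error_counts.wrong_test,
                    error_counts.wrong_date)
    if exposures.n_gold_tuples == 0 and any(tuple_counts):
        raise ConfigError("per-tuple error counts with zero gold-tuple exposure")
    if exposures.n_notes == 0 and (error_counts.hallucination
                                   or exposures.n_parse_fail):
        raise ConfigError("per-note error counts with zero note exposure")
    div_t = exposures.n_gold_tuples or 1
    div_n = exposures.n_notes or 1
    return ErrorModelConfig(
        p_miss=error_counts.missed / div_t,
        p_wrong_test=error_counts.wrong_test / div_t,
        p_wrong_date=error_counts.wrong_date / div_t,
        p_hallucinate=error_counts.hallucination / div_n,
        p_parse_fail=exposures.n_parse_fail / div_n,
        seed=seed,
    )


def preset_error_config(name: str, seed: int = 0) -> ErrorModelConfig:
    """Ship calibrated presets for the two extractor behaviours emulated.

    Both presets are *approximate*: they convert published double-review
    error-mode counts for MMSE over an exposure base of ~352 gold instances
    in ~306 parsed notes (the gold-instance base is itself back-computed from
    pooled precision/recall and instance counts, and the "chatgpt-like"
    missed count from the same arithmetic), plus a 12/722 parse-failure rate.
    """
    from .metrics import ErrorTaxonomy  # local import avoids a cycle

    presets = {
        "chatgpt-like": (ErrorTaxonomy(hallucination=3, wrong_test=17,
                                       wrong_date=19, missed=8),
                         ExposureCounts(n_gold_tuples=352, n_notes=306,
                                        n_parse_fail=int(306 * 12 / 722))),
        "llama2-like": (ErrorTaxonomy(hallucination=27, wrong_test=19,
                                      wrong_date=23, missed=25),
                        ExposureCounts(n_gold_tuples=352, n_notes=306,
                                       n_parse_fail=int(306 * 12 / 722))),
    }
    try:
        counts, exposures = presets[name]
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {sorted(presets)}") from None
    return calibrate_error_config(counts, exposures, seed=seed)


PRESET_NAMES = ("chatgpt-like", "llama2-like")


# ---------------------------------------------------------------------------
# External-model adapter contract
# ---------------------------------------------------------------------------

class ExtractorAdapter(abc.ABC):
    """Contract for plugging a real external model into the pipeline.

    An adapter maps preprocessed plain text to a raw response document; it
    must never mutate notes, and any failure (timeout, refusal, transport
    error) must surface as a raised exception which :func:`apply_adapter`
    records — the note is then excluded from evaluation, mirroring how
    API-error notes are dropped from a study sample.
    """

    name: str = "adapter"

    @abc.abstractmethod
    def extract(self, plain_text: str) -> str:
        """Return the raw response text for one preprocessed note."""


@dataclass
class AdapterRun:
    extractions: list[NoteExtraction]
    failures: dict[str, str]  # note_id -> failure description


def apply_adapter(adapter: ExtractorAdapter,
                  notes: list[NoteRecord]) -> AdapterRun:
    """Run an adapter over notes; failed calls are recorded, not raised."""
    extractions, failures = [], {}
    for note in notes:
        try:
            raw = adapter.extract(note.plain_text)
        except Exception as exc:  # a failed call is a value
            failures[note.note_id] = f"{type(exc).__name__}: {exc}"
            logger.warning("adapter %s failed on note %s: %s",
                           adapter.name, note.note_id, exc)
            continue
        extractions.append(parse_extraction_json(raw, note_id=note.note_id))
    return AdapterRun(extractions=extractions, failures=failures)
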