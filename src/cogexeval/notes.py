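"""Data model for clinical notes and score extractions.

This module holds the atomic unit of the whole harness — the
:class:`ExtractionTuple`, a single (test, score, date) claim about a note —
plus the note preprocessing contract applied before any extractor sees the
text, score/date normalization across the free-text dialects clinicians
actually write, and parsing/validation of extractor JSON responses.

Design notes
------------
* Parse failure is a *value*, never an exception: a malformed extractor
  response yields a :class:`NoteExtraction` with ``parse_ok=False`` and a
  reason, so downstream metrics can count failed notes separately instead of
  crashing mid-corpus.
* Dates are normalized month-first by default (US EHR convention); month-year
  mentions resolve to day 1 and carry a ``partial`` flag so a partial date can
  never silently equal a full one during exact matching.
"""

from __future__ import annotations

import datetime as _dt
import html
import json
import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

TESTS = ("MMSE", "CDR", "MoCA")

#: CDR global staging levels accepted by default.
CDR_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)

MONTH_NAMES = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)
_MONTH_INDEX = {m.lower(): i + 1 for i, m in enumerate(MONTH_NAMES)}
_MONTH_INDEX.update({m[:3].lower(): i + 1 for i, m in enumerate(MONTH_NAMES)})


class ScoreError(ValueError):
    """A score token is malformed or outside the test's valid range."""


class DateError(ValueError):
    """A non-empty date token could not be parsed under any known dialect."""


class ConfigError(ValueError):
    """A configuration field violates its invariant."""


# ---------------------------------------------------------------------------
# Core records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtractionTuple:
    """One (test, score, date) claim about a note.

    ``denominator`` keeps the "/30" surface form when present but does not
    participate in matching: "27/30" and a bare "27" are the same score.
    ``date_partial`` marks month-year-only dates (stored with day=1).
    """

    test: str
    score: float
    denominator: float | None = None
    date: _dt.date | None = None
    date_partial: bool = False
    raw_span: str | None = None

    def match_key(self) -> tuple:
        """Key under which exact tuple matching operates."""
        return (self.test, float(self.score), self.date, self.date_partial)

    def sort_key(self) -> tuple:
        d = self.date or _dt.date.min
        return (d, self.date_partial, float(self.score))


def validate_tuple(t: ExtractionTuple, *, allow_cdr_sum_of_boxes: bool = False) -> None:
    """Enforce per-test score domains; raise :class:`ScoreError` on violation."""
    if t.test not in TESTS:
        raise ScoreError(f"unknown test {t.test!r}")
    if t.test in ("MMSE", "MoCA"):
        if t.score != int(t.score) or not (0 <= t.score <= 30):
            raise ScoreError(f"{t.test} score {t.score} not an integer in [0, 30]")
        if t.denominator is not None and t.denominator != 30:
            raise ScoreError(f"{t.test} denominator must be 30, got {t.denominator}")
    else:  # CDR
        if allow_cdr_sum_of_boxes:
            if not (0 <= t.score <= 18) or (t.score * 2) != int(t.score * 2):
                raise ScoreError(f"CDR sum-of-boxes {t.score} not in 0-18 by halves")
        elif float(t.score) not in CDR_LEVELS:
            raise ScoreError(f"CDR score {t.score} not in {{0, 0.5, 1, 2, 3}}")
        if t.denominator is not None:
            raise ScoreError("CDR scores carry no denominator")


@dataclass
class NoteRecord:
    """A clinical note: raw (possibly marked-up) text plus its preprocessed form."""

    note_id: str
    encounter_date: _dt.date
    raw_text: str
    plain_text: str = ""


@dataclass
class NoteExtraction:
    """An extractor's (or reviewer's) full per-note answer.

    Invariant: ``parse_ok=False`` implies both tuple lists are empty and
    ``failure_reason`` is set. Empty lists with ``parse_ok=True`` are a
    legitimate "no scores in this note" answer.
    """

    note_id: str
    mmse: list[ExtractionTuple] = field(default_factory=list)
    cdr: list[ExtractionTuple] = field(default_factory=list)
    parse_ok: bool = True
    failure_reason: str | None = None

    def tuples(self, test: str) -> list[ExtractionTuple]:
        if test == "MMSE":
            return self.mmse
        if test == "CDR":
            return self.cdr
        raise ValueError(f"extractions carry only MMSE and CDR lists, not {test!r}")


@dataclass
class PreprocessConfig:
    """Note preprocessing knobs: context-window size and date-prefix dialect."""

    max_tokens: int = 3696
    date_prefix_format: str = "iso"

    def __post_init__(self) -> None:
        if self.max_tokens < 1:
            raise ConfigError("max_tokens must be >= 1")
        if self.date_prefix_format not in DATE_DIALECTS:
            raise ConfigError(f"unknown date dialect {self.date_prefix_format!r}")


# ---------------------------------------------------------------------------
# Date dialects
# ---------------------------------------------------------------------------

def _parse_iso(s: str):
    m = re.fullmatch(r"(\d{4})-(\d{1,2})-(\d{1,2})", s)
    if m:
        return _dt.date(int(m[1]), int(m[2]), int(m[3])), False
    return None


def _parse_mdy_dash(s: str):
    m = re.fullmatch(r"(\d{1,2})-(\d{1,2})-(\d{4})", s)
    if m:
        return _dt.date(int(m[3]), int(m[1]), int(m[2])), False
    return None


def _parse_mdy_slash(s: str):
    m = re.fullmatch(r"(\d{1,2})/(\d{1,2})/(\d{2,4})", s)
    if not m:
        return None
    year = int(m[3])
    if len(m[3]) == 2:  # strptime %y pivot: 00-68 -> 2000s, 69-99 -> 1900s
        year += 2000 if year <= 68 else 1900
    elif len(m[3]) == 3:
        return None
    return _dt.date(year, int(m[1]), int(m[2])), False


def _parse_month_name(s: str):
    m = re.fullmatch(r"([A-Za-z]+)\.?\s+(\d{1,2}),?\s+(\d{4})", s)
    if m and m[1].lower() in _MONTH_INDEX:
        return _dt.date(int(m[3]), _MONTH_INDEX[m[1].lower()], int(m[2])), False
    return None


def _parse_month_year(s: str):
    m = re.fullmatch(r"([A-Za-z]+)\.?\s+(\d{4})", s)
    if m and m[1].lower() in _MONTH_INDEX:
        return _dt.date(int(m[2]), _MONTH_INDEX[m[1].lower()], 1), True
    return None


#: dialect id -> (parser, renderer); order of this dict is the default parse order.
DATE_DIALECTS = {
    "iso": (_parse_iso, lambda d: d.isoformat()),
    "mdy_dash": (_parse_mdy_dash, lambda d: f"{d.month:02d}-{d.day:02d}-{d.year}"),
    "mdy_slash": (_parse_mdy_slash, lambda d: f"{d.month}/{d.day}/{d.year % 100:02d}"),
    "month_name": (_parse_month_name,
                   lambda d: f"{MONTH_NAMES[d.month - 1]} {d.day}, {d.year}"),
    "month_year": (_parse_month_year,
                   lambda d: f"{MONTH_NAMES[d.month - 1]} {d.year}"),
}

DEFAULT_DIALECT_ORDER = tuple(DATE_DIALECTS)


def render_date(date: _dt.date, dialect: str = "iso") -> str:
    """Render a date in one of the supported free-text dialects."""
    try:
        return DATE_DIALECTS[dialect][1](date)
    except KeyError:
        raise ConfigError(f"unknown date dialect {dialect!r}") from None


def normalize_date(raw: str | None,
                   dialect_order=DEFAULT_DIALECT_ORDER
                   ) -> tuple[_dt.date | None, bool]:
    """Resolve a free-text date token to ``(date, partial)``.

    Empty/absent input returns ``(None, False)``. Month-year-only inputs
    resolve with day=1 and ``partial=True``. Ambiguous numeric dates are read
    month-first under the default dialect order. Unparseable non-empty text
    raises :class:`DateError` — the caller decides whether that is fatal.
    """
    if raw is None:
        return None, False
    s = raw.strip().strip("“”\"'")
    if not s:
        return None, False
    for dialect in dialect_order:
        parsed = None
        try:
            parsed = DATE_DIALECTS[dialect][0](s)
        except ValueError:
            parsed = None  # shape matched but not a real calendar date
        if parsed is not None:
            return parsed
    raise DateError(f"unparseable date {raw!r}")


# ---------------------------------------------------------------------------
# Score normalization
# ---------------------------------------------------------------------------

_SCORE_RE = re.compile(r"\s*(\d+(?:\.\d+)?)\s*(?:/\s*(\d+))?\s*")


def normalize_score(test: str, raw: str | float,
                    *, allow_cdr_sum_of_boxes: bool = False
                    ) -> tuple[float, float | None]:
    """Normalize a score token to ``(score, denominator)``.

    "27/30" -> (27, 30); bare "27" -> (27, None); CDR "0.5" -> (0.5, None).
    Range violations (e.g. MMSE 35/30) raise :class:`ScoreError`.
    """
    if test not in TESTS:
        raise ScoreError(f"unknown test {test!r}")
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        score, denom = float(raw), None
    else:
        m = _SCORE_RE.fullmatch(str(raw))
        if not m:
            raise ScoreError(f"malformed score token {raw!r}")
        score = float(m[1])
        denom = float(m[2]) if m[2] else None
    t = ExtractionTuple(test=test, score=score, denominator=denom)
    validate_tuple(t, allow_cdr_sum_of_boxes=allow_cdr_sum_of_boxes)
    return score, denom


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

_TAG_RE = re.compile(r"<[^>]*>")


def strip_markup(text: str) -> str:
    """Delete markup tags, decode entities, collapse whitespace."""
    return " ".join(html.unescape(_TAG_RE.sub(" ", text)).split())


def truncate_tokens(text: str, max_tokens: int) -> str:
    """Keep the first ``max_tokens`` whitespace-delimited tokens.

    Spacing between kept tokens collapses to single spaces (tokenization here
    is deliberately whitespace-based; it feeds a context-window contract, not
    a model tokenizer).
    """
    if max_tokens < 1:
        raise ConfigError("max_tokens must be >= 1")
    return " ".join(text.split()[:max_tokens])


def preprocess_note(raw_text: str, encounter_date: _dt.date,
                    config: PreprocessConfig | None = None) -> str:
    """Apply the standard pre-extraction transform to a raw note.

    The result is ``<rendered encounter date>:`` followed by the
    markup-stripped text, truncated to the configured token budget. The date
    prefix gives an extractor an anchor for relative or missing dates.
    """
    config = config or PreprocessConfig()
    body = strip_markup(raw_text)
    prefix = render_date(encounter_date, config.date_prefix_format) + ":"
    text = f"{prefix} {body}" if body else prefix
    return truncate_tokens(text, config.max_tokens)


# ---------------------------------------------------------------------------
# Extractor-response JSON (canonical dialect)
# ---------------------------------------------------------------------------
# Canonical response document: {"MMSE": [{"score": "27/30", "date": "2010-10-10"}],
# "CDR": []}. Scores are strings (slash form allowed), dates ISO or null.
# This schema is this harness's own dialect, versioned in corpus manifests.

RESPONSE_SCHEMA_VERSION = "1"


def _score_to_text(t: ExtractionTuple) -> str:
    s = int(t.score) if t.score == int(t.score) else t.score
    return f"{s}/{int(t.denominator)}" if t.denominator is not None else f"{s}"


def _date_to_text(t: ExtractionTuple) -> str | None:
    if t.date is None:
        return None
    # month-year dates round-trip through their own dialect, keeping the
    # partial flag distinguishable from a true first-of-month date
    if t.date_partial:
        return render_date(t.date, "month_year")
    return t.date.isoformat()


def serialize_extraction_json(ext: NoteExtraction) -> str:
    """Render a NoteExtraction as a canonical response document."""
    doc = {}
    for key, tuples in (("MMSE", ext.mmse), ("CDR", ext.cdr)):
        doc[key] = [{"score": _score_to_text(t), "date": _date_to_text(t)}
                    for t in tuples]
    return json.dumps(doc)


def parse_extraction_json(document: str, note_id: str = "",
                          *, allow_cdr_sum_of_boxes: bool = False
                          ) -> NoteExtraction:
    """Parse and validate an extractor's JSON response.

    Never raises on bad input: malformed JSON, a wrong shape, or a score/date
    normalization failure all yield ``parse_ok=False`` with a reason, since
    failed parses are excluded from metric denominators and counted
    separately. Unknown extra keys are ignored with a logged warning.
    """

    def fail(reason: str) -> NoteExtraction:
        return NoteExtraction(note_id=note_id, parse_ok=False, failure_reason=reason)

    try:
        doc = json.loads(document)
    except (json.JSONDecodeError, TypeError):
        return fail("malformed")
    if not isinstance(doc, dict):
        return fail("wrong shape: top level is not an object")
    extra = set(doc) - {"MMSE", "CDR"}
    if extra:
        logger.warning("note %s: ignoring unknown response keys %s",
                       note_id, sorted(extra))
    lists: dict[str, list[ExtractionTuple]] = {}
    for test in ("MMSE", "CDR"):
        entries = doc.get(test, [])
        if not isinstance(entries, list):
            return fail(f"wrong shape: {test} is not a list")
        out = []
        for entry in entries:
            if not isinstance(entry, dict) or "score" not in entry:
                return fail(f"wrong shape: {test} entry missing score")
            try:
                score, denom = normalize_score(
                    test, entry["score"],
                    allow_cdr_sum_of_boxes=allow_cdr_sum_of_boxes)
                date, partial = normalize_date(entry.get("date"))
            except (ScoreError, DateError) as exc:
                return fail(f"{test}: {exc}")
            out.append(ExtractionTuple(test=test, score=score, denominator=denom,
                                       date=date, date_partial=partial))
        lists[test] = out
    return NoteExtraction(note_id=note_id, mmse=lists["MMSE"], cdr=lists["CDR"])


# ---------------------------------------------------------------------------
# JSONL persistence
# ---------------------------------------------------------------------------

def _tuple_to_obj(t: ExtractionTuple) -> dict:
    return {
        "test": t.test,
        "score": t.score,
        "denominator": t.denominator,
        "date": None if t.date is None else t.date.isoformat(),
        "date_partial": t.date_partial,
    }


def tuple_from_obj(obj: dict) -> ExtractionTuple:
    date = None if obj.get("date") is None else _dt.date.fromisoformat(obj["date"])
    return ExtractionTuple(
        test=obj["test"], score=float(obj["score"]),
        denominator=obj.get("denominator"), date=date,
        date_partial=bool(obj.get("date_partial", False)),
    )


def extraction_to_obj(ext: NoteExtraction) -> dict:
    return {
        "note_id": ext.note_id,
        "mmse": [_tuple_to_obj(t) for t in ext.mmse],
        "cdr": [_tuple_to_obj(t) for t in ext.cdr],
        "parse_ok": ext.parse_ok,
        "failure_reason": ext.failure_reason,
    }


def extraction_from_obj(obj: dict) -> NoteExtraction:
    return NoteExtraction(
        note_id=obj["note_id"],
        mmse=[tuple_from_obj(o) for o in obj.get("mmse", [])],
        cdr=[tuple_from_obj(o) for o in obj.get("cdr", [])],
        parse_ok=bool(obj.get("parse_ok", True)),
        failure_reason=obj.get("failure_reason"),
    )


def write_extractions_jsonl(path, extractions) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ext in extractions:
            fh.write(json.dumps(extraction_to_obj(ext)) + "\n")


def read_extractions_jsonl(path) -> list[NoteExtraction]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                out.append(extraction_from_obj(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad extraction record: {exc}")
    return out
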