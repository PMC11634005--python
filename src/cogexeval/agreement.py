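"""Fleiss' kappa for the sparse multi-rater design.

Kappa is valid here because reviewer pairs are assigned to notes uniformly at
random: any constant number r of raters per item supports the statistic even
when the *identity* of the raters varies between items. Two families of
matrices are built:

* binary-question matrices — items are double-reviewed notes, categories are
  yes/no answers to one of the four questions (r = 2);
* tuple matrices — items are (note, position) slots of the canonically
  sorted tuple lists, categories are the normalized score values or dates at
  that position, with a distinguished ABSENT category when one rater's list
  is shorter. A machine extractor can join as a third rater (r = 3).

For each item i with category counts n_ij and r raters,

    P_i  = (sum_j n_ij^2 - r) / (r (r - 1))
    Pbar = mean_i P_i,   p_j = sum_i n_ij / (N r),   Pbar_e = sum_j p_j^2
    kappa = (Pbar - Pbar_e) / (1 - Pbar_e)

with kappa = 1 when chance agreement is total and observed agreement perfect,
and an explicitly flagged undefined result (never a silent 0) when
Pbar_e = 1 with imperfect agreement.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .notes import ExtractionTuple, NoteExtraction
from .review import QUESTIONS, ReviewRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RatingMatrix", "KappaResult", "fleiss_kappa",
    "build_question_matrix", "build_tuple_matrix", "three_way_matrix",
    "agreement_report",
]


# ---------------------------------------------------------------------------
# Rating matrices
# ---------------------------------------------------------------------------

@dataclass
class RatingMatrix:
    """Items x categories counts with a constant number of raters per item."""

    counts: np.ndarray
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] < 1:
            raise ValueError("rating matrix needs at least one item row")
        if self.counts.shape[1] != len(self.categories):
            raise ValueError("category labels do not match matrix width")
        if (self.counts < 0).any():
            raise ValueError("rating counts must be nonnegative")
        sums = self.counts.sum(axis=1)
        if not (sums == sums[0]).all():
            raise ValueError("every item must have the same number of raters")
        if sums[0] < 2:
            raise ValueError("Fleiss' kappa needs at least 2 raters per item")

    @property
    def n_items(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_raters(self) -> int:
        return int(self.counts.sum(axis=1)[0])

    @classmethod
    def from_ratings(cls, ratings: list[list[str]]) -> "RatingMatrix":
        """Build from per-item lists of category labels (one per rater)."""
        categories = tuple(sorted({c for row in ratings for c in row}))
        index = {c: j for j, c in enumerate(categories)}
        counts = np.zeros((len(ratings), len(categories)), dtype=int)
        for i, row in enumerate(ratings):
            for c in row:
                counts[i, index[c]] += 1
        return cls(counts=counts, categories=categories)


@dataclass
class KappaResult:
    """Fleiss' kappa with its observed and chance agreement components."""

    kappa: float
    p_bar: float
    p_e: float
    n_items: int
    n_raters: int
    undefined: bool = False

    def to_dict(self) -> dict:
        return {"kappa": self.kappa, "p_bar": self.p_bar, "p_e": self.p_e,
                "n_items": self.n_items, "n_raters": self.n_raters,
                "undefined": self.undefined}


def fleiss_kappa(matrix: RatingMatrix) -> KappaResult:
    """Standard Fleiss computation over an items x categories count matrix."""
    counts = matrix.counts
    n, r = matrix.n_items, matrix.n_raters
    p_i = ((counts.astype(float) ** 2).sum(axis=1) - r) / (r * (r - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (n * r)
    p_e = float((p_j ** 2).sum())
    if p_e >= 1.0 - 1e-15:
        if p_bar >= 1.0 - 1e-15:
            return KappaResult(kappa=1.0, p_bar=1.0, p_e=1.0,
                               n_items=n, n_raters=r)
        return KappaResult(kappa=math.nan, p_bar=p_bar, p_e=1.0,
                           n_items=n, n_raters=r, undefined=True)
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return KappaResult(kappa=float(kappa), p_bar=p_bar, p_e=p_e,
                       n_items=n, n_raters=r)


# ---------------------------------------------------------------------------
# Matrix builders
# ---------------------------------------------------------------------------

def build_question_matrix(reviews: list[ReviewRecord],
                          question: str) -> RatingMatrix:
    """Yes/no rating matrix for one binary question over double reviews.

    Items are notes with exactly two reviews; notes with any other review
    count are excluded with a warning.
    """
    if question not in QUESTIONS:
        raise ValueError(f"unknown question {question!r}")
    by_note: dict[str, list[ReviewRecord]] = {}
    for r in reviews:
        by_note.setdefault(r.note_id, []).append(r)
    idx = QUESTIONS.index(question)
    rows = []
    for note_id in sorted(by_note):
        group = by_note[note_id]
        if len(group) != 2:
            logger.warning("note %s has %d reviews, expected 2; excluded",
                           note_id, len(group))
            continue
        rows.append(["yes" if r.flags()[idx] else "no" for r in group])
    if not rows:
        raise ValueError("no double-reviewed notes to build a matrix from")
    categories = ("no", "yes")
    index = {c: j for j, c in enumerate(categories)}
    counts = np.zeros((len(rows), 2), dtype=int)
    for i, row in enumerate(rows):
        for c in row:
            counts[i, index[c]] += 1
    return RatingMatrix(counts=counts, categories=categories)


def _canon_sorted(ext: NoteExtraction, test: str) -> list[ExtractionTuple]:
    return sorted(ext.tuples(test), key=lambda t: t.sort_key())


def _field_label(t: ExtractionTuple, which: str) -> str:
    if which == "value":
        return f"{t.score:g}"
    if which == "date":
        if t.date is None:
            return "NONE"
        return t.date.isoformat() + ("~partial" if t.date_partial else "")
    raise ValueError(f"unknown tuple field {which!r}")


ABSENT = "ABSENT"


def build_tuple_matrix(raters: list[dict[str, NoteExtraction]], test: str,
                       field: str) -> RatingMatrix:
    """Positional rating matrix over tuple lists from r raters.

    Per note, each rater's list is canonically sorted (date, then value);
    items are (note, position) slots up to the longest list, the category is
    the normalized score value or date at that position, and raters whose
    list is shorter rate the distinguished ABSENT category. Notes missing
    from any rater (or unparsed) are excluded with a warning; notes where
    every rater's list is empty contribute no items.
    """
    if not raters or len(raters) < 2:
        raise ValueError("need at least 2 raters")
    common = set(raters[0])
    for other in raters[1:]:
        common &= set(other)
    rows: list[list[str]] = []
    for note_id in sorted(common):
        exts = [r[note_id] for r in raters]
        if not all(e.parse_ok for e in exts):
            logger.warning("note %s: unparsed extraction, excluded from "
                           "tuple agreement", note_id)
            continue
        lists = [_canon_sorted(e, test) for e in exts]
        longest = max(len(lst) for lst in lists)
        for pos in range(longest):
            rows.append([_field_label(lst[pos], field) if pos < len(lst)
                         else ABSENT for lst in lists])
    dropped = set().union(*(set(r) for r in raters)) - common
    for note_id in sorted(dropped):
        logger.warning("note %s missing from some rater, excluded", note_id)
    if not rows:
        raise ValueError("no rated tuple slots to build a matrix from")
    return RatingMatrix.from_ratings(rows)


def three_way_matrix(machine: dict[str, NoteExtraction],
                     review_a: dict[str, NoteExtraction],
                     review_b: dict[str, NoteExtraction],
                     test: str, field: str) -> RatingMatrix:
    """Joint machine + two-reviewer matrix (machine treated as a rater, r=3)."""
    return build_tuple_matrix([machine, review_a, review_b], test, field)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def _safe_kappa(builder, *args) -> KappaResult | None:
    try:
        return fleiss_kappa(builder(*args))
    except ValueError as exc:
        logger.warning("agreement row skipped: %s", exc)
        return None


def agreement_report(double_reviews: list[ReviewRecord],
                     machine: dict[str, NoteExtraction] | None = None) -> dict:
    """Kappa for the four binary questions (2-way) and for tuple values and
    dates per test (2-way among reviewers; 3-way adding the machine).

    Returns a JSON-ready mapping; kappas are on the 0-100 percent scale with
    undefined results reported as flagged nulls.
    """
    by_note: dict[str, list[ReviewRecord]] = {}
    for r in double_reviews:
        by_note.setdefault(r.note_id, []).append(r)
    pairs = {n: g for n, g in by_note.items() if len(g) == 2}
    rater_a = {n: g[0].corrected for n, g in pairs.items()
               if g[0].json_valid and g[1].json_valid}
    rater_b = {n: g[1].corrected for n, g in pairs.items()
               if g[0].json_valid and g[1].json_valid}

    def cell(result: KappaResult | None) -> dict:
        if result is None or result.undefined:
            return {"kappa_pct": None, "undefined": True,
                    "n_items": getattr(result, "n_items", 0)}
        return {"kappa_pct": 100.0 * result.kappa, "n_items": result.n_items}

    report: dict = {"n_double_notes": len(pairs), "binary_questions": {},
                    "tuples_2way": {}, "tuples_3way": {}}
    for q in QUESTIONS:
        report["binary_questions"][q] = cell(
            _safe_kappa(build_question_matrix, double_reviews, q))
    machine_on_doubles = None
    if machine is not None:
        machine_on_doubles = {n: machine[n] for n in rater_a if n in machine}
    for test in ("MMSE", "CDR"):
        for which in ("value", "date"):
            key = f"{test.lower()}_{which}s"
            report["tuples_2way"][key] = cell(
                _safe_kappa(build_tuple_matrix, [rater_a, rater_b],
                            test, which))
            if machine_on_doubles is not None:
                report["tuples_3way"][key] = cell(
                    _safe_kappa(three_way_matrix, machine_on_doubles,
                                rater_a, rater_b, test, which))
    return report
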