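"""Tuple matching, per-note flags, aggregate report statistics and the
four-mode error taxonomy.

The matching rule is deliberately strict: a predicted (score, date) tuple
counts only if it exactly equals a ground-truth tuple — score, denominator-
normalized value, date and partial-date flag all together. A score that is
off by one is exactly as wrong as one that is off by twenty, and so is a
right score on the wrong date. Duplicates are matched one-to-one as
multisets.

Aggregation mirrors the standard report layout for this kind of evaluation:

* accuracy — fraction of parsed notes whose predicted tuple multiset is
  fully identical to the truth (both-empty counts as correct);
* TNR / FNR — among notes *predicted* empty, the fraction truly empty
  (the conventional truth-empty-conditioned rate is also emitted, as
  ``tnr_conventional``, but the predicted-empty denominator is the primary
  definition here; see docs/methods.md);
* macro precision/recall — note-level means over the subset of notes with a
  non-empty prediction; micro — pooled ratios over the same subset. Notes
  with an empty prediction but non-empty truth surface in the FNR, not in
  macro recall; an all-parsed-notes recall variant is emitted alongside.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np

from .corpus import GoldAnnotation
from .notes import ExtractionTuple, NoteExtraction

__all__ = [
    "NoteFlags", "MetricsReport", "ErrorTaxonomy", "ErrorBreakdown",
    "match_tuples", "compute_note_flags", "aggregate_metrics",
    "classify_errors", "classify_errors_detailed", "flags_from_counts",
    "evaluate_run",
]


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_tuples(pred: list[ExtractionTuple], truth: list[ExtractionTuple]
                 ) -> tuple[int, list[bool], list[bool]]:
    """Maximum multiset matching under exact tuple equality.

    Returns (matched count, per-pred matched flags, per-truth matched flags).
    Because the match relation is exact equality, greedy counting over match
    keys attains the maximum bipartite matching (equality edges form disjoint
    bicliques, one per key, each contributing min(#pred, #truth) matches).
    """
    tests = {t.test for t in pred} | {t.test for t in truth}
    if len(tests) > 1:
        raise ValueError(f"mixed test types in matching: {sorted(tests)}")
    truth_keys = Counter(t.match_key() for t in truth)
    pred_flags = []
    for p in pred:
        k = p.match_key()
        if truth_keys[k] > 0:
            truth_keys[k] -= 1
            pred_flags.append(True)
        else:
            pred_flags.append(False)
    pred_keys = Counter(p.match_key() for p in pred)
    truth_flags = []
    for t in truth:
        k = t.match_key()
        if pred_keys[k] > 0:
            pred_keys[k] -= 1
            truth_flags.append(True)
        else:
            truth_flags.append(False)
    return sum(pred_flags), pred_flags, truth_flags


@dataclass
class NoteFlags:
    """Per-note, per-test matching summary feeding aggregation."""

    note_id: str
    test: str
    pred_count: int
    truth_count: int
    matched_count: int
    pred_empty: bool
    truth_empty: bool
    exact_match: bool

    def __post_init__(self) -> None:
        assert self.matched_count <= min(self.pred_count, self.truth_count)
        assert self.exact_match == (
            self.matched_count == self.pred_count == self.truth_count)


def compute_note_flags(pred: NoteExtraction, truth: NoteExtraction
                       ) -> dict[str, NoteFlags]:
    """NoteFlags for each test type; requires a parsed prediction."""
    if not pred.parse_ok:
        raise ValueError(f"note {pred.note_id}: prediction did not parse; "
                         "failed notes are counted separately, not evaluated")
    out = {}
    for test in ("MMSE", "CDR"):
        p, t = pred.tuples(test), truth.tuples(test)
        matched, _, _ = match_tuples(p, t)
        out[test] = NoteFlags(
            note_id=pred.note_id, test=test,
            pred_count=len(p), truth_count=len(t), matched_count=matched,
            pred_empty=len(p) == 0, truth_empty=len(t) == 0,
            exact_match=(matched == len(p) == len(t)))
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Every aggregate quantity of the per-test report, as raw fractions.

    Percentages are floats on the 0-100 scale; undefined rates (zero
    denominator) are NaN. Rounding to one decimal happens only at render
    time.
    """

    test: str
    n_parsed: int = 0
    n_truth_empty: int = 0
    n_pred_empty: int = 0
    n_correct_empty: int = 0
    tnr: float = math.nan
    fnr: float = math.nan
    tnr_conventional: float = math.nan
    n_eval_subset: int = 0
    n_instances_pred: int = 0
    macro_precision: float = math.nan
    macro_precision_sd: float = math.nan
    macro_recall: float = math.nan
    macro_recall_sd: float = math.nan
    micro_precision: float = math.nan
    micro_recall: float = math.nan
    macro_recall_all_notes: float = math.nan
    micro_recall_all_notes: float = math.nan
    n_error_notes: int = 0
    accuracy: float = math.nan

    def to_dict(self) -> dict:
        return asdict(self)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    if not values:
        return math.nan, math.nan
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def aggregate_metrics(flags: list[NoteFlags]) -> MetricsReport:
    """Aggregate per-note flags (one test type) into a MetricsReport."""
    tests = {f.test for f in flags}
    if len(tests) > 1:
        raise ValueError(f"flags mix test types: {sorted(tests)}")
    report = MetricsReport(test=tests.pop() if tests else "?")
    report.n_parsed = len(flags)
    if not flags:
        return report
    report.n_truth_empty = sum(f.truth_empty for f in flags)
    report.n_pred_empty = sum(f.pred_empty for f in flags)
    report.n_correct_empty = sum(f.pred_empty and f.truth_empty for f in flags)
    if report.n_pred_empty:
        report.tnr = 100.0 * report.n_correct_empty / report.n_pred_empty
        report.fnr = 100.0 - report.tnr
    if report.n_truth_empty:
        report.tnr_conventional = (100.0 * report.n_correct_empty
                                   / report.n_truth_empty)
    eval_subset = [f for f in flags if not f.pred_empty]
    report.n_eval_subset = len(eval_subset)
    report.n_instances_pred = sum(f.pred_count for f in eval_subset)
    report.macro_precision, report.macro_precision_sd = _mean_sd(
        [100.0 * f.matched_count / f.pred_count for f in eval_subset])
    report.macro_recall, report.macro_recall_sd = _mean_sd(
        [100.0 * f.matched_count / f.truth_count
         for f in eval_subset if f.truth_count > 0])
    pooled_pred = sum(f.pred_count for f in eval_subset)
    pooled_truth = sum(f.truth_count for f in eval_subset)
    pooled_matched = sum(f.matched_count for f in eval_subset)
    if pooled_pred:
        report.micro_precision = 100.0 * pooled_matched / pooled_pred
    if pooled_truth:
        report.micro_recall = 100.0 * pooled_matched / pooled_truth
    recall_all = [100.0 * f.matched_count / f.truth_count
                  for f in flags if f.truth_count > 0]
    report.macro_recall_all_notes, _ = _mean_sd(recall_all)
    all_truth = sum(f.truth_count for f in flags)
    if all_truth:
        report.micro_recall_all_notes = (
            100.0 * sum(f.matched_count for f in flags) / all_truth)
    report.n_error_notes = sum(not f.exact_match for f in flags)
    report.accuracy = (100.0 * (report.n_parsed - report.n_error_notes)
                       / report.n_parsed)
    return report


def flags_from_counts(test: str, n_parsed: int, n_truth_empty: int,
                      n_pred_empty: int, n_correct_empty: int,
                      n_error_notes: int) -> list[NoteFlags]:
    """Reconstruct a minimal per-note flag population from report counts.

    Used to recompute the rate cells of a published count structure through
    the same aggregation code as a live run: notes are materialized with
    single-tuple predictions/truths consistent with the given counts (which
    pins accuracy, TNR and FNR; the precision/recall cells additionally
    depend on per-note tuple detail that counts alone do not determine).
    """
    if not (0 <= n_correct_empty <= n_pred_empty <= n_parsed):
        raise ValueError("inconsistent predicted-empty counts")
    if not (n_correct_empty <= n_truth_empty <= n_parsed):
        raise ValueError("inconsistent truth-empty counts")
    wrong_empty = n_pred_empty - n_correct_empty  # pred empty, truth not
    if n_error_notes < wrong_empty or n_error_notes > n_parsed:
        raise ValueError("error-note count inconsistent with empty counts")
    # predictions that are non-empty while the truth is empty (false positives)
    fp_notes = n_truth_empty - n_correct_empty
    other_errors = n_error_notes - wrong_empty
    if fp_notes > other_errors:
        raise ValueError("truth-empty count inconsistent with error count")
    flags = []
    i = 0

    def add(pred_count, truth_count, matched):
        nonlocal i
        flags.append(NoteFlags(
            note_id=f"cell-{i:04d}", test=test,
            pred_count=pred_count, truth_count=truth_count,
            matched_count=matched,
            pred_empty=pred_count == 0, truth_empty=truth_count == 0,
            exact_match=(matched == pred_count == truth_count)))
        i += 1

    for _ in range(n_correct_empty):
        add(0, 0, 0)
    for _ in range(wrong_empty):
        add(0, 1, 0)
    for _ in range(fp_notes):
        add(1, 0, 0)
    for _ in range(other_errors - fp_notes):
        add(1, 1, 0)
    for _ in range(n_parsed - len(flags)):
        add(1, 1, 1)
    return flags


def evaluate_run(preds: list[NoteExtraction],
                 truth_by_note: dict[str, NoteExtraction]
                 ) -> tuple[dict[str, MetricsReport], int]:
    """Metrics per test for one extractor run against adjudicated truth.

    Notes whose prediction failed to parse are excluded from the metric
    denominators and returned as a separate count.
    """
    per_test: dict[str, list[NoteFlags]] = {"MMSE": [], "CDR": []}
    n_parse_fail = 0
    for pred in preds:
        if not pred.parse_ok:
            n_parse_fail += 1
            continue
        truth = truth_by_note.get(pred.note_id)
        if truth is None:
            continue
        for test, f in compute_note_flags(pred, truth).items():
            per_test[test].append(f)
    return ({test: aggregate_metrics(fl) for test, fl in per_test.items()},
            n_parse_fail)


# ---------------------------------------------------------------------------
# Error taxonomy
# ---------------------------------------------------------------------------

@dataclass
class ErrorTaxonomy:
    """Counts of the four qualitative error modes.

    Each erroneous predicted tuple lands in exactly one of hallucination /
    wrong_test / wrong_date; each unmatched truth tuple not explained by a
    paired erroneous prediction lands in missed.
    """

    hallucination: int = 0
    wrong_test: int = 0
    wrong_date: int = 0
    missed: int = 0

    def __add__(self, other: "ErrorTaxonomy") -> "ErrorTaxonomy":
        return ErrorTaxonomy(
            hallucination=self.hallucination + other.hallucination,
            wrong_test=self.wrong_test + other.wrong_test,
            wrong_date=self.wrong_date + other.wrong_date,
            missed=self.missed + other.missed)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ErrorBreakdown:
    """Full bookkeeping of one note/test classification (taxonomy + pairings)."""

    taxonomy: ErrorTaxonomy = field(default_factory=ErrorTaxonomy)
    matched: int = 0
    wrong_test_displaced: int = 0  # gold tuples consumed by wrong-test preds
    pred_count: int = 0
    truth_count: int = 0


def _same_score(a: float, b: float) -> bool:
    return float(a) == float(b)


def classify_errors_detailed(pred: NoteExtraction, gold: GoldAnnotation,
                             test: str) -> ErrorBreakdown:
    """Classify one note's errors for one test with full bookkeeping.

    Priority per unmatched predicted tuple: wrong_test (its score — or score
    and date — coincides with another test's gold tuple in the same note),
    then wrong_date (its score pairs with an otherwise-unmatched same-test
    gold tuple whose date differs), else hallucination. Gold tuples consumed
    by a wrong_test or wrong_date prediction are not also counted missed.
    """
    pred_list = pred.tuples(test)
    gold_same = gold.by_test(test)
    gold_other = [g for g in gold.tuples if g.test != test]
    matched, pred_flags, truth_flags = match_tuples(pred_list, gold_same)
    remaining = [g for g, f in zip(gold_same, truth_flags) if not f]
    bd = ErrorBreakdown(matched=matched, pred_count=len(pred_list),
                        truth_count=len(gold_same))
    tax = bd.taxonomy
    for p, ok in zip(pred_list, pred_flags):
        if ok:
            continue
        if any(_same_score(p.score, g.score) for g in gold_other):
            tax.wrong_test += 1
            if remaining:  # this prediction displaced a true same-test tuple
                remaining.pop(0)
                bd.wrong_test_displaced += 1
            continue
        paired = next((g for g in remaining
                       if _same_score(p.score, g.score)
                       and (g.date, g.date_partial) != (p.date, p.date_partial)),
                      None)
        if paired is not None:
            remaining.remove(paired)
            tax.wrong_date += 1
            continue
        tax.hallucination += 1
    tax.missed = len(remaining)
    # bookkeeping identities (conservation of tuples)
    assert bd.pred_count == (bd.matched + tax.hallucination
                             + tax.wrong_test + tax.wrong_date)
    assert bd.truth_count == (bd.matched + tax.wrong_date
                              + bd.wrong_test_displaced + tax.missed)
    return bd


def classify_errors(pred: NoteExtraction, gold: GoldAnnotation,
                    test: str | None = None) -> ErrorTaxonomy:
    """Four-mode error taxonomy for one note (summed over MMSE and CDR
    unless ``test`` restricts it)."""
    tests = (test,) if test else ("MMSE", "CDR")
    total = ErrorTaxonomy()
    for t in tests:
        total = total + classify_errors_detailed(pred, gold, t).taxonomy
    return total
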