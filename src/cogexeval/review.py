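"""Human-review machinery: randomized assignment, the four binary questions,
disagreement detection, third-review adjudication, and a reviewer simulator.

The design mirrors a double-annotation study: each note goes to one reviewer,
a random subset goes to a uniformly drawn *pair* of reviewers (enabling
chance-corrected agreement statistics), reviewers answer four yes/no
questions per note (is the MMSE answer correct / complete, is the CDR answer
correct / complete) and supply corrected tuples as their ground truth. Pairs
that disagree on any question get a third, dedicated reviewer, and a
per-question majority vote picks the final answer; the corrected tuples of a
majority-side reviewer become the adjudicated truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .corpus import GoldAnnotation, gold_to_extraction
from .metrics import match_tuples
from .notes import (
    CDR_LEVELS,
    ConfigError,
    ExtractionTuple,
    NoteExtraction,
    extraction_from_obj,
    extraction_to_obj,
)

logger = logging.getLogger(__name__)

__all__ = [
    "QUESTIONS", "AssignmentPlan", "ReviewRecord", "AdjudicatedTruth",
    "CapacityError", "AdjudicationError", "UnadjudicatableError",
    "assign_notes", "derive_binary_questions", "detect_disagreement",
    "adjudicate", "simulate_reviewer", "write_reviews_jsonl",
    "read_reviews_jsonl",
]

QUESTIONS = ("mmse_correct", "mmse_complete", "cdr_correct", "cdr_complete")


class CapacityError(ValueError):
    """The assignment demand cannot fit the reviewers' caps."""


class AdjudicationError(ValueError):
    """Adjudication preconditions violated (e.g. missing third review)."""


class UnadjudicatableError(AdjudicationError):
    """No reviewer on the note produced usable (valid-JSON) ground truth."""


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentPlan:
    assignments: dict[str, list[str]]    # note_id -> reviewer ids
    double_set: set[str] = field(default_factory=set)
    reviewer_loads: dict[str, int] = field(default_factory=dict)

    def per_reviewer_double_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in self.reviewer_loads}
        for note in self.double_set:
            for r in self.assignments[note]:
                counts[r] += 1
        return counts


def assign_notes(note_ids, reviewer_ids, n_double: int, cap: int,
                 seed: int) -> AssignmentPlan:
    """Randomized single/double assignment under a per-reviewer cap.

    Notes are shuffled; the first ``n_double`` each receive a uniformly drawn
    pair of distinct below-cap reviewers, the rest a single uniformly drawn
    below-cap reviewer. Deterministic under the seed.
    """
    note_ids = list(note_ids)
    reviewer_ids = list(reviewer_ids)
    if n_double < 0 or cap < 1:
        raise ConfigError("n_double must be >= 0 and cap >= 1")
    if n_double > len(note_ids):
        raise CapacityError("more double-review notes than notes")
    if n_double > 0 and len(reviewer_ids) < 2:
        raise CapacityError("double review needs at least 2 distinct reviewers")
    demand = len(note_ids) + n_double
    supply = cap * len(reviewer_ids)
    if demand > supply:
        raise CapacityError(
            f"assignment needs {demand} review slots but the cap allows "
            f"only {supply}")
    rng = np.random.default_rng(seed)
    order = [note_ids[i] for i in rng.permutation(len(note_ids))]
    loads = {r: 0 for r in reviewer_ids}
    assignments: dict[str, list[str]] = {}
    double_set = set(order[:n_double])
    for note in order:
        below = [r for r in reviewer_ids if loads[r] < cap]
        k = 2 if note in double_set else 1
        if len(below) < k:
            raise CapacityError(
                f"note {note}: needs {k} below-cap reviewers, "
                f"only {len(below)} available")
        picks = [below[j] for j in rng.choice(len(below), size=k,
                                              replace=False)]
        assignments[note] = picks
        for r in picks:
            loads[r] += 1
    return AssignmentPlan(assignments=assignments, double_set=double_set,
                          reviewer_loads=loads)


# ---------------------------------------------------------------------------
# Review records and the four questions
# ---------------------------------------------------------------------------

@dataclass
class ReviewRecord:
    """One reviewer's judgment of one extractor response.

    ``corrected`` is the reviewer's own ground truth for the note. If
    ``json_valid`` is false the corrected tuples are unusable for tuple-level
    statistics (the flags may still vote).
    """

    note_id: str
    reviewer_id: str
    mmse_correct: bool
    mmse_complete: bool
    cdr_correct: bool
    cdr_complete: bool
    corrected: NoteExtraction
    json_valid: bool = True

    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.mmse_correct, self.mmse_complete,
                self.cdr_correct, self.cdr_complete)


def derive_binary_questions(pred: NoteExtraction, truth: NoteExtraction
                            ) -> dict[str, bool]:
    """The four yes/no questions, by the multiset-containment definition.

    Per test: *correct* — every predicted tuple exactly matches some truth
    tuple (pred ⊆ truth as multisets); *complete* — every truth tuple is
    matched (truth ⊆ pred).
    """
    if not (pred.parse_ok and truth.parse_ok):
        raise ValueError("binary questions require parsed extractions")
    out = {}
    for test, prefix in (("MMSE", "mmse"), ("CDR", "cdr")):
        p, t = pred.tuples(test), truth.tuples(test)
        matched, _, _ = match_tuples(p, t)
        out[f"{prefix}_correct"] = matched == len(p)
        out[f"{prefix}_complete"] = matched == len(t)
    return out


def detect_disagreement(a: ReviewRecord, b: ReviewRecord
                        ) -> tuple[bool, list[str]]:
    """True (plus the disagreeing question names) iff any flag differs."""
    if a.note_id != b.note_id:
        raise ValueError(f"reviews of different notes: "
                         f"{a.note_id!r} vs {b.note_id!r}")
    diff = [q for q, fa, fb in zip(QUESTIONS, a.flags(), b.flags())
            if fa != fb]
    return bool(diff), diff


# ---------------------------------------------------------------------------
# Adjudication
# ---------------------------------------------------------------------------

@dataclass
class AdjudicatedTruth:
    note_id: str
    final: NoteExtraction
    source: str  # "full_agreement_random_pick" | "majority_vote"
    contributing_reviews: list[str] = field(default_factory=list)


def adjudicate(a: ReviewRecord, b: ReviewRecord,
               c: ReviewRecord | None, rng) -> AdjudicatedTruth:
    """Resolve a double-reviewed note into final ground truth.

    Full agreement: the corrected tuples of one of the two reviewers, chosen
    at random (seeded); if only one has valid JSON, that one. Disagreement
    (third review required): per-question majority of the three; the final
    tuples come from a reviewer on the majority side — among valid-JSON
    reviewers whose answers best agree with the majority vote, one is picked
    at random when several qualify equally.
    """
    disagree, _ = detect_disagreement(a, b)
    if disagree and c is None:
        raise AdjudicationError(
            f"note {a.note_id}: reviewers disagree, third review required")
    if not disagree and c is not None:
        raise AdjudicationError(
            f"note {a.note_id}: third review supplied without disagreement")
    if not disagree:
        valid = [r for r in (a, b) if r.json_valid]
        if not valid:
            raise UnadjudicatableError(
                f"note {a.note_id}: no valid-JSON review to adjudicate")
        pick = valid[int(rng.integers(len(valid)))]
        return AdjudicatedTruth(
            note_id=a.note_id, final=pick.corrected,
            source="full_agreement_random_pick",
            contributing_reviews=[r.reviewer_id for r in (a, b)])
    panel = (a, b, c)
    majority = tuple(sum(r.flags()[i] for r in panel) >= 2
                     for i in range(len(QUESTIONS)))
    valid = [r for r in panel if r.json_valid]
    if not valid:
        raise UnadjudicatableError(
            f"note {a.note_id}: no valid-JSON review to adjudicate")
    scores = [sum(f == m for f, m in zip(r.flags(), majority)) for r in valid]
    best = max(scores)
    top = [r for r, s in zip(valid, scores) if s == best]
    pick = top[int(rng.integers(len(top)))]
    return AdjudicatedTruth(
        note_id=a.note_id, final=pick.corrected, source="majority_vote",
        contributing_reviews=[r.reviewer_id for r in panel])


# ---------------------------------------------------------------------------
# Reviewer simulator
# ---------------------------------------------------------------------------

def _perturb_tuple(t: ExtractionTuple, rng) -> ExtractionTuple:
    """A small reviewer slip: nudge the score or shift the date."""
    import datetime as _dt

    if t.date is not None and rng.random() < 0.5:
        shift = (1 if rng.random() < 0.5 else -1) * int(rng.integers(30, 401))
        return ExtractionTuple(test=t.test, score=t.score,
                               denominator=t.denominator,
                               date=t.date + _dt.timedelta(days=shift))
    if t.test == "CDR":
        i = CDR_LEVELS.index(float(t.score))
        j = i + 1 if i + 1 < len(CDR_LEVELS) else i - 1
        score = CDR_LEVELS[j]
    else:
        score = t.score + 1 if t.score < 30 else t.score - 1
    return ExtractionTuple(test=t.test, score=score, denominator=t.denominator,
                           date=t.date, date_partial=t.date_partial)


def simulate_reviewer(truth: GoldAnnotation, pred: NoteExtraction,
                      noise_q: float, rng, reviewer_id: str = "sim",
                      tuple_noise: float | None = None) -> ReviewRecord:
    """A noisy reviewer: the ideal judgment with independent flag flips.

    Computes the ideal four-question record by comparing the prediction
    against gold, then flips each flag independently with probability
    ``noise_q`` and perturbs each corrected tuple with probability
    ``tuple_noise`` (default ``noise_q / 2``). ``noise_q`` = 0 reproduces the
    ideal record with corrected tuples equal to the gold MMSE/CDR tuples.
    """
    if not (0.0 <= noise_q <= 0.5):
        raise ConfigError("noise_q must be in [0, 0.5]")
    if tuple_noise is None:
        tuple_noise = noise_q / 2.0
    if not (0.0 <= tuple_noise <= 1.0):
        raise ConfigError("tuple_noise must be in [0, 1]")
    ideal_truth = gold_to_extraction(truth)
    comparable = pred if pred.parse_ok else NoteExtraction(note_id=pred.note_id)
    flags = derive_binary_questions(comparable, ideal_truth)
    noisy = {q: (not v) if rng.random() < noise_q else v
             for q, v in flags.items()}
    corrected = NoteExtraction(
        note_id=truth.note_id,
        mmse=[_perturb_tuple(t, rng) if rng.random() < tuple_noise else t
              for t in ideal_truth.mmse],
        cdr=[_perturb_tuple(t, rng) if rng.random() < tuple_noise else t
             for t in ideal_truth.cdr])
    return ReviewRecord(note_id=truth.note_id, reviewer_id=reviewer_id,
                        corrected=corrected, json_valid=True, **noisy)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def write_reviews_jsonl(path, reviews) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reviews:
            obj = {"note_id": r.note_id, "reviewer_id": r.reviewer_id,
                   "json_valid": r.json_valid,
                   "corrected": extraction_to_obj(r.corrected)}
            obj.update({q: v for q, v in zip(QUESTIONS, r.flags())})
            fh.write(json.dumps(obj) + "\n")


def read_reviews_jsonl(path) -> list[ReviewRecord]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                out.append(ReviewRecord(
                    note_id=obj["note_id"], reviewer_id=obj["reviewer_id"],
                    corrected=extraction_from_obj(obj["corrected"]),
                    json_valid=bool(obj.get("json_valid", True)),
                    **{q: bool(obj[q]) for q in QUESTIONS}))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad review record: {exc}")
    return out
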