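"""Assignment, the four binary questions, disagreement, adjudication and the
reviewer simulator."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogexeval.corpus import CorpusConfig, generate_corpus, gold_to_extraction
from cogexeval.notes import ExtractionTuple, NoteExtraction
from cogexeval.review import (
    QUESTIONS,
    AdjudicationError,
    CapacityError,
    ReviewRecord,
    UnadjudicatableError,
    adjudicate,
    assign_notes,
    derive_binary_questions,
    detect_disagreement,
    simulate_reviewer,
)


def _ext(note_id, *scores, test="MMSE", day=1):
    tuples = [ExtractionTuple(test=test, score=float(s),
                              date=dt.date(2019, 1, day)) for s in scores]
    kw = {"mmse": tuples} if test == "MMSE" else {"cdr": tuples}
    return NoteExtraction(note_id=note_id, **kw)


def _review(note_id, reviewer, flags, corrected=None, json_valid=True):
    return ReviewRecord(note_id=note_id, reviewer_id=reviewer,
                        mmse_correct=flags[0], mmse_complete=flags[1],
                        cdr_correct=flags[2], cdr_complete=flags[3],
                        corrected=corrected or _ext(note_id, 27),
                        json_valid=json_valid)


class TestAssignNotes:
    def test_study_scale_plan(self):
        """722 notes, 21 reviewers, 309 double-reviewed, cap 50: the plan
        fills 1031 slots with every load at or under the cap."""
        notes = [f"n{i}" for i in range(722)]
        reviewers = [f"r{i}" for i in range(21)]
        plan = assign_notes(notes, reviewers, n_double=309, cap=50, seed=5)
        assert sum(plan.reviewer_loads.values()) == 722 + 309
        assert max(plan.reviewer_loads.values()) <= 50
        assert len(plan.double_set) == 309
        for note, assigned in plan.assignments.items():
            expected = 2 if note in plan.double_set else 1
            assert len(assigned) == len(set(assigned)) == expected
        # double review spreads over reviewers (~15 each under uniform pairs)
        doubles = plan.per_reviewer_double_counts()
        assert sum(doubles.values()) == 2 * 309

    def test_single_reviewer_takes_everything(self):
        notes = [f"n{i}" for i in range(10)]
        plan = assign_notes(notes, ["r0"], n_double=0, cap=10, seed=0)
        assert plan.reviewer_loads == {"r0": 10}
        assert all(v == ["r0"] for v in plan.assignments.values())

    def test_double_review_needs_two_reviewers(self):
        with pytest.raises(CapacityError):
            assign_notes([f"n{i}" for i in range(10)], ["r0"],
                         n_double=1, cap=20, seed=0)

    def test_capacity_error_reports_slots(self):
        with pytest.raises(CapacityError, match="slots"):
            assign_notes([f"n{i}" for i in range(10)], ["r0"],
                         n_double=0, cap=5, seed=0)

    def test_determinism(self):
        notes = [f"n{i}" for i in range(60)]
        reviewers = [f"r{i}" for i in range(5)]
        a = assign_notes(notes, reviewers, 20, 40, seed=3)
        b = assign_notes(notes, reviewers, 20, 40, seed=3)
        assert a.assignments == b.assignments
        assert a.double_set == b.double_set

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_plan_legality_property(self, data):
        n_notes = data.draw(st.integers(1, 40), label="n_notes")
        n_rev = data.draw(st.integers(1, 6), label="n_reviewers")
        max_double = min(n_notes, (n_rev >= 2) * n_notes)
        n_double = data.draw(st.integers(0, max_double), label="n_double")
        lo = -(-(n_notes + n_double) // n_rev)  # ceil division: feasible cap
        cap = data.draw(st.integers(lo, lo + 30), label="cap")
        seed = data.draw(st.integers(0, 2 ** 16), label="seed")
        try:
            plan = assign_notes([f"n{i}" for i in range(n_notes)],
                                [f"r{i}" for i in range(n_rev)],
                                n_double, cap, seed)
        except CapacityError:
            # greedy pairing can strand capacity at exactly-tight caps
            assert (n_notes + n_double) > (cap - 1) * n_rev
            return
        assert set(plan.assignments) == {f"n{i}" for i in range(n_notes)}
        assert max(plan.reviewer_loads.values(), default=0) <= cap
        for note, assigned in plan.assignments.items():
            want = 2 if note in plan.double_set else 1
            assert len(assigned) == len(set(assigned)) == want


class TestBinaryQuestions:
    def test_identical_answers_all_true(self):
        pred = _ext("n", 27, 25)
        truth = _ext("n", 27, 25)
        assert all(derive_binary_questions(pred, truth).values())

    def test_off_by_one_score_is_incorrect(self):
        pred = _ext("n", 26)
        truth = _ext("n", 27)
        q = derive_binary_questions(pred, truth)
        assert not q["mmse_correct"] and not q["mmse_complete"]
        assert q["cdr_correct"] and q["cdr_complete"]

    def test_strict_subset_is_correct_but_incomplete(self):
        pred = _ext("n", 27, 25)
        truth = _ext("n", 27, 25, 20)
        q = derive_binary_questions(pred, truth)
        assert q["mmse_correct"] and not q["mmse_complete"]

    def test_empty_prediction_with_truth_is_incomplete(self):
        q = derive_binary_questions(_ext("n"), _ext("n", 27))
        assert q["mmse_correct"] and not q["mmse_complete"]


class TestDisagreement:
    def test_identical_flags_agree(self):
        a = _review("n", "r0", (True, True, False, True))
        b = _review("n", "r1", (True, True, False, True))
        assert detect_disagreement(a, b) == (False, [])

    def test_single_field_difference_listed(self):
        a = _review("n", "r0", (True, True, True, True))
        b = _review("n", "r1", (True, False, True, True))
        flag, which = detect_disagreement(a, b)
        assert flag and which == ["mmse_complete"]

    def test_mismatched_note_ids_error(self):
        with pytest.raises(ValueError):
            detect_disagreement(_review("n1", "r0", (True,) * 4),
                                _review("n2", "r1", (True,) * 4))

    def test_rate_matches_independent_flip_closed_form(self):
        """Two reviewers flipping each of four flags independently with
        probability q disagree on a note with probability
        1 - (1 - 2q(1-q))^4."""
        q = 0.15
        bundle = generate_corpus(CorpusConfig(n_notes=600, seed=17))
        rng = np.random.default_rng(23)
        n_disagree = 0
        for gold in bundle.gold:
            pred = gold_to_extraction(gold)
            a = simulate_reviewer(gold, pred, q, rng, "ra", tuple_noise=0.0)
            b = simulate_reviewer(gold, pred, q, rng, "rb", tuple_noise=0.0)
            n_disagree += detect_disagreement(a, b)[0]
        p = 1 - (1 - 2 * q * (1 - q)) ** 4
        se = math.sqrt(p * (1 - p) / len(bundle.gold))
        assert abs(n_disagree / len(bundle.gold) - p) <= 3 * se


class TestAdjudicate:
    def test_full_agreement_picks_one_of_the_pair(self):
        a = _review("n", "r0", (True,) * 4, corrected=_ext("n", 27))
        b = _review("n", "r1", (True,) * 4, corrected=_ext("n", 27))
        out = adjudicate(a, b, None, np.random.default_rng(0))
        assert out.source == "full_agreement_random_pick"
        assert out.final in (a.corrected, b.corrected)

    def test_majority_vote_uses_majority_side_truth(self):
        a = _review("n", "r0", (True, True, False, True),
                    corrected=_ext("n", 27))
        b = _review("n", "r1", (True, True, True, True),
                    corrected=_ext("n", 25))
        c = _review("n", "r2", (True, True, False, True),
                    corrected=_ext("n", 26))
        out = adjudicate(a, b, c, np.random.default_rng(0))
        assert out.source == "majority_vote"
        assert out.final in (a.corrected, c.corrected)

    def test_invalid_json_falls_back_to_valid_reviewer(self):
        a = _review("n", "r0", (True,) * 4, corrected=_ext("n", 27),
                    json_valid=False)
        b = _review("n", "r1", (True,) * 4, corrected=_ext("n", 25))
        out = adjudicate(a, b, None, np.random.default_rng(0))
        assert out.final is b.corrected

    def test_disagreement_without_third_review_errors(self):
        a = _review("n", "r0", (True,) * 4)
        b = _review("n", "r1", (False,) + (True,) * 3)
        with pytest.raises(AdjudicationError):
            adjudicate(a, b, None, np.random.default_rng(0))

    def test_all_invalid_is_unadjudicatable(self):
        a = _review("n", "r0", (True,) * 4, json_valid=False)
        b = _review("n", "r1", (True,) * 4, json_valid=False)
        with pytest.raises(UnadjudicatableError):
            adjudicate(a, b, None, np.random.default_rng(0))

    def test_idempotent_on_identical_reviews_regardless_of_seed(self):
        a = _review("n", "r0", (True,) * 4, corrected=_ext("n", 27, 22))
        b = _review("n", "r1", (True,) * 4, corrected=_ext("n", 27, 22))
        keys = set()
        for seed in range(5):
            out = adjudicate(a, b, None, np.random.default_rng(seed))
            keys.add(tuple(t.match_key() for t in out.final.mmse))
        assert len(keys) == 1


class TestSimulateReviewer:
    def test_zero_noise_is_ideal_record(self, small_bundle):
        rng = np.random.default_rng(1)
        for gold in small_bundle.gold[:50]:
            pred = gold_to_extraction(gold)
            rec = simulate_reviewer(gold, pred, 0.0, rng, "r0")
            assert rec.flags() == (True,) * 4
            assert [t.match_key() for t in rec.corrected.mmse] == \
                [t.match_key() for t in gold_to_extraction(gold).mmse]

    def test_two_zero_noise_reviewers_never_disagree(self, small_bundle):
        rng = np.random.default_rng(2)
        for gold in small_bundle.gold[:50]:
            pred = gold_to_extraction(gold)
            a = simulate_reviewer(gold, pred, 0.0, rng, "ra")
            b = simulate_reviewer(gold, pred, 0.0, rng, "rb")
            assert not detect_disagreement(a, b)[0]

    def test_flip_fraction_recovery_3_sd(self):
        q = 0.1
        bundle = generate_corpus(CorpusConfig(n_notes=1000, seed=29))
        rng = np.random.default_rng(31)
        flips = 0
        for gold in bundle.gold:
            pred = gold_to_extraction(gold)
            rec = simulate_reviewer(gold, pred, q, rng, "r", tuple_noise=0.0)
            flips += sum(not f for f in rec.flags())  # ideal flags all True
        n = 4 * len(bundle.gold)
        sd = math.sqrt(n * q * (1 - q))
        assert abs(flips - n * q) <= 3 * sd

    def test_noise_out_of_range_rejected(self):
        bundle = generate_corpus(CorpusConfig(n_notes=1, seed=0))
        pred = gold_to_extraction(bundle.gold[0])
        with pytest.raises(Exception):
            simulate_reviewer(bundle.gold[0], pred, 0.7,
                              np.random.default_rng(0))
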