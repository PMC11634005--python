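"""Tuple matching (against a brute-force oracle), note flags, aggregation
and the error taxonomy."""

import datetime as dt
import itertools

import numpy as np
import pytest

from _oracles import brute_force_max_matching, mmse_tuple
from cogexeval.corpus import GoldAnnotation
from cogexeval.extractors import ErrorModelConfig, run_error_model
from cogexeval.metrics import (
    aggregate_metrics,
    classify_errors,
    classify_errors_detailed,
    compute_note_flags,
    flags_from_counts,
    match_tuples,
)
from cogexeval.notes import ExtractionTuple, NoteExtraction

D1 = dt.date(2010, 10, 10)
D2 = dt.date(2012, 10, 10)


class TestMatchTuples:
    def test_near_miss_scores_match_nothing(self):
        # an off-by-one score is exactly as wrong as a wildly different one
        pred = [mmse_tuple(26, 0)]
        truth = [mmse_tuple(27, 0)]
        assert match_tuples(pred, truth)[0] == 0

    def test_identical_lists_fully_match(self):
        lst = [mmse_tuple(27, 0), mmse_tuple(25, 3), mmse_tuple(27, 0)]
        matched, pf, tf = match_tuples(lst, list(lst))
        assert matched == 3 and all(pf) and all(tf)

    def test_duplicates_match_one_to_one(self):
        pred = [mmse_tuple(27, 0), mmse_tuple(27, 0)]
        truth = [mmse_tuple(27, 0)]
        matched, pf, tf = match_tuples(pred, truth)
        assert matched == 1 and pf.count(True) == 1 and tf == [True]
        assert matched == brute_force_max_matching(pred, truth)

    def test_partial_date_never_equals_full_date(self):
        pred = [mmse_tuple(27, 0, partial=True)]
        truth = [mmse_tuple(27, 0, partial=False)]
        assert match_tuples(pred, truth)[0] == 0

    def test_undated_matches_only_undated(self):
        assert match_tuples([mmse_tuple(27, None)], [mmse_tuple(27, 0)])[0] == 0
        assert match_tuples([mmse_tuple(27, None)],
                            [mmse_tuple(27, None)])[0] == 1

    def test_mixed_test_types_error(self):
        cdr = ExtractionTuple(test="CDR", score=1.0, date=D1)
        with pytest.raises(ValueError):
            match_tuples([mmse_tuple(27, 0)], [cdr])

    def test_exhaustive_oracle_equivalence_two_values_len_5(self):
        """Greedy multiset matching equals brute-force maximum matching for
        every pair of lists up to length 5 over a two-value alphabet."""
        alphabet = [mmse_tuple(27, 0), mmse_tuple(25, 1)]
        lists = [list(c) for n in range(5 + 1)
                 for c in itertools.product(alphabet, repeat=n)]
        for pred in lists:
            for truth in lists:
                assert match_tuples(pred, truth)[0] == \
                    brute_force_max_matching(pred, truth)

    def test_exhaustive_oracle_equivalence_three_values_len_3(self):
        alphabet = [mmse_tuple(27, 0), mmse_tuple(27, 1), mmse_tuple(5, None)]
        lists = [list(c) for n in range(3 + 1)
                 for c in itertools.product(alphabet, repeat=n)]
        for pred in lists:
            for truth in lists:
                assert match_tuples(pred, truth)[0] == \
                    brute_force_max_matching(pred, truth)


def _note(pred_scores, truth_scores, note_id="n"):
    pred = NoteExtraction(note_id=note_id,
                          mmse=[mmse_tuple(s, d) for s, d in pred_scores])
    truth = NoteExtraction(note_id=note_id,
                           mmse=[mmse_tuple(s, d) for s, d in truth_scores])
    return pred, truth


class TestNoteFlags:
    def test_both_empty_is_exact_match(self):
        pred, truth = _note([], [])
        f = compute_note_flags(pred, truth)["MMSE"]
        assert f.pred_empty and f.truth_empty and f.exact_match

    def test_empty_prediction_with_truth(self):
        pred, truth = _note([], [(27, 0)])
        f = compute_note_flags(pred, truth)["MMSE"]
        assert f.pred_empty and not f.truth_empty and not f.exact_match

    def test_exact_match_iff_counts_align(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            mk = lambda: [(int(rng.integers(25, 28)), int(rng.integers(0, 2)))
                          for _ in range(rng.integers(0, 4))]
            pred, truth = _note(mk(), mk())
            f = compute_note_flags(pred, truth)["MMSE"]
            assert f.exact_match == (
                f.matched_count == f.pred_count == f.truth_count)

    def test_unparsed_prediction_rejected(self):
        bad = NoteExtraction(note_id="n", parse_ok=False,
                             failure_reason="malformed")
        with pytest.raises(ValueError):
            compute_note_flags(bad, NoteExtraction(note_id="n"))


class TestAggregateMetrics:
    def test_published_count_structure_reproduces_rates(self):
        """Reconstructing a 306-note double-review count structure (48
        truth-empty, 25 predicted-empty of which 24 truly empty, 52 error
        notes) yields TNR 96.0, FNR 4.0 and accuracy 83.0."""
        flags = flags_from_counts("MMSE", n_parsed=306, n_truth_empty=48,
                                  n_pred_empty=25, n_correct_empty=24,
                                  n_error_notes=52)
        r = aggregate_metrics(flags)
        assert round(r.tnr, 1) == 96.0
        assert round(r.fnr, 1) == 4.0
        assert round(r.accuracy, 1) == 83.0
        assert r.n_eval_subset == 306 - 25

    def test_perfect_predictions_are_all_100(self):
        flags = flags_from_counts("MMSE", n_parsed=50, n_truth_empty=10,
                                  n_pred_empty=10, n_correct_empty=10,
                                  n_error_notes=0)
        r = aggregate_metrics(flags)
        assert r.accuracy == 100.0
        assert r.macro_precision == r.macro_recall == 100.0
        assert r.micro_precision == r.micro_recall == 100.0
        assert r.n_error_notes == 0

    def test_empty_input_marks_rates_undefined(self):
        r = aggregate_metrics([])
        assert r.n_parsed == 0
        assert np.isnan(r.tnr) and np.isnan(r.accuracy)

    def test_monotonicity_of_precision_and_recall(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            mk = lambda: [(int(rng.integers(20, 24)), 0)
                          for _ in range(rng.integers(1, 4))]
            pred, truth = _note(mk(), mk())
            base = aggregate_metrics([compute_note_flags(pred, truth)["MMSE"]])
            # an extra unmatched prediction can only hurt precision
            pred2 = NoteExtraction(note_id="n",
                                   mmse=pred.mmse + [mmse_tuple(1, 9)])
            worse_p = aggregate_metrics(
                [compute_note_flags(pred2, truth)["MMSE"]])
            assert worse_p.macro_precision <= base.macro_precision
            assert worse_p.micro_precision <= base.micro_precision
            # an extra unmatched truth tuple can only hurt recall
            truth2 = NoteExtraction(note_id="n",
                                    mmse=truth.mmse + [mmse_tuple(2, 9)])
            worse_r = aggregate_metrics(
                [compute_note_flags(pred, truth2)["MMSE"]])
            if not np.isnan(base.macro_recall):
                assert worse_r.macro_recall <= base.macro_recall
                assert worse_r.micro_recall <= base.micro_recall

    def test_fnr_complements_tnr(self):
        flags = flags_from_counts("CDR", n_parsed=100, n_truth_empty=60,
                                  n_pred_empty=50, n_correct_empty=45,
                                  n_error_notes=30)
        r = aggregate_metrics(flags)
        assert r.fnr == pytest.approx(100.0 - r.tnr)


class TestSimulationRecovery:
    def test_hallucination_rate_drives_micro_precision(self, big_bundle):
        """With a pure hallucination process at per-note rate h, pooled
        precision equals G/(G + F) for G gold tuples and F ~ Binomial(n, h)
        fabrications, within the propagated 3-SE band."""
        import math

        from cogexeval.corpus import gold_to_extraction

        h = 0.15
        preds = run_error_model(big_bundle,
                                ErrorModelConfig(p_hallucinate=h, seed=3))
        truth = {g.note_id: gold_to_extraction(g) for g in big_bundle.gold}
        from cogexeval.metrics import evaluate_run

        per_test, _ = evaluate_run(preds, truth)
        n_notes = len(big_bundle.notes)
        g_tuples = sum(len(g.by_test("MMSE")) + len(g.by_test("CDR"))
                       for g in big_bundle.gold)
        pooled_matched = g_tuples  # everything faithful under pure hallucination
        expected_fab = h * n_notes
        expected_precision = 100.0 * g_tuples / (g_tuples + expected_fab)
        # sensitivity of the pooled precision to the fabrication count
        dp_df = 100.0 * g_tuples / (g_tuples + expected_fab) ** 2
        tol = 3 * dp_df * math.sqrt(n_notes * h * (1 - h))
        measured = np.average(
            [per_test["MMSE"].micro_precision, per_test["CDR"].micro_precision],
            weights=[per_test["MMSE"].n_instances_pred,
                     per_test["CDR"].n_instances_pred])
        assert abs(measured - expected_precision) <= tol


class TestClassifyErrors:
    def test_moca_score_reported_as_mmse_is_wrong_test(self):
        gold = GoldAnnotation(note_id="n", tuples=[
            ExtractionTuple(test="MoCA", score=22.0, date=D1)])
        pred = NoteExtraction(note_id="n",
                              mmse=[ExtractionTuple(test="MMSE", score=22.0,
                                                    date=D1)])
        tax = classify_errors(pred, gold)
        assert tax.to_dict() == {"hallucination": 0, "wrong_test": 1,
                                 "wrong_date": 0, "missed": 0}

    def test_right_score_wrong_date(self):
        gold = GoldAnnotation(note_id="n", tuples=[
            ExtractionTuple(test="MMSE", score=27.0, date=D1)])
        pred = NoteExtraction(note_id="n",
                              mmse=[ExtractionTuple(test="MMSE", score=27.0,
                                                    date=D2)])
        tax = classify_errors(pred, gold)
        assert tax.wrong_date == 1 and tax.missed == 0

    def test_perfect_prediction_counts_nothing(self):
        gold = GoldAnnotation(note_id="n", tuples=[
            ExtractionTuple(test="MMSE", score=27.0, date=D1),
            ExtractionTuple(test="CDR", score=0.5, date=D1)])
        pred = NoteExtraction(
            note_id="n",
            mmse=[ExtractionTuple(test="MMSE", score=27.0, date=D1)],
            cdr=[ExtractionTuple(test="CDR", score=0.5, date=D1)])
        assert sum(classify_errors(pred, gold).to_dict().values()) == 0

    def test_unsupported_tuple_is_hallucination_and_gold_is_missed(self):
        gold = GoldAnnotation(note_id="n", tuples=[
            ExtractionTuple(test="MMSE", score=27.0, date=D1)])
        pred = NoteExtraction(note_id="n",
                              mmse=[ExtractionTuple(test="MMSE", score=3.0,
                                                    date=D2)])
        tax = classify_errors(pred, gold)
        assert tax.hallucination == 1 and tax.missed == 1

    def test_conservation_identity_over_simulated_corpus(self, small_bundle):
        """pred tuples = matched + hallucination + wrong_test + wrong_date;
        truth tuples = matched + wrong-date-paired + displaced + missed."""
        config = ErrorModelConfig(p_miss=0.15, p_wrong_test=0.1,
                                  p_wrong_date=0.1, p_hallucinate=0.1, seed=4)
        preds = run_error_model(small_bundle, config)
        for pred, gold in zip(preds, small_bundle.gold):
            if not pred.parse_ok:
                continue
            for test in ("MMSE", "CDR"):
                bd = classify_errors_detailed(pred, gold, test)
                tax = bd.taxonomy
                assert bd.pred_count == (bd.matched + tax.hallucination
                                         + tax.wrong_test + tax.wrong_date)
                assert bd.truth_count == (bd.matched + tax.wrong_date
                                          + bd.wrong_test_displaced
                                          + tax.missed)
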