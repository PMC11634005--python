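# cogexeval

An evaluation harness for judging how well automatic extractors — large
language models or rule-based systems — pull **cognitive exam scores and
their dates** out of free-text clinical notes.

Dementia care and research lean on two exams that are usually buried in
narrative text rather than structured fields: the Mini-Mental State
Examination (MMSE, an integer out of 30, often written "27/30") and the
Clinical Dementia Rating (CDR, global staging levels 0 / 0.5 / 1 / 2 / 3),
with the Montreal Cognitive Assessment (MoCA) appearing nearby as a
confusable third test. Validating an extractor for these scores needs more
than a single accuracy number: it needs an annotation design (who reviews
what, how disagreements are resolved), a strict matching rule, negative-rate
bookkeeping, and chance-corrected agreement statistics. Real dementia-clinic
notes are protected health information, so this package makes the entire
evaluation reproducible on synthetic corpora that emulate their statistical
structure.

## What the harness computes

The atomic unit is the **extraction tuple** (test, score, date). A predicted
tuple counts only if it *exactly* equals a ground-truth tuple — an MMSE of
26/30 on the right date is exactly as wrong as 5/30 on the wrong date.
Duplicates match one-to-one as multisets. On top of this rule, per test
type:

- **Accuracy** — fraction of parsed notes whose predicted tuple multiset is
  fully identical to the truth (both-empty counts as correct).
- **TNR / FNR** — among notes *predicted* to contain no score, the fraction
  that truly contain none (and its complement).
- **Macro precision / recall** — note-level means of per-note correct
  fractions, over notes with a non-empty prediction; **micro** variants pool
  tuples across those notes.
- **Error taxonomy** — each wrong predicted tuple is classified as
  *hallucination* (unsupported by the note), *wrong test* (another test's
  score reported, e.g. a MoCA under MMSE), or *wrong date* (right score,
  wrong date); unexplained missing truth tuples are *missed*.
- **Fleiss' kappa** — chance-corrected inter-rater agreement for the
  four binary review questions (is the MMSE/CDR answer correct / complete,
  2 raters) and for tuple values and dates (2 reviewers, or 3 raters with
  the machine joined in), valid because reviewer pairs are assigned to notes
  uniformly at random:
  `kappa = (P̄ − P̄e) / (1 − P̄e)` with `P̄` the mean per-item agreement and
  `P̄e = Σ p_j²` the chance agreement.

The pieces — synthetic corpus generator, regex baseline, calibrated
error-model simulators, double-review workflow with majority-vote
adjudication, metrics and agreement — are importable modules wired together
by a deterministic pipeline: same config and seed, byte-identical artifacts.

## Worked example

Reproducing printed rate cells from a published count structure — for a
run over 306 double-reviewed parsed notes with 48 truth-empty MMSE notes,
25 predicted-empty of which 24 truly empty, and 52 notes with any MMSE
error:

```python
from cogexeval.metrics import aggregate_metrics, flags_from_counts

flags = flags_from_counts("MMSE", n_parsed=306, n_truth_empty=48,
                          n_pred_empty=25, n_correct_empty=24,
                          n_error_notes=52)
report = aggregate_metrics(flags)
print(round(report.tnr, 1), round(report.fnr, 1), round(report.accuracy, 1))
# 96.0 4.0 83.0
```

24 of 25 predicted-empty notes were truly empty (TNR 96.0%, FNR 4.0%), and
254 of 306 notes were fully correct (accuracy 83.0%).

A full synthetic run, end to end:

```bash
cogexeval run --seed 11 --n-notes 300 --out scratch/run
```

generates 300 annotated notes, runs two simulated extractors whose error
profiles are calibrated from published double-review error-mode counts
("chatgpt-like": rare hallucinations, mostly wrong-test and wrong-date
slips; "llama2-like": several-fold more hallucinations and misses), reviews
them with six noisy simulated experts (120 notes double-reviewed,
disagreements adjudicated by a third reviewer and majority vote), and prints
the aggregate table — e.g. with this seed, 41 of 120 double-reviewed notes
had at least one question disagreement, and the error taxonomy counted
2 hallucinations / 9 wrong-test / 22 wrong-date / 7 missed for the
chatgpt-like run against 22 / 11 / 23 / 28 for the llama2-like run.

The same stages are available as numbered drivers under `analysis/`
(01 corpus → 02 extraction → 03 review → 04 metrics → 05 agreement →
06 worked examples), each writing its tables under `results/`.

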