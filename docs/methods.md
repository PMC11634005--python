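# Methods

This note documents the models, conventions and design choices behind
`cogexeval`, in the order data flows through the harness.

## The synthetic corpus

**What it emulates.** Clinic notes from a dementia service in which most
notes document an MMSE (Mini-Mental State Examination, integer 0–30, often
"x/30"), a minority document a CDR (Clinical Dementia Rating, global levels
{0, 0.5, 1, 2, 3}), and a MoCA (Montreal Cognitive Assessment, also 0–30)
appears as a confusable distractor. Defaults: per-note presence is an
independent Bernoulli draw at 89.1% (MMSE), 14.3% (CDR) and 30% (MoCA);
given presence, the instance count is a truncated geometric with mean 1.5
(cap 4), deliberately a little above the ≈1.3 instances/note implied by
published instance and note counts, to exercise multi-instance matching.
15% of mentions are undated. Dated mentions render in one of five dialects
(ISO, `MM-DD-YYYY`, `M/D/YY`, "Month D, YYYY", month-year only, the last at
half weight), and one of 7–9 sentence templates per test (slash,
score-first, date-first, prose with the full test name, bare-colon forms).
Every mention is rendered by exactly one (template, dialect) pair and the
gold annotation stores the exact tuple, so normalization of the rendered
tokens provably recovers the gold values (enforced by a round-trip test
over the full template enumeration).

**Distractors.** Besides MoCA mentions, notes carry vital-sign numerals
("BP 120/80") and non-exam visit-date sentences, creating the wrong-test
and wrong-date opportunities the error taxonomy needs.

**What it does not emulate.** Narrative coherence, long-distance references
("scored the same as last visit"), markup (tag stripping is tested on
hand-written fixtures), PHI-like identifiers, or realistic note length:
filler defaults to 150–600 words to keep runs fast, with a
`realistic_length` switch matching the ~8,400-word mean (sd ~3,800) of full
EHR notes. Passing tests therefore demonstrate correctness of the
*evaluation machinery*, not extraction difficulty on real clinical prose.

**Determinism.** One `numpy` generator seeded from the config; identical
(config, seed) reproduce the corpus byte for byte.

## Preprocessing and the response dialect

Notes are stripped of markup (tags deleted, entities decoded, whitespace
collapsed), prefixed with the encounter date and a colon
(`2023-05-10: ...`) so extractors have an anchor for undated mentions, and
truncated to a whitespace-token budget (default 3,696 tokens, a typical
open-model context window; whitespace tokenization is a deliberate
simplification — the downstream statistics do not depend on the tokenizer).

Extractor responses use a canonical JSON dialect, versioned in corpus
manifests: top-level keys `"MMSE"` and `"CDR"`, each a list of
`{"score": text, "date": text-or-null}`. Parsing never raises: malformed
JSON, wrong shapes, or out-of-range values yield `parse_ok=false` with a
reason, and such notes are excluded from metric denominators and counted
separately — parse validity is a first-class outcome, mirroring how API
errors and invalid JSON are reported in LLM evaluations.

Dates: ambiguous numeric forms are read month-first (US EHR convention;
configurable through the dialect order). Month-year mentions resolve to
day 1 with a `partial` flag that participates in matching, so a partial
date never silently equals a full one. CDR values outside the five global
levels (e.g. sum-of-boxes up to 18) are rejected by default and accepted
under an explicit switch, since the accepted CDR domain is a modelling
choice.

## Extractors

The **regex baseline** is sentence-scoped: per keyword occurrence it takes
the first valid score token in a bounded post-keyword window (slash form
preferred; numbers inside date tokens are never read as scores; vital-sign
fractions fail the range checks) and the nearest parseable date in the
sentence, skipping the encounter-date prefix. MoCA mentions are recognized
and deliberately excluded from the answer.

The **error-model simulator** starts from gold and injects the four
empirically observed LLM failure modes. Per gold tuple one mutually
exclusive outcome is drawn — faithful, missed, wrong test (substituting a
distractor tuple's score from the same note, falling back to faithful with
a log entry when no valid distractor exists), wrong date (uniform nonzero
shift of ±30–400 days, guaranteeing inequality after normalization) — and
per note a hallucinated tuple may be injected (its score drawn to avoid
every gold score in the note, so it is classifiable as unsupported) and the
whole response may fail to parse. Mutual exclusivity per tuple matches how
qualitative error counts are tallied one-per-instance; hallucination is
additive per note.

`calibrate_error_config` converts observed mode counts over exposures
(gold tuples for per-tuple modes, notes for per-note modes) into
probabilities. The shipped presets convert published double-review MMSE
error counts — "chatgpt-like": 3 hallucinations, 17 wrong-test, 19
wrong-date; "llama2-like": 27 hallucinations, 19 wrong-test, 23 wrong-date,
25 missed — over an exposure base of ≈352 gold instances in 306 parsed
notes. That base, and the chatgpt-like missed count (≈8), are back-computed
from pooled precision/recall and instance counts, so the presets are
documented as approximate.

The real-LLM adapter is interface-only (plain text in, raw response out;
failures recorded and the note excluded); no network code ships.

## Review workflow

Assignment shuffles notes, gives each double-review note a uniformly random
pair of distinct below-cap reviewers, then singles uniformly among
below-cap reviewers. The published design states the objective (random
pairs, a per-reviewer cap, ~15 doubles per reviewer) rather than an
algorithm; this realization satisfies all stated constraints, treats the
per-reviewer double count as an emergent property, and reports it in the
plan. Uniform random pairing is also what licenses Fleiss' kappa on the
double-reviewed subset.

The four binary questions are defined by multiset containment: *correct* =
every predicted tuple matches some truth tuple; *complete* = every truth
tuple is matched. Disagreement on any of the four sends the note to a
dedicated third reviewer; adjudication takes the per-question majority of
the three and the corrected tuples of a majority-side reviewer (random
seeded pick when several qualify equally — the tie among majority-side
ground truths is not addressed by the published design, so the pick is our
choice, made deterministic). Full agreement takes one of the two corrected
sets at random (seeded); invalid-JSON reviews fall back to the valid one,
and a note with no valid review is excluded and logged.

The reviewer simulator computes the ideal record against gold, flips each
flag independently with probability `noise_q` (≤ 0.5) and perturbs each
corrected tuple with probability `tuple_noise` (default `noise_q/2`;
score nudges or 30–400-day date shifts). Under independent flips the
double-review disagreement rate has the closed form
`1 − (1 − 2q(1−q))⁴`, which the tests verify by simulation.

## Metrics

Matching is maximum multiset matching under exact equality of (test, score,
date, partial flag); the denominator of a slash form is surface syntax and
does not participate. Because the match relation is exact equality, greedy
counting over match keys attains the true maximum (equality edges form
disjoint bicliques); an exhaustive brute-force maximum-matching oracle
confirms this for all list pairs up to length 5.

Two aggregation conventions deserve explicit statement:

- **TNR denominator.** The primary "true negative rate" here is
  correctly-empty / *predicted*-empty. The conventional truth-conditioned
  rate is emitted alongside (`tnr_conventional`), but the predicted-empty
  denominator is the definition under which published count structures
  reproduce their printed rate cells (e.g. 24/25 = 96.0, 66/110 = 60.0,
  532/533 = 99.8), and it is what the worked examples check.
- **Precision/recall subset.** Macro and micro precision/recall are
  computed over notes with a non-empty prediction; a note predicted empty
  against non-empty truth surfaces in the FNR, not in recall. All-notes
  recall variants (`macro_recall_all_notes`, `micro_recall_all_notes`) are
  emitted for users — and the miss-rate recovery check uses the all-notes
  micro recall, since conditioning on a non-empty response biases the
  subset recall upward under a pure miss process.

Both-empty notes count as exact matches for accuracy (the convention under
which error-note counts and accuracy cells are mutually consistent).
Percentages are rendered at one decimal; raw fractions are always stored.
Macro standard deviations use the sample convention (ddof = 1).

The error classifier processes each unmatched predicted tuple with priority
wrong-test → wrong-date → hallucination: wrong-test if its score (or score
and date) coincides with another test's gold tuple in the note; wrong-date
if its score pairs with an otherwise-unmatched same-test gold tuple on a
different date; else hallucination. Gold tuples consumed by wrong-test or
wrong-date pairings are not also counted missed, giving the exact
bookkeeping identities (asserted in code): predicted = matched +
hallucination + wrong-test + wrong-date, and truth = matched +
wrong-date-paired + wrong-test-displaced + missed. Whether "wrong test"
should require date agreement as well as score agreement is underdetermined;
the score-first priority rule is our documented choice.

## Agreement

Fleiss' kappa is computed from items × categories count matrices with a
constant rater count r ≥ 2. Binary questions: items are double-reviewed
notes, categories yes/no. Tuple matrices: per note each rater's list is
canonically sorted (date, then value); items are (note, position) slots up
to the longest list; the category is the normalized value or date at that
position, with a distinguished ABSENT category for shorter lists. This
sort-then-align construction is one realization of "kappa over tuple
lists" — the quantity is standard, the alignment is not — so it is isolated
behind one operation and can be swapped. Notes where every rater's list is
empty contribute no items (counting them as unanimous-ABSENT would inflate
kappa). A degenerate matrix (chance agreement 1 with imperfect observed
agreement) is reported as a flagged undefined result, never a silent 0.
The machine joins as a third rater for the 3-way statistic. No variance or
confidence intervals are computed (point estimates only).

## Pipeline, sizes and budgets

The demonstration configuration — 300 notes, the two calibrated presets,
six reviewers with a load cap, 40% of notes double-reviewed, reviewer flip
noise 0.05 — runs in about a second and is the default for the analysis
drivers and the acceptance script; recovery checks that need tighter
binomial error (miss-rate, calibration closed loop) use 1,200–1,600-note
corpora (≥ 2,000 gold tuples). Per-stage seeds are derived from one master
seed via `SeedSequence`, every artifact is written with its config echo,
and manifest counts are asserted consistent (evaluated = generated −
parse-failed). Reviewers judge the primary (first-listed) extractor; its
adjudicated corrections become the ground truth all extractors are scored
against, reproducing the design in which one model's answers seed the
annotation. With zero reviewer noise the adjudicated truth provably equals
gold, which is the basis of the end-to-end identity test.

## Known limitations

- Template-rendered sentences are far easier than clinical prose; absolute
  metric levels on synthetic corpora say nothing about real-note
  difficulty (relative comparisons between error models are meaningful).
- The calibrated presets inherit the approximations in their exposure base
  (back-computed gold-instance counts) and apply MMSE-derived rates to CDR
  tuples as well.
- Wrong-test substitution requires a range-valid distractor, so simulated
  CDR wrong-test errors are rarer than the configured probability (the
  fallback is logged); the closed-loop calibration check therefore uses an
  MMSE-only corpus with a distractor in every note.
- The tuple-matrix alignment for kappa is one defensible construction;
  alternatives (e.g. value-multiset alignment) would give different
  numbers on discordant lists.
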