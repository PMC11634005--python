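#!/usr/bin/env python
"""Run the simulated review workflow end to end on the study corpus: random
single/double assignment under a cap, noisy reviewers answering the four
binary questions, third reviews on disagreement, and majority-vote
adjudication into final ground truth.

Writes results/03_review_summary.json (assignment and disagreement counts
plus mean answers to the four questions); reviews and adjudicated truth go
under scratch/analysis/ via the pipeline artifacts.
"""

import json
from pathlib import Path

import numpy as np

from cogexeval.pipeline import demo_config, run_pipeline
from cogexeval.review import QUESTIONS

SEED = 11
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    result = run_pipeline(demo_config(seed=SEED, n_notes=300),
                          ROOT / "scratch" / "analysis" / "pipeline")
    counts = result.manifest.counts
    question_means = {}
    for i, q in enumerate(QUESTIONS):
        vals = [r.flags()[i] for r in result.reviews]
        question_means[q] = {"mean_pct": 100.0 * float(np.mean(vals)),
                             "sd_pct": 100.0 * float(np.std(vals))}
    summary = {
        "assigned": counts["assigned"],
        "double_reviewed": counts["double_reviewed"],
        "disagreements": counts["disagreements"],
        "adjudicated": counts["adjudicated"],
        "unadjudicatable": counts["unadjudicatable"],
        "question_means": question_means,
    }
    out = ROOT / "results" / "03_review_summary.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(summary, indent=2))
    print(f"{counts['assigned']} notes reviewed, "
          f"{counts['double_reviewed']} double-reviewed, "
          f"{counts['disagreements']} disagreements sent to a third reviewer")
    for q, m in question_means.items():
        print(f"  {q}: {m['mean_pct']:.1f}% yes (sd {m['sd_pct']:.1f})")
    print(f"Summary -> {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
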