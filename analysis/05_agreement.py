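#!/usr/bin/env python
"""Inter-rater agreement over the double-reviewed notes: Fleiss' kappa for
the four binary questions (2-way between reviewers) and for tuple values and
dates per test, both 2-way (reviewers) and 3-way (primary extractor joined
as a third rater).

Writes results/05_agreement.json.
"""

import json
from pathlib import Path

from cogexeval.pipeline import demo_config, run_pipeline

SEED = 11
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    result = run_pipeline(demo_config(seed=SEED, n_notes=300),
                          ROOT / "scratch" / "analysis" / "pipeline")
    out = ROOT / "results" / "05_agreement.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(result.agreement, indent=2, sort_keys=True))
    print(f"Fleiss' kappa over {result.agreement['n_double_notes']} "
          f"double-reviewed notes (%):")
    for block in ("binary_questions", "tuples_2way", "tuples_3way"):
        for key, cell in result.agreement[block].items():
            v = cell.get("kappa_pct")
            shown = "undefined" if v is None else f"{v:.1f}"
            print(f"  {block}/{key}: {shown} (n={cell.get('n_items', 0)})")
    print(f"Report -> {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
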