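"""Independent oracles used by the tests.

These deliberately avoid the package's own algorithms: the matcher is a
generic recursive maximum bipartite matching over equality edges, and the
kappa oracle is a direct transcription of the agreement formula (plus
statsmodels' implementation where the tests want a third opinion).
"""

from __future__ import annotations

import datetime as dt

import numpy as np

from cogexeval.notes import ExtractionTuple


def brute_force_max_matching(pred, truth) -> int:
    """Maximum one-to-one matching size under exact tuple equality,
    by exhaustive recursion over pairings."""

    def recurse(i: int, used: tuple[bool, ...]) -> int:
        if i == len(pred):
            return 0
        best = recurse(i + 1, used)  # leave pred[i] unmatched
        for j, taken in enumerate(used):
            if not taken and pred[i].match_key() == truth[j].match_key():
                nxt = used[:j] + (True,) + used[j + 1:]
                best = max(best, 1 + recurse(i + 1, nxt))
        return best

    return recurse(0, tuple(False for _ in truth))


def fleiss_kappa_by_hand(counts: np.ndarray) -> float:
    """Direct formula evaluation, written independently of the package."""
    counts = np.asarray(counts, dtype=float)
    n, _ = counts.shape
    r = counts.sum(axis=1)[0]
    p_i = (np.square(counts).sum(axis=1) - r) / (r * (r - 1.0))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / (n * r)
    p_e = np.square(p_j).sum()
    return (p_bar - p_e) / (1.0 - p_e)


def mmse_tuple(score: float, day: int | None, partial: bool = False
               ) -> ExtractionTuple:
    """Compact MMSE tuple builder for matcher tests (day indexes a date)."""
    date = None if day is None else dt.date(2020, 1, 1) + dt.timedelta(days=day)
    return ExtractionTuple(test="MMSE", score=float(score), date=date,
                           date_partial=partial)
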