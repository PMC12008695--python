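"""Packaged reference data: the published reliance-pattern case counts.

A web-based study of 223 dermatologists × 24 lesion-classification trials
(5352 cases) reported the distribution of cases over the eight reliance
patterns.  ``REFERENCE_PATTERN_COUNTS`` stores those counts;
:func:`pattern_fixture_trials` rebuilds a synthetic trial table whose derived
(initial-correct, advice-correct, final-correct) triples realise them exactly,
so the pooled summary stage can be validated against the published numbers
(RAIR 139/1384 ≈ 10.04%, RSR 487/569 ≈ 85.6%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import PATTERN_BY_TRIPLE

#: Published case counts per (initial correct, advice correct, final correct) triple.
REFERENCE_PATTERN_COUNTS: dict[tuple[int, int, int], int] = {
    (0, 0, 0): 543,   # detrimental reliance
    (0, 0, 1): 3,     # beneficial underreliance
    (0, 1, 0): 1245,  # detrimental self-reliance
    (0, 1, 1): 139,   # beneficial overreliance
    (1, 0, 0): 82,    # detrimental overreliance
    (1, 0, 1): 487,   # beneficial self-reliance
    (1, 1, 0): 6,     # detrimental underreliance
    (1, 1, 1): 2847,  # beneficial reliance
}

REFERENCE_N_PARTICIPANTS = 223
REFERENCE_N_TRIALS = 24

# Representative slider values on a malignant-truth trial (correct region
# [61, 100], advice extremes [75, 85] / [15, 25]): any triple can be realised.
_R1 = {0: 30.0, 1: 70.0}
_ADVICE = {0: 20.0, 1: 80.0}
_R2 = {0: 25.0, 1: 75.0}


def pattern_fixture_trials(
    counts: dict[tuple[int, int, int], int] | None = None,
    n_participants: int | None = None,
) -> pd.DataFrame:
    """Build a synthetic trials long table realising the given pattern counts.

    Every trial uses a malignant truth with slider placements chosen so the
    derived correctness triple matches its pattern; rows are distributed over
    participants in round-robin order.  With the default counts the table has
    exactly 5352 rows over 223 participants × 24 trials.
    """
    counts = counts if counts is not None else REFERENCE_PATTERN_COUNTS
    unknown = set(counts) - set(PATTERN_BY_TRIPLE)
    if unknown:
        raise ValueError(f"unknown correctness triples: {sorted(unknown)}")
    total = int(sum(counts.values()))
    if n_participants is None:
        n_participants = (
            REFERENCE_N_PARTICIPANTS if total % REFERENCE_N_PARTICIPANTS == 0 else 1
        )
    c1 = np.concatenate([np.full(n, t[0]) for t, n in counts.items()])
    adv = np.concatenate([np.full(n, t[1]) for t, n in counts.items()])
    c2 = np.concatenate([np.full(n, t[2]) for t, n in counts.items()])
    idx = np.arange(total)
    return pd.DataFrame(
        {
            "participant_id": idx % n_participants,
            "trial": idx // n_participants,
            "truth": "malignant",
            "advice": [_ADVICE[v] for v in adv],
            "advice_correct": adv.astype(bool),
            "response_1": [_R1[v] for v in c1],
            "response_2": [_R2[v] for v in c2],
        }
    )
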