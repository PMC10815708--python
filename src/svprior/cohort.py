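"""Severe / non-severe subgroup partition from THI scores.

The Tinnitus Handicap Inventory (THI) is a 0-100 questionnaire score.  A
sample is *severe* when its score strictly exceeds the third quartile of the
cohort's empirical THI distribution (or an explicit published threshold,
e.g. 68); everything else is non-severe.  Q3 is estimated by linear
interpolation between order statistics, the common default in statistical
software.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .model import CohortTable, Subgroup


def thi_third_quartile(cohort: CohortTable) -> float:
    """Linear-interpolation Q3 of the cohort's THI scores (needs >= 4)."""
    scores = np.asarray(list(cohort.entries.values()), dtype=float)
    if scores.size < 4:
        raise ValueError(
            f"only {scores.size} samples: too few to estimate quartiles; "
            "pass an explicit threshold_override"
        )
    return float(np.quantile(scores, 0.75, method="linear"))


def partition_by_thi(
    cohort: CohortTable,
    threshold_override: Optional[float] = None,
) -> CohortTable:
    """Assign every sample to exactly one subgroup: severe iff THI > threshold.

    The inequality is strict ("higher than" the third quartile), so a score
    exactly equal to the threshold is non-severe.  With
    ``threshold_override`` the data-driven Q3 is bypassed, which makes any
    published cut-off exactly reproducible.
    """
    threshold = (
        float(threshold_override)
        if threshold_override is not None
        else thi_third_quartile(cohort)
    )
    cohort.subgroup = {
        sid: (Subgroup.SEVERE if score > threshold else Subgroup.NON_SEVERE)
        for sid, score in cohort.entries.items()
    }
    return cohort
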