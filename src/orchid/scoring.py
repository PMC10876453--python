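"""Rating formulas and assembly of the 20-component diversity score.

Two rating systems exist:

* **positive** (encouraged groups): ``points = occurrences * weight``.
* **threshold** (groups to consume in moderation): up to the threshold each
  occurrence earns one point; past it, ``points = (occurrences - threshold)
  * weight`` with a (typically negative) weight.  This printed piecewise
  form is discontinuous at the threshold — the below-threshold points are
  forfeited once the threshold is exceeded.  The ``continuous`` mode keeps
  them (``threshold + (occurrences - threshold) * weight``) and is offered
  as an explicit alternative.

Recall-group occurrences are integers summed over the three recall days;
FPQ-group occurrences are real weekly frequencies and are scored without
rounding.  The total score is the exact sum of the 20 component points.
"""

from __future__ import annotations

from typing import Literal

import pandas as pd

from .errors import CohortError
from .model import ALL_GROUPS, FPQ_GROUPS, RECALL_GROUPS, FoodGroupConfig, config_by_id

ScoringMode = Literal["literal", "continuous"]


def score_positive(occurrences: float, weight: float) -> float:
    """Points for a positively rated group: occurrences x weight."""
    if occurrences < 0:
        raise ValueError("occurrences must be >= 0")
    return occurrences * weight


def score_threshold(
    occurrences: float, threshold: int, weight: float, mode: ScoringMode = "literal"
) -> float:
    """Points for a threshold-rated group.

    ``literal`` follows the printed piecewise rule (points reset past the
    threshold); ``continuous`` retains the threshold points and applies the
    weight only to the excess.
    """
    if occurrences < 0:
        raise ValueError("occurrences must be >= 0")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if occurrences <= threshold:
        return float(occurrences)
    excess = (occurrences - threshold) * weight
    return threshold + excess if mode == "continuous" else excess


def compute_orchid(
    recall_counts: pd.DataFrame,
    weekly: pd.DataFrame,
    configs: list[FoodGroupConfig],
    mode: ScoringMode = "literal",
) -> pd.DataFrame:
    """Score a cohort: one row per individual, 20 component columns + total.

    Parameters
    ----------
    recall_counts:
        ``individual_id, group_id, occurrences`` for the 13 recall groups
        (zeros allowed, but every group must be present for every
        individual).
    weekly:
        ``individual_id, group_id, occurrences_per_week`` for the 7 FPQ
        groups.
    configs:
        Complete scoring configuration.
    mode:
        Threshold-rating variant, see :func:`score_threshold`.

    Raises
    ------
    CohortError
        Naming the first individual and group found missing.
    """
    cfg = config_by_id(configs)
    rc = recall_counts.pivot(index="individual_id", columns="group_id", values="occurrences")
    wk = weekly.pivot(index="individual_id", columns="group_id", values="occurrences_per_week")
    individuals = rc.index.union(wk.index)

    occ = pd.DataFrame(index=individuals)
    for gid in RECALL_GROUPS:
        occ[gid] = rc[gid] if gid in rc.columns else float("nan")
    for gid in FPQ_GROUPS:
        occ[gid] = wk[gid] if gid in wk.columns else float("nan")
    if occ.isna().any().any():
        col = occ.columns[occ.isna().any()][0]
        ind = occ.index[occ[col].isna()][0]
        raise CohortError(f"individual '{ind}' is missing group '{col}'")

    points = pd.DataFrame(index=individuals)
    for gid in ALL_GROUPS:
        c = cfg[gid]
        if c.rating == "positive":
            points[gid] = occ[gid] * c.weight
        else:
            below = occ[gid] <= c.threshold
            excess = (occ[gid] - c.threshold) * c.weight
            if mode == "continuous":
                excess = excess + c.threshold
            points[gid] = occ[gid].where(below, excess)
    points["total"] = points[list(ALL_GROUPS)].sum(axis=1)
    points.index.name = "individual_id"
    return points
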