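"""Rating formulas and score assembly."""

import numpy as np
import pandas as pd
import pytest

from orchid.errors import CohortError
from orchid.model import ALL_GROUPS, FPQ_GROUPS, RECALL_GROUPS, config_by_id
from orchid.scoring import compute_orchid, score_positive, score_threshold


@pytest.mark.parametrize(
    "occ,weight,expected",
    [(6, 1, 6), (0, 2.5, 0), (3.5, 2, 7)],
)
def test_positive_rating(occ, weight, expected):
    assert score_positive(occ, weight) == expected


@pytest.mark.parametrize(
    "occ,thr,weight,mode,expected",
    [
        (2, 3, -2, "literal", 2),       # below threshold: one point per occurrence
        (5, 3, -2, "literal", -4),      # (5-3) x (-2)
        (5, 3, -2, "continuous", -1),   # 3 + (5-3) x (-2)
        (3, 3, -2, "literal", 3),       # at the threshold: below-branch
        (0, 0, -2, "literal", 0),
        (1, 0, -2, "literal", -2),
    ],
)
def test_threshold_rating(occ, thr, weight, mode, expected):
    assert score_threshold(occ, thr, weight, mode) == expected


def test_threshold_slope_shape():
    """Literal points rise with slope 1 up to the threshold, then slope=weight."""
    pts = [score_threshold(k, 4, -2, "literal") for k in range(10)]
    assert pts[:5] == [0, 1, 2, 3, 4]
    diffs = np.diff(pts[5:])
    assert (diffs == -2).all()


def _cohort_tables(occ_by_group):
    counts = pd.DataFrame(
        [
            {"individual_id": "a", "group_id": g, "occurrences": occ_by_group.get(g, 0)}
            for g in RECALL_GROUPS
        ]
    )
    weekly = pd.DataFrame(
        [
            {"individual_id": "a", "group_id": g, "occurrences_per_week": occ_by_group.get(g, 0.0)}
            for g in FPQ_GROUPS
        ]
    )
    return counts, weekly


def test_all_zero_occurrences_score_zero(configs):
    counts, weekly = _cohort_tables({})
    res = compute_orchid(counts, weekly, configs)
    assert (res.loc["a"] == 0).all()


def test_single_fruit_occurrence_scores_its_weight(configs):
    counts, weekly = _cohort_tables({"fruits": 1})
    w = config_by_id(configs)["fruits"].weight
    res = compute_orchid(counts, weekly, configs)
    assert res.loc["a", "total"] == pytest.approx(w)
    assert res.loc["a", "fruits"] == pytest.approx(w)


def test_missing_group_rejected_with_names(configs):
    counts, weekly = _cohort_tables({})
    weekly = weekly[weekly["group_id"] != "nuts"]
    with pytest.raises(CohortError, match="nuts"):
        compute_orchid(counts, weekly, configs)


def _straight_line_score(occ, configs, mode="literal"):
    """Independent re-implementation of the two printed formulas."""
    total = 0.0
    for c in configs:
        x = occ[c.group_id]
        if c.rating == "positive":
            total += x * c.weight
        elif x <= c.threshold:
            total += x
        else:
            total += (x - c.threshold) * c.weight + (c.threshold if mode == "continuous" else 0)
    return total


@pytest.mark.parametrize("mode", ["literal", "continuous"])
def test_random_cohort_matches_straight_line_oracle(configs, mode):
    rng = np.random.default_rng(7)
    counts_rows, weekly_rows, expected = [], [], {}
    for i in range(200):
        ind = f"i{i}"
        occ = {}
        for g in RECALL_GROUPS:
            occ[g] = int(rng.integers(0, 12))
            counts_rows.append({"individual_id": ind, "group_id": g, "occurrences": occ[g]})
        for g in FPQ_GROUPS:
            occ[g] = float(np.round(rng.uniform(0, 8), 3))
            weekly_rows.append(
                {"individual_id": ind, "group_id": g, "occurrences_per_week": occ[g]}
            )
        expected[ind] = _straight_line_score(occ, configs, mode)
    res = compute_orchid(
        pd.DataFrame(counts_rows), pd.DataFrame(weekly_rows), configs, mode=mode
    )
    for ind, want in expected.items():
        assert res.loc[ind, "total"] == pytest.approx(want, abs=1e-9)
    # additivity holds exactly
    comp_sum = res[list(ALL_GROUPS)].sum(axis=1)
    assert np.allclose(comp_sum, res["total"], atol=0)


def test_positive_group_monotonicity(configs):
    """One extra occurrence of a positive group moves the total by its weight."""
    base_counts, weekly = _cohort_tables({"vegetables": 3})
    base = compute_orchid(base_counts, weekly, configs).loc["a", "total"]
    more_counts, _ = _cohort_tables({"vegetables": 4})
    more = compute_orchid(more_counts, weekly, configs).loc["a", "total"]
    w = config_by_id(configs)["vegetables"].weight
    assert more - base == pytest.approx(w)


def test_default_config_reaches_negative_and_above_100(configs):
    """Adversarial extremes span the sign and magnitude of observed totals."""
    bad = {g: 0 for g in ALL_GROUPS}
    bad.update({"sweetened_beverages": 12, "sweetened_products": 15, "salted_aperitif_products": 8})
    counts, weekly = _cohort_tables(bad)
    low = compute_orchid(counts, weekly, configs).loc["a", "total"]
    assert low < -30

    good = {"vegetables": 15, "fruits": 15, "wholemeal_or_semi_wholemeal_products": 10,
            "legumes": 5, "fatty_fish": 3, "lean_fish_and_shellfish": 3}
    counts, weekly = _cohort_tables(good)
    high = compute_orchid(counts, weekly, configs).loc["a", "total"]
    assert high > 100
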