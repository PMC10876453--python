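"""Dish disaggregation and the half-portion occurrence gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orchid.errors import CohortError
from orchid.model import EXCLUDED, RECALL_GROUPS, config_by_id
from orchid.occurrences import count_occurrences, disaggregate, main_ingredients

from conftest import make_recalls


def naive_counts(declarations, mapping, configs, inclusive=True):
    """Independent oracle: triple loop over individual x day x group."""
    cfg = config_by_id(configs)
    code_to_group = dict(zip(mapping["food_code"], mapping["group_id"]))
    records = declarations[["individual_id", "day", "food_code", "grams"]].values.tolist()
    out = {}
    for ind in declarations["individual_id"].unique():
        for g in RECALL_GROUPS:
            total = 0
            for day in declarations["day"].unique():
                rows = [
                    r
                    for r in records
                    if r[0] == ind and r[1] == day
                    and code_to_group.get(r[2], EXCLUDED) == g
                ]
                grams = sum(r[3] for r in rows)
                half = cfg[g].standard_portion_g / 2
                ok = grams >= half if inclusive else grams > half
                if ok:
                    total += len(rows)
            out[(ind, g)] = total
    return out


def recipe(*pairs):
    return pd.DataFrame([{"food_code": c, "grams": g} for c, g in pairs])


@pytest.mark.parametrize(
    "ingredients,expected",
    [
        # dominant ingredient alone reaches half of the 100 g recipe
        ([("veg", 60), ("pasta", 30), ("cheese", 10)], {"veg"}),
        # 40 < 50 so the prefix extends to 80 >= 50
        ([("veg", 40), ("pasta", 40), ("cheese", 20)], {"veg", "pasta"}),
        ([("veg", 100)], {"veg"}),
        # boundary tie: the second 50 g ingredient is included too
        ([("veg", 50), ("pasta", 50)], {"veg", "pasta"}),
    ],
)
def test_main_ingredients_prefix_rule(ingredients, expected):
    mains = main_ingredients(recipe(*ingredients))
    assert set(mains["food_code"]) == expected


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(1, 500), min_size=1, max_size=8),
    st.floats(10, 400),
)
def test_disaggregation_conserves_mass(masses, declared):
    """Sum of scaled main-ingredient grams never exceeds the declared dish grams."""
    rec = recipe(*[(f"i{k}", m) for k, m in enumerate(masses)])
    rec["dish_code"] = "d"
    decl = make_recalls([("a", 1, "d", declared)])
    decl["is_complex_dish"] = True
    out, warnings = disaggregate(decl, rec)
    assert not warnings
    assert out["grams"].sum() <= declared + 1e-9
    # mains cover at least half of the declared mass
    assert out["grams"].sum() >= declared / 2 - 1e-9


def test_unknown_dish_routed_to_excluded_with_warning():
    decl = make_recalls([("a", 1, "mystery_dish", 120)])
    decl["is_complex_dish"] = True
    out, warnings = disaggregate(decl, pd.DataFrame(columns=["dish_code", "food_code", "grams"]))
    assert len(warnings) == 1 and "mystery_dish" in warnings[0]
    assert out["food_code"].tolist() == [EXCLUDED]


def test_half_portion_gate_on_cooked_ham(configs):
    """50 g standard portion: a 20 g day is ignored, a 40 g day counts each declaration."""
    mapping = pd.DataFrame({"food_code": ["ham"], "group_id": ["cooked_ham"]})
    below = make_recalls([("a", 1, "ham", 20)])
    counts = count_occurrences(below, mapping, configs)
    assert counts.loc[counts["group_id"] == "cooked_ham", "occurrences"].item() == 0

    two = make_recalls([("a", 1, "ham", 20), ("a", 1, "ham", 20)])
    counts = count_occurrences(two, mapping, configs)
    assert counts.loc[counts["group_id"] == "cooked_ham", "occurrences"].item() == 2


def test_gate_boundary_inclusive_vs_strict(configs):
    mapping = pd.DataFrame({"food_code": ["ham"], "group_id": ["cooked_ham"]})
    exact = make_recalls([("a", 1, "ham", 25)])
    inc = count_occurrences(exact, mapping, configs, inclusive=True)
    strict = count_occurrences(exact, mapping, configs, inclusive=False)
    assert inc.loc[inc["group_id"] == "cooked_ham", "occurrences"].item() == 1
    assert strict.loc[strict["group_id"] == "cooked_ham", "occurrences"].item() == 0


def test_all_excluded_gives_zero_everywhere(configs):
    mapping = pd.DataFrame({"food_code": ["water"], "group_id": [EXCLUDED]})
    decl = make_recalls([("a", d, "water", 500) for d in (1, 2, 3)])
    counts = count_occurrences(decl, mapping, configs)
    assert (counts["occurrences"] == 0).all()
    assert set(counts["group_id"]) == set(RECALL_GROUPS)


def _random_menu(rng, configs, n_ind=3, n_days=3, n_decl=20):
    groups = list(RECALL_GROUPS) + [EXCLUDED]
    codes = [f"{g}_c" for g in groups]
    mapping = pd.DataFrame({"food_code": codes, "group_id": groups})
    portions = {c.group_id: c.standard_portion_g for c in configs}
    rows = []
    for _ in range(n_decl):
        g = groups[rng.integers(len(groups))]
        portion = portions.get(g, 100)
        rows.append(
            (
                f"i{rng.integers(n_ind)}",
                int(rng.integers(1, n_days + 1)),
                f"{g}_c",
                float(rng.uniform(0, 1.4) * portion),
            )
        )
    return make_recalls(rows), mapping


def test_engine_matches_naive_oracle_on_random_menus(configs):
    rng = np.random.default_rng(123)
    for _ in range(120):
        decl, mapping = _random_menu(rng, configs)
        got = count_occurrences(decl, mapping, configs)
        want = naive_counts(decl, mapping, configs)
        got_map = {(r.individual_id, r.group_id): r.occurrences for r in got.itertuples()}
        assert got_map == want


def test_adding_a_declaration_never_decreases_counts(configs):
    rng = np.random.default_rng(42)
    for _ in range(40):
        decl, mapping = _random_menu(rng, configs)
        base = count_occurrences(decl, mapping, configs).set_index(
            ["individual_id", "group_id"]
        )["occurrences"]
        extra, _ = _random_menu(rng, configs, n_decl=1)
        extra["individual_id"] = decl["individual_id"].iloc[0]
        bigger = count_occurrences(
            pd.concat([decl, extra], ignore_index=True), mapping, configs
        ).set_index(["individual_id", "group_id"])["occurrences"]
        assert (bigger.reindex(base.index, fill_value=0) >= base).all()


def test_doubling_grams_never_decreases_counts(configs):
    rng = np.random.default_rng(99)
    for _ in range(40):
        decl, mapping = _random_menu(rng, configs)
        base = count_occurrences(decl, mapping, configs)["occurrences"]
        doubled = decl.assign(grams=decl["grams"] * 2)
        more = count_occurrences(doubled, mapping, configs)["occurrences"]
        assert (more >= base).all()


def test_empty_recipe_rejected():
    with pytest.raises(CohortError):
        main_ingredients(pd.DataFrame(columns=["food_code", "grams"]))
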