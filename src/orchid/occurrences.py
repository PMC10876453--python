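"""Turn recall declarations into per-group consumption occurrence counts.

The pipeline is: (1) disaggregate complex dishes into their *main*
ingredients (the heaviest ingredients jointly making up at least half of the
recipe's mass), (2) map every food code to one of the 13 recall-source food
groups (or the EXCLUDED sentinel), (3) apply the half-standard-portion
daily gate — a day's declarations of a group count only when that day's
total grams for the group reach half the group's standard portion — and
(4) sum qualifying declarations over the recall days.

Each qualifying eating-occasion declaration counts as one occurrence, so a
group eaten twice in a qualifying day contributes two occurrences.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import CohortError
from .model import EXCLUDED, RECALL_GROUPS, FoodGroupConfig, config_by_id

logger = logging.getLogger(__name__)


def main_ingredients(recipe: pd.DataFrame) -> pd.DataFrame:
    """Select a recipe's main ingredients.

    Ingredients are sorted by descending mass; the main ingredients are the
    smallest prefix whose cumulative mass reaches 50 % of the recipe's total
    mass.  Ingredients tied (equal grams) with the last prefix member are
    included as well, so the selection does not depend on input order.

    Parameters
    ----------
    recipe:
        Rows of one dish: columns ``food_code, grams`` (grams > 0).

    Returns
    -------
    The selected rows (original grams, descending order).
    """
    if len(recipe) == 0:
        raise CohortError("recipe has no ingredients")
    srt = recipe.sort_values("grams", ascending=False, kind="mergesort").reset_index(drop=True)
    total = srt["grams"].sum()
    cum = srt["grams"].cumsum()
    k = int(np.argmax(cum.values >= total / 2))  # first index reaching half
    boundary = srt.loc[k, "grams"]
    keep = (srt.index <= k) | (srt["grams"] == boundary)
    return srt[keep]


def disaggregate(
    recalls: pd.DataFrame, recipes: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Replace complex-dish declarations by their main-ingredient declarations.

    Ingredient grams are scaled by declared dish grams over total recipe
    grams, so the sum of main-ingredient grams never exceeds the declared
    dish grams.  Dishes with no recipe are logged and routed to EXCLUDED
    (the declaration is kept with food_code EXCLUDED so it still appears in
    audit output but can never score).

    Returns the ingredient-level declarations plus a list of warnings.
    """
    warnings: list[str] = []
    if len(recalls) == 0 or not recalls["is_complex_dish"].any():
        return recalls.copy(), warnings

    simple = recalls[~recalls["is_complex_dish"]]
    dishes = recalls[recalls["is_complex_dish"]]
    by_dish = {code: grp for code, grp in recipes.groupby("dish_code")} if len(recipes) else {}

    pieces = [simple]
    for _, row in dishes.iterrows():
        recipe = by_dish.get(row["food_code"])
        if recipe is None:
            msg = f"dish '{row['food_code']}' has no recipe; routed to EXCLUDED"
            warnings.append(msg)
            logger.warning(msg)
            repl = row.to_frame().T.copy()
            repl["food_code"] = EXCLUDED
            repl["is_complex_dish"] = False
            pieces.append(repl)
            continue
        mains = main_ingredients(recipe)
        scale = row["grams"] / recipe["grams"].sum()
        out = pd.DataFrame(
            {
                "individual_id": row["individual_id"],
                "day": row["day"],
                "food_code": mains["food_code"].values,
                "grams": mains["grams"].values * scale,
                "is_solid": row["is_solid"],
                "is_complex_dish": False,
            }
        )
        for extra in set(recalls.columns) - set(out.columns):
            out[extra] = row[extra]
        pieces.append(out)
    result = pd.concat(pieces, ignore_index=True)
    return result[recalls.columns], warnings


def count_occurrences(
    declarations: pd.DataFrame,
    mapping: pd.DataFrame,
    configs: list[FoodGroupConfig],
    inclusive: bool = True,
) -> pd.DataFrame:
    """Count gated consumption occurrences per individual and recall group.

    Parameters
    ----------
    declarations:
        Dish-disaggregated recall declarations.
    mapping:
        ``food_code -> group_id`` table; unknown codes are warned about and
        treated as EXCLUDED, never fatal.
    configs:
        Complete 20-group scoring configuration (for standard portions).
    inclusive:
        If True (default) a day qualifies when its group total is *at or
        above* half a standard portion; if False, strictly above.

    Returns
    -------
    Tidy frame ``individual_id, group_id, occurrences`` covering every
    individual x all 13 recall groups (zeros filled in).  FPQ-source groups
    never appear.
    """
    cfg = config_by_id(configs)
    individuals = pd.unique(declarations["individual_id"]) if len(declarations) else []
    grid = pd.MultiIndex.from_product(
        [individuals, list(RECALL_GROUPS)], names=["individual_id", "group_id"]
    )
    empty = pd.DataFrame({"occurrences": 0}, index=grid).reset_index()
    if len(declarations) == 0:
        return empty

    df = declarations.merge(mapping, on="food_code", how="left")
    unknown = df["group_id"].isna() & (df["food_code"] != EXCLUDED)
    if unknown.any():
        codes = sorted(df.loc[unknown, "food_code"].unique())
        logger.warning("unmapped food code(s) treated as EXCLUDED: %s", codes)
    df["group_id"] = df["group_id"].fillna(EXCLUDED)
    df = df[df["group_id"].isin(RECALL_GROUPS)]
    if len(df) == 0:
        return empty

    daily = df.groupby(["individual_id", "day", "group_id"], sort=False).agg(
        total_g=("grams", "sum"), n_decl=("grams", "size")
    )
    portions = daily.index.get_level_values("group_id").map(
        lambda g: cfg[g].standard_portion_g
    )
    half = np.asarray(portions, dtype=float) / 2.0
    gate = daily["total_g"].values >= half if inclusive else daily["total_g"].values > half
    daily["occ"] = np.where(gate, daily["n_decl"], 0)
    counts = (
        daily.groupby(["individual_id", "group_id"])["occ"]
        .sum()
        .reindex(grid, fill_value=0)
        .rename("occurrences")
        .reset_index()
    )
    counts["occurrences"] = counts["occurrences"].astype(int)
    return counts
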