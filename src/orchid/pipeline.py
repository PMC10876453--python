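"""High-level glue: from raw survey tables to scores, metrics and report."""

from __future__ import annotations

import pandas as pd

from . import fpq as fpq_mod
from .diet_quality import cohort_diet_quality
from .model import ALL_GROUPS, FoodGroupConfig
from .occurrences import count_occurrences, disaggregate
from .scoring import ScoringMode, compute_orchid
from .validation import validity_report


def score_cohort(
    recalls: pd.DataFrame,
    recipes: pd.DataFrame,
    mapping: pd.DataFrame,
    fpq: pd.DataFrame,
    fpq_item_map: pd.DataFrame,
    covariates: pd.DataFrame,
    configs: list[FoodGroupConfig],
    seed: int = 0,
    mode: ScoringMode = "literal",
    impute: bool = True,
) -> dict:
    """Run recalls + FPQ through the full scoring chain.

    Returns a dict with the intermediate artifacts: ``declarations`` (dish-
    disaggregated), ``counts`` (recall occurrences), ``weekly`` (FPQ group
    frequencies), ``scores`` (components + total) and ``warnings``.
    """
    declarations, warnings = disaggregate(recalls, recipes)
    counts = count_occurrences(declarations, mapping, configs)

    weekly_long = fpq_mod.fpq_to_weekly(fpq)
    matrix = fpq_mod.to_item_matrix(weekly_long)
    if impute and matrix.isna().any().any():
        cov_numeric = covariates.set_index("individual_id")
        completed, _ = fpq_mod.impute_missing(matrix, cov_numeric, seed=seed)
    else:
        completed = matrix.fillna(0.0)
    weekly = fpq_mod.aggregate_to_groups(completed, fpq_item_map)

    # individuals present in only one source get explicit zeros in the other
    individuals = pd.Index(
        sorted(set(counts["individual_id"]) | set(weekly["individual_id"]))
    )
    counts = _complete(counts, individuals, "occurrences")
    weekly = _complete(weekly, individuals, "occurrences_per_week")
    scores = compute_orchid(counts, weekly, configs, mode=mode)
    return {
        "declarations": declarations,
        "counts": counts,
        "weekly": weekly,
        "scores": scores,
        "warnings": warnings,
    }


def _complete(tidy: pd.DataFrame, individuals: pd.Index, value: str) -> pd.DataFrame:
    groups = tidy["group_id"].unique()
    grid = pd.MultiIndex.from_product([individuals, groups], names=["individual_id", "group_id"])
    return (
        tidy.set_index(["individual_id", "group_id"])[value]
        .reindex(grid, fill_value=0)
        .reset_index()
    )


def group_intakes(
    declarations: pd.DataFrame, mapping: pd.DataFrame, n_days: int = 3
) -> pd.DataFrame:
    """Mean daily grams per food group per individual (all 20 groups)."""
    df = declarations.merge(mapping, on="food_code", how="left")
    df = df[df["group_id"].isin(ALL_GROUPS)]
    totals = (
        df.groupby(["individual_id", "group_id"])["grams"].sum().unstack(fill_value=0.0)
    )
    totals = totals.reindex(columns=list(ALL_GROUPS), fill_value=0.0)
    return totals / n_days


def analyse_cohort(
    recalls: pd.DataFrame,
    recipes: pd.DataFrame,
    mapping: pd.DataFrame,
    fpq: pd.DataFrame,
    fpq_item_map: pd.DataFrame,
    nutrients: pd.DataFrame,
    covariates: pd.DataFrame,
    design: pd.DataFrame | None,
    configs: list[FoodGroupConfig],
    mar_references: pd.DataFrame,
    pandiet_references: pd.DataFrame,
    seed: int = 0,
    mode: ScoringMode = "literal",
) -> dict:
    """Full pipeline: scoring, diet-quality metrics, validity report."""
    scored = score_cohort(
        recalls, recipes, mapping, fpq, fpq_item_map, covariates, configs, seed, mode
    )
    n_days = int(recalls["day"].max()) if len(recalls) else 3
    intakes = group_intakes(scored["declarations"], mapping, n_days)
    metrics = cohort_diet_quality(
        nutrients, scored["declarations"], covariates, mar_references, pandiet_references
    )
    weights = None
    if design is not None and len(design):
        weights = design.set_index("individual_id")["weight"]
    report = validity_report(scored["scores"], intakes, metrics, covariates, weights)
    return {**scored, "group_intakes": intakes, "metrics": metrics, "report": report}
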