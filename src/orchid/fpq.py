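"""Food-propensity-questionnaire processing.

The FPQ records usual consumption frequencies of ~60 food items over the
past year, either per week or per month.  Monthly frequencies are converted
to weekly using the average number of weeks in a month (365/12/7 = 4.345).
Missing responses are imputed with a missForest-style chained
random-forest imputer trained on the individuals' covariates and the
observed FPQ columns.  Item frequencies are finally aggregated (summed)
into the seven FPQ-source food groups that enter the diversity score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .errors import CohortError
from .model import FPQ_GROUPS

#: Average weeks per month used for monthly -> weekly frequency conversion.
WEEKS_PER_MONTH = 4.345


def to_weekly(frequency: float, unit: str, weeks_per_month: float = WEEKS_PER_MONTH) -> float:
    """Convert one frequency to occurrences per week.

    ``per_week`` values pass through; ``per_month`` values are divided by
    the average weeks-per-month constant.
    """
    if frequency < 0:
        raise ValueError(f"frequency must be >= 0, got {frequency}")
    if unit == "per_week":
        return float(frequency)
    if unit == "per_month":
        return float(frequency) / weeks_per_month
    raise ValueError(f"unknown frequency unit '{unit}'")


def fpq_to_weekly(fpq: pd.DataFrame, weeks_per_month: float = WEEKS_PER_MONTH) -> pd.DataFrame:
    """Vectorised weekly conversion of an FPQ long table (missing cells kept)."""
    if (fpq["frequency"].dropna() < 0).any():
        raise ValueError("negative FPQ frequency")
    out = fpq.copy()
    factor = np.where(out["unit"] == "per_month", 1.0 / weeks_per_month, 1.0)
    out["occurrences_per_week"] = out["frequency"] * factor
    return out.drop(columns=["frequency", "unit"])


def to_item_matrix(fpq_weekly: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long weekly FPQ table into an individuals x items matrix."""
    return fpq_weekly.pivot_table(
        index="individual_id",
        columns="item_id",
        values="occurrences_per_week",
        aggfunc="first",
        dropna=False,
    )


def impute_missing(
    fpq_matrix: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    max_iter: int = 10,
    n_estimators: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing FPQ cells with chained random-forest imputation.

    One random-forest regressor per incomplete column is fitted, in round
    robin, on all other columns (plus the numeric covariates), iterating
    until the imputer converges or ``max_iter`` rounds have run.  Observed
    cells are never modified; imputed values are clamped at zero; the whole
    procedure is deterministic for a given seed.

    Parameters
    ----------
    fpq_matrix:
        Individuals x items weekly-frequency matrix with NaN for missing.
    covariates:
        Optional complete numeric covariate frame aligned on individual_id,
        used as auxiliary predictors only.
    seed, max_iter, n_estimators:
        Imputer controls.

    Returns
    -------
    (completed matrix, boolean mask of imputed cells), both aligned with
    the input.

    Raises
    ------
    CohortError
        If an item column has no observed value at all.
    """
    mask = fpq_matrix.isna()
    all_missing = [c for c in fpq_matrix.columns if mask[c].all()]
    if all_missing:
        raise CohortError(f"FPQ item(s) with no observed responses: {all_missing}")
    if covariates is not None:
        cov = covariates.reindex(fpq_matrix.index)
        if cov.isna().any().any():
            raise CohortError("covariates must be complete for every individual")
        cov = cov.select_dtypes(include=[np.number])
    else:
        cov = pd.DataFrame(index=fpq_matrix.index)

    if not mask.any().any():
        return fpq_matrix.copy(), mask

    design = pd.concat([fpq_matrix, cov.add_prefix("cov__")], axis=1)
    imputer = IterativeImputer(
        estimator=RandomForestRegressor(
            n_estimators=n_estimators,
            max_features="sqrt",  # missForest's mtry
            min_samples_leaf=5,
            random_state=seed,
            n_jobs=1,
        ),
        max_iter=max_iter,
        random_state=seed,
        sample_posterior=False,
        keep_empty_features=True,
    )
    with warnings.catch_warnings():
        # hitting the iteration cap is normal missForest behaviour
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        filled = imputer.fit_transform(design.values)
    completed = pd.DataFrame(
        filled[:, : fpq_matrix.shape[1]],
        index=fpq_matrix.index,
        columns=fpq_matrix.columns,
    ).clip(lower=0.0)
    completed = completed.where(mask, fpq_matrix)  # observed cells untouched
    return completed, mask


def aggregate_to_groups(
    item_matrix: pd.DataFrame, item_map: pd.DataFrame
) -> pd.DataFrame:
    """Sum item weekly frequencies into the 7 FPQ-source group frequencies.

    ``item_map`` has columns ``item_id, group_id``; items mapping to groups
    outside the 7 FPQ groups (or absent from the map) are dropped.  Every
    individual gets all 7 groups, zero-filled.

    Returns a tidy frame ``individual_id, group_id, occurrences_per_week``.
    """
    lookup = item_map.set_index("item_id")["group_id"]
    long = item_matrix.stack().rename("occurrences_per_week").reset_index()
    long.columns = ["individual_id", "item_id", "occurrences_per_week"]
    long["group_id"] = long["item_id"].map(lookup)
    long = long[long["group_id"].isin(FPQ_GROUPS)]
    grid = pd.MultiIndex.from_product(
        [item_matrix.index, list(FPQ_GROUPS)], names=["individual_id", "group_id"]
    )
    weekly = (
        long.groupby(["individual_id", "group_id"])["occurrences_per_week"]
        .sum()
        .reindex(grid, fill_value=0.0)
        .reset_index()
    )
    return weekly
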