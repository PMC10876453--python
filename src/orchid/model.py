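"""Domain types, scoring configuration and tabular IO for dietary-survey data.

The scoring model rates consumption *occurrences* of 20 canonical food
groups.  Thirteen groups are observed through repeated 24-h dietary recalls
(foods eaten on a daily basis: vegetables, fruits, dairy...), the remaining
seven through a food propensity questionnaire, FPQ (foods eaten weekly or
less: fish, legumes, nuts...).  Per-group scoring parameters (standard
portion, rating type, weight, threshold) live in an editable YAML
configuration; the defaults shipped with the package are a documented
approximation of the expert-panel values, which are not published in full.

All tabular inputs are plain CSV files read into pandas DataFrames with
row-level validation; invalid rows raise :class:`~orchid.errors.SchemaError`
naming the offending row.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, field_validator, model_validator

from .errors import ConfigError, SchemaError

#: Sentinel group for foods that do not enter the score (water, spices, sauces...).
EXCLUDED = "EXCLUDED"

#: The 13 groups scored from the three 24-h recalls (daily-consumption foods).
RECALL_GROUPS = (
    "meat_excluding_poultry",
    "cooked_ham",
    "deli_meats_excluding_cooked_ham",
    "milk_and_fresh_dairy_products",
    "cheese",
    "refined_starches_and_potatoes",
    "vegetables",
    "fruits",
    "oils",
    "butter_margarine_and_fresh_cream",
    "salted_aperitif_products",
    "sweetened_products",
    "sweetened_beverages",
)

#: The 7 groups scored from FPQ weekly frequencies (infrequently eaten foods).
FPQ_GROUPS = (
    "poultry",
    "eggs",
    "fatty_fish",
    "lean_fish_and_shellfish",
    "legumes",
    "nuts",
    "wholemeal_or_semi_wholemeal_products",
)

ALL_GROUPS = RECALL_GROUPS + FPQ_GROUPS


class FoodGroupConfig(BaseModel):
    """Scoring parameters for one of the 20 canonical food groups.

    Attributes
    ----------
    group_id:
        Canonical lower-snake-case identifier (stable join key).
    standard_portion_g:
        Reference serving mass in grams; half of it is the daily gate below
        which recall declarations of the group are ignored.
    source:
        ``recall`` for the 13 daily groups, ``fpq`` for the 7 weekly groups.
    rating:
        ``positive`` — points = occurrences x weight (encouraged groups);
        ``threshold`` — points = occurrences up to the threshold, then
        (occurrences - threshold) x weight (discouraged beyond moderation).
    weight:
        Dimensionless points per occurrence (per excess occurrence for
        threshold groups, where it is typically negative).
    threshold:
        Occurrence count up to which a threshold-rated group earns one point
        per occurrence.  Required iff ``rating == "threshold"``.
    """

    group_id: str
    label: str
    standard_portion_g: float
    source: Literal["recall", "fpq"]
    rating: Literal["positive", "threshold"]
    weight: float
    threshold: Optional[int] = None

    @field_validator("standard_portion_g")
    @classmethod
    def _portion_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("standard_portion_g must be > 0")
        return v

    @model_validator(mode="after")
    def _threshold_consistency(self) -> "FoodGroupConfig":
        if self.rating == "threshold":
            if self.threshold is None:
                raise ValueError(
                    f"group '{self.group_id}': rating=threshold requires a threshold"
                )
            if self.threshold < 0:
                raise ValueError(f"group '{self.group_id}': threshold must be >= 0")
        return self


def validate_group_configs(configs: list[FoodGroupConfig]) -> None:
    """Check the cross-group invariants of a complete 20-group configuration."""
    ids = [c.group_id for c in configs]
    dupes = {g for g in ids if ids.count(g) > 1}
    if dupes:
        raise ConfigError(f"duplicate group_id(s): {sorted(dupes)}")
    missing = set(ALL_GROUPS) - set(ids)
    if missing:
        raise ConfigError(f"missing group(s): {sorted(missing)}")
    extra = set(ids) - set(ALL_GROUPS)
    if extra:
        raise ConfigError(f"unknown group(s): {sorted(extra)}")
    for c in configs:
        canonical = "recall" if c.group_id in RECALL_GROUPS else "fpq"
        if c.source != canonical:
            raise ConfigError(
                f"group '{c.group_id}' must have source={canonical}, got {c.source}"
            )
        if c.source == "fpq" and c.rating != "positive":
            raise ConfigError(
                f"fpq group '{c.group_id}' must use the positive rating"
            )


def load_group_config(path: str | Path) -> list[FoodGroupConfig]:
    """Load and validate a 20-group scoring configuration from YAML.

    The file holds a ``groups:`` mapping of group_id to
    ``{label, portion_g, source, rating, weight[, threshold]}``.

    Raises
    ------
    ConfigError
        On any invariant violation, naming the offending group.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "groups" not in raw:
        raise ConfigError(f"{path}: expected a top-level 'groups' mapping")
    configs = []
    for gid, block in raw["groups"].items():
        if not isinstance(block, dict):
            raise ConfigError(f"group '{gid}': expected a mapping of parameters")
        try:
            configs.append(
                FoodGroupConfig(
                    group_id=gid,
                    label=block.get("label", gid),
                    standard_portion_g=block.get("portion_g", 0),
                    source=block.get("source", ""),
                    rating=block.get("rating", ""),
                    weight=block.get("weight", 0.0),
                    threshold=block.get("threshold"),
                )
            )
        except ValueError as exc:
            raise ConfigError(f"group '{gid}': {exc}") from exc
    validate_group_configs(configs)
    return configs


def default_group_config() -> list[FoodGroupConfig]:
    """The packaged default scoring configuration (documented approximation)."""
    ref = resources.files("orchid.data") / "default_groups.yaml"
    with resources.as_file(ref) as path:
        return load_group_config(path)


def config_by_id(configs: list[FoodGroupConfig]) -> dict[str, FoodGroupConfig]:
    return {c.group_id: c for c in configs}


# ---------------------------------------------------------------------------
# Tabular readers.  Row numbers in error messages are 1-based data rows
# (header excluded), matching what a user sees in a spreadsheet minus 1.
# ---------------------------------------------------------------------------

_RECALL_COLUMNS = ["individual_id", "day", "food_code", "grams", "is_solid", "is_complex_dish"]


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    return series.astype(str).str.strip().str.lower().map(mapping).fillna(False).astype(bool)


def load_recalls(path: str | Path) -> pd.DataFrame:
    """Read 24-h recall food declarations.

    Expected columns: ``individual_id, day, food_code, grams, is_solid,
    is_complex_dish``; extra columns (e.g. ``energy_kcal``) pass through.
    """
    df = pd.read_csv(path)
    _require_columns(df, _RECALL_COLUMNS, path)
    if len(df) == 0:
        return df
    df = df.copy()
    df["grams"] = pd.to_numeric(df["grams"], errors="coerce")
    bad = df.index[df["grams"].isna() | (df["grams"] < 0)]
    if len(bad):
        row = int(bad[0]) + 1
        raise SchemaError(f"{path}: row {row}: grams must be a number >= 0")
    df["day"] = pd.to_numeric(df["day"], errors="coerce")
    bad = df.index[df["day"].isna() | (df["day"] < 1) | (df["day"] % 1 != 0)]
    if len(bad):
        row = int(bad[0]) + 1
        raise SchemaError(f"{path}: row {row}: day must be a positive integer")
    df["day"] = df["day"].astype(int)
    df["is_solid"] = _as_bool(df["is_solid"])
    df["is_complex_dish"] = _as_bool(df["is_complex_dish"])
    return df


def load_mapping(path: str | Path) -> pd.DataFrame:
    """Read the food_code -> group_id mapping (group_id may be EXCLUDED)."""
    df = pd.read_csv(path)
    _require_columns(df, ["food_code", "group_id"], path)
    if df["food_code"].duplicated().any():
        dup = df.loc[df["food_code"].duplicated(), "food_code"].iloc[0]
        raise SchemaError(f"{path}: food_code '{dup}' maps to more than one target")
    legal = set(ALL_GROUPS) | {EXCLUDED}
    bad = df.index[~df["group_id"].isin(legal)]
    if len(bad):
        row = int(bad[0]) + 1
        raise SchemaError(
            f"{path}: row {row}: unknown group_id '{df.loc[bad[0], 'group_id']}'"
        )
    return df


def load_recipes(path: str | Path) -> pd.DataFrame:
    """Read recipes for complex dishes: one row per (dish_code, ingredient)."""
    df = pd.read_csv(path)
    _require_columns(df, ["dish_code", "food_code", "grams"], path)
    if len(df) == 0:
        return df
    df = df.copy()
    df["grams"] = pd.to_numeric(df["grams"], errors="coerce")
    bad = df.index[df["grams"].isna() | (df["grams"] <= 0)]
    if len(bad):
        row = int(bad[0]) + 1
        raise SchemaError(f"{path}: row {row}: ingredient grams must be > 0")
    return df


def load_fpq(path: str | Path) -> pd.DataFrame:
    """Read FPQ responses: ``individual_id, item_id, frequency, unit``.

    Empty frequency cells are missing responses (kept as NaN, later imputed).
    ``unit`` is ``per_month`` or ``per_week``.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["individual_id", "item_id", "frequency", "unit"], path)
    if len(df) == 0:
        return df
    df = df.copy()
    df["frequency"] = pd.to_numeric(df["frequency"], errors="coerce")
    raw = pd.read_csv(path, dtype=str)["frequency"]
    # a non-empty cell that failed numeric conversion is a parse error, not missing
    bad = df.index[df["frequency"].isna() & raw.notna() & (raw.str.strip() != "")]
    if len(bad):
        row = int(bad[0]) + 1
        raise SchemaError(f"{path}: row {row}: frequency is not a number")
    bad = df.index[df["frequency"] < 0]
    if len(bad):
        row = int(bad[0]) + 1
        raise SchemaError(f"{path}: row {row}: frequency must be >= 0")
    bad = df.index[~df["unit"].isin(["per_month", "per_week"])]
    if len(bad):
        row = int(bad[0]) + 1
        raise SchemaError(f"{path}: row {row}: unknown unit '{df.loc[bad[0], 'unit']}'")
    return df


def load_nutrients(path: str | Path) -> pd.DataFrame:
    """Read per-day nutrient intakes (wide: individual_id, day, one column per nutrient)."""
    df = pd.read_csv(path)
    _require_columns(df, ["individual_id", "day"], path)
    value_cols = [c for c in df.columns if c not in ("individual_id", "day")]
    for col in value_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 0)]
        if len(bad):
            row = int(bad[0]) + 1
            raise SchemaError(f"{path}: row {row}: {col} must be a number >= 0")
        df[col] = vals
    return df


def load_reference_table(path: str | Path, kind: Literal["mar", "pandiet"]) -> pd.DataFrame:
    """Read a nutrient reference table.

    MAR tables have columns ``nutrient_id, sex, age_band, rda`` (rda > 0);
    PANDiet tables have ``nutrient_id, sex, age_band, ref, direction`` with
    direction in {at_least, at_most} and each nutrient assigned to exactly
    one direction.
    """
    df = pd.read_csv(path)
    if kind == "mar":
        _require_columns(df, ["nutrient_id", "sex", "age_band", "rda"], path)
        if (df["rda"] <= 0).any():
            row = int(df.index[df["rda"] <= 0][0]) + 1
            raise SchemaError(f"{path}: row {row}: rda must be > 0")
    else:
        _require_columns(df, ["nutrient_id", "sex", "age_band", "ref", "direction"], path)
        bad = df.index[~df["direction"].isin(["at_least", "at_most"])]
        if len(bad):
            row = int(bad[0]) + 1
            raise SchemaError(f"{path}: row {row}: direction must be at_least or at_most")
        ndir = df.groupby("nutrient_id")["direction"].nunique()
        mixed = ndir.index[ndir > 1].tolist()
        if mixed:
            raise SchemaError(f"{path}: nutrient(s) {mixed} assigned to both directions")
    return df


def default_reference_table(kind: Literal["mar", "pandiet"]) -> pd.DataFrame:
    """Packaged example reference tables (synthetic values, for demos/tests)."""
    name = "mar_references_example.csv" if kind == "mar" else "pandiet_references_example.csv"
    ref = resources.files("orchid.data") / name
    with resources.as_file(ref) as path:
        return load_reference_table(path, kind)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any orchid table back to CSV (inverse of the loaders)."""
    df.to_csv(path, index=False)
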