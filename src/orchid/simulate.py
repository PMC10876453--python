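"""Seeded synthetic dietary-survey cohorts for end-to-end testing.

The generator emulates the structure of a national food-consumption survey
for older adults: three non-consecutive 24-h recalls per individual, a
~60-item food propensity questionnaire with missing responses, per-day
nutrient intakes derived from food-group consumption, socio-demographic
covariates and sampling weights.

One latent *healthiness* dimension ``h ~ N(0,1)`` per individual drives
everything: daily food-group declaration counts are Poisson with log-rate
``log(base_rate) + loading * h`` (positive loadings for fruits, vegetables,
wholemeal...; negative for sweets, processed meat...), per-declaration
grams are log-normal around the group's standard portion, FPQ frequencies
track the same rates with noise, nutrient intakes follow a per-group
nutrient-density matrix, and covariates (education, smoking, physical
activity, BMI) load on ``h`` in the directions reported for diet quality.

Everything is reproducible bitwise from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import CohortError
from .model import ALL_GROUPS, EXCLUDED, FPQ_GROUPS, RECALL_GROUPS, default_group_config

# ---------------------------------------------------------------------------
# Default simulation parameters (the study conditions of the generator)
# ---------------------------------------------------------------------------

#: (daily declaration rate at h=0, healthiness loading) per food group.
DEFAULT_GROUP_PARAMS: dict[str, tuple[float, float]] = {
    "meat_excluding_poultry": (1.0, -0.2),
    "cooked_ham": (0.25, 0.0),
    "deli_meats_excluding_cooked_ham": (0.3, -0.3),
    "milk_and_fresh_dairy_products": (1.0, 0.1),
    "cheese": (0.8, 0.0),
    "refined_starches_and_potatoes": (1.5, -0.1),
    "vegetables": (1.5, 0.4),
    "fruits": (1.5, 0.4),
    "oils": (1.0, 0.1),
    "butter_margarine_and_fresh_cream": (1.0, -0.2),
    "salted_aperitif_products": (0.2, -0.3),
    "sweetened_products": (1.0, -0.4),
    "sweetened_beverages": (0.3, -0.5),
    "poultry": (0.15, 0.1),
    "eggs": (0.2, 0.0),
    "fatty_fish": (0.1, 0.3),
    "lean_fish_and_shellfish": (0.12, 0.3),
    "legumes": (0.12, 0.3),
    "nuts": (0.15, 0.3),
    "wholemeal_or_semi_wholemeal_products": (0.3, 0.5),
}

#: Foods outside the score (water, coffee, condiment base): daily rate, loading 0.
EXCLUDED_RATE = 2.0
EXCLUDED_GRAMS = 200.0

#: Energy density, kcal per 100 g, per group (EXCLUDED last).
ENERGY_DENSITY: dict[str, float] = {
    "meat_excluding_poultry": 200,
    "cooked_ham": 120,
    "deli_meats_excluding_cooked_ham": 320,
    "milk_and_fresh_dairy_products": 70,
    "cheese": 370,
    "refined_starches_and_potatoes": 130,
    "vegetables": 30,
    "fruits": 55,
    "oils": 880,
    "butter_margarine_and_fresh_cream": 720,
    "salted_aperitif_products": 500,
    "sweetened_products": 430,
    "sweetened_beverages": 40,
    "poultry": 150,
    "eggs": 145,
    "fatty_fish": 190,
    "lean_fish_and_shellfish": 100,
    "legumes": 95,
    "nuts": 620,
    "wholemeal_or_semi_wholemeal_products": 250,
    EXCLUDED: 1,
}

AT_LEAST_NUTRIENTS = (
    "protein_g", "fiber_g", "alpha_linolenic_g", "vitamin_a_ug", "thiamin_mg",
    "riboflavin_mg", "niacin_mg", "vitamin_b6_mg", "folate_ug", "vitamin_b12_ug",
    "vitamin_c_mg", "vitamin_d_ug", "vitamin_e_mg", "calcium_mg", "magnesium_mg",
    "iron_mg", "zinc_mg", "potassium_mg", "copper_mg", "selenium_ug",
    "iodine_ug", "phosphorus_mg", "manganese_mg",
)
AT_MOST_NUTRIENTS = ("sodium_mg", "free_sugars_g", "saturated_fat_g", "cholesterol_mg")
ALL_NUTRIENTS = AT_LEAST_NUTRIENTS + AT_MOST_NUTRIENTS
#: The 22 nutrients entering the MAR (adequacy nutrients minus ALA).
MAR_NUTRIENTS = tuple(n for n in AT_LEAST_NUTRIENTS if n != "alpha_linolenic_g")

# Explicit macronutrient densities (per 100 g); groups not listed get 0.
_MACRO_DENSITY: dict[str, dict[str, float]] = {
    "protein_g": {
        "meat_excluding_poultry": 20, "poultry": 22, "cooked_ham": 18,
        "deli_meats_excluding_cooked_ham": 15, "fatty_fish": 20,
        "lean_fish_and_shellfish": 22, "eggs": 12,
        "milk_and_fresh_dairy_products": 4, "cheese": 25, "legumes": 8,
        "nuts": 20, "wholemeal_or_semi_wholemeal_products": 8,
        "refined_starches_and_potatoes": 3, "vegetables": 2, "fruits": 0.7,
    },
    "fiber_g": {
        "vegetables": 3, "fruits": 2.5, "wholemeal_or_semi_wholemeal_products": 7,
        "legumes": 6, "nuts": 7, "refined_starches_and_potatoes": 1.5,
    },
    "alpha_linolenic_g": {
        "oils": 8, "nuts": 8, "fatty_fish": 2.5, "butter_margarine_and_fresh_cream": 0.5,
    },
    "free_sugars_g": {
        "sweetened_products": 40, "sweetened_beverages": 10,
        "milk_and_fresh_dairy_products": 5, "salted_aperitif_products": 2,
    },
    "saturated_fat_g": {
        "butter_margarine_and_fresh_cream": 50, "cheese": 18,
        "deli_meats_excluding_cooked_ham": 12, "meat_excluding_poultry": 6,
        "sweetened_products": 10, "oils": 8, "nuts": 6, "salted_aperitif_products": 8,
        "cooked_ham": 3, "milk_and_fresh_dairy_products": 2,
    },
    "sodium_mg": {
        "deli_meats_excluding_cooked_ham": 1000, "cooked_ham": 900,
        "salted_aperitif_products": 1500, "cheese": 600,
        "refined_starches_and_potatoes": 250,
        "wholemeal_or_semi_wholemeal_products": 300, "sweetened_products": 120,
        "meat_excluding_poultry": 70, "vegetables": 30,
    },
    "cholesterol_mg": {
        "eggs": 400, "butter_margarine_and_fresh_cream": 200,
        "meat_excluding_poultry": 80, "deli_meats_excluding_cooked_ham": 90,
        "cheese": 90, "fatty_fish": 60, "lean_fish_and_shellfish": 60,
        "poultry": 80, "cooked_ham": 50,
    },
}

#: Micronutrient richness multiplier per group (nutrient-dense foods high).
_RICHNESS: dict[str, float] = {
    "vegetables": 1.5, "fruits": 1.2, "wholemeal_or_semi_wholemeal_products": 1.5,
    "legumes": 1.5, "nuts": 1.3, "fatty_fish": 1.4, "lean_fish_and_shellfish": 1.4,
    "meat_excluding_poultry": 1.2, "poultry": 1.2, "eggs": 1.2,
    "milk_and_fresh_dairy_products": 1.0, "cheese": 1.0, "cooked_ham": 0.8,
    "deli_meats_excluding_cooked_ham": 0.8, "refined_starches_and_potatoes": 0.5,
    "oils": 0.1, "butter_margarine_and_fresh_cream": 0.2,
    "sweetened_products": 0.2, "sweetened_beverages": 0.05,
    "salted_aperitif_products": 0.3, EXCLUDED: 0.0,
}

#: Per-100-g unit scale of each generic micronutrient (sets realistic magnitudes).
_MICRO_UNIT: dict[str, float] = {
    "vitamin_a_ug": 60, "thiamin_mg": 0.1, "riboflavin_mg": 0.12, "niacin_mg": 1.2,
    "vitamin_b6_mg": 0.12, "folate_ug": 25, "vitamin_b12_ug": 0.3, "vitamin_c_mg": 8,
    "vitamin_d_ug": 0.3, "vitamin_e_mg": 1.0, "calcium_mg": 80, "magnesium_mg": 25,
    "iron_mg": 1.0, "zinc_mg": 0.8, "potassium_mg": 250, "copper_mg": 0.12,
    "selenium_ug": 5, "iodine_ug": 10, "phosphorus_mg": 90, "manganese_mg": 0.25,
}

SIM_GROUPS = list(ALL_GROUPS) + [EXCLUDED]


def default_density_matrix() -> pd.DataFrame:
    """Nutrient density per 100 g: rows = groups (incl. EXCLUDED), columns =
    27 nutrients + energy_kcal.  Deterministic construction."""
    dens = pd.DataFrame(0.0, index=SIM_GROUPS, columns=["energy_kcal", *ALL_NUTRIENTS])
    for g, e in ENERGY_DENSITY.items():
        dens.loc[g, "energy_kcal"] = e
    for nutrient, per_group in _MACRO_DENSITY.items():
        for g, v in per_group.items():
            dens.loc[g, nutrient] = v
    for nutrient, unit in _MICRO_UNIT.items():
        for g in SIM_GROUPS:
            dens.loc[g, nutrient] = unit * _RICHNESS[g]
    return dens


class GroupSim(BaseModel):
    """Per-group generator parameters."""

    base_rate: float = Field(ge=0)  # expected declarations per day at h = 0
    loading: float  # log-rate change per unit of latent healthiness


def _default_group_params() -> dict[str, GroupSim]:
    return {
        g: GroupSim(base_rate=r, loading=l) for g, (r, l) in DEFAULT_GROUP_PARAMS.items()
    }


class SyntheticCohortSpec(BaseModel):
    """Distributions and effect sizes driving the cohort generator."""

    n_individuals: int = Field(gt=0)
    n_days: int = Field(default=3, gt=0)
    seed: int = 0
    group_params: dict[str, GroupSim] = Field(default_factory=_default_group_params)
    grams_sigma: float = Field(default=0.35, ge=0)  # log-normal scale of grams
    dish_fraction: float = Field(default=0.05, ge=0, le=1)
    items_per_group: int = Field(default=8, gt=0)
    fpq_missing_prob: float = Field(default=0.1, ge=0, le=1)
    fpq_noise_sigma: float = Field(default=0.3, ge=0)
    nutrient_noise_frac: float = Field(default=0.1, ge=0)
    energy_neutral: bool = False

    def validate_groups(self) -> None:
        missing = set(ALL_GROUPS) - set(self.group_params)
        if missing:
            raise CohortError(f"group_params missing group(s): {sorted(missing)}")


@dataclass
class CohortBundle:
    """All tables of one synthetic cohort plus its hidden ground truth."""

    spec: SyntheticCohortSpec
    recalls: pd.DataFrame
    mapping: pd.DataFrame
    recipes: pd.DataFrame
    fpq: pd.DataFrame
    fpq_item_map: pd.DataFrame
    nutrients: pd.DataFrame
    covariates: pd.DataFrame
    design: pd.DataFrame
    truth: pd.DataFrame = field(repr=False, default=None)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "recalls": self.recalls,
            "mapping": self.mapping,
            "recipes": self.recipes,
            "fpq": self.fpq,
            "fpq_item_map": self.fpq_item_map,
            "nutrients": self.nutrients,
            "covariates": self.covariates,
            "design": self.design,
        }


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(spec: SyntheticCohortSpec) -> CohortBundle:
    """Generate a complete cohort bundle from a spec (bitwise seeded)."""
    spec.validate_groups()
    rng = np.random.default_rng(spec.seed)
    n, days = spec.n_individuals, spec.n_days
    ids = np.array([f"ind_{i:05d}" for i in range(n)])
    h = rng.standard_normal(n)

    portions = {c.group_id: c.standard_portion_g for c in default_group_config()}
    portions[EXCLUDED] = EXCLUDED_GRAMS
    dens = default_density_matrix()

    # --- recall declarations, group by group (fixed order => determinism) ---
    rows_ind, rows_day, rows_group, rows_grams = [], [], [], []
    for g in SIM_GROUPS:
        if g == EXCLUDED:
            rate = np.full(n, EXCLUDED_RATE)
        else:
            p = spec.group_params[g]
            rate = p.base_rate * np.exp(p.loading * h)
        counts = rng.poisson(np.repeat(rate, days))  # (n*days,)
        total = int(counts.sum())
        if total == 0:
            continue
        flat = np.repeat(np.arange(n * days), counts)
        grams = rng.lognormal(np.log(portions[g] * 0.9), spec.grams_sigma, total)
        rows_ind.append(flat // days)
        rows_day.append(flat % days + 1)
        rows_group.append(np.full(total, g))
        rows_grams.append(grams)
    ind_idx = np.concatenate(rows_ind)
    decl = pd.DataFrame(
        {
            "individual_id": ids[ind_idx],
            "day": np.concatenate(rows_day),
            "group_id": np.concatenate(rows_group),
            "grams": np.concatenate(rows_grams),
        }
    )
    decl["_ind"] = ind_idx

    # --- per-day group grams -> nutrient intakes -------------------------
    day_grams = (
        decl.groupby(["_ind", "day", "group_id"], sort=True)["grams"].sum().unstack(fill_value=0.0)
    )
    day_grams = day_grams.reindex(columns=SIM_GROUPS, fill_value=0.0)
    grid = pd.MultiIndex.from_product([range(n), range(1, days + 1)], names=["_ind", "day"])
    day_grams = day_grams.reindex(grid, fill_value=0.0)
    intakes = day_grams.values @ dens.loc[SIM_GROUPS].values / 100.0
    noise = rng.standard_normal(intakes.shape) * spec.nutrient_noise_frac * intakes
    intakes = np.clip(intakes + noise, 0.0, None)
    nutrients = pd.DataFrame(intakes, index=grid, columns=dens.columns).reset_index()
    nutrients["individual_id"] = ids[nutrients["_ind"]]
    nutrients = nutrients[["individual_id", "day", *dens.columns]]

    if spec.energy_neutral:
        # pin each individual's mean energy to the cohort mean times noise
        # independent of everything else, so energy carries no diet signal
        mean_e = nutrients.groupby("individual_id", sort=True)["energy_kcal"].mean()
        target = float(mean_e.mean()) * rng.lognormal(0.0, 0.08, n)
        factor = pd.Series(target / mean_e.values, index=ids)
        scale = nutrients["individual_id"].map(factor).values
        cols = list(dens.columns)
        nutrients[cols] = nutrients[cols].values * scale[:, None]

    # --- food codes, energy per declaration, complex dishes --------------
    code_alt = np.arange(len(decl)) % 2
    decl["food_code"] = decl["group_id"] + "_" + code_alt.astype(str)
    decl["is_solid"] = ~decl["group_id"].isin(["sweetened_beverages", EXCLUDED])
    decl["energy_kcal"] = (
        decl["grams"] * decl["group_id"].map(dens["energy_kcal"]).values / 100.0
    )
    if spec.energy_neutral:
        decl["energy_kcal"] *= decl["individual_id"].map(factor).values
    decl["is_complex_dish"] = False

    if spec.dish_fraction > 0:
        eligible = decl["group_id"].isin(RECALL_GROUPS).values
        as_dish = eligible & (rng.random(len(decl)) < spec.dish_fraction)
        sauce_density = 60.0  # kcal/100 g of the generic sauce filler
        dish_codes = "dish__" + decl.loc[as_dish, "food_code"]
        dish_grams = decl.loc[as_dish, "grams"] / 0.7
        decl.loc[as_dish, "is_complex_dish"] = True
        decl.loc[as_dish, "energy_kcal"] = dish_grams * (
            0.7 * decl.loc[as_dish, "group_id"].map(dens["energy_kcal"]).values
            + 0.3 * sauce_density
        ) / 100.0
        decl.loc[as_dish, "grams"] = dish_grams
        base_codes = sorted(dish_codes.str.removeprefix("dish__").unique())
        decl.loc[as_dish, "food_code"] = dish_codes
        recipes = pd.DataFrame(
            [
                row
                for code in base_codes
                for row in (
                    {"dish_code": f"dish__{code}", "food_code": code, "grams": 70.0},
                    {"dish_code": f"dish__{code}", "food_code": "sauce_mix", "grams": 30.0},
                )
            ]
        )
    else:
        recipes = pd.DataFrame(columns=["dish_code", "food_code", "grams"])

    recalls = decl[
        ["individual_id", "day", "food_code", "grams", "is_solid", "is_complex_dish", "energy_kcal"]
    ].reset_index(drop=True)

    mapping = pd.DataFrame(
        [
            {"food_code": f"{g}_{k}", "group_id": g if g != EXCLUDED else EXCLUDED}
            for g in SIM_GROUPS
            for k in (0, 1)
        ]
        + [{"food_code": "sauce_mix", "group_id": EXCLUDED}]
    )

    # --- FPQ ---------------------------------------------------------------
    item_rows = []
    map_rows = []
    share = np.array([0.30] + [0.70 / (spec.items_per_group - 1)] * (spec.items_per_group - 1)) \
        if spec.items_per_group > 1 else np.array([1.0])
    for g in FPQ_GROUPS:
        p = spec.group_params[g]
        weekly = 7.0 * p.base_rate * np.exp(p.loading * h)
        for k in range(spec.items_per_group):
            item = f"{g}__item{k}"
            map_rows.append({"item_id": item, "group_id": g})
            noise = rng.lognormal(0.0, spec.fpq_noise_sigma, n)
            freq_week = weekly * share[k] * noise
            per_month = k % 2 == 1
            item_rows.append(
                pd.DataFrame(
                    {
                        "individual_id": ids,
                        "item_id": item,
                        "frequency": freq_week * (4.345 if per_month else 1.0),
                        "unit": "per_month" if per_month else "per_week",
                    }
                )
            )
    for extra in ("herbal_tea", "broth", "tap_water", "coffee"):
        map_rows.append({"item_id": extra, "group_id": EXCLUDED})
        item_rows.append(
            pd.DataFrame(
                {
                    "individual_id": ids,
                    "item_id": extra,
                    "frequency": rng.lognormal(np.log(5.0), 0.5, n),
                    "unit": "per_week",
                }
            )
        )
    fpq = pd.concat(item_rows, ignore_index=True)
    if spec.fpq_missing_prob > 0:
        holes = rng.random(len(fpq)) < spec.fpq_missing_prob
        fpq.loc[holes, "frequency"] = np.nan
    fpq_item_map = pd.DataFrame(map_rows)

    # --- covariates and design --------------------------------------------
    sex = np.where(rng.random(n) < 0.58, "F", "M")  # older cohorts skew female
    edu_latent = 0.5 * h + rng.standard_normal(n)
    education = pd.cut(
        edu_latent, [-np.inf, -0.4, 0.6, np.inf], labels=["primary", "secondary", "tertiary"]
    ).astype(str)
    smoking = np.where(rng.random(n) < _sigmoid(-1.5 - 0.5 * h), "current", "non_smoker")
    pa_latent = 0.4 * h + rng.standard_normal(n)
    activity = pd.cut(
        pa_latent, [-np.inf, -0.4, 0.6, np.inf], labels=["low", "moderate", "high"]
    ).astype(str)
    bmi = 27.0 - 1.2 * h + rng.standard_normal(n) * 3.5
    age = rng.integers(60, 80, n)
    covariates = pd.DataFrame(
        {
            "individual_id": ids,
            "sex": sex,
            "age": age,
            "age_band": "60+",
            "education": education,
            "smoking": smoking,
            "physical_activity": activity,
            "bmi": np.round(bmi, 1),
        }
    )
    design = pd.DataFrame(
        {"individual_id": ids, "weight": rng.lognormal(0.0, 0.3, n)}
    )

    rates = {
        f"rate_{g}": spec.group_params[g].base_rate * np.exp(spec.group_params[g].loading * h)
        for g in ALL_GROUPS
    }
    truth = pd.DataFrame({"individual_id": ids, "healthiness": h, **rates})

    return CohortBundle(
        spec=spec,
        recalls=recalls,
        mapping=mapping,
        recipes=recipes,
        fpq=fpq,
        fpq_item_map=fpq_item_map,
        nutrients=nutrients,
        covariates=covariates,
        design=design,
        truth=truth,
    )


def ground_truth(spec: SyntheticCohortSpec, cohort: CohortBundle) -> pd.DataFrame:
    """Latent healthiness and expected group rates of a generated cohort.

    Raises :class:`CohortError` if the cohort was not generated by ``spec``.
    """
    if cohort.spec != spec:
        raise CohortError("cohort was not generated by this spec")
    return cohort.truth.copy()
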