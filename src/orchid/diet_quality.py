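"""Diet-quality measures used to validate the diversity score.

* **SED** — solid energy density, kcal per 100 g: total energy of solid
  foods over their total mass, pooled across recall days.  A proxy of low
  nutritional quality (energy-dense, nutrient-poor diets score high).
* **MAR** — mean adequacy ratio: the mean over 22 key nutrients of the
  ratio of mean daily intake to the sex- and age-specific recommended
  dietary allowance (RDA), each ratio capped at 1, expressed in percent.
* **PANDiet** — probability-of-adequate-nutrient-intake score: for each of
  27 nutrients, the probability that the *usual* intake satisfies its
  reference, under a Gaussian model of the usual-intake mean (observed
  day-mean, standard error = between-day SD / sqrt(n days)).  Nutrients
  whose intake should exceed a lower reference form the adequacy sub-score,
  those that should stay below an upper reference the moderation sub-score;
  the PANDiet is the average of the two sub-scores, on a 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortError

#: When the observed between-day SD of a nutrient is zero, this fraction of
#: the reference value substitutes for it, avoiding degenerate 0/1
#: probabilities on constant toy intakes.
DEFAULT_VARIANCE_FLOOR = 0.10


def solid_energy_density(declarations: pd.DataFrame) -> float:
    """Pooled solid energy density in kcal per 100 g.

    Parameters
    ----------
    declarations:
        Food declarations with columns ``grams, is_solid, energy_kcal``
        (all recall days together; beverages are ignored).
    """
    solids = declarations[declarations["is_solid"]]
    grams = solids["grams"].sum()
    if grams <= 0:
        raise CohortError("no solid food with positive grams; SED undefined")
    return 100.0 * solids["energy_kcal"].sum() / grams


def mean_adequacy_ratio(
    mean_intakes: Mapping[str, float], rda: Mapping[str, float]
) -> float:
    """MAR in percent: 100 x mean over nutrients of min(intake/RDA, 1).

    Every nutrient in ``rda`` must be present in ``mean_intakes``.
    """
    ratios = []
    for nutrient, reference in rda.items():
        if nutrient not in mean_intakes:
            raise CohortError(f"missing intake for nutrient '{nutrient}'")
        if reference <= 0:
            raise CohortError(f"RDA for '{nutrient}' must be > 0")
        ratios.append(min(mean_intakes[nutrient] / reference, 1.0))
    if not ratios:
        raise CohortError("empty RDA table")
    return 100.0 * float(np.mean(ratios))


def probability_of_adequacy(
    day_values: np.ndarray | list[float],
    reference: float,
    direction: str,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> float:
    """Probability that the usual intake of one nutrient meets its reference.

    The usual-intake mean is modelled as Gaussian with mean the observed
    day-mean and standard error sd/sqrt(n); an observed sd of zero is
    replaced by ``variance_floor * |reference|``.
    """
    values = np.asarray(day_values, dtype=float)
    n = values.size
    if n < 2:
        raise CohortError("probability of adequacy needs at least 2 recall days")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0.0:
        sd = variance_floor * abs(reference)
    se = sd / np.sqrt(n)
    if se == 0.0:  # reference 0 and constant intakes: degenerate step
        p_above = 1.0 if mean > reference else (0.5 if mean == reference else 0.0)
    else:
        p_above = float(stats.norm.sf((reference - mean) / se))
    if direction == "at_least":
        return p_above
    if direction == "at_most":
        return 1.0 - p_above
    raise ValueError(f"unknown direction '{direction}'")


@dataclass(frozen=True)
class PANDietResult:
    adequacy: float
    moderation: float
    total: float


def pandiet(
    day_intakes: pd.DataFrame,
    references: pd.DataFrame,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> PANDietResult:
    """PANDiet sub-scores and total for one individual.

    Parameters
    ----------
    day_intakes:
        One row per recall day, one column per nutrient (n >= 2 rows).
    references:
        Columns ``nutrient_id, ref, direction`` (direction: at_least /
        at_most), one row per nutrient for this individual's sex/age band.
    """
    if len(day_intakes) < 2:
        raise CohortError("PANDiet needs at least 2 recall days")
    probs: dict[str, list[float]] = {"at_least": [], "at_most": []}
    for _, row in references.iterrows():
        nutrient = row["nutrient_id"]
        if nutrient not in day_intakes.columns:
            raise CohortError(f"missing intake for nutrient '{nutrient}'")
        pa = probability_of_adequacy(
            day_intakes[nutrient].values, row["ref"], row["direction"], variance_floor
        )
        probs[row["direction"]].append(pa)
    if not probs["at_least"] or not probs["at_most"]:
        raise CohortError("PANDiet needs nutrients in both directions")
    adequacy = 100.0 * float(np.mean(probs["at_least"]))
    moderation = 100.0 * float(np.mean(probs["at_most"]))
    return PANDietResult(adequacy, moderation, (adequacy + moderation) / 2.0)


def cohort_diet_quality(
    nutrients: pd.DataFrame,
    declarations: pd.DataFrame,
    covariates: pd.DataFrame,
    mar_references: pd.DataFrame,
    pandiet_references: pd.DataFrame,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> pd.DataFrame:
    """Per-individual SED, MAR and PANDiet for a whole cohort.

    Parameters
    ----------
    nutrients:
        Wide per-day intakes: ``individual_id, day, energy_kcal, <nutrients...>``.
    declarations:
        Recall declarations carrying ``energy_kcal`` (for the SED).
    covariates:
        Must carry ``individual_id, sex, age_band`` to select reference rows.
    mar_references, pandiet_references:
        Reference tables as read by :func:`orchid.model.load_reference_table`.
    """
    cov = covariates.set_index("individual_id")
    rows = []
    nutrient_cols = [c for c in nutrients.columns if c not in ("individual_id", "day")]
    for ind, day_df in nutrients.groupby("individual_id"):
        if ind not in cov.index:
            raise CohortError(f"individual '{ind}' missing from covariates")
        sex, band = cov.loc[ind, "sex"], cov.loc[ind, "age_band"]
        mar_ref = mar_references[
            (mar_references["sex"] == sex) & (mar_references["age_band"] == band)
        ]
        if len(mar_ref) == 0:
            raise CohortError(f"no MAR references for sex={sex}, age_band={band}")
        mean_intakes = day_df[nutrient_cols].mean()
        mar = mean_adequacy_ratio(
            mean_intakes.to_dict(), mar_ref.set_index("nutrient_id")["rda"].to_dict()
        )
        pd_ref = pandiet_references[
            (pandiet_references["sex"] == sex) & (pandiet_references["age_band"] == band)
        ]
        if len(pd_ref) == 0:
            raise CohortError(f"no PANDiet references for sex={sex}, age_band={band}")
        res = pandiet(day_df[nutrient_cols], pd_ref, variance_floor)
        decl = declarations[declarations["individual_id"] == ind]
        sed = solid_energy_density(decl)
        rows.append(
            {
                "individual_id": ind,
                "sed": sed,
                "mar": mar,
                "pandiet": res.total,
                "pandiet_adequacy": res.adequacy,
                "pandiet_moderation": res.moderation,
                "energy_kcal": day_df["energy_kcal"].mean(),
            }
        )
    return pd.DataFrame(rows)
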