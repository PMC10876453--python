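import pandas as pd
import pytest

from orchid.model import default_group_config
from orchid.pipeline import score_cohort
from orchid.simulate import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def configs():
    return default_group_config()


@pytest.fixture(scope="session")
def small_cohort():
    """Small complete cohort (no FPQ holes, so no imputation needed)."""
    spec = SyntheticCohortSpec(n_individuals=60, seed=7, fpq_missing_prob=0.0)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_scored(small_cohort, configs):
    b = small_cohort
    return score_cohort(
        b.recalls, b.recipes, b.mapping, b.fpq, b.fpq_item_map,
        b.covariates, configs, seed=7,
    )


def make_recalls(rows):
    """Build a recall declarations frame from (ind, day, code, grams) tuples."""
    return pd.DataFrame(
        [
            {
                "individual_id": ind,
                "day": day,
                "food_code": code,
                "grams": grams,
                "is_solid": True,
                "is_complex_dish": False,
            }
            for ind, day, code, grams in rows
        ]
    )
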