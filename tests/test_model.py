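"""Configuration and table-IO contracts."""

import copy

import pandas as pd
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from orchid.errors import ConfigError, SchemaError
from orchid.model import (
    ALL_GROUPS,
    FPQ_GROUPS,
    RECALL_GROUPS,
    load_fpq,
    load_group_config,
    load_mapping,
    load_recalls,
    load_recipes,
    validate_group_configs,
    write_table,
)

DEFAULT_YAML = None


def _default_raw():
    global DEFAULT_YAML
    if DEFAULT_YAML is None:
        from importlib import resources

        ref = resources.files("orchid.data") / "default_groups.yaml"
        DEFAULT_YAML = yaml.safe_load(ref.read_text())
    return copy.deepcopy(DEFAULT_YAML)


def _write(tmp_path, raw):
    p = tmp_path / "cfg.yaml"
    p.write_text(yaml.safe_dump(raw))
    return p


def test_default_config_has_20_groups_13_recall_7_fpq(configs):
    assert len(configs) == 20
    assert sum(c.source == "recall" for c in configs) == 13
    assert sum(c.source == "fpq" for c in configs) == 7
    assert {c.group_id for c in configs if c.source == "fpq"} == set(FPQ_GROUPS)
    assert all(c.rating == "positive" for c in configs if c.source == "fpq")
    assert all(c.standard_portion_g > 0 for c in configs)


def test_missing_group_is_named(tmp_path):
    raw = _default_raw()
    del raw["groups"]["fruits"]
    with pytest.raises(ConfigError, match="fruits"):
        load_group_config(_write(tmp_path, raw))


def test_threshold_required_for_threshold_rating(tmp_path):
    raw = _default_raw()
    del raw["groups"]["sweetened_products"]["threshold"]
    with pytest.raises(ConfigError, match="sweetened_products"):
        load_group_config(_write(tmp_path, raw))


def test_fpq_group_must_be_positive(tmp_path):
    raw = _default_raw()
    raw["groups"]["nuts"]["rating"] = "threshold"
    raw["groups"]["nuts"]["threshold"] = 2
    with pytest.raises(ConfigError, match="nuts"):
        load_group_config(_write(tmp_path, raw))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_accepted_configs_satisfy_invariants(tmp_path_factory, data):
    """Randomly corrupted configs either fail loudly or load as valid configs."""
    raw = _default_raw()
    gid = data.draw(st.sampled_from(list(ALL_GROUPS)))
    field = data.draw(st.sampled_from(["portion_g", "weight", "threshold", "rating", "source", None]))
    if field == "portion_g":
        raw["groups"][gid]["portion_g"] = data.draw(st.floats(-50, 500))
    elif field == "weight":
        raw["groups"][gid]["weight"] = data.draw(st.floats(-5, 5))
    elif field == "threshold":
        raw["groups"][gid]["threshold"] = data.draw(st.integers(-2, 6))
    elif field == "rating":
        raw["groups"][gid]["rating"] = data.draw(st.sampled_from(["positive", "threshold"]))
        raw["groups"][gid].setdefault("threshold", 1)
    elif field == "source":
        raw["groups"][gid]["source"] = data.draw(st.sampled_from(["recall", "fpq"]))
    path = tmp_path_factory.mktemp("cfg") / "cfg.yaml"
    path.write_text(yaml.safe_dump(raw))
    try:
        configs = load_group_config(path)
    except ConfigError:
        return
    validate_group_configs(configs)  # must hold for anything accepted
    for c in configs:
        assert c.standard_portion_g > 0
        if c.rating == "threshold":
            assert c.threshold is not None and c.threshold >= 0


def test_recalls_round_trip(tmp_path):
    df = pd.DataFrame(
        {
            "individual_id": ["a", "a", "b"],
            "day": [1, 2, 1],
            "food_code": ["vegetables_0", "fruits_1", "cheese_0"],
            "grams": [150.0, 80.0, 30.0],
            "is_solid": [True, True, True],
            "is_complex_dish": [False, False, False],
        }
    )
    p = tmp_path / "recalls.csv"
    write_table(df, p)
    back = load_recalls(p)
    pd.testing.assert_frame_equal(back, df)
    assert back.groupby("individual_id")["day"].nunique().to_dict() == {"a": 2, "b": 1}


def test_empty_file_with_header_is_empty_not_error(tmp_path):
    p = tmp_path / "recalls.csv"
    p.write_text("individual_id,day,food_code,grams,is_solid,is_complex_dish\n")
    assert len(load_recalls(p)) == 0


def test_negative_grams_names_row(tmp_path):
    p = tmp_path / "recalls.csv"
    p.write_text(
        "individual_id,day,food_code,grams,is_solid,is_complex_dish\n"
        "a,1,x,10,true,false\n"
        "a,1,y,-5,true,false\n"
    )
    with pytest.raises(SchemaError, match="row 2"):
        load_recalls(p)


def test_mapping_rejects_unknown_group_and_duplicates(tmp_path):
    p = tmp_path / "map.csv"
    p.write_text("food_code,group_id\nx,vegetables\nx,fruits\n")
    with pytest.raises(SchemaError, match="x"):
        load_mapping(p)
    p.write_text("food_code,group_id\nx,not_a_group\n")
    with pytest.raises(SchemaError, match="not_a_group"):
        load_mapping(p)


def test_fpq_loader_missing_cells_and_bad_unit(tmp_path):
    p = tmp_path / "fpq.csv"
    p.write_text(
        "individual_id,item_id,frequency,unit\na,i1,2,per_week\na,i2,,per_month\n"
    )
    df = load_fpq(p)
    assert df["frequency"].isna().sum() == 1
    p.write_text("individual_id,item_id,frequency,unit\na,i1,2,per_year\n")
    with pytest.raises(SchemaError, match="per_year"):
        load_fpq(p)


def test_recipes_require_positive_grams(tmp_path):
    p = tmp_path / "recipes.csv"
    p.write_text("dish_code,food_code,grams\nd,x,0\n")
    with pytest.raises(SchemaError, match="row 1"):
        load_recipes(p)
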