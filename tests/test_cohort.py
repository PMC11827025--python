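"""Food-security scoring, analytic-sample filters, and table I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from pandas.testing import assert_frame_equal

from usualintake.cohort import (
    SchemaError,
    build_analytic_sample,
    read_tables,
    score_child_food_security,
    score_food_security_column,
    validate_recalls,
    write_tables,
)


@pytest.mark.parametrize(
    "affirmed, category, binary",
    [
        (0, "high", "secure"),
        (1, "marginal", "secure"),
        (2, "low", "insecure"),
        (4, "low", "insecure"),
        (5, "very_low", "insecure"),
        (8, "very_low", "insecure"),
    ],
)
def test_child_scale_thresholds(affirmed, category, binary):
    st_ = score_child_food_security(affirmed)
    assert (st_.category, st_.binary) == (category, binary)


@pytest.mark.parametrize("bad", [-1, 9, 100])
def test_out_of_range_raw_score_rejected(bad):
    with pytest.raises(ValueError):
        score_child_food_security(bad)


@given(a=st.integers(0, 8), b=st.integers(0, 8))
@settings(max_examples=100, deadline=None)
def test_scoring_monotone_in_affirmations(a, b):
    """More affirmed items can never move a person from insecure to secure."""
    lo, hi = sorted((a, b))
    order = {"high": 0, "marginal": 1, "low": 2, "very_low": 3}
    s_lo, s_hi = score_child_food_security(lo), score_child_food_security(hi)
    assert order[s_hi.category] >= order[s_lo.category]
    assert not (s_lo.binary == "insecure" and s_hi.binary == "secure")


def test_missing_scores_yield_missing_status():
    out = score_food_security_column(pd.Series([0, np.nan, 7]))
    assert out["food_security"].tolist()[0] == "secure"
    assert pd.isna(out["food_security"].iloc[1])
    assert out["food_security"].iloc[2] == "insecure"


def _toy_tables():
    persons = pd.DataFrame(
        {
            "person_id": [1, 2, 3, 4, 5],
            "age_y": [15, 16, 13, 17, 14],  # person 3 too young
            "sex": ["female"] * 5,
            "stratum": 1,
            "psu": [1, 2, 1, 2, 1],
            "weight_day1_diet": 1.0,
            # persons 2 and 4 missing the food-security raw score
            "hfssm_child_affirmed": [0, np.nan, 2, np.nan, 6],
        }
    )
    recalls = pd.DataFrame(
        {
            "person_id": [1, 1, 3, 4, 5],
            "day": [1, 2, 1, 1, 2],  # person 5 has only a day-2 recall
            "weekend": False,
            "sequence": [1, 2, 1, 1, 2],
            "choline": [250.0, 300.0, 200.0, 220.0, 260.0],
        }
    )
    return persons, recalls


class TestAnalyticSample:
    def test_stated_filters_and_log(self):
        persons, recalls = _toy_tables()
        p, r, log = build_analytic_sample(persons, recalls)
        # retained: 1 (complete) and 5 (day-2-only recall still counts)
        assert sorted(p["person_id"]) == [1, 5]
        assert log["excluded_missing_food_security"] == 2
        assert log["excluded_age"] == 1
        assert log["retained_persons"] == 2
        assert set(r["person_id"]) == {1, 5}

    def test_day2_only_person_retained(self):
        persons, recalls = _toy_tables()
        p, _, _ = build_analytic_sample(persons, recalls)
        assert 5 in set(p["person_id"])

    def test_row_order_invariance(self):
        persons, recalls = _toy_tables()
        base, _, _ = build_analytic_sample(persons, recalls)
        shuffled = persons.sample(frac=1, random_state=7).reset_index(drop=True)
        perm, _, _ = build_analytic_sample(shuffled, recalls)
        assert sorted(base["person_id"]) == sorted(perm["person_id"])

    def test_dsmq_requirement(self):
        persons, recalls = _toy_tables()
        persons["supp_choline"] = [0.0, 10.0, 0.0, 0.0, np.nan]
        p, _, log = build_analytic_sample(persons, recalls, require_dsmq=True)
        assert sorted(p["person_id"]) == [1]  # person 5 lacks supplement info
        assert log["excluded_incomplete_dsmq"] == 1

    def test_dsmq_without_columns_raises(self):
        persons, recalls = _toy_tables()
        with pytest.raises(SchemaError, match="supp"):
            build_analytic_sample(persons, recalls, require_dsmq=True)

    def test_empty_sample_warns(self):
        persons, recalls = _toy_tables()
        persons["age_y"] = 13
        with pytest.warns(RuntimeWarning, match="empty"):
            build_analytic_sample(persons, recalls)


class TestIO:
    def test_roundtrip(self, tmp_path, small_cohort):
        paths = write_tables(tmp_path, small_cohort.persons, small_cohort.recalls)
        tables = read_tables(paths["persons"], paths["recalls"])
        assert_frame_equal(
            tables["persons"].reset_index(drop=True),
            small_cohort.persons.reset_index(drop=True),
            check_dtype=False,
        )

    def test_negative_nutrient_named_in_error(self, tmp_path, small_cohort):
        rec = small_cohort.recalls.copy()
        rec.loc[3, "choline"] = -5.0
        with pytest.raises(SchemaError, match="choline.*row 3"):
            validate_recalls(small_cohort.persons, rec)

    def test_nhanes_alias_mapping(self, tmp_path):
        persons = pd.DataFrame(
            {
                "SEQN": [1, 2, 3],
                "RIDAGEYR": [14, 15, 16],
                "RIAGENDR": ["female", "male", "female"],
                "SDMVSTRA": [1, 1, 2],
                "SDMVPSU": [1, 2, 1],
                "WTDRD1": [1.0, 2.0, 1.5],
                "FSD652CW": [0, 3, 1],
            }
        )
        recalls = pd.DataFrame(
            {
                "SEQN": [1, 2, 3],
                "day": 1,
                "weekend": False,
                "sequence": 1,
                "choline": [200.0, 250.0, 300.0],
            }
        )
        pp, rp = tmp_path / "p.csv", tmp_path / "r.csv"
        persons.to_csv(pp, index=False)
        recalls.to_csv(rp, index=False)
        tables = read_tables(pp, rp, aliases=True)
        assert "person_id" in tables["persons"].columns
        assert "hfssm_child_affirmed" in tables["persons"].columns
        assert tables["persons"]["weight_day1_diet"].tolist() == [1.0, 2.0, 1.5]

    def test_missing_columns_hard_error(self, tmp_path):
        pd.DataFrame({"person_id": [1]}).to_csv(tmp_path / "p.csv", index=False)
        pd.DataFrame({"person_id": [1]}).to_csv(tmp_path / "r.csv", index=False)
        with pytest.raises(SchemaError, match="missing columns"):
            read_tables(tmp_path / "p.csv", tmp_path / "r.csv")
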