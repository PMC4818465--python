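import dataclasses

import numpy as np
import pandas as pd
import pytest

from whtrcut.cohort import (Cohort, CohortParseError, SchemaError,
                            _prop_test, compare_samples,
                            complete_case_filter, read_cohort, write_cohort)
from whtrcut.simulate import simulate_cohort


def test_read_write_read_roundtrip(tmp_path, cohort_frame):
    path = tmp_path / "c.csv"
    write_cohort(Cohort(cohort_frame), path)
    first = read_cohort(path)
    path2 = tmp_path / "c2.csv"
    write_cohort(first, path2)
    second = read_cohort(path2)
    pd.testing.assert_frame_equal(first.data, second.data)
    assert len(first) == len(cohort_frame)


def test_tab_delimited_accepted(tmp_path, cohort_frame):
    path = tmp_path / "c.tsv"
    write_cohort(Cohort(cohort_frame), path, delimiter="\t")
    assert len(read_cohort(path)) == len(cohort_frame)


def test_missing_mapped_column_is_schema_error(tmp_path, cohort_frame):
    path = tmp_path / "c.csv"
    cohort_frame.drop(columns=["waist_cm"]).to_csv(path, index=False)
    with pytest.raises(SchemaError, match="waist_cm"):
        read_cohort(path)


def test_missing_tokens_become_missing_not_zero(tmp_path):
    # hand-built file: NA / NaN / empty cells must parse to missing
    path = tmp_path / "c.csv"
    path.write_text(
        "id,sex,race,age,smoking_days,height_cm,waist_cm,sbp,dbp,"
        "hba1c_pct,tg_decile,hdl_decile,weight,stratum,psu\n"
        "a,1,Hispanic,28,0,170,95,120,80,NA,3,4,1.5,S0,U0\n"
        "b,2,Hispanic,29,NaN,165,90,118,,5.6,2,9,1.5,S0,U0\n"
        "c,female,Hispanic,30,5,160,88,121,79,5.9,1,10,1.5,S0,U1\n")
    cohort = read_cohort(path)
    d = cohort.data
    assert len(cohort) == 3
    assert pd.isna(d.loc[0, "hba1c_pct"]) and d.loc[0, "hba1c_pct"] != 0
    assert pd.isna(d.loc[1, "smoking_days"]) and pd.isna(d.loc[1, "dbp"])
    assert d.loc[2, "hba1c_pct"] == 5.9
    # numeric sex codes and the word both map onto the category
    assert list(d["sex"]) == ["male", "female", "female"]


def test_garbage_numeric_cell_names_the_row(tmp_path, cohort_frame):
    cohort_frame["sbp"] = cohort_frame["sbp"].astype(object)
    cohort_frame.loc[4, "sbp"] = "high"
    path = tmp_path / "c.csv"
    cohort_frame.to_csv(path, index=False)
    with pytest.raises(CohortParseError, match="row 5"):
        read_cohort(path)


def test_duplicate_ids_rejected(cohort_frame):
    cohort_frame.loc[1, "id"] = cohort_frame.loc[0, "id"]
    with pytest.raises(ValueError, match="duplicate"):
        Cohort(cohort_frame)


def test_complete_case_partition_exhaustive_disjoint(cohort_frame):
    cohort_frame.loc[:1, "hba1c_pct"] = np.nan
    cohort = Cohort(cohort_frame)
    complete, incomplete = complete_case_filter(cohort, ["hba1c_pct"])
    assert len(complete) == len(cohort) - 2
    assert len(incomplete) == 2
    assert set(complete.data["id"]).isdisjoint(incomplete.data["id"])
    # vacuous requirement keeps everyone
    allc, none = complete_case_filter(cohort, [])
    assert len(allc) == len(cohort) and len(none) == 0
    with pytest.raises(ValueError, match="unknown"):
        complete_case_filter(cohort, ["bmi"])


def test_complete_fraction_matches_independent_missingness(small_cfg):
    # 10 % missingness per field, 5 required fields -> ~0.9^5 complete
    cfg = dataclasses.replace(small_cfg, missingness_rate=0.10, seed=5,
                              n_per_psu=600)
    cohort, _ = simulate_cohort(cfg, compute_truth=False)
    required = ["sex", "height_cm", "waist_cm", "sbp", "hba1c_pct"]
    complete, _ = complete_case_filter(cohort, required)
    frac = len(complete) / len(cohort)
    expected = 0.9 ** 5
    se = np.sqrt(expected * (1 - expected) / len(cohort))
    assert abs(frac - expected) < 4 * se


def test_design_present_flag(cohort_frame):
    assert Cohort(cohort_frame).design_present
    cohort_frame.loc[0, "weight"] = np.nan
    assert not Cohort(cohort_frame).design_present


class TestCompareSamples:
    def test_identical_cohorts_give_p_one(self, cohort_frame):
        c = Cohort(cohort_frame)
        out = compare_samples(c, Cohort(cohort_frame.assign(
            id=["Y" + str(i) for i in range(len(cohort_frame))])))
        assert np.allclose(out["p_value"].dropna(), 1.0, atol=1e-12)

    def test_symmetric_in_arguments(self, cohort_frame, rng):
        a = Cohort(cohort_frame)
        other = cohort_frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        other["age"] = other["age"] + rng.normal(0, 1, len(other))
        other["id"] = ["Z" + str(i) for i in range(len(other))]
        b = Cohort(other)
        ab = compare_samples(a, b)
        ba = compare_samples(b, a)
        assert np.allclose(ab["p_value"].to_numpy(float),
                           ba["p_value"].to_numpy(float), equal_nan=True)

    def test_empty_cohort_rejected(self, cohort_frame):
        with pytest.raises(ValueError):
            compare_samples(Cohort(cohort_frame),
                            Cohort(cohort_frame.iloc[:0]))

    def test_proportion_test_type_i_error_near_nominal(self, rng):
        # two groups with identical true proportion: ~5 % rejections
        reps, n, p = 500, 2000, 0.5
        x1 = rng.binomial(n, p, reps)
        x2 = rng.binomial(n, p, reps)
        pvals = np.array([_prop_test(a, n, b, n) for a, b in zip(x1, x2)])
        rate = (pvals < 0.05).mean()
        assert 0.02 < rate < 0.08

    def test_mean_test_power_at_large_effect(self, rng):
        # means 0 vs 1, sd 1, n = 1000 -> essentially certain rejection
        base = make_frame_pair(rng, delta=1.0, n=1000)
        out = compare_samples(*base, categorical={}, continuous=["age"])
        assert out.loc[out["variable"] == "age", "p_value"].iloc[0] < 1e-4


def make_frame_pair(rng, delta, n):
    from conftest import make_cohort_frame

    a = make_cohort_frame(n, rng)
    b = make_cohort_frame(n, rng)
    b["id"] = ["B" + str(i) for i in range(n)]
    a["age"] = rng.normal(30, 1, n)
    b["age"] = rng.normal(30 + delta, 1, n)
    return Cohort(a), Cohort(b)
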