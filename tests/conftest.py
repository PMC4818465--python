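import dataclasses
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from whtrcut.cohort import ALL_FIELDS, Cohort, complete_case_filter, write_cohort
from whtrcut.mets import classify_cohort
from whtrcut.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_cohort_frame(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Small schema-complete cohort table with plausible values."""
    sex = rng.choice(["male", "female"], n)
    height = np.where(sex == "male", 178.0, 163.0) + rng.normal(0, 6, n)
    waist = 0.55 * height + rng.normal(0, 8, n)
    return pd.DataFrame({
        "id": [f"X{i}" for i in range(n)],
        "sex": sex,
        "race": rng.choice(["nonHispanic Caucasian", "Hispanic"], n),
        "age": rng.uniform(25, 34, n).round(2),
        "smoking_days": rng.integers(0, 31, n).astype(float),
        "height_cm": height.round(1),
        "waist_cm": waist.round(1),
        "sbp": rng.normal(120, 12, n).round(0),
        "dbp": rng.normal(75, 9, n).round(0),
        "hba1c_pct": rng.normal(5.4, 0.5, n).round(1),
        "tg_decile": rng.integers(1, 11, n).astype(float),
        "hdl_decile": rng.integers(1, 11, n).astype(float),
        "weight": rng.uniform(50, 200, n).round(3),
        "stratum": rng.choice(["S0", "S1"], n),
        "psu": rng.choice(["U0", "U1", "U2", "U3"], n),
    })[list(ALL_FIELDS)]


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def cohort_frame(rng):
    return make_cohort_frame(60, rng)


@pytest.fixture
def cohort_file(tmp_path, cohort_frame):
    path = tmp_path / "cohort.csv"
    write_cohort(Cohort(cohort_frame), path)
    return path


@pytest.fixture
def small_cfg():
    """Scaled-down simulation: ~1.8k sampled, no ground-truth run."""
    return dataclasses.replace(SimulationConfig(), n_strata=3,
                               psus_per_stratum=4, n_per_psu=150,
                               stratum_pop_shares=(0.5, 0.3, 0.2))


@pytest.fixture(scope="session")
def default_run():
    """One full default-condition run shared across tests: cohort of
    16k sampled / ~8k complete, classification, and the Monte-Carlo
    ground truth."""
    cfg = SimulationConfig()
    cohort, truth = simulate_cohort(cfg)
    required = ["sex", "race", "age", "smoking_days", "height_cm", "waist_cm",
                "sbp", "dbp", "hba1c_pct", "tg_decile", "hdl_decile"]
    complete, incomplete = complete_case_filter(cohort, required)
    classified = classify_cohort(complete)
    return SimpleNamespace(cfg=cfg, cohort=cohort, truth=truth,
                           complete=complete, incomplete=incomplete,
                           classified=classified)
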