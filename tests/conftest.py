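import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ttemu import ClaimsDB, RunConfig, SimConfig, generate_population, prepare_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _d(s):
    return np.datetime64(s, "D")


@pytest.fixture(scope="session")
def tiny_db() -> ClaimsDB:
    """Five hand-written persons for screening at fiscal year 2012.

    p0: age 45, visits in lookback, SHC checkup July 2012 -> eligible, SHC arm
    p1: age 39 at entry -> excluded by age
    p2: age 50, I10 diagnosis + C03 dispensing before entry -> excluded
    p3: age 60, checkup in 2011 -> excluded (prior checkup)
    p4: age 70, visits, no checkup in FY2012 -> eligible, non-SHC arm
    """

    persons = pd.DataFrame(
        {
            "person_id": [0, 1, 2, 3, 4],
            "birth_date": [_d("1967-01-15"), _d("1973-02-01"), _d("1962-03-03"),
                           _d("1952-05-20"), _d("1941-12-01")],
            "sex": ["F", "M", "F", "M", "F"],
            "employed": [True, True, False, True, False],
            "enroll_start": [_d("2010-01-01")] * 5,
            "enroll_end": [_d("2015-12-31")] * 5,
        }
    )
    claims = pd.DataFrame(
        [
            (0, _d("2011-06-01"), "outpatient_visit", ""),
            (0, _d("2011-10-01"), "outpatient_visit", ""),
            (1, _d("2011-07-01"), "outpatient_visit", ""),
            (2, _d("2011-05-01"), "diagnosis", "I10"),
            (2, _d("2011-07-01"), "dispensing", "C03CA01"),
            (2, _d("2011-08-01"), "outpatient_visit", ""),
            (3, _d("2011-09-01"), "outpatient_visit", ""),
            (4, _d("2012-01-10"), "outpatient_visit", ""),
            (4, _d("2011-11-02"), "hospitalization", ""),
        ],
        columns=["person_id", "date", "kind", "code"],
    )
    checkups = pd.DataFrame(
        [
            (0, _d("2012-07-01"), 2012, "shc", 22.0, 80.0, 118.0, 5.4, 0.0),
            (3, _d("2011-09-15"), 2011, "shc", 24.0, 88.0, 130.0, 5.6, 1.0),
        ],
        columns=["person_id", "date", "fiscal_year", "kind", "bmi", "waist_cm",
                 "sbp", "hba1c", "smoker"],
    )
    return ClaimsDB(persons=persons, claims=claims, checkups=checkups).validate()


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_persons=3000, seed=5)


@pytest.fixture(scope="session")
def small_db(small_cfg) -> ClaimsDB:
    return generate_population(small_cfg)


@pytest.fixture(scope="session")
def reference_config() -> RunConfig:
    return RunConfig.reference()


@pytest.fixture(scope="session")
def small_prep(small_db, reference_config):
    return prepare_cohort(small_db, reference_config)


def make_exact_periods(h1: float, h0: float, n1: int, n0: int, K: int = 3):
    """Person-period table whose weighted event fractions are exactly h1/h0
    per interval (fractional responses with arm/interval cell weights)."""

    rows = []
    eid = 0
    for arm, h, n in ((1, h1, n1), (0, h0, n0)):
        for k in range(1, K + 1):
            rows.append((eid, eid, arm, k, h, float(n)))
            eid += 1
    df = pd.DataFrame(
        rows, columns=["entry_id", "person_id", "arm", "k", "event", "weight"]
    )
    return df
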