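"""Cohort construction: eligibility screening against a hand-traced fixture,
sequential-entry semantics, covariate derivation, outcome ascertainment with
the code+drug conjunction, and person-period expansion arithmetic."""

import numpy as np
import pandas as pd
import pytest

from ttemu import (
    ClaimsDB,
    EligibilityCriteria,
    OutcomeDefinition,
    baseline_covariates,
    build_sequential_cohort,
    expand_person_periods,
    find_first_outcome,
    screen_fiscal_year,
)
from ttemu.trial_emulation import DBIndex


def _d(s):
    return np.datetime64(s, "D")


def _db(persons_rows, claims_rows, checkup_rows):
    persons = pd.DataFrame(
        persons_rows,
        columns=["person_id", "birth_date", "sex", "employed",
                 "enroll_start", "enroll_end"],
    )
    claims = pd.DataFrame(
        claims_rows, columns=["person_id", "date", "kind", "code"]
    )
    checkups = pd.DataFrame(
        checkup_rows,
        columns=["person_id", "date", "fiscal_year", "kind", "bmi", "waist_cm",
                 "sbp", "hba1c", "smoker"],
    )
    return ClaimsDB(persons=persons, claims=claims, checkups=checkups)


# --------------------------------------------------------------------------- #
# screening
# --------------------------------------------------------------------------- #

def test_screen_hand_traced_fixture(tiny_db):
    """The five-person fixture has a fully hand-traced eligible set."""
    out = screen_fiscal_year(tiny_db, 2012, EligibilityCriteria())
    got = dict(zip(out["person_id"], out["arm"]))
    assert got == {0: 1, 4: 0}
    att = out.attrs["attrition"]
    assert att["screened"] == 5 and att["eligible"] == 2
    # exclusions partition the screened-out persons
    dropped = sum(v for k, v in att.items() if k not in ("screened", "eligible"))
    assert att["screened"] - att["eligible"] == dropped


def test_age_bound_and_exclusion_conjunction(tiny_db):
    out = screen_fiscal_year(tiny_db, 2012, EligibilityCriteria())
    ids = set(out["person_id"])
    assert 1 not in ids  # aged 39 at fiscal-year start
    assert 2 not in ids  # I10 diagnosis + C03 dispensing in history
    assert 3 not in ids  # prior checkup


def test_diagnosis_without_drug_is_not_excluded():
    db = _db(
        [(0, _d("1960-01-01"), "M", True, _d("2009-01-01"), _d("2015-12-31"))],
        [
            (0, _d("2011-05-01"), "diagnosis", "I10"),  # no antihypertensive
            (0, _d("2011-08-01"), "outpatient_visit", ""),
        ],
        [],
    )
    out = screen_fiscal_year(db, 2012, EligibilityCriteria())
    assert list(out["person_id"]) == [0]


def test_screen_before_any_enrollment_is_empty(tiny_db):
    out = screen_fiscal_year(tiny_db, 2005, EligibilityCriteria())
    assert len(out) == 0


def test_screening_idempotence(small_db, reference_config):
    crit = reference_config.criteria()
    first = screen_fiscal_year(small_db, 2012, crit)
    keep = set(first["person_id"])
    sub = ClaimsDB(
        persons=small_db.persons[small_db.persons["person_id"].isin(keep)],
        claims=small_db.claims[small_db.claims["person_id"].isin(keep)],
        checkups=small_db.checkups[small_db.checkups["person_id"].isin(keep)],
    )
    second = screen_fiscal_year(sub, 2012, crit)
    assert set(second["person_id"]) == keep
    merged = first.merge(second, on="person_id", suffixes=("_1", "_2"))
    assert (merged["arm_1"] == merged["arm_2"]).all()


def test_tightening_criteria_never_adds_entries(small_db):
    idx = DBIndex(small_db)
    loose = build_sequential_cohort(idx, range(2010, 2015), EligibilityCriteria())
    tight = build_sequential_cohort(
        idx, range(2010, 2015),
        EligibilityCriteria(age_min=45, age_max=65, min_visits_in_lookback=2),
    )
    loose_keys = set(zip(loose["person_id"], loose["trial_fy"]))
    tight_keys = set(zip(tight["person_id"], tight["trial_fy"]))
    assert tight_keys <= loose_keys
    assert len(tight_keys) < len(loose_keys)


# --------------------------------------------------------------------------- #
# sequential entries
# --------------------------------------------------------------------------- #

def _sequential_person_db(first_checkup_fy=2013):
    claims = [
        (0, _d(f"{y}-06-15"), "outpatient_visit", "") for y in range(2009, 2016)
    ]
    checkups = []
    if first_checkup_fy:
        checkups = [
            (0, _d(f"{first_checkup_fy}-09-01"), first_checkup_fy, "shc",
             22.0, 80.0, 120.0, 5.5, 0.0)
        ]
    return _db(
        [(0, _d("1965-01-01"), "F", True, _d("2008-06-01"), _d("2016-03-31"))],
        claims, checkups,
    )


def test_non_shc_entries_until_first_checkup_then_one_shc_entry():
    db = _sequential_person_db(first_checkup_fy=2013)
    entries = build_sequential_cohort(db, range(2010, 2015), EligibilityCriteria())
    got = list(zip(entries["trial_fy"], entries["arm"]))
    assert got == [(2010, 0), (2011, 0), (2012, 0), (2013, 1)]


def test_checkup_in_first_observable_year_gives_single_shc_entry():
    db = _sequential_person_db(first_checkup_fy=2010)
    entries = build_sequential_cohort(db, range(2010, 2015), EligibilityCriteria())
    assert list(zip(entries["trial_fy"], entries["arm"])) == [(2010, 1)]


def test_cohort_counts_regression(small_prep):
    # frozen regression pin for the bundled generator at n=3000, seed=5
    e = small_prep.entries
    assert len(e) == e["entry_id"].nunique()
    assert (len(e), int((e["arm"] == 1).sum()), e["person_id"].nunique()) == (
        5804, 562, 1774
    )
    assert (e.groupby("person_id")["arm"].sum() <= 1).all()  # one SHC entry max


# --------------------------------------------------------------------------- #
# covariates
# --------------------------------------------------------------------------- #

def test_hospitalization_and_visit_categories():
    claims = [(0, _d("2011-06-0" + str(i)), "outpatient_visit", "") for i in range(1, 5)]
    db = _db(
        [(0, _d("1960-01-01"), "F", False, _d("2009-01-01"), _d("2015-12-31"))],
        claims, [],
    )
    entries = build_sequential_cohort(db, [2012], EligibilityCriteria())
    cov = baseline_covariates(db, entries)
    assert cov["hosp_cat"].iloc[0] == "0"
    assert cov["visit_cat"].iloc[0] == "3-5"


def test_prevalence_floor_drops_rare_codes():
    persons = [
        (i, _d("1960-01-01"), "F", False, _d("2009-01-01"), _d("2015-12-31"))
        for i in range(4)
    ]
    claims = [(i, _d("2011-06-01"), "outpatient_visit", "") for i in range(4)]
    claims += [(0, _d("2011-07-01"), "diagnosis", "J06")]  # 1 of 4 entries
    claims += [(i, _d("2011-08-01"), "diagnosis", "J30") for i in range(4)]
    db = _db(persons, claims, [])
    entries = build_sequential_cohort(db, [2012], EligibilityCriteria())
    cov = baseline_covariates(db, entries, prevalence_floor=0.5)
    assert "dx_J30" in cov.columns and "dx_J06" not in cov.columns


def test_excluded_code_families_absent(small_db, small_prep):
    cov = small_prep.covariates
    banned = {"dx_E10", "dx_E14", "dx_I10", "dx_I15"}
    assert not banned & set(cov.columns)
    assert not any(c.startswith(("dx_O", "dx_P")) for c in cov.columns)


def test_tiny_fixture_covariates_hand_checked(tiny_db):
    entries = build_sequential_cohort(tiny_db, [2012], EligibilityCriteria())
    cov = baseline_covariates(tiny_db, entries)
    by_pid = cov.set_index(entries["person_id"].to_numpy())
    assert by_pid.loc[0, "age"] == 45 and by_pid.loc[0, "female"] == 1.0
    assert by_pid.loc[4, "age"] == 70 and by_pid.loc[4, "employed"] == 0.0
    assert by_pid.loc[4, "hosp_cat"] == "1"


# --------------------------------------------------------------------------- #
# outcome ascertainment
# --------------------------------------------------------------------------- #

def _outcome_db(rows):
    persons = [(0, _d("1960-01-01"), "M", True, _d("2009-01-01"), _d("2020-12-31"))]
    return _db(persons, rows, [])


def test_conjunction_within_window():
    db = _outcome_db([
        (0, _d("2013-05-01"), "diagnosis", "E11"),
        (0, _d("2013-05-11"), "dispensing", "A10BA02"),
    ])
    out = OutcomeDefinition.preset("diabetes")
    assert find_first_outcome(db, 0, _d("2012-04-01"), out) == _d("2013-05-01")


def test_conjunction_fails_without_drug():
    db = _outcome_db([(0, _d("2013-05-01"), "diagnosis", "I10")])
    out = OutcomeDefinition.preset("hypertension")
    assert find_first_outcome(db, 0, _d("2012-04-01"), out) is None


def test_conjunction_window_boundary():
    out = OutcomeDefinition.preset("diabetes", conjunction_window_days=90)
    db_in = _outcome_db([
        (0, _d("2013-05-01"), "diagnosis", "E11"),
        (0, _d("2013-07-30"), "dispensing", "A10BA02"),  # +90 days
    ])
    db_out = _outcome_db([
        (0, _d("2013-05-01"), "diagnosis", "E11"),
        (0, _d("2013-07-31"), "dispensing", "A10BA02"),  # +91 days
    ])
    assert find_first_outcome(db_in, 0, _d("2012-04-01"), out) == _d("2013-05-01")
    assert find_first_outcome(db_out, 0, _d("2012-04-01"), out) is None


def test_composite_takes_earliest_component():
    db = _outcome_db([
        (0, _d("2013-02-01"), "diagnosis", "I10"),
        (0, _d("2013-02-05"), "dispensing", "C03CA01"),
        (0, _d("2014-06-01"), "diagnosis", "E11"),
        (0, _d("2014-06-01"), "dispensing", "A10BA02"),
    ])
    out = OutcomeDefinition.preset("composite")
    assert find_first_outcome(db, 0, _d("2012-04-01"), out) == _d("2013-02-01")


def test_unknown_outcome_name_rejected():
    from ttemu import ConfigurationError

    with pytest.raises(ConfigurationError):
        OutcomeDefinition.preset("nonsense")


# --------------------------------------------------------------------------- #
# person-period expansion
# --------------------------------------------------------------------------- #

def _expansion_db(event_offset_days=None, enroll_end="2030-12-31"):
    claims = [(0, _d(f"{y}-06-15"), "outpatient_visit", "") for y in range(2009, 2012)]
    if event_offset_days is not None:
        d = _d("2012-04-01") + event_offset_days
        claims += [(0, d, "diagnosis", "E11"), (0, d, "dispensing", "A10BA02")]
    db = _db(
        [(0, _d("1965-01-01"), "F", True, _d("2008-06-01"), _d(enroll_end))],
        claims, [],
    )
    return db


def _expand(db, **kw):
    entries = build_sequential_cohort(db, [2012], EligibilityCriteria())
    return expand_person_periods(
        entries, db, OutcomeDefinition.preset("composite"),
        admin_end_date=_d("2031-03-31"), **kw,
    )


def test_event_midway_through_third_year():
    per = _expand(_expansion_db(event_offset_days=int(2.5 * 365.25)))
    assert list(per["k"]) == [1, 2, 3]
    assert list(per["event"]) == [0, 0, 1]
    assert list(per["censored"]) == [0, 0, 0]


def test_disenrollment_censors_first_period():
    per = _expand(_expansion_db(enroll_end="2012-10-01"))
    assert list(per["k"]) == [1]
    assert per["event"].iloc[0] == 0 and per["censored"].iloc[0] == 1


def test_full_observation_hits_ten_year_horizon():
    per = _expand(_expansion_db())
    assert list(per["k"]) == list(range(1, 11))
    assert per["event"].sum() == 0
    assert per["censored"].iloc[-1] == 1 and per["censored"].iloc[:-1].sum() == 0


def test_period_accounting_gap_free(small_prep):
    per = small_prep.periods
    g = per.groupby("entry_id")
    assert (g["event"].sum() <= 1).all()
    assert (g["k"].min() == 1).all()
    assert (g["k"].max() == g["k"].size()).all()  # consecutive 1..n
    assert not (per["event"].astype(bool) & per["censored"].astype(bool)).any()


def test_monthly_and_annual_agree_on_year_boundary_events():
    # event exactly two years after entry: annual period 3 start == monthly 25
    db = _expansion_db(event_offset_days=731)
    annual = _expand(db, interval="year")
    monthly = _expand(db, interval="month")
    assert annual["event"].sum() == monthly["event"].sum() == 1
    k_year = annual.loc[annual["event"] == 1, "k"].iloc[0]
    k_month = monthly.loc[monthly["event"] == 1, "k"].iloc[0]
    assert (k_month - 1) // 12 + 1 == k_year


def test_cumulative_sessions_counts_checkups_from_entry():
    claims = [(0, _d(f"{y}-06-15"), "outpatient_visit", "") for y in range(2009, 2012)]
    checkups = [
        (0, _d(f"{y}-07-01"), y, "shc", 22.0, 80.0, 120.0, 5.5, 0.0)
        for y in (2012, 2013, 2015)
    ]
    db = _db(
        [(0, _d("1965-01-01"), "F", True, _d("2008-06-01"), _d("2030-12-31"))],
        claims, checkups,
    )
    per = _expand(db)
    assert per["arm"].iloc[0] == 1
    assert list(per["cumulative_shc_sessions"][:5]) == [1, 2, 2, 3, 3]
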