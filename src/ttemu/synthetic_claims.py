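"""Synthetic employee-insurance claims database with known ground truth.

The generator emulates the structure the emulation pipeline assumes: fiscal
years running April-March, enrollment and disenrollment spans, annual checkup
participation confounded by observed covariates (plus an optional persistent
unmeasured health-seeking trait), chronic-disease onset as yearly Bernoulli
hazards on the logit scale with a persistent treatment switch from the fiscal
year of first checkup onward, a depression-coded negative-control outcome that
the checkup never affects, and benign background diagnosis codes that give the
propensity model realistic high-dimensional signal.

A Monte-Carlo oracle (:func:`ground_truth`) returns the marginal discrete-time
hazard ratio implied by the two counterfactual incidence curves (checkup from
the first eligible year versus never), which is the estimand the intention-to-
treat pipeline targets up to treatment crossover in the non-checkup arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dates import (
    fiscal_year_of,
    from_days,
    fy_end_day,
    fy_start_day,
    to_days,
)
from ._glm import fit_logit, sigmoid
from .config import ConfigurationError, SimConfig

_BIG = np.iinfo(np.int64).max // 4

CLAIM_KINDS = ("diagnosis", "dispensing", "outpatient_visit", "hospitalization")

# representative full codes written for onsets; matching is by 3-char prefix
DIABETES_DIAG_CODES = ("E11", "E14")
DIABETES_DRUG_CODE = "A10BA02"
HYPERTENSION_DIAG_CODE = "I10"
HYPERTENSION_DRUG_CODE = "C03CA01"
NC_DIAG_CODE = "F32"


@dataclass
class ClaimsDB:
    """Three linked tables keyed by ``person_id``.

    persons:  person_id, birth_date, sex ('F'/'M'), employed, enroll_start,
              enroll_end (all dates ISO / datetime64[D])
    claims:   person_id, date, kind in CLAIM_KINDS, code (ICD-10 for
              diagnoses, ATC for dispensings, '' otherwise)
    checkups: person_id, date, fiscal_year, kind ('shc'/'other'), bmi,
              waist_cm, sbp, hba1c, smoker (measurements may be NaN)
    """

    persons: pd.DataFrame
    claims: pd.DataFrame
    checkups: pd.DataFrame

    def validate(self) -> "ClaimsDB":
        pid = set(self.persons["person_id"])
        for name, tab in (("claims", self.claims), ("checkups", self.checkups)):
            if len(tab) and not set(tab["person_id"]).issubset(pid):
                raise ValueError(f"{name} has person_id values missing from persons")
        spans = self.persons.set_index("person_id")
        for name, tab in (("claims", self.claims), ("checkups", self.checkups)):
            if not len(tab):
                continue
            start = to_days(spans.loc[tab["person_id"], "enroll_start"].to_numpy())
            end = to_days(spans.loc[tab["person_id"], "enroll_end"].to_numpy())
            d = to_days(tab["date"].to_numpy())
            if np.any((d < start) | (d > end)):
                raise ValueError(f"{name} has records outside enrollment spans")
        if len(self.checkups):
            fy = fiscal_year_of(to_days(self.checkups["date"].to_numpy()))
            if np.any(fy != self.checkups["fiscal_year"].to_numpy()):
                raise ValueError("checkup dates fall outside their stated fiscal year")
        return self

    def write_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.persons.to_csv(out / "persons.csv", index=False)
        self.claims.to_csv(out / "claims.csv", index=False)
        self.checkups.to_csv(out / "checkups.csv", index=False)

    @staticmethod
    def read_csv(in_dir) -> "ClaimsDB":
        from pathlib import Path

        p = Path(in_dir)
        persons = pd.read_csv(
            p / "persons.csv",
            parse_dates=["birth_date", "enroll_start", "enroll_end"],
        )
        claims = pd.read_csv(
            p / "claims.csv", parse_dates=["date"], keep_default_na=False,
            dtype={"code": str},
        )
        checkups = pd.read_csv(p / "checkups.csv", parse_dates=["date"])
        return ClaimsDB(persons=persons, claims=claims, checkups=checkups)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class _Population:
    """Person-level latent state shared by the generator and the oracle."""

    birth: np.ndarray
    female: np.ndarray
    employed: np.ndarray
    conditions: np.ndarray  # (n, m) binary
    u: np.ndarray


def _draw_population(cfg: SimConfig, seed: int, n: int) -> _Population:
    lo, hi = cfg.age_range_at_entry
    base = fy_start_day(cfg.fy_start)
    age_days = _rng(seed, 0).uniform(lo * 365.25, (hi + 1) * 365.25, n)
    birth = base - np.ceil(age_days).astype(np.int64)
    female = _rng(seed, 1).random(n) < cfg.sex_female_prob
    employed = _rng(seed, 2).random(n) < cfg.employed_prob
    m = len(cfg.confounder_spec)
    conditions = np.empty((n, m), dtype=np.float64)
    for j, c in enumerate(cfg.confounder_spec):
        conditions[:, j] = _rng(seed, 3, j).random(n) < c.prevalence
    u = _rng(seed, 4).standard_normal(n)
    return _Population(birth, female, employed, conditions, u)


def _uptake_logit(cfg: SimConfig, pop: _Population, age, fy_offset) -> np.ndarray:
    beta = np.array([c.effect_uptake for c in cfg.confounder_spec])
    return (
        cfg.uptake_intercept
        + cfg.uptake_age_per_decade * (age - 50.0) / 10.0
        + cfg.uptake_female * pop.female
        + cfg.uptake_employed * pop.employed
        + pop.conditions @ beta
        + cfg.unmeasured_effect_uptake * pop.u
        + cfg.uptake_fy_trend * fy_offset
    )


def _outcome_logit(cfg: SimConfig, pop: _Population, age, treated) -> np.ndarray:
    gamma = np.array([c.effect_outcome for c in cfg.confounder_spec])
    h0 = cfg.baseline_annual_outcome_hazard
    return (
        np.log(h0 / (1.0 - h0))
        + cfg.outcome_age_per_decade * (age - 50.0) / 10.0
        + cfg.outcome_female * pop.female
        + cfg.outcome_employed * pop.employed
        + pop.conditions @ gamma
        + cfg.unmeasured_effect_outcome * pop.u
        + cfg.log_hr_treatment * treated
    )


def _nc_logit(cfg: SimConfig, pop: _Population, age) -> np.ndarray:
    gamma = np.array([c.effect_nc for c in cfg.confounder_spec])
    h0 = cfg.baseline_annual_nc_hazard
    return (
        np.log(h0 / (1.0 - h0))
        + cfg.nc_age_per_decade * (age - 50.0) / 10.0
        + cfg.nc_female * pop.female
        + cfg.nc_employed * pop.employed
        + pop.conditions @ gamma
        + cfg.unmeasured_effect_nc * pop.u
    )


def _frac_prob(p: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Probability of at least one event when exposed for ``frac`` of a year."""
    return 1.0 - np.power(1.0 - p, frac)


def generate_population(cfg: SimConfig) -> ClaimsDB:
    """Simulate a claims database under ``cfg``; deterministic given cfg.seed.

    Randomness is drawn from named sub-streams (one per purpose and fiscal
    year) derived from the single seed, so person-level draws are stable when
    unrelated parts of the configuration change.
    """

    cfg.validate()
    n = cfg.n_persons
    seed = cfg.seed
    admin_end = fy_end_day(cfg.admin_end_fy)

    if n == 0:
        persons = pd.DataFrame(
            columns=["person_id", "birth_date", "sex", "employed",
                     "enroll_start", "enroll_end"]
        )
        claims = pd.DataFrame(columns=["person_id", "date", "kind", "code"])
        checkups = pd.DataFrame(
            columns=["person_id", "date", "fiscal_year", "kind", "bmi",
                     "waist_cm", "sbp", "hba1c", "smoker"]
        )
        return ClaimsDB(persons, claims, checkups)

    pop = _draw_population(cfg, seed, n)
    base = fy_start_day(cfg.fy_start)
    last_entry = fy_start_day(cfg.fy_end)
    enroll_start = np.floor(
        _rng(seed, 5).uniform(base - cfg.enroll_pre_years * 365.25, last_entry + 1, n)
    ).astype(np.int64)
    if cfg.annual_disenroll_prob > 0:
        dur_years = _rng(seed, 6).geometric(cfg.annual_disenroll_prob, n)
    else:
        dur_years = np.full(n, 10_000)
    enroll_end = np.minimum(
        enroll_start + (dur_years * 365.25).astype(np.int64), admin_end
    )
    vmult = np.exp(_rng(seed, 7).normal(0.0, cfg.visit_dispersion_sd, n))
    never_taker = _rng(seed, 60).random(n) < cfg.never_taker_prob
    ever_eligible = np.zeros(n, dtype=bool)

    m_bg = len(cfg.background_codes)
    n_cond = pop.conditions.sum(axis=1)
    bg_trait = np.empty((n, m_bg), dtype=bool)
    for j, (_, prev) in enumerate(cfg.background_codes):
        prev = min(max(prev, 1e-6), 1 - 1e-6)
        pj = sigmoid(np.log(prev / (1 - prev)) + 0.25 * n_cond)
        bg_trait[:, j] = _rng(seed, 8, j).random(n) < pj

    first_shc = np.full(n, _BIG, dtype=np.int64)
    outcome_day = np.full(n, _BIG, dtype=np.int64)
    nc_day = np.full(n, _BIG, dtype=np.int64)

    cl_pid: list[np.ndarray] = []
    cl_day: list[np.ndarray] = []
    cl_kind: list[np.ndarray] = []
    cl_code: list[np.ndarray] = []
    ck_rows: list[dict] = []
    pid_all = np.arange(n, dtype=np.int64)

    def add_claims(idx, days, kind, code):
        if len(idx) == 0:
            return
        cl_pid.append(idx.astype(np.int64))
        cl_day.append(days.astype(np.int64))
        cl_kind.append(np.full(len(idx), kind, dtype=object))
        if isinstance(code, str):
            cl_code.append(np.full(len(idx), code, dtype=object))
        else:
            cl_code.append(np.asarray(code, dtype=object))

    # utilization history starts with enrollment (pre-study fiscal years) so
    # the data-lookback criteria have real records to see; checkup uptake and
    # incident-outcome ascertainment begin at the study window fy_start
    pre_years = int(np.ceil(cfg.enroll_pre_years))
    for y in range(cfg.fy_start - pre_years, cfg.admin_end_fy + 1):
        in_study = y >= cfg.fy_start
        ws, we = fy_start_day(y), fy_start_day(y + 1)
        a = np.maximum(enroll_start, ws)
        b = np.minimum(enroll_end + 1, we)
        active = b > a
        frac = np.where(active, (b - a) / 365.0, 0.0)
        age = np.floor((ws - pop.birth) / 365.25).astype(np.int64)

        def rand_day(stream, mask):
            u = _rng(seed, stream, y).random(n)
            return a + np.floor(u * np.maximum(b - a, 1)).astype(np.int64), mask

        # --- SHC participation -------------------------------------------- #
        elig = in_study & active & (age >= 40) & (age <= 74) & ~never_taker
        logit_u = _uptake_logit(cfg, pop, age, y - cfg.fy_start)
        repeat_nonattender = ever_eligible & (first_shc == _BIG)
        logit_u = logit_u + cfg.uptake_repeat_penalty * repeat_nonattender
        p_take = sigmoid(logit_u)
        take = elig & (_rng(seed, 10, y).random(n) < _frac_prob(p_take, frac))
        ever_eligible |= elig
        day_shc, _ = rand_day(11, take)
        idx = pid_all[take]
        if len(idx):
            first_shc[idx] = np.minimum(first_shc[idx], day_shc[idx])
            meas = _checkup_measurements(cfg, pop, age, idx, seed, y)
            ck_rows.append(
                dict(person_id=idx, date=day_shc[idx], fiscal_year=y,
                     kind="shc", **meas)
            )

        # --- voluntary pre-40 checkups ------------------------------------ #
        oth = (
            in_study & active & (age < 40)
            & (_rng(seed, 12, y).random(n) < _frac_prob(
                np.full(n, cfg.other_checkup_prob), frac))
        )
        day_oth, _ = rand_day(13, oth)
        idx = pid_all[oth]
        if len(idx):
            nan = np.full(len(idx), np.nan)
            ck_rows.append(
                dict(person_id=idx, date=day_oth[idx], fiscal_year=y,
                     kind="other", bmi=nan, waist_cm=nan, sbp=nan,
                     hba1c=nan, smoker=nan)
            )

        # --- composite outcome onset -------------------------------------- #
        treated = first_shc < we
        at_risk = in_study & active & (outcome_day == _BIG)
        p_evt = sigmoid(_outcome_logit(cfg, pop, age, treated))
        evt = at_risk & (_rng(seed, 14, y).random(n) < _frac_prob(p_evt, frac))
        day_evt, _ = rand_day(15, evt)
        idx = pid_all[evt]
        if len(idx):
            outcome_day[idx] = day_evt[idx]
            is_diab = _rng(seed, 16, y).random(n)[idx] < 0.45
            di, hi_ = idx[is_diab], idx[~is_diab]
            for code in DIABETES_DIAG_CODES:
                add_claims(di, day_evt[di], "diagnosis", code)
            add_claims(di, day_evt[di], "dispensing", DIABETES_DRUG_CODE)
            add_claims(hi_, day_evt[hi_], "diagnosis", HYPERTENSION_DIAG_CODE)
            add_claims(hi_, day_evt[hi_], "dispensing", HYPERTENSION_DRUG_CODE)

        # --- negative-control onset (depression) -------------------------- #
        at_risk_nc = in_study & active & (nc_day == _BIG)
        p_nc = sigmoid(_nc_logit(cfg, pop, age))
        nc = at_risk_nc & (_rng(seed, 17, y).random(n) < _frac_prob(p_nc, frac))
        day_nc, _ = rand_day(18, nc)
        idx = pid_all[nc]
        if len(idx):
            nc_day[idx] = day_nc[idx]
            add_claims(idx, day_nc[idx], "diagnosis", NC_DIAG_CODE)

        # --- visits and hospitalizations ---------------------------------- #
        lam = cfg.visit_rate_per_year * frac * vmult * (1.0 + 0.15 * n_cond)
        nv = _rng(seed, 19, y).poisson(lam) * active
        rep = np.repeat(pid_all, nv)
        if len(rep):
            u = _rng(seed, 20, y).random(len(rep))
            days = a[rep] + np.floor(u * np.maximum(b[rep] - a[rep], 1)).astype(np.int64)
            add_claims(rep, days, "outpatient_visit", "")
        nh = _rng(seed, 21, y).poisson(cfg.hosp_rate_per_year * frac) * active
        rep = np.repeat(pid_all, nh)
        if len(rep):
            u = _rng(seed, 22, y).random(len(rep))
            days = a[rep] + np.floor(u * np.maximum(b[rep] - a[rep], 1)).astype(np.int64)
            add_claims(rep, days, "hospitalization", "")

        # --- chronic-condition codes (recorded every enrolled year) ------- #
        for j, c in enumerate(cfg.confounder_spec):
            has = active & (pop.conditions[:, j] > 0)
            day_c, _ = rand_day(25 + j, has)
            add_claims(pid_all[has], day_c[has], "diagnosis", c.code)

        # --- background noise codes --------------------------------------- #
        for j, (code, _) in enumerate(cfg.background_codes):
            u = _rng(seed, 40 + j, y).random(n)
            rec = active & bg_trait[:, j] & (u < 0.5)
            day_c = a + np.floor(
                _rng(seed, 80 + j, y).random(n) * np.maximum(b - a, 1)
            ).astype(np.int64)
            add_claims(pid_all[rec], day_c[rec], "diagnosis", code)

    persons = pd.DataFrame(
        {
            "person_id": pid_all,
            "birth_date": from_days(pop.birth),
            "sex": np.where(pop.female, "F", "M"),
            "employed": pop.employed.astype(bool),
            "enroll_start": from_days(enroll_start),
            "enroll_end": from_days(enroll_end),
        }
    )
    if cl_pid:
        claims = pd.DataFrame(
            {
                "person_id": np.concatenate(cl_pid),
                "date": from_days(np.concatenate(cl_day)),
                "kind": pd.Categorical(
                    np.concatenate(cl_kind), categories=list(CLAIM_KINDS)
                ),
                "code": np.concatenate(cl_code),
            }
        ).sort_values(["person_id", "date", "kind", "code"], kind="stable")
        claims = claims.reset_index(drop=True)
    else:
        claims = pd.DataFrame(columns=["person_id", "date", "kind", "code"])
    if ck_rows:
        checkups = pd.concat(
            [pd.DataFrame({k: v for k, v in row.items()}) for row in ck_rows],
            ignore_index=True,
        )
        checkups["date"] = from_days(checkups["date"].to_numpy())
        checkups = checkups.sort_values(["person_id", "date"], kind="stable")
        checkups = checkups.reset_index(drop=True)
    else:
        checkups = pd.DataFrame(
            columns=["person_id", "date", "fiscal_year", "kind", "bmi",
                     "waist_cm", "sbp", "hba1c", "smoker"]
        )
    return ClaimsDB(persons=persons, claims=claims, checkups=checkups)


def _checkup_measurements(cfg, pop, age, idx, seed, y) -> dict:
    r = _rng(seed, 9, y)
    k = len(idx)
    bmi = np.round(np.exp(r.normal(np.log(22.0), 0.12, k)), 1)
    waist = np.round(
        58.0 + 0.95 * bmi + 3.0 * (~pop.female[idx]) + r.normal(0, 3.0, k), 0
    )
    sbp = np.round(112.0 + 0.35 * (age[idx] - 45) + 0.3 * bmi + r.normal(0, 11.0, k), 0)
    hba1c = np.round(5.35 + 0.008 * (age[idx] - 45) + r.normal(0, 0.22, k), 1)
    smoker = (r.random(k) < (0.10 + 0.25 * (~pop.female[idx]))).astype(float)
    for arr, miss in ((bmi, 0.0004), (waist, 0.0004), (sbp, 0.002),
                      (hba1c, 0.127), (smoker, 0.019)):
        arr[r.random(k) < miss] = np.nan
    return dict(bmi=bmi, waist_cm=waist, sbp=sbp, hba1c=hba1c, smoker=smoker)


# --------------------------------------------------------------------------- #
# ground-truth oracle
# --------------------------------------------------------------------------- #

@dataclass
class GroundTruth:
    true_conditional_hr: float
    true_marginal_hr: float
    mc_se: float
    true_10y_risk_by_arm: tuple[float, float]  # (treated, untreated)


def _marginal_hr_from_survival(surv1: np.ndarray, surv0: np.ndarray) -> float:
    """Common discrete-time odds ratio implied by two survival curves.

    ``surv`` arrays include S(0)=1 at position 0.  Fitted by weighted logistic
    regression of the marginal interval hazards on arm + interval dummies with
    at-risk mass as weights.
    """

    K = len(surv1) - 1
    h1 = 1.0 - surv1[1:] / surv1[:-1]
    h0 = 1.0 - surv0[1:] / surv0[:-1]
    y = np.concatenate([h1, h0])
    w = np.concatenate([surv1[:-1], surv0[:-1]])
    arm = np.concatenate([np.ones(K), np.zeros(K)])
    kd = np.tile(np.arange(K), 2)
    X = np.column_stack(
        [np.ones(2 * K), arm] + [(kd == j).astype(float) for j in range(1, K)]
    )
    fit = fit_logit(X, y, weights=w)
    return float(np.exp(fit.params[1]))


def ground_truth(
    cfg: SimConfig,
    n_mc: int = 100_000,
    seed: int | None = None,
    horizon_years: int = 10,
    n_batches: int = 20,
    outcome: str = "composite",
) -> GroundTruth:
    """Monte-Carlo oracle for the marginal discrete-time hazard ratio.

    Simulates both potential-outcome trajectories (checkup from the first
    eligible year versus never) for ``n_mc`` persons drawn from the
    configuration's covariate distribution, using each person's exact
    conditional per-year event probabilities, and returns the common odds
    ratio implied by the two counterfactual incidence curves together with a
    batch-means Monte-Carlo standard error.
    """

    cfg.validate()
    if n_mc < 1000:
        raise ConfigurationError("n_mc must be >= 1000")
    seed = cfg.seed + 101 if seed is None else seed
    pop = _draw_population(cfg, seed, n_mc)
    lo, hi = cfg.age_range_at_entry
    age0 = _rng(seed, 50).integers(max(40, lo), min(74, hi) + 1, n_mc)
    # one uniform per person-year, shared between the two potential-outcome
    # arms (common random numbers couple the trajectories)
    uu = _rng(seed, 51).random((n_mc, horizon_years))

    def curves(idx) -> tuple[np.ndarray, np.ndarray]:
        sub = _Population(
            pop.birth[idx], pop.female[idx], pop.employed[idx],
            pop.conditions[idx], pop.u[idx],
        )
        alive1 = np.ones(len(idx), dtype=bool)
        alive0 = np.ones(len(idx), dtype=bool)
        S1 = [1.0]
        S0 = [1.0]
        for k in range(horizon_years):
            age = age0[idx] + k
            if outcome == "negative_control":
                lam1 = lam0 = sigmoid(_nc_logit(cfg, sub, age))
            else:
                lam1 = sigmoid(_outcome_logit(cfg, sub, age, np.ones(len(idx))))
                lam0 = sigmoid(_outcome_logit(cfg, sub, age, np.zeros(len(idx))))
            u = uu[idx, k]
            alive1 &= u >= lam1
            alive0 &= u >= lam0
            S1.append(float(np.mean(alive1)))
            S0.append(float(np.mean(alive0)))
        return np.array(S1), np.array(S0)

    S1, S0 = curves(np.arange(n_mc))
    hr = _marginal_hr_from_survival(S1, S0)
    batch_hrs = []
    bounds = np.linspace(0, n_mc, n_batches + 1).astype(int)
    for g in range(n_batches):
        idx = np.arange(bounds[g], bounds[g + 1])
        b1, b0 = curves(idx)
        batch_hrs.append(_marginal_hr_from_survival(b1, b0))
    mc_se = float(np.std(batch_hrs, ddof=1) / np.sqrt(n_batches))
    cond = 1.0 if outcome == "negative_control" else float(np.exp(cfg.log_hr_treatment))
    return GroundTruth(
        true_conditional_hr=cond,
        true_marginal_hr=hr,
        mc_se=mc_se,
        true_10y_risk_by_arm=(1.0 - S1[-1], 1.0 - S0[-1]),
    )
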