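"""Sequential nested-trial cohort construction, outcome ascertainment, and
person-period expansion.

Each fiscal year (or calendar month, for the monthly sensitivity design) the
claims universe is re-screened against the eligibility criteria; every
eligible person enters a new emulated trial at that time zero, assigned to the
SHC arm iff a checkup record exists in the entry window.  A person may enter
the non-SHC arm in many successive years but the SHC arm at most once, because
the no-prior-checkup criterion removes them from later screens.  Trial entries
are then expanded into discrete follow-up intervals carrying event/censor
indicators, per-protocol adherence state, and cumulative checkup sessions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._dates import (
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    age_completed_years,
    fiscal_year_of,
    from_days,
    fy_start_day,
    month_start_days,
    to_days,
)
from .config import ConfigurationError, EligibilityCriteria, OutcomeDefinition
from .synthetic_claims import ClaimsDB

_BIG = np.iinfo(np.int64).max // 4
_KEY = np.int64(1) << 22  # > any day value; person*_KEY + day is sort-safe

_REQUIRED_CLAIMS_COLS = {"person_id", "date", "kind", "code"}


class SchemaError(ValueError):
    pass


def _code3(codes: pd.Series) -> np.ndarray:
    return codes.astype(str).str.slice(0, 3).to_numpy()


class DBIndex:
    """Precomputed per-person lookup structures over one claims database.

    Built once per database; every screening, covariate and expansion call
    reuses it.  Dates are int64 days; per-person record streams are stored as
    globally sorted ``person * 2^22 + day`` keys so that windowed counts and
    first-occurrence queries are single ``searchsorted`` calls.
    """

    def __init__(self, db: ClaimsDB):
        if not _REQUIRED_CLAIMS_COLS.issubset(db.claims.columns):
            raise SchemaError(
                f"claims table must have columns {sorted(_REQUIRED_CLAIMS_COLS)}"
            )
        self.db = db
        persons = db.persons.reset_index(drop=True)
        self.n = len(persons)
        self.person_ids = persons["person_id"].to_numpy()
        self._pid_index = pd.Index(self.person_ids)
        if self._pid_index.has_duplicates:
            raise SchemaError("persons table has duplicate person_id values")
        self.birth = to_days(persons["birth_date"].to_numpy()) if self.n else np.empty(0, np.int64)
        self.enroll_start = to_days(persons["enroll_start"].to_numpy()) if self.n else np.empty(0, np.int64)
        self.enroll_end = to_days(persons["enroll_end"].to_numpy()) if self.n else np.empty(0, np.int64)

        claims = db.claims
        if len(claims):
            pos = self.positions(claims["person_id"].to_numpy())
            day = to_days(claims["date"].to_numpy())
            kind = claims["kind"].astype(str).to_numpy()
            code3 = _code3(claims["code"])
        else:
            pos = day = np.empty(0, np.int64)
            kind = code3 = np.empty(0, dtype=object)
        self._claims_pos, self._claims_day = pos, day
        self._claims_kind, self._claims_code3 = kind, code3

        is_visit = (kind == "outpatient_visit") | (kind == "hospitalization")
        self.visit_keys = np.sort(pos[is_visit] * _KEY + day[is_visit])
        is_hosp = kind == "hospitalization"
        self.hosp_keys = np.sort(pos[is_hosp] * _KEY + day[is_hosp])

        ck = db.checkups
        if len(ck):
            cpos = self.positions(ck["person_id"].to_numpy())
            cday = to_days(ck["date"].to_numpy())
            ckind = (
                ck["kind"].astype(str).to_numpy()
                if "kind" in ck.columns
                else np.full(len(ck), "shc")
            )
        else:
            cpos = cday = np.empty(0, np.int64)
            ckind = np.empty(0, dtype=object)
        shc = ckind == "shc"
        self.shc_keys = np.sort(cpos[shc] * _KEY + cday[shc])
        self.any_checkup_keys = np.sort(cpos * _KEY + cday)
        self._first_cache: dict = {}
        self._outcome_cache: dict = {}

    # ------------------------------------------------------------------ #
    def positions(self, person_ids) -> np.ndarray:
        pos = self._pid_index.get_indexer(np.asarray(person_ids))
        if np.any(pos < 0):
            raise SchemaError("person_id not present in persons table")
        return pos.astype(np.int64)

    def count_in_window(self, keys: np.ndarray, pos, w0, w1) -> np.ndarray:
        """Records with day in [w0, w1) for each person position."""
        pos = np.asarray(pos, dtype=np.int64)
        lo = np.searchsorted(keys, pos * _KEY + np.asarray(w0, dtype=np.int64))
        hi = np.searchsorted(keys, pos * _KEY + np.asarray(w1, dtype=np.int64))
        return hi - lo

    def first_on_or_after(self, keys: np.ndarray, pos, day) -> np.ndarray:
        """First record day >= day per person position, _BIG if none."""
        pos = np.asarray(pos, dtype=np.int64)
        i = np.searchsorted(keys, pos * _KEY + np.asarray(day, dtype=np.int64))
        out = np.full(len(pos), _BIG, dtype=np.int64)
        ok = i < len(keys)
        cand = keys[np.minimum(i, max(len(keys) - 1, 0))] if len(keys) else None
        if len(keys):
            same = ok & ((cand // _KEY) == pos)
            out[same] = cand[same] % _KEY
        return out

    def first_day(self, kind: str, code_prefixes: frozenset) -> np.ndarray:
        """Per-person first day with a record of ``kind`` whose 3-char code
        prefix is in ``code_prefixes``; _BIG if none.  Cached."""
        key = (kind, tuple(sorted(code_prefixes)))
        if key not in self._first_cache:
            prefixes = np.array(sorted(code_prefixes))
            mask = (self._claims_kind == kind) & np.isin(self._claims_code3, prefixes)
            out = np.full(self.n, _BIG, dtype=np.int64)
            if mask.any():
                np.minimum.at(out, self._claims_pos[mask], self._claims_day[mask])
            self._first_cache[key] = out
        return self._first_cache[key]

    # ------------------------------------------------------------------ #
    def qualifying_outcome_keys(self, outdef: OutcomeDefinition) -> np.ndarray:
        """Sorted person*KEY+day keys of diagnosis dates satisfying the
        outcome's code+drug conjunction."""
        ck = (outdef.name, outdef.conjunction_window_days)
        if ck in self._outcome_cache:
            return self._outcome_cache[ck]
        w = outdef.conjunction_window_days
        keys_all = []
        for comp in outdef.components:
            dmask = (self._claims_kind == "diagnosis") & np.isin(
                self._claims_code3, np.array(sorted(comp.diagnosis_codes))
            )
            dpos = self._claims_pos[dmask]
            dday = self._claims_day[dmask]
            if comp.require_drug:
                rmask = (self._claims_kind == "dispensing") & np.isin(
                    self._claims_code3, np.array(sorted(comp.drug_codes))
                )
                rkeys = np.sort(self._claims_pos[rmask] * _KEY + self._claims_day[rmask])
                lo = np.searchsorted(rkeys, dpos * _KEY + (dday - w))
                hi = np.searchsorted(rkeys, dpos * _KEY + (dday + w + 1))
                ok = hi > lo
                dpos, dday = dpos[ok], dday[ok]
            keys_all.append(dpos * _KEY + dday)
        out = np.sort(np.concatenate(keys_all)) if keys_all else np.empty(0, np.int64)
        self._outcome_cache[ck] = out
        return out


# --------------------------------------------------------------------------- #
# screening
# --------------------------------------------------------------------------- #

def _screen_at(
    idx: DBIndex,
    entry_day: int,
    criteria: EligibilityCriteria,
    arm_window: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Positions of eligible persons at ``entry_day``, their arm (0/1), and
    Figure-1-style attrition counts for this screen.

    ``arm_window`` is the half-open day window in which an SHC checkup makes
    the entry an SHC-arm entry.
    """

    c = criteria
    n = idx.n
    att = {
        "screened": n, "age_or_enrollment": 0, "no_visit_in_lookback": 0,
        "prior_checkup": 0, "prevalent_condition": 0, "resource_use": 0,
        "eligible": 0,
    }
    if n == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64), att
    age = age_completed_years(idx.birth, entry_day)
    ok = (age >= c.age_min) & (age <= c.age_max)
    ok &= idx.enroll_start <= entry_day - c.lookback_days
    ok &= idx.enroll_end >= entry_day

    pos = np.flatnonzero(ok)
    att["age_or_enrollment"] = n - len(pos)
    if len(pos) == 0:
        return pos, np.empty(0, np.int64), att

    nvis = idx.count_in_window(
        idx.visit_keys, pos, entry_day - c.lookback_days, entry_day
    )
    keep = nvis >= c.min_visits_in_lookback
    att["no_visit_in_lookback"] = int((~keep).sum())
    pos, nvis = pos[keep], nvis[keep]

    if c.require_no_prior_checkup and len(pos):
        keys = idx.shc_keys if c.allow_prior_other_checkups else idx.any_checkup_keys
        # all record days are nonnegative (post-1970), so 0 is "any time before"
        prior = idx.count_in_window(keys, pos, 0, entry_day)
        att["prior_checkup"] = int((prior > 0).sum())
        pos, nvis = pos[prior == 0], nvis[prior == 0]

    for diag_set, drug_set in criteria.exclusion_code_sets:
        if not len(pos):
            break
        fd = idx.first_day("diagnosis", frozenset(diag_set))[pos]
        fr = idx.first_day("dispensing", frozenset(drug_set))[pos]
        excl = (fd < entry_day) & (fr < entry_day)
        att["prevalent_condition"] += int(excl.sum())
        pos, nvis = pos[~excl], nvis[~excl]
    if criteria.extra_exclusion_diag and len(pos):
        fd = idx.first_day("diagnosis", frozenset(criteria.extra_exclusion_diag))[pos]
        keep = fd >= entry_day
        att["prevalent_condition"] += int((~keep).sum())
        pos, nvis = pos[keep], nvis[keep]

    if len(pos) and criteria.resource_use_exclusion_percentile < 100:
        # 'higher' keeps the threshold on an observed count, so re-screening
        # an already-screened cohort is a no-op (idempotence)
        thr = np.quantile(
            nvis, criteria.resource_use_exclusion_percentile / 100.0,
            method="higher",
        )
        keep = nvis <= thr
        att["resource_use"] = int((~keep).sum())
        pos = pos[keep]

    att["eligible"] = len(pos)
    a0, a1 = arm_window
    arm = (idx.count_in_window(idx.shc_keys, pos, a0, a1) > 0).astype(np.int64)
    return pos, arm, att


def screen_fiscal_year(
    db: ClaimsDB | DBIndex, fy: int, criteria: EligibilityCriteria
) -> pd.DataFrame:
    """Persons eligible at the April 1 start of fiscal year ``fy`` with their
    assigned arm (1 = SHC checkup recorded during the fiscal year)."""

    idx = db if isinstance(db, DBIndex) else DBIndex(db)
    criteria.validate()
    entry = fy_start_day(fy)
    pos, arm, att = _screen_at(idx, entry, criteria, (entry, fy_start_day(fy + 1)))
    out = pd.DataFrame({"person_id": idx.person_ids[pos], "arm": arm})
    out.attrs["attrition"] = att
    return out


def build_sequential_cohort(
    db: ClaimsDB | DBIndex,
    fy_range,
    criteria: EligibilityCriteria,
    interval: str = "year",
    monthly_nonshc_fraction: float | None = None,
    subsample_seed: int = 0,
) -> pd.DataFrame:
    """Union of per-screen eligible sets materialized as trial entries.

    ``fy_range`` is an iterable of fiscal years.  With ``interval='month'``
    eligibility is re-checked at every month start within those fiscal years
    and (optionally) only a random fraction of non-SHC entries is kept at each
    entry time point, drawn with a dedicated seed.
    """

    idx = db if isinstance(db, DBIndex) else DBIndex(db)
    criteria.validate()
    fy_list = sorted(fy_range)
    if not fy_list:
        raise ConfigurationError("fy_range must be nonempty")
    rows = []
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=subsample_seed, spawn_key=(999,))
    )
    if interval == "year":
        screens = [(fy_start_day(fy), fy, (fy_start_day(fy), fy_start_day(fy + 1)))
                   for fy in fy_list]
    elif interval == "month":
        days = month_start_days(fy_list[0], fy_list[-1])
        fy_of = fiscal_year_of(days)
        # each month's arm window ends at the next month start; the final
        # window (March of the last fiscal year) ends April 1
        nxt = int(
            (from_days(days[-1]).astype("datetime64[M]") + 1)
            .astype("datetime64[D]")
            .astype("int64")
        )
        ends = np.append(days[1:], nxt)
        screens = [
            (int(d0), int(fy), (int(d0), int(d1)))
            for d0, d1, fy in zip(days, ends, fy_of)
        ]
    else:
        raise ConfigurationError("interval must be 'year' or 'month'")

    total_att: dict = {}
    for entry_day, fy, window in screens:
        pos, arm, att = _screen_at(idx, entry_day, criteria, window)
        for key, v in att.items():
            total_att[key] = total_att.get(key, 0) + v
        if interval == "month" and monthly_nonshc_fraction is not None and len(pos):
            nonshc = np.flatnonzero(arm == 0)
            keep = rng.random(len(nonshc)) < monthly_nonshc_fraction
            drop = nonshc[~keep]
            mask = np.ones(len(pos), dtype=bool)
            mask[drop] = False
            pos, arm = pos[mask], arm[mask]
        if len(pos):
            rows.append(
                pd.DataFrame(
                    {
                        "person_id": idx.person_ids[pos],
                        "_pos": pos,
                        "trial_fy": fy,
                        "arm": arm,
                        "entry_day": entry_day,
                    }
                )
            )
    if rows:
        entries = pd.concat(rows, ignore_index=True)
    else:
        entries = pd.DataFrame(
            columns=["person_id", "_pos", "trial_fy", "arm", "entry_day"]
        )
    entries.insert(0, "entry_id", np.arange(len(entries), dtype=np.int64))
    entries["entry_date"] = from_days(entries["entry_day"].to_numpy().astype(np.int64)) if len(entries) else pd.Series(dtype="datetime64[ns]")
    entries["age_at_entry"] = (
        age_completed_years(
            idx.birth[entries["_pos"].to_numpy().astype(np.int64)],
            entries["entry_day"].to_numpy().astype(np.int64),
        )
        if len(entries)
        else pd.Series(dtype="int64")
    )
    entries.attrs["attrition"] = total_att
    return entries


def cohort_summary(entries: pd.DataFrame) -> dict:
    n_unique = int(entries["person_id"].nunique()) if len(entries) else 0
    return {
        "n_entries": int(len(entries)),
        "n_shc": int((entries["arm"] == 1).sum()) if len(entries) else 0,
        "n_nonshc": int((entries["arm"] == 0).sum()) if len(entries) else 0,
        "n_unique_persons": n_unique,
        "mean_entries_per_person": float(len(entries) / n_unique) if n_unique else 0.0,
    }


# --------------------------------------------------------------------------- #
# baseline covariates
# --------------------------------------------------------------------------- #

HOSP_CAT_LABELS = ("0", "1", "2+")
VISIT_CAT_LABELS = ("1-2", "3-5", "6-11", "12+")

_DEFAULT_DROPPED_CODE_FAMILIES = frozenset(
    {"E10", "E14", "I10", "I11", "I12", "I13", "I14", "I15"}
)


def _categorize(counts: np.ndarray, bins: list[int], labels) -> pd.Categorical:
    cat = np.digitize(counts, bins)
    return pd.Categorical.from_codes(cat, categories=list(labels))


def baseline_covariates(
    db: ClaimsDB | DBIndex,
    entries: pd.DataFrame,
    prevalence_floor: float = 0.0001,
    lookback_days: int = 365,
    dropped_code_families: frozenset = _DEFAULT_DROPPED_CODE_FAMILIES,
) -> pd.DataFrame:
    """One covariate row per trial entry.

    Columns: age, female, employed, trial_fy (categorical), hosp_cat,
    visit_cat, and one 0/1 ``dx_<code>`` column per 3-digit ICD-10 code in the
    person's pre-entry history, after dropping codes below the cohort
    prevalence floor and the excluded code families (component-disease,
    pregnancy O* and perinatal P* codes).  Absence of a code is treated as
    absence of the condition.
    """

    idx = db if isinstance(db, DBIndex) else DBIndex(db)
    pos = (
        entries["_pos"].to_numpy().astype(np.int64)
        if "_pos" in entries.columns
        else idx.positions(entries["person_id"].to_numpy())
    )
    entry_day = (
        entries["entry_day"].to_numpy().astype(np.int64)
        if "entry_day" in entries.columns
        else to_days(entries["entry_date"].to_numpy())
    )
    if np.any(idx.enroll_start[pos] > entry_day - 1):
        raise ValueError("entry with no pre-entry observation window")

    nvis = idx.count_in_window(idx.visit_keys, pos, entry_day - lookback_days, entry_day)
    nhosp = idx.count_in_window(idx.hosp_keys, pos, entry_day - lookback_days, entry_day)
    out = pd.DataFrame(
        {
            "age": age_completed_years(idx.birth[pos], entry_day).astype(float),
            "female": (idx.db.persons["sex"].to_numpy()[pos] == "F").astype(float),
            "employed": idx.db.persons["employed"].to_numpy()[pos].astype(float),
            "trial_fy": pd.Categorical(entries["trial_fy"].to_numpy()),
            "hosp_cat": _categorize(nhosp, [1, 2], HOSP_CAT_LABELS),
            "visit_cat": _categorize(nvis, [3, 6, 12], VISIT_CAT_LABELS),
        },
        index=entries.index,
    )

    dmask = idx._claims_kind == "diagnosis"
    if dmask.any():
        hist = pd.DataFrame(
            {
                "pos": idx._claims_pos[dmask],
                "code": idx._claims_code3[dmask],
                "day": idx._claims_day[dmask],
            }
        )
        first = hist.groupby(["pos", "code"], sort=True)["day"].min().reset_index()
        codes = [
            c
            for c in first["code"].unique()
            if c not in dropped_code_families and not c.startswith(("O", "P"))
        ]
        code_ix = {c: j for j, c in enumerate(sorted(codes))}
        fd = np.full((idx.n, len(code_ix)), _BIG, dtype=np.int64)
        sel = first["code"].map(code_ix).notna()
        fsel = first[sel]
        fd[fsel["pos"].to_numpy(), fsel["code"].map(code_ix).to_numpy().astype(int)] = (
            fsel["day"].to_numpy()
        )
        ind = (fd[pos, :] < entry_day[:, None]).astype(np.float64)
        prev = ind.mean(axis=0) if len(ind) else np.zeros(len(code_ix))
        keep = prev >= prevalence_floor
        kept_codes = [c for c, j in sorted(code_ix.items(), key=lambda kv: kv[1]) if keep[j]]
        dx = pd.DataFrame(
            ind[:, keep], columns=[f"dx_{c}" for c in kept_codes], index=entries.index
        )
        out = pd.concat([out, dx], axis=1)
    return out


# --------------------------------------------------------------------------- #
# outcomes and person-period expansion
# --------------------------------------------------------------------------- #

def find_first_outcome(
    db: ClaimsDB | DBIndex, person_id, from_date, outdef: OutcomeDefinition
):
    """Earliest qualifying outcome date >= from_date for one person, or None."""
    idx = db if isinstance(db, DBIndex) else DBIndex(db)
    pos = idx.positions([person_id])
    day = int(to_days([from_date])[0])
    keys = idx.qualifying_outcome_keys(outdef)
    first = idx.first_on_or_after(keys, pos, day)[0]
    if first >= _BIG:
        return None
    return from_days([first])[0]


def expand_person_periods(
    entries: pd.DataFrame,
    db: ClaimsDB | DBIndex,
    outdef: OutcomeDefinition,
    interval: str = "year",
    horizon_years: int = 10,
    admin_end_date=None,
) -> pd.DataFrame:
    """Expand trial entries into discrete person-period rows.

    Each entry contributes consecutive intervals ``k = 1..n`` until the first
    of: qualifying outcome (event=1 in the interval containing the event),
    disenrollment or administrative end (censored=1), or the follow-up
    horizon (censored=1 in the final interval).  ``still_in_non_shc_protocol``
    flips to 0 from the interval of a non-SHC entry's first SHC checkup;
    ``cumulative_shc_sessions`` counts the SHC arm's checkups from entry
    through the end of interval k (always 0 for the non-SHC arm).
    """

    idx = db if isinstance(db, DBIndex) else DBIndex(db)
    if interval == "year":
        delta, K = DAYS_PER_YEAR, horizon_years
    elif interval == "month":
        delta, K = DAYS_PER_MONTH, horizon_years * 12
    else:
        raise ConfigurationError("interval must be 'year' or 'month'")

    if not len(entries):
        return pd.DataFrame(
            columns=["entry_id", "person_id", "trial_fy", "arm", "k", "event",
                     "censored", "still_in_non_shc_protocol",
                     "cumulative_shc_sessions"]
        )

    pos = (
        entries["_pos"].to_numpy().astype(np.int64)
        if "_pos" in entries.columns
        else idx.positions(entries["person_id"].to_numpy())
    )
    entry_day = (
        entries["entry_day"].to_numpy().astype(np.int64)
        if "entry_day" in entries.columns
        else to_days(entries["entry_date"].to_numpy())
    )
    admin_end = (
        int(idx.enroll_end.max())
        if admin_end_date is None
        else int(to_days([admin_end_date])[0])
    )
    if np.any(entry_day > admin_end):
        raise ConfigurationError("entry date after administrative end")

    cens_day = np.minimum(idx.enroll_end[pos], admin_end)
    okeys = idx.qualifying_outcome_keys(outdef)
    evt_day = idx.first_on_or_after(okeys, pos, entry_day)
    has_evt = evt_day < _BIG

    t_evt = np.where(has_evt, evt_day - entry_day, _BIG).astype(np.float64)
    t_cens = np.maximum(cens_day - entry_day, 0).astype(np.float64)
    k_evt = np.floor(t_evt / delta).astype(np.int64) + 1
    k_cens = np.minimum(np.floor(t_cens / delta).astype(np.int64) + 1, K)
    event_final = has_evt & (k_evt <= k_cens) & (k_evt <= K)
    n_per = np.where(event_final, k_evt, k_cens).astype(np.int64)

    rep = np.repeat(np.arange(len(entries)), n_per)
    if len(rep):
        starts = np.concatenate([[0], np.cumsum(n_per)[:-1]])
        k = np.arange(len(rep)) - starts[rep] + 1
        last = k == n_per[rep]
    else:
        k = np.empty(0, np.int64)
        last = np.empty(0, bool)

    arm = entries["arm"].to_numpy()[rep]
    event = (last & event_final[rep]).astype(np.int8)
    censored = (last & ~event_final[rep]).astype(np.int8)

    # first SHC checkup on/after entry (crossover for non-SHC; sessions for SHC)
    first_shc_after = idx.first_on_or_after(idx.shc_keys, pos, entry_day)
    k_dev = np.where(
        first_shc_after < _BIG,
        np.floor((first_shc_after - entry_day) / delta).astype(np.int64) + 1,
        _BIG,
    )
    still = np.where((arm == 0) & (k >= k_dev[rep]), 0, 1).astype(np.int8)

    cum = np.zeros(len(rep), dtype=np.int64)
    shc_rows = arm == 1
    if shc_rows.any():
        p = pos[rep[shc_rows]]
        e = entry_day[rep[shc_rows]]
        upper = p.astype(np.float64) * float(_KEY) + e + k[shc_rows] * delta
        lower = p * _KEY + e
        cum[shc_rows] = np.searchsorted(idx.shc_keys, upper) - np.searchsorted(
            idx.shc_keys, lower
        )

    return pd.DataFrame(
        {
            "entry_id": entries["entry_id"].to_numpy()[rep],
            "person_id": entries["person_id"].to_numpy()[rep],
            "trial_fy": entries["trial_fy"].to_numpy()[rep],
            "arm": arm.astype(np.int8),
            "k": k.astype(np.int64),
            "event": event,
            "censored": censored,
            "still_in_non_shc_protocol": still,
            "cumulative_shc_sessions": cum,
        }
    )


def apply_protocol_censoring(periods: pd.DataFrame) -> pd.DataFrame:
    """Artificially censor non-SHC entries at the interval of their first SHC
    checkup (per-protocol analysis); the deviation interval itself becomes a
    censored, event-free period and later periods are dropped."""

    dev = (periods["arm"] == 0) & (periods["still_in_non_shc_protocol"] == 0)
    if not dev.any():
        return periods.copy()
    first_dev_k = (
        periods.loc[dev].groupby("entry_id")["k"].min().rename("k_dev")
    )
    out = periods.merge(first_dev_k, on="entry_id", how="left")
    out["k_dev"] = out["k_dev"].fillna(np.iinfo(np.int64).max // 4)
    out = out[out["k"] <= out["k_dev"]].copy()
    at_dev = out["k"] == out["k_dev"]
    out.loc[at_dev, "event"] = 0
    out.loc[at_dev, "censored"] = 1
    return out.drop(columns="k_dev").reset_index(drop=True)
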