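"""Descriptive baseline table for the emulated cohort.

Per arm: entry counts, age and entry-year medians/IQRs, sex and employment
percentages, the most common preexisting illnesses, and — for the SHC arm
only, since nonparticipants have no checkup record — checkup measurement
summaries (BMI, waist circumference with sex-specific obesity thresholds,
systolic blood pressure, HbA1c, smoking) with per-measure missingness.
Quantiles use linear interpolation (numpy default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._dates import to_days
from .ipw import smd, smd_from_samples
from .synthetic_claims import ClaimsDB

WAIST_OBESITY_THRESHOLD_CM = {"M": 85.0, "F": 90.0}


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        return (float("nan"),) * 3
    q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    return float(q50), float(q25), float(q75)


def _fmt_med_iqr(x) -> str:
    m, lo, hi = _median_iqr(x)
    if np.isnan(m):
        return ""
    return f"{m:g} ({lo:g}-{hi:g})"


def baseline_table(entries: pd.DataFrame, db: ClaimsDB, top_n_illness: int = 3
                   ) -> pd.DataFrame:
    """Arm-by-arm descriptive table with SMD column for shared covariates.

    Returns a tidy frame: variable, shc, non_shc, smd, missing_shc_pct.
    """

    persons = db.persons.set_index("person_id")
    rows: list[dict] = []

    def row(variable, shc="", non_shc="", smd_val=None, missing=None):
        rows.append(
            {
                "variable": variable,
                "shc": shc,
                "non_shc": non_shc,
                "smd": round(smd_val, 2) if smd_val is not None else np.nan,
                "missing_shc_pct": round(missing, 1) if missing is not None else np.nan,
            }
        )

    is_shc = entries["arm"].to_numpy() == 1
    e1 = entries[is_shc]
    e0 = entries[~is_shc]
    row("n", str(len(e1)), str(len(e0)))
    if not len(entries):
        return pd.DataFrame(rows)

    age1 = e1["age_at_entry"].to_numpy(dtype=float)
    age0 = e0["age_at_entry"].to_numpy(dtype=float)
    row(
        "age_median_iqr", _fmt_med_iqr(age1), _fmt_med_iqr(age0),
        smd_from_samples(age1, age0, "continuous") if len(e1) and len(e0) else None,
    )

    sex1 = (persons.loc[e1["person_id"], "sex"] == "F").to_numpy(dtype=float)
    sex0 = (persons.loc[e0["person_id"], "sex"] == "F").to_numpy(dtype=float)
    p1, p0 = (sex1.mean() if len(sex1) else np.nan,
              sex0.mean() if len(sex0) else np.nan)
    row("female_pct", f"{100 * p1:.1f}", f"{100 * p0:.1f}",
        smd(p1, p0, "binary") if len(sex1) and len(sex0) else None)

    fy1 = e1["trial_fy"].to_numpy(dtype=float)
    fy0 = e0["trial_fy"].to_numpy(dtype=float)
    row(
        "entry_fy_median_iqr", _fmt_med_iqr(fy1), _fmt_med_iqr(fy0),
        smd_from_samples(fy1, fy0, "continuous") if len(e1) and len(e0) else None,
    )

    emp1 = persons.loc[e1["person_id"], "employed"].to_numpy(dtype=float)
    emp0 = persons.loc[e0["person_id"], "employed"].to_numpy(dtype=float)
    q1, q0 = (emp1.mean() if len(emp1) else np.nan,
              emp0.mean() if len(emp0) else np.nan)
    row("employed_pct", f"{100 * q1:.1f}", f"{100 * q0:.1f}",
        smd(q1, q0, "binary") if len(emp1) and len(emp0) else None)

    # most common pre-entry 3-digit diagnosis codes across the whole cohort
    diag = db.claims[db.claims["kind"].astype(str) == "diagnosis"]
    if len(diag) and len(entries):
        code3 = diag["code"].astype(str).str.slice(0, 3)
        first = (
            pd.DataFrame({"person_id": diag["person_id"], "code": code3,
                          "day": to_days(diag["date"].to_numpy())})
            .groupby(["person_id", "code"])["day"].min().reset_index()
        )
        entry_day = to_days(entries["entry_date"].to_numpy())
        # prevalence of each code among entries (history strictly before entry)
        merged = entries[["person_id", "arm"]].assign(entry_day=entry_day).merge(
            first, on="person_id", how="inner"
        )
        merged = merged[merged["day"] < merged["entry_day"]]
        top = merged["code"].value_counts().head(top_n_illness).index
        for code in top:
            has = merged[merged["code"] == code].groupby("arm")["person_id"].count()
            n1 = int(has.get(1, 0))
            n0 = int(has.get(0, 0))
            pr1 = n1 / max(len(e1), 1)
            pr0 = n0 / max(len(e0), 1)
            row(f"illness_{code}_pct", f"{100 * pr1:.1f}", f"{100 * pr0:.1f}",
                smd(pr1, pr0, "binary"))

    # SHC-arm checkup measurements at entry (first checkup in the entry FY)
    ck = db.checkups
    if len(ck) and len(e1):
        ck_shc = ck[ck["kind"].astype(str) == "shc"] if "kind" in ck.columns else ck
        m = e1[["person_id", "trial_fy"]].merge(
            ck_shc, left_on=["person_id", "trial_fy"],
            right_on=["person_id", "fiscal_year"], how="left",
        ).drop_duplicates(subset=["person_id", "trial_fy"])
        sex = persons.loc[m["person_id"], "sex"].to_numpy()

        def meas(col, label, extra=None):
            v = m[col].to_numpy(dtype=float)
            miss = 100.0 * np.mean(np.isnan(v)) if len(v) else np.nan
            row(label, _fmt_med_iqr(v), "NA", None, miss)
            if extra:
                extra(v)

        def bmi_extra(v):
            ok = ~np.isnan(v)
            row("bmi_ge_25_pct", f"{100 * np.mean(v[ok] >= 25):.1f}" if ok.any() else "",
                "NA")

        def waist_extra(v):
            thr = np.array([WAIST_OBESITY_THRESHOLD_CM[s] for s in sex])
            ok = ~np.isnan(v)
            row(
                "waist_above_obesity_threshold_pct",
                f"{100 * np.mean(v[ok] >= thr[ok]):.1f}" if ok.any() else "", "NA",
            )

        meas("bmi", "bmi_median_iqr", bmi_extra)
        meas("waist_cm", "waist_cm_median_iqr", waist_extra)
        meas("sbp", "sbp_median_iqr")
        meas("hba1c", "hba1c_median_iqr")
        smk = m["smoker"].to_numpy(dtype=float)
        miss = 100.0 * np.mean(np.isnan(smk)) if len(smk) else np.nan
        ok = ~np.isnan(smk)
        row("smoking_pct", f"{100 * np.mean(smk[ok]):.1f}" if ok.any() else "",
            "NA", None, miss)
    return pd.DataFrame(rows)
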