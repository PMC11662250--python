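"""Fiscal-year and day-resolution date helpers.

All internal dates are integer days since 1970-01-01 (the numpy datetime64[D]
epoch).  The Japanese fiscal year FY(y) runs April 1 of calendar year y through
March 31 of year y+1 and is labeled by its starting calendar year.
"""

from __future__ import annotations

import numpy as np

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0


def to_days(dates) -> np.ndarray:
    """Convert datetime64/str/Timestamp-like input to int64 days since epoch."""
    return np.asarray(np.asarray(dates, dtype="datetime64[D]").astype("int64"))


def from_days(days) -> np.ndarray:
    return np.asarray(days, dtype="int64").astype("datetime64[D]")


def fy_start_day(fy: int) -> int:
    """First day (April 1) of fiscal year ``fy`` as days since epoch."""
    return int(np.datetime64(f"{fy:04d}-04-01", "D").astype("int64"))


def fy_end_day(fy: int) -> int:
    """Last day (March 31 of fy+1), inclusive."""
    return fy_start_day(fy + 1) - 1


def fiscal_year_of(days) -> np.ndarray:
    """Fiscal-year label for each day (vectorized)."""
    d = from_days(np.asarray(days, dtype="int64"))
    y = d.astype("datetime64[Y]").astype("int64") + 1970
    month = (d.astype("datetime64[M]").astype("int64") % 12) + 1
    return np.where(month >= 4, y, y - 1)


def month_start_days(first_fy: int, last_fy: int) -> np.ndarray:
    """First day of every calendar month from April ``first_fy`` through
    March of ``last_fy``+1 (all month starts inside the fiscal-year range)."""
    start = np.datetime64(f"{first_fy:04d}-04", "M")
    end = np.datetime64(f"{last_fy + 1:04d}-04", "M")
    months = np.arange(start, end)
    return months.astype("datetime64[D]").astype("int64")


def age_completed_years(birth_days, at_days) -> np.ndarray:
    """Age in completed years, by elapsed days / 365.25 (package convention)."""
    return np.floor(
        (np.asarray(at_days, dtype="int64") - np.asarray(birth_days, dtype="int64"))
        / DAYS_PER_YEAR
    ).astype("int64")


def interval_boundary(entry_days, k, delta_days: float) -> np.ndarray:
    """End day of interval k (1-based): entry + round(k * delta)."""
    return np.asarray(entry_days, dtype="int64") + np.rint(
        np.asarray(k, dtype="float64") * delta_days
    ).astype("int64")
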