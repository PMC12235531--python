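"""Whole-day time grid helpers: day indices, calendar quarters, 5-year age bands.

All analysis happens at day resolution (pharmacy fill data carry no finer
grain). Dates are mapped to integer day offsets from a study origin; a year
is 365.25 days, so 5-year age bands change every 1826.25 days. Working in
quarters of a day (the factor 4 below) keeps band boundaries exact integers.
"""

from __future__ import annotations

import datetime as dt

import numpy as np

DAYS_PER_YEAR = 365.25
_BAND_NUM = 7305  # 4 * 5 * 365.25 days per 5-year band, times four


def day_index(d, origin) -> int:
    """Integer day offset of ``d`` from ``origin`` (both date-like)."""
    return int((np.datetime64(d, "D") - np.datetime64(origin, "D")).astype(int))


def days_to_dates(days, origin):
    """Map integer day offsets back to datetime64[D] dates."""
    return np.datetime64(origin, "D") + np.asarray(days, dtype="int64")


def quarter_of_days(origin, n_days: int) -> np.ndarray:
    """Calendar quarter (1..4) of each of the first ``n_days`` days."""
    dates = np.datetime64(origin, "D") + np.arange(n_days)
    months = dates.astype("datetime64[M]").astype(int) % 12
    return (months // 3 + 1).astype(np.int8)


def quarter_start_days(origin, n_days: int) -> np.ndarray:
    """Day indices in (0, n_days) on which a calendar quarter begins."""
    m0 = np.datetime64(origin, "M")
    months = np.arange(m0, m0 + n_days // 28 + 3)
    # months since 1970-01; Jan/Apr/Jul/Oct are multiples of 3
    qmonths = months[months.astype(int) % 3 == 0]
    days = (qmonths.astype("datetime64[D]") - np.datetime64(origin, "D")).astype(int)
    return days[(days > 0) & (days < n_days)]


def age_band(days, birth_day):
    """5-year age band index (0 = ages [0,5), 13 = ages [65,70), ...)."""
    return (np.asarray(days) - birth_day) * 4 // _BAND_NUM


def age_years(days, birth_day):
    """Whole years of age at the given day offsets (365.25-day years)."""
    return ((np.asarray(days) - birth_day) * 4 // 1461).astype(np.int64)


def band_crossings(birth_day: int, lo: int, hi: int) -> np.ndarray:
    """Days strictly inside (lo, hi) on which the 5-year age band increments."""
    b_lo = int(age_band(lo, birth_day))
    b_hi = int(age_band(hi - 1, birth_day))
    ks = np.arange(b_lo + 1, b_hi + 1)
    days = birth_day + (_BAND_NUM * ks + 3) // 4
    return days[(days > lo) & (days < hi)]
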