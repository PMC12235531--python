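"""Exposure-episode construction from longitudinal pharmacy fill data.

Each controller fill covers ``ceil(days_supply * (1 + grace))`` days from
its fill date; overlapping or abutting coverage of the same drug-device
class merges into maximal half-open intervals. Where the two named classes'
coverages compete, the later-starting fill wins from its start date (the
patient is taken to have switched at the new device's fill, truncating the
prior fill's remaining coverage): each day's state is that of the most
recent fill at or before it, provided the day lies within that fill's
graced coverage. Observation time covered by neither class — including
time covered only by other controllers — is tiled as ``neither``, so each
patient's periods partition the observation window exactly.

A patient's observation window is [first controller fill, min(death date +
1 day, study end + 1 day)), all at day resolution with half-open intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import timegrid as tg
from .errors import InputError

MDI = "mdi_bf"
DPI = "dpi_fs"
NEITHER = "neither"

CONTROLLER_PRODUCTS = ("bf_mdi", "fs_dpi", "other_controller")

#: fixed-day reading of a "3-month" treatment gap
DEFAULT_MAX_GAP_DAYS = 91


@dataclass(frozen=True)
class GracePolicy:
    """Adherence allowance appended to each fill's days supply.

    grace_fraction 0 assumes perfect use (a 30-day supply covers 30 days);
    1/3 assumes use 75% of the time (30-day supply covers 40 days); 1 assumes
    use half the time (30-day supply covers 60 days).
    """

    grace_fraction: float = 1 / 3

    def __post_init__(self):
        if self.grace_fraction < 0:
            raise InputError("grace_fraction must be >= 0")

    def coverage_days(self, days_supply: int) -> int:
        if days_supply <= 0:
            raise InputError("days_supply must be positive")
        return math.ceil(days_supply * (1 + self.grace_fraction))


def _coverage(days, supplies, policy: GracePolicy) -> list:
    """Merged coverage intervals (int day units) for sorted same-class fills."""
    days = np.asarray(days, dtype=np.int64)
    if len(days) > 1 and (np.diff(days) < 0).any():
        raise InputError("fills must be sorted by fill date")
    supplies = np.broadcast_to(np.asarray(supplies, dtype=np.int64), days.shape)
    out: list = []
    for d, s in zip(days.tolist(), supplies.tolist()):
        e = d + policy.coverage_days(s)
        if out and d <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([d, e])
    return [(s, e) for s, e in out]


def coverage_from_fills(fills: pd.DataFrame, policy: GracePolicy,
                        origin=None) -> list:
    """Coverage intervals for one patient's fills of a single product class.

    ``fills`` needs ``fill_date`` (date-like or integer day) and
    ``days_supply`` columns and must be sorted by fill date; a ``product``
    column, if present, must contain a single value. Returns a list of
    half-open ``(start, end)`` pairs, as numpy dates when the input holds
    dates (``origin`` defaults to the first fill date), otherwise as ints.
    """
    if "product" in fills.columns and fills["product"].nunique() > 1:
        raise InputError("coverage_from_fills requires a single product class")
    dates = fills["fill_date"]
    if pd.api.types.is_integer_dtype(dates):
        return _coverage(dates.to_numpy(), fills["days_supply"].to_numpy(), policy)
    dates = pd.to_datetime(dates)
    if origin is None:
        origin = dates.iloc[0]
    days = (dates - pd.Timestamp(origin)).dt.days.to_numpy()
    iv = _coverage(days, fills["days_supply"].to_numpy(), policy)
    o = np.datetime64(pd.Timestamp(origin), "D")
    return [(o + s, o + e) for s, e in iv]


def fill_intervals(days, supplies, policy: GracePolicy) -> list:
    """Per-fill coverage intervals [fill, fill + coverage_days), unmerged."""
    days = np.asarray(days, dtype=np.int64)
    if len(days) > 1 and (np.diff(days) < 0).any():
        raise InputError("fills must be sorted by fill date")
    supplies = np.broadcast_to(np.asarray(supplies, dtype=np.int64), days.shape)
    return [(int(d), int(d) + policy.coverage_days(int(s)))
            for d, s in zip(days, supplies)]


def tile_exposure(obs_lo: int, obs_hi: int, mdi_cov, dpi_cov) -> list:
    """Tile an observation window into (state, start, end) periods.

    ``mdi_cov``/``dpi_cov`` are per-fill coverage interval lists (int days,
    sorted by start; merged same-class intervals also work). The
    later-starting fill wins from its start date — a switch truncates the
    prior fill's remaining coverage, which does not resume — so each day's
    state is that of the most recent fill, or ``neither`` once that fill's
    coverage has run out. On an exact start tie the switch target (DPI)
    wins. Uncovered time becomes ``neither``; the result partitions
    [obs_lo, obs_hi) exactly, and each day's exposed/unexposed status is
    monotone in the grace fraction.
    """
    if obs_lo >= obs_hi:
        return []
    tagged = sorted(
        [(s, e, MDI) for s, e in mdi_cov] + [(s, e, DPI) for s, e in dpi_cov],
        key=lambda t: (t[0], t[2] == DPI),
    )
    exposed: list = []
    cur = None
    for s, e, st in tagged:
        s, e = max(s, obs_lo), min(e, obs_hi)
        if s >= e:
            continue
        if cur is None:
            cur = [st, s, e]
        elif s >= cur[2]:
            exposed.append(tuple(cur))
            cur = [st, s, e]
        else:  # overlap: the later-starting fill truncates the earlier one
            if s > cur[1]:
                exposed.append((cur[0], cur[1], s))
            cur = [st, s, e]
    if cur is not None:
        exposed.append(tuple(cur))
    # coalesce contiguous same-state runs (adjacent fills of one class)
    merged: list = []
    for st, s, e in exposed:
        if merged and merged[-1][0] == st and merged[-1][2] == s:
            merged[-1][2] = e
        else:
            merged.append([st, s, e])
    out: list = []
    prev = obs_lo
    for st, s, e in merged:
        if s > prev:
            out.append((NEITHER, prev, s))
        out.append((st, s, e))
        prev = e
    if prev < obs_hi:
        out.append((NEITHER, prev, obs_hi))
    return out


def build_exposure_periods(fills: pd.DataFrame, policy: GracePolicy, *,
                           study_start, study_end, death_date=None) -> pd.DataFrame:
    """Tiled exposure periods for one patient.

    ``fills`` holds the patient's controller fills (must contain at least
    one). Returns a DataFrame with ``state``, ``start``, ``end`` (datetime64)
    plus integer ``start_day``/``end_day`` offsets from ``study_start``.
    """
    ctrl = fills[fills["product"].isin(CONTROLLER_PRODUCTS)]
    if ctrl.empty:
        raise InputError("patient has no controller fills")
    origin = study_start
    days = (pd.to_datetime(ctrl["fill_date"]) - pd.Timestamp(origin)).dt.days.to_numpy()
    order = np.argsort(days, kind="stable")
    days, prods = days[order], ctrl["product"].to_numpy()[order]
    supplies = ctrl["days_supply"].to_numpy()[order]
    obs_lo = int(days.min())
    obs_hi = tg.day_index(study_end, origin) + 1
    if death_date is not None and not pd.isna(death_date):
        obs_hi = min(obs_hi, tg.day_index(death_date, origin) + 1)
    mdi_cov = fill_intervals(days[prods == "bf_mdi"],
                             supplies[prods == "bf_mdi"], policy)
    dpi_cov = fill_intervals(days[prods == "fs_dpi"],
                             supplies[prods == "fs_dpi"], policy)
    rows = tile_exposure(obs_lo, obs_hi, mdi_cov, dpi_cov)
    df = pd.DataFrame(rows, columns=["state", "start_day", "end_day"])
    df["start"] = tg.days_to_dates(df["start_day"].to_numpy(), origin)
    df["end"] = tg.days_to_dates(df["end_day"].to_numpy(), origin)
    return df


def build_exposure_table(patients: pd.DataFrame, fills: pd.DataFrame,
                         policy: GracePolicy, *, study_start,
                         study_end) -> pd.DataFrame:
    """Tiled exposure periods for every patient with a controller fill."""
    death = patients.set_index("patient_id")["death_date"] \
        if "death_date" in patients.columns else pd.Series(dtype="datetime64[ns]")
    ctrl = fills[fills["product"].isin(CONTROLLER_PRODUCTS)]
    frames = []
    for pid, grp in ctrl.groupby("patient_id", sort=True):
        dd = death.get(pid) if pid in death.index else None
        df = build_exposure_periods(grp, policy, study_start=study_start,
                                    study_end=study_end, death_date=dd)
        if df.empty:
            continue
        df.insert(0, "patient_id", pid)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["patient_id", "state", "start_day", "end_day", "start", "end"]
        )
    return pd.concat(frames, ignore_index=True)


def sccs_inclusion(fills: pd.DataFrame, window_start) -> np.ndarray:
    """Patients with an MDI fill before and a DPI fill on/after window start."""
    ws = pd.Timestamp(window_start)
    dates = pd.to_datetime(fills["fill_date"])
    pre = fills.loc[(fills["product"] == "bf_mdi") & (dates < ws), "patient_id"]
    post = fills.loc[(fills["product"] == "fs_dpi") & (dates >= ws), "patient_id"]
    return np.intersect1d(pre.unique(), post.unique())


def gap_exclusion(periods: pd.DataFrame,
                  max_gap_days: int = DEFAULT_MAX_GAP_DAYS) -> pd.Series:
    """Flag patients with an uncovered gap longer than ``max_gap_days``.

    Only ``neither`` periods lying strictly between two exposed (MDI or DPI)
    periods count as treatment gaps; a gap of exactly ``max_gap_days`` days
    is retained. Returns a boolean Series (True = excluded) indexed by
    patient_id.
    """
    if periods.empty:
        return pd.Series(dtype=bool)
    df = periods.sort_values(["patient_id", "start_day"], kind="stable")
    exposed = (df["state"] != NEITHER).to_numpy()
    g = df.groupby("patient_id", sort=True)
    before = g["state"].transform(lambda s: (s != NEITHER).cummax()).to_numpy()
    after = g["state"].transform(
        lambda s: (s != NEITHER)[::-1].cummax()[::-1]).to_numpy()
    length = (df["end_day"] - df["start_day"]).to_numpy()
    is_gap = (~exposed) & before.astype(bool) & after.astype(bool) \
        & (length > max_gap_days)
    return pd.Series(is_gap, index=df["patient_id"]).groupby(level=0).any()
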