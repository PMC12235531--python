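"""Segmentation of exposure periods into constant-covariate person-time.

Each patient's observation window is split at every exposure boundary,
calendar-quarter boundary, 5-year age-band crossing, and region-move date.
Within a resulting interval the exposure state, age band, quarter, and
region are all constant; outcome events are assigned to the interval
containing their date, and a patient's intervals tile the observation
window exactly (half-open, day resolution). Events dated outside a
patient's observation window are dropped with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import timegrid as tg
from .config import SCCS_OUTCOMES
from .errors import InputError
from .io import parse_region_timeline
from .outcomes import CauseClassifier, DEFAULT_CLASSIFIER, classify_codes, \
    round_half_up

logger = logging.getLogger(__name__)

META_COLUMNS = ["patient_id", "start", "end", "exposure", "age_band",
                "quarter", "region", "length_days"]


@dataclass
class SCCSDesign:
    """Analysis-side knobs: outcome set and rescue-med standardization."""

    outcomes: tuple = SCCS_OUTCOMES
    doses_per_inhaler_equivalent: float = 100.0


def _per_patient_slices(pidx: np.ndarray, n: int) -> np.ndarray:
    """Prefix boundaries of a sorted integer patient-index array."""
    return np.searchsorted(pidx, np.arange(n + 1))


def _event_day_arrays(df: pd.DataFrame, mask, pid_to_idx, origin, n):
    """Sorted per-patient day arrays for rows of ``df`` selected by ``mask``."""
    sub = df.loc[mask, ["patient_id", "_day"]]
    pidx = sub["patient_id"].map(pid_to_idx).to_numpy(dtype=np.int64)
    day = sub["_day"].to_numpy(dtype=np.int64)
    order = np.lexsort((day, pidx))
    pidx, day = pidx[order], day[order]
    return day, _per_patient_slices(pidx, n)


def segment_person_time(periods, birth_day: int, timeline_days, timeline_regions,
                        quarter_boundaries, qday, outcome_days: dict,
                        neb_days=None, neb_doses=None,
                        doses_per_equivalent: float = 100.0):
    """Segment one patient's tiled periods; returns (rows dict, n_dropped).

    ``periods`` is a list of (state, start_day, end_day); ``outcome_days``
    maps outcome name -> sorted int day array (for albuterol these are the
    MDI fill days; nebulized dispensings come in via ``neb_days``/
    ``neb_doses`` and are converted to inhaler equivalents per interval).
    """
    lo, hi = periods[0][1], periods[-1][2]
    starts = np.array([s for _, s, _ in periods], dtype=np.int64)
    cuts = np.unique(np.concatenate([
        starts, [hi],
        quarter_boundaries[(quarter_boundaries > lo) & (quarter_boundaries < hi)],
        tg.band_crossings(birth_day, lo, hi),
        np.asarray([d for d in timeline_days if lo < d < hi], dtype=np.int64),
    ]))
    seg_start, seg_end = cuts[:-1], cuts[1:]
    exp_idx = np.searchsorted(starts, seg_start, side="right") - 1
    states = np.array([st for st, _, _ in periods], dtype=object)
    rows = {
        "start": seg_start,
        "end": seg_end,
        "exposure": states[exp_idx],
        "age_band": tg.age_band(seg_start, birth_day),
        "quarter": qday[seg_start],
        "region": np.asarray(timeline_regions, dtype=object)[
            np.searchsorted(timeline_days, seg_start, side="right") - 1],
        "length_days": seg_end - seg_start,
    }
    dropped = 0
    for name, ev in outcome_days.items():
        ev = np.asarray(ev, dtype=np.int64)
        ok = (ev >= lo) & (ev < hi)
        dropped += int((~ok).sum())
        idx = np.searchsorted(cuts, ev[ok], side="right") - 1
        rows[name] = np.bincount(idx, minlength=len(seg_start)).astype(np.int64)
    if neb_days is not None and len(neb_days):
        nd = np.asarray(neb_days, dtype=np.int64)
        ok = (nd >= lo) & (nd < hi)
        dropped += int((~ok).sum())
        idx = np.searchsorted(cuts, nd[ok], side="right") - 1
        dose_sum = np.bincount(idx, weights=np.asarray(neb_doses, float)[ok],
                               minlength=len(seg_start))
        if "albuterol" in rows:
            rows["albuterol"] = rows["albuterol"] + round_half_up(
                dose_sum / doses_per_equivalent)
    return rows, dropped


def build_person_time(patients: pd.DataFrame, exposure_periods: pd.DataFrame,
                      fills: pd.DataFrame, events: pd.DataFrame, *,
                      study_start, study_end, design: SCCSDesign = None,
                      classifier: CauseClassifier = DEFAULT_CLASSIFIER
                      ) -> pd.DataFrame:
    """Constant-covariate person-time intervals for a whole cohort.

    Returns one row per interval with the metadata columns plus one event
    count column per outcome in ``design.outcomes``.
    """
    design = design or SCCSDesign()
    origin = study_start
    n_days = tg.day_index(study_end, origin) + 1
    qday = tg.quarter_of_days(origin, n_days)
    qbound = tg.quarter_start_days(origin, n_days)

    pids = exposure_periods["patient_id"].unique()
    pid_to_idx = {p: i for i, p in enumerate(pids)}
    n = len(pids)

    pinfo = patients.set_index("patient_id")
    birth_days = {
        p: tg.day_index(pinfo.at[p, "birth_date"], origin) for p in pids}
    timelines = {}
    for p in pids:
        tl = parse_region_timeline(pinfo.at[p, "region_timeline"])
        timelines[p] = (
            np.array([tg.day_index(d, origin) for d, _ in tl], dtype=np.int64),
            [r for _, r in tl])

    # ---- pre-index events and fills by patient and outcome
    ev = events.copy()
    sources = {}
    if len(ev):
        ev["_day"] = (pd.to_datetime(ev["event_date"])
                      - pd.Timestamp(origin)).dt.days
        ev = ev[ev["patient_id"].isin(pid_to_idx)]
        cause = classify_codes(ev["principal_icd10"], classifier)
        is_ed = (ev["encounter"] == "ed_visit").to_numpy()
        is_hosp = (ev["encounter"] == "hospitalization").to_numpy()
        masks = {
            "ed_all": is_ed,
            "ed_respiratory": is_ed & np.isin(cause, ("copd", "asthma")),
            "ed_pneumonia": is_ed & (cause == "pneumonia"),
            "hosp_all": is_hosp,
            "hosp_respiratory": is_hosp & np.isin(cause, ("copd", "asthma")),
            "hosp_pneumonia": is_hosp & (cause == "pneumonia"),
        }
        for name, m in masks.items():
            if name in design.outcomes:
                sources[name] = _event_day_arrays(ev, m, pid_to_idx, origin, n)
    fl = fills.copy()
    neb_src = None
    if len(fl):
        fl["_day"] = (pd.to_datetime(fl["fill_date"])
                      - pd.Timestamp(origin)).dt.days
        fl = fl[fl["patient_id"].isin(pid_to_idx)]
        prod = fl["product"].to_numpy()
        if "albuterol" in design.outcomes:
            sources["albuterol"] = _event_day_arrays(
                fl, prod == "albuterol_mdi", pid_to_idx, origin, n)
            neb = fl[prod == "albuterol_neb"]
            if len(neb):
                if neb["neb_doses"].isna().any():
                    raise InputError("nebulized albuterol fill lacks neb_doses")
                pidx = neb["patient_id"].map(pid_to_idx).to_numpy(np.int64)
                day = neb["_day"].to_numpy(np.int64)
                doses = neb["neb_doses"].to_numpy(dtype=float)
                order = np.lexsort((day, pidx))
                neb_src = (day[order], doses[order],
                           _per_patient_slices(pidx[order], n))
        if "prednisone" in design.outcomes:
            sources["prednisone"] = _event_day_arrays(
                fl, prod == "prednisone", pid_to_idx, origin, n)
    for name in design.outcomes:
        if name not in sources:
            sources[name] = (np.empty(0, np.int64), np.zeros(n + 1, np.int64))

    # ---- per-patient segmentation
    grouped = exposure_periods.sort_values(
        ["patient_id", "start_day"], kind="stable")
    pcodes = grouped["patient_id"].map(pid_to_idx).to_numpy(np.int64)
    order = np.argsort(pcodes, kind="stable")
    pcodes = pcodes[order]
    st = grouped["state"].to_numpy()[order]
    sd = grouped["start_day"].to_numpy(np.int64)[order]
    ed = grouped["end_day"].to_numpy(np.int64)[order]
    ptr = _per_patient_slices(pcodes, n)

    parts, total_dropped = [], 0
    for i, p in enumerate(pids):
        a, b = ptr[i], ptr[i + 1]
        periods = list(zip(st[a:b], sd[a:b], ed[a:b]))
        tdays, tregions = timelines[p]
        outcome_days = {}
        for name in design.outcomes:
            day, slc = sources[name]
            outcome_days[name] = day[slc[i]:slc[i + 1]]
        kw = {}
        if neb_src is not None:
            nd, ndo, nslc = neb_src
            kw = {"neb_days": nd[nslc[i]:nslc[i + 1]],
                  "neb_doses": ndo[nslc[i]:nslc[i + 1]],
                  "doses_per_equivalent": design.doses_per_inhaler_equivalent}
        rows, dropped = segment_person_time(
            periods, birth_days[p], tdays, tregions, qbound, qday,
            outcome_days, **kw)
        total_dropped += dropped
        rows["patient_id"] = np.full(len(rows["start"]), p, dtype=object)
        parts.append(rows)
    if total_dropped:
        logger.warning("dropped %d events/fills outside observation windows",
                       total_dropped)
    if not parts:
        return pd.DataFrame(columns=META_COLUMNS + list(design.outcomes))
    out = {key: np.concatenate([pt[key] for pt in parts])
           for key in parts[0]}
    df = pd.DataFrame(out)
    df["start_day"] = df.pop("start")
    df["end_day"] = df.pop("end")
    df["start"] = tg.days_to_dates(df["start_day"].to_numpy(), origin)
    df["end"] = tg.days_to_dates(df["end_day"].to_numpy(), origin)
    cols = ["patient_id", "start", "end", "start_day", "end_day", "exposure",
            "age_band", "quarter", "region", "length_days"] \
        + [o for o in design.outcomes]
    return df[cols]
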