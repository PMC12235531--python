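"""Synthetic claims cohort generator.

Generates seeded patients, controller-inhaler fill histories that switch
from budesonide-formoterol MDI to fluticasone-salmeterol DPI inside the
formulary window, and outcome event streams drawn from piecewise-constant
Poisson processes at day resolution (events per day ~ Poisson of the daily
rate, which is exact for piecewise-constant rates on a whole-day grid).

The generator's ground-truth DPI exposure state is the grace-1/3 coverage of
the controller fills with switch truncation — i.e. the same rule the primary
analysis applies — so downstream estimates are checked against a truth that
is well defined at the day grain. Deaths censor both event generation and
fills; region moves happen only at calendar-quarter boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import timegrid as tg
from .config import CohortConfig, OUTCOME_STREAMS
from .exposure import DPI, GracePolicy, fill_intervals, tile_exposure
from .io import FILL_COLUMNS, EVENT_COLUMNS, PATIENT_COLUMNS, \
    format_region_timeline, write_cohort

# Population mix of the emulated cohort: older, mostly male veterans with
# COPD and/or asthma, regionally weighted to the South.
FEMALE_FRACTION = 0.086
COPD_PREVALENCE = 0.692
ASTHMA_PREVALENCE = 0.324
SMOKING_P = (0.278, 0.526, 0.196)  # current, former, never
COMBAT_FRACTION = 0.304
REGION_WEIGHTS_4 = (0.448, 0.242, 0.186, 0.124)
MEAN_AGE_AT_SWITCH, SD_AGE = 69.0, 10.0
CONTROLLER_DAYS_SUPPLY = 30
ENTRY_LEAD_DAYS = 90  # every patient enters at least this long before the window

# ICD-10 principal-code pools per cause; classification round-trips.
RESPIRATORY_CODES = ("J441", "J440", "J449", "J439", "J42", "J4520", "J45901", "J469")
PNEUMONIA_CODES = ("J189", "J159", "J181", "J13", "J121", "A3701", "B052", "J851")
OTHER_CODES = ("I509", "N179", "K921", "R079", "S0990XA", "E1165")

_ENCOUNTER_STREAMS = (
    ("ed_other", "ed_visit", OTHER_CODES),
    ("ed_respiratory", "ed_visit", RESPIRATORY_CODES),
    ("ed_pneumonia", "ed_visit", PNEUMONIA_CODES),
    ("hosp_other", "hospitalization", OTHER_CODES),
    ("hosp_respiratory", "hospitalization", RESPIRATORY_CODES),
    ("hosp_pneumonia", "hospitalization", PNEUMONIA_CODES),
)


@dataclass
class SyntheticCohort:
    """The three claims tables plus generator bookkeeping."""

    patients: pd.DataFrame
    fills: pd.DataFrame
    events: pd.DataFrame
    config: CohortConfig
    truth: pd.DataFrame  # synthetic ground truth: entry/switch/death per patient
    expected_event_totals: dict  # analytic sum of daily rates per stream

    def to_csv(self, outdir) -> None:
        write_cohort(outdir, self.patients, self.fills, self.events,
                     config=self.config)
        self.truth.to_csv(f"{outdir}/truth.csv", index=False)


def generate_region_moves(config: CohortConfig, rng: np.random.Generator,
                          n: int = 1) -> list:
    """Region timelines for ``n`` patients, as [(day_index, region_index)].

    Timelines start at day 0 (study start), cover the whole study period,
    and move only at calendar-quarter boundaries, each boundary
    independently with probability ``region_move_probability``; a move
    always lands on a different region.
    """
    k = config.n_regions
    n_days = tg.day_index(config.study_end, config.study_start) + 1
    boundaries = tg.quarter_start_days(config.study_start, n_days)
    weights = np.asarray(REGION_WEIGHTS_4, dtype=float) if k == 4 \
        else np.full(k, 1.0 / k)
    weights = weights / weights.sum()
    cur = rng.choice(k, size=n, p=weights)
    timelines = [[(0, int(cur[i]))] for i in range(n)]
    if k < 2 or config.region_move_probability == 0:
        return timelines
    moves = rng.random((n, len(boundaries))) < config.region_move_probability
    jumps = rng.integers(1, k, size=(n, len(boundaries)))
    for j, b in enumerate(boundaries):
        movers = np.nonzero(moves[:, j])[0]
        cur[movers] = (cur[movers] + jumps[movers, j]) % k
        for i in movers:
            timelines[i].append((int(b), int(cur[i])))
    return timelines


def _region_grid(timelines, n_days: int) -> np.ndarray:
    g = np.empty((len(timelines), n_days), dtype=np.int8)
    for i, tl in enumerate(timelines):
        nxt = [t[0] for t in tl[1:]] + [n_days]
        for (s, r), e in zip(tl, nxt):
            g[i, s:e] = r
    return g


def _empty_tables(config):
    patients = pd.DataFrame(columns=PATIENT_COLUMNS)
    fills = pd.DataFrame(columns=FILL_COLUMNS)
    events = pd.DataFrame(columns=EVENT_COLUMNS)
    truth = pd.DataFrame(columns=["patient_id", "entry_date", "is_switcher",
                                  "switch_date", "death_date"])
    return SyntheticCohort(patients, fills, events, config, truth, {})


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one synthetic cohort; identical config+seed is byte-stable."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    origin = config.study_start
    n_days = tg.day_index(config.study_end, origin) + 1
    win_lo = tg.day_index(config.formulary_window[0], origin)
    win_hi = tg.day_index(config.formulary_window[1], origin)
    n = config.n_patients
    if n == 0:
        return _empty_tables(config)

    # ---- patient-level draws (fixed call order for reproducibility)
    age_at_switch = np.clip(rng.normal(MEAN_AGE_AT_SWITCH, SD_AGE, n), 40.0, 95.0)
    birth_day = win_lo - np.rint(age_at_switch * tg.DAYS_PER_YEAR).astype(np.int64)
    sex = np.where(rng.random(n) < FEMALE_FRACTION, "female", "male")
    copd = rng.random(n) < COPD_PREVALENCE
    asthma = rng.random(n) < ASTHMA_PREVALENCE
    copd[~copd & ~asthma] = True  # every patient carries a qualifying diagnosis
    smoking = rng.choice(np.array(["current", "former", "never"]), size=n,
                         p=SMOKING_P)
    combat = rng.random(n) < COMBAT_FRACTION
    if config.death_rate > 0:
        death_day = np.floor(
            rng.exponential(1.0 / config.death_rate, n) * tg.DAYS_PER_YEAR
        ).astype(np.int64)
    else:
        death_day = np.full(n, np.iinfo(np.int64).max // 4)
    obs_end = np.minimum(death_day + 1, n_days)  # exclusive
    entry_day = rng.integers(0, win_lo - ENTRY_LEAD_DAYS, size=n)
    is_switcher = rng.random(n) < config.switch_probability
    switch_day = rng.integers(win_lo, win_hi + 1, size=n)
    timelines = generate_region_moves(config, rng, n)
    region_grid = _region_grid(timelines, n_days)

    # ---- controller fill histories
    max_fills = n_days // CONTROLLER_DAYS_SUPPLY + 2
    gap_flag = rng.random((n, max_fills)) < config.gap_probability
    gap_len = rng.geometric(1.0 / config.mean_gap_days, size=(n, max_fills))
    f_pid, f_day, f_prod = [], [], []
    bf_days = [[] for _ in range(n)]
    fs_days = [[] for _ in range(n)]
    for i in range(n):
        d, end, j = int(entry_day[i]), int(obs_end[i]), 0
        sw = bool(is_switcher[i])
        while d < end and j < max_fills:
            if sw:
                prod = "bf_mdi" if d < switch_day[i] else "fs_dpi"
                (bf_days[i] if prod == "bf_mdi" else fs_days[i]).append(d)
            else:
                prod = "other_controller"
            f_pid.append(i)
            f_day.append(d)
            f_prod.append(prod)
            d += CONTROLLER_DAYS_SUPPLY + (int(gap_len[i, j]) if gap_flag[i, j] else 0)
            j += 1

    # ---- ground-truth DPI exposure grid (grace-1/3 coverage, switch-truncated)
    policy = GracePolicy(1 / 3)
    dpi_mask = np.zeros((n, n_days), dtype=bool)
    for i in range(n):
        if obs_end[i] <= entry_day[i] or not fs_days[i]:
            continue
        cov_bf = fill_intervals(bf_days[i], CONTROLLER_DAYS_SUPPLY, policy)
        cov_fs = fill_intervals(fs_days[i], CONTROLLER_DAYS_SUPPLY, policy)
        for st, s, e in tile_exposure(int(entry_day[i]), int(obs_end[i]),
                                      cov_bf, cov_fs):
            if st == DPI:
                dpi_mask[i, s:e] = True

    # ---- daily log-rate offsets shared by all streams
    eff = config.covariate_effects
    k = config.n_regions
    qday = tg.quarter_of_days(origin, n_days).astype(np.float64)
    seasonal = np.cos(2 * np.pi * (qday - 1) / 4.0)
    region_off = np.array([eff.region_offsets[r % len(eff.region_offsets)]
                           for r in range(k)])
    phase = (np.arange(k) % 4) * (np.pi / 2)
    days = np.arange(n_days)
    band = tg.age_band(days[None, :], birth_day[:, None])
    log_offset = (
        eff.age_band_slope * (band - eff.reference_age_band)
        + eff.quarter_amplitude * seasonal[None, :]
        + region_off[region_grid]
        + eff.interaction_amplitude
        * np.cos(2 * np.pi * (qday[None, :] - 1) / 4.0 + phase[region_grid])
    )
    observed = (days[None, :] >= entry_day[:, None]) \
        & (days[None, :] < obs_end[:, None])

    # ---- event streams: Poisson per day, masked to each patient's window
    expected_totals = {}
    stream_events = {}
    for name in OUTCOME_STREAMS:
        if name not in config.baseline_rate:
            continue
        base = config.baseline_rate[name]
        if base == 0:
            expected_totals[name] = 0.0
            stream_events[name] = (np.empty(0, np.int64), np.empty(0, np.int64))
            continue
        irr = config.true_log_irr.get(name, 0.0)
        lam = np.exp(np.log(base / tg.DAYS_PER_YEAR) + log_offset
                     + irr * dpi_mask)
        lam = np.where(observed, lam, 0.0)
        counts = rng.poisson(lam)
        expected_totals[name] = float(lam.sum())
        pi, dj = np.nonzero(counts)
        c = counts[pi, dj]
        stream_events[name] = (np.repeat(pi, c), np.repeat(dj, c))

    # ---- assemble fills (controller + albuterol + prednisone)
    pid_labels = np.array([f"P{i:06d}" for i in range(n)])
    fill_frames = [pd.DataFrame({
        "patient_id": pid_labels[np.asarray(f_pid, dtype=np.int64)],
        "fill_date": tg.days_to_dates(np.asarray(f_day, dtype=np.int64), origin),
        "product": f_prod,
        "days_supply": CONTROLLER_DAYS_SUPPLY,
        "neb_doses": pd.array([None] * len(f_pid), dtype="Int64"),
    })]
    if "albuterol" in stream_events:
        pi, dj = stream_events["albuterol"]
        is_neb = rng.random(len(pi)) < config.neb_fraction
        fill_frames.append(pd.DataFrame({
            "patient_id": pid_labels[pi],
            "fill_date": tg.days_to_dates(dj, origin),
            "product": np.where(is_neb, "albuterol_neb", "albuterol_mdi"),
            "days_supply": CONTROLLER_DAYS_SUPPLY,
            "neb_doses": pd.array(
                np.where(is_neb, config.neb_doses, None), dtype="Int64"),
        }))
    if "prednisone" in stream_events:
        pi, dj = stream_events["prednisone"]
        fill_frames.append(pd.DataFrame({
            "patient_id": pid_labels[pi],
            "fill_date": tg.days_to_dates(dj, origin),
            "product": "prednisone",
            "days_supply": 1,  # discrete course
            "neb_doses": pd.array([None] * len(pi), dtype="Int64"),
        }))
    fills = pd.concat(fill_frames, ignore_index=True)
    fills = fills.sort_values(
        ["patient_id", "fill_date", "product"], kind="stable"
    ).reset_index(drop=True)[FILL_COLUMNS]

    # ---- assemble ED / hospitalization events with cause-matched codes
    event_frames = []
    for name, encounter, pool in _ENCOUNTER_STREAMS:
        if name not in stream_events:
            continue
        pi, dj = stream_events[name]
        codes = rng.choice(np.array(pool), size=len(pi))
        event_frames.append(pd.DataFrame({
            "patient_id": pid_labels[pi],
            "event_date": tg.days_to_dates(dj, origin),
            "encounter": encounter,
            "principal_icd10": codes,
        }))
    if event_frames:
        events = pd.concat(event_frames, ignore_index=True)
        events = events.sort_values(
            ["patient_id", "event_date", "encounter", "principal_icd10"],
            kind="stable").reset_index(drop=True)[EVENT_COLUMNS]
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)

    # ---- patients table and ground-truth bookkeeping
    region_names = config.regions
    death_dates = pd.Series(
        np.where(death_day < n_days,
                 tg.days_to_dates(np.minimum(death_day, n_days - 1), origin),
                 np.datetime64("NaT")))
    patients = pd.DataFrame({
        "patient_id": pid_labels,
        "birth_date": tg.days_to_dates(birth_day, origin),
        "sex": sex,
        "copd": copd,
        "asthma": asthma,
        "smoking": smoking,
        "combat_veteran": combat,
        "region_timeline": [
            format_region_timeline(
                [(tg.days_to_dates(s, origin), region_names[r]) for s, r in tl])
            for tl in timelines],
        "death_date": death_dates,
    })[PATIENT_COLUMNS]
    truth = pd.DataFrame({
        "patient_id": pid_labels,
        "entry_date": tg.days_to_dates(entry_day, origin),
        "is_switcher": is_switcher,
        "switch_date": pd.Series(np.where(
            is_switcher, tg.days_to_dates(switch_day, origin),
            np.datetime64("NaT"))),
        "death_date": death_dates,
        "has_dpi_fill": [len(d) > 0 for d in fs_days],
    })
    return SyntheticCohort(patients, fills, events, config, truth,
                           expected_totals)
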