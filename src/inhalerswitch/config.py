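"""Generator configuration: study window, event-rate model, population mix.

The defaults describe the study setting the pipeline is built for: a
five-year observation window (2018-01-01 to 2022-12-31) around a national
formulary switch carried out between 2021-07-01 and 2021-09-30, in which a
budesonide-formoterol metered-dose inhaler (MDI) was replaced by a
fluticasone-salmeterol dry-powder inhaler (DPI) as the preferred combination
controller. Outcome event streams are piecewise-constant Poisson processes
whose log daily rate is

    log(baseline_rate / 365.25)
      + true_log_irr * 1[DPI-exposed]
      + age-band, calendar-quarter, region and quarter-by-region offsets.

Streams are cause-specific (ED and hospitalization each split into
respiratory, pneumonia, and other causes) so that ICD-10 cause
classification round-trips; the all-cause analysis outcomes are the unions
of the cause streams, and their implied rate ratio is the rate-weighted
mixture of the stream-level ratios.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field

from .errors import ConfigError

CENSUS_REGIONS = ("South", "Midwest", "West", "Northeast")
CENSUS_DIVISIONS = (
    "New England", "Middle Atlantic", "East North Central", "West North Central",
    "South Atlantic", "East South Central", "West South Central", "Mountain",
    "Pacific",
)

#: cause-specific event streams the generator can simulate
OUTCOME_STREAMS = (
    "albuterol", "prednisone",
    "ed_other", "ed_respiratory", "ed_pneumonia",
    "hosp_other", "hosp_respiratory", "hosp_pneumonia",
)

#: the eight outcomes of the within-person analysis
SCCS_OUTCOMES = (
    "albuterol", "prednisone",
    "ed_all", "ed_respiratory", "ed_pneumonia",
    "hosp_all", "hosp_respiratory", "hosp_pneumonia",
)

DEFAULT_STUDY_START = dt.date(2018, 1, 1)
DEFAULT_STUDY_END = dt.date(2022, 12, 31)
DEFAULT_FORMULARY_WINDOW = (dt.date(2021, 7, 1), dt.date(2021, 9, 30))

#: default true DPI-vs-MDI rate ratios, on the log scale (headline estimates
#: of the study setting; the two "other"-cause streams are set so the implied
#: all-cause mixtures land near the reported all-cause estimates)
DEFAULT_LOG_IRR = {
    "albuterol": math.log(0.90),
    "prednisone": math.log(1.02),
    "ed_other": math.log(1.04),
    "ed_respiratory": math.log(1.06),
    "ed_pneumonia": math.log(1.25),
    "hosp_other": math.log(1.06),
    "hosp_respiratory": math.log(1.10),
    "hosp_pneumonia": math.log(1.24),
}

#: baseline (MDI-reference) event rates, events per person-year
DEFAULT_BASELINE_RATE = {
    "albuterol": 6.0,
    "prednisone": 0.8,
    "ed_other": 0.25,
    "ed_respiratory": 0.12,
    "ed_pneumonia": 0.02,
    "hosp_other": 0.22,
    "hosp_respiratory": 0.05,
    "hosp_pneumonia": 0.05,
}


@dataclass(frozen=True)
class CovariateEffects:
    """Log-rate offsets for the time-varying covariates.

    ``quarter_amplitude`` drives a seasonal sinusoid over calendar quarters
    (peak in Q1); ``region_offsets`` are cycled over region index;
    ``interaction_amplitude`` adds a region-phase-shifted seasonal term so the
    quarter-by-region adjustment is exercised without overwhelming signal.
    """

    age_band_slope: float = 0.03
    reference_age_band: int = 13  # ages 65-70
    quarter_amplitude: float = 0.2
    region_offsets: tuple = (0.0, -0.1, 0.1, 0.2)
    interaction_amplitude: float = 0.05

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass
class CohortConfig:
    """Full specification of one synthetic claims cohort."""

    n_patients: int = 1000
    study_start: dt.date = DEFAULT_STUDY_START
    study_end: dt.date = DEFAULT_STUDY_END
    formulary_window: tuple = DEFAULT_FORMULARY_WINDOW
    true_log_irr: dict = field(default_factory=lambda: dict(DEFAULT_LOG_IRR))
    baseline_rate: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_RATE))
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    switch_probability: float = 0.65
    gap_probability: float = 0.20
    mean_gap_days: float = 21.0
    region_move_probability: float = 0.02
    death_rate: float = 0.035  # deaths per person-year
    n_regions: int = 4
    neb_fraction: float = 0.10  # share of albuterol dispensings that are nebulized
    neb_doses: int = 100  # doses per nebulized-albuterol dispensing
    seed: int = 0

    @property
    def regions(self) -> tuple:
        return CENSUS_REGIONS if self.n_regions == 4 else CENSUS_DIVISIONS[: self.n_regions]

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients: must be non-negative")
        lo, hi = self.formulary_window
        if not (self.study_start < lo < hi < self.study_end):
            raise ConfigError(
                "formulary_window: requires study_start < window start < "
                "window end < study_end"
            )
        for name, rate in self.baseline_rate.items():
            if name not in OUTCOME_STREAMS:
                raise ConfigError(f"baseline_rate: unknown outcome stream {name!r}")
            if rate < 0:
                raise ConfigError(f"baseline_rate: {name} must be >= 0")
        for name in self.true_log_irr:
            if name not in OUTCOME_STREAMS:
                raise ConfigError(f"true_log_irr: unknown outcome stream {name!r}")
        for name in ("switch_probability", "gap_probability",
                     "region_move_probability", "neb_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: must lie in [0, 1]")
        if self.death_rate < 0:
            raise ConfigError("death_rate: must be >= 0")
        if self.mean_gap_days <= 0:
            raise ConfigError("mean_gap_days: must be positive")
        if self.n_regions not in (4, 9):
            raise ConfigError("n_regions: must be 4 (census regions) or 9 (divisions)")
        if self.neb_doses <= 0:
            raise ConfigError("neb_doses: must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        d["formulary_window"] = [x.isoformat() for x in self.formulary_window]
        d["covariate_effects"] = self.covariate_effects.to_dict()
        d["covariate_effects"]["region_offsets"] = list(
            self.covariate_effects.region_offsets
        )
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("study_start", "study_end"):
            if isinstance(d.get(key), str):
                d[key] = dt.date.fromisoformat(d[key])
        if "formulary_window" in d:
            d["formulary_window"] = tuple(
                dt.date.fromisoformat(x) if isinstance(x, str) else x
                for x in d["formulary_window"]
            )
        if isinstance(d.get("covariate_effects"), dict):
            eff = dict(d["covariate_effects"])
            if "region_offsets" in eff:
                eff["region_offsets"] = tuple(eff["region_offsets"])
            d["covariate_effects"] = CovariateEffects(**eff)
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
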