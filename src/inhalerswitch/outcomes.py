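"""ICD-10 cause classification and rescue-medication standardization.

Events are attributed to a cause by prefix-wildcard matching of the
principal ICD-10 code (dots ignored). The pneumonia list is checked first,
then COPD, then asthma: none of the printed code families actually collide,
but a fixed precedence guards malformed inputs. "Respiratory-related" in the
analysis means a principal diagnosis of COPD or asthma; pneumonia is its own
outcome family.

Nebulized albuterol dispensings are standardized to inhaler equivalents:
one metered-dose albuterol fill counts as one equivalent, and nebulized
doses are divided by a configurable doses-per-inhaler factor (default 100),
summed per patient-interval, and rounded half up to whole equivalents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

COPD_PATTERNS = ("J41", "J42", "J43", "J44")
ASTHMA_PATTERNS = ("J45", "J46")
PNEUMONIA_PATTERNS = (
    "J09X1", "J10", "J11", "J12", "J13", "J14", "J15", "J16", "J17", "J18",
    "A0103", "A0222", "A3701", "A3711", "A3781", "A3791", "A5484",
    "B012", "B052", "B0681", "B7781", "J851", "J22",
)

DOSES_PER_INHALER_EQUIVALENT = 100.0


def _normalize(code: str) -> str:
    return str(code).upper().replace(".", "").strip()


@dataclass(frozen=True)
class CauseClassifier:
    """Prefix-wildcard ICD-10 cause classifier with fixed precedence."""

    pneumonia_patterns: tuple = PNEUMONIA_PATTERNS
    copd_patterns: tuple = COPD_PATTERNS
    asthma_patterns: tuple = ASTHMA_PATTERNS

    def classify(self, code) -> str:
        """Return 'pneumonia', 'copd', 'asthma', or 'other' for one code."""
        if code is None or (isinstance(code, float) and math.isnan(code)):
            return "other"
        c = _normalize(code)
        if not c:
            return "other"
        for patterns, label in (
            (self.pneumonia_patterns, "pneumonia"),
            (self.copd_patterns, "copd"),
            (self.asthma_patterns, "asthma"),
        ):
            if c.startswith(patterns):
                return label
        return "other"


DEFAULT_CLASSIFIER = CauseClassifier()


def classify_event(event, classifier: CauseClassifier = DEFAULT_CLASSIFIER) -> str:
    """Classify one event record (anything with a ``principal_icd10`` key)."""
    try:
        code = event["principal_icd10"]
    except (KeyError, IndexError) as exc:
        raise InputError("event lacks a principal_icd10 code") from exc
    return classifier.classify(code)


def classify_codes(codes: pd.Series,
                   classifier: CauseClassifier = DEFAULT_CLASSIFIER) -> np.ndarray:
    """Vectorized cause classification of a Series of ICD-10 code strings."""
    s = codes.fillna("").astype(str).str.upper().str.replace(".", "", regex=False)
    cause = np.full(len(s), "other", dtype=object)
    for patterns, label in (
        (classifier.pneumonia_patterns, "pneumonia"),
        (classifier.copd_patterns, "copd"),
        (classifier.asthma_patterns, "asthma"),
    ):
        m = np.zeros(len(s), dtype=bool)
        for p in patterns:
            m |= s.str.startswith(p).to_numpy()
        cause = np.where((cause == "other") & m, label, cause)
    return cause


def round_half_up(x) -> np.ndarray:
    """Round to the nearest integer with halves rounded up."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def albuterol_equivalents(fills: pd.DataFrame,
                          doses_per_equivalent: float = DOSES_PER_INHALER_EQUIVALENT) -> int:
    """Inhaler-equivalent count for a set of albuterol fills.

    ``fills`` needs a ``product`` column with values ``albuterol_mdi`` /
    ``albuterol_neb``; nebulized rows must carry ``neb_doses``.
    """
    mdi = int((fills["product"] == "albuterol_mdi").sum())
    neb = fills[fills["product"] == "albuterol_neb"]
    if len(neb):
        if "neb_doses" not in neb.columns or neb["neb_doses"].isna().any():
            raise InputError("nebulized albuterol fill lacks neb_doses")
        neb_eq = float(neb["neb_doses"].astype(float).sum()) / doses_per_equivalent
    else:
        neb_eq = 0.0
    return mdi + int(round_half_up(neb_eq))
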