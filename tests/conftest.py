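"""Shared fixtures: small seeded synthetic cohorts and toy tables."""

import numpy as np
import pandas as pd
import pytest

from inhalerswitch import CohortConfig, OUTCOME_STREAMS, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 500-patient cohort under the default (study-condition) generator."""
    return generate_cohort(CohortConfig(n_patients=500, seed=123))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort generated with no exposure effect on any stream."""
    cfg = CohortConfig(n_patients=600, seed=7,
                       true_log_irr={s: 0.0 for s in OUTCOME_STREAMS})
    return generate_cohort(cfg)


def make_patient(pid="P1", birth="1950-06-15", sex="male", copd=True,
                 asthma=False, smoking="former", combat=False,
                 timeline="2018-01-01:South", death=None):
    """One-row patients table for hand-built scenarios."""
    return pd.DataFrame([{
        "patient_id": pid, "birth_date": pd.Timestamp(birth), "sex": sex,
        "copd": copd, "asthma": asthma, "smoking": smoking,
        "combat_veteran": combat, "region_timeline": timeline,
        "death_date": pd.Timestamp(death) if death else pd.NaT,
    }])


def make_fills(pid, rows):
    """rows: list of (date, product[, days_supply[, neb_doses]])."""
    out = []
    for row in rows:
        date, product = row[0], row[1]
        supply = row[2] if len(row) > 2 else 30
        neb = row[3] if len(row) > 3 else None
        out.append({"patient_id": pid, "fill_date": pd.Timestamp(date),
                    "product": product, "days_supply": supply,
                    "neb_doses": neb})
    df = pd.DataFrame(out)
    df["neb_doses"] = df["neb_doses"].astype("Int64")
    return df


def make_events(pid, rows):
    """rows: list of (date, encounter, icd10)."""
    return pd.DataFrame([
        {"patient_id": pid, "event_date": pd.Timestamp(d), "encounter": enc,
         "principal_icd10": code} for d, enc, code in rows])
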