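"""Per-patient, per-year inhaler-attributable greenhouse-gas accounting.

Metered-dose inhalers carry hydrofluorocarbon propellants with a large
per-device CO2-equivalent footprint; dry-powder inhalers do not. Emissions
are the sum over a patient's dispensed inhalers in a calendar year of the
per-device factor. The default factor table is an order-of-magnitude,
literature-typical placeholder (MDIs ~28 kg CO2e, DPIs ~1 kg) and is a
config input, not a claim about any specific product.
"""

from __future__ import annotations

import pandas as pd

from .errors import EmissionsError

#: kg CO2e per dispensed unit; provenance: literature-typical placeholders
DEFAULT_EMISSION_FACTORS = {
    "bf_mdi": 28.0,
    "fs_dpi": 1.0,
    "albuterol_mdi": 28.0,
    "albuterol_neb": 0.0,
    "prednisone": 0.0,
    "other_controller": 1.0,
}


def patient_year_emissions(fills: pd.DataFrame,
                           factors: dict = None) -> pd.DataFrame:
    """kg CO2e per (patient, calendar year): sum of per-fill factors."""
    factors = dict(DEFAULT_EMISSION_FACTORS if factors is None else factors)
    for v in factors.values():
        if v < 0:
            raise EmissionsError("emission factors must be >= 0")
    if fills.empty:
        return pd.DataFrame(columns=["patient_id", "year", "kg_co2e"])
    missing = set(fills["product"].unique()) - set(factors)
    if missing:
        raise EmissionsError(
            f"missing emission factor for product(s): {', '.join(sorted(missing))}")
    df = fills[["patient_id", "fill_date", "product"]].copy()
    df["year"] = pd.to_datetime(df["fill_date"]).dt.year
    df["kg_co2e"] = df["product"].map(factors).astype(float)
    out = df.groupby(["patient_id", "year"], as_index=False)["kg_co2e"].sum()
    return out.sort_values(["patient_id", "year"]).reset_index(drop=True)


def cohort_year_means(fills: pd.DataFrame, patients: pd.DataFrame = None,
                      factors: dict = None) -> pd.DataFrame:
    """Mean kg CO2e per cohort member per calendar year.

    The denominator in each year is the full cohort (``patients`` if given,
    else every patient appearing in ``fills``); patients with no fills that
    year contribute zero.
    """
    per = patient_year_emissions(fills, factors)
    if patients is not None:
        n = patients["patient_id"].nunique()
    else:
        n = fills["patient_id"].nunique() if len(fills) else 0
    if n == 0:
        return pd.DataFrame(columns=["year", "mean_kg_co2e"])
    out = per.groupby("year", as_index=False)["kg_co2e"].sum()
    out["mean_kg_co2e"] = out.pop("kg_co2e") / n
    return out
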