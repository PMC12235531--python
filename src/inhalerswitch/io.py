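"""Reading and writing the claims-shaped CSV tables.

The pipeline's common currency is three tables: ``patients.csv`` (one row
per patient; the region timeline is serialized as
``YYYY-MM-DD:Region;YYYY-MM-DD:Region;...``), ``fills.csv`` and
``events.csv``. All dates are ISO-8601; files are plain CSV so every
intermediate is inspectable.
"""

from __future__ import annotations

import hashlib
import json
import os

import pandas as pd

from .errors import InputError

PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "copd", "asthma",
                   "smoking", "combat_veteran", "region_timeline", "death_date"]
FILL_COLUMNS = ["patient_id", "fill_date", "product", "days_supply", "neb_doses"]
EVENT_COLUMNS = ["patient_id", "event_date", "encounter", "principal_icd10"]


def format_region_timeline(timeline) -> str:
    """Serialize [(start_date, region), ...] to the CSV string form."""
    return ";".join(f"{pd.Timestamp(s).date().isoformat()}:{r}" for s, r in timeline)


def parse_region_timeline(text: str) -> list:
    """Parse the serialized region timeline back to [(Timestamp, region)]."""
    out = []
    for tok in str(text).split(";"):
        if not tok:
            continue
        try:
            d, r = tok.split(":", 1)
            out.append((pd.Timestamp(d), r))
        except ValueError as exc:
            raise InputError(f"malformed region timeline token {tok!r}") from exc
    if not out:
        raise InputError("empty region timeline")
    return out


def write_cohort(outdir, patients: pd.DataFrame, fills: pd.DataFrame,
                 events: pd.DataFrame, config=None) -> None:
    os.makedirs(outdir, exist_ok=True)
    patients.to_csv(os.path.join(outdir, "patients.csv"), index=False)
    fills.to_csv(os.path.join(outdir, "fills.csv"), index=False)
    events.to_csv(os.path.join(outdir, "events.csv"), index=False)
    if config is not None:
        config.to_json(os.path.join(outdir, "config.json"))


def read_cohort(indir):
    """Load patients/fills/events CSVs with parsed dates."""
    paths = {name: os.path.join(indir, f"{name}.csv")
             for name in ("patients", "fills", "events")}
    for name, path in paths.items():
        if not os.path.exists(path):
            raise FileNotFoundError(path)
    patients = pd.read_csv(paths["patients"],
                           parse_dates=["birth_date", "death_date"])
    fills = pd.read_csv(paths["fills"], parse_dates=["fill_date"],
                        dtype={"neb_doses": "Int64"})
    events = pd.read_csv(paths["events"], parse_dates=["event_date"])
    return patients, fills, events


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(outdir, record: dict) -> None:
    """Write a JSON provenance record (config, seed, versions, checksums)."""
    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
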