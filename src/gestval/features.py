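"""Covariate extraction from encounter-linked relational tables.

Turns long-format vitals and labs, dated diagnosis codes and prior
admissions into the screening model's covariate vector, enforcing the
first-hours vitals window (default 240 minutes) and the one-year
admission lookback.  Extraction is pure: the same tables always yield
the same features.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "summarize_vitals",
    "select_labs",
    "count_admissions",
    "flag_diagnoses",
    "extract_features",
    "load_dx_catalog",
]

DEFAULT_VITALS_WINDOW_MINUTES = 240
ROOM_AIR_VALUES = frozenset({"room_air", "none", "ra", ""})

LAB_ANALYTES = (
    "hemoglobin",
    "hematocrit",
    "blood_urea_nitrogen",
    "red_cell_distribution_width",
    "lymphocyte_count",
    "mean_corpuscular_volume",
)


class FeatureExtractionError(ValueError):
    pass


def load_dx_catalog(path: str | Path | None = None) -> dict[str, tuple[str, ...]]:
    """Covariate -> ICD-10 prefix tuple.  ``None`` loads the shipped catalog."""
    if path is None:
        ref = resources.files("gestval.data").joinpath("gest_dx_catalog.yaml")
        with resources.as_file(ref) as p:
            return load_dx_catalog(p)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: tuple(str(p).upper() for p in v) for k, v in raw.items()}


def summarize_vitals(
    vitals: pd.DataFrame, window_minutes: int = DEFAULT_VITALS_WINDOW_MINUTES
) -> dict[str, float | bool | None]:
    """First-window vital summaries for one encounter.

    Mean heart rate, minimum systolic blood pressure, and whether any
    in-window oxygen-device observation indicates non-room-air.  Each
    output is ``None`` when the encounter has no in-window observation
    of that kind.  Observation offsets are minutes from ED arrival and
    must be non-negative.
    """
    if window_minutes <= 0:
        raise FeatureExtractionError("window_minutes must be positive")
    out: dict[str, float | bool | None] = {
        "mean_heart_rate": None,
        "min_systolic_bp": None,
        "supplemental_oxygen": None,
    }
    if vitals.empty:
        return out
    offsets = pd.to_numeric(vitals["offset_minutes"])
    if (offsets < 0).any():
        raise FeatureExtractionError("negative vital observation offsets (timestamp bug upstream)")
    inwin = vitals.loc[offsets <= window_minutes]
    hr = inwin.loc[inwin["vital"] == "heart_rate", "value"]
    if len(hr):
        out["mean_heart_rate"] = float(pd.to_numeric(hr).mean())
    sbp = inwin.loc[inwin["vital"] == "systolic_bp", "value"]
    if len(sbp):
        out["min_systolic_bp"] = float(pd.to_numeric(sbp).min())
    dev = inwin.loc[inwin["vital"] == "oxygen_device", "value"]
    if len(dev):
        out["supplemental_oxygen"] = bool(
            (~dev.astype(str).str.strip().str.lower().isin(ROOM_AIR_VALUES)).any()
        )
    return out


def select_labs(labs: pd.DataFrame) -> dict[str, float | None]:
    """Earliest resulted value per analyte for one encounter.

    Ties on result offset resolve to the lower row index (logged).
    Non-numeric results are an explicit failure naming the row.
    """
    out: dict[str, float | None] = {a: None for a in LAB_ANALYTES}
    if labs.empty:
        return out
    for analyte in LAB_ANALYTES:
        rows = labs.loc[labs["analyte"] == analyte]
        if rows.empty:
            continue
        vals = pd.to_numeric(rows["value"], errors="coerce")
        if vals.isna().any():
            bad = rows.loc[vals.isna()].index[0]
            raise FeatureExtractionError(
                f"non-numeric lab result for {analyte!r} at row {bad!r}: "
                f"{rows.loc[bad, 'value']!r}"
            )
        offsets = pd.to_numeric(rows["offset_minutes"])
        earliest = offsets.min()
        hits = rows.loc[offsets == earliest]
        if len(hits) > 1:
            log.debug("duplicate result offsets for %s; keeping lowest row index", analyte)
        out[analyte] = float(vals.loc[hits.index[0]])
    return out


def count_admissions(
    admissions: pd.DataFrame, patient_id: str, arrival_date: pd.Timestamp
) -> int:
    """Admissions in [arrival - 365 d, arrival), closed on the left."""
    if admissions.empty:
        return 0
    rows = admissions.loc[admissions["patient_id"] == patient_id]
    if rows.empty:
        return 0
    arrival = pd.Timestamp(arrival_date)
    dates = pd.to_datetime(rows["admit_date"])
    lo = arrival - pd.Timedelta(days=365)
    return int(((dates >= lo) & (dates < arrival)).sum())


def flag_diagnoses(
    diagnoses: pd.DataFrame,
    patient_id: str,
    arrival_date: pd.Timestamp,
    catalog: Mapping[str, Sequence[str]] | None = None,
    encounter_id: str | None = None,
    history_lookback_days: int | None = None,
) -> dict[str, bool]:
    """Diagnosis-history booleans for one encounter by ICD-10 prefix match.

    History flags are true iff any matching code is dated strictly
    before arrival (optionally within ``history_lookback_days``); the
    syncope/CVA flag comes only from codes attached to the index
    encounter itself.  Malformed (empty) code strings are logged and
    skipped.
    """
    if catalog is None:
        catalog = load_dx_catalog()
    arrival = pd.Timestamp(arrival_date)
    out = {name: False for name in catalog}
    if diagnoses.empty:
        return out
    rows = diagnoses.loc[diagnoses["patient_id"] == patient_id].copy()
    if rows.empty:
        return out
    codes = rows["code"].astype(str).str.strip().str.upper()
    bad = ~codes.str.match(r"^[A-Z][0-9]")
    if bad.any():
        log.warning("skipping %d malformed diagnosis code(s)", int(bad.sum()))
        rows, codes = rows.loc[~bad], codes.loc[~bad]
    dates = pd.to_datetime(rows["date"])
    enc = rows["encounter_id"].fillna("").astype(str) if "encounter_id" in rows else ""
    for name, prefixes in catalog.items():
        match = codes.str.startswith(tuple(str(p).upper() for p in prefixes))
        if name == "ed_dx_syncope_or_cva":
            hit = match & (enc == (encounter_id or ""))
            if encounter_id is None:
                hit = pd.Series(False, index=rows.index)
        else:
            hit = match & (dates < arrival)
            if history_lookback_days is not None:
                hit &= dates >= arrival - pd.Timedelta(days=history_lookback_days)
        out[name] = bool(hit.any())
    return out


def extract_features(
    encounters: pd.DataFrame,
    vitals: pd.DataFrame,
    labs: pd.DataFrame,
    diagnoses: pd.DataFrame,
    admissions: pd.DataFrame,
    window_minutes: int = DEFAULT_VITALS_WINDOW_MINUTES,
    dx_catalog: Mapping[str, Sequence[str]] | None = None,
    history_lookback_days: int | None = None,
) -> pd.DataFrame:
    """One covariate row per encounter (NaN = absent).

    ``outpatient_cv_meds`` is emitted as all-absent: the covariate is
    not observable from these tables and is left to model imputation.
    """
    if dx_catalog is None:
        dx_catalog = load_dx_catalog()
    vit_groups = dict(tuple(vitals.groupby("encounter_id"))) if len(vitals) else {}
    lab_groups = dict(tuple(labs.groupby("encounter_id"))) if len(labs) else {}
    dx_groups = dict(tuple(diagnoses.groupby("patient_id"))) if len(diagnoses) else {}
    adm_groups = dict(tuple(admissions.groupby("patient_id"))) if len(admissions) else {}
    empty = vitals.iloc[0:0]
    empty_lab = labs.iloc[0:0]
    rows = []
    for rec in encounters.itertuples(index=False):
        eid, pid, arrival = rec.encounter_id, rec.patient_id, rec.arrival_date
        feat: dict = {"encounter_id": eid, "age": float(rec.age)}
        feat.update(summarize_vitals(vit_groups.get(eid, empty), window_minutes))
        feat.update(select_labs(lab_groups.get(eid, empty_lab)))
        feat["admissions_past_year"] = count_admissions(
            adm_groups.get(pid, admissions.iloc[0:0]), pid, arrival
        )
        feat.update(
            flag_diagnoses(
                dx_groups.get(pid, diagnoses.iloc[0:0]),
                pid,
                arrival,
                catalog=dx_catalog,
                encounter_id=eid,
                history_lookback_days=history_lookback_days,
            )
        )
        feat["outpatient_cv_meds"] = None
        rows.append(feat)
    df = pd.DataFrame(rows)
    for col in df.columns:
        if col == "encounter_id":
            continue
        df[col] = pd.to_numeric(df[col].map(lambda v: float(v) if v is not None else np.nan))
    return df
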