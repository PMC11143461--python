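"""Binary serious-illness screen from ICD-10 diagnosis history.

An encounter screens positive when any code in a configurable
category->prefix catalog appears within a one-year lookback from the
index ED visit (closed at the visit day), or — optionally, and on by
default — when the patient is aged 80 or older.  A single qualifying
category suffices; the screen is binary by design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = ["DiagnosisCatalog", "SeriousIllnessFlag", "flag_encounter", "flag_cohort"]

LOOKBACK_DAYS = 365
AGE_CRITERION_YEARS = 80.0

_PREFIX_RE = re.compile(r"^[A-Z][A-Z0-9.]*$")


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class DiagnosisCatalog:
    """Serious-illness category name -> ICD-10 code prefixes."""

    categories: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, prefixes in self.categories.items():
            if not prefixes:
                raise CatalogError(f"category {name!r} has no code prefixes")
            for p in prefixes:
                if not _PREFIX_RE.match(p):
                    raise CatalogError(f"category {name!r}: malformed prefix {p!r}")

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "DiagnosisCatalog":
        """Load a catalog file; ``None`` loads the shipped default."""
        if path is None:
            ref = resources.files("gestval.data").joinpath("serious_illness_catalog.yaml")
            with resources.as_file(ref) as p:
                return cls.from_yaml(p)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({k: tuple(str(p).upper() for p in v) for k, v in raw.items()})

    def match_categories(self, codes: Sequence[str]) -> list[str]:
        """Categories met by any of ``codes`` (prefix match, case-folded)."""
        cleaned = [str(c).strip().upper() for c in codes]
        met = []
        for name, prefixes in self.categories.items():
            if any(c.startswith(prefixes) for c in cleaned):
                met.append(name)
        return met


@dataclass(frozen=True)
class SeriousIllnessFlag:
    flagged: bool
    categories_met: tuple[str, ...]
    age_criterion_met: bool


def flag_encounter(
    history: pd.DataFrame,
    age: float,
    arrival_date,
    catalog: DiagnosisCatalog | None = None,
    include_age: bool = True,
    lookback_days: int = LOOKBACK_DAYS,
) -> SeriousIllnessFlag:
    """Screen one encounter.

    ``history`` needs ``code`` and ``date`` columns; codes dated within
    [arrival - lookback, arrival] count (index-day codes included).
    With ``include_age``, age >= 80 flags the encounter regardless of
    history.
    """
    if catalog is None:
        catalog = DiagnosisCatalog.from_yaml()
    arrival = pd.Timestamp(arrival_date)
    met: list[str] = []
    if len(history):
        dates = pd.to_datetime(history["date"])
        inwin = history.loc[
            (dates >= arrival - pd.Timedelta(days=lookback_days)) & (dates <= arrival)
        ]
        met = catalog.match_categories(inwin["code"].tolist())
    age_met = bool(include_age and age >= AGE_CRITERION_YEARS)
    return SeriousIllnessFlag(
        flagged=bool(met) or age_met,
        categories_met=tuple(met),
        age_criterion_met=age_met,
    )


def flag_cohort(
    encounters: pd.DataFrame,
    diagnoses: pd.DataFrame,
    catalog: DiagnosisCatalog | None = None,
    include_age: bool = True,
    lookback_days: int = LOOKBACK_DAYS,
) -> pd.Series:
    """Vector screen over a cohort; boolean Series aligned with ``encounters``."""
    if catalog is None:
        catalog = DiagnosisCatalog.from_yaml()
    groups = dict(tuple(diagnoses.groupby("patient_id"))) if len(diagnoses) else {}
    empty = diagnoses.iloc[0:0]
    flags = [
        flag_encounter(
            groups.get(rec.patient_id, empty),
            float(rec.age),
            rec.arrival_date,
            catalog=catalog,
            include_age=include_age,
            lookback_days=lookback_days,
        ).flagged
        for rec in encounters.itertuples(index=False)
    ]
    return pd.Series(flags, index=encounters.index, name="serious_illness")
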