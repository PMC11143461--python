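"""Kaplan-Meier survival for first encounters with administrative censoring.

The product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i) is
computed at day granularity via :class:`lifelines.KaplanMeierFitter`
(deaths precede censorings at tied times, the standard convention) and
truncated at a 183-day horizon, the analysis's operational "6 months".
Curves are produced for the total population, for model-risk strata
(risk greater than each cutoff), and for the serious-illness screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

log = logging.getLogger(__name__)

__all__ = ["SurvivalCurve", "first_encounter_filter", "km_estimate", "stratified_km"]

HORIZON_DAYS = 183
DEFAULT_RISK_CUTOFFS = (0.05, 0.10, 0.20, 0.30)


class SurvivalError(ValueError):
    pass


@dataclass(frozen=True)
class SurvivalCurve:
    event_times: np.ndarray  # ascending death times (days)
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    n_events: int
    n_censored: int
    n: int
    stratum_label: str = "total"
    skipped: bool = False

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "stratum": self.stratum_label,
            }
        )


def first_encounter_filter(encounters: pd.DataFrame) -> pd.DataFrame:
    """Earliest arrival per patient; timestamp ties keep the lower encounter id."""
    df = encounters.sort_values(
        ["patient_id", "arrival_date", "encounter_id"], kind="stable"
    )
    ties = df.duplicated(subset=["patient_id", "arrival_date"], keep=False) & ~df.duplicated(
        subset=["patient_id"], keep=False
    )
    first = df.groupby("patient_id", as_index=False, sort=False).head(1)
    n_ties = int(
        df.duplicated(subset=["patient_id", "arrival_date"], keep=False).sum()
    )
    if n_ties:
        log.info("first-encounter filter: %d tied arrival timestamps broken by encounter id", n_ties)
    return first.sort_index()


def km_estimate(
    time_to_event: Sequence[float],
    event_observed: Sequence[int],
    horizon_days: float = HORIZON_DAYS,
    stratum_label: str = "total",
) -> SurvivalCurve:
    """Product-limit estimate truncated at the horizon.

    Times must be positive (the cohort excludes same-day deaths);
    events after the horizon count as censored at their own time.
    """
    t = np.asarray(time_to_event, dtype=float)
    e = np.asarray(event_observed).astype(int)
    if t.shape != e.shape or t.ndim != 1 or len(t) == 0:
        raise SurvivalError("time and event arrays must be equal-length, non-empty 1-D")
    if (t <= 0).any():
        raise SurvivalError("non-positive follow-up times")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tbl = kmf.event_table
    death_rows = tbl.loc[(tbl["observed"] > 0) & (tbl.index <= horizon_days)]
    times = death_rows.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.survival_function_at_times(x).iloc[0]) for x in times])
    at_risk = death_rows["at_risk"].to_numpy(dtype=int)
    return SurvivalCurve(
        event_times=times,
        survival=surv,
        at_risk=at_risk,
        n_events=int(death_rows["observed"].sum()),
        n_censored=int(len(t) - ((e == 1) & (t <= horizon_days)).sum()),
        n=len(t),
        stratum_label=stratum_label,
    )


def stratified_km(
    time_to_event: Sequence[float],
    event_observed: Sequence[int],
    scores: Sequence[float],
    si_flags: Sequence[int],
    risk_cutoffs: Sequence[float] = DEFAULT_RISK_CUTOFFS,
    horizon_days: float = HORIZON_DAYS,
) -> list[SurvivalCurve]:
    """Curves for the total population, each risk-> cutoff stratum, and the
    serious-illness stratum.  Empty strata are reported as skipped."""
    t = np.asarray(time_to_event, dtype=float)
    e = np.asarray(event_observed).astype(int)
    scores = np.asarray(scores, dtype=float)
    si = np.asarray(si_flags).astype(bool)
    curves = [km_estimate(t, e, horizon_days, stratum_label="total")]
    masks = [(f"risk>{c:g}", scores > c) for c in risk_cutoffs]
    masks.append(("serious_illness", si))
    for label, mask in masks:
        if mask.sum() == 0:
            curves.append(
                SurvivalCurve(
                    event_times=np.array([]), survival=np.array([]),
                    at_risk=np.array([], dtype=int), n_events=0, n_censored=0,
                    n=0, stratum_label=label, skipped=True,
                )
            )
        else:
            curves.append(km_estimate(t[mask], e[mask], horizon_days, stratum_label=label))
    return curves
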