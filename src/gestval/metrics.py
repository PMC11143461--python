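"""Discrimination and calibration metrics.

AUROC is the probability a randomly chosen case outranks a randomly
chosen control (ties credited 1/2), computed from midranks; its variance
follows DeLong's structural-component estimator over case and control
placement values, giving the normal-approximation 95% CI.  Calibration
compares mean predicted risk with observed event rates within risk
groups (deciles by default, or fixed probability edges).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "DiscriminationResult",
    "CalibrationTable",
    "auroc_delong",
    "stratified_auroc",
    "calibration_bins",
]


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class DiscriminationResult:
    auroc: float
    variance: float
    ci95: tuple[float, float]
    n_cases: int
    n_controls: int
    stratum_label: str = "overall"
    skipped: bool = False

    def to_row(self) -> dict:
        return {
            "stratum": self.stratum_label,
            "auroc": self.auroc,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "skipped": self.skipped,
        }


@dataclass(frozen=True)
class CalibrationTable:
    bins: pd.DataFrame  # columns: bin, predicted_mean, observed_rate, count

    @property
    def n(self) -> int:
        return int(self.bins["count"].sum())


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise MetricError("scores and labels must be equal-length 1-D arrays")
    if not np.isin(labels, (0, 1)).all():
        raise MetricError("labels must be binary 0/1")
    return scores, labels


def auroc_delong(
    scores: Sequence[float], labels: Sequence[int], stratum_label: str = "overall"
) -> DiscriminationResult:
    """Midrank AUROC with DeLong variance and truncated 95% CI.

    Both classes must be present; otherwise the missing class is named
    in the error.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    m = int(labels.sum())
    n = int(len(labels) - m)
    if m == 0 or n == 0:
        missing = "cases" if m == 0 else "controls"
        raise MetricError(f"AUROC undefined: no {missing} in input")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # placement values via midranks (Sun & Xu formulation)
    rank_all = rankdata(np.concatenate([pos, neg]))
    rank_pos = rankdata(pos)
    rank_neg = rankdata(neg)
    v10 = (rank_all[:m] - rank_pos) / n  # per-case placements
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m  # per-control placements
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return DiscriminationResult(
        auroc=auc, variance=var, ci95=ci, n_cases=m, n_controls=n,
        stratum_label=stratum_label,
    )


def stratified_auroc(
    scores: Sequence[float], labels: Sequence[int], strata: Sequence
) -> list[DiscriminationResult]:
    """One DeLong AUROC per stratum label.

    Strata lacking a class are reported as skipped rather than failing
    the whole analysis.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    strata = np.asarray(strata)
    if strata.shape != scores.shape:
        raise MetricError("strata must align with scores")
    out = []
    for s in pd.unique(strata):
        mask = strata == s
        ls = labels[mask]
        if ls.sum() == 0 or ls.sum() == mask.sum():
            out.append(
                DiscriminationResult(
                    auroc=np.nan, variance=np.nan, ci95=(np.nan, np.nan),
                    n_cases=int(ls.sum()), n_controls=int(mask.sum() - ls.sum()),
                    stratum_label=str(s), skipped=True,
                )
            )
        else:
            out.append(auroc_delong(scores[mask], ls, stratum_label=str(s)))
    return out


def calibration_bins(
    scores: Sequence[float],
    labels: Sequence[int],
    n_bins: int = 10,
    edges: Sequence[float] | None = None,
) -> CalibrationTable:
    """Observed-vs-predicted table by risk group.

    Default grouping is deciles of the score distribution; passing
    ``edges`` uses fixed probability cut points instead.  Under fixed
    edges an empty bin is retained with count 0 and NaN rates.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    if np.any((scores < 0) | (scores > 1)):
        raise MetricError("scores must be probabilities in [0, 1]")
    if edges is not None:
        edges = np.asarray(edges, dtype=float)
        bin_idx = np.digitize(scores, edges, right=False)
        n_groups = len(edges) + 1
    else:
        # decile (quantile) grouping; duplicate quantiles collapse
        qs = np.quantile(scores, np.linspace(0, 1, n_bins + 1)[1:-1])
        qs = np.unique(qs)
        bin_idx = np.digitize(scores, qs, right=True)
        n_groups = len(qs) + 1
    rows = []
    for b in range(n_groups):
        mask = bin_idx == b
        cnt = int(mask.sum())
        rows.append(
            {
                "bin": b,
                "predicted_mean": float(scores[mask].mean()) if cnt else np.nan,
                "observed_rate": float(labels[mask].mean()) if cnt else np.nan,
                "count": cnt,
            }
        )
    df = pd.DataFrame(rows)
    if edges is None:
        df = df.loc[df["count"] > 0].reset_index(drop=True)
        df["bin"] = np.arange(len(df))
    return CalibrationTable(bins=df)
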