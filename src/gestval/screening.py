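"""Screening test characteristics, decision curves, and the
serious-illness x model-risk misclassification cross-tab.

Thresholding is strict (positive iff score > cutoff, reading "risk
> 5%" literally).  Proportion CIs use the Wilson score interval;
likelihood-ratio CIs use the standard log method.  Net benefit at a
threshold probability p_t is

    NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t)

i.e. true positives minus false positives weighted by the exchange rate
(the odds form of p_t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "ScreeningCharacteristics",
    "DecisionCurvePoint",
    "confusion_at_threshold",
    "characteristics",
    "characteristics_table",
    "net_benefit_curve",
    "misclassification_crosstab",
    "fraction_positive_from_rates",
    "ppv_from_rates",
    "npv_from_rates",
    "lr_pos_from_rates",
    "lr_neg_from_rates",
]

DEFAULT_THRESHOLDS = (0.05, 0.10, 0.20, 0.30)


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ScreeningError("confusion matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ScreeningCharacteristics:
    label: str
    fraction_positive: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    ci: dict  # name -> (low, high); NaN bounds where undefined
    ci_method: str = "wilson"

    def to_row(self) -> dict:
        row = {"screen": self.label}
        for name in ("fraction_positive", "sensitivity", "specificity", "ppv", "npv",
                     "lr_pos", "lr_neg"):
            row[name] = getattr(self, name)
            lo, hi = self.ci.get(name, (np.nan, np.nan))
            row[f"{name}_ci_low"], row[f"{name}_ci_high"] = lo, hi
        row["ci_method"] = self.ci_method
        return row


@dataclass(frozen=True)
class DecisionCurvePoint:
    threshold_probability: float
    net_benefit: float
    strategy: str


def _as_binary(x) -> np.ndarray:
    x = np.asarray(x).astype(int)
    if not np.isin(x, (0, 1)).all():
        raise ScreeningError("labels/flags must be binary 0/1")
    return x


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionMatrix:
    """Counts with strict '>' thresholding."""
    scores = np.asarray(scores, dtype=float)
    labels = _as_binary(labels)
    pos = scores > threshold
    return ConfusionMatrix(
        tp=int((pos & (labels == 1)).sum()),
        fp=int((pos & (labels == 0)).sum()),
        fn=int((~pos & (labels == 1)).sum()),
        tn=int((~pos & (labels == 0)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def _lr_ci(lr: float, num_events: int, num_total: int, den_events: int, den_total: int):
    """Log-method CI for a likelihood ratio (Simel et al. form)."""
    if not np.isfinite(lr) or lr <= 0 or 0 in (num_events, den_events):
        return (np.nan, np.nan)
    se = np.sqrt(
        1.0 / num_events - 1.0 / num_total + 1.0 / den_events - 1.0 / den_total
    )
    z = norm.ppf(0.975)
    return (float(lr * np.exp(-z * se)), float(lr * np.exp(z * se)))


def characteristics(
    cm: ConfusionMatrix, label: str = "", ci_method: str = "wilson"
) -> ScreeningCharacteristics:
    """Sens/spec/PPV/NPV/LR+-/fraction-positive with 95% CIs.

    Ratios with zero denominators are reported as NaN (flagged
    undefined), never fabricated.  Requires at least one case.
    """
    if cm.n == 0:
        raise ScreeningError("empty confusion matrix")
    if cm.tp + cm.fn == 0:
        raise ScreeningError("no cases present; sensitivity undefined")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    lr_pos = _ratio(sens, 1.0 - spec) if np.isfinite(spec) else np.nan
    lr_neg = _ratio(1.0 - sens, spec) if np.isfinite(spec) else np.nan
    frac_pos = (cm.tp + cm.fp) / cm.n

    def prop_ci(k: int, n: int):
        if n == 0:
            return (np.nan, np.nan)
        lo, hi = proportion_confint(k, n, alpha=0.05, method=ci_method)
        return (float(lo), float(hi))

    ci = {
        "sensitivity": prop_ci(cm.tp, cm.tp + cm.fn),
        "specificity": prop_ci(cm.tn, cm.tn + cm.fp),
        "ppv": prop_ci(cm.tp, cm.tp + cm.fp),
        "npv": prop_ci(cm.tn, cm.tn + cm.fn),
        "fraction_positive": prop_ci(cm.tp + cm.fp, cm.n),
        "lr_pos": _lr_ci(lr_pos, cm.tp, cm.tp + cm.fn, cm.fp, cm.fp + cm.tn),
        "lr_neg": _lr_ci(lr_neg, cm.fn, cm.tp + cm.fn, cm.tn, cm.fp + cm.tn),
    }
    return ScreeningCharacteristics(
        label=label, fraction_positive=frac_pos, sensitivity=sens, specificity=spec,
        ppv=ppv, npv=npv, lr_pos=lr_pos, lr_neg=lr_neg, ci=ci, ci_method=ci_method,
    )


def characteristics_table(
    scores: Sequence[float],
    labels: Sequence[int],
    binary_flags: Sequence[int] | None = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    binary_label: str = "serious_illness",
    ci_method: str = "wilson",
) -> pd.DataFrame:
    """One row per screen: the binary criterion plus each model cutoff.

    Any first-visit-only restriction is applied upstream by filtering
    the inputs; this function is agnostic to it.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ScreeningError("thresholds must be sorted ascending")
    labels = _as_binary(labels)
    rows = []
    if binary_flags is not None:
        flags = _as_binary(binary_flags)
        cm = confusion_at_threshold(flags.astype(float), labels, 0.5)
        rows.append(characteristics(cm, label=binary_label, ci_method=ci_method).to_row())
    for t in thresholds:
        cm = confusion_at_threshold(scores, labels, t)
        rows.append(
            characteristics(cm, label=f"model>{t:g}", ci_method=ci_method).to_row()
        )
    return pd.DataFrame(rows)


def net_benefit_curve(
    labels: Sequence[int],
    scores: Sequence[float] | None = None,
    binary_flags: Sequence[int] | None = None,
    grid: Sequence[float] | None = None,
    strategy: str = "model",
) -> list[DecisionCurvePoint]:
    """Decision curve for one strategy over a threshold-probability grid.

    Strategies: ``model`` reclassifies at each p_t (score > p_t);
    ``binary_criterion`` applies its fixed classification at every p_t;
    ``treat_all`` flags everyone; ``treat_none`` is identically zero.
    Grid default: 0.01 to 0.50 step 0.01.
    """
    labels = _as_binary(labels)
    n = len(labels)
    if grid is None:
        grid = np.round(np.arange(0.01, 0.501, 0.01), 10)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ScreeningError("threshold grid must lie strictly inside (0, 1)")
    points = []
    for pt in grid:
        if strategy == "treat_none":
            nb = 0.0
        else:
            if strategy == "model":
                if scores is None:
                    raise ScreeningError("model strategy requires scores")
                pos = np.asarray(scores, dtype=float) > pt
            elif strategy == "binary_criterion":
                if binary_flags is None:
                    raise ScreeningError("binary_criterion strategy requires flags")
                pos = _as_binary(binary_flags).astype(bool)
            elif strategy == "treat_all":
                pos = np.ones(n, dtype=bool)
            else:
                raise ScreeningError(f"unknown strategy {strategy!r}")
            tp = int((pos & (labels == 1)).sum())
            fp = int((pos & (labels == 0)).sum())
            nb = tp / n - (fp / n) * pt / (1.0 - pt)
        points.append(DecisionCurvePoint(float(pt), float(nb), strategy))
    return points


def decision_curve_table(
    labels: Sequence[int],
    scores: Sequence[float],
    binary_flags: Sequence[int],
    grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """All four strategies on one grid, long format."""
    rows = []
    for strategy in ("model", "binary_criterion", "treat_all", "treat_none"):
        rows.extend(
            net_benefit_curve(labels, scores=scores, binary_flags=binary_flags,
                              grid=grid, strategy=strategy)
        )
    return pd.DataFrame(
        [{"threshold": p.threshold_probability, "net_benefit": p.net_benefit,
          "strategy": p.strategy} for p in rows]
    )


def misclassification_crosstab(
    si_flags: Sequence[int],
    scores: Sequence[float],
    labels: Sequence[int],
    low_cut: float = 0.10,
    high_cut: float = 0.30,
) -> pd.DataFrame:
    """(serious illness yes/no) x (risk <low, [low, high], >high) cells.

    Each cell reports count, share of all encounters, share within its
    serious-illness row, and observed mortality.  Discordant encounters
    are serious-illness-with-low-risk and no-serious-illness-with-high-
    risk.
    """
    si = _as_binary(si_flags).astype(bool)
    labels = _as_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if not (len(si) == len(labels) == len(scores)):
        raise ScreeningError("inputs must be aligned")
    band = np.where(scores < low_cut, "low", np.where(scores > high_cut, "high", "middle"))
    rows = []
    n = len(si)
    for si_val, si_name in ((True, "serious_illness"), (False, "no_serious_illness")):
        row_n = int((si == si_val).sum())
        for b in ("low", "middle", "high"):
            mask = (si == si_val) & (band == b)
            cnt = int(mask.sum())
            rows.append(
                {
                    "serious_illness": si_name,
                    "risk_band": b,
                    "count": cnt,
                    "share_of_all": cnt / n if n else np.nan,
                    "share_of_row": cnt / row_n if row_n else np.nan,
                    "observed_mortality": float(labels[mask].mean()) if cnt else np.nan,
                    "discordant": (si_val and b == "low") or (not si_val and b == "high"),
                }
            )
    return pd.DataFrame(rows)


def discordant_share(crosstab: pd.DataFrame) -> float:
    return float(crosstab.loc[crosstab["discordant"], "share_of_all"].sum())


# ---------------------------------------------------------------------------
# Bayes / likelihood-ratio identities.  These reconstruct the predictive
# values a published characteristics table implies from its marginal rates,
# which is also the internal-consistency check that ties such a table
# together: PPV = sens*prev/frac_pos and NPV = spec*(1-prev)/(1-frac_pos).


def fraction_positive_from_rates(sens: float, spec: float, prev: float) -> float:
    return sens * prev + (1.0 - spec) * (1.0 - prev)


def ppv_from_rates(sens: float, spec: float, prev: float) -> float:
    return sens * prev / fraction_positive_from_rates(sens, spec, prev)


def npv_from_rates(sens: float, spec: float, prev: float) -> float:
    return spec * (1.0 - prev) / (1.0 - fraction_positive_from_rates(sens, spec, prev))


def lr_pos_from_rates(sens: float, spec: float) -> float:
    return sens / (1.0 - spec)


def lr_neg_from_rates(sens: float, spec: float) -> float:
    return (1.0 - sens) / spec
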