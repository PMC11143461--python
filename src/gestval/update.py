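"""Model updating on a temporal split: recalibration and refitting.

Recalibration keeps every covariate effect fixed and re-estimates only
the intercept for the new setting: with the original linear predictor
eta entering as an offset with slope 1, the MLE shift delta is the
calibration-in-the-large correction, and the updated intercept is
intercept + delta.  Because an intercept shift is strictly monotone,
recalibration never changes discrimination.

Refitting re-estimates all coefficients by ordinary logistic maximum
likelihood on the standardized covariates (imputation and
standardization constants are kept from the original specification, so
the updated model remains a drop-in file).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metrics import CalibrationTable, DiscriminationResult, auroc_delong, calibration_bins
from .model import ModelSpecification, model_matrix, score_frame

__all__ = ["TemporalSplit", "recalibrate_intercept", "refit", "compare_updates"]


class UpdateError(ValueError):
    pass


@dataclass(frozen=True)
class TemporalSplit:
    """Disjoint, non-empty year sets for updating vs validating."""

    train_years: frozenset[int]
    test_years: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_years", frozenset(self.train_years))
        object.__setattr__(self, "test_years", frozenset(self.test_years))
        if not self.train_years or not self.test_years:
            raise UpdateError("train and test year sets must be non-empty")
        if self.train_years & self.test_years:
            raise UpdateError("train and test years must be disjoint")

    @classmethod
    def default(cls) -> "TemporalSplit":
        # modify on the first two study years, validate on the rest
        return cls(frozenset({2017, 2018}), frozenset({2019, 2020, 2021}))


def _check_outcomes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise UpdateError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise UpdateError("training outcomes are all one class; update is undefined")
    return y


def recalibrate_intercept(
    spec: ModelSpecification,
    features: pd.DataFrame,
    outcomes: Sequence[int],
    include_slope: bool = False,
) -> ModelSpecification:
    """Intercept-only update (optionally intercept+slope, off by default).

    Fits ``y ~ 1`` with the full linear predictor as an offset; the
    fitted constant is delta and the new intercept is ``old + delta``.
    With ``include_slope`` a logistic calibration ``y ~ a + b*eta`` is
    fitted instead and folded back into the spec (all coefficients
    scaled by b).
    """
    y = _check_outcomes(np.asarray(outcomes))
    eta = score_frame(features, spec)["linear_predictor"].to_numpy()
    if include_slope:
        res = sm.GLM(y, sm.add_constant(eta), family=sm.families.Binomial()).fit()
        a, b = float(res.params[0]), float(res.params[1])
        covs = tuple(replace(c, coefficient=c.coefficient * b) for c in spec.covariates)
        return replace(spec, covariates=covs, intercept=a + b * spec.intercept,
                       name=f"{spec.name}-recalibrated-slope")
    res = sm.GLM(
        y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=eta
    ).fit()
    delta = float(res.params[0])
    return replace(spec, intercept=spec.intercept + delta, name=f"{spec.name}-recalibrated")


def refit(
    spec: ModelSpecification,
    features: pd.DataFrame,
    outcomes: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ModelSpecification:
    """Full logistic re-estimation on the spec's standardized covariates.

    IRLS via statsmodels GLM, converged when the max coefficient change
    drops below ``tol`` (or ``max_iter`` sweeps).  Diverging
    coefficients (quasi-separation) raise an explicit failure naming
    the worst covariate.
    """
    y = _check_outcomes(np.asarray(outcomes))
    X = sm.add_constant(model_matrix(features, spec), has_constant="add")
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", PerfectSeparationWarning)
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            tol=tol, maxiter=max_iter
        )
    params = np.asarray(res.params, dtype=float)
    separated = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
    if not np.all(np.isfinite(params)) or (separated and np.any(np.abs(params[1:]) > 10)):
        worst = int(np.nanargmax(np.abs(params[1:])))
        raise UpdateError(
            f"separation suspected while refitting: coefficient for "
            f"{spec.covariates[worst].name!r} diverged ({params[1 + worst]:.3g})"
        )
    covs = tuple(
        replace(c, coefficient=float(params[1 + i])) for i, c in enumerate(spec.covariates)
    )
    return replace(spec, covariates=covs, intercept=float(params[0]), name=f"{spec.name}-refit")


def refit_standard_errors(
    spec: ModelSpecification, features: pd.DataFrame, outcomes: Sequence[int]
) -> np.ndarray:
    """MLE standard errors (intercept first) for the refit on this data."""
    y = _check_outcomes(np.asarray(outcomes))
    X = sm.add_constant(model_matrix(features, spec), has_constant="add")
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return np.asarray(res.bse, dtype=float)


def compare_updates(
    models: Mapping[str, ModelSpecification],
    features: pd.DataFrame,
    outcomes: Sequence[int],
) -> dict[str, tuple[DiscriminationResult, CalibrationTable]]:
    """Score each spec on the same validation records.

    Returns per-model (discrimination, calibration) computed on the
    supplied records; callers pass test-years-only data per the
    temporal split.
    """
    y = np.asarray(outcomes).astype(int)
    out = {}
    for label, spec in models.items():
        p = score_frame(features, spec)["probability"].to_numpy()
        out[label] = (
            auroc_delong(p, y, stratum_label=label),
            calibration_bins(p, y),
        )
    return out
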