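"""Declarative logistic risk model: impute, standardize, predict.

A :class:`ModelSpecification` carries, per covariate, the raw-scale
imputation value used for missing data, the standardization mean/SD from
the derivation cohort, and a log-odds coefficient per standardized unit,
plus a global intercept.  Scoring a record is then

    z_i = (x_i - mean_i) / sd_i          (x_i imputed when absent)
    eta  = intercept + sum_i beta_i z_i
    p    = 1 / (1 + exp(-eta))

Coefficients are data, not code: specs round-trip losslessly through a
YAML file, so a transcribed published model and a synthetic stand-in are
interchangeable inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CovariateSpec",
    "ModelSpecification",
    "RiskPrediction",
    "load_model_spec",
    "save_model_spec",
    "default_model_spec",
    "impute_and_standardize",
    "predict_risk",
    "score_frame",
]


class ModelSpecError(ValueError):
    """Raised for structurally invalid model specifications."""


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate's imputation, standardization and effect."""

    name: str
    imputation_value: float
    standardization_mean: float
    standardization_sd: float
    coefficient: float
    standardize: bool = True  # binary covariates may opt out

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelSpecError("covariate name must be non-empty")
        if not (self.standardization_sd > 0):
            raise ModelSpecError(
                f"covariate {self.name!r}: standardization_sd must be > 0, "
                f"got {self.standardization_sd!r}"
            )
        for fld in ("imputation_value", "standardization_mean", "coefficient"):
            v = getattr(self, fld)
            if not math.isfinite(v):
                raise ModelSpecError(f"covariate {self.name!r}: {fld} must be finite")

    def transform(self, x: float) -> float:
        """Raw value -> model scale (z-score, or pass-through 0/1)."""
        if not self.standardize:
            return float(x)
        return (float(x) - self.standardization_mean) / self.standardization_sd


@dataclass(frozen=True)
class ModelSpecification:
    covariates: tuple[CovariateSpec, ...]
    intercept: float
    name: str = "unnamed"

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ModelSpecError(f"duplicate covariate names: {dup}")
        if not math.isfinite(self.intercept):
            raise ModelSpecError("intercept must be finite")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    def __getitem__(self, name: str) -> CovariateSpec:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def with_intercept(self, intercept: float) -> "ModelSpecification":
        return replace(self, intercept=float(intercept))

    def coefficient_vector(self) -> np.ndarray:
        return np.array([c.coefficient for c in self.covariates], dtype=float)


@dataclass(frozen=True)
class RiskPrediction:
    linear_predictor: float
    probability: float
    imputed_fields: tuple[str, ...] = field(default_factory=tuple)


def _require(entry: Mapping, key: str, context: str):
    if key not in entry:
        raise ModelSpecError(f"model spec {context}: missing key {key!r}")
    return entry[key]


def load_model_spec(path: str | Path) -> ModelSpecification:
    """Load and validate a model specification from a YAML file.

    Raises :class:`ModelSpecError` naming the offending entry on any
    missing key or non-positive standardization SD.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ModelSpecError(f"model spec file {path}: expected a mapping at top level")
    intercept = _require(raw, "intercept", "top level")
    cov_entries = _require(raw, "covariates", "top level")
    covs = []
    for i, entry in enumerate(cov_entries):
        name = _require(entry, "name", f"covariate #{i}")
        covs.append(
            CovariateSpec(
                name=str(name),
                imputation_value=float(_require(entry, "imputation_value", name)),
                standardization_mean=float(_require(entry, "standardization_mean", name)),
                standardization_sd=float(_require(entry, "standardization_sd", name)),
                coefficient=float(_require(entry, "coefficient", name)),
                standardize=bool(entry.get("standardize", True)),
            )
        )
    return ModelSpecification(
        covariates=tuple(covs),
        intercept=float(intercept),
        name=str(raw.get("name", "unnamed")),
    )


def save_model_spec(spec: ModelSpecification, path: str | Path) -> None:
    """Write a spec as YAML.  Floats survive a write/load round trip exactly."""
    doc = {
        "name": spec.name,
        "intercept": spec.intercept,
        "covariates": [
            {
                "name": c.name,
                "imputation_value": c.imputation_value,
                "standardization_mean": c.standardization_mean,
                "standardization_sd": c.standardization_sd,
                "coefficient": c.coefficient,
                "standardize": c.standardize,
            }
            for c in spec.covariates
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_model_spec() -> ModelSpecification:
    """The shipped synthetic stand-in model (clinically signed coefficients).

    The published model's numeric values live in a supplement that is not
    redistributed here; this spec has the same covariates and plausible
    magnitudes, and is clearly labelled synthetic.
    """
    ref = resources.files("gestval.data").joinpath("gest_model_synthetic.yaml")
    with resources.as_file(ref) as p:
        return load_model_spec(p)


def impute_and_standardize(
    features: Mapping[str, float | bool | None],
    spec: ModelSpecification,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Impute absent covariates and map all to the model scale.

    ``features`` maps covariate name -> raw value, with ``None`` (or NaN)
    meaning absent.  Every covariate named in ``features`` must be in the
    spec; spec covariates absent from ``features`` are treated as missing
    and imputed.  Returns the model-scale vector in spec covariate order
    and the names of imputed fields.
    """
    unknown = set(features) - set(spec.covariate_names)
    if unknown:
        raise ModelSpecError(f"features carry covariates with no spec entry: {sorted(unknown)}")
    z = np.empty(len(spec.covariates), dtype=float)
    imputed: list[str] = []
    for i, cov in enumerate(spec.covariates):
        x = features.get(cov.name)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            x = cov.imputation_value
            imputed.append(cov.name)
        elif isinstance(x, (bool, np.bool_)):
            x = float(x)
        z[i] = cov.transform(float(x))
    return z, tuple(imputed)


def predict_risk(
    z: Sequence[float] | np.ndarray,
    spec: ModelSpecification,
    imputed_fields: Sequence[str] = (),
) -> RiskPrediction:
    """eta = intercept + beta . z ;  p = logistic(eta)."""
    z = np.asarray(z, dtype=float)
    if z.shape != (len(spec.covariates),):
        raise ModelSpecError(
            f"model-scale vector has shape {z.shape}, expected ({len(spec.covariates)},)"
        )
    if not np.all(np.isfinite(z)):
        bad = [spec.covariates[i].name for i in np.flatnonzero(~np.isfinite(z))]
        raise ModelSpecError(f"non-finite model-scale values for: {bad}")
    eta = float(spec.intercept + spec.coefficient_vector() @ z)
    p = float(1.0 / (1.0 + np.exp(-eta)))
    return RiskPrediction(linear_predictor=eta, probability=p, imputed_fields=tuple(imputed_fields))


def score_record(
    features: Mapping[str, float | bool | None], spec: ModelSpecification
) -> RiskPrediction:
    z, imputed = impute_and_standardize(features, spec)
    return predict_risk(z, spec, imputed)


def score_frame(features: pd.DataFrame, spec: ModelSpecification) -> pd.DataFrame:
    """Score a feature table (one row per encounter, NaN = absent).

    Returns a frame indexed like ``features`` with columns
    ``linear_predictor``, ``probability`` and ``n_imputed``.
    """
    cols = [c for c in features.columns if c in spec.covariate_names]
    X = np.empty((len(features), len(spec.covariates)), dtype=float)
    n_imputed = np.zeros(len(features), dtype=int)
    for j, cov in enumerate(spec.covariates):
        if cov.name in cols:
            x = pd.to_numeric(features[cov.name], errors="coerce").to_numpy(dtype=float)
        else:
            x = np.full(len(features), np.nan)
        missing = ~np.isfinite(x)
        n_imputed += missing
        x = np.where(missing, cov.imputation_value, x)
        X[:, j] = (x - cov.standardization_mean) / cov.standardization_sd if cov.standardize else x
    eta = spec.intercept + X @ spec.coefficient_vector()
    return pd.DataFrame(
        {
            "linear_predictor": eta,
            "probability": 1.0 / (1.0 + np.exp(-eta)),
            "n_imputed": n_imputed,
        },
        index=features.index,
    )


def model_matrix(features: pd.DataFrame, spec: ModelSpecification) -> np.ndarray:
    """Imputed, model-scale design matrix in spec covariate order (no intercept)."""
    X = np.empty((len(features), len(spec.covariates)), dtype=float)
    for j, cov in enumerate(spec.covariates):
        if cov.name in features.columns:
            x = pd.to_numeric(features[cov.name], errors="coerce").to_numpy(dtype=float)
        else:
            x = np.full(len(features), np.nan)
        x = np.where(np.isfinite(x), x, cov.imputation_value)
        X[:, j] = (x - cov.standardization_mean) / cov.standardization_sd if cov.standardize else x
    return X
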