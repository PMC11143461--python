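"""Seeded synthetic ED cohort generator.

Emulates the relational shape of a geriatric emergency-department
extract — encounters, long-format vitals and labs, dated diagnosis
codes, prior admissions, and death dates with administrative right
censoring — with the statistical structure the downstream validation
analysis assumes:

* ages >= 65 (truncated normal, mean ~77, SD ~8);
* a configurable target 6-month mortality prevalence (default 13.8%),
  hit by bisecting the outcome-model intercept;
* repeat visits per patient (geometric count), covariates redrawn
  around a patient-level anchor;
* a single latent severity factor inducing dependence between
  covariates, diagnoses and mortality;
* per-covariate missingness;
* death dates that can fall after the 6-month horizon and after the
  administrative censor date, so survival censoring is exercised.

Everything is driven by one :func:`numpy.random.default_rng` seed:
identical configs give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .model import ModelSpecification, default_model_spec, model_matrix

__all__ = [
    "CovariateGenerator",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "inject_missingness",
    "six_month_mortality",
    "survival_times",
    "default_covariate_generators",
]

SIX_MONTH_DAYS = 183

LAB_COVARIATES = (
    "hemoglobin",
    "hematocrit",
    "blood_urea_nitrogen",
    "red_cell_distribution_width",
    "lymphocyte_count",
    "mean_corpuscular_volume",
)
VITAL_COVARIATES = ("mean_heart_rate", "min_systolic_bp", "supplemental_oxygen")
DX_HISTORY_COVARIATES = (
    "dx_secondary_cancer",
    "dx_cognitive_disorder",
    "dx_lung_cancer",
    "dx_pancreatic_cancer",
)

# one representative ICD-10 code per diagnosis-history covariate
_DX_CODES = {
    "dx_secondary_cancer": "C78.0",
    "dx_cognitive_disorder": "F03.90",
    "dx_lung_cancer": "C34.90",
    "dx_pancreatic_cancer": "C25.9",
}
_ED_DX_CODE = "I63.9"  # acute cerebrovascular disease at the index visit

# Base per-patient rates for serious-illness categories (roughly echoing
# published geriatric ED prevalences); severity shifts them on the logit.
# Codes are chosen not to collide with the risk model's own diagnosis
# prefixes, so the generator's covariate truth and feature extraction
# agree (dementia is fed by the cognitive-disorder covariate instead).
_SI_CATEGORY_CODES = {
    "kidney_failure": ("N18.6", 0.026),
    "diabetes_pvd": ("E11.51", 0.073),
    "neurodegenerative_disease": ("G12.21", 0.001),
    "lung_disease": ("J44.9", 0.126),
    "heart_disease": ("I50.9", 0.143),
    "cancer": ("C18.9", 0.053),
    "hip_fracture": ("S72.001", 0.006),
    "liver_disease": ("K74.60", 0.025),
    "stroke_tia": ("I63.9", 0.018),
    "coronary_artery_disease": ("I25.10", 0.08),
    "chronic_kidney_disease": ("N18.4", 0.06),
    "hiv_aids": ("B20", 0.003),
}
_SI_LOADING = 0.5  # severity loading of serious-illness categories


class GeneratorError(ValueError):
    """Raised when a cohort configuration cannot be realised."""


@dataclass(frozen=True)
class CovariateGenerator:
    """Marginal family plus latent-severity loading for one covariate.

    ``family`` is one of ``normal``, ``truncnorm``, ``lognormal``,
    ``bernoulli``, ``poisson``.  ``loading`` in [-1, 1] is the share of
    the covariate's spread driven by the patient-level severity factor
    (sign gives the clinical direction).
    """

    family: str
    params: tuple[float, ...]
    loading: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("normal", "truncnorm", "lognormal", "bernoulli", "poisson"):
            raise GeneratorError(f"unknown covariate family {self.family!r}")
        if not -1.0 <= self.loading <= 1.0:
            raise GeneratorError(f"loading must be in [-1, 1], got {self.loading}")

    def draw(self, severity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n = severity.shape[0]
        lam = self.loading
        resid = np.sqrt(max(0.0, 1.0 - lam * lam))
        if self.family in ("normal", "truncnorm"):
            mean, sd = self.params[0], self.params[1]
            x = mean + sd * (lam * severity + resid * rng.standard_normal(n))
            if self.family == "truncnorm":
                lo, hi = self.params[2], self.params[3]
                x = np.clip(x, lo, hi)
            return x
        if self.family == "lognormal":
            meanlog, sdlog = self.params[0], self.params[1]
            return np.exp(meanlog + sdlog * (lam * severity + resid * rng.standard_normal(n)))
        if self.family == "bernoulli":
            p = self.params[0]
            logit = np.log(p / (1.0 - p)) if 0.0 < p < 1.0 else np.inf * np.sign(p - 0.5)
            padj = 1.0 / (1.0 + np.exp(-(logit + 2.0 * lam * severity)))
            return (rng.random(n) < padj).astype(float)
        # poisson
        return rng.poisson(self.params[0] * np.exp(lam * severity)).astype(float)

    @property
    def scale(self) -> float:
        """Per-visit redraw scale in raw units (0 for discrete families)."""
        if self.family in ("normal", "truncnorm"):
            return float(self.params[1])
        if self.family == "lognormal":
            # approximate raw-scale SD of the lognormal
            m, s = self.params
            return float(np.exp(m) * s)
        return 0.0


def default_covariate_generators() -> dict[str, CovariateGenerator]:
    """Defaults for the screening model's covariates.

    Age follows the published cohort moments (truncated normal on
    [65, 105]); labs and vitals use plausible adult ranges; diagnosis
    flags are Bernoulli.  Loadings put anaemia, azotaemia, anisocytosis,
    tachycardia, hypotension, oxygen use, utilisation and cancer history
    on the high-severity side.
    """
    return {
        "age": CovariateGenerator("truncnorm", (77.0, 8.0, 65.0, 105.0), 0.15),
        "hemoglobin": CovariateGenerator("normal", (12.5, 2.0), -0.30),
        "hematocrit": CovariateGenerator("normal", (37.5, 5.5), -0.30),
        "blood_urea_nitrogen": CovariateGenerator("lognormal", (np.log(20.0), 0.45), 0.40),
        "red_cell_distribution_width": CovariateGenerator("truncnorm", (14.5, 2.0, 11.0, 30.0), 0.40),
        "lymphocyte_count": CovariateGenerator("lognormal", (np.log(1.4), 0.5), -0.25),
        "mean_corpuscular_volume": CovariateGenerator("normal", (90.0, 6.0), 0.10),
        "mean_heart_rate": CovariateGenerator("normal", (85.0, 15.0), 0.30),
        "min_systolic_bp": CovariateGenerator("truncnorm", (125.0, 22.0, 60.0, 240.0), -0.35),
        "supplemental_oxygen": CovariateGenerator("bernoulli", (0.15,), 0.50),
        "admissions_past_year": CovariateGenerator("poisson", (0.55,), 0.50),
        "dx_secondary_cancer": CovariateGenerator("bernoulli", (0.05,), 0.35),
        "dx_cognitive_disorder": CovariateGenerator("bernoulli", (0.08,), 0.30),
        "dx_lung_cancer": CovariateGenerator("bernoulli", (0.03,), 0.30),
        "dx_pancreatic_cancer": CovariateGenerator("bernoulli", (0.01,), 0.30),
        "ed_dx_syncope_or_cva": CovariateGenerator("bernoulli", (0.04,), 0.20),
        "outpatient_cv_meds": CovariateGenerator("bernoulli", (0.70,), 0.10),
    }


def default_missingness_rates() -> dict[str, float]:
    # modest lab/vital missingness; outpatient medications are entirely
    # unavailable in the validation setting, hence rate 1.0
    rates = {name: 0.05 for name in LAB_COVARIATES}
    rates["mean_heart_rate"] = 0.02
    rates["min_systolic_bp"] = 0.02
    rates["supplemental_oxygen"] = 0.0
    rates["outpatient_cv_meds"] = 1.0
    return rates


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int
    seed: int = 0
    visits_per_patient_mean: float = 2.0
    study_start: date = date(2017, 1, 1)
    study_end: date = date(2021, 12, 31)
    censor_date: date = date(2022, 12, 31)
    true_model: ModelSpecification | None = None  # None -> shipped synthetic spec
    covariate_generators: Mapping[str, CovariateGenerator] = field(
        default_factory=default_covariate_generators
    )
    missingness_rates: Mapping[str, float] = field(default_factory=default_missingness_rates)
    target_prevalence: float = 0.138
    late_death_rate: float = 0.15
    visit_redraw_sd: float = 0.25
    visit_gap_mean_days: float = 45.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise GeneratorError("n_patients must be positive")
        if not 0.0 < self.target_prevalence < 1.0:
            raise GeneratorError("target_prevalence must be in (0, 1)")
        if self.visits_per_patient_mean < 1.0:
            raise GeneratorError("visits_per_patient_mean must be >= 1")
        if not self.study_start < self.study_end:
            raise GeneratorError("study_window start must precede end")
        if self.censor_date < self.study_end:
            raise GeneratorError("censor_date must be on/after study end")
        for name, r in self.missingness_rates.items():
            if not 0.0 <= r <= 1.0:
                raise GeneratorError(f"missingness rate for {name!r} must be in [0, 1]")
        if not 0.0 <= self.late_death_rate <= 1.0:
            raise GeneratorError("late_death_rate must be in [0, 1]")

    def resolved_model(self) -> ModelSpecification:
        return self.true_model if self.true_model is not None else default_model_spec()


@dataclass
class SyntheticCohort:
    """Relational tables of one generated cohort.

    ``features_true`` holds the complete per-encounter covariate truth
    used to assign outcomes; ``features_observed`` is the same table
    after missingness (what an analyst would reconstruct).
    """

    encounters: pd.DataFrame
    vitals: pd.DataFrame
    labs: pd.DataFrame
    diagnoses: pd.DataFrame
    admissions: pd.DataFrame
    outcomes: pd.DataFrame
    features_true: pd.DataFrame
    features_observed: pd.DataFrame
    manifest: dict

    _TABLES = (
        "encounters",
        "vitals",
        "labs",
        "diagnoses",
        "admissions",
        "outcomes",
        "features_true",
        "features_observed",
    )

    def write_tables(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            df = getattr(self, name).copy()
            for col in df.columns:
                if pd.api.types.is_datetime64_any_dtype(df[col]):
                    df[col] = df[col].dt.strftime("%Y-%m-%d")
            df.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=False)

    @classmethod
    def read_tables(cls, indir: str | Path) -> "SyntheticCohort":
        indir = Path(indir)
        kw = {}
        date_cols = {"arrival_date", "date", "admit_date", "death_date"}
        for name in cls._TABLES:
            df = pd.read_csv(indir / f"{name}.csv")
            for col in df.columns:
                if col in date_cols:
                    df[col] = pd.to_datetime(df[col])
            kw[name] = df
        with open(indir / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)
        return cls(manifest=manifest, **kw)


def _tune_intercept(
    score: np.ndarray, target: float, lo: float = -30.0, hi: float = 30.0
) -> float:
    """Bisect c so that mean(logistic(c + score)) == target."""

    def mean_p(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(c + score)))))

    if mean_p(lo) > target or mean_p(hi) < target:
        raise GeneratorError(
            f"target prevalence {target} unreachable by intercept in [{lo}, {hi}] "
            "given the coefficient scale"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _grouped_cumsum(values: np.ndarray, group_starts: np.ndarray) -> np.ndarray:
    out = np.cumsum(values)
    offsets = np.repeat(out[group_starts] - values[group_starts], np.diff(np.append(group_starts, len(values))))
    return out - offsets


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a seeded synthetic cohort (deterministic given config).

    Mortality mechanism: the true model is evaluated on each patient's
    anchor covariates; the intercept is bisected so the mean predicted
    6-month death probability equals ``target_prevalence``; a Bernoulli
    draw assigns death, dated uniformly within (1, 183] days of the
    first arrival.  A fraction of survivors dies later, exercising
    right-censoring at ``censor_date``.
    """
    rng = np.random.default_rng(config.seed)
    spec = config.resolved_model()
    gens = dict(config.covariate_generators)
    missing_gen = [n for n in spec.covariate_names if n not in gens]
    if missing_gen:
        raise GeneratorError(f"true model covariates without a generator: {missing_gen}")

    n = config.n_patients
    severity = rng.standard_normal(n)

    # --- patient-level anchor covariates (deterministic iteration order) ---
    anchors = pd.DataFrame(index=pd.RangeIndex(n))
    for name in spec.covariate_names:
        anchors[name] = gens[name].draw(severity, rng)

    # --- outcome assignment with intercept bisection ---
    X = model_matrix(anchors, spec)
    score = X @ spec.coefficient_vector()
    intercept = _tune_intercept(score, config.target_prevalence)
    p_death = 1.0 / (1.0 + np.exp(-(intercept + score)))
    dies_6mo = rng.random(n) < p_death

    # --- visit schedule ---
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    window_days = (end - start).days
    first_offset = rng.integers(0, window_days + 1, size=n)
    first_arrival = start + pd.to_timedelta(first_offset, unit="D")

    # death dates relative to first arrival
    death_days = np.full(n, -1, dtype=int)
    death_days[dies_6mo] = rng.integers(2, SIX_MONTH_DAYS + 1, size=int(dies_6mo.sum()))
    late = (~dies_6mo) & (rng.random(n) < config.late_death_rate)
    death_days[late] = rng.integers(SIX_MONTH_DAYS + 1, 549, size=int(late.sum()))
    has_death = death_days > 0
    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    death_date[has_death] = first_arrival[has_death] + pd.to_timedelta(
        death_days[has_death], unit="D"
    )

    mean_v = config.visits_per_patient_mean
    k = rng.geometric(1.0 / mean_v, size=n) if mean_v > 1.0 else np.ones(n, dtype=int)
    k = np.minimum(k, 30)
    total = int(k.sum())
    pat_idx = np.repeat(np.arange(n), k)
    group_starts = np.concatenate(([0], np.cumsum(k)[:-1]))
    visit_no = np.arange(total) - np.repeat(group_starts, k)
    gaps = np.ceil(rng.exponential(config.visit_gap_mean_days, size=total)).astype(int) + 1
    gaps[visit_no == 0] = 0
    arrival = first_arrival.values[pat_idx] + pd.to_timedelta(
        _grouped_cumsum(gaps.astype(float), group_starts).astype(int), unit="D"
    )

    keep = arrival <= end
    dd = death_date.values[pat_idx]
    keep &= pd.isna(dd) | (arrival < dd)
    keep[visit_no == 0] = True  # first visit always valid by construction
    pat_idx, visit_no, arrival = pat_idx[keep], visit_no[keep], arrival[keep]
    m = len(pat_idx)

    patient_ids = np.array([f"P{i:06d}" for i in range(n)])
    encounter_ids = np.array([f"E{i:07d}" for i in range(m)])

    # --- per-encounter covariate truth: anchor + redraw noise (visit 0 = anchor) ---
    feats = pd.DataFrame({"encounter_id": encounter_ids})
    for name in spec.covariate_names:
        gen = gens[name]
        base = anchors[name].to_numpy()[pat_idx]
        if name == "ed_dx_syncope_or_cva":
            # an index-visit diagnosis: redrawn each visit
            p = gens[name].params[0]
            logit = np.log(p / (1 - p))
            padj = 1.0 / (1.0 + np.exp(-(logit + 2 * gen.loading * severity[pat_idx])))
            val = (rng.random(m) < padj).astype(float)
            val[visit_no == 0] = base[visit_no == 0]
        elif gen.scale > 0:
            noise = rng.standard_normal(m) * gen.scale * config.visit_redraw_sd
            noise[visit_no == 0] = 0.0
            val = base + noise
            if gen.family == "truncnorm":
                val = np.clip(val, gen.params[2], gen.params[3])
            elif gen.family == "lognormal":
                val = np.maximum(val, 0.01)
        else:
            val = base.copy()
        feats[name] = val

    # --- admissions table; true admissions_past_year recomputed per encounter ---
    n_adm = anchors["admissions_past_year"].to_numpy().astype(int)
    adm_pat = np.repeat(np.arange(n), n_adm)
    adm_back = rng.integers(1, 366, size=int(n_adm.sum()))
    adm_date = first_arrival.values[adm_pat] - pd.to_timedelta(adm_back, unit="D")
    admissions = pd.DataFrame(
        {"patient_id": patient_ids[adm_pat], "admit_date": adm_date}
    ).sort_values(["patient_id", "admit_date"], kind="stable", ignore_index=True)

    adm_per_enc = np.zeros(m, dtype=float)
    adm_dates_by_pat: dict[int, np.ndarray] = {}
    if len(adm_pat):
        order = np.argsort(adm_pat, kind="stable")
        sorted_pat = adm_pat[order]
        sorted_dates = adm_date.values[order]
        starts = np.searchsorted(sorted_pat, np.arange(n), side="left")
        stops = np.searchsorted(sorted_pat, np.arange(n), side="right")
        for i in range(n):
            if stops[i] > starts[i]:
                adm_dates_by_pat[i] = sorted_dates[starts[i]:stops[i]]
    arr_ns = arrival.values if isinstance(arrival, pd.DatetimeIndex) else np.asarray(arrival)
    for j in range(m):
        dates = adm_dates_by_pat.get(pat_idx[j])
        if dates is not None:
            lo = arr_ns[j] - np.timedelta64(365, "D")
            adm_per_enc[j] = np.sum((dates >= lo) & (dates < arr_ns[j]))
    feats["admissions_past_year"] = adm_per_enc

    # --- diagnoses table ---
    dx_rows: list[tuple[str, str, str, pd.Timestamp]] = []
    for name in DX_HISTORY_COVARIATES:
        flag = anchors[name].to_numpy() > 0.5
        idx = np.flatnonzero(flag)
        back = rng.integers(30, 301, size=len(idx))
        for i, b in zip(idx, back):
            dx_rows.append(
                (patient_ids[i], "", _DX_CODES[name], first_arrival[i] - pd.Timedelta(days=int(b)))
            )
    si_sigma = 2.0 * _SI_LOADING
    # logit-normal marginal correction: keeps the per-category prevalence
    # near its base rate despite the severity shift
    si_scale = np.sqrt(1.0 + (np.pi**2) * si_sigma**2 / 8.0)
    for cat in sorted(_SI_CATEGORY_CODES):
        code, base_p = _SI_CATEGORY_CODES[cat]
        logit = np.log(base_p / (1 - base_p)) * si_scale
        padj = 1.0 / (1.0 + np.exp(-(logit + si_sigma * severity)))
        flag = rng.random(n) < padj
        idx = np.flatnonzero(flag)
        back = rng.integers(0, 365, size=len(idx))
        for i, b in zip(idx, back):
            dx_rows.append((patient_ids[i], "", code, first_arrival[i] - pd.Timedelta(days=int(b))))
    ed_flag = feats["ed_dx_syncope_or_cva"].to_numpy() > 0.5
    for j in np.flatnonzero(ed_flag):
        dx_rows.append((patient_ids[pat_idx[j]], encounter_ids[j], _ED_DX_CODE, pd.Timestamp(arr_ns[j])))
    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "encounter_id", "code", "date"])
    diagnoses["date"] = pd.to_datetime(diagnoses["date"])
    diagnoses = diagnoses.sort_values(
        ["patient_id", "date", "code"], kind="stable", ignore_index=True
    )

    # --- encounters / outcomes ---
    year = pd.DatetimeIndex(arr_ns).year
    encounters = pd.DataFrame(
        {
            "encounter_id": encounter_ids,
            "patient_id": patient_ids[pat_idx],
            "arrival_date": pd.DatetimeIndex(arr_ns),
            "year": year,
            "age": feats["age"].round(1),
            "sex": np.where(rng.random(n) < 0.543, "F", "M")[pat_idx],
        }
    )
    known = death_date.copy()
    known[known > pd.Timestamp(config.censor_date)] = pd.NaT
    outcomes = pd.DataFrame({"patient_id": patient_ids, "death_date": known.values})

    # --- long vitals ---
    hr = feats["mean_heart_rate"].to_numpy()
    sbp = feats["min_systolic_bp"].to_numpy()
    o2 = feats["supplemental_oxygen"].to_numpy() > 0.5
    d1 = rng.standard_normal(m) * 5.0
    d2 = rng.standard_normal(m) * 5.0
    hr_vals = np.column_stack([hr + d1, hr + d2, hr - d1 - d2, hr + 20.0])
    s1 = np.abs(rng.standard_normal(m)) * 8.0 + 1.0
    s2 = np.abs(rng.standard_normal(m)) * 8.0 + 1.0
    sbp_vals = np.column_stack([sbp, sbp + s1, sbp + s2, sbp - 15.0])
    in_off = rng.integers(5, 236, size=(m, 3))
    out_off = rng.integers(250, 400, size=(m, 2))
    vit_frames = []
    for kind, vals, offs in (
        ("heart_rate", hr_vals, np.column_stack([in_off, out_off[:, 0]])),
        ("systolic_bp", sbp_vals, np.column_stack([in_off[:, ::-1], out_off[:, 1]])),
    ):
        vit_frames.append(
            pd.DataFrame(
                {
                    "encounter_id": np.repeat(encounter_ids, 4),
                    "offset_minutes": offs.ravel(),
                    "vital": kind,
                    "value": vals.ravel().round(6).astype(str),
                }
            )
        )
    device = np.where(o2, "nasal_cannula", "room_air")
    vit_frames.append(
        pd.DataFrame(
            {
                "encounter_id": encounter_ids,
                "offset_minutes": rng.integers(5, 236, size=m),
                "vital": "oxygen_device",
                "value": device,
            }
        )
    )
    vitals = pd.concat(vit_frames, ignore_index=True).sort_values(
        ["encounter_id", "vital", "offset_minutes"], kind="stable", ignore_index=True
    )

    # --- long labs ---
    lab_frames = []
    for analyte in LAB_COVARIATES:
        lab_frames.append(
            pd.DataFrame(
                {
                    "encounter_id": encounter_ids,
                    "offset_minutes": rng.integers(30, 241, size=m),
                    "analyte": analyte,
                    "value": feats[analyte].to_numpy().round(6),
                }
            )
        )
    labs = pd.concat(lab_frames, ignore_index=True).sort_values(
        ["encounter_id", "analyte", "offset_minutes"], kind="stable", ignore_index=True
    )

    manifest = {
        "seed": int(config.seed),
        "n_patients": int(n),
        "n_encounters": int(m),
        "tuned_intercept": float(intercept),
        "target_prevalence": float(config.target_prevalence),
        "study_start": config.study_start.isoformat(),
        "study_end": config.study_end.isoformat(),
        "censor_date": config.censor_date.isoformat(),
        "true_model": spec.name,
        "visits_per_patient_mean": float(config.visits_per_patient_mean),
        "late_death_rate": float(config.late_death_rate),
    }

    cohort = SyntheticCohort(
        encounters=encounters,
        vitals=vitals,
        labs=labs,
        diagnoses=diagnoses,
        admissions=admissions,
        outcomes=outcomes,
        features_true=feats,
        features_observed=feats.copy(),
        manifest=manifest,
    )
    rates = {k: v for k, v in sorted(config.missingness_rates.items()) if v > 0}
    if rates:
        cohort = inject_missingness(cohort, rates, seed=config.seed + 1)
    return cohort


_VITAL_OF_COVARIATE = {
    "mean_heart_rate": "heart_rate",
    "min_systolic_bp": "systolic_bp",
    "supplemental_oxygen": "oxygen_device",
}


def inject_missingness(
    cohort: SyntheticCohort, rates: Mapping[str, float], seed: int = 0
) -> SyntheticCohort:
    """Blank covariate values independently at the stated rates.

    The observed feature table gets NaNs; for lab and vital covariates
    the corresponding long-table rows are dropped too, so downstream
    feature extraction reproduces the blanking.
    """
    known = set(cohort.features_observed.columns) - {"encounter_id"}
    unknown = set(rates) - known
    if unknown:
        raise GeneratorError(f"unknown covariate name(s) in missingness rates: {sorted(unknown)}")
    for name, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise GeneratorError(f"missingness rate for {name!r} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    feats = cohort.features_observed.copy()
    labs = cohort.labs
    vitals = cohort.vitals
    drop_lab = pd.Series(False, index=labs.index)
    drop_vit = pd.Series(False, index=vitals.index)
    for name in sorted(rates):
        r = rates[name]
        if r == 0.0:
            continue
        mask = rng.random(len(feats)) < r
        feats[name] = feats[name].astype(float).where(~mask, np.nan)
        blanked = set(feats.loc[mask, "encounter_id"])
        if name in LAB_COVARIATES:
            drop_lab |= (labs["analyte"] == name) & labs["encounter_id"].isin(blanked)
        elif name in _VITAL_OF_COVARIATE:
            vit = _VITAL_OF_COVARIATE[name]
            drop_vit |= (vitals["vital"] == vit) & vitals["encounter_id"].isin(blanked)
    return dataclasses.replace(
        cohort,
        features_observed=feats,
        labs=labs.loc[~drop_lab].reset_index(drop=True),
        vitals=vitals.loc[~drop_vit].reset_index(drop=True),
    )


def six_month_mortality(
    encounters: pd.DataFrame, outcomes: pd.DataFrame, horizon_days: int = SIX_MONTH_DAYS
) -> pd.Series:
    """Per-encounter binary outcome: known death within ``horizon_days`` of arrival."""
    merged = encounters.merge(outcomes, on="patient_id", how="left")
    dt = (merged["death_date"] - merged["arrival_date"]).dt.days
    lab = (dt.notna() & (dt <= horizon_days)).astype(int)
    lab.index = encounters.index
    return lab


def survival_times(
    encounters: pd.DataFrame, outcomes: pd.DataFrame, censor_date: date | pd.Timestamp
) -> pd.DataFrame:
    """Days from arrival to death or administrative censoring.

    Returns columns ``time`` (days, > 0) and ``event`` (1 = observed
    death).  Encounters without a known death date are censored at
    ``censor_date``.
    """
    merged = encounters.merge(outcomes, on="patient_id", how="left")
    censor = pd.Timestamp(censor_date)
    dead = merged["death_date"].notna()
    t = np.where(
        dead,
        (merged["death_date"] - merged["arrival_date"]).dt.days,
        (censor - merged["arrival_date"]).dt.days,
    )
    out = pd.DataFrame({"time": t.astype(float), "event": dead.astype(int)})
    out.index = encounters.index
    return out
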