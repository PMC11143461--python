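"""End-to-end orchestration: simulate/load -> extract -> score ->
validate -> update -> screen -> decision curves -> survival -> cross-tab.

:func:`run_pipeline` is the library's one-call surface; the command-line
interface in :mod:`gestval.cli` is a thin wrapper over it.  Every stage
failure is re-raised as :class:`PipelineError` naming the stage.  All
randomness flows from the single seed in the run configuration, and the
emitted manifest records everything needed to reproduce the bundle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import extract_features
from .metrics import auroc_delong, calibration_bins, stratified_auroc
from .model import ModelSpecification, load_model_spec, default_model_spec, save_model_spec, score_frame
from .screening import (
    characteristics_table,
    decision_curve_table,
    discordant_share,
    misclassification_crosstab,
)
from .serious_illness import DiagnosisCatalog, flag_cohort
from .simulate import (
    CohortConfig,
    SyntheticCohort,
    generate_cohort,
    six_month_mortality,
    survival_times,
)
from .survival import first_encounter_filter, stratified_km
from .update import TemporalSplit, UpdateError, compare_updates, recalibrate_intercept, refit

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "ReportBundle"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one full validation run.

    Either ``simulate`` (a :class:`CohortConfig`) or ``input_dir``
    (tables previously written by the generator) must be given.  A
    ``model_spec_path`` of ``None`` scores with the shipped synthetic
    stand-in spec.
    """

    simulate: CohortConfig | None = None
    input_dir: str | Path | None = None
    model_spec_path: str | Path | None = None
    thresholds: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30)
    dca_grid_max: float = 0.50
    dca_grid_step: float = 0.01
    censor_date: date = date(2022, 12, 31)
    horizon_days: int = 183
    ci_method: str = "wilson"
    seed: int = 0
    split: TemporalSplit = field(default_factory=TemporalSplit.default)
    si_catalog_path: str | Path | None = None
    include_age_criterion: bool = True

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulate/input_dir must be set")
        for t in self.thresholds:
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class ReportBundle:
    cohort: SyntheticCohort
    features: pd.DataFrame
    scores: pd.DataFrame
    labels: pd.Series
    serious_illness: pd.Series
    discrimination: pd.DataFrame
    calibration: pd.DataFrame
    updated_models: dict[str, ModelSpecification]
    update_comparison: pd.DataFrame
    screening: pd.DataFrame
    screening_first_visit: pd.DataFrame
    screening_no_age: pd.DataFrame
    dca: pd.DataFrame
    crosstab: pd.DataFrame
    survival: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cohort.write_tables(outdir / "cohort")
        frames = {
            "features.csv": self.features,
            "scores.csv": self.scores,
            "discrimination.csv": self.discrimination,
            "calibration.csv": self.calibration,
            "update_comparison.csv": self.update_comparison,
            "screening.csv": self.screening,
            "screening_first_visit.csv": self.screening_first_visit,
            "screening_no_age.csv": self.screening_no_age,
            "dca.csv": self.dca,
            "crosstab.csv": self.crosstab,
            "survival.csv": self.survival,
        }
        for name, df in frames.items():
            df.to_csv(outdir / name, index=False)
        for label, spec in self.updated_models.items():
            save_model_spec(spec, outdir / f"model_{label}.yaml")
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=False)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run every analysis stage and return the in-memory report bundle.

    Deterministic given the config (including its seed).
    """
    with _stage("synthetic_cohort"):
        if config.simulate is not None:
            cohort = generate_cohort(config.simulate)
        else:
            cohort = SyntheticCohort.read_tables(config.input_dir)
    enc = cohort.encounters

    with _stage("feature_extraction"):
        features = extract_features(
            enc, cohort.vitals, cohort.labs, cohort.diagnoses, cohort.admissions
        )

    with _stage("risk_model"):
        if config.model_spec_path is not None:
            spec = load_model_spec(config.model_spec_path)
        else:
            spec = default_model_spec()
        feat_cov = features.drop(columns=["encounter_id"])
        scores = score_frame(feat_cov, spec)
        scores.insert(0, "encounter_id", features["encounter_id"].to_numpy())

    with _stage("serious_illness"):
        catalog = DiagnosisCatalog.from_yaml(config.si_catalog_path)
        si = flag_cohort(enc, cohort.diagnoses, catalog=catalog,
                         include_age=config.include_age_criterion)
        si_no_age = flag_cohort(enc, cohort.diagnoses, catalog=catalog, include_age=False)

    labels = six_month_mortality(enc, cohort.outcomes, config.horizon_days)
    p = scores["probability"].to_numpy()

    with _stage("discrimination_calibration"):
        rows = [auroc_delong(p, labels, stratum_label="overall").to_row()]
        rows += [r.to_row() for r in stratified_auroc(p, labels, enc["sex"])]
        rows += [r.to_row() for r in stratified_auroc(p, labels, enc["year"])]
        discrimination = pd.DataFrame(rows)
        cal = calibration_bins(p, labels)
        calibration = cal.bins.assign(model="original")

    with _stage("model_update"):
        train = enc["year"].isin(config.split.train_years).to_numpy()
        test = enc["year"].isin(config.split.test_years).to_numpy()
        updated = {"original": spec}
        comparison_rows = []
        update_skipped = None
        if labels[train].nunique() == 2 and labels[test].nunique() == 2:
            recal = recalibrate_intercept(spec, feat_cov.loc[train], labels[train])
            updated["recalibrated"] = recal
            try:
                updated["refit"] = refit(spec, feat_cov.loc[train], labels[train])
            except UpdateError as exc:
                # sparse training data can separate on a rare flag; report
                # the refit as unavailable rather than abort the run
                update_skipped = f"refit skipped: {exc}"
            cmp = compare_updates(updated, feat_cov.loc[test], labels[test])
            for label, (disc, caltab) in cmp.items():
                row = disc.to_row()
                row["model"] = label
                row["max_calibration_gap"] = float(
                    (caltab.bins["predicted_mean"] - caltab.bins["observed_rate"]).abs().max()
                )
                comparison_rows.append(row)
        else:
            update_skipped = "temporal split lacks both outcome classes"
        update_comparison = pd.DataFrame(comparison_rows)

    with _stage("screening_dca"):
        screening = characteristics_table(
            p, labels, binary_flags=si.astype(int),
            thresholds=config.thresholds, ci_method=config.ci_method,
        )
        first = first_encounter_filter(enc)
        fmask = enc.index.isin(first.index)
        screening_first = characteristics_table(
            p[fmask], labels[fmask], binary_flags=si[fmask].astype(int),
            thresholds=config.thresholds, ci_method=config.ci_method,
        )
        screening_no_age = characteristics_table(
            p, labels, binary_flags=si_no_age.astype(int),
            thresholds=config.thresholds, ci_method=config.ci_method,
            binary_label="serious_illness_no_age",
        )
        grid = np.round(
            np.arange(config.dca_grid_step, config.dca_grid_max + 1e-9, config.dca_grid_step), 10
        )
        dca = decision_curve_table(labels, p, si.astype(int), grid=grid)
        crosstab = misclassification_crosstab(si.astype(int), p, labels)

    with _stage("survival"):
        st = survival_times(first, cohort.outcomes, config.censor_date)
        curves = stratified_km(
            st["time"], st["event"], p[fmask], si[fmask].astype(int),
            risk_cutoffs=config.thresholds, horizon_days=config.horizon_days,
        )
        survival = pd.concat([c.to_frame() for c in curves if not c.skipped],
                             ignore_index=True)

    manifest = {
        "gestval_version": __version__,
        "seed": int(config.seed),
        "model_spec": spec.name,
        "n_encounters": int(len(enc)),
        "n_patients": int(enc["patient_id"].nunique()),
        "prevalence": float(labels.mean()),
        "serious_illness_fraction": float(si.mean()),
        "overall_auroc": float(discrimination.iloc[0]["auroc"]),
        "discordant_share": discordant_share(crosstab),
        "thresholds": [float(t) for t in config.thresholds],
        "horizon_days": int(config.horizon_days),
        "censor_date": config.censor_date.isoformat(),
        "ci_method": config.ci_method,
        "update_skipped": update_skipped,
        "cohort_manifest": cohort.manifest,
    }
    return ReportBundle(
        cohort=cohort, features=features, scores=scores, labels=labels,
        serious_illness=si, discrimination=discrimination, calibration=calibration,
        updated_models=updated, update_comparison=update_comparison,
        screening=screening, screening_first_visit=screening_first,
        screening_no_age=screening_no_age, dca=dca, crosstab=crosstab,
        survival=survival, manifest=manifest,
    )
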