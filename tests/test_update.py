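"""Model updating: intercept recalibration and full refit."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gestval import six_month_mortality
from gestval.metrics import auroc_delong
from gestval.model import CovariateSpec, ModelSpecification, model_matrix, score_frame
from gestval.update import (
    TemporalSplit,
    UpdateError,
    compare_updates,
    recalibrate_intercept,
    refit,
    refit_standard_errors,
)


@pytest.fixture(scope="module")
def self_generated(single_visit_cohort):
    """Features and outcomes drawn from the cohort's own true model."""
    cohort = single_visit_cohort
    spec = dataclasses.replace(
        cohort_spec(cohort), intercept=cohort.manifest["tuned_intercept"]
    )
    feats = cohort.features_true.drop(columns=["encounter_id"])
    labels = six_month_mortality(cohort.encounters, cohort.outcomes).to_numpy()
    return spec, feats, labels


def cohort_spec(cohort):
    from gestval.model import default_model_spec

    return default_model_spec()


def test_temporal_split_validation():
    with pytest.raises(UpdateError, match="disjoint"):
        TemporalSplit({2017, 2019}, {2019, 2020})
    with pytest.raises(UpdateError, match="non-empty"):
        TemporalSplit(set(), {2019})
    assert TemporalSplit.default().train_years == frozenset({2017, 2018})


class TestRecalibrate:
    def test_self_consistent_delta_is_small(self, self_generated):
        """Data generated from the spec itself: delta -> 0 in probability."""
        spec, feats, labels = self_generated
        recal = recalibrate_intercept(spec, feats, labels)
        assert abs(recal.intercept - spec.intercept) < 0.05

    def test_known_odds_multiplier_recovered(self, self_generated):
        """Outcomes redrawn with odds multiplied by k: delta ~ log k."""
        spec, feats, _ = self_generated
        k = 2.0
        eta = score_frame(feats, spec)["linear_predictor"].to_numpy()
        p_shift = 1.0 / (1.0 + np.exp(-(eta + np.log(k))))
        rng = np.random.default_rng(42)
        y = (rng.random(len(p_shift)) < p_shift).astype(int)
        recal = recalibrate_intercept(spec, feats, y)
        delta = recal.intercept - spec.intercept
        se = 1.0 / np.sqrt(np.sum(p_shift * (1 - p_shift)))
        assert abs(delta - np.log(k)) < 3 * se

    def test_idempotent(self, self_generated):
        spec, feats, labels = self_generated
        once = recalibrate_intercept(spec, feats, labels)
        twice = recalibrate_intercept(once, feats, labels)
        assert abs(twice.intercept - once.intercept) < 1e-6

    def test_all_one_class_fails(self, self_generated):
        spec, feats, _ = self_generated
        with pytest.raises(UpdateError, match="one class"):
            recalibrate_intercept(spec, feats.head(50), np.ones(50))

    def test_auroc_unchanged_by_intercept_shift(self, self_generated):
        """Rank invariance: recalibration can never change discrimination."""
        spec, feats, labels = self_generated
        recal = recalibrate_intercept(spec, feats, labels)
        a = auroc_delong(score_frame(feats, spec)["probability"], labels)
        b = auroc_delong(score_frame(feats, recal)["probability"], labels)
        assert a.auroc == pytest.approx(b.auroc, abs=1e-12)

    def test_slope_variant_fits_calibration_line(self, self_generated):
        spec, feats, labels = self_generated
        recal = recalibrate_intercept(spec, feats, labels, include_slope=True)
        # slope on self-generated data should be near 1
        ratio = recal.covariates[0].coefficient / spec.covariates[0].coefficient
        assert 0.8 < ratio < 1.2


class TestRefit:
    def test_parameter_recovery_within_3_se(self, self_generated):
        spec, feats, labels = self_generated
        fitted = refit(spec, feats, labels)
        se = refit_standard_errors(spec, feats, labels)
        assert abs(fitted.intercept - spec.intercept) < 3 * se[0]
        for i, (a, b) in enumerate(zip(fitted.covariates, spec.covariates)):
            assert abs(a.coefficient - b.coefficient) < 3 * se[1 + i], a.name

    def test_row_duplication_invariance(self, self_generated):
        spec, feats, labels = self_generated
        sub = feats.head(2000)
        y = labels[:2000]
        once = refit(spec, sub, y)
        twice = refit(spec, pd.concat([sub, sub], ignore_index=True),
                      np.concatenate([y, y]))
        assert once.intercept == pytest.approx(twice.intercept, abs=1e-6)
        for a, b in zip(once.covariates, twice.covariates):
            assert a.coefficient == pytest.approx(b.coefficient, abs=1e-6)

    def test_balanced_symmetric_data_zero_intercept(self):
        spec = ModelSpecification(
            covariates=(CovariateSpec("x", 0.0, 0.0, 1.0, 1.0),), intercept=0.5
        )
        # mirror-symmetric, overlapping classes: 70/30 at +1, 30/70 at -1
        x = np.concatenate([np.full(100, 1.0), np.full(100, -1.0)])
        y = np.concatenate([np.repeat([1, 0], [70, 30]), np.repeat([1, 0], [30, 70])])
        fitted = refit(spec, pd.DataFrame({"x": x}), y)
        assert abs(fitted.intercept) < 1e-6

    def test_separation_detected(self):
        spec = ModelSpecification(
            covariates=(CovariateSpec("x", 0.0, 0.0, 1.0, 1.0),), intercept=0.0
        )
        x = np.concatenate([np.full(30, -1.0), np.full(30, 1.0)])
        y = np.concatenate([np.zeros(30), np.ones(30)])
        with pytest.raises(UpdateError, match="x"):
            refit(spec, pd.DataFrame({"x": x}), y)

    def test_refit_likelihood_dominates_original(self, self_generated):
        """MLE dominance on the training data."""
        spec, feats, labels = self_generated
        perturbed = dataclasses.replace(spec, intercept=spec.intercept + 0.7)
        fitted = refit(perturbed, feats, labels)

        def loglik(s):
            p = score_frame(feats, s)["probability"].to_numpy()
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return np.sum(labels * np.log(p) + (1 - labels) * np.log(1 - p))

        assert loglik(fitted) >= loglik(perturbed) - 1e-6


class TestCompare:
    def test_identical_specs_identical_metrics(self, self_generated):
        spec, feats, labels = self_generated
        out = compare_updates({"a": spec, "b": spec}, feats.head(3000), labels[:3000])
        (da, ca), (db, cb) = out["a"], out["b"]
        assert da.auroc == db.auroc
        pd.testing.assert_frame_equal(ca.bins, cb.bins)

    def test_refit_fixes_shifted_intercept_calibration(self, self_generated):
        """Truth has a shifted intercept: the refit's calibration-in-the-
        large must beat the unshifted original's."""
        spec, feats, _ = self_generated
        truth = dataclasses.replace(spec, intercept=spec.intercept + 1.0)
        p_true = score_frame(feats, truth)["probability"].to_numpy()
        rng = np.random.default_rng(3)
        y = (rng.random(len(p_true)) < p_true).astype(int)
        fitted = refit(spec, feats, y)
        gap_orig = abs(score_frame(feats, spec)["probability"].mean() - y.mean())
        gap_refit = abs(score_frame(feats, fitted)["probability"].mean() - y.mean())
        assert gap_refit < gap_orig
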