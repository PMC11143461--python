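"""Threshold screening characteristics, net benefit, cross-tab."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gestval.screening import (
    ConfusionMatrix,
    ScreeningError,
    characteristics,
    characteristics_table,
    confusion_at_threshold,
    decision_curve_table,
    discordant_share,
    lr_pos_from_rates,
    misclassification_crosstab,
    net_benefit_curve,
    npv_from_rates,
    ppv_from_rates,
)


class TestConfusion:
    def test_threshold_zero_flags_everyone(self):
        cm = confusion_at_threshold([0.2, 0.8], [0, 1], 0.0)
        assert (cm.fn, cm.tn) == (0, 0) and cm.tp == 1 and cm.fp == 1

    def test_threshold_one_flags_no_one(self):
        cm = confusion_at_threshold([0.2, 0.8], [0, 1], 1.0)
        assert (cm.tp, cm.fp) == (0, 0)

    def test_strict_inequality_at_cutoff(self):
        # a score exactly at the cutoff is negative ("risk > 30%")
        cm = confusion_at_threshold([0.31, 0.30, 0.05], [1, 1, 0], 0.30)
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 0)


class TestCharacteristics:
    def test_direct_arithmetic(self):
        out = characteristics(ConfusionMatrix(tp=8, fp=2, fn=2, tn=8))
        assert out.sensitivity == pytest.approx(0.8)
        assert out.specificity == pytest.approx(0.8)
        assert out.lr_pos == pytest.approx(4.0)
        assert out.fraction_positive == pytest.approx(0.5)

    def test_published_style_row_reconstruction(self):
        """A binary screen with sens 77.4%, spec 50.5% at 13.8% prevalence
        implies LR+ 1.6 and PPV 20.0% — the identity that makes a printed
        characteristics row internally consistent."""
        sens, spec, prev = 0.774, 0.505, 0.138
        assert round(lr_pos_from_rates(sens, spec), 1) == 1.6
        assert round(100 * ppv_from_rates(sens, spec, prev), 1) == 20.0
        assert round(100 * npv_from_rates(sens, spec, prev), 1) == 93.3

    def test_no_positives_flags_lr_undefined(self):
        out = characteristics(ConfusionMatrix(tp=0, fp=0, fn=5, tn=5))
        assert np.isnan(out.ppv)
        assert out.lr_pos == 0.0 or np.isnan(out.lr_pos)  # sens=0 -> LR+ 0
        assert out.npv == pytest.approx(0.5)

    def test_no_cases_is_an_error(self):
        with pytest.raises(ScreeningError, match="no cases"):
            characteristics(ConfusionMatrix(tp=0, fp=3, fn=0, tn=7))

    def test_wilson_ci_brackets_point(self):
        out = characteristics(ConfusionMatrix(tp=80, fp=20, fn=20, tn=80))
        lo, hi = out.ci["sensitivity"]
        assert lo < out.sensitivity < hi

    @given(
        tp=st.integers(1, 200), fp=st.integers(0, 200),
        fn=st.integers(1, 200), tn=st.integers(1, 200),
    )
    def test_bayes_consistency(self, tp, fp, fn, tn):
        """PPV/NPV reconstructed from sens/spec/prev/frac_pos match the
        direct counts (the identity behind any consistent 2x2 table)."""
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        out = characteristics(cm)
        prev = (tp + fn) / cm.n
        if tp + fp > 0:
            assert ppv_from_rates(out.sensitivity, out.specificity, prev) == pytest.approx(
                out.ppv, abs=1e-12
            )
        if tn + fn > 0 and out.fraction_positive < 1:
            assert npv_from_rates(out.sensitivity, out.specificity, prev) == pytest.approx(
                out.npv, abs=1e-12
            )


class TestCharacteristicsTable:
    SCORES = np.array([0.02, 0.07, 0.15, 0.25, 0.4, 0.6])
    LABELS = np.array([0, 0, 0, 1, 1, 1])

    def test_cardinality_binary_plus_thresholds(self):
        tbl = characteristics_table(self.SCORES, self.LABELS,
                                    binary_flags=[0, 1, 0, 1, 1, 1])
        assert len(tbl) == 5
        assert tbl["screen"].tolist()[0] == "serious_illness"

    def test_monotone_threshold_sweep(self):
        rng = np.random.default_rng(8)
        scores = rng.random(500)
        labels = (rng.random(500) < scores).astype(int)
        tbl = characteristics_table(scores, labels)
        assert (np.diff(tbl["fraction_positive"]) <= 1e-12).all()
        assert (np.diff(tbl["specificity"]) >= -1e-12).all()

    def test_oracle_scores_perfect_at_half(self):
        labels = np.array([0, 1, 0, 1])
        tbl = characteristics_table(labels.astype(float), labels, thresholds=[0.5])
        assert tbl.loc[0, "sensitivity"] == 1.0
        assert tbl.loc[0, "specificity"] == 1.0

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ScreeningError, match="sorted"):
            characteristics_table(self.SCORES, self.LABELS, thresholds=[0.3, 0.1])


class TestNetBenefit:
    def test_treat_none_identically_zero(self):
        pts = net_benefit_curve([0, 1, 0, 1], strategy="treat_none")
        assert all(p.net_benefit == 0.0 for p in pts)

    def test_single_point_arithmetic(self):
        # n=100, tp=20, fp=30 at p_t=0.2: NB = 0.20 - 0.30 * 0.25 = 0.125
        labels = np.array([1] * 20 + [0] * 30 + [1] * 0 + [0] * 50)
        scores = np.array([0.9] * 50 + [0.01] * 50)
        pts = net_benefit_curve(labels, scores=scores, grid=[0.2], strategy="model")
        assert pts[0].net_benefit == pytest.approx(0.125)

    def test_treat_all_limit_is_prevalence(self):
        labels = np.array([1] * 3 + [0] * 17)
        pts = net_benefit_curve(labels, grid=[1e-9 + 0.001], strategy="treat_all")
        assert pts[0].net_benefit == pytest.approx(labels.mean(), abs=1e-3)

    def test_grid_boundary_rejected(self):
        with pytest.raises(ScreeningError, match="strictly inside"):
            net_benefit_curve([0, 1], scores=[0.1, 0.9], grid=[1.0])

    def test_positive_nb_when_tp_outweigh_exchange_rate(self):
        rng = np.random.default_rng(9)
        scores = rng.random(2000)
        labels = (rng.random(2000) < scores).astype(int)
        for pt in (0.1, 0.3):
            pos = scores > pt
            tp, fp = (pos & (labels == 1)).sum(), (pos & (labels == 0)).sum()
            nb = net_benefit_curve(labels, scores=scores, grid=[pt])[0].net_benefit
            if tp / max(fp, 1) > pt / (1 - pt):
                assert nb >= 0.0

    def test_better_separated_score_dominates_in_expectation(self):
        """Averaged over seeds, a strictly better-separated score has at
        least the net benefit of a noisier one at every grid point."""
        grid = np.arange(0.05, 0.45, 0.05)
        diff = np.zeros(len(grid))
        for seed in range(50):
            rng = np.random.default_rng(200 + seed)
            p = rng.beta(2, 8, 400)
            labels = (rng.random(400) < p).astype(int)
            noisy = np.clip(p + rng.normal(0, 0.15, 400), 0, 1)
            nb_true = [x.net_benefit for x in net_benefit_curve(labels, scores=p, grid=grid)]
            nb_noisy = [x.net_benefit for x in net_benefit_curve(labels, scores=noisy, grid=grid)]
            diff += np.array(nb_true) - np.array(nb_noisy)
        assert (diff / 50 >= -1e-3).all()

    def test_all_strategies_in_one_table(self):
        tbl = decision_curve_table([0, 1, 1, 0], [0.1, 0.8, 0.6, 0.2], [0, 1, 1, 1])
        assert set(tbl["strategy"]) == {"model", "binary_criterion", "treat_all", "treat_none"}


class TestCrosstab:
    def test_single_occupied_cell(self):
        tab = misclassification_crosstab([1] * 5, [0.2] * 5, [0, 1, 0, 0, 1])
        occupied = tab.loc[tab["count"] > 0]
        assert len(occupied) == 1
        assert occupied.iloc[0]["risk_band"] == "middle"
        assert occupied.iloc[0]["serious_illness"] == "serious_illness"

    def test_hand_tallied_fixture(self):
        si =     [1,    1,    1,    0,    0,    0,    1,    0,    1,    0]
        scores = [0.05, 0.15, 0.40, 0.05, 0.20, 0.50, 0.09, 0.25, 0.35, 0.02]
        labels = [0,    0,    1,    0,    0,    1,    0,    1,    1,    0]
        tab = misclassification_crosstab(si, scores, labels).set_index(
            ["serious_illness", "risk_band"]
        )
        assert tab.loc[("serious_illness", "low"), "count"] == 2        # 0.05, 0.09
        assert tab.loc[("serious_illness", "middle"), "count"] == 1     # 0.15
        assert tab.loc[("serious_illness", "high"), "count"] == 2       # 0.40, 0.35
        assert tab.loc[("no_serious_illness", "low"), "count"] == 2     # 0.05, 0.02
        assert tab.loc[("no_serious_illness", "middle"), "count"] == 2  # 0.20, 0.25
        assert tab.loc[("no_serious_illness", "high"), "count"] == 1    # 0.50
        assert tab.loc[("serious_illness", "high"), "observed_mortality"] == 1.0
        assert discordant_share(tab.reset_index()) == pytest.approx(3 / 10)

    def test_partition_identity(self):
        rng = np.random.default_rng(5)
        si = (rng.random(300) < 0.5).astype(int)
        scores = rng.random(300)
        labels = (rng.random(300) < scores).astype(int)
        tab = misclassification_crosstab(si, scores, labels)
        assert tab["share_of_all"].sum() == pytest.approx(1.0)
        d = discordant_share(tab)
        concordant = tab.loc[~tab["discordant"], "share_of_all"].sum()
        assert d + concordant == pytest.approx(1.0)
        assert 0.0 <= d <= 1.0
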