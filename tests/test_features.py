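"""Covariate extraction: windows, lookbacks, tie rules, purity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gestval.features import (
    FeatureExtractionError,
    count_admissions,
    extract_features,
    flag_diagnoses,
    select_labs,
    summarize_vitals,
)


def vit(rows):
    return pd.DataFrame(rows, columns=["encounter_id", "offset_minutes", "vital", "value"])


def lab(rows):
    return pd.DataFrame(rows, columns=["encounter_id", "offset_minutes", "analyte", "value"])


class TestVitals:
    def test_mean_uses_only_first_window(self):
        v = vit([("e", 10, "heart_rate", 80), ("e", 60, "heart_rate", 100),
                 ("e", 300, "heart_rate", 140)])
        assert summarize_vitals(v, 240)["mean_heart_rate"] == pytest.approx(90.0)

    def test_singleton_sbp_is_its_own_minimum(self):
        v = vit([("e", 5, "systolic_bp", 120)])
        assert summarize_vitals(v)["min_systolic_bp"] == 120.0

    def test_empty_table_yields_all_absent(self):
        out = summarize_vitals(vit([]))
        assert out == {"mean_heart_rate": None, "min_systolic_bp": None,
                       "supplemental_oxygen": None}

    def test_oxygen_device_flag(self):
        v = vit([("e", 30, "oxygen_device", "room_air"),
                 ("e", 90, "oxygen_device", "nasal_cannula")])
        assert summarize_vitals(v)["supplemental_oxygen"] is True
        v2 = vit([("e", 30, "oxygen_device", "room_air"),
                  ("e", 300, "oxygen_device", "nasal_cannula")])
        assert summarize_vitals(v2)["supplemental_oxygen"] is False

    def test_negative_offset_is_an_error(self):
        with pytest.raises(FeatureExtractionError, match="negative"):
            summarize_vitals(vit([("e", -5, "heart_rate", 80)]))

    @given(
        obs=st.lists(
            st.tuples(st.integers(0, 500), st.floats(40, 180, allow_nan=False)),
            min_size=0, max_size=12,
        ),
        window=st.integers(1, 500),
    )
    def test_matches_filter_then_aggregate_oracle(self, obs, window):
        """Shrinking the window never adds observations; summaries equal a
        brute-force filter-then-aggregate."""
        v = vit([("e", o, "heart_rate", x) for o, x in obs])
        out = summarize_vitals(v, window)
        kept = [x for o, x in obs if o <= window]
        if kept:
            assert out["mean_heart_rate"] == pytest.approx(float(np.mean(kept)))
        else:
            assert out["mean_heart_rate"] is None


class TestLabs:
    def test_earliest_result_wins(self):
        rows = lab([("e", 30, "hemoglobin", 12.1), ("e", 200, "hemoglobin", 11.0)])
        assert select_labs(rows)["hemoglobin"] == 12.1

    def test_absent_analyte_is_none(self):
        assert select_labs(lab([("e", 30, "hemoglobin", 12.1)]))["blood_urea_nitrogen"] is None

    def test_duplicate_offsets_keep_lower_row_index(self):
        rows = lab([("e", 30, "hemoglobin", 12.1), ("e", 30, "hemoglobin", 12.3)])
        assert select_labs(rows)["hemoglobin"] == 12.1

    def test_non_numeric_result_fails_with_row_identity(self):
        rows = lab([("e", 30, "hemoglobin", "pending")])
        with pytest.raises(FeatureExtractionError, match="hemoglobin"):
            select_labs(rows)


class TestAdmissions:
    ARRIVAL = pd.Timestamp("2019-06-01")

    def adm(self, day_offsets):
        return pd.DataFrame(
            {"patient_id": "p", "admit_date": [self.ARRIVAL + pd.Timedelta(days=d)
                                               for d in day_offsets]}
        )

    def test_only_past_year_counts(self):
        assert count_admissions(self.adm([-30, -400]), "p", self.ARRIVAL) == 1

    def test_empty_table(self):
        assert count_admissions(self.adm([]), "p", self.ARRIVAL) == 0

    def test_365_days_before_is_counted(self):
        # window closed on the left
        assert count_admissions(self.adm([-365]), "p", self.ARRIVAL) == 1

    def test_same_day_admission_not_counted(self):
        assert count_admissions(self.adm([0]), "p", self.ARRIVAL) == 0


class TestDiagnoses:
    ARRIVAL = pd.Timestamp("2019-06-01")
    CATALOG = {"dx_secondary_cancer": ("C77", "C78", "C79"),
               "ed_dx_syncope_or_cva": ("R55", "I63")}

    def dx(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "encounter_id", "code", "date"])

    def test_prefix_match(self):
        d = self.dx([("p", "", "C78.0", self.ARRIVAL - pd.Timedelta(days=100))])
        out = flag_diagnoses(d, "p", self.ARRIVAL, self.CATALOG)
        assert out["dx_secondary_cancer"] is True

    def test_empty_history_all_false(self):
        out = flag_diagnoses(self.dx([]), "p", self.ARRIVAL, self.CATALOG)
        assert not any(out.values())

    def test_no_lookahead(self):
        d = self.dx([("p", "", "C78.0", self.ARRIVAL + pd.Timedelta(days=10))])
        assert flag_diagnoses(d, "p", self.ARRIVAL, self.CATALOG)["dx_secondary_cancer"] is False

    def test_ed_flag_requires_index_encounter_attachment(self):
        d = self.dx([("p", "e1", "I63.9", self.ARRIVAL),
                     ("p", "", "R55", self.ARRIVAL - pd.Timedelta(days=50))])
        out = flag_diagnoses(d, "p", self.ARRIVAL, self.CATALOG, encounter_id="e1")
        assert out["ed_dx_syncope_or_cva"] is True
        out2 = flag_diagnoses(d, "p", self.ARRIVAL, self.CATALOG, encounter_id="e2")
        assert out2["ed_dx_syncope_or_cva"] is False

    def test_history_lookback_limit(self):
        d = self.dx([("p", "", "C78.0", self.ARRIVAL - pd.Timedelta(days=400))])
        assert flag_diagnoses(d, "p", self.ARRIVAL, self.CATALOG)["dx_secondary_cancer"] is True
        out = flag_diagnoses(d, "p", self.ARRIVAL, self.CATALOG, history_lookback_days=365)
        assert out["dx_secondary_cancer"] is False


def test_extraction_is_pure_and_matches_generated_truth(small_cohort):
    """Same tables => same vector; extracted values equal the generator's
    observed feature table (labs/vitals to write precision)."""
    c = small_cohort
    f1 = extract_features(c.encounters, c.vitals, c.labs, c.diagnoses, c.admissions)
    f2 = extract_features(c.encounters, c.vitals, c.labs, c.diagnoses, c.admissions)
    pd.testing.assert_frame_equal(f1, f2)
    obs = c.features_observed.set_index("encounter_id")
    got = f1.set_index("encounter_id")
    for col in ("hemoglobin", "blood_urea_nitrogen", "mean_heart_rate",
                "min_systolic_bp", "admissions_past_year", "dx_secondary_cancer",
                "dx_lung_cancer", "ed_dx_syncope_or_cva", "supplemental_oxygen"):
        assert (obs[col].isna() == got[col].isna()).all(), col
        both = obs[col].notna()
        assert np.allclose(obs.loc[both, col], got.loc[both, col], atol=1e-5), col
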