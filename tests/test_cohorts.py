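"""Cohorting rules against hand-enumerated truth and boundary cases."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glycorank.cohorts import (
    ConfounderImputer,
    apply_exclusions,
    assign_cohort,
    attribute_treatment,
    build_snapshot_table,
    build_snapshots,
    compute_cci,
    split_train_test,
)

from conftest import dx, hba1c, make_history, rx


class TestExclusions:
    @pytest.mark.parametrize(
        "category",
        ["type1_diabetes", "gestational_diabetes", "diabetic_ketoacidosis",
         "cystic_fibrosis", "solid_organ_transplant"],
    )
    def test_flagged_condition_drops_patient(self, category):
        h = make_history(labs=[hba1c(0, 9.5), hba1c(100, 9.0)],
                         diagnoses=[dx(-10, category)])
        log = []
        assert apply_exclusions([h], drop_log=log) == []
        assert log[0][1] == f"excluded_condition:{category}"

    def test_minor_at_index_dropped(self):
        seventeen = -int(17 * 365.25)
        h = make_history(birth_day=seventeen, labs=[hba1c(0, 9.5), hba1c(100, 9.0)])
        assert apply_exclusions([h]) == []

    def test_unflagged_adult_retained(self):
        h = make_history(labs=[hba1c(0, 9.5), hba1c(100, 9.0)],
                         diagnoses=[dx(-10, "renal_disease")])
        assert apply_exclusions([h]) == [h]


class TestSnapshotConstruction:
    def test_three_labs_give_two_snapshots_with_enumerated_durations(self):
        h = make_history(
            labs=[hba1c(0, 9.5), hba1c(100, 9.2), hba1c(300, 9.1)],
            prescriptions=[rx(1, "metformin", 400)],
        )
        snaps = build_snapshots(h)
        assert [(s.index_day, s.terminal_day) for s in snaps] == [(0, 100), (100, 300)]
        assert [s.duration for s in snaps] == [100, 200]

    @pytest.mark.parametrize("gap,kept", [(89, 0), (90, 1), (365, 1), (366, 0), (60, 0)])
    def test_duration_window_inclusive_boundaries(self, gap, kept):
        h = make_history(
            labs=[hba1c(0, 9.5), hba1c(gap, 9.0)],
            prescriptions=[rx(1, "metformin", 400)],
        )
        assert len(build_snapshots(h)) == kept

    def test_single_lab_yields_none(self):
        h = make_history(labs=[hba1c(0, 10.0)],
                         prescriptions=[rx(1, "metformin", 400)])
        assert build_snapshots(h) == []

    @pytest.mark.parametrize("index_value,kept", [(8.5, 0), (8.99, 0), (9.0, 1)])
    def test_index_must_be_at_least_nine(self, index_value, kept):
        h = make_history(
            labs=[hba1c(0, index_value), hba1c(100, 10.0)],
            prescriptions=[rx(1, "metformin", 400)],
        )
        assert len(build_snapshots(h)) == kept

    def test_untreated_snapshot_excluded(self):
        h = make_history(labs=[hba1c(0, 9.5), hba1c(100, 9.0)])
        log = []
        assert build_snapshots(h, drop_log=log) == []
        assert log[0][2] == "untreated"

    def test_duplicate_same_day_lab_keeps_last(self, caplog):
        h = make_history(
            labs=[hba1c(0, 9.5), hba1c(0, 10.5), hba1c(100, 9.0)],
            prescriptions=[rx(1, "metformin", 400)],
        )
        snaps = build_snapshots(h)
        assert len(snaps) == 1
        assert snaps[0].index_hba1c == 10.5

    def test_delta_is_terminal_minus_index(self):
        h = make_history(
            labs=[hba1c(0, 10.5), hba1c(120, 9.1)],
            prescriptions=[rx(1, "metformin", 400)],
        )
        (s,) = build_snapshots(h)
        assert s.delta_hba1c == pytest.approx(9.1 - 10.5, abs=1e-12)


class TestTreatmentAttribution:
    def frame(self, *rows):
        return pd.DataFrame(rows, columns=["fill_day", "drug_class", "days_supply"])

    def test_grace_period_extends_coverage(self):
        # 90-day supply from day 0 covers day 100 only via the 30-day grace.
        rxs = self.frame(rx(0, "metformin", 90))
        assert attribute_treatment(rxs, 100) == "metformin"

    def test_expired_supply_even_with_grace_is_uncovered(self):
        rxs = self.frame(rx(0, "metformin", 60))
        assert attribute_treatment(rxs, 100) is None

    @pytest.mark.parametrize("day,expected", [
        (119, "metformin"),  # 0 + 90 + 30 = 120 exclusive upper bound
        (120, None),
        (0, "metformin"),    # fill day itself is covered
        (-1, None),          # before the fill
    ])
    def test_coverage_interval_boundaries(self, day, expected):
        rxs = self.frame(rx(0, "metformin", 90))
        assert attribute_treatment(rxs, day) == expected

    def test_concurrent_fills_form_combination(self):
        rxs = self.frame(rx(0, "metformin", 90), rx(10, "sulfonylurea", 90))
        assert attribute_treatment(rxs, 50) == "metformin+sulfonylurea"

    def test_negative_supply_rejected(self):
        with pytest.raises(ValueError):
            attribute_treatment(self.frame(rx(0, "metformin", -1)), 0)

    def test_regimen_change_attributed_to_new_regimen(self):
        """A switch during the snapshot: the terminal-lab regimen wins."""
        h = make_history(
            labs=[hba1c(0, 10.0), hba1c(180, 9.0)],
            prescriptions=[rx(-30, "sulfonylurea", 60), rx(100, "glp1", 90)],
        )
        (s,) = build_snapshots(h)
        assert s.regimen == "glp1"
        assert s.prior_regimen == "sulfonylurea"


class TestCci:
    def test_no_diagnoses_zero(self):
        assert compute_cci(pd.DataFrame(columns=["day", "condition_category"]), 0) == 0

    def test_repeat_category_counts_once(self):
        d = pd.DataFrame([dx(-5, "renal_disease"), dx(-1, "renal_disease")])
        assert compute_cci(d, 0) == 1

    def test_future_diagnoses_ignored(self):
        d = pd.DataFrame([
            dx(-5, "renal_disease"), dx(-1, "dementia"), dx(10, "malignancy"),
        ])
        assert compute_cci(d, 0) == 2

    def test_non_charlson_categories_do_not_count(self):
        d = pd.DataFrame([dx(-5, "type1_diabetes")])
        assert compute_cci(d, 0) == 0


class TestCohortAssignment:
    @pytest.mark.parametrize("insulin,age,cci,label", [
        (False, 54, 2, "A"),
        (False, 40, 3, "B"),
        (False, 40, 4, "B"),
        (False, 40, 5, "C"),
        (False, 64.99, 2, "A"),
        (False, 65.0, 0, "D"),
        (False, 70, 4, "D"),
        (False, 70, 5, "E"),
        (True, 54, 2, "F"),
        (True, 40, 3, "G"),
        (True, 40, 5, "H"),
        (True, 65.0, 4, "I"),
        (True, 70, 6, "J"),
    ])
    def test_boundary_cases(self, insulin, age, cci, label):
        assert assign_cohort(insulin, age, cci) == label

    @given(
        insulin=st.booleans(),
        age=st.floats(min_value=18.0, max_value=110.0,
                      allow_nan=False, allow_infinity=False),
        cci=st.integers(min_value=0, max_value=14),
    )
    @settings(max_examples=200, deadline=None)
    def test_total_and_single_valued(self, insulin, age, cci):
        label = assign_cohort(insulin, age, cci)
        assert label in set("ABCDEFGHIJ")
        half = "ABCDE" if not insulin else "FGHIJ"
        assert label in half


class TestConfounderImputation:
    def frame(self):
        return pd.DataFrame({
            "age_years": [50.0, 60.0, 70.0],
            "sex_male": [1.0, 0.0, 1.0],
            "index_hba1c": [9.5, 10.5, 11.5],
            "egfr": [90.0, np.nan, 98.0],
            "creatinine": [0.8, 0.9, 1.0],
            "zcta_income": [np.nan, 50000.0, 60000.0],
            "zcta_frac_black": [0.2, 0.2, 0.2],
            "zcta_frac_asian": [0.1, 0.1, 0.1],
            "zcta_frac_other": [0.1, 0.1, 0.1],
        })

    def test_missing_filled_with_training_mean_and_flagged(self):
        df = self.frame()
        out = ConfounderImputer().fit_transform(df)
        assert out.loc[1, "egfr"] == pytest.approx(94.0)
        assert out.loc[1, "egfr_missing"] == 1.0
        assert out.egfr_missing.sum() == 1.0

    def test_complete_data_unchanged_with_zero_indicators(self):
        df = self.frame().fillna({"egfr": 94.0, "zcta_income": 55000.0})
        out = ConfounderImputer().fit_transform(df)
        assert (out.filter(like="_missing") == 0).all().all()
        pd.testing.assert_frame_equal(out[df.columns], df)

    def test_test_set_uses_training_means(self):
        imp = ConfounderImputer().fit(self.frame())
        test = self.frame().iloc[:1].copy()
        test["egfr"] = np.nan
        out = imp.transform(test)
        assert out.loc[0, "egfr"] == pytest.approx(94.0)

    def test_missing_age_or_sex_raises(self):
        df = self.frame()
        df.loc[0, "age_years"] = np.nan
        with pytest.raises(ValueError):
            ConfounderImputer().fit(df)


class TestTrainTestSplit:
    def test_eighty_twenty_sizes_and_determinism(self):
        df = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(100)],
            "delta_hba1c": np.linspace(-3, 1, 100),
        })
        tr1, te1, _ = split_train_test(df, seed=4)
        tr2, te2, _ = split_train_test(df, seed=4)
        assert len(tr1) == 80 and len(te1) == 20
        pd.testing.assert_frame_equal(tr1, tr2)
        pd.testing.assert_frame_equal(te1, te2)

    def test_patient_level_split_keeps_patients_together(self):
        df = pd.DataFrame({
            "patient_id": np.repeat([f"P{i}" for i in range(30)], 3),
            "delta_hba1c": np.zeros(90),
        })
        tr, te, _ = split_train_test(df, seed=1, by_patient=True)
        assert set(tr.patient_id) & set(te.patient_id) == set()

    def test_split_smds_small_on_homogeneous_data(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(10000)],
            "x1": rng.normal(size=10000),
            "x2": rng.normal(size=10000),
        })
        _, _, report = split_train_test(df, seed=2)
        assert (report.set_index("column").loc[["x1", "x2"], "smd"] < 0.1).all()


def test_snapshot_table_row_counts_on_enumerated_fixture():
    """Two patients with hand-countable snapshots end to end."""
    h1 = make_history(
        patient_id="P1",
        labs=[hba1c(0, 9.5), hba1c(100, 9.2), hba1c(160, 9.3), hba1c(300, 9.0)],
        prescriptions=[rx(1, "metformin", 500)],
    )  # pairs: (0,100) keep, (100,160) gap 60 drop, (160,300) gap 140 keep
    h2 = make_history(
        patient_id="P2",
        labs=[hba1c(0, 8.5), hba1c(120, 9.4), hba1c(240, 9.1)],
        prescriptions=[rx(1, "glp1", 400)],
    )  # (0,120) index<9 drop, (120,240) keep
    table = build_snapshot_table([h1, h2])
    assert len(table) == 3
    assert list(table.patient_id) == ["P1", "P1", "P2"]
    assert (table.groupby("patient_id").size() == pd.Series(
        {"P1": 2, "P2": 1})).all()
    # every retained row satisfies the snapshot invariants
    assert table.duration_days.between(90, 365).all()
    assert (table.index_hba1c >= 9.0).all()
    assert (table.regimen != "").all()
    assert np.allclose(
        table.delta_hba1c, table.terminal_hba1c - table.index_hba1c
    )
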