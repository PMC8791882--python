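"""Cohort I/O, filtering and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from periotree.cohort import (
    Cohort,
    CohortSchemaError,
    CohortValidationError,
    annual_loss_rate,
    build_cohort,
    cohorts_equal,
    complete_case_filter,
    descriptive_tables,
    merge_bone_loss,
    read_cohort_csv,
    write_cohort_csv,
)
from periotree.simulate import SimConfig, generate

from conftest import cohort_from_jaw_counts, make_patient, make_tooth


class TestReadWrite:
    def test_round_trip_tiny_fixture(self, tiny_cohort, tmp_path):
        path = write_cohort_csv(tiny_cohort, tmp_path / "tiny.csv")
        back = read_cohort_csv(path)
        assert back.n_patients == 2
        assert back.n_teeth == 4
        assert cohorts_equal(tiny_cohort, back)

    def test_third_molar_rejected_with_diagnostic(self, tmp_path):
        patients = pd.DataFrame([make_patient("A")])
        teeth = pd.DataFrame([make_tooth("A", 11), make_tooth("A", 18, tooth_type="molar")])
        # FDI x8 codes are excluded globally, with a row-indexed diagnostic
        c = build_cohort(patients, teeth)
        assert c.n_teeth == 1
        assert any("third molar" in d for d in c.provenance["rejected_rows"])

    def test_unknown_level_raises_naming_row_and_field(self, tmp_path):
        patients = pd.DataFrame([make_patient("A")])
        teeth = pd.DataFrame([make_tooth("A", 11, jaw="upper")])
        with pytest.raises(ValueError, match=r"row 0.*'upper'.*jaw"):
            build_cohort(patients, teeth)

    def test_missing_column_is_schema_error(self, tmp_path):
        df = pd.DataFrame({"patient_id": ["A"], "tooth_id": [11]})
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(CohortSchemaError, match="missing required column"):
            read_cohort_csv(p)

    def test_separate_patient_file_join(self, tiny_cohort, tmp_path):
        merged = tiny_cohort.merged()
        tooth_only = merged.drop(columns=["age", "gender", "smoking", "diabetes", "pcr"])
        tooth_path = tmp_path / "teeth.csv"
        tooth_only.to_csv(tooth_path, index=False)
        pat_path = tmp_path / "patients.csv"
        tiny_cohort.patients.to_csv(pat_path, index=False)
        back = read_cohort_csv(tooth_path, patient_path=pat_path)
        assert cohorts_equal(tiny_cohort, back)

    def test_na_token_is_missing(self, tmp_path, tiny_cohort):
        path = write_cohort_csv(tiny_cohort, tmp_path / "c.csv")
        text = path.read_text().replace("21-40", "NA", 1)
        path.write_text(text)
        back = read_cohort_csv(path)
        assert back.teeth["bone_loss_raw"].isna().sum() == 1

    def test_anterior_multirooted_rejected(self):
        patients = pd.DataFrame([make_patient("A")])
        teeth = pd.DataFrame([make_tooth("A", 11, furcation_class="multi_fi")])
        with pytest.raises(CohortValidationError, match="anterior"):
            build_cohort(patients, teeth)

    def test_duplicate_tooth_rejected(self):
        patients = pd.DataFrame([make_patient("A")])
        teeth = pd.DataFrame([make_tooth("A", 11), make_tooth("A", 11)])
        with pytest.raises(CohortValidationError, match="duplicate"):
            build_cohort(patients, teeth)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_random_cohorts(self, seed, tmp_path_factory):
        cohort = generate(SimConfig(n_patients=8, seed=seed))
        path = tmp_path_factory.mktemp("rt") / "c.csv"
        write_cohort_csv(cohort, path)
        assert cohorts_equal(cohort, read_cohort_csv(path))


class TestCompleteCase:
    def test_removes_exactly_injected_positions(self, default_cohort):
        cohort = default_cohort.copy()
        rng = np.random.default_rng(0)
        full = cohort.teeth["furcation_class"].notna() & cohort.teeth["bone_loss_raw"].notna() & cohort.teeth["abutment"].notna()
        idx = rng.choice(np.flatnonzero(full.to_numpy()), size=14, replace=False)
        cohort.teeth.loc[idx, "furcation_class"] = np.nan
        before_missing = int(cohort.merged()["furcation_class"].isna().sum())
        filtered, report = complete_case_filter(cohort, ["furcation_class"])
        assert report.removed_teeth_by_var["furcation_class"] == before_missing
        assert filtered.n_teeth == cohort.n_teeth - before_missing
        kept_ids = set(zip(filtered.teeth["patient_id"], filtered.teeth["tooth_id"]))
        dropped = set(zip(cohort.teeth.loc[idx, "patient_id"], cohort.teeth.loc[idx, "tooth_id"]))
        assert not kept_ids & dropped

    def test_no_missing_is_identity(self, tiny_cohort):
        filtered, report = complete_case_filter(tiny_cohort)
        assert report.n_teeth_removed == 0
        assert report.n_patients_removed == 0
        assert all(v == 0 for v in report.removed_teeth_by_var.values())
        assert cohorts_equal(filtered, tiny_cohort)

    def test_idempotent(self, default_cohort):
        once, _ = complete_case_filter(default_cohort)
        twice, rep2 = complete_case_filter(once)
        assert rep2.n_teeth_removed == 0
        assert cohorts_equal(once, twice)

    def test_missing_patient_covariate_drops_all_teeth(self, tiny_cohort):
        cohort = tiny_cohort.copy()
        cohort.patients.loc[cohort.patients["patient_id"] == "A", "age"] = np.nan
        filtered, report = complete_case_filter(cohort)
        assert set(filtered.teeth["patient_id"]) == {"B"}
        assert report.n_patients_removed == 1

    def test_empty_result_is_error(self, tiny_cohort):
        cohort = tiny_cohort.copy()
        cohort.patients["age"] = np.nan
        with pytest.raises(ValueError, match="every tooth"):
            complete_case_filter(cohort)

    def test_unknown_variable_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="unknown covariate"):
            complete_case_filter(tiny_cohort, ["bone_loss"])


class TestDescriptives:
    def test_jaw_loss_percentages_match_printed_table(self):
        cohort = cohort_from_jaw_counts()
        teeth_tab = descriptive_tables(cohort)["teeth"]
        jaw = teeth_tab[teeth_tab["variable"] == "jaw"].set_index("level")
        assert jaw.loc["maxilla", "lost_pct"] == pytest.approx(7.90, abs=0.005)
        assert jaw.loc["mandible", "lost_pct"] == pytest.approx(5.22, abs=0.005)
        assert jaw.loc["maxilla", "retained_pct"] == pytest.approx(92.1, abs=0.05)

    def test_chi2_equals_hand_computed_pearson(self):
        cohort = cohort_from_jaw_counts()
        teeth_tab = descriptive_tables(cohort)["teeth"]
        p_pkg = teeth_tab.loc[teeth_tab["variable"] == "jaw", "chi2_p_naive"].iloc[0]
        # textbook Pearson statistic from the four cells
        obs = np.array([[1119.0, 96.0], [1271.0, 70.0]])
        rowsum = obs.sum(axis=1, keepdims=True)
        colsum = obs.sum(axis=0, keepdims=True)
        exp = rowsum * colsum / obs.sum()
        stat = ((obs - exp) ** 2 / exp).sum()
        from scipy.stats import chi2

        assert p_pkg == pytest.approx(chi2.sf(stat, 1), rel=1e-12)

    def test_single_tooth_degenerates_to_100_percent(self):
        patients = pd.DataFrame([make_patient("A")])
        teeth = pd.DataFrame([make_tooth("A", 11)])
        tabs = descriptive_tables(build_cohort(patients, teeth))
        t = tabs["teeth"]
        assert (t["retained_pct"] == 100.0).all()
        assert (t["lost_pct"] == 0.0).all()

    def test_percentages_sum_to_100_within_variable(self, default_cohort):
        tabs = descriptive_tables(default_cohort)
        for var, grp in tabs["patients"].groupby("variable"):
            assert grp["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        for var, grp in tabs["teeth"].groupby("variable"):
            assert (grp["retained_pct"] + grp["lost_pct"]).max() == pytest.approx(100.0, abs=1e-9)

    def test_empty_cohort_rejected(self, tiny_cohort):
        empty = Cohort(tiny_cohort.patients.iloc[:0], tiny_cohort.teeth.iloc[:0])
        with pytest.raises(ValueError):
            descriptive_tables(empty)


class TestAnnualLossRate:
    def test_printed_totals_give_015(self):
        cohort = cohort_from_jaw_counts()  # 166 lost, 110 patients
        assert round(annual_loss_rate(cohort, years=10), 2) == 0.15

    def test_zero_lost(self, tiny_cohort):
        cohort = tiny_cohort.copy()
        cohort.teeth["lost_by_T2"] = 0
        assert annual_loss_rate(cohort) == 0.0

    def test_exact_arithmetic(self):
        cohort = cohort_from_jaw_counts(maxilla_total=600, maxilla_lost=30, mandible_total=600, mandible_lost=25)
        assert annual_loss_rate(cohort, years=5.0) == pytest.approx(55 / (5 * 110))

    def test_zero_patients_error(self, tiny_cohort):
        empty = Cohort(tiny_cohort.patients.iloc[:0], tiny_cohort.teeth.iloc[:0])
        with pytest.raises(ValueError):
            annual_loss_rate(empty)

    def test_nonpositive_years_error(self, tiny_cohort):
        with pytest.raises(ValueError):
            annual_loss_rate(tiny_cohort, years=0.0)


def test_bone_loss_merge_rule():
    assert merge_bone_loss("61-80") == ">60"
    assert merge_bone_loss(">80") == ">60"
    assert merge_bone_loss("41-60") == "41-60"
    assert np.isnan(merge_bone_loss(np.nan))
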