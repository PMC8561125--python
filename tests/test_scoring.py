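"""Clinical CVH scoring: category boundaries, summation, inclusion filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvh_windows.scoring import (
    IDEAL,
    INTERMEDIATE,
    POOR,
    ExamRecord,
    apply_completeness_filter,
    categorize_bmi,
    categorize_bp,
    categorize_cholesterol,
    categorize_glucose,
    clinical_cvh_score,
    score_dataset,
)
from cvh_windows.simulate import GeneratorConfig, preset, generate_raw_metrics
from dataclasses import replace


@pytest.mark.parametrize(
    "age,bmi,pct,expected",
    [
        (30, 24.9, None, IDEAL),
        (30, 25.0, None, INTERMEDIATE),
        (30, 29.99, None, INTERMEDIATE),
        (30, 30.0, None, POOR),
        (12, None, 84.9, IDEAL),
        (12, None, 85.0, INTERMEDIATE),
        (12, None, 95.0, INTERMEDIATE),
        (12, None, 96.0, POOR),
        (19.9, 40.0, 50.0, IDEAL),  # percentile governs below age 20
    ],
)
def test_bmi_categories(age, bmi, pct, expected):
    assert categorize_bmi(age, bmi, pct) == expected


@pytest.mark.parametrize(
    "age,sbp,dbp,pct,med,expected",
    [
        (25, 118, 78, None, False, IDEAL),
        (25, 118, 78, None, True, INTERMEDIATE),  # treated to ideal levels
        (25, 142, 70, None, False, POOR),
        (25, 120, 78, None, False, INTERMEDIATE),
        (25, 118, 80, None, False, INTERMEDIATE),
        (25, 139, 89, None, False, INTERMEDIATE),
        (25, 118, 90, None, False, POOR),
        (15, 112, 70, 92.0, False, INTERMEDIATE),
        (15, 112, 70, 89.9, False, IDEAL),
        (15, 112, 70, 95.1, False, POOR),
        (15, 122, 70, 85.0, False, INTERMEDIATE),  # absolute clause demotes
        (15, 112, 82, 85.0, False, INTERMEDIATE),
    ],
)
def test_bp_categories(age, sbp, dbp, pct, med, expected):
    assert categorize_bp(age, sbp, dbp, pct, med) == expected


@pytest.mark.parametrize(
    "chol,med,expected",
    [
        (184, False, IDEAL),
        (185, False, INTERMEDIATE),
        (219, False, INTERMEDIATE),
        (220, False, POOR),
        (180, True, INTERMEDIATE),
    ],
)
def test_cholesterol_categories(chol, med, expected):
    assert categorize_cholesterol(chol, med) == expected


@pytest.mark.parametrize(
    "glu,med,expected",
    [
        (99, False, IDEAL),
        (100, False, INTERMEDIATE),
        (125, False, INTERMEDIATE),
        (126, False, POOR),
        (95, True, INTERMEDIATE),
    ],
)
def test_glucose_categories(glu, med, expected):
    assert categorize_glucose(glu, med) == expected


def test_score_extremes_and_arithmetic():
    ideal = ExamRecord("s", 30, bmi=22, sbp=110, dbp=70, total_chol=150, glucose=90)
    assert clinical_cvh_score(ideal).score == 8
    poor = ExamRecord("s", 30, bmi=35, sbp=150, dbp=95, total_chol=240, glucose=140)
    assert clinical_cvh_score(poor).score == 0
    mixed = ExamRecord("s", 30, bmi=22, sbp=110, dbp=70, total_chol=200, glucose=140)
    assert clinical_cvh_score(mixed).score == 2 + 2 + 1 + 0


def test_missing_factor_marks_incomplete_not_error():
    rec = ExamRecord("s", 30, bmi=None, sbp=110, dbp=70, total_chol=150, glucose=90)
    scored = clinical_cvh_score(rec)
    assert not scored.complete and scored.score is None
    # pediatric exam without percentile is equally incomplete
    ped = ExamRecord("s", 12, bmi=20.0, sbp=100, dbp=60, bp_pct=50.0,
                     total_chol=150, glucose=90)
    assert clinical_cvh_score(ped).categories["bmi"] is None


def _category_grid(factor_fn, values, **kw):
    return [factor_fn(v, **kw) for v in values]


def test_boundaries_partition_domain():
    """Each factor's three categories partition a fine grid of its domain."""
    grid = np.arange(10.0, 60.0, 0.01)
    cats = [categorize_bmi(30, b) for b in grid]
    assert all(c in (POOR, INTERMEDIATE, IDEAL) for c in cats)
    assert sorted(set(cats)) == [POOR, INTERMEDIATE, IDEAL]
    # categories are monotone nonincreasing in BMI
    assert all(a >= b for a, b in zip(cats, cats[1:]))
    for fn, lo, hi in [
        (categorize_cholesterol, 100.0, 300.0),
        (categorize_glucose, 60.0, 200.0),
    ]:
        vals = np.arange(lo, hi, 0.01)
        cats = [fn(v) for v in vals]
        assert sorted(set(cats)) == [POOR, INTERMEDIATE, IDEAL]
        assert all(a >= b for a, b in zip(cats, cats[1:]))
    pcts = np.arange(0.0, 100.001, 0.05)
    cats = [categorize_bmi(12, None, p) for p in pcts]
    assert sorted(set(cats)) == [POOR, INTERMEDIATE, IDEAL]
    assert all(a >= b for a, b in zip(cats, cats[1:]))


@settings(max_examples=200, derandomize=True)
@given(
    bmi=st.floats(15, 45),
    sbp=st.floats(90, 180),
    dbp=st.floats(50, 110),
    chol=st.floats(120, 280),
    glu=st.floats(70, 160),
    med=st.booleans(),
)
def test_score_monotone_under_worsening(bmi, sbp, dbp, chol, glu, med):
    """Raising any single input (or medicating an ideal factor) never raises
    the score, and the score always equals the sum of the category points."""
    base = ExamRecord("s", 40, bmi=bmi, sbp=sbp, dbp=dbp, total_chol=chol,
                      glucose=glu, bp_med=med, lipid_med=med, glucose_med=med)
    s0 = clinical_cvh_score(base)
    assert s0.score == sum(s0.categories.values())
    for col, delta in [("bmi", 3.0), ("sbp", 10.0), ("dbp", 5.0),
                       ("total_chol", 20.0), ("glucose", 15.0)]:
        worse = replace(base, **{col: getattr(base, col) + delta})
        assert clinical_cvh_score(worse).score <= s0.score
    medicated = replace(base, bp_med=True, lipid_med=True, glucose_med=True)
    assert clinical_cvh_score(medicated).score <= s0.score


def test_completeness_filter_drops_subjects_without_complete_exam():
    df = pd.DataFrame(
        {
            "subject_id": ["a", "a", "b", "c"],
            "age": [30.0, 31.0, 30.0, 30.0],
            "cvh_score": [5.0, np.nan, 6.0, np.nan],
        }
    )
    kept, report = apply_completeness_filter(df)
    assert set(kept.subject_id) == {"a", "b"}
    assert report.n_subjects_in == 3 and report.n_subjects_retained == 2
    # all-complete input passes through unchanged
    full = df[df.cvh_score.notna()].reset_index(drop=True)
    kept2, rep2 = apply_completeness_filter(full)
    assert len(kept2) == len(full) and rep2.n_subjects_retained == 2


def test_empty_input_yields_empty_output():
    out, report = score_dataset(pd.DataFrame(columns=["subject_id", "age"]))
    assert len(out) == 0 and report.n_records_in == 0


def test_total_missingness_empties_dataset():
    config = replace(
        preset("single_break", seed=5, n_subjects=40),
        raw_metric_mode=True, missing_exam_p=0.999999,
    )
    raw = generate_raw_metrics(config)
    scored, report = score_dataset(raw)
    assert len(scored) == 0 and report.n_subjects_retained == 0


def test_retention_matches_closed_form_probability():
    """With per-visit missingness p and v visits/subject, P(retained) =
    1 - p^v; the empirical retained-subject fraction should match."""
    p, visits = 0.5, 4
    config = replace(
        preset("single_break", seed=9, n_subjects=2500),
        raw_metric_mode=True, missing_exam_p=p,
    )
    config = replace(
        config,
        cohorts=(replace(config.cohorts[0], n_subjects=2500,
                         baseline_age_range=(8.0, 20.0), n_visits=visits,
                         visit_interval=2.0),),
    )
    raw = generate_raw_metrics(config)
    scored, report = score_dataset(raw)
    frac = report.n_subjects_retained / report.n_subjects_in
    expected = 1.0 - p ** visits
    assert abs(frac - expected) < 0.02


def test_scored_dataset_categories_accompany_score():
    config = replace(preset("single_break", seed=4, n_subjects=50),
                     raw_metric_mode=True)
    raw = generate_raw_metrics(config)
    scored, _ = score_dataset(raw)
    assert {"bmi_cat", "bp_cat", "chol_cat", "glu_cat"} <= set(scored.columns)
    assert scored["cvh_score"].between(0, 8).all()
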