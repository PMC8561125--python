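"""Model comparison, interaction contrasts and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest

from cvh_windows.reporting import (
    baseline_table,
    compare_models,
    fit_piecewise_interaction,
    mean_difference_test,
    metric_means_at_ages,
    three_way_interaction_test,
    total_delta,
)
from cvh_windows.simulate import (
    CohortDesign,
    GeneratorConfig,
    TrueModel,
    generate_scores,
    preset,
)


# ---------------------------------------------------------------------------
# total change over a segment
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "slope,width,expected",
    [(-0.09, 20.0, -1.8), (-0.06, 20.0, -1.2), (0.0, 9.0, 0.0)],
)
def test_total_delta(slope, width, expected):
    assert total_delta(slope, width) == pytest.approx(expected)


def test_total_delta_rejects_nonpositive_width():
    with pytest.raises(ValueError):
        total_delta(-0.1, 0.0)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


def test_information_criteria_identities(single_break_data):
    cm = compare_models(single_break_data)
    t = cm.table.dropna(subset=["loglik"])
    assert np.allclose(t.aic, -2 * t.loglik + 2 * t.n_params)
    assert np.allclose(
        t.bic, -2 * t.loglik + np.log(len(single_break_data)) * t.n_params
    )
    # nested pairs: larger model never has lower loglik
    tt = t.set_index("model")
    assert tt.loc["cubic", "loglik"] >= tt.loc["quadratic", "loglik"] - 1e-6
    assert tt.loc["quadratic", "loglik"] >= tt.loc["linear", "loglik"] - 1e-6
    davies = cm.lrt[cm.lrt.alternative.str.startswith("segmented")]
    assert davies.note.str.len().gt(0).all()


def test_single_break_truth_prefers_segmented_one(single_break_data):
    cm = compare_models(single_break_data)
    assert cm.best_aic in ("segmented-1", "segmented-2")
    tt = cm.table.set_index("model")
    assert tt.loc["segmented-1", "aic"] < tt.loc["linear", "aic"]


def test_linear_null_keeps_linear_competitive():
    """Under a no-break truth, the linear model stays within 2 AIC of the
    best candidate in at least half of the replicates."""
    hits = 0
    n_seeds = 8
    for seed in range(n_seeds):
        df = generate_scores(preset("linear_null", seed=100 + seed, n_subjects=150))
        cm = compare_models(df)
        tt = cm.table.set_index("model")
        if tt.loc["linear", "aic"] - tt["aic"].min() <= 2.0:
            hits += 1
    assert hits >= n_seeds / 2


def test_quadratic_truth_detected_by_lrt():
    """A strongly curved truth is detected by the quadratic-vs-linear LRT in
    nearly every replicate."""
    rng_detect = 0
    n_seeds = 10
    for seed in range(n_seeds):
        rng = np.random.default_rng(200 + seed)
        n_subj, visits = 300, 5
        base = rng.uniform(8, 35, n_subj)
        rows = []
        for i in range(n_subj):
            b0 = rng.normal(0, 0.8)
            for k in range(visits):
                a = base[i] + 5.0 * k
                if a > 55.99:
                    continue
                y = 7.0 - 0.002 * (a - 8.0) ** 2 + b0 + rng.normal(0, 0.5)
                rows.append((f"s{i}", a, y))
        df = pd.DataFrame(rows, columns=["subject_id", "age", "cvh_score"])
        cm = compare_models(df)
        row = cm.lrt[(cm.lrt.null == "linear") & (cm.lrt.alternative == "quadratic")]
        if float(row.p_value.iloc[0]) < 0.05:
            rng_detect += 1
    assert rng_detect >= 0.9 * n_seeds


# ---------------------------------------------------------------------------
# piecewise interaction model
# ---------------------------------------------------------------------------


def _two_group_noiseless(slopes_f, slopes_m, psi=25.0, n=60):
    rows = []
    for sex, slopes in (("female", slopes_f), ("male", slopes_m)):
        for i in range(n):
            base = 8.0 + (i % 12) * 2.0
            for k in range(5):
                a = base + 5.0 * k
                if a > 55.9:
                    continue
                y = 7.0 + slopes[0] * min(a - 8.0, psi - 8.0)
                y += slopes[1] * max(a - psi, 0.0)
                rows.append((f"{sex}{i}", sex, a, y))
    return pd.DataFrame(rows, columns=["subject_id", "sex", "age", "cvh_score"])


def test_noiseless_group_contrasts_recovered_exactly():
    df = _two_group_noiseless((0.0, -0.06), (-0.01, -0.09))
    pw = fit_piecewise_interaction(df, knots=(25.0,), group="sex")
    s = pw.slopes.set_index(["level", "segment"]).slope
    assert s["female", 0] == pytest.approx(0.0, abs=1e-8)
    assert s["female", 1] == pytest.approx(-0.06, abs=1e-8)
    assert s["male", 0] == pytest.approx(-0.01, abs=1e-8)
    assert s["male", 1] == pytest.approx(-0.09, abs=1e-8)
    d = pw.differences.set_index("segment").slope_diff
    assert d[0] == pytest.approx(-0.01, abs=1e-8)
    assert d[1] == pytest.approx(-0.03, abs=1e-8)


def test_difference_rows_equal_slope_subtraction(paper_preset_data):
    pw = fit_piecewise_interaction(
        paper_preset_data, knots=(17.0, 37.0), group="sex",
        adjust=("race", "cohort"),
    )
    s = pw.slopes.set_index(["level", "segment"]).slope
    d = pw.differences.set_index("segment").slope_diff
    for seg in range(3):
        assert d[seg] == pytest.approx(
            s["male", seg] - s["female", seg], rel=1e-10
        )
    # total delta equals slope x width on unrounded values
    row = pw.slopes.iloc[4]
    assert row.total_delta == pytest.approx(
        row.slope * (row.window_hi - row.window_lo), rel=1e-12
    )


def test_null_contrasts_are_mostly_insignificant():
    """When both sexes share the same mean structure, slope-difference
    contrasts stay within 2 SE in the vast majority of replicates."""
    inside = total = 0
    for seed in range(12):
        df = generate_scores(preset("single_break", seed=300 + seed, n_subjects=200))
        rng = np.random.default_rng(seed)
        ids = df.subject_id.unique()
        sex = dict(zip(ids, rng.choice(["female", "male"], size=len(ids))))
        df = df.assign(sex=df.subject_id.map(sex))
        pw = fit_piecewise_interaction(df, knots=(25.0,), group="sex")
        for _, row in pw.differences.iterrows():
            total += 1
            inside += abs(row.slope_diff) < 2.0 * row.se
    assert inside / total >= 0.9


def test_absent_group_level_marked_inestimable():
    df = _two_group_noiseless((0.0, -0.06), (-0.01, -0.09))
    # remove every male observation beyond the knot
    df = df[~((df.sex == "male") & (df.age > 25.0))].reset_index(drop=True)
    pw = fit_piecewise_interaction(df, knots=(25.0,), group="sex")
    s = pw.slopes.set_index(["level", "segment"])
    assert not s.loc[("male", 1), "estimable"]
    assert np.isnan(s.loc[("male", 1), "slope"])


def test_three_way_interaction_screen(paper_preset_data):
    out = three_way_interaction_test(paper_preset_data)
    assert out["df"] == len(out["terms"]) > 0
    assert 0.0 <= out["p_value"] <= 1.0


# ---------------------------------------------------------------------------
# Welch comparisons
# ---------------------------------------------------------------------------


def test_welch_difference_direction_and_identity():
    f = [163.0, 164.0, 162.0]
    m = [151.0, 150.0, 152.0]
    r = mean_difference_test(f, m)
    assert r["difference"] == pytest.approx(np.mean(m) - np.mean(f))
    same = mean_difference_test(f, f)
    assert same["difference"] == 0.0 and same["p_value"] == pytest.approx(1.0)


def test_welch_constant_equal_samples_p_one():
    r = mean_difference_test([5.0, 5.0, 5.0], [5.0, 5.0])
    assert r["p_value"] == 1.0 and r["difference"] == 0.0


def test_welch_reduces_to_student_under_equal_variance():
    from scipy import stats

    rng = np.random.default_rng(8)
    a = rng.normal(0, 1, 40)
    b = rng.normal(0.5, 1, 40)
    # equal sample sizes and equal sample variances => Welch == Student
    b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + 0.5
    r = mean_difference_test(a, b)
    t, p = stats.ttest_ind(b, a, equal_var=True)
    assert r["p_value"] == pytest.approx(p, rel=1e-9)
    assert r["df"] == pytest.approx(len(a) + len(b) - 2, rel=1e-9)


def test_welch_p_matches_permutation_oracle():
    """At moderate sample sizes the Welch p-value approximates the exact
    (permutation) reference distribution of the mean difference."""
    rng = np.random.default_rng(5)
    a = rng.normal(0.0, 1.0, 110)
    b = rng.normal(0.30, 1.4, 95)
    r = mean_difference_test(a, b)

    pooled = np.concatenate([a, b])
    n_a = len(a)
    count = 0
    n_perm = 100_000
    obs = abs(np.mean(b) - np.mean(a))
    for chunk in range(100):
        idx = np.argsort(rng.random((n_perm // 100, len(pooled))), axis=1)
        perm = pooled[idx]
        da = perm[:, :n_a].mean(axis=1)
        db = perm[:, n_a:].mean(axis=1)
        count += int(np.sum(np.abs(db - da) >= obs - 1e-12))
    p_perm = count / n_perm
    assert r["p_value"] == pytest.approx(p_perm, abs=0.005)


# ---------------------------------------------------------------------------
# descriptive tables
# ---------------------------------------------------------------------------


def test_metric_means_at_ages_recovers_anchors():
    from dataclasses import replace

    from cvh_windows.simulate import generate_raw_metrics

    config = replace(
        preset("paper2021", seed=6), raw_metric_mode=True, missing_exam_p=0.0,
        raw_noise_scale=0.15,  # low noise isolates the anchored means
    )
    raw = generate_raw_metrics(config)
    table = metric_means_at_ages(raw, ages=(17.0,), metrics=("total_chol", "sbp"))
    chol = table[table.metric == "total_chol"].iloc[0]
    assert chol.mean_female == pytest.approx(163.3, abs=1.5)
    assert chol.mean_male == pytest.approx(151.1, abs=1.5)
    assert chol.difference == pytest.approx(chol.mean_male - chol.mean_female)
    sbp = table[table.metric == "sbp"].iloc[0]
    assert sbp.difference == pytest.approx(6.3, abs=1.0)


def test_baseline_table_counts_and_means(paper_preset_data):
    table = baseline_table(paper_preset_data)
    first = (
        paper_preset_data.sort_values(["subject_id", "age"])
        .groupby("subject_id")
        .head(1)
    )
    # female share within binomial error of the design's ~52%
    n_f = table[(table.group == "female") & (table.characteristic == "n_subjects")]
    share = float(n_f.value.iloc[0]) / first.subject_id.nunique()
    assert share == pytest.approx(0.52, abs=0.04)
    # independent streaming mean cross-check
    mean_age_f = first[first.sex == "female"].age.mean()
    got = table[(table.group == "female") & (table.characteristic == "age")]
    assert float(got.value.iloc[0]) == pytest.approx(mean_age_f, rel=1e-12)


def test_baseline_table_single_subject_has_no_sd():
    df = pd.DataFrame(
        {
            "subject_id": ["a"],
            "sex": ["female"],
            "age": [12.0],
            "cvh_score": [7.0],
        }
    )
    table = baseline_table(df)
    age_row = table[table.characteristic == "age"]
    assert np.isnan(age_row.sd.iloc[0])
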