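"""Change-point estimator: update rule, fixed points, oracle equivalence,
likelihood monotonicity and derived slopes."""

import numpy as np
import pandas as pd
import pytest

from cvh_windows.lmm import fit_lmm
from cvh_windows.segmented import (
    DeltaZeroError,
    SegmentedModelSpec,
    build_design,
    fit_lmm_fixed_knots,
    fit_segmented,
    muggeo_step,
    profile_grid_oracle,
    psi_update,
    segment_slopes,
)


def test_update_rule_arithmetic():
    assert psi_update([15.0], [-0.12], [-0.06]) == pytest.approx([17.0])
    assert psi_update([20.0, 40.0], [0.1, -0.2], [0.05, 0.1]) == pytest.approx(
        [22.0, 38.0]
    )


def test_noiseless_fixed_point(noiseless_break_data):
    """With psi at the truth on noise-free data, the gap coefficient is ~0 and
    the update leaves psi unchanged."""
    psi_next, fit = muggeo_step(noiseless_break_data, [25.0])
    assert fit.coef("V1") == pytest.approx(0.0, abs=1e-6)
    assert psi_next[0] == pytest.approx(25.0, abs=1e-4)


def test_single_step_matches_hand_assembled_design(single_break_data):
    """One linearization step equals a fit on an explicitly constructed
    U/V design with the update computed by hand."""
    df = single_break_data
    psi0 = 20.0
    psi_next, fit = muggeo_step(df, [psi0])

    age = df.age.to_numpy()
    X = np.column_stack(
        [
            np.ones(len(df)),
            age - 8.0,
            np.clip(age - psi0, 0.0, None),
            -(age > psi0).astype(float),
        ]
    )
    hand = fit_lmm(
        df.cvh_score.to_numpy(), X, age, df.subject_id.to_numpy(),
        exog_names=["intercept", "age", "U1", "V1"],
    )
    expected = psi0 + hand.coef("V1") / hand.coef("U1")
    assert fit.loglik == pytest.approx(hand.loglik, abs=1e-5)
    assert psi_next[0] == pytest.approx(expected, abs=1e-4)


def test_flat_kink_is_flagged():
    rng = np.random.default_rng(4)
    n_subj, visits = 60, 5
    age = np.tile(np.linspace(10, 50, visits), n_subj)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n_subj), visits),
            "age": age,
            # purely linear mean: no kink anywhere
            "cvh_score": 7.0 - 0.05 * (age - 8.0)
            + np.repeat(rng.normal(0, 0.1, n_subj), visits),
        }
    )
    with pytest.raises(DeltaZeroError):
        muggeo_step(df, [30.0])


def test_noiseless_identifiability(noiseless_break_data):
    fit = fit_segmented(noiseless_break_data, SegmentedModelSpec(n_changepoints=1))
    assert fit.converged
    assert fit.psi[0] == pytest.approx(25.0, abs=1e-3)
    slopes = fit.segment_slopes
    assert slopes.slope.to_numpy() == pytest.approx([0.0, -0.08], abs=1e-6)


def test_loglik_monotone_over_accepted_iterations(single_break_data):
    fit = fit_segmented(single_break_data, SegmentedModelSpec(n_changepoints=1))
    lls = [ll for _, ll in fit.trace]
    assert all(b >= a - 1e-7 for a, b in zip(lls, lls[1:]))
    assert fit.converged


def test_more_breaks_never_lower_loglik(single_break_data):
    f1 = fit_segmented(single_break_data, SegmentedModelSpec(n_changepoints=1))
    f2 = fit_segmented(
        single_break_data, SegmentedModelSpec(n_changepoints=2)
    )
    assert f2.loglik >= f1.loglik - 1e-6
    f0 = fit_segmented(single_break_data, SegmentedModelSpec(n_changepoints=0))
    assert f1.loglik >= f0.loglik - 1e-6


def test_zero_changepoints_delegates_to_plain_lmm(single_break_data):
    fit = fit_segmented(single_break_data, SegmentedModelSpec(n_changepoints=0))
    plain = fit_lmm_fixed_knots(single_break_data, (), ())
    assert fit.loglik == pytest.approx(plain.loglik, abs=1e-6)
    assert len(fit.psi) == 0


def test_grid_oracle_noiseless(noiseless_break_data):
    spec = SegmentedModelSpec(n_changepoints=1)
    argmax, profile = profile_grid_oracle(noiseless_break_data, spec, grid_step=0.5)
    assert argmax[0] == pytest.approx(25.0, abs=0.26)
    best = profile.loglik.max()
    assert (profile.loglik <= best).all()


def test_iterative_estimator_matches_grid_oracle(small_break_data):
    """The iterative fit lands within one grid cell of the brute-force
    profile-likelihood argmax."""
    spec = SegmentedModelSpec(n_changepoints=1)
    fit = fit_segmented(small_break_data, spec)
    argmax, _ = profile_grid_oracle(small_break_data, spec, grid_step=0.5)
    assert abs(fit.psi[0] - argmax[0]) <= 0.5


def test_telescoping_segment_slopes(paper_preset_data):
    fit = fit_segmented(
        paper_preset_data,
        SegmentedModelSpec(n_changepoints=2,
                           fixed_covariates=("sex", "race", "cohort")),
    )
    slopes = fit.segment_slopes.slope.to_numpy()
    beta1 = fit.final_fit.coef("age")
    d1, d2 = fit.final_fit.coef("U1"), fit.final_fit.coef("U2")
    assert slopes == pytest.approx([beta1, beta1 + d1, beta1 + d1 + d2], rel=1e-12)
    # psi ordered with the minimum gap and inside the observed range
    assert fit.psi[1] - fit.psi[0] >= fit.spec.min_gap
    age = paper_preset_data.age
    assert age.min() < fit.psi[0] < fit.psi[1] < age.max()


def test_delta_method_se_reduces_to_gamma_se_over_delta(single_break_data):
    fit = fit_segmented(single_break_data, SegmentedModelSpec(n_changepoints=1))
    _, work = muggeo_step(single_break_data, fit.psi)
    approx = work.se("V1") / abs(work.coef("U1"))
    assert fit.psi_se[0] == pytest.approx(approx, rel=0.05)


def test_slope_contrast_se_matches_subject_bootstrap(small_break_data):
    """Delta-method SE of the post-break slope agrees with a subject-level
    bootstrap within 25%."""
    df = small_break_data
    fit = fit_lmm_fixed_knots(df, (25.0,), ())
    slopes = segment_slopes(fit, psi=[25.0])
    se_analytic = slopes.loc[1, "se"]

    rng = np.random.default_rng(12)
    ids = df.subject_id.unique()
    boot = []
    theta = fit.theta
    for _ in range(200):
        sample = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for k, sid in enumerate(sample):
            part = df[df.subject_id == sid].copy()
            part["subject_id"] = f"b{k}"
            parts.append(part)
        bdf = pd.concat(parts, ignore_index=True)
        bfit = fit_lmm_fixed_knots(bdf, (25.0,), (), start_theta=theta)
        boot.append(bfit.coef("age") + bfit.coef("U1"))
    se_boot = np.std(boot, ddof=1)
    assert abs(se_analytic - se_boot) / se_boot < 0.25


def test_psi_init_validation(single_break_data):
    with pytest.raises(ValueError):
        fit_segmented(
            single_break_data,
            SegmentedModelSpec(n_changepoints=2, psi_init=(20.0,)),
        )
    with pytest.raises(ValueError):
        SegmentedModelSpec(n_changepoints=3)
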