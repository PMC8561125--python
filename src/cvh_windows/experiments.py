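"""Monte-Carlo experiments over the synthetic presets.

These drive the parameter-recovery and calibration studies: each replicate
draws a fresh cohort from a preset, runs the full change-point analysis, and
the replicate-level estimates are summarized.  Shared by the analysis
scripts, the acceptance checks and the test suite so that every consumer
exercises identical code paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scoring import apply_completeness_filter
from .segmented import SegmentedModelSpec, fit_segmented
from .simulate import generate_scores, preset

__all__ = ["recovery_experiment", "ci_coverage_experiment"]

_COVARIATES = ("sex", "race", "cohort")


def recovery_experiment(
    n_reps: int = 20,
    base_seed: int = 1,
    preset_name: str = "paper2021",
    n_subjects: int | None = None,
    fit_one_break: bool = True,
) -> pd.DataFrame:
    """Replicate-level change-point recovery on a preset.

    For seeds ``base_seed .. base_seed + n_reps - 1``: generate a cohort,
    apply the completeness filter, fit the 2-change-point segmented LMM
    (adjusted for sex, race and cohort), and record the estimated change
    points, the middle-segment slope, and — when ``fit_one_break`` — the
    AIC/BIC verdict against the 1-change-point model.
    """
    rows = []
    for rep in range(n_reps):
        seed = base_seed + rep
        data = generate_scores(preset(preset_name, seed=seed, n_subjects=n_subjects))
        data, _ = apply_completeness_filter(data)
        covs = tuple(c for c in _COVARIATES if data[c].nunique() > 1)
        fit2 = fit_segmented(
            data, SegmentedModelSpec(n_changepoints=2, fixed_covariates=covs)
        )
        slopes = fit2.segment_slopes
        row = {
            "seed": seed,
            "n_subjects": data["subject_id"].nunique(),
            "n_obs": len(data),
            "psi1": fit2.psi[0],
            "psi2": fit2.psi[1],
            "psi1_se": fit2.psi_se[0],
            "psi2_se": fit2.psi_se[1],
            "slope1": slopes.loc[0, "slope"],
            "slope2": slopes.loc[1, "slope"],
            "slope3": slopes.loc[2, "slope"],
            "loglik2": fit2.loglik,
            "aic2": fit2.aic,
            "bic2": fit2.bic,
            "converged": fit2.converged,
        }
        if fit_one_break:
            # start the 1-break search at the sharp break the 2-break fit found
            fit1 = fit_segmented(
                data,
                SegmentedModelSpec(
                    n_changepoints=1, fixed_covariates=covs,
                    psi_init=(float(fit2.psi[0]),),
                ),
            )
            row.update(
                loglik1=fit1.loglik, aic1=fit1.aic, bic1=fit1.bic,
                seg2_wins_aic=bool(fit2.aic < fit1.aic),
                seg2_wins_bic=bool(fit2.bic < fit1.bic),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def ci_coverage_experiment(
    n_sims: int = 200,
    base_seed: int = 0,
    preset_name: str = "single_break",
    true_psi: float = 25.0,
) -> pd.DataFrame:
    """Delta-method CI calibration for a single change point.

    Simulates from the single-break preset, fits the 1-change-point model and
    records whether the 95% CI covers the generating change point.
    """
    rows = []
    for seed in range(base_seed, base_seed + n_sims):
        data = generate_scores(preset(preset_name, seed=seed))
        fit = fit_segmented(data, SegmentedModelSpec(n_changepoints=1))
        lo, hi = fit.psi_ci[0]
        rows.append(
            {
                "seed": seed,
                "psi": fit.psi[0],
                "se": fit.psi_se[0],
                "ci_lo": lo,
                "ci_hi": hi,
                "covered": bool(lo <= true_psi <= hi),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
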