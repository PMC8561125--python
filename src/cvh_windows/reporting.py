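"""Model selection, fixed-knot interaction contrasts and descriptive tables.

Three pieces of downstream machinery over the mixed-model fits:

* ``compare_models`` — linear, quadratic and cubic mixed models against
  segmented models with 1 and 2 change points, all by ML on identical data,
  ranked by AIC and BIC with likelihood-ratio tests for nested pairs.  The
  test of "no break" vs "break" is flagged: the change point is unidentified
  under the null (Davies problem) so the chi-square reference is approximate
  and AIC/BIC carry the default verdict.
* ``fit_piecewise_interaction`` — the fixed-knot piecewise-linear model with
  the age spline fully interacted with a grouping covariate (sex), yielding
  per-group segment slopes, between-group slope differences with Wald tests,
  and the cumulative change over each segment (slope x width).
* descriptive helpers — Welch two-sample comparisons of metric means at
  chosen ages and a baseline (first-exam) characteristics table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import EstimationError, LMMFit, fit_lmm
from .segmented import (
    AGE_CENTER,
    SegmentedModelSpec,
    _dummies,
    fit_segmented,
)

__all__ = [
    "ModelComparisonTable",
    "PiecewiseFit",
    "compare_models",
    "fit_piecewise_interaction",
    "total_delta",
    "mean_difference_test",
    "baseline_table",
    "three_way_interaction_test",
]

_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


@dataclass
class ModelComparisonTable:
    """Per-model fit statistics plus LRTs for nested pairs."""

    table: pd.DataFrame
    lrt: pd.DataFrame
    best_aic: str = field(init=False)
    best_bic: str = field(init=False)

    def __post_init__(self) -> None:
        ok = self.table.dropna(subset=["aic"])
        self.best_aic = str(ok.loc[ok["aic"].idxmin(), "model"])
        self.best_bic = str(ok.loc[ok["bic"].idxmin(), "model"])


def _fit_polynomial(
    data: pd.DataFrame, degree: int, covariates, value_col: str
) -> LMMFit:
    """ML LMM with a polynomial fixed effect of age (degree 1-3)."""
    age = data["age"].to_numpy(float)
    a = age - AGE_CENTER
    cols = [np.ones_like(a)] + [a ** d for d in range(1, degree + 1)]
    names = ["intercept", "age"] + [f"age^{d}" for d in range(2, degree + 1)]
    ccols, cnames = _dummies(data, tuple(covariates))
    X = np.column_stack(cols + ccols)
    return fit_lmm(
        y=data[value_col].to_numpy(float),
        X=X,
        age=age,
        groups=data["subject_id"].to_numpy(),
        exog_names=names + cnames,
        re_center=AGE_CENTER,
    )


def compare_models(
    data: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    value_col: str = "cvh_score",
    min_gap: float = 3.0,
) -> ModelComparisonTable:
    """Fit the five candidate mean structures by ML on identical data.

    Candidates: linear, quadratic, cubic, segmented with 1 and 2 change
    points (all with random intercept and slope).  A failing member is
    reported as a failed row and the comparison proceeds.  LRTs cover the
    polynomial nestings; the segmented-1 vs segmented-2 LRT conditions on the
    estimated change points (flagged approximate), and polynomial-vs-
    segmented tests are flagged for the Davies problem.
    """
    rows, fits = [], {}
    for name, degree in (("linear", 1), ("quadratic", 2), ("cubic", 3)):
        try:
            fit = _fit_polynomial(data, degree, covariates, value_col)
            fits[name] = fit
            rows.append((name, fit.loglik, fit.df_model, fit.aic, fit.bic, ""))
        except EstimationError as exc:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, f"failed: {exc}"))
    for name, n_cp in (("segmented-1", 1), ("segmented-2", 2)):
        try:
            fit = fit_segmented(
                data,
                SegmentedModelSpec(
                    n_changepoints=n_cp,
                    fixed_covariates=tuple(covariates),
                    value_col=value_col,
                    min_gap=min_gap,
                ),
            )
            fits[name] = fit
            k = fit.final_fit.df_model + n_cp
            rows.append((name, fit.loglik, k, fit.aic, fit.bic, ""))
        except EstimationError as exc:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, f"failed: {exc}"))
    table = pd.DataFrame(
        rows, columns=["model", "loglik", "n_params", "aic", "bic", "note"]
    )

    nested = [
        ("linear", "quadratic", ""),
        ("quadratic", "cubic", ""),
        ("linear", "cubic", ""),
        ("linear", "segmented-1", "approximate: psi unidentified under H0 (Davies)"),
        ("linear", "segmented-2", "approximate: psi unidentified under H0 (Davies)"),
        ("segmented-1", "segmented-2", "approximate: conditions on estimated psi"),
    ]
    lrt_rows = []
    tt = table.set_index("model")
    for small, big, note in nested:
        if small not in fits or big not in fits:
            continue
        ll0, ll1 = tt.loc[small, "loglik"], tt.loc[big, "loglik"]
        df = tt.loc[big, "n_params"] - tt.loc[small, "n_params"]
        # numerical slack: the larger model nests the smaller
        stat = max(2.0 * (ll1 - ll0), 0.0)
        p = float(stats.chi2.sf(stat, df)) if df > 0 else np.nan
        lrt_rows.append((small, big, stat, int(df), p, note))
    lrt = pd.DataFrame(
        lrt_rows, columns=["null", "alternative", "lr_stat", "df", "p_value", "note"]
    )
    return ModelComparisonTable(table=table, lrt=lrt)


# ---------------------------------------------------------------------------
# fixed-knot piecewise interaction model
# ---------------------------------------------------------------------------


def total_delta(slope: float, width: float) -> float:
    """Cumulative change over a segment: slope (points/year) x width (years)."""
    if width <= 0:
        raise ValueError("segment width must be positive")
    return slope * width


@dataclass
class PiecewiseFit:
    """Fixed-knot interaction model results.

    ``slopes`` has one row per (group level, segment) with the segment slope,
    CI and total change over the segment; ``differences`` contrasts each
    non-reference level against the reference level per segment (difference =
    level minus reference, e.g. male - female when female is the reference).
    """

    knots: tuple[float, ...]
    group: str
    group_levels: tuple[str, ...]
    fit: LMMFit
    slopes: pd.DataFrame
    differences: pd.DataFrame
    intercepts: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "knots": list(self.knots),
            "group": self.group,
            "group_levels": list(self.group_levels),
            "loglik": self.fit.loglik,
            "aic": self.fit.aic,
            "bic": self.fit.bic,
            "slopes": self.slopes.to_dict(orient="records"),
            "differences": self.differences.to_dict(orient="records"),
            "intercepts": self.intercepts.to_dict(orient="records"),
        }


def _segment_windows(knots, age_lo, age_hi):
    bounds = [age_lo, *knots, age_hi]
    return [(bounds[k], bounds[k + 1]) for k in range(len(knots) + 1)]


def fit_piecewise_interaction(
    data: pd.DataFrame,
    knots: tuple[float, ...] = (17.0, 37.0),
    group: str = "sex",
    adjust: tuple[str, ...] = (),
    value_col: str = "cvh_score",
    windows: list[tuple[float, float]] | None = None,
) -> PiecewiseFit:
    """Piecewise-linear LMM with the age spline fully interacted with a group.

    The spline basis (age and one ``(age-k)_+`` term per knot, knots fixed in
    advance) is crossed with reference-coded dummies of ``group``; adjustment
    covariates enter as main effects; the random intercept+slope structure is
    retained.  Per-group segment slopes and their between-group differences
    are linear contrasts with Wald (normal) inference.  Total change over a
    segment multiplies the *unrounded* slope by the window width (windows
    default to [age 8, k1], [k1, k2], [k2, 55.9]); rounding happens only in
    presentation.
    """
    levels = tuple(sorted(data[group].astype(str).unique()))
    if len(levels) < 2:
        raise EstimationError(f"group {group!r} needs >= 2 levels")
    ref = levels[0]
    age = data["age"].to_numpy(float)
    base_cols = [np.ones_like(age), age - AGE_CENTER]
    base_names = ["intercept", "age"]
    for k, knot in enumerate(knots, start=1):
        if not age.min() < knot < age.max():
            raise EstimationError(f"knot {knot} outside the observed age range")
        base_cols.append(np.clip(age - knot, 0.0, None))
        base_names.append(f"U{k}")
    cols, names = list(base_cols), list(base_names)
    gvals = data[group].astype(str).to_numpy()
    for level in levels[1:]:
        ind = (gvals == level).astype(float)
        for col, nm in zip(base_cols, base_names):
            cols.append(col * ind)
            names.append(f"{nm}:{group}[{level}]")
    ccols, cnames = _dummies(data, tuple(adjust))
    X = np.column_stack(cols + ccols)
    all_names = names + cnames
    # a group level absent from a segment leaves its interaction column
    # all-zero; drop such columns and mark the affected contrasts inestimable
    nonzero = np.abs(X).sum(axis=0) > 0
    X = X[:, nonzero]
    all_names = [n for n, keep in zip(all_names, nonzero) if keep]
    fit = fit_lmm(
        y=data[value_col].to_numpy(float),
        X=X,
        age=age,
        groups=data["subject_id"].to_numpy(),
        exog_names=all_names,
        re_center=AGE_CENTER,
    )

    if windows is None:
        windows = _segment_windows(knots, AGE_CENTER, 55.9)
    nm = fit.exog_names

    def contrast(level: str, segment: int, base: str = "age") -> np.ndarray | None:
        c = np.zeros(len(nm))
        terms = [base] + [f"U{j+1}" for j in range(segment)] if base == "age" else [base]
        for t in terms:
            if t not in nm:
                return None
            c[nm.index(t)] = 1.0
            if level != ref:
                t_int = f"{t}:{group}[{level}]"
                if t_int not in nm:
                    return None
                c[nm.index(t_int)] = 1.0
        return c

    def wald(c: np.ndarray | None):
        if c is None:
            return np.nan, np.nan, np.nan
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.cov_beta @ c))
        z = est / se if se > 0 else np.nan
        p = float(2.0 * stats.norm.sf(abs(z))) if se > 0 else np.nan
        return est, se, p

    slope_rows, diff_rows, int_rows = [], [], []
    n_seg = len(knots) + 1
    # group presence per segment (a level absent from a segment's age range
    # leaves its slope there inestimable in any meaningful sense)
    for level in levels:
        sub_age = age[gvals == level]
        c0 = contrast(level, 0, base="intercept")
        est, se, p = wald(c0)
        int_rows.append(
            {"level": level, "mean_at_age8": est, "se": se,
             "ci_lo": est - _Z95 * se, "ci_hi": est + _Z95 * se, "p_value": p}
        )
        for s in range(n_seg):
            w_lo, w_hi = windows[s]
            estimable = bool(np.any((sub_age >= w_lo) & (sub_age <= w_hi)))
            c = contrast(level, s)
            estimable = estimable and c is not None
            est, se, p = wald(c)
            slope_rows.append(
                {
                    "level": level, "segment": s,
                    "window_lo": w_lo, "window_hi": w_hi,
                    "slope": est if estimable else np.nan,
                    "se": se if estimable else np.nan,
                    "ci_lo": est - _Z95 * se if estimable else np.nan,
                    "ci_hi": est + _Z95 * se if estimable else np.nan,
                    "p_value": p if estimable else np.nan,
                    "total_delta": total_delta(est, w_hi - w_lo) if estimable else np.nan,
                    "estimable": estimable,
                }
            )
    for level in levels[1:]:
        for s in range(n_seg):
            w_lo, w_hi = windows[s]
            ca, cb = contrast(level, s), contrast(ref, s)
            c = ca - cb if ca is not None and cb is not None else None
            est, se, p = wald(c)
            diff_rows.append(
                {
                    "contrast": f"{level} - {ref}", "segment": s,
                    "window_lo": w_lo, "window_hi": w_hi,
                    "slope_diff": est, "se": se,
                    "ci_lo": est - _Z95 * se, "ci_hi": est + _Z95 * se,
                    "p_value": p,
                    "total_delta": total_delta(est, w_hi - w_lo),
                }
            )
    return PiecewiseFit(
        knots=tuple(knots), group=group, group_levels=levels, fit=fit,
        slopes=pd.DataFrame(slope_rows),
        differences=pd.DataFrame(diff_rows),
        intercepts=pd.DataFrame(int_rows),
    )


def three_way_interaction_test(
    data: pd.DataFrame,
    knots: tuple[float, ...] = (17.0, 37.0),
    factors: tuple[str, str] = ("race", "sex"),
    adjust: tuple[str, ...] = ("cohort",),
    value_col: str = "cvh_score",
) -> dict:
    """Wald screen for an age x factor1 x factor2 interaction.

    Fits the fixed-knot spline fully crossed with both factors and their
    product, then tests the block of three-way terms (spline x f1 x f2).  A
    small p-value motivates stratifying the change-point analysis.
    """
    f1, f2 = factors
    age = data["age"].to_numpy(float)
    spline_cols = [age - AGE_CENTER] + [
        np.clip(age - k, 0.0, None) for k in knots
    ]
    spline_names = ["age"] + [f"U{k+1}" for k in range(len(knots))]
    lev1 = sorted(data[f1].astype(str).unique())[1:]
    lev2 = sorted(data[f2].astype(str).unique())[1:]
    v1 = data[f1].astype(str).to_numpy()
    v2 = data[f2].astype(str).to_numpy()
    cols = [np.ones_like(age)]
    names = ["intercept"]
    groups_of_cols: dict[str, list[int]] = {"threeway": []}
    def add(col, name, block=None):
        if block is not None:
            groups_of_cols[block].append(len(names))
        cols.append(col)
        names.append(name)
    for c, n in zip(spline_cols, spline_names):
        add(c, n)
    for a in lev1:
        ia = (v1 == a).astype(float)
        add(ia, f"{f1}[{a}]")
        for c, n in zip(spline_cols, spline_names):
            add(c * ia, f"{n}:{f1}[{a}]")
    for b in lev2:
        ib = (v2 == b).astype(float)
        add(ib, f"{f2}[{b}]")
        for c, n in zip(spline_cols, spline_names):
            add(c * ib, f"{n}:{f2}[{b}]")
    for a in lev1:
        for b in lev2:
            iab = ((v1 == a) & (v2 == b)).astype(float)
            add(iab, f"{f1}[{a}]:{f2}[{b}]")
            for c, n in zip(spline_cols, spline_names):
                add(c * iab, f"{n}:{f1}[{a}]:{f2}[{b}]", block="threeway")
    ccols, cnames = _dummies(data, tuple(adjust))
    X = np.column_stack(cols + ccols)
    fit = fit_lmm(
        y=data[value_col].to_numpy(float), X=X, age=age,
        groups=data["subject_id"].to_numpy(),
        exog_names=names + cnames, re_center=AGE_CENTER,
    )
    idx = groups_of_cols["threeway"]
    b = fit.beta[idx]
    V = fit.cov_beta[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return {
        "wald_stat": stat,
        "df": df,
        "p_value": float(stats.chi2.sf(stat, df)),
        "terms": [fit.exog_names[i] for i in idx],
    }


# ---------------------------------------------------------------------------
# descriptive comparisons
# ---------------------------------------------------------------------------


def mean_difference_test(values_a, values_b) -> dict:
    """Welch two-sample t-test; difference is mean(b) - mean(a).

    With the pooled-cohort convention group *a* is female and *b* male, so
    the difference column reads mu_male - mu_female.  Zero variance in both
    groups with equal means yields p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    ma, mb = float(a.mean()), float(b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    diff = mb - ma
    se2 = va / len(a) + vb / len(b)
    if se2 == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
        return {
            "mean_a": ma, "mean_b": mb, "sd_a": 0.0, "sd_b": 0.0,
            "difference": diff, "ci_lo": diff, "ci_hi": diff,
            "p_value": p, "df": float(len(a) + len(b) - 2),
        }
    se = float(np.sqrt(se2))
    # Welch-Satterthwaite degrees of freedom
    df = se2 ** 2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return {
        "mean_a": ma, "mean_b": mb,
        "sd_a": float(np.sqrt(va)), "sd_b": float(np.sqrt(vb)),
        "difference": diff,
        "ci_lo": diff - tcrit * se, "ci_hi": diff + tcrit * se,
        "p_value": p, "df": float(df),
    }


def metric_means_at_ages(
    data: pd.DataFrame,
    ages: tuple[float, ...] = (8.0, 17.0, 37.0, 55.0),
    metrics: tuple[str, ...] = ("bmi", "sbp", "dbp", "total_chol", "glucose"),
    window: float = 0.5,
    group: str = "sex",
) -> pd.DataFrame:
    """Sex-specific metric means near each age with Welch comparisons.

    Visits within ``age +/- window`` years contribute; difference is
    male - female.
    """
    rows = []
    for target in ages:
        sel = data[np.abs(data["age"] - target) <= window]
        for metric in metrics:
            f = sel.loc[sel[group] == "female", metric].to_numpy(float)
            m = sel.loc[sel[group] == "male", metric].to_numpy(float)
            f, m = f[~np.isnan(f)], m[~np.isnan(m)]
            if len(f) < 2 or len(m) < 2:
                continue
            r = mean_difference_test(f, m)
            rows.append(
                {
                    "age": target, "metric": metric,
                    "mean_female": r["mean_a"], "sd_female": r["sd_a"],
                    "mean_male": r["mean_b"], "sd_male": r["sd_b"],
                    "difference": r["difference"],
                    "ci_lo": r["ci_lo"], "ci_hi": r["ci_hi"],
                    "p_value": r["p_value"],
                    "n_female": len(f), "n_male": len(m),
                }
            )
    return pd.DataFrame(rows)


def baseline_table(data: pd.DataFrame, group: str = "sex") -> pd.DataFrame:
    """Descriptive table at each subject's first (complete) exam, by group.

    Numeric columns get mean (SD); categorical columns get level counts and
    shares.  SDs are absent when a stratum has a single subject.
    """
    first = (
        data.sort_values(["subject_id", "age"], kind="stable")
        .groupby("subject_id", sort=False)
        .head(1)
    )
    rows = []
    numeric = [
        c for c in ("age", "bmi", "bmi_pct", "sbp", "dbp", "bp_pct",
                    "total_chol", "glucose", "cvh_score")
        if c in first.columns and first[c].notna().any()
    ]
    categorical = [c for c in ("race", "cohort") if c in first.columns]
    for level, sub in first.groupby(group):
        n = len(sub)
        rows.append({"group": level, "characteristic": "n_subjects",
                     "value": float(n), "sd": np.nan})
        for c in numeric:
            v = sub[c].to_numpy(float)
            v = v[~np.isnan(v)]
            rows.append(
                {
                    "group": level, "characteristic": c,
                    "value": float(v.mean()) if len(v) else np.nan,
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else np.nan,
                }
            )
        for c in categorical:
            for lv, cnt in sub[c].value_counts().items():
                rows.append(
                    {
                        "group": level, "characteristic": f"{c}={lv}",
                        "value": float(cnt), "sd": np.nan,
                        "share": float(cnt) / n,
                    }
                )
    return pd.DataFrame(rows)
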