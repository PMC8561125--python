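"""Change-point (broken-line) estimation in linear mixed models.

The population mean of the outcome is piecewise linear in age with up to two
change points psi, on top of a random intercept and slope per subject.  The
change points are estimated by iterative linearization: at a working value
``psi_k`` the break term ``(age - psi)_+`` is expanded to first order, adding

* ``U_k = (age - psi_k)_+`` carrying the slope increment ``delta_k``, and
* ``V_k = -1{age > psi_k}`` carrying the gap coefficient ``gamma_k``,

as fixed covariates of the mixed model; the update is
``psi_k <- psi_k + gamma_k / delta_k``, iterated to a fixed point where the
fitted gap vanishes and the broken line is continuous.  Asymptotic standard
errors for psi follow from the delta method on the ratio gamma/delta using
the working fit's coefficient covariance; at convergence (gamma ~ 0) this
reduces to SE(gamma)/|delta|.

A brute-force profile-likelihood grid search over candidate change points is
provided as an independent oracle for the iterative estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import EstimationError, LMMFit, fit_lmm

__all__ = [
    "SegmentedModelSpec",
    "SegmentedFit",
    "DeltaZeroError",
    "build_design",
    "fit_lmm_fixed_knots",
    "muggeo_step",
    "fit_segmented",
    "profile_grid_oracle",
    "segment_slopes",
    "fitted_mean_curve",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile

AGE_CENTER = 8.0  # fixed and random intercepts refer to age 8


class DeltaZeroError(EstimationError):
    """A flat kink (slope increment ~ 0) makes the psi update undefined."""


@dataclass(frozen=True)
class SegmentedModelSpec:
    """Configuration of a segmented LMM fit.

    ``psi_init`` may be "grid" (the default: a coarse profile-likelihood
    scan picks the starting point, so the local linearization starts inside
    the global optimum's basin of attraction — weak second breaks otherwise
    trap quantile starts in local optima), "auto" (age quantiles: median for
    one change point, 33rd/67th percentiles for two) or an explicit tuple of
    starting ages.  Estimation is by maximum likelihood (not REML) so that
    fits with different fixed effects are comparable by LRT/AIC/BIC.
    """

    n_changepoints: int = 2
    fixed_covariates: tuple[str, ...] = ()
    psi_init: str | tuple[float, ...] = "grid"
    tol_psi: float = 1e-3
    max_iter: int = 50
    min_gap: float = 3.0
    value_col: str = "cvh_score"

    def __post_init__(self) -> None:
        if self.n_changepoints not in (0, 1, 2):
            raise ValueError("n_changepoints must be 0, 1 or 2")
        if self.tol_psi <= 0 or self.min_gap <= 0:
            raise ValueError("tol_psi and min_gap must be positive")


@dataclass
class SegmentedFit:
    """Estimated change points with CIs plus the final fixed-knot fit.

    ``aic``/``bic`` count the estimated change points as parameters in
    addition to the fixed effects and the 4 variance parameters.  ``trace``
    records (psi, loglik) per accepted iteration.
    """

    psi: np.ndarray
    psi_se: np.ndarray
    psi_ci: np.ndarray
    gamma: np.ndarray
    final_fit: LMMFit
    spec: SegmentedModelSpec
    trace: list[tuple[tuple[float, ...], float]]
    converged: bool
    loglik: float = field(init=False)
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        self.loglik = self.final_fit.loglik
        k = self.final_fit.df_model + len(self.psi)
        self.aic = -2.0 * self.loglik + 2.0 * k
        self.bic = -2.0 * self.loglik + np.log(self.final_fit.n_obs) * k

    @property
    def beta(self) -> pd.Series:
        return pd.Series(self.final_fit.beta, index=self.final_fit.exog_names)

    @property
    def vc(self) -> dict[str, float]:
        return self.final_fit.vc

    @property
    def segment_slopes(self) -> pd.DataFrame:
        return segment_slopes(self)

    def to_dict(self) -> dict:
        return {
            "psi": self.psi.tolist(),
            "psi_se": self.psi_se.tolist(),
            "psi_ci": self.psi_ci.tolist(),
            "gamma": self.gamma.tolist(),
            "coefficients": dict(zip(self.final_fit.exog_names,
                                     self.final_fit.beta.tolist())),
            "coef_se": dict(zip(self.final_fit.exog_names,
                                np.sqrt(np.diag(self.final_fit.cov_beta)).tolist())),
            "segment_slopes": self.segment_slopes.to_dict(orient="records"),
            "vc": self.vc,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "n_obs": self.final_fit.n_obs,
            "n_subjects": self.final_fit.n_groups,
            "trace": [{"psi": list(p), "loglik": ll} for p, ll in self.trace],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _dummies(data: pd.DataFrame, covariates: tuple[str, ...]):
    """Reference-coded dummies with deterministic (sorted) level order."""
    cols, names = [], []
    for cov in covariates:
        levels = sorted(data[cov].astype(str).unique())
        for level in levels[1:]:
            cols.append((data[cov].astype(str) == level).to_numpy(float))
            names.append(f"{cov}[{level}]")
    return cols, names


def build_design(
    data: pd.DataFrame,
    knots: tuple[float, ...] = (),
    covariates: tuple[str, ...] = (),
    v_at: tuple[float, ...] = (),
):
    """Fixed-effect design: intercept, age (centered at 8), one ``U_k`` per
    knot, optional ``V_k`` linearization terms, and covariate dummies."""
    age = data["age"].to_numpy(float)
    cols = [np.ones_like(age), age - AGE_CENTER]
    names = ["intercept", "age"]
    for k, knot in enumerate(knots, start=1):
        cols.append(np.clip(age - knot, 0.0, None))
        names.append(f"U{k}")
    for k, knot in enumerate(v_at, start=1):
        cols.append(-(age > knot).astype(float))
        names.append(f"V{k}")
    ccols, cnames = _dummies(data, covariates)
    X = np.column_stack(cols + ccols)
    return X, names + cnames


def fit_lmm_fixed_knots(
    data: pd.DataFrame,
    knots: tuple[float, ...] = (),
    covariates: tuple[str, ...] = (),
    value_col: str = "cvh_score",
    v_at: tuple[float, ...] = (),
    start_theta: np.ndarray | None = None,
) -> LMMFit:
    """ML fit of the random-intercept+slope LMM with fixed spline knots.

    The mean is ``intercept + beta1*(age-8) + sum_k delta_k*(age-knot_k)_+``
    plus covariate dummies; the per-subject random design is (1, age-8).
    """
    age = data["age"].to_numpy(float)
    lo, hi = float(age.min()), float(age.max())
    for knot in knots:
        if not lo < knot < hi:
            raise EstimationError(
                f"knot {knot} outside the observed age range ({lo:.2f}, {hi:.2f})"
            )
    X, names = build_design(data, knots, covariates, v_at)
    return fit_lmm(
        y=data[value_col].to_numpy(float),
        X=X,
        age=age,
        groups=data["subject_id"].to_numpy(),
        exog_names=names,
        re_center=AGE_CENTER,
        start_theta=start_theta,
    )


# ---------------------------------------------------------------------------
# iterative change-point estimation
# ---------------------------------------------------------------------------


def _admissible_range(age: np.ndarray, min_gap: float) -> tuple[float, float]:
    return float(age.min()) + min_gap, float(age.max()) - min_gap


def _project(psi: np.ndarray, lo: float, hi: float, min_gap: float) -> np.ndarray:
    """Clip into the admissible range, order, and enforce the minimum gap."""
    psi = np.sort(np.clip(np.asarray(psi, float), lo, hi))
    if len(psi) == 2 and psi[1] - psi[0] < min_gap:
        mid = 0.5 * (psi[0] + psi[1])
        psi = np.array([mid - 0.5 * min_gap, mid + 0.5 * min_gap])
        psi = np.clip(psi, lo, hi)
        if psi[1] - psi[0] < min_gap:  # squeezed against a boundary
            if psi[0] <= lo:
                psi[1] = psi[0] + min_gap
            else:
                psi[0] = psi[1] - min_gap
    return psi


def muggeo_step(
    data: pd.DataFrame,
    psi_current,
    covariates: tuple[str, ...] = (),
    value_col: str = "cvh_score",
    min_gap: float = 3.0,
    start_theta: np.ndarray | None = None,
):
    """One linearization step: fit the working model with U/V terms at
    ``psi_current`` and update ``psi_k <- psi_k + gamma_k/delta_k``.

    Returns ``(psi_next, fit)`` with ``psi_next`` projected back into the
    admissible range (ordered, minimum gap enforced).  Raises
    :class:`DeltaZeroError` when a slope increment is numerically zero.
    """
    psi = np.sort(np.asarray(psi_current, dtype=float))
    fit = fit_lmm_fixed_knots(
        data, tuple(psi), covariates, value_col, v_at=tuple(psi),
        start_theta=start_theta,
    )
    delta = np.array([fit.coef(f"U{k+1}") for k in range(len(psi))])
    gamma = np.array([fit.coef(f"V{k+1}") for k in range(len(psi))])
    if np.any(np.abs(delta) < 1e-10):
        raise DeltaZeroError(
            "slope increment ~ 0 at a change point; the update gamma/delta "
            "is undefined (flat kink) — re-initialize psi"
        )
    age = data["age"].to_numpy(float)
    lo, hi = _admissible_range(age, min_gap)
    psi_next = _project(psi_update(psi, gamma, delta), lo, hi, min_gap)
    return psi_next, fit


def psi_update(psi, gamma, delta) -> np.ndarray:
    """The linearization update rule: ``psi + gamma/delta`` per change point."""
    return np.asarray(psi, float) + np.asarray(gamma, float) / np.asarray(delta, float)


def _psi_delta_se(fit: LMMFit, psi: np.ndarray) -> np.ndarray:
    """Delta-method SE of each psi from the covariance of (gamma, delta)."""
    se = np.empty(len(psi))
    for k in range(len(psi)):
        g = fit.coef(f"V{k+1}")
        d = fit.coef(f"U{k+1}")
        vg = fit.cov(f"V{k+1}", f"V{k+1}")
        vd = fit.cov(f"U{k+1}", f"U{k+1}")
        cgd = fit.cov(f"V{k+1}", f"U{k+1}")
        r = g / d
        var = (vg - 2.0 * r * cgd + r * r * vd) / (d * d)
        se[k] = np.sqrt(max(var, 0.0))
    return se


def _auto_init(age: np.ndarray, n_cp: int) -> np.ndarray:
    if n_cp == 1:
        return np.array([np.quantile(age, 0.5)])
    return np.quantile(age, [1.0 / 3.0, 2.0 / 3.0])


_GRID_INIT_POINTS = 15
#: scan points within this log-likelihood margin of the scan maximum count as
#: competing optima and each seeds its own iteration (near-tied bumps)
_TIE_MARGIN = 2.0
_MAX_STARTS = 3


def _local_maxima(points: list[tuple], lls: np.ndarray) -> list[tuple]:
    """Scan candidates: local maxima within the tie margin, best first."""
    keep = []
    for i, ll in enumerate(lls):
        left = lls[i - 1] if i > 0 else -np.inf
        right = lls[i + 1] if i + 1 < len(lls) else -np.inf
        if ll >= left and ll >= right and ll >= lls.max() - _TIE_MARGIN:
            keep.append((ll, points[i]))
    keep.sort(key=lambda t: -t[0])
    return [pt for _, pt in keep[:_MAX_STARTS]]


def _grid_init(
    data: pd.DataFrame, spec: SegmentedModelSpec, lo: float, hi: float
) -> list[np.ndarray]:
    """Profile-likelihood scan for starting points.

    One change point: a 1-D scan of single-knot fits.  Two change points:
    hierarchical — first locate the best single break (typically the sharp,
    well-identified one), then scan the second break over the whole range
    conditional on it.  A joint coarse lattice is *not* used: it samples the
    sharp break too crudely and can seed the iteration in the basin of a
    spurious close-pair optimum.  Every near-tied local maximum of the scan
    (up to three) is returned so the iteration can be multi-started when the
    profile has competing bumps.
    """
    grid = np.linspace(lo, hi, _GRID_INIT_POINTS)

    def scan(points):
        lls, kept, theta = [], [], None
        for pt in points:
            try:
                fit = fit_lmm_fixed_knots(
                    data, pt, spec.fixed_covariates, spec.value_col,
                    start_theta=theta,
                )
            except EstimationError:
                continue
            theta = fit.theta
            lls.append(fit.loglik)
            kept.append(pt)
        if not kept:
            raise EstimationError("no admissible starting point on the grid")
        return kept, np.asarray(lls)

    pts, lls = scan([(g,) for g in grid])
    if spec.n_changepoints == 1:
        return [np.array(pt) for pt in _local_maxima(pts, lls)]
    single = pts[int(np.argmax(lls))][0]
    pairs = [
        tuple(sorted((single, g))) for g in grid if abs(g - single) >= spec.min_gap
    ]
    if not pairs:
        raise EstimationError("no admissible second break on the grid")
    pts2, lls2 = scan(pairs)
    return [np.asarray(pt, dtype=float) for pt in _local_maxima(pts2, lls2)]


_POLISH_STEPS = (0.5, 0.25, 0.1, 0.05, 0.02)
_POLISH_BUDGET = 100
_SWEEP_RADIUS = 2.0
_SWEEP_STEP = 0.25


def _pattern_polish(
    data: pd.DataFrame,
    spec: SegmentedModelSpec,
    psi: np.ndarray,
    fit: LMMFit,
    lo: float,
    hi: float,
):
    """Local refinement of the profile likelihood around ``psi``.

    The profile is piecewise-smooth with kinks at observed ages and can carry
    shallow micro-bumps, so the linearization fixed point may stall slightly
    off the local maximum or on the wrong side of a small dip.  Two stages,
    both accepting improvements only: a coordinate-wise sweep at 0.25-year
    resolution within +/- 2 years (jumps local dips), then a halving-step
    pattern descent to sub-0.05-year resolution.  Returns the possibly
    improved (psi, fit) plus accepted moves.
    """
    best_psi, best_fit = np.asarray(psi, float), fit
    moves: list[tuple[tuple[float, ...], float]] = []
    budget = _POLISH_BUDGET

    offsets = np.arange(_SWEEP_STEP, _SWEEP_RADIUS + 1e-9, _SWEEP_STEP)
    for k in range(len(best_psi)):
        for off in offsets:
            for sign in (1.0, -1.0):
                cand = np.sort(best_psi + sign * off * np.eye(len(best_psi))[k])
                if cand[0] < lo or cand[-1] > hi:
                    continue
                if len(cand) == 2 and cand[1] - cand[0] < spec.min_gap:
                    continue
                budget -= 1
                try:
                    cfit = fit_lmm_fixed_knots(
                        data, tuple(cand), spec.fixed_covariates,
                        spec.value_col, start_theta=best_fit.theta,
                    )
                except EstimationError:
                    continue
                if cfit.loglik > best_fit.loglik + 1e-9:
                    best_psi, best_fit = cand, cfit
                    moves.append((tuple(cand), cfit.loglik))
    for step in _POLISH_STEPS:
        improved = True
        while improved and budget > 0:
            improved = False
            for k in range(len(best_psi)):
                for sign in (1.0, -1.0):
                    if budget <= 0:
                        break
                    cand = np.sort(best_psi + sign * step * np.eye(len(best_psi))[k])
                    if cand[0] < lo or cand[-1] > hi:
                        continue
                    if len(cand) == 2 and cand[1] - cand[0] < spec.min_gap:
                        continue
                    budget -= 1
                    try:
                        cfit = fit_lmm_fixed_knots(
                            data, tuple(cand), spec.fixed_covariates,
                            spec.value_col, start_theta=best_fit.theta,
                        )
                    except EstimationError:
                        continue
                    if cfit.loglik > best_fit.loglik + 1e-9:
                        best_psi, best_fit = cand, cfit
                        moves.append((tuple(cand), cfit.loglik))
                        improved = True
    return best_psi, best_fit, moves


_MAX_HALVINGS = 6


def _iterate(
    data: pd.DataFrame,
    spec: SegmentedModelSpec,
    psi: np.ndarray,
    lo: float,
    hi: float,
):
    """Linearization fixed-point iteration with step-halving from one start.

    Returns ``(psi, obj_fit, trace, converged, flat_kink)`` where ``obj_fit``
    is the fixed-knot fit at the final psi and the accepted-iteration
    log-likelihood is non-decreasing along ``trace``.
    """
    cov = spec.fixed_covariates
    theta = None
    obj_fit = fit_lmm_fixed_knots(data, tuple(psi), cov, spec.value_col)
    trace = [(tuple(psi), obj_fit.loglik)]
    converged = False
    flat_kink = False

    for _ in range(spec.max_iter):
        try:
            psi_prop, work_fit = muggeo_step(
                data, psi, cov, spec.value_col, spec.min_gap, start_theta=theta
            )
        except DeltaZeroError:
            flat_kink = True
            break
        step = psi_prop - psi
        accepted = None
        for h in range(_MAX_HALVINGS + 1):
            cand = _project(psi + step * (0.5 ** h), lo, hi, spec.min_gap)
            try:
                cand_fit = fit_lmm_fixed_knots(
                    data, tuple(cand), cov, spec.value_col,
                    start_theta=work_fit.theta,
                )
            except EstimationError:
                continue
            if cand_fit.loglik >= obj_fit.loglik - 1e-9:
                accepted = (cand, cand_fit)
                break
        if accepted is None:
            # no admissible improvement: treat current psi as the optimum
            converged = True
            break
        move = float(np.max(np.abs(accepted[0] - psi)))
        psi, obj_fit = accepted
        theta = obj_fit.theta
        trace.append((tuple(psi), obj_fit.loglik))
        if move < spec.tol_psi:
            converged = True
            break
    return psi, obj_fit, trace, converged, flat_kink


def fit_segmented(data: pd.DataFrame, spec: SegmentedModelSpec) -> SegmentedFit:
    """Estimate the segmented LMM: iterate linearization steps with
    step-halving until the change points move less than ``tol_psi``.

    The reported coefficients, log-likelihood and information criteria come
    from a final refit at the estimated change points without the V terms;
    psi standard errors use the delta method on the last working fit.  With
    ``n_changepoints == 0`` this is a plain linear LMM (psi empty).
    """
    age = data["age"].to_numpy(float)
    n_cp = spec.n_changepoints
    cov = spec.fixed_covariates

    if n_cp == 0:
        fit = fit_lmm_fixed_knots(data, (), cov, spec.value_col)
        empty = np.empty(0)
        return SegmentedFit(
            psi=empty, psi_se=empty.copy(), psi_ci=np.empty((0, 2)),
            gamma=empty.copy(), final_fit=fit, spec=spec,
            trace=[((), fit.loglik)], converged=True,
        )

    lo, hi = _admissible_range(age, spec.min_gap)
    if spec.psi_init == "grid":
        starts = _grid_init(data, spec, lo, hi)
    elif spec.psi_init == "auto":
        starts = [_auto_init(age, n_cp)]
    else:
        psi0 = np.asarray(spec.psi_init, dtype=float)
        if len(psi0) != n_cp:
            raise ValueError("psi_init length must equal n_changepoints")
        starts = [psi0]

    best = None
    for start in starts:
        result = _iterate(data, spec, _project(start, lo, hi, spec.min_gap), lo, hi)
        if best is None or result[1].loglik > best[1].loglik:
            best = result
    psi, obj_fit, trace, converged, flat_kink = best

    # derivative-free polish: the profile has kinks at observed ages where
    # the linearization fixed point can stall short of the local maximum
    psi, obj_fit, moves = _pattern_polish(data, spec, psi, obj_fit, lo, hi)
    trace = trace + moves

    # working fit at the final psi for gamma and the delta-method SE
    try:
        _, work_fit = muggeo_step(
            data, psi, cov, spec.value_col, spec.min_gap,
            start_theta=obj_fit.theta,
        )
        gamma = np.array([work_fit.coef(f"V{k+1}") for k in range(n_cp)])
        psi_se = _psi_delta_se(work_fit, psi)
    except DeltaZeroError:
        flat_kink = True
        gamma = np.full(n_cp, np.nan)
        psi_se = np.full(n_cp, np.nan)

    ci = np.column_stack([psi - _Z95 * psi_se, psi + _Z95 * psi_se])
    return SegmentedFit(
        psi=psi, psi_se=psi_se, psi_ci=ci, gamma=gamma,
        final_fit=obj_fit, spec=spec, trace=trace,
        converged=converged and not flat_kink,
    )


# ---------------------------------------------------------------------------
# profile-likelihood grid oracle
# ---------------------------------------------------------------------------


def profile_grid_oracle(
    data: pd.DataFrame,
    spec: SegmentedModelSpec,
    grid_step: float = 0.5,
):
    """Brute-force profile likelihood over a grid of candidate change points.

    Fits the fixed-knot LMM at every admissible grid point (ordered pairs
    with the minimum gap for two change points) and returns
    ``(psi_argmax, profile)`` where ``profile`` is a DataFrame of grid points
    and log-likelihoods.  By construction the argmax log-likelihood is >= the
    profile at any other grid point; it independently verifies the iterative
    estimator.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    age = data["age"].to_numpy(float)
    lo, hi = _admissible_range(age, spec.min_gap)
    grid = np.arange(lo, hi + 1e-9, grid_step)
    if len(grid) == 0:
        raise ValueError("empty grid after range constraints")
    if spec.n_changepoints == 1:
        points = [(g,) for g in grid]
    elif spec.n_changepoints == 2:
        points = [
            (g1, g2) for g1 in grid for g2 in grid if g2 - g1 >= spec.min_gap
        ]
        if not points:
            raise ValueError("empty grid after the minimum-gap constraint")
    else:
        raise ValueError("grid oracle requires 1 or 2 change points")

    rows = []
    theta = None
    for pt in points:
        try:
            fit = fit_lmm_fixed_knots(
                data, pt, spec.fixed_covariates, spec.value_col, start_theta=theta
            )
        except EstimationError:
            continue
        theta = fit.theta
        rows.append((*pt, fit.loglik))
    cols = [f"psi{k+1}" for k in range(spec.n_changepoints)] + ["loglik"]
    profile = pd.DataFrame(rows, columns=cols)
    best = profile.iloc[int(profile["loglik"].idxmax())]
    argmax = tuple(float(best[c]) for c in cols[:-1])
    return argmax, profile


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def segment_slopes(fit: SegmentedFit | LMMFit, psi=None) -> pd.DataFrame:
    """Per-segment slopes (beta1 + cumulative delta) with delta-method CIs.

    The slope of segment *k* is the linear contrast ``beta_age +
    sum_{j<=k-1} delta_j`` on the fitted coefficients; its SE comes from the
    coefficient covariance.
    """
    if isinstance(fit, SegmentedFit):
        lmm, psi = fit.final_fit, fit.psi
    else:
        lmm = fit
        psi = np.asarray(psi if psi is not None else [], dtype=float)
    names = lmm.exog_names
    n_seg = len(psi) + 1
    rows = []
    for k in range(n_seg):
        c = np.zeros(len(names))
        c[names.index("age")] = 1.0
        for j in range(k):
            c[names.index(f"U{j+1}")] = 1.0
        slope = float(c @ lmm.beta)
        se = float(np.sqrt(c @ lmm.cov_beta @ c))
        rows.append(
            {
                "segment": k,
                "age_lo": AGE_CENTER if k == 0 else float(psi[k - 1]),
                "age_hi": float(psi[k]) if k < len(psi) else np.inf,
                "slope": slope,
                "se": se,
                "ci_lo": slope - _Z95 * se,
                "ci_hi": slope + _Z95 * se,
            }
        )
    return pd.DataFrame(rows)


def fitted_mean_curve(fit: SegmentedFit, ages) -> pd.DataFrame:
    """Population-mean curve at the reference covariate levels, for plotting."""
    ages = np.asarray(ages, dtype=float)
    lmm = fit.final_fit
    y = np.full(ages.shape, lmm.coef("intercept"))
    y += lmm.coef("age") * (ages - AGE_CENTER)
    for k, knot in enumerate(fit.psi, start=1):
        y += lmm.coef(f"U{k}") * np.clip(ages - knot, 0.0, None)
    return pd.DataFrame({"age": ages, "mean_score": y})
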