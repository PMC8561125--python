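"""Maximum-likelihood linear mixed model with a random intercept and slope.

This is the numerical engine behind the change-point estimator.  The model for
subject *j* with visit ages :math:`t_{ij}` is

.. math::

    y_{ij} = x_{ij}^\\top \\beta + b_{0j} + b_{1j} (t_{ij} - c) + \\epsilon_{ij},

with :math:`(b_{0j}, b_{1j}) \\sim N(0, G)` independent of
:math:`\\epsilon_{ij} \\sim N(0, \\sigma^2)`, and *c* a fixed centering age for
the random-slope regressor (a pure reparameterization that improves
conditioning; the likelihood is unchanged).

Estimation profiles :math:`\\beta` and :math:`\\sigma^2` out of the marginal
Gaussian likelihood and optimizes only the 3 parameters of the scaled
covariance :math:`\\Psi = G/\\sigma^2` (log-Cholesky parameterization).  All
per-subject quantities reduce to small sufficient statistics
(:math:`Z_j^\\top Z_j`, :math:`Z_j^\\top X_j`, :math:`Z_j^\\top y_j`) computed
once per design matrix, so one likelihood evaluation is a handful of batched
2x2 operations.  This is what makes the iterative change-point search, the
profile-likelihood grid oracle and the Monte-Carlo calibration suites cheap:
refitting after a design change reuses nothing but these statistics, and the
optimizer can be warm-started from the previous variance parameters.

The implementation is deliberately independent of statsmodels' MixedLM, which
serves as a cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["LMMFit", "EstimationError", "fit_lmm"]


class EstimationError(RuntimeError):
    """Raised when the mixed model cannot be estimated (singular design)."""


@dataclass
class LMMFit:
    """Result of a maximum-likelihood random-intercept+slope LMM fit.

    Attributes
    ----------
    beta : ndarray
        Fixed-effect estimates, ordered as ``exog_names``.
    cov_beta : ndarray
        Asymptotic covariance of ``beta`` (sigma^2 * (X' W^-1 X)^-1).
    sigma2 : float
        Residual variance (ML).
    G : ndarray
        2x2 random-effect covariance in the (intercept, slope) basis, the
        intercept being the deviation at the centering age ``re_center``.
    loglik, aic, bic : float
        ML log-likelihood and information criteria; ``df_model`` counts
        fixed effects + 3 covariance parameters + the residual variance.
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    exog_names: list[str]
    sigma2: float
    G: np.ndarray
    loglik: float
    n_obs: int
    n_groups: int
    df_model: int
    re_center: float
    theta: np.ndarray
    converged: bool
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        self.aic = -2.0 * self.loglik + 2.0 * self.df_model
        self.bic = -2.0 * self.loglik + np.log(self.n_obs) * self.df_model

    # -- convenience accessors -------------------------------------------
    def coef(self, name: str) -> float:
        return float(self.beta[self.exog_names.index(name)])

    def se(self, name: str) -> float:
        i = self.exog_names.index(name)
        return float(np.sqrt(self.cov_beta[i, i]))

    def cov(self, name_a: str, name_b: str) -> float:
        i = self.exog_names.index(name_a)
        j = self.exog_names.index(name_b)
        return float(self.cov_beta[i, j])

    @property
    def resid_sd(self) -> float:
        return float(np.sqrt(self.sigma2))

    @property
    def vc(self) -> dict[str, float]:
        """Variance components as SDs plus correlation."""
        sd0 = float(np.sqrt(max(self.G[0, 0], 0.0)))
        sd1 = float(np.sqrt(max(self.G[1, 1], 0.0)))
        corr = float(self.G[0, 1] / (sd0 * sd1)) if sd0 > 0 and sd1 > 0 else 0.0
        return {
            "re_sd_intercept": sd0,
            "re_sd_slope": sd1,
            "re_corr": corr,
            "resid_sd": self.resid_sd,
        }


class _SuffStats:
    """Per-subject sufficient statistics for the profiled likelihood."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        t: np.ndarray,
        groups: np.ndarray,
    ) -> None:
        order = np.argsort(groups, kind="stable")
        y = np.asarray(y, dtype=float)[order]
        X = np.asarray(X, dtype=float)[order]
        t = np.asarray(t, dtype=float)[order]
        g = np.asarray(groups)[order]
        # reduceat boundaries: first index of each subject block
        change = np.empty(len(g), dtype=bool)
        change[0] = True
        change[1:] = g[1:] != g[:-1]
        starts = np.flatnonzero(change)

        Z = np.column_stack([np.ones_like(t), t])  # (n, 2)
        n, p = X.shape
        # A_j = Z_j' Z_j  -> (m, 2, 2)
        prods = np.einsum("ni,nj->nij", Z, Z)
        self.A = np.add.reduceat(prods.reshape(n, 4), starts, axis=0).reshape(-1, 2, 2)
        # B_j = Z_j' X_j  -> (m, 2, p)
        bx = np.einsum("ni,np->nip", Z, X)
        self.B = np.add.reduceat(bx.reshape(n, 2 * p), starts, axis=0).reshape(-1, 2, p)
        # c_j = Z_j' y_j  -> (m, 2)
        self.c = np.add.reduceat(Z * y[:, None], starts, axis=0)
        self.Sxx = X.T @ X
        self.sxy = X.T @ y
        self.syy = float(y @ y)
        self.n_obs = n
        self.n_groups = len(starts)
        self.p = p


def _psi_from_theta(theta: np.ndarray) -> np.ndarray:
    """Scaled RE covariance Psi = L L' from log-Cholesky parameters."""
    l11 = np.exp(theta[0])
    l21 = theta[1]
    l22 = np.exp(theta[2])
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


_SIGMA2_FLOOR = 1e-12


def _profiled(theta: np.ndarray, s: _SuffStats, want_grad: bool = False):
    """Profiled likelihood quantities at Psi(theta).

    Returns ``(negll, beta, sigma2, XtWX)`` and, with ``want_grad``, appends
    the gradient of negll w.r.t. theta.  The gradient uses the envelope
    theorem (beta and sigma2 are profiled optima, so only the explicit Psi
    dependence contributes): with ``v_j = (I - A_j K_j) Z_j' r_j``,

        d loglik / d Psi = -1/2 [ sum_j (A_j - A_j K_j A_j)
                                  - (1/sigma2) sum_j v_j v_j' ],

    chained through the log-Cholesky parameterization.
    """
    psi = _psi_from_theta(theta)
    # M_j = I + A_j Psi  (2x2, batched); det >= 1 since A, Psi are psd
    M = np.eye(2)[None, :, :] + s.A @ psi
    detM = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    inv = np.empty_like(M)
    inv[:, 0, 0] = M[:, 1, 1]
    inv[:, 1, 1] = M[:, 0, 0]
    inv[:, 0, 1] = -M[:, 0, 1]
    inv[:, 1, 0] = -M[:, 1, 0]
    inv /= detM[:, None, None]
    K = psi[None, :, :] @ inv  # = (Psi^-1 + A)^-1 without inverting Psi
    K = 0.5 * (K + np.swapaxes(K, 1, 2))

    XtWX = s.Sxx - np.einsum("mip,mij,mjq->pq", s.B, K, s.B, optimize=True)
    XtWy = s.sxy - np.einsum("mip,mij,mj->p", s.B, K, s.c, optimize=True)
    ytWy = s.syy - np.einsum("mi,mij,mj->", s.c, K, s.c, optimize=True)

    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise EstimationError(f"singular fixed-effect design: {exc}") from exc
    q = max(float(ytWy - XtWy @ beta), _SIGMA2_FLOOR)
    n = s.n_obs
    sigma2 = q / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + float(np.sum(np.log(detM))))
    if not want_grad:
        return -ll, beta, sigma2, XtWX

    AK = s.A @ K
    T = np.einsum("mij->ij", s.A - AK @ s.A)
    u = s.c - np.einsum("mip,p->mi", s.B, beta)
    v = u - np.einsum("mij,mj->mi", AK, u)
    Svv = np.einsum("mi,mj->ij", v, v)
    dll_dpsi = -0.5 * (T - Svv / sigma2)

    l11, l21, l22 = np.exp(theta[0]), theta[1], np.exp(theta[2])
    L = np.array([[l11, 0.0], [l21, l22]])
    dLs = (
        np.array([[l11, 0.0], [0.0, 0.0]]),   # d/d theta0 (log l11)
        np.array([[0.0, 0.0], [1.0, 0.0]]),   # d/d theta1 (l21)
        np.array([[0.0, 0.0], [0.0, l22]]),   # d/d theta2 (log l22)
    )
    grad = np.array(
        [-np.sum(dll_dpsi * (dL @ L.T + L @ dL.T)) for dL in dLs]
    )
    return -ll, beta, sigma2, XtWX, grad


_DEFAULT_THETA = np.array([0.3, 0.0, -3.5])


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    age: np.ndarray,
    groups: np.ndarray,
    exog_names: list[str] | None = None,
    re_center: float = 8.0,
    start_theta: np.ndarray | None = None,
) -> LMMFit:
    """Fit the random-intercept+slope LMM by profiled maximum likelihood.

    Parameters
    ----------
    y, X, age, groups
        Response, fixed-effect design matrix, visit ages and subject labels,
        all aligned row-wise.  ``age`` only feeds the random-slope regressor
        (centered at ``re_center``); any fixed effect of age must appear as a
        column of ``X``.
    start_theta
        Warm start for the 3 variance parameters (log-Cholesky of G/sigma^2);
        used extensively by the change-point iteration.

    Raises
    ------
    EstimationError
        If the fixed-effect design is singular (e.g. all ages identical so an
        age column is collinear with the intercept).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if exog_names is None:
        exog_names = [f"x{i}" for i in range(X.shape[1])]
    if len(exog_names) != X.shape[1]:
        raise ValueError("exog_names length does not match design columns")
    if len(y) != X.shape[0]:
        raise ValueError("response and design have different lengths")
    if len(y) == 0:
        raise EstimationError("empty dataset")

    # rank check up front for a clear diagnostic
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError(
            "fixed-effect design is rank deficient; check for collinear "
            "columns (e.g. constant age or empty spline segments)"
        )

    s = _SuffStats(y, X, np.asarray(age, dtype=float) - re_center, groups)

    theta0 = np.asarray(start_theta, dtype=float) if start_theta is not None else _DEFAULT_THETA

    def objective(th: np.ndarray):
        out = _profiled(th, s, want_grad=True)
        return out[0], out[4]

    bounds = [(-12.0, 8.0), (-60.0, 60.0), (-12.0, 8.0)]
    res = optimize.minimize(
        objective,
        np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds]),
        method="L-BFGS-B",
        jac=True,
        bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7},
    )
    best = res
    if not res.success:  # one fallback restart from the default
        res2 = optimize.minimize(
            lambda th: _profiled(th, s)[0],
            _DEFAULT_THETA,
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-6, "fatol": 1e-9},
        )
        if res2.fun < best.fun:
            best = res2

    negll, beta, sigma2, XtWX = _profiled(best.x, s)
    try:
        cov_beta = sigma2 * np.linalg.inv(XtWX)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular information matrix: {exc}") from exc
    G = sigma2 * _psi_from_theta(best.x)

    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        exog_names=list(exog_names),
        sigma2=sigma2,
        G=G,
        loglik=-negll,
        n_obs=s.n_obs,
        n_groups=s.n_groups,
        df_model=s.p + 4,
        re_center=re_center,
        theta=np.asarray(best.x, dtype=float),
        converged=bool(best.success or res.success),
    )
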