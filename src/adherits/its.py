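"""Segmented linear regression with AR(1) errors, estimated by REML.

Model for a group-month proportion series y_t (percent), t = 1..n with last
pre-intervention month t0:

    y_t = b0 + b1 * t + b2 * I(t > t0) + b3 * (t - t0) * I(t > t0) + e_t
    e_t = rho * e_{t-1} + u_t,   u_t iid N(0, sigma^2)

b0 is the baseline percentage, b1 the secular (pre-intervention) slope, b2
the immediate level change, b3 the gradual trend change.  The overall
effect at horizon h months post-implementation is the fitted-minus-
counterfactual difference b2 + h * b3.

Estimation profiles the REML criterion over rho in (-0.99, 0.99): for fixed
rho, beta is the GLS estimate and sigma^2 the REML residual variance; the
profiled criterion is maximized by bounded scalar optimization.  The AR(1)
covariance is evaluated at *calendar* lags, so months dropped for zero
denominators simply widen the lag between neighbours — no re-indexing or
interpolation.

Confidence intervals and p-values use a t reference distribution whose
denominator degrees of freedom come from a Satterthwaite approximation
(delta method on the variance parameters (rho, sigma^2) with the observed
REML information), with a plain residual n - 4 fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, ValidationError

DESIGN_COLUMNS = ("intercept", "time", "intervention", "time_after")
_RHO_BOUND = 0.99
_MIN_SEGMENT_POINTS = 3


@dataclass(frozen=True)
class SegmentedDesign:
    """Design matrix and response for one group's segmented regression."""

    t: np.ndarray  # calendar month indices, strictly increasing
    y: np.ndarray  # monthly proportions, percent
    t0: int
    X: np.ndarray  # columns: intercept, t, I(t > t0), (t - t0) * I(t > t0)

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class SegmentedFit:
    """REML fit of the segmented AR(1) model."""

    design: SegmentedDesign
    beta: np.ndarray            # (b0, b1, b2, b3)
    rho: float
    sigma2: float               # innovation variance
    cov_beta: np.ndarray        # 4x4, sigma2 * (X' V^-1 X)^-1
    reml_loglik: float
    fitted: np.ndarray
    residuals: np.ndarray
    mse: float                  # mean squared raw residual
    rho_fixed: bool = False
    converged_at_boundary: bool = False

    @property
    def n(self) -> int:
        return self.design.n

    @property
    def p(self) -> int:
        return self.design.X.shape[1]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_beta), 0.0, None))


@dataclass(frozen=True)
class EffectEstimate:
    """A linear contrast of the segmented coefficients with its t-based CI."""

    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    level: float = 0.95
    horizon: int | None = None


def build_design(series: pd.DataFrame | None, t0: int,
                 t: np.ndarray | None = None, y: np.ndarray | None = None,
                 ) -> SegmentedDesign:
    """Build the segmented design from a group series.

    Accepts either a series frame with ``t`` / ``proportion_pct`` columns
    (rows with a missing proportion are dropped; calendar t values are kept,
    so gaps remain gaps) or raw ``t`` and ``y`` arrays.  Requires at least 3
    observed months on each side of ``t0``.
    """
    if series is not None:
        sub = series[series["proportion_pct"].notna()]
        t = sub["t"].to_numpy(dtype=int)
        y = sub["proportion_pct"].to_numpy(dtype=float)
    t = np.asarray(t, dtype=int)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValidationError("t and y must have equal length")
    if np.any(np.diff(t) <= 0):
        order = np.argsort(t)
        t, y = t[order], y[order]
        if np.any(np.diff(t) <= 0):
            raise ValidationError("duplicate month indices in series")
    n_pre = int((t <= t0).sum())
    n_post = int((t > t0).sum())
    if n_pre < _MIN_SEGMENT_POINTS or n_post < _MIN_SEGMENT_POINTS:
        raise ValidationError(
            f"need >= {_MIN_SEGMENT_POINTS} observed months on each side of t0 "
            f"(got {n_pre} pre, {n_post} post)")
    post = (t > t0).astype(float)
    X = np.column_stack([np.ones_like(post), t.astype(float), post, (t - t0) * post])
    return SegmentedDesign(t=t, y=y, t0=t0, X=X)


def _whiten(t: np.ndarray, rho: float, M: np.ndarray) -> tuple[np.ndarray, float]:
    """Whiten columns of M with the AR(1) Cholesky at calendar lags.

    Uses unit-innovation covariance V_ij = rho^|t_i - t_j| / (1 - rho^2);
    the prediction decomposition gives conditional variances
    v_1 = 1/(1-rho^2), v_i = (1 - rho^(2*dt_i)) / (1 - rho^2).  Returns the
    whitened matrix (so that cov of the whitened response is sigma^2 I) and
    log|V| = sum(log v_i).
    """
    M = np.atleast_2d(M.T).T.astype(float)
    n = M.shape[0]
    if n == 1:
        v = np.array([1.0 / (1.0 - rho * rho)])
        return M / math.sqrt(v[0]), float(np.log(v[0]))
    dt = np.diff(t).astype(float)
    a = rho ** dt
    v = np.empty(n)
    v[0] = 1.0 / (1.0 - rho * rho)
    v[1:] = (1.0 - a * a) / (1.0 - rho * rho)
    W = np.empty_like(M)
    W[0] = M[0]
    W[1:] = M[1:] - a[:, None] * M[:-1]
    W /= np.sqrt(v)[:, None]
    return W, float(np.log(v).sum())


def _gls_pieces(design: SegmentedDesign, rho: float):
    """GLS at fixed rho: beta, RSS, log|V|, log|X'V^-1 X|, (X'V^-1 X)^-1."""
    Xw, logdet_v = _whiten(design.t, rho, design.X)
    yw, _ = _whiten(design.t, rho, design.y[:, None])
    xtx = Xw.T @ Xw
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    if sign <= 0:
        raise ConvergenceError("singular design matrix in GLS step")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (Xw.T @ yw[:, 0])
    resid_w = yw[:, 0] - Xw @ beta
    rss = float(resid_w @ resid_w)
    return beta, rss, logdet_v, logdet_xtx, xtx_inv


def _reml_m2ll(design: SegmentedDesign, rho: float, sigma2: float) -> float:
    """-2 x restricted log-likelihood at (rho, sigma2), beta profiled out."""
    n, p = design.n, design.X.shape[1]
    _, rss, logdet_v, logdet_xtx, _ = _gls_pieces(design, rho)
    return ((n - p) * math.log(2.0 * math.pi * sigma2) + logdet_v + logdet_xtx
            + rss / sigma2)


def _profiled_criterion(design: SegmentedDesign, rho: float) -> float:
    """-2 REML log-likelihood profiled over sigma2 (constants dropped)."""
    n, p = design.n, design.X.shape[1]
    _, rss, logdet_v, logdet_xtx, _ = _gls_pieces(design, rho)
    sigma2 = max(rss / (n - p), 1e-300)
    return (n - p) * math.log(sigma2) + logdet_v + logdet_xtx


def reml_fit_ar1(design: SegmentedDesign, fix_rho: float | None = None,
                 rho_bound: float = _RHO_BOUND, xatol: float = 1e-8) -> SegmentedFit:
    """Fit the segmented AR(1) model by profiled REML.

    ``fix_rho`` constrains the autocorrelation (``fix_rho=0`` reduces the
    estimator to OLS exactly); otherwise rho is found by bounded scalar
    minimization of the profiled criterion on (-rho_bound, rho_bound) to an
    absolute tolerance ``xatol``.  A solution within 1e-4 of the bound is
    recorded as ``converged_at_boundary`` and a warning is emitted.
    """
    n, p = design.n, design.X.shape[1]
    if n <= p:
        raise ValidationError(f"need more than {p} observations, got {n}")
    boundary = False
    if fix_rho is not None:
        if not -1 < fix_rho < 1:
            raise ValidationError("fix_rho must be in (-1, 1)")
        rho_hat = float(fix_rho)
    else:
        res = optimize.minimize_scalar(
            lambda r: _profiled_criterion(design, r), bounds=(-rho_bound, rho_bound),
            method="bounded", options={"xatol": xatol})
        if not res.success:
            raise ConvergenceError(f"rho optimization failed: {res.message}")
        rho_hat = float(res.x)
        if rho_bound - abs(rho_hat) < 1e-4:
            boundary = True
            warnings.warn(
                f"AR(1) parameter converged at the stationarity bound (rho = "
                f"{rho_hat:.4f}); estimates may be unreliable", UserWarning, stacklevel=2)

    beta, rss, logdet_v, logdet_xtx, xtx_inv = _gls_pieces(design, rho_hat)
    sigma2 = rss / (n - p)
    cov_beta = sigma2 * xtx_inv
    loglik = -0.5 * ((n - p) * math.log(2.0 * math.pi * max(sigma2, 1e-300))
                     + logdet_v + logdet_xtx + (n - p))
    fitted = design.X @ beta
    residuals = design.y - fitted
    return SegmentedFit(
        design=design, beta=beta, rho=rho_hat, sigma2=sigma2, cov_beta=cov_beta,
        reml_loglik=loglik, fitted=fitted, residuals=residuals,
        mse=float(np.mean(residuals ** 2)), rho_fixed=fix_rho is not None,
        converged_at_boundary=boundary)


def _satterthwaite_df(fit: SegmentedFit, c: np.ndarray) -> float:
    """Satterthwaite denominator df for the contrast c'beta.

    The contrast variance g(theta) = sigma2 * c'(X'V(rho)^-1 X)^-1 c is a
    function of theta = (rho, log sigma2).  With A the asymptotic covariance
    of theta-hat (inverse observed REML information, from a numeric Hessian
    of -2 l_R), df = 2 g^2 / (grad g' A grad g).  When rho is fixed the
    derivation collapses analytically to the residual df n - p.
    """
    design = fit.design
    n, p = fit.n, fit.p
    if fit.rho_fixed or fit.sigma2 <= 0:
        return float(n - p)

    def gfun(theta: np.ndarray) -> float:
        rho = min(max(theta[0], -0.999), 0.999)
        _, _, _, _, xtx_inv = _gls_pieces(design, rho)
        return math.exp(theta[1]) * float(c @ xtx_inv @ c)

    def m2ll(theta: np.ndarray) -> float:
        rho = min(max(theta[0], -0.999), 0.999)
        return _reml_m2ll(design, rho, math.exp(theta[1]))

    theta = np.array([fit.rho, math.log(fit.sigma2)])
    h = np.array([1e-4, 1e-4])
    try:
        # central-difference Hessian of -2 l_R and gradient of g
        H = np.empty((2, 2))
        f0 = m2ll(theta)
        for i in range(2):
            ei = np.zeros(2)
            ei[i] = h[i]
            H[i, i] = (m2ll(theta + ei) - 2.0 * f0 + m2ll(theta - ei)) / h[i] ** 2
        e0 = np.array([h[0], 0.0])
        e1 = np.array([0.0, h[1]])
        H[0, 1] = H[1, 0] = (
            m2ll(theta + e0 + e1) - m2ll(theta + e0 - e1)
            - m2ll(theta - e0 + e1) + m2ll(theta - e0 - e1)) / (4.0 * h[0] * h[1])
        A = 2.0 * np.linalg.inv(H)  # asymptotic cov of theta-hat
        grad = np.array([
            (gfun(theta + e0) - gfun(theta - e0)) / (2.0 * h[0]),
            (gfun(theta + e1) - gfun(theta - e1)) / (2.0 * h[1]),
        ])
        g = gfun(theta)
        denom = float(grad @ A @ grad)
        if not np.isfinite(denom) or denom <= 0 or g <= 0:
            return float(n - p)
        df = 2.0 * g * g / denom
        if not np.isfinite(df) or df < 1.0:
            return float(n - p)
        return float(df)
    except np.linalg.LinAlgError:
        return float(n - p)


def effect_contrast(fit: SegmentedFit, c, name: str = "contrast",
                    df_method: str = "satterthwaite", level: float = 0.95,
                    horizon: int | None = None) -> EffectEstimate:
    """Estimate a linear contrast c'beta with a t-based CI and p-value.

    ``df_method`` is ``"satterthwaite"`` (default) or ``"residual"`` for the
    plain n - 4 fallback.  Units follow the contrast: percent for level-type
    contrasts, percent per month for slope-type ones.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (fit.p,):
        raise ValidationError(f"contrast must have length {fit.p}, got shape {c.shape}")
    if df_method not in ("satterthwaite", "residual"):
        raise ValidationError("df_method must be 'satterthwaite' or 'residual'")
    estimate = float(c @ fit.beta)
    var = float(c @ fit.cov_beta @ c)
    se = math.sqrt(max(var, 0.0))
    df = (_satterthwaite_df(fit, c) if df_method == "satterthwaite"
          else float(fit.n - fit.p))
    if se > 0:
        tval = estimate / se
        p_value = float(2.0 * stats.t.sf(abs(tval), df))
    else:
        p_value = 0.0 if estimate != 0 else 1.0
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, df))
    return EffectEstimate(
        name=name, estimate=estimate, se=se,
        ci_low=estimate - tcrit * se, ci_high=estimate + tcrit * se,
        p_value=p_value, df=df, level=level, horizon=horizon)


def overall_effect_at(fit: SegmentedFit, h: int, df_method: str = "satterthwaite",
                      level: float = 0.95) -> EffectEstimate:
    """Overall intervention effect at h months post-implementation.

    The contrast (0, 0, 1, h): algebraically the fitted value at month
    t0 + h minus the counterfactual (pre-trend extrapolation) at the same
    month, i.e. the combined immediate and gradual effect b2 + h * b3.
    """
    if h < 0:
        raise ValidationError("horizon h must be >= 0")
    return effect_contrast(fit, np.array([0.0, 0.0, 1.0, float(h)]),
                           name=f"overall_at_{h}", df_method=df_method,
                           level=level, horizon=h)


def trajectories(fit: SegmentedFit, design: SegmentedDesign | None = None) -> pd.DataFrame:
    """Observed, fitted, and counterfactual series for plotting.

    The counterfactual is the pre-intervention line b0 + b1 * t extrapolated
    over the whole calendar; it coincides with the fitted values for
    t <= t0.
    """
    design = design or fit.design
    fitted = design.X @ fit.beta
    counterfactual = fit.beta[0] + fit.beta[1] * design.t
    return pd.DataFrame({
        "t": design.t,
        "post": (design.t > design.t0).astype(int),
        "observed": design.y,
        "fitted": fitted,
        "counterfactual": counterfactual,
    })


def summarize_fit(fit: SegmentedFit, horizon: int = 12,
                  df_method: str = "satterthwaite", level: float = 0.95,
                  ) -> list[EffectEstimate]:
    """The five report rows: baseline, secular trend, immediate, gradual,
    and overall effect at the horizon."""
    rows = [
        effect_contrast(fit, [1, 0, 0, 0], "intercept_baseline_pct", df_method, level),
        effect_contrast(fit, [0, 1, 0, 0], "pre_slope_pct_per_month", df_method, level),
        effect_contrast(fit, [0, 0, 1, 0], "level_change_pct", df_method, level),
        effect_contrast(fit, [0, 0, 0, 1], "trend_change_pct_per_month", df_method, level),
        overall_effect_at(fit, horizon, df_method, level),
    ]
    return rows
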