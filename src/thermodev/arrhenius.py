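"""Arrhenius-coordinate regression, model selection, and slope comparison.

The Arrhenius equation, k = A exp(-Ea / (R T)), becomes linear after the
coordinate change x = 1/T (K^-1), y = ln k:

    y = ln A - (Ea * 1000 / R) * x

so the apparent activation energy of a possibly composite process is
``Ea = -slope * R / 1000`` kJ/mol.  This module provides:

* :class:`ArrheniusLinearRegression` / :class:`ArrheniusQuadraticRegression`
  -- sklearn-style estimators fit on (temperature degC, rate min^-1) data,
  optionally restricted to a core temperature range;
* BIC-based linear-vs-quadratic model selection (:func:`bic_compare`);
* ANCOVA comparison of two intervals' slopes with post-hoc power
  (:func:`compare_slopes_ancova`);
* initial-rate extraction from absorbance traces and the quarter-power
  allometric time-ratio prediction.

Fits consume one point per embryo-interval observation (not per-temperature
means); means with standard errors are display summaries only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .constants import R_J_PER_MOL_K, celsius_to_kelvin

#: Sentinel used when a model-selection log-ratio diverges (zero residual).
LAMBDA_CAP = 1e6


# ---------------------------------------------------------------------------
# coordinates

def to_arrhenius_coords(temperature_c, rate_per_min):
    """Map (temperature degC, rate min^-1) to Arrhenius coordinates (1/T_K, ln rate)."""
    temperature_c = np.asarray(temperature_c, dtype=float)
    rate_per_min = np.asarray(rate_per_min, dtype=float)
    if np.any(temperature_c <= -273.15):
        raise ValueError("temperature at or below absolute zero")
    if np.any(rate_per_min <= 0):
        raise ValueError("rates must be positive to take logarithms")
    return 1.0 / celsius_to_kelvin(temperature_c), np.log(rate_per_min)


def from_arrhenius_coords(x_inv_K, ln_rate):
    """Inverse of :func:`to_arrhenius_coords`."""
    x_inv_K = np.asarray(x_inv_K, dtype=float)
    return 1.0 / x_inv_K - 273.15, np.exp(np.asarray(ln_rate, dtype=float))


def _as_temperature_vector(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ValueError("X must be a single temperature column")
        X = X[:, 0]
    elif X.ndim != 1:
        raise ValueError("X must be 1-D temperatures or an (n, 1) column")
    return X


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class ArrheniusParams:
    """Parameters of a single Arrhenius reaction (Ea kJ/mol, A min^-1)."""

    Ea_kJ_per_mol: float
    lnA: float

    def rate_per_min(self, temperature_c):
        """k(T) = exp(lnA - Ea*1000 / (R T_K))."""
        T = celsius_to_kelvin(np.asarray(temperature_c, dtype=float))
        return np.exp(self.lnA - self.Ea_kJ_per_mol * 1000.0 / (R_J_PER_MOL_K * T))


@dataclass(frozen=True)
class ArrheniusLinearFit:
    """Straight-line fit in Arrhenius coordinates with apparent Ea and 68% CI."""

    slope_K: float
    intercept: float
    Ea_kJ_per_mol: float
    se_Ea_kJ_per_mol: float | None
    ci68_Ea_kJ_per_mol: float | None
    core_range_C: tuple[float, float] | None
    n: int
    rss: float
    dof: int
    start_code: str | None = None
    end_code: str | None = None

    @property
    def params(self) -> ArrheniusParams:
        return ArrheniusParams(Ea_kJ_per_mol=self.Ea_kJ_per_mol, lnA=self.intercept)


@dataclass(frozen=True)
class QuadraticFit:
    """Quadratic fit ln k = c2 x^2 + c1 x + c0 in x = 1/T (K^-1)."""

    c2: float
    c1: float
    c0: float
    n: int
    rss: float

    @property
    def concavity(self) -> str:
        if self.c2 < 0:
            return "downward"
        return "upward" if self.c2 > 0 else "flat"


@dataclass(frozen=True)
class ModelComparison:
    """Penalized-likelihood (BIC) comparison of linear vs quadratic models.

    ``log_ratio`` is Lambda = (BIC_linear - BIC_quadratic) / 2, the natural
    log ratio of penalized likelihoods for quadratic over linear; positive
    values prefer the quadratic.
    """

    bic_linear: float
    bic_quadratic: float
    log_ratio: float
    n: int

    @property
    def preferred(self) -> str:
        return "quadratic" if self.log_ratio > 0 else "linear"


@dataclass(frozen=True)
class SlopeComparison:
    """ANCOVA F-test of a common slope between two regressions."""

    F: float
    p: float
    power: float
    df_num: int
    df_den: int
    slope_diff_K: float


# ---------------------------------------------------------------------------
# estimators

class ArrheniusLinearRegression(RegressorMixin, BaseEstimator):
    """Ordinary least-squares line in Arrhenius coordinates.

    Parameters
    ----------
    core_range_C : tuple of float, optional
        Closed temperature range (degC); points outside are excluded from
        the fit.  ``None`` fits all points.

    Attributes
    ----------
    slope_ : float
        Slope in Kelvin (coefficient of x = 1/T).
    intercept_ : float
        ln A, with A in min^-1.
    Ea_ : float
        Apparent activation energy, ``-slope_ * R / 1000`` kJ/mol.
    se_Ea_ : float or nan
        Standard error of ``Ea_`` (nan when dof == 0).
    ci68_Ea_ : float or nan
        Half-width of the 68% confidence interval on ``Ea_``, using the
        Student-t quantile at the fit's residual degrees of freedom.
    n_, rss_, dof_ : fit size, residual sum of squares, residual dof.
    """

    def __init__(self, core_range_C=None):
        self.core_range_C = core_range_C

    def fit(self, X, y):
        """Fit to temperatures ``X`` (degC) and rates ``y`` (min^-1)."""
        T = _as_temperature_vector(X)
        rate = np.asarray(y, dtype=float)
        if T.shape != rate.shape:
            raise ValueError("temperature and rate arrays differ in length")
        if self.core_range_C is not None:
            lo, hi = self.core_range_C
            mask = (T >= lo) & (T <= hi)
            T, rate = T[mask], rate[mask]
        x, ln_rate = to_arrhenius_coords(T, rate)
        n = x.size
        if n < 2:
            raise ValueError(f"need at least 2 points in range, got {n}")
        if np.ptp(x) == 0:
            raise ValueError("zero variance in 1/T; cannot fit a slope")
        design = np.column_stack([x, np.ones(n)])
        coef, _, _, _ = np.linalg.lstsq(design, ln_rate, rcond=None)
        resid = ln_rate - design @ coef
        rss = float(resid @ resid)
        dof = n - 2
        self.slope_ = float(coef[0])
        self.intercept_ = float(coef[1])
        self.Ea_ = -self.slope_ * R_J_PER_MOL_K / 1000.0
        if dof > 0:
            sxx = float(np.sum((x - x.mean()) ** 2))
            se_slope = math.sqrt(rss / dof / sxx)
            self.se_Ea_ = se_slope * R_J_PER_MOL_K / 1000.0
            # two-sided 68% interval -> upper-tail quantile at 0.84
            self.ci68_Ea_ = float(stats.t.ppf(0.84, dof)) * self.se_Ea_
        else:
            self.se_Ea_ = math.nan
            self.ci68_Ea_ = math.nan
        self.n_ = n
        self.rss_ = rss
        self.dof_ = dof
        return self

    def predict(self, X):
        """Predict rates (min^-1) at temperatures ``X`` (degC)."""
        check_is_fitted(self, "slope_")
        T = _as_temperature_vector(X)
        x = 1.0 / celsius_to_kelvin(T)
        return np.exp(self.slope_ * x + self.intercept_)

    def predict_ln_rate(self, temperature_c):
        check_is_fitted(self, "slope_")
        x = 1.0 / celsius_to_kelvin(np.asarray(temperature_c, dtype=float))
        return self.slope_ * x + self.intercept_

    def result(self, start_code=None, end_code=None) -> ArrheniusLinearFit:
        """Freeze the fitted state into an :class:`ArrheniusLinearFit`."""
        check_is_fitted(self, "slope_")
        return ArrheniusLinearFit(
            slope_K=self.slope_,
            intercept=self.intercept_,
            Ea_kJ_per_mol=self.Ea_,
            se_Ea_kJ_per_mol=None if math.isnan(self.se_Ea_) else self.se_Ea_,
            ci68_Ea_kJ_per_mol=None if math.isnan(self.ci68_Ea_) else self.ci68_Ea_,
            core_range_C=self.core_range_C,
            n=self.n_,
            rss=self.rss_,
            dof=self.dof_,
            start_code=start_code,
            end_code=end_code,
        )


class ArrheniusQuadraticRegression(RegressorMixin, BaseEstimator):
    """Least-squares parabola ln k = c2 x^2 + c1 x + c0 in x = 1/T.

    By default the quadratic is fit over *all* temperatures; pass
    ``range_C`` to restrict (e.g. to the viable regime).

    Attributes
    ----------
    coef_ : ndarray (c2, c1, c0)
    concavity_ : {"downward", "upward", "flat"}
    n_, rss_ : fit size and residual sum of squares.
    """

    def __init__(self, range_C=None):
        self.range_C = range_C

    def fit(self, X, y):
        T = _as_temperature_vector(X)
        rate = np.asarray(y, dtype=float)
        if self.range_C is not None:
            lo, hi = self.range_C
            mask = (T >= lo) & (T <= hi)
            T, rate = T[mask], rate[mask]
        x, ln_rate = to_arrhenius_coords(T, rate)
        n = x.size
        if n < 4:
            raise ValueError(f"need at least 4 points for a quadratic fit, got {n}")
        if np.unique(x).size < 3:
            raise ValueError("rank-deficient design: fewer than 3 distinct 1/T values")
        # centre/scale x for conditioning; map coefficients back afterwards
        mu, sd = x.mean(), x.std()
        z = (x - mu) / sd
        design = np.column_stack([z**2, z, np.ones(n)])
        coef_z, _, _, _ = np.linalg.lstsq(design, ln_rate, rcond=None)
        resid = ln_rate - design @ coef_z
        a2, a1, a0 = coef_z
        c2 = a2 / sd**2
        c1 = a1 / sd - 2 * a2 * mu / sd**2
        c0 = a0 - a1 * mu / sd + a2 * mu**2 / sd**2
        self.coef_ = np.array([c2, c1, c0])
        self.rss_ = float(resid @ resid)
        self.n_ = n
        self.concavity_ = "downward" if c2 < 0 else ("upward" if c2 > 0 else "flat")
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        T = _as_temperature_vector(X)
        x = 1.0 / celsius_to_kelvin(T)
        return np.exp(np.polyval(self.coef_, x))

    def result(self) -> QuadraticFit:
        check_is_fitted(self, "coef_")
        c2, c1, c0 = self.coef_
        return QuadraticFit(c2=float(c2), c1=float(c1), c0=float(c0),
                            n=self.n_, rss=self.rss_)


# ---------------------------------------------------------------------------
# functional wrappers

def fit_linear(temperature_c, rate_per_min, core_range_C=None,
               start_code=None, end_code=None) -> ArrheniusLinearFit:
    """OLS Arrhenius line over the core range; see ArrheniusLinearRegression."""
    est = ArrheniusLinearRegression(core_range_C=core_range_C)
    est.fit(temperature_c, rate_per_min)
    return est.result(start_code=start_code, end_code=end_code)


def fit_interval(observations, core_range_C=None) -> ArrheniusLinearFit:
    """Fit one interval's observations (one point per embryo)."""
    T = [o.temperature_C for o in observations]
    r = [o.rate_per_min for o in observations]
    codes = {(o.start_code, o.end_code) for o in observations}
    if len(codes) != 1:
        raise ValueError("observations span multiple intervals")
    (start, end), = codes
    return fit_linear(T, r, core_range_C=core_range_C,
                      start_code=start, end_code=end)


def fit_quadratic(temperature_c, rate_per_min, range_C=None) -> QuadraticFit:
    """Least-squares quadratic in Arrhenius coordinates (all temperatures)."""
    est = ArrheniusQuadraticRegression(range_C=range_C)
    est.fit(temperature_c, rate_per_min)
    return est.result()


# ---------------------------------------------------------------------------
# BIC model selection

def _rss_floor(ln_rate: np.ndarray) -> float:
    """Threshold below which a residual sum of squares is numerically zero."""
    scale = max(1.0, float(np.max(np.abs(ln_rate))))
    return ln_rate.size * (1e-12 * scale) ** 2


def bic_compare(temperature_c, rate_per_min, range_C=None) -> ModelComparison:
    """Gaussian-BIC comparison of linear vs quadratic Arrhenius-plot models.

    BIC_m = n ln(RSS_m / n) + k_m ln n with the variance profiled out and
    k = 2 (line) or 3 (parabola).  Lambda = (BIC_lin - BIC_quad)/2 > 0
    prefers the quadratic.  Degenerate residuals follow limiting rules:
    both RSS zero -> the penalty decides (Lambda = -ln(n)/2, linear);
    only the quadratic RSS zero -> Lambda capped at +LAMBDA_CAP.
    """
    T = _as_temperature_vector(temperature_c)
    rate = np.asarray(rate_per_min, dtype=float)
    if range_C is not None:
        lo, hi = range_C
        mask = (T >= lo) & (T <= hi)
        T, rate = T[mask], rate[mask]
    n = T.size
    if n < 5:
        raise ValueError(f"need at least 5 points for model selection, got {n}")
    lin = ArrheniusLinearRegression().fit(T, rate)
    quad = ArrheniusQuadraticRegression().fit(T, rate)
    _, ln_rate = to_arrhenius_coords(T, rate)
    floor = _rss_floor(ln_rate)
    rss_lin = 0.0 if lin.rss_ <= floor else lin.rss_
    rss_quad = 0.0 if quad.rss_ <= floor else quad.rss_
    logn = math.log(n)
    if rss_lin == 0.0:  # both models interpolate; penalty decides
        lam = -logn / 2.0
        bic_lin = 2 * logn
        bic_quad = 3 * logn
    elif rss_quad == 0.0:
        lam = LAMBDA_CAP
        bic_lin = n * math.log(rss_lin / n) + 2 * logn
        bic_quad = -math.inf
    else:
        bic_lin = n * math.log(rss_lin / n) + 2 * logn
        bic_quad = n * math.log(rss_quad / n) + 3 * logn
        lam = (bic_lin - bic_quad) / 2.0
        lam = min(lam, LAMBDA_CAP)
    return ModelComparison(bic_linear=bic_lin, bic_quadratic=bic_quad,
                           log_ratio=lam, n=n)


# ---------------------------------------------------------------------------
# ANCOVA slope comparison

def _ols_rss(design: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


def compare_slopes_ancova(
    temperature_A, rate_A, temperature_B, rate_B,
    core_range_C=None, alpha: float = 0.05,
) -> SlopeComparison:
    """F-test of whether two Arrhenius regressions share a common slope.

    The full model has separate slopes and intercepts per group; the
    reduced model shares the slope (group-specific intercepts).  The test
    of the group-by-x interaction has (1, n-4) degrees of freedom.
    Post-hoc power at level ``alpha`` uses the noncentral F distribution
    with noncentrality lambda = F_observed * df_num, the standard
    observed-power convention.
    """
    def prep(temp, rate):
        T = _as_temperature_vector(temp)
        r = np.asarray(rate, dtype=float)
        if core_range_C is not None:
            lo, hi = core_range_C
            mask = (T >= lo) & (T <= hi)
            T, r = T[mask], r[mask]
        return to_arrhenius_coords(T, r)

    xA, yA = prep(temperature_A, rate_A)
    xB, yB = prep(temperature_B, rate_B)
    if xA.size < 3 or xB.size < 3:
        raise ValueError("each group needs at least 3 points in the core range")
    x = np.concatenate([xA, xB])
    y = np.concatenate([yA, yB])
    g = np.concatenate([np.zeros(xA.size), np.ones(xB.size)])
    n = x.size
    full = np.column_stack([np.ones(n), x, g, x * g])
    reduced = full[:, :3]
    if np.linalg.matrix_rank(full) < 4:
        raise ValueError("singular ANCOVA design")
    rss_full = _ols_rss(full, y)
    rss_reduced = _ols_rss(reduced, y)
    df_den = n - 4
    if rss_full <= 0:
        F = math.inf if rss_reduced > rss_full else 0.0
    else:
        F = max(0.0, (rss_reduced - rss_full) / (rss_full / df_den))
    p = float(stats.f.sf(F, 1, df_den)) if math.isfinite(F) else 0.0
    crit = float(stats.f.ppf(1 - alpha, 1, df_den))
    nc = F * 1.0
    power = float(stats.ncf.sf(crit, 1, df_den, nc)) if math.isfinite(F) else 1.0
    # slope difference from per-group OLS
    slope = lambda xx, yy: float(np.polyfit(xx, yy, 1)[0])
    return SlopeComparison(
        F=F, p=p, power=min(1.0, power), df_num=1, df_den=df_den,
        slope_diff_K=slope(xA, yA) - slope(xB, yB),
    )


# ---------------------------------------------------------------------------
# enzyme traces and allometry

def rate_from_absorbance(time_min, absorbance, window_min) -> float:
    """Initial-rate slope (AU/min) of an absorbance trace within a window.

    Least-squares slope of absorbance vs time over the closed window
    ``[window_min[0], window_min[1]]``; requires at least 3 samples inside.
    """
    t = np.asarray(time_min, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    lo, hi = window_min
    mask = (t >= lo) & (t <= hi)
    if mask.sum() == 0:
        raise ValueError(f"no samples inside window [{lo}, {hi}] min")
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 samples inside window, got {int(mask.sum())}")
    return float(np.polyfit(t[mask], a[mask], 1)[0])


def allometric_time_ratio(mass_1_ug: float, mass_2_ug: float) -> float:
    """Quarter-power mass-scaling prediction of a developmental time ratio.

    Developmental rates are predicted to scale inversely with the quarter
    power of embryonic mass, so the time ratio is (m1/m2)^(1/4).
    """
    if mass_1_ug <= 0 or mass_2_ug <= 0:
        raise ValueError("masses must be positive")
    return (mass_1_ug / mass_2_ug) ** 0.25


def duration_ratio(duration_1: float, duration_2: float) -> float:
    """Ratio of two interval durations (same units)."""
    if duration_2 == 0:
        raise ValueError("zero denominator duration")
    return duration_1 / duration_2
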