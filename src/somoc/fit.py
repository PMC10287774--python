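"""Regression fitting of SOM-to-OC conversion equations.

Three functional forms are supported: linear (OC = m*SOM + b), quadratic
(OC = a2*SOM^2 + a1*SOM + a0, optionally through the origin) and power
(OC = a*SOM^p).  Linear and quadratic fits are ordinary least squares with
coefficient standard errors; the power form is nonlinear least squares
initialized from a log-log OLS fit.  R^2 is always computed as 1 - SSE/SST on
the original (untransformed) scale so that linear, quadratic and power fits
are directly comparable.

The core is the scikit-learn style estimator :class:`ConversionCurve`;
the module-level functions (:func:`fit_linear` etc.) are thin wrappers that
return a :class:`FitResult`.  A second estimator use fits the cross-regional
power curve of conversion slope against regional mean SOM
(:func:`fit_slope_vs_mean_som`), the fallback rule for predicting a regional
slope when no regional data exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from somoc.registry import ConversionEquation, Form, ScopeLevel

__all__ = [
    "FitResult",
    "ConversionCurve",
    "fit_linear",
    "fit_quadratic",
    "fit_power_oc",
    "fit_slope_vs_mean_som",
    "predict_slope",
    "predict_slope_band",
    "summarize_regions",
    "RegionSummary",
]

_MAX_NLS_ITER = 200
_NLS_TOL = 1e-8


@dataclass(frozen=True)
class FitResult:
    """Fitted conversion-equation coefficients with uncertainties.

    ``coefficients`` / ``coefficient_se`` use the same slot names as
    :class:`~somoc.registry.ConversionEquation` (linear ``m``/``b``,
    quadratic ``a2``/``a1``/``a0``, power ``a``/``p``).  ``converged`` is
    meaningful for the power form only (True for the closed-form OLS fits).
    """

    form: Form
    coefficients: dict
    coefficient_se: dict
    r_squared: float
    n: int
    residuals: np.ndarray = field(repr=False)
    converged: bool = True

    def to_equation(
        self,
        eq_id: str,
        scope_level: str = ScopeLevel.REGION,
        scope_key: str = "",
        som_validity_range=None,
        provenance: str = "fitted",
    ) -> ConversionEquation:
        """Package the fit as a registrable conversion equation."""
        return ConversionEquation(
            id=eq_id,
            scope_level=scope_level,
            scope_key=scope_key,
            form=self.form,
            coefficients=dict(self.coefficients),
            coefficient_se=dict(self.coefficient_se),
            r_squared=max(0.0, min(1.0, self.r_squared)),
            n=self.n,
            som_validity_range=som_validity_range,
            provenance=provenance,
        )


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr.ravel()
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 1.0 if sse == 0.0 else 0.0
    return 1.0 - sse / sst


class ConversionCurve(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator for a single SOM-to-OC conversion equation.

    Parameters
    ----------
    form : {"linear", "quadratic", "power"}
        Functional form to fit.
    force_zero_intercept : bool
        Quadratic form only: drop the intercept column, as in the published
        zero-intercept saltmarsh quadratic.

    Attributes (after ``fit``)
    --------------------------
    coefficients_ : dict
        Slot-named coefficients on the percent scale.
    coefficient_se_ : dict
        One-standard-error uncertainties.
    r_squared_ : float
        1 - SSE/SST on the original scale.
    residuals_ : ndarray
        Observed minus fitted OC.
    n_ : int
    converged_ : bool
        Power form: whether the nonlinear solver converged (the log-log
        estimate is used, with a warning, when it did not).
    result_ : FitResult
    """

    def __init__(self, form: str = "linear", force_zero_intercept: bool = False):
        self.form = form
        self.force_zero_intercept = force_zero_intercept

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        som = _as_1d(X, "som")
        oc = _as_1d(y, "oc")
        if som.size != oc.size:
            raise ValueError("som and oc must have equal length")
        form = Form(self.form)
        if form is Form.LINEAR:
            result = self._fit_linear(som, oc)
        elif form is Form.QUADRATIC:
            result = self._fit_quadratic(som, oc, self.force_zero_intercept)
        else:
            result = self._fit_power(som, oc)
        self.result_ = result
        self.coefficients_ = result.coefficients
        self.coefficient_se_ = result.coefficient_se
        self.r_squared_ = result.r_squared
        self.residuals_ = result.residuals
        self.n_ = result.n
        self.converged_ = result.converged
        return self

    @staticmethod
    def _fit_linear(som: np.ndarray, oc: np.ndarray) -> FitResult:
        if som.size < 3:
            raise ValueError("linear fit requires n >= 3")
        if np.ptp(som) == 0.0:
            raise ValueError("som has zero variance; slope is not identifiable")
        X = sm.add_constant(som)
        res = sm.OLS(oc, X).fit()
        b, m = res.params
        se_b, se_m = res.bse
        fitted = m * som + b
        return FitResult(
            form=Form.LINEAR,
            coefficients={"m": float(m), "b": float(b)},
            coefficient_se={"m": float(se_m), "b": float(se_b)},
            r_squared=_r_squared(oc, fitted),
            n=int(som.size),
            residuals=oc - fitted,
        )

    @staticmethod
    def _fit_quadratic(som: np.ndarray, oc: np.ndarray, zero_intercept: bool) -> FitResult:
        min_n = 3 if zero_intercept else 4
        if som.size < min_n:
            raise ValueError(f"quadratic fit requires n >= {min_n}")
        cols = [som**2, som] if zero_intercept else [som**2, som, np.ones_like(som)]
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear design; quadratic fit is not identifiable")
        res = sm.OLS(oc, X).fit()
        names = ["a2", "a1"] if zero_intercept else ["a2", "a1", "a0"]
        coeffs = {k: float(v) for k, v in zip(names, res.params)}
        ses = {k: float(v) for k, v in zip(names, res.bse)}
        fitted = X @ res.params
        return FitResult(
            form=Form.QUADRATIC,
            coefficients=coeffs,
            coefficient_se=ses,
            r_squared=max(0.0, _r_squared(oc, fitted)),
            n=int(som.size),
            residuals=oc - fitted,
        )

    @staticmethod
    def _fit_power(som: np.ndarray, oc: np.ndarray) -> FitResult:
        if som.size < 3:
            raise ValueError("power fit requires n >= 3")
        if np.any(som <= 0) or np.any(oc <= 0):
            raise ValueError("power fit requires strictly positive som and oc")
        if np.ptp(som) == 0.0:
            raise ValueError("som has zero variance; exponent is not identifiable")
        # Log-log OLS gives the starting point: log oc = log a + p log som.
        logX = sm.add_constant(np.log(som))
        ols = sm.OLS(np.log(oc), logX).fit()
        a0, p0 = float(np.exp(ols.params[0])), float(ols.params[1])

        def model(s, a, p):
            return a * s**p

        converged = True
        try:
            popt, pcov = curve_fit(
                model, som, oc, p0=[a0, p0],
                maxfev=_MAX_NLS_ITER * 10, xtol=_NLS_TOL, ftol=_NLS_TOL,
            )
            a, p = float(popt[0]), float(popt[1])
            perr = np.sqrt(np.diag(pcov))
            se = {"a": float(perr[0]), "p": float(perr[1])}
        except RuntimeError:
            warnings.warn(
                "power fit did not converge; falling back to the log-log estimate"
            )
            converged = False
            a, p = a0, p0
            # Delta-method SE for a = exp(intercept); exponent SE direct.
            se = {"a": float(a0 * ols.bse[0]), "p": float(ols.bse[1])}
        fitted = a * som**p
        return FitResult(
            form=Form.POWER,
            coefficients={"a": a, "p": p},
            coefficient_se=se,
            r_squared=max(0.0, _r_squared(oc, fitted)),
            n=int(som.size),
            residuals=oc - fitted,
            converged=converged,
        )

    # -- prediction --------------------------------------------------------

    def predict(self, X):
        check_is_fitted(self, "coefficients_")
        som = _as_1d(X, "som")
        c = self.coefficients_
        form = Form(self.form)
        if form is Form.LINEAR:
            return c["m"] * som + c["b"]
        if form is Form.QUADRATIC:
            return c["a2"] * som**2 + c["a1"] * som + c.get("a0", 0.0)
        return c["a"] * som ** c["p"]


# ---------------------------------------------------------------------------
# Functional wrappers

def fit_linear(som: Sequence[float], oc: Sequence[float]) -> FitResult:
    """Ordinary least squares fit of OC = m*SOM + b."""
    return ConversionCurve(form="linear").fit(som, oc).result_


def fit_quadratic(
    som: Sequence[float], oc: Sequence[float], force_zero_intercept: bool = False
) -> FitResult:
    """Least-squares fit of OC = a2*SOM^2 + a1*SOM (+ a0)."""
    est = ConversionCurve(form="quadratic", force_zero_intercept=force_zero_intercept)
    return est.fit(som, oc).result_


def fit_power_oc(som: Sequence[float], oc: Sequence[float]) -> FitResult:
    """Nonlinear least-squares fit of OC = a*SOM^p (log-log initialized)."""
    return ConversionCurve(form="power").fit(som, oc).result_


# ---------------------------------------------------------------------------
# Cross-regional slope curve

@dataclass(frozen=True)
class RegionSummary:
    """Per-region aggregates feeding the cross-regional analyses."""

    region: str
    mean_som: float
    n: int
    slope: float
    intercept: Optional[float] = None
    r_squared: Optional[float] = None
    se_som: Optional[float] = None
    ces: Optional[str] = None
    sedimentary: Optional[str] = None
    latitude: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_som < 100.0:
            raise ValueError("mean_som must lie in (0, 100)")


def summarize_regions(samples) -> list:
    """Per-region linear fits and aggregates from a (screened) sample table.

    Groups a sample DataFrame by ``region``, fits OC = m*SOM + b within each
    group, and returns one :class:`RegionSummary` per region with at least 3
    samples.  Carries along the region's CES/sedimentary labels and latitude
    when those columns are constant within the region.
    """
    import pandas as pd  # noqa: F401  # local: keep fit importable without pandas at top level

    out = []
    for region, grp in samples.dropna(subset=["oc", "som"]).groupby("region", sort=False):
        if len(grp) < 3:
            continue
        res = fit_linear(grp["som"].to_numpy(), grp["oc"].to_numpy())

        def _unique(col):
            if col not in grp.columns:
                return None
            vals = grp[col].dropna().unique()
            return vals[0] if len(vals) == 1 else None

        som = grp["som"].to_numpy(dtype=float)
        out.append(RegionSummary(
            region=str(region),
            mean_som=float(som.mean()),
            se_som=float(som.std(ddof=1) / np.sqrt(som.size)),
            n=res.n,
            slope=res.coefficients["m"],
            intercept=res.coefficients["b"],
            r_squared=res.r_squared,
            ces=_unique("ces"),
            sedimentary=_unique("sedimentary"),
            latitude=_unique("latitude"),
        ))
    return out


def fit_slope_vs_mean_som(summaries: Sequence[RegionSummary]) -> FitResult:
    """Power regression of regional conversion slope on regional mean SOM.

    slope = a * mean_som^p.  The curve rises sharply at low SOM and flattens
    toward high SOM; it predicts an appropriate zero-intercept conversion
    slope for a region where only mean SOM is known.
    """
    if len(summaries) < 3:
        raise ValueError("slope curve requires at least 3 regions")
    mean_som = np.array([s.mean_som for s in summaries], dtype=float)
    slope = np.array([s.slope for s in summaries], dtype=float)
    if np.ptp(mean_som) == 0.0:
        raise ValueError("mean_som has zero variance across regions")
    return ConversionCurve(form="power").fit(mean_som, slope).result_


def predict_slope(fit: FitResult, mean_som: float) -> float:
    """Predicted conversion slope at a regional mean SOM from the power curve.

    The predicted slope implies a zero-intercept conversion equation
    OC = slope * SOM; published regional intercepts are rarely exactly zero,
    so treat this as a rough guide in the absence of regional data.
    """
    if fit.form is not Form.POWER:
        raise ValueError("predict_slope expects a power-form fit")
    if mean_som <= 0:
        raise ValueError("mean_som must be positive")
    c = fit.coefficients
    return c["a"] * mean_som ** c["p"]


def predict_slope_band(fit: FitResult, mean_som: float):
    """(lower, upper) +/- 1 SE band around the slope-curve prediction.

    Delta-method propagation of the coefficient SEs (their covariance is not
    retained, so the band is approximate).
    """
    pred = predict_slope(fit, mean_som)
    a = fit.coefficients["a"]
    p = fit.coefficients["p"]
    se_a = fit.coefficient_se.get("a", 0.0)
    se_p = fit.coefficient_se.get("p", 0.0)
    d_a = mean_som**p
    d_p = a * mean_som**p * np.log(mean_som)
    se = float(np.sqrt((d_a * se_a) ** 2 + (d_p * se_p) ** 2))
    return pred - se, pred + se
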