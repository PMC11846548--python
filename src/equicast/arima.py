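"""ARIMA forecasting stage: differencing order, grid order search, forecasts.

The estimator itself is statsmodels' ``ARIMA`` (maximum likelihood);
this module is the deterministic construction protocol around it:

1. assess stationarity (KPSS by default, ADF as option) and pick the
   smallest differencing order ``d`` that achieves it;
2. exhaustive AICc grid search over (p, q) at that ``d`` — no stochastic
   or stepwise search, so selection is reproducible;
3. fit the chosen order and produce point forecasts with 95% intervals
   and a Ljung-Box residual summary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import adfuller, kpss

from .base import ForecastSeries
from .errors import DomainError, FitError, LengthError, SelectionError

logger = logging.getLogger(__name__)

_MAX_D = 2


@dataclass(frozen=True)
class ArimaOrder:
    """A (p, d, q) order triple."""

    p: int
    d: int
    q: int

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0 or self.d < 0:
            raise DomainError("orders must be non-negative")
        if self.d > _MAX_D:
            raise DomainError(f"d must be <= {_MAX_D}, got {self.d}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


@dataclass
class ArimaFit:
    """Fitted ARIMA model with the coefficient and diagnostic summary."""

    order: ArimaOrder
    trend: str
    ar_coefficients: np.ndarray
    ma_coefficients: np.ndarray
    intercept: float | None
    aicc: float
    ljung_box_pvalue: float | None
    results: object = field(repr=False)  # statsmodels ARIMAResults

    def conf_int(self, alpha: float = 0.05):
        """Coefficient confidence intervals, indexed by parameter name."""
        import pandas as pd

        ci = np.asarray(self.results.conf_int(alpha=alpha), dtype=float)
        return pd.DataFrame(
            ci, index=list(self.results.param_names), columns=["lower", "upper"]
        )


def _is_constant(x: np.ndarray) -> bool:
    scale = max(1.0, float(np.max(np.abs(x))) if x.size else 1.0)
    return bool(np.ptp(x) <= 1e-10 * scale) if x.size else True


def is_stationary(series, test: str = "kpss", alpha: float = 0.05) -> bool:
    """Level-stationarity check.

    KPSS (null = stationary): stationary iff p-value > alpha.
    ADF (null = unit root): stationary iff p-value < alpha.
    A numerically constant series is stationary by convention (both
    tests degenerate there).
    """
    x = np.asarray(series, dtype=float).ravel()
    if _is_constant(x):
        return True
    if test == "kpss":
        with warnings.catch_warnings():
            # p-values outside the lookup table are clamped; fine here
            warnings.simplefilter("ignore", InterpolationWarning)
            _, pvalue, *_ = kpss(x, regression="c", nlags="auto")
        return pvalue > alpha
    if test == "adf":
        _, pvalue, *_ = adfuller(x, autolag="AIC")
        return pvalue < alpha
    raise DomainError(f"unknown stationarity test {test!r}")


def select_difference_order(
    series, max_d: int = _MAX_D, test: str = "kpss", alpha: float = 0.05
) -> int:
    """Smallest d <= max_d whose d-th difference passes the stationarity test.

    If even the max_d-th difference fails, max_d is returned with a
    warning (reported, not fatal).

    Raises
    ------
    LengthError
        if the series has fewer than 10 observations.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 10:
        raise LengthError(f"need >= 10 observations, got {x.size}")
    for d in range(max_d + 1):
        if is_stationary(np.diff(x, n=d) if d else x, test=test, alpha=alpha):
            return d
    logger.warning(
        "series still non-stationary after %d difference(s); using d = %d",
        max_d, max_d,
    )
    return max_d


def _default_trend(d: int) -> str:
    # constant mean for level models; no deterministic term once differenced
    return "c" if d == 0 else "n"


def _fit_one(x: np.ndarray, order: tuple[int, int, int], trend: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ARIMA(x, order=order, trend=trend)
        return model.fit()


def auto_select_order(
    series,
    d: int,
    max_p: int = 5,
    max_q: int = 5,
    ic: str = "aicc",
    trend: str | None = None,
    root_tol: float = 1.01,
) -> ArimaOrder:
    """Exhaustive information-criterion grid search over (p, q) at fixed d.

    The candidate with the smallest criterion wins; ties are broken by
    smaller p + q, then smaller p.  Deterministic given the series and
    the grid.

    Candidates whose fitted AR or MA polynomial has a root of modulus
    below ``root_tol`` (default 1.01) are inadmissible: near-unit or
    near-common roots produce spuriously good likelihoods without
    forecasting value, so they are excluded from the ranking.

    Raises
    ------
    SelectionError
        if no candidate order can be fitted; the error carries the
        per-order failure messages.
    """
    x = np.asarray(series, dtype=float).ravel()
    if ic not in ("aicc", "aic", "bic"):
        raise DomainError(f"unknown information criterion {ic!r}")
    if trend is None:
        trend = _default_trend(d)
    scored: list[tuple[float, int, int]] = []
    failures: dict[tuple[int, int, int], str] = {}
    for p in range(max_p + 1):
        for q in range(max_q + 1):
            order = (p, d, q)
            try:
                res = _fit_one(x, order, trend)
                crit = float(getattr(res, ic))
                if not np.isfinite(crit):
                    raise FitError(f"{ic} is not finite")
                min_root = min(
                    (np.abs(res.arroots).min() if p else np.inf),
                    (np.abs(res.maroots).min() if q else np.inf),
                )
                if min_root < root_tol:
                    raise FitError(
                        f"inadmissible: root modulus {min_root:.4f} < {root_tol}"
                    )
                scored.append((crit, p, q))
            except Exception as exc:  # statsmodels raises a zoo of types
                failures[order] = f"{type(exc).__name__}: {exc}"
    if not scored:
        raise SelectionError(
            f"no ARIMA order converged on the grid p<= {max_p}, q <= {max_q}",
            failures={str(k): v for k, v in failures.items()},
        )
    scored.sort(key=lambda t: (t[0], t[1] + t[2], t[1]))
    _, p, q = scored[0]
    return ArimaOrder(p=p, d=d, q=q)


def fit_arima(series, order: ArimaOrder, trend: str | None = None) -> ArimaFit:
    """Maximum-likelihood fit of a given order; wraps statsmodels ARIMA."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size <= order.p + order.q + order.d + 1:
        raise LengthError(
            f"series of length {x.size} too short for order {order.as_tuple()}"
        )
    if trend is None:
        trend = _default_trend(order.d)
    try:
        res = _fit_one(x, order.as_tuple(), trend)
    except Exception as exc:
        raise FitError(f"ARIMA{order.as_tuple()} failed to fit: {exc}") from exc

    params = res.params
    names = list(res.param_names)
    ar = np.asarray([params[i] for i, s in enumerate(names) if s.startswith("ar.L")])
    ma = np.asarray([params[i] for i, s in enumerate(names) if s.startswith("ma.L")])
    intercept = None
    for cand in ("const", "intercept", "x1", "trend", "drift"):
        if cand in names:
            intercept = float(params[names.index(cand)])
            break

    lb_pvalue = None
    resid = np.asarray(res.resid, dtype=float)
    lags = min(10, max(1, x.size // 5))
    try:
        lb = acorr_ljungbox(resid, lags=[lags], model_df=order.p + order.q)
        lb_pvalue = float(lb["lb_pvalue"].iloc[0])
    except Exception:  # pragma: no cover - tiny-sample corner
        pass

    return ArimaFit(
        order=order,
        trend=trend,
        ar_coefficients=ar,
        ma_coefficients=ma,
        intercept=intercept,
        aicc=float(res.aicc),
        ljung_box_pvalue=lb_pvalue,
        results=res,
    )


def fit_and_forecast(
    series,
    order: ArimaOrder,
    horizon: int = 5,
    trend: str | None = None,
    alpha: float = 0.05,
) -> ForecastSeries:
    """Fit ``order`` and forecast ``horizon`` steps with 95% intervals.

    The returned series carries the fit summary (order, coefficients,
    AICc, Ljung-Box p-value) in ``meta["fit"]``.
    """
    horizon = int(horizon)
    if horizon < 1:
        raise DomainError(f"horizon must be >= 1, got {horizon}")
    fit = fit_arima(series, order, trend=trend)
    pred = fit.results.get_forecast(steps=horizon)
    mean = np.asarray(pred.predicted_mean, dtype=float)
    ci = np.asarray(pred.conf_int(alpha=alpha), dtype=float)
    n = len(np.asarray(series).ravel())
    return ForecastSeries(
        steps=np.arange(n + 1, n + horizon + 1),
        values=mean,
        lower=ci[:, 0],
        upper=ci[:, 1],
        label=f"ARIMA{order.as_tuple()}",
        meta={
            "fit": {
                "order": order.as_tuple(),
                "trend": fit.trend,
                "ar": fit.ar_coefficients.tolist(),
                "ma": fit.ma_coefficients.tolist(),
                "intercept": fit.intercept,
                "aicc": fit.aicc,
                "ljung_box_pvalue": fit.ljung_box_pvalue,
            }
        },
    )
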