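"""Forecast evaluation: MAE, RMSE, MAPE, Willmott's index of agreement,
and the Diebold–Mariano forecast-comparison test.

MAPE and WIA are dimensionless; MAE and RMSE carry the units of the
series (mg/L for dissolved oxygen). MAPE is reported as a proportion,
not multiplied by 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "MetricsReport",
    "DmResult",
    "mae",
    "rmse",
    "mape",
    "wia",
    "metrics_report",
    "dm_test",
]


def _paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: observed {o.shape}, predicted {p.shape}")
    if o.size == 0:
        raise ValueError("need at least one compared point")
    return o, p


def mae(observed, predicted) -> float:
    """Mean absolute error, mean |ŷ − y|."""
    o, p = _paired(observed, predicted)
    return float(np.mean(np.abs(p - o)))


def rmse(observed, predicted) -> float:
    """Root mean square error, sqrt(mean (ŷ − y)²)."""
    o, p = _paired(observed, predicted)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def mape(observed, predicted) -> float:
    """Mean absolute percentage error as a proportion, mean |(ŷ − y)/y|.

    Raises if any observed value is zero (the ratio is undefined there).
    """
    o, p = _paired(observed, predicted)
    if np.any(o == 0):
        raise ZeroDivisionError(
            "MAPE undefined: observed series contains zero values"
        )
    return float(np.mean(np.abs((p - o) / o)))


def wia(observed, predicted) -> float:
    """Willmott's index of agreement.

        WIA = 1 − Σ(O_i − P_i)² / Σ(|P_i − ō| + |O_i − ō|)²

    with ō the observed mean. 1 means the prediction matches the
    observations perfectly; 0 means no agreement. A constant observed
    series with predictions equal to it is defined as WIA = 1 (the
    perfect-match anchor; both sums are zero).
    """
    o, p = _paired(observed, predicted)
    if o.size < 2:
        raise ValueError("WIA needs at least 2 compared points")
    obar = o.mean()
    num = float(np.sum((o - p) ** 2))
    den = float(np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2))
    if den == 0.0:
        return 1.0  # predictions identical to a constant observed series
    # num <= den by the triangle inequality; clamp the floating residue
    return min(1.0, max(0.0, 1.0 - num / den))


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    rmse: float
    mape: float
    wia: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def metrics_report(observed, predicted) -> MetricsReport:
    """All four metrics for one prediction/observation pair of series."""
    o, p = _paired(observed, predicted)
    return MetricsReport(
        mae=mae(o, p), rmse=rmse(o, p), mape=mape(o, p), wia=wia(o, p), n=int(o.size)
    )


@dataclass(frozen=True)
class DmResult:
    statistic: float
    p_value: float
    loss: str
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def dm_test(
    errors_a,
    errors_b,
    loss: str = "absolute",
    observed=None,
    harvey_correction: bool = False,
) -> DmResult:
    """Diebold–Mariano test on the mean loss differential of two forecasts.

    ``errors_a`` and ``errors_b`` are the two models' forecast errors at
    the same time points. The loss differential is d_t = g(e_a,t) − g(e_b,t)
    with g the absolute error (``loss="absolute"``, DM-MAE) or the absolute
    percentage error (``loss="absolute_percentage"``, DM-MAPE; requires
    ``observed``). For one-step-ahead forecasts the long-run variance is
    the plain sample variance of d_t (truncation lag 0); the statistic
    d̄ / sqrt(s²_d / n) is referred to a standard normal, two-sided. With
    ``harvey_correction`` the Harvey–Leybourne–Newbold small-sample scaling
    is applied and a t(n−1) reference is used instead.

    A positive statistic means forecast A has the larger loss.
    """
    e_a = np.asarray(errors_a, dtype=float)
    e_b = np.asarray(errors_b, dtype=float)
    if e_a.shape != e_b.shape:
        raise ValueError("error series must have equal length")
    n = e_a.size
    if n < 10:
        raise ValueError(f"DM test needs n >= 10 error pairs, got {n}")
    if loss == "absolute":
        d = np.abs(e_a) - np.abs(e_b)
    elif loss == "absolute_percentage":
        if observed is None:
            raise ValueError("percentage loss requires the observed series")
        o = np.asarray(observed, dtype=float)
        if o.shape != e_a.shape:
            raise ValueError("observed series must match the error series length")
        if np.any(o == 0):
            raise ZeroDivisionError("percentage loss undefined: observed contains zeros")
        d = np.abs(e_a / o) - np.abs(e_b / o)
    else:
        raise ValueError(f"unknown loss {loss!r}; use 'absolute' or 'absolute_percentage'")

    dbar = float(d.mean())
    s2 = float(d.var(ddof=1))
    if s2 == 0.0:
        if dbar == 0.0:
            return DmResult(statistic=0.0, p_value=1.0, loss=loss, n=n)
        stat = math.inf if dbar > 0 else -math.inf
        return DmResult(statistic=stat, p_value=0.0, loss=loss, n=n)
    stat = dbar / math.sqrt(s2 / n)
    if harvey_correction:
        # h = 1: scaling sqrt((n + 1 - 2h + h(h-1)/n) / n) = sqrt((n-1)/n)
        stat *= math.sqrt((n - 1) / n)
        p = 2.0 * (1.0 - stats.t.cdf(abs(stat), df=n - 1))
    else:
        p = 2.0 * (1.0 - stats.norm.cdf(abs(stat)))
    return DmResult(statistic=float(stat), p_value=float(p), loss=loss, n=n)
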