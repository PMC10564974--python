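"""Classical early-warning indicators for a single record.

Near a local bifurcation the dominant eigenvalue's modulus approaches
1 (critical slowing down): fluctuations around the attractor recover
more slowly, so their variance rises, and lag-1 autocorrelation trends
up or down depending on the eigenvalue angle theta (up for
theta in [0, pi/2), down for theta in (pi/2, pi] — the period-doubling
case).  The indicators here are computed on residuals after detrending,
over a trailing rolling window, and their trend strength is summarised
by the Kendall tau rank correlation against time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter1d
from scipy.stats import kendalltau
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "DetrendSpec",
    "EwsSeries",
    "detrend",
    "rolling_variance",
    "rolling_ac1",
    "kendall_tau",
    "kendall_tau_series",
    "compute_ews",
]


@dataclass(frozen=True)
class DetrendSpec:
    """Detrending method: Lowess with ``span`` (fraction of the series
    length, default 0.25 — used for model runs) or a Gaussian kernel
    with ``bandwidth`` (kernel standard deviation in samples, default
    20 — used for interbeat-interval records)."""

    method: str = "lowess"
    span: float = 0.25
    bandwidth: float = 20.0

    def __post_init__(self) -> None:
        if self.method not in ("lowess", "gaussian"):
            raise ValueError("detrend method must be 'lowess' or 'gaussian'")
        if self.method == "lowess" and not 0 < self.span <= 1:
            raise ValueError("lowess span must be in (0, 1]")
        if self.method == "gaussian" and self.bandwidth < 1:
            raise ValueError("gaussian bandwidth must be >= 1 sample")


def detrend(series: np.ndarray, spec: DetrendSpec = DetrendSpec()):
    """Split a series into (trend, residuals = series - trend)."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 points to detrend")
    if spec.method == "lowess":
        if spec.span * n < 2:
            raise ValueError("lowess span covers fewer than 2 points")
        trend = _sm_lowess(x, np.arange(n), frac=spec.span, return_sorted=False)
    else:
        trend = gaussian_filter1d(x, sigma=spec.bandwidth, mode="nearest")
    return trend, x - trend


def _window_size(n: int, window_fraction: float) -> int:
    if not 0 < window_fraction <= 1:
        raise ValueError("window fraction must be in (0, 1]")
    return max(2, int(round(window_fraction * n)))


def rolling_variance(residuals: np.ndarray, window_fraction: float = 0.5) -> pd.Series:
    """Trailing-window variance (population convention, divide by n),
    indexed by the window's right edge."""
    x = np.asarray(residuals, dtype=float)
    w = _window_size(len(x), window_fraction)
    if w > len(x):
        import warnings

        warnings.warn("rolling window longer than the series; empty output")
        return pd.Series(dtype=float)
    wins = sliding_window_view(x, w)
    return pd.Series(wins.var(axis=1), index=np.arange(w - 1, len(x)))


def rolling_ac1(residuals: np.ndarray, window_fraction: float = 0.5) -> pd.Series:
    """Trailing-window lag-1 autocorrelation (Pearson correlation of the
    window against itself shifted by one), indexed by the right edge.
    Zero-variance windows yield NaN."""
    x = np.asarray(residuals, dtype=float)
    w = max(3, _window_size(len(x), window_fraction))
    if w > len(x):
        import warnings

        warnings.warn("rolling window longer than the series; empty output")
        return pd.Series(dtype=float)
    wins = sliding_window_view(x, w)
    a, b = wins[:, :-1], wins[:, 1:]
    am = a - a.mean(axis=1, keepdims=True)
    bm = b - b.mean(axis=1, keepdims=True)
    num = (am * bm).sum(axis=1)
    den = np.sqrt((am**2).sum(axis=1) * (bm**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        ac = np.where(den > 0, num / den, np.nan)
    return pd.Series(ac, index=np.arange(w - 1, len(x)))


def kendall_tau(indicator: np.ndarray) -> float:
    """Tie-corrected Kendall rank correlation of an indicator series
    against time.  All-equal input returns 0 by convention."""
    y = np.asarray(indicator, dtype=float)
    y = y[np.isfinite(y)]
    if len(y) < 2:
        raise ValueError("need at least 2 points for a trend statistic")
    tau = kendalltau(np.arange(len(y)), y).statistic
    return 0.0 if np.isnan(tau) else float(tau)


def kendall_tau_series(indicator: pd.Series, min_points: int = 2) -> pd.Series:
    """Kendall tau of the full indicator history up to each time point."""
    vals = indicator.to_numpy()
    out = np.full(len(vals), np.nan)
    for i in range(min_points - 1, len(vals)):
        out[i] = kendall_tau(vals[: i + 1])
    return pd.Series(out, index=indicator.index)


@dataclass
class EwsSeries:
    """Residuals, rolling indicators and their trend statistics for one
    record.  Indicator series are indexed from the first full window."""

    residuals: np.ndarray
    trend: np.ndarray
    variance: pd.Series
    ac1: pd.Series
    window_fraction: float
    detrend_spec: DetrendSpec
    _tau_var: Optional[pd.Series] = field(default=None, repr=False)
    _tau_ac1: Optional[pd.Series] = field(default=None, repr=False)

    @property
    def tau_variance(self) -> float:
        """Kendall tau of the variance series over its full history."""
        return kendall_tau(self.variance.to_numpy())

    @property
    def tau_ac1(self) -> float:
        return kendall_tau(self.ac1.to_numpy())

    def tau_variance_series(self) -> pd.Series:
        if self._tau_var is None:
            self._tau_var = kendall_tau_series(self.variance)
        return self._tau_var

    def tau_ac1_series(self) -> pd.Series:
        if self._tau_ac1 is None:
            self._tau_ac1 = kendall_tau_series(self.ac1)
        return self._tau_ac1

    def to_frame(self) -> pd.DataFrame:
        n = len(self.residuals)
        df = pd.DataFrame({"t": np.arange(n), "residual": self.residuals, "trend": self.trend})
        df["variance"] = df["t"].map(self.variance)
        df["ac1"] = df["t"].map(self.ac1)
        df["tau_variance"] = df["t"].map(self.tau_variance_series())
        df["tau_ac1"] = df["t"].map(self.tau_ac1_series())
        return df


def compute_ews(
    series: np.ndarray,
    detrend_spec: DetrendSpec = DetrendSpec(),
    window_fraction: float = 0.5,
) -> EwsSeries:
    """Detrend a (pre-transition) record and compute rolling variance
    and lag-1 autocorrelation with their Kendall tau trends."""
    trend, resid = detrend(series, detrend_spec)
    return EwsSeries(
        residuals=resid,
        trend=trend,
        variance=rolling_variance(resid, window_fraction),
        ac1=rolling_ac1(resid, window_fraction),
        window_fraction=window_fraction,
        detrend_spec=detrend_spec,
    )
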