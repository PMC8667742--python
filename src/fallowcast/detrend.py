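"""Trend / meteorological yield separation.

Measured yield decomposes as y = y_t + y_c (+ e): a slowly varying trend
component y_t attributed to technology, and a weather-driven fluctuation y_c.
The trend is a centered 3-year moving average of the annual per-tillage mean
yield (endpoints use the mean of the years available in the window, so every
year receives a trend value); the error term is absorbed into y_c.  The
relative meteorological yield y_w = y_c / y_t is scale-free and comparable
across technology levels.  A polynomial fit of the trend series (default
cubic) is kept for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class TrendFit:
    tillage: str | None
    degree: int
    coefficients: np.ndarray  # ascending powers of the year index
    r_squared: float


def moving_average_trend(values, window: int = 3) -> np.ndarray:
    """Centered moving average with shrunk windows at the ends.

    Interior years average the full window; the first/last years average
    whatever part of the window exists, so the trend series has the same
    length as the input.
    """
    v = np.asarray(values, dtype=float)
    if window < 1:
        raise ValidationError("window must be >= 1")
    if v.size < window:
        raise ValidationError(f"series length {v.size} < window {window}")
    return pd.Series(v).rolling(window=window, center=True, min_periods=1).mean().to_numpy()


def fit_trend_polynomial(trend, degree: int = 3, tillage: str | None = None) -> TrendFit:
    """Least-squares polynomial (in the 0-based year index) through a trend series."""
    y = np.asarray(trend, dtype=float)
    if degree < 1:
        raise ValidationError("polynomial degree must be >= 1")
    if y.size <= degree:
        raise ValidationError(f"series length {y.size} must exceed degree {degree}")
    t = np.arange(y.size, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(t, y, degree)
    fitted = np.polynomial.polynomial.polyval(t, coeffs)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return TrendFit(tillage=tillage, degree=degree, coefficients=coeffs, r_squared=r2)


def decompose(y, y_t) -> pd.DataFrame:
    """Split measured yield into meteorological and relative meteorological parts.

    y_c = y − y_t and y_w = (y − y_t)/y_t; reconstruction y_t + y_c = y is
    exact by construction.
    """
    y = np.asarray(y, dtype=float)
    yt = np.asarray(y_t, dtype=float)
    if y.shape != yt.shape:
        raise ValidationError("y and y_t must be aligned")
    if np.any(yt <= 0):
        raise ValidationError("trend yield must be positive")
    yc = y - yt
    return pd.DataFrame({"y": y, "y_t": yt, "y_c": yc, "y_w": yc / yt})


def decompose_yields(
    observations: pd.DataFrame, window: int = 3, degree: int = 3
) -> tuple[pd.DataFrame, list[TrendFit]]:
    """Per-plot decomposition using a per-tillage annual-mean trend.

    The trend is computed on each tillage's annual mean yield and assigned to
    every plot of that (year, tillage); plots then decompose against it.
    Returns the observation frame with y_t, y_c, y_w columns added, plus the
    reporting polynomial fits (one per tillage).
    """
    obs = observations.sort_values(["tillage", "year"]).reset_index(drop=True)
    fits: list[TrendFit] = []
    trend_map = {}
    for tillage, grp in obs.groupby("tillage"):
        annual = grp.groupby("year")["yield"].mean()
        trend = moving_average_trend(annual.to_numpy(), window=window)
        fits.append(fit_trend_polynomial(trend, degree=degree, tillage=str(tillage)))
        for year, t in zip(annual.index, trend):
            trend_map[(tillage, year)] = t
    obs["y_t"] = [trend_map[(t, y)] for t, y in zip(obs["tillage"], obs["year"])]
    obs["y_c"] = obs["yield"] - obs["y_t"]
    obs["y_w"] = obs["y_c"] / obs["y_t"]
    return obs, fits
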