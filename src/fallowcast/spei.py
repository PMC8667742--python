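"""Standardized Precipitation Evapotranspiration Index at a monthly scale.

The index standardizes the climatic water balance D = P − PET.  PET is
Thornthwaite's monthly estimate, driven only by mean temperature and an
annual heat index.  The k-month balance (default k = 3, covering the
July–September fallow window when evaluated at September) is fitted, per
calendar month across years, with a three-parameter log-logistic
distribution estimated by unbiased probability-weighted moments, and mapped
to a standard normal deviate through the Abramowitz–Stegun rational
approximation.  A cultivation year is labelled *drought* when its September
SPEI-3 is at or below −0.5, and *normal* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import gamma as _gamma_fn

import numpy as np
import pandas as pd

from .errors import FitError, ValidationError

# Abramowitz & Stegun 26.2.23 rational-approximation constants
C0, C1, C2 = 2.515517, 0.802853, 0.010328
D1, D2, D3 = 1.432788, 0.189269, 0.001308

DROUGHT_THRESHOLD = -0.5
PROB_EPS = 1e-6


@dataclass(frozen=True)
class ThornthwaiteParams:
    """Annual heat index H and the derived exponent A of the PET formula."""

    heat_index: float
    exponent: float

    def __post_init__(self):
        if self.heat_index <= 0:
            raise ValidationError("heat index must be positive")
        if self.exponent <= 0:
            raise ValidationError("Thornthwaite exponent must be positive")


@dataclass(frozen=True)
class LogLogisticParams:
    """Three-parameter log-logistic: scale alpha (mm), shape beta, origin gamma (mm)."""

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError("log-logistic requires alpha > 0 and beta > 0")

    def cdf(self, x):
        """F(x) = [1 + (alpha/(x - gamma))^beta]^-1 on x > gamma, 0 below."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        sup = x > self.gamma
        out[sup] = 1.0 / (1.0 + (self.alpha / (x[sup] - self.gamma)) ** self.beta)
        return out if out.ndim else float(out)


def heat_index(monthly_t_mean) -> ThornthwaiteParams:
    """Annual heat index from 12 monthly mean temperatures (°C).

    H = Σ (T/5)^1.514 over months with T > 0;
    A = 6.75e-7 H³ − 7.71e-5 H² + 1.792e-2 H + 0.49239.
    """
    t = np.asarray(monthly_t_mean, dtype=float)
    if t.size != 12:
        raise ValidationError(f"expected 12 monthly temperatures, got {t.size}")
    warm = t[t > 0]
    if warm.size == 0:
        raise ValidationError("all monthly means <= 0 degC: heat index undefined")
    h = float(np.sum((warm / 5.0) ** 1.514))
    a = 6.75e-7 * h**3 - 7.71e-5 * h**2 + 1.792e-2 * h + 0.49239
    return ThornthwaiteParams(heat_index=h, exponent=a)


def _daylight_hours(latitude_deg: float, month: int) -> float:
    # mean day length of the month via solar declination at mid-month
    day_of_year = 30.4 * month - 15
    decl = 0.409 * np.sin(2 * np.pi / 365 * day_of_year - 1.39)
    lat = np.radians(latitude_deg)
    x = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    sunset_angle = np.arccos(x)
    return float(24 / np.pi * sunset_angle)


def thornthwaite_pet(
    t_mean: float,
    params: ThornthwaiteParams,
    month: int | None = None,
    year: int | None = None,
    correction: str = "none",
    latitude: float | None = None,
) -> float:
    """Monthly potential evapotranspiration (mm).

    PET = 16 (10 T / H)^A for T > 0, and 0 otherwise.  With
    ``correction='day_length'`` the standard (N/12)(days/30) factor is applied
    using ``latitude`` and the calendar month; the default applies no
    correction.
    """
    if t_mean <= 0:
        return 0.0
    pet = 16.0 * (10.0 * t_mean / params.heat_index) ** params.exponent
    if correction == "day_length":
        if latitude is None or month is None:
            raise ValidationError("day_length correction needs latitude and month")
        ndm = pd.Period(year=year or 2001, month=month, freq="M").days_in_month
        pet *= _daylight_hours(latitude, month) / 12.0 * ndm / 30.0
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return float(pet)


def monthly_pet(
    weather: pd.DataFrame, correction: str = "none", latitude: float | None = None
) -> pd.Series:
    """PET for every (year, month) row of a weather frame, heat index per year."""
    out = np.empty(len(weather))
    for year, grp in weather.groupby("year"):
        if len(grp) != 12:
            raise ValidationError(f"year {year} has {len(grp)} months; need 12 for the heat index")
        params = heat_index(grp.sort_values("month")["t_mean"].to_numpy())
        for pos, (_, row) in zip(grp.index, grp.iterrows()):
            out[weather.index.get_loc(pos)] = thornthwaite_pet(
                row["t_mean"], params, month=int(row["month"]), year=int(row["year"]),
                correction=correction, latitude=latitude,
            )
    return pd.Series(out, index=weather.index, name="pet")


def water_balance(precip, pet) -> np.ndarray:
    """Elementwise climatic water balance D = P − PET (mm)."""
    p = np.asarray(precip, dtype=float)
    e = np.asarray(pet, dtype=float)
    if p.shape != e.shape:
        raise ValidationError("precipitation and PET series must be aligned")
    return p - e


def aggregate_scale(d_values, k: int = 3) -> np.ndarray:
    """Trailing k-month sum of the balance; first k−1 positions are NaN."""
    if k < 1:
        raise ValidationError("aggregation scale k must be >= 1")
    d = np.asarray(d_values, dtype=float)
    out = pd.Series(d).rolling(window=k, min_periods=k).sum().to_numpy()
    return out


def _unbiased_pwms(x: np.ndarray) -> tuple[float, float, float]:
    """Unbiased sample PWMs w_s = E[X (1−F)^s], s = 0, 1, 2 (Hosking)."""
    x = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    w0 = x.mean()
    w1 = np.sum(x * (n - i) / (n - 1)) / n
    w2 = np.sum(x * (n - i) * (n - i - 1) / ((n - 1) * (n - 2))) / n
    return float(w0), float(w1), float(w2)


def fit_loglogistic(sample) -> LogLogisticParams:
    """Fit the three-parameter log-logistic by unbiased probability-weighted moments.

    With w0, w1, w2 the order-0..2 PWMs of the sample,

        beta  = (2 w1 − w0) / (6 w1 − w0 − 6 w2)
        alpha = (w0 − 2 w1) beta / (Γ(1 + 1/beta) Γ(1 − 1/beta))
        gamma = w0 − alpha Γ(1 + 1/beta) Γ(1 − 1/beta)

    the canonical estimator used for drought-index standardization.
    Requires n ≥ 4 and a non-degenerate sample; the shape estimate must
    exceed 1 so the mean (used by the origin) exists.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise FitError(f"need at least 4 values to fit, got {x.size}")
    if np.isclose(x.std(), 0.0):
        raise FitError("degenerate (constant) sample")
    w0, w1, w2 = _unbiased_pwms(x)
    denom = 6 * w1 - w0 - 6 * w2
    if np.isclose(denom, 0.0):
        raise FitError("PWM shape denominator vanishes")
    beta = (2 * w1 - w0) / denom
    if beta <= 1.0:
        raise FitError(f"estimated shape beta = {beta:.4f} <= 1; distribution mean undefined")
    g = _gamma_fn(1 + 1 / beta) * _gamma_fn(1 - 1 / beta)
    alpha = (w0 - 2 * w1) * beta / g
    if alpha <= 0:
        raise FitError(f"estimated scale alpha = {alpha:.4f} <= 0")
    gamma = w0 - alpha * g
    return LogLogisticParams(alpha=alpha, beta=beta, gamma=gamma)


def standardize(d_k, params: LogLogisticParams, eps: float = PROB_EPS):
    """Map aggregated balances to SPEI values through the fitted distribution.

    p = 1 − F(x) is the exceedance probability; w = sqrt(−2 ln p̃) with
    p̃ = p when p ≤ 0.5 else 1 − p, and

        SPEI = ± [ w − (c0 + c1 w + c2 w²) / (1 + d1 w + d2 w² + d3 w³) ]

    positive for wet anomalies (p < 0.5), negative for dry.  Probabilities at
    the support edge are clipped to ``eps`` with a warning.
    """
    x = np.atleast_1d(np.asarray(d_k, dtype=float))
    p = 1.0 - params.cdf(x)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn(
            "exceedance probability at/beyond distribution support; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.clip(p, eps, 1.0 - eps)
    sign = np.where(p <= 0.5, 1.0, -1.0)
    pt = np.where(p <= 0.5, p, 1.0 - p)
    w = np.sqrt(-2.0 * np.log(pt))
    z = w - (C0 + C1 * w + C2 * w**2) / (1.0 + D1 * w + D2 * w**2 + D3 * w**3)
    out = sign * z
    return out if np.asarray(d_k).ndim else float(out[0])


def _empirical_exceedance(values: np.ndarray, calibration: np.ndarray) -> np.ndarray:
    # Gringorten plotting positions against the calibration sample: the
    # nonparametric fallback when a parametric fit is unavailable
    n = calibration.size
    ranks = np.array(
        [np.sum(calibration < v) + 0.5 * np.sum(calibration == v) + 0.5 for v in values]
    )
    return 1.0 - (ranks - 0.44) / (n + 0.12)


def spei_series(
    weather: pd.DataFrame,
    scale: int = 3,
    calibration_years=None,
    correction: str = "none",
    latitude: float | None = None,
) -> pd.DataFrame:
    """Full chain: PET → D → k-month aggregation → per-calendar-month fit → SPEI.

    Parameters are fitted, for each calendar month, from the aggregated
    balances of the calibration years (default: every year supplied) and then
    applied to all years.  Short, strongly bimodal samples can defeat the
    PWM log-logistic fit (invalid shape estimate); such months fall back to
    empirical standardization via Gringorten plotting positions, which keeps
    the ranking and the drought/normal partition well defined.  Returns a
    frame (year, month, d, d_k, spei); spei is NaN wherever d_k is undefined.
    """
    wx = weather.sort_values(["year", "month"]).reset_index(drop=True)
    pet = monthly_pet(wx, correction=correction, latitude=latitude)
    d = water_balance(wx["precip"].to_numpy(), pet.to_numpy())
    d_k = aggregate_scale(d, scale)
    out = wx[["year", "month"]].copy()
    out["d"] = d
    out["d_k"] = d_k
    out["spei"] = np.nan
    cal_years = set(calibration_years) if calibration_years is not None else set(wx["year"])
    for month in sorted(out["month"].unique()):
        sel = (out["month"] == month) & out["d_k"].notna()
        cal = sel & out["year"].isin(cal_years)
        if cal.sum() < 4:
            continue
        cal_vals = out.loc[cal, "d_k"].to_numpy()
        vals = out.loc[sel, "d_k"].to_numpy()
        try:
            params = fit_loglogistic(cal_vals)
            out.loc[sel, "spei"] = standardize(vals, params)
        except FitError:
            p = np.clip(_empirical_exceedance(vals, cal_vals), PROB_EPS, 1 - PROB_EPS)
            sign = np.where(p <= 0.5, 1.0, -1.0)
            pt = np.where(p <= 0.5, p, 1.0 - p)
            w = np.sqrt(-2.0 * np.log(pt))
            out.loc[sel, "spei"] = sign * (
                w - (C0 + C1 * w + C2 * w**2) / (1.0 + D1 * w + D2 * w**2 + D3 * w**3)
            )
    return out


def classify_years(
    spei: pd.DataFrame, month: int = 9, threshold: float = DROUGHT_THRESHOLD
) -> pd.DataFrame:
    """Label each year from its September (default) SPEI: drought iff SPEI ≤ threshold."""
    sub = spei[(spei["month"] == month) & spei["spei"].notna()]
    if sub.empty:
        raise ValidationError(f"no defined SPEI values for month {month}")
    out = sub[["year", "spei"]].rename(columns={"spei": "spei3"}).reset_index(drop=True)
    out["label"] = np.where(out["spei3"] <= threshold, "drought", "normal")
    return out
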