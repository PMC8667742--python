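"""Validation metrics and per-year relative-error tables.

Three global metrics compare predictions S against observations O:

    R²   = 1 − Σ(S−O)² / Σ(O−Ō)²
    RMSE = sqrt(Σ(S−O)² / n)
    MRE  = (1/n) Σ |S−O| / S        (predicted-value denominator)

The per-year report instead expresses each group's error as
|pred − true| / true × 100 (true-value denominator, the reporting
convention); MEAN rows average true and predicted values first and apply the
same formula to the means — not the mean of the per-year errors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError


def _aligned(s, o):
    s = np.asarray(s, dtype=float)
    o = np.asarray(o, dtype=float)
    if s.shape != o.shape or s.ndim != 1:
        raise ValidationError("predictions and observations must be aligned 1-D arrays")
    return s, o


def r_squared(predictions, observations) -> float:
    s, o = _aligned(predictions, observations)
    if o.size < 2 or np.isclose(o.var(), 0):
        raise ValidationError("R^2 needs n >= 2 and non-constant observations")
    return float(1.0 - np.sum((s - o) ** 2) / np.sum((o - o.mean()) ** 2))


def rmse(predictions, observations) -> float:
    s, o = _aligned(predictions, observations)
    if o.size < 1:
        raise ValidationError("RMSE needs at least one pair")
    return float(np.sqrt(np.mean((s - o) ** 2)))


def mre(predictions, observations) -> float:
    """Mean relative error with the predicted value as denominator."""
    s, o = _aligned(predictions, observations)
    if np.any(s == 0):
        raise ValidationError("MRE undefined when a predicted value is 0")
    return float(np.mean(np.abs(s - o) / np.abs(s)))


def relative_error(true_value, predicted_value, denominator: str = "true") -> float:
    """|pred − true| / denominator × 100, denominator = 'true' or 'predicted'."""
    base = {"true": true_value, "predicted": predicted_value}.get(denominator)
    if base is None:
        raise ValidationError(f"denominator must be 'true' or 'predicted', got {denominator!r}")
    if base == 0:
        raise ValidationError("zero denominator in relative error")
    return float(abs(predicted_value - true_value) / abs(base) * 100.0)


def relative_error_table(
    pairs: pd.DataFrame, denominator: str = "true"
) -> pd.DataFrame:
    """Per-year error report with per-(type × tillage) MEAN rows.

    ``pairs`` needs columns ``type, tillage, year, true, pred`` (one row per
    group).  Output keeps the per-year rows (error from each pair) and
    appends, per (type, tillage), a MEAN row whose true/pred are the means of
    the group's values and whose error applies the same formula to those
    means.
    """
    required = {"type", "tillage", "year", "true", "pred"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValidationError(f"pairs frame lacks column(s) {sorted(missing)}")
    rows = []
    for (ptype, tillage), grp in pairs.groupby(["type", "tillage"], sort=False):
        for _, rec in grp.sort_values("year").iterrows():
            rows.append(
                {
                    "type": ptype,
                    "tillage": tillage,
                    "year": rec["year"],
                    "true": float(rec["true"]),
                    "pred": float(rec["pred"]),
                    "error_pct": relative_error(rec["true"], rec["pred"], denominator),
                }
            )
        t_mean = float(grp["true"].mean())
        p_mean = float(grp["pred"].mean())
        rows.append(
            {
                "type": ptype,
                "tillage": tillage,
                "year": "MEAN",
                "true": t_mean,
                "pred": p_mean,
                "error_pct": relative_error(t_mean, p_mean, denominator),
            }
        )
    return pd.DataFrame(rows)
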