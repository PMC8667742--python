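"""Monthly weather ingest, validation, gap filling and growth-stage aggregation.

The analysis runs on monthly station records (precipitation, mean/max/min
temperature, sunshine hours).  A wheat cultivation cycle spans two calendar
years; records are keyed to the *test year* — the calendar year of the
July–September fallow window that recharges the soil profile — with the
growth period running from October sowing to June harvest of the following
calendar year.  Stage windows are expressed as (calendar-year offset
relative to the test year, month) pairs.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ImputationError, IncompleteStageError, SchemaError, ValidationError

WEATHER_COLUMNS = ("year", "month", "precip", "t_mean", "t_max", "t_min", "sunshine")

#: Whole-month approximation of the site's stage boundaries, keyed to the
#: *test year*: the calendar year of the July–September fallow window (the
#: drought-index window).  Sowing follows in October of the same year; the
#: growth stages October–March (sowing to jointing), April (jointing to
#: anthesis) and May–June (anthesis to maturity, harvest) spill into the
#: next calendar year, hence the +1 offsets.
DEFAULT_CALENDAR: dict[str, tuple[tuple[int, int], ...]] = {
    "fallow": ((0, 7), (0, 8), (0, 9)),
    "sowing_jointing": ((0, 10), (0, 11), (0, 12), (1, 1), (1, 2), (1, 3)),
    "jointing_anthesis": ((1, 4),),
    "anthesis_maturity": ((1, 5), (1, 6)),
}

GROWTH_STAGES = ("sowing_jointing", "jointing_anthesis", "anthesis_maturity")

_NUMERIC = ("precip", "t_mean", "t_max", "t_min", "sunshine")


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    for col in _NUMERIC:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValidationError(f"non-numeric or missing value in column {col!r}, row {bad[0]}")
    if ((df["month"] < 1) | (df["month"] > 12)).any():
        row = df.index[(df["month"] < 1) | (df["month"] > 12)][0]
        raise ValidationError(f"month out of range 1-12 at row {row}")
    for col, msg in (("precip", "negative precipitation"), ("sunshine", "negative sunshine")):
        if (df[col] < 0).any():
            raise ValidationError(f"{msg} at row {df.index[df[col] < 0][0]}")
    order_ok = (df["t_min"] <= df["t_mean"]) & (df["t_mean"] <= df["t_max"])
    if not order_ok.all():
        raise ValidationError(
            f"temperature ordering t_min <= t_mean <= t_max violated at row {df.index[~order_ok][0]}"
        )
    dup = df.duplicated(subset=["year", "month"]).to_numpy()
    if dup.any():
        row = df.iloc[int(np.argmax(dup))]
        raise ValidationError(
            f"duplicate record for {int(row['year'])}-{int(row['month']):02d}"
        )
    return df.sort_values(["year", "month"], kind="stable").reset_index(drop=True)


def read_monthly_weather(
    path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read, validate and chronologically sort a monthly weather CSV.

    Parameters
    ----------
    path
        CSV file with a header row; comma separated, UTF-8.
    column_map
        Optional mapping from the file's header names to the canonical names
        ``year, month, precip, t_mean, t_max, t_min, sunshine``.

    Returns
    -------
    DataFrame with the canonical columns, sorted by (year, month).
    """
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in WEATHER_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = raw.loc[:, list(WEATHER_COLUMNS)].copy()
    for col in ("year", "month"):
        df[col] = pd.to_numeric(df[col], errors="raise", downcast=None).astype(int)
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = raw.index[df[col].isna() & raw[col].notna()]
        if len(bad):
            raise SchemaError(f"non-numeric cell in column {col!r} at row {bad[0]}")
    return _validate(df)


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory weather frame (same rules as :func:`read_monthly_weather`)."""
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    return _validate(df.copy())


def find_gaps(df: pd.DataFrame) -> list[tuple[int, int]]:
    """Return (year, month) pairs missing inside the record's covered range."""
    if df.empty:
        return []
    idx = pd.PeriodIndex(pd.to_datetime(df[["year", "month"]].assign(day=1)), freq="M")
    full = pd.period_range(idx.min(), idx.max(), freq="M")
    missing = full.difference(idx)
    return [(p.year, p.month) for p in missing]


def impute_missing(df: pd.DataFrame, policy: str = "multi_year_mean") -> pd.DataFrame:
    """Fill internal month gaps.

    ``multi_year_mean`` fills every missing (year, month) with the mean of the
    same calendar month over all other years in the record — the conventional
    station-data patch when short outages occur.  ``drop`` removes every year
    touched by a gap.  Imputation is idempotent: a gap-free record is returned
    unchanged.
    """
    gaps = find_gaps(df)
    if not gaps:
        return df.reset_index(drop=True)
    if policy == "drop":
        bad_years = {y for y, _ in gaps}
        return df[~df["year"].isin(bad_years)].reset_index(drop=True)
    if policy != "multi_year_mean":
        raise ValueError(f"unknown imputation policy {policy!r}")
    if df["year"].nunique() < 2:
        raise ImputationError("multi_year_mean requires at least two years of data")
    month_means = df.groupby("month")[list(_NUMERIC)].mean()
    rows = []
    for year, month in gaps:
        if month not in month_means.index:
            raise ImputationError(f"month {month} absent in every year; cannot impute")
        rec = {"year": year, "month": month, **month_means.loc[month].to_dict()}
        rows.append(rec)
    out = pd.concat([df, pd.DataFrame(rows)], ignore_index=True)
    return out.sort_values(["year", "month"], kind="stable").reset_index(drop=True)


def _days_in_month(year: int, month: int) -> int:
    return pd.Period(year=year, month=month, freq="M").days_in_month


def aggregate_stages(
    df: pd.DataFrame,
    calendar: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Aggregate monthly records into per-test-year growth-stage summaries.

    For each stage: ``precip_sum`` and ``sunshine_sum`` are month sums,
    ``t_mean_avg`` is the mean of the monthly means, and ``accum_temp`` is the
    accumulated temperature Σ(monthly mean × days in month) in °C·d.

    Raises :class:`IncompleteStageError` when any requested stage month is
    absent from the record.
    """
    calendar = dict(calendar or DEFAULT_CALENDAR)
    lookup = df.set_index(["year", "month"])
    if years is None:
        # a test year is reportable when its latest stage month exists
        candidates = sorted(df["year"].unique())
        years = [
            y for y in candidates
            if all(
                (y + off, m) in lookup.index
                for months in calendar.values()
                for off, m in months
            )
        ]
        if not years:
            raise IncompleteStageError("no harvest year has complete stage coverage")
    rows = []
    for hy in years:
        for stage, months in calendar.items():
            keys = [(hy + off, m) for off, m in months]
            missing = [k for k in keys if k not in lookup.index]
            if missing:
                raise IncompleteStageError(
                    f"harvest year {hy}, stage {stage!r}: missing month(s) {missing}"
                )
            sub = lookup.loc[keys]
            days = np.array([_days_in_month(y, m) for y, m in keys])
            rows.append(
                {
                    "year": hy,
                    "stage": stage,
                    "precip_sum": float(sub["precip"].sum()),
                    "t_mean_avg": float(sub["t_mean"].mean()),
                    "accum_temp": float((sub["t_mean"].to_numpy() * days).sum()),
                    "sunshine_sum": float(sub["sunshine"].sum()),
                }
            )
    return pd.DataFrame(rows)


def stage_totals(stages: pd.DataFrame) -> pd.DataFrame:
    """Per-harvest-year fallow, whole-growth and annual precipitation totals.

    ``whole_growth`` sums the three growth stages; ``annual`` adds the fallow
    window, i.e. the July–June harvest-year total.
    """
    wide = stages.pivot(index="year", columns="stage", values="precip_sum")
    out = pd.DataFrame(index=wide.index)
    out["fallow"] = wide["fallow"]
    out["whole_growth"] = wide[list(GROWTH_STAGES)].sum(axis=1)
    out["annual"] = out["fallow"] + out["whole_growth"]
    return out.reset_index()


def write_monthly_weather(df: pd.DataFrame, path) -> None:
    """Write a canonical weather frame to CSV (round-trips with the reader)."""
    df.loc[:, list(WEATHER_COLUMNS)].to_csv(path, index=False)
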