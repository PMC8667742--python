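"""Soil-water storage, yield standardization and treatment summaries.

Storage is measured gravimetrically: profile pits sampled in 0.2 m layers to
3 m depth, oven-dried, and converted to millimetres of stored water per layer
via bulk density.  Yields are standardized to the grain-trade moisture content
of 12.5% before any comparison.  Summaries are unweighted means per
(precipitation-type × tillage) cell; storage–yield screening uses plain
Pearson correlation with unadjusted two-sided p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

TILLAGES = ("DP", "SS", "NT")
SOIL_STAGES = ("sowing", "wintering", "jointing", "anthesis", "maturity")
PROFILE_LAYERS = 15  # 0–3 m in 0.2 m increments
STANDARD_MC = 0.125

RESPONSES = ("yield", "spikes", "grains_per_spike", "tgw")


def gravimetric_water(wet_mass, dry_mass):
    """Gravimetric soil water content GSW (%) = (wet − dry)/dry × 100."""
    wet = np.asarray(wet_mass, dtype=float)
    dry = np.asarray(dry_mass, dtype=float)
    if np.any(dry <= 0):
        raise ValidationError("dry mass must be positive")
    if np.any(wet < dry):
        raise ValidationError("wet mass below dry mass")
    out = (wet - dry) / dry * 100.0
    return out if out.ndim else float(out)


def layer_storage(gsw_pct, bulk_density, thickness_m):
    """Stored water of one layer (mm) = GSW/100 × ρb × SD × 10³.

    GSW in percent, bulk density in g cm⁻³, layer thickness in m.
    """
    g = np.asarray(gsw_pct, dtype=float)
    rb = np.asarray(bulk_density, dtype=float)
    sd = np.asarray(thickness_m, dtype=float)
    if np.any(rb <= 0) or np.any(sd <= 0):
        raise ValidationError("bulk density and thickness must be positive")
    out = g / 100.0 * rb * sd * 1e3
    return out if out.ndim else float(out)


def profile_storage(layers: pd.DataFrame, expected_layers: int = PROFILE_LAYERS) -> float:
    """Total 0–3 m storage (mm) from a layer table.

    Expects columns ``wet_mass, dry_mass, bulk_density, thickness`` (and
    optionally ``top_depth`` for contiguity checking); exactly
    ``expected_layers`` rows.
    """
    if len(layers) != expected_layers:
        raise ValidationError(f"profile needs {expected_layers} layers, got {len(layers)}")
    if "top_depth" in layers.columns:
        srt = layers.sort_values("top_depth")
        tops = srt["top_depth"].to_numpy(dtype=float)
        thick = srt["thickness"].to_numpy(dtype=float)
        if not np.allclose(tops[1:], tops[:-1] + thick[:-1]):
            raise ValidationError("layers are not contiguous")
    gsw = gravimetric_water(layers["wet_mass"], layers["dry_mass"])
    return float(np.sum(layer_storage(gsw, layers["bulk_density"], layers["thickness"])))


def standardize_yield_moisture(fresh_yield, measured_mc, standard_mc: float = STANDARD_MC):
    """Convert yield to the standard moisture basis, conserving dry matter.

    yield_std = fresh × (1 − measured_mc) / (1 − standard_mc), moisture
    contents as fractions.
    """
    mc = np.asarray(measured_mc, dtype=float)
    if np.any((mc < 0) | (mc >= 1)):
        raise ValidationError("measured moisture content must be in [0, 1)")
    if not 0 <= standard_mc < 1:
        raise ValidationError("standard moisture content must be in [0, 1)")
    out = np.asarray(fresh_yield, dtype=float) * (1.0 - mc) / (1.0 - standard_mc)
    return out if out.ndim else float(out)


def summarize_by_type(observations: pd.DataFrame, year_types: pd.DataFrame) -> pd.DataFrame:
    """Mean yield and yield components per (precipitation type × tillage) cell.

    ``observations`` carries plot-year records (year, tillage, yield, spikes,
    grains_per_spike, tgw); ``year_types`` maps year → label.  Means are
    unweighted over all matching plot-years; cell counts are reported.
    """
    unknown = set(observations["tillage"]) - set(TILLAGES)
    if unknown:
        raise ValidationError(f"unknown tillage label(s): {sorted(unknown)}")
    merged = observations.merge(year_types[["year", "label"]], on="year", how="left")
    if merged["label"].isna().any():
        missing = sorted(merged.loc[merged["label"].isna(), "year"].unique())
        raise ValidationError(f"no precipitation-type label for year(s) {missing}")
    value_cols = [c for c in RESPONSES if c in merged.columns]
    out = (
        merged.groupby(["label", "tillage"], sort=True)[value_cols]
        .agg(["mean", "count"])
    )
    out.columns = [f"{v}_{s}" for v, s in out.columns]
    return out.reset_index()


def screen_storage_correlations(
    storage: pd.DataFrame, responses: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and two-sided p for every (soil stage × response) pair.

    ``storage`` is long-form (year, [tillage], stage, storage_mm); ``responses``
    carries matching (year, [tillage]) rows with the yield-component columns.
    Pairs are aligned on the shared key columns; each cell needs ≥ 3 points.
    p-values are reported unadjusted, with significance flags at 0.05 / 0.01.
    """
    keys = [c for c in ("year", "tillage", "replicate") if c in storage.columns and c in responses.columns]
    if not keys:
        raise ValidationError("storage and responses share no alignment keys")
    value_cols = [c for c in RESPONSES if c in responses.columns]
    rows = []
    for stage, grp in storage.groupby("stage"):
        merged = grp.merge(responses, on=keys, how="inner")
        for resp in value_cols:
            sub = merged[["storage_mm", resp]].dropna()
            if len(sub) < 3:
                raise ValidationError(f"stage {stage!r} x {resp!r}: fewer than 3 paired points")
            r, p = stats.pearsonr(sub["storage_mm"], sub[resp])
            rows.append(
                {
                    "stage": stage,
                    "response": resp,
                    "n": len(sub),
                    "r": float(r),
                    "p": float(p),
                    "sig_05": bool(p < 0.05),
                    "sig_01": bool(p < 0.01),
                }
            )
    return pd.DataFrame(rows)
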