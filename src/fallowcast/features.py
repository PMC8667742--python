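"""Meteorological predictor selection by factor analysis.

Fourteen candidate indices (stage precipitation, temperature and sunshine
aggregates) are reduced by principal-component factor extraction on the
correlation matrix: factors with eigenvalue > 1 are retained, loadings are
varimax-rotated, and each factor nominates the variable with the largest
absolute rotated loading.  The nominated variables become the uncontrollable
(weather) inputs of the yield model, alongside the controllable soil-water
storage variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError, ValidationError

#: Canonical names of the 14 candidate meteorological indices.  "Stage 1" is
#: sowing–jointing, "stage 2" jointing–anthesis; growth-period aggregates run
#: sowing to maturity.
METEO_INDICES = (
    "fallow_precip",
    "stage1_precip",
    "stage2_precip",
    "growth_accum_temp",
    "growth_mean_temp",
    "daily_max_temp",
    "daily_min_temp",
    "stage1_mean_temp",
    "stage2_mean_temp",
    "growth_sunshine",
    "stage1_sunshine",
    "stage2_sunshine",
    "stage1_accum_temp",
    "stage2_accum_temp",
)


@dataclass
class FactorSolution:
    eigenvalues: np.ndarray          # all eigenvalues, descending
    n_factors: int                   # count retained (eigenvalue > 1)
    loadings: pd.DataFrame           # variables x retained factors, varimax-rotated
    cumulative_variance_pct: float   # explained by retained factors
    selected: list[str] = field(default_factory=list)  # one variable per factor


def _varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation (Kaiser criterion, SVD updates)."""
    p, k = loadings.shape
    if k < 2:
        return loadings.copy()
    rot = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - lam @ np.diag(np.sum(lam**2, axis=0)) / p)
        )
        rot = u @ vt
        new_var = float(np.sum(s))
        if new_var <= var * (1 + tol):
            break
        var = new_var
    return loadings @ rot


def factor_select(
    features: pd.DataFrame,
    eigenvalue_cutoff: float = 1.0,
    top_k_per_factor: int = 1,
) -> FactorSolution:
    """Retain eigenvalue>1 factors, varimax-rotate, pick top loadings per factor.

    Columns are standardized implicitly by working on the correlation matrix.
    Loadings are extracted by the principal-component method (eigenvector ×
    √eigenvalue).  Ties in |loading| break by column order; a variable already
    claimed by an earlier factor is skipped so selections stay distinct.
    ``top_k_per_factor`` > 1 nominates that many variables per factor.
    """
    x = features.to_numpy(dtype=float)
    n, p = x.shape
    if n < 4:
        raise ValidationError(f"need at least 4 observations, got {n}")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0) or np.any(~np.isfinite(sd)):
        bad = list(features.columns[(sd == 0) | ~np.isfinite(sd)])
        raise FitError(f"constant or non-finite column(s): {bad}")
    corr = np.corrcoef(x, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > eigenvalue_cutoff
    n_factors = int(keep.sum())
    if n_factors == 0:
        raise FitError("no factor exceeds the eigenvalue cutoff")
    raw = eigvecs[:, :n_factors] * np.sqrt(eigvals[:n_factors])
    rotated = _varimax(raw)
    # deterministic sign convention: largest-|loading| entry positive
    for j in range(n_factors):
        pivot = np.argmax(np.abs(rotated[:, j]))
        if rotated[pivot, j] < 0:
            rotated[:, j] = -rotated[:, j]
    loadings = pd.DataFrame(
        rotated,
        index=features.columns,
        columns=[f"factor_{j + 1}" for j in range(n_factors)],
    )
    selected: list[str] = []
    for j in range(n_factors):
        ranked = np.argsort(-np.abs(rotated[:, j]), kind="stable")
        picked = 0
        for idx in ranked:
            name = features.columns[idx]
            if name not in selected:
                selected.append(name)
                picked += 1
                if picked == top_k_per_factor:
                    break
    cum_var = float(eigvals[:n_factors].sum() / p * 100.0)
    return FactorSolution(
        eigenvalues=eigvals,
        n_factors=n_factors,
        loadings=loadings,
        cumulative_variance_pct=cum_var,
        selected=selected,
    )


def communalities(loadings: pd.DataFrame) -> pd.Series:
    """Row-wise sum of squared loadings (invariant under orthogonal rotation)."""
    return (loadings**2).sum(axis=1)
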