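"""Bootstrap ensemble-of-trees regression for yield and yield components.

Protocol: chronological train/validation split by harvest year (no future
leakage), N = 200 trees with m = 5 candidate features per split, OOB RMSE as
the tuning signal, ensemble prediction = mean of tree predictions.  Targets
can be the unit yield, the meteorological yield, the relative meteorological
yield, or a yield component; relative-yield predictions map back to kg ha⁻¹
via ŷ = y_t (1 + ŷ_w).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_perm_importance

from .errors import ValidationError

TARGETS = (
    "unit_yield",
    "meteorological_yield",
    "relative_meteorological_yield",
    "spike_number",
    "grains_per_spike",
)

#: target name -> column holding it in a modelling frame
TARGET_COLUMNS = {
    "unit_yield": "yield",
    "meteorological_yield": "y_c",
    "relative_meteorological_yield": "y_w",
    "spike_number": "spikes",
    "grains_per_spike": "grains_per_spike",
}


@dataclass
class ModelSpec:
    target: str
    predictors: list[str]
    n_trees: int = 200
    m_try: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ValidationError(f"unknown target {self.target!r}; one of {TARGETS}")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        p = len(self.predictors)
        if not 1 <= self.m_try <= p:
            raise ValidationError(f"m_try must be in [1, {p}], got {self.m_try}")
        if self.m_try >= p:
            warnings.warn(
                f"m_try = {self.m_try} >= number of predictors ({p}): "
                "split-level feature sampling is effectively disabled",
                UserWarning,
                stacklevel=2,
            )


@dataclass
class DataSplit:
    train: pd.DataFrame
    valid: pd.DataFrame

    @property
    def counts(self) -> tuple[int, int]:
        return len(self.train), len(self.valid)


@dataclass
class TrainedForest:
    spec: ModelSpec
    estimator: RandomForestRegressor
    oob_rmse: float
    target_column: str = field(init=False)

    def __post_init__(self):
        self.target_column = TARGET_COLUMNS[self.spec.target]


def split_by_year(dataset: pd.DataFrame, train_years, valid_years) -> DataSplit:
    """Partition rows chronologically by harvest year."""
    train_years, valid_years = set(train_years), set(valid_years)
    if train_years & valid_years:
        raise ValidationError("train and validation year sets overlap")
    train = dataset[dataset["year"].isin(train_years)].reset_index(drop=True)
    valid = dataset[dataset["year"].isin(valid_years)].reset_index(drop=True)
    if train.empty:
        raise ValidationError("training set is empty")
    if valid.empty:
        raise ValidationError("validation set is empty")
    if max(train_years) >= min(valid_years):
        warnings.warn("validation years are not strictly after training years", UserWarning,
                      stacklevel=2)
    return DataSplit(train=train, valid=valid)


def train(split: DataSplit, spec: ModelSpec) -> TrainedForest:
    """Fit the bootstrap tree ensemble and record its out-of-bag RMSE.

    Each tree grows on a bootstrap resample with ``m_try`` features examined
    per split; depth unlimited, minimum leaf size 1.  Identical
    (spec, seed, data) reproduce bit-identical predictions.
    """
    target_col = TARGET_COLUMNS[spec.target]
    missing = [c for c in spec.predictors + [target_col] if c not in split.train.columns]
    if missing:
        raise ValidationError(f"training frame lacks column(s) {missing}")
    x = split.train[spec.predictors].to_numpy(dtype=float)
    y = split.train[target_col].to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("missing values in predictors or target")
    rf = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=spec.m_try,
        bootstrap=True,
        oob_score=True,
        min_samples_leaf=1,
        max_depth=None,
        random_state=spec.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # constant targets make OOB R^2 undefined; RMSE below is still valid
        warnings.simplefilter("ignore", UserWarning)
        rf.fit(x, y)
    oob_pred = rf.oob_prediction_
    ok = ~np.isnan(oob_pred)
    oob_rmse = float(np.sqrt(np.mean((oob_pred[ok] - y[ok]) ** 2)))
    return TrainedForest(spec=spec, estimator=rf, oob_rmse=oob_rmse)


def predict(model: TrainedForest, features: pd.DataFrame) -> np.ndarray:
    """Ensemble prediction (mean over trees) for each row."""
    missing = [c for c in model.spec.predictors if c not in features.columns]
    if missing:
        raise ValidationError(f"feature frame lacks column(s) {missing}")
    return model.estimator.predict(features[model.spec.predictors].to_numpy(dtype=float))


def predict_yield_scale(model: TrainedForest, features: pd.DataFrame) -> np.ndarray:
    """Predictions mapped to kg ha⁻¹ regardless of the training target.

    Relative meteorological yield maps back via ŷ = y_t (1 + ŷ_w);
    meteorological yield via ŷ = y_t + ŷ_c; other targets are already on
    their natural scale.
    """
    raw = predict(model, features)
    if model.spec.target == "relative_meteorological_yield":
        return features["y_t"].to_numpy(dtype=float) * (1.0 + raw)
    if model.spec.target == "meteorological_yield":
        return features["y_t"].to_numpy(dtype=float) + raw
    return raw


def tune_ntree(split: DataSplit, spec: ModelSpec, grid, use: str = "oob",
               plateau_tol: float = 0.02) -> tuple[pd.DataFrame, int]:
    """RMSE over a grid of ensemble sizes; choose the smallest near-optimal N.

    ``use='oob'`` scores on out-of-bag predictions, ``'valid'`` on the
    hold-out years.  The chosen N is the smallest grid value whose RMSE is
    within ``plateau_tol`` (relative) of the grid minimum — the elbow rule for
    the RMSE-vs-N curve flattening.
    """
    grid = sorted(set(int(n) for n in grid))
    if not grid:
        raise ValidationError("empty n_trees grid")
    rows = []
    for n in grid:
        s = ModelSpec(spec.target, spec.predictors, n_trees=n, m_try=spec.m_try, seed=spec.seed)
        model = train(split, s)
        if use == "oob":
            rmse = model.oob_rmse
        elif use == "valid":
            truth = split.valid[model.target_column].to_numpy(dtype=float)
            rmse = float(np.sqrt(np.mean((predict(model, split.valid) - truth) ** 2)))
        else:
            raise ValueError(f"unknown scoring source {use!r}")
        rows.append({"n_trees": n, "rmse": rmse})
    curve = pd.DataFrame(rows)
    best = curve["rmse"].min()
    chosen = int(curve.loc[curve["rmse"] <= best * (1 + plateau_tol), "n_trees"].min())
    return curve, chosen


def permutation_importance(
    model: TrainedForest, features: pd.DataFrame, truth, n_repeats: int = 10, seed: int = 0
) -> pd.Series:
    """Mean permutation importance per predictor, descending."""
    res = _sk_perm_importance(
        model.estimator,
        features[model.spec.predictors].to_numpy(dtype=float),
        np.asarray(truth, dtype=float),
        n_repeats=n_repeats,
        random_state=seed,
        n_jobs=1,
    )
    return pd.Series(res.importances_mean, index=model.spec.predictors).sort_values(
        ascending=False
    )
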