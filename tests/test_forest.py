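import warnings

import numpy as np
import pandas as pd
import pytest

from fallowcast.detrend import decompose_yields
from fallowcast.errors import ValidationError
from fallowcast.evaluate import r_squared
from fallowcast.forest import (
    DataSplit,
    ModelSpec,
    permutation_importance,
    predict,
    predict_yield_scale,
    split_by_year,
    train,
    tune_ntree,
)
from fallowcast.synthetic import GeneratorConfig, gen_dataset, modeling_frame

PREDICTORS = [
    "fallow_precip",
    "stage1_precip",
    "storage_sowing",
    "storage_jointing",
    "storage_anthesis",
]


def _spec(target="unit_yield", predictors=PREDICTORS, **kw):
    kw.setdefault("n_trees", 100)
    kw.setdefault("m_try", 3)
    kw.setdefault("seed", 0)
    return ModelSpec(target, list(predictors), **kw)


@pytest.fixture(scope="module")
def trial_frame(default_dataset):
    wx, storage, obs, _ = default_dataset
    dec, _ = decompose_yields(obs)
    return modeling_frame(wx, storage, dec)


@pytest.fixture(scope="module")
def trial_split(trial_frame):
    years = sorted(trial_frame["year"].unique())
    return split_by_year(trial_frame, years[:8], years[8:])


class TestSplit:
    def test_trial_shaped_counts(self, trial_split):
        """10 years x 69 plot-rows with an 8/2 year split gives 552/138."""
        assert trial_split.counts == (552, 138)

    def test_overlap_rejected(self, trial_frame):
        with pytest.raises(ValidationError):
            split_by_year(trial_frame, [2009, 2010], [2010, 2011])

    def test_empty_validation_rejected(self, trial_frame):
        with pytest.raises(ValidationError):
            split_by_year(trial_frame, [2009], [1900])

    def test_leakage_warning_when_not_chronological(self, trial_frame):
        with pytest.warns(UserWarning, match="not strictly after"):
            split_by_year(trial_frame, [2012], [2009])


class TestTrain:
    def test_constant_target_perfectly_predicted(self, trial_split):
        frame = trial_split.train.assign(**{"yield": 4200.0})
        split = DataSplit(train=frame, valid=trial_split.valid)
        model = train(split, _spec())
        np.testing.assert_allclose(predict(model, trial_split.valid), 4200.0)
        assert model.oob_rmse == pytest.approx(0.0, abs=1e-9)

    def test_determinism_contract(self, trial_split):
        m1 = train(trial_split, _spec(seed=7))
        m2 = train(trial_split, _spec(seed=7))
        np.testing.assert_array_equal(
            predict(m1, trial_split.valid), predict(m2, trial_split.valid)
        )

    def test_predictions_bounded_by_training_targets(self, trial_split):
        model = train(trial_split, _spec())
        p = predict(model, trial_split.valid)
        lo, hi = trial_split.train["yield"].min(), trial_split.train["yield"].max()
        assert p.min() >= lo - 1e-9 and p.max() <= hi + 1e-9

    def test_m_try_exceeding_predictors_rejected(self, trial_split):
        with pytest.raises(ValidationError):
            _spec(m_try=6)

    def test_m_try_equal_to_predictors_warns(self):
        with pytest.warns(UserWarning, match="m_try"):
            _spec(m_try=5)

    def test_missing_predictor_column_errors(self, trial_split):
        spec = _spec(predictors=PREDICTORS + ["absent"])
        with pytest.raises(ValidationError, match="absent"):
            train(trial_split, spec)


class TestSignalRecovery:
    def test_validation_r2_on_long_record(self, long_dataset):
        """Detrended yield route recovers the planted signal (R^2 >= 0.8)."""
        wx, storage, obs, _ = long_dataset
        dec, _ = decompose_yields(obs)
        frame = modeling_frame(wx, storage, dec)
        years = sorted(frame["year"].unique())
        split = split_by_year(frame, years[:-30], years[-30:])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = train(split, _spec("meteorological_yield", n_trees=200, m_try=5))
        pred = predict_yield_scale(model, split.valid)
        assert r_squared(pred, split.valid["yield"].to_numpy()) >= 0.8

    def test_negative_validation_shock_inflates_predictions(self):
        """A late-era negative yield shock leaves >56% of forecasts above truth."""
        cfg = GeneratorConfig(
            seed=0, years=50, plots_per_year=10, shock=-300.0, shock_start_year=2049
        )
        wx, storage, obs, _ = gen_dataset(cfg)
        dec, _ = decompose_yields(obs)
        frame = modeling_frame(wx, storage, dec)
        years = sorted(frame["year"].unique())
        split = split_by_year(frame, years[:-10], years[-10:])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = train(
                split, _spec("relative_meteorological_yield", n_trees=200, m_try=5)
            )
        pred = predict_yield_scale(model, split.valid)
        assert (pred > split.valid["yield"].to_numpy()).mean() > 0.56

    def test_oob_and_holdout_rmse_agree_on_exchangeable_rows(self):
        """Without trend or sibling plots, OOB error tracks hold-out error."""
        cfg = GeneratorConfig(seed=2, years=200, plots_per_year=3, trend_slope=0.0)
        wx, storage, obs, _ = gen_dataset(cfg)
        frame = modeling_frame(wx, storage, obs)
        years = sorted(frame["year"].unique())
        split = split_by_year(frame, years[:-40], years[-40:])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = train(split, _spec(n_trees=200, m_try=5))
        hold = float(
            np.sqrt(
                np.mean(
                    (predict(model, split.valid) - split.valid["yield"].to_numpy()) ** 2
                )
            )
        )
        assert abs(model.oob_rmse - hold) / hold < 0.25

    def test_noise_increase_never_improves_oob(self):
        rmses = []
        for noise in (50.0, 150.0, 400.0):
            cfg = GeneratorConfig(seed=3, years=30, plots_per_year=9, noise_sd=noise)
            wx, storage, obs, _ = gen_dataset(cfg)
            dec, _ = decompose_yields(obs)
            frame = modeling_frame(wx, storage, dec)
            years = sorted(frame["year"].unique())
            split = split_by_year(frame, years[:-6], years[-6:])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                model = train(split, _spec("meteorological_yield"))
            rmses.append(model.oob_rmse)
        assert rmses[0] < rmses[1] < rmses[2]


class TestTuning:
    def test_single_point_grid(self, trial_split):
        curve, chosen = tune_ntree(trial_split, _spec(), [1])
        assert chosen == 1
        assert len(curve) == 1

    def test_plateau_rule_prefers_smallest_near_optimal(self, trial_split):
        curve, chosen = tune_ntree(trial_split, _spec(), [10, 50, 100, 200])
        best = curve["rmse"].min()
        assert curve.loc[curve.n_trees == chosen, "rmse"].iloc[0] <= best * 1.02
        assert chosen == curve.loc[curve["rmse"] <= best * 1.02, "n_trees"].min()

    def test_curve_plateaus_by_two_hundred_trees(self, long_dataset):
        wx, storage, obs, _ = long_dataset
        dec, _ = decompose_yields(obs)
        frame = modeling_frame(wx, storage, dec)
        years = sorted(frame["year"].unique())
        split = split_by_year(frame, years[:-30], years[-30:])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            curve, chosen = tune_ntree(
                split, _spec("meteorological_yield", n_trees=200, m_try=5),
                [10, 50, 100, 200, 500],
            )
        assert chosen <= 200
        # RMSE at the plateau is no worse than 2% above the grid minimum
        tail = curve[curve.n_trees >= 200]["rmse"]
        assert (tail <= curve["rmse"].min() * 1.02).all()


class TestImportance:
    def test_true_drivers_outrank_noise(self, long_dataset):
        """Planted drivers beat iid noise columns in >=95% of 20 seeded runs."""
        wx, storage, obs, _ = long_dataset
        dec, _ = decompose_yields(obs)
        frame = modeling_frame(wx, storage, dec)
        gen = np.random.default_rng(99)
        frame = frame.assign(
            noise1=gen.normal(size=len(frame)), noise2=gen.normal(size=len(frame))
        )
        years = sorted(frame["year"].unique())
        split = split_by_year(frame, years[:-30], years[-30:])
        wins = 0
        for seed in range(20):
            spec = _spec(
                "meteorological_yield",
                predictors=PREDICTORS + ["noise1", "noise2"],
                seed=seed,
            )
            model = train(split, spec)
            imp = permutation_importance(
                model, split.valid, split.valid["y_c"], n_repeats=5, seed=seed
            )
            drivers = min(imp["fallow_precip"], imp["storage_jointing"])
            noise = max(imp["noise1"], imp["noise2"])
            wins += int(drivers > noise)
        assert wins >= 19  # >= 95% of 20 runs
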