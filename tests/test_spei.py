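import numpy as np
import pytest
from scipy.stats import fisk

from fallowcast.errors import FitError, ValidationError
from fallowcast.spei import (
    DROUGHT_THRESHOLD,
    LogLogisticParams,
    aggregate_scale,
    classify_years,
    fit_loglogistic,
    heat_index,
    spei_series,
    standardize,
    thornthwaite_pet,
    water_balance,
)


class TestHeatIndex:
    def test_single_warm_month_gives_unit_index(self):
        t = [0.0] * 11 + [5.0]
        params = heat_index(t)
        assert params.heat_index == pytest.approx(1.0)

    def test_site_mean_climate(self):
        # independent scalar evaluation: 12 * (13.72/5)^1.514
        t = [13.72] * 12
        params = heat_index(t)
        assert params.heat_index == pytest.approx(12 * (13.72 / 5) ** 1.514, rel=1e-12)

    def test_all_cold_is_degenerate(self):
        with pytest.raises(ValidationError):
            heat_index([0.0] * 12)

    def test_needs_twelve_months(self):
        with pytest.raises(ValidationError):
            heat_index([10.0] * 11)


class TestThornthwaitePet:
    def test_zero_for_freezing(self):
        params = heat_index([10.0] * 12)
        assert thornthwaite_pet(0.0, params) == 0.0
        assert thornthwaite_pet(-5.0, params) == 0.0

    def test_unit_base_gives_16(self):
        # 10T = H makes the power base 1, so PET = 16 regardless of exponent
        params = heat_index([10.0] * 12)
        h = params.heat_index
        assert thornthwaite_pet(h / 10.0, params) == pytest.approx(16.0)

    def test_direct_evaluation(self):
        # 16 * (10*15/75)^1.5 = 16 * 2^1.5
        from fallowcast.spei import ThornthwaiteParams

        p = ThornthwaiteParams(heat_index=75.0, exponent=1.5)
        assert thornthwaite_pet(15.0, p) == pytest.approx(16 * 2**1.5, rel=1e-12)

    def test_day_length_correction_needs_latitude(self):
        from fallowcast.spei import ThornthwaiteParams

        p = ThornthwaiteParams(heat_index=75.0, exponent=1.5)
        with pytest.raises(ValidationError):
            thornthwaite_pet(15.0, p, correction="day_length")
        north = thornthwaite_pet(
            15.0, p, month=6, correction="day_length", latitude=35.0
        )
        south = thornthwaite_pet(
            15.0, p, month=12, correction="day_length", latitude=35.0
        )
        assert north > south  # June days longer than December at 35N


def test_water_balance_elementwise():
    d = water_balance([50.0, 30.0, 10.0], [30.0, 30.0, 0.0])
    np.testing.assert_allclose(d, [20.0, 0.0, 10.0])
    with pytest.raises(ValidationError):
        water_balance([1.0, 2.0], [1.0])


def test_aggregate_scale_hand_sums():
    np.testing.assert_allclose(aggregate_scale([1.0, 2, 3, 4], 1), [1, 2, 3, 4])
    out = aggregate_scale([1.0, 2, 3, 4], 3)
    assert np.isnan(out[:2]).all()
    np.testing.assert_allclose(out[2:], [6.0, 9.0])
    out12 = aggregate_scale(np.ones(24), 12)
    np.testing.assert_allclose(out12[11:], 12.0)


class TestLogLogisticFit:
    def test_recovers_planted_parameters(self):
        x = fisk.rvs(c=4, loc=-10, scale=30, size=200, random_state=0)
        p = fit_loglogistic(x)
        assert p.alpha == pytest.approx(30.0, rel=0.15)
        assert p.beta == pytest.approx(4.0, rel=0.15)
        assert p.gamma == pytest.approx(-10.0, rel=0.15)

    def test_median_is_gamma_plus_alpha(self):
        p = LogLogisticParams(alpha=30.0, beta=4.0, gamma=-10.0)
        assert p.cdf(p.gamma + p.alpha) == pytest.approx(0.5)
        # and for a different shape too
        p2 = LogLogisticParams(alpha=30.0, beta=2.0, gamma=-10.0)
        assert p2.cdf(p2.gamma + p2.alpha) == pytest.approx(0.5)

    def test_cdf_matches_scipy_fisk(self):
        p = LogLogisticParams(alpha=30.0, beta=4.0, gamma=-10.0)
        x = np.linspace(-9.9, 150, 50)
        np.testing.assert_allclose(
            p.cdf(x), fisk.cdf(x, c=p.beta, loc=p.gamma, scale=p.alpha), atol=1e-12
        )

    def test_degenerate_and_tiny_samples_error(self):
        with pytest.raises(FitError):
            fit_loglogistic([5.0, 5.0, 5.0, 5.0])
        with pytest.raises(FitError):
            fit_loglogistic([1.0, 2.0, 3.0])


class TestStandardize:
    def test_near_zero_at_median(self):
        p = LogLogisticParams(alpha=30.0, beta=4.0, gamma=-10.0)
        assert abs(standardize(p.gamma + p.alpha, p)) < 1e-3

    def test_monotone_in_balance(self):
        p = LogLogisticParams(alpha=30.0, beta=4.0, gamma=-10.0)
        xs = np.linspace(-9.0, 200.0, 100)
        s = standardize(xs, p)
        assert np.all(np.diff(s) > 0)

    def test_monte_carlo_standardization(self):
        p = LogLogisticParams(alpha=30.0, beta=4.0, gamma=-10.0)
        draws = fisk.rvs(c=p.beta, loc=p.gamma, scale=p.alpha, size=1000, random_state=1)
        s = standardize(draws, p)
        assert -0.1 < s.mean() < 0.1
        assert 0.9 < s.std() < 1.1

    def test_support_edge_clips_with_warning(self):
        p = LogLogisticParams(alpha=30.0, beta=4.0, gamma=-10.0)
        with pytest.warns(RuntimeWarning):
            v = standardize(p.gamma - 5.0, p)
        assert np.isfinite(v)


class TestClassification:
    @pytest.mark.parametrize(
        "value,label",
        [(-0.5, "drought"), (-0.49, "normal"), (1.2, "normal"), (-2.0, "drought")],
    )
    def test_threshold_is_inclusive(self, value, label):
        import pandas as pd

        frame = pd.DataFrame({"year": [2000], "month": [9], "spei": [value]})
        out = classify_years(frame)
        assert out.loc[0, "label"] == label

    def test_missing_month_errors(self):
        import pandas as pd

        frame = pd.DataFrame({"year": [2000], "month": [8], "spei": [0.1]})
        with pytest.raises(ValidationError):
            classify_years(frame)


class TestFullChain:
    def test_calibration_moments(self, default_dataset):
        """September SPEI-3 over the calibration years is near-standardized."""
        wx, *_ = default_dataset
        sp = spei_series(wx)
        sept = sp[(sp.month == 9) & sp.spei.notna()]["spei"]
        assert len(sept) >= 10
        assert -0.15 < sept.mean() < 0.15
        assert 0.8 < sept.std() < 1.2

    def test_two_labels_partition_years(self, default_dataset):
        wx, *_ = default_dataset
        labels = classify_years(spei_series(wx))
        assert set(labels["label"]) <= {"normal", "drought"}
        assert labels["year"].is_unique

    def test_drought_years_have_lower_fallow_rainfall(self, default_dataset):
        from fallowcast.weather import aggregate_stages

        wx, _, _, truth = default_dataset
        labels = classify_years(spei_series(wx))
        labels = labels[labels.year.isin(truth.water_signal)]
        stages = aggregate_stages(wx, years=sorted(truth.water_signal))
        fallow = stages[stages.stage == "fallow"].set_index("year")["precip_sum"]
        merged = labels.set_index("year").join(fallow)
        if {"drought", "normal"} <= set(merged["label"]):
            assert (
                merged.loc[merged.label == "drought", "precip_sum"].mean()
                < merged.loc[merged.label == "normal", "precip_sum"].mean()
            )

    def test_monotone_in_fallow_precipitation(self, default_dataset):
        """Raising a fallow month's rain never lowers that year's September SPEI."""
        wx, *_ = default_dataset
        base = spei_series(wx)
        base_val = base[(base.year == 2012) & (base.month == 9)]["spei"].iloc[0]
        bumped = wx.copy()
        mask = (bumped.year == 2012) & (bumped.month == 8)
        bumped.loc[mask, "precip"] += 80.0
        new = spei_series(bumped)
        new_val = new[(new.year == 2012) & (new.month == 9)]["spei"].iloc[0]
        assert new_val >= base_val - 1e-9
        # a normal year must not flip to drought when it gets wetter
        if base_val > DROUGHT_THRESHOLD:
            assert new_val > DROUGHT_THRESHOLD
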