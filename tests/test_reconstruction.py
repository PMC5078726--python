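"""Seasonal aggregation, OLS reconstruction and verification skill."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cellchron as cc
from cellchron.reconstruction import (
    ReconstructionError,
    durbin_watson,
    season_months,
)
from conftest import make_chronology


class TestSeasonalAggregate:
    def test_march_august_is_current_year_sum(self, climate_1948_2013):
        agg = cc.seasonal_aggregate(climate_1948_2013, (3, 8))
        wide = climate_1948_2013.monthly("ppt")
        assert agg.loc[1990] == pytest.approx(wide.loc[1990, 3:8].sum())

    def test_october_march_crosses_boundary(self, climate_1948_2013):
        agg = cc.seasonal_aggregate(climate_1948_2013, (10, 3))
        wide = climate_1948_2013.monthly("ppt")
        expected = wide.loc[1989, 10:12].sum() + wide.loc[1990, 1:3].sum()
        assert agg.loc[1990] == pytest.approx(expected)
        assert 1948 not in agg.index  # needs 1947 months

    def test_constant_ten_mm_per_month(self):
        years = np.repeat(np.arange(2000, 2003), 12)
        months = np.tile(np.arange(1, 13), 3)
        df = pd.DataFrame({"year": years, "month": months, "ppt": 10.0,
                           "tmean": 5.0, "tmax": 10.0, "tmin": 0.0})
        clim = cc.ClimateMatrix(df)
        agg = cc.seasonal_aggregate(clim, (3, 8))
        np.testing.assert_allclose(agg.to_numpy(), 60.0)

    def test_temperature_averaged_not_summed(self, climate_1948_2013):
        agg = cc.seasonal_aggregate(climate_1948_2013, (3, 8), variable="tmean")
        wide = climate_1948_2013.monthly("tmean")
        assert agg.loc[1990] == pytest.approx(wide.loc[1990, 3:8].mean())

    def test_season_months_expansion(self):
        assert season_months((10, 3)) == [(-1, 10), (-1, 11), (-1, 12),
                                          (0, 1), (0, 2), (0, 3)]
        assert season_months((3, 8)) == [(0, m) for m in range(3, 9)]


class TestFitLinearModel:
    def test_noiseless_published_coefficients_recovered(self):
        """A noiseless linear proxy-climate relation is fitted exactly."""
        rng = np.random.default_rng(1)
        x = 1 + 0.1 * rng.normal(size=64)
        chron = make_chronology(x)
        y = pd.Series(1297.30 * x - 976.47, index=chron.years)
        model = cc.fit_linear_model(chron, y, (1950, 2013))
        assert model.slope == pytest.approx(1297.30, abs=1e-8)
        assert model.intercept == pytest.approx(-976.47, abs=1e-8)
        assert model.r_squared == pytest.approx(1.0)

    def test_independent_chronology_has_low_r2(self):
        rng = np.random.default_rng(2)
        low = sum(
            cc.fit_linear_model(
                make_chronology(1 + 0.1 * rng.normal(size=64)),
                pd.Series(300 + 50 * rng.normal(size=64), index=np.arange(1950, 2014)),
                (1950, 2013),
            ).r_squared < 0.1
            for _ in range(50)
        )
        assert low >= 45

    def test_duplicated_points_leave_fit_unchanged(self):
        rng = np.random.default_rng(3)
        x = 1 + 0.1 * rng.normal(size=32)
        y = 500 * x + rng.normal(0, 30, 32)
        chron1 = make_chronology(x, first_year=1950)
        m1 = cc.fit_linear_model(chron1, pd.Series(y, index=chron1.years), (1950, 1981))
        chron2 = make_chronology(np.concatenate([x, x]), first_year=1950)
        m2 = cc.fit_linear_model(
            chron2, pd.Series(np.concatenate([y, y]), index=chron2.years), (1950, 2013)
        )
        assert m2.slope == pytest.approx(m1.slope, abs=1e-9)
        assert m2.intercept == pytest.approx(m1.intercept, abs=1e-9)


class TestVerify:
    def make_pair(self, r=0.55, n=64, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = 300 + 100 * (r * x + np.sqrt(1 - r * r) * rng.normal(size=n))
        return make_chronology(x + 5), pd.Series(y, index=np.arange(1950, 1950 + n))

    def test_perfect_predictions_score_one(self):
        chron, y = self.make_pair(r=0.999999, seed=1)
        y[:] = 10.0 * (chron.values - chron.values.mean()) + 400.0
        model = cc.fit_linear_model(chron, y, (1950, 1981))
        skill = cc.verify(model, chron, y, (1982, 2013))
        assert skill.re == pytest.approx(1.0)
        assert skill.ce == pytest.approx(1.0)

    def test_calibration_mean_prediction_anchors_re_at_zero(self):
        chron, y = self.make_pair(seed=2)
        cal_mean = y.loc[1950:1981].mean()
        model = cc.ReconstructionModel(
            intercept=cal_mean, slope=0.0, r_squared=0.0,
            calibration_period=(1950, 1981), season=(3, 8),
        )
        skill = cc.verify(model, chron, y, (1982, 2013))
        assert skill.re == pytest.approx(0.0, abs=1e-12)
        assert skill.ce <= 0.0

    def test_durbin_watson_hand_value(self):
        assert durbin_watson(np.array([1.0, -1.0, 1.0, -1.0])) == pytest.approx(3.0)

    def test_durbin_watson_white_noise_near_two(self):
        rng = np.random.default_rng(4)
        dws = [durbin_watson(rng.normal(size=32)) for _ in range(200)]
        assert 1.7 < np.mean(dws) < 2.3

    def test_overlapping_periods_rejected(self):
        chron, y = self.make_pair(seed=3)
        model = cc.fit_linear_model(chron, y, (1950, 1981))
        with pytest.raises(ReconstructionError, match="overlap"):
            cc.verify(model, chron, y, (1980, 2013))


class TestSplit:
    def test_default_split_halves(self):
        chron = make_chronology(1 + 0.1 * np.random.default_rng(5).normal(size=64))
        y = pd.Series(500 * chron.values + np.random.default_rng(6).normal(0, 30, 64),
                      index=chron.years)
        cv = cc.split_calibration_verification(chron, y)
        assert cv.forward.n_verification == 32
        assert cv.reverse.n_verification == 32
        assert cv.full_model.calibration_period == (1950, 2013)

    def test_swapping_halves_swaps_skill_records(self):
        chron = make_chronology(1 + 0.1 * np.random.default_rng(7).normal(size=64))
        y = pd.Series(500 * chron.values + np.random.default_rng(8).normal(0, 30, 64),
                      index=chron.years)
        cv = cc.split_calibration_verification(chron, y)
        swapped = cc.split_calibration_verification(
            chron, y, split=((1982, 2013), (1950, 1981))
        )
        assert swapped.forward.re == pytest.approx(cv.reverse.re)
        assert swapped.reverse.ce == pytest.approx(cv.forward.ce)

    def test_overlapping_halves_rejected(self):
        chron = make_chronology(np.linspace(0.9, 1.1, 64))
        y = pd.Series(np.arange(64.0) + 300, index=chron.years)
        with pytest.raises(ReconstructionError, match="overlap"):
            cc.split_calibration_verification(
                chron, y, split=((1950, 1985), (1982, 2013))
            )


class TestReconstruct:
    def test_equals_fitted_values_on_calibration_years(self):
        chron = make_chronology(1 + 0.1 * np.random.default_rng(9).normal(size=64))
        y = pd.Series(400 * chron.values + np.random.default_rng(10).normal(0, 20, 64),
                      index=chron.years)
        model = cc.fit_linear_model(chron, y, (1950, 2013))
        recon = cc.reconstruct(model, chron, y)
        fitted = model.intercept + model.slope * chron.values
        np.testing.assert_allclose(recon.values, fitted)
        assert len(recon) == 64

    def test_zero_slope_gives_constant_series(self):
        chron = make_chronology(1 + 0.1 * np.random.default_rng(11).normal(size=144),
                                first_year=1870)
        model = cc.ReconstructionModel(intercept=250.0, slope=0.0, r_squared=0.0,
                                       calibration_period=(1950, 2013), season=(3, 8))
        recon = cc.reconstruct(model, chron)
        assert len(recon) == 144
        np.testing.assert_allclose(recon.values, 250.0)


@given(st.integers(0, 10_000))
@settings(max_examples=100, deadline=None)
def test_re_never_below_ce(seed):
    """RE >= CE: the calibration mean cannot beat the verification mean in-sample."""
    rng = np.random.default_rng(seed)
    n_ver = int(rng.integers(3, 40))
    n_cal = int(rng.integers(10, 40))
    chron = make_chronology(rng.normal(size=n_cal + n_ver) + 5, first_year=1800)
    obs = pd.Series(rng.normal(300, 50, size=n_cal + n_ver), index=chron.years)
    model = cc.ReconstructionModel(
        intercept=float(rng.normal(300, 50)), slope=float(rng.normal(0, 50)),
        r_squared=0.0, calibration_period=(1800, 1800 + n_cal - 1), season=(3, 8),
    )
    skill = cc.verify(model, chron, obs, (1800 + n_cal, 1800 + n_cal + n_ver - 1))
    assert skill.re >= skill.ce - 1e-12
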