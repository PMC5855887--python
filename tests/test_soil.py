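"""Soil-moisture reconstruction: daily averaging, the rain-day rule,
standardized deviations, the deviation model, series prediction, gap
filling, the cumulative spring covariate, and precipitation extremes."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from steppewater import datagen, soil


def _frame(**cols):
    return pd.DataFrame(cols)


class TestAverageDaily:
    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            soil.average_daily(pd.DataFrame(columns=["date", "plot_id", "group_id",
                                                     "treatment", "vwc", "n_sensors"]))

    @pytest.mark.parametrize("vwc, expect_mean, expect_n", [
        ([0.20], 0.20, 1),
        ([0.10, 0.30], 0.20, 2),
    ])
    def test_plain_means(self, vwc, expect_mean, expect_n):
        df = _frame(date=[pd.Timestamp("2012-05-01")] * len(vwc), plot_id="A",
                    group_id=1, treatment="drought", depth_cm=5, vwc=vwc, n_sensors=1)
        out = soil.average_daily(df)
        assert out["vwc"].iloc[0] == pytest.approx(expect_mean)
        assert out["n_sensors"].iloc[0] == expect_n

    def test_depths_pooled_into_one_mean(self):
        df = _frame(date=[pd.Timestamp("2012-05-01")] * 2, plot_id="A", group_id=1,
                    treatment="drought", depth_cm=[5, 25], vwc=[0.25, 0.15], n_sensors=1)
        out = soil.average_daily(df)
        assert len(out) == 1
        assert out["vwc"].iloc[0] == pytest.approx(0.20)


class TestRainDays:
    @staticmethod
    def _weather(precips, temps):
        dates = pd.date_range("2012-05-01", periods=len(precips), freq="D")
        return _frame(date=dates, precip_mm=precips, tmean_c=temps)

    def test_wet_warm_day_is_rainy(self):
        w = self._weather([2.0], [10.0])
        assert soil.flag_rain_days(w).iloc[0]

    def test_day_after_rain_is_rainy_if_warm(self):
        w = self._weather([2.0, 0.0], [10.0, 5.0])
        assert soil.flag_rain_days(w).iloc[1]

    def test_cold_wet_day_excluded_as_snow(self):
        w = self._weather([2.0], [0.0])
        assert not soil.flag_rain_days(w).iloc[0]

    def test_dry_warm_day_not_rainy(self):
        w = self._weather([0.0, 0.0], [10.0, 10.0])
        assert not soil.flag_rain_days(w).any()

    def test_missing_day_rejected(self):
        w = self._weather([0.0, 0.0], [10.0, 10.0])
        w.loc[1, "date"] = pd.Timestamp("2012-05-04")
        with pytest.raises(ValueError, match="contiguous"):
            soil.flag_rain_days(w)


def _paired_days(n, amb, trt, treatment="drought"):
    dates = pd.date_range("2012-04-01", periods=n, freq="D")
    rows = []
    for d, a, x in zip(dates, amb, trt):
        rows.append({"date": d, "plot_id": "amb1", "group_id": 1,
                     "treatment": "ambient", "vwc": a, "n_sensors": 2})
        rows.append({"date": d, "plot_id": "trt1", "group_id": 1,
                     "treatment": treatment, "vwc": x, "n_sensors": 2})
    return pd.DataFrame(rows)


def _flat_weather(n, precip=0.0, tmean=10.0):
    dates = pd.date_range("2012-04-01", periods=n, freq="D")
    return _frame(date=dates, precip_mm=precip, tmean_c=tmean)


class TestStandardizeDeviations:
    def test_identical_series_give_zero_deltas(self):
        amb = np.linspace(0.1, 0.3, 10)
        pdm = _paired_days(10, amb, amb)
        dev = soil.standardize_deviations(pdm, _flat_weather(10))
        np.testing.assert_allclose(dev.deviations["delta"], 0.0)

    def test_constant_offset_standardized_by_ambient_sd(self):
        # ambient sd (sample) fixed by construction; offset +0.05
        amb = np.array([0.10, 0.20] * 5)
        sd = float(pd.Series(amb).std(ddof=1))
        pdm = _paired_days(10, amb, amb + 0.05)
        dev = soil.standardize_deviations(pdm, _flat_weather(10))
        np.testing.assert_allclose(dev.deviations["delta"], 0.05 / sd)

    def test_constant_ambient_series_rejected(self):
        pdm = _paired_days(10, np.full(10, 0.2), np.full(10, 0.15))
        with pytest.raises(ValueError, match="zero variance"):
            soil.standardize_deviations(pdm, _flat_weather(10))

    def test_ambient_scale_is_cross_group_mean_sd(self):
        amb = np.array([0.10, 0.20] * 5)
        pdm = _paired_days(10, amb, amb + 0.05)
        dev = soil.standardize_deviations(pdm, _flat_weather(10))
        assert dev.ambient_scale == pytest.approx(float(pd.Series(amb).std(ddof=1)))


def _synthetic_deviations(seed=0, n=400):
    """Deviations with known structure for model fitting tests."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2012-01-01", periods=n // 2, freq="D")
    w = _frame(date=dates, precip_mm=rng.choice([0.0, 4.0], size=len(dates)),
               tmean_c=rng.normal(10, 6, size=len(dates)))
    rows = []
    rain = soil.flag_rain_days(w)
    for i, d in enumerate(dates):
        for trt, main in (("drought", -1.5), ("irrigation", 1.5)):
            delta = main + rng.normal(0, 0.3)
            rows.append({"date": d, "group_id": 1 + i % 4, "treatment": trt,
                         "delta": delta,
                         "season": datagen.season_of([d]).iloc[0],
                         "rain_day": bool(rain.iloc[i]), "weight": 2})
    return soil.DeviationData(pd.DataFrame(rows), {1: 0.05, 2: 0.05, 3: 0.04, 4: 0.06}), w


class TestDeviationModel:
    def test_zero_deltas_give_zero_effects_and_variance(self):
        data, _ = _synthetic_deviations()
        data.deviations["delta"] = 0.0
        fit = soil.fit_deviation_model(data)
        np.testing.assert_allclose(fit.params, 0.0, atol=1e-10)
        assert fit.var_group == pytest.approx(0.0, abs=1e-12)
        assert fit.var_date == pytest.approx(0.0, abs=1e-12)

    def test_known_main_effects_recovered(self):
        data, _ = _synthetic_deviations(seed=1)
        fit = soil.fit_deviation_model(data)
        assert fit.treatment_effect("drought") == pytest.approx(-1.5, abs=0.15)
        assert fit.treatment_effect("irrigation") == pytest.approx(1.5, abs=0.15)

    def test_weights_scale_invariant(self):
        data, _ = _synthetic_deviations(seed=2)
        fit1 = soil.fit_deviation_model(data)
        data.deviations["weight"] = data.deviations["weight"] * 2
        fit2 = soil.fit_deviation_model(data)
        np.testing.assert_allclose(fit1.params, fit2.params, rtol=1e-10)

    def test_missing_treatment_level_rejected(self):
        data, _ = _synthetic_deviations()
        data.deviations = data.deviations[data.deviations["treatment"] == "drought"]
        with pytest.raises(ValueError, match="irrigation"):
            soil.DeviationModel(data)

    def test_single_season_rejected(self):
        data, _ = _synthetic_deviations()
        dev = data.deviations
        data.deviations = dev[dev["season"] == "winter"]
        with pytest.raises(ValueError, match="season"):
            soil.DeviationModel(data)


class TestPredictTreatedSeries:
    @staticmethod
    def _fit_with_deltas(drought=-1.0, irrigation=1.0, scale=0.05):
        data, w = _synthetic_deviations(seed=3)
        data.deviations["delta"] = np.where(
            data.deviations["treatment"] == "drought", drought, irrigation)
        for g in data.ambient_sd_by_group:
            data.ambient_sd_by_group[g] = scale
        data.__post_init__()
        return soil.fit_deviation_model(data), w

    def test_zero_model_reproduces_ambient(self):
        fit, w = self._fit_with_deltas(0.0, 0.0)
        amb = _frame(date=w["date"], vwc=np.linspace(0.1, 0.3, len(w)))
        series, gaps = soil.predict_treated_series(fit, amb, w)
        wide = series.pivot(index="date", columns="treatment", values="vwc_mean")
        np.testing.assert_allclose(wide["drought"], wide["ambient"], atol=1e-10)
        assert gaps == []

    def test_backtransform_arithmetic(self):
        fit, w = self._fit_with_deltas(drought=-1.0, scale=0.05)
        amb = _frame(date=w["date"], vwc=0.20)
        series, _ = soil.predict_treated_series(fit, amb, w)
        d = series[series["treatment"] == "drought"]["vwc_mean"]
        np.testing.assert_allclose(d, 0.15, atol=1e-8)

    def test_negative_prediction_clipped_with_warning(self):
        fit, w = self._fit_with_deltas(drought=-2.0, scale=0.05)
        amb = _frame(date=w["date"], vwc=0.02)  # 0.02 - 0.10 < 0
        with pytest.warns(UserWarning, match="clipped"):
            series, _ = soil.predict_treated_series(fit, amb, w)
        assert (series["vwc_mean"] >= 0).all()

    def test_days_without_ambient_reported_as_gaps(self):
        fit, w = self._fit_with_deltas()
        amb = _frame(date=w["date"][:-5], vwc=0.2)
        _, gaps = soil.predict_treated_series(fit, amb, w)
        assert len(gaps) == 5


class TestGapFill:
    @staticmethod
    def _series(dates, trt, vwc, source):
        return _frame(date=dates, treatment=trt, vwc_mean=vwc, source=source)

    def test_no_gaps_returns_statistical_series(self):
        dates = pd.date_range("2012-03-01", periods=10)
        stat = self._series(dates, "drought", 0.2, "statistical")
        surr = self._series(dates, "drought", 0.1, "surrogate")
        out = soil.gap_fill(stat, surr)
        np.testing.assert_allclose(out["vwc_mean"], 0.2)
        assert (out["source"] == "statistical").all()

    def test_empty_statistical_uses_surrogate_everywhere(self):
        dates = pd.date_range("2012-03-01", periods=10)
        stat = self._series(dates[:0], "drought", [], "statistical")
        surr = self._series(dates, "drought", 0.1, "surrogate")
        out = soil.gap_fill(stat, surr)
        assert len(out) == 10
        assert (out["source"] == "surrogate").all()

    def test_single_missing_day_filled_from_surrogate(self):
        dates = pd.date_range("2012-03-01", periods=10)
        stat = self._series(dates.drop(dates[3]), "drought", 0.2, "statistical")
        surr = self._series(dates, "drought", 0.1, "surrogate")
        out = soil.gap_fill(stat, surr)
        filled = out[out["source"] == "surrogate"]
        assert list(filled["date"]) == [dates[3]]

    def test_day_missing_from_both_rejected(self):
        dates = pd.date_range("2012-03-01", periods=10)
        stat = self._series(dates[:5], "drought", 0.2, "statistical")
        surr = self._series(dates[:8], "drought", 0.1, "surrogate")
        with pytest.raises(ValueError, match="missing from both"):
            soil.gap_fill(stat, surr, period=dates)


class TestCumulativeSpringVwc:
    @staticmethod
    def _daily(year=2013, value=0.1, treatment="drought"):
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        return _frame(date=dates, treatment=treatment, vwc_mean=value, source="statistical")

    def test_constant_series_sums_to_days_times_value(self):
        out = soil.cumulative_spring_vwc(self._daily(value=0.1), 2013)
        assert out["drought"] == pytest.approx(12.2)  # 122 days x 0.1

    def test_linear_in_daily_values(self):
        base = self._daily(value=0.13)
        scaled = base.assign(vwc_mean=base["vwc_mean"] * 0.88)
        a = soil.cumulative_spring_vwc(base, 2013)["drought"]
        b = soil.cumulative_spring_vwc(scaled, 2013)["drought"]
        assert b == pytest.approx(0.88 * a)

    def test_missing_window_day_rejected(self):
        daily = self._daily()
        daily = daily[daily["date"] != pd.Timestamp("2013-04-15")]
        with pytest.raises(ValueError, match="2013-04-15"):
            soil.cumulative_spring_vwc(daily, 2013)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            soil.cumulative_spring_vwc(self._daily().iloc[:0], 2013)


class TestPrecipExtremes:
    def test_degenerate_constant_record(self):
        out = soil.precip_extremes(np.full(30, 250.0))
        assert out["q01_mm"] == pytest.approx(250.0)
        assert out["pct_change_low"] == pytest.approx(0.0)
        assert out["pct_change_high"] == pytest.approx(0.0)

    def test_gamma_samples_match_closed_form_quantiles(self):
        rng = np.random.default_rng(12)
        k, theta = 4.0, 60.0
        x = rng.gamma(k, theta, size=5000)
        out = soil.precip_extremes(x)
        q01_true = scipy.stats.gamma.ppf(0.01, k, scale=theta)
        q99_true = scipy.stats.gamma.ppf(0.99, k, scale=theta)
        assert out["q01_mm"] == pytest.approx(q01_true, rel=0.05)
        assert out["q99_mm"] == pytest.approx(q99_true, rel=0.05)

    def test_nonpositive_totals_rejected(self):
        with pytest.raises(ValueError):
            soil.precip_extremes(np.concatenate([np.full(25, 200.0), [0.0]]))

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            soil.precip_extremes(np.full(10, 200.0))


class TestEndToEndRecovery:
    def test_reconstruction_tracks_latent_truth(self, sim_config, true_params, weather,
                                                sensor_data):
        """Full chain: sensors -> deviations -> model -> treated series."""
        readings, latent = sensor_data
        daily = soil.average_daily(readings)
        dev = soil.standardize_deviations(daily, weather)
        fit = soil.fit_deviation_model(dev)
        ambient_daily = (daily[daily["treatment"] == "ambient"]
                         .groupby("date", as_index=False)["vwc"].mean())
        series, _ = soil.predict_treated_series(fit, ambient_daily, weather)
        wide_est = series.pivot(index="date", columns="treatment", values="vwc_mean")
        wide_true = latent.pivot(index="date", columns="treatment", values="vwc_true")
        for trt in ("drought", "irrigation"):
            r = np.corrcoef(wide_est[trt], wide_true.loc[wide_est.index, trt])[0, 1]
            assert r > 0.9
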