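"""Reconstruction of daily soil moisture in treated plots.

Treated-plot volumetric water content (VWC) is only measured on a subset of
plot-days.  The reconstruction standardizes treated-minus-ambient deviations
by each plot group's ambient variability, models those deviations as a
function of treatment, season, and rain with all two-way interactions, adds
fixed-effect predicted deviations (rescaled back to VWC units) to the daily
ambient mean, gap-fills remaining days with a surrogate process-model series,
and aggregates to the cumulative March-June VWC covariate.  A helper fits a
gamma distribution to historical water-year precipitation to characterize
1%/99% extremes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .datagen import season_of

SEASONS = ("winter", "spring", "summer", "fall")


def average_daily(readings: pd.DataFrame) -> pd.DataFrame:
    """Mean VWC per plot-day with summed sensor counts.

    Sensors at both depths (5 and 25 cm) are pooled into a single plot-day
    mean; the total sensor count is carried as the downstream model weight.
    """
    if len(readings) == 0:
        raise ValueError("no sensor readings supplied")
    grouped = (readings
               .groupby(["date", "plot_id", "group_id", "treatment"], as_index=False)
               .agg(vwc=("vwc", "mean"), n_sensors=("n_sensors", "sum")))
    return grouped


def flag_rain_days(weather: pd.DataFrame) -> pd.Series:
    """Rain-day flag: measurable precipitation today or yesterday, and warm.

    A day is a rain day iff (precip > 0 on the day, or precip > 0 on the
    previous day) and the mean temperature exceeds 3 degC — the temperature
    gate excludes snowfall days.  Requires contiguous daily weather.
    """
    dates = pd.DatetimeIndex(weather["date"])
    if len(dates) > 1:
        gaps = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if (gaps != 1).any():
            bad = dates[1:][gaps != 1]
            raise ValueError(f"weather series not contiguous before: {list(bad.strftime('%Y-%m-%d'))[:5]}")
    precip = weather["precip_mm"].to_numpy(dtype=float)
    wet_today = precip > 0
    wet_yesterday = np.concatenate([[False], wet_today[:-1]])
    warm = weather["tmean_c"].to_numpy(dtype=float) > 3.0
    return pd.Series((wet_today | wet_yesterday) & warm, index=weather.index, name="rain_day")


@dataclass
class DeviationData:
    """Standardized deviations plus the ambient scales used to build them."""

    deviations: pd.DataFrame          #: date, group_id, treatment, delta, season, rain_day, weight
    ambient_sd_by_group: dict         #: group_id -> s.d. of that group's ambient series
    ambient_scale: float = field(init=False)  #: cross-group mean ambient s.d. (back-transform scale)

    def __post_init__(self):
        self.ambient_scale = float(np.mean(list(self.ambient_sd_by_group.values())))


def standardize_deviations(plot_day_means: pd.DataFrame, weather: pd.DataFrame) -> DeviationData:
    """Standardized treatment deviations from ambient, per group and day.

    For each group g, day d, and treatment,
    ``delta = (x_trt - x_ambient) / s.d.(x_ambient)`` where the standard
    deviation is taken over all observed days of the group's ambient series.
    Season (meteorological quarters) and the rain-day flag are attached; the
    treated plot-day's sensor count becomes the regression weight.
    """
    rain = flag_rain_days(weather)
    rain_by_date = dict(zip(pd.DatetimeIndex(weather["date"]), rain))

    amb = plot_day_means[plot_day_means["treatment"] == "ambient"]
    trt = plot_day_means[plot_day_means["treatment"] != "ambient"]
    if amb.empty:
        raise ValueError("no ambient readings present")

    sd_by_group = {}
    for g, sub in amb.groupby("group_id"):
        if len(sub) < 2:
            raise ValueError(f"group {g}: ambient series needs >= 2 days for an s.d.")
        sd = float(sub["vwc"].std(ddof=1))
        if sd == 0:
            raise ValueError(f"group {g}: ambient series has zero variance")
        sd_by_group[g] = sd

    amb_lookup = {(r.group_id, r.date): r.vwc for r in amb.itertuples()}
    rows = []
    for r in trt.itertuples():
        key = (r.group_id, r.date)
        if key not in amb_lookup:
            continue  # deviations only defined on days with an ambient measurement
        date = pd.Timestamp(r.date)
        rows.append({
            "date": date, "group_id": r.group_id, "treatment": r.treatment,
            "delta": (r.vwc - amb_lookup[key]) / sd_by_group[r.group_id],
            "season": season_of([date]).iloc[0],
            "rain_day": bool(rain_by_date.get(date, False)),
            "weight": r.n_sensors,
        })
    return DeviationData(pd.DataFrame(rows), sd_by_group)


@dataclass
class DeviationModelResults:
    """Fitted deviation model: fixed effects + variance components."""

    params: pd.Series                 #: fixed-effect coefficients (treatment*season, treatment*rain, season*rain)
    bse: pd.Series                    #: date-cluster-robust standard errors
    var_group: float                  #: group random-intercept variance (moment estimate)
    var_date: float                   #: date random-intercept variance (moment estimate)
    var_resid: float
    ambient_scale: float              #: s (VWC units per standardized-deviation unit)
    seasons: tuple = SEASONS          #: season levels present in the fit
    _sm_results: object = None

    def predict_deviation(self, treatment, season, rain_day) -> np.ndarray:
        """Fixed-effect predicted standardized deviation for given conditions."""
        frame = pd.DataFrame({
            "treatment": np.atleast_1d(treatment),
            "season": np.atleast_1d(season),
            "rain_day": np.atleast_1d(rain_day).astype(bool),
        })
        return np.asarray(self._sm_results.predict(frame))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self._sm_results.conf_int(alpha=alpha)

    def treatment_effect(self, treatment: str, rain_day: bool = False) -> float:
        """Season-averaged predicted deviation for a treatment (rain-free by default)."""
        seasons = list(self.seasons)
        preds = self.predict_deviation([treatment] * len(seasons), seasons,
                                       [rain_day] * len(seasons))
        return float(np.mean(preds))


class DeviationModel:
    """Weighted regression of standardized deviations on treatment x season x rain.

    Fixed effects comprise treatment, season, rain-day and all two-way
    interactions, weighted by sensor counts.  Fixed-effect uncertainty uses
    date-cluster-robust covariance; group and date variance components are
    estimated by the method of moments on weighted residuals, since only the
    fixed-effect predictions feed the downstream reconstruction.
    """

    def __init__(self, data: DeviationData):
        dev = data.deviations
        if dev.empty:
            raise ValueError("no deviation records")
        for col, levels in (("treatment", {"drought", "irrigation"}),
                            ("rain_day", {True, False})):
            missing = levels - set(dev[col].unique())
            if missing:
                raise ValueError(f"design is rank deficient: missing {col} level(s) {sorted(map(str, missing))}")
        if dev["season"].nunique() < 2:
            present = sorted(dev["season"].unique())
            raise ValueError(f"design is rank deficient: only season level(s) {present} present")
        self.data = data

    def fit(self) -> DeviationModelResults:
        dev = self.data.deviations.copy()
        dev["rain_day"] = dev["rain_day"].astype(bool)
        seasons_present = [s for s in SEASONS if s in set(dev["season"])]
        dev["season"] = pd.Categorical(dev["season"], categories=seasons_present)
        formula = ("delta ~ C(treatment) * C(season) + C(treatment) * rain_day "
                   "+ C(season) * rain_day")
        model = smf.wls(formula, data=dev, weights=dev["weight"].to_numpy(dtype=float))
        res = model.fit(cov_type="cluster", cov_kwds={"groups": dev["date"]})

        resid = res.resid.to_numpy() if hasattr(res.resid, "to_numpy") else np.asarray(res.resid)
        var_resid = float(np.average(resid ** 2, weights=dev["weight"]))
        var_group = _between_variance(resid, dev["group_id"].to_numpy(), var_resid)
        var_date = _between_variance(resid, dev["date"].to_numpy(), var_resid)
        return DeviationModelResults(
            params=res.params, bse=res.bse,
            var_group=var_group, var_date=var_date, var_resid=var_resid,
            ambient_scale=self.data.ambient_scale,
            seasons=tuple(seasons_present),
            _sm_results=res,
        )


def _between_variance(resid: np.ndarray, labels: np.ndarray, var_resid: float) -> float:
    """Moment estimate of a random-intercept variance from residual cluster means."""
    df = pd.DataFrame({"r": resid, "g": labels})
    means = df.groupby("g")["r"].mean()
    sizes = df.groupby("g")["r"].size()
    if len(means) < 2:
        return 0.0
    # Var(cluster mean) = var_between + var_resid / n_g
    v = float(means.var(ddof=1) - var_resid * float((1.0 / sizes).mean()))
    return max(v, 0.0)


def fit_deviation_model(deviation_data: DeviationData) -> DeviationModelResults:
    """Convenience wrapper: ``DeviationModel(data).fit()``."""
    return DeviationModel(deviation_data).fit()


def predict_treated_series(fit: DeviationModelResults, ambient_daily: pd.DataFrame,
                           weather: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Daily treated-plot VWC series from fixed-effect predicted deviations.

    ``vwc(trt, d) = s * delta_hat(trt, season(d), rain(d)) + vwc(ambient, d)``
    where s is the cross-group mean ambient s.d. (dimensional back-transform).
    Days without an ambient value are excluded and returned in the gap list.
    Negative back-transformed values are clipped to 0 with a warning.
    """
    rain = flag_rain_days(weather)
    wdates = pd.DatetimeIndex(weather["date"])
    rain_by_date = dict(zip(wdates, rain))

    amb = ambient_daily.dropna(subset=["vwc"]).copy()
    amb["date"] = pd.DatetimeIndex(amb["date"])
    gaps = sorted(set(wdates) - set(amb["date"]))

    out = [pd.DataFrame({"date": amb["date"], "treatment": "ambient",
                         "vwc_mean": amb["vwc"].to_numpy(), "source": "observed"})]
    seasons = season_of(amb["date"]).to_numpy()
    rains = np.array([rain_by_date.get(d, False) for d in amb["date"]])
    n_clipped = 0
    for trt in ("drought", "irrigation"):
        delta = fit.predict_deviation([trt] * len(amb), seasons, rains)
        vwc = fit.ambient_scale * delta + amb["vwc"].to_numpy()
        n_clipped += int((vwc < 0).sum())
        vwc = np.clip(vwc, 0.0, None)
        out.append(pd.DataFrame({"date": amb["date"], "treatment": trt,
                                 "vwc_mean": vwc, "source": "statistical"}))
    if n_clipped:
        warnings.warn(f"{n_clipped} negative predicted VWC value(s) clipped to 0")
    series = pd.concat(out, ignore_index=True).sort_values(["treatment", "date"], ignore_index=True)
    return series, [pd.Timestamp(g) for g in gaps]


def gap_fill(statistical_series: pd.DataFrame, surrogate_series: pd.DataFrame,
             period=None) -> pd.DataFrame:
    """Merge the statistical series with a surrogate process-model series.

    The statistical estimate is used wherever available; the surrogate fills
    the remaining days.  Source flags are preserved (statistical rows keep
    theirs, filled rows are flagged ``surrogate``).  If ``period`` (an
    iterable of dates) is given, any day missing from both series for some
    treatment raises an error listing the dates.
    """
    surr = surrogate_series.copy()
    surr["date"] = pd.DatetimeIndex(surr["date"])
    surr["source"] = "surrogate"
    stat = statistical_series.copy()
    if len(stat):
        stat["date"] = pd.DatetimeIndex(stat["date"])

    pieces = []
    for trt in sorted(surr["treatment"].unique()):
        s_stat = stat[stat["treatment"] == trt] if len(stat) else stat
        s_surr = surr[surr["treatment"] == trt]
        have = set(s_stat["date"]) if len(s_stat) else set()
        fill = s_surr[~s_surr["date"].isin(have)]
        piece = pd.concat([s_stat, fill], ignore_index=True)
        if period is not None:
            covered = set(piece["date"])
            missing = [pd.Timestamp(d) for d in period if pd.Timestamp(d) not in covered]
            if missing:
                shown = ", ".join(d.strftime("%Y-%m-%d") for d in missing[:10])
                raise ValueError(f"treatment {trt!r}: days missing from both series: {shown}")
        pieces.append(piece)
    merged = pd.concat(pieces, ignore_index=True).sort_values(["treatment", "date"], ignore_index=True)
    return merged


def cumulative_spring_vwc(daily_series: pd.DataFrame, year: int) -> pd.Series:
    """Cumulative VWC over March 1 - June 30 of ``year``, per treatment.

    Errors if any day in the window is missing for a treatment (gap-fill
    first); the error lists the missing dates.
    """
    window = pd.date_range(f"{year}-03-01", f"{year}-06-30", freq="D")
    out = {}
    for trt, sub in daily_series.groupby("treatment"):
        dates = set(pd.DatetimeIndex(sub["date"]))
        missing = [d for d in window if d not in dates]
        if missing:
            shown = ", ".join(d.strftime("%Y-%m-%d") for d in missing[:10])
            raise ValueError(f"treatment {trt!r}, year {year}: missing days in Mar-Jun window: {shown}")
        mask = pd.DatetimeIndex(sub["date"]).isin(window)
        out[trt] = float(sub.loc[mask, "vwc_mean"].sum())
    if not out:
        raise ValueError("daily series is empty")
    return pd.Series(out, name=f"cum_vwc_{year}")


def precip_extremes(historical_water_year_precip) -> dict:
    """Gamma-ML characterization of water-year precipitation extremes.

    Fits a two-parameter gamma distribution (location fixed at 0) by maximum
    likelihood and reports the 1% and 99% quantiles plus their percent
    deviation from the fitted distribution mean.
    """
    x = np.asarray(historical_water_year_precip, dtype=float)
    if len(x) < 20:
        raise ValueError("need >= 20 annual precipitation totals")
    if (x <= 0).any():
        raise ValueError("water-year precipitation totals must be > 0")
    if np.allclose(x, x[0]):
        c = float(x[0])
        return {"q01_mm": c, "q99_mm": c, "pct_change_low": 0.0, "pct_change_high": 0.0}
    shape, _, scale = scipy.stats.gamma.fit(x, floc=0)
    mean = shape * scale
    q01 = float(scipy.stats.gamma.ppf(0.01, shape, scale=scale))
    q99 = float(scipy.stats.gamma.ppf(0.99, shape, scale=scale))
    return {
        "q01_mm": q01,
        "q99_mm": q99,
        "pct_change_low": 100.0 * (mean - q01) / mean,
        "pct_change_high": 100.0 * (q99 - mean) / mean,
    }
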