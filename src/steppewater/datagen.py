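"""Seeded generators for every input table the analysis pipeline consumes.

The generators emulate the structure of a multi-year precipitation-manipulation
experiment in a semi-arid steppe: daily weather with discrete rain events,
ambient soil-moisture dynamics with rain pulses and sensor dropout, treatment
deviations expressed in ambient-standard-deviation units, a radiometric
greenness-to-biomass calibration set, plot-year ANPP records drawn from the
hierarchical regression model, and multi-year community abundance matrices
with an optional imposed treatment shift.

Every generator takes an explicit seed (through :class:`SimConfig`) and is
bit-reproducible.  Latent "truth" series and random effects are always
returned alongside the noisy observables so that recovery tests can compare
estimates against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENTS = ("control", "drought", "irrigation")
SENSOR_TREATMENTS = ("ambient", "drought", "irrigation")
#: Radiometer wavelengths (nm): two red and two near-infrared bands.
BANDS = ("r626", "r652", "r859", "r875")

_MONTH_TO_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


def season_of(dates) -> pd.Series:
    """Meteorological season (DJF/MAM/JJA/SON) for a datetime-like series."""
    months = pd.DatetimeIndex(dates).month
    return pd.Series([_MONTH_TO_SEASON[m] for m in months], index=None)


@dataclass
class DeviationEffects:
    """Coefficients of the soil-moisture deviation process.

    All values are in units of the ambient series' standard deviation
    (the scale on which treated-minus-ambient deviations are standardized).

    Parameters
    ----------
    drought, irrigation
        Treatment main effects (deviation on a rain-free reference day).
    season
        Additive season offsets shared by both treatments; keys from
        {"winter", "spring", "summer", "fall"}, missing keys mean 0.
    rain
        Additive offset on rain days shared by both treatments.
    treatment_rain
        Treatment-specific extra offset on rain days (e.g. shelters
        intercept rainfall, so drought plots deviate more on rain days).
    treatment_season
        Optional {(treatment, season): offset} interactions.
    """

    drought: float = -1.5
    irrigation: float = 1.5
    season: dict = field(default_factory=dict)
    rain: float = 0.0
    treatment_rain: dict = field(default_factory=lambda: {"drought": -0.5, "irrigation": 0.5})
    treatment_season: dict = field(default_factory=dict)

    def deviation(self, treatment: str, season: str, rain_day: bool) -> float:
        if treatment == "ambient":
            return 0.0
        d = {"drought": self.drought, "irrigation": self.irrigation}[treatment]
        d += self.season.get(season, 0.0)
        d += self.treatment_season.get((treatment, season), 0.0)
        if rain_day:
            d += self.rain + self.treatment_rain.get(treatment, 0.0)
        return d


@dataclass
class TrueParams:
    """Generative parameters shared by the synthetic tables.

    ``beta`` is the 6-vector of fixed effects on the standardized scale:
    (intercept, drought intercept offset, irrigation intercept offset,
    VWC slope, drought x VWC offset, irrigation x VWC offset).
    ``Sigma`` is the 2x2 covariance of the plot random intercept/slope,
    ``sigma_year`` the s.d. of year effects and ``sigma_obs`` the residual
    s.d.  ``calib_*`` map the greenness index to biomass (g m^-2).
    """

    beta: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.6, -0.4, 0.5, 0.5, 0.0]))
    Sigma: np.ndarray = field(default_factory=lambda: 0.2 * np.eye(2))
    sigma_year: float = 0.3
    sigma_obs: float = 0.5
    deviation_effects: DeviationEffects = field(default_factory=DeviationEffects)
    calib_slope: float = 400.0
    calib_intercept: float = 20.0
    calib_sd: float = 25.0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (6,):
            raise ValueError("beta must be a 6-vector")
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.shape != (2, 2) or not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric 2x2")
        if np.min(np.linalg.eigvalsh(self.Sigma)) < -1e-10:
            raise ValueError("Sigma must be positive semi-definite")
        for name in ("sigma_year", "sigma_obs", "calib_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimConfig:
    """Study-design configuration: plot counts, duration, seed, noise knobs.

    Defaults mirror the field experiment: 14 control, 8 drought and
    8 irrigation plots followed for 5 years, with four sensor-equipped
    drought-irrigation pairs and ~30% sensor dropout.
    """

    n_control: int = 14
    n_drought: int = 8
    n_irrigation: int = 8
    n_years: int = 5
    seed: int = 0
    sensor_dropout_rate: float = 0.3
    rain_prob: float = 0.25
    start_year: int = 2011
    n_sensor_groups: int = 4
    sensors_per_plot: int = 4
    sensor_noise_sd: float = 0.01

    def __post_init__(self):
        if min(self.n_control, self.n_drought, self.n_irrigation) < 1:
            raise ValueError("plot counts must be >= 1")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not 0.0 <= self.sensor_dropout_rate <= 1.0:
            raise ValueError("sensor_dropout_rate must be in [0, 1]")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))

    def dates(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(year=self.start_year, month=1, day=1)
        end = pd.Timestamp(year=self.start_year + self.n_years - 1, month=12, day=31)
        return pd.date_range(start, end, freq="D")


def gen_weather(config: SimConfig) -> pd.DataFrame:
    """Daily weather table: date, precip_mm, tmean_c.

    Temperature follows an annual sinusoid (January minimum around -5 degC,
    July maximum around 22 degC) with day-to-day noise, so winter days fall
    below the 3 degC snow-exclusion threshold.  Precipitation is a Bernoulli
    rain-day process with gamma-distributed amounts.
    """
    rng = config.rng(stream=1)
    dates = config.dates()
    doy = dates.dayofyear.to_numpy()
    # annual cycle peaking mid-July (doy ~196), trough mid-January
    tmean = 8.3 + 13.5 * np.cos(2 * np.pi * (doy - 196) / 365.25)
    tmean = tmean + rng.normal(0.0, 3.0, size=len(dates))
    wet = rng.random(len(dates)) < config.rain_prob
    amounts = rng.gamma(shape=1.2, scale=3.0, size=len(dates))
    precip = np.where(wet, amounts, 0.0)
    return pd.DataFrame({"date": dates, "precip_mm": precip, "tmean_c": tmean})


def _ambient_latent(config: SimConfig, weather: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Ambient daily VWC: spring-peaking sinusoid + exponential rain-pulse decay + AR(1)."""
    dates = pd.DatetimeIndex(weather["date"])
    doy = dates.dayofyear.to_numpy()
    baseline = 0.14 + 0.06 * np.cos(2 * np.pi * (doy - 105) / 365.25)  # peak mid-April
    pulse = np.zeros(len(dates))
    precip = weather["precip_mm"].to_numpy()
    decay = 0.85
    gain = 0.004  # VWC pulse per mm of rain
    for i in range(len(dates)):
        prev = pulse[i - 1] if i > 0 else 0.0
        pulse[i] = decay * prev + gain * precip[i]
    ar = np.zeros(len(dates))
    eps = rng.normal(0.0, 0.004, size=len(dates))
    phi = 0.8
    for i in range(len(dates)):
        ar[i] = phi * (ar[i - 1] if i > 0 else 0.0) + eps[i]
    return np.clip(baseline + pulse + ar, 0.0, None)


def gen_soil_sensor_data(config: SimConfig, true_params: TrueParams,
                         weather: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sensor soil-moisture readings plus the latent daily series.

    Returns
    -------
    readings : DataFrame
        Columns date, plot_id, group_id, treatment, depth_cm, vwc, n_sensors.
        One row per surviving sensor-day (sensors drop out independently at
        ``config.sensor_dropout_rate``); ``n_sensors`` is 1 per raw row.
    latent : DataFrame
        Columns date, treatment, vwc_true with the noise-free daily series
        for ambient, drought and irrigation (treatment-level truth).
    """
    if config.sensor_dropout_rate >= 1.0:
        raise ValueError("sensor_dropout_rate = 1 leaves no observations")
    rng = config.rng(stream=2)
    from .soil import flag_rain_days  # shared rain-day rule

    dates = pd.DatetimeIndex(weather["date"])
    ambient = _ambient_latent(config, weather, rng)
    sd_amb = float(np.std(ambient))
    rain = flag_rain_days(weather).to_numpy()
    seasons = season_of(dates).to_numpy()

    dev = true_params.deviation_effects
    latent = {"ambient": ambient}
    for trt in ("drought", "irrigation"):
        delta = np.array([dev.deviation(trt, s, bool(r)) for s, r in zip(seasons, rain)])
        latent[trt] = np.clip(ambient + sd_amb * delta, 0.0, None)

    latent_df = pd.concat(
        [pd.DataFrame({"date": dates, "treatment": trt, "vwc_true": series})
         for trt, series in latent.items()],
        ignore_index=True,
    )

    rows = []
    depths = [5, 25] * (config.sensors_per_plot // 2) or [5]
    for g in range(1, config.n_sensor_groups + 1):
        for trt in SENSOR_TREATMENTS:
            plot_id = f"G{g}_{trt}"
            series = latent[trt]
            for s_idx in range(config.sensors_per_plot):
                noise = rng.normal(0.0, config.sensor_noise_sd, size=len(dates))
                keep = rng.random(len(dates)) >= config.sensor_dropout_rate
                vwc = np.clip(series + noise, 0.0, None)
                rows.append(pd.DataFrame({
                    "date": dates[keep],
                    "plot_id": plot_id,
                    "group_id": g,
                    "treatment": trt,
                    "depth_cm": depths[s_idx % len(depths)],
                    "vwc": vwc[keep],
                    "n_sensors": 1,
                }))
    readings = pd.concat(rows, ignore_index=True)
    return readings, latent_df


def gen_calibration_set(config: SimConfig, true_params: TrueParams,
                        n_plots: int = 15, year: int | None = None) -> pd.DataFrame:
    """Calibration harvest: four-band radiometer means + dried biomass.

    Biomass is linear in the greenness index computed from the (652, 859) nm
    pair; the (626, 875) nm bands carry a small extra perturbation so the two
    candidate pairings are distinguishable by fit quality.  Negative simulated
    biomass is truncated at zero and flagged in the ``truncated`` column.
    """
    if true_params.calib_sd < 0:
        raise ValueError("calib_sd must be >= 0")
    if n_plots < 3:
        raise ValueError("need at least 3 calibration plots")
    rng = config.rng(stream=3)
    year = config.start_year if year is None else year
    index = rng.uniform(0.05, 0.6, size=n_plots)
    red652 = rng.uniform(0.05, 0.25, size=n_plots)
    nir859 = red652 * (1 + index) / (1 - index)
    # second pairing: same underlying greenness with small band-specific jitter
    jitter = rng.normal(0.0, 0.01, size=n_plots)
    index2 = np.clip(index + jitter, -0.9, 0.9)
    red626 = red652 * rng.uniform(0.97, 1.03, size=n_plots)
    nir875 = red626 * (1 + index2) / (1 - index2)
    biomass = (true_params.calib_intercept + true_params.calib_slope * index
               + rng.normal(0.0, true_params.calib_sd, size=n_plots))
    truncated = biomass < 0
    biomass = np.where(truncated, 0.0, biomass)
    return pd.DataFrame({
        "plot_id": [f"C{i+1}" for i in range(n_plots)],
        "year": year,
        "r626": red626, "r652": red652, "r859": nir859, "r875": nir875,
        "biomass_g_m2": biomass,
        "truncated": truncated,
    })


def gen_anpp_dataset(config: SimConfig, true_params: TrueParams,
                     vwc_by_treatment_year: pd.DataFrame,
                     anpp_log_mean: float = 5.0, anpp_log_sd: float = 0.5,
                     ) -> tuple[pd.DataFrame, dict]:
    """Plot-year ANPP records drawn from the hierarchical regression model.

    The linear predictor on the standardized scale is
    ``y_i = beta.x_i + gamma_j.z_i + eta_t + eps_i`` with plot coefficients
    ``gamma_j ~ MVN(0, Sigma)``, year effects ``eta_t ~ N(0, sigma_year)``
    and residuals ``eps ~ N(0, sigma_obs)``.  The standardized response is
    mapped back to ANPP in g m^-2 through ``exp(anpp_log_mean +
    anpp_log_sd * y)`` so the table carries physically plausible biomass.

    Parameters
    ----------
    vwc_by_treatment_year : DataFrame
        Columns treatment, treatment_year, vwc — one cumulative spring VWC
        value per treatment-year (the shared-covariate structure).

    Returns
    -------
    records : DataFrame with plot_id, treatment, treatment_year, anpp, vwc.
    truth : dict with keys "gamma" (n_plots x 2), "eta" (n_years,),
        "y_std" (standardized response), "plot_ids", and the VWC
        standardization constants.
    """
    vt = vwc_by_treatment_year
    required = {"treatment", "treatment_year", "vwc"}
    if not required.issubset(vt.columns):
        raise ValueError(f"vwc table needs columns {sorted(required)}")
    if vt.duplicated(["treatment", "treatment_year"]).any():
        raise ValueError("vwc table must have one value per treatment-year")
    np.linalg.cholesky(true_params.Sigma + 1e-12 * np.eye(2))  # PSD guard

    rng = config.rng(stream=4)
    plots = ([("control", f"P{i+1}") for i in range(config.n_control)]
             + [("drought", f"D{i+1}") for i in range(config.n_drought)]
             + [("irrigation", f"I{i+1}") for i in range(config.n_irrigation)])
    years = sorted(vt["treatment_year"].unique())

    vwc_all = vt["vwc"].to_numpy(dtype=float)
    v_mean, v_sd = float(np.mean(vwc_all)), float(np.std(vwc_all))
    if v_sd == 0:
        v_sd = 1.0  # degenerate covariate: leave unscaled
    vwc_map = {(r.treatment, r.treatment_year): float(r.vwc) for r in vt.itertuples()}

    n_plots = len(plots)
    # MVN draw via Cholesky of Sigma (works for PSD incl. zero matrix)
    L = np.linalg.cholesky(true_params.Sigma + 1e-12 * np.eye(2))
    gamma = rng.standard_normal((n_plots, 2)) @ L.T
    if np.allclose(true_params.Sigma, 0):
        gamma = np.zeros((n_plots, 2))
    eta = rng.normal(0.0, true_params.sigma_year, size=len(years)) if true_params.sigma_year > 0 \
        else np.zeros(len(years))

    from .response import build_design_row
    rows, y_std = [], []
    for j, (trt, pid) in enumerate(plots):
        for t_idx, year in enumerate(years):
            key = (trt, year)
            if key not in vwc_map:
                raise ValueError(f"vwc table missing treatment-year {key}")
            v = (vwc_map[key] - v_mean) / v_sd
            x = build_design_row(trt, v)
            z = np.array([1.0, v])
            eps = rng.normal(0.0, true_params.sigma_obs) if true_params.sigma_obs > 0 else 0.0
            y = float(true_params.beta @ x + gamma[j] @ z + eta[t_idx] + eps)
            y_std.append(y)
            rows.append({
                "plot_id": pid, "treatment": trt, "treatment_year": year,
                "anpp": float(np.exp(anpp_log_mean + anpp_log_sd * y)),
                "vwc": vwc_map[key],
            })
    records = pd.DataFrame(rows)
    records_std = records[["plot_id", "treatment", "treatment_year"]].copy()
    records_std["y_std"] = np.array(y_std)
    records_std["vwc_std"] = (records["vwc"].to_numpy() - v_mean) / v_sd
    truth = {
        "gamma": gamma, "eta": eta, "y_std": np.array(y_std),
        "records_std": records_std,
        "plot_ids": [p for _, p in plots],
        "vwc_mean": v_mean, "vwc_sd": v_sd,
        "anpp_log_mean": anpp_log_mean, "anpp_log_sd": anpp_log_sd,
    }
    return records, truth


def default_vwc_table(config: SimConfig, base: float = 12.0, spread: float = 3.0,
                      drought_frac: float = 0.88, irrigation_frac: float = 1.19,
                      ) -> pd.DataFrame:
    """Cumulative spring VWC per treatment-year with realistic offsets.

    Control values vary across years around ``base``; drought and irrigation
    scale them by ``drought_frac``/``irrigation_frac`` (the study-scale 12%
    reduction and 19% increase).
    """
    rng = config.rng(stream=5)
    years = np.arange(1, config.n_years + 1)
    control = base + rng.uniform(-spread, spread, size=len(years))
    rows = []
    for t, c in zip(years, control):
        rows.append({"treatment": "control", "treatment_year": int(t), "vwc": c})
        rows.append({"treatment": "drought", "treatment_year": int(t), "vwc": c * drought_frac})
        rows.append({"treatment": "irrigation", "treatment_year": int(t), "vwc": c * irrigation_frac})
    return pd.DataFrame(rows)


def gen_community_matrix(config: SimConfig, shift_size: float = 0.0,
                         n_species: int = 12, stream: int = 6) -> pd.DataFrame:
    """Plot-year x species abundance table with measure-type labels.

    Species abundances are lognormal around species-specific means that are
    stable across years (the multi-year stability seen in long-lived perennial
    communities).  With ``shift_size = 0`` the composition is exchangeable
    across treatments (null case).  With ``shift_size > 0`` treated plots'
    log-mean abundances are displaced by ``shift_size`` s.d. along a fixed
    species direction (drought and irrigation in opposite senses), for power
    experiments.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if shift_size < 0:
        raise ValueError("shift_size must be >= 0")
    rng = config.rng(stream=stream)
    measure_types = rng.choice(["density", "basal_cover", "canopy_cover"], size=n_species)
    log_means = rng.normal(1.0, 1.0, size=n_species)
    log_sd = 0.4
    direction = rng.standard_normal(n_species)
    direction /= np.linalg.norm(direction)

    plots = ([("control", f"P{i+1}") for i in range(config.n_control)]
             + [("drought", f"D{i+1}") for i in range(config.n_drought)]
             + [("irrigation", f"I{i+1}") for i in range(config.n_irrigation)])
    sign = {"control": 0.0, "drought": -1.0, "irrigation": 1.0}
    rows = []
    for year in range(1, config.n_years + 1):
        for trt, pid in plots:
            shift = sign[trt] * shift_size * log_sd * direction
            logs = rng.normal(log_means + shift, log_sd)
            values = np.exp(logs)
            for s in range(n_species):
                rows.append({
                    "plot_id": pid, "treatment": trt, "year": year,
                    "species": f"sp{s+1:02d}",
                    "measure_type": measure_types[s],
                    "value": values[s],
                })
    return pd.DataFrame(rows)
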