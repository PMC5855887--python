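"""End-to-end pipeline driver: simulate -> soil moisture -> calibrate ->
functional response -> sensitivity -> community.

Each stage reads/writes plain CSV tables in a run directory and appends to a
JSON manifest recording package and library versions, seeds, row counts,
convergence diagnostics and collected warnings, so a run is reproducible
from its artifacts alone.
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import calibration as cal
from . import community as com
from . import datagen, response, sensitivity, soil
from .io import write_table

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "run",
    "synthetic": {
        "n_control": 14, "n_drought": 8, "n_irrigation": 8, "n_years": 5,
        "sensor_dropout_rate": 0.3, "rain_prob": 0.25,
        "community_shift": 0.0,
    },
    "true_params": {},            # overrides for datagen.TrueParams fields
    "mcmc": {"chains": 4, "iterations": 10000, "thin": 10},
    "permutations": 999,
    "force": False,               # bypass the R-hat < 1.1 gate with a warning
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sim_objects(config: dict):
    syn = config["synthetic"]
    sim = datagen.SimConfig(
        n_control=syn["n_control"], n_drought=syn["n_drought"],
        n_irrigation=syn["n_irrigation"], n_years=syn["n_years"],
        seed=config["seed"], sensor_dropout_rate=syn["sensor_dropout_rate"],
        rain_prob=syn["rain_prob"],
    )
    tp_kwargs = dict(config.get("true_params") or {})
    if "beta" in tp_kwargs:
        tp_kwargs["beta"] = np.asarray(tp_kwargs["beta"], dtype=float)
    if "Sigma" in tp_kwargs:
        tp_kwargs["Sigma"] = np.asarray(tp_kwargs["Sigma"], dtype=float)
    if "deviation_effects" in tp_kwargs and isinstance(tp_kwargs["deviation_effects"], dict):
        tp_kwargs["deviation_effects"] = datagen.DeviationEffects(**tp_kwargs["deviation_effects"])
    true = datagen.TrueParams(**tp_kwargs)
    return sim, true


def run_pipeline(config: dict | None = None) -> dict:
    """Run every stage on synthetic inputs; returns the manifest dict."""
    config = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "steppewater", "version": __version__,
        "numpy": np.__version__, "pandas": pd.__version__,
        "seed": config["seed"], "config": {k: v for k, v in config.items() if k != "outdir"},
        "stages": {}, "warnings": [],
    }
    collected: list[str] = []

    def stage(name):
        start = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - start, 3), **info}
        return done

    sim, true = _sim_objects(config)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- simulate ----------------------------------------------------
        done = stage("simulate")
        weather = datagen.gen_weather(sim)
        readings, latent = datagen.gen_soil_sensor_data(sim, true, weather)
        calib = datagen.gen_calibration_set(sim, true)
        comm = datagen.gen_community_matrix(sim, shift_size=config["synthetic"]["community_shift"])
        write_table(weather, outdir / "weather.csv")
        write_table(readings, outdir / "sensors.csv")
        write_table(latent, outdir / "latent_vwc.csv")
        write_table(calib, outdir / "calibration.csv")
        write_table(comm, outdir / "community.csv")
        done(rows={"weather": len(weather), "sensors": len(readings),
                   "calibration": len(calib), "community": len(comm)})

        # --- soil moisture ------------------------------------------------
        done = stage("soil_moisture")
        daily = soil.average_daily(readings)
        dev = soil.standardize_deviations(daily, weather)
        dev_fit = soil.fit_deviation_model(dev)
        ambient_daily = (daily[daily["treatment"] == "ambient"]
                         .groupby("date", as_index=False)["vwc"].mean())
        series, gaps = soil.predict_treated_series(dev_fit, ambient_daily, weather)
        surrogate = latent.rename(columns={"vwc_true": "vwc_mean"})
        series = soil.gap_fill(series, surrogate, period=weather["date"])
        write_table(series, outdir / "daily_series.csv")
        years = sorted(pd.DatetimeIndex(weather["date"]).year.unique())
        vwc_rows = []
        for t_idx, year in enumerate(years, start=1):
            cum = soil.cumulative_spring_vwc(series, year)
            for trt, val in cum.items():
                vwc_rows.append({"treatment": "control" if trt == "ambient" else trt,
                                 "treatment_year": t_idx, "vwc": val})
        vwc_table = pd.DataFrame(vwc_rows)
        write_table(vwc_table, outdir / "vwc_by_treatment_year.csv")
        done(n_gap_days=len(gaps),
             drought_effect=dev_fit.treatment_effect("drought"),
             irrigation_effect=dev_fit.treatment_effect("irrigation"))

        # --- calibrate ----------------------------------------------------
        done = stage("calibrate")
        cal_res = cal.fit_calibration(calib)
        fits = pd.DataFrame([vars(f) for f in cal_res.candidates.values()])
        fits["selected"] = fits["band_pair"] == cal_res.selected.band_pair
        write_table(fits, outdir / "calibration_fits.csv")
        done(selected=cal_res.selected.band_pair,
             r_squared=cal_res.selected.r_squared)

        # --- plot-year records (generative model on reconstructed VWC) ----
        done = stage("anpp_records")
        records, truth = datagen.gen_anpp_dataset(sim, true, vwc_table)
        write_table(records, outdir / "plot_year.csv")
        done(rows=len(records))

        # --- functional response ------------------------------------------
        done = stage("functional_response")
        mcmc = config["mcmc"]
        res = response.fit_model(records, chains=mcmc["chains"],
                                 iterations=mcmc["iterations"], thin=mcmc["thin"],
                                 seed=config["seed"])
        rhats = res.rhat()
        max_rhat = max(float(np.max(v)) for v in rhats.values() if v is not None)
        if max_rhat >= 1.1 and not config["force"]:
            raise RuntimeError(
                f"functional_response: max R-hat {max_rhat:.3f} >= 1.1; "
                "increase iterations or pass force=True")
        write_table(res.summary(), outdir / "table1.csv")
        write_table(res.offsets(), outdir / "offsets.csv")
        done(max_rhat=max_rhat,
             drought_slope_tail_prob=float(
                 res.offsets().query("coefficient == 'slope_offset' and treatment == 'drought'")
                 ["tail_probability"].iloc[0]))

        # --- sensitivity ---------------------------------------------------
        done = stage("sensitivity")
        sens = sensitivity.sensitivity_table(records)
        write_table(sens, outdir / "sensitivity.csv")
        trends = pd.DataFrame([
            {"treatment": trt, **sensitivity.sensitivity_trend(sens, trt)}
            for trt in ("drought", "irrigation")
        ])
        write_table(trends, outdir / "sensitivity_trends.csv")
        done(drought_p=float(trends.loc[trends["treatment"] == "drought", "p_value"].iloc[0]))

        # --- community -----------------------------------------------------
        done = stage("community")
        table2 = com.yearly_tests(comm, n_permutations=config["permutations"],
                                  seed=config["seed"])
        write_table(table2, outdir / "table2.csv")
        wide = com.community_pivot(comm)
        mat = com.standardize_abundance(wide)
        D = com.bray_curtis(mat.to_numpy())
        ord_res = com.nmds(D, seed=config["seed"])
        scores = pd.DataFrame(ord_res.scores, columns=["NMDS1", "NMDS2"])
        scores[["plot_id", "year", "treatment"]] = [list(t) for t in mat.index]
        write_table(scores, outdir / "nmds_scores.csv")
        done(stress=ord_res.stress, min_P=float(table2["P"].min()))

        collected = [str(w.message) for w in caught]

    manifest["warnings"] = collected
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
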