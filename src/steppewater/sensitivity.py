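"""Sensitivity of ANPP to the precipitation treatments over time.

Sensitivity of a treated plot in a year is defined as

    (mean control ANPP - treated plot ANPP) / (ambient VWC - treated VWC)

in (g m^-2) per cumulative-VWC unit: the ANPP displacement caused by the
treatment, scaled by the soil-moisture displacement it imposed.  Treated
plots are not paired with individual controls, so each plot is compared to
the control mean for that year; VWC is shared at the treatment-year level.
A per-treatment ordinary least squares regression of sensitivity on year of
treatment tests whether sensitivity changed as the manipulation persisted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm


def compute_sensitivity(anpp_treated_plot: float, anpp_control_mean_year: float,
                        vwc_ambient: float, vwc_treatment: float) -> float:
    """Single plot-year sensitivity value; errors on zero VWC difference."""
    denom = vwc_ambient - vwc_treatment
    if denom == 0:
        raise ValueError("ambient and treatment VWC are equal: sensitivity undefined")
    return (anpp_control_mean_year - anpp_treated_plot) / denom


def sensitivity_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-plot-year sensitivities from a plot-year ANPP/VWC table.

    ``records`` needs columns plot_id, treatment, treatment_year, anpp, vwc.
    Ambient VWC per year is the control treatment's (shared) VWC value.
    """
    control = records[records["treatment"] == "control"]
    if control.empty:
        raise ValueError("no control records to compare against")
    ctrl_anpp = control.groupby("treatment_year")["anpp"].mean()
    ctrl_vwc = control.groupby("treatment_year")["vwc"].first()
    rows = []
    for r in records[records["treatment"] != "control"].itertuples():
        t = r.treatment_year
        if t not in ctrl_anpp.index:
            raise ValueError(f"no control observations in treatment year {t}")
        rows.append({
            "plot_id": r.plot_id, "treatment": r.treatment, "treatment_year": t,
            "sensitivity": compute_sensitivity(r.anpp, float(ctrl_anpp[t]),
                                               float(ctrl_vwc[t]), float(r.vwc)),
        })
    return pd.DataFrame(rows)


def sensitivity_trend(records: pd.DataFrame, treatment: str) -> dict:
    """OLS of sensitivity on year of treatment within one treatment.

    Returns slope, intercept, two-sided p-value for the slope, and n.
    ``records`` is a sensitivity table (plot_id, treatment, treatment_year,
    sensitivity).
    """
    sub = records[records["treatment"] == treatment]
    if len(sub) < 3:
        raise ValueError("need >= 3 sensitivity records")
    years = sub["treatment_year"].to_numpy(dtype=float)
    if len(np.unique(years)) < 2:
        raise ValueError("need records spanning >= 2 years")
    y = sub["sensitivity"].to_numpy(dtype=float)
    X = sm.add_constant(years)
    res = sm.OLS(y, X).fit()
    slope = float(res.params[1])
    p = float(res.pvalues[1])
    exact = res.ssr <= 1e-12 * max(1.0, float(np.sum(y ** 2)))
    if exact or not np.isfinite(p):  # zero residual variance: exact fit
        p = 1.0 if abs(slope) <= 1e-10 * max(1.0, float(np.abs(y).max())) else 0.0
    return {
        "slope": slope,
        "intercept": float(res.params[0]),
        "p_value": p,
        "n": int(len(sub)),
    }
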