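import numpy as np
import pandas as pd
import pytest

from steppewater import datagen


@pytest.fixture(scope="session")
def sim_config():
    return datagen.SimConfig(seed=42, n_years=2)


@pytest.fixture(scope="session")
def true_params():
    return datagen.TrueParams()


@pytest.fixture(scope="session")
def weather(sim_config):
    return datagen.gen_weather(sim_config)


@pytest.fixture(scope="session")
def sensor_data(sim_config, true_params, weather):
    return datagen.gen_soil_sensor_data(sim_config, true_params, weather)


@pytest.fixture()
def toy_plot_year():
    """Tiny plot-year table: 3 treatments x 2 plots x 3 years."""
    rng = np.random.default_rng(0)
    rows = []
    vwc = {("control", t): 10.0 + t for t in (1, 2, 3)}
    vwc.update({("drought", t): 0.88 * (10.0 + t) for t in (1, 2, 3)})
    vwc.update({("irrigation", t): 1.19 * (10.0 + t) for t in (1, 2, 3)})
    for trt, prefix in (("control", "P"), ("drought", "D"), ("irrigation", "I")):
        for p in range(2):
            for t in (1, 2, 3):
                rows.append({
                    "plot_id": f"{prefix}{p}", "treatment": trt, "treatment_year": t,
                    "anpp": float(np.exp(rng.normal(5.0, 0.3))),
                    "vwc": vwc[(trt, t)],
                })
    return pd.DataFrame(rows)
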