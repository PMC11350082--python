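import numpy as np
import pandas as pd
import pytest

import stemflux as sf


@pytest.fixture(scope="session")
def sim_config():
    return sf.SimConfig(seed=1)


@pytest.fixture(scope="session")
def drivers(sim_config):
    return sf.generate_drivers(sim_config)


@pytest.fixture(scope="session")
def truth_clean():
    return sf.default_truth(noise_sd=0.0, rng_seed=1)


@pytest.fixture(scope="session")
def noiseless(drivers, truth_clean):
    """Full noiseless season: chamber fluxes, aligned table, monthly fits."""
    dark, transparent, comp = sf.generate_true_fluxes(drivers, truth_clean)
    table, report = sf.align(dark, transparent, drivers)
    low, per_month = sf.select_low_sapflow(table)
    fits = sf.fit_season(table, low)
    return {
        "dark": dark, "transparent": transparent, "truth_components": comp,
        "table": table, "align_report": report, "low": low,
        "low_per_month": per_month, "fits": fits,
    }


@pytest.fixture(scope="session")
def geometry():
    return sf.ChamberGeometry()


@pytest.fixture()
def flux_frame():
    """Small flux table factory in the shared dialect."""

    def make(values, chamber="dark", tree="A", start="2021-06-01", freq="30min"):
        values = np.asarray(values, dtype=float)
        idx = pd.date_range(start, periods=len(values), freq=freq)
        return pd.DataFrame({"fco2": values, "chamber": chamber, "tree": tree,
                             "flags": ""}, index=idx)

    return make
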