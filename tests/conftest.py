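import numpy as np
import pandas as pd
import pytest

import cprtrends as ct
from cprtrends.aggregate import impute_zeros

#: reduced-draw protocol for test fits; the Gibbs sampler mixes well here
FAST = dict(chains=2, iterations=1500, burn_in=500, thinning=2)


def fast_config(seed=0, **kw):
    opts = {**FAST, **kw}
    return ct.ModelConfig(seed=seed, **opts)


@pytest.fixture(scope="session")
def default_params():
    """Default study conditions over a 30-year window."""
    return ct.GenerativeParams(years=(1978, 2007))


@pytest.fixture(scope="session")
def sim(default_params):
    """(params, sst, imputation-complete bins, anomaly table) shared by
    the model-level tests."""
    p = default_params
    sst = ct.simulate_sst(p, seed=101)
    bins = impute_zeros(ct.simulate_bins(p, sst, seed=101))
    anoms = sst[["province", "lat_band", "year", "month"]].copy()
    anoms["anomaly"] = sst["anomaly_true"].to_numpy()
    return p, sst, bins, anoms


def _fit(sim, response, seed):
    p, sst, bins, anoms = sim
    model = ct.PlanktonTrendModel(bins, response=response,
                                  variant="time-space-temperature",
                                  anomalies=anoms)
    return model.fit(fast_config(seed=seed))


@pytest.fixture(scope="session")
def fit_diatom(sim):
    return _fit(sim, "log_diatom", seed=11)


@pytest.fixture(scope="session")
def fit_dino(sim):
    return _fit(sim, "log_dinoflagellate", seed=12)


@pytest.fixture(scope="session")
def fit_index(sim):
    return _fit(sim, "logit_index", seed=13)


@pytest.fixture()
def empty_bins():
    cols = ["province", "lat_band", "year", "month", "decade",
            "diatom_ugC", "dinoflagellate_ugC", "h"]
    return pd.DataFrame(columns=cols)


@pytest.fixture()
def toy_samples():
    """Hand-sized per-sample biomass table for aggregation tests."""
    return pd.DataFrame({
        "province": ["A", "A", "A", "B"],
        "latitude": [51.0, 52.0, 51.5, 40.1],
        "longitude": [-20.0, -21.0, -22.0, -60.0],
        "year": [1970, 1970, 1970, 1980],
        "month": [3, 3, 4, 7],
        "diatom_ugC": [1.0, 2.0, 4.0, 0.0],
        "dinoflagellate_ugC": [3.0, 5.0, 0.0, 8.0],
    })
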