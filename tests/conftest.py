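"""Shared fixtures: one small synthetic season reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from isoring.chronology import window_for_subsection
from isoring.params import IsotopeParams
from isoring.synthetic import SOUTHERN_BOREAL, build_dataset
from isoring.transport import run_forward

SEED = 7
YEAR = 2015


@pytest.fixture(scope="session")
def dataset():
    return build_dataset(SOUTHERN_BOREAL, (YEAR, YEAR), seed=SEED)


@pytest.fixture(scope="session")
def params():
    return IsotopeParams()


@pytest.fixture(scope="session")
def windows(dataset):
    curves = dataset.growth_curves[YEAR]
    return [window_for_subsection(curves, i / 10, (i + 1) / 10) for i in range(10)]


@pytest.fixture(scope="session")
def forward(dataset, windows, params):
    return run_forward(dataset.drivers, windows, params)


@pytest.fixture()
def constant_drivers():
    """Flat half-hourly drivers: constant RH, temperature and isotopes,
    day/night assimilation cycle."""
    idx = pd.date_range("2015-04-01", "2015-11-01", freq="30min", inclusive="left")
    n = len(idx)
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    day = ((hour >= 8) & (hour < 20)).astype(float)
    tair = np.full(n, 15.0)
    esat = 0.6108 * np.exp(17.27 * tair / (tair + 237.3))
    wi = esat / 101.3
    wa = 0.7 * wi
    an = 4.0 * day - 0.4
    gs = 0.004 + 0.02 * day
    gb = np.full(n, 0.8)
    gtot = gs * gb / (gs + gb)
    return pd.DataFrame(
        {
            "tair_C": tair,
            "rh_pct": np.full(n, 70.0),
            "an_umol_m2_s": an,
            "rd_umol_m2_s": np.full(n, 0.4),
            "gs_mol_m2_s": gs,
            "gb_mol_m2_s": gb,
            "e_mol_m2_s": gtot * (wi - wa),
            "wi_mol_mol": wi,
            "wa_mol_mol": wa,
            "ci_ca": np.full(n, 0.7),
            "d18o_sw_permil": np.full(n, -12.0),
            "d18o_vapor_permil": np.full(n, -21.0),
            "d13c_co2_permil": np.full(n, -8.5),
        },
        index=idx,
    )
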