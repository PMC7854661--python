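import numpy as np
import pandas as pd
import pytest

from dalecmdf import (
    MetDaily,
    ParameterVector,
    PoolState,
    gen_met_drivers,
    make_case,
    run_forward,
)
from dalecmdf.synthetic_data import DEFAULT_INIT


@pytest.fixture(scope="session")
def default_pv():
    return ParameterVector()


@pytest.fixture(scope="session")
def default_init():
    return DEFAULT_INIT


@pytest.fixture(scope="session")
def drivers_3y():
    """Three years of seeded seasonal drivers."""
    return gen_met_drivers(3, seed=7)


@pytest.fixture(scope="session")
def traj_3y(drivers_3y, default_pv, default_init):
    return run_forward(drivers_3y, default_pv, default_init)


@pytest.fixture(scope="session")
def case11():
    """The default 11-year synthetic evergreen site."""
    return make_case(1)


def constant_drivers(n_days: int, ta=18.0, par=7.0, sw=0.30, sc=0.45) -> pd.DataFrame:
    dates = pd.date_range("2000-01-01", periods=n_days, freq="D")
    return pd.DataFrame(
        {
            "date": dates,
            "ta_c": ta,
            "tmax_c": ta + 5.0,
            "tmin_c": ta - 5.0,
            "par": par,
            "rh_pct": 75.0,
            "precip_mm": 3.0,
            "sw": sw,
            "sc": sc,
        }
    )


def met_day(**kwargs) -> MetDaily:
    base = dict(
        date=pd.Timestamp("2005-07-01"),
        ta_c=18.0,
        tmax_c=24.0,
        tmin_c=12.0,
        par=7.0,
        rh_pct=75.0,
        precip_mm=0.0,
        sw=0.30,
        sc=0.45,
    )
    base.update(kwargs)
    return MetDaily(**base)


@pytest.fixture
def sample_met():
    return met_day()


@pytest.fixture(scope="session")
def equilibrium_setup():
    """Constant-driver long run that converges to a fixed point.

    Latitude 0 keeps day length constant so the forcing is truly constant.
    """
    pv = ParameterVector(k_w=1.0 / (10 * 365.25), k_som=1.0 / (8 * 365.25))
    init = PoolState(cf=200.0, cr=300.0, cw=3000.0, clit=200.0, csom=3000.0)
    drivers = constant_drivers(240 * 365)
    traj = run_forward(drivers, pv, init, lat_deg=0.0)
    return pv, init, traj
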