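"""Unit and property tests for the daily carbon box model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dalecmdf import (
    ParameterVector,
    PoolState,
    acm_gpp,
    env_scalars,
    observation_operator,
    run_forward,
    step_day,
)
from dalecmdf.dalec_core import (
    ACMCoefficients,
    ConfigurationError,
    ContiguityError,
    DriverError,
    PropagationError,
    RangeError,
    day_length_hours,
)
from dalecmdf.synthetic_data import sample_true_params

from conftest import constant_drivers, met_day


class TestAcmGpp:
    def test_zero_canopy_and_zero_light(self, default_pv, sample_met):
        assert acm_gpp(sample_met, 0.0, default_pv) == 0.0
        assert acm_gpp(met_day(par=0.0), 4.0, default_pv) == 0.0

    def test_monotone_in_lai_and_par(self, default_pv):
        g1 = acm_gpp(met_day(), 1.0, default_pv)
        g4 = acm_gpp(met_day(), 4.0, default_pv)
        assert g4 > g1 > 0.0
        lo = acm_gpp(met_day(par=3.0), 4.0, default_pv)
        hi = acm_gpp(met_day(par=9.0), 4.0, default_pv)
        assert hi > lo > 0.0

    def test_monotone_over_grid(self, default_pv):
        lais = np.linspace(0.0, 8.0, 17)
        vals = [acm_gpp(met_day(), l, default_pv) for l in lais]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_continuity_near_zero_lai(self, default_pv):
        eps = acm_gpp(met_day(), 1e-9, default_pv)
        assert 0.0 <= eps < 1e-6

    def test_unknown_coefficient_rejected(self):
        with pytest.raises(ConfigurationError, match="a11"):
            ACMCoefficients.from_mapping({"a11": 1.0})

    def test_coefficient_override(self, default_pv, sample_met):
        acm = ACMCoefficients.from_mapping({"a7": 8.618})
        assert acm_gpp(sample_met, 4.0, default_pv, acm) > acm_gpp(
            sample_met, 4.0, default_pv
        )


class TestEnvScalars:
    def test_closed_forms(self, default_pv):
        f_ta, f_sw = env_scalars(met_day(ta_c=10.0, sw=0.45), default_pv.replace(theta=0.0693))
        assert f_ta == pytest.approx(np.exp(0.693), rel=1e-12)
        assert f_sw == 1.0

    def test_zero_theta_gives_unit_scalar(self):
        pv = ParameterVector(theta=0.02).replace(theta=0.0)
        f_ta, _ = env_scalars(met_day(ta_c=-5.0), pv)
        assert f_ta == 1.0

    def test_saturated_soil_gives_unit_scalar(self, default_pv):
        for exp in (0.1, 1.0, 3.0):
            _, f_sw = env_scalars(met_day(sw=0.45), default_pv.replace(sw_exp=exp))
            assert f_sw == 1.0

    def test_invalid_capacity_raises(self, default_pv):
        bad = met_day()
        object.__setattr__(bad, "sc", -1.0)
        with pytest.raises(DriverError):
            env_scalars(bad, default_pv)


class TestStepDay:
    def test_single_pool_euler_arithmetic(self):
        # litter pool with inflow 5 (foliage turnover) and removal rate 0.01:
        # C(t+1) = 100 + 5 - 1 = 104
        pv = ParameterVector(
            f_f=0.0, f_r=0.0, k_f=0.01, k_r=0.0, k_w=0.0,
            k_lit_min=0.01, k_lit_dec=0.0, k_som=0.0, theta=0.0, sw_exp=1.0,
        )
        state = PoolState(cf=500.0, cr=0.0, cw=0.0, clit=100.0, csom=0.0)
        nxt, flux = step_day(state, met_day(sw=0.45, par=0.0), pv, day_of_year=182)
        assert nxt.clit == pytest.approx(104.0, abs=1e-12)
        assert flux.gpp == 0.0

    def test_zero_rates_zero_light_is_identity(self):
        pv = ParameterVector(
            k_f=0.0, k_r=0.0, k_w=0.0, k_lit_min=0.0, k_lit_dec=0.0, k_som=0.0
        )
        state = PoolState(cf=100.0, cr=50.0, cw=1000.0, clit=80.0, csom=900.0)
        nxt, flux = step_day(state, met_day(par=0.0), pv, day_of_year=10)
        assert nxt == state
        for name in ("gpp", "ra", "rh_lit", "rh_som", "npp", "nep"):
            assert getattr(flux, name) == 0.0

    def test_mass_balance_single_step(self, default_pv):
        state = PoolState(cf=250.0, cr=400.0, cw=9000.0, clit=350.0, csom=8500.0)
        nxt, flux = step_day(state, met_day(), default_pv, day_of_year=182)
        d_total = nxt.total() - state.total()
        assert d_total == pytest.approx(flux.nep, abs=1e-9 * state.total())


class TestRunForward:
    def test_one_day_run(self, default_pv, default_init):
        traj = run_forward(constant_drivers(1), default_pv, default_init)
        assert traj.n_days == 1
        assert traj.initial_state.cw == default_init.cw

    def test_deterministic(self, drivers_3y, default_pv, default_init):
        a = run_forward(drivers_3y, default_pv, default_init)
        b = run_forward(drivers_3y, default_pv, default_init)
        assert np.array_equal(a.pools, b.pools)
        assert np.array_equal(a.fluxes, b.fluxes)

    def test_date_gap_rejected(self, default_pv, default_init):
        df = constant_drivers(10).drop(index=4)
        with pytest.raises(ContiguityError):
            run_forward(df, default_pv, default_init)

    def test_nan_driver_rejected(self, default_pv, default_init):
        df = constant_drivers(10)
        df.loc[3, "ta_c"] = np.nan
        with pytest.raises(PropagationError, match="3"):
            run_forward(df, default_pv, default_init)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_mass_balance_random_parameters(self, drivers_3y, seed):
        pv = sample_true_params(seed=seed)
        init = PoolState(cf=250.0, cr=400.0, cw=9000.0, clit=350.0, csom=8500.0)
        traj = run_forward(drivers_3y, pv, init)
        assert traj.mass_balance_error() < 1e-9

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_non_negative_pools_and_gross_fluxes(self, drivers_3y, seed):
        pv = sample_true_params(seed=seed)
        init = PoolState(cf=50.0, cr=50.0, cw=500.0, clit=20.0, csom=500.0)
        traj = run_forward(drivers_3y, pv, init)
        assert traj.pools.min() >= 0.0
        for f in ("gpp", "ra", "rh_lit", "rh_som"):
            assert traj.flux(f).min() >= 0.0

    def test_equilibrium_nep_vanishes(self, equilibrium_setup):
        _, _, traj = equilibrium_setup
        assert abs(traj.flux("nep")[-1]) < 1e-6

    def test_equilibrium_pool_identity(self, equilibrium_setup):
        # at the fixed point each pool satisfies C* = I*/k_eff
        pv, _, traj = equilibrium_setup
        f_ta = np.exp(pv.theta * 18.0)
        f_sw = (0.30 / 0.45) ** pv.sw_exp
        dr = f_ta * f_sw
        npp = traj.flux("npp")[-1]
        cf, cr, cw = traj.final_state.cf, traj.final_state.cr, traj.final_state.cw
        assert cf == pytest.approx(pv.f_f * npp / pv.k_f, rel=1e-6)
        assert cr == pytest.approx(pv.f_r * npp / pv.k_r, rel=1e-6)
        assert cw == pytest.approx((1 - pv.f_f - pv.f_r) * npp / pv.k_w, rel=1e-6)
        clit = traj.final_state.clit
        assert clit == pytest.approx(
            (pv.k_f * cf + pv.k_r * cr) / ((pv.k_lit_min + pv.k_lit_dec) * dr), rel=1e-6
        )


class TestDeciduousPhenology:
    def test_leaf_area_zero_off_season(self):
        pv = ParameterVector()
        init = PoolState(cf=200.0, cr=300.0, cw=5000.0, clit=300.0, csom=6000.0, clab=150.0)
        drivers = constant_drivers(3 * 365)
        traj = run_forward(drivers, pv, init, lat_deg=40.0)
        doy = traj.dates.dayofyear.to_numpy()
        off = (doy >= pv.day_leaffall) | (doy < pv.day_leafout)
        # skip the first year (initial canopy is shed on entry to the rules)
        off[:365] = False
        assert np.all(traj.pool("cf")[off] == 0.0)

    def test_mass_balance_with_labile_pool(self):
        pv = ParameterVector()
        init = PoolState(cf=0.0, cr=300.0, cw=5000.0, clit=300.0, csom=6000.0, clab=150.0)
        traj = run_forward(constant_drivers(2 * 365), pv, init, lat_deg=40.0)
        assert traj.mass_balance_error() < 1e-9


class TestObservationOperator:
    def test_lai_is_foliage_over_lcma(self, traj_3y, default_pv):
        t = traj_3y.dates[100]
        lai = observation_operator(traj_3y, "lai", [t])[0]
        assert lai == pytest.approx(traj_3y.pool("cf")[100] / default_pv.lcma, rel=1e-12)

    def test_wood_biomass_at_start_is_initial(self, traj_3y, default_init):
        v = observation_operator(traj_3y, "biomass_w", [traj_3y.dates[0]])[0]
        assert v == default_init.cw

    def test_nee_vanishes_at_equilibrium(self, equilibrium_setup):
        _, _, traj = equilibrium_setup
        nee = observation_operator(traj, "nee_daily", [traj.dates[-1]])[0]
        assert abs(nee) < 1e-6

    def test_litterfall_annual_sums_foliar_turnover(self, traj_3y):
        y = traj_3y.dates[0].year
        v = observation_operator(
            traj_3y, "litterfall_annual", [pd.Timestamp(year=y, month=12, day=31)]
        )[0]
        mask = traj_3y.dates.year == y
        assert v == pytest.approx(traj_3y.flux("lit_f")[mask].sum(), rel=1e-12)

    def test_out_of_span_timestamp_raises(self, traj_3y):
        with pytest.raises(RangeError, match="1990"):
            observation_operator(traj_3y, "soc", [pd.Timestamp("1990-01-01")])

    def test_unknown_kind_rejected(self, traj_3y):
        with pytest.raises(Exception, match="xylem"):
            observation_operator(traj_3y, "xylem", [traj_3y.dates[0]])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    lat=st.floats(-60, 60),
    doy=st.integers(1, 365),
)
def test_day_length_physical(lat, doy):
    dl = float(day_length_hours(doy, lat))
    assert 0.0 <= dl <= 24.0
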