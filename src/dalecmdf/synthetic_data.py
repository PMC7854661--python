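"""Synthetic forest sites on the CERN observation cadence.

Generates everything an assimilation run needs without any downloads:
sinusoidal-seasonal daily meteorology with seeded day-to-day noise, a
known "true" parameter vector drawn from the priors, the corresponding
forward trajectory, and noisy observation streams sampled the way the
monitoring network samples real sites — tissue biomass and layered soil
carbon every five years, annual litterfall, quarterly LAI, and (default)
daily NEE.  Observation noise is Gaussian per stream, mirroring the
likelihood's error model.

The default site is an evergreen subtropical forest over 2005-2015; a
deciduous preset with labile-pool phenology is included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dalec_core import (
    DEFAULT_BOUNDS,
    RETRIEVED_PARAMS,
    ConfigurationError,
    ParameterVector,
    PoolState,
    Trajectory,
    observation_operator,
    run_forward,
)
from .mdf_engine import (
    DEFAULT_SIGMA_RULES,
    PARAM_EDC_RULES,
    ObservationStream,
    SiteConfig,
    check_edcs,
    default_sigma,
)


@dataclass(frozen=True)
class ClimateConfig:
    """Seasonal-cycle settings for the driver generator.

    Defaults emulate a humid subtropical monsoon forest climate: mild
    winters, a mid-summer temperature and radiation peak, and a summer wet
    season.
    """

    ta_mean_c: float = 16.0
    ta_amp_c: float = 9.0
    ta_noise_c: float = 1.5
    diurnal_half_range_c: float = 5.0
    par_peak: float = 9.0  # MJ m-2 d-1 at midsummer
    par_trough: float = 2.5
    par_noise: float = 1.0
    rh_mean_pct: float = 75.0
    rh_amp_pct: float = 8.0
    rh_noise_pct: float = 5.0
    precip_wet_mm: float = 8.0  # mean daily rain at wet-season peak
    precip_dry_mm: float = 1.0
    sc: float = 0.45  # saturated soil water capacity
    sw_mean_frac: float = 0.65  # mean Sw as fraction of Sc
    sw_amp_frac: float = 0.20
    sw_noise_frac: float = 0.04
    peak_doy: float = 196.0  # day of year of the thermal/radiative maximum

    def validate(self) -> None:
        if self.sc <= 0:
            raise ConfigurationError("sc must be positive")
        if self.par_trough < 0 or self.par_peak < self.par_trough:
            raise ConfigurationError("need 0 <= par_trough <= par_peak")
        if not (0 < self.sw_mean_frac <= 1):
            raise ConfigurationError("sw_mean_frac must lie in (0, 1]")


@dataclass(frozen=True)
class CadenceConfig:
    """Observation sampling cadence (per the network's protocols)."""

    biomass_interval_yr: int = 5
    soc_interval_yr: int = 5
    lai_per_year: int = 4
    include_nee: bool = True


def gen_met_drivers(
    n_years: int,
    climate: ClimateConfig | None = None,
    seed: int = 0,
    start_year: int = 2005,
) -> pd.DataFrame:
    """Daily meteorological drivers with seasonal cycles plus seeded noise."""
    if n_years < 1:
        raise ConfigurationError("n_years must be >= 1")
    climate = climate or ClimateConfig()
    climate.validate()
    rng = np.random.default_rng(seed)
    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D"
    )
    doy = dates.dayofyear.to_numpy(dtype=float)
    # season = +1 at peak_doy, -1 half a year away
    season = np.cos(2.0 * np.pi * (doy - climate.peak_doy) / 365.25)

    ta = climate.ta_mean_c + climate.ta_amp_c * season + rng.normal(
        0.0, climate.ta_noise_c, len(doy)
    )
    half = climate.diurnal_half_range_c * (0.8 + 0.4 * rng.random(len(doy)))
    tmax = ta + half
    tmin = ta - half

    par_mid = 0.5 * (climate.par_peak + climate.par_trough)
    par_amp = 0.5 * (climate.par_peak - climate.par_trough)
    par = np.clip(
        par_mid + par_amp * season + rng.normal(0.0, climate.par_noise, len(doy)),
        0.0,
        None,
    )

    rh = np.clip(
        climate.rh_mean_pct
        + climate.rh_amp_pct * season
        + rng.normal(0.0, climate.rh_noise_pct, len(doy)),
        5.0,
        100.0,
    )

    wet_weight = 0.5 * (1.0 + season)  # 1 at wet-season peak, 0 at trough
    rain_mean = climate.precip_dry_mm + (climate.precip_wet_mm - climate.precip_dry_mm) * wet_weight
    wet_day = rng.random(len(doy)) < 0.45
    precip = np.where(wet_day, rng.exponential(rain_mean / 0.45), 0.0)

    sw = climate.sc * np.clip(
        climate.sw_mean_frac
        + climate.sw_amp_frac * season
        + rng.normal(0.0, climate.sw_noise_frac, len(doy)),
        0.05,
        1.0,
    )

    return pd.DataFrame(
        {
            "date": dates,
            "ta_c": ta,
            "tmax_c": tmax,
            "tmin_c": tmin,
            "par": par,
            "rh_pct": rh,
            "precip_mm": precip,
            "sw": sw,
            "sc": climate.sc,
        }
    )


def sample_true_params(
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    deciduous: bool = False,
    base: ParameterVector | None = None,
    max_tries: int = 10_000,
) -> ParameterVector:
    """Uniform draw of the retrieved parameters, resampled until the
    parameter-level EDCs pass."""
    bounds = bounds or DEFAULT_BOUNDS
    rng = np.random.default_rng(seed)
    names = list(RETRIEVED_PARAMS) + (["k_lab", "clab0"] if deciduous else [])
    base = base or ParameterVector()
    for name in names:
        if name not in bounds:
            raise ConfigurationError(f"no prior bound for parameter {name}")
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    for _ in range(max_tries):
        draw = lo + rng.random(len(names)) * (hi - lo)
        pv = ParameterVector.from_array(draw, names, base=base)
        ok, _ = check_edcs(pv, None, rules=PARAM_EDC_RULES)
        if ok:
            return pv
    raise ConfigurationError(
        f"no EDC-satisfying parameter draw found in {max_tries} tries"
    )


def gen_observations(
    truth_traj: Trajectory,
    cadence: CadenceConfig | None = None,
    noise: dict[str, float] | None = None,
    seed: int = 0,
    lcma: float | None = None,
) -> list[ObservationStream]:
    """Noisy observation streams on the monitoring cadence.

    ``noise`` maps stream kind to sigma; a zero sigma yields noiseless
    streams equal to the observation operator of the truth.  Negative
    draws of physical quantities are truncated at zero (flag recorded on
    the stream as ``truncated``).
    """
    cadence = cadence or CadenceConfig()
    rng = np.random.default_rng(seed)
    dates = truth_traj.dates
    years = sorted(set(dates.year))
    y0 = years[0]

    def first_day(year: int) -> pd.Timestamp:
        return pd.Timestamp(year=year, month=1, day=1)

    stock_years = [y for y in years if (y - y0) % cadence.biomass_interval_yr == 0]
    stock_dates = pd.DatetimeIndex([first_day(y) for y in stock_years])
    soc_years = [y for y in years if (y - y0) % cadence.soc_interval_yr == 0]
    soc_dates = pd.DatetimeIndex([first_day(y) for y in soc_years])

    # full calendar years only, dated at year end
    full_years = [
        y for y in years
        if pd.Timestamp(year=y, month=12, day=31) in dates and first_day(y) in dates
    ]
    litter_dates = pd.DatetimeIndex(
        [pd.Timestamp(year=y, month=12, day=31) for y in full_years]
    )

    quarter_months = {4: (2, 5, 8, 11), 2: (5, 11), 1: (7,)}.get(
        cadence.lai_per_year, (2, 5, 8, 11)
    )
    lai_dates = pd.DatetimeIndex(
        [pd.Timestamp(year=y, month=m, day=15) for y in years for m in quarter_months]
    )
    lai_dates = lai_dates[(lai_dates >= dates[0]) & (lai_dates <= dates[-1])]

    spec_list = [
        ("biomass_f", stock_dates),
        ("biomass_r", stock_dates),
        ("biomass_w", stock_dates),
        ("soc", soc_dates),
        ("litterfall_annual", litter_dates),
        ("lai", lai_dates),
    ]
    if cadence.include_nee:
        spec_list.append(("nee_daily", dates))

    noise = noise or {}
    streams: list[ObservationStream] = []
    for kind, ts in spec_list:
        mu = observation_operator(truth_traj, kind, ts)
        if kind in noise:
            sigma = float(noise[kind])
            if sigma < 0:
                raise ConfigurationError(f"negative sigma for stream {kind}")
        else:
            sigma = default_sigma(kind, mu)
        vals = mu + rng.normal(0.0, sigma, len(mu)) if sigma > 0 else mu.copy()
        truncated = 0
        if kind != "nee_daily":  # NEE is signed; stocks/LAI/litterfall are not
            truncated = int(np.sum(vals < 0))
            vals = np.maximum(vals, 0.0)
        s = ObservationStream(kind=kind, times=ts, values=vals, sigma=max(sigma, 1e-12))
        s.truncated = truncated
        streams.append(s)
    return streams


#: Default initial pool stocks for the synthetic evergreen site, g C m-2
#: (mature subtropical forest magnitudes).
DEFAULT_INIT = PoolState(cf=250.0, cr=420.0, cw=9000.0, clit=350.0, csom=8500.0)


@dataclass
class SyntheticCase:
    """A fully reproducible synthetic site bundle."""

    drivers: pd.DataFrame
    truth: ParameterVector
    init: PoolState
    truth_traj: Trajectory
    streams: list[ObservationStream]
    seed: int
    site: SiteConfig
    climate: ClimateConfig
    cadence: CadenceConfig


def make_case(
    seed: int = 0,
    n_years: int = 11,
    deciduous: bool = False,
    climate: ClimateConfig | None = None,
    cadence: CadenceConfig | None = None,
    noise: dict[str, float] | None = None,
    init: PoolState | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    lat_deg: float = 30.0,
) -> SyntheticCase:
    """Compose drivers, a true parameter vector, the truth trajectory and
    noisy observations into one internally consistent bundle."""
    rng = np.random.default_rng(seed)
    s_drivers, s_params, s_obs = (int(rng.integers(2**31)) for _ in range(3))

    climate = climate or ClimateConfig()
    cadence = cadence or CadenceConfig()
    drivers = gen_met_drivers(n_years, climate=climate, seed=s_drivers)
    truth = sample_true_params(bounds=bounds, seed=s_params, deciduous=deciduous)
    if init is None:
        init = DEFAULT_INIT
        if deciduous:
            init = PoolState(
                init.cf, init.cr, init.cw, init.clit, init.csom, clab=truth.clab0
            )
    site = SiteConfig(
        name=f"synthetic-{seed}",
        lat_deg=lat_deg,
        deciduous=deciduous,
        lcma=truth.lcma,
        clit0=init.clit,
    )
    traj = run_forward(drivers, truth, init, lat_deg=lat_deg)
    streams = gen_observations(
        traj, cadence=cadence, noise=noise, seed=s_obs, lcma=truth.lcma
    )
    return SyntheticCase(
        drivers=drivers,
        truth=truth,
        init=init,
        truth_traj=traj,
        streams=streams,
        seed=seed,
        site=site,
        climate=climate,
        cadence=cadence,
    )
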