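"""Daily-timestep DALEC forest carbon box model.

DALEC (Data Assimilation Linked Ecosystem Carbon) tracks five carbon
reservoirs — foliage (Cf), fine roots (Cr), wood (Cw), litter (Clit) and
soil organic matter (Csom) — plus an optional labile pool (Clab) for
deciduous canopies.  Canopy carbon uptake (GPP) is computed with the
Aggregated Canopy Model (ACM) from leaf area, light, temperature and CO2;
a fixed fraction of GPP is respired autotrophically and the remaining NPP
is partitioned among the plant tissue pools.  Every pool loses carbon by
first-order turnover; decomposition and mineralization of the dead pools
are additionally scaled by an exponential temperature factor and a
soil-moisture factor.

All pools are in g C m-2, all fluxes in g C m-2 d-1.  The state update is
an explicit daily Euler step

    C_i(t+1) = C_i(t) + I_i(t) - k_i C_i(t)

which conserves mass exactly: the total-carbon change each day equals
GPP - Ra - Rh to floating-point precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class DalecError(Exception):
    """Base class for model errors."""


class ConfigurationError(DalecError):
    """A coefficient or configuration entry is missing or invalid."""


class DriverError(DalecError):
    """Meteorological driver values violate their physical invariants."""


class ContiguityError(DriverError):
    """Driver dates are not contiguous daily steps."""


class PropagationError(DalecError):
    """Non-finite value encountered while stepping the model."""


class RangeError(DalecError):
    """A requested timestamp lies outside the simulated span."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetDaily:
    """One day of meteorological forcing."""

    date: pd.Timestamp
    ta_c: float
    tmax_c: float
    tmin_c: float
    par: float  # MJ m-2 d-1
    rh_pct: float
    precip_mm: float
    sw: float  # volumetric soil moisture, same units as sc
    sc: float  # saturated soil water capacity
    co2_ppm: float = 400.0
    lat_deg: float = 30.0

    def validate(self) -> None:
        if not (0.0 <= self.rh_pct <= 100.0):
            raise DriverError(f"rh_pct={self.rh_pct} outside [0, 100] on {self.date}")
        if self.par < 0:
            raise DriverError(f"negative PAR on {self.date}")
        if self.precip_mm < 0:
            raise DriverError(f"negative precipitation on {self.date}")
        if self.sc <= 0:
            raise DriverError(f"sc={self.sc} must be positive on {self.date}")
        if not (0.0 <= self.sw <= self.sc):
            raise DriverError(f"sw={self.sw} outside [0, sc={self.sc}] on {self.date}")
        if not (self.tmin_c <= self.ta_c <= self.tmax_c):
            raise DriverError(f"tmin <= ta <= tmax violated on {self.date}")


@dataclass(frozen=True)
class PoolState:
    """Carbon reservoirs, g C m-2.  ``clab`` is present only for deciduous sites."""

    cf: float
    cr: float
    cw: float
    clit: float
    csom: float
    clab: float | None = None

    @property
    def deciduous(self) -> bool:
        return self.clab is not None

    def total(self) -> float:
        return self.cf + self.cr + self.cw + self.clit + self.csom + (self.clab or 0.0)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.cf, self.cr, self.cw, self.clit, self.csom, self.clab or 0.0]
        )

    def validate(self) -> None:
        for name in ("cf", "cr", "cw", "clit", "csom"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DalecError(f"pool {name}={v} must be finite and >= 0")
        if self.clab is not None and (not np.isfinite(self.clab) or self.clab < 0):
            raise DalecError(f"pool clab={self.clab} must be finite and >= 0")


POOL_NAMES = ("cf", "cr", "cw", "clit", "csom", "clab")

# Parameters retrieved by the data-assimilation engine by default; the
# remaining fields (canopy_eff, sw_exp, lcma, phenology) are site constants.
RETRIEVED_PARAMS = (
    "f_a",
    "f_f",
    "f_r",
    "k_f",
    "k_r",
    "k_w",
    "k_lit_min",
    "k_lit_dec",
    "k_som",
    "theta",
)


@dataclass(frozen=True)
class ParameterVector:
    """All tunable process parameters of the carbon model.

    Allocation fractions are dimensionless, turnover/decomposition rates are
    first-order daily rates (d-1), ``theta`` is the exponential temperature
    sensitivity (degC-1; Q10 = exp(10*theta)), ``sw_exp`` shapes the
    soil-moisture scalar, ``canopy_eff`` scales ACM photosynthetic capacity
    (absorbs foliar nitrogen), and ``lcma`` (g C m-2 leaf) links foliar
    carbon to leaf area index.  Phenology fields are used only when the run
    is deciduous.
    """

    f_a: float = 0.45  # fraction of GPP respired autotrophically
    f_f: float = 0.25  # fraction of NPP to foliage
    f_r: float = 0.25  # fraction of NPP to fine roots (rest to wood)
    k_f: float = 1.0 / (2.5 * 365.25)  # foliage turnover, d-1
    k_r: float = 1.0 / (2.0 * 365.25)  # fine-root turnover, d-1
    k_w: float = 1.0 / (50.0 * 365.25)  # wood turnover, d-1
    k_lit_min: float = 2.0e-3  # litter mineralization (respired), d-1
    k_lit_dec: float = 2.0e-3  # litter decomposition to SOM, d-1
    k_som: float = 5.0e-5  # SOM mineralization, d-1
    theta: float = 0.0693  # temperature sensitivity, degC-1 (Q10 = 2)
    sw_exp: float = 1.0  # soil-moisture scalar exponent
    canopy_eff: float = 3.5  # ACM canopy efficiency (foliar-N proxy)
    lcma: float = 60.0  # leaf C mass per area, g C m-2 (held constant)
    day_leafout: float = 120.0  # deciduous only, day of year
    day_leaffall: float = 290.0  # deciduous only, day of year
    k_lab: float = 0.05  # labile release rate after leaf-out, d-1
    clab0: float = 100.0  # initial labile C, g C m-2 (retrieved)

    def replace(self, **kwargs) -> "ParameterVector":
        return dataclasses.replace(self, **kwargs)

    def to_array(self, names: Sequence[str]) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], dtype=float)

    @classmethod
    def from_array(
        cls, values: Sequence[float], names: Sequence[str], base: "ParameterVector" = None
    ) -> "ParameterVector":
        base = base or cls()
        return base.replace(**{n: float(v) for n, v in zip(names, values)})

    def validate(self, bounds: dict | None = None) -> None:
        bounds = bounds or DEFAULT_BOUNDS
        for name, (lo, hi) in bounds.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigurationError(f"parameter {name}={v} outside prior [{lo}, {hi}]")
        if self.f_f + self.f_r > 1.0:
            raise ConfigurationError("f_f + f_r must not exceed 1")


#: Uniform prior intervals for the retrievable parameters.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "f_a": (0.2, 0.8),
    "f_f": (0.05, 0.5),
    "f_r": (0.05, 0.5),
    "k_f": (1.0 / (10 * 365.25), 1.0 / (0.5 * 365.25)),  # leaf lifespan 0.5-10 yr
    "k_r": (1.0 / (10 * 365.25), 1.0 / (0.5 * 365.25)),
    "k_w": (1.0 / (1000 * 365.25), 1.0 / (10 * 365.25)),  # wood residence 10-1000 yr
    "k_lit_min": (1.0e-4, 1.0e-2),
    "k_lit_dec": (1.0e-4, 1.0e-2),
    "k_som": (1.0 / (1000 * 365.25), 1.0 / (10 * 365.25)),
    "theta": (0.02, 0.08),
    "sw_exp": (0.1, 3.0),
    "canopy_eff": (1.0, 8.0),
    "k_lab": (0.01, 0.2),
    "clab0": (10.0, 1000.0),
}


@dataclass(frozen=True)
class FluxDaily:
    """One day of carbon fluxes, g C m-2 d-1."""

    gpp: float
    ra: float
    rh_lit: float
    rh_som: float
    npp: float
    nep: float
    litterfall_foliar: float
    litterfall_total: float  # turnover leaving all live pools
    alloc_f: float
    alloc_r: float
    alloc_w: float


@dataclass(frozen=True)
class ACMCoefficients:
    """The ten empirical ACM coefficients plus hydraulic constants.

    Defaults are the widely used calibration for temperate/boreal canopies;
    any coefficient may be overridden through configuration.
    """

    a1: float = 2.155
    a2: float = 0.0142
    a3: float = 217.9
    a4: float = 0.980
    a5: float = 0.155
    a6: float = 2.653
    a7: float = 4.309
    a8: float = 0.060
    a9: float = 1.062
    a10: float = 0.0006
    psi_d: float = -2.0  # max soil-leaf water potential difference, MPa
    r_tot: float = 1.0  # total plant-soil hydraulic resistance

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ACMCoefficients":
        required = [f.name for f in dataclasses.fields(cls)]
        defaults = cls()
        values = {}
        for name in required:
            if name in mapping:
                values[name] = float(mapping[name])
            else:
                values[name] = getattr(defaults, name)
        unknown = set(mapping) - set(required)
        if unknown:
            raise ConfigurationError(f"unknown ACM coefficients: {sorted(unknown)}")
        return cls(**values)

    def require_complete(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None or not np.isfinite(v):
                raise ConfigurationError(f"ACM coefficient {f.name} missing or non-finite")


DEFAULT_ACM = ACMCoefficients()

FLUX_COLS = (
    "gpp",
    "ra",
    "rh_lit",
    "rh_som",
    "npp",
    "nep",
    "lit_f",
    "lit_r",
    "lit_w",
    "alloc_f",
    "alloc_r",
    "alloc_w",
)

STREAM_KINDS = (
    "lai",
    "biomass_f",
    "biomass_r",
    "biomass_w",
    "litterfall_annual",
    "soc",
    "nee_daily",
)


# ---------------------------------------------------------------------------
# Driver preparation
# ---------------------------------------------------------------------------

DRIVER_COLUMNS = (
    "date",
    "ta_c",
    "tmax_c",
    "tmin_c",
    "par",
    "rh_pct",
    "precip_mm",
    "sw",
    "sc",
)


def drivers_to_frame(drivers) -> pd.DataFrame:
    """Normalize a driver input (DataFrame or MetDaily sequence) to a frame."""
    if isinstance(drivers, pd.DataFrame):
        df = drivers.copy()
    else:
        rows = list(drivers)
        if not rows:
            raise DriverError("empty driver sequence")
        df = pd.DataFrame(
            {
                "date": [m.date for m in rows],
                "ta_c": [m.ta_c for m in rows],
                "tmax_c": [m.tmax_c for m in rows],
                "tmin_c": [m.tmin_c for m in rows],
                "par": [m.par for m in rows],
                "rh_pct": [m.rh_pct for m in rows],
                "precip_mm": [m.precip_mm for m in rows],
                "sw": [m.sw for m in rows],
                "sc": [m.sc for m in rows],
            }
        )
    if df.empty:
        raise DriverError("empty driver table")
    missing = [c for c in DRIVER_COLUMNS if c not in df.columns]
    if missing:
        raise DriverError(f"driver table missing columns: {missing}")
    df["date"] = pd.to_datetime(df["date"])
    return df.reset_index(drop=True)


def check_driver_contiguity(dates: pd.Series) -> None:
    diffs = pd.to_datetime(dates).diff().dropna()
    bad = diffs[diffs != pd.Timedelta(days=1)]
    if len(bad):
        raise ContiguityError(
            f"driver dates not contiguous daily steps (first gap after row {bad.index[0] - 1})"
        )


def day_length_hours(doy, lat_deg: float):
    """Astronomical day length (hours) from day-of-year and latitude."""
    doy = np.asarray(doy, dtype=float)
    decl = -0.4084 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.25)
    mult = np.tan(np.radians(lat_deg)) * np.tan(decl)
    mult = np.clip(mult, -1.0, 1.0)
    return 24.0 * np.arccos(-mult) / np.pi


@dataclass
class PreparedDrivers:
    """Driver-derived per-day arrays consumed by the simulation kernel."""

    dates: pd.DatetimeIndex
    doy: np.ndarray
    ta: np.ndarray
    par: np.ndarray
    gc: np.ndarray  # ACM canopy conductance term
    light: np.ndarray  # ACM day-length factor a2*s + a5
    exp_a8_tmax: np.ndarray
    log_swr: np.ndarray  # log(sw/sc), <= 0
    co2: np.ndarray
    acm: ACMCoefficients

    @property
    def n_days(self) -> int:
        return len(self.dates)


def prepare_drivers(
    drivers,
    acm: ACMCoefficients = DEFAULT_ACM,
    lat_deg: float = 30.0,
    co2_ppm: float = 400.0,
    check: bool = True,
) -> PreparedDrivers:
    df = drivers_to_frame(drivers)
    acm.require_complete()
    check_driver_contiguity(df["date"])
    arrs = {c: df[c].to_numpy(dtype=float) for c in DRIVER_COLUMNS if c != "date"}
    if check:
        for name, a in arrs.items():
            if not np.all(np.isfinite(a)):
                idx = int(np.flatnonzero(~np.isfinite(a))[0])
                raise PropagationError(f"non-finite driver value {name} at day index {idx}")
        if np.any(arrs["sc"] <= 0):
            raise DriverError("sc must be positive everywhere")
        if np.any((arrs["sw"] < 0) | (arrs["sw"] > arrs["sc"])):
            idx = int(np.flatnonzero((arrs["sw"] < 0) | (arrs["sw"] > arrs["sc"]))[0])
            raise DriverError(f"sw outside [0, sc] at day index {idx}")
        if np.any((arrs["rh_pct"] < 0) | (arrs["rh_pct"] > 100)):
            raise DriverError("rh_pct outside [0, 100]")
        if np.any(arrs["par"] < 0):
            raise DriverError("negative PAR")
    dates = pd.DatetimeIndex(df["date"])
    doy = dates.dayofyear.to_numpy(dtype=float)
    trange = 0.5 * (arrs["tmax_c"] - arrs["tmin_c"])
    gc = np.abs(acm.psi_d) ** acm.a10 / (acm.a6 * acm.r_tot + np.maximum(trange, 0.0))
    dayl = day_length_hours(doy, lat_deg)
    light = acm.a2 * dayl + acm.a5
    exp_a8_tmax = np.exp(acm.a8 * arrs["tmax_c"])
    swr = np.clip(arrs["sw"] / arrs["sc"], 1e-12, 1.0)
    co2 = np.full(len(df), float(co2_ppm))
    if "co2_ppm" in df.columns:
        co2 = df["co2_ppm"].to_numpy(dtype=float)
    return PreparedDrivers(
        dates=dates,
        doy=doy,
        ta=arrs["ta_c"],
        par=arrs["par"],
        gc=gc,
        light=light,
        exp_a8_tmax=exp_a8_tmax,
        log_swr=np.log(swr),
        co2=co2,
        acm=acm,
    )


# ---------------------------------------------------------------------------
# Simulation kernel (JIT-compiled when numba is available)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _acm_gpp_kernel(lai, par, gc, light, exp_a8_tmax, co2, ceff, a3, a4, a7, a9):
    """ACM daily GPP (g C m-2 d-1) for a single day."""
    if lai <= 0.0 or par <= 0.0:
        return 0.0
    p = ceff * lai / gc * exp_a8_tmax
    q = a3 - a4
    aa = co2 + q - p
    disc = aa * aa - 4.0 * (co2 * q - p * a3)
    if disc < 0.0:
        disc = 0.0
    ci = 0.5 * (aa + np.sqrt(disc))
    dc = co2 - ci
    if dc < 0.0:
        dc = 0.0
    e0 = a7 * lai * lai / (lai * lai + a9)
    denom = e0 * par + gc * dc
    if denom <= 0.0:
        return 0.0
    cps = e0 * par * gc * dc / denom
    g = cps * light
    if g < 0.0:
        g = 0.0
    return g


@njit(cache=True, fastmath=False)
def _simulate_kernel(
    doy,
    ta,
    par,
    gc,
    light,
    exp_a8_tmax,
    log_swr,
    co2,
    p,  # parameter array, see _PARAM_ORDER
    pools0,  # (6,) cf cr cw clit csom clab
    a3,
    a4,
    a7,
    a9,
    deciduous,
):
    n = doy.shape[0]
    pools = np.empty((n + 1, 6))
    fluxes = np.empty((n, 12))
    for j in range(6):
        pools[0, j] = pools0[j]

    f_a = p[0]
    f_f = p[1]
    f_r = p[2]
    k_f = p[3]
    k_r = p[4]
    k_w = p[5]
    k_lm = p[6]
    k_ld = p[7]
    k_som = p[8]
    theta = p[9]
    sw_exp = p[10]
    ceff = p[11]
    lcma = p[12]
    leafout = p[13]
    leaffall = p[14]
    k_lab = p[15]

    for t in range(n):
        cf = pools[t, 0]
        cr = pools[t, 1]
        cw = pools[t, 2]
        clit = pools[t, 3]
        csom = pools[t, 4]
        clab = pools[t, 5]

        d = doy[t]
        lai = cf / lcma
        gpp = _acm_gpp_kernel(
            lai, par[t], gc[t], light[t], exp_a8_tmax[t], co2[t], ceff, a3, a4, a7, a9
        )
        ra = f_a * gpp
        npp = gpp - ra
        alloc_f = f_f * npp
        alloc_r = f_r * npp
        alloc_w = npp - alloc_f - alloc_r

        f_ta = np.exp(theta * ta[t])
        f_sw = np.exp(sw_exp * log_swr[t])
        if f_sw > 1.0:
            f_sw = 1.0
        dr = f_ta * f_sw

        # effective first-order removal rates, clipped so no pool overshoots
        ef = k_f if k_f < 1.0 else 1.0
        er = k_r if k_r < 1.0 else 1.0
        ew = k_w if k_w < 1.0 else 1.0
        rlm = k_lm * dr
        rld = k_ld * dr
        rl = rlm + rld
        if rl > 1.0:
            rlm = rlm / rl
            rld = rld / rl
        rs = k_som * dr
        if rs > 1.0:
            rs = 1.0

        release = 0.0
        alloc_to_lab = 0.0
        fall_frac = 0.0
        if deciduous == 1:
            in_season = leafout <= d < leaffall
            if in_season and d < leaffall - 30.0:
                release = k_lab * clab
            elif in_season:
                # senescence window: growth stops, full transfer by day_leaffall
                fall_frac = 1.0 / (leaffall - d)
                alloc_to_lab = alloc_f
                alloc_f = 0.0
            else:
                # off-season: photosynthate stored, any residual canopy shed
                alloc_to_lab = alloc_f
                alloc_f = 0.0
                fall_frac = 1.0
        # combined foliage removal fraction never exceeds 1; when the
        # phenological fall would empty the pool, remove it exactly
        f_rem = ef + fall_frac
        if f_rem >= 1.0:
            lit_f = (ef / f_rem) * cf
            leaffall_flux = cf - lit_f
        else:
            lit_f = ef * cf
            leaffall_flux = fall_frac * cf
        lit_r = er * cr
        lit_w = ew * cw
        rh_lit = rlm * clit
        dec_lit = rld * clit
        rh_som = rs * csom
        nep = gpp - ra - rh_lit - rh_som

        cf_n = cf + alloc_f + release - lit_f - leaffall_flux
        cr_n = cr + alloc_r - lit_r
        cw_n = cw + alloc_w - lit_w
        clit_n = clit + lit_f + lit_r + leaffall_flux - rh_lit - dec_lit
        csom_n = csom + lit_w + dec_lit - rh_som
        clab_n = clab + alloc_to_lab - release

        pools[t + 1, 0] = cf_n
        pools[t + 1, 1] = cr_n
        pools[t + 1, 2] = cw_n
        pools[t + 1, 3] = clit_n
        pools[t + 1, 4] = csom_n
        pools[t + 1, 5] = clab_n

        fluxes[t, 0] = gpp
        fluxes[t, 1] = ra
        fluxes[t, 2] = rh_lit
        fluxes[t, 3] = rh_som
        fluxes[t, 4] = npp
        fluxes[t, 5] = nep
        fluxes[t, 6] = lit_f + leaffall_flux
        fluxes[t, 7] = lit_r
        fluxes[t, 8] = lit_w
        fluxes[t, 9] = alloc_f
        fluxes[t, 10] = alloc_r
        fluxes[t, 11] = alloc_w

    return pools, fluxes


_PARAM_ORDER = (
    "f_a",
    "f_f",
    "f_r",
    "k_f",
    "k_r",
    "k_w",
    "k_lit_min",
    "k_lit_dec",
    "k_som",
    "theta",
    "sw_exp",
    "canopy_eff",
    "lcma",
    "day_leafout",
    "day_leaffall",
    "k_lab",
)


def _param_array(pv: ParameterVector) -> np.ndarray:
    return np.array([getattr(pv, n) for n in _PARAM_ORDER], dtype=float)


def simulate_arrays(
    prep: PreparedDrivers, pv: ParameterVector, init: PoolState
) -> tuple[np.ndarray, np.ndarray]:
    """Low-level forward run returning raw (pools, fluxes) arrays.

    ``pools`` has n+1 rows (row t is the state at the start of day t, row 0
    is ``init``); ``fluxes`` has n rows in FLUX_COLS order.
    """
    init.validate()
    p = _param_array(pv)
    if not np.all(np.isfinite(p)):
        bad = _PARAM_ORDER[int(np.flatnonzero(~np.isfinite(p))[0])]
        raise PropagationError(f"non-finite parameter {bad}")
    pools0 = init.as_array()
    acm = prep.acm
    return _simulate_kernel(
        prep.doy,
        prep.ta,
        prep.par,
        prep.gc,
        prep.light,
        prep.exp_a8_tmax,
        prep.log_swr,
        prep.co2,
        p,
        pools0,
        acm.a3,
        acm.a4,
        acm.a7,
        acm.a9,
        1 if init.deciduous else 0,
    )


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def acm_gpp(
    met: MetDaily,
    lai: float,
    pv: ParameterVector,
    acm: ACMCoefficients = DEFAULT_ACM,
) -> float:
    """Daily GPP (g C m-2 d-1) from the Aggregated Canopy Model."""
    if lai < 0:
        raise DalecError(f"lai={lai} must be >= 0")
    met.validate()
    acm.require_complete()
    trange = 0.5 * (met.tmax_c - met.tmin_c)
    gc = abs(acm.psi_d) ** acm.a10 / (acm.a6 * acm.r_tot + max(trange, 0.0))
    doy = float(pd.Timestamp(met.date).dayofyear)
    dayl = float(day_length_hours(doy, met.lat_deg))
    light = acm.a2 * dayl + acm.a5
    return float(
        _acm_gpp_kernel(
            float(lai),
            met.par,
            gc,
            light,
            float(np.exp(acm.a8 * met.tmax_c)),
            met.co2_ppm,
            pv.canopy_eff,
            acm.a3,
            acm.a4,
            acm.a7,
            acm.a9,
        )
    )


def env_scalars(met: MetDaily, pv: ParameterVector) -> tuple[float, float]:
    """Temperature and soil-moisture scalars on decomposition.

    f_ta = exp(theta * Ta);  f_sw = (Sw/Sc)^sw_exp clipped to [0, 1].
    """
    if met.sc <= 0:
        raise DriverError(f"sc={met.sc} must be positive")
    if not (0.0 <= met.sw <= met.sc):
        raise DriverError(f"sw={met.sw} outside [0, sc={met.sc}]")
    f_ta = float(np.exp(pv.theta * met.ta_c))
    f_sw = float(min((met.sw / met.sc) ** pv.sw_exp, 1.0))
    return f_ta, f_sw


class Trajectory:
    """Daily model output: start-of-day pools plus that day's fluxes.

    ``pools`` carries n+1 rows so that the final state is available; record t
    pairs pools[t] with fluxes[t].
    """

    def __init__(
        self,
        dates: pd.DatetimeIndex,
        pools: np.ndarray,
        fluxes: np.ndarray,
        pv: ParameterVector,
        deciduous: bool = False,
    ):
        if pools.shape[0] != len(dates) + 1:
            raise DalecError("pools must have one more row than dates")
        if fluxes.shape[0] != len(dates):
            raise DalecError("fluxes must have one row per date")
        self.dates = pd.DatetimeIndex(dates)
        self.pools = pools
        self.fluxes = fluxes
        self.pv = pv
        self.deciduous = deciduous

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def pool(self, name: str) -> np.ndarray:
        """Start-of-day series for one pool (length n_days)."""
        return self.pools[:-1, POOL_NAMES.index(name)]

    def flux(self, name: str) -> np.ndarray:
        return self.fluxes[:, FLUX_COLS.index(name)]

    @property
    def initial_state(self) -> PoolState:
        return self._state(0)

    @property
    def final_state(self) -> PoolState:
        return self._state(-1)

    def _state(self, row: int) -> PoolState:
        r = self.pools[row]
        return PoolState(
            cf=r[0], cr=r[1], cw=r[2], clit=r[3], csom=r[4],
            clab=r[5] if self.deciduous else None,
        )

    def index_of(self, timestamps) -> np.ndarray:
        ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
        idx = self.dates.get_indexer(ts)
        if np.any(idx < 0):
            bad = ts[idx < 0][0]
            raise RangeError(f"timestamp {bad.date()} outside trajectory span")
        return idx

    def pools_frame(self) -> pd.DataFrame:
        cols = list(POOL_NAMES if self.deciduous else POOL_NAMES[:5])
        return pd.DataFrame(self.pools[:-1, : len(cols)], index=self.dates, columns=cols)

    def fluxes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fluxes, index=self.dates, columns=list(FLUX_COLS))

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.pools_frame(), self.fluxes_frame()], axis=1)

    def total_carbon(self) -> np.ndarray:
        """Total ecosystem carbon at the start of each day plus final state."""
        return self.pools.sum(axis=1)

    def mass_balance_error(self) -> float:
        """Max relative error of daily dSumC vs (GPP - Ra - Rh)."""
        tot = self.total_carbon()
        d = np.diff(tot)
        nee_model = self.flux("nep")
        denom = np.maximum(tot[:-1], 1.0)
        return float(np.max(np.abs(d - nee_model) / denom)) if len(d) else 0.0


def step_day(
    state: PoolState,
    met: MetDaily,
    pv: ParameterVector,
    day_of_year: int,
    acm: ACMCoefficients = DEFAULT_ACM,
) -> tuple[PoolState, FluxDaily]:
    """Advance the pool state by one daily Euler step."""
    met.validate()
    state.validate()
    df = pd.DataFrame([{c: getattr(met, c) for c in DRIVER_COLUMNS}])
    prep = prepare_drivers(df, acm=acm, lat_deg=met.lat_deg, co2_ppm=met.co2_ppm)
    prep.doy = np.array([float(day_of_year)])
    pools, fluxes = simulate_arrays(prep, pv, state)
    nxt = PoolState(
        cf=pools[1, 0], cr=pools[1, 1], cw=pools[1, 2], clit=pools[1, 3],
        csom=pools[1, 4], clab=pools[1, 5] if state.deciduous else None,
    )
    f = fluxes[0]
    flux = FluxDaily(
        gpp=f[0], ra=f[1], rh_lit=f[2], rh_som=f[3], npp=f[4], nep=f[5],
        litterfall_foliar=f[6], litterfall_total=f[6] + f[7] + f[8],
        alloc_f=f[9], alloc_r=f[10], alloc_w=f[11],
    )
    return nxt, flux


def run_forward(
    drivers,
    pv: ParameterVector,
    init: PoolState,
    acm: ACMCoefficients = DEFAULT_ACM,
    lat_deg: float = 30.0,
    co2_ppm: float = 400.0,
) -> Trajectory:
    """Run the daily model over a contiguous driver sequence.

    Deterministic: identical inputs give bit-identical trajectories.  The
    run is deciduous when ``init.clab`` is set.
    """
    prep = drivers if isinstance(drivers, PreparedDrivers) else prepare_drivers(
        drivers, acm=acm, lat_deg=lat_deg, co2_ppm=co2_ppm
    )
    pools, fluxes = simulate_arrays(prep, pv, init)
    return Trajectory(prep.dates, pools, fluxes, pv, deciduous=init.deciduous)


def observation_operator(traj: Trajectory, stream_kind: str, timestamps) -> np.ndarray:
    """Map a trajectory onto predicted observations for one data stream.

    LAI is Cf/LCMA; biomass and SOC streams read the matching pool at the
    observation date; annual litterfall is the calendar-year sum of foliar
    turnover; daily NEE uses the uptake-negative convention (NEE = -NEP).
    """
    if stream_kind not in STREAM_KINDS:
        raise DalecError(
            f"unknown stream kind {stream_kind!r}; expected one of {STREAM_KINDS}"
        )
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
    if stream_kind == "litterfall_annual":
        years = ts.year.to_numpy()
        flux = traj.flux("lit_f")
        traj_years = traj.dates.year.to_numpy()
        out = np.empty(len(years))
        for i, y in enumerate(years):
            mask = traj_years == y
            if not mask.any():
                raise RangeError(f"year {y} outside trajectory span")
            out[i] = flux[mask].sum()
        return out
    idx = traj.index_of(ts)
    if stream_kind == "lai":
        return traj.pool("cf")[idx] / traj.pv.lcma
    if stream_kind == "biomass_f":
        return traj.pool("cf")[idx]
    if stream_kind == "biomass_r":
        return traj.pool("cr")[idx]
    if stream_kind == "biomass_w":
        return traj.pool("cw")[idx]
    if stream_kind == "soc":
        return traj.pool("csom")[idx]
    # nee_daily
    return -traj.flux("nep")[idx]
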