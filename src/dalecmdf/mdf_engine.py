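"""Non-steady-state Bayesian parameter retrieval for the DALEC model.

The retrieval maximises/samples the Gaussian product likelihood

    log L = sum_j sum_i [ -0.5 ln(2 pi) - ln sigma_j
                          - (x_ji - mu_ji(P))^2 / (2 sigma_j^2) ]

over all observation streams j (biomass per tissue, annual litterfall,
LAI, SOC, optional daily NEE) with a Metropolis simulated-annealing
sampler: a geometric cooling phase from T0 down to 1 (doubling as burn-in,
with proposal-width adaptation) followed by a sampling phase at T = 1
whose draws approximate the posterior.  Ecological and dynamic constraints
(EDCs) on parameter inter-relationships and pool trajectories are enforced
as hard rejections.

Initial pool states come from the earliest stock observations — no
spin-up and no steady-state assumption anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .dalec_core import (
    DEFAULT_ACM,
    DEFAULT_BOUNDS,
    RETRIEVED_PARAMS,
    STREAM_KINDS,
    ACMCoefficients,
    DalecError,
    ParameterVector,
    PoolState,
    PreparedDrivers,
    RangeError,
    Trajectory,
    observation_operator,
    prepare_drivers,
    run_forward,
    simulate_arrays,
)

LOG_2PI = math.log(2.0 * math.pi)


class MDFError(DalecError):
    pass


class MissingStreamError(MDFError):
    pass


# ---------------------------------------------------------------------------
# Observation streams
# ---------------------------------------------------------------------------

#: Default per-stream observation error when none is supplied: relative
#: fractions of the stream mean for stocks, absolute for NEE (g C m-2 d-1).
DEFAULT_SIGMA_RULES: dict[str, tuple[str, float]] = {
    "biomass_f": ("rel", 0.10),
    "biomass_r": ("rel", 0.10),
    "biomass_w": ("rel", 0.10),
    "lai": ("rel", 0.20),
    "litterfall_annual": ("rel", 0.20),
    "soc": ("rel", 0.15),
    "nee_daily": ("abs", 0.5),
}


@dataclass
class ObservationStream:
    """Timestamped observations of one data type with a stream-level sigma."""

    kind: str
    times: pd.DatetimeIndex
    values: np.ndarray
    sigma: float

    def __post_init__(self):
        if self.kind not in STREAM_KINDS:
            raise MDFError(f"unknown stream kind {self.kind!r}; allowed: {STREAM_KINDS}")
        self.times = pd.DatetimeIndex(pd.to_datetime(self.times))
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise MDFError(f"stream {self.kind}: times/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise MDFError(f"stream {self.kind}: non-finite values")
        if not self.times.is_monotonic_increasing or self.times.has_duplicates:
            raise MDFError(f"stream {self.kind}: timestamps must be strictly increasing")
        if not (self.sigma > 0):
            raise MDFError(f"stream {self.kind}: sigma must be positive")

    def __len__(self) -> int:
        return len(self.values)


def default_sigma(kind: str, values: np.ndarray) -> float:
    mode, x = DEFAULT_SIGMA_RULES[kind]
    if mode == "abs":
        return x
    m = float(np.mean(np.abs(values)))
    return x * m if m > 0 else x


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def log_likelihood(
    streams: Sequence[ObservationStream],
    traj: Trajectory,
    pv: ParameterVector | None = None,
) -> float:
    """Gaussian log-likelihood of all streams given a model trajectory.

    Invariant to stream ordering; errors if no stream constrains the model.
    """
    streams = list(streams)
    if not streams:
        raise MDFError("no observation streams supplied — nothing to constrain")
    total = 0.0
    for s in streams:
        mu = observation_operator(traj, s.kind, s.times)
        r = (s.values - mu) / s.sigma
        total += float(-0.5 * np.sum(r * r) - len(s) * (0.5 * LOG_2PI + math.log(s.sigma)))
    return total


# ---------------------------------------------------------------------------
# Ecological and dynamic constraints
# ---------------------------------------------------------------------------


def _edc_alloc_sum(pv, traj):
    return pv.f_f + pv.f_r <= 0.9


def _edc_leaf_faster_than_wood(pv, traj):
    return pv.k_f > pv.k_w


def _edc_root_faster_than_wood(pv, traj):
    return pv.k_r > pv.k_w


def _edc_litter_faster_than_som(pv, traj):
    return pv.k_lit_min + pv.k_lit_dec > pv.k_som


def _edc_fa_range(pv, traj):
    return 0.2 <= pv.f_a <= 0.8


def _edc_pool_floor(pv, traj):
    if traj is None:
        return True
    npools = 6 if traj.deciduous else 5
    return bool(np.all(traj.pools[:, :npools].min(axis=0) >= 1e-3))


def _edc_pool_divergence(pv, traj):
    if traj is None:
        return True
    npools = 6 if traj.deciduous else 5
    init = traj.pools[0, :npools]
    peak = traj.pools[:, :npools].max(axis=0)
    ok = np.ones(npools, dtype=bool)
    pos = init > 0
    ok[pos] = peak[pos] <= 10.0 * init[pos]
    return bool(np.all(ok))


#: Named, individually toggleable EDC rules.  Parameter rules need no
#: trajectory; dynamic rules are checked only when one is supplied.
EDC_RULES: dict[str, Callable] = {
    "alloc_sum": _edc_alloc_sum,
    "leaf_faster_than_wood": _edc_leaf_faster_than_wood,
    "root_faster_than_wood": _edc_root_faster_than_wood,
    "litter_faster_than_som": _edc_litter_faster_than_som,
    "fa_range": _edc_fa_range,
    "pool_floor": _edc_pool_floor,
    "pool_divergence": _edc_pool_divergence,
}

PARAM_EDC_RULES = (
    "alloc_sum",
    "leaf_faster_than_wood",
    "root_faster_than_wood",
    "litter_faster_than_som",
    "fa_range",
)


def check_edcs(
    pv: ParameterVector,
    traj: Trajectory | None = None,
    rules: Iterable[str] | None = None,
) -> tuple[bool, list[str]]:
    """Evaluate EDC rules; returns (all passed, list of violated rule ids)."""
    names = list(rules) if rules is not None else list(EDC_RULES)
    violated = [n for n in names if not EDC_RULES[n](pv, traj)]
    return (not violated, violated)


# ---------------------------------------------------------------------------
# Metropolis simulated annealing
# ---------------------------------------------------------------------------


@dataclass
class MDFConfig:
    """Sampler settings.

    ``n_iter`` total iterations; the first ``anneal_frac`` fraction cools
    geometrically from ``t0`` to 1 and doubles as burn-in (with proposal
    adaptation toward 25-40% acceptance); the rest samples at T = 1.
    """

    n_iter: int = 100_000
    anneal_frac: float = 0.5
    t0: float = 100.0
    step_scale: float = 0.05  # initial proposal sd in [0,1]-normalized space
    seed: int = 0
    bounds: dict[str, tuple[float, float]] | None = None
    adapt_interval: int = 200
    accept_window: tuple[float, float] = (0.25, 0.40)

    def __post_init__(self):
        if self.n_iter < 1000:
            raise MDFError("n_iter must be >= 1000")
        if not (0.0 < self.anneal_frac < 1.0):
            raise MDFError("anneal_frac must lie in (0, 1)")
        if self.t0 < 1.0:
            raise MDFError("t0 must be >= 1")


@dataclass
class MDFResult:
    """Outcome of one retrieval chain."""

    map_params: object  # ParameterVector (site runs) or dict (generic runs)
    names: tuple[str, ...]
    samples: np.ndarray  # (n_samples, n_params), physical units
    acceptance_rate: float
    loglik_trace: np.ndarray
    edc_reject_count: int
    best_loglik: float
    step_scale_final: np.ndarray | None = None

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=list(self.names))

    def credible_interval(self, level: float = 0.90) -> dict[str, tuple[float, float]]:
        a = 100.0 * (1.0 - level) / 2.0
        lo = np.percentile(self.samples, a, axis=0)
        hi = np.percentile(self.samples, 100.0 - a, axis=0)
        return {n: (float(l), float(h)) for n, l, h in zip(self.names, lo, hi)}

    def posterior_mean(self) -> dict[str, float]:
        m = self.samples.mean(axis=0)
        return {n: float(v) for n, v in zip(self.names, m)}


def _reflect_unit(x: np.ndarray) -> np.ndarray:
    """Reflect coordinates into [0, 1]."""
    y = np.mod(x, 2.0)
    return np.where(y > 1.0, 2.0 - y, y)


def propose_params(
    pv: ParameterVector,
    cfg: MDFConfig,
    rng: np.random.Generator,
    names: Sequence[str] = RETRIEVED_PARAMS,
) -> ParameterVector:
    """Gaussian step in normalized parameter space, reflected at the bounds."""
    bounds = cfg.bounds or DEFAULT_BOUNDS
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    x = (pv.to_array(names) - lo) / (hi - lo)
    xp = _reflect_unit(x + rng.normal(0.0, cfg.step_scale, len(names)))
    return ParameterVector.from_array(lo + xp * (hi - lo), names, base=pv)


def metropolis_sa(
    objective: Callable[[np.ndarray], float],
    cfg: MDFConfig,
    init: np.ndarray | Sequence[float],
    bounds: Sequence[tuple[float, float]],
    names: Sequence[str] | None = None,
    edc: Callable[[np.ndarray], bool] | None = None,
) -> MDFResult:
    """Metropolis simulated-annealing chain over a box-bounded space.

    ``objective`` maps a physical parameter array to a log-likelihood; it
    may return -inf to signal a dynamic-constraint violation (counted with
    the EDC rejections).  ``edc`` is a cheap parameter-only pre-check.
    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    k = len(lo)
    names = tuple(names) if names is not None else tuple(f"p{i}" for i in range(k))

    x = (np.asarray(init, dtype=float) - lo) / (hi - lo)
    if np.any(x < 0) or np.any(x > 1):
        raise MDFError("init outside bounds")
    phys = lo + x * (hi - lo)
    ll = float(objective(phys))
    if not np.isfinite(ll):
        raise MDFError("objective not finite at init")

    n_cool = int(cfg.anneal_frac * cfg.n_iter)
    cool_rate = cfg.t0 ** (-1.0 / max(n_cool, 1))
    # adaptive-Metropolis proposal: global factor (tuned on acceptance)
    # times the Cholesky factor of the running chain covariance (Haario
    # et al. adaptation), estimated over the later part of cooling and
    # frozen for the sampling phase
    chol = np.eye(k) * cfg.step_scale
    gfac = 1.0
    prop_chol = gfac * chol
    run_mean = x.copy()
    run_cov = np.zeros((k, k))
    run_n = 0

    best_ll = ll
    best_x = phys.copy()
    n_accept = 0
    edc_rejects = 0
    win_accept = 0
    win_count = 0
    trace = np.empty(cfg.n_iter)
    samples = np.empty((cfg.n_iter - n_cool, k))
    temp = cfg.t0

    for it in range(cfg.n_iter):
        if it < n_cool:
            temp *= cool_rate
            T = max(temp, 1.0)
        else:
            T = 1.0
        xp = _reflect_unit(x + prop_chol @ rng.normal(0.0, 1.0, k))
        physp = lo + xp * (hi - lo)
        win_count += 1
        rejected = True
        if edc is not None and not edc(physp):
            edc_rejects += 1
        else:
            llp = float(objective(physp))
            if math.isnan(llp):
                raise MDFError(f"objective returned NaN at iteration {it}")
            if llp == -math.inf:
                edc_rejects += 1
            elif llp >= ll or rng.random() < math.exp((llp - ll) / T):
                x, phys, ll = xp, physp, llp
                n_accept += 1
                win_accept += 1
                rejected = False
                if ll > best_ll:  # ties keep the earlier-visited state
                    best_ll = ll
                    best_x = phys.copy()
        trace[it] = ll
        # running chain mean/covariance (late cooling onward); the proposal
        # shape keeps adapting with diminishing influence (Haario-style AM)
        # while the acceptance-tuned global width is frozen after cooling
        if it >= (3 * n_cool) // 5:
            run_n += 1
            d0 = x - run_mean
            run_mean += d0 / run_n
            run_cov += np.outer(d0, x - run_mean)
        if (it + 1) % cfg.adapt_interval == 0:
            if it < n_cool:
                rate = win_accept / win_count
                if rate < cfg.accept_window[0]:
                    gfac *= 0.8
                elif rate > cfg.accept_window[1]:
                    gfac *= 1.25
                gfac = min(max(gfac, 1e-3), 10.0)
            if run_n >= 20 * k:
                cov = run_cov / (run_n - 1)
                cov[np.diag_indices(k)] += 1e-8
                try:
                    chol = (2.38 / math.sqrt(k)) * np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass
            prop_chol = gfac * chol
            win_accept = 0
            win_count = 0
        if it >= n_cool:
            samples[it - n_cool] = phys

    return MDFResult(
        map_params={n: float(v) for n, v in zip(names, best_x)},
        names=names,
        samples=samples,
        acceptance_rate=n_accept / cfg.n_iter,
        loglik_trace=trace,
        edc_reject_count=edc_rejects,
        best_loglik=best_ll,
        step_scale_final=np.sqrt(np.diag(prop_chol @ prop_chol.T)),
    )


# ---------------------------------------------------------------------------
# Site assimilation
# ---------------------------------------------------------------------------


@dataclass
class SiteConfig:
    """Per-site constants for an assimilation run."""

    name: str = "site"
    lat_deg: float = 30.0
    deciduous: bool = False
    lcma: float = 60.0
    clit0: float = 350.0  # initial litter stock (litter-layer survey)
    co2_ppm: float = 400.0
    base_params: ParameterVector | None = None
    retrieved: tuple[str, ...] | None = None  # defaults to RETRIEVED_PARAMS
    acm: ACMCoefficients = field(default_factory=lambda: DEFAULT_ACM)


REQUIRED_STREAMS = ("biomass_f", "biomass_r", "biomass_w", "litterfall_annual", "lai", "soc")


def _earliest(streams: dict[str, ObservationStream], kind: str) -> float:
    s = streams[kind]
    return float(s.values[0])


def initial_pools_from_observations(
    streams: Sequence[ObservationStream], site: SiteConfig
) -> PoolState:
    """Fix the initial pool state from the earliest stock observations."""
    by_kind = {s.kind: s for s in streams}
    missing = [k for k in ("biomass_f", "biomass_r", "biomass_w", "soc") if k not in by_kind]
    if missing:
        raise MissingStreamError(f"missing required stream(s): {missing}")
    return PoolState(
        cf=max(_earliest(by_kind, "biomass_f"), 1e-3),
        cr=max(_earliest(by_kind, "biomass_r"), 1e-3),
        cw=max(_earliest(by_kind, "biomass_w"), 1e-3),
        clit=max(site.clit0, 1e-3),
        csom=max(_earliest(by_kind, "soc"), 1e-3),
        clab=0.0 if site.deciduous else None,
    )


class _FastObjective:
    """Precomputed likelihood evaluator: parameter array -> log-likelihood.

    Resolves stream timestamps to day indices once, then each call runs the
    compiled forward kernel and sums Gaussian terms.  Returns -inf when a
    dynamic EDC is violated.
    """

    def __init__(
        self,
        prep: PreparedDrivers,
        streams: Sequence[ObservationStream],
        site: SiteConfig,
        init: PoolState,
        names: Sequence[str],
        edc_dynamic: bool = True,
    ):
        self.prep = prep
        self.site = site
        self.names = tuple(names)
        self.base = site.base_params or ParameterVector(lcma=site.lcma)
        self.edc_dynamic = edc_dynamic
        self.init = init
        self.npools = 6 if site.deciduous else 5
        self.init_arr = init.as_array()[: self.npools]
        dates = prep.dates
        self.plan = []  # (kind, idx or year-mask list, values, sigma)
        years = dates.year.to_numpy()
        for s in streams:
            if s.kind == "litterfall_annual":
                masks = []
                for y in s.times.year:
                    m = np.flatnonzero(years == y)
                    if len(m) == 0:
                        raise RangeError(f"litterfall year {y} outside driver span")
                    masks.append((m[0], m[-1] + 1))
                self.plan.append((s.kind, masks, s.values, s.sigma))
            else:
                idx = dates.get_indexer(s.times)
                if np.any(idx < 0):
                    bad = s.times[idx < 0][0]
                    raise RangeError(
                        f"stream {s.kind}: observation {bad.date()} outside driver span"
                    )
                self.plan.append((s.kind, idx, s.values, s.sigma))
        self.n_calls = 0

    def full_params(self, values: np.ndarray) -> ParameterVector:
        return ParameterVector.from_array(values, self.names, base=self.base)

    def __call__(self, values: np.ndarray) -> float:
        pv = self.full_params(values)
        if self.site.deciduous and "clab0" in self.names:
            init = PoolState(
                cf=self.init.cf, cr=self.init.cr, cw=self.init.cw,
                clit=self.init.clit, csom=self.init.csom, clab=pv.clab0,
            )
        else:
            init = self.init
        pools, fluxes = simulate_arrays(self.prep, pv, init)
        self.n_calls += 1
        if self.edc_dynamic:
            sub = pools[:, : self.npools]
            if sub.min() < 1e-3:
                return -math.inf
            peak = sub.max(axis=0)
            ref = np.where(self.init_arr > 0, self.init_arr, np.inf)
            if np.any(peak > 10.0 * ref):
                return -math.inf
        ll = 0.0
        for kind, idx, vals, sigma in self.plan:
            if kind == "litterfall_annual":
                lf = fluxes[:, 6]
                mu = np.array([lf[a:b].sum() for a, b in idx])
            elif kind == "lai":
                mu = pools[:-1, 0][idx] / pv.lcma
            elif kind == "biomass_f":
                mu = pools[:-1, 0][idx]
            elif kind == "biomass_r":
                mu = pools[:-1, 1][idx]
            elif kind == "biomass_w":
                mu = pools[:-1, 2][idx]
            elif kind == "soc":
                mu = pools[:-1, 4][idx]
            else:  # nee_daily
                mu = -fluxes[:, 5][idx]
            r = (vals - mu) / sigma
            ll += -0.5 * float(r @ r) - len(vals) * (0.5 * LOG_2PI + math.log(sigma))
        return ll


def assimilate_site(
    drivers,
    streams: Sequence[ObservationStream],
    site: SiteConfig | None = None,
    cfg: MDFConfig | None = None,
) -> MDFResult:
    """Retrieve the carbon-cycle parameters of one site.

    Orchestrates forward simulation, the observation operator and the
    Gaussian likelihood inside the simulated-annealing sampler.  Initial
    Cf, Cr, Cw and Csom are fixed from the earliest observations, Clit
    from the site survey value, and (deciduous only) the initial labile
    stock is retrieved alongside the process parameters.
    """
    site = site or SiteConfig()
    cfg = cfg or MDFConfig()
    streams = list(streams)
    if not streams:
        raise MDFError("no observation streams supplied")
    kinds = {s.kind for s in streams}
    missing = [k for k in REQUIRED_STREAMS if k not in kinds]
    if missing:
        raise MissingStreamError(f"missing required stream(s): {missing}")

    bounds = dict(DEFAULT_BOUNDS)
    if cfg.bounds:
        bounds.update(cfg.bounds)
    names = tuple(site.retrieved or RETRIEVED_PARAMS)
    if site.deciduous and "clab0" not in names:
        names = names + ("clab0",)

    prep = drivers if isinstance(drivers, PreparedDrivers) else prepare_drivers(
        drivers, acm=site.acm, lat_deg=site.lat_deg, co2_ppm=site.co2_ppm
    )
    for s in streams:
        if s.times[0] < prep.dates[0]:
            raise RangeError(
                f"stream {s.kind}: observation {s.times[0].date()} precedes driver start"
            )

    init = initial_pools_from_observations(streams, site)
    objective = _FastObjective(prep, streams, site, init, names)
    base = objective.base

    def edc_params(values: np.ndarray) -> bool:
        pv = ParameterVector.from_array(values, names, base=base)
        ok, _ = check_edcs(pv, None, rules=PARAM_EDC_RULES)
        return ok

    # start from the box midpoint, nudged until the parameter EDCs pass
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    x0 = 0.5 * (lo + hi)
    rng0 = np.random.default_rng(cfg.seed)
    tries = 0
    while not edc_params(x0) or not np.isfinite(objective(x0)):
        x0 = lo + rng0.random(len(names)) * (hi - lo)
        tries += 1
        if tries > 1000:
            raise MDFError("could not find an EDC-satisfying start point")

    result = metropolis_sa(
        objective, cfg, x0, [bounds[n] for n in names], names=names, edc=edc_params
    )
    result.map_params = objective.full_params(
        np.array([result.map_params[n] for n in names])
    )
    return result


def map_trajectory(
    drivers, result: MDFResult, streams: Sequence[ObservationStream],
    site: SiteConfig | None = None,
) -> Trajectory:
    """Forward run at the MAP parameters (for products and diagnostics)."""
    site = site or SiteConfig()
    pv = result.map_params
    if not isinstance(pv, ParameterVector):
        raise MDFError("result does not carry a full ParameterVector")
    init = initial_pools_from_observations(streams, site)
    if site.deciduous:
        init = PoolState(init.cf, init.cr, init.cw, init.clit, init.csom, clab=pv.clab0)
    return run_forward(
        drivers, pv, init, acm=site.acm, lat_deg=site.lat_deg, co2_ppm=site.co2_ppm
    )
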