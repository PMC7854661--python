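"""Assimilated carbon-sequestration products and diagnostics.

Turns a daily model trajectory into the quantities the assimilation is
run for: disequilibrium turnover times (stock over outgoing flux, using
multi-year means), annual GPP/Ra/Rh/NPP/NEP and stock series, across-site
summary statistics, goodness-of-fit statistics (R2, RMSE, Taylor
components), and a +/-10% one-at-a-time parameter sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dalec_core import (
    DEFAULT_BOUNDS,
    RETRIEVED_PARAMS,
    DalecError,
    ParameterVector,
    PoolState,
    Trajectory,
    run_forward,
)

DAYS_PER_YEAR = 365.25


class ProductError(DalecError):
    pass


# ---------------------------------------------------------------------------
# Turnover times
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TurnoverSummary:
    """Mean turnover times (years) over an analysis period.

    tau_veg = mean(Cf+Cr+Cw) / mean(litterfall + Ra)
    tau_soil = mean(Clit+Csom) / mean(Rh)
    tau_eco = mean(C_live + C_dead) / mean(Ra + Rh)

    where litterfall is the turnover leaving all live pools.  Stocks in
    g C m-2, fluxes in g C m-2 yr-1.
    """

    tau_veg: float
    tau_soil: float
    tau_eco: float
    c_live: float
    c_dead: float
    ra: float
    rh: float
    litterfall: float

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in (
            "tau_veg", "tau_soil", "tau_eco", "c_live", "c_dead", "ra", "rh", "litterfall"
        )}


def turnover_from_means(
    c_live: float, c_dead: float, ra: float, rh: float, litterfall: float
) -> TurnoverSummary:
    """Turnover times from period-mean stocks (g C m-2) and annualized
    fluxes (g C m-2 yr-1)."""
    out_veg = litterfall + ra
    if out_veg <= 0 or rh <= 0:
        raise ProductError("zero outgoing flux — degenerate trajectory")
    return TurnoverSummary(
        tau_veg=c_live / out_veg,
        tau_soil=c_dead / rh,
        tau_eco=(c_live + c_dead) / (ra + rh),
        c_live=c_live,
        c_dead=c_dead,
        ra=ra,
        rh=rh,
        litterfall=litterfall,
    )


def _full_years(traj: Trajectory) -> list[int]:
    years = traj.dates.year
    out = []
    for y in sorted(set(years)):
        mask = years == y
        first = traj.dates[mask][0]
        last = traj.dates[mask][-1]
        if first.month == 1 and first.day == 1 and last.month == 12 and last.day == 31:
            out.append(int(y))
    return out


def compute_turnover_times(
    traj: Trajectory, period: tuple[int, int] | None = None
) -> TurnoverSummary:
    """Disequilibrium turnover times over whole calendar years.

    ``period`` is an inclusive (first_year, last_year) range; by default
    all complete calendar years in the trajectory are used.
    """
    full = _full_years(traj)
    if not full:
        raise ProductError("trajectory covers no complete calendar year")
    if period is not None:
        y0, y1 = period
        full = [y for y in full if y0 <= y <= y1]
        if not full:
            raise ProductError(f"no complete calendar years in period {period}")
    mask = np.isin(traj.dates.year, full)
    c_live = float((traj.pool("cf") + traj.pool("cr") + traj.pool("cw"))[mask].mean())
    c_dead = float((traj.pool("clit") + traj.pool("csom"))[mask].mean())
    ra = float(traj.flux("ra")[mask].mean()) * DAYS_PER_YEAR
    rh = float((traj.flux("rh_lit") + traj.flux("rh_som"))[mask].mean()) * DAYS_PER_YEAR
    lf = float(
        (traj.flux("lit_f") + traj.flux("lit_r") + traj.flux("lit_w"))[mask].mean()
    ) * DAYS_PER_YEAR
    return turnover_from_means(c_live, c_dead, ra, rh, lf)


# ---------------------------------------------------------------------------
# Annual products
# ---------------------------------------------------------------------------


def compute_annual_products(
    traj: Trajectory, years: Sequence[int] | None = None
) -> pd.DataFrame:
    """Per-calendar-year table of fluxes (annual sums, g C m-2 yr-1) and
    mean pool stocks (g C m-2)."""
    full = _full_years(traj)
    if years is not None:
        missing = [y for y in years if y not in full]
        if missing:
            raise ProductError(f"partial or absent year(s) requested: {missing}")
        full = list(years)
    if not full:
        raise ProductError("trajectory covers no complete calendar year")
    yr = traj.dates.year.to_numpy()
    rows = []
    for y in full:
        m = yr == y
        gpp = float(traj.flux("gpp")[m].sum())
        ra = float(traj.flux("ra")[m].sum())
        rh = float((traj.flux("rh_lit") + traj.flux("rh_som"))[m].sum())
        row = {
            "year": y,
            "gpp": gpp,
            "ra": ra,
            "rh": rh,
            "npp": gpp - ra,
            "nep": gpp - ra - rh,
        }
        for pool in ("cf", "cr", "cw", "clit", "csom"):
            row[pool] = float(traj.pool(pool)[m].mean())
        row["biomass_c"] = row["cf"] + row["cr"] + row["cw"]
        row["soc"] = row["csom"]
        # litter excluded: total follows the Biomass_C + SOC stock convention
        row["total_c"] = row["biomass_c"] + row["soc"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Site summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteSummary:
    """Across-year mean stocks and NEP for one site, with sds of the mean."""

    site: str
    biomass_c: float
    soc: float
    total_c: float
    nep: float
    biomass_c_sd: float = float("nan")
    soc_sd: float = float("nan")
    total_c_sd: float = float("nan")
    nep_sd: float = float("nan")


def site_summary_from_trajectory(traj: Trajectory, site: str = "site") -> SiteSummary:
    """Across-year summary (mean +/- sd of the annual mean) of one run."""
    ann = compute_annual_products(traj)
    n = len(ann)

    def msd(col):
        m = float(ann[col].mean())
        sd = float(ann[col].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return m, sd

    bm, bm_sd = msd("biomass_c")
    soc, soc_sd = msd("soc")
    tot, tot_sd = msd("total_c")
    nep, nep_sd = msd("nep")
    return SiteSummary(site, bm, soc, tot, nep, bm_sd, soc_sd, tot_sd, nep_sd)


#: Published across-site summary (mean stocks in g C m-2, NEP in
#: g C m-2 yr-1) for the ten CERN forest sites, used as the reference
#: input for `summarize_table`.
REFERENCE_SITE_TABLE = pd.DataFrame(
    [
        ("CBF", 4489, 8891, 13380, 314),
        ("BJF", 5930, 4231, 10160, 266),
        ("MXF", 3214, 14795, 18009, 371),
        ("SNF", 10381, 13377, 23758, 351),
        ("HTF", 12917, 7806, 20722, 231),
        ("QYF", 6542, 6721, 13263, 467),
        ("ALF", 24155, 29383, 53538, 302),
        ("DHF", 13501, 9527, 23028, 232),
        ("HSF", 5339, 9068, 14407, 301),
        ("BNF", 16141, 9896, 26037, 266),
    ],
    columns=["site", "biomass_c", "soc", "total_c", "nep"],
)


def summarize_table(site_summaries) -> dict:
    """Across-site summary statistics.

    Accepts a list of SiteSummary or a DataFrame with columns
    site, biomass_c, soc, total_c, nep.  Returns the unweighted mean total
    carbon stock (kg C m-2), the mean per-site soil fraction of total
    carbon (%), and the per-site table.  Invariant to site ordering.
    """
    if isinstance(site_summaries, pd.DataFrame):
        df = site_summaries.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "site": s.site,
                    "biomass_c": s.biomass_c,
                    "soc": s.soc,
                    "total_c": s.total_c,
                    "nep": s.nep,
                }
                for s in site_summaries
            ]
        )
    if df.empty:
        raise ProductError("no site summaries supplied")
    if (df["total_c"] <= 0).any():
        bad = df.loc[df["total_c"] <= 0, "site"].tolist()
        raise ProductError(f"non-positive total_c for site(s) {bad}")
    return {
        "mean_total_c_kg": float(df["total_c"].mean() / 1000.0),
        "mean_soil_fraction_pct": float((100.0 * df["soc"] / df["total_c"]).mean()),
        "per_site": df.reset_index(drop=True),
    }


# ---------------------------------------------------------------------------
# Fit statistics
# ---------------------------------------------------------------------------


def fit_statistics(obs, pred) -> dict:
    """R2, RMSE, bias and Taylor-diagram components for paired series.

    R2 is the squared Pearson correlation; the Taylor components are the
    model/observation sd ratio, the correlation, and the centered
    (bias-removed) RMSD, which satisfy
    cRMSD^2 = sd_o^2 + sd_p^2 - 2 sd_o sd_p r.
    """
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ProductError("obs and pred must be 1-D arrays of equal length")
    if len(o) < 3:
        raise ProductError("need at least 3 pairs")
    sd_o = float(o.std())
    sd_p = float(p.std())
    if sd_o == 0 or sd_p == 0:
        raise ProductError("zero variance — correlation undefined")
    r = float(np.corrcoef(o, p)[0, 1])
    bias = float((p - o).mean())
    rmse = float(np.sqrt(((p - o) ** 2).mean()))
    crmsd = float(np.sqrt((((p - p.mean()) - (o - o.mean())) ** 2).mean()))
    return {
        "r2": r * r,
        "rmse": rmse,
        "bias": bias,
        "taylor": {"sd_ratio": sd_p / sd_o, "corr": r, "centered_rmsd": crmsd},
    }


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

RESPONSE_NAMES = ("nee", "gpp", "ra", "reco", "pools")


def _responses(traj: Trajectory) -> dict[str, float]:
    gpp = float(traj.flux("gpp").mean()) * DAYS_PER_YEAR
    ra = float(traj.flux("ra").mean()) * DAYS_PER_YEAR
    rh = float((traj.flux("rh_lit") + traj.flux("rh_som")).mean()) * DAYS_PER_YEAR
    pools = float(traj.pools[:-1, :5].sum(axis=1).mean())
    return {
        "gpp": gpp,
        "ra": ra,
        "reco": ra + rh,
        "nee": -(gpp - ra - rh),
        "pools": pools,
    }


@dataclass
class SensitivityResult:
    """Per parameter x response table of VR (%) and beta = VR / dP (%)."""

    table: pd.DataFrame
    clipped: list[tuple[str, str]] = field(default_factory=list)

    def beta(self, param: str, response: str, direction: str = "+") -> float:
        t = self.table
        row = t[(t["param"] == param) & (t["response"] == response) & (t["direction"] == direction)]
        if row.empty:
            raise ProductError(f"no sensitivity cell ({param}, {response}, {direction})")
        return float(row["beta"].iloc[0])


def sensitivity_analysis(
    drivers,
    pv: ParameterVector,
    init: PoolState,
    responses: Sequence[str] = RESPONSE_NAMES,
    params: Sequence[str] = RETRIEVED_PARAMS,
    delta: float = 0.10,
    bounds: dict | None = None,
    lat_deg: float = 30.0,
) -> SensitivityResult:
    """One-at-a-time +/-10% parameter perturbation sensitivity.

    For each parameter and direction the model is re-run, the percentage
    change of each response (VR) recorded, and the sensitivity index
    beta = VR / (+/-10) reported.  Perturbations leaving the prior bounds
    are clipped to the bound and noted.
    """
    unknown = [r for r in responses if r not in RESPONSE_NAMES]
    if unknown:
        raise ProductError(f"unknown response(s) {unknown}; allowed: {RESPONSE_NAMES}")
    bounds = bounds or DEFAULT_BOUNDS
    base_traj = run_forward(drivers, pv, init, lat_deg=lat_deg)
    base = _responses(base_traj)
    rows = []
    clipped = []
    for name in params:
        v0 = getattr(pv, name)
        for direction, sign in (("+", 1.0), ("-", -1.0)):
            v = v0 * (1.0 + sign * delta)
            if name in bounds:
                lo, hi = bounds[name]
                vc = min(max(v, lo), hi)
                if vc != v:
                    clipped.append((name, direction))
                    v = vc
            pct_change = 100.0 * (v - v0) / v0 if v0 != 0 else 0.0
            traj = run_forward(drivers, pv.replace(**{name: v}), init, lat_deg=lat_deg)
            resp = _responses(traj)
            for rname in responses:
                b = base[rname]
                if b == 0:
                    rows.append(
                        dict(param=name, response=rname, direction=direction,
                             vr_pct=np.nan, beta=np.nan, undefined=True)
                    )
                    continue
                vr = 100.0 * (resp[rname] - b) / b
                beta = vr / pct_change if pct_change != 0 else 0.0
                rows.append(
                    dict(param=name, response=rname, direction=direction,
                         vr_pct=vr, beta=beta, undefined=False)
                )
    return SensitivityResult(table=pd.DataFrame(rows), clipped=clipped)
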