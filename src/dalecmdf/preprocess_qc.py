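"""Observation-side preprocessing and quality control.

Implements the data-side steps applied to the monitoring-network records
before assimilation: gap filling of daily meteorological series (linear
interpolation for short gaps, regression on a neighbouring station for
longer ones), 3-sigma outlier screening, layered soil organic carbon
density, and dataset integrity/consistency checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dalec_core import DalecError, DRIVER_COLUMNS


class QCError(DalecError):
    pass


class UnfillableGapError(QCError):
    pass


class InsufficientDataError(QCError):
    pass


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) for each maximal run of True values."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def gap_fill_series(
    series: pd.Series,
    neighbor: pd.Series | None = None,
    min_coobserved: int = 10,
) -> tuple[pd.Series, pd.Series]:
    """Fill gaps in a daily series.

    Runs of fewer than three consecutive missing values are filled by
    linear interpolation between the flanking observations; runs of three
    or more (and gaps touching the series ends) are filled by an OLS
    regression of the series on ``neighbor`` fitted over co-observed days.
    Observed values are never altered.

    Returns the filled series and a label series ('' observed, 'interp',
    'regress').
    """
    x = series.astype(float)
    labels = pd.Series("", index=x.index, dtype=object)
    missing = x.isna().to_numpy()
    if not missing.any():
        return x, labels

    vals = x.to_numpy(copy=True)
    n = len(vals)
    runs = _nan_runs(missing)

    coef = None  # lazily fitted regression (slope, intercept)

    def fit_regression():
        nonlocal coef
        if coef is not None:
            return coef
        if neighbor is None:
            raise UnfillableGapError(
                "gap of length >= 3 (or at a series end) requires a neighbor series"
            )
        nb = neighbor.reindex(x.index).astype(float)
        both = (~x.isna()) & (~nb.isna())
        if int(both.sum()) < min_coobserved:
            raise UnfillableGapError(
                f"only {int(both.sum())} co-observed days; need >= {min_coobserved}"
            )
        slope, intercept = np.polyfit(nb[both].to_numpy(), x[both].to_numpy(), 1)
        coef = (slope, intercept)
        return coef

    for start, length in runs:
        interior = start > 0 and start + length < n
        if length < 3 and interior:
            left = vals[start - 1]
            right = vals[start + length]
            for k in range(length):
                frac = (k + 1) / (length + 1)
                vals[start + k] = left + frac * (right - left)
                labels.iloc[start + k] = "interp"
        else:
            slope, intercept = fit_regression()
            if neighbor is None:  # pragma: no cover - guarded in fit
                raise UnfillableGapError("no neighbor series")
            nb = neighbor.reindex(x.index).astype(float).to_numpy()
            seg = nb[start : start + length]
            if np.any(np.isnan(seg)):
                raise UnfillableGapError(
                    f"neighbor series missing inside gap starting at index {start}"
                )
            vals[start : start + length] = slope * seg + intercept
            labels.iloc[start : start + length] = "regress"

    return pd.Series(vals, index=x.index), labels


# ---------------------------------------------------------------------------
# Outlier screening
# ---------------------------------------------------------------------------


def detect_outliers_3sigma(series) -> np.ndarray:
    """Indices where |x - mean| > 3 sd (mean/sd over finite values).

    A zero standard deviation flags nothing.  Deterministic and invariant
    under affine transforms of the series.
    """
    x = np.asarray(series, dtype=float)
    finite = np.isfinite(x)
    if int(finite.sum()) < 4:
        raise InsufficientDataError("need at least 4 finite values for 3-sigma screening")
    mean = x[finite].mean()
    sd = x[finite].std()
    if sd == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(finite & (np.abs(x - mean) > 3.0 * sd))


# ---------------------------------------------------------------------------
# Layered soil organic carbon density
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SoilLayerRecord:
    """One soil layer: thickness H (cm), bulk density B (g cm-3), organic
    matter content O (%), and the volume fraction of >2 mm gravel."""

    h_cm: float
    bd_g_cm3: float
    som_pct: float
    gravel_frac: float = 0.0

    def validate(self, layer_index: int | None = None) -> None:
        tag = f"layer {layer_index}: " if layer_index is not None else ""
        if not (self.h_cm > 0):
            raise QCError(f"{tag}h_cm={self.h_cm} must be > 0")
        if not (self.bd_g_cm3 > 0):
            raise QCError(f"{tag}bd_g_cm3={self.bd_g_cm3} must be > 0")
        if not (0.0 <= self.som_pct <= 100.0):
            raise QCError(f"{tag}som_pct={self.som_pct} outside [0, 100]")
        if not (0.0 <= self.gravel_frac <= 1.0):
            raise QCError(f"{tag}gravel_frac={self.gravel_frac} outside [0, 1]")


def compute_soc_density(layers: Sequence[SoilLayerRecord]) -> float:
    """Soil organic carbon density (g C m-2) summed over the supplied layers.

    SOC = sum_i 0.58 * H_i * B_i * O_i * (1 - theta_i) * 100, with O_i in
    percent.  The 0.58 factor converts organic matter to organic carbon
    (Bemmelen factor); the 100 converts cm * g cm-3 * % to g m-2.  The sum
    runs over exactly the layers supplied; no depth-profile extrapolation
    is attempted.
    """
    layers = list(layers)
    if not layers:
        raise QCError("no soil layers supplied")
    total = 0.0
    for i, layer in enumerate(layers):
        layer.validate(i)
        total += (
            0.58
            * layer.h_cm
            * layer.bd_g_cm3
            * layer.som_pct
            * (1.0 - layer.gravel_frac)
            * 100.0
        )
    return total


# ---------------------------------------------------------------------------
# Dataset integrity / consistency report
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Pure report of integrity and consistency findings; never mutates data."""

    missing_runs: list[tuple[str, int, int]] = field(default_factory=list)
    outlier_indices: list[tuple[str, int]] = field(default_factory=list)
    consistency_flags: list[tuple[str, str]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.missing_runs or self.outlier_indices or self.consistency_flags)

    def to_dict(self) -> dict:
        return {
            "missing_runs": [list(r) for r in self.missing_runs],
            "outlier_indices": [list(r) for r in self.outlier_indices],
            "consistency_flags": [list(r) for r in self.consistency_flags],
        }


def check_dataset_integrity(drivers: pd.DataFrame, streams=None) -> QCReport:
    """Integrity and consistency checks on a driver table and observations.

    Flags duplicate or non-monotone dates, relative humidity outside
    [0, 100], soil moisture above saturation, negative PAR or
    precipitation, and observation timestamps outside the driver span.
    Missing (NaN) runs per driver column are reported for gap filling.
    """
    report = QCReport()
    df = drivers.copy()
    missing_cols = [c for c in DRIVER_COLUMNS if c not in df.columns]
    if missing_cols:
        raise QCError(f"driver table missing columns: {missing_cols}")
    dates = pd.to_datetime(df["date"])
    dup = dates.duplicated()
    for i in dates.index[dup]:
        report.consistency_flags.append(("duplicate_date", f"row {i}"))
    if not dates.is_monotonic_increasing:
        bad = np.flatnonzero(dates.diff().dt.total_seconds().fillna(1) <= 0)
        for i in bad:
            report.consistency_flags.append(("nonmonotone_date", f"row {i}"))

    def flag_rows(mask: pd.Series, rule: str):
        for i in np.flatnonzero(mask.fillna(False).to_numpy()):
            report.consistency_flags.append((rule, f"row {i}"))

    flag_rows((df["rh_pct"] < 0) | (df["rh_pct"] > 100), "rh_out_of_range")
    flag_rows(df["sw"] > df["sc"], "sw_exceeds_sc")
    flag_rows(df["par"] < 0, "negative_par")
    flag_rows(df["precip_mm"] < 0, "negative_precip")
    flag_rows(df["tmin_c"] > df["tmax_c"], "tmin_above_tmax")

    for col in DRIVER_COLUMNS:
        if col == "date":
            continue
        mask = df[col].isna().to_numpy()
        for start, length in _nan_runs(mask):
            report.missing_runs.append((col, start, length))

    if streams is not None:
        lo, hi = dates.min(), dates.max()
        for s in streams:
            for t in s.times:
                if t < lo or t > hi:
                    report.consistency_flags.append(
                        ("obs_outside_driver_span", f"{s.kind} {t.date()}")
                    )
    return report
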