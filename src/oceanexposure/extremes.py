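"""Extreme centennial warming windows and pattern-scaled SNR exposure.

A "century" is a sliding window (default 100 years, stepping 10) over the
area-weighted global-mean SST series. Windows whose OLS warming rate meets
or exceeds a threshold — either supplied directly (0.18 °C/century, the
95th percentile of pre-industrial control natural variability) or
recalibrated from a control run — are extreme. Per-cell trend and
residual-SD statistics are averaged over an era's extreme windows, the
trend is pattern-scaled by the era-mean global rate (change per °C of
global warming), and SNR = |scaled trend| / variability. Exposure is the
future-minus-past change in SNR (δSNR): positive values mark
post-industrial rates that surpass the most extreme rates of the past.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .constants import CONTROL_PERCENTILE, STEP_YEARS, WINDOW_YEARS
from .grids import GridSpec, SSTSeries

__all__ = [
    "CenturyWindow",
    "CellClimateStats",
    "ExposureField",
    "centennial_rates",
    "calibrate_threshold",
    "classify_extreme",
    "cell_stats_for_era",
    "delta_snr",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CenturyWindow:
    """One sliding window over the global-mean series (years inclusive)."""

    start_year: int
    end_year: int
    global_rate: float  # degC / century
    is_extreme: bool | None = None

    @property
    def length(self) -> int:
        return self.end_year - self.start_year + 1


@dataclass
class CellClimateStats:
    """Per-cell trend/variability/SNR averaged over an era's extreme windows."""

    grid: GridSpec
    era: str
    trend: np.ndarray  # degC / yr
    variability: np.ndarray  # degC
    global_trend_mean: float  # degC / century (pattern-scaling divisor)
    snr: np.ndarray  # |trend per degC-global| / variability
    snr_raw: np.ndarray  # |trend| / variability, unscaled
    n_windows: int = 0


@dataclass
class ExposureField:
    """delta-SNR: future SNR minus past SNR, per cell."""

    grid: GridSpec
    delta_snr: np.ndarray
    scenario: str


def _ols_slope_and_resid_sd(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form OLS along axis 0 of y; residual SD uses n-2 dof."""
    n = x.size
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    ym = y.mean(axis=0)
    slope = np.tensordot(xc, y - ym, axes=(0, 0)) / sxx
    resid = (y - ym) - slope[None] * xc.reshape(-1, *([1] * (y.ndim - 1)))
    sd = np.sqrt(np.sum(resid**2, axis=0) / (n - 2))
    return slope, sd


def centennial_rates(
    years: np.ndarray,
    global_sst: np.ndarray,
    window_yr: int = WINDOW_YEARS,
    step_yr: int = STEP_YEARS,
) -> list[CenturyWindow]:
    """Sliding-window OLS warming rates of a global-mean series (°C/century)."""
    years = np.asarray(years)
    global_sst = np.asarray(global_sst, dtype=float)
    if years.size < window_yr:
        raise ValueError(f"series of {years.size} years is shorter than one {window_yr}-year window")
    out = []
    for i in range(0, years.size - window_yr + 1, step_yr):
        x = years[i : i + window_yr].astype(float)
        slope, _ = _ols_slope_and_resid_sd(x, global_sst[i : i + window_yr])
        out.append(CenturyWindow(int(years[i]), int(years[i + window_yr - 1]), float(slope) * 100.0))
    return out


def rates_for_series(series: SSTSeries, window_yr: int = WINDOW_YEARS, step_yr: int = STEP_YEARS) -> list[CenturyWindow]:
    """Convenience: windows over a series' area-weighted global mean."""
    return centennial_rates(series.years, series.global_mean(), window_yr, step_yr)


def calibrate_threshold(control_windows: list[CenturyWindow], percentile: float = CONTROL_PERCENTILE) -> float:
    """Percentile of control-run global rates (linear interpolation).

    Users may bypass calibration and supply a threshold (e.g. 0.18
    °C/century) directly to :func:`classify_extreme`.
    """
    if len(control_windows) < 20:
        raise ValueError(f"need >= 20 control windows to calibrate, got {len(control_windows)}")
    rates = np.array([w.global_rate for w in control_windows])
    return float(np.percentile(rates, percentile))


def classify_extreme(windows: list[CenturyWindow], threshold: float) -> list[CenturyWindow]:
    """Flag windows with rate >= threshold (inclusive) as extreme."""
    return [replace(w, is_extreme=bool(w.global_rate >= threshold)) for w in windows]


def cell_stats_for_era(sst: SSTSeries, extreme_windows: list[CenturyWindow], era: str | None = None) -> CellClimateStats:
    """Average per-cell trend/variability over an era's extreme windows and
    form the pattern-scaled SNR.

    Only windows flagged extreme and fully covered by the series are used.
    The per-window per-cell OLS slope (°C/yr) and residual SD (n-2 dof) are
    averaged across windows; the mean of the windows' global rates is the
    pattern-scaling divisor; SNR = |trend / (global_trend_mean/100)| /
    variability. Cells with zero variability get missing SNR.
    """
    era = era or sst.era
    used = [
        w
        for w in extreme_windows
        if w.is_extreme and w.start_year >= sst.years[0] and w.end_year <= sst.years[-1]
    ]
    if not used:
        raise ValueError("no extreme windows fall inside the era")
    slopes, sds, grates = [], [], []
    for w in used:
        sub = sst.select_years(w.start_year, w.end_year)
        slope, sd = _ols_slope_and_resid_sd(sub.years.astype(float), sub.sst)
        slopes.append(slope)
        sds.append(sd)
        grates.append(w.global_rate)
    trend = np.mean(slopes, axis=0)
    variability = np.mean(sds, axis=0)
    gtm = float(np.mean(grates))
    if gtm == 0:
        raise ValueError("era-mean global trend is zero; cannot pattern-scale")
    # noise-free inputs leave O(1e-16) rounding residue, not exact zeros
    zero_var = variability <= 1e-12
    if np.any(zero_var & sst.grid.ocean_mask):
        log.warning(
            "%d ocean cells have zero variability (noise-free input?); their SNR is set missing",
            int(np.sum(zero_var & sst.grid.ocean_mask)),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.abs(trend / (gtm / 100.0)) / variability
        snr_raw = np.abs(trend) / variability
    snr[zero_var] = np.nan
    snr_raw[zero_var] = np.nan
    snr[sst.grid.land_mask] = np.nan
    snr_raw[sst.grid.land_mask] = np.nan
    return CellClimateStats(sst.grid, era, trend, variability, gtm, snr, snr_raw, len(used))


def delta_snr(past: CellClimateStats, future: CellClimateStats) -> ExposureField:
    """Future minus past SNR; positive = unprecedented post-industrial rates."""
    if past.grid.shape != future.grid.shape:
        raise ValueError("past and future stats are on different grids")
    return ExposureField(future.grid, future.snr - past.snr, future.era)
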