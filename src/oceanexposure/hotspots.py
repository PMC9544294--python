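"""Species richness, biodiversity hotspots and threshold sensitivity.

Richness is the per-cell count of species whose occurrence probability
meets the threshold tau (default 0.4, inclusive). Hotspots are cells at or
above the 95th percentile of richness over ocean cells, after aggregating
richness to the climate grid by block means. Sensitivity of the richness
surface to tau is quantified with Warren's I overlap statistic between
normalised richness surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import HOTSPOT_PERCENTILE, OCCURRENCE_TAU, SENSITIVITY_TAUS
from .grids import GriddedField, GridSpec

__all__ = [
    "RichnessRaster",
    "HotspotMask",
    "richness_from_probs",
    "hotspot_mask",
    "warren_i",
    "threshold_sensitivity",
]


@dataclass
class RichnessRaster:
    """Integer species counts per cell (NaN on land), with provenance."""

    grid: GridSpec
    richness: np.ndarray
    tau: float

    def as_field(self) -> GriddedField:
        return GriddedField(self.grid, self.richness, units="species count")


@dataclass
class HotspotMask:
    grid: GridSpec
    mask: np.ndarray  # boolean, True only on ocean cells
    percentile: float


def richness_from_probs(
    species_probs: np.ndarray,
    grid: GridSpec,
    tau: float = OCCURRENCE_TAU,
    exclude: np.ndarray | None = None,
) -> RichnessRaster:
    """Threshold per-species probabilities (p >= tau) and sum to richness.

    ``exclude`` flags data-scarce species dropped before counting.
    """
    probs = np.asarray(species_probs, dtype=float)
    if probs.ndim != 3 or probs.shape[1:] != grid.shape:
        raise ValueError("species_probs must have shape (n_species, nlat, nlon)")
    finite = probs[np.isfinite(probs)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("occurrence probabilities must lie in [0, 1]")
    if exclude is not None:
        probs = probs[~np.asarray(exclude, bool)]
    presence = probs >= tau
    richness = presence.sum(axis=0).astype(float)
    richness[grid.land_mask] = np.nan
    return RichnessRaster(grid, richness, tau)


def hotspot_mask(richness_coarse: GriddedField, percentile: float = HOTSPOT_PERCENTILE) -> HotspotMask:
    """Cells with richness at or above the given percentile of ocean values."""
    vals = richness_coarse.values
    ok = richness_coarse.grid.ocean_mask & np.isfinite(vals)
    if not ok.any():
        raise ValueError("no ocean cells with defined richness")
    cut = np.percentile(vals[ok], percentile)
    mask = ok & (vals >= cut)
    return HotspotMask(richness_coarse.grid, mask, percentile)


def _surface(values: np.ndarray) -> np.ndarray:
    return np.asarray(getattr(values, "richness", getattr(values, "values", values)), dtype=float)


def warren_i(r1, r2) -> float:
    """Warren's I between two spatial surfaces: 1 - 0.5 * sum (sqrt p - sqrt q)^2.

    Surfaces are normalised to unit sum over their shared defined cells; the
    statistic lies in [0, 1], equalling 1 iff the normalised surfaces match.
    """
    a, b = _surface(r1), _surface(r2)
    if a.shape != b.shape:
        raise ValueError("surfaces must share a grid")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("cannot normalise a zero-sum surface")
    p = a / a.sum()
    q = b / b.sum()
    return float(1.0 - 0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))


def threshold_sensitivity(
    species_probs: np.ndarray,
    grid: GridSpec,
    taus: tuple = SENSITIVITY_TAUS,
    exclude: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pairwise Warren's I between richness maps built at different taus."""
    rasters = {t: richness_from_probs(species_probs, grid, t, exclude) for t in taus}
    rows = [
        {"tau_a": ta, "tau_b": tb, "I": warren_i(rasters[ta], rasters[tb])}
        for i, ta in enumerate(taus)
        for tb in taus[i:]
    ]
    return pd.DataFrame(rows)
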