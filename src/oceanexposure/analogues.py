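"""Thermal analogues over sea-only distances, and Hovmöller summaries.

The question: how far must communities in biodiversity hotspots move to
stay within the upper temperatures they experienced during the Holocene
thermal maximum (HTM, ~9000-5000 yr B.P.), once the deglacial series is
delta-bias-corrected onto the scenario series? A cell j is an analogue of
focal cell i when j's future upper temperature (max of annual means,
2080-2100) does not exceed i's HTM upper temperature. The nearest analogue
minimises shortest-path distance through ocean cells only ("nautical
distance": land is a barrier), optionally restricted to near-shore EEZ
cells. Distances divided by the 2020-2090 horizon give the redistribution
rates the move would require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .constants import (
    BIAS_OVERLAP,
    EARTH_RADIUS_KM,
    FUTURE_UPPER_WINDOW,
    HTM_WINDOW_BP,
    REDISTRIBUTION_HORIZON_YEARS,
    bp_to_ce,
)
from .grids import GriddedField, GridSpec, SSTSeries

__all__ = [
    "AnalogueResult",
    "HovmollerMatrix",
    "SeaGraph",
    "haversine_km",
    "delta_bias_correct",
    "htm_upper_temperature",
    "future_upper_temperature",
    "build_sea_graph",
    "nearest_analogue",
    "realm_crossing_summary",
    "redistribution_rate",
    "hovmoller",
]


def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Great-circle distance between points given in degrees."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# temperature sides of the comparison


def delta_bias_correct(
    past: SSTSeries, reference: SSTSeries, overlap: tuple[int, int] = BIAS_OVERLAP
) -> SSTSeries:
    """Shift the past series by the per-cell overlap-mean difference to the
    reference (a constant per-cell delta)."""
    if past.grid.shape != reference.grid.shape:
        raise ValueError("series must share a grid")
    p = past.select_years(*overlap)
    r = reference.select_years(*overlap)
    delta = r.sst.mean(axis=0) - p.sst.mean(axis=0)
    return SSTSeries(past.grid, past.years, past.sst + delta[None], past.era)


def _window_max(series: SSTSeries, start: int, end: int, units: str) -> GriddedField:
    sub = series.select_years(start, end)
    out = np.full(series.grid.shape, np.nan)
    any_finite = np.isfinite(sub.sst).any(axis=0)
    out[any_finite] = np.nanmax(sub.sst[:, any_finite], axis=0)
    return GriddedField(series.grid, out, units)


def htm_upper_temperature(
    past_corrected: SSTSeries, window_bp: tuple[float, float] = HTM_WINDOW_BP, window_ce: tuple[int, int] | None = None
) -> GriddedField:
    """Per-cell maximum annual-mean SST within the HTM window.

    ``window_bp`` is in years before present (present = 1950); pass
    ``window_ce`` to override with calendar years directly (the synthetic
    demo world uses a scaled-down past and needs its own warm window).
    """
    if window_ce is None:
        window_ce = (int(bp_to_ce(window_bp[0])), int(bp_to_ce(window_bp[1])))
    return _window_max(past_corrected, window_ce[0], window_ce[1], "degC (HTM upper)")


def future_upper_temperature(
    future: SSTSeries, window: tuple[int, int] = FUTURE_UPPER_WINDOW
) -> GriddedField:
    """Per-cell maximum annual-mean SST within the future window (2080-2100)."""
    return _window_max(future, window[0], window[1], "degC (future upper)")


# ---------------------------------------------------------------------------
# sea graph and analogue search


@dataclass
class SeaGraph:
    """Weighted graph over ocean cells (haversine edge lengths, km)."""

    grid: GridSpec
    node_of_cell: np.ndarray  # (nlat, nlon) int, -1 on land
    cells: np.ndarray  # (n_nodes, 2) row/col of each node
    matrix: csr_matrix

    @property
    def n_nodes(self) -> int:
        return self.cells.shape[0]


def build_sea_graph(grid: GridSpec, connectivity: int = 8) -> SeaGraph:
    """Graph over ocean cells: 4- or 8-neighbours, longitude wrapping at the
    dateline, no connection across the poles.

    Diagonal edges are blocked when both shared orthogonal neighbours are
    land (no corner-cutting between diagonally touching land cells).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    ocean = grid.ocean_mask
    nlat, nlon = grid.shape
    node = np.full(grid.shape, -1, dtype=np.int64)
    cells = np.argwhere(ocean)
    node[ocean] = np.arange(cells.shape[0])

    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    rows, cols, weights = [], [], []
    lat = grid.lat_centers
    lon = grid.lon_centers
    for di, dj in offsets:
        # pair each cell (i, j) with (i + di, (j + dj) mod nlon); longitude
        # wraps, latitude does not (no path across the poles)
        ok = ocean & np.roll(np.roll(ocean, -di, axis=0), -dj, axis=1)
        if di:
            ok[nlat - di :] = False
        if di and dj:
            # anti corner-cutting: one of the two shared orthogonal
            # neighbours must be ocean
            side1 = np.roll(ocean, -dj, axis=1)  # (i, j+dj)
            side2 = np.roll(ocean, -di, axis=0)  # (i+di, j)
            ok &= side1 | side2
        ii, jj = np.nonzero(ok)
        jj2 = (jj + dj) % nlon
        ii2 = ii + di
        w = haversine_km(lat[ii], lon[jj], lat[ii2], lon[jj2])
        rows.append(node[ii, jj])
        cols.append(node[ii2, jj2])
        weights.append(w)
    r = np.concatenate(rows) if rows else np.array([], dtype=int)
    c = np.concatenate(cols) if cols else np.array([], dtype=int)
    w = np.concatenate(weights) if weights else np.array([])
    n = cells.shape[0]
    mat = csr_matrix((np.concatenate([w, w]), (np.concatenate([r, c]), np.concatenate([c, r]))), shape=(n, n))
    return SeaGraph(grid, node, cells, mat)


@dataclass
class AnalogueResult:
    """Nearest thermal analogue of one focal (hotspot) cell."""

    focal_cell: tuple[int, int]
    scenario: str
    target_cell: tuple[int, int] | None
    sea_distance_km: float  # NaN when no analogue is reachable
    crosses_realm: bool | None = None
    restricted_to_eez: bool = False
    rate_km_per_yr: float = np.nan

    @property
    def has_analogue(self) -> bool:
        return self.target_cell is not None


def nearest_analogue(
    focal_cells,
    htm_upper: GriddedField,
    future_upper: GriddedField,
    sea_graph: SeaGraph,
    candidate_mask: np.ndarray | None = None,
    tol_degc: float = 0.0,
    scenario: str = "",
    restricted_to_eez: bool = False,
) -> list[AnalogueResult]:
    """Per focal cell, the candidate analogue minimising sea distance.

    Cell j qualifies when it is in the candidate mask and its future upper
    temperature is at most the focal cell's HTM upper temperature (plus
    ``tol_degc``). The focal cell may be its own analogue (distance 0).
    Ties break by (distance, lower future upper temperature, row-major cell
    index). Unreachable focal cells are reported with no analogue.
    """
    grid = sea_graph.grid
    fc = np.asarray(focal_cells)
    if fc.dtype == bool:  # a hotspot-style mask
        focal_cells = [tuple(c) for c in np.argwhere(fc)]
    else:
        focal_cells = [tuple(int(v) for v in c) for c in fc.reshape(-1, 2)]
    for i, j in focal_cells:
        if grid.land_mask[i, j]:
            raise ValueError(f"focal cell ({i}, {j}) is on land")
    if candidate_mask is None:
        candidate_mask = grid.ocean_mask
    cand = np.asarray(candidate_mask, bool) & grid.ocean_mask & np.isfinite(future_upper.values)

    focal_nodes = np.array([sea_graph.node_of_cell[i, j] for i, j in focal_cells], dtype=int)
    if focal_nodes.size == 0:
        return []
    dist = dijkstra(sea_graph.matrix, directed=False, indices=focal_nodes)

    cand_nodes = sea_graph.node_of_cell[cand]
    cand_future = future_upper.values[cand]
    cand_flat = np.flatnonzero(cand.ravel())  # row-major tie-break index
    results = []
    for k, (i, j) in enumerate(focal_cells):
        ceiling = htm_upper.values[i, j] + tol_degc
        ok = cand_future <= ceiling
        d = dist[k, cand_nodes[ok]]
        reachable = np.isfinite(d)
        if not np.any(ok) or not np.any(reachable):
            results.append(AnalogueResult((i, j), scenario, None, np.nan, restricted_to_eez=restricted_to_eez))
            continue
        d = d[reachable]
        fut = cand_future[ok][reachable]
        flat = cand_flat[ok][reachable]
        best = np.lexsort((flat, fut, d))[0]
        ti, tj = divmod(int(flat[best]), grid.nlon)
        results.append(
            AnalogueResult((i, j), scenario, (ti, tj), float(d[best]), restricted_to_eez=restricted_to_eez)
        )
    return results


def realm_crossing_summary(results: list[AnalogueResult], realm_ids: np.ndarray) -> dict:
    """Percentage of focal cells whose nearest analogue lies in a different
    realm (among cells that have an analogue); also sets each result's
    ``crosses_realm`` flag."""
    realm_ids = np.asarray(realm_ids, dtype=float)
    n_with = n_cross = 0
    for r in results:
        if not r.has_analogue:
            r.crosses_realm = None
            continue
        n_with += 1
        r.crosses_realm = bool(realm_ids[r.focal_cell] != realm_ids[r.target_cell])
        n_cross += r.crosses_realm
    return {
        "pct_crossing_realm": 100.0 * n_cross / n_with if n_with else np.nan,
        "pct_no_analogue": 100.0 * (len(results) - n_with) / len(results) if results else np.nan,
        "n_focal": len(results),
        "n_with_analogue": n_with,
    }


def redistribution_rate(
    results: list[AnalogueResult], horizon_years: float = REDISTRIBUTION_HORIZON_YEARS
) -> np.ndarray:
    """Required movement rates (km/yr): analogue distance over the horizon.

    Sets ``rate_km_per_yr`` on each result and returns the rates (NaN for
    cells without an analogue).
    """
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    rates = np.full(len(results), np.nan)
    for k, r in enumerate(results):
        if r.has_analogue:
            r.rate_km_per_yr = r.sea_distance_km / horizon_years
            rates[k] = r.rate_km_per_yr
    return rates


# ---------------------------------------------------------------------------
# Hovmöller


@dataclass
class HovmollerMatrix:
    band_edges: np.ndarray  # length n_bands + 1
    years: np.ndarray
    values: np.ndarray  # (n_bands, n_years), NaN for empty bands


def hovmoller(series: SSTSeries, hotspot_mask: np.ndarray, band_width_deg: float = 5.0) -> HovmollerMatrix:
    """Area-weighted mean SST of hotspot cells per latitude band and year."""
    grid = series.grid
    edges = np.arange(-90.0, 90.0 + band_width_deg / 2, band_width_deg)
    hot = np.asarray(hotspot_mask, bool) & grid.ocean_mask
    out = np.full((edges.size - 1, series.years.size), np.nan)
    for b in range(edges.size - 1):
        in_band = (grid.lat_centers >= edges[b]) & (grid.lat_centers < edges[b + 1])
        cells = hot & in_band[:, None]
        if not cells.any():
            continue
        w = grid.cell_area[cells]
        vals = series.sst[:, cells]
        out[b] = np.nansum(vals * w[None], axis=1) / w.sum()
    return HovmollerMatrix(edges, series.years.copy(), out)
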