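"""Grid geometry, masks, area weighting, aggregation and NetCDF I/O.

All fields in this package live on regular latitude/longitude grids with
cell-centre registration: latitudes ascending from -90 + res/2, longitudes
in [-180, 180) starting at -180 + res/2. Arrays are indexed (lat, lon) or
(time, lat, lon). Land cells carry NaN in ocean-only variables and are
excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import xarray as xr

__all__ = [
    "GridSpec",
    "GriddedField",
    "SSTSeries",
    "global_area_weighted_mean",
    "aggregate_mean",
    "read_netcdf",
    "write_netcdf",
    "ParseError",
]

ERAS = ("past", "control", "historical", "future_scenario_a", "future_scenario_b")


class ParseError(ValueError):
    """A NetCDF file does not contain what this package expects."""


def _centers(lo: float, hi: float, res: float) -> np.ndarray:
    n = round((hi - lo) / res)
    if not np.isclose(n * res, hi - lo):
        raise ValueError(f"resolution {res} does not tile [{lo}, {hi}]")
    return lo + res / 2 + res * np.arange(n)


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid with a land mask and area weights.

    ``cell_area`` holds weights proportional to true cell area; with the
    default ``coslat`` weighting they are cos(latitude of cell centre),
    with ``band`` they are exact spherical band areas (both normalised only
    up to a constant, which every consumer cancels).
    """

    resolution_deg: float
    lat_centers: np.ndarray
    lon_centers: np.ndarray
    land_mask: np.ndarray
    cell_area: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        if np.any(np.diff(lat) <= 0):
            raise ValueError("latitudes must be strictly ascending")
        if lon.min() < -180 or lon.max() >= 180:
            raise ValueError("longitudes must lie in [-180, 180)")
        mask = np.asarray(self.land_mask, dtype=bool)
        if mask.shape != self.shape:
            raise ValueError(f"land_mask shape {mask.shape} != grid shape {self.shape}")
        object.__setattr__(self, "land_mask", mask)
        if self.cell_area is None:
            object.__setattr__(self, "cell_area", self._weights("coslat"))
        area = np.asarray(self.cell_area, dtype=float)
        if area.shape != self.shape:
            raise ValueError("cell_area shape mismatch")
        if np.any(area <= 0):
            raise ValueError("area weights must be strictly positive")
        object.__setattr__(self, "cell_area", area)

    @classmethod
    def regular(
        cls,
        resolution_deg: float,
        land_mask: np.ndarray | None = None,
        area_weighting: Literal["coslat", "band"] = "coslat",
    ) -> "GridSpec":
        """Build a global grid at ``resolution_deg``; all-ocean by default."""
        lat = _centers(-90, 90, resolution_deg)
        lon = _centers(-180, 180, resolution_deg)
        if land_mask is None:
            land_mask = np.zeros((lat.size, lon.size), dtype=bool)
        g = cls(resolution_deg, lat, lon, np.asarray(land_mask, bool), np.ones((lat.size, lon.size)))
        return replace(g, cell_area=g._weights(area_weighting))

    def _weights(self, kind: str) -> np.ndarray:
        lat = np.deg2rad(self.lat_centers)
        if kind == "coslat":
            w = np.cos(lat)
        elif kind == "band":
            half = np.deg2rad(self.resolution_deg) / 2
            w = np.sin(lat + half) - np.sin(lat - half)
        else:
            raise ValueError(f"unknown area weighting {kind!r}")
        return np.broadcast_to(w[:, None], self.shape).copy()

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_centers.size, self.lon_centers.size)

    @property
    def nlat(self) -> int:
        return self.lat_centers.size

    @property
    def nlon(self) -> int:
        return self.lon_centers.size

    @property
    def ocean_mask(self) -> np.ndarray:
        return ~self.land_mask

    def with_land(self, land_mask: np.ndarray) -> "GridSpec":
        return replace(self, land_mask=np.asarray(land_mask, bool))


@dataclass
class GriddedField:
    """One variable on a grid; NaN marks missing (land) cells."""

    grid: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")


@dataclass
class SSTSeries:
    """Annual-mean SST on a grid over a continuous calendar-year axis."""

    grid: GridSpec
    years: np.ndarray
    sst: np.ndarray
    era: str

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.sst = np.asarray(self.sst, dtype=float)
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must increase with unit (annual) step")
        if self.sst.shape != (self.years.size, *self.grid.shape):
            raise ValueError("sst shape must be (time, lat, lon)")
        if self.era not in ERAS:
            raise ValueError(f"unknown era {self.era!r}; expected one of {ERAS}")

    def global_mean(self) -> np.ndarray:
        """Area-weighted global ocean mean SST per year."""
        w = np.where(self.grid.ocean_mask, self.grid.cell_area, 0.0)
        if w.sum() == 0:
            raise ValueError("no ocean cells")
        return np.nansum(self.sst * w, axis=(1, 2)) / w.sum()

    def select_years(self, start: int, end: int) -> "SSTSeries":
        """Inclusive year slice; errors if the window is not fully covered."""
        if start < self.years[0] or end > self.years[-1]:
            raise ValueError(
                f"years [{start}, {end}] not covered by series "
                f"[{self.years[0]}, {self.years[-1]}]"
            )
        sel = (self.years >= start) & (self.years <= end)
        return SSTSeries(self.grid, self.years[sel], self.sst[sel], self.era)


def global_area_weighted_mean(field: GriddedField) -> float:
    """Area-weighted mean over ocean cells with defined values."""
    ok = field.grid.ocean_mask & np.isfinite(field.values)
    if not ok.any():
        raise ValueError("no ocean cells")
    w = field.grid.cell_area[ok]
    return float(np.sum(w * field.values[ok]) / np.sum(w))


def _nesting_factor(fine: GridSpec, coarse: GridSpec) -> int:
    ratio = coarse.resolution_deg / fine.resolution_deg
    factor = round(ratio)
    if factor < 1 or not np.isclose(ratio, factor):
        raise ValueError(
            f"coarse resolution {coarse.resolution_deg} is not an integer "
            f"multiple of fine resolution {fine.resolution_deg}"
        )
    if fine.nlat != coarse.nlat * factor or fine.nlon != coarse.nlon * factor:
        raise ValueError("grids do not nest exactly")
    return factor


def aggregate_mean(fine: GriddedField, coarse_spec: GridSpec) -> GriddedField:
    """Block-average a fine field onto a nesting coarse grid.

    Each coarse cell is the arithmetic mean of its non-missing fine
    children; it is missing iff all children are missing.
    """
    f = _nesting_factor(fine.grid, coarse_spec)
    blocks = fine.values.reshape(coarse_spec.nlat, f, coarse_spec.nlon, f)
    with np.errstate(invalid="ignore"):
        counts = np.isfinite(blocks).sum(axis=(1, 3))
        sums = np.nansum(np.where(np.isfinite(blocks), blocks, 0.0), axis=(1, 3))
    out = np.full(coarse_spec.shape, np.nan)
    np.divide(sums, counts, out=out, where=counts > 0)
    return GriddedField(coarse_spec, out, fine.units)


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style dimension order (time, lat, lon); scipy backend)

_ENGINE = "scipy"


def _grid_to_coords(grid: GridSpec) -> dict:
    return {
        "lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
        "lon": ("lon", grid.lon_centers, {"units": "degrees_east"}),
    }


def write_netcdf(path: str | Path, obj: SSTSeries | GriddedField, var_name: str | None = None) -> None:
    """Write a series or field losslessly, with grid, masks and units."""
    grid = obj.grid
    coords = _grid_to_coords(grid)
    data_vars = {
        "land_mask": (("lat", "lon"), grid.land_mask.astype(np.uint8)),
        "cell_area": (("lat", "lon"), grid.cell_area),
    }
    attrs = {"resolution_deg": grid.resolution_deg}
    if isinstance(obj, SSTSeries):
        coords["time"] = ("time", obj.years, {"units": "calendar year"})
        data_vars["sst"] = (("time", "lat", "lon"), obj.sst, {"units": "degC"})
        attrs["era"] = obj.era
    else:
        name = var_name or "field"
        data_vars[name] = (("lat", "lon"), obj.values, {"units": obj.units})
    ds = xr.Dataset(data_vars, coords=coords, attrs=attrs)
    ds.to_netcdf(Path(path), engine=_ENGINE)


def read_netcdf(path: str | Path) -> SSTSeries | GriddedField:
    """Read back anything :func:`write_netcdf` produced."""
    with xr.open_dataset(Path(path), engine=_ENGINE, decode_times=False) as ds:
        ds.load()
    for coord in ("lat", "lon"):
        if coord not in ds.coords:
            raise ParseError(f"file lacks required coordinate {coord!r}")
    for var in ("land_mask", "cell_area"):
        if var not in ds:
            raise ParseError(f"file lacks required variable {var!r}")
    grid = GridSpec(
        resolution_deg=float(ds.attrs.get("resolution_deg", np.diff(ds.lat.values).mean())),
        lat_centers=ds.lat.values,
        lon_centers=ds.lon.values,
        land_mask=ds.land_mask.values.astype(bool),
        cell_area=ds.cell_area.values,
    )
    if "sst" in ds:
        if "time" not in ds.coords:
            raise ParseError("sst variable present but file lacks coordinate 'time'")
        if "era" not in ds.attrs:
            raise ParseError("file lacks global attribute 'era'")
        return SSTSeries(grid, ds.time.values.astype(np.int64), ds.sst.values, str(ds.attrs["era"]))
    extras = [v for v in ds.data_vars if v not in ("land_mask", "cell_area")]
    if not extras:
        raise ParseError("file contains no data variable besides the grid masks")
    var = ds[extras[0]]
    return GriddedField(grid, var.values, str(var.attrs.get("units", "")))
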