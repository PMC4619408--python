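"""NetCDF (CF-style) round-tripping of the pipeline's gridded products.

Rasters are written as classic NetCDF through xarray's scipy backend
with ``lat``/``lon`` (and ``time`` or ``month``) coordinates and CF
``units`` attributes.  Biome maps carry a sidecar JSON legend.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import xarray as xr

from .biomes import BIOME_LABELS, Biome, BiomeMap
from .fields import VARIABLES, ClimatologyField, MonthlySeries
from .grid import ElevationField, GridSpec, build_grid

__all__ = [
    "climatology_to_dataset",
    "dataset_to_climatology",
    "series_to_dataset",
    "dataset_to_series",
    "elevation_to_dataset",
    "dataset_to_elevation",
    "write_dataset",
    "write_biome_map",
    "read_biome_map",
]

_ENGINE = "scipy"


def _grid_attrs(grid: GridSpec) -> dict:
    return {
        "lat_min": grid.lat_min,
        "lat_max": grid.lat_max,
        "lon_min": grid.lon_min,
        "lon_max": grid.lon_max,
        "resolution": grid.resolution,
        "registration": grid.registration,
    }


def _grid_from_attrs(attrs: dict) -> GridSpec:
    return build_grid(
        attrs["lat_min"], attrs["lat_max"], attrs["lon_min"], attrs["lon_max"],
        attrs["resolution"],
    )


def _coords(grid: GridSpec) -> dict:
    return {
        "lat": ("lat", grid.lat_centers, {"units": "degrees_north"}),
        "lon": ("lon", grid.lon_centers, {"units": "degrees_east"}),
    }


def climatology_to_dataset(clim: ClimatologyField) -> xr.Dataset:
    ds = xr.Dataset(
        {clim.variable: (("month", "lat", "lon"), clim.values,
                         {"units": VARIABLES[clim.variable]})},
        coords={"month": np.arange(1, 13), **_coords(clim.grid)},
        attrs={**_grid_attrs(clim.grid),
               "base_period_start": clim.base_period[0],
               "base_period_end": clim.base_period[1]},
    )
    return ds


def dataset_to_climatology(ds: xr.Dataset, variable: str) -> ClimatologyField:
    return ClimatologyField(
        variable=variable,
        values=ds[variable].values,
        grid=_grid_from_attrs(ds.attrs),
        base_period=(int(ds.attrs["base_period_start"]), int(ds.attrs["base_period_end"])),
    )


def series_to_dataset(series: MonthlySeries) -> xr.Dataset:
    ny = series.n_years
    flat = series.values.reshape((ny * 12,) + series.values.shape[2:])
    time = series.years[0] + (np.arange(ny * 12) + 0.5) / 12.0
    return xr.Dataset(
        {series.variable: (("time", "lat", "lon"), flat,
                           {"units": VARIABLES[series.variable], "mode": series.mode})},
        coords={"time": ("time", time, {"units": "decimal_year"}),
                **_coords(series.grid)},
        attrs={**_grid_attrs(series.grid),
               "year_start": series.years[0], "year_end": series.years[1],
               "series_mode": series.mode},
    )


def dataset_to_series(ds: xr.Dataset, variable: str) -> MonthlySeries:
    years = (int(ds.attrs["year_start"]), int(ds.attrs["year_end"]))
    ny = years[1] - years[0] + 1
    flat = ds[variable].values
    return MonthlySeries(
        variable=variable,
        values=flat.reshape((ny, 12) + flat.shape[1:]),
        years=years,
        mode=ds.attrs["series_mode"],
        grid=_grid_from_attrs(ds.attrs),
    )


def elevation_to_dataset(elev: ElevationField) -> xr.Dataset:
    values = np.where(elev.mask, np.nan, elev.values)
    return xr.Dataset(
        {"elevation": (("lat", "lon"), values, {"units": "m"})},
        coords=_coords(elev.grid),
        attrs=_grid_attrs(elev.grid),
    )


def dataset_to_elevation(ds: xr.Dataset) -> ElevationField:
    return ElevationField(grid=_grid_from_attrs(ds.attrs), values=ds["elevation"].values)


def write_dataset(ds: xr.Dataset, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine=_ENGINE)


def write_biome_map(bm: BiomeMap, path) -> None:
    """Integer biome raster plus a sidecar ``<path>.legend.json``."""
    path = Path(path)
    ds = xr.Dataset(
        {"biome": (("lat", "lon"), bm.codes.astype(np.int16), {"units": "category"})},
        coords=_coords(bm.grid) if bm.grid is not None else {},
        attrs=_grid_attrs(bm.grid) if bm.grid is not None else {},
    )
    write_dataset(ds, path)
    legend = {int(b): BIOME_LABELS[b] for b in Biome if b != Biome.MASKED}
    legend[0] = "masked"
    path.with_suffix(path.suffix + ".legend.json").write_text(
        json.dumps(legend, indent=2)
    )


def read_biome_map(path) -> BiomeMap:
    ds = xr.open_dataset(path, engine=_ENGINE)
    grid = _grid_from_attrs(ds.attrs) if "lat_min" in ds.attrs else None
    return BiomeMap(codes=ds["biome"].values.astype(np.int16), grid=grid)
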