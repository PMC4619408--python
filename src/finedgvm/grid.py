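"""Study-grid geometry, elevation assignment, and geodetic areas.

The study grid is a regular geographic (lat-lon) raster of cell-centre
points.  Latitude rows are stored south-to-north and longitude columns
west-to-east; longitudes are signed decimal degrees (west negative).
Elevation is attached to fine grid points by a containing-cell lookup in
a coarser digital elevation model (DEM): each fine point takes the value
of the single DEM cell whose half-open extent ``[west, east) x [south,
north)`` contains it.  No interpolation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AUTHALIC_RADIUS_M",
    "GridSpec",
    "ElevationField",
    "build_grid",
    "box_area",
    "assign_elevation",
]

#: Radius (m) of the sphere with the same surface area as the WGS84 ellipsoid.
AUTHALIC_RADIUS_M = 6_371_007.2

#: Square metres per hectare.
_M2_PER_HA = 1e4


class GridConfigurationError(ValueError):
    """Raised when grid bounds and resolution are inconsistent."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lat-lon raster with cell-centre registration.

    Parameters
    ----------
    lat_min, lat_max, lon_min, lon_max : float
        Outer bounds of the raster in decimal degrees.
    resolution : float
        Cell size in degrees (same in both axes).
    n_rows, n_cols : int
        Raster shape; must equal span / resolution.
    registration : str
        ``"cell-center"`` (points at cell centres) or ``"node"``.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float
    n_rows: int
    n_cols: int
    registration: str = "cell-center"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise GridConfigurationError("resolution must be positive")
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise GridConfigurationError(
                f"latitude bounds [{self.lat_min}, {self.lat_max}] invalid"
            )
        for name, span, n in (
            ("latitude", self.lat_max - self.lat_min, self.n_rows),
            ("longitude", self.lon_max - self.lon_min, self.n_cols),
        ):
            if abs(span / self.resolution - n) > 1e-6:
                raise GridConfigurationError(
                    f"resolution {self.resolution} does not divide the "
                    f"{name} span {span} ({span / self.resolution:.8f} cells)"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-centre latitudes, south to north."""
        return self.lat_min + (np.arange(self.n_rows) + 0.5) * self.resolution

    @property
    def lon_centers(self) -> np.ndarray:
        """Cell-centre longitudes, west to east."""
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.lat_min + (row + 0.5) * self.resolution,
            self.lon_min + (col + 0.5) * self.resolution,
        )

    def index_of(self, lat, lon):
        """Containing-cell indices for points, half-open in each axis.

        Returns ``(row, col, inside)`` arrays; ``inside`` is False where a
        point falls outside ``[lat_min, lat_max) x [lon_min, lon_max)``.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        row = np.floor((lat - self.lat_min) / self.resolution).astype(int)
        col = np.floor((lon - self.lon_min) / self.resolution).astype(int)
        inside = (
            (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        )
        return row, col, inside


@dataclass
class ElevationField:
    """Elevation raster (m above sea level) with a validity mask.

    ``mask`` is True where a cell has no usable value; masked cells are
    excluded from every downstream stage.
    """

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool) | ~np.isfinite(
                self.values
            )


def build_grid(
    lat_min: float,
    lat_max: float,
    lon_min: float,
    lon_max: float,
    resolution: float,
) -> GridSpec:
    """Construct a cell-centre grid covering the given bounding box.

    The resolution must divide both spans to within 1e-6 of a cell;
    otherwise a :class:`GridConfigurationError` names the offending span.
    """
    if lat_max <= lat_min or lon_max <= lon_min:
        raise GridConfigurationError("bounds must satisfy max > min")
    n_rows = round((lat_max - lat_min) / resolution)
    n_cols = round((lon_max - lon_min) / resolution)
    return GridSpec(
        lat_min, lat_max, lon_min, lon_max, resolution, n_rows, n_cols
    )


def box_area(
    lat_min: float, lat_max: float, lon_min: float, lon_max: float
) -> float:
    """Area in hectares of a lat-lon box on the authalic sphere.

    Uses the exact spherical-zone formula
    ``R^2 * dlon * (sin(lat_max) - sin(lat_min))``.
    """
    if lat_max < lat_min or lon_max < lon_min:
        raise ValueError("bounds must satisfy max >= min")
    dlon = np.deg2rad(lon_max - lon_min)
    area_m2 = (
        AUTHALIC_RADIUS_M**2
        * dlon
        * (np.sin(np.deg2rad(lat_max)) - np.sin(np.deg2rad(lat_min)))
    )
    return float(area_m2 / _M2_PER_HA)


def assign_elevation(grid: GridSpec, dem: ElevationField) -> ElevationField:
    """Assign each grid point the elevation of the DEM cell containing it.

    Containing-cell rule, not interpolation: point (lat, lon) takes the
    value of the DEM cell whose half-open extent [west, east) x [south,
    north) contains it.  Points outside the DEM are masked; if no grid
    point falls inside the DEM at all, a ValueError is raised.
    """
    lat2d = grid.lat_centers[:, None] + np.zeros((1, grid.n_cols))
    lon2d = np.zeros((grid.n_rows, 1)) + grid.lon_centers[None, :]
    row, col, inside = dem.grid.index_of(lat2d, lon2d)
    if not inside.any():
        raise ValueError("grid does not overlap the DEM extent")
    values = np.full(grid.shape, np.nan)
    r = np.clip(row, 0, dem.grid.n_rows - 1)
    c = np.clip(col, 0, dem.grid.n_cols - 1)
    picked = dem.values[r, c]
    picked_mask = dem.mask[r, c]
    ok = inside & ~picked_mask
    values[ok] = picked[ok]
    return ElevationField(grid=grid, values=values, mask=~ok)
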