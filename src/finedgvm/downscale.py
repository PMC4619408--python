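"""Topographic lapse-rate downscaling and anomaly time-series assembly.

The downscaling scheme has two legs:

* the base climatology is interpolated from the coarse grid to the fine
  grid with geographic-distance-weighted bilinear interpolation, each
  contributing coarse node first adjusted along a locally regressed
  (topographic, not adiabatic) lapse rate to the elevation of the fine
  point;
* monthly anomalies (differences for temperature, ratios for
  precipitation/sunshine/cloud) are interpolated with the same
  geographic-distance weighting but *without* elevational adjustment,
  then applied to the fine base climatology.

Fine points exactly coincident with a coarse node receive the node
value verbatim (elevation adjustment vanishes when the elevations are
equal).  Applied sunshine is clamped to [0, 100] % and precipitation is
floored at 0 mm.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Union

import numpy as np
import statsmodels.api as sm

from .fields import ClimatologyField, LapseRateField, MonthlySeries
from .grid import AUTHALIC_RADIUS_M, ElevationField, GridSpec

__all__ = [
    "fit_local_lapse_rates",
    "interpolate_with_lapse",
    "interpolate_series",
    "compute_anomalies",
    "apply_anomalies",
    "cloud_to_sunshine",
    "build_spinup",
]

logger = logging.getLogger(__name__)

_ANOMALY_MODE_FOR = {
    "tmean": "difference",
    "precip": "ratio",
    "sunshine": "ratio",
    "cloud": "ratio",
}


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres on the authalic sphere."""
    lat1, lon1, lat2, lon2 = (np.deg2rad(np.asarray(x, float)) for x in (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2.0 * AUTHALIC_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Local lapse-rate regression

def fit_local_lapse_rates(
    clim: ClimatologyField,
    elev_coarse: ElevationField,
    window_radius: int = 5,
    min_points: int = 10,
    min_elev_sd: float = 10.0,
) -> LapseRateField:
    """Moving-window local regression of climate on elevation.

    For every coarse cell and month, the slope of a weighted
    least-squares regression of the climate value on elevation over the
    ``(2r+1)^2`` window, with tricube weights on great-circle distance
    from the window centre.  Windows with fewer than ``min_points``
    valid neighbours are masked, as are windows whose weighted
    elevation spread is below ``min_elev_sd`` metres: a lapse rate
    (units per metre) is not identifiable without elevational contrast,
    and regressing noise on a near-constant regressor produces
    arbitrarily large slopes.
    """
    if clim.grid is None or clim.grid != elev_coarse.grid:
        raise ValueError("climatology and elevation must share a grid")
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    grid = clim.grid
    nr, nc = grid.shape
    lat = grid.lat_centers
    lon = grid.lon_centers
    valid = ~(clim.mask | elev_coarse.mask)
    z = elev_coarse.values
    v = clim.values  # (12, nr, nc)

    slopes = np.full((12, nr, nc), np.nan)
    n_masked = 0
    r = window_radius
    for i in range(nr):
        i0, i1 = max(0, i - r), min(nr, i + r + 1)
        for j in range(nc):
            j0, j1 = max(0, j - r), min(nc, j + r + 1)
            vw = valid[i0:i1, j0:j1]
            if vw.sum() < min_points:
                n_masked += 1
                continue
            zz = z[i0:i1, j0:j1][vw]
            wl_lat = np.broadcast_to(lat[i0:i1, None], vw.shape)[vw]
            wl_lon = np.broadcast_to(lon[None, j0:j1], vw.shape)[vw]
            d = haversine_m(lat[i], lon[j], wl_lat, wl_lon)
            dmax = d.max() * 1.0001
            w = (1.0 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
            wsum = w.sum()
            zbar = (w * zz).sum() / wsum
            dz = zz - zbar
            denom = (w * dz * dz).sum()
            if np.sqrt(denom / wsum) < min_elev_sd:
                n_masked += 1
                continue
            yy = v[:, i0:i1, j0:j1][:, vw]  # (12, k)
            ybar = (w * yy).sum(axis=1) / wsum
            slopes[:, i, j] = (w * dz * (yy - ybar[:, None])).sum(axis=1) / denom
    if n_masked:
        logger.info("lapse-rate fit: %d cells masked (< %d window points)", n_masked, min_points)
    return LapseRateField(
        variable=clim.variable, values=slopes, grid=grid, window_radius=window_radius
    )


# ---------------------------------------------------------------------------
# Geographic-distance-weighted bilinear interpolation

def _stencil(source: GridSpec, target: GridSpec):
    """Corner indices, inverse-distance weights and coincidence flags.

    Returns ``(rows, cols, weights, coincident_corner, inside)`` where
    ``rows``/``cols`` are (N, 4) corner indices into the source lattice
    of cell-centre nodes for the N flattened target points.
    """
    tlat = np.repeat(target.lat_centers, target.n_cols)
    tlon = np.tile(target.lon_centers, target.n_rows)
    slat0 = source.lat_min + 0.5 * source.resolution
    slon0 = source.lon_min + 0.5 * source.resolution
    u = (tlat - slat0) / source.resolution
    v = (tlon - slon0) / source.resolution
    eps = 1e-9
    inside = (u >= -eps) & (u <= source.n_rows - 1 + eps) & (v >= -eps) & (
        v <= source.n_cols - 1 + eps
    )
    i0 = np.clip(np.floor(u).astype(int), 0, source.n_rows - 2 if source.n_rows > 1 else 0)
    j0 = np.clip(np.floor(v).astype(int), 0, source.n_cols - 2 if source.n_cols > 1 else 0)
    di = np.array([0, 0, 1, 1])
    dj = np.array([0, 1, 0, 1])
    rows = np.clip(i0[:, None] + di[None, :], 0, source.n_rows - 1)
    cols = np.clip(j0[:, None] + dj[None, :], 0, source.n_cols - 1)
    nlat = slat0 + rows * source.resolution
    nlon = slon0 + cols * source.resolution
    d = haversine_m(tlat[:, None], tlon[:, None], nlat, nlon)
    coincident = d < 1e-6  # metres
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    # Coincident node: all weight on that node.
    any_co = coincident.any(axis=1)
    w[any_co] = coincident[any_co].astype(float)
    w /= w.sum(axis=1, keepdims=True)
    return rows, cols, w, inside


def _interpolate_layers(
    layers: np.ndarray,
    source: GridSpec,
    target: GridSpec,
    source_mask: Optional[np.ndarray],
    lapse: Optional[np.ndarray] = None,
    target_elev: Optional[ElevationField] = None,
    coarse_elev: Optional[ElevationField] = None,
) -> np.ndarray:
    """Interpolate (K, nr, nc) source layers onto the target grid.

    When ``lapse`` (same shape as ``layers``) is given, each corner
    value is adjusted by ``lapse * (z_target - z_node)`` before
    weighting.
    """
    k = layers.shape[0]
    rows, cols, w, inside = _stencil(source, target)
    n = rows.shape[0]
    w = w.copy()
    if source_mask is not None:
        corner_ok = ~source_mask[rows, cols]
        w = np.where(corner_ok, w, 0.0)
    wsum = w.sum(axis=1)
    usable = inside & (wsum > 0)
    w = np.where(usable[:, None], w / np.where(wsum > 0, wsum, 1.0)[:, None], 0.0)

    if lapse is not None:
        if target_elev is None or coarse_elev is None:
            raise ValueError("lapse adjustment requires target and coarse elevations")
        zt = target_elev.values.reshape(n)
        zn = coarse_elev.values[rows, cols]
        dz = zt[:, None] - zn
        lapse_ok = np.isfinite(lapse)
        usable = usable & ~target_elev.mask.reshape(n)
    out = np.full((k, n), np.nan)
    for m in range(k):
        corner_vals = layers[m][rows, cols]
        if lapse is not None:
            lm = lapse[m][rows, cols]
            adj = np.where(np.isfinite(lm), lm, 0.0) * dz
            corner_vals = corner_vals + adj
        out[m] = np.where(usable, (w * np.nan_to_num(corner_vals)).sum(axis=1), np.nan)
    return out.reshape((k,) + target.shape)


def _clamp(variable: str, values: np.ndarray) -> np.ndarray:
    if variable in ("sunshine", "cloud"):
        return np.clip(values, 0.0, 100.0)
    if variable == "precip":
        return np.maximum(values, 0.0)
    return values


def interpolate_with_lapse(
    clim: ClimatologyField,
    lapse: LapseRateField,
    target: GridSpec,
    target_elev: ElevationField,
    coarse_elev: ElevationField,
) -> ClimatologyField:
    """Downscale a coarse climatology with elevational adjustment.

    Each fine point takes the inverse-great-circle-distance-weighted
    combination of the four surrounding coarse nodes, every node value
    adjusted by its local lapse rate times the elevation difference to
    the fine point.  Fine points coincident with a coarse node take
    that node's value (plus lapse adjustment if the elevations differ).
    Sunshine is clamped to [0, 100] and precipitation floored at 0;
    points outside the coarse node hull are masked (NaN).
    """
    if lapse.grid != clim.grid:
        raise ValueError("lapse rates must live on the climatology grid")
    if lapse.variable != clim.variable:
        raise ValueError("lapse variable does not match climatology")
    out = _interpolate_layers(
        clim.values,
        clim.grid,
        target,
        clim.mask,
        lapse=lapse.values,
        target_elev=target_elev,
        coarse_elev=coarse_elev,
    )
    out = np.where(np.isfinite(out), _clamp(clim.variable, out), np.nan)
    return ClimatologyField(
        variable=clim.variable, values=out, grid=target, base_period=clim.base_period
    )


def interpolate_series(series: MonthlySeries, target: GridSpec) -> MonthlySeries:
    """Plain geographic-distance-weighted bilinear interpolation.

    Used for anomaly series, which are interpolated without elevational
    adjustment.
    """
    if series.grid is None:
        raise ValueError("series must carry a grid")
    ny = series.n_years
    flat = series.values.reshape((ny * 12,) + series.grid.shape)
    out = _interpolate_layers(flat, series.grid, target, None)
    return MonthlySeries(
        variable=series.variable,
        values=out.reshape((ny, 12) + target.shape),
        years=series.years,
        mode=series.mode,
        grid=target,
    )


# ---------------------------------------------------------------------------
# Anomalies

def compute_anomalies(
    series: MonthlySeries, base: ClimatologyField, mode: str
) -> MonthlySeries:
    """Monthly anomalies of a series against a base-period climatology.

    ``mode="difference"`` (temperature): value minus the base monthly
    mean.  ``mode="ratio"`` (precipitation, sunshine, cloud): value
    divided by the base monthly mean, with a zero base defined as
    "no change" (ratio 1) and counted in the log.
    """
    if series.variable != base.variable:
        raise ValueError("series and base variables differ")
    if series.grid != base.grid:
        raise ValueError("series and base must share a grid")
    if series.mode != "absolute":
        raise ValueError("anomalies are computed from absolute series")
    expected = _ANOMALY_MODE_FOR[series.variable]
    if mode != expected:
        raise ValueError(
            f"{series.variable} anomalies use mode={expected!r}, got {mode!r}"
        )
    b = base.values[None]  # (1, 12, *spatial)
    if mode == "difference":
        values = series.values - b
        out_mode = "anomaly-difference"
    else:
        if np.any(series.values[np.isfinite(series.values)] < 0):
            raise ValueError("ratio anomalies require non-negative values")
        zero_base = b == 0
        values = np.where(zero_base, 1.0, series.values / np.where(zero_base, 1.0, b))
        n_zero = int(zero_base.sum())
        if n_zero:
            logger.info("ratio anomalies: %d zero-base cells set to 1.0", n_zero)
        out_mode = "anomaly-ratio"
    return MonthlySeries(
        variable=series.variable,
        values=values,
        years=series.years,
        mode=out_mode,
        grid=series.grid,
    )


def apply_anomalies(
    fine_base: ClimatologyField, anoms: MonthlySeries, mode: Optional[str] = None
) -> MonthlySeries:
    """Apply interpolated anomalies to a fine base climatology.

    Difference anomalies add; ratio anomalies multiply.  Sunshine is
    clamped to [0, 100] and precipitation floored at 0 afterwards.
    """
    if anoms.variable != fine_base.variable:
        raise ValueError("anomaly and base variables differ")
    if anoms.grid != fine_base.grid:
        raise ValueError("anomalies and base must share a grid")
    if mode is None:
        mode = {"anomaly-difference": "difference", "anomaly-ratio": "ratio"}.get(
            anoms.mode
        )
        if mode is None:
            raise ValueError("anomaly series has absolute mode")
    expected = _ANOMALY_MODE_FOR[fine_base.variable]
    if mode != expected:
        raise ValueError(
            f"{fine_base.variable} anomalies use mode={expected!r}, got {mode!r}"
        )
    b = fine_base.values[None]
    if mode == "difference":
        if anoms.mode != "anomaly-difference":
            raise ValueError("difference application needs difference anomalies")
        values = b + anoms.values
    else:
        if anoms.mode != "anomaly-ratio":
            raise ValueError("ratio application needs ratio anomalies")
        values = b * anoms.values
    values = _clamp(fine_base.variable, values)
    return MonthlySeries(
        variable=fine_base.variable,
        values=values,
        years=anoms.years,
        mode="absolute",
        grid=fine_base.grid,
    )


def cloud_to_sunshine(
    data: Union[MonthlySeries, ClimatologyField]
) -> Union[MonthlySeries, ClimatologyField]:
    """Convert cloud cover (%) to possible sunshine (%) as 100 - cloud.

    An involution: applying it twice returns the input.  Values outside
    [0, 100] raise, reporting the offending cell count.
    """
    values = data.values
    finite = np.isfinite(values)
    bad = finite & ((values < 0) | (values > 100))
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} value(s) outside [0, 100] cannot be converted"
        )
    new_var = {"cloud": "sunshine", "sunshine": "cloud"}.get(data.variable)
    if new_var is None:
        raise ValueError("cloud_to_sunshine applies to cloud or sunshine fields")
    out = np.where(finite, 100.0 - values, np.nan)
    if isinstance(data, MonthlySeries):
        return MonthlySeries(
            variable=new_var, values=out, years=data.years, mode=data.mode,
            grid=data.grid,
        )
    return ClimatologyField(
        variable=new_var, values=out, grid=data.grid, base_period=data.base_period
    )


# ---------------------------------------------------------------------------
# Spin-up construction

def build_spinup(
    series: MonthlySeries, n_years: int = 800, loess_span: float = 0.5
) -> MonthlySeries:
    """Detrended, tiled spin-up series from a 30-year block.

    Per cell and calendar month, a locally weighted (loess, degree 1)
    regression across the 30 years estimates the long-term trend, which
    is subtracted with the mean preserved; the detrended block is then
    repeated to cover ``n_years`` years.
    """
    if n_years <= 0:
        raise ValueError("n_years must be positive")
    if series.n_years != 30:
        raise ValueError(f"spin-up input must span exactly 30 years, got {series.n_years}")
    v = series.values  # (30, 12, *spatial)
    spatial = v.shape[2:]
    flat = v.reshape(30, 12, -1)
    x = np.arange(30, dtype=float)
    detrended = np.empty_like(flat)
    for m in range(12):
        for c in range(flat.shape[2]):
            y = flat[:, m, c]
            if not np.all(np.isfinite(y)):
                detrended[:, m, c] = y
                continue
            trend = sm.nonparametric.lowess(
                y, x, frac=loess_span, it=1, return_sorted=False
            )
            detrended[:, m, c] = y - trend + trend.mean()
    detrended = detrended.reshape((30, 12) + spatial)
    reps = math.ceil(n_years / 30)
    tiled = np.tile(detrended, (reps,) + (1,) * (detrended.ndim - 1))[:n_years]
    start = series.years[0]
    return MonthlySeries(
        variable=series.variable,
        values=_clamp(series.variable, tiled) if series.mode == "absolute" else tiled,
        years=(start - n_years, start - n_years + n_years - 1),
        mode=series.mode,
        grid=series.grid,
    )
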