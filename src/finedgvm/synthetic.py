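"""Synthetic gridded inputs with known statistical structure.

Every generator is a pure function of ``(seed, parameters)``: child
random streams are derived from a root seed with named, order-stable
spawn keys, and all fields are drawn as whole arrays, so values do not
depend on raster traversal order.  The default scenario
(``cascadia-toy``) is a 20x20 coarse / 240x240 fine mountain domain
with a meridional ridge, a prescribed temperature lapse rate of
-6.5 degC/km, winter-wet orographic precipitation, smooth drifting
anomalies, and spatially autocorrelated soil texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .biomes import RuleConfig, classify_grid
from .fields import ClimatologyField, MonthlySeries
from .grid import ElevationField, GridSpec, build_grid
from .soil import derive_soil_hydraulics

__all__ = [
    "SyntheticScenario",
    "cascadia_toy",
    "make_terrain",
    "make_coarse_climatology",
    "make_anomaly_series",
    "make_soil_texture",
    "make_truth_vegetation",
    "OBSERVED_LEGEND",
]

# Spawn keys for independent random streams, one per generated product.
_STREAMS = {
    "terrain": 1,
    "climatology": 2,
    "anomalies": 3,
    "soil": 4,
    "vegetation": 5,
}

#: Class codes of the synthetic "observed" vegetation raster.
OBSERVED_LEGEND = {
    1: "conifer forest",
    2: "grassland",
    3: "shrubland",
    10: "agriculture",
    11: "urban",
    12: "wetland",
}

#: Default mapping of observed codes to forest/grass/shrub.
OBSERVED_TO_FGS = {1: "forest", 2: "grass", 3: "shrub",
                   10: "exclude", 11: "exclude", 12: "exclude"}


@dataclass(frozen=True)
class SyntheticScenario:
    """A fully specified synthetic world.

    ``true_lapse`` holds the prescribed per-month temperature lapse
    rates (degC per metre); precipitation and sunshine respond to
    elevation through explicit orographic terms rather than a linear
    lapse.  ``trend`` gives per-variable drift over the anomaly years
    (degC per year for temperature; fractional change per year for
    ratio variables).
    """

    seed: int = 42
    name: str = "cascadia-toy"
    coarse: GridSpec = field(
        default_factory=lambda: build_grid(43.0, 48.0, -124.0, -119.0, 0.25)
    )
    fine: GridSpec = field(
        default_factory=lambda: build_grid(43.0, 48.0, -124.0, -119.0, 0.25 / 12.0)
    )
    terrain_relief_m: float = 2500.0
    true_lapse_degc_per_m: tuple = tuple([-6.5e-3] * 12)
    sea_level_tmean_degc: float = 11.0
    seasonal_amplitude_degc: float = 9.0
    noise_sd: dict = field(
        default_factory=lambda: {"tmean": 0.5, "precip": 5.0, "sunshine": 3.0}
    )
    trend: dict = field(
        default_factory=lambda: {"tmean": 0.01, "precip": 0.0005, "sunshine": 0.0}
    )
    anomaly_noise_sd: dict = field(
        default_factory=lambda: {"tmean": 0.6, "precip": 0.15, "sunshine": 0.05}
    )
    ar1: float = 0.3
    label_flip_rate: float = 0.0

    def rng(self, stream: str) -> np.random.Generator:
        """An independent generator for one named product stream."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    def with_seed(self, seed: int) -> "SyntheticScenario":
        return replace(self, seed=seed)


def cascadia_toy(seed: int = 42, **overrides) -> SyntheticScenario:
    """The repo's standard fixture scenario."""
    return SyntheticScenario(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Terrain

def _fractal_surface(rng: np.random.Generator, shape, beta: float = 1.8) -> np.ndarray:
    """Spectrally synthesised fractal surface, zero mean, unit sd."""
    white = rng.standard_normal(shape)
    f = np.fft.fft2(white)
    ky = np.fft.fftfreq(shape[0])[:, None]
    kx = np.fft.fftfreq(shape[1])[None, :]
    k = np.sqrt(ky**2 + kx**2)
    k[0, 0] = np.inf  # kill the DC component
    surf = np.real(np.fft.ifft2(f * k ** (-beta)))
    sd = surf.std()
    return (surf - surf.mean()) / (sd if sd > 0 else 1.0)


def make_terrain(scenario: SyntheticScenario) -> tuple[ElevationField, ElevationField]:
    """Fine terrain plus its block-mean coarse aggregate.

    A Gaussian meridional ridge (a toy Cascade crest) plus fractal
    roughness, scaled by the scenario relief and floored at sea level.
    The coarse field is the exact block mean of the fine cells it
    covers.
    """
    if scenario.terrain_relief_m < 0:
        raise ValueError("relief must be non-negative")
    fine = scenario.fine
    if scenario.terrain_relief_m == 0:
        zf = np.zeros(fine.shape)
    else:
        rng = scenario.rng("terrain")
        lon = fine.lon_centers[None, :]
        ridge_lon = 0.35 * fine.lon_min + 0.65 * fine.lon_max
        width = 0.18 * (fine.lon_max - fine.lon_min)
        ridge = np.exp(-(((lon - ridge_lon) / width) ** 2))
        rough = _fractal_surface(rng, fine.shape)
        zf = scenario.terrain_relief_m * (0.85 * ridge + 0.3 * rough)
        zf = np.maximum(zf, 0.0)
    fine_field = ElevationField(grid=fine, values=zf)

    coarse = scenario.coarse
    ratio_r = fine.n_rows // coarse.n_rows
    ratio_c = fine.n_cols // coarse.n_cols
    if coarse.n_rows * ratio_r != fine.n_rows or coarse.n_cols * ratio_c != fine.n_cols:
        raise ValueError("fine grid must tile the coarse grid evenly")
    zc = zf.reshape(coarse.n_rows, ratio_r, coarse.n_cols, ratio_c).mean(axis=(1, 3))
    return fine_field, ElevationField(grid=coarse, values=zc)


# ---------------------------------------------------------------------------
# Climatology

def _seasonal_cycle(mean: float, amplitude: float) -> np.ndarray:
    """12 monthly values peaking in July (northern-hemisphere phase)."""
    months = np.arange(12)
    return mean + amplitude * np.cos(2.0 * np.pi * (months - 6.0) / 12.0)


def _correlated_noise(rng, shape, sd: float, length: float = 2.0) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=length, mode="nearest")
    s = smooth.std()
    return sd * smooth / (s if s > 0 else 1.0)


def make_coarse_climatology(
    scenario: SyntheticScenario, terrain_coarse: ElevationField
) -> dict[str, ClimatologyField]:
    """Coarse monthly climatologies with known lapse structure.

    Temperature is a sea-level seasonal cycle plus the prescribed
    per-month lapse times elevation plus spatially correlated noise;
    precipitation is a winter-wet cycle enhanced orographically with
    elevation; sunshine decreases modestly with elevation.  All fields
    obey their physical ranges.
    """
    grid = terrain_coarse.grid
    z = terrain_coarse.values
    rng = scenario.rng("climatology")
    lapse = np.asarray(scenario.true_lapse_degc_per_m)
    t0 = _seasonal_cycle(scenario.sea_level_tmean_degc, scenario.seasonal_amplitude_degc)

    tmean = t0[:, None, None] + lapse[:, None, None] * z[None]
    for m in range(12):
        tmean[m] += _correlated_noise(rng, grid.shape, scenario.noise_sd["tmean"])

    p0 = _seasonal_cycle(90.0, 70.0)[::-1].copy()  # winter-wet: phase-inverted cycle
    # Orographic structure: enhancement with elevation on the windward side
    # and a rain shadow east of the crest, as in maritime mountain ranges.
    lon = grid.lon_centers[None, :]
    ridge_lon = 0.35 * grid.lon_min + 0.65 * grid.lon_max
    east = np.clip((lon - ridge_lon) / (grid.lon_max - ridge_lon), 0.0, 1.0)
    shadow = 1.0 / (1.0 + 6.0 * east)
    shadow = np.broadcast_to(shadow, grid.shape)
    precip = p0[:, None, None] * (1.0 + z[None] / 2000.0) * shadow[None]
    for m in range(12):
        precip[m] += _correlated_noise(rng, grid.shape, scenario.noise_sd["precip"])
    precip = np.maximum(precip, 0.0)

    s0 = _seasonal_cycle(55.0, 25.0)
    sun = s0[:, None, None] - z[None] / 150.0
    for m in range(12):
        sun[m] += _correlated_noise(rng, grid.shape, scenario.noise_sd["sunshine"])
    sun = np.clip(sun, 0.0, 100.0)

    return {
        "tmean": ClimatologyField("tmean", tmean, grid=grid),
        "precip": ClimatologyField("precip", precip, grid=grid),
        "sunshine": ClimatologyField("sunshine", sun, grid=grid),
    }


# ---------------------------------------------------------------------------
# Anomaly series

def make_anomaly_series(
    scenario: SyntheticScenario,
    years: tuple[int, int] = (1901, 2000),
    base_period: tuple[int, int] = (1961, 1990),
) -> dict[str, MonthlySeries]:
    """Coarse-grid anomaly series with linear drift and AR(1) noise.

    Temperature anomalies are differences recentred to zero mean over
    the base period; precipitation and sunshine anomalies are
    non-negative ratios whose log is recentred over the base period, so
    base-period means are 0 (difference) and ~1 (ratio) by
    construction.
    """
    start, end = years
    ny = end - start + 1
    if ny < 30:
        raise ValueError("anomaly series must span at least 30 years")
    grid = scenario.coarse
    rng = scenario.rng("anomalies")
    b0, b1 = base_period
    t_axis = np.arange(start, end + 1, dtype=float)
    in_base = (t_axis >= b0) & (t_axis <= b1)
    if not in_base.any():  # base period outside the span: centre on the span mean
        in_base = np.ones_like(t_axis, dtype=bool)

    def ar1_noise(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros((ny, 12) + grid.shape)
        eps = rng.standard_normal((ny * 12,) + grid.shape)
        out = np.empty_like(eps)
        out[0] = eps[0]
        phi = scenario.ar1
        innov = np.sqrt(1.0 - phi**2)
        for t in range(1, ny * 12):
            out[t] = phi * out[t - 1] + innov * eps[t]
        return sd * out.reshape((ny, 12) + grid.shape)

    series = {}
    for var, mode in (("tmean", "anomaly-difference"),
                      ("precip", "anomaly-ratio"),
                      ("sunshine", "anomaly-ratio")):
        drift = scenario.trend.get(var, 0.0) * (t_axis - t_axis[in_base].mean())
        raw = drift[:, None, None, None] + ar1_noise(scenario.anomaly_noise_sd.get(var, 0.0))
        raw = raw - raw[in_base].mean(axis=0, keepdims=True)
        if mode == "anomaly-ratio":
            values = np.exp(raw)  # log-normal around a drifting geometric mean
        else:
            values = raw
        series[var] = MonthlySeries(
            variable=var, values=values, years=years, mode=mode, grid=grid
        )
    return series


# ---------------------------------------------------------------------------
# Soils

def make_soil_texture(scenario: SyntheticScenario, grid: Optional[GridSpec] = None):
    """Spatially autocorrelated sand/clay rasters and AWC totals.

    Returns ``(sand, clay, awc_total)`` arrays on the given grid
    (default: the scenario's fine grid).  Texture is uniform with
    depth; the 8-layer column hydraulics are summed to a whole-column
    available water capacity (mm).
    """
    grid = grid or scenario.fine
    rng = scenario.rng("soil")
    sand = 45.0 + _correlated_noise(rng, grid.shape, 15.0, length=6.0)
    clay = 20.0 + _correlated_noise(rng, grid.shape, 8.0, length=6.0)
    sand = np.clip(sand, 5.0, 90.0)
    clay = np.clip(clay, 5.0, np.minimum(60.0, 95.0 - sand))
    # texture constant over the 8 layers: AWC scales with the 1000-mm column
    _, awc_frac, _ = derive_soil_hydraulics(sand, clay, 1.0)
    awc_total = awc_frac * 1000.0
    return sand, clay, awc_total


# ---------------------------------------------------------------------------
# Truth vegetation and synthetic observations

def make_truth_vegetation(
    scenario: SyntheticScenario,
    summaries: dict,
    rules: RuleConfig = RuleConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """A biome truth raster and a noisy "observed" class raster.

    The truth is ``classify_grid`` applied to the supplied cell
    summaries.  The observed raster uses the :data:`OBSERVED_LEGEND`
    codes: forest/grass/shrub from the truth's mega-class, each cell's
    label flipped to one of the other two classes with probability
    ``scenario.label_flip_rate``, plus planted agriculture and urban
    patches for exclusion tests.  Cells outside the three compared
    classes (alpine, barren) are labelled wetland so both sides exclude
    them.
    """
    from .evaluate import DEFAULT_BIOME_TO_FGS  # local import avoids a cycle

    truth = classify_grid(summaries, rules=rules)
    codes = truth.codes
    rng = scenario.rng("vegetation")

    fgs = np.zeros(codes.shape, dtype=np.int16)
    for biome_code, target in DEFAULT_BIOME_TO_FGS.items():
        sel = codes == biome_code
        fgs[sel] = {"forest": 1, "grass": 2, "shrub": 3, "exclude": 12}[target]

    observed = fgs.copy()
    flip = scenario.label_flip_rate
    if flip > 0:
        in_play = (fgs >= 1) & (fgs <= 3)
        do_flip = in_play & (rng.random(fgs.shape) < flip)
        offset = rng.integers(1, 3, size=fgs.shape)  # one of the 2 other classes
        observed = np.where(do_flip, (fgs - 1 + offset) % 3 + 1, observed)

    # planted non-vegetation patches (agriculture, urban) in fixed corners
    nr, nc = codes.shape
    observed[: max(1, nr // 10), : max(1, nc // 10)] = 10
    observed[-max(1, nr // 20):, -max(1, nc // 20):] = 11
    return codes, observed
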