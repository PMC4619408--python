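"""Reduced plant-functional-type vegetation model.

The model screens ten PFTs against bioclimatic limits (minimum/maximum
coldest-month temperature, minimum growing degree days, minimum annual
temperature range), then distributes foliage projective cover (FPC)
among the survivors with a simple equilibrium productivity rule driven
by growing degree days, a bucket-model moisture index, and a
logarithmic CO2 response.  It is an explicit stand-in for a full
process DGVM: the downstream biome classifier consumes only the
:class:`CellSummary` interface, so a process model can replace this
module without touching the classifier.

Bioclimatic indices follow the usual DGVM conventions: GDD5 is the
annual sum of pseudo-daily degree-day excesses over a 5 degC base, with
daily temperatures linearly interpolated between monthly means placed
at month midpoints on a 365-day year, averaged over a 30-year window.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fields import MonthlySeries
from .soil import SoilColumn

__all__ = [
    "PFTParams",
    "load_pft_params",
    "PFT_NAMES",
    "BioclimIndices",
    "CellSummary",
    "bioclim_indices",
    "screen_pfts",
    "thornthwaite_pet",
    "water_balance",
    "simulate_cell",
    "simulate_grid",
]

# ---------------------------------------------------------------------------
# PFT parameters

@dataclass(frozen=True)
class PFTParams:
    """One plant functional type and its bioclimatic limits.

    Unbounded limits are represented as ``None``.  Units: temperatures
    degC, ``gdd5_min`` degree-days.
    """

    name: str
    life_form: str  # woody | herbaceous
    thermal_class: str  # tropical | temperate | boreal
    leaf_class: str  # needleleaf | broadleaf | herb
    phenology: Optional[str]
    tc_min: Optional[float] = None
    tc_max: Optional[float] = None
    gdd5_min: Optional[float] = None
    twtc_min: Optional[float] = None

    def __post_init__(self) -> None:
        if self.life_form not in ("woody", "herbaceous"):
            raise ValueError(f"bad life form {self.life_form!r}")
        if self.tc_min is not None and self.tc_max is not None:
            if self.tc_min > self.tc_max:
                raise ValueError(f"{self.name}: tc_min > tc_max")

    @property
    def is_woody(self) -> bool:
        return self.life_form == "woody"


def load_pft_params() -> list[PFTParams]:
    """Load the shipped 10-PFT parameter table (CSV, versioned with the code)."""
    text = resources.files("finedgvm.data").joinpath("pft_params.csv").read_text()
    df = pd.read_csv(io.StringIO(text))
    out = []
    for rec in df.to_dict("records"):
        def opt(v):
            return None if pd.isna(v) else float(v)

        out.append(
            PFTParams(
                name=rec["name"],
                life_form=rec["life_form"],
                thermal_class=rec["thermal_class"],
                leaf_class=rec["leaf_class"],
                phenology=None if pd.isna(rec["phenology"]) else rec["phenology"],
                tc_min=opt(rec["tc_min"]),
                tc_max=opt(rec["tc_max"]),
                gdd5_min=opt(rec["gdd5_min"]),
                twtc_min=opt(rec["twtc_min"]),
            )
        )
    return out


DEFAULT_PFTS: list[PFTParams] = load_pft_params()
PFT_NAMES: tuple[str, ...] = tuple(p.name for p in DEFAULT_PFTS)

# ---------------------------------------------------------------------------
# Reduced-model constants (stand-in calibration, not process parameters)

#: Reference CO2 concentration (ppm) at which the CO2 multiplier is 1.
CO2_REF_PPM = 368.0
#: Sensitivity of the logarithmic CO2 multiplier g(c) = 1 + k ln(c/368).
CO2_SENSITIVITY = 0.2
#: Half-saturation (degree-days) of the GDD5 productivity response.
GDD5_HALF_SAT = 500.0
#: Maximum total woody FPC under ideal conditions.
WOODY_COVER_CAP = 0.95
#: Fraction of non-woody space herbaceous PFTs can occupy at moisture 1.
HERB_FILL = 0.8
#: Fire-return-interval scale (yr); FRI = FRI_BASE / (fuel * dryness).
#: Chosen so fire-prone low-cover cells (fuel*dryness ~ 0.25-0.31) fall
#: below the 63-yr savanna split while mesic forests (< 0.17) stay above.
FRI_BASE_YEARS = 15.0
FRI_MIN_YEARS = 1.0
FRI_MAX_YEARS = 1.0e4
#: Coldest-month temperature (degC) of peak affinity, per thermal class.
TC_AFFINITY_CENTER = {"boreal": -15.0, "temperate": 5.0, "tropical": 22.0}
TC_AFFINITY_SD = 10.0
#: Height (m) a woody PFT reaches at productivity score 1.
HEIGHT_CAP_M = {"boreal": 18.0, "temperate": 30.0, "tropical": 35.0}

# ---------------------------------------------------------------------------
# Bioclimatic indices

_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], float)


def _daily_interp_weights() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map each of 365 days to a pair of month indices and a blend weight.

    Day d (centre at d + 0.5 in [0, 365)) interpolates linearly between
    the two nearest month midpoints, wrapping periodically at the year
    boundary.
    """
    mid = np.cumsum(_MONTH_LENGTHS) - _MONTH_LENGTHS / 2.0
    ext_mid = np.concatenate([[mid[-1] - 365.0], mid, [mid[0] + 365.0]])
    ext_idx = np.concatenate([[11], np.arange(12), [0]])
    days = np.arange(365) + 0.5
    seg = np.searchsorted(ext_mid, days) - 1
    m0 = ext_idx[seg]
    m1 = ext_idx[seg + 1]
    w1 = (days - ext_mid[seg]) / (ext_mid[seg + 1] - ext_mid[seg])
    return m0, m1, w1


_DAY_M0, _DAY_M1, _DAY_W1 = _daily_interp_weights()


@dataclass
class BioclimIndices:
    """30-year-mean bioclimatic indices for one cell or a raster.

    gdd5: growing degree days (5 degC base); tc/tw: coldest/warmest
    calendar-month mean temperature (degC).
    """

    gdd5: Union[float, np.ndarray]
    tc: Union[float, np.ndarray]
    tw: Union[float, np.ndarray]
    window: int = 30


def _series_values(series, variable_hint: str) -> np.ndarray:
    if isinstance(series, MonthlySeries):
        return series.values
    arr = np.asarray(series, dtype=float)
    if arr.ndim < 2 or arr.shape[1] != 12:
        raise ValueError(f"{variable_hint} series must have shape (n_years, 12, ...)")
    return arr


def annual_gdd5(tmean_year: np.ndarray) -> np.ndarray:
    """GDD5 for one year of monthly means, pseudo-daily interpolation.

    ``tmean_year`` has shape (12, *spatial).
    """
    t0 = tmean_year[_DAY_M0]
    t1 = tmean_year[_DAY_M1]
    w = _DAY_W1.reshape((365,) + (1,) * (tmean_year.ndim - 1))
    daily = t0 * (1.0 - w) + t1 * w
    return np.maximum(daily - 5.0, 0.0).sum(axis=0)


def bioclim_indices(tmean_series, window: int = 30) -> BioclimIndices:
    """Window-mean GDD5 and coldest/warmest month temperatures.

    Uses the trailing ``window`` years of the series.  Raises if the
    series is shorter than the window.
    """
    values = _series_values(tmean_series, "temperature")
    if values.shape[0] < window:
        raise ValueError(
            f"series holds {values.shape[0]} years, fewer than window={window}"
        )
    values = values[values.shape[0] - window :]
    monthly_mean = values.mean(axis=0)  # (12, *spatial)
    tc = monthly_mean.min(axis=0)
    tw = monthly_mean.max(axis=0)
    gdd = np.zeros(values.shape[2:], dtype=float)
    for y in range(window):  # chunked per year to bound memory
        gdd += annual_gdd5(values[y])
    gdd /= window
    if gdd.ndim == 0:
        return BioclimIndices(float(gdd), float(tc), float(tw), window)
    return BioclimIndices(gdd, tc, tw, window)


# ---------------------------------------------------------------------------
# PFT screening

def _survival_mask(
    indices: BioclimIndices, params: Sequence[PFTParams]
) -> np.ndarray:
    """Boolean survival array of shape (n_pft, *spatial)."""
    gdd5 = np.asarray(indices.gdd5, dtype=float)
    tc = np.asarray(indices.tc, dtype=float)
    tw = np.asarray(indices.tw, dtype=float)
    out = np.ones((len(params),) + gdd5.shape, dtype=bool)
    for i, p in enumerate(params):
        ok = np.ones_like(out[i])
        if p.tc_min is not None:
            ok &= tc >= p.tc_min
        if p.tc_max is not None:
            ok &= tc <= p.tc_max
        if p.gdd5_min is not None:
            ok &= gdd5 >= p.gdd5_min
        if p.twtc_min is not None:
            ok &= (tw - tc) >= p.twtc_min
        out[i] = ok
    return out


def screen_pfts(
    indices: BioclimIndices, params: Optional[Sequence[PFTParams]] = None
) -> list[PFTParams]:
    """PFTs whose every bounded bioclimatic limit is met by ``indices``."""
    if params is None:
        params = DEFAULT_PFTS
    mask = _survival_mask(indices, params)
    if mask.ndim != 1:
        raise ValueError("screen_pfts expects scalar indices; see _survival_mask")
    return [p for p, ok in zip(params, mask) if ok]


# ---------------------------------------------------------------------------
# Water balance

def thornthwaite_pet(tmean_monthly: np.ndarray) -> np.ndarray:
    """Monthly potential evapotranspiration (mm) from monthly temperature.

    Classic Thornthwaite formulation without day-length correction
    (12-hour days, 30-day months): heat index I = sum (T/5)^1.514 over
    months with T > 0, exponent a = 6.75e-7 I^3 - 7.71e-5 I^2 +
    1.792e-2 I + 0.49239, PET = 16 (10 T / I)^a, zero for T <= 0.
    """
    t = np.asarray(tmean_monthly, dtype=float)
    if t.shape[0] != 12:
        raise ValueError("expected 12 monthly layers")
    tpos = np.maximum(t, 0.0)
    heat = ((tpos / 5.0) ** 1.514).sum(axis=0)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    with np.errstate(divide="ignore", invalid="ignore"):
        pet = 16.0 * (10.0 * tpos / np.where(heat > 0, heat, np.nan)) ** a
    pet = np.where((tpos > 0) & (heat > 0), pet, 0.0)
    return pet


def water_balance(
    precip_series,
    tmean_series,
    awc_total,
    max_cycles: int = 100,
    tol: float = 1e-10,
) -> Union[float, np.ndarray]:
    """Equilibrium moisture index from a single-bucket water balance.

    The mean annual cycle of precipitation and Thornthwaite PET drives a
    bucket of capacity ``awc_total`` (mm): each month the store gains
    precipitation, actual evapotranspiration (AET) removes
    ``min(PET, store + P)``, and the store is capped at capacity.  The
    cycle is iterated to a periodic steady state and the index is the
    annual moisture ratio alpha = sum(AET) / sum(PET) (1.0 if PET is
    zero all year), which weights months by evaporative demand.
    Result lies in [0, 1].
    """
    p = _series_values(precip_series, "precipitation").mean(axis=0)
    t = _series_values(tmean_series, "temperature").mean(axis=0)
    if np.any(p < 0):
        raise ValueError("precipitation must be non-negative")
    awc = np.asarray(awc_total, dtype=float)
    if np.any(awc <= 0):
        raise ValueError("awc_total must be positive")
    pet = thornthwaite_pet(t)

    store = np.broadcast_to(awc, p.shape[1:]).astype(float).copy()
    for _ in range(max_cycles):
        start = store.copy()
        for m in range(12):
            avail = store + p[m]
            aet = np.minimum(pet[m], avail)
            store = np.minimum(awc, avail - aet)
        if np.max(np.abs(store - start)) < tol:
            break
    aet_sum = np.zeros_like(store)
    pet_sum = pet.sum(axis=0)
    for m in range(12):
        avail = store + p[m]
        aet = np.minimum(pet[m], avail)
        store = np.minimum(awc, avail - aet)
        aet_sum += aet
    index = np.where(pet_sum > 0, aet_sum / np.where(pet_sum > 0, pet_sum, 1.0), 1.0)
    index = np.clip(index, 0.0, 1.0)
    return float(index) if index.ndim == 0 else index


# ---------------------------------------------------------------------------
# Cell summaries and the reduced dynamics stand-in

@dataclass
class CellSummary:
    """Per-cell vegetation summary consumed by the biome classifier.

    ``fpc`` and ``height`` are vectors aligned with :data:`PFT_NAMES`
    (herbaceous heights are 0).  ``tc`` and ``annual_precip`` are
    optional covariates used only by the maritime classifier rule.
    """

    fpc: np.ndarray
    height: np.ndarray
    fire_return_interval: float
    gdd5: float
    moisture_index: float
    tc: Optional[float] = None
    annual_precip: Optional[float] = None

    def __post_init__(self) -> None:
        self.fpc = np.asarray(self.fpc, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        if self.fpc.shape != (len(PFT_NAMES),):
            raise ValueError(f"fpc must have length {len(PFT_NAMES)}")
        if self.height.shape != self.fpc.shape:
            raise ValueError("height must align with fpc")
        if np.any(self.fpc < -1e-12) or self.fpc.sum() > 1.0 + 1e-9:
            raise ValueError("fpc must be non-negative and sum to <= 1")
        if np.any(self.height < 0):
            raise ValueError("heights must be non-negative")
        if not self.fire_return_interval > 0:
            raise ValueError("fire return interval must be positive")

    @property
    def total_fpc(self) -> float:
        return float(self.fpc.sum())

    def woody_fpc(self, params: Sequence[PFTParams] = None) -> float:
        params = params or DEFAULT_PFTS
        woody = np.array([p.is_woody for p in params])
        return float(self.fpc[woody].sum())


def co2_multiplier(co2_ppm: float) -> float:
    """Logarithmic CO2 productivity multiplier, g(368) = 1, increasing."""
    if np.any(np.asarray(co2_ppm) <= 0):
        raise ValueError("co2 must be positive")
    return 1.0 + CO2_SENSITIVITY * np.log(np.asarray(co2_ppm, float) / CO2_REF_PPM)


def simulate_grid(
    tmean_series,
    precip_series,
    awc_total,
    co2_ppm: float = CO2_REF_PPM,
    params: Optional[Sequence[PFTParams]] = None,
    window: int = 30,
) -> dict:
    """Vectorised reduced-model run over the trailing ``window`` years.

    Returns a dict of arrays: ``fpc`` and ``height`` with leading PFT
    axis, plus ``fire_return_interval``, ``gdd5``, ``moisture_index``,
    ``tc`` and ``annual_precip`` on the spatial shape.
    """
    if params is None:
        params = DEFAULT_PFTS
    idx = bioclim_indices(tmean_series, window=window)
    moisture = water_balance(precip_series, tmean_series, awc_total)
    gdd5 = np.asarray(idx.gdd5, dtype=float)
    tc = np.asarray(idx.tc, dtype=float)
    moisture = np.asarray(moisture, dtype=float)
    surv = _survival_mask(idx, params)

    g = co2_multiplier(co2_ppm)
    score = np.clip(gdd5 / (gdd5 + GDD5_HALF_SAT) * moisture * g, 0.0, 1.0)

    woody = np.array([p.is_woody for p in params])
    affinity = np.zeros_like(surv, dtype=float)
    for i, p in enumerate(params):
        if p.is_woody:
            center = TC_AFFINITY_CENTER[p.thermal_class]
            affinity[i] = np.exp(-(((tc - center) / TC_AFFINITY_SD) ** 2))
    affinity *= surv & woody[(...,) + (None,) * gdd5.ndim]
    w_sum = affinity.sum(axis=0)
    any_woody = w_sum > 0
    woody_total = np.where(any_woody, WOODY_COVER_CAP * score, 0.0)
    shares = np.where(any_woody, affinity / np.where(any_woody, w_sum, 1.0), 0.0)
    fpc = woody_total * shares

    herb = ~woody
    herb_surv = surv & herb[(...,) + (None,) * gdd5.ndim]
    n_herb = herb_surv.sum(axis=0)
    # herbaceous cover also needs warmth and water: scale by the same
    # productivity score so frozen or hyper-arid cells stay near-barren
    herb_total = (1.0 - woody_total) * score * HERB_FILL
    fpc += np.where(
        herb_surv, herb_total / np.maximum(n_herb, 1), 0.0
    )

    height = np.zeros_like(fpc)
    for i, p in enumerate(params):
        if p.is_woody:
            height[i] = np.where(surv[i], HEIGHT_CAP_M[p.thermal_class] * score, 0.0)

    fuel = fpc.sum(axis=0)
    dryness = 1.0 - moisture
    hazard = fuel * dryness
    fri = np.where(
        hazard > 0,
        np.clip(FRI_BASE_YEARS / np.where(hazard > 0, hazard, 1.0),
                FRI_MIN_YEARS, FRI_MAX_YEARS),
        FRI_MAX_YEARS,
    )

    p_values = _series_values(precip_series, "precipitation")
    annual_precip = p_values[p_values.shape[0] - window :].sum(axis=1).mean(axis=0)

    return {
        "fpc": fpc,
        "height": height,
        "fire_return_interval": fri,
        "gdd5": gdd5,
        "moisture_index": moisture,
        "tc": tc,
        "annual_precip": np.asarray(annual_precip, dtype=float),
    }


def simulate_cell(
    climate: dict,
    soil: SoilColumn,
    co2_ppm: float = CO2_REF_PPM,
    params: Optional[Sequence[PFTParams]] = None,
    window: int = 30,
) -> CellSummary:
    """Run the reduced model for one cell.

    ``climate`` maps ``"tmean"`` and ``"precip"`` to
    :class:`~finedgvm.fields.MonthlySeries` (or ``(n_years, 12)``
    arrays) covering spin-up plus transient years; the trailing
    ``window`` years drive the equilibrium summary.  Deterministic
    given its inputs.
    """
    out = simulate_grid(
        climate["tmean"],
        climate["precip"],
        soil.awc_total,
        co2_ppm=co2_ppm,
        params=params,
        window=window,
    )
    return CellSummary(
        fpc=out["fpc"],
        height=out["height"],
        fire_return_interval=float(out["fire_return_interval"]),
        gdd5=float(out["gdd5"]),
        moisture_index=float(out["moisture_index"]),
        tc=float(out["tc"]),
        annual_precip=float(out["annual_precip"]),
    )
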