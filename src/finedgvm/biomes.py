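"""Biome assignment from simulated PFT cover, height, and fire regime.

The classifier is a fixed decision tree over a :class:`CellSummary`:

1. 30-year mean GDD5 <= 350 degree-days -> alpine grass/shrub (this
   rule precedes every other rule);
2. total FPC below a barren threshold -> barren;
3. woody FPC <= 0.30: fire return interval < 63 yr ->
   savanna/grassland/steppe, otherwise xeric shrub (dry) or
   shrub-steppe (moister);
4. woody FPC > 0.30: maximum woody height > 10 m -> forest,
   <= 10 m -> open forest/woodland;
5. thermal modifier from the dominant woody PFT (boreal-dominant ->
   cold, otherwise cool), with maritime and broadleaf-evergreen
   variants of the cool classes.

The 350 degree-day, 0.30 FPC, 63 yr and 10 m thresholds are the
published decision boundaries; the barren, moisture-split, maritime and
broadleaf-evergreen thresholds are explicit reconstructions exposed on
:class:`RuleConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

import numpy as np
import pandas as pd

from .grid import GridSpec
from .vegmodel import DEFAULT_PFTS, PFT_NAMES, CellSummary

__all__ = ["Biome", "RuleConfig", "BiomeMap", "classify", "classify_grid"]


class Biome(IntEnum):
    """The 11 biome categories, in reporting-table order.  0 = masked."""

    MASKED = 0
    ALPINE_GRASS_SHRUB = 1
    COLD_FOREST = 2
    COOL_FOREST = 3
    MARITIME_COOL_FOREST = 4
    COLD_OPEN_FOREST_WOODLAND = 5
    COOL_OPEN_FOREST_WOODLAND = 6
    COOL_OPEN_FOREST_WOODLAND_BROADLEAF_EVERGREEN = 7
    SAVANNA_GRASSLAND_STEPPE = 8
    SHRUB_STEPPE = 9
    XERIC_SHRUB = 10
    BARREN = 11


BIOME_LABELS = {
    Biome.ALPINE_GRASS_SHRUB: "Alpine grass/shrub",
    Biome.COLD_FOREST: "Cold forest",
    Biome.COOL_FOREST: "Cool forest",
    Biome.MARITIME_COOL_FOREST: "Maritime cool forest",
    Biome.COLD_OPEN_FOREST_WOODLAND: "Cold open forest/woodland",
    Biome.COOL_OPEN_FOREST_WOODLAND: "Cool open forest/woodland",
    Biome.COOL_OPEN_FOREST_WOODLAND_BROADLEAF_EVERGREEN:
        "Cool open forest/woodland with broadleaf evergreen plant functional type",
    Biome.SAVANNA_GRASSLAND_STEPPE: "Savanna/grassland/steppe",
    Biome.SHRUB_STEPPE: "Shrub-steppe",
    Biome.XERIC_SHRUB: "Xeric shrub",
    Biome.BARREN: "Barren",
}


@dataclass(frozen=True)
class RuleConfig:
    """Classifier thresholds.

    The first four are published decision boundaries; the rest are
    configurable reconstructions of branches the source scheme leaves
    implicit.
    """

    alpine_gdd5_max: float = 350.0  # alpine when GDD5 <= this
    savanna_woody_fpc_max: float = 0.30  # low-cover branch when woody FPC <= this
    savanna_fri_max_years: float = 63.0  # savanna when FRI < this
    forest_height_min_m: float = 10.0  # forest when max woody height > this
    barren_total_fpc: float = 0.10  # barren when total FPC < this
    xeric_moisture_max: float = 0.15  # xeric shrub when moisture index < this
    maritime_tc_min: float = -2.0  # maritime needs tc >= this ...
    maritime_precip_min_mm: float = 1200.0  # ... and annual precip >= this
    broadleaf_evergreen_fpc_min: float = 0.05  # BE variant needs TeBE FPC >= this


_TEBE_INDEX = PFT_NAMES.index("temperate broadleaf evergreen")
_WOODY = np.array([p.is_woody for p in DEFAULT_PFTS])
_BOREAL_WOODY = np.array(
    [p.is_woody and p.thermal_class == "boreal" for p in DEFAULT_PFTS]
)


def classify(cell: CellSummary, rules: RuleConfig = RuleConfig()) -> Biome:
    """Assign a biome to one cell summary.  Total and deterministic."""
    if cell.gdd5 <= rules.alpine_gdd5_max:
        return Biome.ALPINE_GRASS_SHRUB
    if cell.total_fpc < rules.barren_total_fpc:
        return Biome.BARREN
    woody_fpc = float(cell.fpc[_WOODY].sum())
    if woody_fpc <= rules.savanna_woody_fpc_max:
        if cell.fire_return_interval < rules.savanna_fri_max_years:
            return Biome.SAVANNA_GRASSLAND_STEPPE
        if cell.moisture_index < rules.xeric_moisture_max:
            return Biome.XERIC_SHRUB
        return Biome.SHRUB_STEPPE

    # Closed-canopy branch: thermal class from the dominant woody PFT
    # (argmax FPC; ties broken by table order via argmax's first-hit rule).
    woody_cover = np.where(_WOODY, cell.fpc, -np.inf)
    dominant = int(np.argmax(woody_cover))
    cold = bool(_BOREAL_WOODY[dominant])
    max_height = float(cell.height[_WOODY].max())

    if max_height > rules.forest_height_min_m:
        if cold:
            return Biome.COLD_FOREST
        maritime = (
            cell.tc is not None
            and cell.annual_precip is not None
            and cell.tc >= rules.maritime_tc_min
            and cell.annual_precip >= rules.maritime_precip_min_mm
        )
        return Biome.MARITIME_COOL_FOREST if maritime else Biome.COOL_FOREST
    if cold:
        return Biome.COLD_OPEN_FOREST_WOODLAND
    if cell.fpc[_TEBE_INDEX] >= rules.broadleaf_evergreen_fpc_min:
        return Biome.COOL_OPEN_FOREST_WOODLAND_BROADLEAF_EVERGREEN
    return Biome.COOL_OPEN_FOREST_WOODLAND


@dataclass
class BiomeMap:
    """Classified biome raster; code 0 marks masked cells."""

    codes: np.ndarray
    grid: Optional[GridSpec] = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        valid = set(int(b) for b in Biome)
        present = set(np.unique(self.codes).tolist())
        if not present <= valid:
            raise ValueError(f"invalid biome codes {sorted(present - valid)}")

    def area_percent(self) -> pd.Series:
        """Percent of unmasked cells per biome, in reporting order."""
        unmasked = self.codes[self.codes != Biome.MASKED]
        n = unmasked.size
        data = {
            BIOME_LABELS[b]: (
                100.0 * np.count_nonzero(unmasked == b) / n if n else np.nan
            )
            for b in Biome
            if b != Biome.MASKED
        }
        return pd.Series(data, name="percent_of_area")


def classify_grid(
    summaries: dict,
    rules: RuleConfig = RuleConfig(),
    mask: Optional[np.ndarray] = None,
    grid: Optional[GridSpec] = None,
) -> BiomeMap:
    """Vectorised classification of a raster of cell summaries.

    ``summaries`` is the dict produced by
    :func:`finedgvm.vegmodel.simulate_grid` (``fpc``/``height`` with a
    leading PFT axis).  Masked input cells yield masked output.
    """
    fpc = np.asarray(summaries["fpc"], dtype=float)
    height = np.asarray(summaries["height"], dtype=float)
    gdd5 = np.asarray(summaries["gdd5"], dtype=float)
    fri = np.asarray(summaries["fire_return_interval"], dtype=float)
    moisture = np.asarray(summaries["moisture_index"], dtype=float)
    tc = np.asarray(summaries.get("tc"), dtype=float) if "tc" in summaries else None
    precip = (
        np.asarray(summaries["annual_precip"], dtype=float)
        if "annual_precip" in summaries
        else None
    )

    total = fpc.sum(axis=0)
    woody_fpc = fpc[_WOODY].sum(axis=0)
    woody_cover = np.where(
        _WOODY[(...,) + (None,) * gdd5.ndim], fpc, -np.inf
    )
    dominant = np.argmax(woody_cover, axis=0)
    cold = _BOREAL_WOODY[dominant]
    max_height = height[_WOODY].max(axis=0)

    codes = np.full(gdd5.shape, int(Biome.MASKED), dtype=np.int16)
    remaining = np.ones(gdd5.shape, dtype=bool)
    if mask is not None:
        remaining &= ~np.asarray(mask, dtype=bool)

    def assign(cond, biome):
        nonlocal remaining
        sel = remaining & cond
        codes[sel] = int(biome)
        remaining &= ~sel

    assign(gdd5 <= rules.alpine_gdd5_max, Biome.ALPINE_GRASS_SHRUB)
    assign(total < rules.barren_total_fpc, Biome.BARREN)
    low = woody_fpc <= rules.savanna_woody_fpc_max
    assign(low & (fri < rules.savanna_fri_max_years), Biome.SAVANNA_GRASSLAND_STEPPE)
    assign(low & (moisture < rules.xeric_moisture_max), Biome.XERIC_SHRUB)
    assign(low, Biome.SHRUB_STEPPE)
    tall = max_height > rules.forest_height_min_m
    assign(tall & cold, Biome.COLD_FOREST)
    if tc is not None and precip is not None:
        maritime = (tc >= rules.maritime_tc_min) & (
            precip >= rules.maritime_precip_min_mm
        )
        assign(tall & maritime, Biome.MARITIME_COOL_FOREST)
    assign(tall, Biome.COOL_FOREST)
    assign(cold, Biome.COLD_OPEN_FOREST_WOODLAND)
    assign(
        fpc[_TEBE_INDEX] >= rules.broadleaf_evergreen_fpc_min,
        Biome.COOL_OPEN_FOREST_WOODLAND_BROADLEAF_EVERGREEN,
    )
    assign(np.ones_like(remaining), Biome.COOL_OPEN_FOREST_WOODLAND)
    return BiomeMap(codes=codes, grid=grid)
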