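"""Forest/grass/shrub reclassification and map-agreement statistics.

Simulated biome maps and observed vegetation rasters are collapsed to
three mega-classes (forest, grass, shrub) through an explicit mapping
table; classes a vegetation model does not simulate (agriculture,
urban, wetlands, ...) are marked excluded and dropped from the
comparison.  Agreement is reported as a 3x3 confusion matrix with row
percentages and an overall percent-correct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .biomes import Biome, BiomeMap

__all__ = [
    "FGS_CLASSES",
    "EXCLUDE",
    "DEFAULT_BIOME_TO_FGS",
    "FGSMap",
    "ConfusionMatrix",
    "reclassify_to_fgs",
    "agreement",
]

FGS_CLASSES = ("forest", "grass", "shrub")
EXCLUDE = "exclude"

# Integer codes used inside FGSMap rasters.
_FGS_CODE = {"forest": 1, "grass": 2, "shrub": 3, EXCLUDE: 4}
_MASK_CODE = 0

# Default biome -> forest/grass/shrub mapping.  This is a configurable
# package default, not an authoritative crosswalk: forest and open
# forest/woodland classes count as forest; alpine and barren are
# excluded as classes outside the three-way comparison.
DEFAULT_BIOME_TO_FGS = {
    int(Biome.ALPINE_GRASS_SHRUB): EXCLUDE,
    int(Biome.COLD_FOREST): "forest",
    int(Biome.COOL_FOREST): "forest",
    int(Biome.MARITIME_COOL_FOREST): "forest",
    int(Biome.COLD_OPEN_FOREST_WOODLAND): "forest",
    int(Biome.COOL_OPEN_FOREST_WOODLAND): "forest",
    int(Biome.COOL_OPEN_FOREST_WOODLAND_BROADLEAF_EVERGREEN): "forest",
    int(Biome.SAVANNA_GRASSLAND_STEPPE): "grass",
    int(Biome.SHRUB_STEPPE): "shrub",
    int(Biome.XERIC_SHRUB): "shrub",
    int(Biome.BARREN): EXCLUDE,
}


@dataclass
class FGSMap:
    """Forest/grass/shrub raster with exclusion and mask codes."""

    codes: np.ndarray  # 0 masked, 1 forest, 2 grass, 3 shrub, 4 excluded
    provenance: str = "simulated"  # or "observed"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        bad = set(np.unique(self.codes).tolist()) - {0, 1, 2, 3, 4}
        if bad:
            raise ValueError(f"invalid FGS codes {sorted(bad)}")

    @property
    def comparable(self) -> np.ndarray:
        """True where the cell carries one of the three compared classes."""
        return (self.codes >= 1) & (self.codes <= 3)


def reclassify_to_fgs(
    source: Union[BiomeMap, np.ndarray],
    mapping: Optional[dict] = None,
    provenance: str = "simulated",
) -> FGSMap:
    """Collapse a classed raster to forest/grass/shrub via a mapping table.

    ``mapping`` maps every source class code to ``"forest"``,
    ``"grass"``, ``"shrub"`` or ``"exclude"``.  Raises KeyError listing
    any raster codes absent from the mapping (masked 0 cells pass
    through as masked).
    """
    if isinstance(source, BiomeMap):
        raster = source.codes
        if mapping is None:
            mapping = DEFAULT_BIOME_TO_FGS
    else:
        raster = np.asarray(source)
        if mapping is None:
            raise ValueError("a mapping table is required for non-biome rasters")
    present = set(int(v) for v in np.unique(raster)) - {_MASK_CODE}
    missing = sorted(present - set(int(k) for k in mapping))
    if missing:
        raise KeyError(
            f"raster contains class codes with no mapping entry: {missing}"
        )
    bad_targets = {
        v for v in mapping.values() if v not in FGS_CLASSES and v != EXCLUDE
    }
    if bad_targets:
        raise ValueError(f"invalid mapping targets {sorted(bad_targets)}")

    out = np.full(raster.shape, _MASK_CODE, dtype=np.int16)
    for code, target in mapping.items():
        out[raster == int(code)] = _FGS_CODE[target]
    return FGSMap(codes=out, provenance=provenance)


@dataclass
class ConfusionMatrix:
    """3x3 agreement counts, observed classes in rows, simulated in columns."""

    counts: pd.DataFrame

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "ConfusionMatrix":
        df = pd.DataFrame(
            np.asarray(counts, dtype=np.int64),
            index=pd.Index(FGS_CLASSES, name="observed"),
            columns=pd.Index(FGS_CLASSES, name="simulated"),
        )
        return cls(counts=df)

    @property
    def row_percent(self) -> pd.DataFrame:
        """Per observed class, the percent simulated as each class."""
        totals = self.counts.sum(axis=1)
        return 100.0 * self.counts.div(totals.replace(0, np.nan), axis=0)

    @property
    def overall_percent(self) -> float:
        """Percent of comparable cells on the diagonal."""
        total = self.counts.to_numpy().sum()
        return float(100.0 * np.trace(self.counts.to_numpy()) / total)

    def rounded_table(self) -> pd.DataFrame:
        """Row percentages rounded to integers (presentation layout)."""
        return self.row_percent.round(0).astype("Int64")

    def transpose(self) -> "ConfusionMatrix":
        return ConfusionMatrix.from_counts(self.counts.to_numpy().T)


def agreement(sim: FGSMap, obs: FGSMap) -> ConfusionMatrix:
    """Cellwise agreement between simulated and observed FGS maps.

    Cells where either side is excluded or masked are dropped; raises if
    no comparable cells remain.
    """
    if sim.codes.shape != obs.codes.shape:
        raise ValueError("maps must share a grid")
    keep = sim.comparable & obs.comparable
    if not keep.any():
        raise ValueError("no comparable cells (all excluded or masked)")
    s = sim.codes[keep] - 1
    o = obs.codes[keep] - 1
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (o, s), 1)
    return ConfusionMatrix.from_counts(counts)
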