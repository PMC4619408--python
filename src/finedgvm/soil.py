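"""Layered soil columns: texture-derived hydraulics and root distributions.

The soil column is the top metre of the profile split into eight layers
(50, 50, 100, 100, 100, 200, 200, 200 mm).  Per-layer water contents at
wilting point (-1500 kPa), field capacity (-33 kPa) and saturation are
derived from sand/clay percentages with the Saxton et al. (1986)
texture regressions, and vertical root distributions follow the
exponential cumulative profile Y(d) = 1 - beta**d (d in cm) of Jackson
et al. (1996).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_LAYER_THICKNESS_MM",
    "DEFAULT_ROOT_BETA",
    "SAXTON_1986",
    "SoilColumn",
    "derive_soil_hydraulics",
    "root_fractions",
    "build_soil_column",
]

#: Layer thicknesses (mm), top to bottom; sum to the 1-m profile.
DEFAULT_LAYER_THICKNESS_MM = (50.0, 50.0, 100.0, 100.0, 100.0, 200.0, 200.0, 200.0)

#: Default root-profile extinction coefficient (temperate vegetation).
DEFAULT_ROOT_BETA = 0.966

# Saxton, Rawls, Romberger & Papendick (1986) regression constants for the
# water-retention curve  psi = A * theta**B  (psi in kPa, theta volumetric)
# and for porosity.  S = sand %, C = clay %.
SAXTON_1986 = {
    # A = 100 * exp(a + b*C + c*S^2 + d*S^2*C)
    "a": -4.396,
    "b": -0.0715,
    "c": -4.880e-4,
    "d": -4.285e-5,
    # B = e + f*C^2 + g*S^2*C
    "e": -3.140,
    "f": -0.00222,
    "g": -3.484e-5,
    # theta_sat = h + j*S + k*log10(C)
    "h": 0.332,
    "j": -7.251e-4,
    "k": 0.1276,
    # stated applicability window of the texture regression
    "sand_valid": (5.0, 95.0),
    "clay_valid": (5.0, 60.0),
}

#: Matric potentials (kPa, magnitude) defining wilting point and field capacity.
PSI_WILT_KPA = 1500.0
PSI_FC_KPA = 33.0


@dataclass
class SoilColumn:
    """An 8-layer soil column with derived hydraulics and root fractions.

    All water quantities are per-layer millimetres of water (volumetric
    fraction times layer thickness).  ``awc`` is plant-available water:
    field capacity minus wilting point.
    """

    layer_thickness: np.ndarray  # mm
    sand: np.ndarray  # %
    clay: np.ndarray  # %
    wilting_point: np.ndarray  # mm
    awc: np.ndarray  # mm
    saturation: np.ndarray  # mm
    root_fraction: np.ndarray  # unitless, sums to 1

    def __post_init__(self) -> None:
        for name in (
            "layer_thickness",
            "sand",
            "clay",
            "wilting_point",
            "awc",
            "saturation",
            "root_fraction",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.layer_thickness.shape[0]
        if any(
            getattr(self, f).shape[0] != n
            for f in ("sand", "clay", "wilting_point", "awc", "saturation", "root_fraction")
        ):
            raise ValueError("all per-layer arrays must share a leading layer axis")
        if np.any(self.sand + self.clay > 100.0 + 1e-9) or np.any(self.sand < 0) or np.any(self.clay < 0):
            raise ValueError("sand and clay must be non-negative with sand+clay <= 100")
        if abs(float(np.sum(self.root_fraction)) - 1.0) > 1e-9:
            raise ValueError("root fractions must sum to 1")

    @property
    def awc_total(self) -> float:
        """Whole-column plant-available water (mm)."""
        return float(np.sum(self.awc))


def _clamp_texture(sand: np.ndarray, clay: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s_lo, s_hi = SAXTON_1986["sand_valid"]
    c_lo, c_hi = SAXTON_1986["clay_valid"]
    out = (sand < s_lo) | (sand > s_hi) | (clay < c_lo) | (clay > c_hi)
    if np.any(out):
        warnings.warn(
            f"{int(np.sum(out))} texture value(s) outside the Saxton regression "
            f"validity domain (sand {s_lo}-{s_hi}%, clay {c_lo}-{c_hi}%); "
            "clamped before evaluation",
            stacklevel=3,
        )
    return np.clip(sand, s_lo, s_hi), np.clip(clay, c_lo, c_hi)


def derive_soil_hydraulics(sand, clay, thickness):
    """Per-layer wilting point, available water capacity and saturation (mm).

    Volumetric water contents at -1500 kPa (wilting), -33 kPa (field
    capacity) and saturation are computed from the Saxton et al. (1986)
    sand/clay regressions and multiplied by layer thickness.  Inputs may
    be scalars or arrays (broadcast together).

    Returns
    -------
    (wilting_point, awc, saturation) : ndarray or float triples, mm of water.
    """
    sand = np.asarray(sand, dtype=float)
    clay = np.asarray(clay, dtype=float)
    thickness = np.asarray(thickness, dtype=float)
    if np.any(sand < 0) or np.any(clay < 0) or np.any(sand + clay > 100.0 + 1e-9):
        raise ValueError("require sand, clay >= 0 and sand + clay <= 100")
    if np.any(thickness <= 0):
        raise ValueError("layer thickness must be positive")

    s, c = _clamp_texture(sand, clay)
    k = SAXTON_1986
    A = 100.0 * np.exp(k["a"] + k["b"] * c + k["c"] * s**2 + k["d"] * s**2 * c)
    B = k["e"] + k["f"] * c**2 + k["g"] * s**2 * c
    theta_wp = (PSI_WILT_KPA / A) ** (1.0 / B)
    theta_fc = (PSI_FC_KPA / A) ** (1.0 / B)
    theta_sat = k["h"] + k["j"] * s + k["k"] * np.log10(c)

    wp = theta_wp * thickness
    awc = (theta_fc - theta_wp) * thickness
    sat = theta_sat * thickness
    if wp.ndim == 0:
        return float(wp), float(awc), float(sat)
    return wp, awc, sat


def root_fractions(
    beta: float = DEFAULT_ROOT_BETA,
    layer_bounds=None,
) -> np.ndarray:
    """Per-layer root fractions from the exponential rooting profile.

    The cumulative fraction of roots above depth d (cm) is
    ``Y(d) = 1 - beta**d``; each layer receives ``Y(bottom) - Y(top)``,
    renormalised so the truncated 1-m column sums to exactly 1.

    Parameters
    ----------
    beta : float
        Extinction coefficient in (0, 1); larger values put roots deeper.
    layer_bounds : sequence of increasing depths (mm) starting at 0,
        defaults to the cumulative bounds of the standard 8-layer column.
    """
    if not (0.0 < beta < 1.0):
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    if layer_bounds is None:
        layer_bounds = np.concatenate(
            [[0.0], np.cumsum(DEFAULT_LAYER_THICKNESS_MM)]
        )
    bounds = np.asarray(layer_bounds, dtype=float)
    if bounds[0] != 0.0 or np.any(np.diff(bounds) <= 0):
        raise ValueError("layer bounds must increase from 0")
    depth_cm = bounds / 10.0
    cumulative = 1.0 - beta**depth_cm
    raw = np.diff(cumulative)
    return raw / raw.sum()


def build_soil_column(
    sand,
    clay,
    layer_thickness=DEFAULT_LAYER_THICKNESS_MM,
    beta: float = DEFAULT_ROOT_BETA,
) -> SoilColumn:
    """Assemble a :class:`SoilColumn` from per-layer texture."""
    thickness = np.asarray(layer_thickness, dtype=float)
    sand = np.broadcast_to(np.asarray(sand, dtype=float), thickness.shape).copy()
    clay = np.broadcast_to(np.asarray(clay, dtype=float), thickness.shape).copy()
    wp, awc, sat = derive_soil_hydraulics(sand, clay, thickness)
    bounds = np.concatenate([[0.0], np.cumsum(thickness)])
    return SoilColumn(
        layer_thickness=thickness,
        sand=sand,
        clay=clay,
        wilting_point=wp,
        awc=awc,
        saturation=sat,
        root_fraction=root_fractions(beta, bounds),
    )
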