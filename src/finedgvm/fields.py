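"""Gridded climate containers: monthly climatologies and time series.

These are thin, validated wrappers around numpy arrays.  A climatology
holds 12 monthly layers (a multi-year mean annual cycle); a monthly
series holds ``(n_years, 12, *spatial)`` values and a mode tag saying
whether they are absolute values, difference anomalies (temperature) or
ratio anomalies (precipitation, sunshine, cloud).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grid import GridSpec

__all__ = ["VARIABLES", "ClimatologyField", "MonthlySeries", "LapseRateField"]

#: Recognised climate variables and their units.
VARIABLES = {
    "tmean": "degC",
    "precip": "mm",
    "sunshine": "percent",
    "cloud": "percent",
}

_PERCENT_VARS = ("sunshine", "cloud")


def _check_variable(variable: str) -> None:
    if variable not in VARIABLES:
        raise ValueError(
            f"unknown variable {variable!r}; expected one of {sorted(VARIABLES)}"
        )


def _check_physical(variable: str, values: np.ndarray, what: str) -> None:
    finite = values[np.isfinite(values)]
    if variable in _PERCENT_VARS:
        if finite.size and (finite.min() < -1e-9 or finite.max() > 100.0 + 1e-9):
            raise ValueError(f"{variable} {what} must lie in [0, 100]")
    elif variable == "precip":
        if finite.size and finite.min() < -1e-9:
            raise ValueError(f"precip {what} must be non-negative")


@dataclass
class ClimatologyField:
    """Twelve monthly mean layers of one climate variable on one grid."""

    variable: str
    values: np.ndarray  # (12, *spatial)
    grid: Optional[GridSpec] = None
    base_period: tuple[int, int] = (1961, 1990)
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        _check_variable(self.variable)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != 12:
            raise ValueError("a climatology must have exactly 12 monthly layers")
        if self.grid is not None and self.values.shape[1:] != self.grid.shape:
            raise ValueError(
                f"spatial shape {self.values.shape[1:]} != grid {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = ~np.all(np.isfinite(self.values), axis=0)
        _check_physical(self.variable, self.values[:, ~self.mask], "climatology")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.values.shape[1:]


@dataclass
class MonthlySeries:
    """Per-cell monthly values for a run of years.

    ``values`` has shape ``(n_years, 12, *spatial)``.  ``mode`` is
    ``"absolute"``, ``"anomaly-difference"`` or ``"anomaly-ratio"``.
    """

    variable: str
    values: np.ndarray
    years: tuple[int, int]
    mode: str = "absolute"
    grid: Optional[GridSpec] = None

    def __post_init__(self) -> None:
        _check_variable(self.variable)
        if self.mode not in ("absolute", "anomaly-difference", "anomaly-ratio"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim < 2 or self.values.shape[1] != 12:
            raise ValueError("values must have shape (n_years, 12, ...)")
        start, end = self.years
        if end - start + 1 != self.values.shape[0]:
            raise ValueError(
                f"years {self.years} imply {end - start + 1} years but values "
                f"hold {self.values.shape[0]}"
            )
        if self.grid is not None and self.values.shape[2:] != self.grid.shape:
            raise ValueError("spatial shape does not match grid")
        finite = self.values[np.isfinite(self.values)]
        if self.mode == "absolute":
            _check_physical(self.variable, finite, "series")
        elif self.mode == "anomaly-ratio":
            if finite.size and finite.min() < -1e-12:
                raise ValueError("ratio anomalies must be non-negative")

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.values.shape[2:]

    def last_window(self, window: int) -> "MonthlySeries":
        """The trailing ``window`` years as a new series."""
        if window > self.n_years:
            raise ValueError(
                f"series holds {self.n_years} years, fewer than window={window}"
            )
        start, end = self.years
        return MonthlySeries(
            variable=self.variable,
            values=self.values[self.n_years - window :],
            years=(end - window + 1, end),
            mode=self.mode,
            grid=self.grid,
        )

    def climatology(self, base_period: Optional[tuple[int, int]] = None) -> ClimatologyField:
        """Monthly means over ``base_period`` (default: the full span)."""
        if self.mode != "absolute":
            raise ValueError("climatology requires an absolute-mode series")
        start, end = self.years
        if base_period is None:
            base_period = self.years
        b0, b1 = base_period
        if b0 < start or b1 > end:
            raise ValueError(f"base period {base_period} outside series {self.years}")
        sel = self.values[b0 - start : b1 - start + 1]
        return ClimatologyField(
            variable=self.variable,
            values=sel.mean(axis=0),
            grid=self.grid,
            base_period=base_period,
        )


@dataclass
class LapseRateField:
    """Monthly local lapse-rate slopes (variable units per metre)."""

    variable: str
    values: np.ndarray  # (12, *spatial)
    grid: Optional[GridSpec] = None
    window_radius: int = 5
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        _check_variable(self.variable)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != 12:
            raise ValueError("lapse rates must have 12 monthly layers")
        if self.mask is None:
            self.mask = ~np.all(np.isfinite(self.values), axis=0)
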