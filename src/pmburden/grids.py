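"""Grid data model, regridding, population weighting and country aggregation.

All rasters in a run live on axis-aligned, cell-center-registered grids in a
single planar projection.  A :class:`GridSpec` is row-major with the origin at
the lower-left cell center, so row ``i`` maps to ``y = origin_y + i * cell_size``
and column ``j`` to ``x = origin_x + j * cell_size``.  Concentrations are
intensive (annual-mean μg/m³), so bilinear interpolation — not conservative
remapping — is the appropriate way to move them from the coarse model grid to
the fine health-calculation grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

logger = logging.getLogger(__name__)

#: Sentinel country code for sea / out-of-domain cells.
NO_COUNTRY = ""

Species = Literal["PM25", "ACA"]

#: The 12 adult age classes, ordered.
AGE_CLASSES: tuple[str, ...] = (
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80plus",
)


class GridAlignmentError(ValueError):
    """Inputs that must share a grid (or scenario) do not."""


class GridExtentError(ValueError):
    """Regrid target extends beyond the source grid's spatial extent."""


class WeightingError(ValueError):
    """Population weighting is undefined (zero total weight)."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: shape, cell size and lower-left cell center.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid shape; rows run south → north, columns west → east.
    cell_size : float
        Cell edge length in km (e.g. 20.0 for the model grid, 5.0 for the
        health grid).
    origin : (float, float)
        (x, y) of the lower-left **cell center**, in km.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def x(self) -> np.ndarray:
        """Cell-center x coordinates (km), west → east."""
        return self.origin[0] + self.cell_size * np.arange(self.n_cols)

    @property
    def y(self) -> np.ndarray:
        """Cell-center y coordinates (km), south → north."""
        return self.origin[1] + self.cell_size * np.arange(self.n_rows)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the covered area, cell edges included."""
        h = self.cell_size / 2.0
        return (
            self.origin[0] - h,
            self.origin[0] + self.cell_size * (self.n_cols - 1) + h,
            self.origin[1] - h,
            self.origin[1] + self.cell_size * (self.n_rows - 1) + h,
        )


def _check_values(values: np.ndarray, grid: GridSpec, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape[-2:] != grid.shape:
        raise ValueError(
            f"{name} values shape {values.shape} does not match grid {grid.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} values must be finite")
    if np.any(values < 0):
        raise ValueError(f"{name} values must be non-negative")
    return values


@dataclass
class ConcentrationField:
    """Gridded annual-mean concentration (μg/m³) of one species, one scenario."""

    grid: GridSpec
    species: str
    scenario: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.species not in ("PM25", "ACA"):
            raise ValueError(f"unknown species {self.species!r}")
        self.values = _check_values(self.values, self.grid, "concentration")


@dataclass
class PopulationGrid:
    """Persons per cell per adult age class.

    ``values`` has shape ``(12, n_rows, n_cols)`` in the order of
    :data:`AGE_CLASSES`.
    """

    grid: GridSpec
    values: np.ndarray
    age_classes: tuple[str, ...] = AGE_CLASSES

    def __post_init__(self) -> None:
        if tuple(self.age_classes) != AGE_CLASSES:
            raise ValueError("age classes must be exactly the 12 adult classes")
        self.values = _check_values(self.values, self.grid, "population")
        if self.values.shape != (len(AGE_CLASSES), *self.grid.shape):
            raise ValueError(
                f"population shape {self.values.shape} must be (12, {self.grid.n_rows}, {self.grid.n_cols})"
            )

    @property
    def total(self) -> np.ndarray:
        """Total adult population per cell (sum over age classes)."""
        return self.values.sum(axis=0)


@dataclass
class CountryMask:
    """Per-cell country code (ISO alpha-2) or :data:`NO_COUNTRY` for sea cells."""

    grid: GridSpec
    values: np.ndarray  # dtype str
    registry: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype="U8")
        if self.values.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        present = set(np.unique(self.values)) - {NO_COUNTRY}
        if not self.registry:
            self.registry = tuple(sorted(present))
        else:
            unknown = present - set(self.registry)
            if unknown:
                raise ValueError(f"mask codes missing from registry: {sorted(unknown)}")

    @property
    def countries(self) -> tuple[str, ...]:
        """Codes actually present in the mask, sorted."""
        present = set(np.unique(self.values)) - {NO_COUNTRY}
        return tuple(sorted(present))


def regrid_field(
    field: ConcentrationField,
    target: GridSpec,
    method: Literal["nearest", "bilinear"] = "bilinear",
) -> ConcentrationField:
    """Interpolate a concentration field onto another grid.

    Bilinear interpolation evaluates at the target cell centers; coordinates
    falling between a source edge cell's center and the grid boundary use
    constant edge extension, so output values never leave the source's
    [min, max] range.  ``nearest`` picks the closest source cell center.

    Raises
    ------
    GridExtentError
        If any target cell center lies outside the source grid's covered area.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown regrid method {method!r}")
    src = field.grid
    x_min, x_max, y_min, y_max = src.extent
    tx, ty = target.x, target.y
    if tx[0] < x_min or tx[-1] > x_max or ty[0] < y_min or ty[-1] > y_max:
        raise GridExtentError(
            f"target extent x[{tx[0]}, {tx[-1]}] y[{ty[0]}, {ty[-1]}] exceeds "
            f"source extent x[{x_min}, {x_max}] y[{y_min}, {y_max}]"
        )

    # Clip evaluation points to the source cell-center hull: constant edge
    # extension for the half-cell fringe, and a guard for 1-cell axes where
    # RegularGridInterpolator cannot interpolate.
    cx = np.clip(tx, src.x[0], src.x[-1])
    cy = np.clip(ty, src.y[0], src.y[-1])
    yy, xx = np.meshgrid(cy, cx, indexing="ij")
    points = np.column_stack([yy.ravel(), xx.ravel()])

    if 1 in src.shape:
        # Degenerate axis: fall back to per-axis nearest/linear handling.
        vals = _interp_degenerate(src, field.values, points, method)
    else:
        interp = RegularGridInterpolator(
            (src.y, src.x),
            field.values,
            method="linear" if method == "bilinear" else "nearest",
            bounds_error=True,
        )
        vals = interp(points)
    out = vals.reshape(target.shape)
    return ConcentrationField(grid=target, species=field.species,
                              scenario=field.scenario, values=out)


def _interp_degenerate(
    src: GridSpec, values: np.ndarray, points: np.ndarray, method: str
) -> np.ndarray:
    """Interpolation when the source grid is a single row and/or column."""
    kind = "linear" if method == "bilinear" else "nearest"
    if src.n_rows == 1 and src.n_cols == 1:
        return np.full(points.shape[0], values[0, 0])
    if src.n_rows == 1:
        interp = RegularGridInterpolator((src.x,), values[0, :], method=kind)
        return interp(points[:, 1])
    interp = RegularGridInterpolator((src.y,), values[:, 0], method=kind)
    return interp(points[:, 0])


def _require_same_grid(*grids: GridSpec) -> None:
    if any(g != grids[0] for g in grids[1:]):
        raise GridAlignmentError("inputs must share one GridSpec")


def population_weighted_mean(
    conc: ConcentrationField,
    pop: PopulationGrid,
    mask: CountryMask,
    country: str,
    age_classes: tuple[str, ...] | None = None,
) -> float:
    """Population-weighted mean concentration over one country's cells.

    Weights are the total adult population per cell by default; pass a subset
    of :data:`AGE_CLASSES` in ``age_classes`` to weight by specific classes.

    Raises
    ------
    WeightingError
        If the country's total population is zero (the mean is undefined,
        not 0).
    """
    _require_same_grid(conc.grid, pop.grid, mask.grid)
    sel = mask.values == country
    if not sel.any():
        raise WeightingError(f"country {country!r} has no cells in the mask")
    if age_classes is None:
        weights = pop.total[sel]
    else:
        idx = [AGE_CLASSES.index(a) for a in age_classes]
        weights = pop.values[idx][:, sel].sum(axis=0)
    wsum = weights.sum()
    if wsum <= 0:
        raise WeightingError(f"country {country!r} has zero population")
    return float(np.sum(conc.values[sel] * weights) / wsum)


def aca_fraction(aca: ConcentrationField, pm: ConcentrationField) -> np.ndarray:
    """Per-cell mass fraction aCA / PM2.5, clamped to [0, 1].

    Cells with zero PM2.5 yield 0 (there is no mass to attribute).  Fractions
    above 1 — possible only for inconsistent inputs — are clamped with a
    warning.
    """
    _require_same_grid(aca.grid, pm.grid)
    if aca.scenario != pm.scenario:
        raise GridAlignmentError(
            f"scenario mismatch: {aca.scenario!r} vs {pm.scenario!r}"
        )
    if aca.species != "ACA" or pm.species != "PM25":
        raise GridAlignmentError("expected species (ACA, PM25)")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(pm.values > 0, aca.values / np.where(pm.values > 0, pm.values, 1.0), 0.0)
    if np.any(frac > 1):
        logger.warning("aCA exceeds PM2.5 in %d cells; clamping fraction to 1",
                       int(np.sum(frac > 1)))
    return np.clip(frac, 0.0, 1.0)


def country_aggregate(
    values: np.ndarray,
    mask: CountryMask,
    reducer: Literal["sum", "pop_weighted_mean"] = "sum",
    pop: PopulationGrid | None = None,
) -> pd.Series:
    """Aggregate a per-cell field to one value per country present in the mask.

    ``sum`` partitions the masked total exactly; ``pop_weighted_mean`` needs
    ``pop``.  Countries with no cells are absent from the output, not zero.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != mask.grid.shape:
        raise GridAlignmentError("field shape does not match mask grid")
    if reducer == "pop_weighted_mean":
        if pop is None:
            raise TypeError("pop_weighted_mean reducer requires a PopulationGrid")
        _require_same_grid(mask.grid, pop.grid)
    elif reducer != "sum":
        raise ValueError(f"unknown reducer {reducer!r}")

    out: dict[str, float] = {}
    for code in mask.countries:
        sel = mask.values == code
        if reducer == "sum":
            out[code] = float(values[sel].sum())
        else:
            w = pop.total[sel]
            if w.sum() <= 0:
                raise WeightingError(f"country {code!r} has zero population")
            out[code] = float(np.sum(values[sel] * w) / w.sum())
    return pd.Series(out, name=reducer, dtype=float)
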