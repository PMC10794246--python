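"""Readers and writers for the pipeline's on-disk formats.

Rasters are NetCDF (classic format via the scipy backend): dimensions
``y``/``x``, concentration variables named ``conc_<species>`` with a
``scenario`` attribute and ``units = "ug m-3"``.  The country mask is an
integer raster paired with a CSV code table.  All tabular data (baseline
rates, risk curves, aggregates, reports) is CSV.  Writes preserve full
precision; rounding happens only in rendered reports.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grids import AGE_CLASSES, NO_COUNTRY, ConcentrationField, CountryMask, GridSpec, PopulationGrid
from .mortality import BaselineMortalityTable, MortalityResult
from .risk import BRANCHES, CAUSES, DEFAULT_TMREL, CurveSet, curves_from_frame, curves_to_frame

_ENGINE = "scipy"  # classic NetCDF, no extra backend dependencies

UNITS = "ug m-3"


def _grid_coords(grid: GridSpec) -> dict[str, np.ndarray]:
    return {"y": grid.y, "x": grid.x}


def _grid_attrs(grid: GridSpec) -> dict[str, float]:
    return {
        "cell_size_km": grid.cell_size,
        "origin_x_km": grid.origin[0],
        "origin_y_km": grid.origin[1],
    }


def _grid_from_attrs(ds: xr.Dataset) -> GridSpec:
    return GridSpec(
        n_rows=ds.sizes["y"], n_cols=ds.sizes["x"],
        cell_size=float(ds.attrs["cell_size_km"]),
        origin=(float(ds.attrs["origin_x_km"]), float(ds.attrs["origin_y_km"])),
    )


def write_field(field: ConcentrationField, path: str | Path) -> None:
    var = f"conc_{field.species.lower()}"
    ds = xr.Dataset(
        {var: (("y", "x"), field.values, {"units": UNITS})},
        coords=_grid_coords(field.grid),
        attrs={"scenario": field.scenario, **_grid_attrs(field.grid)},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_field(path: str | Path) -> ConcentrationField:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    var = next(v for v in ds.data_vars if str(v).startswith("conc_"))
    species = str(var).removeprefix("conc_").upper()
    return ConcentrationField(
        grid=_grid_from_attrs(ds), species=species,
        scenario=str(ds.attrs["scenario"]), values=ds[var].values,
    )


def write_population(pop: PopulationGrid, path: str | Path) -> None:
    ds = xr.Dataset(
        {"population": (("age_class", "y", "x"), pop.values, {"units": "persons"})},
        coords={"age_class": np.arange(len(AGE_CLASSES)), **_grid_coords(pop.grid)},
        attrs={"age_class_labels": ",".join(AGE_CLASSES), **_grid_attrs(pop.grid)},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_population(path: str | Path) -> PopulationGrid:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    labels = tuple(str(ds.attrs["age_class_labels"]).split(","))
    return PopulationGrid(grid=_grid_from_attrs(ds),
                          values=ds["population"].values, age_classes=labels)


def write_mask(mask: CountryMask, raster_path: str | Path, codes_path: str | Path) -> None:
    """Integer raster (0 = sea) plus CSV code table (code_id, country)."""
    codes = list(mask.registry)
    lut = {NO_COUNTRY: 0, **{c: i + 1 for i, c in enumerate(codes)}}
    ids = np.vectorize(lut.__getitem__, otypes=[np.int32])(mask.values)
    ds = xr.Dataset(
        {"country_id": (("y", "x"), ids)},
        coords=_grid_coords(mask.grid),
        attrs=_grid_attrs(mask.grid),
    )
    ds.to_netcdf(raster_path, engine=_ENGINE)
    pd.DataFrame({"code_id": range(1, len(codes) + 1), "country": codes}) \
        .to_csv(codes_path, index=False)


def read_mask(raster_path: str | Path, codes_path: str | Path) -> CountryMask:
    with xr.open_dataset(raster_path, engine=_ENGINE) as ds:
        ds.load()
    table = pd.read_csv(codes_path)
    lut = {0: NO_COUNTRY, **dict(zip(table["code_id"], table["country"]))}
    values = np.vectorize(lut.__getitem__, otypes=["U8"])(ds["country_id"].values)
    return CountryMask(grid=_grid_from_attrs(ds), values=values,
                       registry=tuple(table["country"]))


def write_bmr(bmr: BaselineMortalityTable, path: str | Path) -> None:
    # %.17g: shortest-repr round-trip for doubles; rounding belongs to reports.
    bmr.frame.to_csv(path, index=False, float_format="%.17g")


def read_bmr(path: str | Path) -> BaselineMortalityTable:
    return BaselineMortalityTable(
        pd.read_csv(path, float_precision="round_trip"))


def write_curves(curves: CurveSet, path: str | Path) -> None:
    curves_to_frame(curves).to_csv(path, index=False, float_format="%.17g")


def read_curves(path: str | Path, tmrel: float = DEFAULT_TMREL) -> CurveSet:
    return curves_from_frame(
        pd.read_csv(path, float_precision="round_trip"), tmrel=tmrel)


def write_mortality(m: MortalityResult, path: str | Path) -> None:
    ds = xr.Dataset(
        {"excess_deaths": (("cause", "age_class", "branch", "y", "x"), m.values,
                           {"units": "deaths yr-1"})},
        coords={
            "cause": np.arange(len(CAUSES)),
            "age_class": np.arange(len(AGE_CLASSES)),
            "branch": np.arange(len(BRANCHES)),
            **_grid_coords(m.grid),
        },
        attrs={
            "scenario": m.scenario,
            "cause_labels": ",".join(c.value for c in CAUSES),
            "age_class_labels": ",".join(AGE_CLASSES),
            "branch_labels": ",".join(BRANCHES),
            **_grid_attrs(m.grid),
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_mortality(path: str | Path) -> MortalityResult:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        ds.load()
    return MortalityResult(grid=_grid_from_attrs(ds),
                           scenario=str(ds.attrs["scenario"]),
                           values=ds["excess_deaths"].values)
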