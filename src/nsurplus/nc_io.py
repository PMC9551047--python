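"""NetCDF / CSV readers and writers.

Gridded annual variables are stored one per file with dims (time, lat, lon)
and mandatory ``units`` / ``long_name`` attributes, mirroring the published
file layout ``N_sur_total_kg_ha_grid_<y0>_<y1>_method_<xx>_v1.0.nc``.
Readers validate rather than coerce: a missing units attribute or a
non-contiguous year coordinate is a hard error.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .fields import AnnualField
from .grid import GridSpec


def write_annual_field(path: str | Path, field: AnnualField, grid: GridSpec,
                       long_name: str | None = None) -> None:
    data = field.values.reshape(field.n_years, grid.n_lat, grid.n_lon)
    if field.mask is not None:
        data = np.where(field.mask.reshape(data.shape), np.nan, data)
    da = xr.DataArray(
        data,
        dims=("time", "lat", "lon"),
        coords={"time": field.years, "lat": grid.lat_centers, "lon": grid.lon_centers},
        name=field.name,
        attrs={"units": field.units, "long_name": long_name or field.name},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_annual_field(path: str | Path, variable: str | None = None) -> tuple[AnnualField, GridSpec]:
    """Read one annual variable and its grid; validates layout and metadata."""
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable is None:
            names = list(ds.data_vars)
            if len(names) != 1:
                raise ValueError(f"file holds {len(names)} variables; pass `variable`")
            variable = names[0]
        da = ds[variable]
        if "time" not in da.dims:
            raise ValueError("variable lacks a year (time) coordinate")
        if "units" not in da.attrs:
            raise ValueError("variable lacks a units attribute")
        years = np.asarray(da["time"].values, dtype=int)
        if len(years) > 1 and not np.array_equal(np.diff(years), np.ones(len(years) - 1, int)):
            raise ValueError("year coordinate must be contiguous")
        lat = np.asarray(da["lat"].values, float)
        lon = np.asarray(da["lon"].values, float)
        values = np.asarray(da.values, float).reshape(len(years), len(lat) * len(lon))
        mask = np.isnan(values)
        field = AnnualField(variable, str(da.attrs["units"]), int(years[0]),
                            np.nan_to_num(values), mask if mask.any() else None)
        res = float(abs(lat[0] - lat[1])) if len(lat) > 1 else float(abs(lon[1] - lon[0]))
        from .grid import spherical_cell_area_ha
        area = np.repeat(spherical_cell_area_ha(lat, res), len(lon))
        grid = GridSpec(lat, lon, area, np.ones(len(lat) * len(lon), int), res)
        return field, grid


def surplus_filename(year0: int, year1: int, member: int) -> str:
    return f"N_sur_total_kg_ha_grid_{year0}_{year1}_method_{member:02d}_v1.0.nc"


def write_region_csv(path: str | Path, table: pd.DataFrame) -> None:
    """Region table in long form with columns region_id, year, mean, sd, ..."""
    table.to_csv(path, index=False)


def read_region_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
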