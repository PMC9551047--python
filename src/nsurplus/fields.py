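"""In-memory containers: gridded annual fields and country statistics tables.

Unit discipline is enforced at module boundaries: every gridded array is an
:class:`AnnualField` with an explicit units tag, and conversion between
intensive (kg per ha of grid area) and extensive (kg per cell) units is only
done through the dedicated methods.  All internal budget arithmetic happens
in extensive units so that mass-conservation checks are exact.

Country tables keep an explicit missing mask (NaN in the backing frame plus
a boolean mask); consumers must handle gaps deliberately, never by silent
zero-fill.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import GridSpec

VALID_UNITS = ("ha", "kg_per_ha_grid", "kg_per_ha_landtype", "kg_per_cell", "dimensionless")


@dataclass
class AnnualField:
    """One variable on (year, cell) with a declared units tag.

    ``values`` has shape (n_years, n_cells) over a contiguous year range
    starting at ``year0``.  ``mask`` flags missing entries (True = missing).
    """

    name: str
    units: str
    year0: int
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units tag {self.units!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_years, n_cells)")
        if self.units == "ha" and np.any(self.values < -1e-9):
            raise ValueError("area fields must be non-negative")

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @property
    def years(self) -> np.ndarray:
        return self.year0 + np.arange(self.n_years)

    def index_of(self, year: int) -> int:
        i = int(year) - self.year0
        if not 0 <= i < self.n_years:
            raise KeyError(f"year {year} outside [{self.year0}, {self.year0 + self.n_years - 1}]")
        return i

    def at(self, year: int) -> np.ndarray:
        """Values for one year (view, shape (n_cells,))."""
        return self.values[self.index_of(year)]

    def like(self, values: np.ndarray, name: str | None = None, units: str | None = None) -> "AnnualField":
        return replace(self, values=np.asarray(values, float),
                       name=name or self.name, units=units or self.units, mask=None)

    # --- unit conversion ----------------------------------------------------

    def to_per_cell(self, grid: GridSpec) -> "AnnualField":
        if self.units == "kg_per_cell":
            return self
        if self.units != "kg_per_ha_grid":
            raise ValueError(f"cannot convert {self.units!r} to kg_per_cell")
        return replace(self, units="kg_per_cell", values=self.values * grid.cell_area)

    def to_per_ha_grid(self, grid: GridSpec) -> "AnnualField":
        if self.units == "kg_per_ha_grid":
            return self
        if self.units != "kg_per_cell":
            raise ValueError(f"cannot convert {self.units!r} to kg_per_ha_grid")
        return replace(self, units="kg_per_ha_grid", values=self.values / grid.cell_area)

    # --- arithmetic (units must agree; names are combined) --------------------

    def _check(self, other: "AnnualField") -> None:
        if self.units != other.units:
            raise ValueError(f"units mismatch: {self.units} vs {other.units}")
        if self.year0 != other.year0 or self.values.shape != other.values.shape:
            raise ValueError("year range / shape mismatch")

    def __add__(self, other: "AnnualField") -> "AnnualField":
        self._check(other)
        return self.like(self.values + other.values, name=f"{self.name}+{other.name}")

    def __sub__(self, other: "AnnualField") -> "AnnualField":
        self._check(other)
        return self.like(self.values - other.values, name=f"{self.name}-{other.name}")

    @classmethod
    def zeros(cls, name: str, units: str, year0: int, n_years: int, n_cells: int) -> "AnnualField":
        return cls(name, units, year0, np.zeros((n_years, n_cells)))

    def country_sum(self, grid: GridSpec, country: int) -> np.ndarray:
        """Sum over a country's cells, per year (extensive units assumed)."""
        return self.values[:, grid.country_id == country].sum(axis=1)


def _check_table(df: pd.DataFrame) -> None:
    if not df.index.is_monotonic_increasing:
        raise ValueError("year index must be increasing")
    if np.any(df.to_numpy(dtype=float) < -1e-9):
        raise ValueError("amount/area tables must be non-negative")


@dataclass
class CountryYearTable:
    """Country x year statistics with an explicit missing mask.

    Backing frame is indexed by year with one column per country id; missing
    entries are NaN and mirrored in :attr:`missing`.
    """

    df: pd.DataFrame
    units: str = "kg"

    def __post_init__(self) -> None:
        self.df = self.df.astype(float).sort_index()
        _check_table(self.df)

    @property
    def missing(self) -> pd.DataFrame:
        return self.df.isna()

    @property
    def years(self) -> np.ndarray:
        return self.df.index.to_numpy()

    @property
    def countries(self) -> list[int]:
        return list(self.df.columns)

    def value(self, country: int, year: int) -> float:
        return float(self.df.at[year, country])


@dataclass
class CountryCropYearTable:
    """Country x crop x year statistics.

    Backing frame is indexed by year with MultiIndex columns
    (country, crop); missing entries are NaN.
    """

    df: pd.DataFrame
    units: str = "ha"
    crops: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.df = self.df.astype(float).sort_index()
        _check_table(self.df)
        table_crops = tuple(sorted({c for _, c in self.df.columns}))
        if not self.crops:
            self.crops = table_crops
        unknown = set(table_crops) - set(self.crops)
        if unknown:
            raise ValueError(f"crops not in registry: {sorted(unknown)}")

    @property
    def missing(self) -> pd.DataFrame:
        return self.df.isna()

    @property
    def countries(self) -> list[int]:
        return sorted({u for u, _ in self.df.columns})

    def series(self, country: int, crop: str) -> pd.Series:
        return self.df[(country, crop)]

    def value(self, country: int, crop: str, year: int) -> float:
        return float(self.df.at[year, (country, crop)])
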