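"""Gridded demographic surfaces from country/region tables.

Baseline cause-specific mortality rates y0 are country-level where
available; where a country's rates are unavailable they fall back to its
region's rate.  The fraction of the population aged 30 and over and the
baseline years of life lost per death (YLL0) are regional.  Tables are
mapped onto the grid through a cell-to-country area-weight table: cells
overlapping multiple countries get the area-weighted average of the
contributing countries' values.

CSV schemas
-----------
countries.csv : country_code, region_id, cause, rate, available
regions.csv   : region_id, cause, rate, fraction_30plus, yll0
weights.csv   : cell_index, country_code, weight
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GriddedField, GridSpec, RegionMap, OCEAN, require_same_grid

CAUSES = ("respiratory", "cardiopulmonary", "lung_cancer", "all_cause")

WEIGHT_TOL = 1e-6


class DemographyError(ValueError):
    pass


@dataclass
class CountryWeightMap:
    """Per land cell, the (country_code, weight) split; weights sum to 1.

    Stored long-form as a DataFrame with columns (cell_index, country_code,
    weight); cell_index is the row-major flat index on the shared grid.
    """

    grid: GridSpec
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cell_index", "country_code", "weight"}
        if not required.issubset(self.table.columns):
            raise DemographyError(f"weight table needs columns {sorted(required)}")
        if (self.table["weight"] < 0).any():
            raise DemographyError("negative cell-country weight")
        sums = self.table.groupby("cell_index")["weight"].sum()
        bad = sums[(sums - 1.0).abs() > WEIGHT_TOL]
        if len(bad):
            raise DemographyError(
                f"weights do not sum to 1 for cells {bad.index.tolist()[:5]}"
            )

    @property
    def land_cells(self) -> np.ndarray:
        return np.asarray(sorted(self.table["cell_index"].unique()))


@dataclass
class DemographyTables:
    """Country rates with regional fallbacks, adult fractions, and YLL0.

    ``countries``: one row per (country_code, cause) with the annual baseline
    mortality rate as a fraction/year and an availability flag; every country
    carries its region_id.  ``regions``: one row per (region_id, cause) with
    the regional fallback rate, the regional fraction of population >= 30
    (repeated across causes), and the regional YLL0 per death in years.
    """

    countries: pd.DataFrame
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        for df, cols in (
            (self.countries, {"country_code", "region_id", "cause", "rate", "available"}),
            (self.regions, {"region_id", "cause", "rate", "fraction_30plus", "yll0"}),
        ):
            if not cols.issubset(df.columns):
                raise DemographyError(f"table needs columns {sorted(cols)}")
        if ((self.countries["rate"] < 0) | (self.countries["rate"] > 0.1)).any():
            raise DemographyError("country rate outside [0, 0.1]/year")
        fr = self.regions["fraction_30plus"]
        if ((fr < 0) | (fr > 1)).any():
            raise DemographyError("fraction_30plus outside [0, 1]")
        if ((self.regions["yll0"] <= 0) | (self.regions["yll0"] >= 40)).any():
            raise DemographyError("yll0 outside (0, 40) years/death")

    def country_region(self, country: str) -> int:
        rows = self.countries.loc[self.countries["country_code"] == country, "region_id"]
        if rows.empty:
            raise DemographyError(f"unknown country {country!r}")
        return int(rows.iloc[0])

    def region_rate(self, region_id: int, cause: str) -> float:
        sel = self.regions[
            (self.regions["region_id"] == region_id) & (self.regions["cause"] == cause)
        ]
        if sel.empty:
            raise DemographyError(f"no regional rate for region {region_id}, cause {cause!r}")
        return float(sel["rate"].iloc[0])

    def region_fraction_30plus(self, region_id: int) -> float:
        sel = self.regions[self.regions["region_id"] == region_id]
        if sel.empty:
            raise DemographyError(f"no demographic row for region {region_id}")
        return float(sel["fraction_30plus"].iloc[0])

    def region_yll0(self, region_id: int, cause: str) -> float:
        sel = self.regions[
            (self.regions["region_id"] == region_id) & (self.regions["cause"] == cause)
        ]
        if sel.empty:
            raise DemographyError(f"no YLL0 for region {region_id}, cause {cause!r}")
        return float(sel["yll0"].iloc[0])

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        self.countries.to_csv(path / "countries.csv", index=False)
        self.regions.to_csv(path / "regions.csv", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "DemographyTables":
        path = Path(path)
        return cls(
            countries=pd.read_csv(path / "countries.csv"),
            regions=pd.read_csv(path / "regions.csv"),
        )


def resolve_rate(country: str, cause: str, tables: DemographyTables) -> float:
    """Country baseline rate if available, else the regional fallback."""
    sel = tables.countries[
        (tables.countries["country_code"] == country) & (tables.countries["cause"] == cause)
    ]
    if sel.empty:
        raise DemographyError(f"unknown country/cause: {country!r}/{cause!r}")
    row = sel.iloc[0]
    if bool(row["available"]):
        return float(row["rate"])
    return tables.region_rate(int(row["region_id"]), cause)


def _per_country_series(tables: DemographyTables, cause: str) -> pd.Series:
    sel = tables.countries[tables.countries["cause"] == cause]
    if sel.empty:
        raise DemographyError(f"no country rows for cause {cause!r}")
    return pd.Series(
        {r["country_code"]: resolve_rate(r["country_code"], cause, tables)
         for _, r in sel.iterrows()}
    )


def _weighted_surface(values_by_country: pd.Series, weights: CountryWeightMap) -> np.ndarray:
    grid = weights.grid
    tab = weights.table
    vals = values_by_country.reindex(tab["country_code"]).to_numpy()
    if np.isnan(vals).any():
        missing = tab.loc[np.isnan(vals), "country_code"].unique()
        raise DemographyError(f"no value for countries {list(missing)[:5]}")
    flat = np.zeros(grid.n_cells)
    np.add.at(flat, tab["cell_index"].to_numpy(), tab["weight"].to_numpy() * vals)
    return flat.reshape(grid.shape)


def rate_surface(tables: DemographyTables, weights: CountryWeightMap, cause: str) -> GriddedField:
    """Gridded baseline mortality rate: per cell the area-weighted average of
    the contributing countries' (resolved) rates; ocean cells 0."""
    rates = _per_country_series(tables, cause)
    return GriddedField(weights.grid, _weighted_surface(rates, weights), units="1/year")


def yll0_surface(tables: DemographyTables, weights: CountryWeightMap, cause: str) -> GriddedField:
    """Gridded baseline YLL per death (regional values mapped via countries)."""
    sel = tables.countries.drop_duplicates("country_code")
    yll = pd.Series(
        {r["country_code"]: tables.region_yll0(int(r["region_id"]), cause)
         for _, r in sel.iterrows()}
    )
    return GriddedField(weights.grid, _weighted_surface(yll, weights), units="years/death")


def adult_population(pop: GriddedField, tables: DemographyTables,
                     regions: RegionMap) -> GriddedField:
    """Population aged >= 30 per cell: pop x regional fraction_30plus."""
    require_same_grid(pop, GriddedField(regions.grid, np.zeros(regions.grid.shape)))
    ids = regions.region_ids
    uncovered = (ids == OCEAN) & (pop.values > 0)
    if uncovered.any():
        raise DemographyError(f"{int(uncovered.sum())} populated cells have no region")
    frac = np.zeros(regions.grid.shape)
    for rid in np.unique(ids[ids != OCEAN]):
        frac[ids == rid] = tables.region_fraction_30plus(int(rid))
    return GriddedField(pop.grid, pop.values * frac, units=pop.units)


def write_weights(weights: CountryWeightMap, path: str | Path) -> None:
    weights.table.to_csv(path, index=False)


def read_weights(path: str | Path, grid: GridSpec) -> CountryWeightMap:
    return CountryWeightMap(grid, pd.read_csv(path))
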