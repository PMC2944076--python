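"""Regional aggregation, percent-change and table/map conventions.

Tables report mortality and YLL totals per region (six continental
regions plus World) in thousands, as "mean +/- 1 SD"; sensitivity rows
carry the signed percent change from a baseline scenario at 0.1%
resolution.  All rounding is half-away-from-zero and is applied only at
formatting time; World rows are sums of the unrounded regional entries.
Density maps normalize per-cell burdens per 1,000 km^2 and per million
people (the latter undefined where population is zero).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import GriddedField, OCEAN, RegionMap, require_same_grid


class ReportingError(ValueError):
    pass


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (numpy rounds half to even)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def aggregate_regions(burden: GriddedField, regions: RegionMap) -> pd.Series:
    """Regional totals plus a World row equal to their (unrounded) sum.

    Cells carrying burden must belong to a region.
    """
    require_same_grid(burden, GriddedField(regions.grid, np.zeros(regions.grid.shape)))
    vals = np.nan_to_num(burden.values)
    stray = (regions.region_ids == OCEAN) & (vals > 0)
    if stray.any():
        raise ReportingError(f"{int(stray.sum())} cells carry burden but no region")
    totals = {
        name: float(vals[regions.region_ids == rid].sum())
        for rid, name in enumerate(regions.names)
    }
    totals["World"] = float(sum(totals.values()))
    return pd.Series(totals, name=burden.units)


def percent_change(alternative: float, baseline: float) -> float:
    """Signed percent change 100*(alt - base)/base at 0.1% resolution,
    rounded half away from zero."""
    if baseline <= 0:
        raise ReportingError("percent change undefined for non-positive baseline")
    return round_half_away(100.0 * (alternative - baseline) / baseline, decimals=1)


def density_maps(burden: GriddedField, areas: GriddedField,
                 pop: GriddedField) -> tuple[GriddedField, GriddedField]:
    """Per-area and per-capita burden maps.

    Returns (burden per 1,000 km^2, burden per 10^6 people); the per-capita
    map is NaN (absent) where population is zero.
    """
    require_same_grid(burden, areas, pop)
    per_area = burden.values / (areas.values / 1_000.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_capita = np.where(pop.values > 0, burden.values / (pop.values / 1e6), np.nan)
    return (
        GriddedField(burden.grid, per_area, units=f"{burden.units} per 1000 km2"),
        GriddedField(burden.grid, per_capita, units=f"{burden.units} per 1e6 people"),
    )


def format_entry(mean: float, sd: float) -> str:
    """One table entry in thousands: '470 +/- 288' style (unicode +-)."""
    return f"{round_half_away(mean / 1e3):.0f} ± {round_half_away(sd / 1e3):.0f}"


def format_regional_table(regional: pd.DataFrame, which: str = "mort") -> pd.DataFrame:
    """Render an MC regional summary as 'mean ± sd' strings in thousands.

    ``regional`` is the frame produced by the Monte Carlo driver, indexed by
    region with '<which>_mean' and '<which>_sd' columns.
    """
    mean_col, sd_col = f"{which}_mean", f"{which}_sd"
    if mean_col not in regional or sd_col not in regional:
        raise ReportingError(f"regional table lacks {mean_col}/{sd_col}")
    out = pd.DataFrame(index=regional.index)
    out["estimate (x1000)"] = [
        format_entry(m, s) for m, s in zip(regional[mean_col], regional[sd_col])
    ]
    return out


def provenance_block(meta: dict) -> str:
    """Human-readable run-provenance lines appended to report artifacts."""
    lines = ["# provenance"]
    for key in sorted(meta):
        lines.append(f"# {key}: {meta[key]}")
    return "\n".join(lines) + "\n"
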