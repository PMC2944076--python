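"""Epidemiology-ready exposure surfaces and anthropogenic deltas.

Two exposure metrics are supported, matching the cohort studies the
concentration-response functions come from:

* ``o3_season_dmax1h`` -- the mean of the daily 1-hr maximum ozone over the
  consecutive 6-month window with the highest mean, found per grid cell so
  that the metric tracks the local high-ozone season in either hemisphere;
* ``pm25_annual`` -- annual-mean PM2.5 mass reconstructed from speciated
  aerosol components (sulfate, nitrate, ammonium, black carbon, primary
  organic carbon), excluding dust, sea salt and secondary organics.

The anthropogenic delta dX is formed from present and preindustrial
surfaces under a low/high concentration-threshold policy and is the
exposure change entering the health impact function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .grid import GriddedField, require_same_grid

O3_METRIC = "o3_season_dmax1h"
PM_METRIC = "pm25_annual"

# molar masses: (NH4)2SO4 / SO4 and NH4NO3 / NO3
SULFATE_SALT_FACTOR = 132.14 / 96.06
NITRATE_SALT_FACTOR = 80.04 / 62.00

PM_SPECIES = ("so4", "no3", "nh4", "bc", "oc")


class ExposureError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdPolicy:
    """Low and high concentration thresholds bounding the exposure delta.

    ``lct`` is the concentration below which no mortality effect is assumed:
    the counterfactual baseline per cell is max(preindustrial, lct), i.e. the
    threshold replaces the natural background except where preindustrial
    concentrations already exceed it.  ``hct`` caps the present-day
    concentration before subtraction.  Either may be None (inactive).
    """

    lct: float | None = None
    hct: float | None = None

    def __post_init__(self) -> None:
        if self.lct is not None and self.hct is not None and not self.lct < self.hct:
            raise ExposureError(f"lct ({self.lct}) must be < hct ({self.hct})")


@dataclass(frozen=True)
class SpeciationConfig:
    """How speciated aerosol masses combine into a PM2.5 mass.

    OC mass is multiplied by 1.4 to account for non-carbon organic mass.
    In ``drop_simulated_nh4`` mode (default), full neutralization is assumed:
    simulated ammonium is discarded and sulfate/nitrate are scaled to
    ammonium sulfate and ammonium nitrate by stoichiometric factors.  In
    ``add_simulated_nh4`` mode the simulated NH4 mass is added instead and
    the salt factors are not applied (applying both would double-count
    ammonium).
    """

    oc_multiplier: float = 1.4
    sulfate_salt_factor: float = SULFATE_SALT_FACTOR
    nitrate_salt_factor: float = NITRATE_SALT_FACTOR
    ammonium_mode: Literal["drop_simulated_nh4", "add_simulated_nh4"] = "drop_simulated_nh4"

    def __post_init__(self) -> None:
        for name in ("oc_multiplier", "sulfate_salt_factor", "nitrate_salt_factor"):
            if getattr(self, name) < 1.0:
                raise ExposureError(f"{name} must be >= 1")


@dataclass
class ExposureSurface:
    """A gridded exposure metric; for O3 also the per-cell season start month."""

    metric: str
    values: GriddedField
    window_start_month: np.ndarray | None = None  # 1..12, O3 only

    def __post_init__(self) -> None:
        if self.metric not in (O3_METRIC, PM_METRIC):
            raise ExposureError(f"unknown exposure metric {self.metric!r}")
        if self.metric == O3_METRIC:
            if self.window_start_month is None:
                raise ExposureError("O3 exposure surface requires window_start_month")
            self.window_start_month = np.asarray(self.window_start_month, dtype=int)


@dataclass
class DeltaExposure:
    """Anthropogenic concentration increase dX >= 0, per cell."""

    metric: str
    values: GriddedField


def o3_season_average(monthly: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best consecutive 6-month mean of monthly daily-1-hr-max O3.

    Parameters
    ----------
    monthly : array, shape (12, ...)
        Monthly means of the daily 1-hr maximum, January first.

    Returns
    -------
    (seasonal_mean, start_month)
        Maximum over the 12 wrap-around consecutive 6-month windows of the
        window mean, and the 1-based first month of the winning window.
        Ties break to the earliest start month.
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.shape[0] != 12:
        raise ExposureError(f"expected 12 monthly values, got {monthly.shape[0]}")
    if not np.isfinite(monthly).all():
        raise ExposureError("incomplete series: non-finite monthly value")
    wrapped = np.concatenate([monthly, monthly[:6]], axis=0)
    windows = np.stack([wrapped[s : s + 6].mean(axis=0) for s in range(12)], axis=0)
    start = np.argmax(windows, axis=0)  # argmax takes the first maximum: earliest start
    best = np.take_along_axis(windows, start[None, ...], axis=0)[0]
    return best, start + 1


def o3_exposure(monthly: np.ndarray, grid, units: str = "ppb") -> ExposureSurface:
    """Wrap the seasonal window metric of a (12, lat, lon) bundle as a surface."""
    mean, start = o3_season_average(monthly)
    return ExposureSurface(O3_METRIC, GriddedField(grid, mean, units=units), start)


def pm25_reconstruct(species: dict[str, GriddedField],
                     cfg: SpeciationConfig | None = None) -> ExposureSurface:
    """Reconstruct PM2.5 mass from speciated surfaces.

    PM2.5 = f_s*SO4 + f_n*NO3 + BC + 1.4*OC in the default full-neutralization
    mode, or SO4 + NO3 + NH4 + BC + 1.4*OC when adding simulated ammonium.
    """
    cfg = cfg or SpeciationConfig()
    missing = [s for s in PM_SPECIES if s not in species]
    if missing:
        raise ExposureError(f"missing species surfaces: {missing}")
    grid = require_same_grid(*(species[s] for s in PM_SPECIES))
    for name in PM_SPECIES:
        if np.nanmin(species[name].values) < 0:
            raise ExposureError(f"negative {name} mass")
    if cfg.ammonium_mode == "drop_simulated_nh4":
        total = (
            cfg.sulfate_salt_factor * species["so4"].values
            + cfg.nitrate_salt_factor * species["no3"].values
            + species["bc"].values
            + cfg.oc_multiplier * species["oc"].values
        )
    else:
        total = (
            species["so4"].values
            + species["no3"].values
            + species["nh4"].values
            + species["bc"].values
            + cfg.oc_multiplier * species["oc"].values
        )
    return ExposureSurface(PM_METRIC, GriddedField(grid, total, units="ug/m3"))


def delta_exposure(present: ExposureSurface, preindustrial: ExposureSurface,
                   policy: ThresholdPolicy | None = None) -> DeltaExposure:
    """Anthropogenic exposure increase under a threshold policy.

    Per cell: dX = max(0, min(present, hct) - max(preindustrial, lct)).
    An absent LCT leaves the preindustrial baseline; an absent HCT leaves
    the present concentration uncapped.  dX is floored at zero: cells where
    the (thresholded) baseline exceeds the present concentration contribute
    no effect.
    """
    if present.metric != preindustrial.metric:
        raise ExposureError(
            f"metric mismatch: {present.metric!r} vs {preindustrial.metric!r}"
        )
    policy = policy or ThresholdPolicy()
    require_same_grid(present.values, preindustrial.values)
    top = present.values.values
    if policy.hct is not None:
        top = np.minimum(top, policy.hct)
    base = preindustrial.values.values
    if policy.lct is not None:
        base = np.maximum(base, policy.lct)
    delta = np.maximum(0.0, top - base)
    return DeltaExposure(
        present.metric,
        GriddedField(present.values.grid, delta, units=present.values.units),
    )


def popweighted_stats(fld: GriddedField, pop: GriddedField) -> tuple[float, float, float]:
    """Population-weighted mean and the (unweighted) min/max over cells.

    mean = sum(pop*x)/sum(pop) over non-missing cells; the range is the
    lowest and highest individual grid-cell value.
    """
    require_same_grid(fld, pop)
    ok = ~fld.missing & ~pop.missing
    w = pop.values[ok]
    x = fld.values[ok]
    wsum = w.sum()
    if wsum <= 0:
        raise ExposureError("zero total population: population-weighted mean undefined")
    return float((w * x).sum() / wsum), float(x.min()), float(x.max())
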