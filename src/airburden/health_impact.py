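"""Health impact functions: from relative risks to attributable burdens.

The core model is the log-linear concentration-response relation used
throughout the air-pollution cohort literature,

    RR = exp(beta * dX),

where beta is the concentration-response factor (CRF), the slope of the
log-linear relation between concentration and mortality, and dX the
anthropogenic concentration increase.  The attributable fraction is

    AF = (RR - 1)/RR = 1 - exp(-beta * dX),

and excess mortality per cell is dMort = y0 * AF * Pop over the exposed
(adult, >= 30) population, with years of life lost dYLL = dMort * YLL0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .exposure import (
    DeltaExposure,
    ExposureSurface,
    O3_METRIC,
    PM_METRIC,
    ThresholdPolicy,
    delta_exposure,
    o3_exposure,
    pm25_reconstruct,
)
from .grid import GriddedField, require_same_grid
from . import demography as dmg

Z95 = 1.96  # two-sided 95% normal quantile used to invert CI half-widths


class HealthImpactError(ValueError):
    pass


@dataclass(frozen=True)
class CRFSpec:
    """A cause-specific concentration-response factor.

    beta is per unit of the exposure metric (1/ppb for the seasonal O3
    metric, 1/(ug/m3) for annual PM2.5); beta_se its standard error.
    ``source_rr`` records the (central, lo, hi) relative risk per
    ``increment`` units when the CRF was derived from a published RR.
    """

    cause: str
    pollutant: str  # "o3" | "pm25"
    beta: float
    beta_se: float
    source_rr: tuple[float, float, float] | None = None
    increment: float | None = None
    model: str = ""

    def __post_init__(self) -> None:
        if self.beta_se < 0:
            raise HealthImpactError("beta_se must be >= 0")
        if self.pollutant not in ("o3", "pm25"):
            raise HealthImpactError(f"unknown pollutant {self.pollutant!r}")

    @property
    def metric(self) -> str:
        return O3_METRIC if self.pollutant == "o3" else PM_METRIC


def crf_from_rr(rr_central: float, rr_lo: float, rr_hi: float, increment: float,
                pollutant: str, cause: str, model: str = "") -> CRFSpec:
    """CRF from a published relative risk and its 95% CI per ``increment``.

    beta = ln(rr_central)/increment; the SE uses the symmetric log-scale
    formula beta_se = ln(rr_hi/rr_lo)/(2 * 1.96 * increment).
    """
    if not (0 < rr_lo <= rr_central <= rr_hi):
        raise HealthImpactError(
            f"confidence interval not ordered: {rr_lo} <= {rr_central} <= {rr_hi}"
        )
    if increment <= 0:
        raise HealthImpactError("increment must be > 0")
    beta = math.log(rr_central) / increment
    beta_se = math.log(rr_hi / rr_lo) / (2 * Z95 * increment)
    return CRFSpec(cause=cause, pollutant=pollutant, beta=beta, beta_se=beta_se,
                   source_rr=(rr_central, rr_lo, rr_hi), increment=increment, model=model)


def crf_direct(beta: float, beta_se: float, pollutant: str, cause: str,
               model: str = "") -> CRFSpec:
    """Pass-through CRF for studies that report the slope directly
    (e.g. the 56-ppb threshold model of the O3 cohort analysis)."""
    return CRFSpec(cause=cause, pollutant=pollutant, beta=beta, beta_se=beta_se, model=model)


# ---------------------------------------------------------------------------
# Default CRF registry.
#
# Central sets: the ACS-cohort O3 respiratory RR from the two-pollutant model
# controlling for PM2.5 (Jerrett et al. 2009), and the ACS PM2.5 reanalysis
# RRs (Krewski et al. 2009, 1999-2000 random-effects model).  Alternatives:
# the O3 single-pollutant model, the 56-ppb threshold-model slope, and the
# Pope et al. 2002 (1979-1983) and Laden et al. 2006 PM2.5 sets for
# sensitivity analysis.  All per 10 units of the exposure metric.

CRF_REGISTRY: dict[str, tuple[CRFSpec, ...]] = {
    "jerrett2009": (
        crf_from_rr(1.040, 1.013, 1.067, 10.0, "o3", "respiratory", "two-pollutant"),
    ),
    "jerrett2009_single": (
        crf_from_rr(1.029, 1.010, 1.048, 10.0, "o3", "respiratory", "single-pollutant"),
        crf_from_rr(1.014, 1.007, 1.022, 10.0, "o3", "cardiopulmonary", "single-pollutant"),
    ),
    # slope and SE reported directly for the model including a 56-ppb threshold
    "jerrett2009_threshold56": (
        crf_direct(0.00432, 0.00121, "o3", "respiratory", "threshold-56ppb"),
    ),
    "krewski2009": (
        crf_from_rr(1.06, 1.04, 1.08, 10.0, "pm25", "all_cause"),
        crf_from_rr(1.13, 1.10, 1.16, 10.0, "pm25", "cardiopulmonary"),
        crf_from_rr(1.14, 1.06, 1.23, 10.0, "pm25", "lung_cancer"),
    ),
    "pope2002": (
        crf_from_rr(1.04, 1.01, 1.08, 10.0, "pm25", "all_cause", "1979-1983"),
        crf_from_rr(1.06, 1.02, 1.10, 10.0, "pm25", "cardiopulmonary", "1979-1983"),
        crf_from_rr(1.08, 1.01, 1.16, 10.0, "pm25", "lung_cancer", "1979-1983"),
    ),
    "laden2006": (
        crf_from_rr(1.16, 1.07, 1.26, 10.0, "pm25", "all_cause"),
        crf_from_rr(1.28, 1.13, 1.44, 10.0, "pm25", "cardiopulmonary"),
        crf_from_rr(1.27, 0.96, 1.69, 10.0, "pm25", "lung_cancer"),
    ),
}


def attributable_fraction(crf: CRFSpec, dx: DeltaExposure) -> GriddedField:
    """AF = 1 - exp(-beta*dX) per cell, in [0, 1)."""
    if crf.metric != dx.metric:
        raise HealthImpactError(
            f"CRF metric {crf.metric!r} does not match exposure {dx.metric!r}"
        )
    af = 1.0 - np.exp(-crf.beta * dx.values.values)
    return GriddedField(dx.values.grid, af, units="1")


def excess_mortality(af: GriddedField, y0: GriddedField,
                     pop_adult: GriddedField) -> GriddedField:
    """dMort = y0 * AF * Pop per cell (deaths/year)."""
    require_same_grid(af, y0, pop_adult)
    for name, f in (("AF", af), ("y0", y0), ("population", pop_adult)):
        if np.nanmin(f.values) < 0:
            raise HealthImpactError(f"negative {name} values")
    return GriddedField(af.grid, y0.values * af.values * pop_adult.values,
                        units="deaths/year")


def years_of_life_lost(mort: GriddedField, yll0: GriddedField) -> GriddedField:
    """dYLL = dMort * YLL0 per cell (years/year)."""
    require_same_grid(mort, yll0)
    return GriddedField(mort.grid, mort.values * yll0.values, units="years/year")


@dataclass
class BurdenSurface:
    """Per-cell attributable mortality and YLL for one pollutant-cause pair."""

    pollutant: str
    cause: str
    mort: GriddedField
    yll: GriddedField
    provenance: dict = field(default_factory=dict)

    @property
    def total_mort(self) -> float:
        return float(np.nansum(self.mort.values))

    @property
    def total_yll(self) -> float:
        return float(np.nansum(self.yll.values))


def _present_exposures(world) -> dict[str, ExposureSurface]:
    return {
        "o3": o3_exposure(world.o3_present_monthly, world.grid),
        "pm25": pm25_reconstruct(world.pm_present, world.speciation),
    }


def _preindustrial_exposures(world) -> dict[str, ExposureSurface]:
    return {
        "o3": o3_exposure(world.o3_pre_monthly, world.grid),
        "pm25": pm25_reconstruct(world.pm_pre, world.speciation),
    }


def run_scenario(world, crfs: tuple[CRFSpec, ...],
                 policies: Mapping[str, ThresholdPolicy] | None = None,
                 present_override: Mapping[str, ExposureSurface] | None = None,
                 ) -> dict[tuple[str, str], BurdenSurface]:
    """Point-estimate burdens for every requested pollutant-cause pair.

    For each CRF: build the exposure metric, apply the pollutant's threshold
    policy to form dX, then AF -> dMort -> dYLL using the world's gridded
    demography.  Burdens are per cause and pollutant and are not summed
    across pollutants (summing O3 and PM2.5 burdens risks double counting).

    ``present_override`` substitutes perturbed present exposure surfaces
    (the Monte Carlo wrapper uses this); preindustrial surfaces are never
    perturbed.
    """
    if not crfs:
        raise HealthImpactError("no CRFs requested")
    policies = dict(policies or {})
    present = dict(present_override) if present_override else _present_exposures(world)
    pre = _preindustrial_exposures(world)
    pop30 = dmg.adult_population(world.population, world.demography, world.regions)

    out: dict[tuple[str, str], BurdenSurface] = {}
    for crf in crfs:
        pol = crf.pollutant
        policy = policies.get(pol, ThresholdPolicy())
        dx = delta_exposure(present[pol], pre[pol], policy)
        af = attributable_fraction(crf, dx)
        y0 = dmg.rate_surface(world.demography, world.weights, crf.cause)
        mort = excess_mortality(af, y0, pop30)
        yll0 = dmg.yll0_surface(world.demography, world.weights, crf.cause)
        yll = years_of_life_lost(mort, yll0)
        out[(pol, crf.cause)] = BurdenSurface(
            pollutant=pol,
            cause=crf.cause,
            mort=mort,
            yll=yll,
            provenance={
                "crf": {"beta": crf.beta, "beta_se": crf.beta_se, "model": crf.model,
                        "source_rr": crf.source_rr, "increment": crf.increment},
                "policy": {"lct": policy.lct, "hct": policy.hct},
            },
        )
    return out


def crf_with_beta(crf: CRFSpec, beta: float) -> CRFSpec:
    """A copy of ``crf`` with the slope replaced (Monte Carlo draws)."""
    return replace(crf, beta=beta, source_rr=None, increment=None)
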