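"""Synthetic world generator: gridded inputs with the structure the
burden analysis assumes.

Real applications of this pipeline consume chemical-transport-model
concentration fields, a gridded population, and WHO-style vital
statistics.  This module generates a complete stand-in world so that
every downstream stage can be exercised and tested without any external
data: a synthetic land mask, six continental regions, flood-fill
countries with fractional border weights, a hotspot-clustered population,
region-structured demographic tables spanning realistic ranges, and
present/preindustrial concentration bundles in which anthropogenic
pollution plumes co-locate with population hotspots (so population-
weighted concentrations exceed unweighted means, as in the real world)
and the preindustrial scenario retains only a scaled-down natural
background.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .demography import CountryWeightMap, DemographyTables
from .exposure import (
    NITRATE_SALT_FACTOR,
    SULFATE_SALT_FACTOR,
    SpeciationConfig,
)
from .grid import (
    GriddedField,
    GridSpec,
    OCEAN,
    REGION_NAMES,
    RegionMap,
    make_grid,
    read_field,
    read_monthly,
    write_field,
    write_monthly,
)

# NH4 mass bound per unit SO4 in (NH4)2SO4 and per unit NO3 in NH4NO3
NH4_PER_SO4 = 36.08 / 96.06
NH4_PER_NO3 = 18.04 / 62.00


class ConfigError(ValueError):
    pass


# Regional defaults emulating published adult (>= 30) vital statistics:
# cause-specific baseline mortality rates in %/year, the regional fraction
# of population aged >= 30, and baseline YLL per death in years (global
# averages 7.89 / 9.77 / 8.93 for cardiopulmonary / respiratory / lung
# cancer).  The all-cause rates are plausible adult all-cause mortality
# scaled by each region's cardiopulmonary burden.
REGION_RATE_DEFAULTS = {
    # region: (respiratory, cardiopulmonary, lung_cancer, all_cause) %/year
    "Africa": (0.206, 0.739, 0.011, 1.90),
    "North America": (0.081, 0.502, 0.071, 1.00),
    "Europe": (0.127, 1.22, 0.056, 2.10),
    "Asia": (0.171, 0.746, 0.037, 1.40),
    "South America": (0.121, 0.515, 0.025, 1.10),
    "Oceania": (0.074, 0.346, 0.035, 0.90),
}
REGION_FRACTION_30PLUS = {
    "Africa": 0.30,
    "North America": 0.52,
    "Europe": 0.60,
    "Asia": 0.45,
    "South America": 0.39,
    "Oceania": 0.55,
}
YLL0_GLOBAL = {
    "cardiopulmonary": 7.89,
    "respiratory": 9.77,
    "lung_cancer": 8.93,
    "all_cause": 8.5,
}
CAUSE_ORDER = ("respiratory", "cardiopulmonary", "lung_cancer", "all_cause")


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Study conditions for the synthetic world.

    Concentration ranges default to the published world-row ranges of the
    present-day simulations (seasonal O3 6.41-90.3 ppb, annual PM2.5
    0.25-55.9 ug/m3); the preindustrial scales reproduce the published
    world population-weighted preindustrial/present ratios (~0.35 for O3,
    ~0.07 for PM2.5).  Total population defaults to 6.6 billion.
    """

    seed: int = 0
    n_lat: int = 64
    n_lon: int = 128
    n_countries: int = 60
    total_population: float = 6.6e9
    pollution_hotspot_count: int = 25
    o3_range_present: tuple[float, float] = (6.41, 90.3)
    pm_range_present: tuple[float, float] = (0.25, 55.9)
    preindustrial_scale: float = 0.35
    pm_preindustrial_scale: float = 0.07
    land_fraction: float = 0.30
    unavailable_fraction: float = 0.30
    seasonal_amplitude: float = 0.35
    n_violating_cells: int = 0
    pm_composition: tuple[float, float, float, float] = (45.6, 9.1, 4.9, 40.4)
    pm_composition_pre: tuple[float, float, float, float] = (62.3, 6.3, 0.3, 31.0)

    def __post_init__(self) -> None:
        for name in ("o3_range_present", "pm_range_present"):
            lo, hi = getattr(self, name)
            if not 0 <= lo < hi:
                raise ConfigError(f"{name} must be an ordered non-negative range")
        for name in ("preindustrial_scale", "pm_preindustrial_scale"):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigError(f"{name} must be in [0, 1)")
        if not 0 < self.land_fraction < 1:
            raise ConfigError("land_fraction must be in (0, 1)")
        if self.n_countries < len(REGION_NAMES):
            raise ConfigError(f"need at least {len(REGION_NAMES)} countries")


@dataclass
class SyntheticWorld:
    """All inputs of one burden analysis, on a single shared grid."""

    config: SyntheticWorldConfig
    grid: GridSpec
    regions: RegionMap
    weights: CountryWeightMap
    population: GriddedField
    demography: DemographyTables
    o3_present_monthly: np.ndarray  # (12, lat, lon) ppb
    o3_pre_monthly: np.ndarray
    pm_present: dict[str, GriddedField]  # so4/no3/nh4/bc/oc, ug/m3
    pm_pre: dict[str, GriddedField]
    speciation: SpeciationConfig = dc_field(default_factory=SpeciationConfig)


# ---------------------------------------------------------------------------
# building blocks


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Spatially correlated standard field; periodic in longitude."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=sigma, mode=["nearest", "wrap"])
    sm -= sm.mean()
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _kernel_field(grid: GridSpec, centers: np.ndarray, amps: np.ndarray,
                  sigma_cells: float) -> np.ndarray:
    """Sum of Gaussian bumps at the given (i_lat, i_lon) centers, with the
    longitudinal distance wrapped."""
    ii = np.arange(grid.n_lat)[:, None]
    jj = np.arange(grid.n_lon)[None, :]
    out = np.zeros(grid.shape)
    for (ci, cj), a in zip(centers, amps):
        dj = np.abs(jj - cj)
        dj = np.minimum(dj, grid.n_lon - dj)
        d2 = (ii - ci) ** 2 + dj**2
        out += a * np.exp(-d2 / (2 * sigma_cells**2))
    return out


def _flood_fill(allowed: np.ndarray, seeds: list[tuple[int, int]],
                labels: list[int], n_lon: int) -> np.ndarray:
    """Multi-source BFS over ``allowed`` cells, longitude-periodic."""
    out = np.full(allowed.shape, -1, dtype=int)
    q: deque[tuple[int, int]] = deque()
    for (i, j), lab in zip(seeds, labels):
        out[i, j] = lab
        q.append((i, j))
    while q:
        i, j = q.popleft()
        for ni, nj in ((i - 1, j), (i + 1, j), (i, (j - 1) % n_lon), (i, (j + 1) % n_lon)):
            if 0 <= ni < allowed.shape[0] and allowed[ni, nj] and out[ni, nj] == -1:
                out[ni, nj] = out[i, j]
                q.append((ni, nj))
    return out


def _land_and_regions(grid: GridSpec, cfg: SyntheticWorldConfig,
                      rng: np.random.Generator) -> RegionMap:
    noise = _smooth_noise(rng, grid.shape, sigma=max(2.0, grid.n_lat / 12))
    thresh = np.quantile(noise, 1.0 - cfg.land_fraction)
    land = noise > thresh
    if not land.any():
        land[grid.n_lat // 2, grid.n_lon // 2] = True
    cells = np.argwhere(land)
    idx = rng.choice(len(cells), size=len(REGION_NAMES), replace=len(cells) < len(REGION_NAMES))
    seeds = [tuple(cells[k]) for k in idx]
    ids = _flood_fill(land, seeds, list(range(len(REGION_NAMES))), grid.n_lon)
    # disconnected land patches unreachable from any seed: attach to the
    # nearest seeded region by centre distance
    orphan = land & (ids == -1)
    if orphan.any():
        seed_arr = np.array(seeds)
        for i, j in np.argwhere(orphan):
            dj = np.abs(seed_arr[:, 1] - j)
            dj = np.minimum(dj, grid.n_lon - dj)
            d2 = (seed_arr[:, 0] - i) ** 2 + dj**2
            ids[i, j] = int(np.argmin(d2))
    ids[~land] = OCEAN
    return RegionMap(grid, ids)


def _countries(regions: RegionMap, n_countries: int,
               rng: np.random.Generator) -> tuple[np.ndarray, dict[int, int]]:
    """Flood-fill country labels on land, nested within regions.

    Returns the per-cell country label array and a country -> region map.
    """
    grid = regions.grid
    land = regions.land
    n_land = int(land.sum())
    if n_countries > n_land:
        raise ConfigError(f"n_countries ({n_countries}) exceeds land cells ({n_land})")
    region_ids = [r for r in np.unique(regions.region_ids) if r != OCEAN]
    sizes = {r: int((regions.region_ids == r).sum()) for r in region_ids}
    # at least one country per region, remainder proportional to region size
    alloc = {r: 1 for r in region_ids}
    remaining = n_countries - len(region_ids)
    total = sum(sizes.values())
    for r in region_ids:
        extra = int(round(remaining * sizes[r] / total))
        alloc[r] += min(extra, sizes[r] - alloc[r])
    while sum(alloc.values()) < n_countries:
        r = max(region_ids, key=lambda r: sizes[r] - alloc[r])
        if sizes[r] <= alloc[r]:
            break
        alloc[r] += 1

    labels = np.full(grid.shape, -1, dtype=int)
    country_region: dict[int, int] = {}
    seed_of_label: dict[int, tuple[int, int]] = {}
    next_label = 0
    for r in region_ids:
        cells = np.argwhere(regions.region_ids == r)
        k = min(alloc[r], len(cells))
        idx = rng.choice(len(cells), size=k, replace=False)
        seeds = [tuple(cells[m]) for m in idx]
        labs = list(range(next_label, next_label + k))
        sub = _flood_fill(regions.region_ids == r, seeds, labs, grid.n_lon)
        labels[sub >= 0] = sub[sub >= 0]
        for lab, s in zip(labs, seeds):
            country_region[lab] = r
            seed_of_label[lab] = s
        next_label += k
    # disconnected patches of a region unreachable from its country seeds:
    # attach each to the nearest country seed of the same region
    missed = land & (labels == -1)
    if missed.any():
        for i, j in np.argwhere(missed):
            r = int(regions.region_ids[i, j])
            best, best_d2 = None, None
            for lab, (si, sj) in seed_of_label.items():
                if country_region[lab] != r:
                    continue
                dj = abs(sj - j)
                dj = min(dj, grid.n_lon - dj)
                d2 = (si - i) ** 2 + dj**2
                if best is None or d2 < best_d2:
                    best, best_d2 = lab, d2
            labels[i, j] = best
    labels[~land] = -1
    return labels, country_region


def _country_weights(labels: np.ndarray, grid: GridSpec,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Weight table; cells bordering another country split their area
    fractionally between the two, exercising the area-weighted averaging."""
    rows: list[tuple[int, str, float]] = []
    n_lon = grid.n_lon
    for i, j in np.argwhere(labels >= 0):
        own = labels[i, j]
        neighbours = set()
        for ni, nj in ((i - 1, j), (i + 1, j), (i, (j - 1) % n_lon), (i, (j + 1) % n_lon)):
            if 0 <= ni < labels.shape[0] and labels[ni, nj] >= 0 and labels[ni, nj] != own:
                neighbours.add(int(labels[ni, nj]))
        cell = grid.cell_index(i, j)
        if neighbours:
            other = int(rng.choice(sorted(neighbours)))
            w = float(rng.uniform(0.55, 0.95))
            rows.append((cell, f"C{own:03d}", w))
            rows.append((cell, f"C{other:03d}", 1.0 - w))
        else:
            rows.append((cell, f"C{own:03d}", 1.0))
    return pd.DataFrame(rows, columns=["cell_index", "country_code", "weight"])


def gen_demography(regions: RegionMap, n_countries: int, seed: int,
                   unavailable_fraction: float = 0.0,
                   country_region: dict[int, int] | None = None) -> DemographyTables:
    """Region-structured vital-statistics tables.

    Regional fallback rates are the canonical defaults; each country's rate
    is its region's rate with log-normal dispersion (sd 0.15 on the log
    scale).  ``unavailable_fraction`` of countries are flagged as having no
    country-specific rates, exercising the regional-fallback path.  Regional
    YLL0 values scatter around the published global averages.
    """
    rng = np.random.default_rng(seed)
    if country_region is None:
        present = [r for r in np.unique(regions.region_ids) if r != OCEAN]
        country_region = {c: present[c % len(present)] for c in range(n_countries)}

    region_rows = []
    for rid, name in enumerate(REGION_NAMES):
        frac = REGION_FRACTION_30PLUS[name]
        for cause, rate_pct in zip(CAUSE_ORDER, _region_rates(name)):
            yll0 = YLL0_GLOBAL[cause] * float(np.exp(rng.normal(0.0, 0.05)))
            region_rows.append((rid, cause, rate_pct / 100.0, frac, yll0))
    regions_df = pd.DataFrame(
        region_rows, columns=["region_id", "cause", "rate", "fraction_30plus", "yll0"]
    )

    country_rows = []
    for c in sorted(country_region):
        rid = country_region[c]
        name = REGION_NAMES[rid]
        available = rng.uniform() >= unavailable_fraction
        for cause, rate_pct in zip(CAUSE_ORDER, _region_rates(name)):
            rate = rate_pct / 100.0 * float(np.exp(rng.normal(0.0, 0.15)))
            country_rows.append((f"C{c:03d}", rid, cause, min(rate, 0.1), available))
    countries_df = pd.DataFrame(
        country_rows, columns=["country_code", "region_id", "cause", "rate", "available"]
    )
    return DemographyTables(countries=countries_df, regions=regions_df)


def _region_rates(name: str) -> tuple[float, float, float, float]:
    return REGION_RATE_DEFAULTS[name]


def gen_o3_monthly(grid: GridSpec, hemispheric_phase: int = 0, seed: int = 0,
                   annual: np.ndarray | None = None, amplitude: float = 0.35,
                   noise_sd: float = 0.04) -> np.ndarray:
    """Monthly daily-1-hr-max O3 bundle with a hemisphere-dependent season.

    The seasonal cycle is sinusoidal with peak month offset by six months
    between hemispheres (northern peak at mid-year), shifted by
    ``hemispheric_phase`` months, plus multiplicative noise.  Southern-
    hemisphere cells therefore have their high-ozone season wrapping the
    year end, exercising wrap-around window searches.  If ``annual`` is
    omitted a smooth positive annual field is generated.
    """
    rng = np.random.default_rng(seed)
    if annual is None:
        annual = 30.0 + 15.0 * _smooth_noise(rng, grid.shape, sigma=grid.n_lat / 10)
        annual = np.maximum(annual, 1.0)
    months = np.arange(12)
    peak = np.where(grid.lat_centers >= 0, 6.0, 0.0) + hemispheric_phase  # July / January
    cycle = 1.0 + amplitude * np.cos(
        2 * np.pi * (months[:, None] - peak[None, :]) / 12.0
    )  # (12, n_lat)
    bundle = annual[None, :, :] * cycle[:, :, None]
    if noise_sd > 0:
        bundle = bundle * (1.0 + noise_sd * rng.standard_normal(bundle.shape))
    return np.maximum(bundle, 0.0)


def gen_pm_species(grid: GridSpec, composition_weights, seed: int = 0,
                   total: np.ndarray | None = None,
                   speciation: SpeciationConfig | None = None,
                   modulation_sd: float = 0.15) -> dict[str, GriddedField]:
    """Speciated aerosol surfaces with prescribed PM2.5 composition.

    ``composition_weights`` gives the (OC, BC, NO3, SO4) shares of the
    reconstructed PM2.5 mass (they are normalized, so only ratios matter).
    Shares are defined on the contributions entering the PM2.5 mass, i.e.
    after the 1.4 OC multiplier and the ammonium-salt factors; raw species
    masses are backed out by dividing those factors, and ammonium is the
    stoichiometric mass bound to sulfate and nitrate.  Each species gets a
    smooth spatial modulation and is then rescaled so its global mean share
    is exact.
    """
    w = np.asarray(composition_weights, dtype=float)
    if w.shape != (4,) or (w < 0).any():
        raise ConfigError("composition_weights must be four non-negative numbers (oc, bc, no3, so4)")
    if w.sum() == 0:
        raise ConfigError("composition weights are all zero")
    w = w / w.sum()
    cfg = speciation or SpeciationConfig()
    rng = np.random.default_rng(seed)
    if total is None:
        total = 10.0 + 4.0 * _smooth_noise(rng, grid.shape, sigma=grid.n_lat / 10)
        total = np.maximum(total, 0.0)

    contribs = {}
    for share, name in zip(w, ("oc", "bc", "no3", "so4")):
        g = np.exp(modulation_sd * _smooth_noise(rng, grid.shape, sigma=grid.n_lat / 8))
        c = share * total * g
        mass = c.sum()
        if mass > 0:
            c *= share * total.sum() / mass  # exact global mean share
        contribs[name] = c

    so4 = contribs["so4"] / cfg.sulfate_salt_factor
    no3 = contribs["no3"] / cfg.nitrate_salt_factor
    oc = contribs["oc"] / cfg.oc_multiplier
    bc = contribs["bc"]
    nh4 = NH4_PER_SO4 * so4 + NH4_PER_NO3 * no3
    return {
        name: GriddedField(grid, vals, units="ug/m3")
        for name, vals in (("so4", so4), ("no3", no3), ("nh4", nh4), ("bc", bc), ("oc", oc))
    }


def gen_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate the complete synthetic world for one configuration."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = make_grid(cfg.n_lat, cfg.n_lon)

    regions = _land_and_regions(grid, cfg, rng)
    labels, country_region = _countries(regions, cfg.n_countries, rng)
    weights = CountryWeightMap(grid, _country_weights(labels, grid, rng))
    demography = gen_demography(
        regions, cfg.n_countries, seed=int(rng.integers(2**31)),
        unavailable_fraction=cfg.unavailable_fraction, country_region=country_region,
    )

    # population: log-normal hotspot bumps on land plus a thin rural base
    land = regions.land
    land_cells = np.argwhere(land)
    k = min(cfg.pollution_hotspot_count, len(land_cells))
    centers = land_cells[rng.choice(len(land_cells), size=k, replace=False)]
    amps = np.exp(rng.normal(0.0, 1.0, size=k))
    bumps = _kernel_field(grid, centers, amps, sigma_cells=max(1.5, grid.n_lat / 32))
    pop = np.where(land, 0.05 * bumps.max() + bumps, 0.0)
    pop *= cfg.total_population / pop.sum()
    population = GriddedField(grid, pop, units="persons")

    # concentrations: shared natural background + anthropogenic plumes at
    # the population hotspots; preindustrial keeps only the scaled background
    def scenario_pair(rng_c, rng_range, pre_scale):
        bg = _smooth_noise(rng_c, grid.shape, sigma=grid.n_lat / 10)
        bg = (bg - bg.min()) / (bg.max() - bg.min())  # natural background in [0, 1]
        plume_amps = np.exp(rng_c.normal(0.0, 0.5, size=k))
        plumes = _kernel_field(grid, centers, plume_amps, sigma_cells=max(1.5, grid.n_lat / 32))
        plumes /= plumes.max()
        raw = bg + 1.5 * plumes
        lo, hi = rng_range
        present = lo + (hi - lo) * (raw - raw.min()) / (raw.max() - raw.min())
        bg_scaled = np.maximum(0.0, lo + (hi - lo) * (bg - raw.min()) / (raw.max() - raw.min()))
        pre = pre_scale * bg_scaled
        return present, pre

    o3_present_annual, o3_pre_annual = scenario_pair(
        rng, cfg.o3_range_present, cfg.preindustrial_scale
    )
    # one shared seasonal/noise pattern so present >= preindustrial holds
    # month by month
    season_seed = int(rng.integers(2**31))
    o3_present_monthly = gen_o3_monthly(
        grid, seed=season_seed, annual=o3_present_annual, amplitude=cfg.seasonal_amplitude
    )
    o3_pre_monthly = gen_o3_monthly(
        grid, seed=season_seed, annual=o3_pre_annual, amplitude=cfg.seasonal_amplitude
    )

    pm_present_total, pm_pre_total = scenario_pair(
        rng, cfg.pm_range_present, cfg.pm_preindustrial_scale
    )
    speciation = SpeciationConfig()
    pm_present = gen_pm_species(
        grid, cfg.pm_composition, seed=int(rng.integers(2**31)),
        total=pm_present_total, speciation=speciation,
    )
    pm_pre = gen_pm_species(
        grid, cfg.pm_composition_pre, seed=int(rng.integers(2**31)),
        total=pm_pre_total, speciation=speciation,
    )

    if cfg.n_violating_cells > 0:
        # inject cells where preindustrial exceeds present, to exercise the
        # dX >= 0 clamp downstream
        flat = rng.choice(grid.n_cells, size=min(cfg.n_violating_cells, grid.n_cells),
                          replace=False)
        ii, jj = np.unravel_index(flat, grid.shape)
        o3_pre_monthly[:, ii, jj] = 1.5 * o3_present_monthly[:, ii, jj]
        for name in pm_pre:
            pm_pre[name].values[ii, jj] = 1.5 * pm_present[name].values[ii, jj] + 1.0

    return SyntheticWorld(
        config=cfg,
        grid=grid,
        regions=regions,
        weights=weights,
        population=population,
        demography=demography,
        o3_present_monthly=o3_present_monthly,
        o3_pre_monthly=o3_pre_monthly,
        pm_present=pm_present,
        pm_pre=pm_pre,
        speciation=speciation,
    )


# ---------------------------------------------------------------------------
# directory round-trip (the CLI's on-disk world layout)

PM_SPECIES_FILES = ("so4", "no3", "nh4", "bc", "oc")


def world_to_dir(world: SyntheticWorld, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    grid = world.grid
    write_field(GriddedField(grid, world.regions.region_ids.astype(float), units="region_id"),
                path / "regions.nc", name="region_id")
    write_field(world.population, path / "population.nc", name="population")
    write_monthly(world.o3_present_monthly, grid, path / "o3_present.nc", "o3", "ppb")
    write_monthly(world.o3_pre_monthly, grid, path / "o3_preindustrial.nc", "o3", "ppb")
    for name in PM_SPECIES_FILES:
        write_field(world.pm_present[name], path / f"pm_present_{name}.nc", name=name)
        write_field(world.pm_pre[name], path / f"pm_preindustrial_{name}.nc", name=name)
    world.weights.table.to_csv(path / "weights.csv", index=False)
    world.demography.to_dir(path)


def world_from_dir(path: str | Path) -> SyntheticWorld:
    path = Path(path)
    region_field = read_field(path / "regions.nc", name="region_id")
    grid = region_field.grid
    regions = RegionMap(grid, region_field.values.astype(int))
    population = read_field(path / "population.nc", name="population", grid=grid)
    o3_present = read_monthly(path / "o3_present.nc", "o3", grid)
    o3_pre = read_monthly(path / "o3_preindustrial.nc", "o3", grid)
    pm_present = {n: read_field(path / f"pm_present_{n}.nc", name=n, grid=grid)
                  for n in PM_SPECIES_FILES}
    pm_pre = {n: read_field(path / f"pm_preindustrial_{n}.nc", name=n, grid=grid)
              for n in PM_SPECIES_FILES}
    weights = CountryWeightMap(grid, pd.read_csv(path / "weights.csv"))
    demography = DemographyTables.from_dir(path)
    return SyntheticWorld(
        config=SyntheticWorldConfig(n_lat=grid.n_lat, n_lon=grid.n_lon),
        grid=grid,
        regions=regions,
        weights=weights,
        population=population,
        demography=demography,
        o3_present_monthly=o3_present,
        o3_pre_monthly=o3_pre,
        pm_present=pm_present,
        pm_pre=pm_pre,
    )
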