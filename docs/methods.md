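# Methods

## The health impact function

The pipeline quantifies the mortality attributable to the anthropogenic
share of ground-level O₃ and PM₂.₅, defined as the difference between a
present-day and a preindustrial concentration scenario. For each grid
cell, pollutant p and cause of death c:

* relative risk `RR = exp(β·ΔX)`, with β the concentration–response
  factor (CRF): the slope of the log-linear relation between
  concentration and mortality estimated by cohort epidemiology;
* attributable fraction `AF = (RR − 1)/RR = 1 − exp(−β·ΔX)`;
* excess deaths `ΔMort = y₀ · AF · Pop`, with y₀ the baseline rate for
  cause c (fraction/year) and Pop the exposed population aged ≥ 30
  (matching the cohort study population);
* years of life lost `ΔYLL = ΔMort · YLL₀`, with YLL₀ the baseline YLL
  per death (regional values incorporating 3% discounting and
  non-uniform age weights; the package treats YLL₀ as given inputs and
  does not recompute life tables).

Assumptions inherited from this model class: CRFs estimated in North
American cohorts apply globally; one adult CRF per cause (no age
stratification); the relation is log-linear over the exposure range;
burdens are computed per pollutant and cause and are **not** summed
across pollutants by default, since O₃ and PM₂.₅ burdens estimated from
overlapping cohorts can double-count deaths.

## Exposure metrics

* **O₃** — the mean of the monthly daily-1-hr-maximum concentrations over
  the consecutive 6-month window with the highest mean, searched per cell
  over all 12 wrap-around windows (the high-ozone season differs between
  hemispheres). Ties break to the earliest start month. Monthly means are
  the finest temporal input; daily data would not change the metric.
* **PM₂.₅** — annual mean mass reconstructed from speciated components:
  `f_s·SO₄ + f_n·NO₃ + BC + 1.4·OC`, with stoichiometric factors
  f_s = 132.14/96.06 and f_n = 80.04/62.00 converting sulfate and nitrate
  to ammonium sulfate and ammonium nitrate (full neutralization), and the
  1.4 multiplier accounting for non-carbon organic mass. In this default
  mode the simulated ammonium mass is dropped — applying both it and the
  salt factors would double-count ammonium. An `add_simulated_nh4` mode
  instead adds simulated NH₄ with unit factors. Dust, sea salt and
  secondary organic aerosol never enter (assumed unchanged from
  preindustrial).

## Thresholds and the anthropogenic delta

`ΔX = max(0, min(present, HCT) − max(preindustrial, LCT))` per cell.

* The LCT (defaults 33.3 ppb O₃ / 5.8 μg/m³ PM₂.₅, the lowest measured
  levels in the underlying cohorts) replaces the natural background as
  counterfactual except where preindustrial concentrations already exceed
  it.
* The HCT caps the present-day level before subtraction, so only cells
  whose concentrations exceed the cap are affected.
* ΔX is floored at zero everywhere: cells where the (thresholded)
  baseline exceeds the present concentration contribute no burden. The
  synthetic generator can inject such violating cells to exercise the
  clamp.

## Demographic surfaces

Country-level cause-specific rates are used where available; countries
flagged unavailable fall back to their region's rate (plain substitution
— the subtractive back-calculation variant would need country population
weights that are not part of the inputs). Tables are gridded through a
cell→country area-weight table; cells overlapping multiple countries get
the weighted average (weights sum to 1 per cell, tolerance 1e-6). The
adult fraction and YLL₀ are regional. A single ≥ 30 age cutoff is used
throughout.

## Monte Carlo uncertainty

Defaults: 500 draws; β ~ N(β̂, se²) truncated at 0; present-day exposure
surfaces scaled by a N(1, 0.25²) factor, floored at 0; preindustrial
surfaces never perturbed. Two correlation modes:

* `correlated` (default): one factor per draw for all cells. The 25%
  represents model-level bias, and independent cell noise would shrink
  aggregate SDs implausibly.
* `independent`: one factor per cell, provided for comparison.

The perturbation applies to the derived exposure metric rather than to
monthly fields before the window search; for the default correlated mode
the two commute for O₃ (a global factor rescales every window equally).
Regional and world SDs are computed from draw-level regional sums, which
preserves within-draw spatial covariance; per-cell variances accumulate
deviations from the point estimate, which keeps the zero-uncertainty case
exactly degenerate (SD = 0) and avoids cancellation error. YLL statistics
scale the mortality draws by the point-estimate regional YLL-per-death
ratio, since YLL₀ is not itself sampled.

## Reporting conventions

Regional tables report thousands of deaths (or YLL) as "mean ± 1 SD";
World rows are sums of unrounded regional entries; rounding is applied
only at formatting, half away from zero. Sensitivity percent changes are
`100·(alternative − baseline)/baseline` from unrounded totals, rounded
half away from zero to one decimal — this convention exactly reproduces
the packaged benchmark percentages from their printed numerators and
baselines. Density maps divide per-cell burden by area/1,000 km² and by
population/10⁶; per-capita values are reported as absent (NaN), not zero,
where nobody lives.

## The synthetic world

The generator emulates the statistical structure of the real inputs, not
their geography:

* **Land and regions** — a smooth (Gaussian-filtered, longitude-periodic)
  noise field thresholded at ~30% land; six continental regions grown by
  flood-fill from random land seeds; disconnected patches attach to the
  nearest seed.
* **Countries** — flood-fill within regions (default 60 countries); cells
  bordering another country split their area weight (0.55–0.95 vs the
  remainder) between the two, exercising the weighted-averaging path.
* **Population** — log-normal-amplitude Gaussian hotspots on land plus a
  thin rural base, normalized to 6.6 × 10⁹ exactly.
* **Concentrations** — shared natural background plus anthropogenic
  plumes centered on the *population* hotspots (so population-weighted
  concentrations exceed unweighted means and the land-cell
  population–PM₂.₅ correlation is positive); present-day fields are
  scaled to the published world-row ranges (O₃ 6.41–90.3 ppb, PM₂.₅
  0.25–55.9 μg/m³). Preindustrial = scaled background only, with scales
  reproducing the published preindustrial/present population-weighted
  ratios: 0.35 for O₃, 0.07 for PM₂.₅. Present ≥ preindustrial holds by
  construction (month by month for O₃, which shares one seasonal/noise
  pattern across scenarios).
* **O₃ seasonality** — sinusoidal cycle (amplitude 0.35) peaking in July
  north of the equator and January south of it, plus 4% multiplicative
  noise; southern cells therefore exercise wrap-around window searches.
* **PM speciation** — composition shares are defined on the contributions
  entering the reconstructed PM₂.₅ mass (i.e. after the OC and salt
  factors); defaults OC 45.6 / BC 9.1 / NO₃ 4.9 / SO₄ 40.4% present-day
  and 62.3 / 6.3 / 0.3 / 31.0% preindustrial. Each species gets a smooth
  modulation and an exact global-share rescale; ammonium is the
  stoichiometric mass bound to sulfate and nitrate.
* **Demography** — regional rate defaults are the published regional
  baseline rates (e.g. world respiratory 0.134, cardiopulmonary 0.754,
  lung-cancer 0.042%/yr); country rates scatter log-normally (sd 0.15)
  around them; 30% of countries default to "rates unavailable". Regional
  adult fractions use the published world ratio (≈ 0.44) with regional
  values from standard demographic structure (Africa 0.30 … Europe 0.60),
  since regional total populations are not among the printed inputs.
  All-cause rates (needed for the all-cause CRF path) are plausible adult
  values (world ≈ 1.4%/yr) scaled by regional cardiopulmonary burden.
  YLL₀ scatters (sd 0.05, log scale) around the published global averages
  7.89 / 9.77 / 8.93 years per death.

What passing tests on this world do **not** show: agreement with real
absolute burden totals (those require the real CTM fields, gridded
population and WHO tables), realistic spatial patterns, urban-scale
exposure gradients (a ~2.8° grid dilutes urban concentrations), or the
behaviour of the 14-region demographic partition used by real
assessments (the generator uses the six continental regions; a finer
partition is a config matter).

## Numerical choices

* Earth radius fixed at 6,371 km (authalic); cell areas are exact
  spherical quadrilaterals, so the global sum is 4πR² to rounding.
* Uniform lat–lon grid (default 64 × 128 ≈ 2.8°) rather than a Gaussian
  CTM grid; the method is grid-agnostic, and area checks against CTM
  cell sizes carry 10% tolerance for this reason.
* Mixing grids between surfaces is an error; there is no silent
  regridding. Ocean cells carry population 0, not missing, so global
  sums need no masking.
* CRF standard errors from 95% CIs use the symmetric log-scale formula
  `se = ln(RR_hi/RR_lo)/(2·1.96·increment)`.
* Negative Monte Carlo draws (β or concentration factor) are truncated
  at 0 rather than resampled — simple, monotone, and the tail mass is
  small at the shipped parameter values.
* Window-search ties break to the earliest start month. A perfectly
  symmetric seasonal cycle makes the two windows flanking the peak
  mathematically equal; at float precision either may win, which is
  irrelevant to the seasonal mean itself.

## Problem sizes

Default test and acceptance runs use 16 × 32 to 64 × 128 grids with 500
Monte Carlo draws — the full default configuration of the method; the
whole suite runs in seconds on one core because every per-draw step is
vectorized over cells.

## Known limitations

* The regional fallback is substitution, not subtractive
  back-calculation.
* No covariance between O₃ and PM₂.₅ CRFs, no CRF model averaging, no
  Bayesian treatment.
* The preindustrial perturbation question (whether baseline fields share
  the present-day concentration uncertainty) is resolved by never
  perturbing preindustrial surfaces; the alternative would narrow SDs
  where deltas are small.
* Single age cutoff, no projection of baseline rates, no urban-increment
  correction.
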