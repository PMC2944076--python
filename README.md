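# airburden

Estimating the global burden of premature mortality attributable to
anthropogenic ground-level ozone (O₃) and fine particulate matter (PM₂.₅)
from gridded concentration fields, in the style of chemical-transport-model
(CTM) based health impact assessments.

The package is for researchers in air-pollution epidemiology and
atmospheric science who want a tested, reusable implementation of the
standard health-impact-function pipeline: exposure-metric construction
(seasonal daily-1-hr-maximum O₃, speciated PM₂.₅ mass), counterfactual
deltas against a preindustrial baseline with low/high concentration
thresholds, demographic regridding of country/region vital statistics, and
Monte Carlo uncertainty propagation. A first-class synthetic-data module
generates a complete world (land, countries, population, rates,
present/preindustrial concentrations) with the statistical structure the
analysis assumes, so the whole pipeline runs and is tested without any
external download.

## Model

For each grid cell, pollutant and cause of death, the log-linear
concentration–response relation gives

    RR = exp(β·ΔX)
    AF = (RR − 1)/RR = 1 − exp(−β·ΔX)
    ΔMort = y₀ · AF · Pop
    ΔYLL = ΔMort · YLL₀

where β is the concentration–response factor (slope of the log-linear
relation, from cohort studies, e.g. RR 1.04 per 10 ppb seasonal O₃ for
respiratory mortality; RR 1.13 per 10 μg/m³ PM₂.₅ for cardiopulmonary
mortality), ΔX the anthropogenic concentration increase, y₀ the baseline
cause-specific mortality rate, Pop the exposed population aged ≥ 30, and
YLL₀ the baseline years of life lost per death.

ΔX is formed per cell as `max(0, min(present, HCT) − max(preindustrial,
LCT))`: a low concentration threshold (LCT) replaces the natural background
except where preindustrial concentrations already exceed it, and a high
concentration threshold (HCT) caps the present-day level. Uncertainty is
propagated by Monte Carlo (default 500 draws) over the CRF's reported
normal distribution and a multiplicative present-day concentration
perturbation (SD = 25% of the simulated value).

## Worked example

```python
from airburden import (CRF_REGISTRY, SyntheticWorldConfig, ThresholdPolicy,
                       gen_world, run_scenario, percent_change)

world = gen_world(SyntheticWorldConfig(seed=42))          # 64 x 128 world
crfs = CRF_REGISTRY["jerrett2009"] + tuple(
    c for c in CRF_REGISTRY["krewski2009"] if c.cause != "all_cause")
background = run_scenario(world, crfs)
threshold = run_scenario(world, crfs, {
    "o3": ThresholdPolicy(lct=33.3), "pm25": ThresholdPolicy(lct=5.8)})
for key, b in background.items():
    t = threshold[key]
    print(key, f"{b.total_mort/1e3:.0f}k ->", f"{t.total_mort/1e3:.0f}k",
          f"({percent_change(t.total_mort, b.total_mort):+.1f}%)")
```

prints

```
('o3', 'respiratory') 409k -> 167k (-59.1%)
('pm25', 'cardiopulmonary') 3560k -> 2655k (-25.4%)
('pm25', 'lung_cancer') 270k -> 210k (-22.4%)
```

i.e. on this synthetic world anthropogenic PM₂.₅ accounts for ~3.6 million
cardiopulmonary deaths/yr without thresholds, falling by a quarter under
the 5.8 μg/m³ LCT — the threshold excludes exposure below the lowest
concentration measured by the underlying cohort study. The `examples/`
directory has one narrative script per capability (synthetic world,
exposure metrics, burdens and thresholds, Monte Carlo, reporting
conventions); each prints the numbers it computes and what they mean.

A thin CLI mirrors the pipeline stages:

```sh
airburden simulate --seed 1 --out world/
airburden burden --world world/ --lct-o3 33.3 --lct-pm 5.8 --out burden.nc
airburden report --world world/ --draws 500 --out report/
```

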