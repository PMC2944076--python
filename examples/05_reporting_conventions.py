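"""Reporting conventions: table formatting, percent changes, density maps.

Published burden tables report thousands of deaths as "mean ± 1 SD" and
sensitivity scenarios as signed percent changes from the no-threshold
baseline at 0.1% resolution (half-away-from-zero rounding).  The packaged
benchmark totals reproduce those conventions; density maps normalize
burdens per 1,000 km^2 and per million people.
"""

from airburden import SyntheticWorldConfig, cell_areas, gen_world, run_scenario
from airburden import CRF_REGISTRY, density_maps, format_entry, percent_change
from airburden.published import O3_SENSITIVITY, PM_BASELINE_THOUSANDS, PM_SENSITIVITY

print("benchmark sensitivity percentages recomputed from printed totals:")
for scen, (total, baseline, printed) in O3_SENSITIVITY.items():
    pc = percent_change(total, baseline)
    print(f"  o3 respiratory {scen:22s} {total:6.0f}k vs {baseline:.0f}k "
          f"-> {pc:+.1f}% (printed {printed:+.1f}%)")
for cause, (total, printed) in PM_SENSITIVITY["lct5.8"].items():
    pc = percent_change(total, PM_BASELINE_THOUSANDS[cause])
    print(f"  pm25 {cause:16s} LCT 5.8: {pc:+.1f}% (printed {printed:+.1f}%)")

print("\ntable entry formatting:", format_entry(470_000, 288_000))

world = gen_world(SyntheticWorldConfig(seed=42, n_lat=32, n_lon=64, n_countries=24))
burden = run_scenario(world, CRF_REGISTRY["jerrett2009"])[("o3", "respiratory")]
per_area, per_capita = density_maps(burden.mort, cell_areas(world.grid), world.population)
import numpy as np

print(f"max burden density: {np.nanmax(per_area.values):.2f} deaths per 1,000 km2, "
      f"{np.nanmax(per_capita.values):.0f} deaths per 10^6 people")
# per-capita values are undefined (masked) where nobody lives
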