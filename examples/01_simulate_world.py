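"""Generate a synthetic study region and inspect its demographic ledger.

The world is a planar 1-km grid tiled by rectangular counties grouped into
census divisions, with elevation-dependent population density, disc-shaped
urban areas obeying the area-population scaling law, and per-decade
exponential population trajectories. Ground-truth per-pixel population is
attached for every decade.
"""

import numpy as np

from dasypop import WorldConfig, generate_world

world = generate_world(WorldConfig(seed=7))
study = world.study

print(f"grid: {study.spec.n_rows} x {study.spec.n_cols} km")
print(f"counties: {len(study.county_ids())}, urban areas: {len(study.registry)}")
print(f"decades: {study.decades[0]}..{study.decades[-1]}, baseline {study.baseline_decade}")

t = study.baseline_decade
total = sum(study.county_census.populations(t).values())
urban = sum(ua.population(t) for ua in study.registry.existing_in(t))
print(f"\n{t}: total population {total:,.0f}, urban share {urban / total:.1%}")
print("(the urban share falls going back in time as urban areas drop below")
print(" the 2500-person census threshold)")
for decade in (1850, 1900, 1950, 2000):
    truth = world.truth_by_decade[decade]
    print(f"  {decade}: national truth {np.nansum(truth.values):,.0f} persons")
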