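# larvadrift

Biophysical modelling of larval dispersal for broadcast-spawning marine
invertebrates — built around the spat-collection problem of black-lip pearl
oyster (*Pinctada margaritifera*) aquaculture, where wild-caught juveniles
(spat) are the seed supply and collectors must be deployed where larvae
actually aggregate. `larvadrift` simulates current-driven larval transport,
maps potential settlement areas as cumulative particle-visit counts, and
tests whether simulated site counts predict observed spat recruitment.

The package is aimed at fisheries/aquaculture modellers who have gridded
surface-current output (HYCOM-style netCDF), habitat polygons for spawning
areas, and a table of collector sites with spat counts — or who want to
exercise the full pipeline on the built-in synthetic scenario generator.

## Model

Particles are passive surface drifters. Over a substep Δt the displacement
is

    Δx = u_p Δt + K

with `u_p` the surface current bilinearly interpolated (and linearly in
time) at the particle position, and `K` an isotropic random-walk
parameterisation of sub-grid turbulence: with `R_NA`, `R_NB` uniform on
(0, 1),

    ρ = sqrt(−4 E_h Δt ln(1 − R_NA)),   K = (ρ cos 2πR_NB, ρ sin 2πR_NB)

so `E[ρ²] = 4 E_h Δt` and per-axis positional variance grows as `2 E_h t`
(horizontal eddy diffusivity `E_h = 5 m² s⁻¹` by default). Δt is chosen so
the advective step stays below one grid cell. A season run releases a fixed
cohort daily over the first 10 days (full scale: 10 × 202,240 = 2,022,400
particles), runs 60 days with no mortality or behaviour, and records
positions daily. Visit counts per ~10 km² cell over the recruitment phase
(days 30–60, past the 26–30-day pelagic larval duration) are the proxy for
settlement intensity; per-site counts are compared with arcsinh-transformed
spat totals by Pearson correlation, a continuity-corrected Wilcoxon
rank-sum test, per-site one-sample t-tests, and a pairwise site-corridor
median density matrix.

## Worked example

```python
import numpy as np
from larvadrift import (
    SimulationConfig, SyntheticFieldSpec, SyntheticSpatSpec,
    arcsinh_transform, build_release_schedule, make_collector_sites,
    make_field, make_island_polygons, pearson_with_df,
    run_season_simulation, simulate_spat_counts, window_counts,
)
from larvadrift.visit_grid import site_counts_table

spec = SyntheticFieldSpec(seed=3)          # 50x50 grid, double gyre, 3 islands
field = make_field(spec)
polygons = make_island_polygons(spec)      # annular reef seed belts
schedule = build_release_schedule(seed_days=10, particles_per_day=2000)
traj = run_season_simulation(field, polygons, schedule,
                             SimulationConfig(eh=5.0, rng_seed=3))
grids = window_counts(traj, field)         # early/late/full/cumulative60
sites = make_collector_sites(spec, n_sites=28)
counts = site_counts_table(grids["cumulative60"], sites)["count"].values
sites["spat"] = simulate_spat_counts(counts, SyntheticSpatSpec(rho=0.45, seed=3),
                                     np.random.default_rng(3))
print(f"total released: {schedule.total}")
print(f"day-60 active:  {(traj.status[-1] == 1).sum()}")
print(pearson_with_df(counts, arcsinh_transform(sites['spat'].values)))
```

prints

```
total released: 20000
day-60 active:  19382
r(26) = 0.555, p = 0.00218, R2 = 0.3079
```

20,000 virtual larvae were released in the island seed belts; 19,382 were
still inside the domain on day 60 (the rest drifted out and were frozen).
The cumulative day-60 visit counts at the 28 collector sites correlate with
the arcsinh-transformed synthetic spat totals at r = 0.555 on 26 degrees of
freedom — a single 28-site draw from a generator targeting ρ = 0.45, so
individual realizations scatter around that value (the sampling standard
deviation of r at n = 28 is roughly 0.15).

The same pipeline runs from the shell:

```bash
larvadrift synth all --out-dir scenario --seed 3
larvadrift run --field scenario/field.nc --seeds scenario/seeds.geojson \
               --sites scenario/sites.csv --out-dir results --rng-seed 3
```

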