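# Methods

## Model and assumptions

`larvadrift` treats larvae as passive particles advected by surface
currents with an added random walk for unresolved turbulence. The
assumptions, in order of consequence:

- **Surface-only transport.** Only the surface (mixed-layer) current is
  used; vertical shear, diel migration, tides and wind drift are ignored.
  Early-stage bivalve larvae have very limited motility and drift near the
  surface, which is what makes the passive approximation workable.
- **No biology.** No mortality, competency, swimming or settlement
  triggers: a particle's presence in a cell during the recruitment window
  is the proxy for potential settlement. Particle *age* is tracked so such
  behaviour can be layered on later.
- **Uniform spawning.** Releases are uniform over the seed polygons
  (habitat belts from the shoreline into deeper water), because spawning
  densities in the wild are generally unknown.
- **Small-displacement geometry.** Metres and degrees convert with a
  spherical-earth constant (111,320 m/deg; zonal scaling by cos φ). At the
  ~10 km grid scale and sub-cell substeps this is accurate to well below
  interpolation error.

## Numerics

**Velocity sampling.** Linear interpolation in time between daily
snapshots, then bilinear in lon/lat. Land nodes contribute (0, 0) to the
stencil rather than being excluded and renormalised: the flow ramps
smoothly to zero toward the coast, and no velocity is ever manufactured
from land data. Queries exactly on the last grid row/column/snapshot are
inside (closed upper boundary); everywhere else cell membership is
half-open ([west, east) × [south, north), cells centred on forcing nodes),
so every point belongs to exactly one cell and a point on a shared edge
goes east/north.

**Substep rule.** Δt = clamp(s·dx_min/u_max, 60 s, 1 day) with safety
s = 0.5 and dx_min the smallest node spacing over the grid's latitude
range; u_max is recomputed once per simulation day from that day's
snapshots, and the day is divided into equal substeps so snapshots land
exactly on day boundaries. By construction the advective displacement per
substep stays below one cell.

**Random walk.** The eddy-diffusivity kick uses radial magnitude
ρ = sqrt(−4·E_h·Δt·ln(1−R_NA)) with direction 2π·R_NB — one shared radial
draw with cos/sin pairing, i.e. an isotropic 2-D walk. Without the square
root the radial term has units m², not a displacement, so the square root
is taken to recover the standard random-walk form; the natural logarithm is
used. Uniform draws are on [0, 1), so ln(1−R) is always finite.
E[ρ²] = 4·E_h·Δt, hence per-axis variance 2·E_h·t — the property the
diffusion-law test regresses for.

**Draw order and reproducibility.** One seeded PCG64 generator drives a
run. Each release day consumes the seeding draws first; then, within every
substep, each *active* particle in ascending id order consumes R_NA then
R_NB. Because NumPy fills an (n, 2) uniform block in the same stream order
as n sequential pairs, a deliberately naive per-particle stepper replays
the identical stream — the test suite holds the two bit-identical.

**Boundaries.** A displacement crossing the domain edge exits the particle:
frozen at its pre-step position, flagged, never recycled, excluded from
visit counts. A displacement landing on a land-masked cell is cancelled for
that substep (the particle holds position and stays active) — the simplest
non-absorbing rule, consistent with coastal accumulation; the behaviour of
the original GPU implementation at coastlines is not documented, so this is
a package design choice.

**Counting.** A visit is one active particle in one cell at one daily
snapshot, cumulative over the window, with no per-particle deduplication —
counting per substep would make totals Δt-dependent. Windows are half-open
(start, end] in days: the day 30–40 window spans exactly 10 snapshots.
Both a recruitment-phase grid (30, 60] and a cumulative-from-release grid
(0, 60] are emitted, since "cumulative to day 60" can be read either way.

## Statistics

- Correlation: untransformed site visit counts against arcsinh-transformed
  spat (the transform is applied to the recruitment data, which includes
  zeros); t = r·sqrt(df/(1−r²)), df = n−2, two-sided p. A flag transforms
  both sides instead.
- Rank-sum: Mann–Whitney with midranks, tie-adjusted variance and
  continuity correction; W is the first sample's U, so printed statistics
  compare across conventions only up to orientation. In the pipeline the
  pooled seasonal counts are arcsinh-transformed before this location test:
  raw visit counts sit ~10⁴× above spat counts, which would make the
  comparison vacuous.
- Per-site one-sample t-tests: the test's arrangement is open to
  interpretation, so both vectors are z-standardised across sites (each
  season column; the arcsinh-spat vector) to share a scale, then each
  site's standardised seasonal values are tested against its standardised
  spat value. Sites with no across-season variance are flagged and their p
  omitted; raw and Benjamini–Hochberg-adjusted p are reported side by side.
- Pairwise corridor density: for each site pair, the cells crossed by the
  straight lon/lat segment between them (supercover traversal, corner
  crossings include both neighbours), the median count per grid, then the
  median across the supplied grids (early/late windows × seasons).
  The matrix is symmetric; the diagonal is the site's own cell median.
- Diagnostics: Shapiro–Wilk per sample (valid n 3–5000) and Levene with
  median centring across groups.

## Synthetic data

The generator produces the desk-scale study conditions: a 50 × 50 node grid
at 1/12°, 61 daily snapshots, peak current 0.3 m s⁻¹, three circular
islands, 28 collector sites, and 2,000 particles per release day × 10 days
over 60 days — the full-scale configuration (1/12° daily forcing,
202,240/day, 2,022,400 total) scaled down ~100× in particle count and ~8×
in domain so the full pipeline runs in seconds.

- **Flow regimes.** `constant` and `zonal_jet` exist for analytic tests;
  the default `double_gyre` (ψ = A sin 2πX sin πY) has no normal flow
  through the domain boundary, producing recirculation, coastal
  accumulation and retention zones — the qualitative structure the visit
  maps are meant to reveal. Velocities come from centred differences of the
  node-sampled streamfunction, so the centred discrete divergence vanishes
  identically in the interior (the incompressibility test exploits this).
- **Seed areas** are annuli one coastal gap (1.5 cells) off each island
  with a 0.25° outer buffer — the analogue of reef belts mapped from the
  shoreline into deeper water. Allocation weights use planar degree-space
  areas; at a few degrees of latitude span the distortion is negligible and
  is a documented limitation.
- **Spat counts** come from a latent-Gaussian, gamma–Poisson
  (negative-binomial) generator: z = ρ_l·standardize(counts) +
  sqrt(1−ρ_l²)·ε feeds μ = m·exp(bz − b²/2), and counts are drawn
  NB(μ, dispersion). Defaults: mean level 120 (the order of single-harvest
  collector totals), dispersion 0.15, latent slope b = 1.2, target
  ρ = 0.45 — the regime of the motivating field comparison (r ≈ 0.43,
  p = 0.02 at n = 28). ρ_l carries an analytic attenuation correction,
  ρ_l = ρ·sqrt(b² + σ²)/b with σ² ≈ dispersion + 1/mean, for the extra
  log-scale variance of the count noise; the calibration test confirms the
  mean realized r over 500 replicates lands in [0.40, 0.50].

What the synthetic scenario does **not** emulate: realistic bathymetry and
coastline geometry, season-to-season forcing differences (seasons differ
only by their random seed against a steady field), ENSO-conditioned
interannual variability, and the spatial error structure of a real
hindcast. Passing tests therefore demonstrate that the machinery is
correct and calibrated — not that any particular real coastline's
recruitment field is predicted.

## Problem sizes in the checks

The automated checks run the stepper at 10⁵ particles × 10 days for the
diffusion law, 100 particles × 5 days for oracle equivalence, 500
replicates at n = 28 for correlation recovery, exhaustive enumeration up to
m = n = 8 for the rank-sum comparison, and the 50 × 50 / 2,000-per-day
preset for the end-to-end run — sizes at which every Monte-Carlo tolerance
in the suite is several standard errors wide.

## Known limitations

- Positions advance with a forward-Euler advection step; with sub-cell
  substeps the scheme error is far below the eddy-diffusivity noise floor,
  but tight vortex cores would benefit from a higher-order integrator.
- The land-cancellation rule lets particles hover at the coast rather than
  beach or reflect; absorbing/reflecting variants would change coastal
  visit totals.
- The corridor matrix reads "pairwise density between sites" as a
  straight-segment traversal; other readings (e.g. neighbourhood kernels)
  would need a different extractor.
- Season labels are free-form strings; the package attaches no calendar
  semantics to them.
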