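# Methods

## Model overview

`capdrift` simulates passive larval transport as Lagrangian particles in a
gridded, climatological-monthly 3-D velocity field and reduces the
trajectories to closure-network statistics. Larvae are passive throughout:
no swimming, buoyancy, diel migration, mortality or settlement competency.
This is the deliberate minimal model for deep-sea taxa whose larval biology
is essentially unobserved; everything the package computes should be read
as physical transport potential, not realized recruitment.

### Advection

Positions evolve by x_t = x_0 + ∫ v dt, integrated with the classical
fourth-order Runge–Kutta scheme. Each RK4 stage samples the velocity field
trilinearly in (lon, lat, depth) and linearly in time between adjacent
climatological month centers (month m is centered at m − 0.5 fractional
months; December wraps to January). Meter displacements convert to degrees
at the latitude of the evaluation point (dλ = dx/(R cos φ), dφ = dy/R,
R = 6 371 000 m). The interpolation order is a package choice: trilinear
space / linear climatological time is the standard kernel for
structured-grid trackers, and no statement in the underlying model family
demands more.

Sampling conventions worth knowing:

- the land/sub-seabed mask is static; masked corner weights are
  renormalized over unmasked corners, so near-bottom velocities are not
  artificially damped toward zero. If all eight corners are masked the
  sample reports *grounded*, distinct from *out-of-domain* (horizontally
  outside the grid box);
- vertical positions above the first or below the last grid level clamp to
  the nearest level (near-surface and near-bottom extrapolation by nearest
  value);
- fields with a single time slice are steady; seasonal scenarios use the
  unweighted mean of that season's three monthly slices, the "average"
  scenario the mean of all twelve.

### Diffusion

Sub-grid stirring is an uncorrelated Gaussian random walk per horizontal
axis with standard deviation √(2 K_h Δt) meters per step, K_h = 100 m² s⁻¹
and Δt = 1200 s by default, converted to degrees at the particle latitude.
There is no vertical diffusion. The Gaussian increment (rather than a
uniform one) is chosen for its standard kurtosis; the ensemble obeys
⟨r²⟩ = 4 K_h t, which the test suite verifies to within 5% at N = 10⁴.
Backward runs keep the same forward random walk — it is sign-symmetric, and
this is the usual heuristic, not an exact adjoint of the
advection–diffusion operator.

### Boundaries and status accounting

A particle is **removed** when its horizontal position leaves the domain
box (default 73.9–31.4° W, 40.8–70.5° N) *or* the velocity grid's own
bounding box — on the synthetic ocean the grid edge is the effective domain
edge. Depth is clamped to [0, local seafloor] (bilinear seafloor depth);
**grounding** is declared only when the horizontal cell is land. Clamping
rather than removal at the seabed matches the persistence of near-surface
particles in shallow release scenarios and keeps deep releases alive on the
slope; the cost is a ratchet effect (a clamped particle cannot later be
"unclamped" backward in time), which is why reversibility holds only for
ensembles that never touch the seafloor. Every run satisfies
seeded = active + removed + grounded at every record.

One RNG stream per run, seeded from the run configuration, with one draw
pair per particle per step in fixed order: runs are bit-reproducible, and
identical manifests yield byte-identical CSV outputs.

## The synthetic ocean

The generator produces the *structure* the analyses assume, not a
dynamically consistent ocean:

- **Bathymetry** — a Gaussian cap, H(r) = H_abyss − (H_abyss − H_summit)
  e^(−r²/R²), defaults 140 m summit, 4000 m abyss, R = 160 km. The radius
  was set so the 500–2800 m slope band is wide (~120 km) compared with the
  30-day diffusive spread (~30 km); on a much narrower slope the seafloor
  clamp dominates deep releases and biases their vertical displacement
  upward, which is a geometry artifact rather than a circulation feature.
- **Horizontal flow** — u = −∂ψ/∂y, v = ∂ψ/∂x with ψ a function of seafloor
  depth only (dψ/dH a Gaussian bump centered on the 1700 m jet-core
  isobath, width 700 m, closed form via erf). Streamlines therefore
  coincide with isobaths: the discrete field is non-divergent (central
  differences commute), the flow is tangent to depth contours like a slope
  boundary current, speed peaks (0.30 m s⁻¹) over the jet-core isobath and
  vanishes over the flat summit and abyssal plain. The sense is clockwise
  (anticyclonic) by default. Horizontal velocity is depth-independent down
  to the seabed.
- **Vertical velocity** — prescribed independently of continuity:
  w = s(z)·[w_dn e^(−((H−1500)/1100)²) + w_up e^(−((H−3600)/300)²)] with
  w_dn = −3×10⁻⁴ m s⁻¹, w_up = +1.5×10⁻⁴ m s⁻¹ and s(z) ramping from 0 at
  the surface to 1 below 200 m. This reproduces the qualitative pattern of
  upper-slope downwelling with offshore upwelling and magnitudes of order
  10⁻⁴ m s⁻¹, at the price of 3-D mass conservation — acceptable for a
  kinematic test ocean.
- **Seasonality** — all three components scale by
  1 + A cos(2π(m − 8)/12), A = 0.3, peaking in August, so summer/autumn
  means exceed winter/spring means at every node. Season month sets follow
  the DJF/MAM/JJA/SON convention.
- **Hydrography** — exponential T/S profiles (bottom water < 4 °C below the
  upper slope, salinity > 34.8 at depth), a surface-trapped seasonal cycle,
  and optional per-year Gaussian offsets (default 0.05 °C / 0.005 salinity)
  for multi-year stability analyses.
- **Closures** — 14 annular-sector polygons laid out on two radially
  disjoint rings (shallow sea-pen ring 500–900 m; deep sponge/gorgonian
  ring 950–2760 m, plus one full-depth wedge spanning 490–2150 m as the
  large downstream closure). Group labels: sponges {1–6}, sea pens
  {2, 7–12, 14}, gorgonians {2, 4, 5, 13}. Two areas (7, 14) are capped
  near 700 m so that 1000 m releases cannot seed them. The polygons are
  geometric stand-ins; real closure coordinates can be supplied as GeoJSON.

What passing tests on this ocean do **not** show: behavior under eddies,
meandering jets, or vertically sheared horizontal flow; interactions with
real coastlines; dispersal driven by dynamically consistent w. They do
show that the integrator, the seeding, the statistics and the orchestration
are correct on fields whose answers are known.

## Statistics conventions

- "Passing over" a closure is horizontal containment at any depth
  (boundary-inclusive point-in-polygon); a depth-aware mode exists behind a
  flag. Retention is terminating inside the release closure, regardless of
  intermediate exits; the matrix diagonal counts only terminations.
- Transit-time histograms bin first arrivals by whole days
  (floor(t/1 day)), exclude arrivals of a particle into its own release
  closure, and are normalized per receiving closure.
- "Depth reached by the first p% of particles" is the p-th percentile
  (linear interpolation) of the per-particle maximum-depth distribution;
  the shallow side mirrors it as the (100 − p)-th percentile of the
  minima. This reading keeps every percentile between the release depth
  and the absolute extreme, matching the structure of per-scenario
  displacement tables.
- Seeding lattices anchor at the polygon bounding-box minimum with
  half-open [min, max) inclusion and a boundary-inclusive containment
  test: a 1° × 1° rectangle at 0.01° spacing yields exactly 10 000 seeds.
  Lattice points over seafloor shallower than the release depth are
  dropped, so seed counts decrease with release depth on a slope.
- Along-pathway and matrix statistics use the population (N-denominator)
  standard deviation and Pearson correlation over flattened count vectors;
  a matrix correlated with itself returns exactly 1.0.
- Per-closure bottom values are taken at the deepest unmasked level of
  each in-area grid column, averaged without area weighting.

## Numerical verification

The RK4 oracle is a solid-body rotation field (ω = 10⁻⁴ s⁻¹). The oracle
grid sits on the equator: at 47° N the cos φ metric perturbs the naive
u = −ωy, v = ωx orbit at relative order Δφ·tan φ ≈ 2×10⁻³ per revolution,
swamping the integrator error the test is after, while at the equator the
perturbation is second order (~10⁻⁶). One revolution is not a whole number
of 20-min steps, so orbit error is measured against the analytic position
at the integrated time n·Δt; at Δt = 1200 s it is ~0.09 m on a 10 km orbit,
and halving the step from 4800 s to 2400 s shrinks the error 16.1× (the
clean fourth-order regime; at very small steps the C⁰ kinks of trilinear
interpolation at cell faces set a floor and the ratio degrades).

Problem sizes in the shipped tests and the acceptance script — ensembles of
200–10 000 particles, drifts of 2–30 days, seed lattices of 0.04–0.08°,
five synthetic years of hydrography — are the package's reference
configuration for the synthetic ocean; they keep every statistic's sampling
error well inside the asserted tolerances while the full suite runs in a
few minutes on one core.

## Known limitations

- w is prescribed, not derived from continuity; vertical and horizontal
  transports are individually plausible but not jointly mass-conserving.
- Backward tracking inverts advection only; with K_h > 0 it samples a
  plausible, not the exact, upstream distribution.
- Seafloor clamping is irreversible, so forward/backward reversibility
  degrades for ensembles that interact with the seabed.
- No dateline support (longitudes in [−180, 180), study domains far from
  ±180°); no curvilinear or unstructured grids; climatological (12-slice)
  or steady forcing only.
- The closure polygons are idealized sectors; quantitative connectivity
  percentages on the synthetic ocean characterize the method, not any real
  closure network.
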