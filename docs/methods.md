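# Methods

This note documents the model as implemented, its assumptions, parameter
defaults, numerical choices, and what the synthetic test worlds do and do
not establish about real migration systems.

## Model overview and assumptions

The simulator couples three layers:

1. **A migration model** of one naive migrant's autumn journey — nightly
   constant-heading flights, signpost gauging on landings, stopover
   energetics, coastline detection when over water, and terminal fates.
2. **A geomagnetic layer** providing declination D, inclination I and total
   intensity F at any surface point and decimal time: either an analytic
   centred tilted dipole with a configurable pole-drift track, or an IGRF
   spherical-harmonic coefficient file (full file degree, linear epoch
   interpolation, secular-variation extrapolation for ≤ 5 years past the
   final epoch). Evaluation is on a 6371-km sphere at the surface; crustal
   anomalies and magnetic storms are out of scope, as is altitude.
3. **An evolutionary strategy** (comma-strategy: only offspring survive into
   the next generation) that repopulates every natal location each year from
   two successful migrants and recombines their traits with intrinsic
   stochastic variability. Population size and natal locations never change;
   demography (births, deaths outside migration, density) is not modelled,
   and neither is spring migration.

Fitness of an orientation program is the geometric mean of yearly arrival
fractions, computed in log space, with any zero year collapsing the mean to
zero. Geometric averaging is the appropriate long-run survival statistic
because it penalizes catastrophic years disproportionately.

## Angular conventions

All headings and bearings are degrees clockwise from the relevant north
(magnetic or geographic), stored in [0, 360); angle differences are
reported in (−180, 180]. Circular precision uses the scale
σ = 180/(π√κ), which is nearly the circular standard deviation for
σ < 30°; no further SD correction is applied, and the empirical dispersion
estimator inverts R̄ = I₁(κ)/I₀(κ) by the standard three-regime rational
approximation so that generated σ values are recovered without the
small-κ bias of the √(−2 ln R̄) estimator.

Degenerate circular means (antipodal parents, zero resultant) raise a
flagged error at the library level; the inheritance code catches it and
deterministically takes the first parent's angle.

## The journey model: parameters and defaults

| Quantity | Default | Notes |
| --- | --- | --- |
| Ground speed | 15 m/s (54 km/h) | mean-tailwind-adjusted; winds not modelled |
| Flight-step precision | σ = 15° (κ ≈ 14.6) | one von Mises draw per nightly flight step |
| Nightly duration | 24(1 − H/π) − 3 h, clipped 6–12 h | H = arccos(−tan ψ tan δ_s); Spencer series for δ_s |
| Departure date | normal(Aug 20, 5 d) truncated Aug 6–Sep 3 | day-of-year, 365-day calendar |
| Flight capacity | uniform 48–72 h | replenished to max(draw, current) at stopovers |
| Stopover | 5 d (14 d at a signpost switch) | triggered when capacity < 3 nightly durations or after a sea-begun flight; no refuelling on barren land (vegetation = 0 or NDVI ≤ 0) |
| Coast detection | p = max(0, 1 − d/300 km) | evaluated at the last three flight deciles plus dawn; hourly during continued over-water flights |
| Gauging precision | 5° (inclination), 2% (intensity), 5° (declination) | declination gauging precision is unspecified in the source system; it defaults to the inclination value and is configurable |
| Goal test | within 90 days of departure | overshoot when a dawn position passes the goal box by half its latitudinal or longitudinal width; poleward exit beyond 87.5° N checked every hourly substep |

The sunset hour angle uses cos H = −tan ψ tan δ_s (the standard sign), which
reproduces the intended limits: 9 h at the equator or equinox, polar night
→ 21 h before clipping, midnight sun → −3 h before clipping.

Interpretation choices where the rules admit more than one reading (each
deterministic and documented here):

- "Last 3 deciles of the nightly flight" = positions at the ends of the
  hours nearest 70%, 80% and 90% of the flight, plus the dawn endpoint;
  during a continued next-day flight the check runs every hour, which for a
  10–15 h continuation is the decile cadence.
- "Until land was in sight" applies only to flights that began at sea; such
  flights also terminate on reaching land. Overland flights never stop
  mid-night, preventing spurious coastal landings on land crossings.
- Capacity is charged one hour per flight hour over land and water alike;
  "potential flight range" is the remaining capacity in hours.
- A signpost switch does not itself force a stopover; it extends the
  stopover to 14 days when one is triggered at that landing. Gauging occurs
  once per landing, before the stopover decision, and the perceived noise is
  redrawn at each landing.
- Overshoot is evaluated at dawn positions (over land or water); the
  latitudinal test applies south of the goal box, the longitudinal test at
  and south of the goal's top latitude.
- The natal-site declination used for cross-frame imprinting is evaluated at
  the mean departure date; within-season field change is negligible at
  secular-variation rates.

## Compass modes

The compass-mode triple (inherited frame, primary, in-flight) spans 8
combinations. The operative heading is expressed in the primary compass's
frame; when the inherited frame differs, the heading is imprinted at the
natal site via the local declination (geographic-inherited headings with a
magnetic primary compass automatically track between-year declination
change at the natal site; magnetic-inherited headings with a star primary
are fixed geographically at departure). A magnetic in-flight compass
re-resolves the geographic bearing hourly against local declination; a star
in-flight compass holds the departure bearing all night (cue transfer). In
a zero-declination field all 8 modes produce bit-identical trajectories,
which the test suite asserts.

## Evolutionary algorithm

**Selection.** Candidates are all successful migrants of the year, pooled
globally; each natal location draws two parents with replacement, weighted
by the half-normal dispersal density at the great-circle distance from the
candidate's natal site to the focal location. The kernel is parameterized
by its mean D_N, so the density scale is s = D_N·√(π/2). Weights are
computed in log space and normalized per location, which keeps selection
well defined when all candidates are distant. If a year produces zero
successes the run records p_y = 0 and terminates (no rescue rule exists in
the modelled system).

**Inheritance.** Headings: von Mises around the pairwise circular mean with
κ from the offspring's σ_θ. Inclination/declination signposts: von Mises
around the arithmetic parental mean (inclination clipped to ±90°).
Intensity signposts: normal with SD = σ_s% of the parental mean. Perfect
inheritance (the uncertainty analysis) takes exact parental means with no
noise.

**Spin-up and self-adaptation.** The spin-up runs 50 generations with the
field year drawn uniformly from the experiment period, then 25 generations
at the initial year (desk-scale: 10 + 5). During spin-up the intrinsic
variabilities (σ_θ ∈ [0.025°, 5°]; angular signpost σ ∈ [0.1°, 1°];
intensity signpost σ ∈ [0.1%, 1%]; dispersal-inheritance σ ∈ [2.5 m, 1 km])
and mean dispersal D_N ∈ [25 m, 25 km] evolve as individual traits:
offspring σ values are parental means multiplied by a log-normal mutation
exp(τ·N(0,1)) with learning rate τ = 1/√(2·n_traits) (the standard
evolution-strategy choice; the source system's exact mechanism is not
published), clipped to the ranges; D_N inherits as the parental mean plus
normal noise with the offspring's σ_D. During spin-up the selection kernel
uses each candidate's own D_N — the only way the trait is exposed to
selection. After spin-up every variability trait and D_N are frozen at
their population means for the experiment proper.

Initial spin-up headings point from each natal site toward an independently
drawn random goal-region point (as great-circle initial bearings, offset by
natal declination for magnetic frames); initial signposts are uniform
between the component values at the natal site and that goal point on the
initial year's mean departure date.

**Determinism.** All engine randomness comes from counter-based Philox
streams keyed by (seed, year index, day), drawn in a fixed order at full
population size, so results are independent of iteration order and of
which individuals remain active; year-ordering wrappers (forward, reversed,
fixed-year) change only the field epoch, so reversed equals forward on a
static field bit for bit. Track recording draws nothing and cannot alter
outcomes.

## Synthetic worlds

Real land-cover and IGRF data are deliberately not shipped; the scenario
module builds seeded stand-ins:

- **barrier** — a high-latitude natal landmass (with a northeastern arm)
  separated from a southern goal landmass by ocean. A single-heading course
  aimed at the goal from the natal centroid faces > 4000 km of contiguous
  water, beyond the 72 h × 54 km/h ≈ 3888 km maximum range, while an
  east-then-south detour crosses ≤ ~1800 km of water to a land corridor
  that runs to the goal — so signposted *Zugknick* routes out-perform
  single-heading migration for the population as a whole, while the short
  northern crossing keeps non-signposted migration marginally viable.
- **secular_drift(r)** — the barrier world under a dipole whose boreal pole
  orbits a small circle of 20° angular radius centred on the natal
  centroid, at bearing r·(t − t₀); the declination at the centroid then
  equals that bearing, giving an exactly linear drift of r °/yr there and a
  smooth, smaller drift elsewhere.
- **uniform** — one contiguous landmass under an axial dipole: declination
  zero everywhere, inclination and intensity monotone in latitude; the null
  world for compass-mode equivalence.

Habitat layers (vegetation, low-vegetation and barren fractions, an NDVI
proxy scalar per 1° cell) are jittered around per-landmass means so natal
qualification (≥ 10% low vegetation, < 15% barren) is non-trivial; a small
fraction of cells become barren desert. Coastal points are laid every
~20 km along land/sea cell edges. What these worlds do **not** emulate:
real coastline shape, sub-degree habitat heterogeneity, seasonal NDVI,
wind, and the real field's non-dipole structure — so passing tests
establish the mechanisms (selection, signposting, drift tracking), not
quantitative predictions for any real flyway.

## Scaled test conditions

Full-scale runs (population 50,000, 124 years, 50 + 25 spin-up) are hours
of compute; the package's own experiments run at desk scale, chosen once
as: signpost-benefit comparison — population 600, 24 years, spin-up
10 + 5, five seed-paired replicates; secular-drift comparison — population
400, 40 years at +0.3°/yr, five seed-paired replicates; consistency sweep —
populations {250, 1000, 4000} × 3 replicates, 12 years. At these sizes the
assertions are directional (orderings and signs), which the underlying
sweep shows to be robust down to populations in the hundreds, though with
larger between-replicate variability; at a few hundred individuals perfect
inheritance also retains more standing spatial variation than at full
scale, so its residual heading shift is bounded at half the intrinsic
shift rather than the tenth observed in full-scale runs.

## Numerical choices and degenerate inputs

- Spherical Earth, R = 6371 km; closed-form great-circle direct problem per
  hourly substep (error vs an independent rotation oracle < 1 m/step).
- Dipole declination is the initial great-circle bearing toward the boreal
  pole — exact for a centred dipole on a sphere; evaluation at the pole or
  its antipode raises (declination undefined).
- IGRF evaluation uses Schmidt quasi-normalized associated Legendre
  recursions; the degree-1 path is verified against the dipole closed form
  to < 0.1° (in practice ~1e−10).
- von Mises sampling switches to the wrapped-normal limit above κ = 1e6,
  where rejection sampling degrades; κ = 0 is the circular uniform.
- Decimal years are year + day_of_year/365.25 (365-day calendar, hourly
  resolution); leap days are ignored.
- Detection queries prefilter by a cached cell-centre distance-to-coast
  grid and only consult the exact coastal k-d tree within 450 km.
- Coastal-point ties resolve to the k-d tree's nearest point; equal-weight
  parent selection reduces to uniform choice.

## Known limitations

Single-cohort years (no age structure or carry-over effects); hourly flight
integration with the bearing held per night for star compasses (a
loxodrome-like course, matching the hourly update cadence rather than a
true great circle); overshoot geometry derived from the goal box rather
than a route-specific corridor; the self-adaptation mechanism is the
standard log-normal scheme, not a published reference; and desk-scale
populations under-sample the dispersal kernel relative to full-scale runs,
which inflates drift in evolved trait means.
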