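# Methods

This note documents the models implemented in `vectornav`, the choices
made where the design was open, and what the test suite does and does not
establish.

## Scientific setting

Shorebirds staging in the Yukon-Kuskokwim Delta (SW Alaska) in autumn
depart toward wintering grounds on both sides of the North Pacific:
the Pacific Northwest coast of North America, and coastal East Asia.
A bird relying on *vector navigation* — flying an inherited compass
course rather than navigating to a known goal — traces a route whose
geometry depends on the reference frame of its compass.  `vectornav`
simulates four such mechanisms from a common departure point and
implements the circular-statistics pipeline used to analyse the
orientation-cage (Emlen funnel) experiments that motivate the simulated
departure directions.

## Route simulation

Routes are integrated on a sphere of mean radius 6371.0088 km as a
sequence of fixed-length great-circle steps (default 10 km, total
5000 km).  At each step the heading is set by the mechanism:

* **Geographic loxodrome** — heading equals the initial direction
  throughout (a rhumb line).
* **Magnetic loxodrome** — the course relative to magnetic north is held
  constant; heading = magnetic course + local declination, with the
  magnetic course fixed so the first step matches the requested initial
  direction.
* **Time-compensated sun compass, clock fixed at departure** — the
  internal-clock instant is the absolute UTC time of sunset at the
  departure point on the departure date.  At each position the heading is
  the initial direction plus the difference between the local sun azimuth
  at that fixed instant and the departure-point sun azimuth at the same
  instant.  Because the sun-azimuth difference across longitude
  approximates the convergence of meridians, this mechanism approximates
  the orthodrome: for the 5667 km study-site-to-southern-Japan crossing
  the route started on the great-circle bearing misses the goal by 4.8%
  of the route length, versus 67% for the constant-course route from the
  same bearing.  The calendar date is held fixed along the route; a
  multi-day progression would require a flight speed the model does not
  assume.
* **Magnetoclinic compass** — the bird holds constant the *apparent*
  inclination gamma', the dip angle projected onto the vertical plane of
  its flight direction: tan(gamma') = tan(gamma) / cos(beta), where gamma
  is the local inclination and beta the course relative to the magnetic
  meridian.  gamma' is fixed either from the initial direction and the
  departure-point field (direct mode) or, in the two-phase variant used
  at high magnetic latitude, after first following the isocline (the
  constant-inclination contour) to a switch meridian and fixing gamma'
  there from a chosen onward course.  Each subsequent heading solves
  cos(beta) = tan(gamma)/tan(gamma'), keeping the side of the magnetic
  meridian chosen at the start; where |tan(gamma)| > |tan(gamma')| no
  course exists and the route terminates early with a reason.

**Magnetoclinic sign convention.**  The apparent inclination keeps the
sign of cos(beta): a course with a southward magnetic component (beta
obtuse) gives a gamma' of large magnitude and negative sign (the dip
appears tipped past the vertical, toward the bird's tail).  Under this
convention courses with beta near ±90° are near-neutral equilibria, so a
magnetoclinic bird departing along the isocline tangent keeps following
isoclines — which is why the two isocline tangents at the departure
point (NW branch toward East Asia, SE branch toward the Pacific
Northwest) are the natural magnetoclinic departure directions, and why
the two-phase construction (isocline to the coast, then a fixed
gamma') remains a single-mechanism account.  An alternative convention
that folds gamma' to positive values makes all obtuse-beta courses
infeasible and sends the routes poleward; it cannot reproduce the
two-phase coastal routes, so it is not used.

**Solvers.**  `solve_initial_direction` scans all integer departure
directions, simulates each candidate route in lockstep (vectorized
across candidates), and golden-section-refines the terminal-distance
minimum to 0.1°; ties resolve to the lowest direction, and no randomness
is involved.  Terminal distance is the objective even when the goal lies
beyond the route length; in that regime the argmin can legitimately
deviate a degree or two from the closed-form rhumb course, which is why
the loxodrome departure directions are reported via `rhumb_course`.
`shared_direction_min_mean_distance` runs a 1° grid over a *common*
departure direction for all four mechanisms (the magnetoclinic in direct
mode) and minimizes the mean terminal distance.

**Default destinations.**  "Southern Japan" is operationalized as
(31.0 N, 130.5 E) and the Pacific-Northwest loxodrome goal as
(45.0 N, 124.0 W); these reproduce the published rhumb departures (235°
and 124°) exactly and are configuration values, not hard-coded
constants.  The two-phase switch meridians default to 158 W (Alaska
Peninsula side, SE branch) and 175 E (Chukotka coast, NW branch) —
simple stand-ins for a coastline crossing that keep the mechanism
testable without GIS data.

## Geomagnetic field

The field model synthesizes declination, inclination and intensity from
the vendored definitive Gauss coefficient table (epochs 2005.0 and
2010.0, degree 13, linearly interpolated; degrees >= 10 held constant
across the window, a sub-nT simplification).  Synthesis is the standard
Schmidt semi-normalized spherical-harmonic expansion evaluated
geocentrically and rotated into the local geodetic frame; altitude is
fixed at sea level.  All replication runs use epoch 2005.67 (early
September 2005); the field's sensitivity there is under 0.1°/month.  An
`axial_dipole` mode (declination 0 everywhere, tan(inclination) =
2 tan(latitude)) supports analytic tests and isolates declination
effects.  Crustal and external-field contributions and storm-time
variation are out of scope, so agreement with the true local field is
limited to the main field (~0.1-0.5°).

The isocline tangent is the heading perpendicular to the
central-finite-difference gradient of inclination (step 0.1°, gradient in
km-scaled local east/north axes); the NW/SE branch selects the tangent
nearer the named quadrant, and the two branches are antipodal by
construction.

## Solar ephemeris

Solar position uses the standard low-precision almanac algorithm
(geometric mean longitude and anomaly, equation of center, apparent
ecliptic longitude, obliquity with nutation correction, declination and
equation of time, then hour angle to azimuth/elevation), accurate to
~0.01-0.1° over 1950-2050 — far below the 5° granularity of funnel
bearings.  Sunset is the downward zero-crossing of the geometric
(refraction-free) elevation, found by bracketing and bisection to 1 s;
the -0.833° refracted-disk convention shifts it under 4 minutes and can
be requested via the `horizon` argument.

## Circular statistics

* Mean vector (alpha, r) by vector addition; alpha undefined (flagged)
  at r = 0.
* Rayleigh test, Z = n r², with the second-order series p-value, refused
  below n = 4.
* 95% confidence arc of the mean direction by the chi-square-based
  approximation (separate variant for r > 0.9), defined only for
  Rayleigh-significant samples with n >= 8.  Monte-Carlo coverage at
  kappa = 2, n = 20 is 96.1% (2000 replicates).
* Watson's two-sample U² from the pooled ordered bearings with midranks
  for ties (5°-granular data tie heavily); p from the limiting
  alternating series, exact permutation p available alongside.  The
  series tracks a 10^4-shuffle permutation p to ~±0.01 except in the
  discrete far-null tail (p > 0.9), where they differ by up to ~0.03.
* Mardia's one-way classification test for equal mean directions,
  F = (N-2)(R_a + R_b - R)/(N - R_a - R_b) on (1, N-2) df, times the
  standard concentration correction 1 + 3/(8 kappa_hat); intended for
  two individually directed samples.  Simulated type-I error at
  kappa = 2, n = 20 is 4.2%.
* Mardia's two-sample concentration-homogeneity test with the
  variance-stabilizing transformation selected by the pooled mean
  resultant length (arcsine below 0.45, inverse hyperbolic sine on
  [0.45, 0.70], variance-ratio F above 0.70).  Simulated type-I error
  4.3%.
* Pearson chi-square contingency tests without continuity correction
  (the published degrees of freedom indicate plain Pearson on
  multi-category tables).
* kappa = A^-1(r) by the standard piecewise approximation refined with
  Newton steps to 1e-8.

All p-values are two-sided.  Axial (doubled-angle) statistics and modern
uniformity tests are out of scope.

## Cage-analysis pipeline

A record enters the analysis only if its activity score (0: fewer than
40 scratches ... 4: more than 2000) and concentration score are both at
least 1 and their sum at least 3.  Within each diagram a bird is
represented once, by its chronologically first included test.  "Clear"
is 1/8-6/8 cloud cover; natural (8/8) and simulated (Plexiglas) overcast
are pooled as "overcast" with provenance retained.  Fat class splits at
visual fat score 3.  The seven reported groups are the adult clear-sky
cell, the four juvenile cells (early/late × clear/overcast), and the two
pooled juvenile diagrams.  Mean-direction comparisons use Mardia's F
when both samples are Rayleigh-significant and Watson's U² when either
is random; scatter comparisons use the concentration-homogeneity test;
activity contrasts use chi-square tables of active vs inactive counts.
The pipeline is deterministic: identical input yields byte-identical
output CSVs.

## Synthetic data

The study's raw records are not deposited, so the generator emulates
them: per-cell von Mises headings at the published (alpha, r, n),
rounded to 5°; activity/concentration scores drawn uniformly over the
passing region of the inclusion rule; an inactive-test pool sized to the
published inactivity split (44% of overcast tests, 17% of clear-sky
tests); fat scores uniform over 0-6 (the per-cell fat distributions are
not published); capture windows 8-11 Aug / 4-9 Sep with session dates in
the corresponding testing windows and session start times within 90 min
before the computed local sunset.  Headings are i.i.d. unimodal von
Mises per cell — the pooled juvenile diagrams then arise as mixtures, as
in the study.  Inactivity is a Bernoulli mark independent of heading.

What passing tests show — and do not.  Because three published
group p-values (0.059, 0.065, 0.021) sit essentially on the 0.05
boundary, no generator calibrated to the published parameters can
reproduce the full significance pattern reliably: over 100 seeds the
all-seven-groups pattern matches in ~7% of replicates, while the
decisively-reported groups (printed p < 0.01) reproduce at 0.81-0.99.
The tests therefore assert reproduction only where the published
evidence is decisive.  The generator also omits features of real cage
data — within-bird correlation across repeat tests, weather-driven
session clustering, observer scoring error — so passing tests validate
the pipeline's arithmetic and decision rules, not the biology.

## Problem sizes

Default simulations use 10 km steps over 5000 km (500 steps); solver
scans cover 360 integer departures with golden-section refinement;
statistical calibrations use 2000 replicates (10^4 for the Rayleigh
type-I rate and the Watson permutation comparison).  Halving the step
length moves any terminal point by well under 5 km.

## Known limitations

Wind drift and compensation are not modelled; sun-compass variants with
partial or no time compensation are not included; the coastline switch
is a meridian, not a coastline polygon; the vendored field is the main
(core) field only; the published per-individual comparison statistics
(U² = 0.28/0.29, F = 0.0015, t = 0.72/-0.36, chi²_10 = 25.1) depend on
supplementary per-individual bearings that are not deposited — the
pipeline accepts such tables in the documented CSV format if supplied,
and is otherwise validated by calibration and power simulation.
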