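# Methods

This note documents the models, estimators, and numerical choices behind
`frognav`, and what the synthetic-data tests do and do not demonstrate
about real tracking data.

## Coordinate frame and time

All coordinates are an already-projected local planar frame in meters
(field plots mapped with compasses and laser rangefinders); no geodesy is
performed and GPS ingestion is out of scope. Timestamps are
timezone-naive local time; calendar days break at local midnight. Daytime
defaults to a fixed 06:00–18:00 window (equatorial sites) and is
overridable per site.

## Two-step downsampling

Spatial metrics grow with sampling effort, so all trajectories are
standardized before analysis.

*Step 1* targets days whose fix count exceeds the dataset-wide daily mean
by more than `daily_excess` (default 2). In the original field workflow
this thinning was done by an experienced observer; an unrecoverable
manual choice is replaced here by a deterministic greedy rule that keeps
the first and last fix of the day and all parental/mating fixes, then
repeatedly adds the fix maximizing the minimum time gap to the kept set
until `target_daily_median` (default 4) fixes remain. Kept/dropped fixes
can be recorded through the optional `log` argument. Reproducibility is
preferred over fidelity to the manual procedure.

*Step 2* is a linear scan keeping a fix when it is ≥ `min_interval_min`
(default 60) after the last *kept* fix, or farther than `fast_move_m`
(default 20 m) from it — the retention clause for long, fast movements.
Comparing against the last kept fix (rather than the preceding raw fix)
makes the scan idempotent, which the tests rely on; the alternative is
available by composing `downsample_min_interval` differently. Navigation
tracks use a finer 15-min interval (`nav_min_interval_min`) for explored
area and straightness.

## Behavior days

A fix is parental if annotated so or within 1 m of a known breeding pool;
pool proximity is ignored for (species, sex) combinations without
parental care (*O. sylvatica* males by default, configurable). A fix is
mating if annotated so or within 1 m of a same-day opposite-sex
encounter. A day with at least one parental fix is parental even if
mating was also seen (parental movements are larger in scale); otherwise
mating, otherwise other. Daily travel is the cumulative Euclidean
distance across the day's (downsampled) fixes and is zero only when all
fixes coincide.

## Space-use estimators

**MCP / extent distance.** Movement extent is the convex hull of 100% of
the fixes (shoelace area; collinear sets return area 0 with a degenerate
flag) and the hull diameter (always realized between hull vertices, and
verified against pairwise enumeration in tests).

**Kernel home range.** The utilization distribution is a Gaussian
product-kernel density with a per-axis bandwidth vector. The default
selector is the two-stage direct plug-in: ψ₈ is seeded by the normal
reference at scale `min(sd, IQR/1.349)`, ψ₆ and ψ₄ are estimated by
kernel functional estimators at their own optimal pilot bandwidths, and
`h = (R(K)/(μ₂² ψ₄ n))^{1/5}`. On a frozen mixed-normal sample this
reproduces R's `bw.SJ(method="dpi")` to 0.5% (frozen-oracle test). A
normal-reference (Silverman) rule and an explicit `(h_x, h_y)` override
are also available. Unconstrained (full-matrix) bandwidths are out of
scope.

The density is evaluated on a `grid_cells²` regular grid (default 256)
padded by `grid_pad` (default 3) times the larger bandwidth, which keeps
>99.9% of kernel mass on the grid. The 95% contour threshold is taken
over *grid mass*: cells are sorted by density and accumulated until the
utilization level is reached — the utilization-distribution convention,
not a sample-point count. The home-range area is the superlevel cell
count times the cell area, so it differs from the polygonized contour
area at O(cell size); the contour polygons are exported for mapping.
Home ranges are reported only for animals tracked ≥ 7 distinct days (and
≥ 8 fixes), mirroring the study-inclusion rule; shorter tracks get daily
travel only.

Known limitation: on strongly multimodal data the per-axis plug-in
selector inherits the scale of the whole point cloud through its pilot
stage and oversmooths each mode (verified against the R reference
selector, which behaves identically). The mixture-additivity property of
the superlevel-set area therefore holds at a common fixed bandwidth, and
is tested that way. Autocorrelation-adjusted estimators (aKDE, Brownian
bridges) are out of scope.

**Percent difference** between group means is `100·(a−b)/b` on the
natural (back-transformed) scale; spatial variables are conventionally
modeled downstream on the natural-log scale because they are
approximately log-normal.

## Navigation metrics

The home center is the coordinate-wise arithmetic mean of the
pre-translocation fixes; the home polygon is their convex hull.

* **Homing success** uses the full-resolution track: true iff some fix
  within the class window (3 days for the ~50 m class, 6 for ~200 m,
  counted as 24-h periods from release with an inclusive boundary)
  approaches the home center to within `(1 − 0.70)` of the translocation
  distance.
* **Explored area** buffers the 15-min-downsampled path by the 5-m
  perceptual radius (round caps/joins; 64 quadrant segments by default,
  configurable) and takes the union area; a single fix gives πr².
* **Straightness** is net displacement over cumulative path length of
  the 15-min track truncated at the first entry into the 10-m home
  buffer (the entering step is clipped at the boundary), so post-arrival
  wandering does not dilute the ratio; tracks that never cross the
  buffer keep their full extent.
* **Angular deviation** is the wrapped signed difference between the
  bearing from release to the first point in the class-specific annulus
  ([5, 15] m or [20, 60] m from release — center at ~20% of the
  translocation distance, halfwidths absorbing sparse sampling) and the
  bearing from release to home. By default the first recorded fix inside
  the annulus is used (`band_mode="fix"`); a step that jumps clean
  across the annulus is interpolated at the center radius and flagged.
  `band_mode="interp"` always interpolates the center-circle crossing.
  The metric is undefined when the animal never reaches the inner
  radius.
* **Homing duration** runs from release to the (linearly interpolated)
  crossing of the 10-m home buffer, minus a fixed 12-h block per
  complete night (18:00–06:00) contained in the interval, clamped at
  zero — the study species do not move at night. A warning (not an
  error) flags durations below the straight-line-distance/maximum-speed
  bound.
* **Homeward normalization** rigidly maps release to the origin and the
  home bearing to +y for overlay plots; distances are preserved.

## Circular statistics

The V-test statistic is `V = r cos(θ̄ − μ_home)`; the asymptotic
one-sided p-value uses `u = V√(2n)` against the standard-normal upper
tail. For n < 5 a seeded Monte-Carlo p (uniform resampling) is forced
with a warning, and Monte-Carlo is always available. An undirected
Rayleigh test is exposed for completeness.

The two-group comparison maps angles to (cos θ, sin θ) and runs a one-way
MANOVA. For two groups and two responses Wilks' Λ has an exact F
transform, `F = ((N−3)/2)·(1−Λ)/Λ` with df (2, N−3) (identical to
Hotelling's T² and, for g = 2, to Pillai's trace). The implementation
computes the SSCP matrices directly — one call costs microseconds, which
the calibration tests exploit — and is verified against statsmodels'
MANOVA as an independent reference. Mixed-effects circular models and
second-order analyses are out of scope.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes;
its defaults are the study conditions used throughout the tests.

**Residents.** Latent position follows
`x_{t+1} = x_t + κ(c − x_t) + ε`, `ε ~ N(0, σ²_daytype I)`, at 48 steps
per day, with κ = 0.15 and σ = 2.0 / 1.2 / 4.0 m for other / mating /
parental days — parental excursions are the largest, mating days the
quietest. The stationary per-axis sd is `σ√(1/(κ(2−κ)))` (≈ 3.8 m for
other days), giving home ranges of a few hundred m², the right order for
small territorial frogs. Parental days insert a midday round-trip to a
breeding pool with the frog sitting at the pool at the apex. Day types
are drawn i.i.d. per day; in the `paper-like` scenario the caring sex
(male in *A. femoralis* and *D. tinctorius*, female in *O. sylvatica*)
has more parental days (0.30 vs 0.05) and larger baseline noise, and in
the `null` scenario the sexes are identical.

The observation operator keeps 3–7 daytime fixes per day (median 4,
distribution 0.20/0.35/0.20/0.15/0.10 over 3..7) at latent times at
least an hour apart — the field protocol's spacing — so the daily counts
survive downsampling. The latent walk also runs at night for analytic
simplicity (the stationary-sd formula stays exact); only daytime fixes
are ever observed.

**Translocations.** A three-state biased correlated random walk at 5-min
daytime steps: `local` (uniform headings, 0.2-m mean steps), `explore`
(von Mises turning angles, κ = 4, 1-m mean steps), `home` (headings von
Mises around the true home bearing, κ = 8). Step lengths are
exponential. The default transition matrix mixes all three phenotypes
and yields ~50% homing at 50 m and ~25% at 200 m, inside the ranges
observed across species and sexes in the field; the `paper-like` male
preset leaves `local` sooner and explores longer. The walk is absorbed
on reaching the home area itself (1-m buffer around the home polygon) —
not at the field protocol's wider ~10-m tracking cutoff, which for
realistically sized home polygons can lie outside the homing-criterion
radius and would strand returned walkers in a non-homing state. Nights
pass without movement. Observation samples the full-resolution track at
20-min intervals plus the absorption fix.

All randomness flows through one injectable numpy `Generator`;
`make_study(seed, …)` is byte-deterministic and writes the complete CSV
input set (fixes, pools, translocations, post-release fixes, half-hourly
sinusoidal temperature log).

**What passing tests do not show.** The generator has no measurement
error on positions, no tag loss or missing days, isotropic noise, no
landscape barriers or enclosure edges, i.i.d. day types (no breeding
phenology), and temperature that influences nothing. Tests against it
validate the estimators and their calibration, not the biological
conclusions one would draw from field data.

## Problem sizes and test design

The acceptance-style tests use: 200 random instances (n ≤ 12) against an
O(n³) hull oracle; 2000-point Gaussian samples over 10 seeds against the
`π·χ²₂(0.95)` area (15% tolerance — grid resolution, bandwidth bias, and
Monte-Carlo noise all enter); 2000 replicates at n = 20 for V-test
type-I calibration (±0.01); 1000 label permutations for p-uniformity
(K-S at the 1% level); 100 replicates of 16 tracked days for effect-sign
recovery; a 10,000-rep brute-force success-probability oracle against
the classifier at 500 evaluated tracks (2 Monte-Carlo SE); and full
pipeline runs compared byte-for-byte. These sizes keep the default suite
under a minute of simulation-heavy work while leaving each check's
power adequate for its stated tolerance.

## Input/output conventions

Fix tables are CSV/TSV with configurable column names; duplicate
(animal, time) rows error by default (`keep_first` optionally), because
silent merging hides data problems. Floats are written with `repr` and
parsed with Python's correctly-rounded `float`, so tables and GeoJSON
round-trip bit-exactly. GeoJSON declares a local engineering CRS name to
prevent accidental lon/lat interpretation. The original study's GIS
point schema is not reproduced field-by-field; the CSV schema is a
faithful abstraction.
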