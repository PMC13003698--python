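# Methods

`petreltrack` reconstructs, as a tested pipeline, the at-sea foraging
analysis of two seasonally segregated populations of a central-place
foraging seabird (band-rumped storm-petrels breeding in alternating "hot"
and "cool" seasons at the same colony). This note documents the models and
procedures, the parameters that matter, the synthetic study the package
ships for end-to-end testing, and the numerical choices made where the
design was genuinely open.

## Geodesy and preprocessing

All distances are great circles on a sphere of radius 6371.0088 km (the
WGS84 mean radius); at trip scales of a few hundred kilometres the
spherical error is far below every tolerance used downstream. Gridded work
uses an azimuthal-equidistant projection centred on the colony, which
preserves colony-to-point ranges exactly — the quantity every trip rule is
written in. Implausible fixes are removed by a single automatic rule,
applied forward-iteratively against the last retained fix: a fix is
dropped when reaching it would require more than `vmax` = 50 km/h
sustained over at least a 2-h window (i.e. distance > vmax × max(Δt, 2 h)).
Iterating forward makes the filter deterministic and idempotent; with the
backward direction untested in the original protocol, forward-only is the
package's fixed choice. Duplicate timestamps keep the first fix.

## Trip segmentation

A candidate trip is a maximal run of consecutive retained fixes more than
20 km from the colony; it is complete if a later fix returns within 30 km.
Categories: `short_neglect` — incubation-stage excursions of at most 24 h,
additionally requiring an on-duty nest-attendance record for the departure
date when attendance data are supplied; `long` — at least 6 fixes beyond
the 20-km buffer. Trips satisfying neither rule are tagged `unclassified`
and excluded from metric comparisons rather than forced into a category.
Trip metrics: duration, cumulative great-circle distance over consecutive
fixes, maximum colony range, and the bearing from the colony to the most
distal fix (ties broken to the earlier fix, for determinism).

## First passage time and foraging classification

Trips are linearly interpolated in projected XY to whole-hour offsets from
the trip start; gaps longer than 6 h are left as breaks and never
interpolated across. FPT at a position and radius r is the backward plus
forward exit time from the circle of radius r, with each exit instant
linearly interpolated between the straddling hourly positions; it is
missing where the path never exits within the trip (notably the first and
last positions). The radius ladder is 30 log-spaced radii from 2 to
250 km, bracketing plausible storm-petrel search scales and trip extents.

Per trip, the search scale is the radius maximizing the variance of
log-FPT (natural log, sample variance over positions with defined FPT,
ties to the smaller radius); the population scale is the arithmetic mean
of per-trip peaks snapped to the nearest ladder radius. Original fixes
take the FPT of their nearest-in-time hourly position at that scale and
are labelled foraging when their FPT strictly exceeds the grand mean FPT
across all labelled locations of all trips (equivalently FPT/mean > 1.0).
The grand mean is pooled across trips rather than computed per trip: with
a per-trip mean, every trip would by construction contain foraging
locations, which contradicts using the labels to compare foraging effort
between seasons. Fixes with undefined FPT stay unlabelled and are excluded
from the per-trip proportion of time foraging.

## Space use

Utilisation distributions are isotropic bivariate Gaussian kernel
densities evaluated exactly at the centres of 1 × 1 km cells and
renormalized over the finite grid; renormalization is the edge correction,
and it guarantees the unit-mass invariant the overlap index requires. The
smoothing parameter defaults to the fixed 44-km value used in the original
protocol; the ad hoc reference bandwidth h = sqrt((var x + var y)/2) ·
n^(−1/6) is available when no override is set. The grid spans the bounding
box of all compared point sets padded by 3h, so all distributions share
one support. The X% volume contour takes cells in descending mass order
until the cumulative mass reaches X/100, including every cell tied with
the boundary mass (deterministic; under exactly uniform mass this returns
the full support). Overlap is Bhattacharyya affinity, BA = Σ √(p_i q_i).

## Seasonal statistics

* Trip bearings: circular mean direction with circular SD
  √(−2 ln R̄); seasons compared by the Watson–Williams high-concentration
  F test with the 1 + 3/(8κ̂) correction, κ̂ estimated from the pooled
  mean resultant length (Fisher's three-range approximation). A warning is
  emitted when κ̂ < 1, where the approximation is unreliable.
* Trip metrics: gamma GLMMs with log link, fixed effects season + sex +
  stage, crossed random intercepts for individual and year; the season
  effect is tested by a likelihood-ratio test of the full model against
  the same model without season (df = 1, the difference in parameters).
  No Python library in the dependency stack fits gamma-family mixed
  models, so the optimizer is delegated to R's lme4 through a batched
  Rscript bridge; the model formulas and the LRT live in Python. The
  bridge accepts many replicates per invocation so calibration studies
  cost one subprocess.
* Nest survival: the logistic-exposure model, η = logit(μ^(1/t)) for an
  interval of t exposure days. Fixed-effects fits use a statsmodels GLM
  with a custom exposure link (at t = 1 it reduces exactly to logistic
  regression); configurations with a nest/season random intercept delegate
  to lme4 with the standard custom logexp family.
* Environmental contrasts: percentile bootstrap (B = 10,000, seeded) of
  the difference in group means, 2.5/97.5 percentiles; percentile rather
  than BCa intervals, matching the stated protocol, with the point
  estimate taken from the raw data.

## Habitat selection

Nine daily variables enter the models: air temperature, total cloud
cover, rain, wind direction and speed, chlorophyll a, SST, wave direction
and height. Wind speed/direction are derived at annotation time from
stored zonal/meridional components; direction uses the meteorological
convention (degrees FROM which the wind blows), recorded in the layer
metadata. Annotation samples the nearest grid cell of the same-calendar-day
layer; rows with any missing value are dropped and counted (no
imputation).

Availability within a season is the opposite season's foraging locations
re-timed by sampling timestamps with replacement from the focal season's
empirical foraging-timestamp distribution (one re-timed copy per
opposite-season location, annotated once against the focal season's
layers). The design never invents coordinates: those places were
demonstrably reachable yet unused.

Three random-forest classifiers (500 trees, default tree controls,
seeded) are fitted: used-vs-available within each season and hot-vs-cool
on used locations. Internal cross-validation is realised as out-of-bag
prediction — each row scored only by trees that never saw it — reported
as per-class accuracy; this is fold-free and deterministic given the
seed. Variable importance is the mean accuracy drop over 10 seeded
permutations of each predictor, rescaled so the largest drop is exactly
100%. Partial dependence sweeps a 50-point grid over a variable's
observed range, predicting for every data row with that variable replaced,
and reports the per-grid median and 2.5/97.5% quantiles. Transferability
applies one season's model to the other season's set and reports the
per-class fraction predicted correctly.

## The synthetic two-season study

The generator exists so every stage is testable without any download. It
emulates: a single colony; two seasonal populations of 10 birds and 15
long trips each (plus 5/8 short neglect excursions), tracked over two
"years" per season in 30-day windows; 2-h fixes during incubation and 1-h
during chick rearing; and nine daily environmental layers on a 0.75°
grid within 1,500 km of the colony.

Movement is a two-mode biased correlated random walk, not an
optimal-foraging model — the pipeline only needs known bearings, ARS
patches and trip envelopes, which a CRW controls directly. Long trips
draw a destination bearing from a von Mises around the seasonal mean
(215° SW for hot, 131° SE for cool) and a distance around the seasonal
patch centre (500/550 km), commute outbound, switch to a slow tortuous
ARS walk (2–5 km/h, uniform turning) for the remainder of the trip
duration (drawn from the seasonal duration distributions, 136 ± 47 h hot
and 117 ± 58 h cool), and home straight back. All step speeds stay below
30 km/h, so the 50-km/h filter removes nothing by construction. Neglect
trips are sub-day excursions within ~90 km with a westward (271°) bias,
and nest-attendance records mark those days on duty.

Parameter choices worth stating explicitly:

* **Per-trip bearing concentration κ = 18** (~14° circular SD), much
  tighter than the spread of realized distal bearings reported for the
  real populations. The tight value encodes inter-annual site fidelity —
  both populations return to the same seasonal foraging area year after
  year — and keeps simulated foraging inside the SST patch that defines
  the season's habitat signal. Wide independent per-trip draws would make
  each simulated "year" a different place, destroying the year-to-year UD
  overlap and the SST selection contrast that are the whole point of the
  two-season design. The printed bearing dispersions are instead honoured
  where they matter statistically: the circular-ANOVA calibration uses
  von Mises κ = 3 at the real sample sizes (n = 18/20).
* **SST field**: seasonal background (23.65 °C hot, 20.56 °C cool) plus a
  plateau-shaped anomaly — a super-Gaussian bump exp(−½(d/σ)⁶), σ =
  380 km — reaching the patch value (21.27 °C hot, 23.12 °C cool) at the
  seasonal foraging centre, with small AR(1) daily wander (0.12 °C) and
  cell noise (0.05 °C). The plateau keeps used locations near the patch
  value so the used/available SST contrast has the clean separation the
  study reports, while the opposite season's locations sit on the
  background.
* **Other variables** are seeded noise fields around season-specific
  means with enough day-to-day and cell-to-cell spread that their
  seasonal contrasts overlap between groups (as the study's summary
  tables show): air temperature partially coupled to SST (slope 0.6,
  noise 0.8 °C), chlorophyll weakly and negatively coupled to SST, steady
  trade winds (u = 5, v = −5 m/s → direction ≈ 315°, speed ≈ 7 m/s) plus
  noise, cloud/rain/wave fields around their seasonal means. SST is thus
  the only near-perfectly separating variable — which is what makes it
  earn the maximal permutation importance, as in the real analysis.
* **Travel speeds** differ by season (hot 15–25, cool 11–17 km/h) so that
  with near-equal trip durations and ranges, cool-season trips spend a
  larger share of time commuting; simulated dwell fractions come out
  ≈ 0.55 (hot) vs ≈ 0.3 (cool), mirroring the reported foraging-effort
  contrast. Chick-rearing trips (about a fifth of birds) are shorter and
  target the near edge of the seasonal patch.

What the generator does **not** emulate: location error, ocean-physics
realism (fronts, advection, seasonally drifting isotherms), prey fields,
wind-dependent flight, device failure, or behavioural states beyond the
two movement modes. Passing tests therefore demonstrate that the pipeline
recovers known structure from data with the study's design and printed
parameter values — not that the original field results are numerically
reproduced. The real analysis's headline numbers (75 trips, ~600,000 km²
UDs, specific BA values, the exact accuracy percentages) depend on the
deposited tracking data, which the package supports as an external-data
mode (`simulate: false` plus Movebank-style CSV, NetCDF layers and an
attendance table) but does not require.

## Calibration studies and problem sizes

The test suite exercises the statistics at these sizes, chosen to give
stable Monte-Carlo estimates at desk scale: gamma-GLMM type-I error over
200 null replicates (20 birds, 2 trips each, bird SD 0.2 and year SD 0.1
on the log scale, gamma shape 5) with the band 0.05 ± 0.04, and power
≥ 80% at a 2× seasonal mean ratio over 40 replicates; logistic-exposure
type-I error over 200 null replicates (60 one-interval nests, daily
survival 0.98); Watson–Williams rejection at α = 0.001 in ≥ 95% of 200
replicates at the seasonal bearing design; search-scale recovery within
[R/2, 2R] in ≥ 90% of 20 replicates for confined-walk patches of R = 20
and 40 km (dwell scaled as 3 h per km of radius so the walk actually
fills the patch). The full pipeline on the default bundle runs in about a
minute on one CPU.

## Numerical choices and degenerate inputs

* Distal-point, ladder-snapping and contour ties all break toward the
  earlier fix / smaller radius / inclusion, so no tie needs randomness.
* var(log FPT) needs ≥ 2 defined FPT values per radius; radii the trip
  never crosses yield missing columns, not errors.
* The Watson–Williams test refuses groups with a vanishing resultant;
  circular means are undefined below R̄ = 10⁻¹².
* Bootstrap and forest seeds derive from one master seed via numpy
  `SeedSequence` spawning, so every stage is independently reproducible
  and the whole run is deterministic (re-running with the same seed
  reproduces every output table byte for byte).
* The LRT statistic is clamped at zero against tiny negative optimizer
  slack; non-convergence of a mixed model raises rather than silently
  reporting.
* Degenerate inputs fail loudly with typed exceptions: empty or malformed
  track CSVs, tracks reduced below two fixes by the speed filter,
  single-fix trips, identical points for bearings, zero-variance
  bandwidths, grids that do not cover the data, non-positive gamma
  responses, and fully separated survival data.

## Known limitations

* The speed filter is the only location-quality control; there is no
  error model or smoother, so datasets with heavy-tailed location error
  need external preprocessing.
* The Watson–Williams approximation degrades at low concentration; the
  package warns but does not switch to a randomization test.
* Permutation importance is computed on the fitted set; with strongly
  correlated predictors it can split credit (the synthetic fields are
  built so this does not obscure the SST signal, but real data may
  differ).
* Annotation is nearest-cell, same-day; no bilinear interpolation in
  space or time.
* The lme4 bridge requires `Rscript` with lme4 on PATH; all other stages
  are pure Python.
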