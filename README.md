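# petreltrack

At-sea foraging analysis for central-place seabirds tracked with GPS:
trip segmentation, first-passage-time (FPT) foraging classification,
kernel utilisation distributions (UDs) with Bhattacharyya overlap,
seasonal statistics, and used-vs-available habitat selection — built for
the question of whether two seasonally segregated breeding populations of
band-rumped storm-petrels (*Hydrobates castro*) at the same colony forage
in different places and select different oceanographic conditions.

The package is aimed at movement ecologists who have Movebank-style GPS
deployments from a colony, daily environmental raster layers, and want
the whole chain from raw fixes to habitat-selection models as one
reproducible, seeded pipeline. A built-in synthetic generator emulates
the two-season study design end to end, so every stage is tested without
downloading any data.

## The analysis

1. **Preprocessing** — fixes requiring unrealistic travel (> 50 km h⁻¹
   sustained over 2 h) are removed; all geometry is great-circle on the
   mean-radius sphere, gridded work in an azimuthal-equidistant
   projection centred on the colony.
2. **Trips** — maximal runs of fixes > 20 km from the colony;
   `short_neglect` (incubation excursions ≤ 24 h, attendance-confirmed)
   vs `long` (> 5 fixes beyond 20 km); complete if the bird returns
   within 30 km. Metrics: duration, total distance, maximum range, and
   the bearing to the most distal point.
3. **Foraging effort** — FPT(r), the time to cross a circle of radius r,
   on hourly-interpolated trips; the per-trip peak of var(log FPT) sets
   the search scale, and locations with FPT above the across-trip mean at
   the population scale are classed as area-restricted search (foraging).
4. **Space use** — Gaussian-kernel UDs on a 1-km grid (bandwidth 44 km by
   default, or the ad hoc reference h = √((var x + var y)/2)·n^(−1/6));
   50/75/95% volume contours; overlap via Bhattacharyya affinity
   BA = Σ√(p·q).
5. **Statistics** — Watson–Williams circular ANOVA for trip bearings;
   gamma(log) GLMMs with crossed bird/year random intercepts and a
   likelihood-ratio test for the season effect (optimizer delegated to
   lme4 via Rscript); logistic-exposure nest-survival models; seeded
   10,000-rep percentile bootstrap for environmental mean differences.
6. **Habitat selection** — nine daily variables (air temperature, cloud,
   rain, wind direction/speed from u/v, chlorophyll a, SST, wave
   direction/height) annotated at locations; availability = the opposite
   season's foraging locations re-timed into the focal season; three
   500-tree random forests (used vs available per season, hot vs cool
   between seasons) with out-of-bag per-class accuracy, permutation
   importance scaled to 100%, partial dependence, and cross-season
   transfer.

## Worked example

Run the full pipeline on the built-in synthetic two-season study:

```python
import pandas as pd
from petreltrack import pipeline as pl

manifest = pl.run_pipeline(pl.PipelineConfig(out_dir="out", seed=1))
fpt = manifest["stages"]["fpt"]
print(f"population search scale: {fpt['search_scale_km']:.1f} km")
print(f"time foraging  hot: {fpt['prop_foraging_hot']:.1%}   cool: {fpt['prop_foraging_cool']:.1%}")
print(pd.read_csv("out/ba_overlap.csv").to_string(index=False))
sst = pd.read_csv("out/env_comparisons.csv").query("variable == 'sst_c'")
print(sst[["season", "contrast", "mean_used", "mean_available",
           "mean_difference", "lcl", "ucl"]].round(2).to_string(index=False))
```

prints

```
population search scale: 17.4 km
time foraging  hot: 50.5%   cool: 17.0%
           comparison       ba
     between_cool_hot 0.111149
within_cool_2018_2019 0.946994
 within_hot_2017_2018 0.924977
season          contrast  mean_used  mean_available  mean_difference   lcl   ucl
  cool used_vs_available      23.06           20.63             2.43  2.40  2.47
   hot used_vs_available      21.29           23.57            -2.28 -2.31 -2.26
  both   between_seasons        NaN             NaN            -1.77 -1.81 -1.74
```

Reading this: the FPT analysis finds a ~17-km search scale and hot-season
birds spending a much larger share of trip time in area-restricted search
than cool-season birds; the two seasonal UDs barely overlap (BA 0.11)
while each season overlaps strongly with itself across years (BA ≈ 0.93–0.95)
— spatial segregation with within-season site fidelity; and the
used-minus-available SST contrast has opposite signs in the two seasons
(hot birds select water ~2.3 °C cooler than what was available, cool
birds ~2.4 °C warmer), with bootstrap CIs excluding zero. The output
directory also holds per-trip metrics and summaries, per-location FPT
labels, UD contour areas, the Watson–Williams and GLMM test results,
variable importances (SST maximal in all three forest models), partial
dependence of predicted use on SST, and cross-season transfer accuracies.

The same pipeline runs on real data via a YAML config with
`simulate: false`, a Movebank-style tracks CSV
(`individual-local-identifier, deployment-id, timestamp, location-long,
location-lat`), per-season NetCDF environmental layers, and an optional
nest-attendance CSV.

There is also a thin CLI:

```bash
petreltrack simulate --seed 7 --out fixture_bundle   # write the synthetic bundle
petreltrack run-all --config config.yaml --seed 1    # full analysis
```

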