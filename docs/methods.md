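# Methods

## Unit of analysis and model

The pipeline treats the census tract as the neighborhood unit and the urban
area as the comparison frame.  Privilege is measured by the Index of
Concentration at the Extremes, ICE = (most − least)/total ∈ [−1, 1].  For
the combined race+income variant, "most" is non-Hispanic-white householders
in the top income brackets, "least" is Black householders in the bottom
brackets, and the denominator is the all-race householder count; the
race-only variant uses population counts by race/ethnicity and the
income-only variant uses the all-race bracket counts at both extremes.
Tracts with a zero denominator have undefined ICE; they are excluded from
quartiles and all downstream means and counted in the run log.  Undefined
privilege cannot be ranked, and imputing it would manufacture contrast where
there is none.

Income cutpoints approximate "top and bottom ~20% of householders" on a
bracketed table: cumulative sums run from each end of the bracket ordering
and the contiguous set whose share is closest to the target is kept.  On an
exact tie the extra bracket is included — overshoot (e.g. a 21% low set) is
tolerated rather than undershoot, because the extremes should not silently
shrink.  The high-end search is restricted to brackets above the chosen low
set so the two extremes remain disjoint even on degenerate tables.  Pooled
(default) and per-urban-area scopes are both supported; pooling keeps the
definition of "privileged" comparable across cities, while city-specific
cutpoints absorb inter-city income differences (a sensitivity option).

Quartiles are rank-based within each urban area with Q1 = least privileged.
Ties are broken by tract id (stable and reproducible); sizes differ by at
most one, with extras assigned to the lower quartiles.  A warning is emitted
when tied ICE values straddle a quartile boundary, since the split there is
an arbitrary (but deterministic) choice.

## Park geometry

Park polygons are sectioned by tract boundaries; a section is a
positive-area park∩tract intersection (zero-area boundary touches produce
no section, as they would carry no exposure weight).  Invalid geometries get
one `make_valid` repair pass.  Percent park unions overlapping park
footprints before dividing by tract area, so stacked polygons can never
produce > 100%.  The largest-intersecting-park metric uses the intersects
predicate (boundary touches included) and reports the park's full area, not
the clipped part — it is a size-of-access measure, and the accessible park
does not end at the tract line.

All geometry lives in a planar equal-area frame with km units, so polygon
area is Euclidean area.  Real-world data must be projected to an equal-area
CRS before entering the pipeline.

## Exposure aggregation

The zonal mean weights each raster cell by the exact area of its
intersection with the polygon, computed with vectorized rectangle-polygon
intersections.  Fractional weighting (not cell-center membership) matters
because park sections are routinely smaller than an exposure cell.  Nodata
cells are excluded from numerator and denominator, and every aggregate
reports its valid-weight fraction so consumers can flag aggregates dominated
by nodata (the pipeline records the fraction; no automatic rejection is
applied below it).

Tract park exposure is the section-area-weighted mean of section zonal
means; for disjoint sections this equals the zonal mean over their union.
The non-park mean (a sensitivity output) is the zonal mean over the tract
minus the union of its park sections.  The urban-area mean is defined as the
area-weighted mean over the full urban extent, land cells only — one of
several defensible definitions (tract-averaged or population-weighted being
others); it is fixed, documented here, and written into every result row.

NDVI composites follow the order: drop scenes with cloud coverage ≥ 20%;
per retained scene compute per-pixel NDVI with cloudy pixels masked; average
each pixel over its clear observations; then mask water.  Computing NDVI
per scene before the temporal mean (rather than averaging bands first)
keeps the index's normalization per acquisition.  Pixels with zero clear
observations become nodata, and an all-discarded stack is an error rather
than a silent gap.

## Disparity statistics

Tract-level park means are the observations.  Q1 vs Q4 is tested with
Welch's unequal-variance t-test, two-sided, with Welch–Satterthwaite
degrees of freedom — quartile groups have no reason to share a variance, and
Welch costs little when they do.  The percent difference uses the Q4 mean as
denominator: positive values mean the least privileged quartile is higher.
No multiple-testing correction is applied across cities or variables; the
run log records the number of tests performed so readers can apply their
own.  Cross-city summaries report the mean |Q1 − Q4| gap, its range, and
counts of cities significant at p < 0.05 by sign.

## The synthetic-city generator

The generator exists to give every stage a ground truth.  A city is an
n×n lattice of 1 km square tracts.  A linear gradient maps tract position to
a latent privilege score in [−1, 1] (default direction 45°, so privilege
rises toward one corner).

* **Demographics** (default 1200 householders/tract, 16 income brackets,
  matching the bracket count of the standard household-income table):
  bracket probabilities come from a discretized normal whose mean shifts by
  0.8·latent; within each bracket the non-Hispanic-white share rises and the
  Black share falls logistically in latent privilege and bracket rank.
  Counts are multinomial/binomial draws (`sampled`) or rounded expectations
  (`expected`); either way the combined ICE is monotone in the latent score
  in expectation, which is the property the pipeline tests rely on.
* **Parks** (default 60 squares, base areas uniform on 0.05–1.2 km²):
  placement acceptance and a size multiplier are both logistic in local
  privilege with bias 0.5 by default, planting the empirically observed
  pattern of larger and more numerous parks in privileged neighborhoods and
  overall park coverage near 9% of the urban area.  Bias 0 gives unbiased
  placement for null calibration.
* **Exposure rasters** (default 0.25 km cells, nested inside tracts): each
  cell is intercept + slope·latent(containing tract) + iid Gaussian noise.
  Defaults — NO2 12 − 1.0·latent ppb (sd 1.0), PM2.5 8 − 0.8·latent µg/m³
  (sd 0.8), WBGT 24 − 1.0·latent °C (sd 0.5), NDVI 0.35 + 0.025·latent
  (sd 0.05, clipped to [−1, 1]) — were chosen once so that with the default
  gradient (Q1/Q4 latent gap ≈ 1.2) the planted Q1−Q4 park contrasts sit at
  the magnitudes typical of large US urban areas: ≈ +1.2 ppb NO2, +1.0 µg/m³
  PM2.5, +1.2 °C WBGT against the least privileged quartile, and ≈ 0.03 NDVI
  in favor of the most privileged.
* **Scenes**: clear pixels carry NIR/Red bands whose normalized difference
  equals the truth NDVI exactly (constant band sum 0.5); cloud-flagged
  pixels get contaminated reflectances so that using them would visibly
  corrupt a composite.  A deterministic count round(cloud_scene_fraction ·
  n_scenes) of scenes receives a per-pixel cloud probability ≥ 0.35, forcing
  them over the 20% coverage threshold; the rest use cloud_pixel_fraction
  (default 0.10).  The water mask is a contiguous quarter-disc blob at the
  map corner covering 5% of cells by default.

Because raster cells nest inside tracts and each cell's value depends only
on its containing tract, the noise-free pipeline recovers the planted effect
exactly: Q1 − Q4 park exposure equals slope × (mean latent in Q1 − mean
latent in Q4) over the tracts that contribute park means.

What the generator does **not** emulate: irregular tract and park shapes,
spatial autocorrelation of exposure noise, within-tract privilege gradients,
population-density variation, raster/vector misalignment and reprojection
error, and real satellite radiometry.  Passing tests therefore demonstrate
the correctness of the algorithms and the statistical machinery under the
planted model, not robustness to those real-data features.

## Numerical choices

* Intersections with area ≤ 1e-12 km² are treated as zero-area touches.
* NaN is the undefined marker throughout (ICE, zonal means, park means);
  aggregates drop NaN observations and report per-quartile n.
* Cutpoint ties use an absolute tolerance of 1e-12 on cumulative shares.
* Degenerate Welch inputs (a group with < 2 values, or both variances zero)
  raise at the function level; the per-city sweep converts this to NaN
  statistics so a batch over many small cities does not abort.
* Determinism: one `numpy.random.Generator` seeded from the config drives
  the entire city generation in a fixed order, so identical (config, seed)
  reproduce byte-identical written artifacts.

## Problem sizes in tests and validation

The validation suite exercises the pipeline at sizes chosen to make the
statistical checks sharp while keeping the whole suite quick: effect
recovery and power use 20×20-tract cities (100 seeds for the power check);
null calibration of the Q1-vs-Q4 test uses 1000 cities of 8×8 tracts with
24 parks each — enough parks that fewer than ~2% of null cities lack the two
park-bearing tracts per quartile a t-test needs; geometry conservation runs
100 random small cities; the zonal oracle uses jittered fine-grid
integration at 150 subcells per cell edge.  The acceptance script simulates
8 default-sized (20×20) urban areas.

## Known limitations

* Park access is geometric: a park intersecting a tract counts regardless of
  whether residents can actually reach or use it.
* The urban mean definition (extent-wide, land cells) is one choice among
  several; medians of quartile differences from it shift under other
  definitions.
* No margin-of-error propagation from survey-style demographic estimates.
* No regridding/reprojection between raster resolutions: each variable is
  analyzed on its native grid.
* The ICE variants cover only the white/Black extremes by income; other
  combined race×income extremes are not available from bracketed tables of
  this shape.
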