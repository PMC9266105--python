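# Methods

## Scope and carriers

All gridded quantities travel as a `Raster`: a 2-D numpy array with an ESRI
ASCII-grid placement (lower-left corner, square cell, default 1 km) and a
nodata convention (NaN in float grids, an integer sentinel in categorical
grids).  Coordinates are 0-based row/col with cell-centre registration.
Zones are a categorical `ZoneMap` input — the regionalisation itself is out
of scope; the pipeline consumes whatever partition it is given.

## Feature space and edges

The dry/wet edges of a zone are estimated from per-NDVI-bin LST extrema.
Bins are half-open `[lo + k·w, lo + (k+1)·w)` with the last bin closed, so
every in-range pixel maps to exactly one bin.  Defaults: bin width
w = 0.01 NDVI (the conventional discretisation of scaled NDVI), minimum
bin occupancy 1 (every nonempty bin used), NDVI range (0.2, 1.0) with a
configurable list of zones fitted on (0.0, 1.0) — the treatment for
sparsely vegetated plateau-lake zones where the full range is informative.
Edges are ordinary least squares of the bin maxima (dry) and minima (wet)
on bin-mid NDVI.  Extrema, not per-bin quantiles, define the envelope; a
quantile option was considered and deliberately not implemented.  A fit
whose dry edge dips below its wet edge anywhere on the range is flagged
degenerate on the result rather than raised, so a batch run over many
zone-years can report rather than die.

## TVDI, compositing, smoothing, grading, mosaicking

TVDI is computed per pixel from the fitted edges evaluated at that pixel's
NDVI.  Pixels whose edges separate by less than ε = 0.5 °C (configurable)
become nodata and are counted as degenerate; noise can place LST slightly
outside the fitted envelope, and those values are clipped into [0, 1] with
the clipped count reported — clipping preserves the range invariant and the
grade partition.  Annual (and seasonal) inputs are maximum-value composites:
per-pixel maxima over the period, nodata only where every input is nodata.
Annual TVDI is computed from annual composites, not as a mean of monthly
TVDI.  NDVI sequences can be Savitzky–Golay filtered (window 5, order 2 by
default); NaN gaps are linearly interpolated before filtering and re-masked
after, and series shorter than the window pass through unchanged.  Grades
use lower-open/upper-closed intervals with the first interval closed at 0,
so the boundary values 0.2/0.4/0.6/0.8 belong to the class below and the
five grades partition [0, 1] exactly.  Zone mosaics take each pixel from
its own zone's grid and attach an edge-effect diagnostic: the mean absolute
TVDI difference over 4-neighbour pairs straddling a zone boundary versus
pairs within one zone.  Independently fitted edges make the boundary figure
larger; no moving-window smoothing across boundaries is attempted.

## Trend analysis

The per-pixel trend is the closed-form least-squares slope of annual TVDI
on the year index i = 1..n (algebraically identical to the OLS slope, and
oracle-tested against it).  Significance is the slope t-test with df = n−2,
two-sided — equivalent to testing the correlation coefficient in simple
regression.  Classes combine the slope sign with p cutpoints: p ≤ 0.01
extremely significant, 0.01 < p ≤ 0.05 significant, p > 0.05
non-significant; boundary p values go to the more significant class, and an
exact zero slope (a measure-zero event on floats) falls to "non-significant
increase" by convention.  Missing years are dropped pairwise with the index
kept; series shorter than 3 give nodata.  Perfect fits (zero residual
variance) get p = 0 for a nonzero slope, p = 1 otherwise.

## Climate-driver zoning

Per pixel over the annual series: partial correlation
r = (Rxy − Rxz·Ryz)/√((1−Rxz²)(1−Ryz²)) of TVDI with each climate variable
holding the other fixed, and the multiple correlation via
R² = 1 − (1−Rxy²)(1−r²_xz·y), which equals the coefficient of
determination of the two-covariate regression (both identities are
oracle-tested).  The |Rxy| = 1 limit is handled explicitly (R = 1).  Tests:
t = r·√((n−3)/(1−r²)) with df = n−3 (one controlled variable), two-sided;
F = (R²/2)/((1−R²)/(n−3)) with df = (2, n−3).  Classification: F not
significant → other drive types; else precipitation-driven or
temperature-driven when exactly one partial test is significant; otherwise
(both or neither) jointly driven — the rule table leaves the
both-significant cell open and it is assigned to the joint class.  Tests
are two-sided and no multiple-testing correction is applied: each pixel is
its own analysis, matching the field's practice for driver maps.

## Zone clustering

Nine indicators per zone: max, min, mean and SD of the zone-mean annual
TVDI series; the zone-mean trend slope scaled by 10³ (the published
indicator matrix prints slope-mean values spanning roughly −3 to 10, i.e.
raw TVDI/yr × 10³; the scale is configurable); and the area fractions of
trend classes 3–6.  Rows are clustered unstandardised with distance
d = 1 − Pearson(row_u, row_v) — already location/scale-invariant per row —
and average linkage, the common default for correlation-distance
"systematic" clustering.  The packaged reference matrix for the eight QTP
divisions reproduces its published three-group partition under average
linkage (and, as it happens, under complete, single and Ward as well, so
the result is not linkage-fragile).  Percent columns are converted to
fractions on ingest.  k is a parameter (default 3); no automatic selection.

## Random forest

Factors are aggregated to the analysis cell (default 4× the native cell,
i.e. 4 km from 1 km inputs): continuous factors by block mean, land use by
block mode with ties broken to the lowest category code, response TVDI by
block mean; rows with any missing value are dropped and counted.  The
forest (scikit-learn, 500 trees by default, other hyperparameters library
defaults, single-threaded for reproducibility) is fitted on exactly
⌊0.7·n⌋ rows chosen by a seeded index permutation.  Importance is the
impurity-based (variance-reduction) measure with one-hot land-use columns
summed back into a single entry, so the eight-factor ranking is stable in
structure.  Partial dependence is the classical kind: force the factor to
each grid value, average predictions over the sample; categorical factors
are evaluated per category.  Aspect (circular, 0–360°) enters as-is; its
circularity is a known caveat — a pixel at 1° and one at 359° are treated
as far apart.

## Soil-moisture validation

Point samples collocate to the nearest cell centre (points outside the grid
or on nodata drop; multiple points in one cell are averaged) and ordinary
least squares of moisture on TVDI is reported pooled and per year.  R²
equals the squared Pearson correlation by construction.  The headline check
is directional: the slope is negative and, on domains whose zones have
genuinely different edges, the per-zone product validates at least as well
as a single global fit.

## Synthetic scenes: what they emulate, and what they do not

The generator draws, from one root seed split in a fixed
`SeedSequence.spawn` order (NDVI, wetness, LST noise, climate, statics,
points):

* **Zones** — contiguous vertical strips, the simplest partition that makes
  mosaicking and edge-effect checks meaningful.
* **NDVI** — per-pixel Beta within zone (default Beta(2,2)), drawn once per
  year and held constant across that year's seasons so a maximum-value
  composite pairs a pixel's LST extreme with that same pixel NDVI; an
  optional mean filter adds spatial autocorrelation, and values are snapped
  to the 0.01 grid-centres, emulating the discreteness of scaled satellite
  products and aligning pixels with the conventional bins.
* **Latent wetness** — a static per-pixel base drawn uniformly on a
  tail-widened interval and clipped to [0, 1] (the clipping plants genuine
  fully-dry and saturated pixels — the physical anchors that make the edges
  observable), plus a per-zone annual drift (default −0.004/yr for most
  zones, +0.004 for the last two, mirroring a humid-south/drying-north
  contrast), optional couplings to standardised interannual climate
  anomalies, and i.i.d. noise.
* **LST** — wet edge + (1 − wetness)·(dry − wet) + Gaussian noise truncated
  at 3σ (default σ = 1 °C), so true TVDI = 1 − wetness exactly at σ = 0.
* **Climate** — base + linear column gradient (−2 mm/cell, −0.03 °C/cell)
  + annual trend (−0.39 mm/yr precipitation, +0.02 °C/yr temperature, the
  weak plateau-scale trends the study design targets) + pixel noise.
* **Statics** — a smoothed random elevation surface with slope/aspect from
  its gradient, Euclidean distance transforms to randomly placed water and
  built-up cells, and a grassland-dominated categorical land-use field.
* **Soil moisture** — 50 points/yr at random vegetated pixels, summer
  wetness rescaled to volumetric fraction (0.05 + 0.40·wetness) plus noise
  of 0.02; volumetric fraction is the documented unit choice.

Not emulated: orbital/compositing artifacts, cloud masks, seasonal
phenology (NDVI is constant within a year), spatially structured climate
anomalies, or real plateau geography.  Passing parameter-recovery tests
therefore demonstrates correctness of the estimators under the stated
generative model, not skill on real MODIS scenes — in particular the
edge-fit tests say nothing about edge stability under real NDVI–LST
dependence structures.

## Problem sizes and numerical choices

Recovery checks run on single-date two-zone scenes of 300×200 cells
(30,000 pixels/zone, comfortably above the 10⁴/zone needed for ±10% slope
recovery at 1 °C noise); driver-zoning scenes use 60×60 cells × 18 years;
the end-to-end demo uses 120×120 × 20 years × 4 seasons; type-I
calibrations use 10,000 replicate series.  These sizes make every
Monte-Carlo margin comfortable while keeping a full run in seconds.
Tolerances: exact identities are asserted at 1e-8–1e-10 (they measure at
machine precision); calibration rates at ±0.01 around 0.05.  Degenerate
inputs (constant series, collinear controls, empty zones, all-nodata
points) return NaN/nodata or raise with the offending zone named, as
documented per module.
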