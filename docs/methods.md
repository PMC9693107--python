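# Methods

## Scope and data model

The pipeline estimates monthly vegetation net primary productivity (NPP) on
a common raster grid with the CASA light-use-efficiency model and quantifies
earthquake impact per seismic-intensity zone with three indices:
vulnerability S, resilience R and impact coefficient I = S·(1−R). Everything
flows through one container, `RasterGrid`: a single-band 2D field with an
axis-aligned north-up affine georeference, an explicit nodata sentinel and a
free-text CRS label. Row 0 is the northernmost row, indices start at the
upper-left cell, and coordinates refer to cell centers. Grids interoperate
only when shape, transform and CRS label all match; every operation
propagates nodata and never manufactures a valid value where all
contributing inputs are missing.

Rasters are stored as single-band GeoTIFFs written through tifffile with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, a GDAL nodata
tag, GeoAsciiParams for the CRS label); payloads are float32 on disk and
float64 in memory. Reprojection between datum families is out of scope —
alignment is affine resampling (bilinear for continuous fields, nearest for
categorical ones) onto a template grid, with a nearest-valid fallback
wherever a bilinear stencil touches nodata so that missing data can never
bleed numeric values into valid cells.

## Preprocessing

Monthly NDVI is a per-cell maximum-value composite of two sub-monthly
grids; a missing half falls back to the other with the maximum rule, and a
month with only one composite passes through with a logged warning.  NDVI is
clamped to ±0.999 before the simple-ratio transform so SR stays finite.

Station records (monthly mean temperature in °C, monthly total solar
radiation in MJ/m²) are interpolated to the working grid by ordinary kriging
with an exponential variogram fitted by weighted least squares on the binned
empirical semivariogram (deterministic given the inputs), or by
inverse-distance weighting with power 2 as the documented fallback when the
kriging system is singular or fewer than five stations exist. Both
interpolators are exact at station cells and return a constant field for
constant inputs; kriging logs a warning when it extrapolates more than 10%
beyond the station value range.

## CASA core

The chain is NPP = APAR·E with APAR = 0.5·SOL·FPAR and
E = TE1·TE2·WE·Emax; FPAR is the capped linear ramp of the simple ratio
SR = (1+NDVI)/(1−NDVI) between SRmin = 1.08 (unvegetated land) and the
per-class SRmax, capped at 0.95 and floored at 0. Numerical choices that the
model statement leaves open:

* `Topt` is computed per pixel from the months available in the processed
  year (argmax of NDVI, ties broken by the earliest month). The window is a
  parameter of the orchestration, defaulting to every month supplied.
* TE1 = 0.8 + 0.02·Topt − 0.0005·Topt² is floored at 0 — the quadratic turns
  negative above ≈55 °C, which is non-physical for a stress multiplier.
* WE = 0.5 + 0.5·ET/ETp is clamped to [0.5, 1]; cells with ETp = 0 take the
  dry floor 0.5 with a logged count, and ET > ETp (possible in externally
  sourced evapotranspiration products) is clamped to equality at scene
  construction with a logged count.
* Unvegetated classes (lake, rock) are evaluated with their parameter-table
  rows like any vegetated class rather than masked; masking is left to a
  region mask if the user wants it.
* NPP is floored at 0.

The shipped parameter table (nine classes, SRmax and Emax per class) is the
standard high-cold-altitude set for southwest China; users can substitute
any CSV with columns `class_code,class_name,sr_max,e_max`.

`casa_scalar` re-implements the full chain as straight-line scalar code and
serves as an independent oracle: the raster pipeline must agree with it at
randomly sampled cells to 1e-10 relative, which the test suite enforces.

## Zonal statistics

Zones are integer label grids (0 = outside) built from labeled polygons by
the cell-center-inside test; later polygons win overlaps, polygons sharing a
label union. Per zone the pipeline reports NPPmax, NPPmean and NPPsum over
valid cells only — a zone with no valid cell is flagged undefined, not
reported as zero. Area proportions by NPP class use nine half-open
30 gC/m²-wide bins by default (the last bin closed above), spanning the
0–270 gC/m² envelope of growing-season monthly NPP in this kind of system.

## Impact assessment

The dur-quake change is NPP(quake month) − NPP(month before); post-quake is
NPP(month after) − NPP(quake month). Sign partitions count strictly negative
and strictly positive cells; exact zeros are reported separately and enter
neither fraction nor the index bins.

Normalization anchors are always taken over the whole region, even when
proportions are then evaluated per zone. Two conventions are implemented:

* **oriented** (default): S is computed over declining cells with
  N = |ΔNPP| / max|ΔNPP| (largest decline → 1), R over gaining cells with
  N = ΔNPP / max ΔNPP. Because a shocked scene's dur-quake field is almost
  entirely negative and its post-quake field almost entirely positive, the
  oriented and raw conventions coincide on the dominant sign while keeping
  the meaning of S and R explicit (damage magnitude, recovery magnitude).
* **raw**: the literal signed min–max (region minimum → 0, maximum → 1) over
  all valid cells, applied identically to both periods.

Bins are half-open with the last closed, so a normalized value of exactly
0.2 belongs to the second class. The expected-value index Σ AᵢBᵢ requires B
to sum to 1; printed tables whose rows sum to 99.9–100.1% (rounding) are
renormalized with a warning. Indices are conventionally reported to three
decimals, and the reproduction path computes I from the three-decimal S and
R so that every reported (S, R, I) triple is internally consistent at the
reporting precision — with full-precision S and R the IX+ impact coefficient
would round to 0.212 rather than the reported 0.213.

A consequence of region-wide min–max anchoring worth knowing: uniformly
scaling the declines of the zone that holds the region's maximum decline
rescales the anchor identically and leaves that zone's normalized
distribution — hence its S — invariant. Monotonicity of S in injected damage
is therefore a between-zone ordering property, not a within-anchor-zone
absolute one; the tests check it in both forms.

## Synthetic scenes

The generator emulates a monsoon-climate alpine valley in the growing
season. Defaults (fixed once, at field-realistic values):

* 120×120 grid of 250 m cells (~30 km extent — a desk-scale stand-in for a
  720 km² park, configurable), months June–September 2017, earthquake in
  August 2017.
* Synthetic elevation 2000–4900 m rising southward with smooth relief;
  temperature is a seasonal valley-floor cycle (−4 to 18 °C) minus a
  6 °C/km lapse; monthly solar radiation cycles between 250 and 560 MJ/m²
  (≈18 MJ/m²/day midsummer under monsoon cloud), and the ET/ETp ratio
  between 0.45 and 0.8. These norms keep monthly NPP inside the 0–270 gC/m²
  growing-season envelope, which the tests assert.
* Land cover is a spatially coherent categorical field over the nine
  parameter-table classes (forest-dominated mix), drawn by thresholding a
  smoothed Gaussian field at the mix quantiles.
* NDVI per class follows a seasonal curve between a winter floor and a
  midsummer peak (e.g. 0.40–0.85 for needle-leaved evergreen forest) plus a
  static spatial texture and per-month noise (sd 0.02).
* Zones: three concentric intensity rings around the grid-center epicenter
  (IX+ core, VIII–IX ring, VII–VIII everywhere else; outer radii 0.25 and
  0.55 of the half-extent) and 128 circular geohazard patches (21
  landslides, 84 collapses, 23 debris-flow gullies; radii 2–4 cells),
  placed uniformly — together covering roughly a quarter to a third of each
  ring, comparable to the ~30% ecosystem share affected in the motivating
  event.
* The earthquake depresses NDVI multiplicatively inside geohazard patches by
  the enclosing ring's shock fraction (defaults 0.15 / 0.30 / 0.45), so the
  damage propagates into NPP through SR and FPAR as real vegetation
  destruction would; the following months restore a configurable recovery
  fraction (default 0.5) of the shock. The injected truth is recorded per
  zone for parameter-recovery tests.
* Randomness: one substream per variable keyed by (seed, fixed stream id),
  so scenes are bit-reproducible and adding a variable never perturbs the
  others. Station records are noisy point samples of the temperature and
  solar fields at 49 fixed random sites.

What the generator does not emulate: topographic shading, clouds, realistic
spatial covariance of mountain climate, mixed pixels, sensor noise
correlated with view geometry. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline and the recoverability
of injected effects — not calibration against real imagery.

Parameter recovery is measured as the Spearman rank agreement, within each
generated scene, between the injected per-zone damage (mean cell shock:
shock level × affected area fraction) and the computed zone S, averaged over
20 seeds; pooling raw (damage, S) pairs across seeds would conflate
scene-to-scene level shifts with the within-scene ordering the index is
meant to capture. With full injected recovery the impact coefficient falls
monotonically but not to zero: even complete NDVI restoration is
superimposed on the seasonal decline, so post-quake gains stay heterogeneous
and R saturates well below 1 — the same behavior the index shows on real
data.

## Problem sizes

Unit and property tests run on 1×1 to 48×48 grids; the parameter-recovery
and determinism checks use the generator's default 120×120 grid across 20
seeds. The published-index reproduction is pure desk arithmetic on the
shipped 8-row proportion table.

## Known limitations

* Kriging solves one dense system for all stations; intended for the
  ~50-station networks it models, not thousands of points.
* Alignment assumes both grids share an axis-aligned projected CRS; no
  datum transformations.
* The assessment uses single-month differences; multi-year baselines (e.g.
  same-month-previous-year comparisons) can be built from the zonal
  statistics but are not packaged as an index.
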