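# Methods

This note documents the models, defaults and numerical choices behind
`grazescape`, the way they interact, and what the synthetic-data tests do and
do not demonstrate about real data.

## The analysis in one paragraph

The question is whether a bulk-feeding savanna herbivore eats grass in
proportion to how much grass surrounds the places where it feeds. Two remote
measurements are coupled: (i) a categorical land-cover map of the woody-cover
gradient derived from a dual-date reflectance composite, summarised into a
scalar "grassiness" of the landscape inside circular buffers around each
faecal collection site; and (ii) the %C4 (grass) fraction of the diet
estimated from faecal δ13C through a two-endmember mixing model. The
diet–landscape relationship is then tested with simple linear regressions of
%C4 on grassiness, made robust to repeated collections at a locality by a
blocked resampling scheme, separately for dry and wet seasons and for four
buffer radii.

## Land-cover classification

Grass and woody canopies are spectrally confusable on a single date but
phenologically distinct: a senescent-season scene and a flushed-season scene
are therefore composited into a 12-band stack (six reflective bands per
date: blue, green, red, NIR, SWIR1, SWIR2), and a random forest is trained
on labelled points. Reference points are split into training and validation
sets by per-class alternation, which yields equal-sized disjoint sets.

Defaults: 500 trees, fixed `random_state` recorded in the output raster
metadata. The forest size is a conventional stabilising choice — per-pixel
class votes stop changing well below it — not a tuned hyperparameter.
Accuracy assessment follows standard confusion-matrix conventions: rows are
classified labels, columns reference labels; overall accuracy is
100·trace/total, user's accuracy is row-wise (commission), producer's
accuracy column-wise (omission). Classes with empty rows or columns are
reported as undefined (NaN), never as 0%. Printed percentages use decimal
half-up rounding to 2 d.p., which is the convention under which 372/410
prints as 90.73.

## Class scheme and grassiness index

The nine-class nomenclature stratifies the forest–grassland gradient at 25%
woody-cover intervals: closed deciduous woodland (CDW, 75–100%), open
deciduous woodland (ODW, 50–75%), discontinuous grassland (DG, 25–50%) and
continuous grassland (CG, 0–25%), plus agriculture, built-up, coniferous
plantation, bare and water, which sit outside the gradient.

The grassiness index of a buffer is the sum over the four gradient classes
of (percentage of buffer area × modifier), with modifiers ×1 (CDW) to ×4
(CG). The endpoints are fixed by the definition; the intermediate modifiers
2 and 3 are the linear integer interpolation — the only reading consistent
with a 4-point woody-cover scale. The index is linear in the composition,
ranges over [0, 400] for fully-gradient buffers, and equals 400 iff the
valid buffer is 100% CG.

One genuine ambiguity is the denominator: percentages can be taken over the
whole valid buffer area (water, bare and anthropogenic cover then dilute the
index) or over gradient-class area only. The default is the whole valid
area, on the argument that non-forage cover really does reduce the grass
available within a fixed range; `renormalise_gradient=True` switches to the
gradient-only denominator. Both are tested; the default is recorded in
output metadata.

## Buffer extraction

Membership uses the pixel-centre rule: a pixel belongs to a buffer when its
centre lies within the radius. Against 2–12 km radii and 30–100 m cells the
discretisation error of ignoring partial pixels is far below every other
uncertainty in the analysis; the rule is recorded in run metadata. Exact
equivalence with an exhaustive brute-force distance loop is asserted in
tests up to 200×200 rasters.

Edge and nodata handling: proportions are computed over valid member pixels
only, and each profile reports the valid fraction (valid members / all
members on the infinite lattice). Profiles below a configurable minimum
valid fraction (default 0.5) are excluded from analysis rather than silently
kept; a buffer with zero valid members is flagged, and a buffer with no
member pixel inside the raster at all is an error. When the radius is too
small to capture any pixel centre, the pixel containing the point stands in,
so single-pixel buffers behave sensibly. Coordinates are interpreted in the
raster's projected CRS (metres); a degree-unit raster is rejected rather
than reprojected.

## Isotope mixing model

With δ_C3 and δ_C4 the plant endmember compositions (‰ VPDB) and ε the
diet–faeces discrimination,

    %C4 = 100 · ((δ_faeces − ε) − δ_C3) / (δ_C4 − δ_C3),

clamped to [0, 100] with a QC flag when the raw value falls outside; the
inverse map is used by the sample generator so the round trip is exact to
well below analytical precision. Endmembers are configuration, not
constants: the defaults δ_C3 = −27.0‰, δ_C4 = −12.5‰, ε = −0.9‰ are typical
savanna values, and season/region override tables accommodate known spatial
and temporal variation in plant compositions. Analyses that start from
deposited per-sample %C4 bypass this module entirely, so its defaults never
touch reproduction of published regression results. Analytical precision of
<0.1‰ propagates to <0.8 %C4 at any endmember separation ≥ 12.5‰.

## Blocked permutation regression

Most localities contribute several specimens per sampling interval, so an
all-specimen OLS is weighted toward heavily collected localities. Each
iteration draws exactly one specimen uniformly at random from every
locality × interval unit and fits the OLS of %C4 on grassiness; 10³
iterations give the permuted mean and 95% confidence limits of r², intercept
and slope, and the Monte Carlo significance

    p̂ = 1 − (# iterations with p < 0.05) / iterations,

with α = 0.05. The confidence limits default to mean ± 1.96·sd/√iterations
(the standard error of the permuted mean, matching the very narrow intervals
this framework prints); percentile limits of the iteration distribution are
available behind `cl_mode="percentile"`. With one specimen per unit the
procedure degenerates exactly to the single OLS fit with zero-width limits
(enforced explicitly, so no floating-summation residue leaks into the
interval). An alternative within-unit label-shuffle scheme
(`scheme="shuffle"`) is provided for sensitivity analysis only.

Season contrasts (null: dry ≤ wet, on r² or slope) use the paired
per-iteration differences: the two-sided empirical p is twice the smaller
tail fraction of the differences, capped at 1, then halved for the one-tailed
test. Identical draws give p = 0.5 exactly; complete separation reports the
Monte Carlo floor (below 1/iterations) and a flag, never 0. p̂ itself follows
the printed formula literally and may be 0.

Reproducibility: one seeded generator drives a whole report in a documented
order (radius-major; both, dry, wet per radius; units in sorted
(locality, interval) order; `iterations` uniform draws per unit), so reports
are bit-identical under a fixed seed. Under different seeds, permuted means
agree within Monte Carlo error (tested at 3× the combined standard error).

OLS itself is the closed-form normal-equations fit, vectorised across
iterations, with the two-sided slope t-test p-value; it is verified against
an independent closed-form oracle in tests. Degenerate inputs: fewer than 3
points or a constant predictor are errors; a constant response returns
slope 0, r² 0, p 1; a perfect fit returns p 0.

## Synthetic-data generator

The generator defines the conditions under which the framework is tested.

**Landscape.** A standard-normal field, smoothed by a Gaussian kernel of
scale `autocorrelation_length` (wrap-around boundaries), is rank-thresholded
at the mixture quantiles, so class proportions are exact to one cell
(largest-remainder apportionment) and patchiness is tunable by a single
length. The default mixture is the published coverage of the study
landscape: CG 40.8%, DG 32.7%, ODW 21.6%, CDW 4.1%, bare 0.6%, water 0.1%
(renormalised over the six generator classes). The default grid is 400×400
cells of 100 m (a 40×40 km tile) with a 4 km correlation length. No
published number fixes these last three; they were chosen once, before any
acceptance measurement, by a design (power) argument: at a 4 km patch scale
the 4-km-buffer grassiness spread across localities (s.d. ≈ 65 index units)
makes the standard error of a recovered slope ≈ 0.01 at the default sample
sizes, so slope-recovery checks test the method rather than sampling noise.
A much shorter correlation length would average away between-locality
contrast at the buffer scale and turn those checks into coin flips without
making the landscape more realistic.

**Samples.** Localities are placed uniformly at random on non-water cells
(an error if the count exceeds placeable cells). For each locality × monthly
interval, a uniform 1–8 specimens are generated (most localities therefore
have repeated collections), each with true
%C4 = a_season + b_season · G + N(0, σ), clamped to [0, 100], where G is the
locality's grassiness at the 4 km reference radius (the species' mean daily
range). Defaults are the fitted 4-km seasonal models: a_dry = −2.3,
b_dry = 0.10, a_wet = 36.8, b_wet = 0.04, with σ = 10 %C4, 100 localities
and six months spanning both seasons (Jan, Mar, May, Jul, Sep, Nov; May–Oct
is dry — the month-to-season mapping is the southern-hemisphere convention,
stated here because the source does not print one). δ13C is back-computed
through the inverse mixing model, so the isotope stage recovers the true
%C4 exactly.

**What passing tests do and do not show.** The generator reproduces the
*statistical* structure the analysis assumes — spatial autocorrelation,
locality clustering, repeated collections, season-dependent linear diet
response with additive Gaussian noise, clamping. It does not simulate
reflectance, phenology, non-linear or threshold foraging responses,
spatially correlated residuals, or observation error in sample coordinates.
Parameter-recovery results therefore validate the estimator and its
implementation under the stated model, not the ecological model itself.

## Pipeline

A single YAML config drives classify → buffers → grassiness → isotopes →
permutation report. Stages skip when their inputs are supplied pre-computed
(a classified raster; a samples table already carrying `pct_c4`, the route
for deposited per-sample data), and skipping is recorded in the metadata
sidecar together with seeds, library versions, a config hash and per-stage
timings. Outputs other than the metadata sidecar are byte-reproducible under
a fixed config and seed. Rasters persist as ESRI ASCII grids (a plain-text,
GDAL-readable format); reflectance stacks as multiband TIFF or `.npy` with a
JSON geometry sidecar; points as CSV or plain GeoJSON.

## Problem sizes used in the bundled checks

The bundled tests and the acceptance script run the generator at its default
sizes (400×400-cell landscape, 100 localities × 6 intervals, 10³ permutation
iterations; 50 replicates for the null-slope coverage check) — the same
sizes the defaults document above, chosen as the package's standard demo
scale. Oracle-equivalence checks use rasters up to 200×200.

## Known limitations

* The published accuracy table is reproduced from its printed counts; the
  imagery, training polygons and classifier hyperparameters behind it are
  not public, so the classification itself cannot be re-derived.
* Reproduction of the published permutation-regression table requires the
  study's deposited per-sample table, which is not redistributable with this
  package; the corresponding test stays red until a user supplies
  `data/kruger_supplemental_s1.csv` (columns: locality_id, interval, season,
  pct_c4, grassiness_2000 … grassiness_12000).
* The exact construction of the pre-halving season-comparison p-value is an
  interpretation (paired iteration differences); it reproduces the stated
  endpoints (0.5 under identical draws, sub-floor under separation) and is
  documented above.
* Whether buffers were clipped to the park boundary in the original analysis
  is unstated; here truncation is handled by the valid-fraction rule, and a
  boundary mask can be emulated by setting outside-park pixels to nodata.
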