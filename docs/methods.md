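# Methods

This note documents the models, estimators and numerical choices behind
`auvspat`, and what the synthetic-survey tests do and do not demonstrate
about real survey data.

## Survey geometry

**Frames and rotation.** World coordinates are metric easting/northing/up;
the vehicle body frame is forward/starboard/down. Attitude is applied as an
intrinsic Z–Y–X rotation (yaw = heading clockwise from north, then pitch
nose-up, then roll starboard-down), composed in the north-east-down frame
and re-expressed in east-north-up. The published record of the method names
only "a 3D rotation matrix calculation", so the composition order and sign
conventions are this package's choice; they are pinned by unit tests
(heading 90° maps body-forward to east) and cross-checked against an
independent quaternion implementation.

**Footprints.** Each camera is a pinhole view cone: four corner rays at
±half-FOV (along/across) around the boresight, the boresight depressed 90°
(vertical camera) or 35° (oblique camera) below horizontal. Rays are
rotated into the world frame and intersected with a horizontal plane at the
measured altitude below the vehicle. The seafloor under a single image
(metres across) is treated as flat; bathymetric slope matters only at the
scale of the hill, not of a footprint. A ray that fails to descend (extreme
attitude on the oblique camera) marks the image invalid and removes it from
survey effort. Footprint area is the shoelace area of the projected
quadrilateral. The exact tilted-projection area grows like
(tan(θ+h) − tan(θ−h)) / (2 tan h) per tilted axis — about +2.5 % at 5° roll
for the 14.8° across half-FOV — so attitude noise slightly inflates mean
area; this is real geometry, not error.

**FOV calibration.** The lens specifications are not part of the survey
record, but the level-pose footprint areas at the 3.2 m target altitude
are: 2.4 m² (vertical) and 16.5 m² (oblique). `calibrate_fov` inverts the
projection for the half-FOV angles — closed form for the vertical camera
(area = 4 h² tan α tan β with tan β/tan α fixed by the 2448:2048 pixel
aspect), Brent root-finding on the tangent scale for the oblique trapezoid.
Re-projection reproduces the target areas to well within 1 %.

**Image selection.** Photographs outside 1.9–4.1 m altitude are dropped
(both cameras). Consecutive oblique images overlap ~80–85 % at the 0.87 s
interval, so the oblique series is decimated to every second image;
vertical images are all retained. Survey effort is the sum of retained
footprint areas.

## Synthetic surveys: what they emulate

The generator reproduces the study conditions end-to-end: a 4850 m plain
with an isotropic Gaussian hill of 240 m (σ = 850 m puts the 4800 m contour
~1.5 km from the summit, matching a summit at ~4610–4615 m); a 10×10 km
boustrophedon broad grid at 1 km spacing (11 lines) and 1×1 km crosshatched
fine grids at 90 m spacing; pose fixes every 2 s with independent Gaussian
jitter (σ: 0.3 m altitude, 2° pitch/roll, 1° heading); photographs every
0.87 s interpolated within lines. Vehicle speed is not part of the survey
record; 1.2 m s⁻¹ is used so that 100 images ≈ 100 m (vertical) and ≈200 m
(retained oblique), consistent with the published image-to-distance
conversions.

Fish are dimensionless points with taxon labels drawn from fixed
multinomial proportions (two dominant macrourid morphotypes at 41/37 %,
two common scavengers, a residual class). Placement regimes:

* **csr** — homogeneous Poisson at intensity λ (individuals km⁻²);
* **thomas** — Poisson parents (λ / mean offspring) with Gaussian-displaced
  offspring (σ default 50 m), parents drawn on a 4σ-padded region;
* **hardcore** — sequential dart throwing with a minimum inter-point
  distance (cell-list search); infeasibly dense requests terminate at an
  attempt cap with fewer points;
* **covariate** — inhomogeneous Poisson with relative intensity
  exp(−d/τ), d = distance to the hill summit, normalised on a quadrature
  grid so the spatial mean equals λ, sampled by thinning.

Patterns are always generated on a region padded 50 m beyond the survey
bounds: fauna exists beyond the surveyed box, and an unpadded pattern
edge-truncates boundary footprints, which measurably biases both densities
and the distance-to-contour null (boundary images sit far from the central
hill).

**Detection.** A fish inside a footprint polygon yields one observation;
a fish covered by several overlapping images is reported once, in the image
whose capture position is closest — the duplicate-suppression rule used
when the same individual appears in sequential photographs. Detection is
deterministic given pattern and footprints (STRtree containment queries).

**What the generator does not emulate:** fish movement and vehicle
avoidance/attraction, body size and orientation, misidentification,
navigation drift, terrain-following lag, and image-quality variation.
Passing calibration tests therefore demonstrates that the *estimators* are
correct and calibrated, not that real surveys are free of observation
bias.

## Density estimation

Density is the ratio estimator Σcounts/Σareas on the km² scale.
Uncertainty comes from resampling *images* with replacement (the image
carries both its count and its area, keeping the ratio well defined per
replicate), 10,000 replicates by default, percentile 2.5/97.5 bounds.
Group contrasts use the CI-overlap rule: significant iff the closed
intervals are disjoint.

One estimator property matters when footprints overlap: duplicate fish are
counted once, but effort sums areas, so the area-normalised density is
conservative in proportion to the overlap fraction (~26 % for vertical
images at the 0.87 s interval, more for oblique even after decimation).
This mirrors the original effort accounting, and is consistent with the
oblique camera reporting systematically lower densities than the vertical
one. The bootstrap-coverage calibration therefore runs on a survey
configured with a 2.0 s interval, where vertical footprints tile without
overlap and the detected count is exactly Poisson with mean λ·Σareas;
measured coverage of the 95 % CI is ~95 % over 200 replicates.

Depth split: images are classed elevated (< 4840 m at the footprint
centre, nearest-cell sample) or plain (≥ 4840 m); the exact-threshold tie
goes to the plain, a zero-probability event for continuous synthetic
bathymetry.

## Terrain association

Contours are extracted by marching squares with linear interpolation
(`skimage.measure.find_contours`) at 4800/4750/4700/4650 m. Distances are
computed by rasterising each contour (segments densified to half-cell
steps) and taking a Euclidean distance transform, sampled at footprint
centres — faithful to the raster-grid workflow of the original analysis
and within cell·√2 of exact segment distance (verified against shapely).

The two-sample KS statistic D is the sup-norm ECDF distance, evaluated
tie-aware at run ends of the pooled sort. Significance comes from a pooled
bootstrap: both groups redrawn (sizes preserved) with replacement from the
pooled sample, p = (1 + #{D* ≥ D}) / (n_boot + 1), so p is never zero and
the null is consistent with "no difference" even under heavy ties (raster
distances tie frequently). Whether the original procedure pooled before
resampling is not recorded; pooled resampling is the null-consistent
choice and calibrates at 3–8 % rejection at α = 0.05 on CSR surveys. No
multiple-testing correction is applied across the four contour levels;
results are reported per level.

## Dispersion

**1D neighbour-K.** Retained images are ordered in time and placed at
rank × metres-per-image (median within-line spacing), implementing the
assumption that survey lines are contiguous; K(t) is the mean number of
other individuals within along-track distance t of an individual, with no
edge correction. Multi-fish images contribute coincident positions. The
null scatters N individuals over N distinct randomly chosen images (1,000
replicates by default); L(t) = K(t)/mean(K_null(t)) − 1 anchors randomness
at 0 (ratio rather than difference, since K scales with intensity), and
verdicts per t compare K against the 2.5/97.5 envelope. t is expressed in
images and converted to metres for reporting.

A packing constraint limits what the broad survey can detect: a planar
hard-core pattern requires λπr² ≲ 1, and a photo strip of width w only
preserves along-track spacings ≈ r when w ≳ πr. At realistic intensities
(λ ≈ 700 km⁻², so r ≲ 20 m) a 2–5 m strip cannot retain a detectable
inhibition signal — dispersion at these scales is essentially invisible to
the survey, consistent with the original surveys detecting almost no
non-random structure. The hard-core power study therefore feeds 1D
inhibited (circular hard-core renewal, exact minimum gap) along-track
patterns directly to the sequence statistics, which detect them with
power ~100 % at N = 150, r = 250 m over ~110 km of track; Thomas-cluster
power runs through the full 2D detection pipeline (σ = 50 m, λ = 700 km⁻²,
>80 % detection).

**Quadrats.** Each fine grid is an 11×11 quadrat (121 cells) whose centres
form the uniform lattice spanning the extent — the nominal intersections
of the horizontal and vertical survey lines (the 90 m line spacing yields
12 lines per orientation, so the lattice is the 11×11 idealisation at
extent/10 spacing). Images are assigned to the nearest centre (ties toward
the lower index). The dispersion index is the variance-to-mean ratio of
cell counts (sample variance, n−1); the null reassigns every photograph,
its fish count travelling with it, to a uniformly random cell (10,000
replicates), and the verdict compares the observed VMR with the 2.5/97.5
interval (with a 1e-9 relative guard so degenerate one-fish nulls read
random). Under CSR the "random" verdict rate is ~95 %.

## Community comparison

Each camera's retained images are shuffled (seeded) into four equal
groups (remainder dropped); per-group taxon densities form the abundance
matrix, optionally reduced to presence/absence (idempotent transform).
ANOSIM uses Bray–Curtis dissimilarities (Σ|u−v|/Σ(u+v); scale-dependent,
deliberately not normalised), average ranks for ties, R = (mean between −
mean within rank)/(M/2), and a one-sided permutation p with the add-one
rule — the conventional clustering alternative. SIMPER averages the
per-taxon terms |uᵢ−vᵢ|/Σ(u+v) over all between-group pairs; contributions
sum exactly to the mean between-group dissimilarity. Whether the original
subdivision balanced image counts or seabed area per group is not
recorded; equal image counts are used.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; identical seeds give bit-identical outputs, and pipeline
  reruns produce byte-identical `summary.json`.
* Percentile (not BCa) bootstrap intervals, matching the simplicity of the
  original description and keeping results reproducible.
* Boundary rules: closed altitude window [1.9, 4.1]; CI-overlap counts
  touching endpoints as overlap; depth threshold ties to plain; quadrat
  ties to the lower cell index; add-one permutation/bootstrap p-values.
* Bathymetry rasters default to 5 m cells; tests and the bundled pipeline
  run at 20–50 m for speed, with contour-distance tolerances scaled to the
  cell size (the distance transform is exact to cell·√2 at any
  resolution).
* Problem sizes in the test suite (e.g. 100–400 Monte-Carlo study
  replicates, 199–1,000 null replicates, reduced bootstrap sizes) are
  chosen to bound each study's Monte-Carlo standard error well inside the
  asserted bands while keeping the suite quick to run; the per-operation
  defaults remain the full published values (10,000 bootstrap, 1,000 KS
  bootstrap, 999 permutations, 10,000 quadrat reassignments).

## Known limitations

* The seafloor is planar under each footprint; on steep flanks oblique
  footprints would in reality be foreshortened or extended.
* Density is conservative wherever retained footprints overlap (see
  above); no detectability or avoidance correction is applied.
* The 1D neighbour-K concatenates lines with no treatment of line joins;
  apparent structure at t comparable to the line length should be
  interpreted cautiously (as in any contiguity-assuming transect
  statistic).
* GLM occurrence modelling, illumination correction, taxonomic
  identification, towed-vehicle layback estimation and multibeam
  processing are out of scope.
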