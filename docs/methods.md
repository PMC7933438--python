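# Methods

This note records the models, conventions and numerical choices behind
each pipeline stage, what the synthetic phantoms do and do not emulate,
and the known limitations.

## Coordinate and unit conventions

All volumes are `(z, y, x)` arrays with per-axis voxel spacing in
micrometres; a voxel's physical position is `index × spacing`
(voxel-centre convention).  Micrometres are used internally everywhere;
volumes are converted to mm³ (÷10⁹) and curvatures to mm⁻¹ (×10³) only at
the reporting boundary, because thickness thresholds are naturally stated
in µm while organ volumes are naturally mm³.  Masks are written as 8-bit
0/255 TIFF; zone partitions as 8-bit labels (0 background, 1 infarct,
2 border, 3 remote).  NIfTI voxel sizes are interpreted as millimetres
and converted on read.

## Phantoms

Two generators provide seeded synthetic data with exact voxel-level
ground truth, mirroring the two imaging regimes of a light-sheet infarct
study: whole-heart overview scans for chamber morphometry and wall
thickness, and high-resolution patches for vasculature.  One phantom
cannot carry both faithfully at desk scale — resolving < 10 µm vessel
lumina over a ~7 mm heart would need grids of ~10¹¹ voxels — so the split
itself is a deliberate design choice.

**Whole-heart phantom.**  An analytic chamber solid (cone, capped cone or
prolate ellipsoid; optionally rotated to exercise principal-axis
recovery) is voxelised, then wrapped in a myocardial shell whose
thickness is prescribed per angular sector and apico-basal position via
the Euclidean distance transform from the chamber surface.  The reference
diastolic heart uses semi-axes 2.2 × 1.1 × 1.1 mm (11.15 mm³ chamber,
4.4 mm long axis — passing the diastole filter) and a 600 µm healthy
wall, with 30 µm voxels; the infarcted variant thins an apical 90° sector
to 250 µm with 5°-wide linear ramps back to 600 µm.  The narrow ramp
models the abrupt infarct-to-remote transition (~100 µm of arc) and
sweeps through the 300–500 µm border-zone range.  The opposite 120°
sector is labelled "septum" to exercise the LV-free-wall restriction.
The base can be opened (valve plane) by removing the wall plug inside a
configurable aperture cylinder, so the capping logic of the segmenter is
testable.

**Wall patch.**  Parallel bands of prescribed thickness (default
250/400/600 µm) sharing a base plane, at 5 µm isotropic voxels, each
seeded with straight random tubes (radius 4–5 µm, i.e. lumen diameter
8–10 µm; length 200 µm; uniformly random orientations) until the band's
target vessel volume fraction is met *exactly*: tubes mostly overlapping
existing vessels are rejected, vessel voxels are never double-counted,
and the last tube is trimmed in raster order.  Default fractions follow
the vehicle-treated infarcted LV: 7 % (infarct), 15.6 % (border), 21.9 %
(remote); treated-group means 8.2/18.9/23.8 % and a healthy-wall ~33 %
are used in the cohort design.  A straight-tube network suffices for
density and tubularity testing; branching topology is out of scope.

**Rendering.**  Both channels are piecewise-constant class intensities
(background 100, tissue 600, vessel 1500 by default) plus additive
Gaussian noise (σ = 30); the lectin channel carries no tissue
autofluorescence by default.  No PSF blur is applied unless requested, so
the ground truth stays exact.  All randomness flows from one
`numpy.random.default_rng(seed)`; identical (spec, seed) gives
bit-identical bundles.

**What the phantoms do not emulate:** light-sheet stripe artefacts,
depth-dependent attenuation, clearing-induced deformation, trabecular
fine structure, and realistic coronary branching.  Passing tests
therefore demonstrate correctness of the measurement operators under
known geometry and noise, not robustness to every real acquisition
artefact — the segmentation interface accepts externally produced masks
precisely so that learned segmenters can replace the classical default on
real data.

## Segmentation

Tissue: global Otsu threshold → binary opening (one 6-connected
iteration) → largest 26-connected component (ties broken to the earliest
raster label, for determinism) → fill enclosed holes smaller than 5 % of
the component, so noise holes close but the chamber cavity never does.  A
volume with no dominant component (largest below 0.3 % of the grid, e.g.
pure noise) is rejected rather than silently segmented.

Chamber: the valve-plane opening is capped by morphological closing with
a 1 mm ball (EDT-based, padded so the structuring element behaves at the
array border; the radius must exceed the aperture radius and stay below
the chamber radius).  The capped mask only defines the heart's interior
via hole filling; the chamber is then the largest 6-connected cavity of
the *original* tissue inside that interior.  This two-step construction
matters: closing alone would swallow narrow chamber features such as a
conical apex, which the cavity-within-interior step preserves.

Diastole QC applies strict inequalities (volume > 10 mm³, long axis
> 4 mm, both configurable) on cleared-tissue dimensions; long axis is the
chamber extent along its first principal axis.

## Morphometry

Principal axes are eigenvectors of the voxel-position covariance, ordered
by descending eigenvalue; the long axis points toward the farther chamber
extreme (the apex), the second axis takes a canonical sign, and the third
completes a right-handed frame.  Exact eigenvalue ties (a sphere) fall
back deterministically to grid axes.

The silhouette is the logical-OR projection of the chamber along the
third principal axis after nearest-neighbour resampling onto an isotropic
grid (pixel = finest voxel spacing).  A union projection was chosen over
a central slice because it is deterministic and insensitive to slice
placement.  Conicity uses one consistent base plane — through the chamber
centroid, perpendicular to the long axis — shared with the apex-volume
measurement.  Discretization conventions: silhouette rows crossing the
base line contribute fractional area; the fitted triangle's base and
height are measured over pixel cells (half a pixel beyond extreme
centres).  These conventions keep the conical anchor at 1.00 ± 0.02 and a
semicircular apex at π/2 ± 0.02 at the default resolutions.  Voxels
exactly on the base plane split half/half between apex and base, so the
two parts sum to the chamber volume exactly.

Meshing: marching cubes at the 0.5 level of the Gaussian-smoothed
(σ = 1 voxel) mask, scaled to µm, followed by volume-preserving Taubin
smoothing (λ = 0.5, µ = −0.53, 30 iterations).  Both steps suppress the
voxel staircase, which otherwise dominates discrete curvature; Taubin
with these coefficients does not systematically shrink the surface (the
sphere's area-weighted mean curvature stays within 0.3 % of 1/r).

Mean curvature is the cotangent-Laplacian mean-curvature normal with
Meyer mixed-Voronoi vertex areas; the sign comes from the dot product
with the outward vertex normal, so convex (outward-bulging) chamber
surface is positive and papillary/trabecular indentations are negative.
The histogram over the apical mesh half is area-weighted — marching-cubes
vertex density varies with surface orientation, so raw vertex counts
would bias it — with 64 bins on [−1, 1] mm⁻¹ by default and outliers
clipped into the end bins; the reported mean uses unclipped values.  The
sign convention and units (mm⁻¹) are package-wide choices; group
comparisons must be run under one convention consistently.  Per-vertex
curvature on voxel-derived meshes remains noisy at the voxel scale even
after smoothing (s.d. ≈ 0.3 mm⁻¹ at 40 µm voxels on a 2 mm sphere);
area-weighted summaries are accurate to a few per mille.

## Wall thickness

Local thickness at a voxel is the *diameter* of the largest sphere fully
inside the mask containing it.  The diameter convention is the natural
wall-thickness reading; a radius convention would halve every threshold
and contradict the 400 µm cardiomyocyte-loss cutoff.  Implementation:
the EDT (computed with physical per-axis sampling — anisotropic grids are
handled without resampling, avoiding interpolation artefacts in thin
walls) gives the inscribed-sphere radius at every voxel; centres whose
sphere is contained in a 26-neighbour's sphere (r_q ≥ r_p + |p−q|, a
lossless reduction by the triangle inequality) are dropped; surviving
spheres are painted in descending radius order by a numba kernel.  The
result is exactly the exhaustive per-voxel maximum, and the test suite
verifies bit-exact agreement with an O(N²) brute-force oracle on random
masks.  Sphere membership uses centre-to-centre distances, so a slab of
k voxels reads exactly k × spacing.

Zone cutoffs read "300–500 µm" as a closed interval: thickness exactly
300 or 500 µm is border zone.  At thickness steps (sector boundaries) the
measured map deviates from the nominal design in a band of roughly one
sphere radius — a property of the definition, not an implementation
error; the phantom's narrow-ramp transition keeps the designed thin-wall
volume recoverable within a few per cent.

The LV-free-wall restriction is, faithfully to practice, a passthrough
for user-supplied masks; the geometric default keeps tissue within a
configurable distance of the chamber surface and outside an angular
exclusion sector around a user-marked septal direction (how the original
workflow delineated the septum is not specified, so this default is an
explicit artifact decision).

## Vasculature

Vessel enhancement is multiscale Hessian tubularity of Frangi's form for
bright tubes: Gaussian second derivatives with per-axis sigmas =
scale/spacing (physical units, anisotropy-aware), s²-normalised, with
α = β = 0.5 and the structureness scale γ set per scale to half the
maximal Frobenius norm; the response is the maximum over scales
(default 2, 3.5 and 5 µm, covering lumen diameters below 10 µm).
Eigenvalues of the symmetric 3×3 Hessians come from the closed-form
trigonometric solution (vectorised; verified against LAPACK to 1e-8).

Thresholding defaults to hysteresis: Otsu on the vesselness distribution
inside tissue sets the high threshold, and connected voxels above a
quarter of it are kept.  Plain Otsu systematically clips the vessel rim,
where the tubularity response decays (Dice 0.74 vs 0.91 on tube
phantoms); hysteresis recovers the rim without admitting isolated
background.  A separation guard declares the volume vessel-free (empty
mask) when the above/below-threshold class means differ by less than
10-fold — any adaptive threshold must split a noise-only distribution,
and on vessel-free phantoms the guard is what keeps the false-positive
fraction at zero, while genuine vessel images separate 40–70-fold.  A
fixed numeric threshold remains available for exact reproduction of a
chosen cutoff.

Density uses zone tissue volume as denominator (vessel voxels included),
so whole-wall density is exactly the zone-volume-weighted mean of zone
densities.  Empty zones report density as undefined (None), never 0.

## Statistics

Tukey–Kramer is implemented directly from the studentized-range
distribution (`scipy.stats.studentized_range`) in its unequal-n form,
with pooled within-group variance on N − k degrees of freedom; it agrees
with `statsmodels.pairwise_tukeyhsd` to machine precision (the test suite
cross-checks at 1e-6).  Alongside the plain two-tailed two-sample t-test,
`group_compare` also reports Fisher-LSD p-values on the pooled ANOVA
error: against these the Tukey–Kramer adjusted p is mathematically never
smaller (both share the pooled SE; the studentized range of k ≥ 2 groups
stochastically dominates √2·|t|), which is the invariant the tests
assert.  No correction is applied across endpoints.

The percent-change formula defaults to the week-0 baseline,
100 × (week4 − week0)/week0; the alternative week-4 denominator (which
appears in some report conventions) is available behind the `baseline`
flag rather than guessed between.  Percent change is antisymmetric for an
equal-magnitude gain and loss only on the same baseline — a documented
asymmetry of ratio changes, covered by a property test.

The cohort design draws per-subject zone fractions around the group
means with 1 percentage point s.d. (consistent with the reported group
s.e.m. of ~1 % at n ≈ 10) and n = 6 per group; the designed border-zone
treatment effect (15.6 % → 18.9 %) is then detected by ANOVA/Tukey with
large margin.  ANOVA type-I calibration uses 2 000 vectorised null
simulations (3 × 10 standard normals).

## Problem sizes

Analytic anchors use 40 µm voxels (cone: 200³ grid; spheres/ellipsoids
~120³), whole-heart phantoms 30 µm (~200 × 130 × 130), wall patches 5 µm
(~135 × 240 × 50), oracle comparisons ≤ 64³, and the ordering study 20
replicates — sizes at which every reported quantity is stable to well
inside its test tolerance while the whole suite and the acceptance script
each run in minutes on a single CPU.

## Known limitations

* The classical chamber segmenter assumes a closed (or cappable)
  myocardial shell brighter than background; heavily damaged walls may
  need an externally supplied mask (the interface accepts one at every
  stage).
* Conicity inherits ~1 % discretization sensitivity from silhouette
  rasterisation; comparisons should keep voxel size constant within a
  study.
* Local thickness near mask boundaries and thickness steps reflects the
  maximal-sphere definition, not the nominal wall design; zone volumes
  at step boundaries carry bands of reassignment about one sphere radius
  wide.
* The vesselness γ parameter adapts per volume; absolute response values
  are therefore not comparable across volumes, only within (thresholds
  are computed per volume accordingly).
* Tukey–Kramer assumes homoscedastic groups; strongly unequal variances
  would call for Games–Howell, which is out of scope.
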