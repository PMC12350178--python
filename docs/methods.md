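# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data experiments do and do not
demonstrate about real microscopy data.

## Shape descriptor

**Construction.** An outline is a simple closed polygon in physical µm,
normalized to clockwise orientation in image coordinates (y down; clockwise
then means positive shoelace area). The descriptor centers the polygon on
its area centroid and computes, for D uniformly spaced directions and T
uniform thresholds on [−R, R], the Euler characteristic of the directional
sublevel sets. Two discretizations are provided:

* **exact (default):** the polygon is triangulated by ear clipping and
  filtered as a piecewise-linear complex under the lower-star rule (a cell
  enters at the maximum height of its vertices). The curve values are exact
  for the PL region, and rotating the polygon by a multiple of the direction
  spacing permutes descriptor rows exactly — crucial for the rotation
  invariance of the aligned distance.
* **raster:** the polygon is rasterized (pixel-center, even–odd rule) and
  filtered as a cubical complex (pixels with their edges and vertices,
  heights at cell vertices, ties broken vertices → edges → faces). This
  route also serves mask-level analysis and the χ = V − E + F operation,
  which equals 8-connected components minus 4-connected holes. Near
  tangents the pixel staircase produces transient χ excursions; the exact
  route is therefore preferred for descriptor work.

Each χ curve is centered to threshold-mean zero and cumulatively integrated
(trapezoid), the published smoothing of the transform. A consequence worth
knowing: the norm of the smoothed descriptor is *not* monotone in shape
size — for a disc in a fixed window it is largest when the filtration step
sits mid-window — so the norm is a signature magnitude, not a size readout.
Size and change-over-time are measured by distances, not norms.

**Defaults.** D = 72 directions, T = 128 thresholds, N = 256 raster pixels,
R = 1.25 × the largest centroid-to-vertex distance in a series. R is shared
across a time course so absolute compaction remains visible; per-frame
normalization would erase the signal being scored.

**Distance and alignment.** Distances are L2 with measure Δθ·Δt. With
alignment, the distance is minimized over rotations of one descriptor's
direction axis: all D integer cyclic shifts (evaluated directly, so identity
and grid-angle rotations align to exact zero) plus sub-grid rotations via
trigonometric interpolation of the circular cross-correlation (upsampling
factor 16). These rotations form a group of isometries, so the aligned
distance remains symmetric and satisfies the triangle inequality. For
shapes with sharp lobes the direction axis is undersampled at D = 72 and
an off-grid rotation leaves a residual of a few percent of the norm after
the best alignment; this is a genuine sampling property of the transform,
not an alignment failure, and vanishes for rotationally symmetric shapes.

**Temporal score.** d₀ is the first frame's descriptor magnitude (its
distance to the empty shape); d₁ is the distance from the final frame to the
first (a summed consecutive-interval variant is available as `mode="path"`).
The rotational alignment is estimated once on frame 0 (the direction of the
largest row norm) and frozen for the series: an organoid's orientation in
the well is common to all frames, and re-aligning each frame would absorb
genuine shape change. Clustering of morphologies uses average-linkage
agglomerative clustering on the aligned distance matrix with deterministic
first-occurrence relabelling; the choice of linkage is a package decision,
made for its robustness on compact, well-separated families.

## Bile-canaliculi pipeline

Stages, with defaults and the reasoning behind them:

* **median filter**, radius 1 voxel: standard speckle suppression, and it
  tightens the intensity histogram so the automatic threshold separates
  classes cleanly.
* **IsoData (intermeans) threshold** per channel, iterated from the global
  mean on the integer histogram to a fixed point, mask = intensity > t.
  Global histogram thresholds need a non-negligible bright class: below
  roughly 2% bright voxels the intermeans fixed point lands inside the
  background mode and the mask is dominated by noise. The downstream
  overlap/size/border filters tolerate a generous mask, but the phantom
  generator is parameterized to stay in the regime where thresholding is
  well behaved (see below).
* **overlap** of apical and cortical masks: the apical-patch seed; the
  cortical cell-border sheets and channel-specific false positives rarely
  coincide, so the AND suppresses both.
* **completion**: dilate k_in = 3 layers (6-connected), fill enclosed
  cavities (6-connected background reachability), erode k_out = 3 layers
  with the outside treated as foreground, making the operation extensive.
  Three layers (0.9 µm at 0.3 µm voxels) close the lumen of tubes up to
  ~2 µm diameter so hollow membrane shells become solid lumina.
* **filtering**: 26-connected components below 500 voxels (≈13.5 µm³)
  removed, then components touching excluded faces (all six by default;
  a lateral-only policy exists for thin stacks). Counts of both removals
  are reported.
* **local thickness**: largest-inscribed-sphere diameter per voxel
  (Hildebrand–Rüegsegger), computed by painting spheres from the distance
  transform ridge in decreasing radius, with unpainted voxels falling back
  to their own inscribed sphere. The sphere radius is the Euclidean
  distance to the nearest background-voxel center, the convention of the
  reference distance-ridge implementation; it reads a lone voxel as 2 voxel
  diameters and slightly over- rather than under-estimates tube diameters.
* **skeletonization**: homotopy-preserving 3D thinning; a component whose
  skeleton would vanish entirely (very small blobs) is restored as its
  single deepest voxel so component counts are preserved exactly.
* **network graph**: skeleton voxels classified by 26-neighbor count
  (endpoint 1, slab 2, junction candidate ≥ 3); adjacent candidates merge
  into one junction node, so a clean 4-way crossing is one quadruple
  junction rather than two triples. Thinning sometimes renders a crossing
  as two degree-3 points a couple of voxels apart; junction nodes linked by
  stubs shorter than 2.5 µm are therefore contracted into one node (real
  junctions in the synthetic ground truth are kept ≥ 4 µm apart, so the
  merge cannot conflate them). Branch length sums Euclidean voxel steps
  (1, √2, √3 × voxel size) including the step onto the junction node;
  branch diameter is the mean local thickness over the branch's voxels.
  The largest network is chosen by total length, ties broken by junction
  count then component id.

Diameter distributions use half-open 0.25 µm bins reported as percentages of
branches; values on a bin edge fall upward.

## SHG quantification

Maximum projection over z, inclusive band threshold (defaults 60–110, the
hand-selected band used for fibrillar collagen), selection restricted to the
polygon ROI interior (pixel centers at (col + 0.5, row + 0.5), even–odd
rule), RawIntDen = Σ pixel values, IntDen = area × mean (equal when area is
in pixels). An empty selection returns zeros with a warning, since absence
of collagen signal is a valid measurement.

## Statistics

The Mann–Whitney U test reports U = min(U_x, U_y) and a two-tailed p. For
n₁ + n₂ ≤ 20 without ties the p is exact: twice the smaller tail of the
closed-form null distribution (the Gaussian-binomial box-partition
recurrence), capped at 1. Ties in that regime fall back to a seeded
permutation distribution (10⁴ permutations); larger samples use the normal
approximation with tie-corrected variance and continuity correction. The
method actually used is recorded in the result. Kernel density curves use a
Gaussian kernel with Scott's-rule bandwidth; constant data requires an
explicit bandwidth (computed then as a direct kernel sum).

## Synthetic data: what it emulates, and what it does not

**Outlines.** Ball: r(θ) = R(1 + ε·η(θ)); grape: r(θ) = R(1 + a·cos kθ +
ε·η(θ)), with η a smooth periodic unit-amplitude Fourier noise field.
Defaults: R = 50 µm, k = 5 lobes, a = 0.35, 360 vertices. The default
frame-to-frame boundary noise is ε = 0.1% of the radius, the scale of
sub-pixel jitter from automated segmentation of a high-contrast boundary
(~0.05 µm on a 50 µm organoid). Time courses either re-noise the same shape
("static") or shrink the radius and lobe amplitude by 15% per frame
("compacting" — smaller and smoother), three frames at 2, 26 and 50 h.

**Tube phantoms.** A random tree-structured centerline graph in a 26 µm
cube: edges 5–9 µm, tube radius 1.0 µm, membrane thickness 0.6 µm (2
voxels, so the hollow-shell-to-solid-lumen completion is genuinely
exercised), junction separation ≥ 4 µm, non-adjacent centerline clearance
4.8 µm (tube surfaces stay separate through the completion dilations),
gentle bends (≥ 140°) at pass-through nodes — sharp elbows would weld shut
during closing and skeletonize into spurious loops — and ≥ 75° arm
separation at junctions. The apical channel is the hollow membrane shell of
each tube (the marker coats the lumen wall; expected measured branch
diameter is therefore 2r + h); the cortical channel adds planar cell-border
sheets. Intensities are 280 (membrane) over 100 (background, a detector
baseline that keeps additive noise unclipped) with additive Gaussian noise,
SNR = (fg − bg)/σ = 5 by default.

**Limits.** The generators model neither the optical point-spread function,
photobleaching, depth-dependent attenuation, anisotropic sampling, nor the
dense multicellular context of real stacks; intensity noise is additive
Gaussian rather than Poisson-dominated. Passing the synthetic recovery
checks therefore demonstrates the correctness of the measurement chain —
segmentation logic, topology bookkeeping, length/diameter calibration,
statistics — not robustness to every optical artifact of real data. On real
stacks the configurable stages (threshold method per channel, inflation
counts, size threshold, border policy) are expected to need study-specific
settings, which every run logs.

## Problem sizes

The shipped tests and the acceptance script run at the scale the analyses
are designed for on a single CPU: 200 random masks for the χ oracle, 40
shapes for clustering, 16 + 16 three-frame time courses, a 10-edge phantom
in an 87³ volume, and 50 replicates per noise level for the stability
sweep.
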