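# hepmorph

Quantification tools for liver organoid and assembloid imaging. The package
implements two bespoke measurement pipelines used to characterize hepatocyte
organoids, periportal assembloids and their fibrotic remodelling, exercised
end-to-end on synthetic shapes and phantom volumes with known ground truth:

1. **Temporal shape descriptors (ECT / DETECT).** Organoid morphologies split
   into two classes — smooth spheres ("ball", associated with cholestatic,
   non-draining structures) and lobed, folded shapes ("bubbly/grape-like",
   which form functional bile-canaliculi networks). Shapes are compared with
   the smooth Euler characteristic transform, and morphological change over
   time (e.g. fibrotic compaction) is scored by a distance ratio *d₁/d₀*.
2. **3D bile-canaliculi network features.** Two-channel fluorescence stacks
   (apical marker such as CD13 + cortical F-actin) are segmented, the lumina
   completed and filtered, and the skeletonized network measured: largest
   network length, triple/quadruple junction counts, branch diameters.
3. **SHG fibrillar-collagen readout.** Band-thresholded integrated density of
   second-harmonic-generation signal inside a hand-drawn region of interest.

Group comparisons use the exact two-tailed Mann–Whitney U test; diameter
distributions use 0.25 µm bins and Gaussian kernel density estimates.

## The shape descriptor

An organoid outline (a closed 2D polygon, exported clockwise in image
coordinates) is centered on its centroid. For each of D = 72 unit directions
v and T = 128 thresholds t spanning the raster window [−R, R], the Euler
characteristic curve of the sublevel filtration is

    ECC_v(t) = χ({x in shape : ⟨x, v⟩ ≤ t}),

computed exactly on the piecewise-linear complex of the triangulated polygon
(and available on a cubical pixel complex for mask inputs). Each curve is
centered to mean zero over thresholds and cumulatively integrated, giving the
smooth transform S(d, t) — a square-integrable signature that is invariant to
translation and turns rotation into a cyclic shift of the direction axis.
Distances between descriptors are L2 under the measure Δθ·Δt, optionally
minimized over rotations of one descriptor's direction axis.

For a time course the window R is fixed by the largest frame (so absolute
compaction is preserved) and the score is

    d₀ = ‖S(frame 0)‖   (distance to the empty shape),
    d₁ = distance(final frame, frame 0),
    ratio = d₁ / d₀.

A static organoid gives ratio ≈ 0; progressive compaction gives ratios near 1.

## The bile-canaliculi pipeline

median filter → per-channel IsoData (intermeans) threshold → voxelwise
overlap of the two channel masks → lumen completion (inflate, fill holes,
deflate) → size and border filtering → Hildebrand–Rüegsegger local thickness
+ homotopy-preserving 3D thinning → junction/branch graph per connected
skeleton component. A *network* is one connected component; its junctions
(degree ≥ 3 nodes, adjacent candidates merged) quantify interconnectivity and
its total length is the sum of branch lengths (Euclidean voxel steps ×
voxel size, default 0.3 µm isotropic).

## Worked example

```python
import numpy as np
from hepmorph.synthetic import ShapeSpec, gen_timecourse, random_tube_graph, gen_tube_phantom
from hepmorph.temporal import build_timecourse, distance_ratio
from hepmorph.bcnet import run_bc_pipeline

for mode in ("static", "compacting"):
    tc = build_timecourse(gen_timecourse(ShapeSpec(family="ball", seed=7),
                                         mode, shrink=0.15, seed=7))
    r = distance_ratio(tc)
    print(f"{mode:>10}: d0 = {r.d0:.2f}, d1 = {r.d1:.2f}, ratio = {r.ratio:.3f}")

gt = random_tube_graph(n_edges=10, seed=1)
vol = gen_tube_phantom(gt, snr=5.0, seed=1)
feats, row, _ = run_bc_pipeline(vol)
print(f"largest network: {feats.total_length_um:.1f} um "
      f"(ground truth {gt.total_length_um:.1f} um)")
print(f"junctions: {feats.triple_junctions} triple, {feats.quadruple_junctions} quadruple")
print(f"mean branch diameter: {np.mean(feats.branch_diameters_um):.2f} um "
      f"(ground truth {gt.expected_diameters_um()[0]:.2f} um)")
```

prints

```
    static: d0 = 176.28, d1 = 0.00, ratio = 0.000
compacting: d0 = 176.20, d1 = 167.76, ratio = 0.952
largest network: 69.9 um (ground truth 68.3 um)
junctions: 1 triple, 2 quadruple
mean branch diameter: 2.58 um (ground truth 2.60 um)
```

A static organoid scores a distance ratio of zero while a 15%-per-frame
compacting one scores ≈ 0.95, and the bile-canaliculi pipeline recovers the
phantom's centerline length within a few percent, its junction taxonomy
exactly, and branch diameters to well under one voxel.

## Command line

One entry point with four groups:

```
hepmorph simulate shapes|timecourse|phantom --seed N --out DIR
hepmorph shape score --outlines DIR --times 2,26,50 --out ratios.csv
hepmorph shape cluster --outlines DIR --k 2 --out clusters.csv
hepmorph bcnet run --apical a.tif --cortical c.tif --voxel 0.3 --out features.csv
hepmorph shg quantify --image shg.tif --roi outline.txt --lo 60 --hi 110 --out shg.csv
```

Every run writes a `manifest.json` with the resolved configuration, inputs,
package version and seed.

## Scope

Image analysis only: no culture protocols, no sequencing workflows, no
proprietary microscope formats, and no GUI. ROIs are drawn by hand upstream;
outline coordinate scale (pixel vs µm) must be supplied explicitly.
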