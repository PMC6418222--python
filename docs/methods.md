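# Methods

## Model and assumptions

The pipeline assumes grayscale images in which nuclei are darker than
the background (the loader can complement bright-foreground images), and
that a nucleus is a roughly oval, mostly convex object whose intensity
is lowest near its centroid and rises toward its rim. Everything else —
noise level, staining, illumination gradients — is handled adaptively;
no training and no shape priors beyond convexity are used. The single
scientifically meaningful parameter is ω_min, the minimum object size in
pixels (2D) or voxels (3D); it should be set near the smallest nucleus
one wants to keep.

Phase I classifies foreground locally: a global Otsu threshold finds
seed objects, the frame is partitioned into nearest-object watershed
regions, and each region with a seed larger than 0.1·ω_min is
re-thresholded on its own histogram. Phase II splits clustered objects
by watershed flooding of the quantized, cleaned saliency S = Ī − D̄.
Phase III rejoins over-split fragments using the size-and-convexity
nucleus model; phase IV re-thresholds each object in its own region
(keeping a strictly more convex replacement), removes objects below
ω_min, and leaves the rest untouched. Phases form a strict prefix chain;
disabling later phases yields the intermediate result.

## Numerical choices

- **Otsu thresholds** (global, per-region, and in correction) use
  scikit-image's exhaustive 256-bin search. The returned value is
  shifted from the center of the winning bin to its upper edge so the
  classification rule "value < threshold is foreground" captures the
  entire final foreground bin; without the shift, values lying above the
  bin center in the last dark bin are misclassified. Constant inputs are
  flagged degenerate and contribute no foreground.
- **Watershed regions** are computed as per-object Euclidean distance
  transforms with arg-min assignment; the first (lowest-id) object wins
  distance ties. This realizes the equal-distance-to-boundaries
  partition directly and is exactly reproducible by a brute-force
  nearest-boundary search, which the tests exploit.
- **Distance maps** use the exact Euclidean transform on the object
  crop padded with one background pixel, so border-touching objects
  still fall off at the frame edge; a foreground pixel adjacent to
  background has distance 1. Spacing-weighted (anisotropic) transforms
  are available but off by default.
- **Quantization of S** uses L = clamp(⌈size/(2·ω_min)⌉ + 1, 2, 10)
  thresholds, so the number of levels grows with the object. Thresholds
  minimize within-class variance: for up to 4 thresholds this is
  scikit-image's exact multilevel Otsu; beyond that the exact search is
  exponential in the class count, so thresholds come from a
  deterministic Lloyd (1D k-means) iteration on a 256-bin histogram
  seeded at equal-mass quantiles — the same objective, optimized
  locally. Cleaning then scans levels bottom-up; at 1-based iteration k,
  connected pieces smaller than k·⌈0.1·ω_min⌉ move up one level, so
  tolerance grows with the iteration.
- **Watershed flooding** of the cleaned landscape assigns every in-mask
  pixel to a basin (no unlabeled ridge pixels), which gives exact pixel
  conservation: the foreground of the split label image equals the
  hole-filled phase-I mask.
- **Convexity** is object size divided by the number of grid centers
  inside the convex hull of the object's pixel centers
  (boundary-inclusive, via Delaunay point location). This definition has
  exact, reproducible boundary semantics, verified against an
  independent GEOS rasterization in 2D and a hull-volume test in 3D.
  Degenerate (collinear/coplanar) objects fall back to a hull of
  pixel-square corners and still score ≤ 1.
- **Merging** iterates to a fixpoint: per connected group of adjacent
  labels, the whole-group merge is tried first, then adjacent pairs in
  order of decreasing convexity gain; each accepted merge requires union
  convexity strictly above the fragments' mean and union size strictly
  under 10·ω_min (overridable for non-nucleus objects). The fixpoint
  makes the operation idempotent.
- **Centroid matching** is globally nearest-pair-first greedy with a
  strict radius (default 10 px, applied in index units in 3D unless a
  spacing is given). On spread point fields this equals maximum
  matching; in contrived dense geometry it can fall short by one match,
  a bound the tests verify. Zero-denominator scores return 0 with a
  degenerate flag rather than NaN.
- Label ids are assigned in raster-scan order of first occurrence, so
  identical inputs give identical outputs; comparisons in the tests are
  nevertheless permutation-invariant where only the partition matters.

## Synthetic data: what it emulates and what it does not

The generator places elliptical (2D) or axis-aligned ellipsoidal (3D)
nuclei, a chosen fraction of them in touching clumps where neighbors
share boundaries with at most ~2 px overlap (ownership of contested
pixels goes to the nearest nucleus center). Each nucleus ramps radially
from `center_darkness` to `rim_darkness`; the background carries a
low-order polynomial illumination field plus additive Gaussian noise.
Defaults describe a moderately crowded field: 256×256, 40 nuclei of
8–13 px radius, cluster fraction 0.5, intensities 0.2 → 0.5 on a 0.85
background, gradient amplitude 0.06, noise σ = 0.03; the 3D study uses
12×128×128 stacks with 15 nuclei and ω_min = 300 voxels. These sizes
keep a full study (20 2D images + 5 stacks) in the low minutes on one
CPU while still exercising every phase.

The generator reproduces the features the algorithm exploits — dark
centroids, touching clumps, heterogeneous background — but not
photorealistic staining: no color, no point-spread blur, no texture
inside nuclei, no debris or non-nuclear counterstain, and clump overlap
is bounded. Passing the synthetic suite therefore demonstrates the
mechanics of the method (thresholding, splitting, merge/correction
logic) under controlled conditions, not performance on any particular
real stain; on real data the intensity model is noisier and scores will
be lower.

## Open design points and limitations

- The exact schedules of the quantization step (threshold count and
  piece-size floors) are package choices matching the stated
  proportionalities; other monotone schedules would also be defensible.
- "Group" merging treats each connected component of the adjacency graph
  as a group; maximal cliques would be stricter but are expensive and
  rarely differ on nucleus-shaped objects.
- Heavily overlapping nuclei whose union is nearly convex can satisfy
  the merge conditions and be wrongly fused; the convexity model cannot
  distinguish this case from a genuinely over-split convex nucleus.
- 3D stacks are treated isotropically by default; pass a spacing to
  weight the distance transform and centroid matching if the z step is
  large.
- The correction phase replaces an object only when re-thresholding its
  region strictly improves convexity, so it never degrades a clean
  segmentation, but it also cannot recover a nucleus deleted earlier.
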