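# Methods

## Model and assumptions

The stitching model treats consecutive Z-layers of instance masks as discrete
measures and asks for the cheapest coupling between them. Layer z with m
cells becomes P on [m+1], where P(x) is the pixel count of label x divided by
the layer's total pixel count and bin 0 is background; likewise P′ on [n+1]
for layer z+1. The cost of moving mass from label x to label y is
C_xy = 1 − J(x, y), the Jaccard complement of their pixel supports compared
at identical (Y, X) coordinates; background participates as an ordinary
row/column. The exact plan M̂ minimizes ⟨C, M⟩ over couplings with marginals
P and P′.

Why overlap and not distance: in densely packed tissue the nearest centroid
in the next layer frequently belongs to a neighbouring cell, so
centroid-distance costs systematically swap labels; the support overlap is
the quantity that actually persists across layers of one cell. Including
background in the marginals matters too — a cell with no plausible
continuation sends its mass to the background bin rather than being forced
onto an arbitrary cell.

The model assumes the 2D masks are reliable (garbage slices stitch into
garbage volumes), and that one cell's consecutive slices overlap
substantially. It repairs over-segmentation (two fragments competing for one
continuation: only the least-cost fragment relabels it, the loser ends up
confined to isolated layers and is erased by the final pass) but cannot
repair under-segmentation, since it relabels masks and never reshapes them.

## Tracing, new cells, and the rejection vote

From M̂, each source cell traces to T(x) = argmax_y M̂_xy. A target cell y is
claimed by argmin_{x ∈ T⁻¹(y)} C_xy, or declared new when T⁻¹(y) is empty. A
best tracer with C_xy = 1 is also treated as absent: zero overlap means the
transported mass corresponds to no shared pixels (it is pure background
routing), and accepting such matches would glue disjoint objects — a 1×1
counterexample: with one lone cell per layer, rerouting both masses through
the background bins costs strictly more than one unit-cost "match", so the
plan alone would pair them.

Stacked distinct cells can overlap almost perfectly in XY, which no
Z-directional quantity can detect. The rejection vote uses the two orthogonal
mask stacks: for each pixel (r, c) of y, the YZ-plane at X = c votes to
reject iff its labels at (z+1, r) and (z, r) differ, and the XZ-plane at
Y = r votes likewise on its (z+1, c) vs (z, c) labels. The match is accepted
iff the rejecting fraction of the 2·|y| votes is below the threshold.

Numerical and policy choices:

* **Exact LP, not entropic OT.** Problems have tens of bins; HiGHS solves
  them exactly in milliseconds, and a basic (vertex) solution makes the
  argmax tracing deterministic. Regularized solvers would blur the plan and
  the tracing function with it.
* **Ties** in argmax/argmin go to the lowest label; labels are kept sorted
  with background first, so NumPy's first-argmax implements this directly.
* **Vote threshold** defaults to 0.5 (majority rejection); rejection
  requires fraction ≥ threshold. With no orthogonal masks the vote is
  skipped and every traced match is accepted.
* **Background-background agreement** (0 = 0 in both planes) counts as a
  non-rejecting vote: only a *different cell label* is evidence of stacking,
  and penalizing border-adjacent cells for neighbouring background would
  reject legitimate matches at the volume boundary.
* **Fresh labels** come from one global counter starting above the maximum
  raw input label, so outputs never collide with inputs.
* **Isolated-cell cleanup** erases cells spanning fewer than
  `min_layers_per_cell` (default 2) distinct Z-layers.

Two behaviours of the published procedure are worth knowing. First, the vote
also fires on honest lateral growth: at a cell's first slices (a cone-like
apex), the next slice can be more than twice the previous one, the
"different label" fraction exceeds 0.5, and the apex slice is split off and
then removed as isolated. The volume cost is a few voxels per affected cell,
so metrics stay at 1.0 on typical clean scenes, but voxel-exact recovery of
tapering cell tips should not be expected — and occasionally (roughly one
random 20-cell scene in ten) a two-layer apex stub survives the cleanup and
costs one spurious cell. Second, over-segmentation repair chooses
the chain carrier going down (mass argmax) and the continuation winner
coming up (max IoU) by different criteria; when a cell is cut into
near-equal fragments the two can disagree, severing the cell into two
multi-layer chains instead of isolating one fragment. On random
centroid-chord splits this happens in roughly a fifth of cases; the
acceptance script therefore reports the median repaired count and the
exact-recovery rate over replicate scenes.

## Interpolation

For anisotropy N (Z spacing = N × XY spacing), each pair of matched
consecutive slices of a cell is morphed through N − 1 internal layers.
Boundaries are the 4-connectivity contours (cell pixels with a 4-neighbour
outside the cell; image borders count as outside). The exact OT plan between
the uniform distributions on the two contours under squared-Euclidean cost
pairs boundary points; layer k rasterizes round((1 − k/N)·p + (k/N)·q) over
all coupled pairs with positive weight, vectorized over k from the single
coupling.

* **Fill**: rasterized points are closed with a 3×3 structuring element
  (rounding can perforate the contour), re-unioned with the points, and
  hole-filled with 4-connected background. For convex-ish slices the
  identity case (source = target) reproduces the support exactly; narrow
  concave notches can be over-filled by the closing.
* **Rounding** is half-away-from-zero per axis, for cross-platform
  determinism.
* **Conflicts**: voxels claimed by several cells' interpolants go to the
  lowest label (first-wins, deterministic).
* **Births/deaths**: a cell present on only one side of a pair gets no
  internal voxels — there is no target shape to transport to, so it stops at
  its last original layer. Cell tips beyond the outermost observed slice are
  therefore never reconstructed.

The output volume has depth (D − 1)·N + 1 with the original layers
bit-identical at indices z·N.

## Evaluation

Instance matching is greedy in descending IoU over all pairs with IoU
strictly greater than t, one-to-one, ties broken by (predicted label, GT
label). For t ≥ 0.5 at most one candidate exists per instance, so greedy
equals the optimal assignment; at t = 0.25 the procedure is a documented
convention. Degenerate 0/0 ratios are reported as 0 so empty predictions
score 0. `mean_cell_iou` (mean over GT cells of the best overlapping
prediction's IoU) quantifies shape recovery without a threshold.

## Synthetic scenes: what they emulate, what they do not

`generate_scene` packs seed points by uniform rejection sampling with a
minimum pairwise distance (up to 1000 draws, then error) and builds either
Voronoi cells restricted to the volume minus a background margin — densely
packed, convex, space-filling, like plant epidermis — or ellipsoids clipped
against their neighbours, with background in between, like sparse nuclei.
Scenes violating the contract (every cell 6-connected, spanning ≥ 2 layers)
are re-drawn deterministically from the same stream. `slice_masks` renumbers
each plane's labels independently in random order, exactly what independent
2D segmentation produces; perturbations emulate segmenter faults
(centroid-chord splits for over-segmentation, boundary erosion/dilation
jitter, whole-plane dropouts). `subsample_z` keeps every Nth layer, the
standard anisotropy-degradation protocol.

Not emulated: intensity images, point-spread functions, noise, staining
artifacts, non-convex or touching-and-intergrown cell shapes, and systematic
2D segmenter biases. Passing tests therefore demonstrate correctness of the
stitching/interpolation machinery on well-posed geometry, not performance on
real microscopy — on real data the quality of the 2D backbone dominates.

## Acceptance protocols and their sizes

Problem sizes are chosen so the whole suite runs in seconds on one CPU while
every mechanism is still exercised end to end:

* Transport exactness: 200 random 12×12-pixel layer pairs with ≤ 10
  labels/layer; marginal error ≤ 1e−8; plan cost ≤ 100 exactly feasible
  couplings per instance sampled by the northwest-corner rule on randomly
  permuted bins.
* Brute-force agreement: 50 two-layer instances of ≤ 4 jittered disjoint
  squares (each cell overlaps exactly its counterpart); stitching must equal
  the exhaustive minimum-cost injective matching.
* Perfect recovery: 32×64×64 Voronoi scene, 20 cells, minimum seed distance
  10; clean Z/YZ/XZ masks; threshold 0.5; 20 cells out, all metrics 1.0.
* Stacked-cell vote: two cells sharing one 6×6 footprint across adjacent
  layer pairs; 2 cells with the vote, 1 without.
* Over-segmentation repair: 16×32×32, 6 Voronoi cells, one mid-span slice of
  one cell split by a centroid chord; final count 6 (see the severing caveat
  above for why the script aggregates over replicates).
* De-anisotropization: 49×128×128, 5 spheres of radius 16 (≈ 4N, so each
  cell is observed in ~8 kept slices — with smaller cells the hard-stop at
  terminal slices dominates the error budget), minimum seed distance 36,
  margin 0 (so border-clipped flat faces lie on kept layers rather than
  between them), subsample to every 4th layer, full pipeline with the vote,
  interpolate back; mean per-cell IoU ≥ 0.8 (measured ≈ 0.87–0.92 across
  seeds).
* Interpolation oracles: concentric discs r = 3 → 5 must pass within IoU 0.9
  of the r = 4 disc at the midpoint; a shape translated by 8 px must hit its
  half-shift at the midpoint.

## Known limitations

* Under-segmented 2D masks are propagated, never corrected.
* Tapering cell tips lose their apex slice to the growth/vote interaction
  (clean scenes) and their unobserved caps to the interpolation hard-stop
  (subsampled scenes).
* Over-segmentation repair can sever a cell cut into near-equal fragments.
* The rejection vote needs orthogonal masks of stitching-direction quality;
  on strongly anisotropic data, YZ/XZ segmentations are inherently worse,
  and the vote inherits their errors.
* Exact LP transport is sized for tens of cells per layer and a few hundred
  boundary pixels per slice; very large slices would need coarsening or a
  faster solver backend.
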