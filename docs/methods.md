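# Methods

This note documents the models, numerical choices and defaults behind
`smarttrace`, and what the synthetic phantoms do and do not establish.

## Conventions

SWC `x, y, z` are 0-based voxel coordinates in (x, y, z) order; arrays are
indexed `(z, y, x)`. Non-integer SWC coordinates are legal; nearest-voxel
rounding happens only at voxel access. A missing or zero SWC radius is
treated as 1 voxel. Volumes are unsigned 8- or 16-bit; distances and lengths
are in voxel units (the `spacing` field of `Image3D` is informational — no
anisotropy correction enters path costs, a documented non-goal).

## Segment decomposition and morphology

A reconstruction is cut at its critical nodes (roots, nodes with ≥ 2
children, tips) into segments whose interiors are single-child chains; the
segments partition the edge set. Conventions: a multifurcation counts as one
bifurcation node while each child opens its own segment (branch counts are
therefore child-based, bifurcation counts node-based); the root is never a
tip; forests are measured per component and summed. Total length is the sum
of Euclidean parent–child distances.

## Confidence score

For a segment with endpoints `i, j`, the masked image zeroes every voxel
whose exact distance to the segment's centerline polyline is within
`max(node radius, 1) + 1`, except inside 2-voxel protection spheres around
the endpoints (without them the path search would start inside the mask).
The alternative path minimizes, over 26-connected voxel paths, the sum of
`step length × mean of endpoint node costs` with node cost

```
c(x) = (1 − I(x)/I_max)² + ε,    ε = 1e−6 .
```

Masked voxels carry a large finite barrier cost (1e9) instead: the method's
front propagation moves at speed proportional to intensity, and zero
intensity means zero speed, so the detour must physically avoid the masked
corridor. This matters: with the intensity cost alone, the cheapest path
would often retrace the zeroed corridor itself (background cost ≈ corridor
cost), and since both means are read from the *original* image every segment
would score ≈ 1. A large finite cost rather than a hard barrier keeps every
instance solvable. The search runs in the endpoints' bounding box padded by
`path_margin` (default 16) voxels; on small volumes this is the full graph,
where the returned cost equals an independent Dijkstra (tested).

Means are discretized as arc-length-weighted trapezoidal sums of trilinearly
interpolated intensities, sampled at ≤ 0.5-voxel steps along the segment;
this is the natural reading of the continuous line integral divided by
length. `C = Ī*/Ī ≤ θ` (default θ = 0.5) labels a segment confident. The
score is scale-invariant (numerator and denominator share the image scale)
and increases monotonically with the brightness of a genuine alternative
corridor (tested on loop phantoms). Segments with fewer than 3 nodes or
shorter than 5 voxels inherit the upstream segment's label — their own
integral is too short to mean anything; with no upstream neighbor they
default to confident. A zero-mean segment scores +∞ and is uncertain.

Brightfield (inverted-contrast) volumes are scored on `I_max − I` rather
than by taking `1/C`: this keeps the bright-is-cheap semantics of the cost
function, which a reciprocal score would not.

Path-search tie-breaking is delegated to the shortest-path library's
deterministic expansion order; identical inputs give identical paths.

## Exemplar layers

Voxel labels come from Euclidean distance transforms of the rasterized
(0.5-voxel sampled, nearest-voxel rounded) centerlines of confident and
uncertain segments. With distances `(core, middle, outer)`:
`d ≤ core` → foreground sample, `core < d ≤ middle` → uncertain,
`middle < d ≤ outer` → background sample, neighborhood of uncertain
segments (≤ outer) → uncertain; precedence is foreground > uncertain >
background, so training never sees a contradictory label. Defaults:
`core = max(1, median node radius)`, `middle = core + 2`,
`outer = core + half the feature window (8)`. The outer bound is chosen so
background exemplars come only from windows in which the neurite appears
peripherally; windows that straddle the structure are left uncertain rather
than taught as background — teaching them as background is exactly what
suppresses the classifier's willingness to bridge signal gaps, whose windows
contain bright structure on both sides. Voxels within half a window of the
volume border are irrelevant (no full feature window exists there).
Sampling draws `min(cap, available)` voxels per class (cap 500) uniformly
without replacement, equal in both classes.

If no segment is confident, an `InsufficientExemplarsError` is raised — the
observed failure mode of self-supervised tracing on inadequate initial
reconstructions; the remedies (relax θ, another tracer, another round) are
in the error message.

## Wavelet features

Windows are 16³ (configurable, power of two), mirror-extended at volume
borders. The multi-resolution representation applies one separable DWT
level (8 subbands, LLL…HHH, filters applied along z, y, x) and recurses on
LLL, 3 levels deep. Haar is the default filter pair — the simplest
orthogonal choice, with Daubechies-4 selectable; boundary handling inside
the transform is periodization, which keeps the coefficient count equal to
the window voxel count (16³ → 7·512 + 7·64 + 7·8 + 8 = 4096), preserves
orthogonality (Parseval holds to ~1e−15 relative) and inverts exactly.
The feature layout is fixed: finest-level details first (LLH, LHL, LHH,
HLL, HLH, HHL, HHH, each C-flattened), then coarser levels, then the final
LLL.

## mRMR selection

Features are discretized to 3 states at mean ± one standard deviation (the
customary convention for this selector); labels stay discrete. Mutual
information is the plug-in estimate from joint empirical histograms, in
bits. Selection is the standard first-order incremental scheme — the first
pick maximizes relevance `I(c, f)`, each next pick maximizes
`I(c, f) − (1/|S|) Σ_{s∈S} I(f, f_s)` — the only scheme consistent with
per-step work linear in the remaining candidates; the redundancy sum is
maintained incrementally. Ties break to the lowest feature index, making
runs deterministic; a constant feature has zero MI everywhere and can win
only against other zero-score candidates. Default k = 20.

## Classifier and growth

The SVM uses the classic library defaults (C = 1, RBF kernel with
γ = 1/feature-dimension) on per-feature standardized inputs — an RBF kernel
needs comparable feature scales, and class balance is guaranteed upstream.
Training accuracy is logged.

Growth is breadth-first over the chosen connectivity (26 default, 6
selectable): the whole front's unknown neighbors are deduplicated, sorted
lexicographically, batch-featured and batch-classified each sweep. Since
acceptance depends only on a voxel's own features and each voxel is
classified at most once, the final mask is independent of expansion order;
FIFO sweeps are used for determinism and cache behavior. The mask is
26-connected to the seeds by construction. The front never enters the
border margin where a full feature window does not exist — mirror padding
there reflects real structure back into the window, which otherwise makes
border voxels look like continuations of whatever touches the border (a
measurable source of runaway growth at volume faces).

Image adjustment: background → 0; foreground below the tracing threshold →
threshold; otherwise unchanged. Idempotent, dtype-preserving.

## Baseline tracer

The built-in tracer is a minimal shortest-path-tree tracer, deliberately
gap-limited: it thresholds (fixed value or Otsu), keeps only the
26-connected foreground component containing the soma seed — this is what
makes it stop at gaps, mirroring the limitation of the production tracers
this framework is designed to repair — then builds a shortest-path tree
from the seed. The tracing cost divides the confidence module's intensity
cost by `(1 + distance-to-background)` and adds a 0.05 per-unit-length
charge: the division pulls paths onto the medial axis of plateau-intensity
tubes, and the charge dominates intra-plateau noise fluctuation so
centerlines stay straight, while background (cost ≈ 1) remains an order of
magnitude more expensive. Centerlines are extracted by repeatedly tracing
back from the farthest (by accumulated Euclidean path length) voxel not yet
covered by the tree's tubes (coverage radius: local radius + 2); a
traceback stops at the first covered voxel and attaches to the nearest
existing node, which merges parallel predecessor wires inside one tube.
Branches shorter than `min_branch_length` (default 8 voxels ≈ 2–3 tube
radii) are pruned — shorter stubs are artifacts of blob-shaped mask ends
and voxelization, not anatomy. Pruning is plain length-based, a documented
divergence from production tracers' hierarchical pruning. Node radii are
distances to background. The seed is re-centered to the deepest foreground
voxel within 4 voxels (an intensity argmax lands on an arbitrary corner of
a saturated plateau). A seed that falls mid-tube becomes a degree-2 root,
which the morphology conventions count as a bifurcation — callers that
care seed at a structure end.

## Pipeline

Defaults reproduce the standard operating point: window 16, 3 levels,
k = 20, final trace threshold 1, confidence θ = 0.5, sample cap 500,
26-connectivity. One top-level seed drives sampling and training; identical
config + seed gives bit-identical SWC output (tested). Stage timings are
logged under the keys `T_in, T_s, T_m, T_t, T_p, T_st` (initial trace,
scoring, feature selection, training, prediction, final trace). Iterative
mode feeds each round's tree back as the next initial reconstruction and
stops at `rounds` or when total length changes by less than
`convergence_ratio` (default 0.05); `rounds = 1` is exactly the single
round. The final trace reuses the initial tree's root as its soma seed —
the adjusted image preserves the original bright soma region, so the root
location stays valid.

## Phantoms: what they emulate, and what they do not

The generator renders anti-aliased tubes (exact point-to-segment distances,
1-voxel linear intensity falloff beyond the radius) along polylines, with
branch points, arc-length-parameterized signal gaps (the removal interval
is widened by the tube reach so the requested gap length is the actual dark
slot between the rounded stump caps), optional per-axis linear illumination
ramps, brightfield inversion, and additive Gaussian noise clipped to the
dtype range (Poisson statistics are a non-goal). Ground-truth trees sample
the polylines exactly at ~1-voxel spacing, so their SWC length equals the
analytic length. Defaults: 96×128×128, radius 2, foreground 200,
background 10, σ = 5 — a high-but-realistic single-neuron contrast regime;
identical specs (including seed) render bit-identical volumes. The loop
phantom draws a closed circle and returns a half-circle ground truth, so
the traced half has an equal-intensity alternative pathway.

Phantoms establish the mechanics — scoring discriminates
alternative-pathway topologies, exemplar geometry is exact, gaps are
crossed and recovered — but not performance on real microscopy: no PSF,
no depth-dependent attenuation, no autofluorescence clutter, single-neuron
scenes only.

Problem sizes: the oracle-checked fixtures run at 14³–48³ (exhaustive
Dijkstra and distance oracles are cubic in voxels); the end-to-end runs use
the full 96×128×128 default. The wide-gap iterative-rescue fixture (gap 6,
a fixed noise realization) is deliberately calibrated into the narrow
regime where one round penetrates the gap only partially and the second
round's added exemplars finish the crossing — the rescue phenomenon lives
only in that band: narrower gaps cross in one round, much wider ones defeat
both rounds.

## Known limitations

* The confidence score assumes endpoints lie on real signal; a completely
  hallucinated segment in empty background scores low (confident) if no
  brighter detour exists — confidence measures *alternative-pathway
  absence*, not correctness.
* Window-based classification dilates structures by several voxels; the
  re-trace's pruning absorbs most but not all of it, so final lengths can
  exceed the truth by a few percent.
* Gap bridging is probabilistic near its width limit (≈ window half-side);
  success depends on the noise realization, which is why the iterative mode
  exists.
* The mRMR redundancy term uses pairwise MI only (first-order scheme);
  jointly redundant triples are not detected.
* Costs are isotropic; strongly anisotropic voxels need resampling first.
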