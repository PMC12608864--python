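# Methods

This note documents the model, the choices made where the design was open,
and what the synthetic experiments do and do not demonstrate.

## Problem setting and assumptions

Input is a single-plant point cloud in meters, gravity-aligned with +z up
(potted-plant scans are conventionally leveled; the slicer's depth-0
direction and the "plant height" both assume this). Points carry optional
unit normals — estimated from the k-NN covariance (k = 16) when absent —
and, for training data, per-point semantic labels {background, stem, leaf}
and leaf instance ids. One plant is one sample; attention is computed over
all points of a plant, so the method targets desk-scale clouds (roughly
10² – 10⁴ points per plant), not field-scale scenes.

## Pipeline

### Recursive slicing

Three independent recursions run per plant, one per scale. Thicknesses are
data-adaptive:

| scale  | thickness                              | default |
|--------|----------------------------------------|---------|
| coarse | `coarse_fraction` × plant height       | 0.08 (kept in the 5–10% band) |
| medium | 0.2 × height / √(expected leaf count), or an absolute override | K̂ = 6 |
| fine   | `fine_multiplier` × median NN spacing  | 4 |

computed once per cloud and clamped to fine ≤ medium ≤ coarse. Depth 0
slices along +z; deeper levels re-slice each slab along its own principal
axis (sign fixed to nonneg z, then x, then y — also the eigenvalue
tie-break) with thickness halved per depth, the "zooming-in" behavior.
Recursion stops at `min_points` (32; desk preset 24), at geometric
simplicity (normal-dispersion statistic 1 − ‖mean of hemisphere-aligned
unit normals‖ < 0.01 — rotation-invariant, bounded in [0, 1], exactly 0 for
a plane), or at `max_depth` (3). Checks run in that order, so a slab that
is both small and flat records `min_points`. Slab bins are half-open
[low, low + t); a point exactly on a boundary joins the upper bin.
Termination is guaranteed: every recursion level either halves the
thickness or trips a floor.

The slab encoder maps each point's slab-centered, diagonal-scaled
coordinates plus its normal through a shared 6→32→64→D MLP, scores each
point with a learned scalar, normalizes scores to unit mean within the slab
(a soft attention gate — unit *mean* rather than unit sum so that
duplicating a point cannot dilute the encoding), gates the features and
max-pools. The result is bitwise invariant to point order: the slab
centroid and the gate normalizer are accumulated in sorted order, and max
pooling is order-free.

Each point's per-scale feature is the concatenation of its root-to-leaf
slab encodings, zero-padded to `max_depth + 1` slots. Pyramid levels are
realized as farthest-point-sampled subsets (ratios 1, 1/4, 1/16) carrying
the fine, medium and coarse path features respectively.

### Positional channels

Slab encodings are translation-normalized, so two geometrically similar
leaves on opposite sides of the plant would be indistinguishable from path
features alone — yet the embedding head must assign them different vectors.
Nine per-point channels are therefore appended at every pyramid level:
normalized xyz (plant-centered, extent-scaled), the normal, and cylindrical
coordinates about the plant axis (sin/cos azimuth and radial distance).
The cylindrical pair matters most: phyllotaxy gives every leaf a distinct
azimuth sector, and in held-out tests it is what separates azimuth-adjacent
leaves that otherwise merge in embedding space.

### Context fusion

Single-head scaled dot-product attention, exactly one head (the governing
formulation is single-head), with d = model_dim; `n_blocks` residual blocks
(attention → add & layer-norm → per-point feed-forward → add & layer-norm)
run per level before fusion. Pyramid fusion is top-down: level 2 features
are interpolated onto level-1 positions by inverse-distance-weighted k-NN
(k = 3, weights 1/(dist + 1e−8); a query within 1e−8 of a source returns
that source's feature exactly), fused by concatenation + a two-layer map
(concatenation rather than addition keeps level provenance learnable), then
the same toward level 0. Absent levels are skipped, which is what the
ablation switches exploit.

### Heads, loss, decoding

Embedding and semantic heads are parallel two-layer per-point MLPs. The
embedding loss uses margins δ_v = 0.5, δ_d = 1.5 (the margins are free
parameters of the loss family; these defaults keep δ_d > δ_v with room for
a decoding bandwidth between them) and weights (α, β, γ) = (0.5, 0.3, 0.2),
plus unit-weight cross-entropy. Instances are leaves only; stem and
background points contribute through cross-entropy alone. C (the instance
count in the loss) is per plant, averaged over the batch. Singleton
instances contribute zero variance loss. The row norms inside the hinges
are exact at zero (guarded subgradient), so the hand-checkable fixtures
hold to machine precision.

Decoding: semantic argmax (ties to the lower class index) → flat-kernel
mean shift over the leaf points' embeddings (every point seeds; convergence
at shift < 1e−4 × bandwidth or 300 sweeps; modes within bandwidth/2 merged
in order of descending support; points assigned to the nearest surviving
mode) → clusters under `min_cluster_size` (20) dissolved, survivors
renumbered by descending size. Default bandwidth is 1.2 δ_v: it must exceed
the compliant cluster radius δ_v, and a flat-kernel seed on a cluster's
edge starts capturing a neighboring compliant cluster once the bandwidth
exceeds δ_d − 2 δ_v, so the default sits just above the lower bound rather
than midway between the margins. Stem-predicted points are grouped into one
stem instance per plant (`stem_as_instance`), which is what makes the
stem row of the evaluation computable; the ground-truth stem instance is
likewise derived from semantic labels.

### Training

Adam, learning rate 0.001, batch size 8 plants, gradients accumulated over
per-plant forward passes (no padding). The full-scale default is 150
epochs; the desk preset (D_slice 32, model_dim 64, D_e 16, 1 attention
block, 30 epochs) trains 24 plants of ~500–1000 points in about a minute
per 30 epochs on one CPU core. Static per-plant structures — slice trees,
encoder batches, FPS subsets, interpolation neighborhoods — are built once
and reused across epochs. Fixed seed + single-threaded evaluation gives
bitwise-reproducible loss logs, checkpoints and predictions.

Gradients come from a compact reverse-mode autodiff engine written for this
package (`leafseg._autodiff`): float64 tensors, a tape of backward
closures, fused softmax/layer-norm/segment ops. It is validated against
finite differences op-by-op and through the composite loss.

## Synthetic data: what it emulates, what it does not

`make_plant` builds a stem cylinder and K elliptic blades with curvature
along the midrib, optional sinusoidal margin serration, phyllotactic
azimuths (137.5°), random droop (15–55°), and exact analytic normals.
`apply_sensor_effects` adds Gaussian coordinate noise (default σ = 1 mm),
linear height-dependent thinning (default top-to-bottom retention ratio 2),
and optional point-based hidden-surface culling: directions from a
viewpoint are quantized into angular cells (default 0.35°) and only points
within a depth band (default 1 cm) of each cell's minimum range survive.
All randomness flows from one integer seed via `SeedSequence` spawning, so
per-plant generation is order-independent.

The standard evaluation split (also used by `scripts/acceptance.py`) draws
4–8 leaves per plant with a viewpoint at (0.8, 0, 0.5) m and a 2 cm depth
band, hiding roughly 10–25% of each plant's points — a mild
single-viewpoint scan. A crowded configuration (many leaves on a short
stem) drives blades of different leaves to within the noise scale,
exercising the adhesion regime; the test suite asserts the generator can
reach it.

What the generator does not model: leaflet/compound morphology, petioles,
venation relief, pots and soil clutter (a background class exists but is
unpopulated by default), registration artifacts between multiple scans, and
species-level shape families beyond the parameter ranges. Passing the
synthetic benchmarks therefore demonstrates that the architecture, loss and
decoding work end-to-end under controlled occlusion/adhesion/density
stress — not that the trained weights transfer to real scans; on real data
the pipeline should be retrained.

## Ablation ladder

`leafseg ablate` trains five variants on the same split: A — set-abstraction
baseline encoder, no attention/fusion, no embedding head (instances by
Euclidean connected components on predicted-leaf points at the fine slab
thickness); B — + recursive slicing; C — + attention/pyramid fusion;
D-NSF — full model clustering all points (clusters classed by majority
semantic vote); D — full model with leaf-only clustering. A reduced ladder
(A, C, D) covers the baseline/full comparison at a third of the cost.
Connected components are exact when leaves never approach within the
merge radius, so the baseline is strong on clean separated plants; the
embedding model's advantage appears once occlusion fragments leaves or
adhesion bridges them.

## Numerical details and edge cases

- Empty clouds: slicing returns an empty tree; prediction returns an empty
  labeling; mean shift on zero points returns zero clusters.
- Degenerate geometry (zero z-extent, all-coincident sub-regions) raises a
  dedicated error at thickness computation / direction choice; sub-regions
  that cannot yield a direction terminate as "simple".
- All tie rules are pinned: boundary points to the upper bin, argmax ties
  to the lower class, cluster renumbering by size then lexicographic
  center, mode merging by support then first-seen, direction signs by the
  z→x→y cascade.
- Evaluation uses greedy confidence-ranked matching (ties by size then
  insertion order) against pooled scenes per class, the all-point
  interpolated AP integral, and defines IoU of two empty sets as 0.
  Confidence is the cluster's share of clustered points. "Overall" is the
  unweighted class mean; classes absent from the ground truth are omitted
  and recorded.
- Checkpoints are single `.npz` archives holding every parameter plus the
  full estimator configuration and loss history; reloading reproduces
  predictions bitwise under single-threaded evaluation.

## Known limitations

- Attention is O(N²) in points per plant; clouds beyond ~20k points need
  chunking or subsampling that this package does not implement.
- The slab encoder sees only coordinates and normals; curvature or color
  channels would require widening its input.
- The geometric-simplicity criterion uses normal dispersion only; the
  dimensionality-based alternative is not implemented.
- Mean-shift bandwidth is a global constant tied to the loss margins;
  per-plant adaptive bandwidths are not attempted.
- Desk-scale results on synthetic plants are not comparable to
  full-scale training on real scan collections; the full-scale recipe
  (256-dim features, 2 blocks, 150 epochs) is configured but not exercised
  by the shipped experiments.
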