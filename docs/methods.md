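# Methods

This note documents the models and numerical choices behind the package:
what each stage computes, the parameters that matter, and what the
synthetic data does and does not establish about real dermoscopy images.

## Fuzzy c-means and the ambiguity factor

FCM partitions n objects into c clusters by minimizing
J = Σ_j Σ_i u_ij^m ‖x_j − v_i‖² with Euclidean distances, alternating the
membership update u_ij = 1 / Σ_k (d_ij/d_kj)^(2/(m−1)) with the centroid
update v_i = Σ_j u_ij^m x_j / Σ_j u_ij^m. Defaults: fuzzifier m = 2,
c = 2. Initialization draws c *distinct* objects as centroids (seeded);
convergence is declared when the maximum centroid displacement falls
below `tol` (default 1e-6, cap 300 iterations) — an exact
"centroids unchanged" test never fires in floating point. Where an object
coincides with a centroid the membership formula is undefined; such
objects are assigned crisply to the nearest centroid(s), ties split
equally, which preserves row-stochasticity. Distances small enough to
overflow the negative power take the same branch.

The network reduces a layer's two-column membership matrix to the
*ambiguity factor* a = mean_j (u₁j − u₂j)² ∈ [0, 1]: 0 when every object
sits exactly between the clusters, 1 when memberships are crisp. If all
activation rows are identical, clustering is meaningless and a = 0 is
returned with a warning, which freezes that layer for the epoch.

## The F-MLP

Architecture 2-4-2-1 (two irregularity features in, one probability out),
weights initialized uniformly on (−0.5, 0.5) from a seed, biases zero.
The type-II sigmoid pair is φ_L = sig^α, φ_U = sig^(1/α) with α = 2
(larger α pushes the bounds toward 0/1 and adds nothing for image-derived
features); both bounds and the plain sigmoid share the derivative form
e·s^(e−1)·s(1−s) with e ∈ {α, 1/α, 1}.

Training is full batch. Per epoch: forward pass caching all activations;
FCM with c = 2 on the input layer's and each hidden layer's activation
table (objects = training samples by default — the per-neuron transpose
is available as `orientation="neurons"`); backpropagation of the error
delta (true − pred)·φ′(z) (squared-error form, gradients averaged over
the batch); and the fuzzy update w ← w − a·η·∇ for every weight matrix,
where a is the ambiguity of the matrix's *source* layer. The output layer
is never clustered, so the source-layer convention uses exactly the
computed scalars: the input-layer factor scales the first weight matrix
and each hidden layer's factor scales the matrix it feeds. A
`global` mode averages the per-layer factors into one scalar, and
`force_ambiguity` pins the factor (a = 1 with the plain sigmoid
reproduces standard backpropagation bit-for-bit; a = 0 freezes training —
both are asserted in the tests). Standard mode is exactly that reduction.

Decisions are transductive, as in the reference protocol: the threshold
is the mean of the evaluated batch's probabilities and "regular" requires
p strictly above it (a 1e-12 guard keeps all-equal batches on the
irregular side of the strict inequality). A deployment would instead
freeze a train-derived threshold; the transductive rule is kept because
the protocol defines it that way.

`FuzzyNetwork` defaults (η = 0.001, 1 epoch) mirror the reference
instance. The comparison harness (`TrainSettings`) instead trains to
convergence — 300 full-batch epochs at η = 1.0 on z-scored features
(train-split statistics) — because a freshly initialized network after a
single 0.001-rate update still predicts at chance with an arbitrary sign,
and the synthetic-separability check is about the trained model. On
two-feature separable data these settings converge with a wide margin;
they are not tuned per dataset.

## FuzzEdge

Algorithm: the gray axis [0, L−1] (L = 256) is cut at
Dark_end = ⌊(L−1)/N_f⌋ and Bright_begin = (N_f−1)·⌊(L−1)/N_f⌋ (N_f = 3,
overlaps 0 by default, brackets read as floor); Dark_begin/Bright_end
shrink to the first/last occupied gray level. Within each interval the
histogram mode becomes the concept center m, and the distances to the
interval ends the spreads (α, β) of a *triangular* membership function —
a center and two spreads determine a triangle, and the construction
stores exactly those three numbers. An empty interval centers the concept
at the interval midpoint with a warning (binary masks always leave Median
empty).

The filter computes, per pixel, three membership-weighted standard
deviations of the 3×3 neighborhood — deviations taken about the *plain*
neighborhood mean, weighted by each concept's membership of the neighbor
values — plus the fuzzy estimator: the deviation under a uniform interval
membership over the occupied range, i.e. the plain standard deviation.
The output is the concept deviation nearest the estimator (ties:
Dark < Median < Bright). Weighting deviations about the plain mean rather
than the concept's own weighted mean is essential: with per-concept means
a two-level neighborhood has zero weighted variance under every concept
and the filter would be blind to exactly the steps it must mark. Frame
pixels use edge replication; constant neighborhoods respond 0, so
`response > 0` binarizes the edge map without a tuned threshold.

Border tracing is Moore-neighbor contour following on the largest
8-connected component, starting at the topmost-then-leftmost pixel,
clockwise in image coordinates, with Jacob's stopping criterion; the
traced contour's arc length uses steps of 1 (axial) and √2 (diagonal).

## Irregularity measures

Box counting uses a lattice anchored at the image origin (single offset —
an offset search is deliberately omitted to keep N(e) a fixed-grid
count), and the dimension is the least-squares slope of log N(e) on
log(1/e). The default ladder is powers of 2 from 2 up to **side/8**:
boxes above roughly an eighth of the image hold so few cells that the
additive small-count bias of closed curves dominates and can even invert
comparisons between shapes; capping at side/8 keeps every rung in the
scaling regime. The estimate is only meaningful between the smallest real
feature of the curve and a fraction of its extent — the level-4 Koch
check therefore uses sizes 8–64 (its elementary segment is 9 px at side
729) and measures 1.19 against the analytic log 4/log 3 ≈ 1.262, and a
straight-edged square border needs its side to be several times the
largest box before its dimension reads 1 (asserted at side 200 in a
512-px image).

Convexity divides the convex-hull perimeter (polygon arc length over the
hull of foreground pixel coordinates) by the traced-contour perimeter.
For axis-aligned polygons the two metrics agree exactly (the filled
square measures 1.0 to machine precision). For *smooth* digital
boundaries the √2-weighted chain code overestimates arc length by a few
percent, so a digital disk of radius 50 measures ≈ 0.955 rather than 1;
this bias is a property of the metric, applies equally to all smooth
shapes, and leaves the regular/irregular ordering intact. The documented
allowance ε = 0.05 covers the opposite (hull-exceeding) discretization
edge cases.

Routing follows the measurement design: fractal dimension is computed on
the *border image* (the edge detector's output), convexity on the
*segmentation mask*.

## Synthetic data

Regular lesions are randomly oriented ellipses (aspect 0.75–1, radius R);
irregular lesions are star-convex regions
r(θ) = R·(1 + roughness·s(θ)), where s is a sum of random-phase cosines
at frequencies 2..harmonics+1 with amplitudes ∝ k^(−1/2), normalized to
max |s| = 1. The slow spectral decay is deliberate: coarse components
carve the indentations and protrusions that lower convexity, while the
retained high-frequency energy adds the fine-scale raggedness that raises
the measured box-counting dimension. A smooth (∝ 1/k) spectrum fails the
second part — its excess boundary length sits at one coarse wavelength,
which thickens coarse box covers instead of adding fine-scale structure
and empirically *lowers* the measured dimension below the regular class.
Defaults: image side 128, R = 30, roughness 0.4, harmonics 24. Roughness
≥ 1 is rejected (the radius could reach zero); every generated mask is
validated to be a single 4-connected component clear of the frame.
Augmentation is restricted to 90° rotations and axis flips — exact pixel
isometries, so areas, convexity and dimension are preserved without
interpolation artifacts.

The generator emulates boundary *shape* only. It does not model hair,
illumination, color, segmentation noise, or the texture of real
dermoscopy images, and its class separation is by construction much
cleaner than dermatologist-labeled data: the end-to-end accuracy
demonstrates that the pipeline's stages compose correctly, not that the
classifier would reach the same accuracy on clinical images.

## Evaluation protocol

Splits are stratified and seeded; the test quota is round(n·fraction)
apportioned across classes by largest remainder, so the 310-sample
dataset reproduces the 248/62, 217/93, 186/124 and 155/155 partitions
exactly. The positive class is *regular* (sensitivity = true-regular
rate) — note this is the opposite of the dermatological instinct to treat
the malignant-looking class as positive. Percentages are rounded to one
decimal, half away from zero; a zero-denominator metric is reported as
undefined (None), never as 0. ROC curves sweep all probability
thresholds with the trapezoid-rule area. The comparison harness trains
the standard network and both fuzzy bounds on the identical split and
seed, applies the mean-threshold decision, and reports the max-accuracy
bound as the F-MLP result.

## Known limitations

- The edge filter's exact weighting in the original FuzzEdge tool is not
  specified anywhere in print; the membership-weighted deviation used
  here is one defensible reading and is validated against morphological
  oracles, not against the original binaries.
- Box-counting estimates carry finite-size bias at small image sizes
  (a 32-px square's border reads ≈ 1.3 on a 64-px grid); measured
  dimensions are comparable within a fixed resolution, not absolute.
- The chain-code perimeter bias caps convexity of smooth digital shapes
  around 0.95–0.96; values are again comparable, not absolute.
- Class decisions depend on the composition of the evaluated batch
  (transductive threshold); single-sample prediction degenerates to
  "irregular" by the strict-inequality rule.
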