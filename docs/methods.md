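# Methods

## Model

`spherecnn` classifies per-node scalar maps on the unit sphere with a CNN
whose convolution and pooling are native to the icosphere mesh hierarchy.

**Icosphere.** The base icosahedron uses the golden-ratio construction:
the 12 vertices are the cyclic permutations of (0, ±1, ±φ), normalized to
unit length; the z-axis is the pole of the coordinate convention. One
subdivision inserts a node at the midpoint of every unique edge
(re-projected onto the sphere, otherwise the mesh would drift off the
sphere) and splits each triangle into four. Node counts follow
N(L) = 10·4^L + 2: 12, 42, 162, 642, 2562, 10242, 40962 for L = 0…6 — the
40,962-node working resolution of surface neuroimaging pipelines is
therefore **level 6** in this package's indexing (six subdivisions of the
icosahedron). Parent nodes keep their indices as a prefix of the child
mesh, and new nodes are appended in sorted (min-index, max-index) edge
order, so the whole hierarchy is bit-reproducible. All indices are
0-based.

**Patch sampling.** A rectangular Sx × Sy (default 5×5) or circular
template lives in the tangent plane and is mapped to the sphere by the
azimuthal-equidistant (exponential-map) projection: a planar point at
distance d and bearing θ lands at geodesic distance d radians along
bearing θ. This preserves the regular angular spacing of the grid, which
gnomonic or orthographic projections would distort toward the patch edge.
The template x-axis is aligned with the local east direction ẑ×n̂/‖ẑ×n̂‖
("along the geographical latitude"); at the two coordinate poles, where
east is undefined, the global x-axis stands in — a deterministic tie-break,
never an error. Each filter point then snaps to its nearest mesh node
(greatest dot product; near-ties within 1e-12 chord distance resolve to
the lowest node index). Interpolation is deliberately order-0
(nearest-node): the sampling map is a pure gather, so convolution remains
an exact matrix product and its adjoint an exact scatter. Polygonal
patches instead take the node itself, then its 1st…R-th order graph
neighbors (each order sorted by index); ragged rows are padded with a
sentinel index whose sampled value is 0 and which receives no gradient,
keeping the filter point matrix rectangular for batched multiplication.

Default patch spacing is the working mesh's mean 1-ring angular edge
length (0.0189 rad at the 40,962-node level), so a 5×5 patch spans about
four inter-node distances — the "set by the node resolution" heuristic made
explicit. Spacing is a configuration knob; sampling maps depend only on
(template, level) and are cached (in memory, optionally HDF5 on disk) and
shared across layers and folds.

**Layers.** Convolution output is O[n,f] = Σ_{p,c} I[n,p,c]·W_f[p,c] + b_f.
Biases (initialized to 0) are included as standard CNN practice and can be
disabled. Weights use fan-in-scaled uniform initialization,
U(±√(6/fan_in)), from a seed recorded in the model spec. Mean pooling
averages each coarse node's child set — the node's own fine-level value
plus its 1-ring (the self term is configurable; excluding it would discard
information for no benefit). The backward rule "distribute the error
equally to the children" is implemented as the exact adjoint Aᵀ of the
averaging matrix A: each parent's gradient divided by its child count,
summed over a fine node's (up to two) parents. This reading is both
equal-distribution and gradient-exact; a looser "copy to children" rule
would fail the finite-difference checks. Max pooling with argmax routing is
available as an option but mean is the default. Batch normalization
normalizes per feature over batch × nodes with learned scale/shift and
exponential running statistics (momentum 0.1, ε 1e-5); training mode
refuses batches of one. All layer gradients are hand-written; the suite
checks them by central differences (step 1e-6) layer-by-layer and through
the whole network.

## Training

Semi-batch SGD, batch 50, classical momentum 0.9, weight decay 0 (both
configurable and stored with checkpoints), cross-entropy on softmax
outputs. The learning rate starts at 0.02 and drops once to 0.001 "for
fine tuning" when the training-error curve saturates; saturation is
operationalized as: the window-5 moving average of training error improves
by less than 0.1 percentage points over 5 epochs. Runs last 40 epochs,
extended to at most 70 if unsaturated. Early stopping returns the
checkpoint of the epoch with minimum validation error. An optional
`stop_patience` aborts a run once the validation error has not improved
for a given number of epochs; the statistical tests use patience 6, which
on the strongly separable synthetic cohorts converges within ~10 epochs.
Cross-validation is stratified k-fold (default 10) with per-fold model
seeds derived from the base seed, each fold evaluated on a shared held-out
test set; the summary is the mean and SD of the per-fold test accuracies.

Transfer retraining freezes the first 4·(number of complexes) layers —
conv, batch norm, ReLU, pool per complex, i.e. 20 layers for the
five-complex model — and retrains only the classifier head, with no fine
tuning of the reused layers: frozen layers receive no gradient and frozen
batch-norm units keep their stored running statistics, so their parameters
are bit-identical before and after. Since the frozen prefix is
deterministic in inference mode, its features are computed once and the
optimizer only ever sees the head.

Saliency follows the gradient-of-class-score construction: the magnitude
of ∂(true-class logit)/∂(input map) per node and channel, computed by one
inference-mode backward pass; group maps average the individual maps.

## Data conditioning

Per-subject demeaning subtracts one scalar — the mean over valid nodes of
both hemisphere channels — and is idempotent. Invalid (medial-wall) nodes
are excluded from every statistic and enter the network as 0. Resampling
from an arbitrary source sphere (e.g. 32,492 nodes) to the icosphere uses
barycentric interpolation inside the containing source triangle — the
2-simplex analogue of bilinear interpolation — with weights from the
central projection onto the triangle plane; a target node is flagged
invalid if any vertex of its containing triangle is invalid. The flat-
triangle (chord-vs-arc) error of this scheme is O(h²) in the source edge
length, verified by the convergence test; at operational resolutions it is
below 1e-3. Global rotations default to the z-axis (a longitude shift;
configurable) and resample by nearest-node pull-back, matching the
sampler's interpolation order; a 180° rotation about z is a symmetry of
the icosphere node set and hence an exact permutation, which the tests
exploit for exact-recovery checks. Both hemisphere channels rotate
identically.

## Synthetic cohorts

The generator emulates two-class cortical-thickness cohorts: a
subject-invariant smooth baseline (random degree ≤ 2 real spherical-
harmonic combination scaled into the 2–4 mm range typical of thickness
maps), a class-1 regional mean shift on one or more geodesic discs with a
cosine taper over the outer 20% of the radius, additive spatially
correlated noise (3 iterations of 1-ring mean smoothing of white noise,
rescaled per subject and channel to the requested SD — a cheap mesh-native
surrogate for geodesic Gaussian fields), and an invalid cap of 0.3 rad
around the south pole per channel standing in for the medial wall. The
reference conditions used across the statistical tests are 200 subjects
per class on the 642-node mesh, one region of radius 0.5 rad with a 0.3 mm
effect, noise SD 0.1 mm. Generation is bit-reproducible by seed, and the
truth record (per-node expected class difference, region membership,
centers) travels with the cohort, including through rotations.

What the generator does **not** emulate: cortical folding and sulcal
patterns, hemispheric asymmetries, inter-subject covariance structure, or
registration error. Passing tests therefore demonstrate the correctness
and statistical soundness of the pipeline on data with a known planted
signal — not clinical-grade accuracy on real cohorts.

## Problem sizes and numerical choices

Structural checks (hierarchy counts, the 40,962 × 25 sampling map, the
42 × 36 pre-classifier contract) run at the full working resolution.
Statistical checks run on the 642-node reference cohort with a
three-complex, 16-filter model — the same architecture family at a scale
where a 10-fold cross-validation completes in minutes on one core; the
stronger-effect examples use the 162-node mesh. Gradient checks use
central differences with step 1e-6 at tolerances 1e-5 (convolution), 1e-6
(pooling) and 1e-4 relative (end-to-end). The pooling adjoint identity
holds to 1e-12. Ties, degenerate inputs and frozen-layer semantics are
as described above; training raises a diagnostic error on non-finite loss
rather than continuing silently.

## Known limitations

- Nearest-node sampling makes the filter response piecewise constant in
  the patch spacing; barycentric sampling inside the convolution is not
  implemented (only in mesh-to-mesh resampling).
- Rotations that are not symmetries of the node set incur nearest-node
  resampling error; histograms are preserved only for permutation-type
  rotations.
- The layer stack is sequential; strided/dilated mesh convolution,
  multi-level pooling jumps and attention are out of scope.
- Training is CPU NumPy; it is adequate for the mesh sizes here but not
  tuned for GPU-scale throughput.
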