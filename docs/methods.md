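# Methods

## Problem and model

The package classifies static hand gestures from 3D surface point
clouds.  The gesture vocabulary treats each of the five fingers as a
binary variable — extended or bent — so there are `2^5 = 32` classes;
class id `c` encodes the finger states bitwise with the thumb in the
least-significant bit (a repository convention; only the count 32 is
intrinsic).

A cloud of `N` points is treated as an undirected graph: nodes are
points, edges encode spatial proximity.  Three constructions are
implemented (`gsfan.graph`): k-nearest neighbors (directed lists,
distance ties broken by ascending point index), a strict distance
threshold (`dist < d_thresh`), and an inclusive radius neighborhood
(`dist <= r`).  The network uses the kNN graph with `k = 8` by default:
it guarantees a constant node degree on normalized clouds, whereas a
fixed metric threshold is brittle against the cloud-scale normalization.
The "local density" statistic `rho(p_i)` — the mean distance from a
point to its k nearest neighbors — is exposed as a diagnostic and as an
optional adaptive per-point radius; note that despite its conventional
name, larger values mean a locally *sparser* cloud.

The classifier (`GSFANClassifier`) is, per cloud:

1. **Normalization** — centroid to the origin, maximum point norm 1.
2. **Edge convolution** (default 3 layers, 64 channels each):
   `h_i = LeakyReLU( W · mean_{j in N(i) ∪ {i}} x_j )`.
   The aggregation is the plain neighborhood mean with an explicit
   self-loop (normalizer `|N(i)| + 1`).  This is deliberately *not* the
   DGCNN edge function built from `(x_i, x_j − x_i)` pairs with max
   aggregation: the model family implemented here is defined by the
   mean-with-self-loop update, and the receptive-field analysis
   (`receptive_field`) and over-smoothing behavior refer to that
   operator.  A `dynamic_graph` flag rebuilds the kNN graph from each
   layer's output features instead of reusing the spatial graph; the
   spatial graph is the default because neighborhoods are defined as
   distances between 3D points.
3. **Dimension abstraction** (`gsfan.abstraction`): shared-weight MLP
   stages lift per-point features to the target embedding dimension
   (default 128).  Stage widths are `[64, target]` — one shared hidden
   stage and a projection; a deeper doubling chain adds cost roughly
   quadratic in the target with no observed benefit at these problem
   sizes.  By default the ladder input is the concatenation of all
   edge-conv layer outputs (`concat_layers=True`); the non-concatenated
   variant (last layer only) is available and measurably worse at every
   depth ≥ 2, because without the skip-like concatenation deeper stacks
   only smooth.
4. **Global max pooling** over points — the symmetric reduction that
   makes evaluation-mode outputs exactly invariant to point order
   (mean pooling available by flag).
5. **Gated nonlinear transform**
   `z̃ = V · ( σ(z) ⊙ tanh(W2 · z + β) ) + γ`,
   with `σ` = Leaky ReLU: the activated signal path is modulated
   elementwise by a tanh gate, then linearly mixed with a learned
   offset.  Because `tanh(0) = 0`, zero input with zero `β, γ` maps to
   zero, and outputs are bounded by `‖V‖ · max|σ(z)| + ‖γ‖` for bounded
   inputs.  The transform is applied **once to the pooled global
   descriptor** by default (`gate_location="global"`): the gate acts on
   a single cloud-level vector `z`, which is the reading this package
   adopts of an ambiguous design; a per-point placement before pooling
   is implemented (`gate_location="per_point"`) but costs ~4·d² flops
   per *point* and is prohibitive at large embedding dimensions.
6. **Dropout** (rate 0.5, training only, applied to the pooled/gated
   global feature) and a **linear 32-way head**.

## Training

Minibatch SGD with momentum: `v' = μ v − η g`, `p' = p + v'`, with
`η = 0.001`, `μ = 0.9`, batch size 32, cross-entropy loss, no early
stopping.  Weights use scaled-uniform fan-in initialization
(`U(±√(6/fan_in))`); biases, `β`, `γ` start at zero.  The default epoch
budget is 100; the benchmark sweeps use a reduced budget (below).  All
randomness — initialization, shuffling, dropout — flows from one seeded
`numpy` Generator, so training is bit-reproducible for a fixed seed.

The implementation is NumPy with hand-written backpropagation (verified
against central-difference numerical gradients for every parameter
tensor in the test suite), with small fused numba kernels for the
memory-bound elementwise steps.  Aggregation over a fixed graph is a
per-cloud dense row-stochastic matrix applied as a batched matmul.

## Synthetic hand generator

The generator (`gsfan.hand`) emulates depth-sensor recordings of a
hand:

* **Palm**: a rounded box (box Minkowski-summed with a sphere of radius
  half the palm thickness), default extents 9 × 8 × 2 cm.
* **Fingers**: capsule chains (3 phalanges; 2 for the thumb) attached
  at fixed palm sockets, lengths 5.5–8 cm, radii 7–10 mm.  A *bent*
  finger has every joint rotated by the flexion angle (default 100°)
  about its knuckle axis, curling the chain toward the palm.
* **Sampling**: area-uniform over the union of primitives (sum of
  closed-form capsule/rounded-box areas); self-occlusion is *not*
  modeled — a real sensor sees only the facing surface.
* **Sensor effects**: isotropic Gaussian noise (default sd 1 mm, a
  consumer-LiDAR scale) and a random rigid pose per cloud (rotations
  uniform within ±15° per axis, translations within ±5 cm), emulating
  unfixed sensor–hand geometry.
* **Subjects**: each subject perturbs every shape parameter uniformly
  within ±15%, emulating inter-individual morphology.

What passing tests on these data do **not** show: robustness to
occlusion, to segmentation artifacts, to sensor-specific noise
structure, or to continuous (non-binary) joint angles.  The generator
makes the 32 classes geometrically separable by construction; real
LiDAR recordings are harder in ways the generator does not represent.

Cleanup of non-hand returns is emulated by a statistical outlier filter
(`remove_outliers`, defaults k = 8, sd_mult = 2): a point is dropped
when its mean kNN distance exceeds the cloud mean by more than
`sd_mult` standard deviations.  This replaces an interactive
segmentation step so pipelines run unattended.

## The default benchmark and its scale

`gsfan.benchmark` fixes one evaluation condition shared by the ablation
sweeps, the acceptance script and the test suite: 32 classes × 4
subjects × 10 clouds = 1280 clouds, **64 points per cloud**, 1 mm
noise, default pose jitter; stratified 75/25 split; sweeps use **30
epochs** (≈900 SGD steps) and 3 seeds with paired splits across
settings.

These sizes are the package's desk-scale choice: training is pure
NumPy on a single CPU, and the sweep grid (5 depths + 7 dimensions,
3 seeds each) must complete in minutes.  Two consequences matter for
interpretation:

* At ~900 steps with the fixed learning rate 0.001 the models are far
  from converged (test accuracy ≈ 0.2–0.45 depending on setting).  The
  sweeps therefore compare settings in the *undertrained* regime, where
  outcomes are dominated by optimization speed and random-feature
  richness rather than by converged representational capacity.
* In that regime the depth sweep favors **1 layer** (shallow models fit
  fastest; additional mean-aggregation layers smooth features before
  training can exploit the larger receptive field), and the dimension
  sweep rises monotonically toward **2048** (wider random embeddings
  are linearly more separable).  Interior optima at 3 layers and 128
  dimensions — capacity/overfitting effects of converged models — are
  not recovered at this scale; reaching convergence for the full grid
  was measured to need more than an order of magnitude more compute
  than the intended desk budget.  The sweep machinery itself
  (`sweep_layers`, `sweep_dims`) is scale-free: given more epochs it
  runs the identical protocol.

A further caveat: with the literal mean-with-self-loop edge convolution
(step 2 above), depth adds context only through repeated smoothing of
absolute coordinates.  Architectures whose edge function sees relative
offsets `(x_j − x_i)` gain more from depth; if the original system
behaved that way, a depth optimum at 3 would be easier to reproduce
than it is for the operator implemented here.

## Evaluation protocols

`accuracy` and the 32×32 `confusion_matrix` (rows = true, columns =
predicted) satisfy the standard identities (row sums = class counts,
trace/total = accuracy), enforced in tests.  `per_subject_eval` trains
and tests within each subject's own clouds by default (subjects with
fewer than 32 clouds are skipped with a warning) and reports the
cross-subject mean; a leave-one-subject-out protocol is available via
`cross_subject=True`.  Sweeps reuse the same split for a given seed
across all settings, so setting contrasts are paired.

## Numerical choices and edge cases

* kNN ties: stable sort on distances = (distance, index) lexicographic
  order; a duplicated point is its twin's first neighbor.
* Threshold edges use strict `<`; radius neighborhoods inclusive `<=`.
* Degenerate cloud (all points coincident) normalizes to all zeros.
* Prediction ties break toward the lowest class id (argmax convention).
* `forward` rejects clouds with `N <= k`; `split_dataset` keeps classes
  with a single cloud entirely in train (with a warning).
* Training tensors are float32; the pure functional ops preserve the
  caller's dtype (the gradient checks run them in float64).

## Known limitations

* No occlusion or view-dependence in the generator.
* The per-point gated transform is exact but impractical above ~512
  embedding dimensions on CPU.
* The benchmark's undertrained regime (above) limits what the ablation
  sweeps can say about converged-model behavior.
* No real-sensor data path beyond ASCII XYZ/PLY ingestion; binary PLY,
  PCD and LAS are out of scope.
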