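# Methods

## Problem and scope

`movefuse` classifies segmented multi-axial human-movement signals —
e.g. boxing or taekwondo strikes recorded by wrist/ankle IMUs with a
3-axis accelerometer and 3-axis gyroscope at 100 Hz — into one of `H`
movement classes without any hand-engineered features.  A movement
instance `I` is recorded by `G` sensors; sensor `g` contributes `m_g`
uniaxial channels `s_gm`, for `M_G = Σ m_g` channels in total.  The
package implements four *input models* that differ in how much fusion
happens before classification, and seven classifiers built on them:

| input model | structure | DTW classifier | CNN classifier |
|---|---|---|---|
| VI  (vector)        | `M_G` raw vectors          | DTW-1 | CNN-1 |
| LMI (local matrix)  | `G` matrices `(m_g × n_g)` | DTW-2 | CNN-2 |
| GMI (global matrix) | one matrix `(M_G × N)`     | DTW-3 | CNN-3 |
| GCI (global cuboid) | one cuboid `(M × N × G)`   | —     | CNN-4 |

There is intentionally no cuboid DTW: the frame-wise local cost of a
cuboid equals the column-wise cost of the matrix obtained by stacking
its depth-frames, so cuboid alignment is exactly matrix alignment of the
stacked form (this identity is property-tested to 1e-9), and a cuboid
DTW classifier would coincide with DTW-3.

## Normalization

Matrix/cuboid models need equal channel durations.  Durations are
normalized by piecewise-linear expansion/compression to target lengths
learned from the training set: the rounded (half away from zero) mean
duration per sensor for LMI and globally for GMI/GCI.  The vector model
tolerates unequal durations at alignment time, but element-wise template
averaging and fixed-size CNN inputs do not; VI channels are therefore
also normalized, to their per-channel mean training lengths, when
templates or CNN-1 inputs are built.  Amplitude min-max normalization
(per channel, extrema pooled over the whole training set, applied
without clipping at test time) is available but off by default: the
simulated sensors are homogeneous, and with channel-wise pooled scaling
the choice did not matter for the homogeneous benchmarks.  A constant
training channel raises a degenerate-axis error rather than silently
producing NaNs.

## DTW alignment

The discrepancy between two sequences is `A_XY = (1/K) Σ_k d[w(k)]`
along an alignment path subject to endpoint, monotonicity, and
continuity constraints, with the classic symmetric step set
{(1,0),(0,1),(1,1)} and unit weights.  Local costs are Euclidean
(default), Manhattan, or squared-Euclidean distances between scalars,
matrix columns, or flattened cuboid frames; cost matrices come from
`scipy.spatial.distance.cdist` and the dynamic program is a
numba-compiled suffix recursion.

One genuine ambiguity: minimizing the *K-normalized* cost is not a
Markovian objective, while the standard dynamic program minimizes the
path *sum*.  `dtw_align` minimizes the sum, then normalizes by the K of
the reported path; among minimal-sum paths it reports the shortest, and
among those the lexicographically smallest, which makes the reported
(value, path) pair unique and deterministic.  The exhaustive oracle
`brute_force_align` applies the same two-stage rule by enumeration (this
is what the oracle-equivalence property checks), and also exposes
`objective="normalized"` so the divergence between the two objectives
can be quantified on small instances — the literal normalized optimum is
never larger, and in practice differs only on contrived near-tie
instances.

## DTW classifiers

Templates are element-wise central-tendency estimates over each class's
duration-normalized training instances.  The sample mean is the default
(as in nearest-template practice); median, α-trimmed mean, α-winsorized
mean, and trimean are exposed because a better location estimate does
not necessarily yield a better classification template, so no ordering
is asserted or assumed.  DTW-aware (warping-registered) averaging is out
of scope.

DTW-1 runs `M_G` independent vector alignments per class and averages
the per-channel discrepancies; DTW-2 runs `G` matrix alignments and
averages per sensor; DTW-3 runs a single global-matrix alignment.  All
three assign the least-discrepancy class, ties to the lowest label.

## CNN classifiers

No deep-learning backend is part of the dependency set; the layers are
implemented directly in numpy (im2col correlation, max pooling, dense
layers, softmax cross-entropy, Adam).  The "convolution" layers compute
correlation with no kernel flipping — the operation actually performed
in such layers.  All four models share one fixed architecture:
conv(32 filters) → conv(32) → max-pool → FC(sigmoid, 100) →
FC(softmax, H), with "same" zero-padding (p = (f−1)/2) and unit stride.
First/second-layer filter sizes are (1×3×1)/(1×3×32) for CNN-1 and
(3×3×D₀)/(3×3×32) for CNN-2/3/4, where D₀ = 1 for matrices and G for
the cuboid.  The layer-dimension chain H' = 1 + (H − f + 2p)/s (floored)
is asserted programmatically for all four models over random input
sizes.

Choices the architecture description leaves open, fixed here as
defaults: max pooling (1×2) stride 2 for CNN-1 and (2×2) stride 2
otherwise (clamped for very short feature maps), hidden width 100, Adam
with lr 1e-3, batch 32, up to 200 epochs with early stopping (patience
12) on a 10% validation split.  Training is float32 by default;
`TrainingConfig` overrides all of this.

The softmax output layer is initialized at **zero**: the initial
posterior is exactly uniform, and — because every other source of
randomness (init, shuffling, validation split) is label-independent —
the entire training trajectory is exactly equivariant under permutation
of class labels, which is property-tested.  Per-net seeds are spawned
from the master seed with `SeedSequence([seed, net_index])` and recorded
in each training log, so runs are bit-reproducible at a fixed thread
count.

Inference fuses the `M_G` (CNN-1) or `G` (CNN-2) per-net posteriors by
element-wise averaging (a convex combination of probability vectors, so
the fused vector still sums to 1) and applies the maximum-response rule,
ties to the lowest label.

## Synthetic strike simulator

Real IMU strike recordings are emulated, not replayed: each class
gets one smooth template per channel (sum of 3 Gaussian bumps, centers
in the middle 70% of the window, signed amplitudes 0.5–2, widths 4–12%
of the duration), and each trial corrupts its template with

- a strictly increasing piecewise-linear time map (8 knots, local slopes
  drawn from [1−λ_w, 1+λ_w], endpoints fixed) — segment
  expansion/compression;
- an integer latency shift uniform on ±τ samples, edge-padded (no
  wraparound);
- i.i.d. Gaussian amplitude noise σ;
- a jittered output duration (uniform ±10% of the 64-sample base).

`warp_sharing` draws one (time map, shift, duration) realization per
channel, per sensor, or per trial: exactly the synchronization
assumptions that separate VI from LMI from GMI/GCI, so the
assumption-violation regimes can be produced on demand.  Noise is always
per-channel.

Defaults are the benchmark conditions: H = 8 classes, 2 sensors × 3
axes, N₀ = 64 (a ~0.6 s strike at 100 Hz), 20 trials/class, λ_w = 0.25,
τ = 10, σ = 0.8.  σ was calibrated once, by scanning {0.4, 0.8, 1.2},
so that the best *uniaxial* DTW accuracy sits mid-way in the 50–80%
band (≈58%); the single-axis CNNs are notably stronger (best axis
≈85–89%) and no single σ places both families in that band
simultaneously.  What the simulator does **not** model: limb kinematics,
gravity/orientation coupling between axes, sensor-specific spectra, or
inter-subject technique differences — so passing benchmarks demonstrate
the fusion mechanics and the classifiers' tolerance of non-linear
variation, not field accuracy on real athletes.

## Evaluation protocol

Repeated stratified holdout: per repetition, ~80/20 train/test split
stratified per class (plain random splits can empty a class at desk
scale), fit everything on the training fold only (duration targets,
min-max extrema, templates, CNNs), score the test fold, average over
repetitions; confusion matrices accumulate over repetitions.  The
uniaxial baseline evaluates one single-channel classifier per
(sensor, axis) under the same master seed, hence the same splits, and
flags the best axis.  The random-classification baseline is 100/H
reported to one decimal (5.6% at H = 18).  Reports serialize to
canonical JSON and are byte-identical for a fixed master seed.

## Problem sizes used by tests and the acceptance script

The repository's own benchmark runs are desk-scale by design:
perfect-recovery uses H = 6, 20 trials/class, 48-sample durations, 5
repetitions (3 in the script); the corrupted fusion benchmark uses
H = 8, 15 trials/class, 10 repetitions (5 in the script); null
calibration uses H = 18, 6 trials/class.  CNN runs in these benchmarks
cap training at 60 epochs with patience 8 — accuracy on these problems
saturates well before that.  The full 100-repetition protocol is
available through `repeated_holdout(reps=100)` or the CLI.

## Known limitations

- The sum-then-normalize DTW objective (above) is a documented choice,
  not the only reading of the normalized-cost formulation.
- Plain element-wise template averaging assumes duration-normalized,
  roughly aligned trials; under extreme warp it blurs templates, which
  degrades all DTW models; the CNNs, whose local features are largely
  shift-invariant, are visibly more tolerant.
- The energy-based segmenter is a minimal stand-in (rectangular window,
  global-peak-relative threshold): the classifiers consume pre-segmented
  strikes, so segmentation exactness is not load-bearing here.
- Accuracies on the synthetic benchmark are not comparable in level to
  accuracies on real strike data; only the qualitative orderings
  (fusion > uniaxial, CNN ≥ DTW under non-linear variation) transfer.
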