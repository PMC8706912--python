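# movefuse

Fusion classifiers for multi-axial wearable-sensor movement signals.

Wearable inertial sensors (IMUs) record a movement — a boxing punch, a
taekwondo kick, a rehabilitation exercise — as an ensemble of uniaxial
time series: `G` sensors, each with `m_g` channels (e.g. 2 IMUs × 3
accelerometer/gyroscope axes = 6 channels at 100 Hz).  Trials of the
same movement differ by *non-linear variations*: latency shifts of the
peaks and expansion/compression of signal segments, on top of amplitude
noise and unequal durations.  `movefuse` classifies such segmented
movements feature-blind, fusing the channels at the input level, the
output level, or both.

## Models

A movement with label `ω_h ∈ {ω_1..ω_H}` is rendered in one of four
**input models**: the raw channel vectors (VI), one `(m_g × n_g)` matrix
per sensor (LMI), one global `(M_G × N)` matrix (GMI), or one
`(M × N × G)` cuboid (GCI, requiring equal axis counts).  Seven
classifiers are built on them:

- **DTW-1/2/3** — nearest-template dynamic time warping.  The
  discrepancy between sequences is `A_XY = (1/K) Σ_k d[w(k)]`, the
  path-length-normalized cost of the optimal monotone alignment; local
  costs compare scalars (vectors), columns (matrices), or depth-frames
  (cuboids).  Templates are per-class central-tendency estimates (mean,
  median, trimmed/winsorized mean, trimean) over the training set.
  DTW-1 averages `M_G` per-channel discrepancies, DTW-2 averages `G`
  per-sensor matrix discrepancies, DTW-3 aligns the global matrix
  directly; all pick `ω* = argmin_h D_ωh`.  Cuboid DTW is deliberately
  absent: stacking the cuboid's frames reproduces it exactly as matrix
  DTW (DTW-3).
- **CNN-1..4** — a fixed conv(32)–conv(32)–maxpool–FC(sigmoid,100)–
  FC(softmax,H) network per channel (CNN-1), per sensor (CNN-2), or
  globally on the matrix/cuboid (CNN-3/4), implemented directly in
  numpy (correlation layers, Adam, cross-entropy).  Per-net posteriors
  `p(h) = e^{q_h}/Σ e^{q_j}` are fused by averaging and decided by
  `ω* = argmax_h P_ωh`.

A synthetic strike simulator (class templates of Gaussian bumps,
monotone piecewise-linear time warps, latency shifts, noise, duration
jitter, with per-channel/per-sensor/global warp sharing) and a repeated
stratified-holdout evaluation protocol complete the pipeline.  See
`docs/methods.md` for the full model description and all defaults.

## Worked example

```sh
$ movefuse simulate --out strikes --seed 7
wrote 160 recordings to strikes

$ movefuse train --model dtw3 --data strikes --out dtw3.npz
trained dtw3 on 160 recordings -> dtw3.npz

$ movefuse classify --model-file dtw3.npz --data strikes/rec_00000.csv
recording 0: class 1 scores [1.80438 3.6026 3.24888 3.05402 2.29216 2.97106 2.70191 2.38329]

$ movefuse evaluate --classifier dtw3 --data strikes --out report.json --reps 10 --seed 0
dtw3: mean accuracy 99.06% over 10 repetitions (report: report.json)
```

`simulate` generates the default benchmark ensemble: 8 movement
classes × 20 trials from 2 sensors × 3 axes, corrupted by ±25% segment
warps, ±10-sample latency shifts, and σ = 0.8 amplitude noise.
`classify` prints the fused per-class discrepancy vector — recording 0
is assigned class 1 because its score (1.80) is the smallest; note the
score is well below every other class despite the recording being a
warped, noisy instance, which is exactly what the alignment is for.
`evaluate` runs 10 stratified 80/20 holdout repetitions: the global-
matrix DTW classifier averages 99.06% on this ensemble, whereas the best
*single-axis* DTW classifier reaches only ~58% and random guessing 12.5%
— the gap is the value of fusing axes.  The same commands accept
`cnn1..cnn4` and `dtw1/dtw2`.

In Python:

```python
from movefuse import (SyntheticConfig, generate_dataset, ClassifierSpec,
                      repeated_holdout)
data = generate_dataset(SyntheticConfig(seed=7))
report = repeated_holdout(data, ClassifierSpec("dtw3"), reps=10)
print(report.mean_accuracy)        # 99.06
```

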