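"""The four CNN fusion classifiers, on a compact numpy CNN engine.

Every model shares one fixed architecture: two "same" correlation layers
(32 filters each, ReLU), one max-pooling layer, a sigmoid hidden
fully-connected layer, and a softmax output layer of width ``H`` trained
with cross-entropy.  The models differ only in what each network sees and
in the output-level fusion:

- CNN-1 (vector input):       one net per channel, ``(1 x 3)`` filters;
  the ``M_G`` posterior vectors are averaged (decision-level fusion).
- CNN-2 (local matrix input): one net per sensor, ``(3 x 3)`` filters;
  the ``G`` posteriors are averaged.
- CNN-3 (global matrix input): a single net on the ``(M_G x N)`` matrix.
- CNN-4 (global cuboid input): a single net whose first-layer filters
  span the full sensor depth ``(3 x 3 x G)``.

The engine computes correlation (no kernel flipping), the operation
actually performed in "convolution" layers.  The output layer is
initialized at zero, which makes the initial posterior uniform and makes
training exactly equivariant under class-label permutation; hidden
weights are He/Glorot draws from a per-net seeded generator, so training
is bit-reproducible for a fixed seed and thread count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .signal_model import (
    MODEL_TAGS,
    MovementRecording,
    NormalizationSpec,
    build_input,
)

__all__ = [
    "CNN_TAGS",
    "conv_output_dims",
    "pool_output_dims",
    "CnnArchitecture",
    "build_architecture",
    "TrainingConfig",
    "TrainedCnn",
    "CnnEnsemble",
    "forward_posteriors",
    "fuse_posteriors",
    "decide",
    "train_model",
    "cnn_classify",
]

CNN_TAGS = ("CNN1", "CNN2", "CNN3", "CNN4")
_INPUT_MODEL = {"CNN1": "VI", "CNN2": "LMI", "CNN3": "GMI", "CNN4": "GCI"}


# ---------------------------------------------------------------------------
# Dimension algebra
# ---------------------------------------------------------------------------

def conv_output_dims(
    in_dims: tuple[int, int, int],
    filter_dims: tuple[int, int, int],
    n_filters: int,
    p: int = 0,
    sc: int = 1,
) -> tuple[int, int, int]:
    """Output dims of a convolution layer:
    ``H' = 1 + (H - fh + 2p)/sc`` (floored), ``W'`` analogous, depth = the
    number of filters."""
    h0, w0, d0 = in_dims
    fh, fw, fd = filter_dims
    if fd != d0:
        raise ValueError(f"filter depth {fd} != input depth {d0}")
    if fh > h0 + 2 * p or fw > w0 + 2 * p:
        raise ValueError("filter larger than padded input")
    if sc < 1:
        raise ValueError("stride must be >= 1")
    return (1 + (h0 - fh + 2 * p) // sc, 1 + (w0 - fw + 2 * p) // sc, n_filters)


def pool_output_dims(
    in_dims: tuple[int, int, int], pool_dims: tuple[int, int], sp: int
) -> tuple[int, int, int]:
    """Output dims of pooling: ``H' = 1 + (H - fh_p)/sp`` (floored); depth
    is preserved."""
    h, w, d = in_dims
    ph, pw = pool_dims
    if ph > h or pw > w:
        raise ValueError("pooling window larger than input")
    return (1 + (h - ph) // sp, 1 + (w - pw) // sp, d)


@dataclass(frozen=True)
class CnnArchitecture:
    """conv -> conv -> max-pool -> FC(sigmoid) -> FC(softmax)."""

    model_tag: str
    input_shape: tuple[int, int, int]     # (H0, W0, D0)
    n_classes: int
    k1: int = 32
    k2: int = 32
    filter1: tuple[int, int, int] = (3, 3, 1)
    filter2: tuple[int, int, int] = (3, 3, 32)
    pool: tuple[int, int] = (2, 2)
    pool_stride: int = 2
    fc_width: int = 100
    conv_stride: int = 1                  # "same" convolutions

    def same_padding(self, filter_dims: tuple[int, int, int]) -> tuple[int, int]:
        # p = (f - 1) / 2 per axis for odd filters keeps dims unchanged
        return ((filter_dims[0] - 1) // 2, (filter_dims[1] - 1) // 2)

    def dims_chain(self) -> list[tuple[int, ...]]:
        """Layer-by-layer output dims, following the convolution and
        pooling dimension relations (same padding, unit conv stride)."""
        p1 = self.same_padding(self.filter1)
        c1 = conv_output_dims(self.input_shape, self.filter1, self.k1,
                              p=p1[0], sc=self.conv_stride)
        # width padding may differ from height padding (e.g. 1x3 filters)
        c1 = (c1[0],
              1 + (self.input_shape[1] - self.filter1[1] + 2 * p1[1]) // self.conv_stride,
              self.k1)
        p2 = self.same_padding(self.filter2)
        c2 = (1 + (c1[0] - self.filter2[0] + 2 * p2[0]) // self.conv_stride,
              1 + (c1[1] - self.filter2[1] + 2 * p2[1]) // self.conv_stride,
              self.k2)
        pl = pool_output_dims(c2, self.pool, self.pool_stride)
        flat = pl[0] * pl[1] * pl[2]
        return [self.input_shape, c1, c2, pl, (flat,), (self.fc_width,),
                (self.n_classes,)]


def build_architecture(
    model_tag: str,
    input_shape: tuple[int, int, int],
    n_classes: int,
    k1: int = 32,
    k2: int = 32,
    fc_width: int = 100,
) -> CnnArchitecture:
    """Instantiate the fixed reference architecture for one input model.

    First/second-layer filter dims: ``(1x3x1)/(1x3xK1)`` for CNN-1 and
    ``(3x3xD0)/(3x3xK1)`` for CNN-2/3/4 (depth ``D0`` is 1 for matrices
    and ``G`` for the cuboid).  Pooling is ``(1x2)`` stride 2 for CNN-1
    and ``(2x2)`` stride 2 otherwise, clamped to the feature-map size for
    very short inputs.
    """
    if model_tag not in CNN_TAGS:
        raise ValueError(f"unknown CNN tag {model_tag!r}")
    h0, w0, d0 = input_shape
    if model_tag == "CNN1":
        if h0 != 1 or d0 != 1:
            raise ValueError("CNN1 expects a (1, n, 1) vector input")
        f1, pool = (1, 3, 1), (1, 2)
    elif model_tag == "CNN4":
        if d0 < 1:
            raise ValueError("cuboid input needs depth >= 1")
        f1, pool = (3, 3, d0), (2, 2)
    else:
        if d0 != 1:
            raise ValueError(f"{model_tag} expects a single-depth matrix input")
        f1, pool = (3, 3, 1), (2, 2)
    pool = (min(pool[0], h0), min(pool[1], w0))
    return CnnArchitecture(
        model_tag=model_tag,
        input_shape=input_shape,
        n_classes=n_classes,
        k1=k1,
        k2=k2,
        filter1=f1,
        filter2=(f1[0], f1[1], k1),
        pool=pool,
        pool_stride=2,
        fc_width=fc_width,
    )


# ---------------------------------------------------------------------------
# Layers (forward/backward)
# ---------------------------------------------------------------------------

def _conv_forward(x, w, b, pad):
    B, H, W, D = x.shape
    fh, fw, _, k = w.shape
    ph, pw = pad
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    cols = np.empty((B, H, W, fh * fw * D), dtype=x.dtype)
    i = 0
    for u in range(fh):
        for v in range(fw):
            cols[..., i * D:(i + 1) * D] = xp[:, u:u + H, v:v + W, :]
            i += 1
    out = cols.reshape(-1, fh * fw * D) @ w.reshape(-1, k)
    return out.reshape(B, H, W, k) + b, cols


def _conv_backward(dout, cols, w, x_shape, pad):
    B, H, W, D = x_shape
    fh, fw, _, k = w.shape
    ph, pw = pad
    flat_cols = cols.reshape(-1, fh * fw * D)
    flat_dout = dout.reshape(-1, k)
    dw = (flat_cols.T @ flat_dout).reshape(w.shape)
    db = dout.sum(axis=(0, 1, 2))
    dcols = (flat_dout @ w.reshape(-1, k).T).reshape(B, H, W, fh * fw * D)
    dxp = np.zeros((B, H + 2 * ph, W + 2 * pw, D), dtype=dout.dtype)
    i = 0
    for u in range(fh):
        for v in range(fw):
            dxp[:, u:u + H, v:v + W, :] += dcols[..., i * D:(i + 1) * D]
            i += 1
    return dxp[:, ph:ph + H, pw:pw + W, :], dw, db


def _pool_forward(x, pool, stride):
    B, H, W, D = x.shape
    ph, pw = pool
    Ho = 1 + (H - ph) // stride
    Wo = 1 + (W - pw) // stride
    stacked = np.stack([
        x[:, u:u + (Ho - 1) * stride + 1:stride,
          v:v + (Wo - 1) * stride + 1:stride, :]
        for u in range(ph) for v in range(pw)
    ])
    arg = stacked.argmax(axis=0)
    out = np.take_along_axis(stacked, arg[None], axis=0)[0]
    return out, arg


def _pool_backward(dout, arg, x_shape, pool, stride):
    B, H, W, D = x_shape
    ph, pw = pool
    Ho, Wo = dout.shape[1], dout.shape[2]
    dx = np.zeros(x_shape, dtype=dout.dtype)
    idx = 0
    for u in range(ph):
        for v in range(pw):
            view = dx[:, u:u + (Ho - 1) * stride + 1:stride,
                      v:v + (Wo - 1) * stride + 1:stride, :]
            view += dout * (arg == idx)
            idx += 1
    return dx


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _init_params(arch: CnnArchitecture, rng: np.random.Generator, dtype) -> dict:
    f1h, f1w, f1d = arch.filter1
    f2h, f2w, f2d = arch.filter2
    flat = arch.dims_chain()[4][0]
    def he(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)
    return {
        "w1": he((f1h, f1w, f1d, arch.k1), f1h * f1w * f1d),
        "b1": np.zeros(arch.k1, dtype=dtype),
        "w2": he((f2h, f2w, f2d, arch.k2), f2h * f2w * f2d),
        "b2": np.zeros(arch.k2, dtype=dtype),
        "w3": he((flat, arch.fc_width), flat),
        "b3": np.zeros(arch.fc_width, dtype=dtype),
        # zero output layer: uniform initial posterior, exact label-permutation
        # equivariance of the whole training trajectory
        "w4": np.zeros((arch.fc_width, arch.n_classes), dtype=dtype),
        "b4": np.zeros(arch.n_classes, dtype=dtype),
    }


def _forward(params, arch: CnnArchitecture, x, need_cache=False):
    p1 = arch.same_padding(arch.filter1)
    p2 = arch.same_padding(arch.filter2)
    z1, cols1 = _conv_forward(x, params["w1"], params["b1"], p1)
    a1 = np.maximum(z1, 0.0)
    z2, cols2 = _conv_forward(a1, params["w2"], params["b2"], p2)
    a2 = np.maximum(z2, 0.0)
    pooled, arg = _pool_forward(a2, arch.pool, arch.pool_stride)
    flat = pooled.reshape(x.shape[0], -1)
    z3 = flat @ params["w3"] + params["b3"]
    a3 = expit(z3)
    logits = a3 @ params["w4"] + params["b4"]
    probs = _softmax(logits)
    if not need_cache:
        return probs, None
    return probs, (x, cols1, z1, a1, cols2, z2, a2, arg, pooled, flat, a3)


def _backward(params, arch: CnnArchitecture, cache, probs, y_onehot):
    x, cols1, z1, a1, cols2, z2, a2, arg, pooled, flat, a3 = cache
    B = x.shape[0]
    p1 = arch.same_padding(arch.filter1)
    p2 = arch.same_padding(arch.filter2)
    dlogits = (probs - y_onehot) / B
    g = {}
    g["w4"] = a3.T @ dlogits
    g["b4"] = dlogits.sum(axis=0)
    da3 = dlogits @ params["w4"].T
    dz3 = da3 * a3 * (1.0 - a3)
    g["w3"] = flat.T @ dz3
    g["b3"] = dz3.sum(axis=0)
    dflat = dz3 @ params["w3"].T
    dpooled = dflat.reshape(pooled.shape)
    da2 = _pool_backward(dpooled, arg, a2.shape, arch.pool, arch.pool_stride)
    dz2 = da2 * (z2 > 0)
    da1, g["w2"], g["b2"] = _conv_backward(dz2, cols2, params["w2"], a1.shape, p2)
    dz1 = da1 * (z1 > 0)
    _, g["w1"], g["b1"] = _conv_backward(dz1, cols1, params["w1"], x.shape, p1)
    return g


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Optimizer and schedule settings: standard desk-scale defaults, all
    overridable."""

    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 12
    min_delta: float = 1e-4
    val_frac: float = 0.1
    dtype: str = "float32"


@dataclass
class TrainedCnn:
    architecture: CnnArchitecture
    params: dict
    labels: list[int]                 # sorted class labels; softmax column order
    log: dict = field(default_factory=dict)  # loss per epoch, seed


@dataclass
class CnnEnsemble:
    """The trained networks of one fusion model: M_G nets for CNN-1, G for
    CNN-2, one for CNN-3/4."""

    model_tag: str
    nets: list[TrainedCnn]
    labels: list[int]
    seed: int


def _cross_entropy(probs, y_onehot):
    eps = 1e-12
    return float(-(y_onehot * np.log(probs + eps)).sum(axis=1).mean())


def _train_single(X, y_idx, arch, cfg: TrainingConfig, seed) -> TrainedCnn:
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    dtype = np.dtype(cfg.dtype)
    X = X.astype(dtype)
    n = X.shape[0]
    H = arch.n_classes
    Y = np.zeros((n, H), dtype=dtype)
    Y[np.arange(n), y_idx] = 1.0

    params = _init_params(arch, rng, dtype)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    b1m = b2m = 1.0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    perm = rng.permutation(n)
    n_val = int(round(cfg.val_frac * n))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        tr_idx, val_idx = perm, perm[:0]

    best_loss = np.inf
    best_params = {k: p.copy() for k, p in params.items()}
    best_epoch = 0
    losses = []
    for epoch in range(cfg.max_epochs):
        order = tr_idx[rng.permutation(tr_idx.size)]
        for s in range(0, order.size, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            probs, cache = _forward(params, arch, X[idx], need_cache=True)
            grads = _backward(params, arch, cache, probs, Y[idx])
            b1m *= beta1
            b2m *= beta2
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                params[k] -= (cfg.lr * (m[k] / (1 - b1m))
                              / (np.sqrt(v[k] / (1 - b2m)) + eps)).astype(dtype)
        monitor_idx = val_idx if val_idx.size else tr_idx
        probs, _ = _forward(params, arch, X[monitor_idx])
        loss = _cross_entropy(probs, Y[monitor_idx])
        losses.append(loss)
        if loss < best_loss - cfg.min_delta:
            best_loss = loss
            best_params = {k: p.copy() for k, p in params.items()}
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    return TrainedCnn(arch, best_params, [], {"loss": losses, "seed": seed,
                                              "best_epoch": best_epoch})


def _unit_inputs(rec: MovementRecording, model_tag: str, spec: NormalizationSpec):
    """Per-network input arrays, as (H, W, D) generalized cuboids."""
    in_model = _INPUT_MODEL[model_tag]
    fused = build_input(rec, in_model, spec, normalize_vi_durations=True)
    if model_tag == "CNN1":
        return [v[None, :, None] for v in fused.payload]
    if model_tag == "CNN2":
        return [m[:, :, None] for m in fused.payload]
    if model_tag == "CNN3":
        return [fused.payload[:, :, None]]
    return [fused.payload]


def train_model(
    train: Sequence[MovementRecording],
    model_tag: str,
    spec: NormalizationSpec,
    hyper: TrainingConfig | None = None,
    seed: int = 0,
) -> CnnEnsemble:
    """Train one fusion CNN model on labelled recordings.

    One network per channel (CNN-1), per sensor (CNN-2), or one global
    network (CNN-3/4); per-net seeds are spawned from the master seed so
    every net starts from different but reproducible weights.
    """
    hyper = hyper or TrainingConfig()
    labels = sorted({rec.label for rec in train if rec.label is not None})
    if len(labels) < 2:
        raise ValueError("training needs >= 2 classes")
    if any(rec.label is None for rec in train):
        raise ValueError("training recordings must be labelled")
    label_pos = {lb: i for i, lb in enumerate(labels)}
    y_idx = np.array([label_pos[rec.label] for rec in train])

    per_unit = [_unit_inputs(rec, model_tag, spec) for rec in train]
    n_units = len(per_unit[0])
    nets = []
    for u in range(n_units):
        X = np.stack([pu[u] for pu in per_unit])
        arch = build_architecture(model_tag, X.shape[1:], len(labels))
        net_seed = int(np.random.SeedSequence([seed, u]).generate_state(1)[0] % (2 ** 31))
        net = _train_single(X, y_idx, arch, hyper, net_seed)
        net.labels = labels
        nets.append(net)
    return CnnEnsemble(model_tag, nets, labels, seed)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def forward_posteriors(net: TrainedCnn, x: np.ndarray) -> np.ndarray:
    """Posterior class-probability vector for one (H, W, D) input."""
    if x.shape != net.architecture.input_shape:
        raise ValueError(
            f"input shape {x.shape} != architecture {net.architecture.input_shape}"
        )
    dtype = next(iter(net.params.values())).dtype
    probs, _ = _forward(net.params, net.architecture, x[None].astype(dtype))
    p = probs[0].astype(float)
    return p / p.sum()


def fuse_posteriors(per_unit: Sequence[np.ndarray], model_tag: str | None = None) -> np.ndarray:
    """Element-wise arithmetic mean of per-unit posterior vectors (pass-
    through for a single vector); the fused vector still sums to 1."""
    arr = np.asarray(per_unit, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a list of equal-length posterior vectors")
    return arr.mean(axis=0)


def decide(p: np.ndarray, labels: Sequence[int] | None = None) -> int:
    """Maximum-response rule: argmax posterior; ties -> lowest class."""
    i = int(np.argmax(p))
    return labels[i] if labels is not None else i + 1


def cnn_classify(
    rec: MovementRecording, ensemble: CnnEnsemble, spec: NormalizationSpec
) -> tuple[int, np.ndarray]:
    """Classify a recording: per-net posteriors, average fusion, argmax."""
    xs = _unit_inputs(rec, ensemble.model_tag, spec)
    posteriors = [forward_posteriors(net, x) for net, x in zip(ensemble.nets, xs)]
    fused = fuse_posteriors(posteriors, ensemble.model_tag)
    return decide(fused, ensemble.labels), fused
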